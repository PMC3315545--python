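"""Per-subject inflammation profiles.

For every subject the pipeline takes the paired PP - PN log2 difference per
probe, and for every cell-population signature counts the signature probes
elevated (up) vs decreased (down) in lesional skin. The ratio
R = n_up / n_down summarizes the inferred infiltrate shift; its
significance is called by two criteria that must both hold:

1. a one-sided Fisher exact test of up-enrichment within the signature
   against the rest of the array, Holm-adjusted across all populations;
2. the same test recomputed after removing any probes belonging to the
   signatures of populations with a larger ratio for that subject.

A Wald 95% interval accompanies the proportion of signature probes
PP-elevated, matching the intervals drawn around per-subject proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SignatureSet

Z_95 = 1.96  # fixed normal quantile for the 95% Wald interval


def paired_differences(cohort: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe PP - PN log2 difference, one column per subject.

    Every subject must contribute exactly one PP and one PN sample; ties
    (difference exactly 0) are preserved as zeros and excluded from
    up/down counts downstream.
    """
    meta = cohort.metadata
    diffs = {}
    for subject, sub in meta.groupby("subject", sort=False):
        pp = sub.index[sub["condition"] == "PP"]
        pn = sub.index[sub["condition"] == "PN"]
        if len(pp) != 1 or len(pn) != 1:
            raise ValueError(
                f"subject {subject!r} is not a PP/PN pair "
                f"({len(pp)} PP, {len(pn)} PN samples)"
            )
        diffs[subject] = cohort.values[pp[0]] - cohort.values[pn[0]]
    return pd.DataFrame(diffs, index=cohort.probes)


def adjust_covariates(
    expr: ExpressionMatrix, covariates: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Remove additive sex and batch effects per probe, keeping the grand mean.

    Fits, per probe, ordinary least squares on intercept + sex + batch
    dummies and returns residuals plus the probe's grand mean. A batch
    with a single sample is dropped from the model (identifiability) with
    a warning.
    """
    cov = covariates if covariates is not None else expr.metadata
    cov = cov.loc[expr.values.columns]
    parts = [pd.Series(1.0, index=cov.index, name="intercept")]
    for col in ("sex", "batch"):
        if col not in cov.columns:
            continue
        counts = cov[col].value_counts()
        if col == "batch" and (counts < 2).any():
            warnings.warn(
                f"batch level(s) {counts[counts < 2].index.tolist()} have a "
                "single sample; batch term dropped",
                stacklevel=2,
            )
            continue
        if counts.size > 1:
            parts.append(pd.get_dummies(cov[col], prefix=col, drop_first=True)
                         .astype(float))
    X = pd.concat(parts, axis=1).to_numpy(float)
    Y = expr.values.to_numpy(float)  # probes x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    grand = Y.mean(axis=1, keepdims=True)
    adjusted = Y - fitted + grand
    out = pd.DataFrame(adjusted, index=expr.values.index,
                       columns=expr.values.columns)
    return ExpressionMatrix(out, expr.metadata)


@dataclass
class ProfileScore:
    """Ratio statistic and significance calls for one subject x signature."""

    subject: str
    signature: str
    n_up: int
    n_down: int
    ratio_R: float
    log2_ratio: float
    p_raw: float
    prop_up: float
    ci_low: float
    ci_high: float
    p_holm: float = np.nan
    filtered_p: float = np.nan
    significant: bool | None = None
    reason: str = ""


def _haldane_ratio(n_up: int, n_down: int) -> float:
    """n_up/n_down, with +0.5 on both counts only when one of them is 0."""
    if n_up == 0 or n_down == 0:
        return (n_up + 0.5) / (n_down + 0.5)
    return n_up / n_down


def fisher_up_enrichment(
    n_up: int, n_down: int, bg_up: int, bg_down: int,
    alternative: str = "greater",
) -> float:
    """Fisher exact p for the 2x2 table {signature, background} x {up, down}."""
    table = [[n_up, n_down], [bg_up, bg_down]]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def proportion_ci(prop_up: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wald interval prop +/- z*sqrt(p(1-p)/n), clipped to [0, 1].

    z is fixed at 1.96 for conf=0.95; other confidence levels use the
    exact normal quantile.
    """
    if not 0.0 <= prop_up <= 1.0:
        raise ValueError("prop_up must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = Z_95 if conf == 0.95 else float(stats.norm.ppf(0.5 + conf / 2.0))
    half = z * np.sqrt(prop_up * (1.0 - prop_up) / n)
    return (max(0.0, prop_up - half), min(1.0, prop_up + half))


def _counts_for(diff: pd.Series, probes) -> tuple[int, int]:
    vals = diff.loc[probes]
    return int((vals > 0).sum()), int((vals < 0).sum())


def score_signature(
    profile: pd.Series,
    signature: SignatureSet,
    universe: pd.Index | None = None,
    alternative: str = "greater",
) -> ProfileScore:
    """Score one subject's difference profile against one signature.

    ``profile`` is the per-probe PP - PN difference for one subject (its
    ``name`` is taken as the subject label). Background for the Fisher
    table is every probe of the universe outside the signature; ties are
    excluded on both sides.
    """
    if universe is None:
        universe = profile.index
    sig_probes = pd.Index(signature.probes).intersection(universe)
    if len(sig_probes) == 0:
        raise ValueError(
            f"signature {signature.label!r} shares no probes with the universe"
        )
    bg_probes = pd.Index(universe).difference(sig_probes)
    n_up, n_down = _counts_for(profile, sig_probes)
    bg_up, bg_down = _counts_for(profile, bg_probes)
    p_raw = fisher_up_enrichment(n_up, n_down, bg_up, bg_down, alternative)
    n_eff = n_up + n_down
    prop_up = n_up / n_eff if n_eff else np.nan
    if n_eff:
        lo, hi = proportion_ci(prop_up, n_eff)
    else:
        lo = hi = np.nan
    ratio = _haldane_ratio(n_up, n_down)
    return ProfileScore(
        subject=str(profile.name),
        signature=signature.label,
        n_up=n_up,
        n_down=n_down,
        ratio_R=ratio,
        log2_ratio=float(np.log2(ratio)),
        p_raw=p_raw,
        prop_up=prop_up,
        ci_low=lo,
        ci_high=hi,
    )


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def dual_significance(
    scores: list[ProfileScore],
    signatures: dict[str, SignatureSet],
    profile: pd.Series,
    universe: pd.Index | None = None,
    alpha: float = 0.05,
    adjust_criterion2: bool = True,
) -> list[ProfileScore]:
    """Apply the dual significance criteria to one subject's scores.

    Criterion 1: Holm-adjusted one-sided Fisher p < alpha across all
    populations. Criterion 2: populations ranked by this subject's ratio
    (descending); each signature is re-tested after removing probes that
    belong to any higher-ranked population's signature, with the filtered
    p-values Holm-adjusted within the same family by default. The final
    flag requires both.
    """
    if universe is None:
        universe = profile.index
    labels = [s.signature for s in scores]
    missing = set(labels) - set(signatures)
    if missing:
        raise ValueError(f"signatures missing for: {sorted(missing)}")

    p_holm = holm_adjust([s.p_raw for s in scores])
    for s, ph in zip(scores, p_holm):
        s.p_holm = float(ph)

    # criterion 2: per-subject rank by ratio, descending; ties by label
    order = sorted(scores, key=lambda s: (-s.ratio_R, s.signature))
    seen: set = set()
    filtered_p: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for s in order:
        sig = signatures[s.signature]
        remaining = [p for p in sig.probes if p not in seen]
        if not remaining:
            filtered_p[s.signature] = 1.0
            reasons[s.signature] = "criterion-2 subset empty after filtering"
        else:
            rem_idx = pd.Index(remaining).intersection(universe)
            bg = pd.Index(universe).difference(rem_idx)
            n_up, n_down = _counts_for(profile, rem_idx)
            bg_up, bg_down = _counts_for(profile, bg)
            filtered_p[s.signature] = fisher_up_enrichment(
                n_up, n_down, bg_up, bg_down
            )
        seen.update(sig.probes)

    fp = np.array([filtered_p[s.signature] for s in scores])
    fp_adj = holm_adjust(fp) if adjust_criterion2 else fp
    for s, p2_raw, p2 in zip(scores, fp, fp_adj):
        s.filtered_p = float(p2_raw)
        c1 = s.p_holm < alpha
        c2 = p2 < alpha and s.signature not in reasons
        s.significant = bool(c1 and c2)
        s.reason = reasons.get(s.signature, "")
    return scores


@dataclass
class CategorySummary:
    """Representative-population bookkeeping for one cell-type category."""

    category: str
    member_populations: list
    per_population_mean_ratio: dict = field(default_factory=dict)
    grand_mean: float = np.nan
    representative: str = ""


def select_representative(
    category: str, mean_ratios: dict[str, float]
) -> CategorySummary:
    """Pick the population that displays a category of related populations.

    R* is the grand mean of the member populations' mean ratios; the
    representative is the max-ratio member when R* > 1, else the
    min-ratio member. Ties break lexicographically.
    """
    if not mean_ratios:
        raise ValueError("category has no member populations")
    members = sorted(mean_ratios)
    r_star = float(np.mean([mean_ratios[m] for m in members]))
    if r_star > 1.0:
        rep = max(members, key=lambda m: (mean_ratios[m], ))
        rep = min(m for m in members if mean_ratios[m] == mean_ratios[rep])
    else:
        rep = min(members, key=lambda m: (mean_ratios[m], ))
        rep = min(m for m in members if mean_ratios[m] == mean_ratios[rep])
    return CategorySummary(
        category=category,
        member_populations=members,
        per_population_mean_ratio=dict(mean_ratios),
        grand_mean=r_star,
        representative=rep,
    )


def score_cohort(
    diffs: pd.DataFrame,
    signatures: dict[str, SignatureSet],
    alpha: float = 0.05,
    adjust_criterion2: bool = True,
) -> pd.DataFrame:
    """Score every subject against every signature with dual criteria.

    Returns a long-format table (subject, signature, counts, ratio,
    p-values, flags, CI bounds), one row per subject x signature.
    """
    universe = diffs.index
    rows = []
    for subject in diffs.columns:
        profile = diffs[subject]
        scores = [score_signature(profile, sig, universe)
                  for sig in signatures.values()]
        scores = dual_significance(
            scores, signatures, profile, universe, alpha, adjust_criterion2
        )
        rows.extend(scores)
    return pd.DataFrame(
        {
            "subject": [s.subject for s in rows],
            "signature": [s.signature for s in rows],
            "n_up": [s.n_up for s in rows],
            "n_down": [s.n_down for s in rows],
            "ratio_R": [s.ratio_R for s in rows],
            "log2_ratio": [s.log2_ratio for s in rows],
            "p_raw": [s.p_raw for s in rows],
            "p_holm": [s.p_holm for s in rows],
            "filtered_p": [s.filtered_p for s in rows],
            "significant": [s.significant for s in rows],
            "prop_up": [s.prop_up for s in rows],
            "ci_low": [s.ci_low for s in rows],
            "ci_high": [s.ci_high for s in rows],
        }
    )


def score_matrix(long_table: pd.DataFrame, value: str = "log2_ratio") -> pd.DataFrame:
    """Pivot the long score table to subjects x signatures."""
    return long_table.pivot(index="subject", columns="signature", values=value)
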