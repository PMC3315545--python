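"""Risk-allele genetics of the expression-defined subgroups.

Per-locus association between tier membership and risk-allele burden is
measured with Cliff's delta (the probability that a random subject of one
group carries more risk alleles than one of the other, minus the
reverse), with Mann-Whitney p-values and BH adjustment across loci. A
cumulative genetic risk score (100 x predicted case probability from a
logistic model on 0/1/2 allele burdens fit to an external case/control
training set) is compared between tiers with rank-sum and Welch t tests.
A treatment-history screen runs two-sample t-tests of every signature
score against every prior-treatment indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeTable
from .cytokines import fdr_adjust

MAX_MISSING_LOCI = 15
EXACT_PAIR_LIMIT = 400


@dataclass
class CliffResult:
    locus: str
    delta: float
    p_raw: float
    group_sizes: tuple[int, int]
    p_fdr: float = np.nan


def cliffs_delta(x, y, locus: str = "") -> CliffResult:
    """Cliff's delta for ordinal samples x vs y, with a Mann-Whitney p.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y). The p-value is
    the exact Mann-Whitney enumeration when n_x*n_y <= 400 and there are
    no ties, else the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    gt = (x[:, None] > y[None, :]).sum()
    lt = (x[:, None] < y[None, :]).sum()
    delta = float(gt - lt) / (x.size * y.size)
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size * y.size <= EXACT_PAIR_LIMIT and not ties) else "asymptotic"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method=method).pvalue)
    return CliffResult(locus=locus, delta=delta, p_raw=p,
                       group_sizes=(x.size, y.size))


def cliff_scan(
    genotypes: GenotypeTable,
    group_x: list,
    group_y: list,
) -> pd.DataFrame:
    """Per-locus Cliff's delta between two subject groups, BH-adjusted.

    Missing genotypes are dropped per locus; loci where either group is
    empty after dropping are reported with NaN.
    """
    rows = []
    for locus in genotypes.loci:
        col = genotypes.counts[locus]
        x = col.loc[[s for s in group_x if s in col.index]].dropna()
        y = col.loc[[s for s in group_y if s in col.index]].dropna()
        if len(x) == 0 or len(y) == 0:
            rows.append({"locus": locus, "delta": np.nan, "p_raw": np.nan,
                         "n_x": len(x), "n_y": len(y)})
            continue
        res = cliffs_delta(x.to_numpy(), y.to_numpy(), str(locus))
        rows.append({"locus": locus, "delta": res.delta, "p_raw": res.p_raw,
                     "n_x": len(x), "n_y": len(y)})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = fdr_adjust(out.loc[ok, "p_raw"].to_numpy())
    return out


@dataclass
class RiskModel:
    """Logistic model on per-locus risk-allele burden (0/1/2)."""

    loci: list
    coefficients: pd.Series  # indexed by loci
    intercept: float
    training_n: tuple[int, int]

    def predict_proba(self, burdens: pd.Series) -> float:
        eta = self.intercept + float(
            burdens.loc[self.loci].to_numpy(float) @
            self.coefficients.loc[self.loci].to_numpy(float)
        )
        return float(1.0 / (1.0 + np.exp(-eta)))


def fit_risk_model(training: GenotypeTable, ridge: bool = False,
                   ridge_alpha: float = 1.0) -> RiskModel:
    """Maximum-likelihood logistic regression of case status on burdens.

    Missing training genotypes are mode-imputed per locus. Raises on
    (quasi-)separation with a suggestion to set ``ridge=True`` (L2
    penalized fallback).
    """
    import statsmodels.api as sm

    if training.labels is None:
        raise ValueError("training table has no case/control labels")
    y = training.labels.loc[training.subjects]
    classes = sorted(map(str, y.unique()))
    if len(classes) != 2:
        raise ValueError("training labels must have exactly two classes")
    positive = "case" if "case" in classes else classes[-1]
    ybin = (y.astype(str) == positive).astype(float).to_numpy()
    X = impute_modal(training.counts).to_numpy(float)
    if X.shape[1] >= X.shape[0]:
        raise ValueError("more loci than training subjects")
    Xd = sm.add_constant(X, has_constant="add")
    if ridge:
        fit = sm.Logit(ybin, Xd).fit_regularized(
            alpha=ridge_alpha, L1_wt=0.0, disp=False
        )
        params = np.asarray(fit.params)
    else:
        try:
            with warnings_as_errors_on_separation():
                fit = sm.Logit(ybin, Xd).fit(disp=False, maxiter=200,
                                             gtol=1e-8, method="bfgs")
            params = np.asarray(fit.params)
        except (np.linalg.LinAlgError, SeparationError) as err:
            raise ValueError(
                "separation detected in logistic fit; rerun with ridge=True"
            ) from err
        # per-allele log odds beyond ~15 only arise under (quasi-)separation
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 15:
            raise ValueError(
                "separation detected in logistic fit; rerun with ridge=True"
            )
    n_case = int(ybin.sum())
    return RiskModel(
        loci=list(training.loci),
        coefficients=pd.Series(params[1:], index=training.loci),
        intercept=float(params[0]),
        training_n=(n_case, len(ybin) - n_case),
    )


class SeparationError(RuntimeError):
    pass


class warnings_as_errors_on_separation:
    """Turn statsmodels perfect-separation warnings into exceptions."""

    def __enter__(self):
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        self._ctx = warnings.catch_warnings()
        self._ctx.__enter__()
        warnings.simplefilter("error", PerfectSeparationWarning)
        return self

    def __exit__(self, exc_type, exc, tb):
        self._ctx.__exit__(exc_type, exc, tb)
        if exc_type is not None and "Separation" in exc_type.__name__:
            raise SeparationError(str(exc)) from exc
        return False


def impute_modal(counts: pd.DataFrame) -> pd.DataFrame:
    """Impute missing allele counts with the per-locus mode (smallest on ties)."""
    out = counts.copy()
    for locus in out.columns:
        col = out[locus]
        if col.isna().any():
            modes = col.mode(dropna=True)
            if modes.empty:
                raise ValueError(f"locus {locus!r} has no observed genotypes")
            out[locus] = col.fillna(modes.min())
    return out


def risk_score(
    model: RiskModel,
    subject_genotypes: pd.Series,
    cohort_counts: pd.DataFrame,
    max_missing: int = MAX_MISSING_LOCI,
) -> float | None:
    """Cumulative genetic risk score (0-100) for one subject.

    Missing loci are imputed with the cohort's per-locus modal burden;
    subjects untyped at more than ``max_missing`` loci get no score.
    """
    g = subject_genotypes.loc[model.loci]
    n_missing = int(g.isna().sum())
    if n_missing > max_missing:
        return None
    if n_missing:
        g = g.copy()
        for locus in g.index[g.isna()]:
            modes = cohort_counts[locus].mode(dropna=True)
            if modes.empty:
                raise ValueError(f"locus {locus!r} has no observed genotypes")
            g.loc[locus] = modes.min()
    return 100.0 * model.predict_proba(g)


def risk_scores(model: RiskModel, cohort: GenotypeTable,
                max_missing: int = MAX_MISSING_LOCI) -> pd.Series:
    out = {
        subj: risk_score(model, cohort.counts.loc[subj], cohort.counts,
                         max_missing)
        for subj in cohort.subjects
    }
    return pd.Series(out, name="risk_score", dtype=float)


def compare_groups(scores_x, scores_y) -> dict:
    """Rank-sum and Welch t comparison of risk scores between two groups."""
    x = np.asarray(pd.Series(scores_x).dropna(), dtype=float)
    y = np.asarray(pd.Series(scores_y).dropna(), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(np.concatenate([x, y])) == 0:
        wilcoxon_p = 1.0
        ttest_p = 1.0
    else:
        ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
        method = "exact" if (x.size * y.size <= EXACT_PAIR_LIMIT and not ties) \
            else "asymptotic"
        wilcoxon_p = float(stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method,
            use_continuity=True).pvalue)
        t_res = stats.ttest_ind(x, y, equal_var=False)
        ttest_p = 1.0 if np.isnan(t_res.pvalue) else float(t_res.pvalue)
    return {
        "wilcoxon_p": wilcoxon_p,
        "ttest_p": ttest_p,
        "mean_x": float(x.mean()),
        "sem_x": float(x.std(ddof=1) / np.sqrt(x.size)),
        "mean_y": float(y.mean()),
        "sem_y": float(y.std(ddof=1) / np.sqrt(y.size)),
        "n_x": int(x.size),
        "n_y": int(y.size),
    }


def treatment_screen(
    scores: pd.DataFrame,
    history: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample t screen of every signature score vs every treatment flag.

    ``scores``: subjects x signatures; ``history``: subjects x treatments
    booleans. Welch t per (treatment, signature); BH across the whole
    table; entries with a degenerate group (size < 2 or zero variance in
    both groups) are NA.
    """
    common = scores.index.intersection(history.index)
    rows = []
    for treatment in history.columns:
        exposed = history.loc[common, treatment].astype(bool)
        if exposed.sum() < 2 or (~exposed).sum() < 2:
            raise ValueError(
                f"treatment {treatment!r} needs >=2 exposed and >=2 unexposed"
            )
        for sig in scores.columns:
            a = scores.loc[common[exposed], sig].to_numpy(float)
            b = scores.loc[common[~exposed], sig].to_numpy(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                rows.append({"treatment": treatment, "signature": sig,
                             "t": np.nan, "p_raw": np.nan})
                continue
            t_res = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"treatment": treatment, "signature": sig,
                         "t": float(t_res.statistic),
                         "p_raw": float(t_res.pvalue)})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = fdr_adjust(out.loc[ok, "p_raw"].to_numpy())
    out["flag_raw"] = out["p_raw"] < alpha
    out["flag_fdr"] = out["p_fdr"] < alpha
    return out
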