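"""Signature derivation: moderated two-sample tests and two-step ranking.

Cell-population signatures are the probes most preferentially expressed in
replicate arrays of one cell population relative to a reference set of skin
samples. Derivation is a two-step ranking: (1) among probes with higher
mean in the population, keep the ``pool`` (default 2000) smallest
empirical-Bayes moderated-t p-values; (2) of those, keep the ``size``
(default 1000) largest fold-changes. Cytokine-response sets use the same
procedure on treated vs untreated keratinocytes, in both directions.

The moderated t shrinks per-probe sample variances toward a common prior:
s2_post = (d0*s0^2 + d*s2) / (d0 + d), with the prior (d0, s0^2) estimated
by moment matching on the log sample variances (the scaled-F model of
empirical-Bayes differential expression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ReferencePanel, SignatureSet


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to the observed sample variances.

    Returns (d0, s0_sq): prior degrees of freedom (may be inf when the
    variances show no extra-sampling heterogeneity) and prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >=2 positive sample variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.mean((e - emean) ** 2) * n / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


@dataclass
class ModeratedTestResult:
    """Per-probe moderated-t results plus the shared variance prior."""

    table: pd.DataFrame  # mean_a, mean_b, log2fc, s2, s2_post, t_mod, p
    d0: float
    s0_sq: float
    df_residual: float

    def __getitem__(self, col):
        return self.table[col]


def moderated_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ModeratedTestResult:
    """Empirical-Bayes moderated two-sample t-test per probe.

    ``group_a`` and ``group_b`` are probes x samples log2 matrices on the
    same probe universe. Pass ``d0``/``s0_sq`` to pin the prior (``d0=0``
    recovers the ordinary t-test; ``d0=np.inf`` a z-like test against
    ``s0_sq``); by default the prior is estimated from the data.
    """
    if not group_a.index.equals(group_b.index):
        raise ValueError("groups must share one probe universe")
    na, nb = group_a.shape[1], group_b.shape[1]
    d = na + nb - 2
    if d < 2 and d0 is None:
        raise ValueError(
            f"only {d} residual df: too few samples to estimate the variance "
            "prior; rerun with a fixed prior (d0=np.inf and s0_sq from config)"
        )

    a = group_a.to_numpy(float)
    b = group_b.to_numpy(float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = mean_a - mean_b
    var_a = a.var(axis=1, ddof=1) if na > 1 else np.zeros(len(a))
    var_b = b.var(axis=1, ddof=1) if nb > 1 else np.zeros(len(b))
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / d if d > 0 else np.zeros(len(a))

    if d0 is None:
        d0, s0_sq = estimate_variance_prior(s2, d)
    elif d0 > 0 and s0_sq is None:
        raise ValueError("fixed d0 > 0 requires s0_sq")
    elif d0 == 0:
        s0_sq = np.nan  # prior unused: ordinary t-test

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = d
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(log2fc == 0, 0.0, log2fc / se)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where((log2fc != 0) & (se == 0), 0.0, p)
    p = np.where(log2fc == 0, 1.0, p)

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "s2": s2,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "p": np.clip(p, 0.0, 1.0),
        },
        index=group_a.index,
    )
    return ModeratedTestResult(table, float(d0), float(s0_sq), float(d))


def _two_step_select(
    table: pd.DataFrame, direction: str, size: int, pool: int
) -> SignatureSet | None:
    """Direction filter -> top-`pool` by p -> top-`size` by |fold-change|.

    Ties at the p boundary break by smaller p then probe id; ties at the
    fold-change boundary by smaller p then probe id (determinism).
    """
    if direction in ("high-in-population", "induced"):
        kept = table[table["log2fc"] > 0].copy()
        fc_key = -kept["log2fc"]
    elif direction == "repressed":
        kept = table[table["log2fc"] < 0].copy()
        fc_key = kept["log2fc"]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if len(kept) < size:
        return None

    kept["_probe"] = kept.index.astype(str)
    kept["_fc_key"] = fc_key
    stage1 = kept.sort_values(["p", "_probe"], kind="mergesort").head(pool)
    stage1 = stage1.assign(_s1=np.arange(1, len(stage1) + 1))
    stage2 = stage1.sort_values(["_fc_key", "p", "_probe"], kind="mergesort").head(size)
    if len(stage2) < size:
        return None
    return SignatureSet(
        name="",
        direction=direction,
        probes=list(stage2.index),
        stage1_rank=dict(zip(stage2.index, stage2["_s1"].astype(int))),
        stage2_rank=dict(zip(stage2.index, range(1, size + 1))),
    )


def derive_signature(
    panel: ReferencePanel,
    population: str,
    size: int = 1000,
    pool: int = 2000,
) -> SignatureSet:
    """Derive the cell-population signature vs the panel's skin reference."""
    if pool < size:
        raise ValueError("pool must be >= size")
    if population not in panel.populations:
        raise ValueError(f"population {population!r} not in panel")
    group_a = panel.expression[panel.samples_of(population)]
    group_b = panel.expression[panel.skin_reference_ids]
    res = moderated_test(group_a, group_b)
    sig = _two_step_select(res.table, "high-in-population", size, pool)
    if sig is None:
        attained = int((res.table["log2fc"] > 0).sum())
        raise ValueError(
            f"{population!r}: only {attained} probes pass the higher-in-"
            f"population filter; cannot build a signature of size {size}"
        )
    sig.name = population
    return sig


def derive_cytokine_sets(
    treated: pd.DataFrame,
    untreated: pd.DataFrame,
    size: int = 1000,
    pool: int = 2000,
    name: str = "cytokine",
) -> tuple[SignatureSet, SignatureSet]:
    """Derive (induced, repressed) sets from treated vs untreated keratinocytes."""
    if pool < size:
        raise ValueError("pool must be >= size")
    res = moderated_test(treated, untreated)
    induced = _two_step_select(res.table, "induced", size, pool)
    repressed = _two_step_select(res.table, "repressed", size, pool)
    for direction, sig in (("induced", induced), ("repressed", repressed)):
        if sig is None:
            raise ValueError(
                f"{name!r}: too few probes pass the {direction} filter for "
                f"size {size}"
            )
        sig.name = name
    return induced, repressed
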