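"""Inflammatory x cytokine association scan.

Every (cell-type signature, cytokine set) pair is tested for association
across subjects: shared probes are removed from both sets, per-subject
scores (proportion of set probes PP-elevated) are recomputed on the
disjoint sets, and a Spearman rank correlation with midrank ties is
estimated. With 41 cell types and 32 cytokine sets this is the full grid
of 1312 pairings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SignatureSet

EXACT_PERMUTATION_MAX_N = 9


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    p-value from the t approximation t = r * sqrt((n-2)/(1-r^2)); for
    n <= 9 the exact two-sided permutation p over all n! orderings is
    returned instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 4:
        raise ValueError("spearman needs equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, r)
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, min(1.0, p)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided exact p over all permutations of one rank vector."""
    perms = np.array(list(permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    num = pc @ rxc
    denom = np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
    rs = num / denom
    return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))


@dataclass
class ScanResult:
    cell_signature: str
    cytokine_set: str
    r_s: float
    p: float
    n_shared_removed: int
    n_subjects: int


def _prop_up(diffs: pd.DataFrame, probes: pd.Index) -> np.ndarray:
    """Per-subject proportion of the given probes PP-elevated (ties excluded)."""
    sub = diffs.loc[probes]
    up = (sub > 0).sum(axis=0).to_numpy(float)
    down = (sub < 0).sum(axis=0).to_numpy(float)
    with np.errstate(invalid="ignore"):
        return np.where(up + down > 0, up / (up + down), np.nan)


def scan_pairs(
    diffs: pd.DataFrame,
    cell_sigs: list[SignatureSet],
    cytokine_sets: list[SignatureSet],
    universe: pd.Index | None = None,
) -> pd.DataFrame:
    """Spearman scan over all cell-type x cytokine-set pairings.

    ``diffs`` is the probes x subjects PP - PN difference matrix. Always
    returns |cell_sigs| x |cytokine_sets| rows; pairs whose sets are
    emptied by overlap removal carry r_s = NaN and a reason.
    """
    if universe is None:
        universe = diffs.index
    if diffs.shape[1] < 4:
        raise ValueError("scan needs >=4 subjects")
    rows = []
    for cell in cell_sigs:
        cell_probes = pd.Index(cell.probes)
        for cyt in cytokine_sets:
            cyt_probes = pd.Index(cyt.probes)
            shared = cell_probes.intersection(cyt_probes)
            cell_kept = cell_probes.difference(shared).intersection(universe)
            cyt_kept = cyt_probes.difference(shared).intersection(universe)
            if len(cell_kept) == 0 or len(cyt_kept) == 0:
                rows.append(
                    {
                        "cell_signature": cell.label,
                        "cytokine_set": cyt.label,
                        "r_s": np.nan,
                        "p": np.nan,
                        "n_shared_removed": len(shared),
                        "n_subjects": diffs.shape[1],
                        "note": "set emptied by overlap removal",
                    }
                )
                continue
            x = _prop_up(diffs, cell_kept)
            y = _prop_up(diffs, cyt_kept)
            r, p = spearman(x, y)
            rows.append(
                {
                    "cell_signature": cell.label,
                    "cytokine_set": cyt.label,
                    "r_s": r,
                    "p": p,
                    "n_shared_removed": len(shared),
                    "n_subjects": diffs.shape[1],
                    "note": "",
                }
            )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        from .cytokines import fdr_adjust

        out.loc[ok, "p_bh"] = fdr_adjust(out.loc[ok, "p"].to_numpy())
    out["significant_raw"] = out["p"] < 0.05
    return out
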