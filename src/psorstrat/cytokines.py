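"""Cytokine activity scoring.

Each subject's paired PP - PN profile is scored against the 32 sets of
cytokine-induced / cytokine-repressed transcripts with the same ratio
statistic used for cell-type signatures. Here the Fisher test is
two-sided (a bias in either direction is a call), adjusted by
Benjamini-Hochberg within subject across the sets, and a directional call
requires both an adjusted p < 0.05 and a ratio beyond 3/2 (up-bias) or
2/3 (down-bias). The thresholds are held as exact rationals so that
negating every difference swaps the two call types exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import SignatureSet
from .profiles import score_signature

UP_RATIO_THRESHOLD = Fraction(3, 2)
DOWN_RATIO_THRESHOLD = Fraction(2, 3)


@dataclass
class CytokineCall:
    subject: str
    cytokine_set: str
    n_up: int
    n_down: int
    ratio_R: float
    p_raw: float
    p_fdr: float
    call: str  # up-bias / down-bias / none


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _call(n_up: int, n_down: int, p_fdr: float, alpha: float) -> str:
    # exact-rational comparison on raw counts; Haldane only affects reporting
    if p_fdr >= alpha or (n_up + n_down) == 0:
        return "none"
    if n_down == 0:
        return "up-bias"
    if n_up == 0:
        return "down-bias"
    ratio = Fraction(n_up, n_down)
    if ratio > UP_RATIO_THRESHOLD:
        return "up-bias"
    if ratio < DOWN_RATIO_THRESHOLD:
        return "down-bias"
    return "none"


def score_cytokines(
    profile: pd.Series,
    sets: list[SignatureSet],
    universe: pd.Index | None = None,
    alpha: float = 0.05,
) -> list[CytokineCall]:
    """Score one subject against all cytokine sets and call direction."""
    if universe is None:
        universe = profile.index
    scores = [score_signature(profile, s, universe, alternative="two-sided")
              for s in sets]
    adj = fdr_adjust([s.p_raw for s in scores])
    calls = []
    for s, p_fdr in zip(scores, adj):
        calls.append(
            CytokineCall(
                subject=s.subject,
                cytokine_set=s.signature,
                n_up=s.n_up,
                n_down=s.n_down,
                ratio_R=s.ratio_R,
                p_raw=s.p_raw,
                p_fdr=float(p_fdr),
                call=_call(s.n_up, s.n_down, float(p_fdr), alpha),
            )
        )
    return calls


def score_cytokine_cohort(
    diffs: pd.DataFrame,
    sets: list[SignatureSet],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Long-format cytokine call table for every subject."""
    rows = []
    for subject in diffs.columns:
        rows.extend(score_cytokines(diffs[subject], sets, diffs.index, alpha))
    return pd.DataFrame(
        {
            "subject": [c.subject for c in rows],
            "cytokine_set": [c.cytokine_set for c in rows],
            "n_up": [c.n_up for c in rows],
            "n_down": [c.n_down for c in rows],
            "ratio_R": [c.ratio_R for c in rows],
            "p_raw": [c.p_raw for c in rows],
            "p_fdr": [c.p_fdr for c in rows],
            "call": [c.call for c in rows],
        }
    )
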