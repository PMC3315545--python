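"""Synthetic cohorts with known planted structure.

Everything downstream is testable without any array download: the
generators emulate (a) reference expression panels (cell populations with
~4 replicates each vs a 21-sample skin reference) with planted marker
probes, (b) paired lesional/non-lesional (PP/PN) cohorts in which
cell-type modules are elevated in PP skin at three inflammatory tiers
(strong/moderate/weak, 23:24:15 by default) and cytokine modules follow
two activity tiers (IL-13-strong / IL-13-weak, 31:31), and (c) genotype
tables with planted between-tier allele-frequency shifts plus a
case/control training set (2568 cases / 2525 controls by default).

All draws are Gaussian on the log2 scale around probe baselines
~ Normal(8, 2^2) (a typical normalized-array dynamic range); noise is
i.i.d. with sd 0.5 by default, so a planted PP-PN shift of delta is
PP-elevated with probability Phi(delta / (0.5 * sqrt(2))). Within-subject
PP/PN correlation beyond the shared probe baseline is deliberately not
modeled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GenotypeTable,
    ReferencePanel,
    SignatureSet,
    SyntheticCohort,
    SyntheticGenotypes,
)

BASELINE_MEAN = 8.0
BASELINE_SD = 2.0
DEFAULT_NOISE_SD = 0.5
DEFAULT_MARKER_SHIFT = 2.0
DEFAULT_TIER_PROPS = (23 / 62, 24 / 62, 15 / 62)
DEFAULT_EFFECT_SCALES = {"strong": 1.0, "moderate": 0.6, "weak": 0.2}
DEFAULT_CYTOKINE_SCALES = {"il13_strong": 1.0, "il13_weak": -0.5}
INFLAMMATORY_TIERS = ("strong", "moderate", "weak")
CYTOKINE_TIERS = ("il13_strong", "il13_weak")
TRAINING_CASES = 2568
TRAINING_CONTROLS = 2525


def _probe_ids(n: int) -> pd.Index:
    return pd.Index([f"P{i:06d}" for i in range(1, n + 1)], name="probe_id")


def generate_reference_panel(
    n_probes: int,
    populations: list[str],
    markers_per_population: int,
    seed: int,
    replicates_per_population: int = 4,
    n_skin_reference: int = 21,
    marker_shift: float = DEFAULT_MARKER_SHIFT,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> ReferencePanel:
    """Reference panel: replicate arrays per population vs a skin reference.

    Marker probes (disjoint blocks per population) get ``marker_shift``
    extra log2 units in their own population's samples only.
    """
    if n_probes <= 0 or replicates_per_population <= 0 or n_skin_reference < 2:
        raise ValueError("counts must be positive (skin reference >= 2)")
    if markers_per_population < 0:
        raise ValueError("markers_per_population must be >= 0")
    if not populations:
        raise ValueError("populations must be non-empty")
    if markers_per_population and n_probes < 20 * markers_per_population:
        raise ValueError("need n_probes >= 20 * markers_per_population")
    if markers_per_population * len(populations) > n_probes:
        raise ValueError("marker blocks exceed probe count")

    rng = np.random.default_rng(seed)
    probes = _probe_ids(n_probes)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_probes)

    sample_ids, pop_of_sample = [], []
    for pop in populations:
        for r in range(1, replicates_per_population + 1):
            sample_ids.append(f"{pop}_rep{r}")
            pop_of_sample.append(pop)
    skin_ids = [f"skin_{i:02d}" for i in range(1, n_skin_reference + 1)]

    shift = np.zeros((n_probes, len(sample_ids)))
    truth: dict = {}
    for pi, pop in enumerate(populations):
        block = slice(pi * markers_per_population,
                      (pi + 1) * markers_per_population)
        cols = [j for j, p in enumerate(pop_of_sample) if p == pop]
        for c in cols:
            shift[block, c] = marker_shift
        for probe in probes[block]:
            truth[probe] = pop

    pop_expr = (baseline[:, None] + shift
                + rng.normal(0.0, noise_sd, size=(n_probes, len(sample_ids))))
    skin_expr = (baseline[:, None]
                 + rng.normal(0.0, noise_sd, size=(n_probes, len(skin_ids))))
    expr = pd.DataFrame(
        np.hstack([pop_expr, skin_expr]),
        index=probes, columns=sample_ids + skin_ids,
    )
    return ReferencePanel(
        expression=expr,
        population_of_sample=pd.Series(
            pop_of_sample + ["skin"] * len(skin_ids), index=expr.columns
        ),
        skin_reference_ids=skin_ids,
        truth_marker_map=truth,
    )


def _apportion(n: int, props) -> list[int]:
    """Largest-remainder apportionment of n into len(props) integer counts."""
    props = np.asarray(props, dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("tier proportions must sum to 1")
    raw = props * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def planted_signature_sets(
    n_probes: int,
    n_cell_sigs: int,
    n_cytokine_pairs: int,
    size: int,
    overlap_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[SignatureSet], list[SignatureSet]]:
    """Construct planted cell-type and cytokine signature probe sets.

    Cell-type sets occupy disjoint probe blocks; each cytokine
    induced/repressed set overlaps the cell-type blocks by
    ``overlap_fraction`` of its probes (exercising overlap-removal logic)
    and is otherwise drawn from the remaining probes.
    """
    probes = _probe_ids(n_probes)
    need_cell = n_cell_sigs * size
    n_cyt_sets = 2 * n_cytokine_pairs
    n_overlap = int(round(overlap_fraction * size))
    need_free = n_cyt_sets * (size - n_overlap)
    if need_cell + need_free > n_probes:
        raise ValueError("not enough probes for the requested signature sets")
    rng = np.random.default_rng(seed)
    cell_sigs = []
    for i in range(n_cell_sigs):
        block = probes[i * size:(i + 1) * size]
        cell_sigs.append(
            SignatureSet(f"celltype_{i + 1:02d}", "high-in-population",
                         list(block))
        )
    free = list(probes[need_cell:])
    cell_pool = list(probes[:need_cell])
    cyt_sigs = []
    pos = 0
    for i in range(n_cytokine_pairs):
        for direction in ("induced", "repressed"):
            own = free[pos:pos + size - n_overlap]
            pos += size - n_overlap
            shared = list(rng.choice(cell_pool, size=n_overlap,
                                     replace=False)) if n_overlap else []
            cyt_sigs.append(
                SignatureSet(f"cytokine_{i + 1:02d}", direction, own + shared)
            )
    return cell_sigs, cyt_sigs


def generate_cohort(
    n_subjects: int,
    n_probes: int,
    signatures: list[SignatureSet],
    tier_props=DEFAULT_TIER_PROPS,
    effect_scales: dict | None = None,
    base_effect: float = 1.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    cytokine_signatures: list[SignatureSet] | None = None,
    cytokine_props=(0.5, 0.5),
    cytokine_scales: dict | None = None,
    cytokine_base_effect: float = 1.0,
    block_correlation: float = 0.0,
) -> SyntheticCohort:
    """Paired PP/PN cohort with planted tiered module shifts.

    PN = probe baseline + noise; PP adds, per planted module probe, the
    module's base effect scaled by the subject's tier. Cell-type modules
    shift positively (infiltrate elevation); cytokine ``induced`` probes
    shift by +scale and ``repressed`` probes by -scale, so a negative
    tier scale (IL-13-weak) suppresses induced and elevates repressed
    transcripts.

    ``block_correlation`` (rho in [0, 1)) adds a shared within-module
    noise component per sample, giving planted-module probes pairwise
    noise correlation rho while keeping the marginal sd at ``noise_sd``.
    """
    if not signatures:
        raise ValueError("signature list must be non-empty")
    if n_subjects <= 0 or n_probes <= 0:
        raise ValueError("counts must be positive")
    effect_scales = dict(DEFAULT_EFFECT_SCALES if effect_scales is None
                         else effect_scales)
    cytokine_scales = dict(DEFAULT_CYTOKINE_SCALES if cytokine_scales is None
                           else cytokine_scales)
    # zero-everywhere scales are allowed (null cohorts); otherwise ordered
    if not (effect_scales["strong"] >= effect_scales["moderate"]
            >= effect_scales["weak"] >= 0):
        raise ValueError("effect scales must satisfy strong >= moderate >= weak >= 0")

    rng = np.random.default_rng(seed)
    probes = _probe_ids(n_probes)
    pos = {p: i for i, p in enumerate(probes)}
    subjects = [f"S{i:03d}" for i in range(1, n_subjects + 1)]

    counts = _apportion(n_subjects, tier_props)
    inf_tier = pd.Series(
        np.repeat(INFLAMMATORY_TIERS[: len(counts)], counts),
        index=subjects, name="inflammatory_tier",
    )
    cyt_counts = _apportion(n_subjects, cytokine_props)
    cyt_order = rng.permutation(n_subjects)
    cyt_tier = pd.Series("il13_strong", index=subjects, name="cytokine_tier")
    cyt_tier.iloc[cyt_order[cyt_counts[0]:]] = "il13_weak"

    truth: dict = {}
    cell_shift = np.zeros(n_probes)
    for sig in signatures:
        for p in sig.probes:
            cell_shift[pos[p]] += base_effect
            truth.setdefault(p, []).append(sig.label)
    cyt_shift = np.zeros(n_probes)
    if cytokine_signatures:
        for sig in cytokine_signatures:
            sgn = 1.0 if sig.direction == "induced" else -1.0
            for p in sig.probes:
                cyt_shift[pos[p]] += sgn * cytokine_base_effect
                truth.setdefault(p, []).append(sig.label)

    if not 0.0 <= block_correlation < 1.0:
        raise ValueError("block_correlation must lie in [0, 1)")
    modules = list(signatures) + list(cytokine_signatures or [])
    module_rows = [np.fromiter((pos[p] for p in sig.probes), dtype=int)
                   for sig in modules]

    def _noise() -> np.ndarray:
        eps = rng.normal(0.0, noise_sd, size=n_probes)
        if block_correlation > 0:
            shared = rng.normal(0.0, noise_sd, size=len(modules))
            for rows, s in zip(module_rows, shared):
                eps[rows] = (np.sqrt(1.0 - block_correlation) * eps[rows]
                             + np.sqrt(block_correlation) * s)
        return eps

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_probes)
    data = {}
    for si, subj in enumerate(subjects):
        shift = cell_shift * effect_scales[inf_tier.iloc[si]]
        if cytokine_signatures:
            shift = shift + cyt_shift * cytokine_scales[cyt_tier.iloc[si]]
        pn = baseline + _noise()
        pp = baseline + shift + _noise()
        data[f"{subj}_PP"] = pp
        data[f"{subj}_PN"] = pn

    expr = pd.DataFrame(data, index=probes)
    meta = pd.DataFrame(
        {
            "subject": [c.rsplit("_", 1)[0] for c in expr.columns],
            "condition": [c.rsplit("_", 1)[1] for c in expr.columns],
            "sex": [("M" if int(c[1:4]) % 2 else "F") for c in expr.columns],
            "batch": [("b1" if int(c[1:4]) <= n_subjects // 2 else "b2")
                      for c in expr.columns],
        },
        index=expr.columns,
    )
    return SyntheticCohort(
        expression=ExpressionMatrix(expr, meta),
        truth_inflammatory_tier=inf_tier,
        truth_cytokine_tier=cyt_tier,
        truth_marker_map=truth,
        effect_scales=effect_scales,
        noise_sd=noise_sd,
    )


def generate_genotypes(
    n_subjects: int,
    n_loci: int = 44,
    planted: list[tuple] | None = None,
    seed: int = 0,
    tiers: pd.Series | None = None,
    missing_rate: float = 0.02,
    baseline_freqs: np.ndarray | None = None,
    training_cases: int = TRAINING_CASES,
    training_controls: int = TRAINING_CONTROLS,
    training_scale: float = 1.0,
    training_log_or: float | np.ndarray = 0.25,
    subjects: list | None = None,
) -> SyntheticGenotypes:
    """Cohort genotypes with planted tier shifts plus a training table.

    ``planted`` holds (locus_name, tier, delta) triples: cohort subjects
    in ``tier`` draw risk alleles at frequency f + delta at that locus.
    Training cases' allele frequencies are exponentially tilted by the
    per-locus log odds ratio, so a logistic refit recovers
    ``training_log_or`` as the per-allele coefficient.
    """
    if n_loci < 1 or n_subjects < 1:
        raise ValueError("counts must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    loci = [f"locus_{i:02d}" for i in range(1, n_loci + 1)]
    if subjects is None:
        subjects = [f"S{i:03d}" for i in range(1, n_subjects + 1)]
    if baseline_freqs is None:
        freqs = rng.uniform(0.2, 0.5, size=n_loci)
    else:
        freqs = np.asarray(baseline_freqs, dtype=float)
    if not ((freqs > 0) & (freqs < 1)).all():
        raise ValueError("baseline frequencies must lie in (0, 1)")

    planted = planted or []
    if planted and tiers is None:
        raise ValueError("planted tier shifts require per-subject tier labels")
    locus_idx = {name: i for i, name in enumerate(loci)}
    fmat = np.tile(freqs, (n_subjects, 1))
    for locus, tier, delta in planted:
        li = locus_idx[locus] if isinstance(locus, str) else int(locus)
        rows = np.asarray(
            [tiers.loc[s] == tier for s in subjects], dtype=bool
        )
        shifted = freqs[li] + delta
        if not 0 < shifted < 1:
            raise ValueError(
                f"shifted frequency {shifted:.3f} at {loci[li]} outside (0, 1)"
            )
        fmat[rows, li] = shifted
    counts = rng.binomial(2, fmat).astype(float)
    if missing_rate > 0:
        counts[rng.random(counts.shape) < missing_rate] = np.nan
    cohort = GenotypeTable(pd.DataFrame(counts, index=subjects, columns=loci))

    n_cases = max(2, int(round(training_cases * training_scale)))
    n_ctrl = max(2, int(round(training_controls * training_scale)))
    beta = np.broadcast_to(np.asarray(training_log_or, dtype=float),
                           (n_loci,)).copy()
    tilt = freqs * np.exp(beta)
    f_case = tilt / (1.0 - freqs + tilt)
    case_counts = rng.binomial(2, np.tile(f_case, (n_cases, 1)))
    ctrl_counts = rng.binomial(2, np.tile(freqs, (n_ctrl, 1)))
    train_ids = ([f"case_{i:04d}" for i in range(1, n_cases + 1)]
                 + [f"ctrl_{i:04d}" for i in range(1, n_ctrl + 1)])
    training = GenotypeTable(
        pd.DataFrame(np.vstack([case_counts, ctrl_counts]).astype(float),
                     index=train_ids, columns=loci),
        labels=pd.Series(["case"] * n_cases + ["control"] * n_ctrl,
                         index=train_ids, name="status"),
    )
    return SyntheticGenotypes(
        cohort_table=cohort,
        training_table=training,
        planted_delta_loci=[loci[locus_idx[l] if isinstance(l, str) else int(l)]
                            for l, _, _ in planted],
        risk_allele_freqs=pd.Series(freqs, index=loci, name="risk_allele_freq"),
    )
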