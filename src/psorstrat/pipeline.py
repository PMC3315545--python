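"""End-to-end pipeline orchestration.

A run is driven by a config mapping (YAML on disk) and materializes every
stage's outputs as TSV/JSON in a run directory, ending with a manifest
that echoes the resolved config, the seed, per-stage wall times and
sha256 checksums of every artifact. Stages communicate through files, so
each can also be invoked on its own against an existing run directory.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .containers import ExpressionMatrix
from .cytokines import score_cytokine_cohort
from .genetics import (
    cliff_scan,
    compare_groups,
    fit_risk_model,
    risk_scores,
    treatment_screen,
)
from .outliers import detect_outliers
from .profiles import adjust_covariates, paired_differences, score_cohort, score_matrix
from .scan import scan_pairs
from .signatures import derive_signature
from .stratify import (
    assign_subgroups,
    silhouette_by_feature,
    standardize,
    to_newick,
)
from .synthetic import (
    generate_cohort,
    generate_genotypes,
    generate_reference_panel,
    planted_signature_sets,
)

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "alpha": 0.05,
    "synthetic": {
        "n_subjects": 62,
        "n_probes": 20000,
        "signature_size": 1000,
        "n_cell_signatures": 6,
        "n_cytokine_pairs": 4,
        "overlap_fraction": 0.1,
        "base_effect": 1.0,
        "cytokine_base_effect": 1.0,
        "noise_sd": 0.5,
        "tier_props": [23 / 62, 24 / 62, 15 / 62],
        "effect_scales": {"strong": 1.0, "moderate": 0.6, "weak": 0.2},
        "cytokine_scales": {"il13_strong": 1.0, "il13_weak": -0.5},
        "n_treatments": 3,
    },
    "derivation": {
        "panel_populations": 3,
        "panel_markers": 400,
        "panel_probes": 8000,
        "pool_factor": 2,
    },
    "stratification": {
        "k_inflammatory": 3,
        "k_cytokine": 2,
        "linkage": "complete",
        "metric": "euclidean",
    },
    "genetics": {
        "n_loci": 44,
        "missing_rate": 0.02,
        "training_scale": 0.25,
        "training_log_or": 0.25,
        "planted": [["locus_01", "strong", 0.2], ["locus_02", "weak", 0.2]],
        "max_missing_loci": 15,
    },
}

# scaled-down profile for quick runs and CI
TEST_CONFIG_OVERRIDES: dict = {
    "synthetic": {"n_subjects": 12, "n_probes": 4000, "signature_size": 200,
                  "n_cell_signatures": 4, "n_cytokine_pairs": 2},
    "derivation": {"panel_markers": 200, "panel_probes": 4000},
    "genetics": {"training_scale": 0.1},
}


def _deep_update(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def default_config(test_profile: bool = False) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if test_profile:
        cfg = _deep_update(cfg, TEST_CONFIG_OVERRIDES)
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_update(default_config(), user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _seed_for(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def stage_simulate(outdir: Path, cfg: dict) -> dict:
    syn = cfg["synthetic"]
    seed = cfg["seed"]
    cell_sigs, cyt_sigs = planted_signature_sets(
        syn["n_probes"], syn["n_cell_signatures"], syn["n_cytokine_pairs"],
        syn["signature_size"], syn["overlap_fraction"],
        _seed_for(seed, "sets"),
    )
    cohort = generate_cohort(
        syn["n_subjects"], syn["n_probes"], cell_sigs,
        tier_props=syn["tier_props"], effect_scales=syn["effect_scales"],
        base_effect=syn["base_effect"], noise_sd=syn["noise_sd"],
        seed=_seed_for(seed, "cohort"),
        cytokine_signatures=cyt_sigs,
        cytokine_scales=syn["cytokine_scales"],
        cytokine_base_effect=syn["cytokine_base_effect"],
    )
    psio.write_expression_tsv(cohort.expression.values, outdir / "expression.tsv")
    psio.write_gct(cohort.expression.values, outdir / "expression.gct")
    cohort.expression.metadata.to_csv(outdir / "metadata.tsv", sep="\t",
                                      index_label="sample")
    pd.DataFrame(
        {
            "inflammatory_tier": cohort.truth_inflammatory_tier,
            "cytokine_tier": cohort.truth_cytokine_tier,
        }
    ).to_csv(outdir / "truth_tiers.tsv", sep="\t", index_label="subject")
    sigdir = outdir / "signatures"
    sigdir.mkdir(exist_ok=True)
    for sig in cell_sigs + cyt_sigs:
        psio.write_signature(sig, sigdir)
    psio.write_gmt(cell_sigs + cyt_sigs, outdir / "signatures.gmt")

    # treatment history: independent of everything (null screen by design)
    rng = np.random.default_rng(_seed_for(seed, "treatment"))
    subjects = cohort.truth_inflammatory_tier.index
    history = pd.DataFrame(
        {f"treatment_{t + 1}": rng.random(len(subjects)) < 0.5
         for t in range(syn["n_treatments"])},
        index=subjects,
    )
    # guard the >=2 exposed / >=2 unexposed precondition at small n
    for col in history.columns:
        if history[col].sum() < 2:
            history.iloc[:2, history.columns.get_loc(col)] = True
        if (~history[col]).sum() < 2:
            history.iloc[-2:, history.columns.get_loc(col)] = False
    history.astype(int).to_csv(outdir / "treatment_history.tsv", sep="\t",
                               index_label="subject")

    if "genetics" in cfg and cfg["genetics"] is not None:
        gen = cfg["genetics"]
        geno = generate_genotypes(
            n_subjects=syn["n_subjects"], n_loci=gen["n_loci"],
            planted=[tuple(p) for p in gen.get("planted", [])],
            seed=_seed_for(seed, "genotypes"),
            tiers=cohort.truth_inflammatory_tier,
            missing_rate=gen["missing_rate"],
            training_scale=gen["training_scale"],
            training_log_or=gen["training_log_or"],
            subjects=list(subjects),
        )
        psio.write_genotypes(geno.cohort_table, outdir / "genotypes.tsv")
        psio.write_genotypes(geno.training_table,
                             outdir / "training_genotypes.tsv")
        geno.training_table.labels.to_frame().to_csv(
            outdir / "training_labels.tsv", sep="\t", index_label="subject"
        )
    return {"n_subjects": syn["n_subjects"], "n_probes": syn["n_probes"],
            "n_cell_signatures": len(cell_sigs),
            "n_cytokine_sets": len(cyt_sigs)}


def stage_derive(outdir: Path, cfg: dict) -> dict:
    """Exercise signature derivation on a synthetic reference panel."""
    der = cfg["derivation"]
    syn = cfg["synthetic"]
    size = min(der["panel_markers"], syn["signature_size"])
    panel = generate_reference_panel(
        der["panel_probes"],
        [f"refpop_{i + 1}" for i in range(der["panel_populations"])],
        der["panel_markers"], _seed_for(cfg["seed"], "panel"),
    )
    outsig = outdir / "derived_signatures"
    outsig.mkdir(exist_ok=True)
    recovery = {}
    for pop in panel.populations:
        if pop == "skin":
            continue
        sig = derive_signature(panel, pop, size=size,
                               pool=size * der["pool_factor"])
        psio.write_signature(sig, outsig)
        truth = {p for p, lab in panel.truth_marker_map.items() if lab == pop}
        recovery[pop] = len(truth.intersection(sig.probes)) / max(len(truth), 1)
    return {"marker_recovery": recovery}


def _load_cohort(outdir: Path) -> ExpressionMatrix:
    expr = psio.read_expression_tsv(outdir / "expression.tsv")
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t", index_col=0)
    return ExpressionMatrix(expr, meta)


def _load_signatures(outdir: Path):
    sigs = [psio.read_signature(p)
            for p in sorted((outdir / "signatures").glob("*.sig.tsv"))]
    cell = [s for s in sigs if s.direction == "high-in-population"]
    cyt = [s for s in sigs if s.direction in ("induced", "repressed")]
    return cell, cyt


def stage_profile(outdir: Path, cfg: dict) -> dict:
    cohort = _load_cohort(outdir)
    adjusted = adjust_covariates(cohort)
    diffs = paired_differences(adjusted)
    diffs.to_csv(outdir / "diffs.tsv", sep="\t", index_label="probe_id")
    cell_sigs, _ = _load_signatures(outdir)
    table = score_cohort(diffs, {s.label: s for s in cell_sigs},
                         alpha=cfg["alpha"])
    table.to_csv(outdir / "profile_scores.tsv", sep="\t", index=False)
    score_matrix(table).to_csv(outdir / "score_matrix_inflammatory.tsv",
                               sep="\t")
    return {"n_scores": len(table),
            "pct_significant": float(table["significant"].mean() * 100)}


def stage_cytokines(outdir: Path, cfg: dict) -> dict:
    diffs = pd.read_csv(outdir / "diffs.tsv", sep="\t", index_col=0)
    _, cyt_sigs = _load_signatures(outdir)
    calls = score_cytokine_cohort(diffs, cyt_sigs, alpha=cfg["alpha"])
    calls.to_csv(outdir / "cytokine_calls.tsv", sep="\t", index=False)
    mat = calls.pivot(index="subject", columns="cytokine_set",
                      values="ratio_R")
    np.log2(mat).to_csv(outdir / "score_matrix_cytokine.tsv", sep="\t")
    return {"n_calls": len(calls),
            "pct_called": float((calls["call"] != "none").mean() * 100)}


def stage_stratify(outdir: Path, cfg: dict) -> dict:
    strat = cfg["stratification"]
    inf = pd.read_csv(outdir / "score_matrix_inflammatory.tsv", sep="\t",
                      index_col=0)
    cyt = pd.read_csv(outdir / "score_matrix_cytokine.tsv", sep="\t",
                      index_col=0)
    assignment = assign_subgroups(
        inf, cyt, strat["k_inflammatory"], strat["k_cytokine"],
        strat["linkage"], strat["metric"],
    )
    out = pd.DataFrame({
        "inflammatory_tier": assignment.inflammatory_tier,
        "cytokine_tier": assignment.cytokine_tier,
    })
    out.to_csv(outdir / "subgroups.tsv", sep="\t", index_label="subject")
    (outdir / "dendrogram_inflammatory.newick").write_text(
        to_newick(assignment.dendrogram_inflammatory, list(inf.index))
    )
    (outdir / "dendrogram_cytokine.newick").write_text(
        to_newick(assignment.dendrogram_cytokine, list(cyt.index))
    )
    silhouette_by_feature(
        standardize(inf), assignment.inflammatory_tier.to_numpy()
    ).to_csv(outdir / "silhouette_inflammatory.tsv", sep="\t",
             index_label="signature")
    silhouette_by_feature(
        standardize(cyt), assignment.cytokine_tier.to_numpy()
    ).to_csv(outdir / "silhouette_cytokine.tsv", sep="\t",
             index_label="signature")

    info: dict = {"tier_counts": assignment.inflammatory_tier
                  .value_counts().to_dict(),
                  "cytokine_counts": assignment.cytokine_tier
                  .value_counts().to_dict()}
    truth_path = outdir / "truth_tiers.tsv"
    if truth_path.exists():
        from sklearn.metrics import adjusted_rand_score

        truth = pd.read_csv(truth_path, sep="\t", index_col=0)
        info["ari_inflammatory"] = float(adjusted_rand_score(
            truth["inflammatory_tier"], assignment.inflammatory_tier
        ))
        info["ari_cytokine"] = float(adjusted_rand_score(
            truth["cytokine_tier"], assignment.cytokine_tier
        ))
    return info


def stage_outliers(outdir: Path, cfg: dict) -> dict:
    info = {}
    for kind in ("inflammatory", "cytokine"):
        mat = pd.read_csv(outdir / f"score_matrix_{kind}.tsv", sep="\t",
                          index_col=0)
        report = detect_outliers(standardize(mat), alpha=cfg["alpha"])
        payload = {
            "var_explained": report.var_explained.tolist(),
            "grubbs": {ax: {"G": g, "p": p}
                       for ax, (g, p) in report.grubbs.items()},
            "gate_open": report.gate_open,
            "outliers": report.outliers,
            "cutoff": report.cutoff,
        }
        (outdir / f"outliers_{kind}.json").write_text(
            json.dumps(payload, indent=2)
        )
        pd.DataFrame({
            "PC1": report.pc_scores["PC1"],
            "PC2": report.pc_scores["PC2"],
            "outlier": report.bivariate_flags,
        }).to_csv(outdir / f"outliers_{kind}.tsv", sep="\t",
                  index_label="subject")
        info[kind] = {"gate_open": report.gate_open,
                      "n_outliers": len(report.outliers)}
    return info


def stage_scan(outdir: Path, cfg: dict) -> dict:
    diffs = pd.read_csv(outdir / "diffs.tsv", sep="\t", index_col=0)
    cell_sigs, cyt_sigs = _load_signatures(outdir)
    results = scan_pairs(diffs, cell_sigs, cyt_sigs)
    results.to_csv(outdir / "scan_results.tsv", sep="\t", index=False)
    return {"n_pairs": len(results),
            "n_significant_raw": int(results["significant_raw"].sum())}


def stage_genetics(outdir: Path, cfg: dict) -> dict:
    gen = cfg["genetics"]
    geno = psio.read_genotypes(outdir / "genotypes.tsv")
    training = psio.read_genotypes(outdir / "training_genotypes.tsv",
                                   outdir / "training_labels.tsv")
    tiers = pd.read_csv(outdir / "subgroups.tsv", sep="\t", index_col=0)
    strong = tiers.index[tiers["inflammatory_tier"] == "strong"].tolist()
    weak = tiers.index[tiers["inflammatory_tier"] == "weak"].tolist()
    cliff = cliff_scan(geno, strong, weak)
    cliff.to_csv(outdir / "cliff_results.tsv", sep="\t", index=False)

    model = fit_risk_model(training)
    (outdir / "risk_model.json").write_text(json.dumps({
        "intercept": model.intercept,
        "coefficients": model.coefficients.to_dict(),
        "training_n": model.training_n,
    }, indent=2))
    scores = risk_scores(model, geno, gen["max_missing_loci"])
    scores.to_frame().to_csv(outdir / "risk_scores.tsv", sep="\t",
                             index_label="subject")
    comparison = compare_groups(scores.loc[strong].dropna(),
                                scores.loc[weak].dropna())
    (outdir / "group_comparison.json").write_text(
        json.dumps(comparison, indent=2)
    )

    history = pd.read_csv(outdir / "treatment_history.tsv", sep="\t",
                          index_col=0).astype(bool)
    inf = pd.read_csv(outdir / "score_matrix_inflammatory.tsv", sep="\t",
                      index_col=0)
    screen = treatment_screen(inf, history, alpha=cfg["alpha"])
    screen.to_csv(outdir / "treatment_screen.tsv", sep="\t", index=False)
    return {
        "n_sig_delta_raw": int((cliff["p_raw"] < 0.05).sum()),
        "risk_score_comparison": {k: comparison[k]
                                  for k in ("wilcoxon_p", "ttest_p",
                                            "mean_x", "mean_y")},
        "n_screen_flags_fdr": int(screen["flag_fdr"].sum()),
    }


STAGES = [
    ("simulate", stage_simulate),
    ("derive-signatures", stage_derive),
    ("profile", stage_profile),
    ("cytokines", stage_cytokines),
    ("stratify", stage_stratify),
    ("outliers", stage_outliers),
    ("scan", stage_scan),
    ("genetics", stage_genetics),
]


def run_pipeline(config: dict | None = None, outdir="psorstrat_run") -> dict:
    """Run every stage in order and write the run manifest."""
    cfg = _deep_update(default_config(), config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_resolved.yaml").write_text(yaml.safe_dump(cfg))
    manifest: dict = {"seed": cfg["seed"], "stages": {}, "skipped": []}
    for name, func in STAGES:
        if name == "genetics" and cfg.get("genetics") is None:
            manifest["skipped"].append(name)
            continue
        t0 = time.perf_counter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            # synthetic baselines may dip below the log2 sanity range
            warnings.filterwarnings("ignore", message=".*log2 scale.*")
            info = func(outdir, cfg)
        manifest["stages"][name] = {
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "info": info,
        }
    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
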