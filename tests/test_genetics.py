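"""Cliff's delta, risk model fitting/scoring, group comparisons, screens."""

import numpy as np
import pandas as pd
import pytest

from oracles import cliffs_delta_brute
from psorstrat.containers import GenotypeTable
from psorstrat.genetics import (
    cliff_scan,
    cliffs_delta,
    compare_groups,
    fit_risk_model,
    impute_modal,
    risk_score,
    risk_scores,
    treatment_screen,
)
from psorstrat.synthetic import generate_genotypes


class TestCliffsDelta:
    def test_identical_multisets_give_zero(self):
        assert cliffs_delta([1, 2, 2, 3], [1, 2, 2, 3]).delta == 0.0

    def test_hand_computed_overlap(self):
        res = cliffs_delta([3, 4, 5], [1, 2, 3])
        assert res.delta == pytest.approx(8 / 9)

    def test_complete_separation(self):
        assert cliffs_delta([4, 5], [1, 2]).delta == 1.0
        assert cliffs_delta([1, 2], [4, 5]).delta == -1.0

    def test_group_swap_negates_delta(self, rng):
        x = rng.integers(0, 3, 10)
        y = rng.integers(0, 3, 8)
        assert cliffs_delta(x, y).delta == pytest.approx(
            -cliffs_delta(y, x).delta
        )

    def test_matches_brute_force_all_pairs(self, rng):
        """Property: delta equals the exhaustive loop for n_x, n_y <= 30."""
        for _ in range(25):
            nx, ny = rng.integers(1, 31, size=2)
            x = rng.integers(0, 3, nx)
            y = rng.integers(0, 3, ny)
            assert cliffs_delta(x, y).delta == pytest.approx(
                cliffs_delta_brute(x, y)
            )

    def test_mann_whitney_identity_without_ties(self, rng):
        """Delta = 2U/(n_x n_y) - 1 on tie-free data."""
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            x = rng.permutation(40)[:12].astype(float)
            y = (rng.permutation(40)[:9] + 100).astype(float)
            y[: len(y) // 2] -= 150  # mix above and below
            u = mannwhitneyu(x, y, alternative="two-sided").statistic
            assert cliffs_delta(x, y).delta == pytest.approx(
                2 * u / (len(x) * len(y)) - 1
            )


class TestRiskModel:
    def _training(self, rng, n=400, n_loci=5, beta=None):
        beta = np.zeros(n_loci) if beta is None else np.asarray(beta)
        f = rng.uniform(0.3, 0.5, n_loci)
        G = rng.binomial(2, np.tile(f, (n, 1))).astype(float)
        eta = G @ beta
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        ids = [f"t{i}" for i in range(n)]
        return GenotypeTable(
            pd.DataFrame(G, index=ids,
                         columns=[f"locus_{j}" for j in range(n_loci)]),
            labels=pd.Series(np.where(y, "case", "control"), index=ids),
        )

    def test_null_training_gives_scores_near_50(self, rng):
        table = self._training(rng)
        model = fit_risk_model(table)
        assert np.abs(model.coefficients).max() < 0.5
        subject = pd.Series(1.0, index=model.loci)
        s = risk_score(model, subject, table.counts)
        assert 30 < s < 70

    def test_planted_effect_sign_recovered(self, rng):
        beta = np.array([1.2, 0.0, 0.0, 0.0, -1.0])
        model = fit_risk_model(self._training(rng, n=800, beta=beta))
        assert model.coefficients.iloc[0] > 0.3
        assert model.coefficients.iloc[4] < -0.3

    def test_permuted_labels_shrink_coefficients(self, rng):
        beta = np.array([1.5, 1.0, -1.0, 0.8, -0.8])
        table = self._training(rng, n=800, beta=beta)
        model = fit_risk_model(table)
        perm = GenotypeTable(
            table.counts,
            labels=pd.Series(
                rng.permutation(table.labels.to_numpy()),
                index=table.labels.index,
            ),
        )
        model_perm = fit_risk_model(perm)
        assert (np.abs(model_perm.coefficients).mean()
                < np.abs(model.coefficients).mean())

    def test_separation_raises_with_ridge_advice(self):
        G = pd.DataFrame({"locus_0": [0.0] * 10 + [2.0] * 10},
                         index=[f"t{i}" for i in range(20)])
        table = GenotypeTable(
            G, labels=pd.Series(["control"] * 10 + ["case"] * 10, index=G.index)
        )
        with pytest.raises(ValueError, match="ridge"):
            fit_risk_model(table)
        model = fit_risk_model(table, ridge=True)
        assert np.isfinite(model.coefficients).all()

    def test_parameter_recovery_at_training_scale(self, rng):
        """Coefficients recovered within +/-0.15 on a 1000/1000-style set."""
        geno = generate_genotypes(
            n_subjects=10, n_loci=8, seed=42, missing_rate=0.0,
            training_scale=0.4, training_log_or=0.25,
        )
        model = fit_risk_model(geno.training_table)
        assert np.abs(model.coefficients - 0.25).max() < 0.15


class TestRiskScore:
    def _model(self, loci, coef=0.0, intercept=0.0):
        from psorstrat.genetics import RiskModel

        return RiskModel(
            loci=list(loci),
            coefficients=pd.Series(coef, index=loci),
            intercept=intercept,
            training_n=(10, 10),
        )

    def test_modal_imputation(self):
        loci = ["l1"]
        cohort = pd.DataFrame({"l1": [0.0, 1.0, 1.0, 2.0, np.nan]})
        assert impute_modal(cohort)["l1"].iloc[4] == 1.0

    def test_zero_model_scores_exactly_50(self):
        model = self._model(["l1", "l2"])
        s = risk_score(model, pd.Series({"l1": 2.0, "l2": 0.0}),
                       pd.DataFrame({"l1": [0.0], "l2": [1.0]}))
        assert s == 50.0

    def test_too_many_missing_loci_gives_no_score(self, rng):
        loci = [f"l{i}" for i in range(44)]
        model = self._model(loci)
        cohort = pd.DataFrame(
            rng.integers(0, 3, (20, 44)).astype(float), columns=loci
        )
        subject = cohort.iloc[0].copy()
        subject.iloc[:16] = np.nan  # untyped at 16 > 15 loci
        assert risk_score(model, subject, cohort) is None
        subject2 = cohort.iloc[1].copy()
        subject2.iloc[:15] = np.nan
        assert risk_score(model, subject2, cohort) is not None


class TestCompareGroups:
    def test_identical_groups_near_one(self):
        out = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["wilcoxon_p"] >= 0.99
        assert out["ttest_p"] == pytest.approx(1.0)

    def test_exact_small_sample_values(self):
        """(1,2,3) vs (4,5,6): Welch p ~ 0.021, exact rank-sum p = 0.1."""
        out = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert out["ttest_p"] == pytest.approx(0.021, abs=0.002)
        assert out["wilcoxon_p"] == pytest.approx(0.1)
        assert out["mean_x"] == 2.0 and out["n_y"] == 3

    def test_power_of_both_tests_comparable(self, rng):
        """1-sd shift at n=31/31: rank-sum and t power within 10 points."""
        hits_w = hits_t = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(0, 1, 31)
            y = rng.normal(1, 1, 31)
            out = compare_groups(x, y)
            hits_w += out["wilcoxon_p"] < 0.05
            hits_t += out["ttest_p"] < 0.05
        assert abs(hits_w - hits_t) / reps < 0.10


class TestTreatmentScreen:
    def test_planted_shift_flagged_after_fdr(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            scores = pd.DataFrame(
                r.normal(0, 1, (40, 6)),
                index=[f"s{i}" for i in range(40)],
                columns=[f"sig{j}" for j in range(6)],
            )
            history = pd.DataFrame(
                {f"trt{j}": r.random(40) < 0.5 for j in range(3)},
                index=scores.index,
            )
            scores.loc[history["trt0"], "sig0"] += 2.0
            out = treatment_screen(scores, history)
            cell = out[(out["treatment"] == "trt0")
                       & (out["signature"] == "sig0")]
            hits += bool(cell["flag_fdr"].iloc[0])
        assert hits >= 19

    def test_constant_column_is_na(self, rng):
        scores = pd.DataFrame(
            {"flat": np.ones(10), "ok": rng.normal(0, 1, 10)},
            index=[f"s{i}" for i in range(10)],
        )
        history = pd.DataFrame({"trt": [True] * 5 + [False] * 5},
                               index=scores.index)
        out = treatment_screen(scores, history)
        flat = out[out["signature"] == "flat"]
        assert flat["p_raw"].isna().all()

    def test_degenerate_group_rejected(self, rng):
        scores = pd.DataFrame({"a": rng.normal(0, 1, 6)},
                              index=[f"s{i}" for i in range(6)])
        history = pd.DataFrame({"trt": [True] + [False] * 5},
                               index=scores.index)
        with pytest.raises(ValueError, match="trt"):
            treatment_screen(scores, history)


class TestCliffScan:
    def test_planted_frequency_shift_detected(self, rng):
        """A +0.2 tier frequency shift yields positive mean delta."""
        tiers = pd.Series(
            ["strong"] * 20 + ["weak"] * 20,
            index=[f"S{i:03d}" for i in range(1, 41)],
        )
        deltas = []
        for seed in range(60):
            geno = generate_genotypes(
                40, n_loci=4, planted=[("locus_01", "strong", 0.2)],
                seed=seed, tiers=tiers, missing_rate=0.0,
                training_scale=0.01,
            )
            out = cliff_scan(
                geno.cohort_table,
                [s for s in tiers.index if tiers[s] == "strong"],
                [s for s in tiers.index if tiers[s] == "weak"],
            )
            deltas.append(out.set_index("locus").loc["locus_01", "delta"])
        assert np.mean(deltas) > 0.1

    def test_null_deltas_centered_and_bounded(self, rng):
        """Null deltas at a 31/31 split center on 0 with sd ~ 0.15.

        The null sd of Cliff's delta is sqrt((n_x+n_y+1)/(3 n_x n_y))
        ~ 0.148 here, so ~95% of draws fall within +/-1.96 sd ~ 0.29.
        """
        tiers = pd.Series(
            ["strong"] * 31 + ["weak"] * 31,
            index=[f"S{i:03d}" for i in range(1, 63)],
        )
        deltas = []
        reps = 100
        for seed in range(reps):
            geno = generate_genotypes(
                62, n_loci=1, seed=seed + 1000, tiers=tiers,
                missing_rate=0.0, training_scale=0.01,
            )
            out = cliff_scan(
                geno.cohort_table, list(tiers.index[:31]),
                list(tiers.index[31:]),
            )
            deltas.append(out["delta"].iloc[0])
        assert abs(np.mean(deltas)) < 0.05
        assert np.mean(np.abs(deltas) < 0.29) >= 0.90


def test_risk_scores_vectorized_consistency(rng):
    geno = generate_genotypes(15, n_loci=6, seed=9, training_scale=0.05)
    model = fit_risk_model(geno.training_table)
    scores = risk_scores(model, geno.cohort_table)
    subj = geno.cohort_table.subjects[0]
    single = risk_score(model, geno.cohort_table.counts.loc[subj],
                        geno.cohort_table.counts)
    assert scores[subj] == pytest.approx(single)
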