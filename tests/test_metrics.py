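"""DMRSE, GCOSE and Seabird against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from methylnorm.datatypes import ValidationError
from methylnorm.metrics import (
    dmrse,
    evaluate_all,
    gcose,
    roc_auc,
    seabird,
    sex_difference_pvalues,
)
from methylnorm.normalize import apply_method

from .conftest import make_dataset
from .oracles import brute_force_auc, welch_t_pvalue


class TestDmrse:
    def test_constant_half_matrix_scores_zero(self):
        betas = np.full((5, 4), 0.5)
        assert dmrse(betas, np.ones(5, bool)) == 0.0

    def test_two_by_two_hand_computation(self):
        betas = np.array([[0.4, 0.6], [0.4, 0.6]])
        # pooled sd of {.4,.6,.4,.6} = 0.115470; / sqrt(2) = 0.081650
        assert dmrse(betas, np.ones(2, bool)) == pytest.approx(0.0816497, abs=1e-5)

    def test_duplicating_columns_scales_by_inverse_root_two(self):
        # pooled sd is unchanged (up to the ddof-1 finite-n factor), so the
        # metric shrinks by the sqrt of the sample-count ratio
        rng = np.random.default_rng(0)
        betas = rng.uniform(0.4, 0.6, (40, 5))
        doubled = np.hstack([betas, betas])
        mask = np.ones(40, bool)
        assert dmrse(doubled, mask) == pytest.approx(
            dmrse(betas, mask) / np.sqrt(2), rel=5e-3
        )

    def test_invariant_under_sample_and_probe_permutation(self):
        rng = np.random.default_rng(1)
        betas = rng.uniform(size=(8, 6))
        mask = np.zeros(8, bool)
        mask[[1, 4, 6]] = True
        base = dmrse(betas, mask)
        perm = rng.permutation(6)
        assert dmrse(betas[:, perm], mask) == pytest.approx(base)
        rperm = rng.permutation(8)
        assert dmrse(betas[rperm], mask[rperm]) == pytest.approx(base)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError, match="no iDMR"):
            dmrse(np.ones((3, 3)), np.zeros(3, bool))

    def test_row_and_col_modes_run(self):
        rng = np.random.default_rng(2)
        betas = rng.uniform(size=(6, 5))
        mask = np.ones(6, bool)
        for mode in ("row", "col"):
            assert dmrse(betas, mask, mode=mode) > 0.0


class TestGcose:
    def test_perfect_trimodal_scores_zero(self):
        betas = np.tile([0.0, 0.0, 0.5, 0.5, 1.0, 1.0], (4, 1))
        by_group, combined = gcose(betas, np.ones(4, bool))
        assert combined == 0.0
        assert all(v == 0.0 for v in by_group.values())

    def test_six_sample_worked_example(self):
        row = np.array([[0.05, 0.15, 0.45, 0.55, 0.85, 0.95]])
        by_group, combined = gcose(row, np.ones(1, bool))
        # per cluster SS = 0.005, n = 2; MS = 0.0025; / sqrt(6) each
        for v in by_group.values():
            assert v == pytest.approx(0.0025 / np.sqrt(6), abs=1e-9)
        assert combined == pytest.approx(0.0010206, abs=1e-6)

    def test_combined_is_mean_of_groups(self):
        rng = np.random.default_rng(3)
        betas = rng.uniform(size=(5, 12))
        by_group, combined = gcose(betas, np.ones(5, bool))
        assert combined == pytest.approx(np.mean(list(by_group.values())))

    def test_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(4)
        betas = rng.uniform(size=(4, 10))
        _, base = gcose(betas, np.ones(4, bool))
        _, permuted = gcose(betas[:, rng.permutation(10)], np.ones(4, bool))
        assert permuted == pytest.approx(base)

    def test_degenerate_probe_contributes_reduced_clusters(self):
        betas = np.vstack(
            [
                np.full(6, 0.5),  # single distinct value
                [0.05, 0.15, 0.45, 0.55, 0.85, 0.95],
            ]
        )
        by_group, combined = gcose(betas, np.ones(2, bool))
        assert np.isfinite(combined) and combined >= 0.0

    def test_monotone_in_cluster_noise(self):
        rng = np.random.default_rng(5)
        centers = np.tile([0.1, 0.1, 0.5, 0.5, 0.9, 0.9], (10, 1))
        scores = []
        for sd in (0.005, 0.02, 0.05):
            noisy = np.clip(centers + rng.normal(0, sd, centers.shape), 0, 1)
            scores.append(gcose(noisy, np.ones(10, bool))[1])
        assert scores[0] < scores[1] < scores[2]

    def test_needs_snp_probes_and_samples(self):
        with pytest.raises(ValidationError, match="no SNP"):
            gcose(np.ones((3, 6)), np.zeros(3, bool))
        with pytest.raises(ValidationError, match=">= 3 samples"):
            gcose(np.ones((3, 2)), np.ones(3, bool))


class TestSexDifference:
    def test_identical_groups_give_p_one(self):
        betas = np.tile([0.3, 0.3, 0.3, 0.3], (2, 1))
        sexes = ["male", "male", "female", "female"]
        np.testing.assert_allclose(sex_difference_pvalues(betas, sexes), 1.0)

    def test_complete_separation_is_significant(self):
        rng = np.random.default_rng(6)
        male = rng.normal(0.2, 0.01, (1, 20))
        female = rng.normal(0.8, 0.01, (1, 20))
        betas = np.hstack([male, female])
        sexes = ["male"] * 20 + ["female"] * 20
        assert sex_difference_pvalues(betas, sexes)[0] < 1e-6

    def test_matches_welch_oracle(self):
        rng = np.random.default_rng(7)
        betas = rng.uniform(size=(10, 7))
        sexes = ["male"] * 3 + ["female"] * 4
        p = sex_difference_pvalues(betas, sexes)
        for i in range(10):
            expected = welch_t_pvalue(betas[i, :3], betas[i, 3:])
            assert p[i] == pytest.approx(expected, abs=1e-8)

    def test_single_sex_rejected(self):
        with pytest.raises(ValidationError, match="redundant"):
            sex_difference_pvalues(np.ones((2, 4)), ["male"] * 4)


class TestSeabird:
    def test_perfect_predictor_scores_zero(self):
        pvalues = np.array([0.001, 0.2, 0.01, 0.9])
        chrom = np.array(["X", "1", "X", "2"])
        assert seabird(
            np.empty((4, 0)), chromosomes=chrom, pvalues=pvalues
        ) == pytest.approx(0.0)

    def test_antisymmetry_of_auc(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        positives = rng.random(40) < 0.3
        assert roc_auc(scores, positives) == pytest.approx(
            1.0 - roc_auc(-scores, positives)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        pvalues = rng.uniform(size=n)
        ties = rng.random(n) < 0.2  # exercise average-rank tie handling
        pvalues[ties] = rng.choice([0.1, 0.5], size=int(ties.sum()))
        chrom = np.where(rng.random(n) < 0.3, "X", "5")
        result = seabird(np.empty((n, 0)), chromosomes=chrom, pvalues=pvalues)
        expected = 1.0 - brute_force_auc(-pvalues, chrom == "X")
        assert result == pytest.approx(expected, abs=1e-12)

    def test_null_permutations_center_on_half(self):
        rng = np.random.default_rng(9)
        betas = rng.uniform(size=(120, 16))
        chrom = np.array(["X"] * 40 + ["2"] * 80)
        sexes = np.array(["male"] * 8 + ["female"] * 8)
        vals = []
        for _ in range(50):
            vals.append(seabird(betas, sexes=rng.permutation(sexes), chromosomes=chrom))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.06)

    def test_requires_both_classes(self):
        with pytest.raises(ValidationError):
            seabird(np.empty((3, 0)), chromosomes=np.array(["X", "X", "X"]),
                    pvalues=np.array([0.1, 0.2, 0.3]))

    def test_exclude_y_drops_y_probes_from_negatives(self):
        pvalues = np.array([0.001, 0.0005, 0.9])
        chrom = np.array(["X", "Y", "1"])
        with_y = seabird(np.empty((3, 0)), chromosomes=chrom, pvalues=pvalues)
        without_y = seabird(
            np.empty((3, 0)), chromosomes=chrom, pvalues=pvalues, include_y=False
        )
        assert with_y > without_y  # the small-p Y probe outranks X only when kept


class TestEvaluateAll:
    def test_cardinality_and_composition(self, small_sim):
        dataset, _ = small_sim
        betas = {name: apply_method(dataset, name) for name in ("raw", "nasen")}
        reports = evaluate_all(betas, dataset_id="d0")
        assert len(reports) == 4
        assert {(r.method, r.assay_type) for r in reports} == {
            ("raw", "I"), ("raw", "II"), ("nasen", "I"), ("nasen", "II"),
        }
        # the raw Type II report matches direct metric calls on the subset
        raw2 = next(r for r in reports if r.method == "raw" and r.assay_type == "II")
        mask = (dataset.probes["AssayType"] == "II").to_numpy()
        sub = betas["raw"].values.to_numpy()[mask]
        manifest = dataset.probes.loc[mask]
        assert raw2.dmrse == pytest.approx(dmrse(sub, manifest["IsIDMR"].to_numpy()))
        assert raw2.gcose == pytest.approx(
            gcose(sub, manifest["IsSNP"].to_numpy())[1]
        )
        assert raw2.gcose == pytest.approx(np.mean(list(raw2.gcose_by_group.values())))

    def test_failing_metric_recorded_not_raised(self, small_sim):
        dataset, _ = small_sim
        single_sex = dataset.samples.copy()
        single_sex["Sex"] = "male"
        betas = {"raw": apply_method(dataset, "raw")}
        reports = evaluate_all(betas, sexes=single_sex["Sex"], dataset_id="d0")
        assert all(r.seabird is None for r in reports)
        assert all(any("seabird" in note for note in r.notes) for r in reports)
        assert all(r.dmrse is not None for r in reports)
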