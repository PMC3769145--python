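"""Beta arithmetic, the method registry and the sklearn-style transformer."""

import numpy as np
import pytest
from sklearn.base import clone

from methylnorm.datatypes import METHOD_NAMES, MethodSpec, ValidationError
from methylnorm.normalize import (
    MethylationNormalizer,
    apply_method,
    beta_to_m,
    compute_beta,
    intensity_to_m,
    m_to_beta,
    normalize_intensities,
)
from methylnorm.qn import quantile_normalize

from .conftest import make_dataset
from .oracles import naive_quantile_normalize

QN_METHODS = [name for name in METHOD_NAMES if name not in ("raw", "danen")]


class TestBetaArithmetic:
    @pytest.mark.parametrize(
        "m,u,alpha,expected",
        [(900.0, 0.0, 100.0, 0.9), (0.0, 0.0, 100.0, 0.0), (450.0, 450.0, 100.0, 0.45)],
    )
    def test_beta_closed_forms(self, m, u, alpha, expected):
        dataset = make_dataset([[m]], [[u]], ["II"])
        assert compute_beta(dataset, alpha).values.iloc[0, 0] == pytest.approx(expected)

    def test_zero_alpha_with_zero_signal_names_the_cell(self):
        dataset = make_dataset([[0.0, 1.0]], [[0.0, 1.0]], ["II"])
        with pytest.raises(ValidationError, match="cg00000.*S0"):
            compute_beta(dataset, alpha=0.0)

    @pytest.mark.parametrize("beta,expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_m_value_from_beta(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected)
        assert m_to_beta(expected) == pytest.approx(beta)

    def test_m_value_domain(self):
        with pytest.raises(ValidationError):
            beta_to_m(0.0)
        with pytest.raises(ValidationError):
            beta_to_m(1.0)

    @pytest.mark.parametrize(
        "m,u,expected", [(300.0, 300.0, 0.0), (700.0, 100.0, 2.0), (0.0, 0.0, 0.0)]
    )
    def test_m_value_from_intensities(self, m, u, expected):
        assert intensity_to_m(m, u, 100.0) == pytest.approx(expected)

    def test_m_value_monotone_in_beta(self):
        betas = np.linspace(0.01, 0.99, 50)
        assert np.all(np.diff(beta_to_m(betas)) > 0)


class TestApplyMethod:
    def test_raw_equals_compute_beta(self, small_sim):
        dataset, _ = small_sim
        raw = apply_method(dataset, "raw")
        direct = compute_beta(dataset, 100.0)
        np.testing.assert_allclose(raw.values.to_numpy(), direct.values.to_numpy())

    def test_dasen_is_identity_when_types_and_samples_already_match(self):
        # two identical samples whose Type I and Type II rows carry the same
        # value multiset per channel: offsets are exactly 0 and QN of
        # identical distributions changes nothing
        rng = np.random.default_rng(0)
        vals = rng.uniform(50, 5000, 40)
        meth = np.column_stack([vals, vals])
        unmeth = np.column_stack([vals[::-1], vals[::-1]])
        types = ["I"] * 20 + ["II"] * 20
        # type II rows mirror the type I value multiset
        meth[20:] = meth[:20]
        unmeth[20:] = unmeth[:20]
        dataset = make_dataset(meth, unmeth, types)
        out = apply_method(dataset, "dasen")
        raw = apply_method(dataset, "raw")
        np.testing.assert_allclose(
            out.values.to_numpy(), raw.values.to_numpy(), atol=1e-9
        )

    def test_naten_matches_hand_quantile_normalization(self):
        rng = np.random.default_rng(3)
        meth = rng.uniform(10, 1000, (4, 2))
        unmeth = rng.uniform(10, 1000, (4, 2))
        dataset = make_dataset(meth, unmeth, ["II"] * 4)
        out = apply_method(dataset, "naten")
        mq = naive_quantile_normalize(meth)
        uq = naive_quantile_normalize(unmeth)
        expected = mq / (mq + uq + 100.0)
        np.testing.assert_allclose(out.values.to_numpy(), expected, atol=1e-10)

    @pytest.mark.parametrize("name", METHOD_NAMES)
    def test_output_always_within_unit_interval(self, small_sim, name):
        dataset, _ = small_sim
        out = apply_method(dataset, name)
        vals = out.values.to_numpy()
        assert np.isfinite(vals).all() and vals.min() >= 0.0 and vals.max() <= 1.0

    def test_betaqn_preserves_within_sample_rank_order(self, small_sim):
        dataset, _ = small_sim
        raw = apply_method(dataset, "raw").values.to_numpy()
        qn = apply_method(dataset, "betaqn").values.to_numpy()
        for j in range(raw.shape[1]):
            assert np.array_equal(np.argsort(raw[:, j]), np.argsort(qn[:, j]))

    def test_unknown_method_lists_valid_names(self):
        with pytest.raises(ValidationError, match="dasen"):
            MethodSpec.from_name("nosuch")

    def test_qn_methods_need_two_samples(self):
        dataset = make_dataset([[1.0], [2.0]], [[3.0], [4.0]], ["I", "II"])
        with pytest.raises(ValidationError, match=">= 2 samples"):
            apply_method(dataset, "nasen")
        with pytest.raises(ValidationError, match=">= 2 samples"):
            apply_method(dataset, "betaqn")

    def test_normalized_groups_share_distributions(self):
        """After any intensity-QN method the sorted per-sample values agree
        within each normalized row group (tie-free input: with within-column
        ties the mean-of-reference tie rule trades exact distribution
        equality for rank fidelity)."""
        rng = np.random.default_rng(12)
        meth = rng.uniform(10, 8000, (120, 5))
        unmeth = rng.uniform(10, 8000, (120, 5))
        dataset = make_dataset(meth, unmeth, ["I"] * 60 + ["II"] * 60)
        type2 = (dataset.probes["AssayType"] == "II").to_numpy()
        for name in ("naten", "nasen", "nanet", "nanes"):
            spec = MethodSpec.from_name(name)
            norm = normalize_intensities(dataset, spec)
            if spec.between_array_qn.endswith("types_together"):
                groups = [np.ones_like(type2, dtype=bool)]
            else:
                groups = [~type2, type2]
            for mask in groups:
                if spec.between_array_qn.startswith("MU_together"):
                    pooled = np.hstack(
                        [norm.methylated.to_numpy()[mask], norm.unmethylated.to_numpy()[mask]]
                    )
                    mats = [pooled]
                else:
                    mats = [norm.methylated.to_numpy()[mask], norm.unmethylated.to_numpy()[mask]]
                for mat in mats:
                    ref = np.sort(mat[:, 0])
                    for j in range(mat.shape[1]):
                        np.testing.assert_allclose(np.sort(mat[:, j]), ref, atol=1e-9)


class TestMethylationNormalizer:
    def test_params_round_trip_and_clone(self):
        est = MethylationNormalizer(method="nasen", alpha=50.0)
        params = est.get_params()
        assert params["method"] == "nasen" and params["alpha"] == 50.0
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(method="dasen")
        assert est.method == "dasen"

    def test_fit_transform_matches_apply_method(self, small_sim):
        dataset, _ = small_sim
        est = MethylationNormalizer(method="nasen").fit(dataset)
        out = est.transform(dataset)
        expected = apply_method(dataset, "nasen")
        np.testing.assert_allclose(
            out.values.to_numpy(), expected.values.to_numpy(), atol=1e-12
        )

    def test_transform_before_fit_rejected(self, small_sim):
        dataset, _ = small_sim
        with pytest.raises(ValidationError, match="not fitted"):
            MethylationNormalizer().transform(dataset)

    def test_offsets_recorded_for_background_methods(self, small_sim):
        dataset, _ = small_sim
        est = MethylationNormalizer(method="danen").fit(dataset)
        est.transform(dataset)
        assert est.offsets_ is not None
        assert set(est.offsets_.per_sample_channel.index) == set(dataset.samples.index)
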