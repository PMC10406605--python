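"""Footprint operator, observation components and explanatory power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

import resptemp as rt
from resptemp.exceptions import GridMismatchError, ParameterError, UndefinedR2Error
from resptemp.transport import OBS_COLUMNS, biospheric_signal


def random_operator(rng, n_obs=5, shape=(3, 4, 5), density=0.3):
    mat = sparse.random(n_obs, int(np.prod(shape)), density=density, random_state=rng,
                        data_rvs=lambda n: rng.uniform(0.01, 1.0, n))
    mat = sparse.csr_matrix(mat)
    # guarantee every observation at least one entry
    for i in np.flatnonzero(np.diff(mat.indptr) == 0):
        mat[i, rng.integers(0, mat.shape[1])] = 0.5
    return rt.FootprintOperator(sparse.csr_matrix(mat), shape)


def obs_from_signal(signal, background=400.0, fossil=1.5):
    n = len(signal)
    return pd.DataFrame({
        "obs_id": [f"o{i}" for i in range(n)],
        "site_id": "T01",
        "time_index": np.arange(n) % 3,
        "raw_ppm": signal + background + fossil,
        "background_ppm": background,
        "fossil_ppm": fossil,
        "biospheric_ppm": signal,
    })[OBS_COLUMNS]


class TestTransport:
    def test_single_entry_unit_sensitivity(self):
        H = rt.FootprintOperator(sparse.csr_matrix(np.array([[1.0, 0.0]])), (1, 1, 2))
        flux = rt.gridded_field([[[2.0, 7.0]]], [45.5], [0.0, 1.0], "umol m-2 s-1")
        assert rt.transport_signal(H, flux) == pytest.approx([2.0])

    def test_matches_triple_loop_oracle(self, rng):
        shape = (3, 4, 5)
        H = random_operator(rng, n_obs=5, shape=shape)
        flux = rng.normal(0, 2, shape)
        table = H.to_table()
        expect = np.zeros(5)
        for _, row in table.iterrows():   # brute force: sum entry by entry
            expect[int(row.obs_index)] += row.sensitivity * flux[
                int(row.time_index), int(row.lat_index), int(row.lon_index)]
        got = H.transport(rt.gridded_field(flux, np.arange(4), np.arange(5), "f"))
        np.testing.assert_allclose(got, expect, atol=1e-12)

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 100))
    @settings(deadline=None, max_examples=25)
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        H = random_operator(rng)
        f1, f2 = rng.normal(size=(2, 3, 4, 5))
        lhs = H.transport(a * f1 + b * f2)
        rhs = a * H.transport(f1) + b * H.transport(f2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_entry_order_irrelevant(self, rng):
        H = random_operator(rng)
        table = H.to_table().sample(frac=1.0, random_state=0)
        H2 = rt.FootprintOperator.from_table(table, H.grid_shape, n_obs=H.n_obs)
        flux = rng.normal(size=(3, 4, 5))
        np.testing.assert_allclose(H.transport(flux), H2.transport(flux), atol=0)

    def test_grid_mismatch_raises(self, rng):
        H = random_operator(rng)
        with pytest.raises(GridMismatchError):
            H.transport(np.zeros((2, 4, 5)))

    def test_invariants_enforced(self):
        with pytest.raises(ParameterError):
            rt.FootprintOperator(sparse.csr_matrix(np.array([[-1.0, 0.0]])), (1, 1, 2))
        with pytest.raises(ParameterError):
            rt.FootprintOperator(sparse.csr_matrix(np.zeros((2, 2))), (1, 1, 2))

    def test_tabular_roundtrip(self, tmp_path, rng):
        H = random_operator(rng)
        H.save(tmp_path / "fp.csv", tmp_path / "fp.json")
        H2 = rt.FootprintOperator.load(tmp_path / "fp.csv", tmp_path / "fp.json")
        assert (H.matrix != H2.matrix).nnz == 0
        assert H2.grid_shape == H.grid_shape


class TestRespiratoryComponent:
    def test_equals_transported_respiration_without_noise(self, noiseless_world):
        w = noiseless_world
        y = rt.respiratory_component(w.obs, w.footprints, w.gpp)
        np.testing.assert_allclose(y, w.footprints.transport(w.re), rtol=1e-10)

    def test_zero_gpp_returns_biospheric_signal(self, noiseless_world):
        w = noiseless_world
        y = rt.respiratory_component(w.obs, w.footprints, w.gpp * 0.0)
        np.testing.assert_allclose(y, biospheric_signal(w.obs), atol=0)

    def test_missing_gpp_rejected(self, noiseless_world):
        with pytest.raises(ParameterError):
            rt.respiratory_component(noiseless_world.obs, noiseless_world.footprints, None)

    def test_residual_noise_matches_generator_sigma(self, default_world):
        w = default_world
        resid = rt.respiratory_component(w.obs, w.footprints, w.gpp) \
            - w.footprints.transport(w.re)
        assert resid.std() == pytest.approx(w.config.noise_ppm, rel=0.1)


class TestExplanatoryPower:
    def test_perfect_and_sign_flipped_signals(self, rng):
        y = rng.normal(size=50)
        assert rt.explanatory_power(y, y) == pytest.approx(1.0, abs=1e-12)
        assert rt.explanatory_power(-y, y) == pytest.approx(1.0, abs=1e-12)

    def test_hand_formula_oracle(self):
        assert rt.explanatory_power(np.array([1.0, 2, 3, 5]), np.array([2.0, 3, 5, 9])) \
            == pytest.approx(0.986086956521739, rel=1e-12)

    @given(a=st.floats(-10, 10), b=st.floats(0.01, 10))
    @settings(deadline=None, max_examples=25)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=(2, 40))
        base = rt.explanatory_power(x, y)
        assert rt.explanatory_power(a + b * x, y) == pytest.approx(base, abs=1e-9)
        assert rt.explanatory_power(a - b * x, y) == pytest.approx(base, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedR2Error):
            rt.explanatory_power(np.ones(5), np.arange(5.0))

    def test_regression_method_penalizes_offsets(self, rng):
        y = rng.normal(size=30)
        assert rt.explanatory_power(y, y, method="regression") == pytest.approx(1.0)
        assert rt.explanatory_power(y + 5.0, y, method="regression") < 0.0


class TestSWBenchmark:
    def test_gate_equals_gpp_r2_when_sw_proportional(self):
        # pure-uptake world: observations carry only the GPP signal, and SW
        # proportional to GPP transports to an identical (rescaled) signal
        cfg = rt.small_world_config(noise_ppm=0.0)
        w = rt.generate_world(cfg)
        sw_prop = w.gpp * 3.7
        obs = w.obs.copy()
        gpp_sig = w.footprints.transport(w.gpp)
        obs["biospheric_ppm"] = -gpp_sig
        y = biospheric_signal(obs_from_signal(-gpp_sig))
        gate = rt.sw_benchmark(w.footprints, sw_prop, y)
        r2_gpp = rt.explanatory_power(gpp_sig, y)
        assert gate == pytest.approx(r2_gpp, abs=1e-12)

    def test_constant_sw_field_rejected(self, small_world):
        w = small_world
        const = w.sw.copy(data=np.full(w.sw.shape, 200.0))
        with pytest.raises(UndefinedR2Error):
            rt.sw_benchmark(w.footprints, const, biospheric_signal(w.obs))

    def test_gate_reproducible_across_reruns(self):
        vals = []
        for _ in range(2):
            w = rt.generate_world(rt.WorldConfig())
            vals.append(rt.sw_benchmark(w.footprints, w.sw, biospheric_signal(w.obs)))
        assert vals[0] == vals[1]


class TestModelEvaluation:
    def test_correct_model_explains_noise_free_obs_perfectly(self, noiseless_world):
        w = noiseless_world
        res = rt.evaluate_model("truth", w.gpp, w.nee, w.footprints, w.obs, sw=w.sw)
        assert res.r2_nee == pytest.approx(1.0, abs=1e-10)
        assert res.delta_r2 == pytest.approx(res.r2_nee - res.r2_gpp, abs=0)
        assert res.pass_sw_gate_nee
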