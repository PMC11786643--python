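import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effconn import connectivity as conn
from effconn import mvar, simulate
from effconn.errors import ValidationError

from conftest import make_window

GRID = conn.default_freq_grid()


def _random_stable_model(seed, m=None, order=None, fs=128.0):
    rng = np.random.default_rng(seed)
    m = m or int(rng.integers(2, 7))
    order = order or int(rng.integers(1, 4))
    A = simulate.rescale_to_stable(rng.standard_normal((order, m, m)) * 0.3,
                                   max_radius=0.95)
    return mvar.MVARModel(order=order, A=A, sigma=np.eye(m), fs=fs)


class TestSpectralCoefficients:
    def test_hand_example_at_zero(self, bivar_var1_model):
        st = conn.spectral_coefficients(bivar_var1_model, np.array([0.0]))
        np.testing.assert_allclose(st.Abar[0], [[0.5, 0.0], [-0.4, 0.5]], atol=1e-12)
        np.testing.assert_allclose(st.H[0], [[2.0, 0.0], [1.6, 2.0]], atol=1e-12)

    def test_zero_coefficients_identity(self):
        model = mvar.MVARModel(order=2, A=np.zeros((2, 3, 3)), sigma=np.eye(3),
                               fs=128.0)
        st = conn.spectral_coefficients(model, GRID)
        eye = np.broadcast_to(np.eye(3), (len(GRID), 3, 3))
        np.testing.assert_allclose(st.Abar, eye, atol=1e-12)
        np.testing.assert_allclose(st.H, eye, atol=1e-12)

    def test_abar_at_dc_equals_i_minus_sum(self):
        model = _random_stable_model(0)
        st = conn.spectral_coefficients(model, np.array([0.0]))
        np.testing.assert_allclose(
            st.Abar[0], np.eye(model.n_channels) - model.A.sum(axis=0), atol=1e-14)

    @pytest.mark.parametrize("seed", range(10))
    def test_inverse_consistency(self, seed):
        model = _random_stable_model(seed)
        st = conn.spectral_coefficients(model, GRID)
        eye = np.eye(model.n_channels)[None]
        assert np.abs(st.Abar @ st.H - eye).max() < 1e-8

    def test_frequency_out_of_range(self, bivar_var1_model):
        with pytest.raises(ValidationError):
            conn.spectral_coefficients(bivar_var1_model, np.array([100.0]))

    def test_unit_root_singular(self):
        model = mvar.MVARModel(order=1, A=np.eye(2)[None], sigma=np.eye(2), fs=128.0)
        with pytest.raises(ValidationError, match="singular"):
            conn.spectral_coefficients(model, np.array([0.0]))


class TestPDC:
    def test_hand_values(self, bivar_var1_model):
        st = conn.spectral_coefficients(bivar_var1_model, np.array([0.0]))
        p = conn.pdc(st)[0]
        assert p[1, 0] == pytest.approx(0.4 / np.sqrt(0.41), abs=1e-10)
        assert p[0, 0] == pytest.approx(0.5 / np.sqrt(0.41), abs=1e-10)
        assert p[0, 1] == 0.0

    def test_structural_zero(self, bivar_var1_model):
        st = conn.spectral_coefficients(bivar_var1_model, GRID)
        assert np.all(conn.pdc(st)[:, 0, 1] == 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_column_normalization(self, seed):
        st = conn.spectral_coefficients(_random_stable_model(seed), GRID)
        p = conn.pdc(st)
        np.testing.assert_allclose((p**2).sum(axis=1), 1.0, atol=1e-10)

    def test_squared_variant(self, bivar_var1_model):
        st = conn.spectral_coefficients(bivar_var1_model, np.array([0.0]))
        np.testing.assert_allclose(conn.pdc(st, squared=True), conn.pdc(st) ** 2)


class TestDTF:
    def test_hand_values(self, bivar_var1_model):
        st = conn.spectral_coefficients(bivar_var1_model, np.array([0.0]))
        d = conn.dtf(st)[0]
        assert d[1, 0] == pytest.approx(1.6 / np.sqrt(6.56), abs=1e-10)
        assert d[1, 1] == pytest.approx(2.0 / np.sqrt(6.56), abs=1e-10)
        assert d[0, 1] == 0.0

    def test_identity_transfer(self):
        model = mvar.MVARModel(order=1, A=np.zeros((1, 4, 4)), sigma=np.eye(4),
                               fs=128.0)
        st = conn.spectral_coefficients(model, GRID)
        d = conn.dtf(st)
        np.testing.assert_allclose(d, np.eye(4)[None] * np.ones((len(GRID), 1, 1)),
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_row_normalization(self, seed):
        st = conn.spectral_coefficients(_random_stable_model(seed), GRID)
        d = conn.dtf(st)
        np.testing.assert_allclose((d**2).sum(axis=2), 1.0, atol=1e-10)

    def test_acyclic_structural_zeros(self):
        # lower-triangular coupling: H inherits the zero upper triangle
        A = np.zeros((1, 3, 3))
        A[0] = [[0.5, 0, 0], [0.4, 0.5, 0], [0.2, 0.4, 0.5]]
        model = mvar.MVARModel(order=1, A=A, sigma=np.eye(3), fs=128.0)
        st = conn.spectral_coefficients(model, GRID)
        d = conn.dtf(st)
        iu = np.triu_indices(3, k=1)
        assert np.abs(d[:, iu[0], iu[1]]).max() < 1e-12


class TestNormalizationProperties:
    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), m=st.integers(2, 6), order=st.integers(1, 3))
    def test_pdc_dtf_normalizations_hold(self, seed, m, order):
        rng = np.random.default_rng(seed)
        A = simulate.rescale_to_stable(rng.standard_normal((order, m, m)) * 0.3,
                                       max_radius=0.95)
        model = mvar.MVARModel(order=order, A=A, sigma=np.eye(m), fs=128.0)
        st_ = conn.spectral_coefficients(model, GRID)
        p = conn.pdc(st_)
        d = conn.dtf(st_)
        assert np.abs((p**2).sum(axis=1) - 1.0).max() < 1e-10
        assert np.abs((d**2).sum(axis=2) - 1.0).max() < 1e-10
        assert p.min() >= 0.0 and p.max() <= 1.0 + 1e-12
        assert d.min() >= 0.0 and d.max() <= 1.0 + 1e-12


class TestGrangerPairwise:
    def test_analytic_value(self):
        # y(n) = 0.9 x(n-1) + e: restricted var(y)=1.81, full=1 -> GC = ln 1.81
        vals, rev = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 10_000
            e = rng.standard_normal((2, n))
            x = e[0]
            y = np.zeros(n)
            y[1:] = 0.9 * x[:-1]
            y += e[1]
            win = make_window(np.vstack([x, y]))
            gc = conn.granger_pairwise(win, order=5)
            vals.append(gc[1, 0])
            rev.append(gc[0, 1])
        assert np.median(vals) == pytest.approx(np.log(1.81), abs=0.05)
        assert np.median(rev) < 0.01

    def test_independent_channels_null(self):
        both = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            win = make_window(rng.standard_normal((2, 10_000)))
            gc = conn.granger_pairwise(win, order=5)
            both.extend([gc[0, 1], gc[1, 0]])
        assert np.median(both) < 0.01

    def test_diagonal_zero_and_nonnegative(self):
        rng = np.random.default_rng(2)
        win = make_window(rng.standard_normal((3, 2000)))
        gc = conn.granger_pairwise(win, order=3)
        assert np.all(np.diag(gc) == 0.0)
        assert np.all(gc >= 0.0)


class TestBandAverage:
    def test_constant_stack(self):
        stack = np.tile(np.array([[1.0, 2.0], [3.0, 4.0]]), (len(GRID), 1, 1))
        cm = conn.band_average(stack, conn.BANDS["alpha"], GRID, method="DTF")
        np.testing.assert_allclose(cm.values, [[1.0, 2.0], [3.0, 4.0]])
        assert cm.band == "alpha"

    def test_brute_force_oracle(self, bivar_var1_model):
        st = conn.spectral_coefficients(bivar_var1_model, GRID)
        stack = conn.pdc(st)
        cm = conn.band_average(stack, conn.BANDS["alpha"], GRID, method="PDC")
        expected = np.mean(
            [stack[k] for k, f in enumerate(GRID) if 8.0 <= f < 13.0], axis=0)
        np.testing.assert_allclose(cm.values, expected, atol=1e-14)

    def test_disjoint_band_error(self):
        stack = np.zeros((len(GRID), 2, 2))
        with pytest.raises(ValidationError):
            conn.band_average(stack, conn.BandDefinition("x", 80.0, 90.0), GRID)


class TestWindowConnectivity:
    def test_35ch_dtf_five_bands(self, canonical_recording):
        win = make_window(canonical_recording.samples[:, :640],
                          labels=canonical_recording.labels,
                          kinds=canonical_recording.kinds)
        out = conn.window_connectivity(win, "DTF")
        assert len(out) == 5
        assert {cm.band for cm in out} == set(conn.BANDS)
        for cm in out:
            assert cm.values.shape == (35, 35)
            assert cm.values.min() >= 0.0 and cm.values.max() <= 1.0

    def test_small_m_warning(self, caplog):
        rng = np.random.default_rng(3)
        win = make_window(rng.standard_normal((2, 640)))
        with caplog.at_level("WARNING"):
            out = conn.window_connectivity(win, "PDC", [conn.BANDS["alpha"]],
                                           conn.ConnectivityConfig(order=5))
        assert out[0].values.shape == (2, 2)
        assert "montage" in caplog.text or "canonical" in caplog.text

    def test_gc_delegation(self):
        rng = np.random.default_rng(4)
        win = make_window(rng.standard_normal((2, 2000)))
        band = conn.BandDefinition("broad", 0.5, 45.0)
        cfg = conn.ConnectivityConfig(order=5)
        out = conn.window_connectivity(win, "GC", [band], cfg)
        direct = conn.granger_pairwise(win, order=5, band=band)
        np.testing.assert_allclose(out[0].values, direct)

    def test_unknown_method(self):
        win = make_window(np.zeros((2, 640)))
        with pytest.raises(ValidationError):
            conn.window_connectivity(win, "PLV")

    def test_save_load_round_trip(self, tmp_path, canonical_recording):
        win = make_window(canonical_recording.samples[:, :640],
                          labels=canonical_recording.labels,
                          kinds=canonical_recording.kinds,
                          emotion="fear", subject_id="s9")
        out = conn.window_connectivity(win, "PDC", [conn.BANDS["alpha"]])
        path = tmp_path / "conn.npz"
        conn.save_connectivity(path, out)
        back = conn.load_connectivity(path)
        assert len(back) == len(out)
        np.testing.assert_array_equal(back[0].values, out[0].values)
        assert back[0].labels == out[0].labels
        assert back[0].meta["emotion"] == "fear"
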