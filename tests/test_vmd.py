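import numpy as np
import pytest

from semgdenoise.signal_model import Signal
from semgdenoise.vmd import ModeSet, VMDParams, reconstruct, vmd_decompose

from .conftest import FS


def fft_peak_hz(x: np.ndarray, fs: float) -> float:
    """Independent oracle: dominant rfft bin frequency."""
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    return float(freqs[int(np.argmax(spec))])


def band_energy(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    return float(spec[(freqs >= lo) & (freqs <= hi)].sum())


@pytest.fixture(scope="module")
def two_tone_modes(two_tone):
    return vmd_decompose(two_tone, VMDParams(K=2, alpha=2000.0))


class TestTwoToneDecomposition:
    def test_center_frequencies_recovered(self, two_tone_modes):
        assert abs(two_tone_modes.omega[0] - 50.0) < 2.0
        assert abs(two_tone_modes.omega[1] - 200.0) < 2.0

    def test_mode_fft_peak_matches_omega(self, two_tone_modes):
        for mode, w in zip(two_tone_modes.modes, two_tone_modes.omega):
            assert abs(fft_peak_hz(mode, two_tone_modes.fs) - w) < 2.0

    def test_reconstruction_error_small(self, two_tone, two_tone_modes):
        rec = reconstruct(two_tone_modes)
        rel = np.linalg.norm(two_tone.samples - rec) / np.linalg.norm(two_tone.samples)
        assert rel < 0.05

    def test_cross_mode_leakage_small(self, two_tone_modes):
        low_mode = two_tone_modes.modes[0]
        leak = band_energy(low_mode, FS, 190, 210)
        total = float(np.dot(low_mode, low_mode))
        assert leak < 0.05 * total

    def test_omega_sorted_and_in_range(self, two_tone_modes):
        w = two_tone_modes.omega
        assert np.all(np.diff(w) >= 0)
        assert np.all((w >= 0) & (w < FS / 2))


class TestAnalyticLimits:
    def test_constant_signal_single_dc_mode(self):
        c = 2.5
        s = Signal(np.full(3000, c), FS)
        ms = vmd_decompose(s, VMDParams(K=1, alpha=2000.0))
        rel = np.linalg.norm(ms.modes[0] - c) / np.linalg.norm(s.samples)
        assert rel < 1e-2
        assert ms.omega[0] < 1.0

    def test_alpha_never_widens_bandwidth(self, two_tone):
        """Doubling the penalty must not increase any mode's second
        spectral moment (bandwidth) on the two-tone probe."""

        def moments(alpha):
            ms = vmd_decompose(two_tone, VMDParams(K=2, alpha=alpha))
            out = []
            for mode, w in zip(ms.modes, ms.omega):
                spec = np.abs(np.fft.rfft(mode)) ** 2
                freqs = np.fft.rfftfreq(mode.size, 1 / FS)
                out.append(np.sum((freqs - w) ** 2 * spec) / np.sum(spec))
            return np.array(out)

        m_lo, m_hi = moments(1000.0), moments(2000.0)
        assert np.all(m_hi <= m_lo * (1 + 1e-6))

    def test_residual_decreases_with_dual_ascent(self, two_tone):
        """With tau > 0 the reconstruction residual shrinks monotonically
        over the final iterations (exact-reconstruction constraint)."""
        caps = range(8, 26)
        residuals = []
        for cap in caps:
            ms = vmd_decompose(
                two_tone, VMDParams(K=2, alpha=2000.0, tau=0.5, max_iter=cap,
                                    tol=1e-14)
            )
            rec = reconstruct(ms)
            residuals.append(
                np.linalg.norm(two_tone.samples - rec) / np.linalg.norm(two_tone.samples)
            )
        last = np.array(residuals[-10:])
        assert np.all(np.diff(last) <= 1e-8)


class TestContracts:
    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            vmd_decompose(Signal(np.arange(10.0), FS), VMDParams(K=6, alpha=500.0))

    @pytest.mark.parametrize(
        "kwargs",
        [dict(K=0, alpha=1.0), dict(K=2, alpha=0.0), dict(K=2, alpha=1.0, tau=-1.0),
         dict(K=2, alpha=1.0, tol=0.0), dict(K=2, alpha=1.0, max_iter=0)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VMDParams(**kwargs)

    def test_determinism(self, two_tone):
        a = vmd_decompose(two_tone, VMDParams(K=3, alpha=1000.0, max_iter=50))
        b = vmd_decompose(two_tone, VMDParams(K=3, alpha=1000.0, max_iter=50))
        assert np.array_equal(a.modes, b.modes)
        assert np.array_equal(a.omega, b.omega)


class TestReconstruct:
    def test_single_mode_identity(self):
        m = np.sin(np.linspace(0, 10, 100))[None, :]
        ms = ModeSet(m, np.array([1.0]), FS, 1, True)
        assert np.array_equal(reconstruct(ms), m[0])

    def test_opposite_modes_cancel(self):
        m = np.sin(np.linspace(0, 10, 100))
        ms = ModeSet(np.stack([m, -m]), np.array([1.0, 2.0]), FS, 1, True)
        assert np.allclose(reconstruct(ms), 0.0)

    def test_zero_modes_sum_to_zero(self):
        ms = ModeSet(np.zeros((3, 50)), np.array([1.0, 2.0, 3.0]), FS, 1, True)
        assert np.array_equal(reconstruct(ms), np.zeros(50))
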