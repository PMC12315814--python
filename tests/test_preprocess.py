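import numpy as np
import pytest

from sersml import (
    ConfigurationError,
    MPLSParams,
    Spectrum,
    WindowSpec,
    despike,
    dft_smooth,
    mpls_baseline,
    preprocess_set,
)
from sersml.synth import lorentzian


@pytest.fixture()
def smooth_spectrum(axis):
    base = 20.0 + 0.01 * np.arange(axis.size)
    peaks = lorentzian(axis, 800.0, 20.0, 60.0) + lorentzian(axis, 1400.0, 20.0, 40.0)
    return Spectrum(axis, base + peaks)


# ---------------------------------------------------------------------------
# despike
# ---------------------------------------------------------------------------


def test_despike_removes_single_spike(smooth_spectrum):
    x = smooth_spectrum.intensities.copy()
    x[300] += 50.0 * x.std()
    spiked = smooth_spectrum.with_intensities(x)
    cleaned = despike(spiked)
    untouched = np.arange(x.size) != 300
    assert np.array_equal(cleaned.intensities[untouched], x[untouched])
    assert abs(cleaned.intensities[300] - smooth_spectrum.intensities[300]) < 1.0


def test_despike_identity_on_clean_signal(smooth_spectrum):
    cleaned = despike(smooth_spectrum)
    assert np.array_equal(cleaned.intensities, smooth_spectrum.intensities)


def test_despike_boundary_spike(smooth_spectrum):
    x = smooth_spectrum.intensities.copy()
    x[0] += 1e4
    cleaned = despike(smooth_spectrum.with_intensities(x))
    assert cleaned.intensities[0] < x[0] / 2


def test_despike_idempotent(smooth_spectrum):
    x = smooth_spectrum.intensities.copy()
    rng = np.random.default_rng(0)
    x += rng.normal(0, 1.0, x.size)
    x[100] += 500.0
    x[400] += 900.0
    once = despike(smooth_spectrum.with_intensities(x))
    twice = despike(once)
    assert np.array_equal(once.intensities, twice.intensities)


def test_despike_window_validation(smooth_spectrum):
    with pytest.raises(ConfigurationError):
        despike(smooth_spectrum, window=4)
    with pytest.raises(ConfigurationError):
        despike(smooth_spectrum, window=2 * smooth_spectrum.n + 1)


# ---------------------------------------------------------------------------
# MPLS
# ---------------------------------------------------------------------------


def test_mpls_constant_spectrum(axis):
    s = Spectrum(axis, np.full(axis.size, 5.0))
    baseline, corrected = mpls_baseline(s)
    assert np.allclose(baseline.intensities, 5.0, atol=1e-8)
    assert np.allclose(corrected.intensities, 0.0, atol=1e-8)


def test_mpls_linear_baseline_peak_recovery(axis):
    """Oracle = the generating baseline: corrected peak height within 5% of
    the true 100, and near-zero residual in peak-free regions."""
    true_base = 0.01 * np.arange(axis.size)
    peak = lorentzian(axis, 1000.0, 10.0, 100.0)
    s = Spectrum(axis, true_base + peak)
    baseline, corrected = mpls_baseline(s)
    peak_idx = np.argmin(np.abs(axis - 1000.0))
    assert corrected.intensities[peak_idx] == pytest.approx(100.0, rel=0.05)
    far = np.abs(axis - 1000.0) > 100.0
    assert abs(np.median(corrected.intensities[far])) <= 0.5


def test_mpls_pure_baseline(axis):
    # the generator's default drift shape: gentle cubic, ~20-count range
    t = np.linspace(0, 1, axis.size)
    cubic = 80.0 - 30.0 * t + 20.0 * t**2 - 10.0 * t**3
    baseline, corrected = mpls_baseline(Spectrum(axis, cubic))
    assert np.max(np.abs(corrected.intensities)) <= 0.01 * (cubic.max() - cubic.min())


def test_mpls_additivity_exact(smooth_spectrum):
    baseline, corrected = mpls_baseline(smooth_spectrum)
    assert np.array_equal(
        smooth_spectrum.intensities - baseline.intensities, corrected.intensities
    )
    assert np.allclose(
        baseline.intensities + corrected.intensities,
        smooth_spectrum.intensities, rtol=1e-15, atol=1e-12,
    )


def test_mpls_baseline_smoother_than_opening(axis):
    from scipy import ndimage

    rng = np.random.default_rng(1)
    x = 30.0 + 10 * np.sin(np.linspace(0, 3, axis.size)) + rng.normal(0, 2, axis.size)
    s = Spectrum(axis, x)
    params = MPLSParams()
    baseline, _ = mpls_baseline(s, params)
    opening = ndimage.grey_opening(x, size=params.struct_width)

    def rough(v):
        return float(np.sum(np.diff(v, 2) ** 2))

    assert rough(baseline.intensities) <= rough(opening)


def test_mpls_struct_width_validation(axis):
    s = Spectrum(axis[:50], np.ones(50))
    with pytest.raises(ConfigurationError):
        mpls_baseline(s, MPLSParams(struct_width=75))
    with pytest.raises(ConfigurationError):
        MPLSParams(struct_width=10)  # even
    with pytest.raises(ConfigurationError):
        MPLSParams(flat_proportion=0.9)


# ---------------------------------------------------------------------------
# DFT smoothing
# ---------------------------------------------------------------------------


def test_dft_constant_unchanged(axis):
    s = Spectrum(axis, np.full(axis.size, 7.0))
    out = dft_smooth(s)
    assert np.allclose(out.intensities, 7.0, atol=1e-10)


def test_dft_passband_cosine_unchanged():
    n = 512
    w = WindowSpec(cutoff_fraction=0.15, rolloff_fraction=0.05)
    k = 10  # frequency fraction 2k/n = 0.039 < 0.10 = cutoff - rolloff
    x = np.cos(2 * np.pi * k * np.arange(n) / n)
    s = Spectrum(np.arange(n, dtype=float), x)
    out = dft_smooth(s, w)
    assert np.allclose(out.intensities, x, atol=1e-8)


def test_dft_matches_circular_convolution_oracle():
    """Independent oracle: explicit time-domain circular convolution with the
    window's impulse response."""
    n = 64
    rng = np.random.default_rng(3)
    x = rng.normal(size=n)
    w = WindowSpec()
    out = dft_smooth(Spectrum(np.arange(n, dtype=float), x), w).intensities
    h = np.fft.irfft(w.response(n), n=n)
    brute = np.array(
        [sum(x[(i - j) % n] * h[j] for j in range(n)) for i in range(n)]
    )
    assert np.allclose(out, brute, atol=1e-9)
    assert out.var() < x.var()


def test_dft_linear(axis):
    rng = np.random.default_rng(4)
    x = rng.normal(size=axis.size)
    y = rng.normal(size=axis.size)
    a, b = 2.5, -1.25
    sx = dft_smooth(Spectrum(axis, x)).intensities
    sy = dft_smooth(Spectrum(axis, y)).intensities
    sxy = dft_smooth(Spectrum(axis, a * x + b * y)).intensities
    assert np.allclose(sxy, a * sx + b * sy, atol=1e-9)


def test_dft_preserves_dc(axis):
    rng = np.random.default_rng(5)
    x = rng.normal(100.0, 3.0, axis.size)
    out = dft_smooth(Spectrum(axis, x)).intensities
    assert out.mean() == pytest.approx(x.mean(), abs=1e-9)


def test_window_spec_validation():
    with pytest.raises(ConfigurationError):
        WindowSpec(cutoff_fraction=0.0)
    with pytest.raises(ConfigurationError):
        WindowSpec(cutoff_fraction=0.1, rolloff_fraction=0.2)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def test_chain_preserves_band_centers(two_class_set):
    """After despike + MPLS + DFT the strongest fingerprint-region band stays
    within one grid point of 1349 cm^-1 for the cancer-like class."""
    pre = preprocess_set(two_class_set)
    ax = pre.axis
    region = (ax >= 1300) & (ax <= 1400)
    cancer_rows = pre.matrix[pre.labels.astype(str) == "a549-like"]
    mean_spec = cancer_rows.mean(axis=0)
    peak_wn = ax[region][np.argmax(mean_spec[region])]
    assert abs(peak_wn - 1349.0) <= 2.0 + 1e-9
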