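"""Spectral cleanup chain: cosmic-ray despiking, morphologically weighted
penalized least squares (MPLS) background removal, and discrete-Fourier-
transform low-pass smoothing.

The chain runs in measurement order: despike -> mpls_baseline -> dft_smooth.
All three operations map a :class:`~sersml.io.Spectrum` to a new spectrum on
the same axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .exceptions import ConfigurationError
from .io import Spectrum, SpectrumSet


# ---------------------------------------------------------------------------
# Cosmic-ray despiking (Hampel-style windowed modified z-score)
# ---------------------------------------------------------------------------


def despike(spectrum: Spectrum, window: int = 5, z_threshold: float = 8.0) -> Spectrum:
    """Replace single-point cosmic-ray spikes by the local median.

    A point is a spike when its modified z-score — 0.6745 |x - m| / MAD over a
    centred window (reflect-padded at the boundaries) — exceeds
    ``z_threshold``.  All other points are returned unchanged.  Flagged points
    are replaced by the median of the unflagged values in their window, so a
    second application changes nothing.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("window must be an odd integer >= 3")
    x = spectrum.intensities
    if window >= x.size:
        raise ConfigurationError(f"window {window} must be < spectrum length {x.size}")
    half = window // 2

    def _flag(values: np.ndarray) -> np.ndarray:
        padded = np.pad(values, half, mode="reflect")
        windows = sliding_window_view(padded, window)
        med = np.median(windows, axis=1)
        mad = np.median(np.abs(windows - med[:, None]), axis=1)
        # short-window MAD is itself noisy; floor it with the global median
        # MAD so ordinary noise never looks like a spike
        mad = np.maximum(mad, np.median(mad))
        dev = np.abs(values - med)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = 0.6745 * dev / mad
        # MAD == 0 everywhere: flat signal; any deviation is a spike
        z = np.where(mad == 0, np.where(dev > 0, np.inf, 0.0), z)
        return z > z_threshold

    flagged = _flag(x)
    if not flagged.any():
        return spectrum.with_intensities(x.copy())
    out = x.copy()
    for i in np.flatnonzero(flagged):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        clean = x[lo:hi][~flagged[lo:hi]]
        out[i] = np.median(clean) if clean.size else np.median(x[lo:hi])
    return spectrum.with_intensities(out)


# ---------------------------------------------------------------------------
# MPLS baseline correction
# ---------------------------------------------------------------------------


@dataclass
class MPLSParams:
    """MPLS settings.

    ``struct_width`` is the flat structuring-element width in grid points
    (default 75), ``penalty`` the Whittaker roughness penalty lambda (default
    10), ``flat_proportion`` the fraction of points at each end forced to be
    baseline (default 1/2000), ``diff_order`` the finite-difference order of
    the penalty (1 or 2)."""

    struct_width: int = 75
    penalty: float = 10.0
    flat_proportion: float = 1.0 / 2000.0
    diff_order: int = 1
    peak_weight: float = 0.001
    presmooth_width: int = 9

    def __post_init__(self) -> None:
        if self.struct_width < 1 or self.struct_width % 2 == 0:
            raise ConfigurationError("struct_width must be an odd positive integer")
        if self.presmooth_width < 0:
            raise ConfigurationError("presmooth_width must be >= 0 (0 disables)")
        if self.penalty <= 0:
            raise ConfigurationError("penalty must be > 0")
        if not (0 < self.flat_proportion < 0.5):
            raise ConfigurationError("flat_proportion must be in (0, 0.5)")
        if self.diff_order not in (1, 2):
            raise ConfigurationError("diff_order must be 1 or 2")


def _whittaker(y: np.ndarray, w: np.ndarray, lam: float, order: int) -> np.ndarray:
    """Weighted Whittaker smoother: solve (W + lam D'D) z = W y."""
    n = y.size
    d = sparse.eye(n, format="csc")
    for _ in range(order):
        d = d[1:] - d[:-1]
    a = sparse.diags(w) + lam * (d.T @ d)
    return spsolve(a.tocsc(), w * y)


def mpls_baseline(
    spectrum: Spectrum, params: MPLSParams | None = None
) -> tuple[Spectrum, Spectrum]:
    """Estimate and subtract the slowly varying background.

    A grey-scale morphological opening (erosion then dilation with a flat
    structuring element of ``struct_width`` points) gives a rough background
    contour lying under the peaks; a weighted Whittaker smoother then refines
    it, anchoring on points where the opening tracks the spectrum (weight 1)
    and nearly ignoring peak regions (small weight), with the first and last
    ``ceil(flat_proportion * n)`` points forced to weight 1.

    Returns ``(baseline, corrected)`` with ``corrected = spectrum - baseline``
    exactly.
    """
    params = params or MPLSParams()
    x = spectrum.intensities
    n = x.size
    if params.struct_width >= n:
        raise ConfigurationError(
            f"struct_width {params.struct_width} must be < spectrum length {n}"
        )
    # estimate the envelope from a median-presmoothed copy so the opening
    # tracks the background rather than the lower noise envelope
    if params.presmooth_width > 1:
        source = ndimage.median_filter(x, size=params.presmooth_width, mode="nearest")
    else:
        source = x
    # extend both ends by linear extrapolation so the flat structuring element
    # does not flatten sloped baselines near the boundaries
    w = params.struct_width
    idx = np.arange(w, dtype=float)
    cl = np.polyfit(idx, source[:w], 1)
    cr = np.polyfit(idx, source[-w:], 1)
    left = np.polyval(cl, np.arange(-w, 0, dtype=float))
    right = np.polyval(cr, np.arange(w, 2 * w, dtype=float))
    extended = np.concatenate([left, source, right])
    opening = ndimage.grey_opening(extended, size=w)[w:-w]
    resid = x - opening  # large over peaks
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    threshold = max(3.0 * sigma, 1e-12 * max(1.0, float(np.abs(x).max())))
    w = np.where(resid <= threshold, 1.0, params.peak_weight)
    m = math.ceil(params.flat_proportion * n)
    w[:m] = 1.0
    w[-m:] = 1.0
    baseline = _whittaker(opening, w, params.penalty, params.diff_order)
    corrected = x - baseline
    return spectrum.with_intensities(baseline), spectrum.with_intensities(corrected)


# ---------------------------------------------------------------------------
# DFT smoothing
# ---------------------------------------------------------------------------


@dataclass
class WindowSpec:
    """Low-pass frequency window with a raised-cosine (Tukey) roll-off.

    Frequencies are expressed as fractions of Nyquist; the window is 1 up to
    ``cutoff_fraction - rolloff_fraction``, tapers by a half-cosine, and is 0
    beyond ``cutoff_fraction``."""

    kind: str = "lowpass_tukey"
    cutoff_fraction: float = 0.15
    rolloff_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.kind != "lowpass_tukey":
            raise ConfigurationError(f"unknown window kind {self.kind!r}")
        if not (0 < self.cutoff_fraction <= 1):
            raise ConfigurationError("cutoff_fraction must be in (0, 1]")
        if not (0 <= self.rolloff_fraction < self.cutoff_fraction):
            raise ConfigurationError("rolloff_fraction must be in [0, cutoff_fraction)")

    def response(self, n: int) -> np.ndarray:
        """Window amplitude at the ``n//2 + 1`` non-negative DFT frequencies."""
        frac = np.fft.rfftfreq(n) * 2.0  # 0 .. 1 of Nyquist
        lo = self.cutoff_fraction - self.rolloff_fraction
        h = np.zeros_like(frac)
        h[frac <= lo] = 1.0
        if self.rolloff_fraction > 0:
            taper = (frac > lo) & (frac < self.cutoff_fraction)
            h[taper] = 0.5 * (
                1.0 + np.cos(np.pi * (frac[taper] - lo) / self.rolloff_fraction)
            )
        return h


def dft_smooth(spectrum: Spectrum, window: WindowSpec | None = None) -> Spectrum:
    """Low-pass the spectrum in the Fourier domain.

    Transforms the intensity vector to the frequency domain, multiplies by the
    window response (DC is always inside the passband, hence preserved
    exactly), and inverse-transforms back.  Equivalent to circular convolution
    with the window's impulse response.
    """
    window = window or WindowSpec()
    x = spectrum.intensities
    if x.size < 4:
        raise ConfigurationError("dft_smooth needs at least 4 points")
    y = np.fft.rfft(x)
    out = np.fft.irfft(y * window.response(x.size), n=x.size)
    return spectrum.with_intensities(out)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def preprocess_spectrum(
    spectrum: Spectrum,
    run_despike: bool = True,
    despike_window: int = 5,
    despike_z: float = 8.0,
    mpls_params: MPLSParams | None = None,
    window: WindowSpec | None = None,
    normalize: bool = False,
) -> Spectrum:
    """despike -> MPLS background removal -> DFT smoothing (-> optional
    max-normalization, off by default)."""
    s = spectrum
    if run_despike:
        s = despike(s, despike_window, despike_z)
    _, s = mpls_baseline(s, mpls_params)
    s = dft_smooth(s, window)
    if normalize:
        peak = np.abs(s.intensities).max()
        if peak > 0:
            s = s.with_intensities(s.intensities / peak)
    return s


def preprocess_set(spectra: SpectrumSet, **kwargs) -> SpectrumSet:
    """Apply :func:`preprocess_spectrum` to every row of a SpectrumSet."""
    return spectra.map_rows(lambda s: preprocess_spectrum(s, **kwargs))
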