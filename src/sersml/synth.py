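"""Seeded synthetic SERS spectrum generator.

Emulates the statistical structure of label-free SERS measurements of
extracellular-vesicle samples on a gold-nanoparticle substrate: Lorentzian
Raman bands at the wavenumbers assigned to lipid/protein vibrations,
class-specific band-amplitude contrasts, a smooth drifting baseline with a
broad citrate-background hump, additive Gaussian noise, and occasional
single-point cosmic-ray spikes.  Every generator output is a pure function of
its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError
from .io import Spectrum, SpectrumSet


@dataclass
class BandSpec:
    """One Raman band: a Lorentzian line at ``center`` cm^-1.

    ``amplitude_cv`` is the coefficient of variation of the per-draw peak
    amplitude (sample-to-sample chemical variability)."""

    center: float
    amplitude_mean: float
    fwhm: float = 12.0
    amplitude_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_mean < 0:
            raise ConfigurationError("amplitude_mean must be >= 0")
        if self.fwhm <= 0:
            raise ConfigurationError("fwhm must be > 0")
        if self.amplitude_cv < 0:
            raise ConfigurationError("amplitude_cv must be >= 0")


@dataclass
class SyntheticClassProfile:
    """Generative recipe for one sample class.

    The baseline is a cubic polynomial in the normalised axis position plus a
    single broad Gaussian hump (the citrate background around 1598 cm^-1 in
    real AuNP measurements).
    """

    name: str
    bands: list[BandSpec]
    poly_coeffs: tuple[float, ...] = (0.0,)  # c0 + c1 t + c2 t^2 + c3 t^3, t in [0,1]
    hump_center: float = 1598.0
    hump_width: float = 150.0
    hump_height: float = 0.0
    noise_sd: float = 0.0
    spike_rate: float = 0.0
    spike_amplitude: float = 500.0
    #: sd of the per-spectrum lognormal enhancement factor (mean 1) applied to
    #: all bands and the hump — hotspot-to-hotspot SERS enhancement variability
    scale_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("a class profile needs at least one band")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.scale_sd < 0:
            raise ConfigurationError("scale_sd must be >= 0")
        if self.spike_rate < 0:
            raise ConfigurationError("spike_rate must be >= 0")
        if len(self.poly_coeffs) > 4:
            raise ConfigurationError("baseline polynomial order must be <= 3")


def default_axis() -> np.ndarray:
    """400-3200 cm^-1 at 2 cm^-1 spacing (1401 points)."""
    return np.arange(400.0, 3202.0, 2.0)


def lorentzian(axis: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    """Lorentzian line with peak value ``amplitude`` at ``center``."""
    half = fwhm / 2.0
    return amplitude * half**2 / ((axis - center) ** 2 + half**2)


def _poly_curve(profile: SyntheticClassProfile, axis: np.ndarray) -> np.ndarray:
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    return np.polynomial.polynomial.polyval(t, np.asarray(profile.poly_coeffs, float))


def _hump_curve(profile: SyntheticClassProfile, axis: np.ndarray) -> np.ndarray:
    if not profile.hump_height:
        return np.zeros_like(axis)
    return profile.hump_height * np.exp(
        -0.5 * ((axis - profile.hump_center) / profile.hump_width) ** 2
    )


def baseline_curve(profile: SyntheticClassProfile, axis: np.ndarray) -> np.ndarray:
    return _poly_curve(profile, axis) + _hump_curve(profile, axis)


def class_template(profile: SyntheticClassProfile, axis: np.ndarray) -> np.ndarray:
    """Noiseless expected spectrum: bands at mean amplitude plus baseline
    (the enhancement scale is lognormal with mean exactly 1, so this is the
    pointwise expectation)."""
    _check_bands(profile, axis)
    signal = baseline_curve(profile, axis)
    for band in profile.bands:
        signal = signal + lorentzian(axis, band.center, band.fwhm, band.amplitude_mean)
    return signal


def _check_bands(profile: SyntheticClassProfile, axis: np.ndarray) -> None:
    for band in profile.bands:
        if not (axis[0] <= band.center <= axis[-1]):
            raise ConfigurationError(
                f"band center {band.center} cm^-1 outside axis "
                f"[{axis[0]}, {axis[-1]}]"
            )


def _draw_signal(
    profile: SyntheticClassProfile, axis: np.ndarray, amp_rng: np.random.Generator
) -> np.ndarray:
    """Bands with amplitudes drawn around their means, times the per-spectrum
    enhancement scale, plus the baseline."""
    _check_bands(profile, axis)
    # lognormal with mean exactly 1; one draw always consumed
    scale_draw = amp_rng.normal(0.0, 1.0)
    if profile.scale_sd > 0:
        sigma = np.sqrt(np.log(1.0 + profile.scale_sd**2))
        scale = np.exp(sigma * scale_draw - 0.5 * sigma**2)
    else:
        scale = 1.0
    enhanced = _hump_curve(profile, axis)
    for band in profile.bands:
        # always consume one draw so stream alignment is independent of cv
        draw = amp_rng.normal(0.0, 1.0)
        amp = max(0.0, band.amplitude_mean * (1.0 + band.amplitude_cv * draw))
        enhanced = enhanced + lorentzian(axis, band.center, band.fwhm, amp)
    return _poly_curve(profile, axis) + scale * enhanced


def _add_noise_and_spikes(
    signal: np.ndarray,
    noise_sd: float,
    spike_rate: float,
    spike_amplitude: float,
    noise_rng: np.random.Generator,
    spike_rng: np.random.Generator,
) -> np.ndarray:
    out = signal + noise_rng.normal(0.0, 1.0, signal.size) * noise_sd
    n_spikes = spike_rng.poisson(spike_rate)
    for _ in range(n_spikes):
        idx = spike_rng.integers(0, signal.size)
        out[idx] += spike_amplitude * spike_rng.uniform(0.5, 1.5)
    return out


def simulate_spectrum(
    profile: SyntheticClassProfile,
    axis: np.ndarray | None = None,
    seed: int = 0,
    sample_id: str | None = None,
) -> Spectrum:
    """Draw one spectrum from a class profile; same seed, same output."""
    axis = default_axis() if axis is None else np.asarray(axis, float)
    if not np.all(np.diff(axis) > 0):
        raise ConfigurationError("axis must be strictly increasing")
    children = np.random.SeedSequence(seed).spawn(4)
    amp_rng, noise_rng, spike_rng = (np.random.default_rng(c) for c in children[:3])
    signal = _draw_signal(profile, axis, amp_rng)
    intensities = _add_noise_and_spikes(
        signal, profile.noise_sd, profile.spike_rate, profile.spike_amplitude,
        noise_rng, spike_rng,
    )
    return Spectrum(
        axis,
        intensities,
        sample_id=sample_id or f"{profile.name}-{seed}",
        label=profile.name,
    )


def simulate_mixture(
    profile_a: SyntheticClassProfile,
    profile_b: SyntheticClassProfile,
    fraction_a: float,
    axis: np.ndarray | None = None,
    seed: int = 0,
    sample_id: str | None = None,
) -> Spectrum:
    """Two-component mixture: convex combination of the class signals.

    The expected (noiseless) spectrum is ``fraction_a * template_a +
    (1 - fraction_a) * template_b``; noise and spikes are drawn once with
    mixture-weighted parameters.  ``fraction_a=1`` reproduces the pure
    profile_a simulation at the same seed bit for bit.
    """
    if not (0.0 <= fraction_a <= 1.0):
        raise ConfigurationError("fraction_a must be in [0, 1]")
    axis = default_axis() if axis is None else np.asarray(axis, float)
    if not np.all(np.diff(axis) > 0):
        raise ConfigurationError("axis must be strictly increasing")
    children = np.random.SeedSequence(seed).spawn(4)
    amp_a, noise_rng, spike_rng, amp_b = (np.random.default_rng(c) for c in children)
    f = float(fraction_a)
    signal = f * _draw_signal(profile_a, axis, amp_a)
    if f < 1.0:
        signal = signal + (1.0 - f) * _draw_signal(profile_b, axis, amp_b)
    noise_sd = f * profile_a.noise_sd + (1 - f) * profile_b.noise_sd
    spike_rate = f * profile_a.spike_rate + (1 - f) * profile_b.spike_rate
    spike_amp = f * profile_a.spike_amplitude + (1 - f) * profile_b.spike_amplitude
    intensities = _add_noise_and_spikes(
        signal, noise_sd, spike_rate, spike_amp, noise_rng, spike_rng
    )
    name = f"{profile_a.name}+{profile_b.name}@{fraction_a:g}"
    return Spectrum(axis, intensities, sample_id=sample_id or name, label=name)


def simulate_dataset(
    profiles: list[SyntheticClassProfile],
    n_per_class: int = 135,
    axis: np.ndarray | None = None,
    seed: int = 0,
) -> SpectrumSet:
    """Simulate ``n_per_class`` spectra per profile into one labelled set."""
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate class names in {names}")
    axis = default_axis() if axis is None else np.asarray(axis, float)
    # one child seed per spectrum, derived from the master seed
    n_total = n_per_class * len(profiles)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_total) % (2**31)
    spectra = []
    k = 0
    for profile in profiles:
        for i in range(n_per_class):
            spectra.append(
                simulate_spectrum(
                    profile, axis, seed=int(child_seeds[k]),
                    sample_id=f"{profile.name}-{i:03d}",
                )
            )
            k += 1
    return SpectrumSet.from_spectra(spectra)


def simulate_mixture_dataset(
    profile_a: SyntheticClassProfile,
    profile_b: SyntheticClassProfile,
    fractions: tuple[float, ...] = (0.99, 0.90, 0.75, 0.50),
    n_per_class: int = 135,
    axis: np.ndarray | None = None,
    seed: int = 0,
) -> SpectrumSet:
    """Labelled mixtures at the study ratios (99:1, 90:10, 75:25, 50:50)."""
    axis = default_axis() if axis is None else np.asarray(axis, float)
    n_total = n_per_class * len(fractions)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_total) % (2**31)
    spectra = []
    k = 0
    for f in fractions:
        label = f"{profile_a.name}:{profile_b.name}={100 * f:g}:{100 * (1 - f):g}"
        for i in range(n_per_class):
            s = simulate_mixture(
                profile_a, profile_b, f, axis, seed=int(child_seeds[k]),
                sample_id=f"{label}-{i:03d}",
            )
            spectra.append(replace(s, label=label))
            k += 1
    return SpectrumSet.from_spectra(spectra)


# ---------------------------------------------------------------------------
# Built-in class presets
# ---------------------------------------------------------------------------

#: Shared band list: assigned lipid/protein vibrations (center, mean amplitude).
#: Amplitudes put signal-to-noise ~10 at the strongest band (C-H stretching).
COMMON_BANDS: tuple[tuple[float, float], ...] = (
    (493.0, 40.0),   # glycogen
    (741.0, 35.0),   # O-CN bending, amide IV
    (1011.0, 50.0),  # benzene ring breathing
    (1078.0, 45.0),  # C-C / C-N stretching (lysine)
    (1221.0, 40.0),  # amide III (beta-sheet)
    (1349.0, 60.0),  # CH bending / C-C stretching (collagen, adenine)
    (1437.0, 55.0),  # CH2 bending of lipids
    (2913.0, 100.0), # C-H stretching of lipids and proteins
)

#: Per-preset amplitude multipliers: +/-30% shifts around the common mean.
#: The cancer-like class sits 30% above at 1349/1437 (collagen/adenine, lipid
#: CH2) and 30% below at 1078/1221, the normal-like class mirrors it; the
#: remaining presets carry their own four-band signatures.
_PRESET_CONTRASTS: dict[str, dict[float, float]] = {
    "a549-like": {1349.0: 1.3, 1437.0: 1.3, 1078.0: 0.7, 1221.0: 0.7},
    "beas2b-like": {1349.0: 0.7, 1437.0: 0.7, 1078.0: 1.3, 1221.0: 1.3},
    "hek-like": {741.0: 1.5, 1011.0: 0.6, 1078.0: 1.4, 1437.0: 0.6},
    "hela-like": {1011.0: 1.5, 741.0: 0.6, 1349.0: 1.4, 1221.0: 0.6},
    "hepg2-like": {493.0: 1.5, 741.0: 0.7, 1349.0: 0.6, 1437.0: 1.4},
}

DEFAULT_NOISE_SD = 10.0
DEFAULT_AMPLITUDE_CV = 0.05
DEFAULT_SCALE_SD = 0.25
DEFAULT_SPIKE_RATE = 0.1
DEFAULT_SPIKE_AMPLITUDE = 800.0
#: gentle cubic drift, ~60-80 counts across the axis
DEFAULT_POLY = (80.0, -30.0, 20.0, -10.0)
DEFAULT_HUMP_HEIGHT = 40.0


def preset_profile(name: str) -> SyntheticClassProfile:
    """One of the five built-in presets: a549-like, beas2b-like, hek-like,
    hela-like, hepg2-like.  All share :data:`COMMON_BANDS` and differ only in
    band amplitudes."""
    if name not in _PRESET_CONTRASTS:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESET_CONTRASTS)}"
        )
    contrast = _PRESET_CONTRASTS[name]
    bands = [
        BandSpec(
            center=c,
            amplitude_mean=a * contrast.get(c, 1.0),
            fwhm=12.0,
            amplitude_cv=DEFAULT_AMPLITUDE_CV,
        )
        for c, a in COMMON_BANDS
    ]
    return SyntheticClassProfile(
        name=name,
        bands=bands,
        poly_coeffs=DEFAULT_POLY,
        hump_height=DEFAULT_HUMP_HEIGHT,
        noise_sd=DEFAULT_NOISE_SD,
        spike_rate=DEFAULT_SPIKE_RATE,
        spike_amplitude=DEFAULT_SPIKE_AMPLITUDE,
        scale_sd=DEFAULT_SCALE_SD,
    )


def preset_profiles(names: list[str] | None = None) -> list[SyntheticClassProfile]:
    names = names or sorted(_PRESET_CONTRASTS)
    return [preset_profile(n) for n in names]
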