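import numpy as np
import pytest
from dataclasses import replace

from sersml import (
    BandSpec,
    ConfigurationError,
    SyntheticClassProfile,
    class_template,
    preset_profile,
    preset_profiles,
    simulate_dataset,
    simulate_mixture,
    simulate_spectrum,
)
from sersml.synth import COMMON_BANDS


def test_single_band_peak_value(quiet_profile):
    ax = np.arange(400.0, 3201.0, 1.0)  # grid containing 1349 and 3000 exactly
    s = simulate_spectrum(quiet_profile, ax, seed=0)
    assert s.intensities[np.argmin(np.abs(ax - 1349.0))] == pytest.approx(100.0, abs=1e-9)
    assert s.intensities[np.argmin(np.abs(ax - 3000.0))] < 0.01


def test_baseline_only_profile(axis):
    profile = SyntheticClassProfile(
        name="base",
        bands=[BandSpec(center=1000.0, amplitude_mean=0.0, fwhm=10.0)],
        poly_coeffs=(5.0, 2.0, -1.0),
        hump_height=3.0,
        hump_center=1200.0,
    )
    s = simulate_spectrum(profile, axis, seed=1)
    from sersml.synth import baseline_curve

    assert np.allclose(s.intensities, baseline_curve(profile, axis))


def test_seed_determinism(axis, quiet_profile):
    noisy = replace(quiet_profile, noise_sd=4.0, spike_rate=0.5)
    a = simulate_spectrum(noisy, axis, seed=9)
    b = simulate_spectrum(noisy, axis, seed=9)
    c = simulate_spectrum(noisy, axis, seed=10)
    assert np.array_equal(a.intensities, b.intensities)
    assert not np.array_equal(a.intensities, c.intensities)


def test_band_outside_axis(axis):
    profile = SyntheticClassProfile(
        name="bad", bands=[BandSpec(center=3000.0, amplitude_mean=1.0, fwhm=10.0)]
    )
    with pytest.raises(ConfigurationError):
        simulate_spectrum(profile, axis, seed=0)


def test_dataset_counts_and_determinism():
    profiles = preset_profiles(["a549-like", "beas2b-like"])
    s = simulate_dataset(profiles, n_per_class=135, seed=2)
    assert s.n_samples == 270
    labels, counts = np.unique(s.labels.astype(str), return_counts=True)
    assert dict(zip(labels, counts)) == {"a549-like": 135, "beas2b-like": 135}
    s2 = simulate_dataset(profiles, n_per_class=135, seed=2)
    assert np.array_equal(s.matrix, s2.matrix)


def test_duplicate_class_names_rejected():
    p = preset_profile("a549-like")
    with pytest.raises(ConfigurationError):
        simulate_dataset([p, p], n_per_class=2, seed=0)


def test_preset_contrasts():
    """Cancer-like mean intensity higher at 1349/1437; normal-like higher at
    1078/1221 — the class difference the classifiers must learn."""
    ax = np.arange(400.0, 3202.0, 2.0)
    cancer = class_template(preset_profile("a549-like"), ax)
    normal = class_template(preset_profile("beas2b-like"), ax)

    def at(template, wn):
        return template[np.argmin(np.abs(ax - wn))]

    assert at(cancer, 1349) > at(normal, 1349)
    assert at(cancer, 1437) > at(normal, 1437)
    assert at(normal, 1078) > at(cancer, 1078)
    assert at(normal, 1221) > at(cancer, 1221)


def test_presets_share_band_list():
    centers = [c for c, _ in COMMON_BANDS]
    for profile in preset_profiles():
        assert [b.center for b in profile.bands] == centers


def test_mean_of_noisy_draws_approaches_template(axis, quiet_profile):
    """Monte-Carlo law of large numbers: the empirical mean of noisy draws
    converges to the noiseless template within 4*noise_sd/sqrt(n)."""
    noise_sd = 5.0
    profile = replace(quiet_profile, noise_sd=noise_sd)
    n = 1000
    acc = np.zeros(axis.size)
    for seed in range(n):
        acc += simulate_spectrum(profile, axis, seed=seed).intensities
    mean = acc / n
    template = class_template(profile, axis)
    assert np.max(np.abs(mean - template)) <= 4.0 * noise_sd / np.sqrt(n)


def test_mixture_convexity(axis, quiet_profile):
    other = SyntheticClassProfile(
        name="other", bands=[BandSpec(center=900.0, amplitude_mean=150.0, fwhm=10.0)]
    )
    half = simulate_mixture(quiet_profile, other, 0.5, axis, seed=0)
    ta = class_template(quiet_profile, axis)
    tb = class_template(other, axis)
    assert np.allclose(half.intensities, 0.5 * ta + 0.5 * tb)
    # fraction 1 reproduces the pure simulation bit for bit
    pure = simulate_spectrum(quiet_profile, axis, seed=4)
    full = simulate_mixture(quiet_profile, other, 1.0, axis, seed=4)
    assert np.array_equal(pure.intensities, full.intensities)
    # fraction 0.99 deviates from pure template by at most 1% of the other max
    near = simulate_mixture(quiet_profile, other, 0.99, axis, seed=0)
    assert np.max(np.abs(near.intensities - ta)) <= 0.01 * tb.max() + 1e-9


def test_mixture_fraction_bounds(axis, quiet_profile):
    with pytest.raises(ConfigurationError):
        simulate_mixture(quiet_profile, quiet_profile, 1.5, axis, seed=0)


def test_class_separation_dial(axis):
    """Larger between-class amplitude contrast at fixed noise raises
    downstream 2-class accuracy on average (5 seeds, simple classifier)."""
    from sklearn.linear_model import LogisticRegression

    def accuracy(contrast, seed):
        bands_a = [BandSpec(1000.0, 50.0 * (1 + contrast), 12.0),
                   BandSpec(1400.0, 50.0 * (1 - contrast), 12.0)]
        bands_b = [BandSpec(1000.0, 50.0 * (1 - contrast), 12.0),
                   BandSpec(1400.0, 50.0 * (1 + contrast), 12.0)]
        pa = SyntheticClassProfile("a", bands_a, noise_sd=10.0)
        pb = SyntheticClassProfile("b", bands_b, noise_sd=10.0)
        data = simulate_dataset([pa, pb], n_per_class=30, axis=axis, seed=seed)
        rng = np.random.default_rng(seed)
        idx = rng.permutation(data.n_samples)
        tr, te = idx[:40], idx[40:]
        clf = LogisticRegression(max_iter=1000).fit(
            data.matrix[tr], data.labels[tr].astype(str)
        )
        return clf.score(data.matrix[te], data.labels[te].astype(str))

    low = np.mean([accuracy(0.02, s) for s in range(5)])
    high = np.mean([accuracy(0.4, s) for s in range(5)])
    assert high > low
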