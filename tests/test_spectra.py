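"""Background subtraction, smoothing, peak metrics, and hit calling."""

import numpy as np
import pytest

from lovscreen.simulate import GeneratorConfig, generate_library, generate_plate_scans
from lovscreen.spectra import (
    BENEFICIAL,
    DELETERIOUS,
    NEUTRAL,
    PROXIMAL_SIX_TARGETS,
    SATURATION_SCREEN_COUNTS,
    SENSITIVE_THREE_TARGETS,
    EmissionSpectrum,
    PeakMetrics,
    ScreenRecord,
    ScreenThresholds,
    SpectrumAlignmentError,
    TierCall,
    aggregate_class_counts,
    classify_clone,
    confirm_across_tiers,
    peak_metrics,
    read_plate_scans,
    records_to_frame,
    run_screen,
    savitzky_golay,
    subtract_background,
    summarize_library,
)
from conftest import gaussian_spectrum

# ---------------------------------------------------------------------------
# Background subtraction


def test_spectrum_minus_itself_is_zero(grid):
    s = gaussian_spectrum(grid)
    assert np.allclose(subtract_background(s, s).intensities, 0.0)


def test_subtraction_is_pointwise_and_keeps_negatives(grid):
    sample = EmissionSpectrum(grid, np.full_like(grid, 2.0))
    background = EmissionSpectrum(grid, np.full_like(grid, 5.0))
    out = subtract_background(sample, background)
    assert np.allclose(out.intensities, -3.0)


def test_grid_mismatch_raises(grid):
    sample = EmissionSpectrum(grid, np.ones_like(grid))
    other = EmissionSpectrum(grid[1:], np.ones(grid.size - 1))
    with pytest.raises(SpectrumAlignmentError):
        subtract_background(sample, other)


# ---------------------------------------------------------------------------
# Savitzky-Golay


def test_cubics_are_reproduced_exactly_on_interior(grid):
    rng = np.random.default_rng(42)
    x = (grid - grid.mean()) / 50.0
    for _ in range(20):
        coeffs = rng.uniform(-5, 5, size=4)
        values = np.polyval(coeffs, x)
        smoothed = savitzky_golay(EmissionSpectrum(grid, values)).intensities
        interior = slice(2, -2)
        np.testing.assert_allclose(smoothed[interior], values[interior], rtol=1e-10)


def test_constant_spectrum_unchanged(flat_spectrum):
    out = savitzky_golay(flat_spectrum)
    np.testing.assert_allclose(out.intensities, 1.0)


def test_smoothing_reduces_noise(grid):
    """Residual sd after smoothing a noisy synthetic peak is below the
    injected noise sd, over 100 seeded replicates."""
    clean = gaussian_spectrum(grid).intensities
    sigma = 3.0
    ratios = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        noisy = EmissionSpectrum(grid, clean + rng.normal(0, sigma, grid.size))
        smoothed = savitzky_golay(noisy).intensities
        ratios.append(np.std(smoothed - clean) / sigma)
    assert np.mean(ratios) < 1.0
    assert np.mean(ratios) == pytest.approx(np.sqrt(595 / 1225), rel=0.1)


def test_window_validation(grid):
    s = gaussian_spectrum(grid)
    with pytest.raises(ValueError):
        savitzky_golay(s, order=3, window=4)
    short = EmissionSpectrum(grid[:3], np.ones(3))
    with pytest.raises(ValueError):
        savitzky_golay(short)


# ---------------------------------------------------------------------------
# Peak metrics


def test_peak_of_noiseless_band(grid):
    metrics = peak_metrics(gaussian_spectrum(grid, peak_nm=495.0, amplitude=80.0))
    assert metrics.peak_wavelength_nm == 495.0
    assert metrics.peak_intensity == pytest.approx(80.0)


def test_flat_spectrum_peak_at_range_start(flat_spectrum):
    assert peak_metrics(flat_spectrum).peak_wavelength_nm == 470.0


def test_ties_break_to_shorter_wavelength(grid):
    intensities = np.zeros_like(grid)
    intensities[grid == 495.0] = 5.0
    intensities[grid == 520.0] = 5.0
    s = EmissionSpectrum(grid, intensities)
    assert peak_metrics(s).peak_wavelength_nm == 495.0


def test_search_range_restricts_peak(grid):
    s = gaussian_spectrum(grid, peak_nm=495.0)
    metrics = peak_metrics(s, search_range=(520.0, 600.0))
    assert metrics.peak_wavelength_nm == 520.0
    with pytest.raises(ValueError):
        peak_metrics(s, search_range=(400.0, 650.0))


# ---------------------------------------------------------------------------
# Classification


@pytest.mark.parametrize(
    "fold, shift, expected",
    [
        (1.0, 0.0, NEUTRAL),
        (2.0, 0.0, BENEFICIAL),  # boundary inclusive: "at least a twofold"
        (1.0, 12.0, BENEFICIAL),  # "and/or a 10 nm or longer shift"
        (1.0, -10.0, BENEFICIAL),
        (0.5, 0.0, DELETERIOUS),
        (0.51, 0.0, NEUTRAL),
        (1.99, 9.0, NEUTRAL),
    ],
)
def test_classification_boundaries(fold, shift, expected):
    reference = PeakMetrics(495.0, 100.0)
    sample = PeakMetrics(495.0 + shift, fold * 100.0)
    call = classify_clone(sample, reference)
    assert call.classification == expected
    assert call.fold_change == pytest.approx(fold)
    assert call.peak_shift_nm == pytest.approx(shift)


def test_self_reference_is_neutral(grid):
    metrics = peak_metrics(gaussian_spectrum(grid))
    assert classify_clone(metrics, metrics).classification == NEUTRAL


def test_nonpositive_reference_rejected():
    with pytest.raises(ValueError):
        classify_clone(PeakMetrics(495.0, 10.0), PeakMetrics(495.0, 0.0))


def test_threshold_validation():
    with pytest.raises(ValueError):
        ScreenThresholds(beneficial_fold=0.9)
    with pytest.raises(ValueError):
        ScreenThresholds(sg_window=4)


# ---------------------------------------------------------------------------
# Tier confirmation


def test_beneficial_requires_every_tier():
    assert (
        confirm_across_tiers({"plate": BENEFICIAL, "flask": BENEFICIAL, "purified": BENEFICIAL})
        == BENEFICIAL
    )
    assert confirm_across_tiers({"plate": BENEFICIAL, "flask": NEUTRAL}) == NEUTRAL
    assert confirm_across_tiers({"plate": DELETERIOUS}) == DELETERIOUS
    assert confirm_across_tiers({"plate": NEUTRAL}) == NEUTRAL


def test_tier_confirmation_requires_plate():
    with pytest.raises(ValueError):
        confirm_across_tiers({})
    with pytest.raises(ValueError):
        confirm_across_tiers({"flask": BENEFICIAL})


# ---------------------------------------------------------------------------
# Summaries


def _record(clone, cls):
    record = ScreenRecord(clone=clone)
    record.tier_calls["plate"] = TierCall("plate", cls, 1.0, 0.0)
    record.final_class = cls
    return record


def test_counts_partition_records():
    records = (
        [_record(f"b{i}", BENEFICIAL) for i in range(2)]
        + [_record(f"n{i}", NEUTRAL) for i in range(5)]
        + [_record(f"d{i}", DELETERIOUS) for i in range(3)]
    )
    summary = summarize_library(records)
    assert summary.counts == {BENEFICIAL: 2, DELETERIOUS: 3, NEUTRAL: 5}
    assert sum(summary.counts.values()) == len(records)
    assert sum(summary.fractions.values()) == pytest.approx(1.0)


def test_single_beneficial_record():
    summary = summarize_library([_record("x", BENEFICIAL)])
    assert summary.counts == {BENEFICIAL: 1, DELETERIOUS: 0, NEUTRAL: 0}


def test_published_screen_fractions():
    """The six chromophore-proximal targets aggregate to ~82% neutral;
    the three sensitive targets to ~40% neutral / ~60% deleterious."""
    six = aggregate_class_counts(SATURATION_SCREEN_COUNTS, PROXIMAL_SIX_TARGETS)
    assert six.n_records == 931
    assert round(six.percentages[NEUTRAL]) == 82

    three = aggregate_class_counts(SATURATION_SCREEN_COUNTS, SENSITIVE_THREE_TARGETS)
    assert three.n_records == 454
    assert round(three.percentages[NEUTRAL]) == 40
    assert round(three.percentages[DELETERIOUS]) == 60


# ---------------------------------------------------------------------------
# End-to-end screen


def test_screen_recovers_classes_on_one_plate_set(config):
    truths = generate_library(config)
    scans = generate_plate_scans(truths, config)
    records = run_screen(scans)
    truth_map = {t.clone: t.true_class for t in truths}
    assert len(records) == len(truths)
    agree = sum(r.final_class == truth_map[r.clone] for r in records)
    assert agree / len(records) >= 0.95


def test_recall_is_perfect_at_boundary_without_noise():
    """With zero noise the inclusive >= 2.0 criterion fires exactly at a
    true twofold enhancement (fold is scale-exact through the linear
    pipeline)."""
    cfg = GeneratorConfig(
        seed=11,
        class_proportions={BENEFICIAL: 1.0},
        fold_ranges={BENEFICIAL: (2.0, 2.0), NEUTRAL: (0.8, 1.2), DELETERIOUS: (0.05, 0.4)},
        noise_sd_fraction=0.0,
        clones_per_library=30,
    )
    records = run_screen(generate_plate_scans(generate_library(cfg), cfg))
    assert all(r.final_class == BENEFICIAL for r in records)
    assert all(r.fold_change == pytest.approx(2.0, abs=1e-9) for r in records)


def test_recall_is_perfect_above_boundary_with_noise():
    """A true fold comfortably above threshold (2.2) survives 5% noise."""
    total = hits = 0
    for seed in range(20):
        cfg = GeneratorConfig(
            seed=seed,
            class_proportions={BENEFICIAL: 1.0},
            fold_ranges={BENEFICIAL: (2.2, 3.0), NEUTRAL: (0.8, 1.2), DELETERIOUS: (0.05, 0.4)},
            noise_sd_fraction=0.05,
            clones_per_library=30,
        )
        records = run_screen(generate_plate_scans(generate_library(cfg), cfg))
        total += len(records)
        hits += sum(r.final_class == BENEFICIAL for r in records)
    assert hits == total


def test_three_tier_confirmation_downgrades_unconfirmed_hits(config):
    truths = generate_library(
        GeneratorConfig(seed=config.seed, clones_per_library=10)
    )
    cfg = GeneratorConfig(seed=config.seed, clones_per_library=10)
    plate = generate_plate_scans(truths, cfg, tier="plate")
    # flask tier where every clone reads wild-type-like
    neutral_truths = [
        t.__class__(t.clone, t.codon, t.residue, NEUTRAL, 1.0, t.true_peak_nm)
        for t in truths
    ]
    flask = generate_plate_scans(neutral_truths, cfg, tier="flask")
    import pandas as pd

    records = run_screen(pd.concat([plate, flask], ignore_index=True))
    for record in records:
        assert record.final_class != BENEFICIAL


def test_plate_csv_round_trip(tmp_path, config):
    cfg = GeneratorConfig(seed=config.seed, clones_per_library=5)
    scans = generate_plate_scans(generate_library(cfg), cfg)
    path = tmp_path / "plate.csv"
    scans.to_csv(path, index=False)
    loaded = read_plate_scans(path)
    records = run_screen(loaded)
    frame = records_to_frame(records)
    assert set(frame["clone"]) == {f"clone{i:04d}" for i in range(1, 6)}
    assert frame["final_class"].notna().all()
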