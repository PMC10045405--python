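import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from pcgpipe import (
    Manifest,
    ManifestEntry,
    chain_report,
    kde_fit,
    kde_mode,
    select_by_duration,
    select_by_gmm,
    select_by_snr,
    select_none,
)
from pcgpipe.signal_stats import SignalStats


def make_table(durations_by_label, snrs_by_label=None):
    """Build (stats, manifest) from per-label duration (and optional SNR) lists."""
    stats, entries = [], []
    for label, durations in durations_by_label.items():
        snrs = (snrs_by_label or {}).get(label, [0.0] * len(durations))
        for i, (d, s) in enumerate(zip(durations, snrs)):
            rid = f"{label}{i}"
            stats.append(SignalStats(id=rid, duration_s=float(d), snr_db=float(s)))
            entries.append(ManifestEntry(id=rid, path="", label=label))
    return stats, Manifest(entries=entries)


class TestDurationSelection:
    def test_window_membership(self):
        stats, manifest = make_table({"normal": [19, 20, 21, 30]})
        result = select_by_duration(stats, manifest, 20.0, 35.0, tolerance_s=1.5)
        assert result.kept_ids == ["normal0", "normal1", "normal2"]
        assert result.per_class_kept == {"normal": 3, "abnormal": 0}

    def test_zero_tolerance_keeps_exact_matches_only(self):
        stats, manifest = make_table({"normal": [20.0, 20.0005, 35.0], "abnormal": [35.0, 20.0]})
        result = select_by_duration(stats, manifest, 20.0, 35.0, tolerance_s=0.0)
        assert set(result.kept_ids) == {"normal0", "abnormal0"}

    def test_kept_fraction_matches_gaussian_mass(self):
        # durations ~ N(20, 4^2); window = KDE mode +/- 2.5 s
        rng = np.random.default_rng(42)
        durations = rng.normal(20.0, 4.0, 2000)
        stats, manifest = make_table({"normal": durations, "abnormal": []})
        mode = kde_mode(kde_fit(durations, "auto"), 0.0, 40.0, 0.5)
        result = select_by_duration(stats, manifest, mode, mode, tolerance_s=2.5)
        kept_fraction = len(result.kept_ids) / 2000
        expected = norm.cdf(mode + 2.5, 20, 4) - norm.cdf(mode - 2.5, 20, 4)
        assert kept_fraction == pytest.approx(expected, abs=0.05)

    def test_missing_stats_named(self):
        stats, manifest = make_table({"normal": [20.0]})
        with pytest.raises(ValueError, match="normal0"):
            select_by_duration([], manifest, 20.0, 35.0)

    def test_idempotent(self):
        stats, manifest = make_table({"normal": [18, 20, 22, 31], "abnormal": [33, 35, 40]})
        first = select_by_duration(stats, manifest, 20.0, 35.0, 2.5)
        reduced = Manifest(entries=[e for e in manifest.entries if e.id in set(first.kept_ids)])
        second = select_by_duration(stats, reduced, 20.0, 35.0, 2.5)
        assert second.kept_ids == first.kept_ids
        assert second.dropped_ids == []


class TestSnrSelection:
    def test_boundary_is_inclusive(self):
        stats, manifest = make_table({"normal": [10, 10, 10]}, {"normal": [-1.0, 0.0, 2.0]})
        result = select_by_snr(stats, manifest, threshold_db=0.0)
        assert result.kept_ids == ["normal1", "normal2"]

    def test_none_threshold_keeps_all(self):
        stats, manifest = make_table({"normal": [10] * 4}, {"normal": [-20, -1, 0, 5]})
        result = select_by_snr(stats, manifest, threshold_db=None)
        assert len(result.kept_ids) == 4

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=20), st.floats(-5, 5), st.floats(0, 5))
    @settings(deadline=None, max_examples=50)
    def test_raising_threshold_never_keeps_more(self, snrs, threshold, bump):
        stats, manifest = make_table({"normal": [10] * len(snrs)}, {"normal": snrs})
        low = select_by_snr(stats, manifest, threshold_db=threshold)
        high = select_by_snr(stats, manifest, threshold_db=threshold + bump)
        assert len(high.kept_ids) <= len(low.kept_ids)
        assert set(high.kept_ids) <= set(low.kept_ids)

    def test_generator_distribution_keeps_half(self):
        # per-recording SNR targets are drawn N(0, 5^2) by the generator and
        # the estimator round-trips them (verified elsewhere), so thresholding
        # at 0 keeps the positive half
        rng = np.random.default_rng(42)
        snrs = rng.normal(0.0, 5.0, 1000)
        stats, manifest = make_table({"normal": [10] * 1000}, {"normal": snrs})
        result = select_by_snr(stats, manifest, threshold_db=0.0)
        assert len(result.kept_ids) / 1000 == pytest.approx(0.5, abs=0.04)


class TestGmmSelection:
    def test_keeps_large_blob_exactly(self):
        rng = np.random.default_rng(42)
        big = rng.normal([20.0, 5.0], 0.5, size=(180, 2))
        small = rng.normal([35.0, -10.0], 0.5, size=(20, 2))
        stats = [
            SignalStats(f"big{i}", d, s) for i, (d, s) in enumerate(big)
        ] + [SignalStats(f"small{i}", d, s) for i, (d, s) in enumerate(small)]
        manifest = Manifest(
            entries=[ManifestEntry(s.id, "", "normal") for s in stats]
        )
        result = select_by_gmm(stats, manifest, seed=42)
        assert sorted(result.kept_ids) == sorted(f"big{i}" for i in range(180))

    def test_identical_points_keep_everything(self):
        stats, manifest = make_table({"normal": [20.0] * 8}, {"normal": [1.0] * 8})
        result = select_by_gmm(stats, manifest, seed=0)
        assert len(result.kept_ids) == 8

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        stats, manifest = make_table(
            {"normal": rng.normal(20, 3, 30), "abnormal": rng.normal(35, 3, 30)}
        )
        a = select_by_gmm(stats, manifest, seed=5)
        b = select_by_gmm(stats, manifest, seed=5)
        assert a.kept_ids == b.kept_ids
        assert a.params == b.params


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=100)
def test_partition_invariant_on_random_manifests(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 30))
    durations = rng.uniform(5, 50, n)
    snrs = rng.normal(0, 5, n)
    labels = rng.choice(["normal", "abnormal"], n)
    stats = [SignalStats(f"r{i}", durations[i], snrs[i]) for i in range(n)]
    manifest = Manifest(entries=[ManifestEntry(f"r{i}", "", labels[i]) for i in range(n)])
    selector = rng.integers(0, 3)
    if selector == 0:
        result = select_by_duration(stats, manifest, 20, 35, rng.uniform(0, 10))
    elif selector == 1:
        result = select_by_snr(stats, manifest, float(rng.normal(0, 3)))
    else:
        result = select_by_gmm(stats, manifest, seed=int(rng.integers(0, 1000)))
    kept, dropped = set(result.kept_ids), set(result.dropped_ids)
    assert kept | dropped == set(manifest.ids)
    assert kept & dropped == set()
    assert sum(result.per_class_kept.values()) == len(result.kept_ids)


def test_chain_report_counts():
    stats, manifest = make_table(
        {"normal": [20, 20, 50], "abnormal": [35, 10]}, {"normal": [1, -1, 2], "abnormal": [0, -3]}
    )
    results = [
        select_none(stats, manifest),
        select_by_duration(stats, manifest, 20, 35, 2.5),
        select_by_snr(stats, manifest, 0.0),
    ]
    report = chain_report(results)
    assert report["none"]["kept_total"] == 5
    assert report["kde_duration"]["per_class_kept"] == {"normal": 2, "abnormal": 1}
    assert report["snr_threshold"]["kept_total"] == 3
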