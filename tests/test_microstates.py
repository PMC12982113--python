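"""Segmentation core: GFP, peaks, polarity-invariant K-means, metrics, GEV."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from easleep.microstates import (
    CLASSES,
    MicrostateError,
    PeakSequence,
    TemplateSet,
    assign_canonical_labels,
    backfit_peaks,
    compute_gev,
    compute_gfp,
    compute_metrics,
    find_gfp_peaks,
    gfp_of_maps,
    modified_kmeans,
    spatial_correlation,
    two_level_templates,
)
from easleep.recording import Recording


class TestGfp:
    def test_all_zero_sample_gives_zero(self):
        rec = Recording(data=np.zeros((4, 16)), rate=256,
                        channel_names=tuple("abcd"), reference="average")
        assert np.all(compute_gfp(rec) == 0.0)

    def test_two_channel_plus_minus_one(self):
        rec = Recording(data=np.array([[1.0], [-1.0]]), rate=256,
                        channel_names=("a", "b"), reference="average")
        assert compute_gfp(rec)[0] == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(26, 50))
        v -= v.mean(axis=0, keepdims=True)
        rec = Recording(data=v, rate=256,
                        channel_names=tuple(f"c{i}" for i in range(26)),
                        reference="average")
        # independent one-line oracle
        expected = np.sqrt(np.mean((v - v.mean(axis=0)) ** 2, axis=0))
        assert np.allclose(compute_gfp(rec), expected, atol=1e-12)

    def test_non_average_referenced_rejected(self):
        rec = Recording(data=np.ones((3, 10)) + np.arange(3)[:, None], rate=256,
                        channel_names=("a", "b", "c"))
        with pytest.raises(MicrostateError, match="average-referenced"):
            compute_gfp(rec)


class TestPeaks:
    def test_strict_maxima_example(self):
        peaks = find_gfp_peaks(np.array([0.0, 1, 0, 1, 0]), 256, 0.0)
        assert peaks.tolist() == [1, 3]

    def test_constant_series_yields_no_peaks(self):
        assert find_gfp_peaks(np.ones(100), 256).size == 0

    def test_rectified_10hz_carrier_has_about_20_peaks_per_second(self):
        t = np.arange(256) / 256.0
        gfp = np.abs(np.sin(2 * np.pi * 10 * t))
        peaks = find_gfp_peaks(gfp, 256, 10.0)
        assert 18 <= peaks.size <= 21

    def test_min_distance_enforced(self):
        rng = np.random.default_rng(1)
        gfp = rng.random(2560)
        peaks = find_gfp_peaks(gfp, 256, 50.0)
        assert np.all(np.diff(peaks) >= int(round(0.05 * 256)))


class TestModifiedKmeans:
    def test_sign_flipped_copies_recover_single_map(self, archetypes):
        rng = np.random.default_rng(0)
        signs = rng.choice([-1.0, 1.0], size=40)
        maps = signs[:, None] * archetypes.maps[2]
        res = modified_kmeans(maps, k=1, restarts=5, seed=0)
        r = abs(spatial_correlation(res.templates.maps[0], archetypes.maps[2]))
        assert r > 1 - 1e-9

    def test_recovers_four_templates_at_high_snr(self, archetypes):
        rng = np.random.default_rng(1)
        truth = archetypes.maps
        labels = rng.integers(4, size=400)
        noise = rng.normal(size=(400, 26)) / (5 * np.sqrt(26))
        maps = truth[labels] * rng.choice([-1, 1], size=(400, 1)) + noise
        res = modified_kmeans(maps, k=4, restarts=20, seed=2)
        corr = np.abs(spatial_correlation(res.templates.maps, truth))
        # each recovered template matches a distinct truth template
        best = corr.argmax(axis=1)
        assert sorted(best.tolist()) == [0, 1, 2, 3]
        assert corr.max(axis=1).min() >= 0.99

    def test_negating_inputs_changes_nothing(self, archetypes):
        rng = np.random.default_rng(3)
        maps = archetypes.maps[rng.integers(4, size=100)] + rng.normal(size=(100, 26)) * 0.05
        a = modified_kmeans(maps, k=4, restarts=10, seed=4)
        b = modified_kmeans(-maps, k=4, restarts=10, seed=4)
        assert np.array_equal(a.assignment, b.assignment)
        assert a.gev == pytest.approx(b.gev, abs=1e-12)

    def test_returned_gev_dominates_every_restart(self, archetypes):
        rng = np.random.default_rng(5)
        maps = archetypes.maps[rng.integers(4, size=60)] + rng.normal(size=(60, 26)) * 0.3
        res = modified_kmeans(maps, k=4, restarts=15, seed=6)
        assert res.gev >= res.restart_gevs.max() - 1e-12

    def test_k_larger_than_maps_rejected(self):
        with pytest.raises(MicrostateError, match="exceeds"):
            modified_kmeans(np.random.default_rng(0).normal(size=(3, 8)), k=4)


class TestTwoLevel:
    def test_identical_subjects_reproduce_templates(self, archetypes):
        res = two_level_templates([archetypes] * 3, restarts=10, seed=0)
        corr = np.abs(spatial_correlation(res.templates.maps, archetypes.maps))
        assert corr.max(axis=1).min() > 1 - 1e-9

    def test_subject_order_invariance(self, small_closure):
        sets = small_closure["subject_sets"]
        a = two_level_templates(sets, restarts=20, seed=1)
        b = two_level_templates(sets[::-1], restarts=20, seed=1)
        corr = np.abs(spatial_correlation(a.templates.maps, b.templates.maps))
        assert corr.max(axis=1).min() >= 0.999

    def test_channel_mismatch_rejected(self, archetypes):
        maps = archetypes.maps[:, :20]
        maps = maps - maps.mean(axis=1, keepdims=True)
        maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
        other = TemplateSet(maps=maps, labels=CLASSES,
                            channel_names=archetypes.channel_names[:20])
        with pytest.raises(MicrostateError, match="mismatch"):
            two_level_templates([archetypes, other])


class TestCanonicalLabels:
    def test_shuffled_reference_restored(self, archetypes):
        shuffled = archetypes.reorder([2, 0, 3, 1], ("C", "A", "D", "B"))
        labeled, match = assign_canonical_labels(shuffled, archetypes)
        assert labeled.labels == CLASSES
        assert np.allclose(labeled.maps, archetypes.maps)
        assert sum(match.values()) == pytest.approx(4.0)

    def test_negated_reference_same_labels(self, archetypes):
        negated = TemplateSet(maps=-archetypes.maps, labels=CLASSES,
                              channel_names=archetypes.channel_names)
        labeled, match = assign_canonical_labels(negated, archetypes)
        assert labeled.labels == CLASSES
        assert sum(match.values()) == pytest.approx(4.0)

    def test_matches_independent_permutation_enumeration(self, archetypes):
        rng = np.random.default_rng(7)
        maps = rng.normal(size=(4, 26))
        maps -= maps.mean(axis=1, keepdims=True)
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        tset = TemplateSet(maps=maps, labels=("0", "1", "2", "3"),
                           channel_names=archetypes.channel_names)
        labeled, _ = assign_canonical_labels(tset, archetypes)
        # independent oracle: exhaustive enumeration with separate code
        corr = np.abs(spatial_correlation(archetypes.maps, maps))
        best = max(itertools.permutations(range(4)),
                   key=lambda p: sum(corr[i, p[i]] for i in range(4)))
        assert np.allclose(labeled.maps, maps[list(best)])


class TestBackfitAndMetrics:
    def test_exact_template_peak_gets_label_and_unit_corr(self, archetypes):
        data = np.zeros((26, 9))
        data[:, 4] = archetypes.maps[2] * 5.0  # a lone peak shaped like C
        data[:, 3] = archetypes.maps[2] * 1.0
        data[:, 5] = archetypes.maps[2] * 1.0
        rec = Recording(data=data, rate=256, channel_names=archetypes.channel_names,
                        reference="average")
        seq = backfit_peaks(rec, archetypes, min_distance_ms=0.0)
        assert CLASSES[seq.label_idx[0]] == "C"
        assert seq.abs_corr[0] == pytest.approx(1.0)
        # negated peak: same label, same correlation
        rec2 = Recording(data=-data, rate=256, channel_names=archetypes.channel_names,
                         reference="average")
        seq2 = backfit_peaks(rec2, archetypes, min_distance_ms=0.0)
        assert seq2.label_idx[0] == seq.label_idx[0]
        assert seq2.abs_corr[0] == pytest.approx(1.0)

    def test_hand_computed_expansion_example(self):
        """Peaks every 10 ms labeled A,A,A,B,B,A over 60 ms of analyzed time."""
        rate = 1000.0
        seq = PeakSequence(
            peak_samples=np.array([0, 10, 20, 30, 40, 50]),
            label_idx=np.array([0, 0, 0, 1, 1, 0]),
            labels=CLASSES,
            abs_corr=np.ones(6),
            rate=rate,
            total_samples=60,
        )
        m = compute_metrics(seq)
        assert m.analyzed_s == pytest.approx(0.060)
        assert m.coverage[0] == pytest.approx(100 * 40 / 60)
        assert m.coverage[1] == pytest.approx(100 * 20 / 60)
        assert m.occurrence[0] == pytest.approx(2 / 0.06)
        assert m.occurrence[1] == pytest.approx(1 / 0.06)
        assert m.duration[0] == pytest.approx(20.0)  # episodes of 30 and 10 ms
        assert m.duration[1] == pytest.approx(20.0)
        assert m.orgtm[0, 1] == pytest.approx(50.0)
        assert m.orgtm[1, 0] == pytest.approx(50.0)
        assert m.n_transitions == 2

    def test_single_label_sequence_flags_empty_orgtm(self):
        seq = PeakSequence(
            peak_samples=np.arange(0, 50, 5),
            label_idx=np.zeros(10, dtype=int),
            labels=CLASSES,
            abs_corr=np.ones(10),
            rate=256.0,
            total_samples=60,
        )
        m = compute_metrics(seq)
        assert m.coverage[0] == pytest.approx(100.0)
        assert np.all(m.orgtm == 0.0)
        assert m.n_transitions == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(labels=st.lists(st.integers(0, 3), min_size=2, max_size=200))
    def test_metric_identities_hold_for_any_sequence(self, labels):
        """Coverage sums to 100, OrgTM to 100 (when transitions exist), and
        coverage/100 == occurrence * duration/1000 per class."""
        n = len(labels)
        seq = PeakSequence(
            peak_samples=np.arange(n) * 3,
            label_idx=np.array(labels),
            labels=CLASSES,
            abs_corr=np.ones(n),
            rate=256.0,
            total_samples=3 * n + 1,
        )
        m = compute_metrics(seq)
        assert m.coverage.sum() == pytest.approx(100.0, abs=0.5)
        if m.n_transitions:
            assert m.orgtm.sum() == pytest.approx(100.0, abs=1e-6)
        for c in range(4):
            if m.occurrence[c] > 0:
                assert m.coverage[c] / 100 == pytest.approx(
                    m.occurrence[c] * m.duration[c] / 1000, rel=0.01
                )


class TestGev:
    def test_perfect_correlation_gives_one(self):
        seq = PeakSequence(np.array([1, 5, 9]), np.array([0, 1, 2]), CLASSES,
                           np.ones(3), 256.0, 12)
        gfp = np.arange(12, dtype=float) + 1
        templates = None  # unused by the formula
        assert compute_gev(seq, gfp, templates) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        n = 40
        peaks = np.sort(rng.choice(1000, size=n, replace=False))
        corr = rng.random(n)
        gfp = rng.random(1000)
        seq = PeakSequence(peaks, rng.integers(4, size=n), CLASSES, corr, 256.0, 1000)
        expected = float((gfp[peaks] ** 2 * corr**2).sum() / (gfp[peaks] ** 2).sum())
        assert compute_gev(seq, gfp, None) == pytest.approx(expected, abs=1e-12)


class TestCohortClosure:
    def test_group_templates_match_truth(self, small_closure):
        assert min(small_closure["match"].values()) >= 0.95

    def test_metrics_within_generator_tolerances(self, small_closure):
        em = small_closure["truth"].expected_metrics()
        mets = small_closure["metrics"]
        dur = np.mean([m.duration for m in mets], axis=0)
        occ = np.mean([m.occurrence for m in mets], axis=0)
        cov = np.mean([m.coverage for m in mets], axis=0)
        org = np.mean([m.orgtm for m in mets], axis=0)
        assert np.abs((dur - em["duration"]) / em["duration"]).max() < 0.10
        assert np.abs((occ - em["occurrence"]) / em["occurrence"]).max() < 0.10
        assert np.abs(cov - em["coverage"]).max() < 5.0
        assert np.abs(org - em["orgtm"]).max() < 3.0

    def test_gfp_of_maps_matches_population_sd(self):
        rng = np.random.default_rng(0)
        maps = rng.normal(size=(5, 26))
        assert np.allclose(gfp_of_maps(maps), maps.std(axis=1))
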