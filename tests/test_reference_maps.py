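import numpy as np
import pytest

from nucfree import reference_maps as rm
from nucfree.io_formats import CoverageTrack


class TestNormalizeCoverage:
    def test_constant_signal_maps_to_target(self):
        t = CoverageTrack("c", np.full(1000, 4.2))
        norm = rm.normalize_coverage(t, target_mean=0.8)
        np.testing.assert_allclose(norm.track.values, 0.8)

    def test_monotone_transform(self, rng):
        t = CoverageTrack("c", np.sort(rng.normal(size=2000)))
        norm = rm.normalize_coverage(t, target_mean=0.6, trim_frac=0.0)
        assert np.all(np.diff(norm.track.values) >= 0)

    def test_two_level_closed_form(self):
        """Signal 0 on half, 1 on half, target 0.6: b = 1 and the low level
        maps to p = 0.2, so a = 1/ln 5."""
        s = np.concatenate([np.zeros(500), np.ones(500)])
        norm = rm.normalize_coverage(CoverageTrack("c", s), target_mean=0.6,
                                     trim_frac=0.0)
        assert norm.b == pytest.approx(1.0)
        assert norm.a == pytest.approx(1 / np.log(5), rel=1e-6)
        assert norm.track.values[0] == pytest.approx(0.2, rel=1e-6)
        assert norm.track.values[-1] == pytest.approx(1.0)

    def test_mean_hits_target_on_lognormal(self, rng):
        s = rng.lognormal(0, 1.0, size=5000)
        norm = rm.normalize_coverage(CoverageTrack("c", np.log(s)), target_mean=0.81)
        p = norm.track.values
        assert np.all((p >= 0) & (p <= 1))
        assert p.mean() == pytest.approx(0.81, abs=1e-6)

    def test_order_preserving_on_untrimmed(self, rng):
        s = rng.normal(size=3000)
        norm = rm.normalize_coverage(CoverageTrack("c", s), target_mean=0.7)
        lo, hi = np.quantile(s, [0.001, 0.999])
        keep = (s >= lo) & (s <= hi)
        order = np.argsort(s[keep], kind="mergesort")
        assert np.all(np.diff(norm.track.values[keep][order]) >= 0)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            rm.normalize_coverage(CoverageTrack("c", np.zeros(10)), target_mean=1.5)


class TestCallNucleosomes:
    def test_single_cluster_single_call(self):
        mids = np.full(100, 500)
        calls = rm.call_nucleosomes(mids, 1000)
        assert len(calls) == 1 and calls[0].dyad == 500

    def test_two_separated_clusters(self):
        mids = np.concatenate([np.full(50, 300), np.full(50, 500)])
        calls = rm.call_nucleosomes(mids, 1000, exclusion_w=147)
        assert sorted(c.dyad for c in calls) == [300, 500]

    def test_exclusion_zone_enforced(self, rng):
        mids = rng.integers(0, 5000, size=3000)
        calls = rm.call_nucleosomes(mids, 5000)
        dyads = sorted(c.dyad for c in calls)
        assert np.min(np.diff(dyads)) >= 147

    def test_planted_array_recovered(self, rng):
        """8 nucleosomes spaced 165 bp, 50 noisy reads each."""
        truth = 400 + 165 * np.arange(8)
        mids = np.concatenate([
            np.clip(np.rint(rng.normal(d, 20, size=50)), 0, 4999).astype(int)
            for d in truth])
        calls = rm.call_nucleosomes(mids, 5000)
        assert len(calls) == 8
        for d, c in zip(truth, sorted(c.dyad for c in calls)):
            assert abs(c - d) <= 10

    def test_empty_input(self):
        assert rm.call_nucleosomes(np.array([], dtype=int), 1000) == []

    def test_height_cutoff_drops_weak_peaks(self):
        mids = np.concatenate([np.full(50, 300), np.full(2, 800)])
        calls = rm.call_nucleosomes(mids, 1000, height_cutoff=10.0)
        assert [c.dyad for c in calls] == [300]


def _calls(dyads, dataset="ds", chrom="chr"):
    return [rm.NucleosomeCall(chrom, int(d), 10.0, dataset) for d in dyads]


class TestReferenceMap:
    def test_identical_datasets_reference_equals_calls(self):
        dyads = [300, 500, 700, 900]
        per_ds = [_calls(dyads, f"ds{i}") for i in range(3)]
        ref = rm.build_reference_map(per_ds, 1200)
        assert [(r.start + r.end) // 2 for r in ref.nucleosomes] == dyads
        assert all(s == 3 for s in ref.support)
        # every uncovered gap is a linker and the genome is tiled
        covered = np.zeros(1200, dtype=bool)
        for r in ref.nucleosomes + ref.linkers:
            assert not covered[r.start:r.end].any()  # non-overlapping
            covered[r.start:r.end] = True

    def test_missing_in_one_dataset_excluded_everywhere(self):
        """A nucleosome absent from one dataset is dropped from the
        reference AND its span stays out of the linkers."""
        full = [300, 600, 900]
        partial = [300, 900]
        per_ds = [_calls(full, "a"), _calls(full, "b"), _calls(partial, "c")]
        ref = rm.build_reference_map(per_ds, 1200, min_support=3)
        dyads = [(r.start + r.end) // 2 for r in ref.nucleosomes]
        assert dyads == [300, 900]
        for linker in ref.linkers:
            assert not (linker.start <= 600 < linker.end)

    def test_min_support_validation(self):
        with pytest.raises(ValueError):
            rm.build_reference_map([_calls([100]), _calls([100])], 500, min_support=3)

    def test_linker_subclass_threshold(self):
        per_ds = [_calls([100, 280, 800]) for _ in range(2)]
        ref = rm.build_reference_map(per_ds, 1200, length_threshold=50)
        by_len = {r.length: r.subclass for r in ref.linkers}
        # gap between the 280- and 800-dyad footprints is 373 bp -> NFR
        assert by_len[373] == "NFR"
        # gap between 100+73 and 280-73 is 33 bp -> short linker
        assert by_len[33] == "short_linker"

    def test_synthetic_truth_recovery(self, rng):
        """4 noisy datasets from one planted truth: >= 90% of true
        nucleosomes recovered within 20 bp."""
        truth = 300 + 180 * np.arange(20)
        per_ds = []
        for d in range(4):
            mids = np.concatenate([
                np.rint(rng.normal(t, 15, size=40)).astype(int) for t in truth])
            per_ds.append(rm.call_nucleosomes(mids, 4200, dataset=f"ds{d}"))
        ref = rm.build_reference_map(per_ds, 4200)
        dyads = np.array([(r.start + r.end) // 2 for r in ref.nucleosomes])
        hits = sum(np.min(np.abs(dyads - t)) <= 20 for t in truth)
        assert hits >= 18


class TestReproducibility:
    def test_identical_datasets_zero_sd(self):
        per_ds = [_calls([300, 600], f"d{i}") for i in range(3)]
        ref = rm.build_reference_map(per_ds, 1000)
        sds, excluded = rm.position_reproducibility(ref, per_ds)
        np.testing.assert_allclose(sds, 0.0)
        assert excluded == 0

    def test_population_sd_convention(self):
        per_ds = [_calls([98]), _calls([100]), _calls([102])]
        ref = rm.ReferenceMap([rm.GenomicRegion("chr", 27, 174, "nucleosome")],
                              [], [3])
        sds, _ = rm.position_reproducibility(ref, per_ds)
        assert sds[0] == pytest.approx(np.std([98, 100, 102], ddof=1))
        assert sds[0] == pytest.approx(2.0)

    def test_randomized_control_less_reproducible(self, rng):
        """Uniformly remapped reads yield larger median SD than structured."""
        truth = 300 + 180 * np.arange(15)
        structured, randomized = [], []
        n_reads = 15 * 40
        for d in range(4):
            mids = np.concatenate([
                np.rint(rng.normal(t, 10, size=40)).astype(int) for t in truth])
            structured.append(rm.call_nucleosomes(mids, 3200, dataset=f"s{d}"))
            rand = rm.randomize_midpoints(mids, 3200, rng)
            randomized.append(rm.call_nucleosomes(rand, 3200, dataset=f"r{d}"))
        ref_s = rm.build_reference_map(structured, 3200)
        sd_s, _ = rm.position_reproducibility(ref_s, structured)
        ref_r = rm.build_reference_map(randomized, 3200, min_support=2)
        sd_r, _ = rm.position_reproducibility(ref_r, randomized)
        assert np.median(sd_s) < np.median(sd_r)


class TestTrackDiagnostics:
    def test_pearson_self_and_negation(self, rng):
        x = rng.normal(size=1000)
        assert rm.trimmed_pearson(x, x) == pytest.approx(1.0)
        assert rm.trimmed_pearson(x, -x) == pytest.approx(-1.0)

    def test_pearson_latent_signal_analytic(self, rng):
        """Two tracks sharing a latent signal with independent noise have
        r = 1/(1+sigma^2) for unit-variance signal."""
        n = 200_000
        z = rng.normal(size=n)
        sigma = 1.0
        a = z + rng.normal(0, sigma, size=n)
        b = z + rng.normal(0, sigma, size=n)
        expected = 1 / (1 + sigma**2)
        r = rm.trimmed_pearson(a, b, trim_frac=0.0)
        assert abs(r - expected) < 3 / np.sqrt(n) * (1 - expected**2) + 0.01

    def test_pearson_too_few_positions(self):
        with pytest.raises(ValueError):
            rm.trimmed_pearson(np.arange(5.0), np.arange(5.0))

    def test_cdf_constant_and_grid(self):
        cdf = rm.coverage_cdf(CoverageTrack("c", np.full(10, 0.8), "probability"))
        assert np.all(cdf[:, 0] == 0.8) and cdf[-1, 1] == 1.0
        grid = rm.coverage_cdf(CoverageTrack("c", np.linspace(0, 1, 101), "probability"))
        np.testing.assert_allclose(grid[:, 0], np.linspace(0, 1, 101))

    def test_cdf_two_tracks_same_truth_close(self, rng):
        """Normalized coverage CDFs from two replicates of the same signal
        agree (KS distance < 0.05)."""
        z = rng.normal(size=20_000)
        out = []
        for _ in range(2):
            s = z + rng.normal(0, 0.3, size=len(z))
            norm = rm.normalize_coverage(CoverageTrack("c", s), target_mean=0.7)
            out.append(np.sort(norm.track.values))
        grid = np.linspace(0, 1, 400)
        cdf_a = np.searchsorted(out[0], grid) / len(out[0])
        cdf_b = np.searchsorted(out[1], grid) / len(out[1])
        assert np.max(np.abs(cdf_a - cdf_b)) < 0.05
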