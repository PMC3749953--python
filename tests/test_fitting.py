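import numpy as np
import pytest

from nucfree import fitting as ft
from nucfree.energy_models import FactorSpec, information_content
from nucfree.io_formats import GenomeSequence, GenomicRegion, WeightMatrix
from nucfree.thermo_core import brute_force


def tiny_regions(n, size, genome_length, rng):
    """Alternating nucleosome/linker regions tiling part of a genome."""
    regions = []
    pos = 0
    for i in range(n):
        end = min(pos + size, genome_length)
        label = "nucleosome" if i % 2 == 0 else "linker"
        regions.append(GenomicRegion("c", pos, end, label))
        pos = end
    return regions


@pytest.fixture
def small_evaluator(rng, toy_wm):
    seq = "".join(rng.choice(list("ACGT"), size=600))
    genome = GenomeSequence("c", seq)
    nuc = FactorSpec("nucleosome", "nucleosome", 20, gamma=0.5, log_conc=0.0)
    # a short-footprint stand-in "nucleosome" so the test genome stays tiny:
    # give it a WM-free dinucleotide energy via the track interface
    from nucfree.energy_models import EnergyTrack
    e = rng.normal(0, 1.5, size=genome.length - 19)
    tracks = {"nucleosome": EnergyTrack("nucleosome", "c", e, None,
                                        np.ones(len(e), dtype=bool))}
    regions = tiny_regions(20, 30, genome.length, rng)
    return ft.ModelEvaluator([nuc], genome, None, regions, tracks=tracks)


class TestKfoldSplit:
    def test_partition_properties(self, rng):
        labels = rng.random(53) < 0.4
        folds = ft.kfold_split(labels, 5, seed=3)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(53))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_ten_regions_five_folds_of_two(self):
        labels = np.array([True, False] * 5)
        folds = ft.kfold_split(labels, 5, seed=0)
        assert all(len(f) == 2 for f in folds)

    def test_stratification_balances_labels(self, rng):
        labels = rng.random(100) < 0.3
        folds = ft.kfold_split(labels, 5, seed=1)
        global_ratio = labels.mean()
        for f in folds:
            assert abs(labels[f].sum() - global_ratio * len(f)) <= 1

    def test_reproducible(self, rng):
        labels = rng.random(40) < 0.5
        a = ft.kfold_split(labels, 4, seed=9)
        b = ft.kfold_split(labels, 4, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestShuffleWm:
    def test_length_one_identity(self):
        wm = WeightMatrix("w", np.array([[0.7, 0.1, 0.1, 0.1]]))
        np.testing.assert_array_equal(ft.shuffle_wm_columns(wm, 0).probs, wm.probs)

    def test_information_content_invariant(self, rng):
        rows = np.maximum(rng.dirichlet(np.ones(4), size=6), 1e-6)
        rows /= rows.sum(1, keepdims=True)
        wm = WeightMatrix("w", rows)
        for seed in range(5):
            shuf = ft.shuffle_wm_columns(wm, seed)
            assert information_content(shuf) == pytest.approx(
                information_content(wm), abs=1e-12)
            # multiset of rows preserved
            assert sorted(map(tuple, shuf.probs)) == sorted(map(tuple, wm.probs))

    def test_permutations_uniform(self):
        import itertools
        wm = WeightMatrix("w", np.array([[0.9, 0.04, 0.03, 0.03],
                                         [0.04, 0.9, 0.03, 0.03],
                                         [0.03, 0.04, 0.9, 0.03]]))
        counts = {}
        for seed in range(1000):
            key = tuple(np.argmax(ft.shuffle_wm_columns(wm, seed).probs, axis=1))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        # each permutation 1/6 +- 3 sigma of a multinomial
        sigma = np.sqrt(1000 * (1 / 6) * (5 / 6))
        for v in counts.values():
            assert abs(v - 1000 / 6) < 3 * sigma


class TestFitModel:
    def test_zero_free_params_evaluates_once(self, small_evaluator):
        cfg = ft.FitConfig(seed=1)
        params, rho, trace = ft.fit_model(small_evaluator, [], cfg)
        assert params == {} and trace == []
        assert 0 <= rho <= 1

    def test_deterministic_given_seed(self, small_evaluator):
        cfg = ft.light_fit_config(seed=5)
        free = [("nucleosome", "log_conc")]
        out1 = ft.fit_model(small_evaluator, free, cfg)
        small_evaluator.set_param("nucleosome", "log_conc", 0.0)
        out2 = ft.fit_model(small_evaluator, free, cfg)
        assert out1[0] == out2[0]
        assert out1[2] == out2[2]

    def test_fit_does_not_decrease_objective(self, small_evaluator):
        cfg = ft.light_fit_config(seed=2)
        rho0 = small_evaluator.rho()
        _, rho_fit, _ = ft.fit_model(
            small_evaluator, [("nucleosome", "log_conc"), ("nucleosome", "gamma")], cfg)
        assert rho_fit >= rho0 - 1e-12


class TestCrossValidate:
    def test_train_at_least_test_on_average(self, rng, toy_wm):
        """The optimizer sees only the training regions, so train rho
        should not fall below test rho systematically."""
        from nucfree.energy_models import EnergyTrack
        genome = GenomeSequence("c", "".join(rng.choice(list("ACGT"), size=1600)))
        nuc = FactorSpec("nucleosome", "nucleosome", 20, gamma=0.5, log_conc=0.0)
        e = rng.normal(0, 1.5, size=genome.length - 19)
        tracks = {"nucleosome": EnergyTrack("nucleosome", "c", e, None,
                                            np.ones(len(e), dtype=bool))}
        regions = tiny_regions(80, 20, genome.length, rng)
        ev = ft.ModelEvaluator([nuc], genome, None, regions, tracks=tracks)
        cfg = ft.light_fit_config(seed=4, k_folds=4)
        cv = ft.cross_validate(ev, [("nucleosome", "log_conc"),
                                    ("nucleosome", "gamma")], cfg)
        assert np.mean(cv.train_rho) >= np.mean(cv.test_rho) - 0.05
        assert len(cv.test_rho) == 4

    def test_folds_partition_regions(self, small_evaluator):
        cfg = ft.light_fit_config(seed=4, k_folds=4)
        cv = ft.cross_validate(small_evaluator, [], cfg)
        idx = np.sort(np.concatenate(cv.folds))
        np.testing.assert_array_equal(idx, np.arange(len(small_evaluator.regions)))


class TestCharacterize:
    def test_single_site_coverage_fraction(self):
        """P = 0.5 for one site of footprint 10 on L = 100 gives phi 0.05."""
        from nucfree.energy_models import EnergyTrack
        genome = GenomeSequence("c", "A" * 100)
        nuc = FactorSpec("nucleosome", "nucleosome", 10, gamma=1.0, log_conc=0.0)
        e = np.full(91, 60.0)
        e[40] = 0.0  # single accessible site
        tracks = {"nucleosome": EnergyTrack("nucleosome", "c", e, None,
                                            np.ones(91, dtype=bool))}
        regions = [GenomicRegion("c", 0, 50, "nucleosome"),
                   GenomicRegion("c", 50, 100, "linker")]
        ev = ft.ModelEvaluator([nuc], genome, None, regions, tracks=tracks)
        # center the energies ourselves: weight exp(lnc - gamma*(e - mean))
        occ = ev.occupancy()
        p = occ.posteriors["nucleosome"]
        char = ft.characterize(ev)
        row = char.table.iloc[0]
        assert row["phi"] == pytest.approx(10 / 100 * p.sum())

    def test_entropy_limits(self):
        from nucfree.energy_models import EnergyTrack
        genome = GenomeSequence("c", "A" * 60)
        nuc = FactorSpec("nucleosome", "nucleosome", 10, gamma=1.0, log_conc=-2.0)
        # m equally accessible, far-apart sites -> S ~ ln m for weak binding
        e = np.full(51, 50.0)
        sites = [0, 20, 40]
        for s in sites:
            e[s] = 0.0
        tracks = {"nucleosome": EnergyTrack("nucleosome", "c", e, None,
                                            np.ones(51, dtype=bool))}
        regions = [GenomicRegion("c", 0, 30, "nucleosome"),
                   GenomicRegion("c", 30, 60, "linker")]
        ev = ft.ModelEvaluator([nuc], genome, None, regions, tracks=tracks)
        char = ft.characterize(ev)
        assert char.table.iloc[0]["entropy"] == pytest.approx(np.log(3), abs=0.05)

    def test_matches_brute_force_posteriors(self, rng):
        """phi from the DP equals the brute-force posterior sum."""
        from conftest import random_instance
        from nucfree.thermo_core import forward_backward, site_posteriors
        w = random_instance(rng, L_max=20, n_factors_max=2)
        occ = site_posteriors(forward_backward(w), w)
        _, post = brute_force(w)
        for fi, name in enumerate(w.names):
            phi_dp = w.footprints[fi] / w.L * occ.posteriors[name].sum()
            phi_bf = w.footprints[fi] / w.L * post[name].sum()
            assert phi_dp == pytest.approx(phi_bf, rel=1e-9)


class TestPositionalProfile:
    def test_constant_track_flat(self):
        offs, mean, n = ft.positional_profile(np.full(100, 0.4),
                                              [(50, "+"), (30, "-")], 10)
        np.testing.assert_allclose(mean, 0.4)
        assert n.max() == 2

    def test_single_anchor_equals_local_values(self, rng):
        vals = rng.random(200)
        offs, mean, n = ft.positional_profile(vals, [(100, "+")], 5)
        np.testing.assert_array_equal(mean, vals[95:106])

    def test_minus_strand_flipped(self, rng):
        vals = rng.random(200)
        _, plus, _ = ft.positional_profile(vals, [(100, "+")], 5)
        _, minus, _ = ft.positional_profile(vals[::-1], [(99, "-")], 5)
        np.testing.assert_allclose(plus, minus)

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError):
            ft.positional_profile(np.zeros(10), [], 3)

    def test_out_of_bounds_skipped_with_counts(self):
        vals = np.ones(20)
        offs, mean, n = ft.positional_profile(vals, [(1, "+")], 5)
        assert n[0] == 0 and np.isnan(mean[0])
        assert n[-1] == 1
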