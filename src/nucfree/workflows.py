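"""Convenience pipelines tying the modules together for a Scenario.

These are the exact steps a user would run on real data: call nucleosomes
per dataset, intersect into a reference map, build an evaluator, fit and
rank.  Kept thin so each stage stays independently testable.
"""

from __future__ import annotations

import numpy as np

from .fitting import FitConfig, ModelEvaluator, cross_validate, fit_model, kfold_split
from .reference_maps import NucleosomeCall, ReferenceMap, build_reference_map, call_nucleosomes
from .synthetic_data import Scenario


def depth_scaled_cutoff(cells_per_dataset: int, reads_per_nucleosome: float,
                        occupancy_fraction: float = 0.5) -> float:
    """Peak-height cutoff (reads-equivalent) matching a target occupancy.

    A nucleosome present in a fraction ``occupancy_fraction`` of cells
    accumulates about that fraction of the per-position read depth, so the
    cutoff scales with depth = cells * reads_per_nucleosome.
    """
    return occupancy_fraction * cells_per_dataset * reads_per_nucleosome


def scenario_calls(sc: Scenario, height_cutoff: float | None = None
                   ) -> list[list[NucleosomeCall]]:
    if height_cutoff is None:
        height_cutoff = depth_scaled_cutoff(sc.truth["cells_per_dataset"],
                                            sc.truth["reads_per_nucleosome"])
    return [call_nucleosomes(d, sc.genome.length, height_cutoff=height_cutoff,
                             chrom=sc.genome.name, dataset=f"ds{i}")
            for i, d in enumerate(sc.datasets)]


def scenario_reference_map(sc: Scenario, height_cutoff: float | None = None,
                           min_support: int | None = None
                           ) -> tuple[list[list[NucleosomeCall]], ReferenceMap]:
    calls = scenario_calls(sc, height_cutoff)
    ref = build_reference_map(calls, sc.genome.length, min_support=min_support,
                              chrom=sc.genome.name)
    return calls, ref


def nucleosome_only_evaluator(sc: Scenario, regions,
                              gamma: float = 0.5, log_conc: float = 0.0
                              ) -> ModelEvaluator:
    """Evaluator for the nucleosome-only model, started from the neutral
    default (weak specificity, unit-scale concentration)."""
    from .energy_models import NUCLEOSOME_FOOTPRINT, FactorSpec

    nuc = FactorSpec("nucleosome", "nucleosome", NUCLEOSOME_FOOTPRINT,
                     gamma=gamma, log_conc=log_conc)
    return ModelEvaluator([nuc], sc.genome, sc.nucleosome_model, regions)


def fit_nucleosome_only_cv(sc: Scenario, regions, config: FitConfig):
    """Cross-validated two-parameter (ln c, gamma) nucleosome-only fit."""
    ev = nucleosome_only_evaluator(sc, regions)
    free = [("nucleosome", "log_conc"), ("nucleosome", "gamma")]
    folds = kfold_split(ev.labels, config.k_folds, config.seed)
    return ev, cross_validate(ev, free, config, folds)


def region_subset_indices(regions, genes=None, classes=None):
    """Indices (into ``regions``) of the promoter/class subset."""
    from .scoring import subset_regions

    sub = subset_regions(regions, genes, classes=classes)
    keys = {(r.start, r.end) for r in sub}
    return np.array([i for i, r in enumerate(regions)
                     if (r.start, r.end) in keys], dtype=int)


def subset_score_gain(base_evaluator, tf_wm, folds, config,
                      eval_idx) -> tuple[float, float, list[float]]:
    """Score gain on a fixed region subset from adding one TF.

    Per fold the TF's (ln c, gamma) are fitted on the genome-wide training
    regions (shared grid) and the quality score on ``eval_idx`` (for
    example, promoter regions) with the fold's parameters is compared with
    the fixed nucleosome-only model.  Returns (mean gain, fold SE, gains).
    The evaluation subset is fixed across folds, so the fold spread
    reflects parameter variability.
    """
    import itertools

    from .energy_models import FactorSpec
    from .fitting import ModelEvaluator
    from .scoring import label_entropy, max_mi_threshold

    regions = base_evaluator.regions
    labels = base_evaluator.labels
    all_idx = np.arange(len(regions))
    base = base_evaluator.rho(eval_idx)
    nuc = base_evaluator.factor("nucleosome")
    tf = FactorSpec(tf_wm.name, "tf", tf_wm.length, wm=tf_wm)
    ev = ModelEvaluator([nuc, tf], base_evaluator.genome, None, regions,
                        tracks=base_evaluator.tracks | {})
    meds_list = []
    for lc, g in itertools.product(config.grid_logc, config.grid_gamma):
        ev.set_param(tf_wm.name, "log_conc", lc)
        ev.set_param(tf_wm.name, "gamma", g)
        meds_list.append(ev.medians())
    gains = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        best, best_r = None, -np.inf
        for meds in meds_list:
            mi, _ = max_mi_threshold(meds[train_idx], labels[train_idx])
            r = mi / label_entropy(labels[train_idx])
            if r > best_r:
                best_r, best = r, meds
        mi, _ = max_mi_threshold(best[eval_idx], labels[eval_idx])
        gains.append(mi / label_entropy(labels[eval_idx]) - base)
    gains = np.asarray(gains)
    se = float(gains.std(ddof=1) / np.sqrt(len(gains)))
    return float(gains.mean()), se, list(gains)


def staged_full_model(sc: Scenario, regions, config: FitConfig,
                      gamma_nuc: float | None = None):
    """Nucleosome + all TFs, fitted in stages.

    1. two-parameter nucleosome-only fit (or ln c only if gamma_nuc fixed);
    2. per-TF (ln c, gamma) grid fit with the nucleosome fixed;
    3. joint refit of the nucleosome parameters with all TFs present.
    Returns the final multi-factor evaluator.
    """
    from .energy_models import FactorSpec
    from .fitting import ModelEvaluator, fit_model

    ev0 = nucleosome_only_evaluator(sc, regions)
    if gamma_nuc is not None:
        ev0.set_param("nucleosome", "gamma", gamma_nuc)
        nuc_free = [("nucleosome", "log_conc")]
    else:
        nuc_free = [("nucleosome", "log_conc"), ("nucleosome", "gamma")]
    fit_model(ev0, nuc_free, config)
    nuc = ev0.factor("nucleosome")
    grid_cfg = config if config.optimizer == "grid" else \
        __import__("dataclasses").replace(config, optimizer="grid")
    tf_specs = []
    for wm in sc.wms:
        tf = FactorSpec(wm.name, "tf", wm.length, wm=wm)
        e2 = ModelEvaluator([nuc, tf], sc.genome, sc.nucleosome_model, regions,
                            tracks={"nucleosome": ev0.tracks["nucleosome"]})
        fit_model(e2, [(wm.name, "log_conc"), (wm.name, "gamma")], grid_cfg)
        tf_specs.append(e2.factor(wm.name))
    full = ModelEvaluator([nuc] + tf_specs, sc.genome, sc.nucleosome_model,
                          regions, tracks={"nucleosome": ev0.tracks["nucleosome"]})
    fit_model(full, nuc_free, config)
    return full


def refit_without_specificity(full_evaluator, config: FitConfig):
    """The same factor content with gamma_nuc forced to 0.

    TF parameters are kept from the full fit; the nucleosome concentration
    is refitted (the only nucleosome parameter left once specificity is
    removed)."""
    import copy

    from .fitting import ModelEvaluator, fit_model

    factors = [copy.deepcopy(f) for f in full_evaluator.factors]
    for f in factors:
        if f.kind == "nucleosome":
            f.gamma = 0.0
    ev = ModelEvaluator(factors, full_evaluator.genome, None,
                        full_evaluator.regions, tracks=full_evaluator.tracks)
    fit_model(ev, [("nucleosome", "log_conc")], config)
    return ev
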