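"""Parameter fitting, cross-validation, TF ranking, and model characterization.

The objective is the quality score rho of the predicted nucleosome occupancy
against a reference map, evaluated on training regions.  Concentrations are
fitted in natural log; specificity scales gamma are linear with a lower
bound at 0; the TF calibration offset E0 is recomputed whenever a gamma
changes (it is not a free parameter).  The default optimizer is simulated
annealing (Metropolis on -rho) followed by a Nelder-Mead polish; a shared
coarse grid is available for the many small two-parameter fits of the
per-TF ranking.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .energy_models import (EnergyTrack, FactorSpec, NucleosomeModel,
                            calibrate_e0, nucleosome_energy, scan_genome)
from .io_formats import GenomeSequence, GenomicRegion, WeightMatrix
from .scoring import labels_from_regions, max_mi_threshold, label_entropy
from .thermo_core import BindingWeights, OccupancyResult, forward_backward, site_posteriors


@dataclass
class FitConfig:
    optimizer: str = "anneal+nelder_mead"  # {nelder_mead, anneal+nelder_mead, grid}
    t0: float = 1.0
    cooling: float = 0.9
    steps_per_t: int = 20
    t_min: float = 1e-3
    proposal_sd_logc: float = 0.3
    proposal_sd_gamma: float = 0.1
    nm_maxfev: int = 200
    nm_fatol: float = 1e-4
    logc_bounds: tuple[float, float] = (-30.0, 10.0)
    gamma_bounds: tuple[float, float] = (0.0, 5.0)
    k_folds: int = 5
    seed: int = 0
    # coarse grid used by the "grid" optimizer (per-TF ranking fits)
    grid_logc: tuple[float, ...] = (-8.0, -6.0, -4.0, -2.0, 0.0)
    grid_gamma: tuple[float, ...] = (0.5, 1.0, 1.5)

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def light_fit_config(seed: int = 0, **overrides) -> FitConfig:
    """A short schedule for small (1-2 parameter) fits."""
    cfg = FitConfig(t0=0.3, cooling=0.7, steps_per_t=8, t_min=0.02,
                    nm_maxfev=80, seed=seed)
    return replace(cfg, **overrides)


@dataclass
class CVResult:
    train_rho: list[float]
    test_rho: list[float]
    params: list[dict]  # fitted free parameters per fold
    folds: list[np.ndarray]

    @property
    def mean_test_rho(self) -> float:
        return float(np.mean(self.test_rho))

    @property
    def se_test_rho(self) -> float:
        k = len(self.test_rho)
        return float(np.std(self.test_rho, ddof=1) / np.sqrt(k))

    def param_means(self) -> dict:
        out: dict = {}
        for key in self.params[0]:
            out[key] = float(np.mean([p[key] for p in self.params]))
        return out


@dataclass
class TFRanking:
    table: pd.DataFrame  # columns: tf, mean_delta, se, z, control; sorted by z desc


@dataclass
class FactorCharacterization:
    table: pd.DataFrame  # columns: factor, phi, mean_energy, sd_energy, entropy


# ---------------------------------------------------------------------------
# Evaluator: parameters -> occupancy -> region medians -> rho
# ---------------------------------------------------------------------------


class ModelEvaluator:
    """Caches energy tracks, per-gamma Boltzmann bases, and region medians
    so repeated objective evaluations are cheap."""

    def __init__(self, factors: list[FactorSpec], genome: GenomeSequence,
                 nucleosome_model: NucleosomeModel | None,
                 regions: list[GenomicRegion],
                 tracks: dict[str, EnergyTrack] | None = None):
        self.factors = [copy.deepcopy(f) for f in factors]
        self.genome = genome
        self.L = genome.length
        self.regions = regions
        self.labels = labels_from_regions(regions)
        self.entropy_all = label_entropy(self.labels)
        self.tracks: dict[str, EnergyTrack] = {}
        for f in self.factors:
            if tracks is not None and f.name in tracks:
                self.tracks[f.name] = tracks[f.name]
            elif f.kind == "tf":
                self.tracks[f.name] = scan_genome(f, genome)
            else:
                if nucleosome_model is None:
                    raise ValueError("nucleosome factor requires a model")
                self.tracks[f.name] = nucleosome_energy(nucleosome_model, genome)
        self._base_cache: dict[str, dict[float, tuple[np.ndarray, float]]] = {
            f.name: {} for f in self.factors}
        self._median_cache: dict[tuple, np.ndarray] = {}
        self._prep_regions()
        self.n_evals = 0

    def _prep_regions(self) -> None:
        buckets: dict[int, list[int]] = {}
        for i, r in enumerate(self.regions):
            buckets.setdefault(r.length, []).append(i)
        self._buckets = []
        for length, idxs in buckets.items():
            starts = np.array([self.regions[i].start for i in idxs])
            self._buckets.append((np.array(idxs), starts[:, None] + np.arange(length)))

    # -- parameters ---------------------------------------------------------

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def set_param(self, name: str, param: str, value: float) -> None:
        setattr(self.factor(name), param, float(value))

    def _params_key(self) -> tuple:
        return tuple((f.name, f.gamma, f.log_conc) for f in self.factors)

    # -- model evaluation ---------------------------------------------------

    def _base_weights(self, f: FactorSpec) -> tuple[np.ndarray, float]:
        """Boltzmann base at unit concentration for the factor's gamma,
        with the calibration offset folded in; cached per gamma."""
        cache = self._base_cache[f.name]
        if f.gamma in cache:
            return cache[f.gamma]
        track = self.tracks[f.name]
        if f.kind == "tf":
            e0 = calibrate_e0(track, f.gamma)
            q = np.exp(-f.gamma * track.e_fwd - e0) + np.exp(-f.gamma * track.e_rev - e0)
        else:
            mean_e = float(np.mean(track.e_fwd[track.valid]))
            e0 = 0.0
            q = np.exp(-f.gamma * (track.e_fwd - mean_e))
        q = np.where(track.valid, q, 0.0)
        q = np.nan_to_num(q, nan=0.0)
        if len(cache) > 64:
            cache.clear()
        cache[f.gamma] = (q, e0)
        return q, e0

    def binding_weights(self) -> BindingWeights:
        names, fps, ws = [], [], []
        for f in self.factors:
            base, e0 = self._base_weights(f)
            f.e0 = e0
            names.append(f.name)
            fps.append(f.footprint)
            ws.append(np.exp(f.log_conc) * base)
        return BindingWeights.from_arrays(names, fps, ws, self.L)

    def occupancy(self) -> OccupancyResult:
        w = self.binding_weights()
        return site_posteriors(forward_backward(w), w)

    def nucleosome_occupancy(self) -> np.ndarray:
        return self.occupancy().occupancy["nucleosome"]

    def medians(self) -> np.ndarray:
        """Median predicted nucleosome occupancy per reference region,
        cached on the full parameter vector."""
        key = self._params_key()
        if key in self._median_cache:
            return self._median_cache[key]
        occ = self.nucleosome_occupancy()
        out = np.empty(len(self.regions))
        for idxs, base_idx in self._buckets:
            out[idxs] = np.median(occ[base_idx], axis=1)
        if len(self._median_cache) > 512:
            self._median_cache.clear()
        self._median_cache[key] = out
        self.n_evals += 1
        return out

    def rho(self, region_idx: np.ndarray | None = None) -> float:
        meds = self.medians()
        if region_idx is None:
            meds_s, labels_s = meds, self.labels
        else:
            meds_s, labels_s = meds[region_idx], self.labels[region_idx]
        h = label_entropy(labels_s)
        if h == 0:
            raise ValueError("scored subset has a single label")
        mi_star, _ = max_mi_threshold(meds_s, labels_s)
        return float(mi_star / h)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

FreeParam = tuple[str, str]  # (factor name, "log_conc" | "gamma")


def _bounds_for(free: list[FreeParam], config: FitConfig) -> list[tuple[float, float]]:
    return [config.logc_bounds if p == "log_conc" else config.gamma_bounds
            for _, p in free]


def fit_model(evaluator: ModelEvaluator, free: list[FreeParam],
              config: FitConfig, train_idx: np.ndarray | None = None,
              rng: np.random.Generator | None = None
              ) -> tuple[dict, float, list[float]]:
    """Maximize rho on the training regions over the free parameters.

    Returns (fitted params dict keyed by (factor, param), best rho, trace of
    objective values).  Deterministic given the config seed.  With no free
    parameters, evaluates rho once and returns it.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not free:
        return {}, evaluator.rho(train_idx), []
    bounds = _bounds_for(free, config)
    x0 = np.array([getattr(evaluator.factor(n), p) for n, p in free])
    trace: list[float] = []

    def objective(x: np.ndarray) -> float:
        for (name, param), v, (lo, hi) in zip(free, x, bounds):
            evaluator.set_param(name, param, float(np.clip(v, lo, hi)))
        val = -evaluator.rho(train_idx)
        trace.append(-val)
        return val

    f0 = objective(x0)
    if not np.isfinite(f0):
        raise ValueError(f"objective non-finite at start: params={dict(zip(free, x0))}")
    best_x, best_f = x0.copy(), f0

    if config.optimizer == "grid":
        axes = [config.grid_logc if p == "log_conc" else config.grid_gamma
                for _, p in free]
        for combo in itertools.product(*axes):
            f = objective(np.array(combo))
            if f < best_f:
                best_x, best_f = np.array(combo), f
    else:
        if config.optimizer == "anneal+nelder_mead":
            x, fx = x0.copy(), f0
            t = config.t0
            sds = np.array([config.proposal_sd_logc if p == "log_conc"
                            else config.proposal_sd_gamma for _, p in free])
            while t > config.t_min:
                for _ in range(config.steps_per_t):
                    prop = x + rng.normal(0, sds)
                    prop = np.clip(prop, [b[0] for b in bounds], [b[1] for b in bounds])
                    fp = objective(prop)
                    if fp < fx or rng.random() < np.exp((fx - fp) / t):
                        x, fx = prop, fp
                    if fx < best_f:
                        best_x, best_f = x.copy(), fx
                t *= config.cooling
        res = optimize.minimize(objective, best_x, method="Nelder-Mead",
                                bounds=bounds,
                                options=dict(maxfev=config.nm_maxfev,
                                             fatol=config.nm_fatol, xatol=1e-3))
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun

    fitted = {}
    for (name, param), v, (lo, hi) in zip(free, best_x, bounds):
        v = float(np.clip(v, lo, hi))
        evaluator.set_param(name, param, v)
        fitted[(name, param)] = v
    return fitted, -best_f, trace


def kfold_split(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Random partition into k folds of near-equal size, stratified by
    label so every fold carries both labels when possible."""
    labels = np.asarray(labels, dtype=bool)
    n = len(labels)
    if n < k:
        raise ValueError("fewer regions than folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if labels.sum() < k or (~labels).sum() < k:
        import logging
        logging.getLogger(__name__).warning(
            "a label has fewer than k members; falling back to unstratified split")
        order = rng.permutation(n)
        return [np.sort(order[i::k]) for i in range(k)]
    for mask in (labels, ~labels):
        idx = rng.permutation(np.flatnonzero(mask))
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.sort(np.array(f)) for f in folds]


def cross_validate(evaluator: ModelEvaluator, free: list[FreeParam],
                   config: FitConfig,
                   folds: list[np.ndarray] | None = None) -> CVResult:
    """k independent fits on the train folds; rho evaluated on the held-out
    regions with the fold's fitted parameters."""
    if folds is None:
        folds = kfold_split(evaluator.labels, config.k_folds, config.seed)
    all_idx = np.arange(len(evaluator.regions))
    train_rhos, test_rhos, fitted = [], [], []
    x_start = {(f.name, p): getattr(f, p) for f in evaluator.factors
               for p in ("log_conc", "gamma")}
    for fold_i, test_idx in enumerate(folds):
        # reset start point so folds are independent
        for (name, param), v in x_start.items():
            evaluator.set_param(name, param, v)
        train_idx = np.setdiff1d(all_idx, test_idx)
        rng = np.random.default_rng([config.seed, fold_i])
        params, train_rho, _ = fit_model(evaluator, free, config, train_idx, rng)
        train_rhos.append(train_rho)
        test_rhos.append(evaluator.rho(test_idx))
        fitted.append(params)
    return CVResult(train_rhos, test_rhos, fitted, folds)


# ---------------------------------------------------------------------------
# Per-TF ranking
# ---------------------------------------------------------------------------


def shuffle_wm_columns(wm: WeightMatrix, seed: int) -> WeightMatrix:
    """Uniformly random permutation of WM positions; preserves composition
    and information content."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(wm.length)
    return WeightMatrix(f"{wm.name}_shuf", wm.probs[perm], wm.pseudocount)


def rank_tfs(nucleosome: FactorSpec, wms: list[WeightMatrix],
             genome: GenomeSequence, nucleosome_model: NucleosomeModel,
             regions: list[GenomicRegion], folds: list[np.ndarray],
             config: FitConfig, controls: set[str] | None = None,
             nuc_track: EnergyTrack | None = None) -> TFRanking:
    """Rank TFs by the paired z-statistic of their cross-validated quality
    gain over the nucleosome-only model.

    The nucleosome parameters stay fixed at their fitted optimum; for each
    TF, its (ln c, gamma) are fitted per fold on the training regions (the
    shared coarse grid by default) and the test-fold gain
    delta = rho(nuc+TF) - rho(nuc) is paired by fold: z = mean/SE.
    """
    controls = controls or set()
    all_idx = np.arange(len(regions))
    labels = labels_from_regions(regions)
    # baseline: fixed nucleosome-only model scored per test fold
    base_eval = ModelEvaluator([nucleosome], genome, nucleosome_model, regions,
                               tracks={"nucleosome": nuc_track} if nuc_track is not None else None)
    base_test = [base_eval.rho(test_idx) for test_idx in folds]
    rows = []
    for wm in wms:
        tf = FactorSpec(wm.name, "tf", wm.length, wm=wm, gamma=1.0, log_conc=-6.0)
        ev = ModelEvaluator([nucleosome, tf], genome, nucleosome_model, regions,
                            tracks={"nucleosome": base_eval.tracks["nucleosome"]})
        free = [(wm.name, "log_conc"), (wm.name, "gamma")]
        deltas = []
        if config.optimizer == "grid":
            # evaluate the shared grid once; per-fold selection on train rho
            grid_pts = list(itertools.product(config.grid_logc, config.grid_gamma))
            meds_list = []
            for lc, g in grid_pts:
                ev.set_param(wm.name, "log_conc", lc)
                ev.set_param(wm.name, "gamma", g)
                meds_list.append(ev.medians())
            for fold_i, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(all_idx, test_idx)
                best_pt, best_train = None, -np.inf
                for meds in meds_list:
                    mi, _ = max_mi_threshold(meds[train_idx], labels[train_idx])
                    r = mi / label_entropy(labels[train_idx])
                    if r > best_train:
                        best_train, best_pt = r, meds
                mi, _ = max_mi_threshold(best_pt[test_idx], labels[test_idx])
                test_rho = mi / label_entropy(labels[test_idx])
                deltas.append(test_rho - base_test[fold_i])
        else:
            for fold_i, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(all_idx, test_idx)
                ev.set_param(wm.name, "log_conc", -6.0)
                ev.set_param(wm.name, "gamma", 1.0)
                rng = np.random.default_rng([config.seed, fold_i])
                fit_model(ev, free, config, train_idx, rng)
                deltas.append(ev.rho(test_idx) - base_test[fold_i])
        deltas = np.asarray(deltas)
        mean = float(deltas.mean())
        se = float(deltas.std(ddof=1) / np.sqrt(len(deltas)))
        if se == 0.0:
            z = 0.0 if mean == 0.0 else float(np.sign(mean) * np.inf)
        else:
            z = mean / se
        rows.append(dict(tf=wm.name, mean_delta=mean, se=se, z=z,
                         control="shuffled" if wm.name in controls else "real"))
    df = pd.DataFrame(rows).sort_values("z", ascending=False).reset_index(drop=True)
    return TFRanking(df)


# ---------------------------------------------------------------------------
# Characterization and profiles
# ---------------------------------------------------------------------------


def characterize(evaluator: ModelEvaluator,
                 entropy_mode: str = "site_distribution") -> FactorCharacterization:
    """Coverage fraction, posterior-weighted site energy statistics, and
    binding-site entropy for every factor of a fitted model.

    phi_f = (l_f / L) * sum_j P_f(j).  Energies are the model's gamma-scaled
    energies in kT.  The default entropy is that of the normalized site
    distribution, S = -sum_j pi_j ln pi_j (high when coverage comes from
    many weak sites); ``entropy_mode="per_site"`` instead averages the
    binary entropy of individual site occupancies.
    """
    occ = evaluator.occupancy()
    rows = []
    for f in evaluator.factors:
        p = occ.posteriors[f.name]
        total = p.sum()
        if total <= 0:
            rows.append(dict(factor=f.name, phi=0.0, mean_energy=np.nan,
                             sd_energy=np.nan, entropy=np.nan, defined=False))
            continue
        phi = f.footprint / evaluator.L * total
        track = evaluator.tracks[f.name]
        if f.kind == "tf":
            # split each start's posterior over the two orientations
            wf = np.exp(-f.gamma * np.nan_to_num(track.e_fwd, nan=np.inf))
            wr = np.exp(-f.gamma * np.nan_to_num(track.e_rev, nan=np.inf))
            denom = np.where(wf + wr > 0, wf + wr, 1.0)
            e_site = np.concatenate([f.gamma * np.nan_to_num(track.e_fwd),
                                     f.gamma * np.nan_to_num(track.e_rev)])
            p_site = np.concatenate([p * wf / denom, p * wr / denom])
        else:
            mean_e = float(np.mean(track.e_fwd[track.valid]))
            e_site = f.gamma * (np.nan_to_num(track.e_fwd, nan=mean_e) - mean_e)
            p_site = p
        mean_E = float(np.sum(p_site * e_site) / total)
        sd_E = float(np.sqrt(max(np.sum(p_site * e_site**2) / total - mean_E**2, 0.0)))
        if entropy_mode == "site_distribution":
            pi = p_site[p_site > 0] / total
            s = float(-np.sum(pi * np.log(pi)))
        elif entropy_mode == "per_site":
            ps = p_site[(p_site > 0) & (p_site < 1)]
            s = float(np.mean(-ps * np.log(ps) - (1 - ps) * np.log1p(-ps))) if len(ps) else 0.0
        else:
            raise ValueError(f"unknown entropy_mode {entropy_mode!r}")
        rows.append(dict(factor=f.name, phi=float(phi), mean_energy=mean_E,
                         sd_energy=sd_E, entropy=s, defined=True))
    return FactorCharacterization(pd.DataFrame(rows))


def positional_profile(values: np.ndarray, anchors: list[tuple[int, str]],
                       window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average a per-base track around anchor positions, strand-aware.

    Returns (offsets, mean, n) where offsets run -window..window in anchor
    orientation (minus-strand anchors are flipped); out-of-bounds bases are
    skipped with per-offset counts kept.
    """
    if not anchors:
        raise ValueError("empty anchor list")
    L = len(values)
    offsets = np.arange(-window, window + 1)
    total = np.zeros(len(offsets))
    n = np.zeros(len(offsets), dtype=int)
    for pos, strand in anchors:
        rel = pos + offsets if strand == "+" else pos - offsets
        ok = (rel >= 0) & (rel < L)
        total[ok] += values[rel[ok]]
        n[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return offsets, mean, n
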