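"""Exact equilibrium statistics of non-overlapping binding configurations.

The model: every configuration of non-overlapping sites gets weight
prod_sites q_f(j), where q_f(j) = exp(ln c_f - gamma_f E_f(j) - E0_f).
The partition sum over all configurations and all per-site marginal
("posterior") probabilities are computed exactly by a forward/backward
recursion; a brute-force enumerator serves as an independent oracle on
small instances, and a stochastic traceback draws exact configuration
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .energy_models import FactorSpec, boltzmann_weights, scan_genome, nucleosome_energy, NucleosomeModel
from .io_formats import GenomeSequence

NORM_TOL = 1e-9


@dataclass
class BindingWeights:
    """Per-factor site Boltzmann weights indexed by start position."""

    names: list[str]
    footprints: np.ndarray  # (F,) int
    q: np.ndarray  # (F, L) float; q[f, j] = 0 at invalid starts
    L: int

    def __post_init__(self) -> None:
        self.footprints = np.asarray(self.footprints, dtype=np.int64)
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q < 0):
            raise ValueError("negative site weight")
        if self.q.shape != (len(self.names), self.L):
            raise ValueError("weight array shape mismatch")

    @classmethod
    def from_arrays(cls, names: list[str], footprints: list[int],
                    weights: list[np.ndarray], L: int) -> "BindingWeights":
        q = np.zeros((len(names), L))
        for fi, (l, w) in enumerate(zip(footprints, weights)):
            n = L - l + 1
            if n < 0:
                continue
            if len(w) != n:
                raise ValueError(f"{names[fi]}: expected {n} start weights, got {len(w)}")
            q[fi, :n] = w
        return cls(names, np.asarray(footprints, dtype=np.int64), q, L)


@dataclass
class PartitionSums:
    logF: np.ndarray  # (L+1,)
    logR: np.ndarray  # (L+1,)
    logZ: float


@dataclass
class OccupancyResult:
    """Site posteriors, per-base occupancies, and the free fraction."""

    names: list[str]
    posteriors: dict[str, np.ndarray] = field(default_factory=dict)  # per start
    occupancy: dict[str, np.ndarray] = field(default_factory=dict)  # per base
    free: np.ndarray | None = None


def build_binding_weights(factors: list[FactorSpec], genome: GenomeSequence,
                          nucleosome_model: NucleosomeModel | None = None,
                          tracks: dict | None = None) -> BindingWeights:
    """Scan the genome (or reuse precomputed energy tracks) and assemble the
    site weight arrays for all factors."""
    names, footprints, weights = [], [], []
    for f in factors:
        if tracks is not None and f.name in tracks:
            track = tracks[f.name]
        elif f.kind == "tf":
            track = scan_genome(f, genome)
        else:
            if nucleosome_model is None:
                raise ValueError("nucleosome factor requires a NucleosomeModel")
            track = nucleosome_energy(nucleosome_model, genome)
        names.append(f.name)
        footprints.append(f.footprint)
        weights.append(boltzmann_weights(f, track))
    return BindingWeights.from_arrays(names, footprints, weights, genome.length)


def forward_backward(weights: BindingWeights) -> PartitionSums:
    """Forward and backward log partition sums via the non-overlap recursion
    F(i) = F(i-1) + sum_f q_f(i - l_f) F(i - l_f)."""
    logF = _dp.forward_log(weights.q, weights.footprints)
    logR = _dp.backward_log(weights.q, weights.footprints)
    logZ = float(logF[-1])
    if not np.isclose(logZ, logR[0], rtol=1e-9, atol=1e-9):
        raise AssertionError(f"forward/backward disagree: {logZ} vs {logR[0]}")
    return PartitionSums(logF, logR, logZ)


def site_posteriors(sums: PartitionSums, weights: BindingWeights) -> OccupancyResult:
    """P_f(j) = F(j) q_f(j) R(j + l_f) / Z, and per-base occupancies.

    The free fraction satisfies sum_f n_f(i) + free(i) = 1 at every base,
    which is asserted.
    """
    L = weights.L
    result = OccupancyResult(list(weights.names))
    total = np.zeros(L)
    for fi, name in enumerate(weights.names):
        l = int(weights.footprints[fi])
        n = L - l + 1
        if n <= 0:
            result.posteriors[name] = np.zeros(0)
            result.occupancy[name] = np.zeros(L)
            continue
        q = weights.q[fi, :n]
        with np.errstate(divide="ignore"):
            logp = sums.logF[:n] + np.log(q) + sums.logR[l:l + n] - sums.logZ
        p = np.where(q > 0, np.exp(logp), 0.0)
        result.posteriors[name] = p
        # occupancy: n_f(i) = sum of P over starts covering base i
        cum = np.concatenate(([0.0], np.cumsum(p)))
        occ = np.empty(L)
        idx_hi = np.minimum(np.arange(L) + 1, n)
        idx_lo = np.maximum(np.arange(L) - l + 1, 0)
        occ = cum[idx_hi] - cum[idx_lo]
        result.occupancy[name] = occ
        total += occ
    result.free = 1.0 - total
    if np.any(np.abs(np.minimum(result.free, 0.0)) > NORM_TOL):
        raise AssertionError("occupancy normalization violated")
    return result


def compute_occupancy(factors: list[FactorSpec], genome: GenomeSequence,
                      nucleosome_model: NucleosomeModel | None = None,
                      tracks: dict | None = None) -> OccupancyResult:
    """Convenience: weights -> partition sums -> posteriors/occupancy."""
    w = build_binding_weights(factors, genome, nucleosome_model, tracks)
    return site_posteriors(forward_backward(w), w)


# ---------------------------------------------------------------------------
# Brute-force oracle (small instances only)
# ---------------------------------------------------------------------------


def _count_configurations(weights: BindingWeights) -> int:
    """Number of configurations with positive weight (integer DP)."""
    L = weights.L
    cnt = [0] * (L + 1)
    cnt[0] = 1
    for i in range(1, L + 1):
        c = cnt[i - 1]
        for fi in range(len(weights.names)):
            j = i - int(weights.footprints[fi])
            if j >= 0 and weights.q[fi, j] > 0:
                c += cnt[j]
        cnt[i] = c
    return cnt[L]


def brute_force(weights: BindingWeights, max_configs: int = 2_000_000
                ) -> tuple[float, dict[str, np.ndarray]]:
    """Exhaustively enumerate all non-overlapping configurations.

    Returns (Z, posteriors) by direct summation; refuses instances whose
    configuration count exceeds ``max_configs``.
    """
    if weights.L > 30:
        raise ValueError(f"instance too large for enumeration: L={weights.L}")
    n_cfg = _count_configurations(weights)
    if n_cfg > max_configs:
        raise ValueError(f"instance too large: ~{n_cfg} configurations")
    L = weights.L
    nf = len(weights.names)
    post = [np.zeros(L) for _ in range(nf)]
    z_total = 0.0
    # DFS over (position, accumulated weight, placed sites)
    stack: list[tuple[int, float, tuple]] = [(0, 1.0, ())]
    while stack:
        i, w, sites = stack.pop()
        if i == L:
            z_total += w
            for fi, j in sites:
                post[fi][j] += w
            continue
        stack.append((i + 1, w, sites))
        for fi in range(nf):
            l = int(weights.footprints[fi])
            if i + l <= L and weights.q[fi, i] > 0:
                stack.append((i + l, w * weights.q[fi, i], sites + ((fi, i),)))
    posteriors = {}
    for fi, name in enumerate(weights.names):
        l = int(weights.footprints[fi])
        n = max(L - l + 1, 0)
        posteriors[name] = post[fi][:n] / z_total
    return z_total, posteriors


# ---------------------------------------------------------------------------
# Sampling and configuration weights
# ---------------------------------------------------------------------------


def sample_configuration(sums: PartitionSums, weights: BindingWeights,
                         seed: int) -> list[tuple[str, int]]:
    """One exact configuration sample: list of (factor name, start)."""
    _, fis, starts = sample_configurations(sums, weights, 1, seed)
    return [(weights.names[fi], int(j)) for fi, j in zip(fis, starts)]


def sample_configurations(sums: PartitionSums, weights: BindingWeights,
                          n_samples: int, seed: int
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Many exact samples; returns (sample_id, factor_index, start) arrays."""
    p_free, site = _dp.traceback_probs(weights.q, weights.footprints, sums.logF)
    return _dp.sample_many(p_free, site, weights.footprints, n_samples, seed)


def validate_configuration(config: list[tuple[str, int]], weights: BindingWeights) -> None:
    ivals = []
    name_to_fi = {n: i for i, n in enumerate(weights.names)}
    for name, j in config:
        fi = name_to_fi[name]
        l = int(weights.footprints[fi])
        if j < 0 or j + l > weights.L:
            raise ValueError(f"site {name}@{j} out of bounds")
        ivals.append((j, j + l))
    ivals.sort()
    for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
        if s2 < e1:
            raise ValueError("overlapping sites in configuration")


def configuration_log_weight(config: list[tuple[str, int]],
                             weights: BindingWeights) -> float:
    """Sum of ln q over placed sites; exp(value - logZ) is the probability."""
    validate_configuration(config, weights)
    name_to_fi = {n: i for i, n in enumerate(weights.names)}
    total = 0.0
    for name, j in config:
        qv = weights.q[name_to_fi[name], j]
        if qv <= 0:
            raise ValueError(f"site {name}@{j} has zero weight")
        total += np.log(qv)
    return float(total)
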