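"""Sequence specificities as binding energies and Boltzmann weights.

Energies follow the mismatch convention: for a factor with weight matrix w,
E_spec(s) = sum_i [ln w(i, a_max_i) - ln w(i, s_i)] >= 0, so the consensus
sequence scores exactly 0 and every energy is in kT units (beta = 1).  A
specificity scale gamma multiplies E_spec on the Boltzmann exponent, so
gamma = 0 removes sequence preference entirely and gamma = 1 reproduces the
base model.  The sequence-independent offset E0 of each TF is fixed by
calibration: after calibration the genome-wide mean of exp(-gamma*E_spec - E0)
over all valid windows on both strands equals 1, which puts all factors on an
equal-overall-affinity footing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .io_formats import BASES, GenomeSequence, WeightMatrix

logger = logging.getLogger(__name__)

NUCLEOSOME_FOOTPRINT = 147


@dataclass
class FactorSpec:
    """One binding species: a TF or the nucleosome."""

    name: str
    kind: str  # {tf, nucleosome}
    footprint: int
    wm: WeightMatrix | None = None
    gamma: float = 1.0
    log_conc: float = 0.0
    e0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("tf", "nucleosome"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == "tf":
            if self.wm is None:
                raise ValueError(f"{self.name}: TF requires a weight matrix")
            if self.footprint != self.wm.length:
                raise ValueError(f"{self.name}: footprint != WM length")
        if self.gamma < 0:
            raise ValueError(f"{self.name}: gamma must be >= 0")
        if self.footprint < 1:
            raise ValueError(f"{self.name}: footprint must be >= 1")


@dataclass
class EnergyTrack:
    """Per-start specific binding energies across one chromosome.

    ``e_fwd[j]`` is the energy (kT) of the window starting at j on the
    forward strand; ``e_rev`` the reverse-complement window (TFs only; the
    nucleosome track is already strand-symmetrized).  ``valid[j]`` is False
    where the window contains N or runs off the chromosome end.
    """

    factor: str
    chrom: str
    e_fwd: np.ndarray
    e_rev: np.ndarray | None
    valid: np.ndarray


@dataclass
class NucleosomeModel:
    """Nucleosome sequence-specificity: a per-start energy track loaded from
    file, or the built-in dinucleotide model (16 log-propensities with a
    ~10.2 bp periodic cosine weighting across the 147 bp footprint)."""

    kind: str = "dinucleotide"  # {track, dinucleotide}
    track_values: np.ndarray | None = None
    propensities: np.ndarray = field(default_factory=lambda: default_dinucleotide_propensities())
    period: float = 10.2
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("track", "dinucleotide"):
            raise ValueError(f"unknown nucleosome model kind {self.kind!r}")
        if self.kind == "track" and self.track_values is None:
            raise ValueError("track model requires values")
        self.propensities = np.asarray(self.propensities, dtype=float)
        if self.propensities.shape != (4, 4):
            raise ValueError("propensities must be a 4x4 matrix (A,C,G,T order)")


def default_dinucleotide_propensities() -> np.ndarray:
    """Log-propensities favoring A/T dinucleotides and penalizing G/C runs,
    a qualitative stand-in for rotational-positioning sequence signals."""
    p = np.zeros((4, 4))
    A, C, G, T = 0, 1, 2, 3
    p[A, A] = p[T, T] = 0.25
    p[A, T] = p[T, A] = 0.15
    p[G, C] = p[C, G] = -0.15
    p[G, G] = p[C, C] = -0.10
    return p


# ---------------------------------------------------------------------------
# WM energies
# ---------------------------------------------------------------------------


def wm_energy(wm: WeightMatrix, segment: str) -> float:
    """Mismatch energy of one segment; NaN if the segment contains N."""
    if len(segment) != wm.length:
        raise ValueError(f"segment length {len(segment)} != WM length {wm.length}")
    logw = np.log(wm.probs)
    logmax = logw.max(axis=1)
    e = 0.0
    for i, base in enumerate(segment.upper()):
        if base == "N":
            return float("nan")
        e += logmax[i] - logw[i, BASES.index(base)]
    return e


def _scan_logw(codes: np.ndarray, logw: np.ndarray) -> np.ndarray:
    """Sum of per-position mismatch energies for every window start."""
    l = logw.shape[0]
    n = len(codes) - l + 1
    logmax = logw.max(axis=1)
    # pad column for N (index 4); contributes 0, masked by `valid`
    padded = np.hstack([logw, np.zeros((l, 1))])
    e = np.zeros(n)
    for i in range(l):
        e += logmax[i] - padded[i, codes[i:i + n]]
    return e


def scan_genome(factor: FactorSpec, genome: GenomeSequence) -> EnergyTrack:
    """Evaluate the factor's mismatch energy at every valid window start,
    on both strands for TFs."""
    l = factor.footprint
    if genome.length < l:
        logger.warning("%s: genome %s shorter than footprint", factor.name, genome.name)
        return EnergyTrack(factor.name, genome.name, np.empty(0), np.empty(0),
                           np.empty(0, dtype=bool))
    codes = genome.codes()
    n = genome.length - l + 1
    has_n = np.convolve((codes == 4).astype(float), np.ones(l), mode="valid") > 0
    valid = ~has_n
    logw = np.log(factor.wm.probs)
    e_fwd = _scan_logw(codes, logw)
    # reverse strand: energy of the reverse-complement window equals scanning
    # with the reverse-complemented WM on the forward sequence
    logw_rc = logw[::-1, ::-1]
    e_rev = _scan_logw(codes, logw_rc)
    e_fwd[~valid] = np.nan
    e_rev[~valid] = np.nan
    return EnergyTrack(factor.name, genome.name, e_fwd, e_rev, valid)


def nucleosome_energy(model: NucleosomeModel, genome: GenomeSequence) -> EnergyTrack:
    """Raw strand-symmetrized nucleosome energies E_K for all 147 bp windows.

    For the dinucleotide model, each window's score is the cosine-weighted
    sum of dinucleotide log-propensities; the energy is minus that score.
    Boltzmann weights of a window and its reverse complement are averaged
    before converting back to an energy, so the track is strand-symmetric.
    The returned energies are raw (not centered, not gamma-scaled).
    """
    L = genome.length
    l = NUCLEOSOME_FOOTPRINT
    if L < l:
        raise ValueError("genome shorter than the nucleosome footprint")
    n = L - l + 1
    if model.kind == "track":
        vals = np.asarray(model.track_values, dtype=float)
        if len(vals) != n:
            raise ValueError(
                f"nucleosome track has {len(vals)} values, expected {n} window starts")
        codes = genome.codes()
        has_n = np.convolve((codes == 4).astype(float), np.ones(l), mode="valid") > 0
        e = vals.copy()
        e[has_n] = np.nan
        return EnergyTrack("nucleosome", genome.name, e, None, ~has_n)

    codes = genome.codes()
    has_n = np.convolve((codes == 4).astype(float), np.ones(l), mode="valid") > 0
    valid = ~has_n
    a, b = codes[:-1], codes[1:]
    dinuc_ok = (a < 4) & (b < 4)
    prop = np.where(dinuc_ok, model.propensities[np.minimum(a, 3), np.minimum(b, 3)], 0.0)
    k = np.arange(l - 1)
    w = 1.0 + model.amplitude * np.cos(2 * np.pi * (k - (l - 1) / 2) / model.period)
    # forward score for window start s: sum_k prop[s+k] * w[k]
    score_fwd = fftconvolve(prop, w[::-1], mode="valid")
    # reverse-complement window: propensity rho_rc(a,b) = rho(comp b, comp a),
    # and the kernel runs in the opposite direction along the window
    comp = np.array([3, 2, 1, 0])
    prop_rc = np.where(dinuc_ok,
                       model.propensities[comp[np.minimum(b, 3)], comp[np.minimum(a, 3)]],
                       0.0)
    score_rev = fftconvolve(prop_rc, w, mode="valid")
    e_fwd = -score_fwd
    e_rev = -score_rev
    # strand symmetrization on the Boltzmann scale
    m = np.minimum(e_fwd, e_rev)
    e_sym = m - np.log(0.5 * (np.exp(m - e_fwd) + np.exp(m - e_rev)))
    e_sym[~valid] = np.nan
    return EnergyTrack("nucleosome", genome.name, e_sym, None, valid)


# ---------------------------------------------------------------------------
# Calibration, scaling, weights
# ---------------------------------------------------------------------------


def calibrate_e0(track: EnergyTrack, gamma: float) -> float:
    """E0 such that the mean of exp(-gamma*E - E0) over all valid windows
    (both strands for TFs) equals exactly 1."""
    es = [track.e_fwd[track.valid]]
    if track.e_rev is not None:
        es.append(track.e_rev[track.valid])
    e = np.concatenate(es)
    if e.size == 0:
        raise ValueError(f"{track.factor}: no valid windows to calibrate")
    # stable log-mean-exp
    mx = np.max(-gamma * e)
    return float(mx + np.log(np.mean(np.exp(-gamma * e - mx))))


def boltzmann_weights(factor: FactorSpec, track: EnergyTrack,
                      recalibrate: bool = True) -> np.ndarray:
    """Per-start site weights q(j) for the partition sum.

    TFs: q = exp(log_conc - E0) * [exp(-gamma*E_fwd) + exp(-gamma*E_rev)]
    (the two orientations are distinct site types sharing one concentration).
    Nucleosome: q = exp(log_conc - gamma*(E - mean E)) — centering absorbs
    the mean into the concentration so gamma acts purely on the variation.
    Invalid windows get weight 0.
    """
    if factor.kind == "tf":
        if recalibrate:
            factor.e0 = calibrate_e0(track, factor.gamma)
        q = np.exp(factor.log_conc - factor.gamma * track.e_fwd - factor.e0)
        q = q + np.exp(factor.log_conc - factor.gamma * track.e_rev - factor.e0)
    else:
        mean_e = float(np.mean(track.e_fwd[track.valid]))
        factor.e0 = 0.0
        q = np.exp(factor.log_conc - factor.gamma * (track.e_fwd - mean_e))
    q = np.where(track.valid, q, 0.0)
    return np.nan_to_num(q, nan=0.0)


def scaled_nucleosome_energy(track: EnergyTrack, gamma: float) -> np.ndarray:
    """gamma * (E_K - mean E_K): the genome-wide SD scales linearly in gamma."""
    mean_e = float(np.mean(track.e_fwd[track.valid]))
    return gamma * (track.e_fwd - mean_e)


def rescale_wm(wm: WeightMatrix, gamma: float) -> WeightMatrix:
    """w'(i,a) = w(i,a)^gamma / sum_b w(i,b)^gamma (gamma=0 gives uniform)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    logp = gamma * np.log(wm.probs)
    logp -= logp.max(axis=1, keepdims=True)
    p = np.maximum(np.exp(logp), 1e-300)  # keep entries strictly positive
    p /= p.sum(axis=1, keepdims=True)
    return WeightMatrix(wm.name, p, wm.pseudocount)


def information_content(wm: WeightMatrix, gamma: float = 1.0,
                        background: np.ndarray | None = None) -> float:
    """Information content in bits of the gamma-rescaled matrix against the
    background (default uniform)."""
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background must sum to 1")
    w = rescale_wm(wm, gamma).probs
    if np.any((background == 0) & (w.sum(axis=0) > 0)):
        raise ValueError("zero background entry with nonzero weight")
    return float(np.sum(w * np.log2(w / background)))
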