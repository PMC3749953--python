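"""Numba kernels for the partition-sum recursions and stochastic traceback.

The forward/backward sums are computed in the linear domain with block
rescaling: values are kept relative to a carried log scale that is bumped
whenever the running sum exceeds 1e100, and per-position log scales are
recorded so that exact log partition sums are recovered at the end.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_RESCALE = 1e100


@njit(cache=True)
def forward_log(q: np.ndarray, footprints: np.ndarray) -> np.ndarray:
    """log F(i) for i = 0..L, F(i) = partition sum over the first i bases.

    q has shape (n_factors, L): q[f, j] is the weight of a site of factor f
    starting at j (0 beyond the last valid start).
    """
    nf, L = q.shape
    f = np.empty(L + 1)
    cum = np.empty(L + 1)
    f[0] = 1.0
    cum[0] = 0.0
    cur = 0.0
    for i in range(1, L + 1):
        d = cum[i - 1] - cur
        tot = f[i - 1] if d == 0.0 else f[i - 1] * np.exp(d)
        for fi in range(nf):
            j = i - footprints[fi]
            if j >= 0:
                qv = q[fi, j]
                if qv > 0.0:
                    d = cum[j] - cur
                    tot += qv * f[j] if d == 0.0 else qv * f[j] * np.exp(d)
        if tot > _RESCALE:
            cur += np.log(tot)
            tot = 1.0
        f[i] = tot
        cum[i] = cur
    return np.log(f) + cum


@njit(cache=True)
def backward_log(q: np.ndarray, footprints: np.ndarray) -> np.ndarray:
    """log R(i) for i = 0..L, R(i) = partition sum over bases i..L-1."""
    nf, L = q.shape
    r = np.empty(L + 1)
    cum = np.empty(L + 1)
    r[L] = 1.0
    cum[L] = 0.0
    cur = 0.0
    for i in range(L - 1, -1, -1):
        d = cum[i + 1] - cur
        tot = r[i + 1] if d == 0.0 else r[i + 1] * np.exp(d)
        for fi in range(nf):
            j = i + footprints[fi]
            if j <= L:
                qv = q[fi, i]
                if qv > 0.0:
                    d = cum[j] - cur
                    tot += qv * r[j] if d == 0.0 else qv * r[j] * np.exp(d)
        if tot > _RESCALE:
            cur += np.log(tot)
            tot = 1.0
        r[i] = tot
        cum[i] = cur
    return np.log(r) + cum


def traceback_probs(q: np.ndarray, footprints: np.ndarray, logF: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-position traceback choice probabilities.

    p_free[i] = F(i-1)/F(i) is the probability that base i-1 is unbound
    given the configuration right of i; site[f, i] = q_f(i-l_f) F(i-l_f)/F(i)
    the probability that a site of factor f ends at i.  Together they sum
    to 1 at every i, so the traceback needs no transcendentals.
    """
    nf, L = q.shape
    p_free = np.zeros(L + 1)
    p_free[1:] = np.exp(logF[:-1] - logF[1:])
    site = np.zeros((nf, L + 1))
    for fi in range(nf):
        l = int(footprints[fi])
        if l <= L:
            with np.errstate(divide="ignore"):
                lw = np.log(q[fi, :L - l + 1])
            site[fi, l:] = np.where(np.isfinite(lw),
                                    np.exp(lw + logF[:L - l + 1] - logF[l:]), 0.0)
    return p_free, site


@njit(cache=True)
def sample_many(p_free: np.ndarray, site: np.ndarray, footprints: np.ndarray,
                n_samples: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw n_samples exact configurations by stochastic traceback.

    Returns (sample_id, factor_index, start) arrays, one row per placed site.
    At each position i the choice between "free step" and "site of factor f
    ending at i" is made with the precomputed probabilities, so each
    configuration is drawn exactly from the Boltzmann distribution.
    """
    np.random.seed(seed)
    nf = site.shape[0]
    L = p_free.shape[0] - 1
    cap = 256
    out_s = np.empty(cap, dtype=np.int64)
    out_f = np.empty(cap, dtype=np.int64)
    out_j = np.empty(cap, dtype=np.int64)
    count = 0
    for s in range(n_samples):
        i = L
        while i > 0:
            u = np.random.random()
            if u < p_free[i]:
                i -= 1
                continue
            acc = p_free[i]
            chosen = -1
            for fi in range(nf):
                acc += site[fi, i]
                if u < acc:
                    chosen = fi
                    break
            if chosen < 0:
                # numerical remainder: attribute to the last positive option
                for fi in range(nf - 1, -1, -1):
                    if site[fi, i] > 0.0:
                        chosen = fi
                        break
                if chosen < 0:
                    i -= 1
                    continue
            j = i - footprints[chosen]
            if count >= cap:
                cap *= 2
                ns = np.empty(cap, dtype=np.int64)
                nfarr = np.empty(cap, dtype=np.int64)
                nj = np.empty(cap, dtype=np.int64)
                ns[:count] = out_s
                nfarr[:count] = out_f
                nj[:count] = out_j
                out_s, out_f, out_j = ns, nfarr, nj
            out_s[count] = s
            out_f[count] = chosen
            out_j[count] = j
            count += 1
            i = j
    return out_s[:count], out_f[:count], out_j[:count]
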