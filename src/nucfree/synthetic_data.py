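"""Fully synthetic study scenarios with recorded ground truth.

A scenario bundles a random genome with planted structure, a TF collection
(a few causal TFs whose consensus sites are planted in promoter windows,
the rest decoys), a ground-truth binding model, exact configuration samples
converted into noisy multi-dataset read midpoints, gene annotations, and a
toy protein-link table.  Every generator is a pure function of its
parameters and seed.

Two kinds of planted structure mirror the two mechanisms under study:

* ``phasing`` — gene-body "slots" carry a ~10 bp periodic A/T dinucleotide
  composition that the built-in nucleosome model recognizes, so nucleosome
  positioning there is sequence-driven;
* ``nfr carving`` — causal TF consensus sites planted in promoter windows
  let TF binding exclude nucleosomes and carve NFRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy_models import (NUCLEOSOME_FOOTPRINT, FactorSpec, NucleosomeModel,
                            information_content, rescale_wm)
from .io_formats import (BASES, GeneAnnotation, GenomeSequence, LinkTable,
                         WeightMatrix, reverse_complement)
from .thermo_core import build_binding_weights, forward_backward, sample_configurations

import pandas as pd

SCENARIO_NAMES = ("phasing_only", "nfr_carving", "mixed", "null")

# Default study conditions (frozen; see docs/methods.md)
DEFAULTS = dict(
    genome_length=200_000,
    gc=0.39,
    n_genes=40,
    n_tfs=20,
    causal_tf_count=3,
    wm_length=8,
    causal_wm_bits=10.0,
    decoy_wm_bits=(7.0, 13.0),
    n_datasets=4,
    cells_per_dataset=2000,
    reads_per_nucleosome=0.05,
    pos_noise_sd=20.0,
    site_mutation_rate=0.05,
    gene_spacing=5000,
    gene_body=1650,
    nuc_spacing=165,
    phasing_bias=0.12,
    gamma_nuc=1.0,
    log_conc_nuc=1.0,
    causal_gamma=1.0,
    causal_log_conc=-4.0,
)


@dataclass
class Scenario:
    name: str
    seed: int
    genome: GenomeSequence
    nucleosome_model: NucleosomeModel
    factors: list[FactorSpec]  # truth model: nucleosome + causal TFs
    wms: list[WeightMatrix]  # full collection (causal + decoys)
    causal: list[str]
    planted_sites: list[tuple[str, int, str]]
    genes: list[GeneAnnotation]
    datasets: list[np.ndarray]  # read midpoints per dataset
    links: LinkTable
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------


def generate_genome(length: int, gc: float, seed: int) -> GenomeSequence:
    """I.i.d. bases at the given G+C fraction."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0 < gc < 1):
        raise ValueError("gc must be strictly inside (0,1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.array(list(BASES)), size=length, p=p)
    return GenomeSequence("chr1", "".join(seq))


def generate_wm(length: int, target_bits: float, seed: int,
                tol: float = 0.1, name: str | None = None) -> WeightMatrix:
    """Dirichlet-drawn rows sharpened/flattened (by exponent bisection)
    until the information content is within ``tol`` bits of the target."""
    if not (0 <= target_bits <= 2 * length):
        raise ValueError("target_bits must be in [0, 2*length]")
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(np.ones(4), size=length)
    rows = np.maximum(rows, 1e-6)
    rows /= rows.sum(axis=1, keepdims=True)
    base = WeightMatrix(name or f"wm{seed}", rows)
    if target_bits <= tol:
        return rescale_wm(base, 0.0)
    lo, hi = 0.0, 1.0
    while information_content(base, hi) < target_bits:
        hi *= 2
        if hi > 1e6:
            if 2 * length - target_bits <= tol:
                return rescale_wm(base, hi)
            raise ValueError(f"target {target_bits} bits unreachable for length {length}")
    mid = (lo + hi) / 2
    for _ in range(200):
        mid = (lo + hi) / 2
        ic = information_content(base, mid)
        if abs(ic - target_bits) <= tol / 2:
            break
        if ic < target_bits:
            lo = mid
        else:
            hi = mid
    return rescale_wm(base, mid)


# ---------------------------------------------------------------------------
# Genome structure
# ---------------------------------------------------------------------------


@dataclass
class _GeneLayout:
    gene: GeneAnnotation
    promoter: tuple[int, int]
    site_slots: list[int]  # planted-site start positions (forward coords)
    nuc_dyads: list[int]


def _layout_genes(p: dict) -> list[_GeneLayout]:
    layouts = []
    body = p["gene_body"]
    n_slots = max((body - 180) // p["nuc_spacing"] + 1, 1)
    for i in range(p["n_genes"]):
        tss = 2500 + i * p["gene_spacing"]
        strand = "+" if i % 2 == 0 else "-"
        # promoter architecture: NFR carved over roughly [-210, -50] by TF
        # sites, +1 nucleosome flush with the NFR edge (dyad ~ +45)
        if strand == "+":
            tes = tss + body - 1
            promoter = (tss - 500, tss + 100)
            sites = [tss - 200, tss - 130, tss - 60]
            dyads = [tss + 45 + k * p["nuc_spacing"] for k in range(n_slots)]
        else:
            tes = tss - body + 1
            promoter = (tss - 100, tss + 500)
            sites = [tss + 53, tss + 123, tss + 193]
            dyads = [tss - 45 - k * p["nuc_spacing"] for k in range(n_slots)]
        gene = GeneAnnotation(f"gene{i:03d}", "chr1", strand, tss, tes)
        layouts.append(_GeneLayout(gene, promoter, sites, dyads))
    return layouts


def _phased_slot(rng: np.random.Generator, bias: float, period: float = 10.2) -> str:
    """147 bp with A/T vs G/C composition oscillating at the nucleosome
    rotational period, anchored at the dyad."""
    l = NUCLEOSOME_FOOTPRINT
    k = np.arange(l)
    ph = np.cos(2 * np.pi * (k - l // 2) / period)
    p_at = 0.25 + bias * ph
    probs = np.stack([p_at / 1, (0.5 - p_at), (0.5 - p_at), p_at], axis=1)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(l)
    cum = np.cumsum(probs, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return "".join(BASES[i] for i in idx)


def _mutate(site: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return site
    out = list(site)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([x for x in BASES if x != b])
    return "".join(out)


def build_truth_model(p: dict, seed: int) -> tuple[GenomeSequence, list[WeightMatrix],
                                                   list[str], list[tuple[str, int, str]],
                                                   list[_GeneLayout]]:
    """Genome with planted structure, the WM collection, and the planted
    sites.  Causal TFs get their (lightly mutated) consensus planted in
    every promoter; decoys get no planted sites; gene bodies optionally get
    the periodic phasing composition."""
    rng = np.random.default_rng(seed)
    genome = generate_genome(p["genome_length"], p["gc"], seed)
    seq = list(genome.residues)
    layouts = _layout_genes(p)

    n_tfs, n_causal = p["n_tfs"], p["causal_tf_count"]
    if not (n_tfs >= n_causal >= 0):
        raise ValueError("need n_tfs >= causal_tf_count >= 0")
    wms = []
    for t in range(n_tfs):
        bits = (p["causal_wm_bits"] if t < n_causal
                else float(rng.uniform(*p["decoy_wm_bits"])))
        wms.append(generate_wm(p["wm_length"], bits, seed=seed * 1000 + t + 1,
                               name=f"TF{t:02d}"))
    causal = [wm.name for wm in wms[:n_causal]]

    if p.get("phasing", False):
        for lay in layouts:
            for dyad in lay.nuc_dyads:
                s = dyad - NUCLEOSOME_FOOTPRINT // 2
                if s < 0 or s + NUCLEOSOME_FOOTPRINT > len(seq):
                    continue
                seq[s:s + NUCLEOSOME_FOOTPRINT] = _phased_slot(rng, p["phasing_bias"])

    planted: list[tuple[str, int, str]] = []
    if p.get("carving", False) and n_causal:
        for gi, lay in enumerate(layouts):
            for si, pos in enumerate(lay.site_slots):
                tf = wms[(gi + si) % n_causal]
                site = _mutate(tf.consensus(), p["site_mutation_rate"], rng)
                strand = lay.gene.strand
                if strand == "-":
                    site = reverse_complement(site)
                if pos < 0 or pos + len(site) > len(seq):
                    continue
                seq[pos:pos + len(site)] = site
                planted.append((tf.name, pos, strand))

    genome = GenomeSequence("chr1", "".join(seq))
    return genome, wms, causal, planted, layouts


# ---------------------------------------------------------------------------
# Dataset sampling
# ---------------------------------------------------------------------------


def sample_datasets(factors: list[FactorSpec], genome: GenomeSequence,
                    nucleosome_model: NucleosomeModel, n_datasets: int,
                    cells_per_dataset: int, reads_per_nucleosome: float,
                    pos_noise_sd: float, seed: int) -> list[np.ndarray]:
    """Exact configuration samples converted to noisy read midpoints.

    Each dataset draws ``cells_per_dataset`` configurations from the truth
    model; every placed nucleosome emits Poisson(reads_per_nucleosome)
    midpoints at its dyad plus Gaussian positional noise.  Datasets differ
    only by their derived seeds.
    """
    weights = build_binding_weights(factors, genome, nucleosome_model)
    sums = forward_backward(weights)
    nuc_idx = weights.names.index("nucleosome")
    datasets = []
    for d in range(n_datasets):
        sub = (seed * 7919 + d * 104729 + 1) % (2**31 - 1)
        rng = np.random.default_rng(sub)
        _, fi, starts = sample_configurations(sums, weights, cells_per_dataset, int(sub))
        dyads = starts[fi == nuc_idx] + NUCLEOSOME_FOOTPRINT // 2
        n_reads = rng.poisson(reads_per_nucleosome, size=len(dyads))
        mids = np.repeat(dyads, n_reads).astype(float)
        if pos_noise_sd > 0:
            mids = mids + rng.normal(0, pos_noise_sd, size=len(mids))
        mids = np.clip(np.rint(mids), 0, genome.length - 1).astype(int)
        datasets.append(np.sort(mids))
    return datasets


# ---------------------------------------------------------------------------
# Toy protein-link table
# ---------------------------------------------------------------------------

_HISTONES = ["H2A", "H2B", "H3", "H4"]
_REMODELERS = [f"REM{i}" for i in range(1, 6)]
_MODIFIERS = [f"MOD{i}" for i in range(1, 6)]

LINK_CATEGORIES = {
    "histones": set(_HISTONES),
    "remodelers": set(_REMODELERS),
    "modifiers": set(_MODIFIERS),
}


def _toy_links(wms: list[WeightMatrix], causal: list[str],
               rng: np.random.Generator) -> LinkTable:
    rows = []
    partners = _REMODELERS + _MODIFIERS + _HISTONES
    for wm in wms:
        if wm.name in causal:
            chosen = rng.choice(_REMODELERS, size=3, replace=False)
            for other in chosen:
                rows.append((wm.name, other, int(rng.integers(600, 950))))
            rows.append((wm.name, rng.choice(_MODIFIERS), int(rng.integers(500, 900))))
        else:
            if rng.random() < 0.4:
                rows.append((wm.name, rng.choice(partners), int(rng.integers(150, 650))))
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])
    return LinkTable(df)


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

_SCENARIO_FLAGS = {
    "phasing_only": dict(phasing=True, carving=False, gamma_nuc=1.0),
    "nfr_carving": dict(phasing=False, carving=True, gamma_nuc=0.3,
                        causal_tf_count=1),
    "mixed": dict(phasing=True, carving=True, gamma_nuc=0.5),
    "null": dict(phasing=False, carving=False, gamma_nuc=0.0,
                 causal_tf_count=0),
}


def make_scenario(name: str, seed: int, **overrides) -> Scenario:
    """Assemble one of the named study scenarios.

    phasing_only: sequence-driven nucleosome arrays, no causal TFs bound.
    nfr_carving: causal TFs carve promoter NFRs; weak nucleosome specificity.
    mixed: both mechanisms.  null: no planted structure at all.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; options: {SCENARIO_NAMES}")
    p = dict(DEFAULTS)
    p.update(_SCENARIO_FLAGS[name])
    p.update(overrides)

    genome, wms, causal, planted, layouts = build_truth_model(p, seed)
    model = NucleosomeModel()
    factors = [FactorSpec("nucleosome", "nucleosome", NUCLEOSOME_FOOTPRINT,
                          gamma=p["gamma_nuc"], log_conc=p["log_conc_nuc"])]
    if p.get("carving", False):
        for wm in wms:
            if wm.name in causal:
                factors.append(FactorSpec(wm.name, "tf", wm.length, wm=wm,
                                          gamma=p["causal_gamma"],
                                          log_conc=p["causal_log_conc"]))
    datasets = sample_datasets(factors, genome, model, p["n_datasets"],
                               p["cells_per_dataset"], p["reads_per_nucleosome"],
                               p["pos_noise_sd"], seed)
    rng = np.random.default_rng(seed + 17)
    links = _toy_links(wms, causal, rng)
    genes = [lay.gene for lay in layouts]
    truth = dict(p)
    truth.update(name=name, seed=seed, causal=list(causal))
    return Scenario(name, seed, genome, model, factors, wms, causal, planted,
                    genes, datasets, links, truth)


def write_scenario(sc: Scenario, outdir) -> None:
    """Write a scenario as plain-text files (genome.fa, wms.pfm, genes.gff,
    datasets/*.tsv, links.tsv, truth.yml)."""
    import yaml
    from pathlib import Path

    from . import io_formats as io

    out = Path(outdir)
    (out / "datasets").mkdir(parents=True, exist_ok=True)
    io.write_fasta([sc.genome], out / "genome.fa")
    io.write_wm(sc.wms, out / "wms.pfm")
    io.write_genes_gff3(sc.genes, out / "genes.gff")
    io.write_links(sc.links, out / "links.tsv")
    for i, mids in enumerate(sc.datasets):
        df = pd.DataFrame({"chrom": sc.genome.name, "midpoint": mids})
        io.write_midpoints(df, out / "datasets" / f"ds{i}.tsv")
    truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in sc.truth.items()}
    truth["planted_sites"] = [list(t) for t in sc.planted_sites]
    (out / "truth.yml").write_text(yaml.safe_dump(truth, sort_keys=True))
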