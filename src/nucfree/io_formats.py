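"""Readers/writers for the external text formats and the shared domain types.

All interval containers are 0-based half-open internally.  Formats that use
other conventions (GFF3, fixedStep wiggle: 1-based) are converted at the
boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """A chromosome/contig: uppercase residues over {A,C,G,T,N}."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.name}: unexpected residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def codes(self) -> np.ndarray:
        """Integer encoding A=0 C=1 G=2 T=3 N=4."""
        table = np.full(256, 4, dtype=np.int8)
        for b, i in BASE_INDEX.items():
            table[ord(b)] = i
        return table[np.frombuffer(self.residues.encode(), dtype=np.uint8)]


@dataclass
class WeightMatrix:
    """Per-position nucleotide probabilities of a TF binding site.

    ``probs`` has shape (length, 4) in A,C,G,T order; every row sums to 1
    and all entries are strictly positive (a pseudocount / floor is applied
    at load time).
    """

    name: str
    probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"{self.name}: weight matrix must be (L, 4)")
        if self.probs.shape[0] < 1:
            raise ValueError(f"{self.name}: weight matrix of length 0")
        rows = self.probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: rows do not sum to 1 (got {rows})")
        if np.any(self.probs <= 0):
            raise ValueError(f"{self.name}: non-positive entries after regularization")

    @property
    def length(self) -> int:
        return int(self.probs.shape[0])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))


@dataclass
class GenomicRegion:
    chrom: str
    start: int
    end: int
    label: str  # {nucleosome, linker}
    subclass: str = "none"  # {short_linker, NFR, none}
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end})")
        if self.subclass != "none" and self.label != "linker":
            raise ValueError("subclass only applies to linkers")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class CoverageTrack:
    chrom: str
    values: np.ndarray
    basis: str = "signal"  # {signal, probability, reads}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.basis == "probability":
            if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
                raise ValueError("probability track has values outside [0,1]")


@dataclass
class LinkTable:
    """Protein-protein links with an integer evidence score."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["protein_a", "protein_b", "score"]))

    def __post_init__(self) -> None:
        df = self.df
        if (df["protein_a"] == df["protein_b"]).any():
            raise ValueError("self-links not allowed")
        if (df["score"] < 0).any():
            raise ValueError("negative evidence scores")

    def filtered(self, cutoff: int) -> pd.DataFrame:
        return self.df[self.df["score"] >= cutoff]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("no FASTA records in %s", path)
    return [GenomeSequence(rec.id, str(rec.seq)) for rec in records]


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, s.length, width):
                fh.write(s.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Weight matrices (JASPAR pfm / TRANSFAC-like)
# ---------------------------------------------------------------------------


def _regularize(mat: np.ndarray, name: str, pseudocount: float) -> np.ndarray:
    """Counts get the pseudocount; probability rows get a small floor."""
    rows = mat.sum(axis=1)
    if np.any(rows <= 0) and pseudocount <= 0:
        raise ValueError(f"{name}: all-zero row and no pseudocount")
    if np.allclose(rows, 1.0, atol=1e-6):  # already probabilities
        mat = np.maximum(mat, 1e-6)
    else:
        mat = mat + pseudocount
    return mat / mat.sum(axis=1, keepdims=True)


def read_wm(path: str | Path, pseudocount: float = 0.5) -> list[WeightMatrix]:
    """Read TRANSFAC-like or JASPAR pfm matrix text.

    JASPAR: ``>name`` then four lines (optionally ``A [ ... ]``), one per base.
    TRANSFAC-like: ``NA name`` / ``P0 A C G T`` header then numbered rows.
    """
    text = Path(path).read_text()
    matrices: list[WeightMatrix] = []
    name = None
    jaspar_rows: list[list[float]] = []
    transfac_rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, jaspar_rows, transfac_rows
        if name is None and not (jaspar_rows or transfac_rows):
            return
        if jaspar_rows:
            if len(jaspar_rows) != 4:
                raise ValueError(f"{path}: matrix {name!r} needs 4 base rows")
            mat = np.array(jaspar_rows, dtype=float).T
        elif transfac_rows:
            mat = np.array(transfac_rows, dtype=float)
        else:
            raise ValueError(f"{path}: matrix {name!r} has no rows")
        if mat.shape[0] < 1:
            raise ValueError(f"{path}: matrix {name!r} has length 0")
        mat = _regularize(mat, name or "wm", pseudocount)
        matrices.append(WeightMatrix(name or f"wm{len(matrices)}", mat, pseudocount))
        name, jaspar_rows, transfac_rows = None, [], []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line == "//" or line == "XX":
            if line == "//":
                flush()
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
            continue
        if line.startswith("NA"):
            flush()
            name = line.split(maxsplit=1)[1].strip()
            continue
        if line.startswith(("P0", "PO")):
            continue
        fields = line.replace("[", " ").replace("]", " ").split()
        if fields[0].upper() in ("A", "C", "G", "T"):
            # JASPAR base row; file order must be A,C,G,T
            try:
                jaspar_rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell") from exc
            continue
        # TRANSFAC numbered row: index A C G T [consensus]
        try:
            vals = [float(x) for x in fields[1:5]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell") from exc
        if len(vals) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 base counts")
        transfac_rows.append(vals)
    flush()
    return matrices


def write_wm(wms: Iterable[WeightMatrix], path: str | Path) -> None:
    """Write matrices as JASPAR-style probability pfm blocks."""
    with open(path, "w") as fh:
        for wm in wms:
            fh.write(f">{wm.name}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{v:.6f}" for v in wm.probs[:, bi])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# BED regions / genes
# ---------------------------------------------------------------------------

_LABEL_TO_FIELDS = {
    "nucleosome": ("nucleosome", "none"),
    "linker": ("linker", "none"),
    "linker_short": ("linker", "short_linker"),
    "linker_NFR": ("linker", "NFR"),
}
_FIELDS_TO_LABEL = {v: k for k, v in _LABEL_TO_FIELDS.items()}


def read_regions(path: str | Path) -> list[GenomicRegion]:
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = f[3] if len(f) > 3 else "nucleosome"
            label, subclass = _LABEL_TO_FIELDS.get(name, (name, "none"))
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                score = float(f[4])
            regions.append(GenomicRegion(f[0], start, end, label, subclass, score))
    return regions


def write_regions(regions: Sequence[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = _FIELDS_TO_LABEL.get((r.label, r.subclass), r.label)
            score = "." if r.score is None else repr(r.score)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\n")


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    """BED6/BED12 gene lines; TSS is the 5' end on the annotated strand."""
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: need >= 6 columns for strand")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if strand == "+":
                tss, tes = start, end - 1
            else:
                tss, tes = end - 1, start
            genes.append(GeneAnnotation(name, chrom, strand, tss, tes))
    return genes


def read_genes_gff3(path: str | Path, feature: str = "gene") -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 line needs 9 columns")
            if f[2] != feature:
                continue
            chrom, start1, end1, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                elif kv.startswith("Name=") and gene_id is None:
                    gene_id = kv[5:]
            if gene_id is None:
                gene_id = f"{chrom}:{start}-{end}"
            if strand == "+":
                tss, tes = start, end - 1
            else:
                tss, tes = end - 1, start
            genes.append(GeneAnnotation(gene_id, chrom, strand, tss, tes))
    return genes


def write_genes_gff3(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = sorted((g.tss, g.tes))
            fh.write(f"{g.chrom}\tnucfree\tgene\t{lo + 1}\t{hi + 1}\t.\t{g.strand}\t."
                     f"\tID={g.gene_id}\n")


# ---------------------------------------------------------------------------
# Coverage tracks: bedGraph and fixedStep wiggle
# ---------------------------------------------------------------------------


def read_track(path: str | Path, length: int | None = None, fill: float = 0.0,
               basis: str = "signal") -> CoverageTrack:
    """Read a bedGraph or fixedStep wiggle file into a per-base track.

    Sparse gaps are filled with ``fill``.  ``length`` extends/validates the
    chromosome length; if omitted it is inferred from the last interval.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith(("#", "track", "browser"))]
    if any(ln.startswith("fixedStep") for ln in lines):
        return _read_wiggle(lines, length, fill, basis)
    chrom = None
    ivals: list[tuple[int, int, float]] = []
    for ln in lines:
        f = ln.split()
        if len(f) < 4:
            raise ValueError(f"{path}: malformed bedGraph line {ln!r}")
        chrom = chrom or f[0]
        ivals.append((int(f[1]), int(f[2]), float(f[3])))
    ivals.sort()
    for (s1, e1, _), (s2, _, _) in zip(ivals, ivals[1:]):
        if s2 < e1:
            raise ValueError(f"{path}: overlapping bedGraph intervals at {s2}")
    L = length if length is not None else (ivals[-1][1] if ivals else 0)
    values = np.full(L, fill, dtype=float)
    for s, e, v in ivals:
        values[s:e] = v
    return CoverageTrack(chrom or "chr", values, basis)


def _read_wiggle(lines: list[str], length: int | None, fill: float, basis: str) -> CoverageTrack:
    chrom = "chr"
    pos = 0
    step = span = 1
    chunks: list[tuple[int, float]] = []
    for ln in lines:
        if ln.startswith("fixedStep"):
            kv = dict(part.split("=") for part in ln.split()[1:])
            chrom = kv.get("chrom", chrom)
            pos = int(kv["start"]) - 1  # wiggle is 1-based
            step = int(kv.get("step", 1))
            span = int(kv.get("span", 1))
            continue
        v = float(ln)
        for k in range(span):
            chunks.append((pos + k, v))
        pos += step
    L = length if length is not None else (max(p for p, _ in chunks) + 1 if chunks else 0)
    values = np.full(L, fill, dtype=float)
    for p, v in chunks:
        values[p] = v
    return CoverageTrack(chrom, values, basis)


def write_track(track: CoverageTrack, path: str | Path, fmt: str = "bedgraph") -> None:
    values = track.values
    with open(path, "w") as fh:
        if fmt == "bedgraph":
            if len(values) == 0:
                return
            # run-length merge of equal adjacent values (lossless)
            breaks = np.flatnonzero(np.diff(values) != 0) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(values)]))
            for s, e in zip(starts, ends):
                fh.write(f"{track.chrom}\t{s}\t{e}\t{float(values[s]):.17g}\n")
        elif fmt == "wiggle":
            fh.write(f"fixedStep chrom={track.chrom} start=1 step=1\n")
            for v in values:
                fh.write(f"{float(v):.17g}\n")
        else:
            raise ValueError(f"unknown track format {fmt!r}")


# ---------------------------------------------------------------------------
# Link tables / midpoints
# ---------------------------------------------------------------------------


def read_links(path: str | Path) -> LinkTable:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["protein_a", "protein_b", "score"], header=None,
                     dtype={"protein_a": str, "protein_b": str})
    if len(df) and df.iloc[0]["protein_a"] == "protein_a":  # header present
        df = df.iloc[1:].reset_index(drop=True)
    df["score"] = df["score"].astype(int)
    return LinkTable(df)


def write_links(links: LinkTable, path: str | Path) -> None:
    links.df.to_csv(path, sep="\t", header=False, index=False)


def read_midpoints(path: str | Path) -> pd.DataFrame:
    """TSV of read midpoints: columns chrom, midpoint."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["chrom", "midpoint"],
                     header=None, dtype={"chrom": str})
    if len(df) and str(df.iloc[0]["chrom"]) == "chrom":
        df = df.iloc[1:].reset_index(drop=True)
    df["midpoint"] = df["midpoint"].astype(int)
    return df


def write_midpoints(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
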