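"""Genome containers and I/O: FASTA, GFF3 (gene features), expression
tables, JASPAR PFMs, promoter extraction and codon-aware back-translation.

Internal coordinates are 0-based half-open; GFF3 I/O converts to and from
the 1-based inclusive convention. Gene ``rank`` is the ordinal position of a
gene among the genes of its chromosome, sorted by start coordinate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "Genome",
    "ExpressionMatrix",
    "PWM",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "extract_promoters",
    "backtranslate_alignment",
    "translate_cds",
    "revcomp",
    "read_expression_tsv",
    "read_jaspar_pwms",
    "read_cluster_map",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

CONDITIONS = ("CK", "D", "H", "DH")
TIMES = ("day", "night")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str, gene_id: str = "?") -> str:
    """Translate a CDS, stripping one terminal stop codon if present.

    Raises ``ValueError`` on length not divisible by 3 or internal stops.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS of {gene_id} has length {len(cds)}, not divisible by 3")
    cds = cds.upper()
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    prot = str(Seq(cds).translate())
    if "*" in prot:
        raise ValueError(f"CDS of {gene_id} contains an internal stop codon")
    return prot


@dataclass
class GeneModel:
    """A protein-coding gene on a chromosome.

    ``start``/``end`` are 0-based half-open; ``rank`` is the 0-based ordinal
    among the genes of the same chromosome sorted by start.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1
    cds: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.cds:
            self.cds = self.cds.upper()
            if set(self.cds) - set("ACGTN"):
                raise ValueError(f"gene {self.gene_id}: CDS has non-ACGTN characters")

    @property
    def protein(self) -> str:
        return translate_cds(self.cds, self.gene_id)


@dataclass
class Genome:
    """An ordered collection of gene models, optionally with chromosome sequences."""

    name: str
    chrom_lengths: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.assign_ranks()

    def assign_ranks(self) -> None:
        """(Re)compute per-chromosome ranks by sorting genes on start."""
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id} extends beyond chromosome {g.chrom}"
                )
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: (g.start, g.gene_id))
            for i, g in enumerate(genes):
                g.rank = i

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes if g.chrom == chrom), key=lambda g: g.rank
        )

    def gene_map(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def cds_map(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self.genes if g.cds}

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes if g.cds}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: uppercase sequence}`` mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA header: {rec.id}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record: {rec.id}")
        out[rec.id] = seq
    return out


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene features only)
# ---------------------------------------------------------------------------

_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff(
    path: str | Path,
    name: str | None = None,
    cds: Mapping[str, str] | None = None,
    sequences: dict[str, str] | None = None,
) -> Genome:
    """Parse gene features from a GFF3 file into a :class:`Genome`.

    Only ``gene`` features are considered (the supported annotation subset
    is one gene model per locus). ``##sequence-region`` pragmas supply
    chromosome lengths; otherwise lengths default to the maximal gene end.
    Optional ``cds``/``sequences`` mappings attach coding and chromosome
    sequences.
    """
    chrom_lengths: dict[str, int] = {}
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            m = _ID_RE.search(attrs)
            if not m:
                raise ValueError(f"{path}: line {lineno}: gene feature without ID")
            gene_id = m.group(1)
            if gene_id in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate gene ID {gene_id}")
            seen.add(gene_id)
            if strand not in "+-":
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start1 - 1,  # GFF 1-based inclusive -> 0-based half-open
                    end=end1,
                    strand=strand,
                    cds=(cds or {}).get(gene_id, ""),
                )
            )
    for g in genes:
        if g.chrom not in chrom_lengths:
            chrom_lengths[g.chrom] = 0
        chrom_lengths[g.chrom] = max(chrom_lengths[g.chrom], g.end)
    return Genome(
        name=name or Path(path).stem,
        chrom_lengths=chrom_lengths,
        genes=genes,
        sequences=sequences,
    )


def write_gff(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genome.chrom_lengths):
            fh.write(
                f"##sequence-region {chrom} 1 {genome.chrom_lengths[chrom]}\n"
            )
        for chrom in sorted(genome.chrom_lengths):
            for g in genome.genes_on(chrom):
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            "paleodup",
                            "gene",
                            str(g.start + 1),
                            str(g.end),
                            ".",
                            g.strand,
                            ".",
                            f"ID={g.gene_id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------


def extract_promoters(genome: Genome, length: int = 2000) -> dict[str, str]:
    """Extract upstream promoter sequences (TSS = annotated gene start).

    For ``+`` strand genes the promoter is ``seq[start-length:start]``; for
    ``-`` strand genes it is the reverse complement of ``seq[end:end+length]``.
    Promoters are truncated at chromosome boundaries and returned 5'->3'
    relative to the gene.
    """
    if genome.sequences is None:
        raise ValueError("genome has no chromosome sequences")
    out: dict[str, str] = {}
    for g in genome.genes:
        if g.chrom not in genome.sequences:
            raise ValueError(f"no sequence for chromosome {g.chrom}")
        seq = genome.sequences[g.chrom]
        if g.strand == "+":
            out[g.gene_id] = seq[max(0, g.start - length) : g.start]
        else:
            chrom_len = genome.chrom_lengths[g.chrom]
            out[g.gene_id] = revcomp(seq[g.end : min(chrom_len, g.end + length)])
    return out


# ---------------------------------------------------------------------------
# Codon-aware back-translation
# ---------------------------------------------------------------------------


def backtranslate_alignment(
    protein_aln: tuple[str, str], cds_a: str, cds_b: str
):
    """Thread CDS nucleotides onto an aligned protein pair, codon by codon.

    Each aligned amino-acid column becomes a codon column; a gap becomes
    ``---``. Returns a :class:`paleodup.kaks.CodonAlignment` whose pair list
    retains only gap-free, N-free, stop-free codon columns.
    """
    from .kaks import CodonAlignment  # local import; kaks does not import us

    aln_a, aln_b = protein_aln
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned protein strings differ in length")
    codons = []
    for label, aln, cds in (("a", aln_a, cds_a), ("b", aln_b, cds_b)):
        prot = translate_cds(cds, label)
        ungapped = aln.replace("-", "")
        if ungapped != prot:
            for i, (x, y) in enumerate(zip(ungapped, prot)):
                if x != y:
                    raise ValueError(
                        f"sequence {label}: aligned residue {i + 1} is {x!r} "
                        f"but CDS translates to {y!r}"
                    )
            raise ValueError(
                f"sequence {label}: aligned protein length {len(ungapped)} != "
                f"translated CDS length {len(prot)}"
            )
        cds_nostop = cds[:-3] if cds[-3:] in STOP_CODONS else cds
        cols = []
        k = 0
        for aa in aln:
            if aa == "-":
                cols.append("---")
            else:
                cols.append(cds_nostop[3 * k : 3 * k + 3])
                k += 1
        codons.append(cols)
    aligned_a = "".join(codons[0])
    aligned_b = "".join(codons[1])
    return CodonAlignment.from_aligned(aligned_a, aligned_b)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sample:
    condition: str  # CK, D, H, DH
    time: str  # day, night
    replicate: int

    @property
    def label(self) -> str:
        return f"{self.condition}_{self.time}_{self.replicate}"


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix with (condition, time, replicate) metadata."""

    gene_ids: list[str]
    samples: list[Sample]
    values: np.ndarray  # shape (n_genes, n_samples), TPM >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("values shape does not match gene_ids x samples")
        if (self.values < 0).any():
            raise ValueError("negative TPM values")
        for s in self.samples:
            if s.condition not in CONDITIONS or s.time not in TIMES:
                raise ValueError(f"bad sample metadata: {s}")

    def conditions(self) -> set[str]:
        return {s.condition for s in self.samples}

    def columns(self, condition: str, time: str) -> np.ndarray:
        idx = [
            i
            for i, s in enumerate(self.samples)
            if s.condition == condition and s.time == time
        ]
        if not idx:
            raise KeyError(f"no samples for ({condition}, {time})")
        return self.values[:, idx]

    def group_mean(self, condition: str, time: str) -> np.ndarray:
        return self.columns(condition, time).mean(axis=1)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=[s.label for s in self.samples],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _parse_sample_label(label: str) -> Sample:
    parts = label.split("_")
    if len(parts) != 3:
        raise ValueError(f"sample column {label!r} is not CONDITION_time_rep")
    cond, time, rep = parts
    return Sample(condition=cond, time=time, replicate=int(rep))


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TPM table with columns like ``CK_day_1``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [_parse_sample_label(c) for c in df.columns]
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        samples=samples,
        values=df.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# PWMs (JASPAR PFM format)
# ---------------------------------------------------------------------------

BASE_ORDER = "ACGT"


@dataclass
class PWM:
    """A position frequency/probability matrix over (A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray  # shape (L, 4)
    cluster_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise ValueError(f"PWM {self.motif_id}: matrix must be L x 4, L >= 1")
        if (self.matrix < 0).any() or (self.matrix.sum(axis=1) <= 0).any():
            raise ValueError(f"PWM {self.motif_id}: rows must be nonnegative with positive sums")

    def __len__(self) -> int:
        return len(self.matrix)

    def probabilities(
        self, pseudocount: float = 0.1, background: np.ndarray | None = None
    ) -> np.ndarray:
        """Row-normalised probabilities with a background-weighted pseudocount."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        totals = self.matrix.sum(axis=1, keepdims=True)
        return (self.matrix + pseudocount * bg) / (totals + pseudocount)

    @property
    def consensus(self) -> str:
        return "".join(BASE_ORDER[j] for j in self.matrix.argmax(axis=1))


def read_jaspar_pwms(
    path: str | Path, cluster_map: Mapping[str, str] | None = None
) -> list[PWM]:
    """Read PWMs from a JASPAR-format PFM file (via Bio.motifs)."""
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            mat = np.array([[m.counts[b][i] for b in BASE_ORDER] for i in range(m.length)])
            motif_id = m.matrix_id or m.name
            out.append(
                PWM(
                    motif_id=motif_id,
                    matrix=mat,
                    cluster_id=(cluster_map or {}).get(motif_id, ""),
                )
            )
    return out


def read_cluster_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping motif_id -> cluster_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["motif_id", "cluster_id"])
    return dict(zip(df["motif_id"].astype(str), df["cluster_id"].astype(str)))


def write_cluster_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def write_jaspar_pwms(pwms: Iterable[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.motif_id}\n")
            for j, base in enumerate(BASE_ORDER):
                row = " ".join(f"{v:.2f}" for v in p.matrix[:, j])
                fh.write(f"{base}  [ {row} ]\n")
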