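"""5'UTR cataloging: transcript eligibility filters, representative selection,
TSS support filtering against CAGE tag clusters, and per-species length summaries.

Eligibility requires an annotated 5'UTR, `known` transcript status, and a
known protein product — conditions under which both UTR termini are
experimentally supported.  One representative transcript is chosen per gene,
either uniformly at random (seeded) or as the isoform with a *pure* 5'UTR:
one whose UTR overlaps no coding interval of any other transcript on the
same chromosome and strand.

Coordinates are 0-based half-open internally; annotation tables on disk use
1-based inclusive coordinates (GFF convention) and are converted at I/O only.
A transcript may carry several 5'UTR sub-intervals (intron-interrupted UTRs);
its length is the sum of widths and its TSS the strand-aware outermost base.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "TranscriptRecord",
    "LengthSummary",
    "CageClusterSet",
    "filter_eligible",
    "is_pure_utr",
    "pure_flags",
    "select_representative",
    "select_representatives",
    "cage_filter",
    "summarize_lengths",
    "restrict_to_orthologs",
    "read_annotation_table",
    "write_annotation_table",
    "read_cage_bed",
    "attach_sequences",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class TranscriptRecord:
    gene_id: str
    transcript_id: str
    status: str  # known | novel | predicted
    has_protein_product: bool
    chrom: str
    strand: str  # '+' or '-'
    utr5_intervals: tuple[Interval, ...] = ()  # 0-based half-open; empty = absent
    cds_intervals: tuple[Interval, ...] = ()
    utr5_seq: str | None = None
    excluded: bool = False  # stand-in for external homology-based purging

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in (*self.utr5_intervals, *self.cds_intervals):
            if e < s:
                raise ValueError(f"negative-width interval ({s}, {e})")
        if self.utr5_intervals and self.utr5_seq is not None:
            if self.utr5_length != len(self.utr5_seq):
                raise ValueError(
                    f"{self.transcript_id}: 5'UTR interval width "
                    f"{self.utr5_length} != sequence length {len(self.utr5_seq)}"
                )

    @property
    def has_utr5(self) -> bool:
        return bool(self.utr5_intervals)

    @property
    def utr5_length(self) -> int:
        return sum(e - s for s, e in self.utr5_intervals)

    @property
    def tss(self) -> int:
        """0-based genomic position of the 5'-most transcribed base."""
        if not self.utr5_intervals:
            raise ValueError(f"{self.transcript_id} has no 5'UTR")
        if self.strand == "+":
            return min(s for s, _ in self.utr5_intervals)
        return max(e for _, e in self.utr5_intervals) - 1


@dataclass(frozen=True)
class LengthSummary:
    species: str
    n_genes: int
    median_bp: float
    mean_bp: float
    mad_bp: float  # median absolute deviation from the median


@dataclass(frozen=True)
class CageClusterSet:
    """CAGE tag clusters: (chrom, start, end, strand), 0-based half-open."""

    clusters: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        for chrom, start, end, strand in self.clusters:
            if start >= end:
                raise ValueError(f"empty cluster {chrom}:{start}-{end}")
            if strand not in ("+", "-"):
                raise ValueError(f"bad cluster strand {strand!r}")


def filter_eligible(records: Sequence[TranscriptRecord]) -> list[TranscriptRecord]:
    """Retain transcripts with an annotated 5'UTR, known status, and a protein
    product; input order preserved.  Idempotent."""
    return [
        r
        for r in records
        if r.has_utr5 and r.status == "known" and r.has_protein_product
    ]


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def is_pure_utr(t: TranscriptRecord, cohort: Sequence[TranscriptRecord]) -> bool:
    """True iff t's 5'UTR intersects no CDS interval of any *other* transcript
    on the same chromosome and strand."""
    if not t.has_utr5:
        raise ValueError(f"{t.transcript_id} has no 5'UTR; purity undefined")
    for other in cohort:
        if other.transcript_id == t.transcript_id:
            continue
        if other.chrom != t.chrom or other.strand != t.strand:
            continue
        for u in t.utr5_intervals:
            for c in other.cds_intervals:
                if _overlaps(u, c):
                    return False
    return True


def pure_flags(records: Sequence[TranscriptRecord]) -> dict[str, bool]:
    """Purity of every 5'UTR-bearing transcript against the whole cohort.

    Interval-tree accelerated; equivalent to calling :func:`is_pure_utr`
    per transcript with ``cohort=records``.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for r in records:
        key = (r.chrom, r.strand)
        tree = trees.setdefault(key, IntervalTree())
        for s, e in r.cds_intervals:
            if e > s:
                tree.addi(s, e, r.transcript_id)
    flags: dict[str, bool] = {}
    for r in records:
        if not r.has_utr5:
            continue
        tree = trees.get((r.chrom, r.strand))
        pure = True
        if tree is not None:
            for s, e in r.utr5_intervals:
                if any(hit.data != r.transcript_id for hit in tree.overlap(s, e)):
                    pure = False
                    break
        flags[r.transcript_id] = pure
    return flags


def _gene_seed(seed: int, gene_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(gene_id.encode())])


def select_representative(
    gene_records: Sequence[TranscriptRecord],
    mode: str,
    seed: int = 0,
    pure: Mapping[str, bool] | None = None,
) -> TranscriptRecord | None:
    """Choose one transcript for a gene.

    mode='random': uniform seeded choice among the records.
    mode='pure': the pure-5'UTR isoform (not flagged ``excluded``), ties broken
    by lexicographically smallest transcript id; None if no isoform qualifies.
    ``pure`` may supply precomputed cohort-wide purity flags; otherwise purity
    is assessed within ``gene_records`` only.
    """
    if not gene_records:
        return None
    gene_ids = {r.gene_id for r in gene_records}
    if len(gene_ids) != 1:
        raise ValueError(f"records span several genes: {sorted(gene_ids)}")
    if mode == "random":
        rng = _gene_seed(seed, gene_records[0].gene_id)
        return gene_records[int(rng.integers(len(gene_records)))]
    if mode == "pure":
        if pure is None:
            pure = pure_flags(gene_records)
        candidates = [
            r
            for r in gene_records
            if not r.excluded and pure.get(r.transcript_id, False)
        ]
        if not candidates:
            return None
        return min(candidates, key=lambda r: r.transcript_id)
    raise ValueError(f"unknown selection mode {mode!r}")


def select_representatives(
    records: Sequence[TranscriptRecord], mode: str, seed: int = 0
) -> list[TranscriptRecord]:
    """One representative per gene over an eligible cohort; purity (for
    mode='pure') is judged against the full cohort.  Genes ordered by first
    appearance."""
    flags = pure_flags(records) if mode == "pure" else None
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    out = []
    for gene_id, group in by_gene.items():
        rep = select_representative(group, mode=mode, seed=seed, pure=flags)
        if rep is not None:
            out.append(rep)
    return out


def cage_filter(
    records: Sequence[TranscriptRecord],
    clusters: CageClusterSet,
    slack_bp: int = 0,
) -> list[TranscriptRecord]:
    """Retain transcripts whose TSS falls within a CAGE cluster (same chrom
    and strand) extended by ``slack_bp`` on each side."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for chrom, start, end, strand in clusters.clusters:
        trees.setdefault((chrom, strand), IntervalTree()).addi(
            start - slack_bp, end + slack_bp
        )
    out = []
    for r in records:
        tree = trees.get((r.chrom, r.strand))
        if tree is not None and tree.overlaps_point(r.tss):
            out.append(r)
    return out


def summarize_lengths(
    representatives: Sequence[TranscriptRecord], species: str
) -> LengthSummary:
    """Median, mean, and median absolute deviation of 5'UTR lengths (bp)."""
    if not representatives:
        raise ValueError(f"no representatives for {species}; summary undefined")
    lengths = np.array([r.utr5_length for r in representatives], dtype=float)
    med = float(np.median(lengths))
    return LengthSummary(
        species=species,
        n_genes=len(lengths),
        median_bp=med,
        mean_bp=float(np.mean(lengths)),
        mad_bp=float(np.median(np.abs(lengths - med))),
    )


def restrict_to_orthologs(
    per_species_genes: Mapping[str, set[str]], ortholog_map: pd.DataFrame
) -> dict[str, set[str]]:
    """Keep only genes in complete one-to-one tuples across all species.

    ``ortholog_map`` has one column per species; each row is a tuple of
    orthologous gene ids (NaN = missing).  A row is kept only if every
    species' entry exists in that species' gene set.
    """
    missing = [sp for sp in per_species_genes if sp not in ortholog_map.columns]
    if missing:
        raise KeyError(f"species absent from ortholog map: {missing}")
    species = list(per_species_genes)
    out: dict[str, set[str]] = {sp: set() for sp in species}
    sub = ortholog_map[species].dropna()
    for row in sub.itertuples(index=False):
        pairs = list(zip(species, row))
        if all(g in per_species_genes[sp] for sp, g in pairs):
            for sp, g in pairs:
                out[sp].add(g)
    return out


# ---------------------------------------------------------------------------
# I/O: GFF-like annotation TSV (1-based inclusive on disk), CAGE BED, FASTA

_COLUMNS = [
    "gene_id",
    "transcript_id",
    "status",
    "protein_product",
    "chrom",
    "strand",
    "utr5_intervals",
    "cds_intervals",
    "excluded",
]


def _intervals_to_text(ivs: tuple[Interval, ...]) -> str:
    # 0-based half-open -> 1-based inclusive "start-end;..."
    return ";".join(f"{s + 1}-{e}" for s, e in ivs)


def _intervals_from_text(text: str) -> tuple[Interval, ...]:
    if not text or text != text:  # NaN-safe
        return ()
    out = []
    for part in str(text).split(";"):
        a, b = part.split("-")
        out.append((int(a) - 1, int(b)))
    return tuple(out)


def write_annotation_table(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "transcript_id": r.transcript_id,
            "status": r.status,
            "protein_product": int(r.has_protein_product),
            "chrom": r.chrom,
            "strand": r.strand,
            "utr5_intervals": _intervals_to_text(r.utr5_intervals),
            "cds_intervals": _intervals_to_text(r.cds_intervals),
            "excluded": int(r.excluded),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> list[TranscriptRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"utr5_intervals": str, "cds_intervals": str})
    df = df.fillna({"utr5_intervals": "", "cds_intervals": ""})
    return [
        TranscriptRecord(
            gene_id=str(row.gene_id),
            transcript_id=str(row.transcript_id),
            status=str(row.status),
            has_protein_product=bool(row.protein_product),
            chrom=str(row.chrom),
            strand=str(row.strand),
            utr5_intervals=_intervals_from_text(row.utr5_intervals),
            cds_intervals=_intervals_from_text(row.cds_intervals),
            excluded=bool(getattr(row, "excluded", False)),
        )
        for row in df.itertuples(index=False)
    ]


def read_cage_bed(path: str | Path) -> CageClusterSet:
    """BED (0-based half-open): chrom, start, end[, name, score, strand]."""
    clusters = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        strand = parts[5] if len(parts) > 5 else "+"
        clusters.append((chrom, start, end, strand))
    return CageClusterSet(clusters=tuple(clusters))


def attach_sequences(
    records: Iterable[TranscriptRecord], seqs: Mapping[str, str]
) -> list[TranscriptRecord]:
    """Attach 5'UTR sequences keyed by transcript id (FASTA record ids)."""
    return [
        replace(r, utr5_seq=seqs[r.transcript_id])
        if r.transcript_id in seqs and r.has_utr5
        else r
        for r in records
    ]
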