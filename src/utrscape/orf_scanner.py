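"""Upstream start codon (uAUG) and upstream ORF (uORF) detection in 5'UTRs.

A uAUG is any occurrence of the start triplet within the 5'UTR, in any of
the three reading frames.  A uORF opens at a uAUG and closes at the first
in-frame stop codon lying entirely within the 5'UTR; it must be at least
``min_len`` nucleotides long (default 9: start codon, stop codon, and at
least one codon in between).  When several in-frame uAUGs precede the same
stop, only the first opens a uORF, so no two uORFs in one frame share a
stop codon.  A uAUG with no downstream in-frame stop inside the 5'UTR
counts toward the uAUG tally but yields no uORF.

Sequences are handled as DNA: input is upper-cased and ``U`` is normalized
to ``T``.  Any triplet containing ``N`` is neither a start nor a stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "UorfReport",
    "count_uaugs",
    "find_uorfs",
    "per_gene_element_rates",
    "scan_sequences",
]

_START = "ATG"
_STOPS = frozenset({"TAA", "TAG", "TGA"})
_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class UorfReport:
    """Per-transcript element counts and uORF intervals.

    ``uorfs`` holds ``(frame, start, end)`` tuples with 0-based half-open
    offsets into the 5'UTR sequence; ``end - start`` is a multiple of 3.
    """

    transcript_id: str
    n_uaug: int
    n_uorf: int
    uorfs: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
    return s


def count_uaugs(seq: str) -> int:
    """Number of start-triplet occurrences in the sequence (all frames)."""
    s = _normalize(seq)
    return sum(1 for p in range(len(s) - 2) if s[p : p + 3] == _START)


def find_uorfs(seq: str, transcript_id: str = "", min_len: int = 9) -> UorfReport:
    """Scan a 5'UTR for uORFs frame by frame.

    Within each frame the sequence is walked codon by codon: an open uORF
    suppresses further start codons until its stop closes it, after which a
    later start may open a new uORF.
    """
    s = _normalize(seq)
    uorfs: list[tuple[int, int, int]] = []
    for frame in range(3):
        open_start: int | None = None
        for p in range(frame, len(s) - 2, 3):
            codon = s[p : p + 3]
            if open_start is None:
                if codon == _START:
                    open_start = p
            elif codon in _STOPS:
                end = p + 3
                if end - open_start >= min_len:
                    uorfs.append((frame, open_start, end))
                open_start = None
    uorfs.sort(key=lambda t: (t[1], t[0]))
    return UorfReport(
        transcript_id=transcript_id,
        n_uaug=count_uaugs(s),
        n_uorf=len(uorfs),
        uorfs=tuple(uorfs),
    )


def per_gene_element_rates(reports: Sequence[UorfReport]) -> tuple[float, float]:
    """Mean uAUGs and uORFs per gene over one report per representative transcript."""
    if not reports:
        raise ValueError("no reports: per-gene rates undefined")
    n = len(reports)
    return (
        sum(r.n_uaug for r in reports) / n,
        sum(r.n_uorf for r in reports) / n,
    )


def scan_sequences(
    items: Iterable[tuple[str, str]], min_len: int = 9
) -> list[UorfReport]:
    """Run :func:`find_uorfs` over ``(transcript_id, sequence)`` pairs."""
    return [find_uorfs(seq, transcript_id=tid, min_len=min_len) for tid, seq in items]
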