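"""Strand-aware gene models and coordinate arithmetic.

All internal coordinates are 0-based, half-open. "Downstream" always means
the transcript 3' direction: higher genomic coordinates on the plus strand,
lower on the minus strand. Every piece of window math in the package routes
through :func:`transcript_interval` / :func:`downstream_of` so the strand
convention lives in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

Interval = Tuple[int, int]


def downstream_of(pos: int, strand: str, offset: int) -> int:
    """Genomic coordinate of the base `offset` nt downstream of `pos`.

    Negative offsets move upstream. Offset 0 is `pos` itself.
    """
    if strand == "+":
        return pos + offset
    if strand == "-":
        return pos - offset
    raise ValueError(f"invalid strand {strand!r}")


def transcript_interval(pos: int, strand: str, start: int, end: int) -> Interval:
    """Genomic half-open interval for transcript offsets [start, end) around `pos`.

    Offsets are in transcript direction relative to `pos` (offset 0 = `pos`,
    negative = upstream). On the minus strand the genomic interval is the
    mirror image: offsets [a, b) map to genomic [pos - b + 1, pos - a + 1).
    """
    if start >= end:
        raise ValueError("window start must be < end")
    if strand == "+":
        return pos + start, pos + end
    if strand == "-":
        return pos - end + 1, pos - start + 1
    raise ValueError(f"invalid strand {strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """One gene: ordered exons on a chromosome strand.

    Exons are sorted genomically and non-overlapping; introns are the gaps
    between consecutive exons. The terminal exon is the transcript-last exon
    (genomically last on '+', first on '-'), and the annotated 3' end is the
    final transcribed base.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    utr3_length: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene needs at least one exon")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError("exons overlap")
        for s, e in exons:
            if e <= s:
                raise ValueError("empty exon")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return self.start, self.end

    @property
    def introns(self) -> Tuple[Interval, ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def terminal_exon_index(self) -> int:
        """Index into the genomically sorted exon list of the transcript-last exon."""
        return len(self.exons) - 1 if self.strand == "+" else 0

    @property
    def terminal_exon(self) -> Interval:
        return self.exons[self.terminal_exon_index]

    @property
    def three_prime_end(self) -> int:
        """0-based coordinate of the final transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def five_prime_end(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def transcript_offset(self, pos: int) -> int:
        """Signed genomic offset of `pos` in transcript direction from the 5' end.

        Monotone in transcript direction; used to order sites proximal/distal.
        Intronic positions are ordered too (genomic, not spliced, distance).
        """
        if self.strand == "+":
            return pos - self.start
        return self.end - 1 - pos

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def in_downstream_extension(self, pos: int, extension: int) -> bool:
        """True when pos lies within `extension` nt past the annotated 3' end."""
        tes = self.three_prime_end
        if self.strand == "+":
            return tes < pos <= tes + extension
        return tes - extension <= pos < tes


def genes_by_location(genes: Iterable[GeneModel]) -> dict:
    """Index genes by (chrom, strand) for assignment lookups."""
    index: dict = {}
    for g in genes:
        index.setdefault((g.chrom, g.strand), []).append(g)
    for key in index:
        index[key].sort(key=lambda g: g.start)
    return index
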