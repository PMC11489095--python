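"""CPA-site calling from 3'-seq read ends.

Read 3'-end positions are clustered per (chromosome, strand) by single
linkage: consecutive positions at most `max_gap` apart join one cluster.
Each cluster's representative cleavage site is its modal position (maximal
summed count over samples), ties broken toward the transcript-downstream
end; downstream windows for internal-priming filtering and cis-element
scanning anchor on that base. Clusters whose downstream genomic window is
A-rich are flagged as likely internal-priming artifacts (oligo-dT priming
on genomic A tracts) and excluded from APA calling but kept in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .genes import GeneModel, genes_by_location
from .motifs import extract_window

READ_END_COLUMNS = ["chrom", "pos", "strand", "sample", "count"]


@dataclass
class PASCluster:
    """A cleavage/polyadenylation site cluster with per-sample read counts."""

    chrom: str
    strand: str
    start: int
    end: int  # half-open span of member positions
    representative: int
    counts: Dict[str, int] = field(default_factory=dict)
    filtered: bool = False

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def __post_init__(self):
        if not self.start <= self.representative < self.end:
            raise ValueError("representative outside cluster span")


def cluster_read_ends(ends: pd.DataFrame, max_gap: int = 24) -> List[PASCluster]:
    """Single-linkage clustering of read 3'-end positions.

    `ends` needs columns chrom, pos, strand, sample, count. Positions on the
    same chromosome and strand whose consecutive gaps are <= max_gap merge
    into one cluster. Zero-count rows are ignored.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    clusters: List[PASCluster] = []
    if ends.empty:
        return clusters
    ends = ends[ends["count"] > 0]
    if ends.empty:
        return clusters
    for (chrom, strand), grp in ends.groupby(["chrom", "strand"], sort=True):
        # per-position per-sample totals
        per_pos = (
            grp.groupby(["pos", "sample"], sort=True)["count"].sum().unstack(fill_value=0)
        )
        positions = per_pos.index.to_numpy()
        totals = per_pos.to_numpy().sum(axis=1)
        breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
        for seg in np.split(np.arange(len(positions)), breaks):
            seg_pos = positions[seg]
            seg_tot = totals[seg]
            best = seg_tot.max()
            candidates = seg_pos[seg_tot == best]
            # tie-break toward the strand-aware downstream (3'-most) position
            rep = int(candidates.max() if strand == "+" else candidates.min())
            counts = {
                s: int(c)
                for s, c in per_pos.iloc[seg].sum(axis=0).items()
                if c > 0
            }
            clusters.append(
                PASCluster(
                    chrom=chrom,
                    strand=strand,
                    start=int(seg_pos.min()),
                    end=int(seg_pos.max()) + 1,
                    representative=rep,
                    counts=counts,
                )
            )
    return clusters


def filter_internal_priming(
    clusters: Iterable[PASCluster],
    genome: Mapping[str, str],
    window: int = 10,
    max_a: int = 7,
    max_run: int = 6,
) -> List[PASCluster]:
    """Flag clusters whose downstream genomic window is A-rich.

    The strand-aware window covers the `window` bases immediately 3' of the
    representative cleavage base (transcript offsets [1, window+1)). A
    cluster is flagged when the window holds >= max_a adenosines in total OR
    a run of >= max_run consecutive A. Windows past the chromosome end are
    truncated, never an error. Returns new cluster objects; input order kept.
    """
    out: List[PASCluster] = []
    for cluster in clusters:
        seq = extract_window(
            genome, cluster.chrom, cluster.representative, cluster.strand, 1, window + 1
        ).upper()
        n_a = seq.count("A")
        run = longest = 0
        for base in seq:
            run = run + 1 if base == "A" else 0
            longest = max(longest, run)
        flagged = n_a >= max_a or longest >= max_run
        out.append(replace(cluster, counts=dict(cluster.counts), filtered=flagged))
    return out


def assign_to_genes(
    clusters: Iterable[PASCluster],
    genes: Iterable[GeneModel],
    downstream_extension: int = 500,
) -> Tuple[Dict[str, List[PASCluster]], List[PASCluster]]:
    """Assign clusters to genes by representative position.

    A cluster belongs to a gene when its representative lies within the gene
    span or within `downstream_extension` nt past the annotated 3' end, on
    the same strand. A cluster matching several genes goes to the gene whose
    annotated 3' end is nearest; exact ties break on lexicographic gene id.
    Returns (gene_id -> clusters, unassigned clusters).
    """
    index = genes_by_location(genes)
    assigned: Dict[str, List[PASCluster]] = {}
    unassigned: List[PASCluster] = []
    for cluster in clusters:
        candidates = [
            g
            for g in index.get((cluster.chrom, cluster.strand), [])
            if g.contains(cluster.representative)
            or g.in_downstream_extension(cluster.representative, downstream_extension)
        ]
        if not candidates:
            unassigned.append(cluster)
            continue
        winner = min(
            candidates,
            key=lambda g: (abs(cluster.representative - g.three_prime_end), g.gene_id),
        )
        assigned.setdefault(winner.gene_id, []).append(cluster)
    return assigned, unassigned


def clusters_to_frame(clusters: Iterable[PASCluster]) -> pd.DataFrame:
    """Flat table view of clusters (per-sample counts as columns)."""
    clusters = list(clusters)
    base = pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "representative": [c.representative for c in clusters],
            "strand": [c.strand for c in clusters],
            "filtered": [c.filtered for c in clusters],
            "total": [c.total for c in clusters],
        }
    )
    samples = sorted({s for c in clusters for s in c.counts})
    for s in samples:
        base[f"count_{s}"] = [c.counts.get(s, 0) for c in clusters]
    return base
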