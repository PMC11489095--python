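"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted on read/write. BED6 read-end files put the sample name in the
name column and the read count in the score column. bedGraph tracks are
run-length compressed on write and expanded to dense per-chromosome
arrays on read. FASTA goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genes import GeneModel
from .pas import READ_END_COLUMNS


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _utr3_interval(gene: GeneModel):
    if gene.utr3_length <= 0:
        return None
    s, e = gene.terminal_exon
    if gene.strand == "+":
        return max(s, e - gene.utr3_length), e
    return s, min(e, s + gene.utr3_length)


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """gene / exon / three_prime_UTR features, 1-based inclusive."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene in genes:
            gid = gene.gene_id
            handle.write(
                f"{gene.chrom}\tapakit\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gid}\n"
            )
            for i, (s, e) in enumerate(gene.exons, start=1):
                handle.write(
                    f"{gene.chrom}\tapakit\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={gid}.exon{i};Parent={gid}\n"
                )
            utr = _utr3_interval(gene)
            if utr:
                handle.write(
                    f"{gene.chrom}\tapakit\tthree_prime_UTR\t{utr[0] + 1}\t{utr[1]}\t.\t"
                    f"{gene.strand}\t.\tID={gid}.utr3;Parent={gid}\n"
                )


def _attributes(field: str) -> Dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gff3(path) -> List[GeneModel]:
    """Reassemble GeneModels from gene/exon/three_prime_UTR rows."""
    exons: Dict[str, List] = {}
    meta: Dict[str, dict] = {}
    utr3: Dict[str, int] = {}
    order: List[str] = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            attrs = _attributes(attrs)
            if ftype == "gene":
                gid = attrs["ID"]
                meta[gid] = {"chrom": chrom, "strand": strand}
                order.append(gid)
            elif ftype == "exon":
                gid = attrs.get("Parent", attrs.get("ID", ""))
                exons.setdefault(gid, []).append((int(start) - 1, int(end)))
            elif ftype == "three_prime_UTR":
                gid = attrs.get("Parent", attrs.get("ID", ""))
                utr3[gid] = utr3.get(gid, 0) + int(end) - (int(start) - 1)
    genes = []
    for gid in order or sorted(exons):
        info = meta.get(gid)
        gene_exons = sorted(exons.get(gid, []))
        if info is None or not gene_exons:
            continue
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=info["chrom"],
                strand=info["strand"],
                exons=tuple(gene_exons),
                utr3_length=utr3.get(gid, 0),
            )
        )
    return genes


def write_read_ends_bed(ends: pd.DataFrame, path) -> None:
    """BED6: chrom, start, end, name=sample, score=count, strand."""
    bed = pd.DataFrame(
        {
            "chrom": ends["chrom"],
            "start": ends["pos"],
            "end": ends["pos"] + 1,
            "name": ends["sample"],
            "score": ends["count"],
            "strand": ends["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_read_ends_bed(path, sample: Optional[str] = None) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    out = pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "pos": bed["start"].astype(int),
            "strand": bed["strand"],
            "sample": sample if sample is not None else bed["name"],
            "count": bed["score"].astype(int),
        }
    )
    return out[READ_END_COLUMNS]


def write_bedgraph(track: Mapping[str, np.ndarray], path) -> None:
    """Run-length compressed bedGraph; zero runs are omitted."""
    with open(path, "w") as handle:
        for chrom in sorted(track):
            values = np.asarray(track[chrom], dtype=float)
            if values.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [values.size]])
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    handle.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> Dict[str, np.ndarray]:
    track = {c: np.zeros(l, dtype=float) for c, l in chrom_sizes.items()}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split()[:4]
            if chrom in track:
                track[chrom][int(start) : int(end)] = float(value)
    return track


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_intensity_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
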