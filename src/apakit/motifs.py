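"""Polyadenylation cis-element scanning with mismatch rules.

Three elements flank plant cleavage/polyadenylation sites: the CFI-bound
UGUA word, the CPSF-bound polyadenylation signal hexamer (canonically
AAUAAA) and a CstF-class U/UG-rich element (UUGUUU). The hexamers are
matched allowing one mismatch, except that the fully degenerate words
AAAAAA and UUUUUU never count; UGUA is matched exactly. Matching is done
on genomic DNA with T treated as U; all reported motifs use the RNA
alphabet.

Window offsets are transcript-relative: negative = upstream of the cleavage
base (offset 0), positive = downstream. Defaults put UGUA in [-200, 0), the
PAS hexamer in [-60, 0) and the U-rich element in [-60, +60); all three are
plain configuration, reported in output headers, since cleavage-site
element placement varies by species and dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genes import transcript_interval

RNA_ALPHABET = "ACGU"

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and map T to U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MotifRule:
    """A consensus word, a mismatch budget and a list of excluded words."""

    consensus: str
    max_mismatches: int = 0
    excluded: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        consensus = normalize_rna(self.consensus)
        excluded = frozenset(normalize_rna(w) for w in self.excluded)
        if self.max_mismatches >= len(consensus):
            raise ValueError("max_mismatches must be < consensus length")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        for w in excluded:
            if len(w) != len(consensus):
                raise ValueError("excluded words must match consensus length")
        object.__setattr__(self, "consensus", consensus)
        object.__setattr__(self, "excluded", excluded)

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class ScanWindow:
    """Transcript-relative half-open window [start, end) for one element."""

    element: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("window start must be < end")


UGUA_RULE = MotifRule("UGUA", 0)
PAS_RULE = MotifRule("AAUAAA", 1, frozenset({"AAAAAA"}))
URICH_RULE = MotifRule("UUGUUU", 1, frozenset({"UUUUUU"}))

DEFAULT_RULES: Dict[str, MotifRule] = {
    "UGUA": UGUA_RULE,
    "PAS": PAS_RULE,
    "U_rich": URICH_RULE,
}

DEFAULT_WINDOWS: Tuple[ScanWindow, ...] = (
    ScanWindow("UGUA", -200, 0),
    ScanWindow("PAS", -60, 0),
    ScanWindow("U_rich", -60, 60),
)

ELEMENTS = tuple(DEFAULT_RULES)


def match_motif(sequence: str, rule: MotifRule) -> Tuple[bool, List[int]]:
    """Scan `sequence` for windows accepted by `rule`.

    A window of consensus length is accepted when its Hamming distance to
    the consensus is <= max_mismatches and the window is not an excluded
    word. Returns (any_match, offsets of accepted windows). A sequence
    shorter than the consensus yields (False, []).
    """
    seq = normalize_rna(sequence)
    k = len(rule)
    offsets: List[int] = []
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if word in rule.excluded:
            continue
        mismatches = sum(1 for a, b in zip(word, rule.consensus) if a != b)
        if mismatches <= rule.max_mismatches:
            offsets.append(i)
    return bool(offsets), offsets


def extract_window(
    genome: Mapping[str, str], chrom: str, site: int, strand: str, start: int, end: int
) -> str:
    """Transcript-oriented sequence at offsets [start, end) around `site`.

    Minus-strand windows are reverse-complemented so the returned string
    always reads 5'->3' along the transcript. Windows are truncated at
    chromosome ends (never an error); a site outside the chromosome raises.
    """
    seq = genome[chrom]
    if not 0 <= site < len(seq):
        raise ValueError(f"site {site} outside chromosome {chrom!r} (len {len(seq)})")
    g0, g1 = transcript_interval(site, strand, start, end)
    g0, g1 = max(0, g0), min(len(seq), g1)
    if g0 >= g1:
        return ""
    sub = seq[g0:g1]
    if strand == "-":
        sub = reverse_complement(sub)
    return sub


def scan_site(
    genome: Mapping[str, str],
    chrom: str,
    site: int,
    strand: str,
    windows: Sequence[ScanWindow] = DEFAULT_WINDOWS,
    rules: Mapping[str, MotifRule] = DEFAULT_RULES,
) -> Dict[str, bool]:
    """Presence flag for every element at one cleavage site."""
    flags: Dict[str, bool] = {}
    for window in windows:
        rule = rules[window.element]
        seq = extract_window(genome, chrom, site, strand, window.start, window.end)
        flags[window.element] = match_motif(seq, rule)[0]
    return flags


def scan_sites(
    genome: Mapping[str, str],
    sites: pd.DataFrame,
    windows: Sequence[ScanWindow] = DEFAULT_WINDOWS,
    rules: Mapping[str, MotifRule] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Scan a table of sites (columns chrom, pos, strand); one flag column per element."""
    records = []
    elements = [w.element for w in windows]
    for row in sites.itertuples(index=False):
        flags = scan_site(genome, row.chrom, int(row.pos), row.strand, windows, rules)
        records.append([flags[e] for e in elements])
    out = sites.reset_index(drop=True).copy()
    for j, e in enumerate(elements):
        out[e] = [r[j] for r in records] if records else pd.Series(dtype=bool)
    return out


def cooccurrence_table(flagged_sites: pd.DataFrame, class_column: str = "site_class",
                       elements: Sequence[str] = ELEMENTS,
                       classes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-class element and all-three co-occurrence fractions.

    `flagged_sites` must hold one boolean column per element plus a class
    label column. When `classes` is given, every listed class is reported
    even if empty (n_sites=0, NaN fractions) rather than dropped.
    """
    groups = {cls: grp for cls, grp in
              flagged_sites.groupby(class_column, sort=True, dropna=False)}
    wanted = list(classes) if classes is not None else sorted(groups, key=str)
    rows = []
    for cls in wanted:
        grp = groups.get(cls, flagged_sites.iloc[0:0])
        n = len(grp)
        row = {"site_class": cls, "n_sites": n}
        if n == 0:
            for e in elements:
                row[f"frac_{e}"] = np.nan
            row["frac_all"] = np.nan
        else:
            all_three = np.ones(n, dtype=bool)
            for e in elements:
                vals = grp[e].to_numpy(dtype=bool)
                row[f"frac_{e}"] = vals.mean()
                all_three &= vals
            row["frac_all"] = all_three.mean()
        rows.append(row)
    return pd.DataFrame(rows)


def nucleotide_profile(
    genome: Mapping[str, str],
    sites: pd.DataFrame,
    flank: int,
) -> pd.DataFrame:
    """Per-position base frequencies over [-flank, +flank] around sites.

    Positions run in transcript orientation (negative = upstream of the
    cleavage base at offset 0); minus-strand sites are reverse-complemented
    first. Frequencies at each covered position sum to 1; positions with no
    data (all sites truncated there) are NaN.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=float)
    totals = np.zeros(width, dtype=float)
    base_index = {b: i for i, b in enumerate(RNA_ALPHABET)}
    for row in sites.itertuples(index=False):
        seq = extract_window(
            genome, row.chrom, int(row.pos), row.strand, -flank, flank + 1
        )
        # align truncated windows: left-truncation shifts the start offset
        g0, _ = transcript_interval(int(row.pos), row.strand, -flank, flank + 1)
        chrom_len = len(genome[row.chrom])
        if row.strand == "+":
            lead_trunc = max(0, -g0)
        else:
            g0_raw, g1_raw = transcript_interval(int(row.pos), row.strand, -flank, flank + 1)
            lead_trunc = max(0, g1_raw - chrom_len)
        seq = normalize_rna(seq)
        for j, base in enumerate(seq):
            idx = base_index.get(base)
            if idx is None:
                continue
            counts[lead_trunc + j, idx] += 1
            totals[lead_trunc + j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / totals[:, None]
    positions = np.arange(-flank, flank + 1)
    return pd.DataFrame(freqs, index=pd.Index(positions, name="offset"),
                        columns=list(RNA_ALPHABET))
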