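"""Synthetic genomes, 3'-seq counts, coverage tracks and IP-MS tables.

Every downstream stage of the pipeline is exercised against data with
known planted truth:

* a chromosome of i.i.d. background sequence carrying non-overlapping,
  strand-alternating multi-exon genes;
* designated cleavage sites — the constitutive/distal site at each
  annotated 3' end, an optional tandem proximal site in the terminal exon,
  and one candidate site per intron;
* cis-element cassettes (UGUA + PAS hexamer + U-rich word) around a
  controlled fraction of sites. Background sequence already contains
  occasional chance co-occurrences, so the generator scans first and only
  tops up by substitution until the requested fraction of sites carries
  all three elements; the requested fraction is therefore the realised
  scan-positive rate, not a rate on top of background;
* per-site read-end counts for two conditions x replicates, with usage
  shifts planted in affected genes (intronic premature-CPA de-repression
  or a distal 3'-UTR shift) and uniform read-end jitter to exercise
  clustering;
* RNAPII-like coverage with a configurable downstream peak displacement;
* protein log2-intensity tables with planted enriched proteins and
  structural missingness in controls.

All draws are split per gene from the master seed, so enlarging a cohort
never perturbs the genes already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genes import GeneModel, downstream_of, transcript_interval
from .motifs import (
    DEFAULT_RULES,
    DEFAULT_WINDOWS,
    ELEMENTS,
    reverse_complement,
    scan_site,
)

EVENT_INTRONIC = "intronic_pCPA"
EVENT_TANDEM = "tandem_utr_shift"
EVENT_NONE = "none"

# transcript-relative start offsets of the planted words (within the
# default scan windows: UGUA in [-200,0), PAS in [-60,0), U-rich in [-60,60))
CASSETTE_OFFSETS = {"UGUA": -35, "PAS": -25, "U_rich": 8}
CASSETTE_WORDS_DNA = {"UGUA": "TGTA", "PAS": "AATAAA", "U_rich": "TTGTTT"}


class SizingError(ValueError):
    """Genes do not fit on the requested chromosome length."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Structural parameters of one synthetic chromosome of genes."""

    n_genes: int = 300
    chrom_length: Optional[int] = None  # None: sized to fit
    gene_length_range: Tuple[int, int] = (1000, 2500)
    exons_per_gene_range: Tuple[int, int] = (2, 6)
    intron_length_range: Tuple[int, int] = (150, 500)
    utr3_length_range: Tuple[int, int] = (180, 320)
    cassette_fraction_introns: float = 0.27
    cassette_fraction_terminal: float = 0.65
    tandem_site_fraction: float = 0.3
    background_gc: float = 0.5
    intergenic_gap_range: Tuple[int, int] = (700, 1400)
    exon_length_min: int = 80
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        for name in (
            "gene_length_range",
            "exons_per_gene_range",
            "intron_length_range",
            "utr3_length_range",
            "intergenic_gap_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a non-empty positive range")
        for name in (
            "cassette_fraction_introns",
            "cassette_fraction_terminal",
            "tandem_site_fraction",
            "background_gc",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    """A planted between-condition usage change."""

    event_type: str = EVENT_NONE
    delta_usage: float = 0.4
    affected_gene_fraction: float = 1.0

    def __post_init__(self):
        if self.event_type not in (EVENT_INTRONIC, EVENT_TANDEM, EVENT_NONE):
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if not 0.0 <= self.delta_usage <= 1.0:
            raise ValueError("delta_usage must be in [0, 1]")
        if not 0.0 <= self.affected_gene_fraction <= 1.0:
            raise ValueError("affected_gene_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SampleDesign:
    """Conditions (reference first), replication and sequencing depth."""

    conditions: Tuple[str, str] = ("WT", "U1KD")
    replicates_per_condition: int = 3
    reads_per_gene: float = 50.0
    overdispersion: float = 0.0

    def __post_init__(self):
        if self.replicates_per_condition < 1:
            raise ValueError("need >= 1 replicate per condition")
        if self.reads_per_gene < 0:
            raise ValueError("depth must be >= 0")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")

    @property
    def samples(self) -> List[str]:
        return [
            f"{cond}_rep{r + 1}"
            for cond in self.conditions
            for r in range(self.replicates_per_condition)
        ]

    @property
    def sample_conditions(self) -> Dict[str, str]:
        return {s: s.rsplit("_rep", 1)[0] for s in self.samples}


BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SITE_DISTAL = "distal"
SITE_TANDEM = "tandem"
SITE_INTRONIC = "intronic"


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    return BASES[rng.choice(4, size=length, p=probs)]


def _split_lengths(total: int, parts: int, minimum: int) -> List[int]:
    total = max(total, parts * minimum)
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def generate_genome(
    spec: SyntheticGenomeSpec,
) -> Tuple[Dict[str, str], List[GeneModel], pd.DataFrame]:
    """Generate (genome, gene models, structural truth table).

    The truth table has one row per designated cleavage site with its
    coordinates, type (distal / tandem / intronic), transcript intron
    index, cassette flag (site scans positive for all three cis-elements
    under the default windows) and candidate flag (the intron site that a
    premature-CPA effect would use: the transcript-first cassette intron,
    falling back to the transcript-first intron).
    """
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(spec.n_genes + 2)
    segments: List[np.ndarray] = []
    genes: List[GeneModel] = []
    rows: List[dict] = []
    cursor = 0
    for i in range(spec.n_genes):
        rng = np.random.default_rng(children[i])
        gap = int(rng.integers(*spec.intergenic_gap_range))
        strand = "+" if i % 2 == 0 else "-"
        n_exons = int(rng.integers(spec.exons_per_gene_range[0],
                                   spec.exons_per_gene_range[1] + 1))
        intron_lengths = [
            int(rng.integers(spec.intron_length_range[0],
                             spec.intron_length_range[1] + 1))
            for _ in range(n_exons - 1)
        ]
        utr3 = int(rng.integers(spec.utr3_length_range[0],
                                spec.utr3_length_range[1] + 1))
        target = int(rng.integers(spec.gene_length_range[0],
                                  spec.gene_length_range[1] + 1))
        terminal_len = utr3 + int(rng.integers(60, 151))
        if n_exons > 1:
            other = _split_lengths(
                target - sum(intron_lengths) - terminal_len,
                n_exons - 1,
                spec.exon_length_min,
            )
        else:
            other = []
        exon_tx = other + [terminal_len]  # transcript order
        # genomic order
        exon_g = exon_tx if strand == "+" else exon_tx[::-1]
        intron_g = intron_lengths if strand == "+" else intron_lengths[::-1]
        gene_start = cursor + gap
        exons = []
        pos = gene_start
        for j, length in enumerate(exon_g):
            exons.append((pos, pos + length))
            pos += length
            if j < len(intron_g):
                pos += intron_g[j]
        gene_end = pos
        gene = GeneModel(
            gene_id=f"G{i + 1:05d}",
            chrom=spec.chrom,
            strand=strand,
            exons=tuple(exons),
            utr3_length=utr3,
        )
        genes.append(gene)
        segments.append(
            _random_sequence(rng, gap + (gene_end - gene_start), spec.background_gc)
        )
        cursor = gene_end

        tes = gene.three_prime_end
        rows.append(
            {
                "gene_id": gene.gene_id,
                "site_id": f"{gene.gene_id}:distal",
                "chrom": spec.chrom,
                "pos": tes,
                "strand": strand,
                "site_type": SITE_DISTAL,
                "intron_index": -1,
            }
        )
        if rng.random() < spec.tandem_site_fraction and utr3 >= 115:
            offset_up = int(rng.integers(80, min(150, utr3 - 30) + 1))
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "site_id": f"{gene.gene_id}:tandem",
                    "chrom": spec.chrom,
                    "pos": downstream_of(tes, strand, -offset_up),
                    "strand": strand,
                    "site_type": SITE_TANDEM,
                    "intron_index": -1,
                }
            )
        introns_g = gene.introns
        intron_order = (
            range(len(introns_g)) if strand == "+" else range(len(introns_g) - 1, -1, -1)
        )
        for tx_idx, g_idx in enumerate(intron_order):
            s, e = introns_g[g_idx]
            margin = 20
            site_pos = int(rng.integers(s + margin, e - margin))
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "site_id": f"{gene.gene_id}:intron{tx_idx}",
                    "chrom": spec.chrom,
                    "pos": site_pos,
                    "strand": strand,
                    "site_type": SITE_INTRONIC,
                    "intron_index": tx_idx,
                }
            )

    tail_rng = np.random.default_rng(children[spec.n_genes])
    tail = int(tail_rng.integers(*spec.intergenic_gap_range))
    total = cursor + tail
    if spec.chrom_length is not None:
        if cursor > spec.chrom_length:
            raise SizingError(
                f"genes need {cursor} bases but chrom_length is {spec.chrom_length}"
            )
        total = spec.chrom_length
        tail = total - cursor
    segments.append(_random_sequence(tail_rng, tail, spec.background_gc))
    chrom_bytes = bytearray(np.concatenate(segments).tobytes()) if segments else bytearray()

    truth = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "site_id", "chrom", "pos", "strand", "site_type", "intron_index",
        ],
    )
    genome = {spec.chrom: chrom_bytes.decode("ascii")}

    # cassette planting: scan natively, then top up to the target rates
    cassette = np.zeros(len(truth), dtype=bool)
    if len(truth):
        native = np.array(
            [
                all(
                    scan_site(genome, r.chrom, int(r.pos), r.strand).values()
                )
                for r in truth.itertuples(index=False)
            ]
        )
        plant_rng = np.random.default_rng(children[spec.n_genes + 1])
        planted = np.zeros(len(truth), dtype=bool)
        is_terminal = truth["site_type"].isin([SITE_DISTAL, SITE_TANDEM]).to_numpy()
        for mask, rate in (
            (~is_terminal, spec.cassette_fraction_introns),
            (is_terminal, spec.cassette_fraction_terminal),
        ):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            n_target = int(round(rate * idx.size))
            negatives = idx[~native[idx]]
            need = n_target - int(native[idx].sum())
            if need > 0 and negatives.size:
                chosen = plant_rng.choice(
                    negatives, size=min(need, negatives.size), replace=False
                )
                planted[chosen] = True
        for row_idx in np.flatnonzero(planted):
            r = truth.iloc[row_idx]
            for element in ELEMENTS:
                word = CASSETTE_WORDS_DNA[element]
                offset = CASSETTE_OFFSETS[element]
                g0, g1 = transcript_interval(
                    int(r.pos), r.strand, offset, offset + len(word)
                )
                insert = word if r.strand == "+" else reverse_complement(word)
                chrom_bytes[g0:g1] = insert.encode("ascii")
        genome = {spec.chrom: chrom_bytes.decode("ascii")}
        cassette = native | planted
    truth["cassette"] = cassette

    # candidate intron per gene: transcript-first cassette intron, else first intron
    truth["is_candidate"] = False
    intronic = truth[truth["site_type"] == SITE_INTRONIC]
    for gene_id, grp in intronic.groupby("gene_id", sort=False):
        grp = grp.sort_values("intron_index")
        with_cassette = grp[grp["cassette"]]
        chosen = (with_cassette if len(with_cassette) else grp).index[0]
        truth.loc[chosen, "is_candidate"] = True
    return genome, genes, truth


def plant_usage(
    truth: pd.DataFrame,
    design: SampleDesign,
    effect: EffectSpec,
    seed: int = 0,
    base_intron_usage: float = 0.10,
    base_tandem_usage: float = 0.30,
) -> pd.DataFrame:
    """Fill per-condition usage fractions and planted event labels.

    Baseline usage per gene: candidate intron site 0.10 (background
    premature CPA), tandem site 0.30, distal the remainder; non-candidate
    intron sites are silent. Affected genes (drawn without replacement from
    the eligible pool) get their usage shifted by `delta_usage` in the
    alternate condition: intronic premature CPA is de-repressed (proximal
    usage rises in the knockdown -> a `repressed` event), the tandem shift
    moves usage from the proximal to the distal terminal-exon site
    (`enhanced` event). Usage fractions sum to 1 per gene per condition.
    """
    rng = np.random.default_rng(seed)
    out = truth.copy()
    ref, alt = design.conditions
    for cond in design.conditions:
        out[f"usage_{cond}"] = 0.0
    out["affected"] = False
    out["planted_direction"] = "none"
    out["planted_category"] = "none"

    has_tandem = set(out.loc[out.site_type == SITE_TANDEM, "gene_id"])
    candidate = out[(out.site_type == SITE_INTRONIC) & out.is_candidate]
    candidate_cassette = set(candidate.loc[candidate.cassette, "gene_id"])
    all_genes = list(dict.fromkeys(out["gene_id"]))

    if effect.event_type == EVENT_INTRONIC:
        eligible = sorted(candidate_cassette)
    elif effect.event_type == EVENT_TANDEM:
        eligible = sorted(has_tandem)
    else:
        eligible = []
    n_affected = int(round(effect.affected_gene_fraction * len(eligible)))
    affected = set(
        rng.choice(eligible, size=n_affected, replace=False) if n_affected else []
    )

    for gene_id in all_genes:
        mask = out["gene_id"] == gene_id
        sites = out[mask]
        intron_row = sites[(sites.site_type == SITE_INTRONIC) & sites.is_candidate]
        tandem_row = sites[sites.site_type == SITE_TANDEM]
        distal_row = sites[sites.site_type == SITE_DISTAL]
        usage = {}
        u_intron = base_intron_usage if len(intron_row) else 0.0
        u_tandem = base_tandem_usage if len(tandem_row) else 0.0
        for cond in design.conditions:
            usage[cond] = {"intron": u_intron, "tandem": u_tandem}
        if gene_id in affected:
            if effect.event_type == EVENT_INTRONIC:
                boosted = min(u_intron + effect.delta_usage, 1.0 - u_tandem - 0.02)
                usage[alt]["intron"] = boosted
                out.loc[mask, "planted_direction"] = "repressed"
                out.loc[mask, "planted_category"] = "intronic_APA"
            else:
                usage[ref]["tandem"] = 0.5 + effect.delta_usage / 2.0
                usage[alt]["tandem"] = 0.5 - effect.delta_usage / 2.0
                out.loc[mask, "planted_direction"] = "enhanced"
                out.loc[mask, "planted_category"] = "tandem_3UTR"
            out.loc[mask, "affected"] = True
        for cond in design.conditions:
            u_distal = 1.0 - usage[cond]["intron"] - usage[cond]["tandem"]
            if u_distal < 0:  # pragma: no cover - prevented by the cap above
                raise ValueError("usage fractions exceed 1")
            if len(intron_row):
                out.loc[intron_row.index, f"usage_{cond}"] = usage[cond]["intron"]
            if len(tandem_row):
                out.loc[tandem_row.index, f"usage_{cond}"] = usage[cond]["tandem"]
            out.loc[distal_row.index, f"usage_{cond}"] = u_distal
    return out


def simulate_3p_counts(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    design: SampleDesign,
    effect: Optional[EffectSpec] = None,
    seed: int = 0,
    jitter: int = 5,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample read 3'-end counts from the planted truth.

    Per gene and replicate the total read count is drawn Poisson (or
    negative-binomial when overdispersion > 0) around the design depth,
    allocated to the gene's planted sites multinomially by the condition's
    usage fractions, and each read's end position is jittered uniformly
    within +/- `jitter` nt. Returns (read-end table, truth with usage
    columns). A design depth of 0 yields an empty table.
    """
    usage_cols = [f"usage_{c}" for c in design.conditions]
    if not all(c in truth.columns for c in usage_cols):
        if any(col.startswith("usage_") for col in truth.columns):
            known = [c[len("usage_"):] for c in truth.columns if c.startswith("usage_")]
            raise ValueError(
                f"unknown condition label(s) {list(design.conditions)}; "
                f"truth has usages for {known}"
            )
        truth = plant_usage(truth, design, effect or EffectSpec(EVENT_NONE), seed=seed)
    mu = design.reads_per_gene
    records: Dict[Tuple[str, int, str, str], int] = {}
    gene_order = {g.gene_id: i for i, g in enumerate(genes)}
    for gene_id, sites in truth.groupby("gene_id", sort=True):
        rng = np.random.default_rng([seed, gene_order.get(gene_id, 0), 7])
        positions = sites["pos"].to_numpy(dtype=int)
        chrom = sites["chrom"].iloc[0]
        strand = sites["strand"].iloc[0]
        for cond in design.conditions:
            usages = sites[f"usage_{cond}"].to_numpy(dtype=float)
            total_usage = usages.sum()
            if total_usage <= 0:
                continue
            usages = usages / total_usage
            for rep in range(design.replicates_per_condition):
                sample = f"{cond}_rep{rep + 1}"
                if mu <= 0:
                    continue
                if design.overdispersion > 0:
                    n_nb = 1.0 / design.overdispersion
                    total = int(rng.negative_binomial(n_nb, n_nb / (n_nb + mu)))
                else:
                    total = int(rng.poisson(mu))
                if total == 0:
                    continue
                alloc = rng.multinomial(total, usages)
                for pos, count in zip(positions, alloc):
                    if count == 0:
                        continue
                    if jitter > 0:
                        offsets = rng.integers(-jitter, jitter + 1, size=count)
                        ends, end_counts = np.unique(pos + offsets, return_counts=True)
                    else:
                        ends, end_counts = np.array([pos]), np.array([count])
                    for p, c in zip(ends, end_counts):
                        key = (chrom, int(p), strand, sample)
                        records[key] = records.get(key, 0) + int(c)
    if records:
        keys = sorted(records)
        counts = pd.DataFrame(
            {
                "chrom": [k[0] for k in keys],
                "pos": [k[1] for k in keys],
                "strand": [k[2] for k in keys],
                "sample": [k[3] for k in keys],
                "count": [records[k] for k in keys],
            }
        )
    else:
        counts = pd.DataFrame(columns=["chrom", "pos", "strand", "sample", "count"])
    return counts, truth


def simulate_coverage(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    shift: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_height: float = 10.0,
    peak_sd: float = 30.0,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Reference and shifted coverage tracks with a 3'-end peak per gene.

    Each gene contributes a Gaussian occupancy peak (height `peak_height`,
    sd `peak_sd` nt) centred on its annotated 3' end; in the alternate
    track the peak is displaced `shift` nt downstream (strand-aware).
    Independent N(0, noise_sd) noise is added to each track and clipped at
    zero. With shift=0 and noise_sd=0 the tracks are identical.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    ref = {c: np.zeros(l, dtype=float) for c, l in chrom_sizes.items()}
    alt = {c: np.zeros(l, dtype=float) for c, l in chrom_sizes.items()}
    half_width = int(4 * peak_sd)
    for gene in genes:
        for track, center in (
            (ref, gene.three_prime_end),
            (alt, downstream_of(gene.three_prime_end, gene.strand, shift)),
        ):
            cov = track[gene.chrom]
            lo = max(0, center - half_width)
            hi = min(len(cov), center + half_width + 1)
            if hi <= lo:
                continue
            x = np.arange(lo, hi)
            cov[lo:hi] += peak_height * np.exp(
                -0.5 * ((x - center) / peak_sd) ** 2
            )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for track in (ref, alt):
            for chrom in track:
                track[chrom] = np.clip(
                    track[chrom] + rng.normal(0.0, noise_sd, len(track[chrom])), 0.0, None
                )
    return ref, alt


def simulate_intensity_table(
    n_proteins: int,
    n_enriched: int,
    effect_log2fc: float = 4.0,
    replicates: int = 3,
    missing_rate: float = 0.0,
    seed: int = 0,
    base_mean: float = 25.0,
    between_protein_sd: float = 2.0,
    within_sd: float = 0.3,
    bait_missing_factor: float = 0.25,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Protein x sample log2-intensity table with planted enriched proteins.

    The first `n_enriched` proteins have their bait-sample mean elevated by
    `effect_log2fc`. Missing values (NaN) are injected at `missing_rate` in
    control samples and `missing_rate * bait_missing_factor` in bait
    samples, emulating the structural missingness of control IPs. Returns
    (table, boolean truth labels indexed like the table).
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched must be <= n_proteins")
    rng = np.random.default_rng(seed)
    index = pd.Index([f"P{i + 1:05d}" for i in range(n_proteins)], name="protein")
    bait_cols = [f"bait_{r + 1}" for r in range(replicates)]
    ctrl_cols = [f"ctrl_{r + 1}" for r in range(replicates)]
    baseline = rng.normal(base_mean, between_protein_sd, n_proteins)
    data = {}
    enriched = np.zeros(n_proteins, dtype=bool)
    enriched[:n_enriched] = True
    for col in bait_cols:
        data[col] = baseline + enriched * effect_log2fc + rng.normal(0, within_sd, n_proteins)
    for col in ctrl_cols:
        data[col] = baseline + rng.normal(0, within_sd, n_proteins)
    table = pd.DataFrame(data, index=index)
    if missing_rate > 0:
        for col in ctrl_cols:
            drop = rng.random(n_proteins) < missing_rate
            table.loc[drop, col] = np.nan
        bait_rate = missing_rate * bait_missing_factor
        if bait_rate > 0:
            for col in bait_cols:
                drop = rng.random(n_proteins) < bait_rate
                table.loc[drop, col] = np.nan
    return table, pd.Series(enriched, index=index, name="enriched")


# ---------------------------------------------------------------------------
# study cohorts


def apa_cohort(
    seed: int,
    n_genes: int = 450,
    event_type: str = EVENT_INTRONIC,
    delta_usage: float = 0.4,
    affected_gene_fraction: float = 1.0,
    reads_per_gene: float = 50.0,
    replicates: int = 3,
    tandem_site_fraction: float = 0.0,
    jitter: int = 5,
) -> dict:
    """One end-to-end APA study: genome, truth, design and read-end counts.

    Defaults give the intronic premature-CPA recovery condition: every gene
    has introns, candidate introns carry cassettes at the background 0.27
    rate and every cassette-candidate gene (~54% of genes, so >= 200 genes
    at the default size) receives a planted usage shift of `delta_usage`.
    Set event_type="none" for the matched null cohort.
    """
    spec = SyntheticGenomeSpec(
        n_genes=n_genes,
        tandem_site_fraction=tandem_site_fraction,
        seed=seed,
    )
    effect = EffectSpec(
        event_type=event_type,
        delta_usage=delta_usage,
        affected_gene_fraction=affected_gene_fraction,
    )
    design = SampleDesign(
        replicates_per_condition=replicates, reads_per_gene=reads_per_gene
    )
    genome, genes, truth = generate_genome(spec)
    counts, truth = simulate_3p_counts(
        genes, truth, design, effect, seed=seed + 1, jitter=jitter
    )
    return {
        "spec": spec,
        "effect": effect,
        "design": design,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "counts": counts,
    }


def coverage_cohort(
    seed: int,
    n_genes: int = 60,
    shift: int = 200,
    noise_sd: float = 0.0,
) -> dict:
    """Genes plus reference/shifted RNAPII-like coverage tracks.

    Intergenic gaps are widened (3-4 kb) so each gene's 3'-end peak is
    isolated within the default metaplot window and the planted downstream
    displacement is recoverable without interference from neighbouring
    genes' peaks.
    """
    spec = SyntheticGenomeSpec(
        n_genes=n_genes,
        intergenic_gap_range=(3000, 4000),
        tandem_site_fraction=0.0,
        seed=seed,
    )
    genome, genes, truth = generate_genome(spec)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    ref, alt = simulate_coverage(
        genes, chrom_sizes, shift=shift, noise_sd=noise_sd, seed=seed + 1
    )
    return {
        "spec": spec,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "chrom_sizes": chrom_sizes,
        "track_ref": ref,
        "track_alt": alt,
    }
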