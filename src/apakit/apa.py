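"""Differential APA event calling and genomic-context classification.

For each gene, only the two most abundant CPA sites are considered. They
are ordered proximal/distal in transcript direction and the proximal-site
usage fraction is compared between a reference condition (WT) and an
alternate condition (knockdown): delta = usage_ref - usage_alt. An event
is `enhanced` when the proximal site is used more in the reference
(delta > 0, significant) and `repressed` when it is used less (delta < 0,
significant); intronic premature CPA de-repressed by a knockdown therefore
surfaces as repressed intronic events.

Events are placed in one of three biological categories from the genomic
context of the two sites: both in the terminal exon -> tandem 3'-UTR
(3'-UTR length change only); proximal in an intron -> intronic APA
(premature cleavage, loss of telescripting); proximal in an internal
(skipped) exon -> alternative terminal exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .genes import GeneModel
from .pas import PASCluster

logger = logging.getLogger(__name__)

CONTEXT_INTRON = "intron"
CONTEXT_TERMINAL_EXON = "terminal_exon"
CONTEXT_INTERNAL_EXON = "internal_exon"
CONTEXT_UTR3_EXTENSION = "utr3_extension"
CONTEXT_INTERGENIC = "intergenic"

CATEGORY_TANDEM = "tandem_3UTR"
CATEGORY_INTRONIC = "intronic_APA"
CATEGORY_ALT_TERMINAL = "alt_terminal_exon"
CATEGORY_OTHER = "other"

DIRECTION_ENHANCED = "enhanced"
DIRECTION_REPRESSED = "repressed"
DIRECTION_NS = "ns"


def classify_site_context(pos: int, gene: GeneModel, extension: int = 500) -> str:
    """Genomic context of a cleavage site within one gene model."""
    for i, (s, e) in enumerate(gene.exons):
        if s <= pos < e:
            return (
                CONTEXT_TERMINAL_EXON
                if i == gene.terminal_exon_index
                else CONTEXT_INTERNAL_EXON
            )
    for s, e in gene.introns:
        if s <= pos < e:
            return CONTEXT_INTRON
    if gene.in_downstream_extension(pos, extension):
        return CONTEXT_UTR3_EXTENSION
    return CONTEXT_INTERGENIC


def categorize_event(prox_context: str, dist_context: str) -> str:
    """Event category from the contexts of the proximal and distal site."""
    if prox_context == CONTEXT_TERMINAL_EXON and dist_context in (
        CONTEXT_TERMINAL_EXON,
        CONTEXT_UTR3_EXTENSION,
    ):
        return CATEGORY_TANDEM
    if prox_context == CONTEXT_INTRON:
        return CATEGORY_INTRONIC
    if prox_context == CONTEXT_INTERNAL_EXON:
        return CATEGORY_ALT_TERMINAL
    return CATEGORY_OTHER


def select_top_two_sites(
    gene: GeneModel,
    clusters: Sequence[PASCluster],
    min_count: int = 10,
) -> Optional[Tuple[PASCluster, PASCluster]]:
    """The gene's two most abundant unfiltered CPA sites, proximal first.

    Abundance is the total count over all samples. Ties break toward the
    transcript-proximal site so the selected pair is deterministic. Returns
    None when fewer than two usable clusters exist or either of the top two
    falls below `min_count` total reads.
    """
    usable = [c for c in clusters if not c.filtered]
    if len(usable) < 2:
        return None
    ranked = sorted(
        usable,
        key=lambda c: (-c.total, gene.transcript_offset(c.representative)),
    )
    top = ranked[:2]
    if any(c.total < min_count for c in top):
        return None
    top.sort(key=lambda c: gene.transcript_offset(c.representative))
    return top[0], top[1]


def fisher_usage_test(
    prox_ref: int, dist_ref: int, prox_alt: int, dist_alt: int
) -> Tuple[float, float]:
    """Two-sided Fisher exact test on pooled proximal/distal counts.

    Returns (p_value, delta) with delta = proximal usage fraction in the
    reference minus in the alternate condition.
    """
    for v in (prox_ref, dist_ref, prox_alt, dist_alt):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if prox_ref + dist_ref == 0 or prox_alt + dist_alt == 0:
        raise ValueError("both conditions need non-zero totals")
    _, p = stats.fisher_exact(
        [[prox_ref, dist_ref], [prox_alt, dist_alt]], alternative="two-sided"
    )
    delta = prox_ref / (prox_ref + dist_ref) - prox_alt / (prox_alt + dist_alt)
    return float(p), float(delta)


def _betabinom_negll(params: np.ndarray, x: np.ndarray, n: np.ndarray,
                     groups: np.ndarray, common: bool) -> float:
    if common:
        logit_mu = np.full(x.shape, params[0])
    else:
        logit_mu = np.where(groups == 0, params[0], params[1])
    log_phi = params[-1]
    mu = special.expit(logit_mu)
    rho = np.exp(log_phi)  # precision of the beta mixing distribution
    a = mu * rho
    b = (1.0 - mu) * rho
    ll = (
        special.betaln(x + a, n - x + b)
        - special.betaln(a, b)
        + special.gammaln(n + 1)
        - special.gammaln(x + 1)
        - special.gammaln(n - x + 1)
    )
    return -float(np.sum(ll))


def betabinom_usage_test(
    prox_ref: Sequence[int],
    dist_ref: Sequence[int],
    prox_alt: Sequence[int],
    dist_alt: Sequence[int],
) -> Tuple[float, float]:
    """Replicate-aware beta-binomial likelihood-ratio test on proximal usage.

    Per-replicate proximal counts are modelled Beta-Binomial with a shared
    precision and either a common or a per-condition mean usage; the LRT
    statistic is referred to chi-square with 1 df. Falls back to the pooled
    Fisher test when every replicate total is zero in a condition.
    """
    x = np.concatenate([np.asarray(prox_ref, float), np.asarray(prox_alt, float)])
    n = x + np.concatenate([np.asarray(dist_ref, float), np.asarray(dist_alt, float)])
    groups = np.concatenate(
        [np.zeros(len(prox_ref), int), np.ones(len(prox_alt), int)]
    )
    keep = n > 0
    x, n, groups = x[keep], n[keep], groups[keep]
    if (groups == 0).sum() == 0 or (groups == 1).sum() == 0:
        raise ValueError("both conditions need replicates with non-zero totals")
    p_ref = x[groups == 0].sum() / n[groups == 0].sum()
    p_alt = x[groups == 1].sum() / n[groups == 1].sum()
    delta = float(p_ref - p_alt)
    p_pool = np.clip(x.sum() / n.sum(), 1e-6, 1 - 1e-6)
    start_mu = float(special.logit(p_pool))
    null = optimize.minimize(
        _betabinom_negll, x0=[start_mu, np.log(50.0)],
        args=(x, n, groups, True), method="Nelder-Mead",
    )
    alt = optimize.minimize(
        _betabinom_negll,
        x0=[special.logit(np.clip(p_ref, 1e-6, 1 - 1e-6)),
            special.logit(np.clip(p_alt, 1e-6, 1 - 1e-6)),
            np.log(50.0)],
        args=(x, n, groups, False), method="Nelder-Mead",
    )
    lrt = max(0.0, 2.0 * (null.fun - alt.fun))
    p = float(stats.chi2.sf(lrt, df=1))
    return p, delta


@dataclass
class APAEvent:
    """A tested proximal/distal CPA-site pair for one gene."""

    gene_id: str
    proximal: PASCluster
    distal: PASCluster
    prox_context: str
    dist_context: str
    category: str
    usage_ref: float
    usage_alt: float
    delta: float
    p_value: float
    q_value: float = np.nan
    direction: str = DIRECTION_NS


def test_differential_usage(
    proximal: PASCluster,
    distal: PASCluster,
    sample_conditions: Mapping[str, str],
    conditions: Sequence[str],
    method: str = "fisher",
) -> Tuple[float, float, float, float]:
    """(p, delta, usage_ref, usage_alt) for one site pair.

    Replicates are pooled within condition for the primary Fisher test;
    method="betabinom" uses the replicate-aware beta-binomial test instead.
    """
    ref, alt = conditions[0], conditions[1]
    samples_by_cond = {ref: [], alt: []}
    for sample in set(proximal.counts) | set(distal.counts):
        cond = sample_conditions.get(sample)
        if cond is None:
            raise ValueError(f"sample {sample!r} has no condition label")
        if cond in samples_by_cond:
            samples_by_cond[cond].append(sample)
    prox = {c: [proximal.counts.get(s, 0) for s in sorted(ss)]
            for c, ss in samples_by_cond.items()}
    dist = {c: [distal.counts.get(s, 0) for s in sorted(ss)]
            for c, ss in samples_by_cond.items()}
    pr, dr = sum(prox[ref]), sum(dist[ref])
    pa, da = sum(prox[alt]), sum(dist[alt])
    if pr + dr == 0 or pa + da == 0:
        raise ValueError("zero total in a condition")
    usage_ref = pr / (pr + dr)
    usage_alt = pa / (pa + da)
    if method == "fisher":
        p, delta = fisher_usage_test(pr, dr, pa, da)
    elif method == "betabinom":
        p, delta = betabinom_usage_test(prox[ref], dist[ref], prox[alt], dist[alt])
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, delta, usage_ref, usage_alt


def call_apa_events(
    assignments: Mapping[str, Sequence[PASCluster]],
    genes: Mapping[str, GeneModel],
    sample_conditions: Mapping[str, str],
    conditions: Sequence[str],
    alpha: float = 0.05,
    min_delta: float = 0.1,
    min_count: int = 10,
    extension: int = 500,
    method: str = "fisher",
) -> pd.DataFrame:
    """Detect, test and categorize APA events across all genes.

    BH correction is applied jointly across all tested events; an event is
    called enhanced/repressed when q < alpha and |delta| >= min_delta, and
    reported as ns otherwise. Genes with fewer than two usable sites, or a
    zero pooled total in either condition, are skipped (logged).
    """
    events: List[APAEvent] = []
    for gene_id in sorted(assignments):
        gene = genes[gene_id]
        pair = select_top_two_sites(gene, assignments[gene_id], min_count=min_count)
        if pair is None:
            continue
        proximal, distal = pair
        try:
            p, delta, usage_ref, usage_alt = test_differential_usage(
                proximal, distal, sample_conditions, conditions, method=method
            )
        except ValueError as exc:
            logger.info("skipping gene %s: %s", gene_id, exc)
            continue
        prox_ctx = classify_site_context(proximal.representative, gene, extension)
        dist_ctx = classify_site_context(distal.representative, gene, extension)
        events.append(
            APAEvent(
                gene_id=gene_id,
                proximal=proximal,
                distal=distal,
                prox_context=prox_ctx,
                dist_context=dist_ctx,
                category=categorize_event(prox_ctx, dist_ctx),
                usage_ref=usage_ref,
                usage_alt=usage_alt,
                delta=delta,
                p_value=p,
            )
        )
    if events:
        q_values = multipletests([e.p_value for e in events], method="fdr_bh")[1]
        for event, q in zip(events, q_values):
            event.q_value = float(q)
            if q < alpha and abs(event.delta) >= min_delta:
                event.direction = (
                    DIRECTION_ENHANCED if event.delta > 0 else DIRECTION_REPRESSED
                )
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in events],
            "chrom": [e.proximal.chrom for e in events],
            "strand": [e.proximal.strand for e in events],
            "proximal_pos": [e.proximal.representative for e in events],
            "distal_pos": [e.distal.representative for e in events],
            "prox_context": [e.prox_context for e in events],
            "dist_context": [e.dist_context for e in events],
            "category": [e.category for e in events],
            "usage_ref": [e.usage_ref for e in events],
            "usage_alt": [e.usage_alt for e in events],
            "delta": [e.delta for e in events],
            "p_value": [e.p_value for e in events],
            "q_value": [e.q_value for e in events],
            "direction": [e.direction for e in events],
        }
    )
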