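import pytest

from apakit import synthetic as syn

# study cohorts are session-scoped: several test modules interrogate the
# same planted truth, and generation is the slow step.

RECOVERY_SEED = 11
NULL_SEED = 12


@pytest.fixture(scope="session")
def recovery_cohort():
    """Intronic premature-CPA recovery condition: >=200 affected genes,
    planted usage shift 0.4, 3 replicates/condition, ~50 reads/gene."""
    return syn.apa_cohort(seed=RECOVERY_SEED, n_genes=450)


@pytest.fixture(scope="session")
def null_cohort():
    """Matched cohort with no planted effect (tandem sites included)."""
    return syn.apa_cohort(
        seed=NULL_SEED, n_genes=250, event_type="none", tandem_site_fraction=0.3
    )


@pytest.fixture(scope="session")
def toy_genome():
    """A handcrafted two-gene locus for coordinate-level unit tests.

    gplus: exons [100,200)+[300,400)+[500,700) on '+', 3'UTR 100 nt.
    gminus: exons [1000,1200)+[1300,1400) on '-', 3'UTR 100 nt
    (terminal exon is the genomically first one).
    """
    from apakit.genes import GeneModel

    seq = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(2600))
    genome = {"chrT": seq}
    gplus = GeneModel(
        "gplus", "chrT", "+", ((100, 200), (300, 400), (500, 700)), utr3_length=100
    )
    gminus = GeneModel(
        "gminus", "chrT", "-", ((1000, 1200), (1300, 1400)), utr3_length=100
    )
    return genome, gplus, gminus
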