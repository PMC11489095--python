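import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apakit.pas import (
    PASCluster,
    assign_to_genes,
    cluster_read_ends,
    cluster_read_ends as _cluster,
    clusters_to_frame,
    filter_internal_priming,
)
from apakit.genes import GeneModel


def ends_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "sample", "count"])


class TestClustering:
    def test_singleton(self):
        clusters = cluster_read_ends(
            ends_frame([("c", 100, "+", "s1", 1)]), max_gap=24
        )
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.end, c.representative) == (100, 101, 100)

    def test_gap_rule_and_modal_representative(self):
        ends = ends_frame(
            [
                ("c", 100, "+", "s1", 5),
                ("c", 101, "+", "s1", 7),
                ("c", 150, "+", "s1", 2),
            ]
        )
        clusters = cluster_read_ends(ends, max_gap=24)
        assert len(clusters) == 2
        assert clusters[0].representative == 101
        assert clusters[0].total == 12
        assert clusters[1].representative == 150

    @pytest.mark.parametrize("strand,expected", [("+", 110), ("-", 100)])
    def test_ties_break_downstream(self, strand, expected):
        ends = ends_frame(
            [("c", 100, strand, "s1", 5), ("c", 110, strand, "s1", 5)]
        )
        (cluster,) = cluster_read_ends(ends, max_gap=24)
        assert cluster.representative == expected

    def test_counts_kept_per_sample(self):
        ends = ends_frame(
            [("c", 100, "+", "a", 3), ("c", 101, "+", "b", 4), ("c", 100, "+", "b", 1)]
        )
        (cluster,) = cluster_read_ends(ends)
        assert cluster.counts == {"a": 3, "b": 5}

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            cluster_read_ends(ends_frame([]), max_gap=-1)

    def test_strands_never_merge(self):
        ends = ends_frame([("c", 100, "+", "s", 1), ("c", 101, "-", "s", 1)])
        assert len(cluster_read_ends(ends)) == 2

    @settings(derandomize=True, max_examples=50)
    @given(
        positions=st.lists(st.integers(0, 2000), min_size=1, max_size=60),
        max_gap=st.integers(0, 40),
    )
    def test_idempotent_on_representatives(self, positions, max_gap):
        """Re-clustering the cluster representatives returns the same
        representatives: cluster spacing already exceeds max_gap."""
        ends = ends_frame([("c", p, "+", "s", 1) for p in positions])
        clusters = cluster_read_ends(ends, max_gap=max_gap)
        reps = sorted(c.representative for c in clusters)
        again = cluster_read_ends(
            ends_frame([("c", r, "+", "s", 1) for r in reps]), max_gap=max_gap
        )
        assert sorted(c.representative for c in again) == reps

    @settings(derandomize=True, max_examples=30)
    @given(
        rows=st.lists(
            st.tuples(
                st.integers(0, 500),
                st.sampled_from("+-"),
                st.sampled_from(["s1", "s2"]),
                st.integers(0, 9),
            ),
            max_size=80,
        )
    )
    def test_count_conservation(self, rows):
        ends = ends_frame([("c", p, s, smp, c) for p, s, smp, c in rows])
        clusters = cluster_read_ends(ends, max_gap=10)
        assert sum(c.total for c in clusters) == int(ends["count"].sum())


class TestInternalPrimingFilter:
    @pytest.mark.parametrize(
        "decamer,flagged",
        [
            ("AAAAAAAAAA", True),  # maximal A content
            ("ACGTACGTAC", False),  # unremarkable
            ("AAAAAACGTG", True),  # run of 6 triggers the run rule alone
            ("AACGAACGAA", False),  # 6 A total but max run 2
        ],
    )
    def test_downstream_decamers(self, decamer, flagged):
        genome = {"c": "C" * 100 + "G" + decamer + "C" * 50}
        cluster = PASCluster("c", "+", 100, 101, 100, {"s": 5})
        (out,) = filter_internal_priming([cluster], genome)
        assert out.filtered is flagged

    def test_minus_strand_reads_sense_adenosines(self):
        # genomic TTTTTTTTTT upstream of a minus-strand site is sense-A
        genome = {"c": "C" * 90 + "T" * 10 + "G" + "C" * 50}
        cluster = PASCluster("c", "-", 100, 101, 100, {"s": 5})
        (out,) = filter_internal_priming([cluster], genome)
        assert out.filtered is True

    def test_window_truncated_at_chromosome_end(self):
        genome = {"c": "C" * 100 + "GAAA"}  # only 3 downstream bases exist
        cluster = PASCluster("c", "+", 100, 101, 100, {"s": 5})
        (out,) = filter_internal_priming([cluster], genome)
        assert out.filtered is False

    def test_flagged_sites_retained_in_output(self):
        genome = {"c": "C" * 100 + "G" + "A" * 20}
        clusters = [PASCluster("c", "+", 100, 101, 100, {"s": 5})]
        out = filter_internal_priming(clusters, genome)
        assert len(out) == 1 and out[0].total == 5


class TestAssignment:
    @pytest.fixture()
    def two_genes(self):
        a = GeneModel("ga", "c", "+", ((100, 300), (400, 600)))
        b = GeneModel("gb", "c", "+", ((800, 1200),))
        return [a, b]

    def cluster_at(self, pos, strand="+"):
        return PASCluster("c", strand, pos, pos + 1, pos, {"s": 1})

    def test_intronic_containment(self, two_genes):
        assigned, unassigned = assign_to_genes([self.cluster_at(350)], two_genes)
        assert list(assigned) == ["ga"] and not unassigned

    def test_downstream_extension_rule(self, two_genes):
        # 300 nt past gb's annotated 3' end (1199), inside default 500
        assigned, _ = assign_to_genes([self.cluster_at(1499)], two_genes)
        assert list(assigned) == ["gb"]
        _, unassigned = assign_to_genes([self.cluster_at(1800)], two_genes)
        assert len(unassigned) == 1

    def test_wrong_strand_unassigned(self, two_genes):
        _, unassigned = assign_to_genes([self.cluster_at(350, "-")], two_genes)
        assert len(unassigned) == 1

    def test_overlapping_genes_nearest_3prime_end_then_lexicographic(self):
        g1 = GeneModel("gx", "c", "+", ((0, 1000),))
        g2 = GeneModel("gy", "c", "+", ((200, 800),))
        # position 790: distance 209 to gx's end (999), 9 to gy's (799)
        assigned, _ = assign_to_genes([self.cluster_at(790)], [g1, g2])
        assert list(assigned) == ["gy"]
        # equidistant tie: pos 899 is 100 from both 3' ends
        g3 = GeneModel("gz", "c", "+", ((0, 1000),))
        g4 = GeneModel("ga", "c", "+", ((200, 800),))
        assigned, _ = assign_to_genes([self.cluster_at(899)], [g3, g4])
        assert list(assigned) == ["ga"]


class TestPlantedSiteRecovery:
    def test_representatives_recover_planted_sites(self, recovery_cohort):
        """With jitter below half the cluster gap and planted sites spaced
        beyond it, >=99% of expressed planted sites are recovered within
        the jitter radius."""
        counts = recovery_cohort["counts"]
        truth = recovery_cohort["truth"]
        clusters = cluster_read_ends(counts, max_gap=24)
        reps = {}
        for c in clusters:
            reps.setdefault((c.chrom, c.strand), []).append(c.representative)
        expressed = truth[truth[["usage_WT", "usage_U1KD"]].sum(axis=1) > 0]
        hits = total = 0
        for row in expressed.itertuples(index=False):
            candidates = np.asarray(reps.get((row.chrom, row.strand), []))
            total += 1
            if candidates.size and np.abs(candidates - row.pos).min() <= 5:
                hits += 1
        assert hits / total >= 0.99

    def test_clusters_to_frame_sums(self, null_cohort):
        clusters = cluster_read_ends(null_cohort["counts"])
        frame = clusters_to_frame(clusters)
        count_cols = [c for c in frame.columns if c.startswith("count_")]
        assert (frame[count_cols].sum(axis=1) == frame["total"]).all()
        assert int(frame["total"].sum()) == int(null_cohort["counts"]["count"].sum())
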