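"""Locus placement, families, naming, clustering and the summary table."""

import numpy as np
import pandas as pd
import pytest

from aphidmir._seq import random_dna, revcomp_dna
from aphidmir.locus_annotation import (
    Cluster,
    MirnaLocus,
    assign_families,
    biased_x_rates,
    chromosome_summary,
    classify_clusters,
    clustered_percentage,
    detect_clusters,
    localize_precursors,
    name_novel_mirnas,
    placed_locus_count,
    summarize_counts,
)


def make_locus(lid, chrom, start, end, mature="ACGU", **kw):
    return MirnaLocus(
        locus_id=lid, chromosome=chrom, start=start, end=end, strand="+",
        precursor_id=f"p{lid}", mature_seq=mature, **kw,
    )


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

class TestLocalize:
    def test_single_forward_occurrence(self):
        genome = {"A1": "GGGG" + "ACGTACGTTT" + "CCCC"}
        loci = localize_precursors({"p1": "ACGTACGTTT"}, genome)
        assert len(loci) == 1
        loc = loci[0]
        assert (loc.chromosome, loc.start, loc.end, loc.strand) == ("A1", 4, 14, "+")

    def test_two_chromosomes_two_loci(self):
        pre = "ACGTACGTTTGG"
        genome = {"A1": "TT" + pre + "AA", "A2": "GG" + pre + "CC"}
        loci = localize_precursors({"p1": pre}, genome)
        assert {loc.chromosome for loc in loci} == {"A1", "A2"}

    def test_one_mismatch_yields_nothing(self):
        pre = "ACGTACGTTTGG"
        mutated = "ACGTACGTTTGC"
        loci = localize_precursors({"p1": pre}, {"A1": "TT" + mutated + "AA"})
        assert loci == []

    def test_reverse_complement_reported_on_minus_strand(self):
        pre = "ACGTACGTTTGG"
        genome = {"A1": "TT" + pre + "AAAA" + revcomp_dna(pre) + "CC"}
        loci = localize_precursors({"p1": pre}, genome)
        assert sorted(loc.strand for loc in loci) == ["+", "-"][::-1] or len(loci) == 2
        assert {loc.strand for loc in loci} == {"+", "-"}

    def test_u_and_t_equivalent(self):
        loci = localize_precursors({"p1": "ACGUACGUUUGG"}, {"A1": "ACGTACGTTTGGAA"})
        assert len(loci) == 1

    def test_ambiguous_bases_never_match(self):
        loci = localize_precursors({"p1": "ACGTACGTTT"}, {"A1": "ACGTNCGTTTAA"})
        assert loci == []

    def test_matches_naive_scan_on_random_genomes(self, rng):
        """Exact localization equals a sliding-window scan of both strands."""
        for trial in range(15):
            genome = {"c1": random_dna(rng, 3000), "c2": random_dna(rng, 2000)}
            pres = {}
            for i in range(4):
                p = random_dna(rng, 25)
                # plant some occurrences
                chrom = "c1" if i % 2 == 0 else "c2"
                pos = int(rng.integers(0, len(genome[chrom]) - 25))
                emb = p if i < 2 else revcomp_dna(p)
                genome[chrom] = genome[chrom][:pos] + emb + genome[chrom][pos + 25:]
                pres[f"p{i}"] = p
            got = {
                (l.precursor_id, l.chromosome, l.start, l.strand)
                for l in localize_precursors(pres, genome)
            }
            naive = set()
            for pid, p in pres.items():
                rc = revcomp_dna(p)
                for chrom, seq in genome.items():
                    for off in range(len(seq) - len(p) + 1):
                        window = seq[off : off + len(p)]
                        if window == p:
                            naive.add((pid, chrom, off, "+"))
                        if window == rc and rc != p:
                            naive.add((pid, chrom, off, "-"))
            assert got == naive


# ---------------------------------------------------------------------------
# families and naming
# ---------------------------------------------------------------------------

class TestFamiliesAndNames:
    def test_identical_matures_share_family(self):
        loci = [
            make_locus("l1", "A1", 0, 10, mature="ACGUACGU"),
            make_locus("l2", "A2", 0, 10, mature="ACGTACGT"),  # same, DNA spelling
            make_locus("l3", "A1", 50, 60, mature="ACGTACGA"),
        ]
        assign_families(loci)
        assert loci[0].family_id == loci[1].family_id
        assert loci[0].family_id != loci[2].family_id
        assert assign_families([]) == []

    def test_novel_naming_convention(self):
        loci = [
            make_locus("l1", "A1", 0, 10, mature="AAAAAAA"),
            make_locus("l2", "A1", 100, 110, mature="CCCCCCC"),
            make_locus("l3", "A2", 0, 10, mature="CCCCCCC"),
        ]
        assign_families(loci)
        names = name_novel_mirnas(loci)
        assert names["l1"] == "api-mir-x1"
        assert names["l2"] == "api-mir-x2a"
        assert names["l3"] == "api-mir-x2b"

    def test_known_names_kept_and_collisions_rejected(self):
        loci = [
            make_locus("l1", "A1", 0, 10, mature="AAAAAAA"),
            make_locus("l2", "A1", 100, 110, mature="CCCCCCC"),
        ]
        assign_families(loci)
        names = name_novel_mirnas(loci, known_names={"l1": "api-mir-87"})
        assert names["l1"] == "api-mir-87"
        assert names["l2"] == "api-mir-x1"
        with pytest.raises(ValueError, match="collides"):
            name_novel_mirnas(loci, known_names={"l1": "api-mir-x1"})


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def brute_force_clusters(loci, max_gap=10_000):
    """Transitive closure of the pairwise '<max_gap apart' interval relation
    (union-find over all pairs; independent of the chaining implementation)."""
    parent = {l.locus_id: l.locus_id for l in loci}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        parent[find(a)] = find(b)

    for i, a in enumerate(loci):
        for b in loci[i + 1:]:
            if a.chromosome == b.chromosome and _near_pair(a, b, max_gap):
                union(a.locus_id, b.locus_id)
    comps = {}
    for l in loci:
        comps.setdefault(find(l.locus_id), set()).add(l.locus_id)
    return {frozenset(c) for c in comps.values() if len(c) >= 2}


def _near_pair(a, b, max_gap):
    gap = max(a.start, b.start) - min(a.end, b.end)
    return gap < max_gap


class TestClusters:
    def test_worked_gap_example(self):
        loci = [
            make_locus("a", "A1", 1000, 1100),
            make_locus("b", "A1", 5000, 5100),
            make_locus("c", "A1", 20000, 20100),
        ]
        clusters = detect_clusters(loci)
        assert len(clusters) == 1
        assert clusters[0].locus_ids == ["a", "b"]
        assert clusters[0].span_bp == 5100 - 1000

    def test_chain_of_three_at_gap_9999(self):
        loci = [
            make_locus("a", "A1", 0, 100),
            make_locus("b", "A1", 100 + 9999, 100 + 9999 + 100),
            make_locus("c", "A1", 10199 + 9999, 10199 + 9999 + 100),
        ]
        (cluster,) = detect_clusters(loci)
        assert cluster.locus_ids == ["a", "b", "c"]

    def test_gap_of_exactly_10kb_does_not_chain(self):
        loci = [make_locus("a", "A1", 0, 100), make_locus("b", "A1", 10100, 10200)]
        assert detect_clusters(loci) == []

    def test_different_chromosomes_never_cluster(self):
        loci = [make_locus("a", "A1", 0, 100), make_locus("b", "A2", 200, 300)]
        assert detect_clusters(loci) == []

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for trial in range(60):
            n = int(rng.integers(2, 60))
            loci = []
            for i in range(n):
                chrom = f"c{int(rng.integers(1, 4))}"
                start = int(rng.integers(0, 120_000))
                length = int(rng.integers(50, 150))
                loci.append(make_locus(f"l{i}", chrom, start, start + length))
            got = {frozenset(c.locus_ids) for c in detect_clusters(loci)}
            assert got == brute_force_clusters(loci)

    def test_classification(self):
        loci = [
            make_locus("a", "A1", 0, 100, mature="AAAA"),
            make_locus("b", "A1", 200, 300, mature="AAAA"),
            make_locus("c", "A1", 400, 500, mature="CCCC"),
        ]
        assign_families(loci)
        clusters = classify_clusters(detect_clusters(loci), loci)
        assert clusters[0].kind == "multifamily"
        clusters2 = classify_clusters(
            [Cluster("x", "A1", ["a", "b"], 300)], loci
        )
        assert clusters2[0].kind == "single-family"


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

class TestSummary:
    def test_counts_sum_to_totals(self):
        loci = [
            make_locus("a", "A1", 0, 100, novel=True),
            make_locus("b", "X", 0, 100, novel=False),
            make_locus("c", "scaf7", 0, 100, novel=True),
        ]
        sizes = {"A1": 1000, "A2": 500, "A3": 300, "X": 800, "scaf7": 100}
        df = chromosome_summary(loci, {"pb"}, sizes)
        total = df[df.chromosome == "Total"].iloc[0]
        body = df[df.chromosome != "Total"]
        for col in ["n_novel", "n_known", "n_total", "n_biased"]:
            assert body[col].sum() == total[col]
        assert total.n_total == 3
        assert placed_locus_count(df) == 2
        assert total.n_biased == 1
        assert df[df.chromosome == "Unplaced scaffolds"].iloc[0].n_total == 1

    def test_genome_proportion(self):
        df = summarize_counts(
            pd.DataFrame(
                {
                    "chromosome": ["A1", "X"],
                    "size_bp": [750, 250],
                    "n_novel": [1, 2],
                    "n_known": [3, 4],
                    "n_biased": [0, 1],
                }
            )
        )
        assert np.allclose(df.genome_proportion[:2], [0.75, 0.25])
        assert df.n_total.tolist() == [4, 6, 10]

    def test_clustered_percentage(self):
        clusters = [Cluster("c1", "A1", ["a", "b", "c"], 500)]
        assert clustered_percentage(clusters, 6) == pytest.approx(50.0)
        assert clustered_percentage([], 0) == 0.0

    def test_biased_x_rates(self):
        df = summarize_counts(
            pd.DataFrame(
                {
                    "chromosome": ["A1", "X", "Unplaced scaffolds"],
                    "size_bp": [700, 200, 100],
                    "n_novel": [5, 5, 2],
                    "n_known": [5, 5, 0],
                    "n_biased": [2, 4, 1],
                }
            )
        )
        pct_b, pct_n = biased_x_rates(df)
        assert pct_b == pytest.approx(100 * 4 / 6)
        assert pct_n == pytest.approx(100 * 6 / 14)
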