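"""Planted-structure guarantees and determinism of the synthetic generator."""

import numpy as np
import pytest

from aphidmir import preset_config
from aphidmir._seq import revcomp_dna, to_dna
from aphidmir.expression_bias import (
    biased_set,
    call_sex_biased,
    count_reads_to_precursors,
    cpm_normalize,
)
from aphidmir.locus_annotation import detect_clusters
from aphidmir.synthetic_data import (
    GroundTruth,
    SizingError,
    SyntheticConfig,
    generate_all,
    generate_genome_and_loci,
    generate_utrs_with_sites,
    simulate_mirna_counts,
    simulate_mrna_counts,
    simulate_small_reads,
)
from aphidmir.target_prediction import find_seed_sites


class TestGenomeAndLoci:
    def test_precursors_embedded_verbatim_and_unique(self):
        cfg = preset_config("small", seed=5)
        genome, loci, gt = generate_genome_and_loci(cfg)
        assert len(loci) == cfg.n_mirnas
        for loc in loci:
            chrom = genome[loc.chromosome]
            window = chrom[loc.start : loc.end]
            expected = (
                to_dna(loc.precursor_seq)
                if loc.strand == "+"
                else revcomp_dna(loc.precursor_seq)
            )
            assert window == expected
            occurrences = sum(
                s.count(to_dna(loc.precursor_seq)) + s.count(revcomp_dna(loc.precursor_seq))
                for s in genome.values()
            )
            assert occurrences == 1

    def test_planted_clusters_recovered_exactly(self):
        cfg = SyntheticConfig(
            n_mirnas=10, n_clusters=2, cluster_size=3, n_single_family_clusters=0,
            n_known=0, n_biased=2, seed=9,
        )
        genome, loci, gt = generate_genome_and_loci(cfg)
        clusters = detect_clusters(loci)
        got = sorted(sorted(c.locus_ids) for c in clusters)
        planted = sorted(sorted(c) for c in gt.planted_clusters)
        assert got == planted
        assert len(got) == 2 and all(len(c) == 3 for c in got)

    def test_zero_mirnas_still_emits_genome(self):
        cfg = preset_config("empty", seed=1)
        genome, loci, gt = generate_genome_and_loci(cfg)
        assert loci == [] and gt.planted_clusters == []
        assert set(genome) == set(cfg.chromosome_lengths)

    def test_determinism_same_seed_identical_output(self):
        cfg = preset_config("small", seed=42)
        g1, l1, _ = generate_genome_and_loci(cfg)
        g2, l2, _ = generate_genome_and_loci(preset_config("small", seed=42))
        assert g1 == g2
        assert [(l.locus_id, l.start, l.strand) for l in l1] == [
            (l.locus_id, l.start, l.strand) for l in l2
        ]
        g3, _, _ = generate_genome_and_loci(preset_config("small", seed=43))
        assert g3 != g1

    def test_sizing_error_when_loci_do_not_fit(self):
        cfg = SyntheticConfig(
            chromosome_lengths={"A1": 30_000}, placed_chromosomes=("A1",),
            n_mirnas=10, n_clusters=0, n_single_family_clusters=0,
            n_known=0, n_biased=0, seed=0,
        )
        with pytest.raises(SizingError):
            generate_genome_and_loci(cfg)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError, match="bias_fold"):
            SyntheticConfig(bias_fold=1.0).validate()
        with pytest.raises(ValueError, match="exceed"):
            SyntheticConfig(n_mirnas=5, n_clusters=2, cluster_size=3).validate()


class TestMirnaCounts:
    def test_matrix_shape_and_labels(self):
        cfg = preset_config("small", seed=2)
        _, loci, gt = generate_genome_and_loci(cfg)
        m = simulate_mirna_counts(loci, cfg, gt)
        assert m.counts.shape == (cfg.n_mirnas, cfg.n_female_samples + 1)
        assert len(m.male_samples) == 1

    def test_bias_recovery_exact_under_recovery_conditions(self):
        cfg = preset_config("recovery", seed=17)
        _, loci, gt = generate_genome_and_loci(cfg)
        m = cpm_normalize(simulate_mirna_counts(loci, cfg, gt))
        calls = call_sex_biased(m)
        assert biased_set(calls, 5.0) == gt.biased_mirna_ids

    def test_no_planted_bias_yields_no_calls(self):
        cfg = preset_config("recovery", seed=17, n_biased=0)
        _, loci, gt = generate_genome_and_loci(cfg)
        m = cpm_normalize(simulate_mirna_counts(loci, cfg, gt))
        assert biased_set(call_sex_biased(m), 5.0) == set()

    def test_zero_depth_is_an_error(self):
        cfg = preset_config("small", seed=2, depth=0)
        _, loci, gt = generate_genome_and_loci(cfg)
        with pytest.raises(ValueError, match="depth"):
            simulate_mirna_counts(loci, cfg, gt)


class TestSmallReads:
    def test_round_trip_reproduces_counts_exactly(self, tmp_path):
        """reads -> quality/length filter -> exact counting == simulated counts
        (unique matures, no decoys)."""
        from aphidmir.expression_bias import process_small_reads
        from aphidmir.synthetic_data import write_fastq

        cfg = preset_config(
            "small", seed=23, n_single_family_clusters=0, decoy_fraction=0.0,
            n_female_samples=3, depth=1500,
        )
        _, loci, gt = generate_genome_and_loci(cfg)
        m = simulate_mirna_counts(loci, cfg, gt)
        reads = simulate_small_reads(loci, m, cfg)
        paths = write_fastq(reads, tmp_path)
        library = {loc.precursor_id: loc.precursor_seq for loc in loci}
        processed = {s: process_small_reads(p) for s, p in paths.items()}
        matrix, unmatched = count_reads_to_precursors(
            processed, library, dict(m.sex)
        )
        assert sum(unmatched.values()) == 0
        assert matrix.counts.loc[m.counts.index, m.counts.columns].equals(m.counts)

    def test_decoys_are_always_filtered(self, tmp_path):
        from aphidmir.expression_bias import process_small_reads
        from aphidmir.synthetic_data import write_fastq

        cfg = preset_config(
            "small", seed=23, n_single_family_clusters=0, decoy_fraction=0.3,
            n_female_samples=2, depth=800,
        )
        _, loci, gt = generate_genome_and_loci(cfg)
        m = simulate_mirna_counts(loci, cfg, gt)
        reads = simulate_small_reads(loci, m, cfg)
        paths = write_fastq(reads, tmp_path)
        for sample, path in paths.items():
            kept = process_small_reads(path)
            assert len(kept) == int(m.counts[sample].sum())
            assert all(18 <= len(r) <= 35 for r in kept)

    def test_zero_count_means_zero_reads(self):
        cfg = preset_config("small", seed=3, decoy_fraction=0.0)
        _, loci, gt = generate_genome_and_loci(cfg)
        m = simulate_mirna_counts(loci, cfg, gt)
        mid = m.counts.index[0]
        m.counts.loc[mid, :] = 0
        reads = simulate_small_reads(loci, m, cfg)
        for sample, recs in reads.items():
            assert not any(rid.split(":")[1] == mid for rid, _, _ in recs)


class TestUtrsAndSites:
    def _gt_with_de(self, cfg):
        gt = GroundTruth()
        simulate_mrna_counts(cfg, gt)
        return gt

    def test_planted_sites_found_at_recorded_offsets(self):
        cfg = preset_config("small", seed=31)
        _, loci, gt = generate_genome_and_loci(cfg)
        simulate_mrna_counts(cfg, gt)
        matures = {l.precursor_id: l.mature_seq for l in loci}
        utrs = generate_utrs_with_sites(matures, cfg, gt)
        assert len(gt.planted_sites) == cfg.n_biased * cfg.n_sites_per_biased
        for mid, gid, offset in gt.planted_sites:
            sites = dict(find_seed_sites(matures[mid], utrs[gid]))
            assert sites.get(offset) == cfg.site_match_len

    def test_no_accidental_seed_matches_for_biased_mirnas(self):
        cfg = preset_config("small", seed=31)
        _, loci, gt = generate_genome_and_loci(cfg)
        simulate_mrna_counts(cfg, gt)
        matures = {l.precursor_id: l.mature_seq for l in loci}
        utrs = generate_utrs_with_sites(matures, cfg, gt)
        planted = {(m, g) for m, g, _ in gt.planted_sites}
        for mid in gt.biased_mirna_ids:
            for gid, utr in utrs.items():
                hits = find_seed_sites(matures[mid], utr)
                assert bool(hits) == ((mid, gid) in planted)

    def test_degenerate_utr_length_warns(self):
        cfg = preset_config("small", seed=31, utr_length=5)
        _, loci, gt = generate_genome_and_loci(cfg)
        matures = {l.precursor_id: l.mature_seq for l in loci}
        with pytest.warns(RuntimeWarning, match="shorter"):
            utrs = generate_utrs_with_sites(matures, cfg, gt)
        assert utrs == {}


class TestMrnaCounts:
    def test_planted_de_recovered(self):
        from aphidmir.de_overlap import differential_expression, filter_significant

        cfg = preset_config("recovery", seed=19)
        gt = GroundTruth()
        counts, labels = simulate_mrna_counts(cfg, gt)
        recs = differential_expression(counts, labels)
        up_m, up_f = filter_significant(recs)
        called = {r.gene_id for r in up_m} | {r.gene_id for r in up_f}
        planted = set(gt.de_gene_ids)
        assert len(called & planted) / len(planted) >= 0.95
        nulls = set(counts.index) - planted
        assert len(called & nulls) / len(nulls) <= 0.01
        down_called = {r.gene_id for r in up_f}
        planted_down = {g for g, d in gt.de_gene_ids.items() if d == "higher-in-female"}
        assert planted_down <= set(counts.index)
        assert down_called >= planted_down - (planted - called)

    def test_directions_planted_symmetrically(self):
        cfg = preset_config("small", seed=4)
        gt = GroundTruth()
        counts, labels = simulate_mrna_counts(cfg, gt)
        dirs = list(gt.de_gene_ids.values())
        assert dirs.count("higher-in-female") == cfg.n_de_genes // 2 + cfg.n_de_genes % 2
        assert counts.shape == (cfg.n_genes, 2 * cfg.n_mrna_replicates)


def test_generate_all_ids_are_consistent():
    bundle = generate_all(preset_config("small", seed=7), with_reads=False)
    gt = bundle.ground_truth
    precursor_ids = {l.precursor_id for l in bundle.loci}
    assert gt.biased_mirna_ids <= precursor_ids
    assert set(bundle.matrix.counts.index) == precursor_ids
    gene_ids = set(bundle.gene_counts.index)
    assert set(gt.de_gene_ids) <= gene_ids
    assert {g for _, g, _ in gt.planted_sites} <= set(bundle.utrs)
    assert {m for m, _, _ in gt.planted_sites} <= gt.biased_mirna_ids
    locus_ids = {l.locus_id for l in bundle.loci}
    assert all(set(c) <= locus_ids for c in gt.planted_clusters)
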