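"""Synthetic genomes, miRNA loci, count matrices, UTRs and mRNA counts with
known planted structure.

Every downstream stage of the pipeline is exercised against data whose truth
is known by construction: clusters are planted with all adjacent gaps below
the clustering threshold and isolated loci at least 10 kb from anything else;
male-biased miRNAs are planted with a fixed male/female expression ratio;
target sites are planted as exact reverse complements of a miRNA 5' window at
recorded UTR offsets; differentially expressed genes are planted with a fixed
fold change. Rejection sampling forbids accidental precursor duplicates in
the genome and accidental seed matches for biased miRNAs in non-target UTRs,
so recovery tests can be exact rather than probabilistic.

Counts are negative binomial with variance mu + alpha * mu^2 (alpha = 0
degenerates to Poisson). The design mirrors an asymmetric study: one male
small-RNA library against many female libraries, and three replicates per
group for the mRNA side. Male-biased miRNAs are modeled as lowly expressed in
females (a fixed low female baseline) with the male mean ``bias_fold`` times
higher, emulating near-male-specific expression; this also keeps the male
library's compositional shift small, so the planted CPM ratio survives
per-library normalization.

All outputs are pure functions of (config, seed): the same seed yields
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import random_dna, revcomp_dna, to_dna
from .candidate_filtering import CandidateRecord
from .expression_bias import FEMALE, MALE, ExpressionMatrix
from .locus_annotation import MirnaLocus

#: isolation distance guaranteeing that non-cluster loci never chain
ISOLATION_BP = 12_000

_DNA_COMP = str.maketrans("ACGT", "TGCA")


class SizingError(ValueError):
    """The requested loci do not fit the genome at the required spacing."""


@dataclasses.dataclass
class SyntheticConfig:
    """All knobs of the synthetic study design (defaults mirror a scaled-down
    version of the real one: four chromosomes plus an unplaced scaffold, one
    male library against 48 female libraries, three mRNA replicates per sex).
    """

    chromosome_lengths: dict[str, int] = dataclasses.field(
        default_factory=lambda: {
            "A1": 320_000,
            "A2": 220_000,
            "A3": 80_000,
            "X": 240_000,
            "Sc1": 140_000,
        }
    )
    placed_chromosomes: tuple[str, ...] = ("A1", "A2", "A3", "X")
    # --- loci ---
    n_mirnas: int = 60
    n_clusters: int = 6
    cluster_size: int = 3
    n_single_family_clusters: int = 2
    cluster_gap_bp: int = 5_000  # planted adjacent gaps are < this (< 10 kb)
    n_known: int = 20  # loci emulating previously described miRNAs
    mature_len: int = 22
    loop_len: int = 15
    star_len: int = 22
    # --- small-RNA expression ---
    n_female_samples: int = 48
    n_male_samples: int = 1
    bias_fold: float = 10.0
    n_biased: int = 6
    biased_baseline_scale: float = 0.2  # female baseline of biased miRNAs
    x_expression_multiplier: float = 0.5  # X-linked mean multiplier (both sexes)
    nb_dispersion: float = 0.02
    depth: int = 20_000
    decoy_fraction: float = 0.05
    # --- candidates ---
    n_candidate_decoys: int = 6
    # --- targets ---
    utr_length: int = 500
    site_match_len: int = 18  # planted complementarity, positions 2..(1+len)
    n_sites_per_biased: int = 2
    # --- mRNA ---
    n_genes: int = 400
    n_de_genes: int = 40
    de_fold: float = 16.0
    mrna_dispersion: float = 0.01
    n_mrna_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if any(v <= 0 for v in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for name in (
            "n_mirnas", "n_clusters", "cluster_size", "n_known", "n_biased",
            "n_genes", "n_de_genes", "n_female_samples", "n_male_samples",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bias_fold <= 1:
            raise ValueError("bias_fold must be > 1")
        if self.n_clusters * self.cluster_size > self.n_mirnas:
            raise ValueError("clustered loci exceed n_mirnas")
        if self.n_single_family_clusters > self.n_clusters:
            raise ValueError("n_single_family_clusters exceeds n_clusters")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        if not (0 < self.cluster_gap_bp < 10_000):
            raise ValueError("cluster_gap_bp must be in (0, 10000)")
        if self.site_match_len > self.mature_len - 1:
            raise ValueError("site_match_len exceeds mature positions 2..end")


@dataclasses.dataclass
class GroundTruth:
    """Planted structure, merged across generator stages."""

    biased_mirna_ids: set[str] = dataclasses.field(default_factory=set)
    planted_clusters: list[list[str]] = dataclasses.field(default_factory=list)
    planted_sites: list[tuple[str, str, int]] = dataclasses.field(default_factory=list)
    de_gene_ids: dict[str, str] = dataclasses.field(default_factory=dict)
    accepted_candidate_ids: set[str] = dataclasses.field(default_factory=set)
    known_names: dict[str, str] = dataclasses.field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "biased_mirna_ids": sorted(self.biased_mirna_ids),
            "planted_clusters": self.planted_clusters,
            "planted_sites": [list(s) for s in self.planted_sites],
            "de_gene_ids": self.de_gene_ids,
            "accepted_candidate_ids": sorted(self.accepted_candidate_ids),
            "known_names": self.known_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            biased_mirna_ids=set(d["biased_mirna_ids"]),
            planted_clusters=[list(c) for c in d["planted_clusters"]],
            planted_sites=[tuple(s) for s in d["planted_sites"]],
            de_gene_ids=dict(d["de_gene_ids"]),
            accepted_candidate_ids=set(d["accepted_candidate_ids"]),
            known_names=dict(d["known_names"]),
        )


# ---------------------------------------------------------------------------
# Genome and loci
# ---------------------------------------------------------------------------

def generate_genome_and_loci(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[MirnaLocus], GroundTruth]:
    """Random-composition chromosomes with precursors embedded verbatim.

    Planted clusters have every adjacent gap < ``cluster_gap_bp``; isolated
    loci are >= 10 kb away from any other locus. Each precursor occurs exactly
    once in the genome (checked on both strands; offending precursors are
    resampled).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    gt = GroundTruth()

    n = config.n_mirnas
    matures = _unique_seqs(rng, config.mature_len, _n_matures(config))
    mature_iter = iter(matures)

    # units: clusters first, then isolated loci
    units: list[list[dict]] = []
    idx = 0
    for c in range(config.n_clusters):
        single_family = c < config.n_single_family_clusters
        shared = next(mature_iter) if single_family else None
        members = []
        for _ in range(config.cluster_size):
            members.append(_make_precursor(config, rng, shared or next(mature_iter), idx))
            idx += 1
        units.append(members)
    while idx < n:
        units.append([_make_precursor(config, rng, next(mature_iter), idx)])
        idx += 1

    placements = _place_units(units, config, rng)

    # build chromosomes then splice precursors in
    genome = {
        chrom: random_dna(rng, length)
        for chrom, length in config.chromosome_lengths.items()
    }
    loci: list[MirnaLocus] = []
    known_idx: set[int] = set()
    if n and config.n_known:
        known_idx = set(
            np.linspace(0, n - 1, min(config.n_known, n)).round().astype(int)
        )
    for chrom, start, unit_members, is_cluster in placements:
        cluster_ids = []
        for member in unit_members:
            seq = member["precursor"]
            strand = "+" if rng.random() < 0.5 else "-"
            embedded = seq if strand == "+" else revcomp_dna(seq)
            g = genome[chrom]
            genome[chrom] = g[: member["pos"]] + embedded + g[member["pos"] + len(seq):]
            novel = member["index"] not in known_idx
            loci.append(
                MirnaLocus(
                    locus_id=member["locus_id"],
                    chromosome=chrom,
                    start=member["pos"],
                    end=member["pos"] + len(seq),
                    strand=strand,
                    precursor_id=member["precursor_id"],
                    precursor_seq=seq,
                    mature_seq=member["mature"],
                    star_seq=member["star"],
                    novel=novel,
                )
            )
            cluster_ids.append(member["locus_id"])
        if is_cluster:
            gt.planted_clusters.append(cluster_ids)

    _enforce_unique_precursors(genome, loci, config, rng)
    for loc in loci:
        if not loc.novel:
            gt.known_names[loc.locus_id] = f"api-mir-{int(loc.precursor_id[3:]) + 1}"

    # biased miRNAs: isolated loci only (unique matures survive read counting)
    clustered = {lid for cl in gt.planted_clusters for lid in cl}
    isolated = [loc for loc in loci if loc.locus_id not in clustered]
    if config.n_biased > len(isolated):
        raise SizingError("n_biased exceeds the number of isolated loci")
    pick = rng.choice(len(isolated), size=config.n_biased, replace=False)
    gt.biased_mirna_ids = {isolated[i].precursor_id for i in sorted(pick)}
    return genome, loci, gt


def _n_matures(config: SyntheticConfig) -> int:
    n_sf = config.n_single_family_clusters
    return config.n_mirnas - n_sf * config.cluster_size + n_sf


def _unique_seqs(rng: np.random.Generator, length: int, count: int) -> list[str]:
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < count:
        s = random_dna(rng, length)
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


def _make_precursor(
    config: SyntheticConfig, rng: np.random.Generator, mature: str, index: int
) -> dict:
    loop = random_dna(rng, config.loop_len)
    star = random_dna(rng, config.star_len)
    return {
        "index": index,
        "locus_id": f"loc{index:03d}",
        "precursor_id": f"mir{index:03d}",
        "mature": mature,
        "loop": loop,
        "star": star,
        "precursor": mature + loop + star,
    }


def _place_units(
    units: Sequence[list[dict]], config: SyntheticConfig, rng: np.random.Generator
) -> list[tuple[str, int, list[dict], bool]]:
    """Assign units (clusters / isolated loci) to chromosomes, balancing by
    occupied fraction, and fix member coordinates."""
    chroms = list(config.chromosome_lengths)
    cursor = {c: 1_000 for c in chroms}
    placements = []
    for members in units:
        # chromosome with the lowest occupied fraction gets the next unit
        chrom = min(chroms, key=lambda c: (cursor[c] / config.chromosome_lengths[c], c))
        pos = cursor[chrom]
        for j, member in enumerate(members):
            if j > 0:
                gap = int(rng.integers(50, config.cluster_gap_bp))
                pos += gap
            member["pos"] = pos
            pos += len(member["precursor"])
        end = pos
        if end + 1_000 > config.chromosome_lengths[chrom]:
            raise SizingError(
                f"loci do not fit chromosome {chrom} at the required spacing; "
                f"reduce n_mirnas or enlarge the genome"
            )
        cursor[chrom] = end + ISOLATION_BP + int(rng.integers(0, 2_000))
        placements.append((chrom, members[0]["pos"], members, len(members) >= 2))
    return placements


def _enforce_unique_precursors(
    genome: dict[str, str],
    loci: Sequence[MirnaLocus],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> None:
    """Verify each precursor occurs exactly once genome-wide (both strands);
    chance duplicates are destroyed by re-randomizing the extra occurrence."""
    for loc in loci:
        for _ in range(10):
            hits = _occurrences(genome, loc.precursor_seq)
            if hits == 1:
                break
            # rewrite a non-planted occurrence with fresh random sequence
            _scrub_extra_occurrence(genome, loc, rng)
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not make precursor {loc.precursor_id} unique")


def _occurrences(genome: Mapping[str, str], seq: str) -> int:
    total = 0
    rc = revcomp_dna(seq)
    for chrom_seq in genome.values():
        for pattern in {seq, rc}:
            start = 0
            while True:
                pos = chrom_seq.find(pattern, start)
                if pos == -1:
                    break
                total += 1
                start = pos + 1
    return total


def _scrub_extra_occurrence(
    genome: dict[str, str], loc: MirnaLocus, rng: np.random.Generator
) -> None:
    seq = loc.precursor_seq
    rc = revcomp_dna(seq)
    for chrom, chrom_seq in genome.items():
        for pattern in {seq, rc}:
            start = 0
            while True:
                pos = chrom_seq.find(pattern, start)
                if pos == -1:
                    break
                if not (chrom == loc.chromosome and pos == loc.start):
                    replacement = random_dna(rng, len(pattern))
                    genome[chrom] = (
                        chrom_seq[:pos] + replacement + chrom_seq[pos + len(pattern):]
                    )
                    return
                start = pos + 1


# ---------------------------------------------------------------------------
# miRNA counts
# ---------------------------------------------------------------------------

def nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson when
    dispersion == 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_mirna_counts(
    loci: Sequence[MirnaLocus],
    config: SyntheticConfig,
    gt: GroundTruth,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Per-sample NB counts around planted means.

    Baselines are lognormal around an equal depth share; biased miRNAs get a
    fixed low female baseline (``biased_baseline_scale`` x the typical share)
    and a male mean ``bias_fold`` times their female mean; X-linked loci get
    ``x_expression_multiplier`` on both sexes.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    if config.n_male_samples < 1 or config.n_female_samples < 1:
        raise ValueError("need at least one male and one female sample")
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    ids = sorted({loc.precursor_id for loc in loci})
    if not ids:
        samples = _sample_names(config)
        counts = pd.DataFrame(
            np.zeros((0, len(samples)), dtype=np.int64), index=[], columns=samples
        )
        return ExpressionMatrix(counts=counts, sex=_sex_series(config))
    chrom_of = {loc.precursor_id: loc.chromosome for loc in loci}
    mu0 = config.depth / len(ids)
    base = np.array(
        [
            config.biased_baseline_scale * mu0
            if mid in gt.biased_mirna_ids
            else float(rng.lognormal(mean=np.log(mu0), sigma=0.5))
            for mid in ids
        ]
    )
    xmask = np.array([chrom_of[mid] == "X" for mid in ids])
    base = np.where(xmask, base * config.x_expression_multiplier, base)
    biased = np.array([mid in gt.biased_mirna_ids for mid in ids])

    samples = _sample_names(config)
    cols = {}
    for s in samples:
        mean = base.copy()
        if s.startswith("M"):
            mean = np.where(biased, mean * config.bias_fold, mean)
        cols[s] = nb_draw(rng, mean, config.nb_dispersion).astype(np.int64)
    counts = pd.DataFrame(cols, index=ids)
    return ExpressionMatrix(counts=counts, sex=_sex_series(config))


def _sample_names(config: SyntheticConfig) -> list[str]:
    return [f"F{i + 1:02d}" for i in range(config.n_female_samples)] + [
        f"M{i + 1:02d}" for i in range(config.n_male_samples)
    ]


def _sex_series(config: SyntheticConfig) -> pd.Series:
    labels = {f"F{i + 1:02d}": FEMALE for i in range(config.n_female_samples)}
    labels.update({f"M{i + 1:02d}": MALE for i in range(config.n_male_samples)})
    return pd.Series(labels, dtype=object)


# ---------------------------------------------------------------------------
# Small reads
# ---------------------------------------------------------------------------

def simulate_small_reads(
    loci: Sequence[MirnaLocus],
    matrix: ExpressionMatrix,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Emit (id, sequence, quality) FASTQ tuples per sample.

    Each counted read is the mature arm of its precursor (a valid 18-35 nt
    subsequence), quality Q40 throughout, so read processing followed by
    counting reproduces the count matrix exactly when ``decoy_fraction`` is 0.
    Decoys are either out-of-range lengths (17 or 36 nt with good qualities)
    or low-quality reads (in-range length, every base below the cutoff) —
    never both valid.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    mature_of = {loc.precursor_id: to_dna(loc.mature_seq) for loc in loci}
    out: dict[str, list[tuple[str, str, str]]] = {}
    for sample in matrix.counts.columns:
        reads: list[tuple[str, str, str]] = []
        for mid, count in matrix.counts[sample].items():
            seq = mature_of[mid]
            qual = "I" * len(seq)
            for r in range(int(count)):
                reads.append((f"{sample}:{mid}:{r}", seq, qual))
        n_decoys = int(round(config.decoy_fraction * len(reads)))
        for d in range(n_decoys):
            kind = d % 3
            if kind == 0:
                seq = random_dna(rng, 17)
                qual = "I" * 17
            elif kind == 1:
                seq = random_dna(rng, 36)
                qual = "I" * 36
            else:
                seq = random_dna(rng, 22)
                qual = "#" * 22  # Q2 everywhere: trimmed to nothing
            reads.append((f"{sample}:decoy:{d}", seq, qual))
        order = rng.permutation(len(reads))
        out[sample] = [reads[i] for i in order]
    return out


# ---------------------------------------------------------------------------
# UTRs with planted sites
# ---------------------------------------------------------------------------

def generate_utrs_with_sites(
    matures: Mapping[str, str],
    config: SyntheticConfig,
    gt: GroundTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Random UTRs with planted seed-complementary sites.

    For every biased miRNA, ``n_sites_per_biased`` sites are planted: the
    reverse complement of mature positions 2..(1 + site_match_len) is inserted
    verbatim at a recorded offset — targets alternate between planted
    male-down genes and background genes, so the final overlap stage has known
    truth. Non-target UTRs are rejection-sampled to contain no perfect seed
    match for any biased miRNA; planted UTRs contain exactly the planted site.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    biased = sorted(gt.biased_mirna_ids & set(matures))
    cores = {
        mid: revcomp_dna(to_dna(matures[mid])[1:8]) for mid in biased
    }

    if config.utr_length < 7:
        warnings.warn(
            "utr_length shorter than the seed; no sites planted and all genes "
            "skipped",
            RuntimeWarning,
            stacklevel=2,
        )
        return {}

    # choose target genes: alternate male-down DE genes and non-DE genes
    male_down = [g for g in gene_ids if gt.de_gene_ids.get(g) == "higher-in-female"]
    background = [g for g in gene_ids if g not in gt.de_gene_ids]
    down_iter = iter(male_down)
    bg_iter = iter(background)
    site_plan: dict[str, str] = {}  # gene -> mirna
    for mid in biased:
        for k in range(config.n_sites_per_biased):
            pool = down_iter if k % 2 == 0 else bg_iter
            gene = next(pool, None)
            if gene is None:
                break
            site_plan[gene] = mid

    utrs: dict[str, str] = {}
    for gid in gene_ids:
        planted_mid = site_plan.get(gid)
        utrs[gid] = _make_utr(config, rng, cores, matures, planted_mid, gt, gid)
    return utrs


def _make_utr(
    config: SyntheticConfig,
    rng: np.random.Generator,
    cores: Mapping[str, str],
    matures: Mapping[str, str],
    planted_mid: str | None,
    gt: GroundTruth,
    gene_id: str,
) -> str:
    L = config.utr_length
    for _ in range(200):
        utr = random_dna(rng, L)
        if any(core in utr for core in cores.values()):
            continue
        if planted_mid is None:
            return utr
        mature = to_dna(matures[planted_mid])
        ins = revcomp_dna(mature[1 : 1 + config.site_match_len])
        if L < len(ins) + 2:
            warnings.warn(
                f"UTR of gene {gene_id} too short for a planted site; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            return utr
        offset = int(rng.integers(1, L - len(ins)))
        cand = utr[:offset] + ins + utr[offset + len(ins):]
        # the site must not extend 5'-ward (would shift the maximal offset)
        nxt = mature[1 + config.site_match_len : 2 + config.site_match_len]
        if nxt and cand[offset - 1] == nxt.translate(_DNA_COMP):
            continue
        # exactly one seed match for the planted miRNA, none for the others
        if cand.count(cores[planted_mid]) != 1:
            continue
        if any(m != planted_mid and c in cand for m, c in cores.items()):
            continue
        gt.planted_sites.append((planted_mid, gene_id, offset))
        return cand
    raise RuntimeError(f"could not build UTR for {gene_id} (rejection limit)")


# ---------------------------------------------------------------------------
# mRNA counts
# ---------------------------------------------------------------------------

def simulate_mrna_counts(
    config: SyntheticConfig,
    gt: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB gene counts, three male vs three female replicates by default.

    The first half of the planted DE genes is down-regulated in males
    (male mean = base / de_fold), the second half up-regulated; everything
    else is null. Fills ``gt.de_gene_ids`` with direction labels.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    n_down = config.n_de_genes // 2 + config.n_de_genes % 2
    de_dirs: dict[str, str] = {}
    for i, gid in enumerate(gene_ids[: config.n_de_genes]):
        de_dirs[gid] = "higher-in-female" if i < n_down else "higher-in-male"
    gt.de_gene_ids.update(de_dirs)

    base = 50.0 + rng.lognormal(mean=np.log(250.0), sigma=0.7, size=config.n_genes)
    reps = config.n_mrna_replicates
    samples = [f"RF{i + 1}" for i in range(reps)] + [f"RM{i + 1}" for i in range(reps)]
    labels = pd.Series(
        {s: (FEMALE if s.startswith("RF") else MALE) for s in samples}, dtype=object
    )
    cols = {}
    for s in samples:
        mean = base.copy()
        if s.startswith("RM"):
            for i, gid in enumerate(gene_ids):
                d = de_dirs.get(gid)
                if d == "higher-in-female":
                    mean[i] = base[i] / config.de_fold
                elif d == "higher-in-male":
                    mean[i] = base[i] * config.de_fold
        cols[s] = nb_draw(rng, mean, config.mrna_dispersion).astype(np.int64)
    counts = pd.DataFrame(cols, index=gene_ids)
    return counts, labels


# ---------------------------------------------------------------------------
# Candidate records
# ---------------------------------------------------------------------------

def generate_candidate_records(
    loci: Sequence[MirnaLocus],
    config: SyntheticConfig,
    gt: GroundTruth,
    rng: np.random.Generator | None = None,
) -> list[CandidateRecord]:
    """Predictor-style candidate rows: one passing record per planted locus
    plus decoys that fail the score, structure and evidence rules in turn.
    One passing record is star-dominant (star reads > mature reads, both above
    the cutoff) to exercise the informational flag."""
    rng = rng or np.random.default_rng(config.seed + 5)
    records: list[CandidateRecord] = []
    for i, loc in enumerate(sorted(loci, key=lambda l: l.locus_id)):
        mature_reads = 30 + int(rng.poisson(200))
        star_reads = int(rng.poisson(20))
        if i == 0:
            star_reads = mature_reads + 30  # star-dominant but both arms >= 30
        loop = loc.precursor_seq[len(loc.mature_seq): len(loc.mature_seq) + config.loop_len]
        records.append(
            CandidateRecord(
                candidate_id=loc.precursor_id,
                score=float(np.round(rng.uniform(1.5, 9.5), 1)),
                precursor_seq=loc.precursor_seq,
                mature_seq=loc.mature_seq,
                star_seq=loc.star_seq,
                loop_seq=loop,
                mature_reads=mature_reads,
                star_reads=star_reads,
                loop_reads=int(rng.poisson(2)),
                homolog_hit=not loc.novel,
                chromosome=loc.chromosome,
                start=loc.start,
                end=loc.end,
                strand=loc.strand,
            )
        )
        gt.accepted_candidate_ids.add(loc.precursor_id)
    for d in range(config.n_candidate_decoys):
        mature = random_dna(rng, config.mature_len)
        loop = random_dna(rng, config.loop_len)
        star = random_dna(rng, config.star_len)
        kind = d % 3
        records.append(
            CandidateRecord(
                candidate_id=f"decoy{d:02d}",
                score=0.5 if kind == 0 else float(np.round(rng.uniform(1.5, 9.5), 1)),
                precursor_seq=mature + loop + star,
                mature_seq=mature,
                star_seq="" if kind == 1 else star,
                loop_seq="" if kind == 1 else loop,
                mature_reads=5 if kind == 2 else 30 + int(rng.poisson(100)),
                star_reads=int(rng.poisson(10)),
                loop_reads=0,
                homolog_hit=False,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: dict[str, str]
    loci: list[MirnaLocus]
    candidates: list[CandidateRecord]
    matrix: ExpressionMatrix
    reads: dict[str, list[tuple[str, str, str]]] | None
    utrs: dict[str, str]
    gene_counts: pd.DataFrame
    gene_labels: pd.Series
    ground_truth: GroundTruth


def generate_all(config: SyntheticConfig, with_reads: bool = True) -> SyntheticBundle:
    """Generate every input the pipeline consumes, with one ground truth."""
    config.validate()
    genome, loci, gt = generate_genome_and_loci(
        config, np.random.default_rng(config.seed)
    )
    gene_counts, gene_labels = simulate_mrna_counts(
        config, gt, np.random.default_rng(config.seed + 4)
    )
    matures = {loc.precursor_id: loc.mature_seq for loc in loci}
    utrs = generate_utrs_with_sites(
        matures, config, gt, np.random.default_rng(config.seed + 3)
    )
    matrix = simulate_mirna_counts(
        loci, config, gt, np.random.default_rng(config.seed + 1)
    )
    reads = None
    if with_reads:
        reads = simulate_small_reads(
            loci, matrix, config, np.random.default_rng(config.seed + 2)
        )
    candidates = generate_candidate_records(
        loci, config, gt, np.random.default_rng(config.seed + 5)
    )
    return SyntheticBundle(
        config=config,
        genome=genome,
        loci=loci,
        candidates=candidates,
        matrix=matrix,
        reads=reads,
        utrs=utrs,
        gene_counts=gene_counts,
        gene_labels=gene_labels,
        ground_truth=gt,
    )


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_fastq(
    reads: Mapping[str, Sequence[tuple[str, str, str]]], outdir: str | Path
) -> dict[str, Path]:
    """One Sanger Phred+33 FASTQ per sample; returns sample -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample, recs in reads.items():
        p = outdir / f"{sample}.fastq"
        with open(p, "w") as fh:
            for rid, seq, qual in recs:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        paths[sample] = p
    return paths


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the full input bundle the pipeline needs, plus the ground-truth
    manifest."""
    from . import candidate_filtering as cf
    from . import expression_bias as eb
    from . import locus_annotation as la

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, outdir / "genome.fa")
    write_fasta(bundle.utrs, outdir / "utrs.fa")
    cf.write_candidates(bundle.candidates, outdir / "candidates.tsv")
    la.write_gff3(bundle.loci, outdir / "planted_loci.gff3")
    eb.write_counts(bundle.matrix, outdir / "mirna_counts.tsv")
    eb.write_sample_sheet(dict(bundle.matrix.sex), outdir / "mirna_samples.tsv")
    bundle.gene_counts.to_csv(outdir / "gene_counts.tsv", sep="\t", index_label="gene_id")
    eb.write_sample_sheet(dict(bundle.gene_labels), outdir / "gene_samples.tsv")
    if bundle.reads is not None:
        write_fastq(bundle.reads, outdir / "reads")
    bundle.ground_truth.to_json(outdir / "ground_truth.json")
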