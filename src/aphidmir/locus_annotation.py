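"""Placement of miRNA precursors on a genome assembly and locus-level annotation.

This module covers the genomic half of the analysis: exact localization of
precursor hairpins on chromosomes, grouping of loci into families (identical
mature sequence), naming of novel miRNAs, detection of genomic clusters
(neighboring loci separated by less than 10 kb), cluster classification into
single-family vs multifamily, and construction of the per-chromosome
distribution summary table.

Localization is exact full-length string matching on both strands: only hits
with 100% query coverage and zero mismatches are biologically meaningful for
this analysis, so a BLAST-style aligner is unnecessary. Ambiguous bases (N)
never match.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd

from ._seq import revcomp_dna, to_dna

#: chromosomes of the chromosome-level pea aphid assembly; everything else is
#: treated as an unplaced scaffold in summaries.
PLACED_CHROMOSOMES = ("A1", "A2", "A3", "X")

#: maximal separation (exclusive) between neighboring loci of one cluster.
DEFAULT_CLUSTER_GAP_BP = 10_000


@dataclasses.dataclass
class MirnaLocus:
    """One placement of a miRNA precursor on the genome.

    Coordinates are 0-based half-open on the forward strand of ``chromosome``
    regardless of ``strand``.
    """

    locus_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    precursor_id: str
    precursor_seq: str = ""
    mature_seq: str = ""
    star_seq: str = ""
    family_id: int | None = None
    novel: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"locus {self.locus_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"locus {self.locus_id}: strand must be '+' or '-'")


@dataclasses.dataclass
class Cluster:
    """A maximal chain of >=2 loci on one chromosome with all adjacent gaps
    below the clustering threshold."""

    cluster_id: str
    chromosome: str
    locus_ids: list[str]
    span_bp: int
    kind: str = ""  # "single-family" | "multifamily"


def localize_precursors(
    precursors: Mapping[str, str],
    genome: Mapping[str, str],
) -> list[MirnaLocus]:
    """Report every exact, full-length occurrence of each precursor.

    Both strands are scanned; one precursor may yield several loci (or none).
    U/T spelling differences are ignored.

    Parameters
    ----------
    precursors
        precursor_id -> sequence.
    genome
        chromosome name -> sequence.
    """
    loci: list[MirnaLocus] = []
    genome_dna = {chrom: to_dna(seq) for chrom, seq in genome.items()}
    for pid in sorted(precursors):
        query = to_dna(precursors[pid])
        if not query:
            continue
        rc = revcomp_dna(query)
        for chrom in sorted(genome_dna):
            subject = genome_dna[chrom]
            for strand, pattern in (("+", query), ("-", rc)):
                # self-reverse-complementary precursors would be double counted
                if strand == "-" and rc == query:
                    continue
                pos = subject.find(pattern)
                while pos != -1:
                    loci.append(
                        MirnaLocus(
                            locus_id=f"{pid}|{chrom}:{pos}:{strand}",
                            chromosome=chrom,
                            start=pos,
                            end=pos + len(pattern),
                            strand=strand,
                            precursor_id=pid,
                            precursor_seq=precursors[pid],
                        )
                    )
                    pos = subject.find(pattern, pos + 1)
    return loci


def assign_families(loci: Sequence[MirnaLocus]) -> list[MirnaLocus]:
    """Give loci with identical mature sequences the same integer family id.

    Ids are assigned by lexicographic order of the mature sequence (RNA
    spelling), starting at 1, so the numbering is deterministic for any input
    order. Returns the same locus objects, mutated.
    """
    matures = sorted({to_dna(loc.mature_seq) for loc in loci})
    fam_of = {m: i + 1 for i, m in enumerate(matures)}
    for loc in loci:
        loc.family_id = fam_of[to_dna(loc.mature_seq)]
    return list(loci)


def name_novel_mirnas(
    loci: Sequence[MirnaLocus],
    known_names: Mapping[str, str] | None = None,
    prefix: str = "api-mir-x",
) -> dict[str, str]:
    """Name novel miRNA loci following the x-number convention.

    Novel families are numbered 1, 2, ... in ascending family_id order and an
    "x" marks novelty, e.g. ``api-mir-x1``. When a family has several loci
    each gets a letter suffix in (chromosome, start) order: ``api-mir-x1a``,
    ``api-mir-x1b``. Loci listed in ``known_names`` (locus_id -> name) keep
    their supplied name.

    Raises ``ValueError`` if a generated name collides with a known name.
    """
    known_names = dict(known_names or {})
    out: dict[str, str] = {}
    novel = [loc for loc in loci if loc.locus_id not in known_names]
    for loc in loci:
        if loc.locus_id in known_names:
            out[loc.locus_id] = known_names[loc.locus_id]
    if any(loc.family_id is None for loc in novel):
        raise ValueError("family ids must be assigned before naming")
    families: dict[int, list[MirnaLocus]] = {}
    for loc in novel:
        families.setdefault(loc.family_id, []).append(loc)
    taken = set(known_names.values())
    for number, fam_id in enumerate(sorted(families), start=1):
        members = sorted(families[fam_id], key=lambda l: (l.chromosome, l.start))
        stem = f"{prefix}{number}"
        for i, loc in enumerate(members):
            name = stem if len(members) == 1 else stem + _letter_suffix(i)
            if name in taken:
                raise ValueError(f"novel name {name!r} collides with a known name")
            out[loc.locus_id] = name
    return out


def _letter_suffix(i: int) -> str:
    # a..z, then aa, ab, ... for implausibly large families
    s = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        s = chr(ord("a") + r) + s
    return s


def detect_clusters(
    loci: Sequence[MirnaLocus],
    max_gap_bp: int = DEFAULT_CLUSTER_GAP_BP,
) -> list[Cluster]:
    """Chain neighboring loci into clusters.

    Per chromosome, loci are sorted by start; an adjacent pair is chained when
    ``next.start - prev.end < max_gap_bp`` where ``prev.end`` is the rightmost
    end seen so far in the chain (so nested/overlapping loci chain too).
    Maximal chains of two or more loci are clusters; singletons are not.
    Strand is ignored.
    """
    by_chrom: dict[str, list[MirnaLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc)

    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.locus_id))
        chain: list[MirnaLocus] = []
        chain_end = None
        for loc in ordered + [None]:  # sentinel flushes the last chain
            if loc is not None and chain and loc.start - chain_end < max_gap_bp:
                chain.append(loc)
                chain_end = max(chain_end, loc.end)
                continue
            if len(chain) >= 2:
                clusters.append(
                    Cluster(
                        cluster_id=f"cl{len(clusters) + 1:03d}",
                        chromosome=chrom,
                        locus_ids=[m.locus_id for m in chain],
                        span_bp=max(m.end for m in chain) - chain[0].start,
                    )
                )
            if loc is not None:
                chain = [loc]
                chain_end = loc.end
    return clusters


def classify_clusters(
    clusters: Sequence[Cluster], loci: Sequence[MirnaLocus]
) -> list[Cluster]:
    """Label each cluster single-family (all members are paralogs, i.e. share
    one family id) or multifamily."""
    fam = {loc.locus_id: loc.family_id for loc in loci}
    for cl in clusters:
        fams = {fam[lid] for lid in cl.locus_ids}
        if None in fams:
            raise ValueError(f"cluster {cl.cluster_id}: family ids not assigned")
        cl.kind = "single-family" if len(fams) == 1 else "multifamily"
    return list(clusters)


# ---------------------------------------------------------------------------
# Distribution summary (Table-1 style)
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "chromosome",
    "size_bp",
    "genome_proportion",
    "n_novel",
    "n_known",
    "n_total",
    "n_biased",
]


def summarize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Complete a per-chromosome locus-count table with derived columns.

    ``table`` needs columns chromosome, size_bp, n_novel, n_known, n_biased
    (one row per chromosome / scaffold group). Adds ``n_total`` and
    ``genome_proportion`` and appends a Total row; this is the arithmetic
    behind the published distribution summary and is reused when the counts
    come from an external table rather than from annotated loci.
    """
    df = table.copy().reset_index(drop=True)
    df["n_total"] = df["n_novel"] + df["n_known"]
    total_size = int(df["size_bp"].sum())
    df["genome_proportion"] = df["size_bp"] / total_size if total_size else 0.0
    total = {
        "chromosome": "Total",
        "size_bp": total_size,
        "genome_proportion": float(df["genome_proportion"].sum()),
        "n_novel": int(df["n_novel"].sum()),
        "n_known": int(df["n_known"].sum()),
        "n_total": int(df["n_total"].sum()),
        "n_biased": int(df["n_biased"].sum()),
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df[SUMMARY_COLUMNS]


def chromosome_summary(
    loci: Sequence[MirnaLocus],
    biased_ids: Iterable[str],
    chromosome_sizes: Mapping[str, int],
    placed_chromosomes: Sequence[str] = PLACED_CHROMOSOMES,
) -> pd.DataFrame:
    """Build the distribution summary from annotated loci.

    ``biased_ids`` may contain locus ids or precursor ids. Chromosomes not in
    ``placed_chromosomes`` are pooled into one "Unplaced scaffolds" row.
    """
    biased = set(biased_ids)
    rows = []
    groups = [(c, [c]) for c in placed_chromosomes]
    unplaced = [c for c in chromosome_sizes if c not in placed_chromosomes]
    if unplaced:
        groups.append(("Unplaced scaffolds", unplaced))
    for label, members in groups:
        sub = [loc for loc in loci if loc.chromosome in members]
        rows.append(
            {
                "chromosome": label,
                "size_bp": int(sum(chromosome_sizes.get(c, 0) for c in members)),
                "n_novel": sum(loc.novel for loc in sub),
                "n_known": sum(not loc.novel for loc in sub),
                "n_biased": sum(
                    loc.locus_id in biased or loc.precursor_id in biased for loc in sub
                ),
            }
        )
    return summarize_counts(pd.DataFrame(rows))


def placed_locus_count(summary: pd.DataFrame) -> int:
    """Loci on named chromosomes = grand total minus the unplaced row."""
    total = int(summary.loc[summary["chromosome"] == "Total", "n_total"].iloc[0])
    unpl = summary.loc[summary["chromosome"] == "Unplaced scaffolds", "n_total"]
    return total - (int(unpl.iloc[0]) if len(unpl) else 0)


def clustered_percentage(clusters: Sequence[Cluster], n_loci: int) -> float:
    """Percentage of loci lying in clusters (e.g. 184/342 -> 53.8)."""
    if n_loci == 0:
        return 0.0
    in_clusters = sum(len(cl.locus_ids) for cl in clusters)
    return 100.0 * in_clusters / n_loci


def biased_x_rates(summary: pd.DataFrame, x_chrom: str = "X") -> tuple[float, float]:
    """Percentage of placed male-biased vs non-biased loci on the X.

    Returns ``(pct_biased_on_x, pct_nonbiased_on_x)`` computed over loci
    placed on named chromosomes only (unplaced scaffolds excluded).
    """
    placed = summary[~summary["chromosome"].isin(["Total", "Unplaced scaffolds"])]
    biased_placed = int(placed["n_biased"].sum())
    nonbiased_placed = int((placed["n_total"] - placed["n_biased"]).sum())
    xrow = placed[placed["chromosome"] == x_chrom]
    if not len(xrow):
        raise ValueError(f"no chromosome {x_chrom!r} in summary")
    x_biased = int(xrow["n_biased"].iloc[0])
    x_nonbiased = int(xrow["n_total"].iloc[0]) - x_biased
    pct_b = 100.0 * x_biased / biased_placed if biased_placed else 0.0
    pct_n = 100.0 * x_nonbiased / nonbiased_placed if nonbiased_placed else 0.0
    return pct_b, pct_n


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_gff3(loci: Sequence[MirnaLocus], path: str | Path) -> None:
    """Write loci as GFF3 ``miRNA_primary_transcript`` features (1-based,
    inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = f"ID={loc.locus_id};precursor={loc.precursor_id}"
            if loc.family_id is not None:
                attrs += f";family={loc.family_id}"
            attrs += f";novel={'true' if loc.novel else 'false'}"
            fh.write(
                "\t".join(
                    [
                        loc.chromosome,
                        "aphidmir",
                        "miRNA_primary_transcript",
                        str(loc.start + 1),
                        str(loc.end),
                        ".",
                        loc.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_clusters_bed(
    clusters: Sequence[Cluster], loci: Sequence[MirnaLocus], path: str | Path
) -> None:
    """Clusters as BED4 (0-based half-open) spanning first start to last end."""
    pos = {loc.locus_id: (loc.start, loc.end) for loc in loci}
    with open(path, "w") as fh:
        for cl in clusters:
            starts, ends = zip(*(pos[lid] for lid in cl.locus_ids))
            name = f"{cl.cluster_id}|{cl.kind or 'unclassified'}|n={len(cl.locus_ids)}"
            fh.write(f"{cl.chromosome}\t{min(starts)}\t{max(ends)}\t{name}\n")
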