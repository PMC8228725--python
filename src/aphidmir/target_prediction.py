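"""Seed-match target prediction with duplex-energy profiles and intersection.

Candidate sites are anchored by the miRNA seed: positions 2..8 from the 5'
end must pair with the 3' UTR by perfect Watson-Crick complementarity — no
G:U wobble and no mismatch inside the seed region. Matches may extend beyond
the minimal 7-nt seed (extension runs 5'-ward along the UTR, because the
miRNA 5' end pairs with the site's 3' end); the maximal extension is reported
per anchor.

A single prediction engine is run under several *profiles* that differ only
in their duplex-energy threshold and optional empirical p-value, standing in
for the common practice of intersecting several external predictors. Duplex
energy is a nearest-neighbor-style sum of base-pair stacking terms over the
perfectly paired region; the packaged table approximates Watson-Crick RNA
stack free energies and is fully replaceable.

A (miRNA, gene) interaction survives the intersection only if that exact pair
is predicted under every profile — a gene being hit by *some* miRNA in each
profile is not enough.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp_rna, to_rna

#: Watson-Crick nearest-neighbor stack approximations, keyed by the miRNA-side
#: dinucleotide 5'->3'; kcal/mol per stack of two adjacent base pairs.
DEFAULT_STACK_TABLE: dict[str, float] = {
    "AA": -0.93, "AC": -2.24, "AG": -2.08, "AU": -1.10,
    "CA": -2.11, "CC": -3.26, "CG": -2.36, "CU": -2.08,
    "GA": -2.35, "GC": -3.42, "GG": -3.26, "GU": -2.24,
    "UA": -1.33, "UC": -2.35, "UG": -2.11, "UU": -0.93,
}


@dataclasses.dataclass
class SeedSpec:
    """Seed-pairing constraints: window starts at miRNA position 2 (1-based),
    minimal length 7, no G:U wobble, no mismatch."""

    seed_start: int = 2
    seed_min_len: int = 7
    allow_gu: bool = False
    allow_mismatch: bool = False

    def __post_init__(self) -> None:
        if self.seed_min_len < 1:
            raise ValueError("seed_min_len must be >= 1")
        if self.allow_gu or self.allow_mismatch:
            raise NotImplementedError(
                "only perfect Watson-Crick seed pairing is supported"
            )


@dataclasses.dataclass
class PredictorProfile:
    name: str
    energy_threshold: float  # kcal/mol; sites kept iff energy <= threshold
    use_permutation_pvalue: bool = False
    pvalue_cutoff: float = 0.05
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy_threshold):
            raise ValueError("energy threshold must be finite")


def default_profiles() -> list[PredictorProfile]:
    """Three profiles mirroring the thresholds commonly used with PITA-like
    (0), RNAhybrid-like (0, with p-value) and RIsearch-like (-15) predictors."""
    return [
        PredictorProfile("pita_like", 0.0),
        PredictorProfile("rnahybrid_like", 0.0, use_permutation_pvalue=True),
        PredictorProfile("risearch_like", -15.0),
    ]


@dataclasses.dataclass
class TargetSite:
    mirna_id: str
    gene_id: str
    utr_offset: int  # 0-based start of the matched UTR window
    matched_len: int
    duplex_energy: float
    profile: str = ""
    empirical_p: float | None = None


# ---------------------------------------------------------------------------
# Seed scanning
# ---------------------------------------------------------------------------

def find_seed_sites(
    mature_seq: str, utr_seq: str, spec: SeedSpec | None = None
) -> list[tuple[int, int]]:
    """All maximal seed-anchored matches of a miRNA in one UTR.

    Returns ``(offset, matched_len)`` pairs: the UTR window
    ``utr[offset : offset + matched_len]`` equals the reverse complement of
    miRNA positions ``seed_start .. seed_start + matched_len - 1`` with
    ``matched_len >= seed_min_len``. One maximal match is reported per seed
    anchor; anchors of overlapping sites may yield overlapping windows.
    """
    spec = spec or SeedSpec()
    mature = to_rna(mature_seq)
    utr = to_rna(utr_seq)
    lo = spec.seed_start - 1  # 0-based index of the first seed base
    if len(mature) < lo + spec.seed_min_len:
        raise ValueError("mature sequence shorter than the seed window")
    seed = mature[lo : lo + spec.seed_min_len]
    core = revcomp_rna(seed)
    best: dict[int, int] = {}
    pos = utr.find(core)
    while pos != -1:
        # the minimal match sits at this core occurrence; longer matches pair
        # further miRNA 3' bases with UTR bases to the left (miRNA and site
        # are antiparallel), each extension step also being a valid match at
        # the shifted offset.
        length = spec.seed_min_len
        left = pos
        k = lo + spec.seed_min_len  # next miRNA index to pair
        best[left] = max(best.get(left, 0), length)
        while left > 0 and k < len(mature) and utr[left - 1] == _wc_rna(mature[k]):
            left -= 1
            length += 1
            k += 1
            best[left] = max(best.get(left, 0), length)
        pos = utr.find(core, pos + 1)
    return sorted(best.items())


_WC = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _wc_rna(base: str) -> str:
    return _WC.get(base, "?")


# ---------------------------------------------------------------------------
# Duplex energy
# ---------------------------------------------------------------------------

def duplex_energy(
    mature_seq: str,
    utr_site_seq: str,
    stack_table: Mapping[str, float] | None = None,
    seed_start: int = 2,
) -> float:
    """Stacking energy of a perfectly paired seed-anchored duplex (kcal/mol).

    ``utr_site_seq`` must be the exact reverse complement of the miRNA window
    starting at ``seed_start``; the energy is the sum over the
    ``len(site) - 1`` adjacent base-pair stacks, looked up by the miRNA-side
    dinucleotide. A single pair has no stack and contributes 0.
    """
    table = dict(stack_table) if stack_table is not None else DEFAULT_STACK_TABLE
    mature = to_rna(mature_seq)
    site = to_rna(utr_site_seq)
    lo = seed_start - 1
    window = mature[lo : lo + len(site)]
    if revcomp_rna(window) != site:
        raise ValueError("site is not the reverse complement of the seed window")
    energy = 0.0
    for i in range(len(window) - 1):
        key = window[i : i + 2]
        if key not in table:
            raise KeyError(f"stack table lacks entry for {key!r}")
        energy += table[key]
    return energy


# ---------------------------------------------------------------------------
# Prediction under a profile
# ---------------------------------------------------------------------------

def predict_targets(
    matures: Mapping[str, str],
    utrs: Mapping[str, str],
    profile: PredictorProfile,
    spec: SeedSpec | None = None,
    stack_table: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> list[TargetSite]:
    """Predict all target sites of each miRNA in each UTR under a profile.

    Sites are seed matches whose duplex energy is <= the profile threshold.
    When the profile requests it, an empirical p-value is attached: the
    fraction of dinucleotide-shuffled versions of the UTR whose *best* site
    energy is at least as low as the observed site's; sites with
    p >= pvalue_cutoff are dropped.
    """
    spec = spec or SeedSpec()
    if profile.use_permutation_pvalue and rng is None:
        rng = np.random.default_rng(0)
    out: list[TargetSite] = []
    shuffle_cache: dict[str, list[str]] = {}
    for mid in sorted(matures):
        mature = matures[mid]
        for gid in sorted(utrs):
            utr = utrs[gid]
            if len(to_rna(utr)) < spec.seed_min_len:
                warnings.warn(
                    f"UTR {gid} shorter than the seed; skipped", RuntimeWarning,
                    stacklevel=2,
                )
                continue
            for offset, length in find_seed_sites(mature, utr, spec):
                site_seq = to_rna(utr)[offset : offset + length]
                energy = duplex_energy(mature, site_seq, stack_table, spec.seed_start)
                if energy > profile.energy_threshold:
                    continue
                emp_p = None
                if profile.use_permutation_pvalue:
                    if gid not in shuffle_cache:
                        shuffle_cache[gid] = [
                            dinucleotide_shuffle(utr, rng)
                            for _ in range(profile.n_permutations)
                        ]
                    emp_p = _empirical_site_p(
                        mature, shuffle_cache[gid], energy, spec, stack_table
                    )
                    if emp_p >= profile.pvalue_cutoff:
                        continue
                out.append(
                    TargetSite(
                        mirna_id=mid,
                        gene_id=gid,
                        utr_offset=offset,
                        matched_len=length,
                        duplex_energy=energy,
                        profile=profile.name,
                        empirical_p=emp_p,
                    )
                )
    return out


def _empirical_site_p(
    mature: str,
    shuffled_utrs: Sequence[str],
    observed_energy: float,
    spec: SeedSpec,
    stack_table: Mapping[str, float] | None,
) -> float:
    hits = 0
    for shuf in shuffled_utrs:
        best = np.inf
        for offset, length in find_seed_sites(mature, shuf, spec):
            site = to_rna(shuf)[offset : offset + length]
            best = min(best, duplex_energy(mature, site, stack_table, spec.seed_start))
        if best <= observed_energy:
            hits += 1
    # add-one correction keeps the estimate away from an impossible zero
    return (hits + 1) / (len(shuffled_utrs) + 1)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition (random
    Eulerian-walk construction on the dinucleotide multigraph)."""
    s = to_rna(seq)
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    # retry greedy Eulerian walks with freshly permuted adjacency lists until
    # one consumes every edge; dead ends are rare on 4-letter alphabets
    for _ in range(50):
        stacks = {a: list(rng.permutation(bs)) for a, bs in edges.items()}
        walk = [s[0]]
        ok = True
        for _ in range(len(s) - 1):
            nxt = stacks.get(walk[-1])
            if not nxt:
                ok = False
                break
            walk.append(nxt.pop())
        if ok:
            return "".join(walk)
    return s  # degenerate composition; return unshuffled


# ---------------------------------------------------------------------------
# Intersection across profiles
# ---------------------------------------------------------------------------

def intersect_predictions(
    site_lists: Sequence[Sequence[TargetSite]],
) -> list[tuple[str, str]]:
    """(miRNA, gene) pairs predicted by every profile.

    Pair-level: the same interaction must exist in each list; site coordinates
    need not agree. Output is deduplicated and sorted. Commutative and
    associative in the profile lists.
    """
    if len(site_lists) < 2:
        raise ValueError("need site lists from at least two profiles")
    sets = [
        {(s.mirna_id, s.gene_id) for s in sites} for sites in site_lists
    ]
    common = set.intersection(*sets)
    return sorted(common)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

SITE_COLUMNS = [
    "mirna_id", "gene_id", "utr_offset", "matched_len",
    "duplex_energy", "profile", "empirical_p",
]


def write_sites(sites: Sequence[TargetSite], path: str | Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(s) for s in sites], columns=SITE_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def write_pairs(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["mirna_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
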