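"""Small-RNA read processing, expression quantification and sex-bias calling.

The quantification path is deliberately simple and exact: processed reads are
counted against the deduplicated precursor library by exact substring match
(a read increments the lexicographically first precursor that contains it;
mismatch-tolerant counting is available but off by default), then scaled to
counts per million (CPM) per library.

The bias rule reflects an asymmetric design with a single male library and
many female libraries: a miRNA is called male-biased at level k when its male
CPM is at least k times the *highest* CPM observed in any female library
(k = 5 stringent, k = 2 relaxed). An expression floor (default 1 CPM) guards
the ratio when no female library expresses the miRNA at all.

Chromosome-distribution statistics (chi-square goodness of fit against genome
proportions, r x c contingency tests) and the X-vs-autosome expression
comparison (Mann-Whitney rank-sum on mean log10(CPM + 1)) live here too.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from ._seq import to_dna

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 35
DEFAULT_QUAL_CUTOFF = 20
DEFAULT_EXPRESSION_FLOOR = 1.0  # CPM

MALE = "male"
FEMALE = "female"


@dataclasses.dataclass
class ExpressionMatrix:
    """miRNA x sample count matrix with per-sample sex labels.

    ``counts`` holds raw integers; ``cpm`` is filled by :func:`cpm_normalize`.
    """

    counts: pd.DataFrame  # rows = mirna ids, columns = sample ids
    sex: pd.Series  # index = sample ids, values in {male, female}
    cpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sex = self.sex.reindex(self.counts.columns)
        if self.sex.isna().any():
            missing = list(self.sex[self.sex.isna()].index)
            raise ValueError(f"samples without sex label: {missing}")
        bad = set(self.sex) - {MALE, FEMALE}
        if bad:
            raise ValueError(f"unknown sex labels: {sorted(bad)}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def male_samples(self) -> list[str]:
        return list(self.sex[self.sex == MALE].index)

    @property
    def female_samples(self) -> list[str]:
        return list(self.sex[self.sex == FEMALE].index)


@dataclasses.dataclass
class BiasCall:
    mirna_id: str
    male_cpm: float
    max_female_cpm: float
    fold_ratio: float
    biased_5x: bool
    biased_2x: bool


# ---------------------------------------------------------------------------
# Read processing
# ---------------------------------------------------------------------------

def process_small_reads(
    fastq_path: str | Path,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    qual_cutoff: int = DEFAULT_QUAL_CUTOFF,
    adapter: str | None = None,
) -> list[str]:
    """Adapter-clip, quality-trim and length-filter a small-RNA FASTQ file.

    Trimming truncates each read at the first base (5'->3') whose Phred
    quality falls below ``qual_cutoff``; reads outside ``[min_len, max_len]``
    after trimming are dropped. Returns the kept read sequences (DNA spelling,
    uppercase).
    """
    kept: list[str] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(fastq_path), "fastq")):
            seq = to_dna(str(rec.seq))
            quals = rec.letter_annotations["phred_quality"]
            if adapter:
                cut = seq.find(to_dna(adapter))
                if cut != -1:
                    seq, quals = seq[:cut], quals[:cut]
            for j, q in enumerate(quals):
                if q < qual_cutoff:
                    seq = seq[:j]
                    break
            if min_len <= len(seq) <= max_len:
                kept.append(seq)
    except ValueError as exc:  # Biopython signals malformed records this way
        line = 4 * locals().get("i", 0) + 1
        raise ValueError(f"malformed FASTQ near line {line}: {exc}") from exc
    return kept


def count_reads_to_precursors(
    reads_by_sample: Mapping[str, Sequence[str]],
    library: Mapping[str, str],
    sex_labels: Mapping[str, str],
    max_mismatches: int = 0,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Count processed reads against a deduplicated precursor library.

    Each read increments exactly one precursor: the first exact substring hit
    in sorted-id order. With ``max_mismatches > 0`` a Hamming scan over all
    alignments is used instead. Unmatched reads are tallied per sample.
    """
    if not library:
        raise ValueError("empty precursor library")
    ids = sorted(library)
    lib_dna = [(pid, to_dna(library[pid])) for pid in ids]
    counts = pd.DataFrame(
        0, index=ids, columns=list(reads_by_sample), dtype=np.int64
    )
    unmatched: dict[str, int] = {}
    assign_cache: dict[str, str | None] = {}
    for sample, reads in reads_by_sample.items():
        miss = 0
        tally: dict[str, int] = {}
        for read in reads:
            read = to_dna(read)
            hit = assign_cache.get(read, "?")
            if hit == "?":
                hit = _assign_read(read, lib_dna, max_mismatches)
                assign_cache[read] = hit
            if hit is None:
                miss += 1
            else:
                tally[hit] = tally.get(hit, 0) + 1
        for pid, n in tally.items():
            counts.loc[pid, sample] = n
        unmatched[sample] = miss
    matrix = ExpressionMatrix(
        counts=counts, sex=pd.Series(dict(sex_labels), dtype=object)
    )
    return matrix, unmatched


def _assign_read(
    read: str, lib_dna: Sequence[tuple[str, str]], max_mismatches: int
) -> str | None:
    if not read:
        return None
    for pid, seq in lib_dna:
        if max_mismatches == 0:
            if read in seq:
                return pid
        elif _hamming_hit(read, seq, max_mismatches):
            return pid
    return None


def _hamming_hit(read: str, seq: str, max_mm: int) -> bool:
    n, m = len(read), len(seq)
    for off in range(m - n + 1):
        mm = 0
        for a, b in zip(read, seq[off : off + n]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return True
    return False


def cpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to counts per million of its matched total.

    An all-zero sample yields an all-zero CPM column (with a warning) rather
    than NaNs.
    """
    totals = matrix.counts.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"samples with zero matched reads: {list(totals.index[zero])}",
            RuntimeWarning,
            stacklevel=2,
        )
        totals[zero] = 1.0  # keeps the division defined; columns stay zero
    matrix.cpm = matrix.counts.div(totals, axis=1) * 1e6
    return matrix


# ---------------------------------------------------------------------------
# Sex-bias calling
# ---------------------------------------------------------------------------

def call_sex_biased(
    matrix: ExpressionMatrix,
    fold_ks: Sequence[float] = (5.0, 2.0),
    expression_floor: float = DEFAULT_EXPRESSION_FLOOR,
) -> list[BiasCall]:
    """Call male-biased miRNAs at each fold level in ``fold_ks``.

    Biased at k iff male CPM >= k * max female CPM and male CPM clears the
    expression floor. With several male samples the maximum male CPM is used.
    The reported ratio uses max(max_female_cpm, floor) as denominator so it
    stays finite when no female library expresses the miRNA.
    """
    if matrix.cpm is None:
        raise ValueError("CPM not computed; run cpm_normalize first")
    males, females = matrix.male_samples, matrix.female_samples
    if not males:
        raise ValueError("no male sample")
    if not females:
        raise ValueError("no female samples")
    male_cpm = matrix.cpm[males].max(axis=1)
    max_female = matrix.cpm[females].max(axis=1)
    ks = sorted(fold_ks, reverse=True)
    calls = []
    for mid in matrix.cpm.index:
        m, f = float(male_cpm[mid]), float(max_female[mid])
        flags = {
            k: (m >= k * f) and (m >= expression_floor) for k in ks
        }
        calls.append(
            BiasCall(
                mirna_id=mid,
                male_cpm=m,
                max_female_cpm=f,
                fold_ratio=m / max(f, expression_floor),
                biased_5x=flags.get(5.0, False),
                biased_2x=flags.get(2.0, False),
            )
        )
    return calls


def biased_set(calls: Iterable[BiasCall], k: float = 5.0) -> set[str]:
    attr = {5.0: "biased_5x", 2.0: "biased_2x"}.get(k)
    if attr is None:
        raise ValueError("k must be 5 or 2; run call_sex_biased with custom ks")
    return {c.mirna_id for c in calls if getattr(c, attr)}


def write_bias_calls(calls: Sequence[BiasCall], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Distribution statistics
# ---------------------------------------------------------------------------

def chisq_goodness_of_fit(
    observed: Sequence[float], proportions: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit against expected proportions.

    Returns (X^2, df, p). No continuity correction. Expected counts are
    total * proportion and must all be positive.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and proportions differ in length")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {props.sum()}, not 1")
    expected = obs.sum() * props
    if (expected <= 0).any():
        raise ValueError("zero expected count; merge categories first")
    x2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    return x2, df, float(stats.chi2.sf(x2, df))


def chisq_contingency(
    table: Sequence[Sequence[float]] | np.ndarray, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence for an r x c table.

    Expected cells are row_total * col_total / grand_total. Yates continuity
    correction is off by default.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise ValueError("degenerate table: a row or column sums to zero")
    expected = np.outer(rows, cols) / t.sum()
    diff = np.abs(t - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    x2 = float((diff**2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return x2, df, float(stats.chi2.sf(x2, df))


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test; returns (U for x, p).

    Exact enumeration for small untied samples (both n <= 20), normal
    approximation with tie correction otherwise; two identical groups give
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def compare_x_autosome(
    matrix: ExpressionMatrix,
    chromosome_of: Mapping[str, str],
    x_chrom: str = "X",
    placed: Sequence[str] = ("A1", "A2", "A3", "X"),
) -> dict:
    """Compare per-miRNA expression between X-linked and autosomal loci.

    Each miRNA is summarized as the mean of log10(CPM + 1) across samples;
    groups are compared with a two-sided rank-sum test. miRNAs mapping to
    unplaced scaffolds (or absent from ``chromosome_of``) are excluded.
    """
    if matrix.cpm is None:
        raise ValueError("CPM not computed; run cpm_normalize first")
    summary = np.log10(matrix.cpm + 1.0).mean(axis=1)
    x_vals, auto_vals = [], []
    for mid, val in summary.items():
        chrom = chromosome_of.get(mid)
        if chrom not in placed:
            continue
        (x_vals if chrom == x_chrom else auto_vals).append(float(val))
    if not x_vals or not auto_vals:
        raise ValueError("both X and autosome groups must be non-empty")
    u, p = rank_sum_test(x_vals, auto_vals)
    return {
        "statistic": u,
        "p_value": p,
        "n_x": len(x_vals),
        "n_autosome": len(auto_vals),
        "x_mean": float(np.mean(x_vals)),
        "autosome_mean": float(np.mean(auto_vals)),
        "x_median": float(np.median(x_vals)),
        "autosome_median": float(np.median(auto_vals)),
    }


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_counts(matrix: ExpressionMatrix, path: str | Path, cpm: bool = False) -> None:
    df = matrix.cpm if cpm else matrix.counts
    if df is None:
        raise ValueError("CPM not computed")
    df.to_csv(path, sep="\t", index_label="mirna_id")


def read_counts(
    counts_path: str | Path, sample_sheet_path: str | Path
) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="mirna_id")
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    sex = pd.Series(sheet.sex.values, index=sheet.sample_id.astype(str))
    return ExpressionMatrix(counts=counts.astype(np.int64), sex=sex)


def write_sample_sheet(sex_labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(sex_labels), "sex": list(sex_labels.values())}
    ).to_csv(path, sep="\t", index=False)
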