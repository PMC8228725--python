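"""Simplified differential-expression stage and the target/DE overlap.

The DE stage is a minimal negative-binomial Wald pipeline: median-of-ratios
size factors, per-gene method-of-moments dispersion (variance model
mu + alpha * mu^2, alpha floored at 1e-8), a Wald test on the log2 fold
change of normalized group means, and Benjamini-Hochberg adjustment over all
tested genes. It is documented as simplified, not equivalent to a full
shrinkage-based DE package; a precomputed DE table can be supplied instead to
reproduce that stage boundary exactly.

The Wald statistic is referred to a t distribution with n1 + n2 - 2 degrees
of freedom rather than a standard normal: with three replicates per group the
plug-in variance makes the normal reference anticonservative, while the t
reference keeps the null p-value distribution close to uniform (see the
methods note).

The final overlap restricts predicted (miRNA, gene) interactions to
male-biased miRNAs and intersects the targeted genes with genes expressed at
lower levels in males, reporting Venn-style counts.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
DEFAULT_FC_MIN = 4.0
DISPERSION_FLOOR = 1e-8
_PSEUDO = 0.5  # added to normalized group means before taking log2 ratios

HIGHER_IN_MALE = "higher-in-male"
HIGHER_IN_FEMALE = "higher-in-female"


@dataclasses.dataclass
class DERecord:
    gene_id: str
    base_mean: float
    log2fc: float  # male vs female
    p: float
    padj: float = float("nan")
    significant: bool = False
    direction: str = ""


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors as the median ratio to the geometric-mean
    reference, over genes with all-positive counts. Falls back to library-size
    ratios when no gene is positive everywhere."""
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive):
        log_ref = np.log(positive).mean(axis=1)
        ratios = np.log(positive).sub(log_ref, axis=0)
        sf = np.exp(ratios.median(axis=0))
    else:
        totals = counts.sum(axis=0).astype(float)
        sf = totals / np.exp(np.log(totals).mean())
    return sf


def differential_expression(
    counts: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    male_label: str = "male",
    female_label: str = "female",
) -> list[DERecord]:
    """NB Wald test of male-vs-female expression for every expressed gene.

    ``counts`` is genes x samples with integer entries; ``labels`` maps sample
    id to group. Genes with zero counts in all samples are excluded from
    testing (and from the BH adjustment).
    """
    labels = pd.Series(dict(labels)).reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    males = list(labels[labels == male_label].index)
    females = list(labels[labels == female_label].index)
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need at least two samples per group")
    vals = counts[females + males]
    if not np.array_equal(vals.values, np.round(vals.values)):
        raise ValueError("counts must be integers")

    sf = size_factors_median_of_ratios(counts)
    norm = counts.div(sf, axis=1)
    expressed = norm.index[(counts.sum(axis=1) > 0)]

    nf, nm = len(females), len(males)
    df_t = nf + nm - 2
    records: list[DERecord] = []
    for gid in expressed:
        f = norm.loc[gid, females].to_numpy(dtype=float)
        m = norm.loc[gid, males].to_numpy(dtype=float)
        mf, mm = f.mean(), m.mean()
        vf, vm = f.var(ddof=1), m.var(ddof=1)
        # pooled method-of-moments dispersion for var = mu + alpha mu^2
        num = (nf - 1) * (vf - mf) + (nm - 1) * (vm - mm)
        den = (nf - 1) * mf**2 + (nm - 1) * mm**2
        alpha = max(num / den if den > 0 else 0.0, DISPERSION_FLOOR)
        log2fc = float(np.log2((mm + _PSEUDO) / (mf + _PSEUDO)))
        var_mean_f = (mf + alpha * mf**2) / nf
        var_mean_m = (mm + alpha * mm**2) / nm
        se2 = (
            var_mean_f / (mf + _PSEUDO) ** 2 + var_mean_m / (mm + _PSEUDO) ** 2
        ) / np.log(2.0) ** 2
        if se2 <= 0:
            p = 1.0
        else:
            t = log2fc / np.sqrt(se2)
            p = float(2.0 * stats.t.sf(abs(t), df_t))
        records.append(
            DERecord(
                gene_id=str(gid),
                base_mean=float(norm.loc[gid].mean()),
                log2fc=log2fc,
                p=min(p, 1.0),
                direction=HIGHER_IN_MALE if log2fc > 0 else HIGHER_IN_FEMALE,
            )
        )
    if records:
        padj = multipletests([r.p for r in records], method="fdr_bh")[1]
        for rec, q in zip(records, padj):
            rec.padj = float(q)
    return records


def filter_significant(
    records: Sequence[DERecord],
    alpha: float = DEFAULT_ALPHA,
    fc_min: float = DEFAULT_FC_MIN,
) -> tuple[list[DERecord], list[DERecord]]:
    """Keep records with padj < alpha and linear fold change strictly > fc_min;
    returns (higher_in_male, higher_in_female)."""
    up_male, up_female = [], []
    for rec in records:
        fold = 2.0 ** abs(rec.log2fc)
        if not rec.direction:
            rec.direction = HIGHER_IN_MALE if rec.log2fc > 0 else HIGHER_IN_FEMALE
        rec.significant = bool(rec.padj < alpha and fold > fc_min)
        if rec.significant:
            (up_male if rec.direction == HIGHER_IN_MALE else up_female).append(rec)
    return up_male, up_female


def overlap_targets_with_de(
    target_pairs: Iterable[tuple[str, str]],
    biased_mirna_ids: Iterable[str],
    male_down_records: Sequence[DERecord],
) -> dict:
    """Overlap genes down-regulated in males with predicted targets of
    male-biased miRNAs.

    ``male_down_records`` are the significant records with higher expression
    in females. Returns the overlap gene list, the targeting miRNAs per
    overlap gene, and Venn counts (targets only, DE-down only, both).
    """
    biased = set(biased_mirna_ids)
    pairs = [(m, g) for m, g in target_pairs if m in biased]
    target_genes = {g for _, g in pairs}
    down_genes = {r.gene_id for r in male_down_records}
    both = sorted(target_genes & down_genes)
    mirnas_of = {
        g: sorted({m for m, g2 in pairs if g2 == g}) for g in both
    }
    return {
        "overlap_genes": both,
        "mirnas_per_gene": mirnas_of,
        "venn": {
            "targets_only": len(target_genes - down_genes),
            "de_down_only": len(down_genes - target_genes),
            "both": len(both),
        },
    }


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "p", "padj", "significant", "direction"]


def write_de_table(records: Sequence[DERecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records], columns=DE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_de_table(path: str | Path) -> list[DERecord]:
    """Load a precomputed DE table (same columns as written by this module)."""
    df = pd.read_csv(path, sep="\t")
    return [
        DERecord(
            gene_id=str(r.gene_id),
            base_mean=float(r.base_mean),
            log2fc=float(r.log2fc),
            p=float(r.p),
            padj=float(r.padj),
            significant=bool(r.significant),
            direction=str(r.direction),
        )
        for r in df.itertuples(index=False)
    ]


def read_gene_counts(
    counts_path: str | Path, sample_sheet_path: str | Path
) -> tuple[pd.DataFrame, pd.Series]:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    labels = pd.Series(sheet.sex.values, index=sheet.sample_id.astype(str))
    return counts.astype(np.int64), labels
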