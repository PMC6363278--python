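"""Linking gene expression to LAD classes and class fates.

Genes are attached to a class by the label of the single base at their
TSS (half-open convention: a TSS sitting exactly on a run's end coordinate
belongs to the following run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .partition import CLASSES, ClassPartition

STABLE_FPKM_THRESHOLD = 0.05  # |delta FPKM| below this counts as stably expressed


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int  # 0-based
    strand: str
    fpkm_control: float
    fpkm_treated: float

    def __post_init__(self) -> None:
        if self.fpkm_control < 0 or self.fpkm_treated < 0:
            raise ValueError(f"negative FPKM for {self.gene_id}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")


def tss_from_bed6(start: int, end: int, strand: str) -> int:
    """TSS of a BED6 gene interval: start for ``+``, ``end - 1`` for ``-``."""
    return start if strand != "-" else end - 1


def assign_genes(genes: list[GeneRecord], partition: ClassPartition) -> dict[str, str]:
    """Map gene id -> class label of the base at its TSS."""
    out = {}
    for g in genes:
        if g.chrom not in partition.genome.names:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        if not 0 <= g.tss < partition.genome.length(g.chrom):
            raise ValueError(f"gene {g.gene_id}: TSS {g.tss} outside {g.chrom}")
        out[g.gene_id] = partition.label_at(g.chrom, g.tss)
    return out


def stable_filter(
    genes: list[GeneRecord], threshold: float = STABLE_FPKM_THRESHOLD
) -> dict[str, bool]:
    """Flag genes whose absolute FPKM change is strictly below threshold."""
    return {g.gene_id: abs(g.fpkm_treated - g.fpkm_control) < threshold for g in genes}


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    n1: int
    n2: int


def compare_groups(
    fpkms_1, fpkms_2, paired: bool = False, equal_var: bool = False
) -> TTestResult:
    """Two-sided t-test between two FPKM samples.

    Unpaired tests use Welch's t by default (``equal_var=True`` selects
    the classical pooled test); ``paired=True`` runs the classical paired
    t-test. NaNs are dropped (pairwise for the paired test).
    """
    x = np.asarray(fpkms_1, dtype=float)
    y = np.asarray(fpkms_2, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length samples")
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if len(x) < 2:
            raise ValueError("need at least 2 pairs")
        if np.std(x - y) == 0 and np.all(x == y):
            return TTestResult(0.0, 1.0, len(x), len(y))
        res = stats.ttest_rel(x, y)
    else:
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need at least 2 observations per group")
        if np.std(x) == 0 and np.std(y) == 0:
            if np.all(x == x[0]) and np.all(y == x[0]):
                return TTestResult(0.0, 1.0, len(x), len(y))
            raise ValueError("degenerate zero-variance groups with differing values")
        res = stats.ttest_ind(x, y, equal_var=equal_var)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat):  # identical zero-spread samples
        stat, p = 0.0, 1.0
    return TTestResult(stat, p, len(x), len(y))


def fate_expression_report(
    genes: list[GeneRecord],
    ctrl: ClassPartition,
    trt: ClassPartition,
    alpha: float = 0.01,
    equal_var: bool = False,
    bh_column: bool = False,
) -> pd.DataFrame:
    """Per fate-pair expression comparison.

    Genes are grouped by (class at TSS in control, class at TSS after
    treatment); within each cell the treated FPKMs are tested against the
    control FPKMs with an unpaired t-test. Cells with fewer than 2 genes
    are reported without a test. ``bh_column=True`` appends
    Benjamini-Hochberg adjusted p-values across tested cells.
    """
    if ctrl.genome != trt.genome:
        raise ValueError("partitions must share a genome")
    ctrl_cls = assign_genes(genes, ctrl)
    trt_cls = assign_genes(genes, trt)
    cells: dict[tuple[str, str], list[GeneRecord]] = {
        (ci, cj): [] for ci in CLASSES for cj in CLASSES
    }
    for g in genes:
        cells[(ctrl_cls[g.gene_id], trt_cls[g.gene_id])].append(g)
    rows = []
    pair = 0
    for ci in CLASSES:
        for cj in CLASSES:
            pair += 1
            members = cells[(ci, cj)]
            fc = np.asarray([g.fpkm_control for g in members])
            ft = np.asarray([g.fpkm_treated for g in members])
            row = {
                "pair": pair,
                "control_class": ci,
                "treated_class": cj,
                "n_genes": len(members),
                "mean_fpkm_control": float(fc.mean()) if len(members) else np.nan,
                "mean_fpkm_treated": float(ft.mean()) if len(members) else np.nan,
                "t": np.nan,
                "pvalue": np.nan,
                "significant": False,
            }
            if len(members) >= 2:
                try:
                    res = compare_groups(ft, fc, paired=False, equal_var=equal_var)
                    row["t"] = res.statistic
                    row["pvalue"] = res.pvalue
                    row["significant"] = res.pvalue < alpha
                except ValueError:
                    pass
            rows.append(row)
    df = pd.DataFrame(rows)
    if bh_column:
        from statsmodels.stats.multitest import multipletests

        tested = df["pvalue"].notna()
        adj = np.full(len(df), np.nan)
        if tested.any():
            adj[tested.to_numpy()] = multipletests(
                df.loc[tested, "pvalue"].to_numpy(), method="fdr_bh"
            )[1]
        df["pvalue_bh"] = adj
    return df
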