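"""LAD class algebra: partitioning, Jaccard overlap, fates and sizes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome
from .intervals import GenomicIntervalSet
from .partition import CLASSES, ILAD, ClassPartition


def partition_classes(
    lads_a: GenomicIntervalSet, lads_b: GenomicIntervalSet, genome: Genome
) -> ClassPartition:
    """Label every base by joint lamin A / lamin B membership.

    In both sets -> ``A-B``; only lamin A -> ``A-only``; only lamin B ->
    ``B-only``; in neither -> ``iLAD``.
    """
    for name, lads in (("A", lads_a), ("B", lads_b)):
        for chrom, _start, end in lads:
            if chrom not in genome.names:
                raise ValueError(f"lamin {name} LADs contain unknown chromosome {chrom}")
            if end > genome.length(chrom):
                raise ValueError(f"lamin {name} LAD beyond end of {chrom}")
    ends: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        pts = np.unique(
            np.concatenate(
                [
                    [0, length],
                    lads_a.intervals(chrom).ravel(),
                    lads_b.intervals(chrom).ravel(),
                ]
            )
        )
        mids = (pts[:-1] + pts[1:]) / 2.0
        in_a = lads_a.contains(chrom, mids)
        in_b = lads_b.contains(chrom, mids)
        lab = np.full(len(mids), ILAD, dtype=np.int8)
        lab[in_a & in_b] = 0
        lab[in_a & ~in_b] = 1
        lab[~in_a & in_b] = 2
        ends[chrom] = pts[1:].astype(np.int64)
        labels[chrom] = lab
    return ClassPartition(genome, ends, labels)


def jaccard(set1: GenomicIntervalSet, set2: GenomicIntervalSet) -> float:
    """Intersection over union of two base-pair coverage sets.

    1 means perfect overlap; raises for two empty sets (0/0).
    """
    union_bp = set1.union(set2).total_bp
    if union_bp == 0:
        raise ValueError("Jaccard undefined: both interval sets are empty")
    return set1.intersection(set2).total_bp / union_bp


@dataclass
class FateMatrix:
    """Base-pair transition counts from control classes to treated classes.

    ``counts[i, j]`` is the number of bases labeled ``CLASSES[i]`` in
    control and ``CLASSES[j]`` after treatment. The grand total equals the
    genome size; row/column sums equal the class coverages of the two
    partitions.
    """

    counts: np.ndarray
    genome: Genome

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(CLASSES), len(CLASSES)):
            raise ValueError("fate matrix must be 4x4")

    def row_proportions(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(sums > 0, self.counts / sums, 0.0)
        return props

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASSES), columns=list(CLASSES))

    def to_long(self) -> pd.DataFrame:
        """Long-format table for alluvial plotting, one row per fate pair."""
        props = self.row_proportions()
        rows = []
        pair = 0
        for i, ci in enumerate(CLASSES):
            for j, cj in enumerate(CLASSES):
                pair += 1
                rows.append(
                    {
                        "pair": pair,
                        "control_class": ci,
                        "treated_class": cj,
                        "bp": int(self.counts[i, j]),
                        "row_proportion": float(props[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def fate_matrix(ctrl: ClassPartition, trt: ClassPartition) -> FateMatrix:
    """Count base pairs moving between classes across two conditions."""
    if ctrl.genome != trt.genome:
        raise ValueError("fate matrix requires partitions on the same genome")
    counts = np.zeros((len(CLASSES), len(CLASSES)), dtype=np.int64)
    for chrom, _length in ctrl.genome.chromosomes:
        ends = np.union1d(ctrl.ends[chrom], trt.ends[chrom])
        starts = np.concatenate([[0], ends[:-1]])
        sizes = ends - starts
        lab_c = ctrl.labels[chrom][np.searchsorted(ctrl.ends[chrom], starts, side="right")]
        lab_t = trt.labels[chrom][np.searchsorted(trt.ends[chrom], starts, side="right")]
        np.add.at(counts, (lab_c, lab_t), sizes)
    return FateMatrix(counts, ctrl.genome)


def lad_sizes(obj: ClassPartition | GenomicIntervalSet) -> dict[str, np.ndarray] | np.ndarray:
    """Sizes in bp of maximal same-class runs (partition) or intervals (set)."""
    if isinstance(obj, ClassPartition):
        return obj.run_sizes()
    return obj.lengths()


@dataclass
class SizeComparison:
    anova: pd.DataFrame
    tukey: pd.DataFrame


def compare_sizes(groups: dict[tuple[str, str], np.ndarray]) -> SizeComparison:
    """Two-way ANOVA (class x condition) on log10 domain size + Tukey HSD.

    ``groups`` maps ``(lad_class, condition)`` to an array of sizes in bp.
    Every group needs at least two observations.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for (lad_class, condition), sizes in groups.items():
        sizes = np.asarray(sizes, dtype=float)
        if sizes.size < 2:
            raise ValueError(f"group {(lad_class, condition)} has fewer than 2 domains")
        if np.any(sizes <= 0):
            raise ValueError("domain sizes must be positive")
        for s in sizes:
            rows.append(
                {
                    "log_size": np.log10(s),
                    "lad_class": lad_class,
                    "condition": condition,
                    "group": f"{lad_class}|{condition}",
                }
            )
    df = pd.DataFrame(rows)
    terms = []
    if df["lad_class"].nunique() > 1:
        terms.append("C(lad_class)")
    if df["condition"].nunique() > 1:
        terms.append("C(condition)")
    if not terms:
        raise ValueError("need variation in class or condition")
    if len(terms) == 2:
        formula = "log_size ~ C(lad_class) * C(condition)"
    else:
        formula = f"log_size ~ {terms[0]}"
    model = smf.ols(formula, data=df).fit()
    anova = anova_lm(model, typ=2)
    hsd = pairwise_tukeyhsd(df["log_size"].to_numpy(), df["group"].to_numpy())
    tukey = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    return SizeComparison(anova=anova, tukey=tukey)


def coverage_summary(partition: ClassPartition) -> pd.DataFrame:
    """Per-class bp, genome fraction and maximal-run count."""
    cov = partition.coverage()
    sizes = partition.run_sizes()
    total = partition.genome.total_bp
    rows = [
        {
            "lad_class": c,
            "bp": cov[c],
            "fraction": cov[c] / total,
            "n_domains": len(sizes[c]),
        }
        for c in CLASSES
    ]
    return pd.DataFrame(rows)


#: Tie priority for the per-domain majority classifier.
_TIE_PRIORITY = ("A-B", "B-only", "A-only", "iLAD")


def classify_domains(
    lads: GenomicIntervalSet, partition: ClassPartition
) -> list[tuple[str, int, int, str]]:
    """Secondary, per-domain view: label each named domain by majority class.

    A domain takes the class covering the largest share of its span; exact
    ties fall back to the priority A-B > B-only > A-only > iLAD.
    """
    out = []
    for chrom, start, end in lads:
        vec = partition.overlap_vector(chrom, start, end)
        best = max(_TIE_PRIORITY, key=lambda c: (vec[CLASSES.index(c)], -_TIE_PRIORITY.index(c)))
        out.append((chrom, start, end, best))
    return out
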