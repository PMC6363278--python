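"""Run-length genome labeling into the four LAD classes.

The four labels tile every chromosome exactly: each base is in exactly one
of ``A-B`` (bound by both lamins), ``A-only``, ``B-only`` or ``iLAD``
(bound by neither).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome
from .intervals import GenomicIntervalSet

#: Canonical class order. Fate-pair numbering is row-major in this order,
#: so (A-B -> A-B) is pair 1 and (iLAD -> iLAD) is pair 16.
CLASSES: tuple[str, ...] = ("A-B", "A-only", "B-only", "iLAD")
ILAD: int = CLASSES.index("iLAD")

#: Class indices in which each lamin participates.
LAMIN_CLASSES: dict[str, tuple[int, ...]] = {"A": (0, 1), "B": (0, 2)}


def class_index(label: str) -> int:
    try:
        return CLASSES.index(label)
    except ValueError:
        raise ValueError(f"unknown LAD class {label!r}; expected one of {CLASSES}") from None


@dataclass
class ClassPartition:
    """Per-chromosome run-length labeling with labels from :data:`CLASSES`.

    ``ends[chrom]`` holds strictly increasing run end coordinates, the last
    equal to the chromosome length; ``labels[chrom]`` holds the class index
    of each run. Adjacent runs with equal labels are merged on construction
    so run counts are well defined.
    """

    genome: Genome
    ends: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, length in self.genome.chromosomes:
            if chrom not in self.ends:
                raise ValueError(f"partition missing chromosome {chrom}")
            ends = np.asarray(self.ends[chrom], dtype=np.int64)
            labels = np.asarray(self.labels[chrom], dtype=np.int8)
            if ends.shape != labels.shape:
                raise ValueError(f"ends/labels length mismatch on {chrom}")
            if ends.size == 0 or ends[-1] != length:
                raise ValueError(f"runs on {chrom} do not tile the chromosome")
            if np.any(np.diff(ends) <= 0) or ends[0] <= 0:
                raise ValueError(f"run ends on {chrom} not strictly increasing")
            if labels.min() < 0 or labels.max() >= len(CLASSES):
                raise ValueError(f"invalid class label on {chrom}")
            # merge adjacent equal-label runs
            keep = np.ones(len(labels), dtype=bool)
            keep[:-1] = labels[:-1] != labels[1:]
            self.ends[chrom] = ends[keep]
            self.labels[chrom] = labels[keep]

    # -- constructors --------------------------------------------------------

    @classmethod
    def all_ilad(cls, genome: Genome) -> "ClassPartition":
        ends = {c: np.asarray([l], dtype=np.int64) for c, l in genome.chromosomes}
        labels = {c: np.asarray([ILAD], dtype=np.int8) for c, _ in genome.chromosomes}
        return cls(genome, ends, labels)

    @classmethod
    def from_runs(
        cls, genome: Genome, runs: dict[str, list[tuple[int, int, str]]]
    ) -> "ClassPartition":
        """Build from sparse labeled runs; unlisted bases become iLAD."""
        ends: dict[str, np.ndarray] = {}
        labels: dict[str, np.ndarray] = {}
        for chrom, length in genome.chromosomes:
            e: list[int] = []
            l: list[int] = []
            cursor = 0
            for start, end, label in sorted(runs.get(chrom, [])):
                if start < cursor:
                    raise ValueError(f"overlapping runs on {chrom} at {start}")
                if end > length:
                    raise ValueError(f"run beyond end of {chrom}")
                if start > cursor:
                    e.append(start)
                    l.append(ILAD)
                e.append(end)
                l.append(class_index(label))
                cursor = end
            if cursor < length:
                e.append(length)
                l.append(ILAD)
            ends[chrom] = np.asarray(e, dtype=np.int64)
            labels[chrom] = np.asarray(l, dtype=np.int8)
        return cls(genome, ends, labels)

    # -- queries -------------------------------------------------------------

    def label_index_at(self, chrom: str, pos: int | np.ndarray) -> np.ndarray:
        """Class index of the base(s) at ``pos`` (0-based)."""
        length = self.genome.length(chrom)
        pos_arr = np.asarray(pos)
        if np.any(pos_arr < 0) or np.any(pos_arr >= length):
            raise ValueError(f"position out of bounds on {chrom}")
        idx = np.searchsorted(self.ends[chrom], pos_arr, side="right")
        return self.labels[chrom][idx]

    def label_at(self, chrom: str, pos: int) -> str:
        return CLASSES[int(self.label_index_at(chrom, pos))]

    def segments(self):
        """Yield ``(chrom, start, end, label)`` runs in genome order."""
        for chrom, _ in self.genome.chromosomes:
            start = 0
            for end, lab in zip(self.ends[chrom], self.labels[chrom]):
                yield chrom, int(start), int(end), CLASSES[lab]
                start = end

    def class_set(self, label: str) -> GenomicIntervalSet:
        """Coverage set of one class."""
        want = class_index(label)
        ivs = [(c, s, e) for c, s, e, lab in self.segments() if CLASSES.index(lab) == want]
        return GenomicIntervalSet(ivs)

    def lamin_set(self, lamin: str) -> GenomicIntervalSet:
        """Union coverage of all classes containing the given lamin (A or B)."""
        if lamin not in LAMIN_CLASSES:
            raise ValueError(f"lamin must be 'A' or 'B', got {lamin!r}")
        members = LAMIN_CLASSES[lamin]
        ivs = [(c, s, e) for c, s, e, lab in self.segments() if CLASSES.index(lab) in members]
        return GenomicIntervalSet(ivs)

    def coverage(self) -> dict[str, int]:
        """Base pairs per class; values sum to the genome size."""
        out = dict.fromkeys(CLASSES, 0)
        for chrom, _ in self.genome.chromosomes:
            starts = np.concatenate([[0], self.ends[chrom][:-1]])
            sizes = self.ends[chrom] - starts
            for lab, size in zip(self.labels[chrom], sizes):
                out[CLASSES[lab]] += int(size)
        return out

    def run_sizes(self) -> dict[str, np.ndarray]:
        """Lengths in bp of maximal same-label runs, per class."""
        out: dict[str, list[int]] = {c: [] for c in CLASSES}
        for chrom, start, end, label in self.segments():
            out[label].append(end - start)
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def overlap_vector(self, chrom: str, start: int, end: int) -> np.ndarray:
        """bp of ``[start, end)`` carrying each class, in CLASSES order."""
        ends = self.ends[chrom]
        labels = self.labels[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(ends, end - 1, side="right")
        out = np.zeros(len(CLASSES), dtype=np.int64)
        run_start = 0 if lo == 0 else int(ends[lo - 1])
        for k in range(lo, hi + 1):
            run_end = int(ends[k])
            out[labels[k]] += min(run_end, end) - max(run_start, start)
            run_start = run_end
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClassPartition):
            return NotImplemented
        if self.genome != other.genome:
            return False
        return all(
            np.array_equal(self.ends[c], other.ends[c])
            and np.array_equal(self.labels[c], other.labels[c])
            for c in self.genome.names
        )
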