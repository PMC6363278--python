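"""Readers and writers for the plain-text formats used by the pipeline.

BED and bedGraph are handwritten line formats (0-based half-open);
tabular data (structures, spots, expression) go through pandas TSV; bead
structures can additionally be read from a CMM-like XML marker dialect.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd

from .expression import GeneRecord, tss_from_bed6
from .genome import Genome
from .intervals import GenomicIntervalSet
from .radial import BeadStructure, SpotRecord
from .tracks import CountTrack, RatioTrack


class ParseError(ValueError):
    """Malformed input line; message carries the file and line number."""

    def __init__(self, path, lineno: int, msg: str):
        super().__init__(f"{path}:{lineno}: {msg}")


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


# -- genome description ----------------------------------------------------


def write_genome_tsv(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#bin_size={genome.bin_size}\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"{chrom}\t{length}\n")


def read_genome_tsv(path, bin_size: int | None = None) -> Genome:
    """Two-column chrom/length TSV; bin size from a ``#bin_size=`` header
    unless overridden."""
    chroms = []
    header_bin = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#bin_size="):
                    header_bin = int(line.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, lineno, "genome line needs chrom and length")
            try:
                chroms.append((fields[0], int(fields[1])))
            except ValueError:
                raise ParseError(path, lineno, "non-integer chromosome length") from None
    return Genome(tuple(chroms), bin_size=bin_size or header_bin or 10_000)


# -- BED -------------------------------------------------------------------


def read_bed(path) -> GenomicIntervalSet:
    """Read a BED file as a merged coverage set. Empty files are fine."""
    intervals = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, "BED line needs at least 3 fields")
        try:
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
        except ValueError:
            raise ParseError(path, lineno, "non-integer BED coordinates") from None
    return GenomicIntervalSet(intervals)


def write_bed(intervals: GenomicIntervalSet, path, name_prefix: str = "") -> None:
    with open(path, "w") as fh:
        for k, (chrom, start, end) in enumerate(intervals, start=1):
            if name_prefix:
                fh.write(f"{chrom}\t{start}\t{end}\t{name_prefix}{k}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


# -- bedGraph --------------------------------------------------------------


def write_ratio_bedgraph(track: RatioTrack, path) -> None:
    """Write unmasked bins of a ratio track; masked bins are omitted."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vals = track.values[chrom]
            ok = track.valid[chrom]
            length = track.chrom_lengths[chrom]
            for i in np.flatnonzero(ok):
                start = i * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{vals[i]:.6g}\n")


def read_ratio_bedgraph(path, bin_size: int) -> RatioTrack:
    """Read a fixed-bin bedGraph back into a ratio track.

    Bins absent from the file are masked. Chromosome lengths are taken as
    the largest end coordinate seen, rounded up to a whole bin.
    """
    records: dict[str, list[tuple[int, float]]] = {}
    maxend: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(path, lineno, "bedGraph line needs 4 fields")
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError:
            raise ParseError(path, lineno, "malformed bedGraph fields") from None
        if start % bin_size != 0 or end - start > bin_size:
            raise ParseError(path, lineno, f"interval not aligned to {bin_size}-bp bins")
        records.setdefault(chrom, []).append((start // bin_size, value))
        maxend[chrom] = max(maxend.get(chrom, 0), end)
    values: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, recs in records.items():
        n = -(-maxend[chrom] // bin_size)
        v = np.full(n, np.nan)
        ok = np.zeros(n, dtype=bool)
        for idx, value in recs:
            v[idx] = value
            ok[idx] = True
        values[chrom] = v
        valid[chrom] = ok
        lengths[chrom] = maxend[chrom]
    return RatioTrack(bin_size, values, valid, lengths)


def write_count_bedgraph(track: CountTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            counts = track.data[chrom]
            length = track.chrom_lengths[chrom]
            for i, c in enumerate(counts):
                start = i * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{int(c)}\n")


def read_count_bedgraph(path, bin_size: int) -> CountTrack:
    """Read integer counts from a fixed-bin bedGraph (missing bins = 0)."""
    records: dict[str, list[tuple[int, int]]] = {}
    maxend: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(path, lineno, "bedGraph line needs 4 fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
            count = int(float(fields[3]))
        except ValueError:
            raise ParseError(path, lineno, "malformed bedGraph fields") from None
        if start % bin_size != 0 or end - start > bin_size:
            raise ParseError(path, lineno, f"interval not aligned to {bin_size}-bp bins")
        records.setdefault(chrom, []).append((start // bin_size, count))
        maxend[chrom] = max(maxend.get(chrom, 0), end)
    data: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, recs in records.items():
        n = -(-maxend[chrom] // bin_size)
        arr = np.zeros(n, dtype=np.int64)
        for idx, count in recs:
            arr[idx] = count
        data[chrom] = arr
        lengths[chrom] = maxend[chrom]
    return CountTrack(bin_size, data, lengths)


# -- genes / expression ----------------------------------------------------


def write_expression_tsv(genes: Sequence[GeneRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
            "fpkm_control": [g.fpkm_control for g in genes],
            "fpkm_treated": [g.fpkm_treated for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "fpkm_control", "fpkm_treated"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
    if "strand" not in df.columns:
        df["strand"] = "."
    return [
        GeneRecord(
            str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand),
            float(r.fpkm_control), float(r.fpkm_treated),
        )
        for r in df.itertuples()
    ]


def read_genes_bed6(path, fpkm_table: pd.DataFrame | None = None) -> list[GeneRecord]:
    """BED6 gene annotation; TSS is start (+) or end-1 (-)."""
    genes = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(path, lineno, "BED6 line needs 6 fields")
        chrom, start, end, name, _score, strand = fields[:6]
        try:
            tss = tss_from_bed6(int(start), int(end), strand)
        except ValueError:
            raise ParseError(path, lineno, "non-integer BED coordinates") from None
        fc = ft = 0.0
        if fpkm_table is not None and name in fpkm_table.index:
            fc = float(fpkm_table.loc[name, "fpkm_control"])
            ft = float(fpkm_table.loc[name, "fpkm_treated"])
        genes.append(GeneRecord(name, chrom, tss, strand, fc, ft))
    return genes


# -- bead structures -------------------------------------------------------

_STRUCT_COLS = ["model_id", "bead_id", "chrom", "start", "end", "x", "y", "z", "bead_radius", "nucleus_radius"]


def write_structures_tsv(structures: Sequence[BeadStructure], path) -> None:
    rows = []
    for s in structures:
        for k in range(s.n_beads):
            rows.append(
                (
                    s.model_id, k, s.chrom[k], int(s.start[k]), int(s.end[k]),
                    s.centers[k, 0], s.centers[k, 1], s.centers[k, 2],
                    s.bead_radius[k], s.radius_um,
                )
            )
    pd.DataFrame(rows, columns=_STRUCT_COLS).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_structures_tsv(path) -> list[BeadStructure]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_STRUCT_COLS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
    out = []
    for model_id, grp in df.groupby("model_id", sort=False):
        grp = grp.sort_values("bead_id")
        out.append(
            BeadStructure(
                model_id=str(model_id),
                chrom=grp["chrom"].to_numpy(dtype=object),
                start=grp["start"].to_numpy(),
                end=grp["end"].to_numpy(),
                centers=grp[["x", "y", "z"]].to_numpy(dtype=float),
                bead_radius=grp["bead_radius"].to_numpy(dtype=float),
                radius_um=float(grp["nucleus_radius"].iloc[0]),
            )
        )
    return out


def read_structure_cmm(path, radius_um: float = 5.0, model_id: str | None = None) -> BeadStructure:
    """Read a CMM-like XML marker file as one structure.

    Each ``<marker>`` needs ``x``, ``y``, ``z``, ``radius`` attributes and
    a ``beadID`` of the form ``chrom:start-end``.
    """
    tree = ET.parse(path)
    chroms, starts, ends, centers, radii = [], [], [], [], []
    for marker in tree.getroot().iter("marker"):
        bead_id = marker.get("beadID", "")
        try:
            chrom, span = bead_id.split(":")
            start, end = span.split("-")
            chroms.append(chrom)
            starts.append(int(start))
            ends.append(int(end))
            centers.append([float(marker.get(a)) for a in ("x", "y", "z")])
            radii.append(float(marker.get("radius", 0.1)))
        except (ValueError, TypeError):
            raise ParseError(path, 0, f"malformed marker beadID {bead_id!r}") from None
    return BeadStructure(
        model_id=model_id or Path(path).stem,
        chrom=np.asarray(chroms, dtype=object),
        start=np.asarray(starts),
        end=np.asarray(ends),
        centers=np.asarray(centers),
        bead_radius=np.asarray(radii),
        radius_um=radius_um,
    )


# -- FISH spots ------------------------------------------------------------

_SPOT_COLS = [
    "nucleus_id", "condition", "probe", "spot_x", "spot_y",
    "center_x", "center_y", "axis_a", "axis_b", "angle",
]


def write_spots_tsv(spots: Sequence[SpotRecord], path) -> None:
    rows = [
        (
            s.nucleus_id, s.condition, s.probe, s.spot_xy[0], s.spot_xy[1],
            s.center_xy[0], s.center_xy[1], s.axis_a, s.axis_b, s.angle,
        )
        for s in spots
    ]
    pd.DataFrame(rows, columns=_SPOT_COLS).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_spots_tsv(path) -> list[SpotRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SPOT_COLS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
    return [
        SpotRecord(
            nucleus_id=str(r.nucleus_id),
            condition=str(r.condition),
            probe=str(r.probe),
            spot_xy=(float(r.spot_x), float(r.spot_y)),
            center_xy=(float(r.center_x), float(r.center_y)),
            axis_a=float(r.axis_a),
            axis_b=float(r.axis_b),
            angle=float(r.angle),
        )
        for r in df.itertuples()
    ]
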