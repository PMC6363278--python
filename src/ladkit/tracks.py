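"""Binned count tracks, depth matching, and log2(ChIP/input) ratio tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_BIN_SIZE = 1000  # bp; ratio tracks are built at 1-kb bins by default


class TrackError(ValueError):
    """Structural problem with a track or a pair of tracks."""


@dataclass
class CountTrack:
    """Fixed-bin non-negative integer counts per chromosome.

    The last bin may be partial: ``n_bins * bin_size >= chrom_length >
    (n_bins - 1) * bin_size``. When ``chrom_lengths`` is omitted, lengths
    default to ``n_bins * bin_size``.
    """

    bin_size: int
    data: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise TrackError("bin_size must be positive")
        clean = {}
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 1:
                raise TrackError(f"counts on {chrom} must be 1-D")
            if np.any(arr < 0):
                raise TrackError(f"negative counts on {chrom}")
            clean[chrom] = arr
            length = self.chrom_lengths.setdefault(chrom, len(arr) * self.bin_size)
            if not (len(arr) - 1) * self.bin_size < length <= len(arr) * self.bin_size:
                raise TrackError(f"chromosome length inconsistent with bin count on {chrom}")
        self.data = clean

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.data)

    def total(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.data[chrom].sum())
        return int(sum(a.sum() for a in self.data.values()))

    def copy(self) -> "CountTrack":
        return CountTrack(
            self.bin_size,
            {c: a.copy() for c, a in self.data.items()},
            dict(self.chrom_lengths),
        )


@dataclass
class RatioTrack:
    """Fixed-bin log2(ChIP/input) values with a validity mask.

    ``valid[chrom]`` is False where the ratio is undefined (zero input or
    zero ChIP counts); values there are NaN and must not be consumed.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise TrackError("bin_size must be positive")
        for chrom, vals in self.values.items():
            vals = np.asarray(vals, dtype=np.float64)
            mask = np.asarray(self.valid[chrom], dtype=bool)
            if vals.shape != mask.shape:
                raise TrackError(f"values/valid shape mismatch on {chrom}")
            if not np.all(np.isfinite(vals[mask])):
                raise TrackError(f"non-finite value in unmasked bin on {chrom}")
            self.values[chrom] = vals
            self.valid[chrom] = mask
            self.chrom_lengths.setdefault(chrom, len(vals) * self.bin_size)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.values)

    def unmasked(self) -> np.ndarray:
        """All valid values across the genome, concatenated."""
        parts = [self.values[c][self.valid[c]] for c in self.values]
        return np.concatenate(parts) if parts else np.empty(0)


def match_depth(
    chip: CountTrack, input_: CountTrack, seed: int | np.random.Generator = 0
) -> tuple[CountTrack, CountTrack]:
    """Equalise ChIP and input read depth per chromosome by down-sampling.

    On each chromosome the track with the larger total is down-sampled
    *without replacement* (multivariate hypergeometric over its bins) to
    the smaller total, so totals match exactly; the smaller track is
    returned unchanged. Already-equal chromosomes are untouched, which
    makes the operation idempotent.
    """
    if chip.bin_size != input_.bin_size:
        raise TrackError("bin sizes differ between ChIP and input")
    if set(chip.chroms) != set(input_.chroms):
        raise TrackError("chromosome sets differ between ChIP and input")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chip_out, input_out = chip.copy(), input_.copy()
    for chrom in chip.chroms:
        tc, ti = chip.total(chrom), input_.total(chrom)
        if tc == ti:
            continue
        big, target = (chip_out, ti) if tc > ti else (input_out, tc)
        counts = big.data[chrom]
        big.data[chrom] = rng.multivariate_hypergeometric(
            counts, target, method="marginals"
        ).astype(np.int64)
    return chip_out, input_out


def build_ratio_track(chip: CountTrack, input_: CountTrack) -> RatioTrack:
    """log2 ratio of ChIP over input per bin, input scaled to ChIP depth.

    The per-bin value is ``log2(chip / (input * totalChip / totalInput))``
    with totals taken genome-wide, so the result is invariant to uniform
    rescaling of either track's depth. Bins with zero input (and, by
    necessity of finiteness, zero ChIP) are masked.
    """
    if chip.bin_size != input_.bin_size:
        raise TrackError("bin sizes differ between ChIP and input")
    if set(chip.chroms) != set(input_.chroms):
        raise TrackError("chromosome sets differ between ChIP and input")
    total_chip, total_input = chip.total(), input_.total()
    if total_input == 0:
        raise TrackError("input track has zero total counts")
    if total_chip == 0:
        raise TrackError("ChIP track has zero total counts")
    scale = total_chip / total_input
    values: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for chrom in chip.chroms:
        c = chip.data[chrom].astype(np.float64)
        i = input_.data[chrom].astype(np.float64)
        if c.shape != i.shape:
            raise TrackError(f"bin counts differ on {chrom}")
        ok = (i > 0) & (c > 0)
        vals = np.full_like(c, np.nan)
        vals[ok] = np.log2(c[ok] / (i[ok] * scale))
        values[chrom] = vals
        valid[chrom] = ok
    return RatioTrack(chip.bin_size, values, valid, dict(chip.chrom_lengths))
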