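"""Broad-domain calling by maximal-scoring-segment search.

Bins at or above an enrichment threshold ``tau`` score ``+1``; all other
bins (including masked ones) score ``-gp``. Domains are the disjoint
maximal-scoring segments of this score sequence: the top-scoring segment
is taken (ties broken toward the longer, then the leftmost segment), then
the search recurses on the flanks, keeping every segment whose score
reaches ``min_score``. The two tuning knobs are the coarse bin size ``bs``
and the gap penalty ``gp``.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicIntervalSet
from .tracks import RatioTrack


class DegenerateTrackError(ValueError):
    """Track carries no usable signal for parameter estimation."""


@dataclass(frozen=True)
class CallerParams:
    """Tuning parameters of the domain caller."""

    bs: int  # coarse bin size, bp; must be a multiple of the native bin size
    gp: float  # gap penalty per non-enriched bin, >= 0
    tau: float  # log-ratio enrichment threshold
    min_score: float = 3.0  # minimal segment score, in enriched-bin units

    def __post_init__(self) -> None:
        if self.bs <= 0:
            raise ValueError("bs must be positive")
        if self.gp < 0:
            raise ValueError("gp must be >= 0")


def rebin(track: RatioTrack, bs: int) -> RatioTrack:
    """Aggregate a track to coarse bins of size ``bs``.

    Each coarse bin takes the mean of its unmasked members and is masked
    only when all members are masked. ``bs`` must be a multiple of the
    native bin size; ``bs`` equal to it is the identity.
    """
    if bs == track.bin_size:
        return track
    if bs % track.bin_size != 0 or bs < track.bin_size:
        raise ValueError(f"bs {bs} is not a multiple of the native bin size {track.bin_size}")
    k = bs // track.bin_size
    values: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for chrom in track.chroms:
        v = track.values[chrom]
        m = track.valid[chrom]
        n_coarse = -(-len(v) // k)
        pad = n_coarse * k - len(v)
        if pad:
            v = np.concatenate([v, np.full(pad, np.nan)])
            m = np.concatenate([m, np.zeros(pad, dtype=bool)])
        v = np.where(m, v, 0.0).reshape(n_coarse, k)
        m = m.reshape(n_coarse, k)
        counts = m.sum(axis=1)
        ok = counts > 0
        out = np.full(n_coarse, np.nan)
        out[ok] = v.sum(axis=1)[ok] / counts[ok]
        values[chrom] = out
        valid[chrom] = ok
    return RatioTrack(bs, values, valid, dict(track.chrom_lengths))


def _best_segment(scores: np.ndarray, lo: int, hi: int) -> tuple[float, int, int]:
    """Max-sum contiguous segment of ``scores[lo:hi]``.

    Returns ``(score, start, end)``; ties prefer the longer segment, then
    the leftmost. Single left-to-right scan over prefix sums.
    """
    best_score = -np.inf
    best_len = 0
    best_start = lo
    best_end = lo
    run_min = 0.0
    run_min_idx = lo
    s = 0.0
    for j in range(lo, hi):
        s += scores[j]
        sc = s - run_min
        ln = j + 1 - run_min_idx
        if sc > best_score or (sc == best_score and ln > best_len):
            best_score, best_len = sc, ln
            best_start, best_end = run_min_idx, j + 1
        if s < run_min:  # keep the earliest minimum so ties yield longer segments
            run_min = s
            run_min_idx = j + 1
    return best_score, best_start, best_end


def _segments(scores: np.ndarray, min_score: float) -> list[tuple[int, int]]:
    """Disjoint maximal-scoring segments with score >= min_score."""
    out: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = [(0, len(scores))]
    while stack:
        lo, hi = stack.pop()
        if hi <= lo:
            continue
        _, i, j = _best_segment(scores, lo, hi)
        # re-sum directly: prefix-difference scores can lose an ulp to
        # cancellation, which matters only at the min_score threshold
        sc = 0.0
        for k in range(i, j):
            sc += scores[k]
        if sc < min_score:
            continue
        out.append((i, j))
        stack.append((lo, i))
        stack.append((j, hi))
    out.sort()
    return out


def call_domains(track: RatioTrack, params: CallerParams) -> GenomicIntervalSet:
    """Call enriched domains on every chromosome of a ratio track.

    The track is rebinned to ``params.bs`` first if needed. Masked coarse
    bins are treated as non-enriched. Returned intervals are clipped to
    chromosome ends, never overlap, and are sorted.
    """
    coarse = rebin(track, params.bs)
    intervals = []
    for chrom in coarse.chroms:
        v = coarse.values[chrom]
        ok = coarse.valid[chrom]
        enriched = ok & (np.nan_to_num(v, nan=-np.inf) >= params.tau)
        scores = np.where(enriched, 1.0, -params.gp)
        length = coarse.chrom_lengths[chrom]
        for i, j in _segments(scores, params.min_score):
            intervals.append((chrom, i * params.bs, min(j * params.bs, length)))
    return GenomicIntervalSet(intervals)


_BS_LADDER = (1, 2, 3, 4, 6, 8)


def _enriched_fraction(track: RatioTrack, bs: int, tau: float) -> float:
    coarse = rebin(track, bs)
    n_valid = n_enriched = 0
    for chrom in coarse.chroms:
        ok = coarse.valid[chrom]
        n_valid += int(ok.sum())
        n_enriched += int((coarse.values[chrom][ok] >= tau).sum())
    if n_valid == 0:
        raise DegenerateTrackError("track has no unmasked bins")
    return n_enriched / n_valid


def auto_estimate(
    track: RatioTrack,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
    min_score: float = 3.0,
) -> CallerParams:
    """Heuristic parameter estimation from the track itself.

    * ``tau`` is the genome-wide median of unmasked values.
    * ``bs`` walks a ladder of multiples of the native bin size and stops
      at the smallest size where the enriched-bin fraction changes by
      < 1 percentage point versus the next step.
    * ``gp`` is the ratio of non-enriched to enriched coarse bins, so
      sparse enrichment is guarded by a proportionally stiffer gap
      penalty; optionally perturbed by seeded Gaussian jitter of
      ``jitter * gp`` (used by the stability protocol to probe call
      robustness).
    """
    vals = track.unmasked()
    if vals.size == 0:
        raise DegenerateTrackError("track has no unmasked bins")
    if np.all(vals == vals[0]):
        raise DegenerateTrackError("constant track: no enrichment structure to estimate")
    tau = float(np.median(vals))

    fractions = [_enriched_fraction(track, k * track.bin_size, tau) for k in _BS_LADDER]
    k_chosen = _BS_LADDER[-1]
    for k, f_now, f_next in zip(_BS_LADDER, fractions, fractions[1:]):
        if abs(f_now - f_next) < 0.01:
            k_chosen = k
            break
    bs = k_chosen * track.bin_size

    frac = _enriched_fraction(track, bs, tau)
    if frac in (0.0, 1.0):
        raise DegenerateTrackError("all bins fall on one side of tau")
    # twice the non-enriched/enriched ratio: crossing a typical gap must
    # cost more than the score of the domain beyond it, or neighbouring
    # domains fuse across inter-LADs of comparable extent
    gp = 2.0 * (1.0 - frac) / frac
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        gp += rng.normal(0.0, jitter * gp)
        gp = max(gp, 1e-3)
    return CallerParams(bs=bs, gp=float(gp), tau=tau, min_score=min_score)


def variable_subdomains(
    lad_sets: list[GenomicIntervalSet],
) -> tuple[GenomicIntervalSet, float]:
    """Bases not shared by all runs, and their median interval length.

    Returns (union minus intersection of all runs' coverage, median length
    of the resulting intervals; 0.0 when the runs agree everywhere).
    """
    if not lad_sets:
        raise ValueError("need at least one LAD set")
    union = inter = lad_sets[0]
    for lads in lad_sets[1:]:
        union = union.union(lads)
        inter = inter.intersection(lads)
    variable = union.difference(inter)
    lengths = variable.lengths()
    return variable, float(np.median(lengths)) if lengths.size else 0.0


@dataclass
class StabilityReport:
    """Outcome of repeated auto-estimated calling runs.

    ``variable_subdomains`` is the union of all runs' coverage minus their
    intersection — the bases on which the runs disagree.
    """

    params_per_run: list[CallerParams]
    lads_per_run: list[GenomicIntervalSet]
    variable_subdomains: GenomicIntervalSet
    median_variable_length: float
    gp_sd: float
    mean_gp: float
    mean_bs: int
    final_params: CallerParams
    final_lads: GenomicIntervalSet

    def to_json_dict(self) -> dict:
        return {
            "n_runs": len(self.params_per_run),
            "params_per_run": [
                {"bs": p.bs, "gp": p.gp, "tau": p.tau} for p in self.params_per_run
            ],
            "gp_sd": self.gp_sd,
            "mean_gp": self.mean_gp,
            "mean_bs": self.mean_bs,
            "n_variable_subdomains": len(self.variable_subdomains),
            "variable_subdomain_bp": self.variable_subdomains.total_bp,
            "median_variable_length": self.median_variable_length,
            "final_params": {
                "bs": self.final_params.bs,
                "gp": self.final_params.gp,
                "tau": self.final_params.tau,
                "min_score": self.final_params.min_score,
            },
            "n_final_lads": len(self.final_lads),
            "final_lad_bp": self.final_lads.total_bp,
        }


def stability_protocol(
    track: RatioTrack,
    n_runs: int = 10,
    seed: int = 0,
    jitter: float = 0.1,
    min_score: float = 3.0,
) -> StabilityReport:
    """Run auto-estimated calling ``n_runs`` times, then a fixed final call.

    Each run re-estimates parameters with seeded jitter on the gap
    penalty. The report captures run-to-run variability (variable
    subdomains and their median length, GP spread), and the final call
    uses the across-run average GP and BS.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    rng = np.random.default_rng(seed)
    params_per_run = [
        auto_estimate(track, rng=rng, jitter=jitter, min_score=min_score) for _ in range(n_runs)
    ]
    lads_per_run = [call_domains(track, p) for p in params_per_run]

    variable, median_len = variable_subdomains(lads_per_run)

    gps = [p.gp for p in params_per_run]
    bss = [p.bs for p in params_per_run]
    native = track.bin_size
    mean_bs = max(native, int(round(float(np.mean(bss)) / native)) * native)
    final_params = CallerParams(
        bs=mean_bs,
        gp=float(np.mean(gps)),
        tau=params_per_run[0].tau,
        min_score=min_score,
    )
    return StabilityReport(
        params_per_run=params_per_run,
        lads_per_run=lads_per_run,
        variable_subdomains=variable,
        median_variable_length=median_len,
        gp_sd=float(statistics.pstdev(gps)) if n_runs > 1 else 0.0,
        mean_gp=float(np.mean(gps)),
        mean_bs=mean_bs,
        final_params=final_params,
        final_lads=call_domains(track, final_params),
    )
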