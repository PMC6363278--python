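"""Synthetic data with planted ground truth for every pipeline stage.

Everything here is seeded and bit-reproducible: a planted LAD architecture
realising a class-transition plan exactly in base pairs, negative-binomial
binned ChIP/input counts with in-LAD enrichment, bead structures with
class-dependent radial bias inside a 5-um nucleus, FPKM tables with
transition-dependent effects, and 2D FISH spot tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .expression import GeneRecord
from .genome import Genome
from .partition import CLASSES, ILAD, ClassPartition, class_index
from .radial import DEFAULT_NUCLEUS_RADIUS_UM, BeadStructure, SpotRecord
from .tracks import CountTrack


class PlanError(ValueError):
    """A transition plan that cannot be realised on the genome."""


@dataclass(frozen=True)
class PlanEntry:
    control_class: str
    treated_class: str
    total_bp: int
    n_domains: int = 1

    def __post_init__(self) -> None:
        class_index(self.control_class)
        class_index(self.treated_class)
        if self.total_bp < 0:
            raise PlanError("total_bp must be non-negative")
        if self.total_bp > 0 and self.n_domains < 1:
            raise PlanError("n_domains must be >= 1 for a nonzero entry")


@dataclass(frozen=True)
class TransitionPlan:
    """A list of (control class, treated class, bp, domain count) entries."""

    entries: tuple[PlanEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def total_bp(self) -> int:
        return sum(e.total_bp for e in self.entries)

    def bp_table(self) -> np.ndarray:
        """4x4 planted bp per (control, treated) cell; iLAD->iLAD excluded."""
        table = np.zeros((len(CLASSES), len(CLASSES)), dtype=np.int64)
        for e in self.entries:
            i, j = class_index(e.control_class), class_index(e.treated_class)
            if (i, j) != (ILAD, ILAD):
                table[i, j] += e.total_bp
        return table

    def expected_fate_counts(self, genome: Genome) -> np.ndarray:
        """Full expected fate matrix: plan table plus the iLAD remainder."""
        table = self.bp_table()
        table[ILAD, ILAD] = genome.total_bp - table.sum()
        return table

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "control_class": e.control_class,
                    "treated_class": e.treated_class,
                    "total_bp": e.total_bp,
                    "n_domains": e.n_domains,
                }
                for e in self.entries
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionPlan":
        return cls(tuple(PlanEntry(**e) for e in d["entries"]))


def default_plan() -> TransitionPlan:
    """A transition plan with every qualitative fate route populated.

    Joint-lamin domains mostly persist with some loss of lamin A;
    A-only domains mostly lose lamin A or switch to B; B-only domains
    mostly persist with a sizeable gain of lamin A; small de novo domains
    arise from inter-LADs.
    """
    mb = 1_000_000
    return TransitionPlan(
        (
            PlanEntry("A-B", "A-B", 8 * mb, 5),
            PlanEntry("A-B", "B-only", 2 * mb, 2),
            PlanEntry("A-only", "iLAD", 4 * mb, 4),
            PlanEntry("A-only", "B-only", 2 * mb, 2),
            PlanEntry("A-only", "A-B", 1 * mb, 1),
            PlanEntry("B-only", "B-only", 6 * mb, 4),
            PlanEntry("B-only", "A-B", 3 * mb, 2),
            PlanEntry("B-only", "iLAD", 1 * mb, 1),
            PlanEntry("iLAD", "A-only", 1 * mb, 1),
            PlanEntry("iLAD", "B-only", 2 * mb, 2),
            PlanEntry("iLAD", "A-B", 1 * mb, 1),
        )
    )


@dataclass
class SimulationConfig:
    """Knobs of all simulators; ``seed`` fixes every source of randomness."""

    seed: int = 0
    enrichment_log2: float = 2.0  # mean in-LAD log2 ChIP enrichment
    depth_per_bin: float = 50.0  # mean input count per bin
    dispersion: float = 0.1  # NB dispersion (variance = m + dispersion * m^2)
    radial_bias: dict[str, float] = field(
        default_factory=lambda: {"A-B": 0.9, "A-only": 0.7, "B-only": 0.9, "iLAD": 0.5}
    )
    expr_effect: dict[tuple[str, str], float] = field(default_factory=dict)
    expr_base_log2_mean: float = 2.0
    expr_base_log2_sd: float = 0.5
    expr_noise_sd: float = 0.2  # log2 sd of treated/control noise
    tad_tile_bp: int = 100_000  # one bead per tile of this size
    radial_concentration: float = 60.0  # Beta concentration of radial placement
    fish_spread: float = 0.05  # sd of normalized FISH spot positions

    def __post_init__(self) -> None:
        if self.depth_per_bin <= 0:
            raise ValueError("depth_per_bin must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for cls, target in self.radial_bias.items():
            class_index(cls)
            if not 0 < target <= 1:
                raise ValueError(f"radial_bias[{cls!r}] must be in (0, 1]")
        for (ci, cj) in self.expr_effect:
            class_index(ci)
            class_index(cj)
        if self.tad_tile_bp <= 0:
            raise ValueError("tad_tile_bp must be positive")


def _rng(cfg_seed: int, *stream: int) -> np.random.Generator:
    """Independent generator for a named sub-stream of the master seed."""
    return np.random.default_rng([cfg_seed, *stream])


# --------------------------------------------------------------------------
# planted architecture
# --------------------------------------------------------------------------


def plant_architecture(
    genome: Genome, plan: TransitionPlan, seed: int = 0
) -> tuple[ClassPartition, ClassPartition]:
    """Realise a transition plan exactly as two bin-aligned partitions.

    Domains are placed on bin boundaries, separated by at least one iLAD
    bin, at seeded random positions. The fate matrix of the returned
    (control, treated) pair reproduces the plan's bp table exactly.
    """
    bs = genome.bin_size
    rng = np.random.default_rng(seed)

    # expand entries into individual domains measured in bins
    domains: list[tuple[PlanEntry, int]] = []
    for entry in plan.entries:
        if entry.total_bp == 0:
            continue
        if entry.control_class == "iLAD" and entry.treated_class == "iLAD":
            continue  # background is already iLAD in both conditions
        if entry.total_bp % bs != 0:
            raise PlanError(f"entry {entry}: total_bp not a multiple of the bin size {bs}")
        nbins = entry.total_bp // bs
        if entry.n_domains > nbins:
            raise PlanError(f"entry {entry}: more domains than {bs}-bp bins")
        base, extra = divmod(nbins, entry.n_domains)
        sizes = [base + (1 if k < extra else 0) for k in range(entry.n_domains)]
        domains.extend((entry, s) for s in sizes)

    order = rng.permutation(len(domains))
    domains = [domains[i] for i in order]

    # balanced assignment to chromosomes, one spacer bin between domains;
    # always fill the emptiest chromosome so gaps stay as wide as possible
    per_chrom: dict[str, list[tuple[PlanEntry, int]]] = {c: [] for c in genome.names}
    used: dict[str, int] = {c: 0 for c in genome.names}
    for entry, nbins in domains:
        candidates = []
        for chrom in rng.permutation(genome.names):
            gap = 1 if per_chrom[chrom] else 0
            free = genome.n_bins(chrom) - used[chrom] - gap
            if free >= nbins:
                candidates.append((free, chrom, gap))
        if not candidates:
            raise PlanError(
                f"plan exceeds genome capacity at entry "
                f"{entry.control_class}->{entry.treated_class} ({entry.total_bp} bp)"
            )
        _free, chrom, gap = max(candidates, key=lambda t: t[0])
        per_chrom[chrom].append((entry, nbins))
        used[chrom] += gap + nbins

    runs_ctrl: dict[str, list[tuple[int, int, str]]] = {c: [] for c in genome.names}
    runs_trt: dict[str, list[tuple[int, int, str]]] = {c: [] for c in genome.names}
    for chrom in genome.names:
        placed_here = per_chrom[chrom]
        if not placed_here:
            continue
        nd = len(placed_here)
        slack = genome.n_bins(chrom) - used[chrom]
        extra = rng.multinomial(slack, np.full(nd + 1, 1.0 / (nd + 1)))
        cursor = int(extra[0])
        for k, (entry, nbins) in enumerate(placed_here):
            if k > 0:
                cursor += 1 + int(extra[k])
            start, end = cursor * bs, (cursor + nbins) * bs
            if entry.control_class != "iLAD":
                runs_ctrl[chrom].append((start, end, entry.control_class))
            if entry.treated_class != "iLAD":
                runs_trt[chrom].append((start, end, entry.treated_class))
            cursor += nbins
    return (
        ClassPartition.from_runs(genome, runs_ctrl),
        ClassPartition.from_runs(genome, runs_trt),
    )


# --------------------------------------------------------------------------
# binned ChIP counts
# --------------------------------------------------------------------------


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = m + dispersion * m^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean).astype(np.int64)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(np.int64)


def simulate_chip_counts(
    genome: Genome,
    truth: ClassPartition,
    lamin: str,
    cfg: SimulationConfig,
    stream: int = 0,
) -> tuple[CountTrack, CountTrack]:
    """Binned ChIP and input counts for one lamin over a planted truth.

    Bins inside classes containing the lamin (A in A-B/A-only, B in
    A-B/B-only) have ChIP mean ``depth * 2**enrichment_log2``; all other
    ChIP bins and every input bin have mean ``depth``. ``stream``
    separates the noise of independent datasets under one seed.
    """
    if lamin not in ("A", "B"):
        raise ValueError("lamin must be 'A' or 'B'")
    rng = _rng(cfg.seed, 1, {"A": 0, "B": 1}[lamin], stream)
    lamin_set = truth.lamin_set(lamin)
    bs = genome.bin_size
    chip: dict[str, np.ndarray] = {}
    inp: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        n = genome.n_bins(chrom)
        mids = np.arange(n) * bs + bs / 2.0
        in_lad = lamin_set.contains(chrom, mids)
        mean = np.where(in_lad, cfg.depth_per_bin * 2.0**cfg.enrichment_log2, cfg.depth_per_bin)
        chip[chrom] = _nb_sample(rng, mean, cfg.dispersion)
        inp[chrom] = _nb_sample(rng, np.full(n, cfg.depth_per_bin), cfg.dispersion)
    return CountTrack(bs, chip), CountTrack(bs, inp)


# --------------------------------------------------------------------------
# bead structures
# --------------------------------------------------------------------------


def genome_tiles(genome: Genome, tile_bp: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-size TAD tiling of the genome (last tile may be shorter)."""
    chroms, starts, ends = [], [], []
    for chrom, length in genome.chromosomes:
        s = np.arange(0, length, tile_bp)
        e = np.minimum(s + tile_bp, length)
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(e)
    return (
        np.asarray(chroms, dtype=object),
        np.concatenate(starts),
        np.concatenate(ends),
    )


def simulate_structures(
    genome: Genome,
    partitions: dict[str, ClassPartition],
    n_models: int,
    cfg: SimulationConfig,
    radius_um: float = DEFAULT_NUCLEUS_RADIUS_UM,
) -> dict[str, list[BeadStructure]]:
    """Bead-on-string ensembles with class-dependent radial bias.

    One bead per fixed-size tile; each bead's normalized radius is drawn
    from a Beta distribution whose mean is the radial-bias target of the
    bead's majority class, direction uniform on the sphere. Chain
    connectivity is not enforced — only radial statistics are consumed
    downstream.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    for c in CLASSES:
        if c not in cfg.radial_bias:
            raise ValueError(f"radial_bias missing class {c}")
    chroms, starts, ends = genome_tiles(genome, cfg.tad_tile_bp)
    n_beads = len(chroms)
    bead_radius = 0.1 * (ends - starts) / cfg.tad_tile_bp  # proportional to tile span

    out: dict[str, list[BeadStructure]] = {}
    for cond_idx, (cond, partition) in enumerate(sorted(partitions.items())):
        # majority class per bead decides its radial target
        targets = np.empty(n_beads)
        for k in range(n_beads):
            vec = partition.overlap_vector(str(chroms[k]), int(starts[k]), int(ends[k]))
            majority = CLASSES[int(np.argmax(vec))]
            targets[k] = cfg.radial_bias[majority]
        targets = np.clip(targets, 0.02, 0.995)
        a = targets * cfg.radial_concentration
        b = (1.0 - targets) * cfg.radial_concentration
        models = []
        for m in range(n_models):
            rng = _rng(cfg.seed, 2, cond_idx, m)
            r = rng.beta(a, b)
            v = rng.normal(size=(n_beads, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            centers = (r * radius_um)[:, None] * v
            models.append(
                BeadStructure(
                    model_id=f"{cond}_{m}",
                    chrom=chroms,
                    start=starts,
                    end=ends,
                    centers=centers,
                    bead_radius=bead_radius,
                    radius_um=radius_um,
                )
            )
        out[cond] = models
    return out


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------


def make_genes(genome: Genome, n_genes: int, seed: int = 0) -> list[GeneRecord]:
    """Random gene skeletons (uniform TSS, random strand, zero FPKM)."""
    rng = np.random.default_rng(seed)
    lengths = np.asarray([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=n_genes, p=probs)
    genes = []
    for k in range(n_genes):
        chrom, length = genome.chromosomes[chrom_idx[k]]
        tss = int(rng.integers(0, length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"gene{k:05d}", chrom, tss, strand, 0.0, 0.0))
    return genes


def simulate_expression(
    genes: list[GeneRecord],
    truth_ctrl: ClassPartition,
    truth_trt: ClassPartition,
    cfg: SimulationConfig,
) -> list[GeneRecord]:
    """FPKM pair per gene with a transition-dependent log2 shift.

    The multiplicative noise is mean-corrected so genes with no planted
    effect have treated FPKM centred on their control FPKM.
    """
    rng = _rng(cfg.seed, 3)
    ln2 = np.log(2.0)
    noise_bias = -0.5 * cfg.expr_noise_sd**2 * ln2  # E[2**(noise)] == 1
    out = []
    for g in genes:
        ci = truth_ctrl.label_at(g.chrom, g.tss)
        cj = truth_trt.label_at(g.chrom, g.tss)
        effect = cfg.expr_effect.get((ci, cj), 0.0)
        fpkm_c = float(2.0 ** rng.normal(cfg.expr_base_log2_mean, cfg.expr_base_log2_sd))
        shift = effect + rng.normal(noise_bias, cfg.expr_noise_sd)
        fpkm_t = float(fpkm_c * 2.0**shift)
        out.append(replace(g, fpkm_control=fpkm_c, fpkm_treated=fpkm_t))
    return out


# --------------------------------------------------------------------------
# FISH spots
# --------------------------------------------------------------------------


def simulate_fish_spots(
    targets: dict[str, float],
    n_nuclei: int,
    seed: int = 0,
    probe: str = "probe1",
    spread: float = 0.05,
) -> list[SpotRecord]:
    """Two spots (alleles) per nucleus around a target normalized position.

    ``targets`` maps condition -> target mean in (0, 1]. Nuclei are
    ellipses with randomized semi-axes and orientation; normalized spot
    positions follow a truncated normal on [0, 1).
    """
    from scipy.stats import truncnorm

    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    for cond, t in targets.items():
        if not 0 < t <= 1:
            raise ValueError(f"target for {cond!r} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    spots = []
    for cond in sorted(targets):
        target = targets[cond]
        lo, hi = (0.0 - target) / spread, (0.999 - target) / spread
        for k in range(n_nuclei):
            axis_a = float(rng.uniform(3.5, 5.5))
            axis_b = float(rng.uniform(3.0, axis_a))
            angle = float(rng.uniform(0.0, np.pi))
            center = tuple(rng.uniform(-1.0, 1.0, size=2))
            for allele in range(2):
                pos = float(truncnorm.rvs(lo, hi, loc=target, scale=spread, random_state=rng))
                theta = float(rng.uniform(0.0, 2 * np.pi))
                # point at normalized radius `pos` along ray theta in ellipse frame
                ex, ey = pos * axis_a * np.cos(theta), pos * axis_b * np.sin(theta)
                ca, sa = np.cos(angle), np.sin(angle)
                spot = (center[0] + ca * ex - sa * ey, center[1] + sa * ex + ca * ey)
                spots.append(
                    SpotRecord(
                        nucleus_id=f"{cond}_n{k:04d}",
                        condition=cond,
                        probe=probe,
                        spot_xy=spot,
                        center_xy=center,
                        axis_a=axis_a,
                        axis_b=axis_b,
                        angle=angle,
                    )
                )
    return spots
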