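import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ladkit.genome import Genome, default_genome
from ladkit.partition import CLASSES, ClassPartition
from ladkit.radial import (
    BeadStructure,
    SpotRecord,
    class_distance_stats,
    fish_compare,
    fish_normalized_position,
    map_classes_to_beads,
    normalized_distance,
    normalized_distances,
    probe_distance,
    transition_distance_stats,
)
from ladkit.synthetic import (
    PlanEntry,
    SimulationConfig,
    TransitionPlan,
    plant_architecture,
    simulate_structures,
)


def structure(centers, intervals=None, R=5.0, model_id="m0"):
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    if intervals is None:
        intervals = [("chr1", i * 100, (i + 1) * 100) for i in range(n)]
    return BeadStructure(
        model_id=model_id,
        chrom=np.asarray([iv[0] for iv in intervals], dtype=object),
        start=np.asarray([iv[1] for iv in intervals]),
        end=np.asarray([iv[2] for iv in intervals]),
        centers=centers,
        bead_radius=np.full(n, 0.1),
        radius_um=R,
    )


class TestNormalizedDistance:
    def test_three_four_five(self):
        assert normalized_distance((1.5, 2.0, 0.0), 5.0) == pytest.approx(0.5)

    def test_center_zero(self):
        assert normalized_distance((0.0, 0.0, 0.0), 5.0) == 0.0

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            normalized_distance((3.0, 4.0, 0.0), 5.0)

    def test_structure_vectorized(self):
        s = structure([[0, 0, 2.5], [3, 0, 0]])
        assert normalized_distances(s).tolist() == [0.5, 0.6]

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, factor):
        d1 = normalized_distance((1.0, 2.0, 1.5), 5.0)
        d2 = normalized_distance((factor, 2 * factor, 1.5 * factor), 5.0 * factor)
        assert d1 == pytest.approx(d2)


class TestMapClasses:
    @pytest.fixture
    def g2m(self):
        return Genome((("chr1", 2_000_000),), bin_size=100_000)

    def test_single_class_bead(self, g2m):
        part = ClassPartition.from_runs(g2m, {"chr1": [(0, 400_000, "A-only")]})
        s = structure([[0, 0, 0]], intervals=[("chr1", 0, 1_000_000)])
        member = map_classes_to_beads(part, s)
        # carries A-only; iLAD share of the bead does not make it inter-LAD
        assert member[0].tolist() == [False, True, False, False]

    def test_two_class_bead(self, g2m):
        part = ClassPartition.from_runs(
            g2m, {"chr1": [(0, 400_000, "A-only"), (400_000, 900_000, "B-only")]}
        )
        s = structure([[0, 0, 0]], intervals=[("chr1", 0, 1_000_000)])
        member = map_classes_to_beads(part, s)
        assert member[0].tolist() == [False, True, True, False]

    def test_ilad_only_bead(self, g2m):
        part = ClassPartition.all_ilad(g2m)
        s = structure([[0, 0, 0]], intervals=[("chr1", 0, 1_000_000)])
        member = map_classes_to_beads(part, s)
        assert member[0].tolist() == [False, False, False, True]

    def test_counts_match_per_base_tallies(self, g2m):
        part = ClassPartition.from_runs(
            g2m,
            {"chr1": [(100_000, 500_000, "A-B"), (1_200_000, 1_500_000, "B-only")]},
        )
        beads = [("chr1", i * 200_000, (i + 1) * 200_000) for i in range(10)]
        s = structure([[0, 0, 0]] * 10, intervals=beads)
        member = map_classes_to_beads(part, s)
        from _oracles import per_base_labels

        labels = per_base_labels(part, "chr1")
        for k, (_, bs, be) in enumerate(beads):
            for ci in range(3):  # lamin classes by >= 1 bp presence
                assert member[k, ci] == ((labels[bs:be] == ci).sum() >= 1)


class TestClassDistanceStats:
    def test_single_structure_single_class(self):
        g = Genome((("chr1", 200),), bin_size=100)
        part = ClassPartition.from_runs(g, {"chr1": [(0, 200, "A-only")]})
        s = structure([[0, 0, 2.5], [0, 3.0, 0]], intervals=[("chr1", 0, 100), ("chr1", 100, 200)])
        summary, _ = class_distance_stats([s], part)
        row = summary.set_index("lad_class").loc["A-only"]
        assert row["n"] == 2 and row["mean"] == pytest.approx(0.55)

    def test_pooled_n_sums_over_models(self):
        g = Genome((("chr1", 100),), bin_size=100)
        part = ClassPartition.from_runs(g, {"chr1": [(0, 100, "B-only")]})
        ss = [structure([[0, 0, 1.0]], intervals=[("chr1", 0, 100)], model_id=f"m{i}") for i in range(7)]
        summary, _ = class_distance_stats(ss, part)
        assert summary.set_index("lad_class").loc["B-only", "n"] == 7

    def test_uniform_random_classes_show_no_ordering(self):
        # all classes at the same radial target: pooled means within 0.02
        g = Genome((("chr1", 10_000_000),), bin_size=10_000)
        rng = np.random.default_rng(0)
        runs = {}
        labels = rng.integers(0, 4, 1000)
        runs["chr1"] = [
            (i * 10_000, (i + 1) * 10_000, CLASSES[labels[i]]) for i in range(1000)
        ]
        part = ClassPartition.from_runs(g, runs)
        cfg = SimulationConfig(
            seed=0,
            radial_bias={c: 0.6 for c in CLASSES},
            tad_tile_bp=10_000,
        )
        structs = simulate_structures(g, {"x": part}, 10, cfg)["x"]
        summary, _ = class_distance_stats(structs, part)
        means = summary["mean"].to_numpy()
        assert np.nanmax(means) - np.nanmin(means) < 0.02


class TestTransitionDistanceStats:
    def test_identical_ensembles_null(self):
        g = Genome((("chr1", 1_000_000),), bin_size=100_000)
        pc = ClassPartition.from_runs(g, {"chr1": [(0, 500_000, "A-B")]})
        rng = np.random.default_rng(1)
        ss = [
            structure(rng.normal(0, 1, (10, 3)), intervals=[("chr1", i * 100_000, (i + 1) * 100_000) for i in range(10)], model_id=f"m{i}")
            for i in range(3)
        ]
        df = transition_distance_stats(ss, ss, pc, pc)
        with_data = df[df.n_ctrl > 0]
        assert (with_data.pvalue == 1.0).all()
        assert (with_data.direction == "none").all()

    def test_pair_numbering_row_major(self):
        g = Genome((("chr1", 100_000),), bin_size=100_000)
        pc = ClassPartition.all_ilad(g)
        s = [structure([[0, 0, 1]], intervals=[("chr1", 0, 100_000)])]
        df = transition_distance_stats(s, s, pc, pc)
        assert df.pair.tolist() == list(range(1, 17))
        assert df.iloc[0].control_class == "A-B" and df.iloc[0].treated_class == "A-B"
        assert df.iloc[15].control_class == "iLAD" and df.iloc[15].treated_class == "iLAD"
        # fate-pair semantics used in the report figures
        assert df.iloc[6].control_class == "A-only" and df.iloc[6].treated_class == "B-only"

    def test_empty_pair_reported(self):
        g = Genome((("chr1", 100_000),), bin_size=100_000)
        pc = ClassPartition.all_ilad(g)
        s = [structure([[0, 0, 1]], intervals=[("chr1", 0, 100_000)])]
        df = transition_distance_stats(s, s, pc, pc).set_index(["control_class", "treated_class"])
        assert df.loc[("A-B", "A-only"), "n_ctrl"] == 0


class TestProbeDistance:
    def test_probe_in_bead(self):
        s = structure([[0, 0, 2.5], [3, 0, 0]])
        d = probe_distance(("chr1", 0, 100), [s])
        assert d.tolist() == [0.5]

    def test_one_distance_per_model(self):
        ss = [structure([[0, 0, float(i)]], intervals=[("chr1", 0, 100)], model_id=f"m{i}") for i in range(4)]
        assert len(probe_distance(("chr1", 10, 20), ss)) == 4

    def test_outside_beads_error(self):
        s = structure([[0, 0, 1]])
        with pytest.raises(ValueError):
            probe_distance(("chr2", 0, 100), [s])

    def test_matches_single_class_bead_distribution(self):
        g = Genome((("chr1", 100_000),), bin_size=100_000)
        part = ClassPartition.from_runs(g, {"chr1": [(0, 100_000, "B-only")]})
        rng = np.random.default_rng(0)
        ss = [
            structure([rng.normal(0, 1, 3)], intervals=[("chr1", 0, 100_000)], model_id=f"m{i}")
            for i in range(5)
        ]
        probe = probe_distance(("chr1", 40_000, 60_000), ss)
        summary, _ = class_distance_stats(ss, part)
        assert summary.set_index("lad_class").loc["B-only", "mean"] == pytest.approx(probe.mean())


class TestFishGeometry:
    def test_circle_half_radius(self):
        s = SpotRecord("n1", "c", "p", (1.0, 0.0), (0.0, 0.0), 2.0, 2.0)
        assert fish_normalized_position(s) == pytest.approx(0.5)

    def test_center_zero(self):
        s = SpotRecord("n1", "c", "p", (0.3, -0.7), (0.3, -0.7), 4.0, 2.0)
        assert fish_normalized_position(s) == 0.0

    def test_ellipse_worked_example(self):
        s = SpotRecord("n1", "c", "p", (2.0, 0.0), (0.0, 0.0), 4.0, 2.0)
        assert abs(fish_normalized_position(s) - 0.5) < 1e-12

    def test_outside_rejected(self):
        s = SpotRecord("n1", "c", "p", (5.0, 0.0), (0.0, 0.0), 4.0, 2.0)
        with pytest.raises(ValueError):
            fish_normalized_position(s)

    @given(st.floats(0.1, 5.0), st.floats(0.0, 0.99), st.floats(0, 2 * np.pi))
    @settings(max_examples=100, deadline=None)
    def test_circle_reduces_to_radius_ratio(self, r, frac, theta):
        spot = (frac * r * np.cos(theta), frac * r * np.sin(theta))
        s = SpotRecord("n", "c", "p", spot, (0.0, 0.0), r, r)
        assert fish_normalized_position(s) == pytest.approx(frac, abs=1e-9)

    def test_rotation_consistency(self):
        # rotating the ellipse and the spot together leaves the position fixed
        base = SpotRecord("n", "c", "p", (2.0, 0.0), (0.0, 0.0), 4.0, 2.0)
        phi = 0.7
        rotated_spot = (2.0 * np.cos(phi), 2.0 * np.sin(phi))
        rot = SpotRecord("n", "c", "p", rotated_spot, (0.0, 0.0), 4.0, 2.0, angle=phi)
        assert fish_normalized_position(rot) == pytest.approx(fish_normalized_position(base))


class TestFishCompare:
    def _spots(self, positions, condition, probe="p1"):
        return [
            SpotRecord(f"n{i}", condition, probe, (p * 3.0, 0.0), (0.0, 0.0), 3.0, 3.0)
            for i, p in enumerate(positions)
        ]

    def test_identical_sets_null(self):
        pos = [0.2, 0.4, 0.6, 0.8]
        df = fish_compare(self._spots(pos, "ctrl"), self._spots(pos, "trt"))
        row = df.iloc[0]
        assert row.pvalue == 1.0 and row.delta_mean == 0.0 and row.direction == "none"

    def test_planted_peripheral_shift(self):
        rng = np.random.default_rng(0)
        ctrl = np.clip(rng.normal(0.7, 0.05, 200), 0, 0.99)
        trt = np.clip(rng.normal(0.85, 0.05, 200), 0, 0.99)
        df = fish_compare(self._spots(ctrl, "ctrl"), self._spots(trt, "trt"))
        row = df.iloc[0]
        assert row.pvalue < 0.01 and row.direction == "periphery"

    def test_counts_reported(self):
        df = fish_compare(self._spots([0.1, 0.2, 0.3], "c"), self._spots([0.1, 0.5], "t"))
        assert df.iloc[0].n_ctrl == 3 and df.iloc[0].n_trt == 2

    def test_missing_probe_warns(self):
        with pytest.warns(UserWarning):
            df = fish_compare(self._spots([0.1, 0.2], "c", probe="pX"), [])
        assert np.isnan(df.iloc[0].pvalue)


class TestSimulatedEnsembleOrdering:
    def test_fig_like_ordering_recovered(self):
        g = default_genome()
        mb = 1_000_000
        plan = TransitionPlan(
            (
                PlanEntry("A-B", "A-B", 10 * mb, 4),
                PlanEntry("A-only", "A-only", 10 * mb, 4),
                PlanEntry("B-only", "B-only", 10 * mb, 4),
            )
        )
        pc, _ = plant_architecture(g, plan, seed=5)
        cfg = SimulationConfig(
            seed=5,
            radial_bias={"iLAD": 0.5, "A-only": 0.7, "A-B": 0.9, "B-only": 0.9},
        )
        structs = simulate_structures(g, {"control": pc}, 30, cfg)["control"]
        summary, pairwise = class_distance_stats(structs, pc)
        means = summary.set_index("lad_class")["mean"]
        assert means["iLAD"] < means["A-only"] < means["A-B"]
        assert means["A-only"] < means["B-only"]
        key = pairwise.set_index(["class_1", "class_2"])
        for pair in [("A-B", "A-only"), ("A-B", "iLAD"), ("A-only", "B-only"),
                     ("A-only", "iLAD"), ("B-only", "iLAD")]:
            assert key.loc[pair, "significant"]
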