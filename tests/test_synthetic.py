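import numpy as np
import pytest

from _oracles import per_base_fate_counts
from ladkit.algebra import fate_matrix
from ladkit.genome import Genome, default_genome
from ladkit.partition import CLASSES
from ladkit.synthetic import (
    PlanEntry,
    PlanError,
    SimulationConfig,
    TransitionPlan,
    default_plan,
    make_genes,
    plant_architecture,
    simulate_chip_counts,
    simulate_expression,
    simulate_fish_spots,
    simulate_structures,
)

MB = 1_000_000


class TestPlanValidation:
    def test_bad_class_rejected(self):
        with pytest.raises(ValueError):
            PlanEntry("A-wat", "B-only", 100, 1)

    def test_zero_domains_rejected(self):
        with pytest.raises(PlanError):
            PlanEntry("A-B", "A-B", 100, 0)

    def test_bp_table_excludes_background(self):
        plan = TransitionPlan((PlanEntry("iLAD", "iLAD", 5 * MB, 1),))
        assert plan.bp_table().sum() == 0


class TestPlantArchitecture:
    def test_single_domain_exact(self):
        g = Genome((("chr1", 10 * MB),), bin_size=10_000)
        plan = TransitionPlan((PlanEntry("A-only", "B-only", 1 * MB, 1),))
        pc, pt = plant_architecture(g, plan, seed=0)
        assert pc.coverage()["A-only"] == 1 * MB
        assert pc.coverage()["iLAD"] == 9 * MB
        assert pt.coverage()["B-only"] == 1 * MB
        # same region switches class
        assert pc.class_set("A-only") == pt.class_set("B-only")

    def test_empty_plan_all_ilad(self):
        g = Genome((("chr1", 10 * MB),), bin_size=10_000)
        pc, pt = plant_architecture(g, TransitionPlan(()), seed=0)
        assert pc.coverage()["iLAD"] == 10 * MB
        assert pt.coverage()["iLAD"] == 10 * MB

    def test_scaled_default_plan_fate_matches_oracle(self):
        # default plan scaled 1/100 on a small genome; verify by per-base count
        g = Genome(tuple((f"chr{i}", 300_000) for i in range(1, 5)), bin_size=100)
        entries = tuple(
            PlanEntry(e.control_class, e.treated_class, e.total_bp // 100, e.n_domains)
            for e in default_plan().entries
        )
        plan = TransitionPlan(entries)
        pc, pt = plant_architecture(g, plan, seed=3)
        expect = plan.expected_fate_counts(g)
        assert np.array_equal(fate_matrix(pc, pt).counts, expect)
        assert np.array_equal(per_base_fate_counts(pc, pt), expect)

    def test_deterministic(self):
        g = default_genome()
        pc1, pt1 = plant_architecture(g, default_plan(), seed=42)
        pc2, pt2 = plant_architecture(g, default_plan(), seed=42)
        assert pc1 == pc2 and pt1 == pt2

    def test_capacity_error_names_entry(self):
        g = Genome((("chr1", 1 * MB),), bin_size=10_000)
        plan = TransitionPlan((PlanEntry("A-B", "A-B", 2 * MB, 1),))
        with pytest.raises(PlanError, match="A-B"):
            plant_architecture(g, plan, seed=0)

    def test_domains_bin_aligned_and_separated(self):
        g = Genome((("chr1", 10 * MB),), bin_size=10_000)
        plan = TransitionPlan((PlanEntry("A-B", "A-B", 1 * MB, 4),))
        pc, _ = plant_architecture(g, plan, seed=1)
        lads = pc.class_set("A-B")
        arr = lads.intervals("chr1")
        assert np.all(arr % 10_000 == 0)
        assert np.all(arr[1:, 0] - arr[:-1, 1] >= 10_000)  # >= 1 iLAD bin apart

    def test_fractional_bin_rejected(self):
        g = Genome((("chr1", 10 * MB),), bin_size=10_000)
        with pytest.raises(PlanError):
            plant_architecture(
                g, TransitionPlan((PlanEntry("A-B", "A-B", 15_000, 1),)), seed=0
            )


class TestRoundTripProperty:
    def test_random_plans_roundtrip(self):
        g = default_genome()
        rng = np.random.default_rng(99)
        for _ in range(20):
            entries = []
            for ci in CLASSES:
                for cj in CLASSES:
                    if (ci, cj) == ("iLAD", "iLAD") or rng.random() < 0.5:
                        continue
                    nbins = int(rng.integers(1, 80))
                    nd = int(rng.integers(1, min(4, nbins) + 1))
                    entries.append(PlanEntry(ci, cj, nbins * 10_000, nd))
            plan = TransitionPlan(tuple(entries))
            pc, pt = plant_architecture(g, plan, seed=int(rng.integers(1 << 31)))
            assert np.array_equal(
                fate_matrix(pc, pt).counts, plan.expected_fate_counts(g)
            )


@pytest.fixture(scope="module")
def planted_a_only():
    g = default_genome()
    plan = TransitionPlan((PlanEntry("A-only", "A-only", 40 * MB, 8),))
    pc, _ = plant_architecture(g, plan, seed=0)
    return g, pc


@pytest.fixture(scope="module")
def planted_switch():
    g = default_genome()
    plan = TransitionPlan(
        (PlanEntry("A-only", "B-only", 25 * MB, 5), PlanEntry("B-only", "B-only", 20 * MB, 4))
    )
    pc, pt = plant_architecture(g, plan, seed=8)
    return g, pc, pt


class TestSimulateChipCounts:

    def test_no_signal_at_zero_enrichment(self, planted_a_only):
        g, pc = planted_a_only
        cfg = SimulationConfig(seed=0, enrichment_log2=0.0)
        chip, _ = simulate_chip_counts(g, pc, "A", cfg)
        mids = np.arange(g.n_bins("chr1")) * g.bin_size + g.bin_size / 2
        in_lad = pc.lamin_set("A").contains("chr1", mids)
        x = chip.data["chr1"][in_lad].astype(float)
        y = chip.data["chr1"][~in_lad].astype(float)
        se = np.sqrt(x.var() / len(x) + y.var() / len(y))
        assert abs(x.mean() - y.mean()) < 3 * se

    def test_enrichment_ratio_recovered(self, planted_a_only):
        g, pc = planted_a_only
        cfg = SimulationConfig(seed=1, enrichment_log2=2.0, depth_per_bin=50.0)
        chip, _ = simulate_chip_counts(g, pc, "A", cfg)
        in_vals, out_vals = [], []
        lamin = pc.lamin_set("A")
        for chrom, _ in g.chromosomes:
            mids = np.arange(g.n_bins(chrom)) * g.bin_size + g.bin_size / 2
            mask = lamin.contains(chrom, mids)
            in_vals.append(chip.data[chrom][mask])
            out_vals.append(chip.data[chrom][~mask])
        in_vals = np.concatenate(in_vals)
        out_vals = np.concatenate(out_vals)
        assert len(in_vals) >= 4000
        assert 3.4 < in_vals.mean() / out_vals.mean() < 4.7

    def test_lamin_b_uses_b_classes(self):
        g = Genome((("chr1", 10 * MB),), bin_size=10_000)
        plan = TransitionPlan((PlanEntry("A-only", "A-only", 2 * MB, 1),))
        pc, _ = plant_architecture(g, plan, seed=0)
        cfg = SimulationConfig(seed=0, enrichment_log2=3.0)
        chip_b, _ = simulate_chip_counts(g, pc, "B", cfg)
        # no B-class bases planted: lamin B track is flat noise
        mids = np.arange(g.n_bins("chr1")) * g.bin_size + g.bin_size / 2
        in_a = pc.lamin_set("A").contains("chr1", mids)
        x = chip_b.data["chr1"][in_a].astype(float)
        y = chip_b.data["chr1"][~in_a].astype(float)
        assert abs(x.mean() - y.mean()) < 3 * np.sqrt(x.var() / len(x) + y.var() / len(y))

    def test_deterministic(self, planted_a_only):
        g, pc = planted_a_only
        cfg = SimulationConfig(seed=7)
        a1, b1 = simulate_chip_counts(g, pc, "A", cfg)
        a2, b2 = simulate_chip_counts(g, pc, "A", cfg)
        assert np.array_equal(a1.data["chr1"], a2.data["chr1"])
        assert np.array_equal(b1.data["chr1"], b2.data["chr1"])

    def test_input_mean_matches_depth(self, planted_a_only):
        g, pc = planted_a_only
        cfg = SimulationConfig(seed=3, depth_per_bin=50.0)
        _, inp = simulate_chip_counts(g, pc, "A", cfg)
        total_bins = sum(len(v) for v in inp.data.values())
        assert total_bins >= 10_000
        mean = inp.total() / total_bins
        assert abs(mean - 50.0) / 50.0 < 0.02


class TestSimulateStructures:
    def test_single_model_inside_sphere(self):
        g = Genome((("chr1", 2 * MB),), bin_size=10_000)
        pc, _ = plant_architecture(g, TransitionPlan(()), seed=0)
        cfg = SimulationConfig(seed=0)
        out = simulate_structures(g, {"x": pc}, 1, cfg)
        assert len(out["x"]) == 1
        s = out["x"][0]
        assert np.all(np.linalg.norm(s.centers, axis=1) < s.radius_um)

    def test_class_target_recovered(self):
        g = default_genome()
        plan = TransitionPlan((PlanEntry("B-only", "B-only", 12 * MB, 4),))
        pc, _ = plant_architecture(g, plan, seed=1)
        cfg = SimulationConfig(seed=1, radial_bias={"A-B": 0.5, "A-only": 0.5, "B-only": 0.9, "iLAD": 0.5})
        structs = simulate_structures(g, {"x": pc}, 20, cfg)["x"]
        from ladkit.radial import pooled_class_distances

        pooled = pooled_class_distances(structs, pc)
        assert 0.85 < pooled["B-only"].mean() < 0.95
        assert abs(pooled["iLAD"].mean() - 0.5) < 0.05

    def test_equal_targets_indistinguishable(self):
        g = default_genome()
        plan = TransitionPlan(
            (PlanEntry("A-B", "A-B", 10 * MB, 3), PlanEntry("B-only", "B-only", 10 * MB, 3))
        )
        pc, _ = plant_architecture(g, plan, seed=2)
        cfg = SimulationConfig(seed=2, radial_bias={c: 0.7 for c in CLASSES})
        structs = simulate_structures(g, {"x": pc}, 15, cfg)["x"]
        from ladkit.radial import pooled_class_distances

        pooled = pooled_class_distances(structs, pc)
        means = [v.mean() for v in pooled.values() if len(v)]
        assert max(means) - min(means) < 0.03

    def test_invalid_bias_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(radial_bias={"A-B": 1.5, "A-only": 0.5, "B-only": 0.5, "iLAD": 0.5})

    def test_deterministic(self):
        g = Genome((("chr1", 2 * MB),), bin_size=10_000)
        pc, _ = plant_architecture(g, TransitionPlan(()), seed=0)
        cfg = SimulationConfig(seed=4)
        s1 = simulate_structures(g, {"x": pc}, 2, cfg)["x"]
        s2 = simulate_structures(g, {"x": pc}, 2, cfg)["x"]
        for a, b in zip(s1, s2):
            assert np.array_equal(a.centers, b.centers)


class TestSimulateExpression:
    def test_zero_effect_centred(self, planted_switch):
        g, pc, pt = planted_switch
        cfg = SimulationConfig(seed=1)
        genes = simulate_expression(make_genes(g, 1500, seed=1), pc, pt, cfg)
        delta = np.asarray([x.fpkm_treated - x.fpkm_control for x in genes])
        se = delta.std(ddof=1) / np.sqrt(len(delta))
        assert abs(delta.mean()) < 2 * se

    def test_planted_effect_recovered(self, planted_switch):
        g, pc, pt = planted_switch
        cfg = SimulationConfig(seed=2, expr_effect={("A-only", "B-only"): -1.0})
        genes = simulate_expression(make_genes(g, 1200, seed=2), pc, pt, cfg)
        lfc = [
            np.log2(x.fpkm_treated / x.fpkm_control)
            for x in genes
            if pc.label_at(x.chrom, x.tss) == "A-only"
            and pt.label_at(x.chrom, x.tss) == "B-only"
        ]
        assert len(lfc) >= 150
        assert -1.3 < np.mean(lfc) < -0.7

    def test_deterministic(self, planted_switch):
        g, pc, pt = planted_switch
        cfg = SimulationConfig(seed=5)
        skel = make_genes(g, 100, seed=5)
        g1 = simulate_expression(skel, pc, pt, cfg)
        g2 = simulate_expression(skel, pc, pt, cfg)
        assert g1 == g2


class TestSimulateFishSpots:
    def test_two_spots_per_nucleus(self):
        spots = simulate_fish_spots({"control": 0.5}, 100, seed=0)
        assert len(spots) == 200

    def test_target_one_all_peripheral(self):
        from ladkit.radial import fish_normalized_position

        spots = simulate_fish_spots({"control": 1.0}, 200, seed=1)
        pos = [fish_normalized_position(s) for s in spots]
        assert min(pos) >= 0.8

    def test_target_half_mean(self):
        from ladkit.radial import fish_normalized_position

        spots = simulate_fish_spots({"control": 0.5}, 1000, seed=2)
        pos = np.asarray([fish_normalized_position(s) for s in spots])
        assert 0.45 < pos.mean() < 0.55

    def test_spots_inside_boundaries(self):
        from ladkit.radial import fish_normalized_position

        spots = simulate_fish_spots({"c": 0.9, "t": 0.2}, 50, seed=3)
        for s in spots:  # fish_normalized_position raises if outside
            assert 0.0 <= fish_normalized_position(s) <= 1.0

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_fish_spots({"c": 1.2}, 10, seed=0)
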