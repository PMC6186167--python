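import itertools
from collections import Counter

import numpy as np
import pytest

from mycotree import design as dz
from mycotree.design import Composition, Treatment


class TestValidTreatments:
    def test_eight_cells(self):
        ts = dz.valid_treatments()
        assert len(ts) == 8

    def test_contains_two_both(self):
        assert Treatment(2, "Both") in dz.valid_treatments()

    def test_excludes_mono_both(self):
        assert Treatment(1, "Both") not in dz.valid_treatments()

    def test_matches_grid_minus_impossible_cell(self):
        expected = {
            (r, lvl)
            for r in (1, 2, 4)
            for lvl in ("AMF", "EMF", "Both")
            if not (r == 1 and lvl == "Both")
        }
        assert {tuple(t) for t in dz.valid_treatments()} == expected


class TestEnumerateCompositions:
    @pytest.mark.parametrize(
        "treatment,expected",
        [
            (Treatment(2, "AMF"), 10),  # C(5,2)
            (Treatment(2, "EMF"), 10),
            (Treatment(2, "Both"), 25),  # 5 x 5
            (Treatment(4, "AMF"), 5),  # C(5,4)
            (Treatment(4, "Both"), 100),  # C(5,2)^2
            (Treatment(1, "AMF"), 5),
        ],
    )
    def test_counts_match_binomials(self, pools, treatment, expected):
        comps = dz.enumerate_compositions(pools, treatment)
        assert len(comps) == expected
        assert len(set(comps)) == expected

    def test_both_split_is_balanced(self, pools):
        for comp in dz.enumerate_compositions(pools, Treatment(4, "Both")):
            n_amf = sum(1 for s in comp.species if s in pools.amf_pool)
            assert n_amf == 2

    def test_invalid_treatment_rejected(self, pools):
        with pytest.raises(ValueError, match="invalid treatment"):
            dz.enumerate_compositions(pools, Treatment(1, "Both"))

    def test_matches_bruteforce_for_two_both(self, pools):
        comps = dz.enumerate_compositions(pools, Treatment(2, "Both"))
        brute = {
            tuple(sorted((a, e)))
            for a in pools.amf_pool
            for e in pools.emf_pool
        }
        assert {c.species for c in comps} == brute


class TestBalancedSubset:
    def test_two_both_each_species_twice(self, pools):
        comps = dz.enumerate_compositions(pools, Treatment(2, "Both"))
        subset = dz.select_balanced_subset(comps, 10, seed=0)
        counts = Counter(s for c in subset for s in c.species)
        assert all(v == 2 for v in counts.values())
        assert len(counts) == 10

    def test_four_both_each_species_four_times(self, pools):
        comps = dz.enumerate_compositions(pools, Treatment(4, "Both"))
        subset = dz.select_balanced_subset(comps, 10, seed=0)
        counts = Counter(s for c in subset for s in c.species)
        assert all(v == 4 for v in counts.values())

    def test_full_enumeration_returned_unchanged(self, pools):
        comps = dz.enumerate_compositions(pools, Treatment(2, "Both"))
        assert dz.select_balanced_subset(comps, len(comps), seed=0) == comps

    def test_infeasible_balance_rejected(self, pools):
        comps = dz.enumerate_compositions(pools, Treatment(2, "Both"))
        with pytest.raises(ValueError, match="infeasible"):
            dz.select_balanced_subset(comps, 7, seed=0)  # 14 slots / 10 species

    def test_deterministic_for_seed(self, pools):
        comps = dz.enumerate_compositions(pools, Treatment(4, "Both"))
        s1 = dz.select_balanced_subset(comps, 10, seed=5)
        s2 = dz.select_balanced_subset(comps, 10, seed=5)
        assert s1 == s2


class TestAssembleDesign:
    def test_plot_counts(self, default_design):
        by_rich = Counter(p.treatment.richness for p in default_design)
        assert len(default_design) == 80
        assert by_rich[1] == 20
        assert by_rich[2] == 30
        assert by_rich[4] == 30

    def test_monoculture_replication(self, default_design):
        monos = [p for p in default_design if p.treatment.richness == 1]
        counts = Counter(p.composition.species[0] for p in monos)
        assert len(counts) == 10
        assert all(v == 2 for v in counts.values())

    def test_treatment_cell_sizes(self, default_design):
        cells = Counter(p.treatment for p in default_design)
        assert cells == {
            Treatment(1, "AMF"): 10,
            Treatment(1, "EMF"): 10,
            Treatment(2, "AMF"): 10,
            Treatment(2, "EMF"): 10,
            Treatment(2, "Both"): 10,
            Treatment(4, "AMF"): 10,
            Treatment(4, "EMF"): 10,
            Treatment(4, "Both"): 10,
        }

    def test_species_balance_across_design(self, default_design):
        assert dz.check_design_balance(default_design) == []

    def test_plot_ids_unique_and_stable(self, pools):
        d1 = dz.assemble_design(pools, seed=9)
        d2 = dz.assemble_design(pools, seed=9)
        assert [p.plot_id for p in d1] == [p.plot_id for p in d2]
        assert [p.composition for p in d1] == [p.composition for p in d2]
        assert len({p.plot_id for p in d1}) == 80

    def test_rule_violating_pool_sizes_rejected(self, pools):
        rules = {Treatment(4, "AMF"): dz.ReplicationRule("subset", subset_size=99)}
        with pytest.raises(ValueError):
            dz.assemble_design(pools, rules=rules, seed=0)


def _toy_bruteforce_feasible(counts, dims):
    """Exhaustive search over multiset placements of a tiny grid.

    Cells beyond the plot count stay empty (``None`` symbols).
    """
    nrows, ncols = dims
    cells = [(r, c) for r in range(nrows) for c in range(ncols)]
    symbols = [t for t, n in sorted(counts.items()) for _ in range(n)]
    symbols += [None] * (len(cells) - len(symbols))
    seen = set()
    for perm in itertools.permutations(symbols):
        if perm in seen:
            continue
        seen.add(perm)
        grid = {c: t for c, t in zip(cells, perm) if t is not None}
        if not dz.check_grid_constraints(grid, dims):
            return True
    return False


class TestRandomizeLayout:
    def test_passes_independent_checker(self, placed_design):
        assert dz.check_layout_constraints(placed_design) == []

    def test_deterministic_for_seed(self, default_design):
        p1 = dz.randomize_layout(default_design, seed=7)
        p2 = dz.randomize_layout(default_design, seed=7)
        assert [(p.plot_id, p.block, p.grid_cell) for p in p1] == [
            (p.plot_id, p.block, p.grid_cell) for p in p2
        ]

    def test_blocks_balanced(self, placed_design):
        per_block = Counter(p.block for p in placed_design)
        assert per_block == {1: 40, 2: 40}
        for block in (1, 2):
            cells = Counter(
                p.treatment for p in placed_design if p.block == block
            )
            assert all(v == 5 for v in cells.values())

    def test_replicates_split_across_blocks(self, placed_design):
        by_comp = {}
        for p in placed_design:
            by_comp.setdefault((p.treatment, p.composition.species), []).append(p.block)
        for blocks in by_comp.values():
            if len(blocks) == 2:
                assert sorted(blocks) == [1, 2]

    def test_checker_catches_adjacent_same_treatment(self):
        t = Treatment(1, "AMF")
        grid = {(0, 0): t, (0, 1): t}
        violations = dz.check_grid_constraints(grid, (3, 3))
        assert any("adjacent" in v for v in violations)

    def test_checker_catches_triple_in_neighbourhood(self):
        a, b = Treatment(1, "AMF"), Treatment(1, "EMF")
        # three 'a' cells around the focal (1,1), none mutually adjacent
        grid = {(1, 1): b, (0, 0): a, (0, 2): a, (2, 1): a}
        # (2,1) is adjacent to nothing with treatment a? (0,*) rows are not
        # Moore-adjacent to row 2 -> only the neighbourhood rule can fire
        violations = dz.check_grid_constraints(grid, (3, 3))
        assert any("appears 3 times" in v for v in violations)

    def test_toy_grid_agrees_with_bruteforce_feasible(self):
        # 2 treatments x 3 plots on a 3x3 grid (3 cells empty): brute force
        # proves a valid layout exists, and the randomiser finds one
        counts = {Treatment(1, "AMF"): 3, Treatment(1, "EMF"): 3}
        dims = (3, 3)
        assert _toy_bruteforce_feasible(counts, dims)
        rng = np.random.default_rng(0)
        grid = dz._place_treatments(counts, dims, rng)
        assert dz.check_grid_constraints(grid, dims) == []
        assert len(grid) == 6

    def test_toy_grid_agrees_with_bruteforce_infeasible(self):
        # a full 3x3 grid is infeasible for any 3x3 treatment multiset: the
        # centre cell touches all others, so its treatment repeats adjacently
        counts = {
            Treatment(1, "AMF"): 3,
            Treatment(1, "EMF"): 3,
            Treatment(2, "AMF"): 3,
        }
        dims = (3, 3)
        assert not _toy_bruteforce_feasible(counts, dims)
        rng = np.random.default_rng(0)
        with pytest.raises(RuntimeError, match="constraint"):
            dz._place_treatments(counts, dims, rng, max_restarts=50)

    def test_overfull_grid_rejected(self, default_design):
        with pytest.raises((ValueError, RuntimeError)):
            dz.randomize_layout(default_design, grid_dims=(4, 5), seed=0)


class TestPlantingLayout:
    def test_monoculture(self, pools):
        comp = Composition((pools.amf_pool[0],), Treatment(1, "AMF"))
        lay = dz.planting_layout(comp, seed=0)
        assert len(lay.positions) == 140
        assert lay.species_counts() == {pools.amf_pool[0]: 140}
        assert lay.n_core() == 64

    def test_richness_two_split_and_adjacency(self, pools):
        comp = Composition(pools.amf_pool[:2], Treatment(2, "AMF"))
        lay = dz.planting_layout(comp, seed=1)
        assert sorted(lay.species_counts().values()) == [70, 70]
        self._assert_no_orthogonal_conspecifics(lay)

    def test_richness_four_split_and_adjacency(self, pools):
        comp = Composition(
            pools.amf_pool[:2] + pools.emf_pool[:2], Treatment(4, "Both")
        )
        lay = dz.planting_layout(comp, seed=2)
        assert sorted(lay.species_counts().values()) == [35, 35, 35, 35]
        self._assert_no_orthogonal_conspecifics(lay)

    @staticmethod
    def _assert_no_orthogonal_conspecifics(lay):
        grid = {(r, c): sp for r, c, sp, _ in lay.positions}
        for (r, c), sp in grid.items():
            for dr, dc in ((0, 1), (1, 0)):
                other = grid.get((r + dr, c + dc))
                assert other is None or other != sp

    def test_core_is_central_block(self, pools):
        comp = Composition((pools.emf_pool[0],), Treatment(1, "EMF"))
        lay = dz.planting_layout(comp, seed=0)
        core = {(r, c) for r, c, _, is_core in lay.positions if is_core}
        assert core == {(r, c) for r in range(3, 11) for c in range(1, 9)}

    def test_indivisible_richness_rejected(self, pools):
        comp = Composition(
            tuple(pools.amf_pool[:3]), Treatment(3, "AMF")
        )
        with pytest.raises(ValueError, match="does not divide"):
            dz.planting_layout(comp, seed=0)

    def test_total_trees(self, layouts):
        assert sum(len(l.positions) for l in layouts.values()) == 11200


class TestDesignIO:
    def test_design_csv_roundtrip(self, placed_design, tmp_path):
        path = tmp_path / "design.csv"
        dz.write_design_csv(placed_design, path)
        back = dz.read_design_csv(path)
        assert [(p.plot_id, p.block, p.grid_cell, p.composition) for p in back] == [
            (p.plot_id, p.block, p.grid_cell, p.composition)
            for p in sorted(placed_design, key=lambda q: q.plot_id)
        ]

    def test_layout_csv_roundtrip(self, layouts, tmp_path):
        path = tmp_path / "layout.csv"
        dz.write_layout_csv(layouts, path)
        back = dz.read_layout_csv(path)
        assert set(back) == set(layouts)
        some = sorted(layouts)[0]
        assert sorted(back[some].positions) == sorted(layouts[some].positions)

    def test_pipeline_bit_reproducible(self, pools, tmp_path):
        for run in ("a", "b"):
            plots = dz.assemble_design(pools, seed=11)
            placed = dz.randomize_layout(plots, seed=12)
            layouts = dz.layouts_for_design(placed, seed=13)
            dz.write_design_csv(placed, tmp_path / f"design_{run}.csv")
            dz.write_layout_csv(layouts, tmp_path / f"layout_{run}.csv")
        assert (tmp_path / "design_a.csv").read_bytes() == (
            tmp_path / "design_b.csv"
        ).read_bytes()
        assert (tmp_path / "layout_a.csv").read_bytes() == (
            tmp_path / "layout_b.csv"
        ).read_bytes()
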