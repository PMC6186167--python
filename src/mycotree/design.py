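"""Experimental design generation under neighbourhood constraints.

Treatments cross species richness (1, 2, 4) with mycorrhizal level (AMF,
EMF, Both).  Compositions are drawn from two five-species pools with
balanced subsetting so every species occurs equally often; plots are
randomised onto block grids such that same-treatment plots are never
adjacent (8-neighbourhood) and no treatment appears more than twice around
any focal plot; each plot gets a regular 140-tree planting layout with a
64-tree core.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .traits import SpeciesPools

logger = logging.getLogger(__name__)

MYCO_LEVELS = ("AMF", "EMF", "Both")
DEFAULT_RICHNESS_LEVELS = (1, 2, 4)

#: per-plot planting grid (rows x cols) and core block size
PLOT_ROWS, PLOT_COLS = 14, 10
CORE_ROWS, CORE_COLS = 8, 8
TREES_PER_PLOT = PLOT_ROWS * PLOT_COLS

#: per-block plot grid (rows x cols)
DEFAULT_GRID_DIMS = (5, 8)
DEFAULT_BLOCKS = 2


class Treatment(NamedTuple):
    richness: int
    myco_level: str


@dataclass(frozen=True)
class Composition:
    """A species set together with its treatment cell."""

    species: tuple[str, ...]
    treatment: Treatment

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(sorted(self.species)))
        if len(set(self.species)) != len(self.species):
            raise ValueError("composition contains duplicate species")
        if len(self.species) != self.treatment.richness:
            raise ValueError(
                f"composition has {len(self.species)} species but treatment "
                f"richness is {self.treatment.richness}"
            )


@dataclass
class PlotDesign:
    plot_id: str
    composition: Composition
    block: int | None = None
    grid_cell: tuple[int, int] | None = None

    @property
    def treatment(self) -> Treatment:
        return self.composition.treatment


@dataclass
class PlantingLayout:
    """Within-plot planting positions: (row, col, species_id, is_core)."""

    plot_id: str
    nrows: int
    ncols: int
    positions: list[tuple[int, int, str, bool]]

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, sp, _ in self.positions:
            counts[sp] = counts.get(sp, 0) + 1
        return counts

    def n_core(self) -> int:
        return sum(1 for *_, core in self.positions if core)


def valid_treatments(
    richness_levels: Sequence[int] = DEFAULT_RICHNESS_LEVELS,
) -> list[Treatment]:
    """All valid richness x mycorrhizal-level cells.

    ``Both`` requires at least two species (a monoculture has a single
    mycorrhizal type) and an even richness for the balanced type split.
    """
    out = []
    for r in richness_levels:
        for level in MYCO_LEVELS:
            if level == "Both" and (r < 2 or r % 2 != 0):
                continue
            out.append(Treatment(r, level))
    return out


def enumerate_compositions(
    pools: SpeciesPools, treatment: Treatment
) -> list[Composition]:
    """All species combinations realising a treatment.

    Within-type treatments use all richness-subsets of the matching pool;
    ``Both`` treatments use every combination with an equal split between the
    two pools (1+1 at richness 2, 2+2 at richness 4).
    """
    r, level = treatment
    if treatment not in valid_treatments((r,)):
        raise ValueError(f"invalid treatment {treatment}")
    if level in ("AMF", "EMF"):
        pool = sorted(pools.pool_of(level))
        if r > len(pool):
            raise ValueError(f"richness {r} exceeds pool size {len(pool)}")
        combos = itertools.combinations(pool, r)
        return [Composition(c, treatment) for c in combos]
    half = r // 2
    a = sorted(pools.amf_pool)
    e = sorted(pools.emf_pool)
    out = []
    for ca in itertools.combinations(a, half):
        for ce in itertools.combinations(e, half):
            out.append(Composition(ca + ce, treatment))
    return out


def select_balanced_subset(
    compositions: Sequence[Composition],
    k: int,
    seed: int | None = 0,
    max_restarts: int = 1000,
) -> list[Composition]:
    """Choose ``k`` compositions so that every species occurs equally often.

    The occurrence target is ``t = k * richness / n_species``; a seeded
    randomised depth-first search over composition orderings enforces counts
    never exceeding ``t``.  Deterministic for a fixed seed.
    """
    compositions = list(compositions)
    if not compositions:
        raise ValueError("no compositions to select from")
    if k > len(compositions):
        raise ValueError(f"k={k} exceeds {len(compositions)} available compositions")
    richness = compositions[0].treatment.richness
    species = sorted({s for c in compositions for s in c.species})
    total_slots = k * richness
    if total_slots % len(species) != 0:
        raise ValueError(
            f"balanced subset infeasible: {k} x richness {richness} slots cannot "
            f"be split equally over {len(species)} species"
        )
    target = total_slots // len(species)
    if k == len(compositions):
        return compositions

    rng = np.random.default_rng(seed)
    sp_index = {s: i for i, s in enumerate(species)}

    for _ in range(max_restarts):
        order = rng.permutation(len(compositions))
        counts = np.zeros(len(species), dtype=int)
        chosen: list[int] = []

        def dfs(pos: int) -> bool:
            if len(chosen) == k:
                return bool((counts == target).all())
            if pos >= len(order) or len(order) - pos < k - len(chosen):
                return False
            idx = order[pos]
            comp = compositions[idx]
            sp_idx = [sp_index[s] for s in comp.species]
            if all(counts[i] < target for i in sp_idx):
                counts[sp_idx] += 1
                chosen.append(idx)
                if dfs(pos + 1):
                    return True
                chosen.pop()
                counts[sp_idx] -= 1
            return dfs(pos + 1)

        if dfs(0):
            return [compositions[i] for i in chosen]
    raise RuntimeError(
        f"no balanced subset of size {k} found within {max_restarts} restarts"
    )


@dataclass(frozen=True)
class ReplicationRule:
    """How a treatment cell is replicated: all compositions (``replicates``
    times each) or a balanced subset of ``subset_size`` compositions."""

    mode: str  # "all" | "subset"
    replicates: int = 1
    subset_size: int | None = None

    def __post_init__(self):
        if self.mode not in ("all", "subset"):
            raise ValueError(f"unknown replication mode {self.mode!r}")
        if self.mode == "subset" and not self.subset_size:
            raise ValueError("subset rule needs subset_size")


def default_replication_rules() -> dict[Treatment, ReplicationRule]:
    """Replication rules for the standard 80-plot design: monocultures twice
    per species, all within-type two-species mixtures once, all within-type
    four-species mixtures twice, and balanced ten-plot subsets of the mixed
    two- and four-species mixtures."""
    return {
        Treatment(1, "AMF"): ReplicationRule("all", replicates=2),
        Treatment(1, "EMF"): ReplicationRule("all", replicates=2),
        Treatment(2, "AMF"): ReplicationRule("all", replicates=1),
        Treatment(2, "EMF"): ReplicationRule("all", replicates=1),
        Treatment(2, "Both"): ReplicationRule("subset", subset_size=10),
        Treatment(4, "AMF"): ReplicationRule("all", replicates=2),
        Treatment(4, "EMF"): ReplicationRule("all", replicates=2),
        Treatment(4, "Both"): ReplicationRule("subset", subset_size=10),
    }


def assemble_design(
    pools: SpeciesPools,
    rules: dict[Treatment, ReplicationRule] | None = None,
    seed: int | None = 0,
) -> list[PlotDesign]:
    """Build the unplaced plot list from pools and replication rules.

    Plot ids are assigned deterministically over treatments sorted by
    (richness, myco level) and compositions in lexicographic order.
    """
    if rules is None:
        rules = default_replication_rules()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(rules))
    plots: list[PlotDesign] = []
    counter = 1
    for i, treatment in enumerate(sorted(rules, key=lambda t: (t.richness, t.myco_level))):
        rule = rules[treatment]
        comps = enumerate_compositions(pools, treatment)
        if rule.mode == "subset":
            child_seed = int(children[i].generate_state(1)[0])
            comps = select_balanced_subset(comps, rule.subset_size, seed=child_seed)
            reps = 1
        else:
            reps = rule.replicates
        for comp in sorted(comps, key=lambda c: c.species):
            for _ in range(reps):
                plots.append(PlotDesign(plot_id=f"P{counter:03d}", composition=comp))
                counter += 1
    return plots


# ---------------------------------------------------------------------------
# block/grid randomisation
# ---------------------------------------------------------------------------


def _moore_neighbors(row, col, nrows, ncols):
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            r, c = row + dr, col + dc
            if 0 <= r < nrows and 0 <= c < ncols:
                yield r, c


def check_grid_constraints(grid: dict[tuple[int, int], Treatment], dims) -> list[str]:
    """Independent checker for the two neighbourhood constraints on one block.

    (c1) no two cells in Moore contact share a treatment; (c2) around any
    focal cell, no single treatment occurs more than twice among the up-to-8
    surrounding cells.  Returns a list of human-readable violations.
    """
    nrows, ncols = dims
    violations = []
    for (r, c), t in sorted(grid.items()):
        neigh = [grid[n] for n in _moore_neighbors(r, c, nrows, ncols) if n in grid]
        if t in neigh:
            violations.append(
                f"cell ({r},{c}): same treatment {t} in adjacent cell"
            )
        for other in set(neigh):
            if neigh.count(other) > 2:
                violations.append(
                    f"cell ({r},{c}): treatment {other} appears "
                    f"{neigh.count(other)} times in the 8-neighbourhood"
                )
    return violations


def check_layout_constraints(plots: Iterable[PlotDesign], grid_dims=DEFAULT_GRID_DIMS) -> list[str]:
    """Validate a placed design: unique cells per block plus grid constraints."""
    violations = []
    by_block: dict[int, dict[tuple[int, int], Treatment]] = {}
    seen: set[tuple[int, tuple[int, int]]] = set()
    for p in plots:
        if p.block is None or p.grid_cell is None:
            violations.append(f"plot {p.plot_id}: not placed")
            continue
        key = (p.block, p.grid_cell)
        if key in seen:
            violations.append(
                f"plot {p.plot_id}: duplicate grid cell {p.grid_cell} in block {p.block}"
            )
        seen.add(key)
        by_block.setdefault(p.block, {})[p.grid_cell] = p.treatment
    for block, grid in sorted(by_block.items()):
        for v in check_grid_constraints(grid, grid_dims):
            violations.append(f"block {block}: {v}")
    return violations


def _place_treatments(
    counts: dict[Treatment, int],
    dims: tuple[int, int],
    rng: np.random.Generator,
    max_restarts: int = 5000,
) -> dict[tuple[int, int], Treatment]:
    """Greedy seeded fill of one block grid honouring both constraints.

    Cells are visited row-major; at each cell a shuffled feasible treatment
    is placed, restarting from scratch on dead ends.
    """
    nrows, ncols = dims
    cells = [(r, c) for r in range(nrows) for c in range(ncols)]
    n_plots = sum(counts.values())
    if n_plots > len(cells):
        raise ValueError(f"{n_plots} plots exceed grid capacity {len(cells)}")
    treatments = sorted(counts)
    last_violation = "grid fill dead end"
    for _ in range(max_restarts):
        remaining = dict(counts)
        grid: dict[tuple[int, int], Treatment] = {}
        ok = True
        for i, cell in enumerate(cells):
            if len(grid) == n_plots:
                break
            r, c = cell
            placed_neigh = [
                n for n in _moore_neighbors(r, c, nrows, ncols) if n in grid
            ]
            options: list[Treatment | None] = [
                t for t in treatments if remaining[t] > 0
            ]
            if len(cells) - i > n_plots - len(grid):
                options.append(None)  # grid not full: this cell may stay empty
            rng.shuffle(options)
            chosen = None
            skip = False
            for t in options:
                if t is None:
                    skip = True
                    break
                # c1: no same-treatment Moore neighbour
                if any(grid[n] == t for n in placed_neigh):
                    continue
                # c2: placing t must not give any neighbour a 3rd t around it
                bad = False
                for n in placed_neigh:
                    nr, nc = n
                    around = sum(
                        1
                        for m in _moore_neighbors(nr, nc, nrows, ncols)
                        if m in grid and grid[m] == t
                    )
                    if around >= 2:
                        bad = True
                        break
                if not bad:
                    chosen = t
                    break
            if skip:
                continue
            if chosen is None:
                ok = False
                last_violation = (
                    f"no feasible treatment at cell {cell} "
                    f"(remaining: { {str(t): n for t, n in remaining.items() if n} })"
                )
                break
            grid[cell] = chosen
            remaining[chosen] -= 1
        if ok and len(grid) == n_plots:
            leftover = check_grid_constraints(grid, dims)
            if not leftover:
                return grid
            last_violation = leftover[0]
    raise RuntimeError(
        f"no valid layout within {max_restarts} restarts; tightest violated "
        f"constraint: {last_violation}"
    )


def _split_into_blocks(
    plots: Sequence[PlotDesign], blocks: int, rng: np.random.Generator
) -> dict[int, list[PlotDesign]]:
    """Deal plots across blocks, one replicate pair split per composition.

    Plots are grouped by composition; each group's members are dealt
    round-robin (so the two replicates of a monoculture or four-species
    composition land in different blocks) and singleton groups are shuffled
    within treatment before dealing so block totals stay even.
    """
    per_block: dict[int, list[PlotDesign]] = {b: [] for b in range(1, blocks + 1)}
    by_treatment: dict[Treatment, list[PlotDesign]] = {}
    for p in plots:
        by_treatment.setdefault(p.treatment, []).append(p)
    for treatment in sorted(by_treatment):
        group = by_treatment[treatment]
        by_comp: dict[tuple[str, ...], list[PlotDesign]] = {}
        for p in group:
            by_comp.setdefault(p.composition.species, []).append(p)
        multi = [ps for _, ps in sorted(by_comp.items()) if len(ps) > 1]
        singles = [ps[0] for _, ps in sorted(by_comp.items()) if len(ps) == 1]
        rng.shuffle(singles)
        cursor = 0
        for ps in multi:
            for p in ps:
                per_block[1 + cursor % blocks].append(p)
                cursor += 1
        for p in singles:
            per_block[1 + cursor % blocks].append(p)
            cursor += 1
    return per_block


def randomize_layout(
    plots: Sequence[PlotDesign],
    blocks: int = DEFAULT_BLOCKS,
    grid_dims: tuple[int, int] = DEFAULT_GRID_DIMS,
    seed: int | None = 0,
    max_restarts: int = 5000,
) -> list[PlotDesign]:
    """Assign plots to block grid cells under the neighbourhood constraints.

    Returns new :class:`PlotDesign` objects with ``block`` and ``grid_cell``
    set; the input is not modified.  Deterministic for a fixed seed; raises
    ``RuntimeError`` naming the tightest violated constraint if no valid
    placement is found within the restart budget.
    """
    rng = np.random.default_rng(seed)
    per_block = _split_into_blocks(plots, blocks, rng)
    placed: list[PlotDesign] = []
    for block, block_plots in sorted(per_block.items()):
        counts: dict[Treatment, int] = {}
        for p in block_plots:
            counts[p.treatment] = counts.get(p.treatment, 0) + 1
        grid = _place_treatments(counts, grid_dims, rng, max_restarts=max_restarts)
        # hand the concrete plots of each treatment to its cells in random order
        cells_by_treatment: dict[Treatment, list[tuple[int, int]]] = {}
        for cell, t in sorted(grid.items()):
            cells_by_treatment.setdefault(t, []).append(cell)
        for t in sorted(cells_by_treatment):
            members = [p for p in block_plots if p.treatment == t]
            order = rng.permutation(len(members))
            for cell, i in zip(cells_by_treatment[t], order):
                p = members[int(i)]
                placed.append(replace(p, block=block, grid_cell=cell))
    placed.sort(key=lambda p: p.plot_id)
    return placed


# ---------------------------------------------------------------------------
# within-plot planting layout
# ---------------------------------------------------------------------------


def planting_layout(
    composition: Composition,
    seed: int | None = 0,
    plot_id: str = "",
    nrows: int = PLOT_ROWS,
    ncols: int = PLOT_COLS,
    core_shape: tuple[int, int] = (CORE_ROWS, CORE_COLS),
) -> PlantingLayout:
    """Regular maximally interspersed planting grid for one plot.

    Species cycle through the grid with a per-row offset, giving exactly
    ``nrows * ncols / richness`` individuals per species and (for richness
    > 1) no orthogonally adjacent conspecifics.  The central core block is
    flagged for measurements.
    """
    r = composition.treatment.richness
    total = nrows * ncols
    if total % r != 0:
        raise ValueError(f"richness {r} does not divide {total} planting positions")
    core_r, core_c = core_shape
    if core_r > nrows or core_c > ncols:
        raise ValueError("core block larger than the planting grid")
    rng = np.random.default_rng(seed)
    seq = [composition.species[int(i)] for i in rng.permutation(r)]
    row0 = (nrows - core_r) // 2
    col0 = (ncols - core_c) // 2
    positions = []
    for row in range(nrows):
        for col in range(ncols):
            if r == 1:
                sp = seq[0]
            elif ncols % r == 0:
                sp = seq[(row + col) % r]  # per-row offset avoids column stripes
            else:
                sp = seq[(row * ncols + col) % r]
            is_core = row0 <= row < row0 + core_r and col0 <= col < col0 + core_c
            positions.append((row, col, sp, is_core))
    return PlantingLayout(plot_id=plot_id, nrows=nrows, ncols=ncols, positions=positions)


def layouts_for_design(
    plots: Sequence[PlotDesign], seed: int | None = 0
) -> dict[str, PlantingLayout]:
    """Planting layout per plot, with per-plot child seeds from one root seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(plots))
    return {
        p.plot_id: planting_layout(
            p.composition,
            seed=int(child.generate_state(1)[0]),
            plot_id=p.plot_id,
        )
        for p, child in zip(sorted(plots, key=lambda q: q.plot_id), children)
    }


# ---------------------------------------------------------------------------
# balance checking and I/O
# ---------------------------------------------------------------------------


def species_occurrence(plots: Iterable[PlotDesign]) -> pd.DataFrame:
    """Long-format species occurrence counts per treatment cell."""
    rows = []
    for p in plots:
        for sp in p.composition.species:
            rows.append(
                {
                    "species": sp,
                    "richness": p.treatment.richness,
                    "myco_level": p.treatment.myco_level,
                }
            )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["richness", "myco_level", "species"])
        .size()
        .rename("n_plots")
        .reset_index()
    )


def check_design_balance(plots: Sequence[PlotDesign]) -> list[str]:
    """Check equal species occurrence within every treatment cell."""
    occ = species_occurrence(plots)
    problems = []
    for (richness, level), grp in occ.groupby(["richness", "myco_level"]):
        if grp["n_plots"].nunique() > 1:
            problems.append(
                f"unequal species occurrence in treatment ({richness}, {level}): "
                + ", ".join(f"{s}={n}" for s, n in zip(grp["species"], grp["n_plots"]))
            )
    return problems


def design_to_frame(plots: Sequence[PlotDesign]) -> pd.DataFrame:
    rows = []
    for p in sorted(plots, key=lambda q: q.plot_id):
        row, col = p.grid_cell if p.grid_cell is not None else (None, None)
        rows.append(
            {
                "plot_id": p.plot_id,
                "block": p.block,
                "row": row,
                "col": col,
                "richness": p.treatment.richness,
                "myco_level": p.treatment.myco_level,
                "species": ";".join(p.composition.species),
            }
        )
    return pd.DataFrame(rows)


def design_from_frame(df: pd.DataFrame) -> list[PlotDesign]:
    plots = []
    for _, r in df.iterrows():
        comp = Composition(
            tuple(str(r["species"]).split(";")),
            Treatment(int(r["richness"]), str(r["myco_level"])),
        )
        block = None if pd.isna(r.get("block")) else int(r["block"])
        if pd.isna(r.get("row")) or pd.isna(r.get("col")):
            cell = None
        else:
            cell = (int(r["row"]), int(r["col"]))
        plots.append(
            PlotDesign(
                plot_id=str(r["plot_id"]), composition=comp, block=block, grid_cell=cell
            )
        )
    return plots


def write_design_csv(plots: Sequence[PlotDesign], path) -> None:
    design_to_frame(plots).to_csv(path, index=False)


def read_design_csv(path) -> list[PlotDesign]:
    return design_from_frame(pd.read_csv(path))


def layouts_to_frame(layouts: dict[str, PlantingLayout]) -> pd.DataFrame:
    rows = []
    for plot_id in sorted(layouts):
        lay = layouts[plot_id]
        for row, col, sp, core in lay.positions:
            rows.append(
                {
                    "plot_id": plot_id,
                    "row": row,
                    "col": col,
                    "species_id": sp,
                    "is_core": int(core),
                }
            )
    return pd.DataFrame(rows)


def layouts_from_frame(df: pd.DataFrame) -> dict[str, PlantingLayout]:
    out: dict[str, PlantingLayout] = {}
    for plot_id, grp in df.groupby("plot_id"):
        positions = [
            (int(r["row"]), int(r["col"]), str(r["species_id"]), bool(r["is_core"]))
            for _, r in grp.iterrows()
        ]
        nrows = max(p[0] for p in positions) + 1
        ncols = max(p[1] for p in positions) + 1
        out[str(plot_id)] = PlantingLayout(
            plot_id=str(plot_id), nrows=nrows, ncols=ncols, positions=positions
        )
    return out


def write_layout_csv(layouts: dict[str, PlantingLayout], path) -> None:
    layouts_to_frame(layouts).to_csv(path, index=False)


def read_layout_csv(path) -> dict[str, PlantingLayout]:
    return layouts_from_frame(pd.read_csv(path))
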