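"""Virtual species and the niche-shift demonstration scenario.

Builds everything needed to exercise the coding + reconstruction pipeline
end to end without real rasters: a synthetic temperature gradient, random
connected accessible areas (M), rectangular-niche virtual species realized
inside them, a pure-birth phylogeny, and the canonical demonstration — a
clade of cool-niche species (fundamental niche 24–28 °C) nested inside a
warm-niche background (25–29 °C), whose ancestral lower thermal limit the
reconstruction should recover as an expansion from 25 °C down to 24 °C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import ancestral, binning, continuous
from .binning import BinScheme, CharacterMatrix, SpeciesEnvProfile, code_matrix
from .phylo import Phylogeny


# ---------------------------------------------------------------------------
# environmental grid
# ---------------------------------------------------------------------------

@dataclass
class EnvGrid:
    """A gridded environmental layer (values in axis units, e.g. °C)."""

    values: np.ndarray  # (n_rows, n_cols)
    mask: np.ndarray | None = None  # True where valid; None = all valid

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def valid_cells(self) -> list[tuple[int, int]]:
        if self.mask is None:
            return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]
        rr, cc = np.nonzero(self.mask)
        return list(zip(rr.tolist(), cc.tolist()))


def make_env_gradient(
    n_rows: int,
    n_cols: int,
    vmin: float,
    vmax: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> EnvGrid:
    """Column-linear gradient from ``vmin`` to ``vmax`` plus Gaussian noise."""
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    if vmin >= vmax:
        raise ValueError("vmin must be < vmax")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols = np.linspace(vmin, vmax, n_cols) if n_cols > 1 else np.array([(vmin + vmax) / 2])
    values = np.tile(cols, (n_rows, 1))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return EnvGrid(values=values)


def sample_accessible_area(
    grid: EnvGrid,
    target_n_cells: int,
    seed: int | np.random.Generator = 0,
) -> set[tuple[int, int]]:
    """A connected (4-neighbor) region grown by random accretion.

    A seed cell is drawn uniformly; cells are then added one at a time by
    picking uniformly from the current frontier, producing compact but
    irregular blobs that stand in for accessible-area polygons.
    """
    cells = grid.valid_cells()
    if target_n_cells < 1 or target_n_cells > len(cells):
        raise ValueError("target_n_cells out of range for this grid")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    valid = set(cells)
    start = cells[int(rng.integers(len(cells)))]
    region = {start}
    frontier: list[tuple[int, int]] = []
    in_frontier: set[tuple[int, int]] = set()

    def push_neighbors(cell):
        r, c = cell
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb in valid and nb not in region and nb not in in_frontier:
                frontier.append(nb)
                in_frontier.add(nb)

    push_neighbors(start)
    while len(region) < target_n_cells:
        if not frontier:
            raise ValueError("grid too small/fragmented to grow region")
        i = int(rng.integers(len(frontier)))
        cell = frontier[i]
        frontier[i] = frontier[-1]
        frontier.pop()
        in_frontier.discard(cell)
        region.add(cell)
        push_neighbors(cell)
    return region


# ---------------------------------------------------------------------------
# virtual species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NicheSpec:
    """A rectangular fundamental niche on one axis: suitable iff
    ``lower <= value <= upper``."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("niche lower bound must be below upper bound")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass
class VirtualSpecies:
    id: str
    niche: NicheSpec
    m_cells: set[tuple[int, int]]
    occupied_cells: set[tuple[int, int]]
    profile: SpeciesEnvProfile
    median_suitable: float


def realize_species(
    grid: EnvGrid,
    m_cells: set[tuple[int, int]],
    niche: NicheSpec,
    species_id: str,
) -> VirtualSpecies | None:
    """Occupy every suitable cell of M; ``None`` when M holds no suitable cell.

    The discard outcome mirrors dropping simulated accessible areas with no
    suitable conditions; the species' profile is built in values mode from
    the occupied and M cell values.
    """
    m_list = sorted(m_cells)
    m_vals = np.array([grid.values[r, c] for r, c in m_list])
    suitable = (m_vals >= niche.lower) & (m_vals <= niche.upper)
    if not suitable.any():
        return None
    occupied_cells = {cell for cell, s in zip(m_list, suitable) if s}
    occ_vals = m_vals[suitable]
    profile = SpeciesEnvProfile(
        species_id=species_id, occupied=occ_vals, accessible=m_vals
    )
    return VirtualSpecies(
        id=species_id,
        niche=niche,
        m_cells=set(m_cells),
        occupied_cells=occupied_cells,
        profile=profile,
        median_suitable=float(np.median(occ_vals)),
    )


def build_species_pool(
    grid: EnvGrid,
    niche: NicheSpec,
    n_species: int,
    m_size_range: tuple[int, int],
    rng: np.random.Generator,
    id_prefix: str = "sp",
) -> tuple[list[VirtualSpecies], int]:
    """Sample species until ``n_species`` are realized; discarded accessible
    areas (no suitable cell) are re-drawn.  Returns (pool, n_discarded)."""
    lo, hi = m_size_range
    pool: list[VirtualSpecies] = []
    n_discarded = 0
    while len(pool) < n_species:
        size = int(rng.integers(lo, hi + 1))
        m = sample_accessible_area(grid, size, rng)
        sp = realize_species(grid, m, niche, f"{id_prefix}{len(pool) + 1}")
        if sp is None:
            n_discarded += 1
            if n_discarded > 100 * n_species:
                raise RuntimeError("accessible areas almost never overlap the niche")
            continue
        pool.append(sp)
    return pool, n_discarded


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_bd_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> Phylogeny:
    """Birth–death tree conditioned on ``n_tips`` extant tips.

    Forward simulation until the extant count reaches ``n_tips``, plus a
    final epoch drawn as the waiting time to the next event, so terminal
    branches are positive; with ``death_rate == 0`` (pure birth) this is
    exact.  Extinct lineages are pruned; complete extinction triggers a
    retry.  Tips are labeled ``t1..tn`` in tree order.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0 or death_rate < 0 or birth_rate <= death_rate:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    for _attempt in range(1000):
        # node records: [children, pendant length, alive]
        nodes: list[list] = [[[], 0.0, True], [[], 0.0, True]]
        root_children = [0, 1]
        alive = [0, 1]
        ok = True
        while len(alive) < n_tips:
            k = len(alive)
            dt = rng.exponential(1.0 / (k * (birth_rate + death_rate)))
            for v in alive:
                nodes[v][1] += dt
            i = int(rng.integers(k))
            v = alive[i]
            if rng.random() < birth_rate / (birth_rate + death_rate):
                a = len(nodes)
                nodes.append([[], 0.0, True])
                b = len(nodes)
                nodes.append([[], 0.0, True])
                nodes[v][0] = [a, b]
                alive[i] = a
                alive.append(b)
            else:
                nodes[v][2] = False
                alive.pop(i)
                if len(alive) < 2:
                    ok = False
                    break
        if not ok:
            continue
        dt = rng.exponential(1.0 / (len(alive) * (birth_rate + death_rate)))
        for v in alive:
            nodes[v][1] += dt
        return _assemble_tree(nodes, root_children, n_tips)
    raise RuntimeError("tree simulation kept going extinct")


def _assemble_tree(nodes, root_children, n_tips) -> Phylogeny:
    # prune extinct subtrees, suppress unifurcations, emit postorder arrays
    def build(v):
        kids, bl, alive_flag = nodes[v]
        if not kids:
            return ("tip", None, bl) if alive_flag else None
        sub = [s for s in (build(c) for c in kids) if s is not None]
        if not sub:
            return None
        if len(sub) == 1:  # unifurcation after pruning: merge branch lengths
            kind, payload, length = sub[0]
            return (kind, payload, length + bl)
        return ("node", sub, bl)

    subs = [s for s in (build(c) for c in root_children) if s is not None]
    if len(subs) == 1:
        if subs[0][0] == "tip":
            raise RuntimeError("degenerate tree after pruning")
        root_entry = ("node", subs[0][1], 0.0)
    else:
        root_entry = ("node", subs, 0.0)

    children: list[list[int]] = []
    lengths: list[float] = []
    labels: list[str] = []
    counter = {"tip": 0}

    def emit(entry) -> int:
        kind = entry[0]
        if kind == "tip":
            children.append([])
            lengths.append(entry[2])
            counter["tip"] += 1
            labels.append(f"t{counter['tip']}")
        else:
            idxs = [emit(s) for s in entry[1]]
            children.append(idxs)
            lengths.append(entry[2])
            labels.append("")
        return len(children) - 1

    emit(root_entry)
    labels = [l if l else f"n{i}" for i, l in enumerate(labels)]
    tree = Phylogeny(children=children, lengths=lengths, labels=labels)
    assert tree.n_tips == n_tips
    return tree


def find_clades_of_size(tree: Phylogeny, size: int) -> list[int]:
    """Internal nodes whose descendant tip count equals ``size``."""
    return [
        v
        for v, s in enumerate(tree.tipsets())
        if not tree.is_tip(v) and len(s) == size
    ]


def assign_tips(
    tree: Phylogeny,
    clade_size: int,
    cool_pool: Sequence[VirtualSpecies],
    warm_pool: Sequence[VirtualSpecies],
    seed: int | np.random.Generator = 0,
) -> dict[str, VirtualSpecies]:
    """Place cool-pool species on one clade of ``clade_size`` tips and
    warm-pool species everywhere else (sampling without replacement)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    candidates = find_clades_of_size(tree, clade_size)
    if not candidates:
        raise ValueError(f"tree has no clade of exactly {clade_size} tips")
    clade = candidates[int(rng.integers(len(candidates)))]
    clade_tips = sorted(tree.tipsets()[clade])
    other_tips = sorted(set(tree.tip_labels) - set(clade_tips))
    if len(cool_pool) < len(clade_tips) or len(warm_pool) < len(other_tips):
        raise ValueError("species pools too small for this tree")
    cool_pick = rng.choice(len(cool_pool), size=len(clade_tips), replace=False)
    warm_pick = rng.choice(len(warm_pool), size=len(other_tips), replace=False)
    mapping: dict[str, VirtualSpecies] = {}
    for tip, i in zip(clade_tips, cool_pick):
        mapping[tip] = cool_pool[int(i)]
    for tip, i in zip(other_tips, warm_pick):
        mapping[tip] = warm_pool[int(i)]
    return mapping


# ---------------------------------------------------------------------------
# demonstration scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemoConfig:
    """Conditions of the niche-shift demonstration.

    Defaults follow the published simulation design: 500 cool-niche
    (24–28 °C) and 500 warm-niche (25–29 °C) virtual species, a 15-taxon
    pure-birth tree (birth 1, death 0) with a 7-taxon cool clade, 1 °C
    bins.  The environmental layer is a synthetic 10–35 °C gradient rather
    than a real raster, so results are qualitative reproductions.
    """

    n_cool: int = 500
    n_warm: int = 500
    cool_niche: NicheSpec = NicheSpec(24.0, 28.0)
    warm_niche: NicheSpec = NicheSpec(25.0, 29.0)
    n_tips: int = 15
    clade_size: int = 7
    bin_width: float = 1.0
    birth_rate: float = 1.0
    death_rate: float = 0.0
    grid_rows: int = 100
    grid_cols: int = 100
    vmin: float = 10.0
    vmax: float = 35.0
    noise_sd: float = 0.5
    m_size_range: tuple[int, int] = (100, 600)
    max_tree_draws: int = 1000
    tie_tol: float = ancestral.DEFAULT_TIE_TOL
    gls_models: tuple[str, ...] = ("bm", "ou", "eb")


@dataclass
class DemoResult:
    config: DemoConfig
    seed: int
    tree: Phylogeny
    assignment: dict[str, VirtualSpecies]
    cool_tips: list[str]
    matrix: CharacterMatrix
    ml: ancestral.ReconstructionResult
    parsimony: ancestral.ReconstructionResult
    gls_fits: list[continuous.FittedModel]
    gls_best: continuous.FittedModel
    gls_nodes: dict[str, continuous.NodeEstimate]
    mrca_label: str
    summary: dict


def _lower_suitable_edge(vec, scheme: BinScheme) -> float | None:
    span = vec.suitable_span()
    if span is None:
        return None
    return float(scheme.edges[span[0]])


def run_demo_scenario(config: DemoConfig | None = None, seed: int = 0) -> DemoResult:
    """Run the full demonstration pipeline for one seed.

    Simulates the two species pools on a shared gradient, draws a
    pure-birth tree containing a clade of the requested size, codes the
    assigned species' niches into a shared bin scheme, reconstructs
    ancestral bins by ML and parsimony, and fits the continuous baseline
    to tip medians.  The summary records the reconstructed lower suitable
    limit at the cool-clade MRCA under each method.
    """
    cfg = config or DemoConfig()
    rng = np.random.default_rng(seed)
    grid = make_env_gradient(
        cfg.grid_rows, cfg.grid_cols, cfg.vmin, cfg.vmax, cfg.noise_sd, rng
    )
    cool_pool, disc_c = build_species_pool(
        grid, cfg.cool_niche, cfg.n_cool, cfg.m_size_range, rng, id_prefix="cool"
    )
    warm_pool, disc_w = build_species_pool(
        grid, cfg.warm_niche, cfg.n_warm, cfg.m_size_range, rng, id_prefix="warm"
    )

    tree = None
    for _ in range(cfg.max_tree_draws):
        cand = simulate_bd_tree(cfg.n_tips, cfg.birth_rate, cfg.death_rate, rng)
        if find_clades_of_size(cand, cfg.clade_size):
            tree = cand
            break
    if tree is None:
        raise RuntimeError(
            f"no {cfg.clade_size}-tip clade in {cfg.max_tree_draws} tree draws"
        )

    assignment = assign_tips(tree, cfg.clade_size, cool_pool, warm_pool, rng)
    cool_ids = {sp.id for sp in cool_pool}
    cool_tips = sorted(t for t, sp in assignment.items() if sp.id in cool_ids)

    # bin scheme from the union of M environments across both whole pools,
    # then code only the species placed on the tree (tips keep tip labels)
    all_profiles = [sp.profile for sp in cool_pool + warm_pool]
    scheme = binning.build_bin_scheme(
        binning.union_env_range(all_profiles), cfg.bin_width, axis_name="temperature"
    )
    tip_profiles = [
        replace(assignment[t].profile, species_id=t) for t in tree.tip_labels
    ]
    matrix = code_matrix(tip_profiles, scheme)

    ml = ancestral.reconstruct_matrix(tree, matrix, "ml", tie_tol=cfg.tie_tol)
    pars = ancestral.reconstruct_matrix(tree, matrix, "parsimony")

    trait = {t: assignment[t].median_suitable for t in tree.tip_labels}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gls_fits = [continuous.fit_evo_model(tree, trait, m) for m in cfg.gls_models]
    gls_best = continuous.select_model(gls_fits)
    gls_nodes = continuous.continuous_asr(tree, trait, gls_best)

    mrca_label = tree.labels[tree.mrca(cool_tips)]
    summary = {
        "seed": seed,
        "n_bins": scheme.n_bins,
        "scheme": (scheme.lower_edge, scheme.upper_edge, scheme.width),
        "n_discarded": disc_c + disc_w,
        "cool_mrca": mrca_label,
        "ml_lower_edge": _lower_suitable_edge(ml.smoothed[mrca_label], scheme),
        "parsimony_lower_edge": _lower_suitable_edge(pars.smoothed[mrca_label], scheme),
        "gls_model": gls_best.model,
        "gls_mrca_estimate": gls_nodes[mrca_label].estimate,
        "true_cool_lower": cfg.cool_niche.lower,
        "true_cool_midpoint": cfg.cool_niche.midpoint,
    }
    return DemoResult(
        config=cfg,
        seed=seed,
        tree=tree,
        assignment=assignment,
        cool_tips=cool_tips,
        matrix=matrix,
        ml=ml,
        parsimony=pars,
        gls_fits=gls_fits,
        gls_best=gls_best,
        gls_nodes=gls_nodes,
        mrca_label=mrca_label,
        summary=summary,
    )
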