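"""Synthetic clades with regime-dependent shape evolution and trait tables.

The generator emulates the statistical structure the analysis assumes: a
pure-birth (Yule) phylogeny scaled to unit root height; dietary regimes
switching along branches by a continuous-time Markov process; landmark
configurations evolving by Brownian motion whose per-coordinate rate is a
regime-dependent multiple of a base rate; raw resource tables whose
majority category matches each tip's regime (omnivores: no majority); and
foraging-behaviour tables scored from regime-typical statements. Raw
landmark output is given a random pose (rotation/translation/scale) per
specimen so the Procrustes step is exercised; the latent pre-pose
configurations are kept as ground truth.

Every generator is a pure function of its seed; scenario metadata records
all parameters and seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from aviamorph.gpa import ShapeDataset
from aviamorph.io import ModulePartition, write_landmarks, write_partition
from aviamorph.trophic import (
    ALL_DIET_GROUPS,
    DIET_GROUPS,
    FORAGING_BEHAVIOURS,
    MERGED_CATEGORIES,
    OMNIVORE,
    RAW_CATEGORIES,
    VERTEBRATE_CATEGORIES,
    ForagingStatement,
    score_foraging,
)
from aviamorph.phylo import simulate_bm

#: default module names for synthetic partitions (cranial regions)
DEFAULT_MODULES = (
    "rostrum", "palate", "vault", "occipital", "basisphenoid",
    "pterygoid_quadrate", "naris",
)


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic clade.

    ``regimes`` maps regime names (dietary groups) to rate multipliers;
    ``base_rate`` is the per-coordinate BM variance per unit tree height
    for a multiplier of 1. The default switching rate (0.5 events per unit
    branch length on a height-1 tree) yields a handful of regime origins
    per clade, so regimes form clusters, as dietary guilds do.
    """

    n_tips: int = 64
    n_landmarks: int = 50
    regimes: dict[str, float] = field(default_factory=lambda: {"granivore": 4.0, "invertivore": 1.0})
    base_rate: float = 0.001
    regime_switch_rate: float = 0.5
    tree_seed: int = 0
    trait_seed: int = 1
    diet_seed: int = 2

    def __post_init__(self) -> None:
        if self.n_landmarks < 3:
            raise ValueError("need at least 3 landmarks")
        if any(m <= 0 for m in self.regimes.values()):
            raise ValueError("regime multipliers must be positive")
        unknown = sorted(set(self.regimes) - set(ALL_DIET_GROUPS))
        if unknown:
            raise ValueError(f"unknown dietary groups as regimes: {unknown}")

    def metadata(self) -> dict:
        return asdict(self)


def simulate_yule_tree(n_tips: int, seed: int | np.random.Generator) -> dendropy.Tree:
    """Pure-birth tree with unit birth rate, rescaled to root height 1.

    Lineages split at exponential waiting times; after the n-th tip
    appears the process runs one further waiting time so the final cherry
    has positive branches. Deterministic per seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    birth: dict[dendropy.Node, float] = {root: 0.0}
    active: list[dendropy.Node] = []
    for _ in range(2):                       # root split at time 0
        child = root.new_child()
        birth[child] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        for _ in range(2):
            child = node.new_child()
            birth[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_tips)
    for i, leaf in enumerate(active, start=1):
        leaf.taxon = taxon_ns.new_taxon(f"t{i}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        # a node's edge spans from its own birth to its split (or the present)
        end = t_end if node.is_leaf() else birth[node.child_nodes()[0]]
        node.edge.length = end - birth[node]
    # rescale to root height exactly 1
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / t_end
    return tree


@dataclass
class RegimePainting:
    """Per-branch regime assignment and tip regime labels."""

    tip_regimes: dict[str, str]              # tip label -> regime
    node_regimes: dict[dendropy.Node, str]   # every node (branch = its child node)
    n_switches: int
    root_regime: str

    def rate_fn(self, multipliers: Mapping[str, float], base_rate: float = 1.0):
        """Per-branch BM rate: base_rate x multiplier of the branch regime."""
        return lambda node: base_rate * multipliers[self.node_regimes[node]]


def assign_regimes(
    tree: dendropy.Tree,
    regimes: Sequence[str],
    switch_rate: float,
    seed: int | np.random.Generator,
    max_attempts: int = 100,
) -> RegimePainting:
    """Paint regimes on branches by a continuous-time Markov switch process.

    The root regime is drawn uniformly; along each branch, switches occur
    at rate ``switch_rate`` jumping to a uniformly chosen other regime. A
    branch carries the regime of its child node. When ``switch_rate > 0``
    and several regimes are requested, paintings are resampled (up to
    ``max_attempts``) until every regime has at least 2 tips; with
    ``switch_rate = 0`` all tips simply share the root regime.
    """
    regimes = list(regimes)
    if len(regimes) < 1:
        raise ValueError("need at least one regime")
    if switch_rate < 0:
        raise ValueError("switch rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def paint_once() -> RegimePainting:
        node_regimes: dict[dendropy.Node, str] = {}
        switches = 0
        root = tree.seed_node
        node_regimes[root] = regimes[int(rng.integers(len(regimes)))]
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            state = node_regimes[node.parent_node]
            length = float(node.edge.length or 0.0)
            if switch_rate > 0 and len(regimes) > 1:
                t = rng.exponential(1.0 / switch_rate)
                while t < length:
                    others = [r for r in regimes if r != state]
                    state = others[int(rng.integers(len(others)))]
                    switches += 1
                    t += rng.exponential(1.0 / switch_rate)
            node_regimes[node] = state
        tips = {leaf.taxon.label: node_regimes[leaf] for leaf in tree.leaf_node_iter()}
        return RegimePainting(tips, node_regimes, switches, node_regimes[root])

    if switch_rate == 0 or len(regimes) == 1:
        return paint_once()
    for _ in range(max_attempts):
        painting = paint_once()
        counts = pd.Series(list(painting.tip_regimes.values())).value_counts()
        if all(counts.get(r, 0) >= 2 for r in regimes):
            return painting
    raise RuntimeError(
        f"could not obtain >=2 tips per regime in {max_attempts} paintings; "
        "increase switch_rate or tip count"
    )


def _sphere_template(n_landmarks: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci spiral),
    centred and scaled to unit centroid size."""
    i = np.arange(n_landmarks)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - 2 * (i + 0.5) / n_landmarks
    r = np.sqrt(np.maximum(0.0, 1 - z ** 2))
    theta = 2 * np.pi * i / golden
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    pts -= pts.mean(axis=0)
    return pts / np.sqrt((pts ** 2).sum())


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


@dataclass
class SimulatedShapes:
    """Raw (posed) and latent (true) shape data plus generating parameters."""

    raw: ShapeDataset                        # randomized pose, exercises GPA
    truth: ShapeDataset                      # latent BM tip configurations
    groups: dict[str, str]                   # tip label -> regime
    template: np.ndarray                     # (L, 3) ancestral configuration
    params: dict


def simulate_shape_dataset(
    tree: dendropy.Tree,
    painting: RegimePainting,
    scenario: SyntheticScenario,
) -> SimulatedShapes:
    """Evolve a landmark template over the tree at regime-dependent rates.

    Each of the 3L coordinates performs BM with branch rate
    ``base_rate * multiplier(regime)``; the root state is a sphere-like
    template of unit centroid size. Tips are returned both as the latent
    configurations and re-posed with random similarity transforms.
    """
    rng = np.random.default_rng(scenario.trait_seed)
    L = scenario.n_landmarks
    template = _sphere_template(L)
    labels, flat = simulate_bm(
        tree,
        rates=painting.rate_fn(scenario.regimes, scenario.base_rate),
        n_traits=3 * L,
        seed=rng,
        root_state=template.ravel(),
    )
    coords = flat.reshape(len(labels), L, 3)
    truth = ShapeDataset(taxa=list(labels), coords=coords.copy())

    posed = np.empty_like(coords)
    for i in range(len(labels)):
        R = _random_rotation(rng)
        scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0)))) * 10.0
        shift = rng.normal(scale=5.0, size=3)
        posed[i] = (coords[i] @ R) * scale + shift
    raw = ShapeDataset(taxa=list(labels), coords=posed)
    return SimulatedShapes(
        raw=raw,
        truth=truth,
        groups=dict(painting.tip_regimes),
        template=template,
        params=scenario.metadata(),
    )


_GROUP_TO_MERGED = {g: c for c, g in DIET_GROUPS.items()}

#: how merged categories split back onto raw table columns
_MERGED_TO_RAW = {
    "terrestrial_invertebrates": ("invertebrates",),
    "aquatic_animals": ("fish",),
    "vertebrates": VERTEBRATE_CATEGORIES,
    "carrion": ("carrion",),
    "fruit": ("fruit",),
    "seeds": ("seeds",),
    "nectar": ("nectar",),
    "other_plants": ("other_plants",),
}

#: foraging behaviours typical of each dietary group (for statement sampling)
_GROUP_BEHAVIOURS = {
    "invertivore": ["glean_arboreal", "glean_ground", "probe_ground", "sally_air", "hawk_aerial"],
    "aquatic_predator": ["pursuit_dive", "plunge_dive", "surface_seize", "wade_stalk"],
    "vertivore": ["pounce_ground", "stoop_aerial", "sally_surface"],
    "scavenger": ["scavenge_carrion", "glean_ground"],
    "frugivore": ["glean_arboreal", "hover_glean", "browse"],
    "granivore": ["crack_seeds", "glean_ground", "scratch_litter"],
    "nectarivore": ["nectar_hover", "nectar_perch", "probe_flowers"],
    "herbivore": ["graze", "browse", "dabble"],
    OMNIVORE: ["glean_ground", "glean_arboreal", "scavenge_carrion", "probe_ground"],
}


def simulate_resource_table(
    tip_labels: Sequence[str],
    group_labels: Mapping[str, str] | Sequence[str],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Raw 10-category resource table whose classification recovers the groups.

    Non-omnivores get 65-92% of their resources in the raw columns of the
    group's merged category; omnivores get a composition with every merged
    category strictly below 60%.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not isinstance(group_labels, Mapping):
        group_labels = dict(zip(tip_labels, group_labels))
    rows = []
    for tip in tip_labels:
        group = group_labels[str(tip)]
        if group != OMNIVORE and group not in _GROUP_TO_MERGED:
            raise ValueError(f"unknown dietary group {group!r} for tip {tip!r}")
        while True:
            if group == OMNIVORE:
                merged = rng.dirichlet(np.full(len(MERGED_CATEGORIES), 2.0))
                if merged.max() < 0.55:
                    merged = dict(zip(MERGED_CATEGORIES, merged))
                    break
            else:
                focal = _GROUP_TO_MERGED[group]
                share = rng.uniform(0.65, 0.92)
                others = [c for c in MERGED_CATEGORIES if c != focal]
                rest = rng.dirichlet(np.ones(len(others))) * (1 - share)
                merged = dict(zip(others, rest))
                merged[focal] = share
                break
        raw = dict.fromkeys(RAW_CATEGORIES, 0.0)
        for cat, value in merged.items():
            targets = _MERGED_TO_RAW[cat]
            split = rng.dirichlet(np.ones(len(targets))) if len(targets) > 1 else np.array([1.0])
            for col, frac in zip(targets, split):
                raw[col] += 100.0 * value * frac
        rows.append(raw)
    table = pd.DataFrame(rows, index=[str(t) for t in tip_labels])
    table.index.name = "species"
    return table


def simulate_foraging_table(
    tip_labels: Sequence[str],
    group_labels: Mapping[str, str] | Sequence[str],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """30-column foraging table scored from regime-typical statements."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not isinstance(group_labels, Mapping):
        group_labels = dict(zip(tip_labels, group_labels))
    qualifiers = ["mostly", "sometimes", "occasionally", "unqualified"]
    rows = {}
    for tip in tip_labels:
        pool = _GROUP_BEHAVIOURS[group_labels[str(tip)]]
        k = int(rng.integers(1, min(3, len(pool)) + 1))
        chosen = list(rng.choice(pool, size=k, replace=False))
        if k == 1:
            entries = [(chosen[0], "sole")]
        else:
            entries = [(chosen[0], "mostly")] + [
                (b, qualifiers[int(rng.integers(1, len(qualifiers)))]) for b in chosen[1:]
            ]
        rows[str(tip)] = score_foraging(ForagingStatement(tuple(entries)))
    table = pd.DataFrame(rows).T.reindex(columns=list(FORAGING_BEHAVIOURS))
    table.index.name = "species"
    return table


def synthetic_partition(n_landmarks: int, modules: Sequence[str] = DEFAULT_MODULES) -> ModulePartition:
    """Contiguous split of ``1..L`` into named modules of near-equal size."""
    bounds = np.linspace(0, n_landmarks, len(modules) + 1).astype(int)
    mapping = {}
    for m, (lo, hi) in zip(modules, zip(bounds[:-1], bounds[1:])):
        for i in range(lo + 1, hi + 1):
            mapping[i] = m
    return ModulePartition(mapping)


def generate_scenario_bundle(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Generate a full analysis bundle on disk.

    Writes landmarks CSV (posed raw data), Newick tree, module partition,
    resource CSV, foraging CSV, true group TSV and a truth JSON with all
    parameters and seeds. Returns the file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_yule_tree(scenario.n_tips, scenario.tree_seed)
    painting = assign_regimes(
        tree, list(scenario.regimes), scenario.regime_switch_rate,
        np.random.default_rng(scenario.tree_seed + 1),
    )
    shapes = simulate_shape_dataset(tree, painting, scenario)
    resources = simulate_resource_table(shapes.raw.taxa, shapes.groups, scenario.diet_seed)
    foraging = simulate_foraging_table(shapes.raw.taxa, shapes.groups, scenario.diet_seed + 1)
    partition = synthetic_partition(scenario.n_landmarks)

    paths = {
        "landmarks": outdir / "landmarks.csv",
        "tree": outdir / "tree.nwk",
        "partition": outdir / "partition.csv",
        "resources": outdir / "resources.csv",
        "foraging": outdir / "foraging.csv",
        "groups": outdir / "true_groups.tsv",
        "truth": outdir / "truth.json",
    }
    write_landmarks([shapes.raw.configuration(i) for i in range(shapes.raw.n_specimens)],
                    paths["landmarks"])
    tree.write(path=str(paths["tree"]), schema="newick", suppress_rooting=True)
    write_partition(partition, paths["partition"])
    resources.round(9).to_csv(paths["resources"])
    foraging.round(9).to_csv(paths["foraging"])
    pd.Series(shapes.groups, name="group").rename_axis("species").to_csv(paths["groups"], sep="\t")
    truth = {
        "scenario": shapes.params,
        "root_regime": painting.root_regime,
        "n_switches": painting.n_switches,
        "tip_regimes": shapes.groups,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
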