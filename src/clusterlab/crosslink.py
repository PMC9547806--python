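"""Stochastic simulation of bivalent-antibody crosslinking of pentameric receptors.

The acetylcholine receptor is a pentamer with two alpha subunits and one each
of beta, delta and epsilon, so an antibody against a non-alpha subunit finds
one epitope per receptor while an anti-alpha antibody finds two.  IgG is
bivalent: one Fab arm binds from solution, the second arm can then capture a
free compatible epitope on another receptor, crosslinking the two.  The
geometry of the epitope map alone therefore dictates the aggregation regime:

* a single non-alpha specificity can only pair receptors (dimers),
* a single anti-alpha specificity builds linear chains (receptor degree <= 2),
* two different specificities give each receptor more than two linkable
  epitope classes, allowing branched, lattice-like aggregates.

The kinetic scheme is a random-sequential-attachment (Gillespie) loop with
two rate constants and no unbinding: a solution antibody binds a free
compatible epitope with weight ``k_on`` per molecule-epitope pair, and a
singly-bound antibody's free arm binds a free compatible epitope on another
receptor with weight ``k_cross`` per arm-epitope pair.  ``k_cross`` defaults
to a value well above ``k_on`` because the tethered second arm is held at the
membrane, where the local antigen concentration (receptors ~10 nm apart at
synaptic densities) vastly exceeds the solution concentration.

Aggregates are scored as connected components of the receptor projection of
the bipartite receptor-antibody graph.  ``complement_proxy`` reports the
fraction of receptors residing in components of at least ``s_min`` receptors,
a monotone stand-in for the formation of complement-activating antibody
platforms; it is validated qualitatively (single vs. combination patterns),
not as a calibrated C3 predictor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

#: Subunit composition of the adult muscle-type acetylcholine receptor.
DEFAULT_STOICHIOMETRY = {"alpha": 2, "beta": 1, "delta": 1, "epsilon": 1}


@dataclass(frozen=True)
class Stoichiometry:
    """Epitope copies per receptor, keyed by subunit name."""

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_STOICHIOMETRY))

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise InvalidArgumentError("epitope counts must be >= 0")
        if sum(self.counts.values()) < 1:
            raise InvalidArgumentError("a receptor must carry at least one epitope")

    @property
    def subunits(self) -> tuple[str, ...]:
        return tuple(self.counts)

    @property
    def total_epitopes(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class AntibodySpecies:
    """A bivalent antibody species with a single subunit specificity.

    ``subclass_label`` (e.g. IgG1/IgG4) is carried as metadata only; the
    simulator models crosslinking, not Fc effector function.
    """

    id: str
    target_subunit: str
    molecule_count: int
    valence: int = 2
    subclass_label: str = ""

    def __post_init__(self) -> None:
        if self.valence != 2:
            raise InvalidArgumentError("only bivalent antibodies are modelled")
        if self.molecule_count < 0:
            raise InvalidArgumentError("molecule_count must be >= 0")


@dataclass(frozen=True)
class BindingParams:
    """Kinetic and topological knobs of the attachment loop.

    ``k_on``/``k_cross`` are per-pair event weights in arbitrary units (only
    their ratio matters).  ``capture_radius`` (nm) restricts second-arm
    binding in ``geometric`` mode; the 15 nm default is the scale of epitope
    separation a bivalent IgG can span.
    """

    k_on: float = 1.0
    k_cross: float = 5.0
    allow_intra_receptor: bool = False
    allow_cycles: bool = True
    max_events: int | None = None
    mode: str = "well_mixed"  # or "geometric"
    capture_radius: float = 15.0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_cross < 0:
            raise InvalidArgumentError("rates must be >= 0")
        if self.max_events is not None and self.max_events < 0:
            raise InvalidArgumentError("max_events must be >= 0")
        if self.capture_radius <= 0:
            raise InvalidArgumentError("capture_radius must be > 0")
        if self.mode not in ("well_mixed", "geometric"):
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")


@dataclass
class ReceptorPool:
    """``n`` receptors with identical epitope slots, optionally positioned."""

    n: int
    stoichiometry: Stoichiometry
    positions: np.ndarray | None = None  # (n, 2) in micrometres


def make_receptor_pool(n: int, stoichiometry: Stoichiometry | None = None) -> ReceptorPool:
    """Create ``n`` receptors with all epitopes free."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    return ReceptorPool(n=n, stoichiometry=stoichiometry or Stoichiometry())


def place_receptors(pool: ReceptorPool, density_per_um2: float, seed: int) -> ReceptorPool:
    """Scatter the pool uniformly on a square patch of membrane.

    The patch side is chosen so the mean density equals ``density_per_um2``
    (receptors per square micrometre).
    """
    if density_per_um2 <= 0:
        raise InvalidArgumentError("density must be > 0")
    rng = np.random.default_rng(seed)
    side = math.sqrt(pool.n / density_per_um2)
    pos = rng.uniform(0.0, side, size=(pool.n, 2))
    return ReceptorPool(n=pool.n, stoichiometry=pool.stoichiometry, positions=pos)


@dataclass
class BoundAntibody:
    """An antibody instance with one or two attachment records."""

    species_id: str
    target_subunit: str
    attachments: list[tuple[int, str, int]]  # (receptor, subunit, slot index)

    @property
    def receptors(self) -> tuple[int, ...]:
        return tuple(a[0] for a in self.attachments)


@dataclass
class CrosslinkGraph:
    """Final binding state: bipartite receptor-antibody incidences."""

    n_receptors: int
    stoichiometry: Stoichiometry
    antibodies: list[BoundAntibody]
    solution_remaining: dict[str, int]
    positions: np.ndarray | None = None

    def receptor_edges(self) -> list[tuple[int, int]]:
        """Inter-receptor links: one edge per doubly, heterologously bound antibody."""
        edges = []
        for ab in self.antibodies:
            if len(ab.attachments) == 2:
                r1, r2 = ab.receptors
                if r1 != r2:
                    edges.append((r1, r2))
        return edges

    def receptor_degree(self) -> np.ndarray:
        """Number of inter-receptor links incident on each receptor."""
        deg = np.zeros(self.n_receptors, dtype=int)
        for r1, r2 in self.receptor_edges():
            deg[r1] += 1
            deg[r2] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_receptors))
        g.add_edges_from(self.receptor_edges())
        return g

    def validate(self) -> None:
        """Assert the structural invariants; raises ``AssertionError`` on breach."""
        seen_epitopes: set[tuple[int, str, int]] = set()
        for ab in self.antibodies:
            assert 1 <= len(ab.attachments) <= 2, "antibody with 0 or >2 attachments"
            for rec, sub, slot in ab.attachments:
                assert 0 <= rec < self.n_receptors, "attachment to unknown receptor"
                assert sub == ab.target_subunit, "attachment off-target"
                assert 0 <= slot < self.stoichiometry.counts[sub], "bad slot index"
                key = (rec, sub, slot)
                assert key not in seen_epitopes, "epitope bound twice"
                seen_epitopes.add(key)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra


def simulate_binding(
    pool: ReceptorPool,
    species: list[AntibodySpecies],
    params: BindingParams | None = None,
    seed: int = 0,
) -> CrosslinkGraph:
    """Run the random-sequential-attachment loop to exhaustion.

    Candidate events and weights:

    * solution binding — one molecule of species ``s`` binds a uniformly
      chosen free epitope of its target subunit, total weight
      ``k_on * n_solution(s) * n_free_epitopes(subunit)``;
    * crosslinking — a uniformly chosen (singly-bound antibody, free
      compatible epitope) pair binds, weight ``k_cross`` per eligible pair.
      Pairs on the anchor receptor itself are eligible only with
      ``allow_intra_receptor``; with ``allow_cycles=False`` pairs inside the
      anchor's current component are excluded; in ``geometric`` mode only
      epitopes on receptors within ``capture_radius`` of the anchor qualify.

    The loop ends when no event has positive weight or ``max_events`` is
    reached.  Identical ``(pool, species, params, seed)`` give identical
    graphs.
    """
    params = params or BindingParams()
    stoich = pool.stoichiometry
    subunits = list(stoich.subunits)
    sub_index = {s: i for i, s in enumerate(subunits)}
    for sp in species:
        if sp.target_subunit not in sub_index:
            raise InvalidArgumentError(
                f"species {sp.id!r} targets unknown subunit {sp.target_subunit!r}"
            )
    if params.mode == "geometric" and pool.positions is None:
        raise InvalidArgumentError("geometric mode requires receptor positions")

    rng = np.random.default_rng(seed)
    n = pool.n
    n_sub = len(subunits)

    # free epitope bookkeeping: swap-remove lists + per-receptor counts
    free_slots: list[list[tuple[int, int]]] = [[] for _ in range(n_sub)]
    slot_pos: list[dict[tuple[int, int], int]] = [dict() for _ in range(n_sub)]
    for si, s in enumerate(subunits):
        for r in range(n):
            for k in range(stoich.counts[s]):
                slot_pos[si][(r, k)] = len(free_slots[si])
                free_slots[si].append((r, k))
    free_per_receptor = np.zeros((n, n_sub), dtype=np.int64)
    for si, s in enumerate(subunits):
        free_per_receptor[:, si] = stoich.counts[s]

    solution = [sp.molecule_count for sp in species]
    antibodies: list[BoundAntibody] = []
    # singly-bound antibody indices grouped by target subunit (swap-remove lists)
    singly: list[list[int]] = [[] for _ in range(n_sub)]
    singly_pos: dict[int, int] = {}
    anchored = np.zeros((n, n_sub), dtype=np.int64)  # singly-bound abs per (receptor, subunit)
    blocked = np.zeros(n_sub, dtype=np.int64)  # sum over singly abs of free slots on own receptor

    fast_path = params.mode == "well_mixed" and params.allow_cycles
    uf = _UnionFind(n)
    comp_free: dict[int, np.ndarray] | None = None
    if not params.allow_cycles:
        comp_free = {r: free_per_receptor[r].copy() for r in range(n)}

    neighbors: list[np.ndarray] | None = None
    if params.mode == "geometric":
        pos = pool.positions
        radius_um = params.capture_radius / 1000.0
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        nb_mask = (d2 <= radius_um**2) & ~np.eye(n, dtype=bool)
        neighbors = [np.flatnonzero(nb_mask[r]) for r in range(n)]

    def occupy(r: int, si: int, k: int) -> None:
        lst, posmap = free_slots[si], slot_pos[si]
        i = posmap.pop((r, k))
        last = lst[-1]
        lst[i] = last
        lst.pop()
        if i < len(lst):
            posmap[last] = i
        free_per_receptor[r, si] -= 1
        blocked[si] -= anchored[r, si]
        if comp_free is not None:
            comp_free[uf.find(r)][si] -= 1

    def add_singly(ab_idx: int, r: int, si: int) -> None:
        singly_pos[ab_idx] = len(singly[si])
        singly[si].append(ab_idx)
        anchored[r, si] += 1
        blocked[si] += free_per_receptor[r, si]

    def remove_singly(ab_idx: int, r: int, si: int) -> None:
        lst = singly[si]
        i = singly_pos.pop(ab_idx)
        last = lst[-1]
        lst[i] = last
        lst.pop()
        if i < len(lst):
            singly_pos[last] = i
        anchored[r, si] -= 1
        blocked[si] -= free_per_receptor[r, si]

    def eligible_pairs_slow(si: int) -> list[tuple[int, int, int]]:
        """Explicit (antibody, receptor, slot) candidates for constrained modes."""
        out = []
        for ab_idx in singly[si]:
            anchor = antibodies[ab_idx].attachments[0][0]
            if neighbors is not None:
                cand_recs = list(neighbors[anchor])
                if params.allow_intra_receptor:
                    cand_recs.append(anchor)
            else:
                cand_recs = None  # all receptors
            for (r, k) in free_slots[si]:
                if cand_recs is not None and r not in cand_recs:
                    continue
                if r == anchor and not params.allow_intra_receptor:
                    continue
                if not params.allow_cycles and uf.find(r) == uf.find(anchor):
                    continue
                out.append((ab_idx, r, k))
        return out

    max_events = params.max_events if params.max_events is not None else np.inf
    n_events = 0
    while n_events < max_events:
        weights: list[float] = []
        actions: list[tuple] = []
        for spi, sp in enumerate(species):
            si = sub_index[sp.target_subunit]
            w = params.k_on * solution[spi] * len(free_slots[si])
            if w > 0:
                weights.append(w)
                actions.append(("on", spi, si))
        slow_pairs: dict[int, list] = {}
        for si in range(n_sub):
            if not singly[si] or not free_slots[si]:
                continue
            if fast_path:
                total_pairs = len(singly[si]) * len(free_slots[si])
                if not params.allow_intra_receptor:
                    total_pairs -= int(blocked[si])
                w = params.k_cross * total_pairs
            else:
                slow_pairs[si] = eligible_pairs_slow(si)
                w = params.k_cross * len(slow_pairs[si])
            if w > 0:
                weights.append(w)
                actions.append(("cross", si))
        if not weights:
            break
        wa = np.asarray(weights)
        choice = int(rng.choice(len(wa), p=wa / wa.sum()))
        action = actions[choice]

        if action[0] == "on":
            _, spi, si = action
            r, k = free_slots[si][int(rng.integers(len(free_slots[si])))]
            occupy(r, si, k)
            solution[spi] -= 1
            ab = BoundAntibody(
                species_id=species[spi].id,
                target_subunit=subunits[si],
                attachments=[(r, subunits[si], k)],
            )
            antibodies.append(ab)
            add_singly(len(antibodies) - 1, r, si)
        else:
            _, si = action
            if fast_path:
                # uniform over eligible (antibody, epitope) pairs via rejection
                while True:
                    ab_idx = singly[si][int(rng.integers(len(singly[si])))]
                    r, k = free_slots[si][int(rng.integers(len(free_slots[si])))]
                    anchor = antibodies[ab_idx].attachments[0][0]
                    if params.allow_intra_receptor or r != anchor:
                        break
            else:
                pairs = slow_pairs[si]
                ab_idx, r, k = pairs[int(rng.integers(len(pairs)))]
                anchor = antibodies[ab_idx].attachments[0][0]
            remove_singly(ab_idx, anchor, si)
            if comp_free is not None:
                ra, rb = uf.find(anchor), uf.find(r)
                if ra != rb:
                    merged = comp_free.pop(rb) + comp_free[ra]
                    root = uf.union(anchor, r)
                    comp_free[root] = merged
            else:
                uf.union(anchor, r)
            occupy(r, si, k)
            antibodies[ab_idx].attachments.append((r, subunits[si], k))
        n_events += 1

    graph = CrosslinkGraph(
        n_receptors=n,
        stoichiometry=stoich,
        antibodies=antibodies,
        solution_remaining={sp.id: solution[i] for i, sp in enumerate(species)},
        positions=pool.positions,
    )
    graph.validate()
    return graph


@dataclass(frozen=True)
class AggregateStats:
    """Connected-component sizes of the receptor projection."""

    component_sizes: tuple[int, ...]  # sorted descending

    @property
    def n_receptors(self) -> int:
        return int(sum(self.component_sizes))

    @property
    def max_size(self) -> int:
        return int(self.component_sizes[0]) if self.component_sizes else 0

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.component_sizes)) if self.component_sizes else float("nan")

    def fraction_in_components_ge(self, k: int) -> float:
        """Fraction of receptors residing in components of >= ``k`` receptors."""
        if k < 1:
            raise InvalidArgumentError("k must be >= 1")
        if not self.component_sizes:
            return 0.0
        sizes = np.asarray(self.component_sizes)
        return float(sizes[sizes >= k].sum() / sizes.sum())


def component_stats(graph: CrosslinkGraph) -> AggregateStats:
    """Exact component sizes: receptors connected iff sharing an antibody."""
    g = graph.to_networkx()
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return AggregateStats(component_sizes=tuple(sizes))


def complement_proxy(stats: AggregateStats, s_min: int = 4) -> float:
    """Fraction of receptors in aggregates of >= ``s_min`` receptors.

    A monotone stand-in for the capacity of crosslinked receptor-antibody
    platforms to initiate complement activation.
    """
    if s_min < 1:
        raise InvalidArgumentError("s_min must be >= 1")
    return stats.fraction_in_components_ge(s_min)


def saturating_antibody_count(n_receptors: int, stoichiometry: Stoichiometry | None = None) -> int:
    """Molecule count matching the largest per-subunit epitope pool.

    With the default pentamer stoichiometry this is ``2 * n_receptors``
    (the alpha epitope count), enough to occupy every epitope of any single
    target subunit.
    """
    stoich = stoichiometry or Stoichiometry()
    return n_receptors * max(stoich.counts.values())


def sweep_combinations(
    n_receptors: int,
    panel: list[AntibodySpecies],
    seeds: list[int] | np.ndarray,
    params: BindingParams | None = None,
    total_count: int | None = None,
    stoichiometry: Stoichiometry | None = None,
    s_min: int = 4,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Mean aggregate statistics for every single and pair in a panel.

    Singles are run at ``total_count`` molecules; pairs at half that count of
    each species, so total antibody is matched across conditions (the
    experimental convention for combination assays).  Returns a long-format
    table with one row per condition: ``species_a == species_b`` marks a
    single.
    """
    if not panel:
        raise InvalidArgumentError("panel must contain at least one species")
    seeds = list(seeds)
    if not seeds:
        raise InvalidArgumentError("at least one seed is required")
    params = params or BindingParams()
    stoich = stoichiometry or Stoichiometry()
    if total_count is None:
        total_count = saturating_antibody_count(n_receptors, stoich)
    if total_count % 2:
        raise InvalidArgumentError("total_count must be even so pairs can split it equally")
    by_id = {sp.id: sp for sp in panel}
    if len(by_id) != len(panel):
        raise InvalidArgumentError("panel species ids must be unique")

    conditions: list[tuple[str, str, list[AntibodySpecies]]] = []
    for sp in panel:
        conditions.append((sp.id, sp.id, [replace(sp, molecule_count=total_count)]))
    if pairs is None:
        pairs = [(a.id, b.id) for a, b in itertools.combinations(panel, 2)]
    for a_id, b_id in pairs:
        half = total_count // 2
        conditions.append(
            (a_id, b_id,
             [replace(by_id[a_id], molecule_count=half),
              replace(by_id[b_id], molecule_count=half)])
        )

    rows = []
    for a_id, b_id, specs in conditions:
        mean_sizes, proxies = [], []
        for sd in seeds:
            pool = make_receptor_pool(n_receptors, stoich)
            stats = component_stats(simulate_binding(pool, specs, params, seed=sd))
            mean_sizes.append(stats.mean_size)
            proxies.append(complement_proxy(stats, s_min))
        rows.append(
            {
                "species_a": a_id,
                "species_b": b_id,
                "mean_size_mean": float(np.mean(mean_sizes)),
                "mean_size_sd": float(np.std(mean_sizes, ddof=1)) if len(seeds) > 1 else 0.0,
                "proxy_mean": float(np.mean(proxies)),
                "proxy_sd": float(np.std(proxies, ddof=1)) if len(seeds) > 1 else 0.0,
                "n_seeds": len(seeds),
            }
        )
    return pd.DataFrame(rows)


def synergy_matrix(sweep: pd.DataFrame, value: str = "proxy_mean") -> pd.DataFrame:
    """Pivot a sweep table into a symmetric species-by-species matrix."""
    labels = sorted(set(sweep["species_a"]) | set(sweep["species_b"]))
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for _, row in sweep.iterrows():
        mat.loc[row["species_a"], row["species_b"]] = row[value]
        mat.loc[row["species_b"], row["species_a"]] = row[value]
    return mat
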