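"""Synthetic data: multispecies coalescent on a species network.

Gene trees are simulated under the multispecies coalescent on an ultrametric
species tree (branch lengths in coalescent units) optionally carrying hybrid
edges.  A hybrid edge is an instantaneous admixture pulse: at its time point,
every gene lineage currently in the recipient branch independently reroutes
into the donor branch with probability gamma (bidirectional edges carry a
second proportion for the reverse move).  Within every branch, co-resident
lineage pairs coalesce at rate 1 per pair per coalescent time unit.

Sequences evolve by Jukes-Cantor along the simulated gene trees, with branch
lengths converted to substitutions/site through a single rate parameter.
Random streams are keyed per locus by (seed, locus index), so any subset of
loci reproduces identically regardless of the total locus count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .alignio import Alignment
from .errors import ConfigError, MissingTaxonError
from .treeio import GeneTreeSet, RootedTree

__all__ = [
    "HybridEdge",
    "SpeciesNetwork",
    "SimulationConfig",
    "simulate_gene_trees",
    "simulate_alignments",
    "random_ultrametric_tree",
    "attach_outgroup",
    "costus_like_preset",
    "expected_rt_gamma",
]


@dataclass(frozen=True)
class HybridEdge:
    """One admixture pulse.

    ``donor`` and ``recipient`` name branches: a tip label, or a
    '|'-separated tip set whose MRCA's stem branch is meant.  ``time`` is the
    pulse time before present (coalescent units); it must fall strictly
    inside the temporal span of both branches.  ``gamma`` is the probability
    a recipient-branch lineage follows the donor branch; ``gamma_back`` > 0
    makes the edge bidirectional.
    """

    donor: str
    recipient: str
    time: float
    gamma: float
    gamma_back: float = 0.0


class SpeciesNetwork:
    """A rooted ultrametric species tree plus hybrid edges."""

    def __init__(self, tree: RootedTree, hybrid_edges: Sequence[HybridEdge] = ()) -> None:
        self.tree = tree
        self.hybrid_edges: List[HybridEdge] = list(hybrid_edges)
        self.ages = tree.node_ages()
        tip_ages = self.ages[tree.tips]
        span = self.ages.max() if self.ages.max() > 0 else 1.0
        if np.any(np.abs(tip_ages) > 1e-6 * span):
            raise ConfigError("species tree must be ultrametric (tips at age 0)")
        if np.any(np.nan_to_num(tree.length, nan=0.0) < 0):
            raise ConfigError("negative branch length in species tree")
        for edge in self.hybrid_edges:
            self._validate_edge(edge)

    def branch_node(self, spec: str) -> int:
        """Resolve a branch description to the node below that branch."""
        labels = spec.split("|")
        for lab in labels:
            if lab not in self.tree:
                raise MissingTaxonError(f"taxon {lab!r} not in species tree")
        if len(labels) == 1:
            return self.tree.tip_node(labels[0])
        node = self.tree.tip_node(labels[0])
        want = set(labels)
        tipsets = self.tree.clade_tipsets()
        while node >= 0 and not want <= set(tipsets[node]):
            node = int(self.tree.parent[node])
        return node

    def _branch_span(self, node: int) -> Tuple[float, float]:
        lo = float(self.ages[node])
        parent = int(self.tree.parent[node])
        hi = math.inf if parent < 0 else float(self.ages[parent])
        return lo, hi

    def _validate_edge(self, edge: HybridEdge) -> None:
        for g in (edge.gamma, edge.gamma_back):
            if not 0.0 <= g <= 1.0:
                raise ConfigError(f"gamma must be in [0, 1], got {g}")
        for spec in (edge.donor, edge.recipient):
            lo, hi = self._branch_span(self.branch_node(spec))
            if not lo < edge.time < hi:
                raise ConfigError(
                    f"hybrid-edge time {edge.time} outside branch {spec!r} span ({lo}, {hi})"
                )

    @property
    def taxa(self) -> List[str]:
        return self.tree.taxa

    def to_yaml(self, path: str) -> None:
        from .treeio import write_newick

        doc = {
            "tree": write_newick(self.tree),
            "hybrid_edges": [
                {
                    "donor": e.donor,
                    "recipient": e.recipient,
                    "time": float(e.time),
                    "gamma": float(e.gamma),
                    "gamma_back": float(e.gamma_back),
                }
                for e in self.hybrid_edges
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SpeciesNetwork":
        from .treeio import parse_newick

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        edges = [HybridEdge(**e) for e in doc.get("hybrid_edges", [])]
        return cls(parse_newick(doc["tree"]), edges)


@dataclass
class SimulationConfig:
    """Reproducible description of one synthetic dataset."""

    n_loci: int = 756
    locus_length: int = 1951
    subst_rate: float = 0.01  # substitutions per site per coalescent unit
    seed: int = 0
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.n_loci <= 0 or self.locus_length <= 0:
            raise ConfigError("n_loci and locus_length must be positive")
        if self.subst_rate < 0:
            raise ConfigError("substitution rate must be nonnegative")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ----------------------------------------------------------------- gene trees
def _prepare_events(network: SpeciesNetwork):
    tree = network.tree
    ages = network.ages
    depth = tree.topo_depth()
    events: List[Tuple[float, int, int, object]] = []
    for node in range(tree.n_nodes):
        if not tree.is_tip(node):
            # deeper nodes first among simultaneous speciations (zero-length
            # internal branches), so children merge before their parent
            events.append((float(ages[node]), 1, -int(depth[node]), node))
    for edge in network.hybrid_edges:
        moves = [(network.branch_node(edge.recipient), network.branch_node(edge.donor), edge.gamma)]
        if edge.gamma_back > 0.0:
            moves.append(
                (network.branch_node(edge.donor), network.branch_node(edge.recipient), edge.gamma_back)
            )
        events.append((float(edge.time), 0, 0, moves))
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    return [(t, kind, payload) for t, kind, _, payload in events]


def _coalesce(lineages, t0, t1, rng, parent, node_time, next_id):
    """Coalesce a branch's lineage list over (t0, t1); mutates in place."""
    k = len(lineages)
    t = t0
    while k >= 2:
        t += rng.exponential(2.0 / (k * (k - 1)))
        if t >= t1:
            break
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        node_time[next_id] = t
        parent[lineages[i]] = next_id
        parent[lineages[j]] = next_id
        if i < j:
            lineages[j] = lineages[k - 1]
            lineages[i] = next_id
        else:
            lineages[i] = lineages[k - 1]
            lineages[j] = next_id
        lineages.pop()
        next_id += 1
        k -= 1
    return next_id


def _simulate_locus(network: SpeciesNetwork, events, rng) -> RootedTree:
    tree = network.tree
    tips = tree.tips
    n_tips = len(tips)
    max_nodes = 2 * n_tips - 1
    parent = np.full(max_nodes, -1, dtype=np.int64)
    node_time = np.zeros(max_nodes)
    active: Dict[int, List[int]] = {tip: [i] for i, tip in enumerate(tips)}
    next_id = n_tips
    t_prev = 0.0
    for t_event, kind, payload in events:
        for lineages in active.values():
            next_id = _coalesce(lineages, t_prev, t_event, rng, parent, node_time, next_id)
        if kind == 0:  # hybrid pulse: decide all moves from a pre-pulse snapshot
            staged = []
            for src, dst, gamma in payload:  # type: ignore[misc]
                pool = active.get(src, [])
                if pool:
                    mask = rng.random(len(pool)) < gamma
                    staged.append((src, dst, [lin for lin, m in zip(pool, mask) if m]))
            for src, dst, movers in staged:
                if movers:
                    active[src] = [l for l in active[src] if l not in movers]
                    active.setdefault(dst, []).extend(movers)
        else:  # speciation: child branches merge into the parent branch
            node = payload  # type: ignore[assignment]
            merged: List[int] = []
            for child in tree.children[node]:  # type: ignore[index]
                merged.extend(active.pop(child, []))
            if node in active:  # lineages parked here by an earlier pulse
                merged.extend(active.pop(node))
            active[node] = merged
        t_prev = t_event
    lineages = [lin for pool in active.values() for lin in pool]
    next_id = _coalesce(lineages, t_prev, math.inf, rng, parent, node_time, next_id)
    n_used = next_id
    lengths = np.full(n_used, np.nan)
    labels: List[Optional[str]] = [None] * n_used
    for i, tip in enumerate(tips):
        labels[i] = tree.label[tip]
    has_parent = parent[:n_used] >= 0
    lengths[has_parent] = node_time[parent[:n_used][has_parent]] - node_time[:n_used][has_parent]
    return RootedTree(parent[:n_used], lengths, labels)


def simulate_gene_trees(
    network: SpeciesNetwork,
    n_loci: int,
    seed: int,
    locus_offset: int = 0,
) -> GeneTreeSet:
    """Simulate one gene tree per locus under the network's coalescent model.

    Gene-tree branch lengths are in coalescent units.  Locus ``i`` uses the
    random stream keyed by ``(seed, locus_offset + i)``.
    """
    if n_loci <= 0:
        raise ConfigError("n_loci must be positive")
    events = _prepare_events(network)
    items = []
    for i in range(n_loci):
        rng = np.random.default_rng([seed, locus_offset + i])
        items.append((f"L{locus_offset + i:05d}", _simulate_locus(network, events, rng)))
    return GeneTreeSet(items)


# ------------------------------------------------------------------ sequences
def _evolve_jc(tree: RootedTree, n_sites: int, rate: float, rng) -> np.ndarray:
    """JC69 evolution of i.i.d. sites; returns (n_tips, n_sites) uint8."""
    seqs = np.empty((tree.n_nodes, n_sites), dtype=np.uint8)
    seqs[tree.root] = rng.integers(0, 4, n_sites, dtype=np.uint8)
    for node in tree.preorder():
        if node == tree.root:
            continue
        d = float(tree.length[node]) * rate
        p_diff = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
        parent_seq = seqs[tree.parent[node]]
        child = parent_seq.copy()
        if p_diff > 0:
            mask = rng.random(n_sites) < p_diff
            n_mut = int(mask.sum())
            if n_mut:
                child[mask] = (child[mask] + rng.integers(1, 4, n_mut, dtype=np.uint8)) % 4
        seqs[node] = child
    return seqs[tree.tips]


def simulate_alignments(
    gene_trees: GeneTreeSet,
    locus_length: int,
    rate: float,
    seed: int,
) -> List[Tuple[str, Alignment]]:
    """Evolve a fixed-length JC69 alignment along every gene tree.

    ``rate`` converts coalescent-unit branch lengths into expected
    substitutions per site.  Locus streams are keyed by (seed, locus index,
    1) so sequences and gene trees draw from independent streams.
    """
    out = []
    for i, (lid, tree) in enumerate(gene_trees):
        rng = np.random.default_rng([seed, i, 1])
        data = _evolve_jc(tree, locus_length, rate, rng)
        out.append((lid, Alignment(tree.taxa, data)))
    return out


# ------------------------------------------------------------ tree generators
def random_ultrametric_tree(
    n_tips: int,
    seed: int,
    height: Optional[float] = None,
    tip_prefix: str = "sp",
) -> RootedTree:
    """Random ultrametric topology from a Yule (pure-birth) process,
    optionally rescaled to a fixed root age.

    Node ages are spread across the whole depth of the tree, giving the mix
    of recent sister pairs and short mid-tree internal branches (high ILS)
    the introgression tests are exercised on.
    """
    rng = np.random.default_rng(seed)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    birth = {0: 0.0}  # active lineage id -> birth time of its edge
    active = [0]
    nxt = 1
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        pick = int(rng.integers(k))
        lineage = active[pick]
        node_time[lineage] = t  # lineage becomes an internal node at t
        for _ in range(2):
            parent[nxt] = lineage
            birth[nxt] = t
            active.append(nxt)
            nxt += 1
        active[pick] = active[-1]
        active.pop()
        del birth[lineage]
    present = t + rng.exponential(1.0 / n_tips)
    for lineage in active:
        node_time[lineage] = present
    if height is not None:
        root_time = node_time[0]
        scale = height / (present - root_time)
        node_time = (node_time - root_time) * scale
    labels: List[Optional[str]] = [None] * n_nodes
    tip_nodes = sorted(active)
    width = max(2, len(str(n_tips)))
    for i, node in enumerate(tip_nodes):
        labels[node] = f"{tip_prefix}{i + 1:0{width}d}"
    lengths = np.full(n_nodes, np.nan)
    has_parent = parent >= 0
    lengths[has_parent] = node_time[has_parent] - node_time[parent[has_parent]]
    return RootedTree(parent, lengths, labels)


def attach_outgroup(tree: RootedTree, outgroup: str = "OUT", root_age: float = 12.0) -> RootedTree:
    """Join an outgroup tip to an ultrametric ingroup tree at ``root_age``."""
    ages = tree.node_ages()
    if root_age <= ages.max():
        raise ConfigError("root_age must exceed the ingroup root age")
    n = tree.n_nodes
    parent = np.append(tree.parent, [n + 1, -1]).astype(np.int64)  # outgroup tip, new root
    parent[tree.root] = n + 1
    length = np.append(tree.length, [root_age, np.nan])
    length[tree.root] = root_age - ages.max()
    label = list(tree.label) + [outgroup, None]
    support = np.append(tree.support, [np.nan, np.nan])
    return RootedTree(parent, length, label, support)


# ---------------------------------------------------------------- the preset
_PRESET_TREE_SEED = 20187
_PRESET_GAMMAS = (0.45, 0.10, 0.22)


def _deep_partner(tree: RootedTree, ages: np.ndarray, tipsets, recipient: str, used: set) -> str:
    """Deterministically pick a donor tip: deep MRCA with the recipient, a
    long tip branch (so pulse times fit inside it), not yet used."""
    best, best_key = None, None
    for tip in tree.tips:
        lab = tree.label[tip]
        if lab in used or lab == "OUT":
            continue
        parent_age = ages[tree.parent[tip]]
        mrca_age = ages[tree.mrca(lab, recipient)]
        key = (round(float(mrca_age), 6), round(float(parent_age), 6), lab)
        if mrca_age > 1.0 and parent_age > 0.5 and (best_key is None or key > best_key):
            best, best_key = lab, key
    if best is None:
        raise ConfigError("preset construction failed: no suitable donor tip")
    return best


def costus_like_preset() -> Tuple[SimulationConfig, SpeciesNetwork]:
    """Synthetic study conditions: 54 ingroup tips + 1 distant outgroup,
    756 loci of 1951 bp, high ILS, and three hybrid edges with inheritance
    proportions 0.45 (tip-tip), 0.10 (tip-tip), 0.22 (tip into the stem of a
    cherry, i.e. an ancestral recipient).

    The species tree is a fixed random ultrametric 54-tip tree (root age 5
    coalescent units, outgroup at 12); hybrid-edge placements are chosen by
    deterministic structural rules, so the preset is bit-stable.
    """
    ingroup = random_ultrametric_tree(54, seed=_PRESET_TREE_SEED, height=5.0)
    tree = attach_outgroup(ingroup, outgroup="OUT", root_age=12.0)
    ages = tree.node_ages()
    tipsets = tree.clade_tipsets()

    # Sister pairs sorted by parent age: recipients come from well-formed
    # cherries so every planted edge is visible to sister-pair triplet tests.
    cherries = []
    for node in range(tree.n_nodes):
        kids = tree.children[node]
        if len(kids) == 2 and all(tree.is_tip(c) for c in kids):
            pair = sorted(tree.label[c] for c in kids)
            cherries.append((float(ages[node]), pair))
    cherries.sort()
    if len(cherries) < 4:
        raise ConfigError("preset tree lacks enough sister pairs")

    used: set = set()
    edges = []
    # Edge 1: tip-tip, strong (gamma 0.45).  Recipient from a recent cherry.
    age1, (r1, s1) = cherries[0]
    used |= {r1, s1}
    d1 = _deep_partner(tree, ages, tipsets, r1, used)
    used.add(d1)
    t1 = 0.5 * min(age1, float(ages[tree.parent[tree.tip_node(d1)]]))
    edges.append(HybridEdge(donor=d1, recipient=r1, time=t1, gamma=_PRESET_GAMMAS[0]))

    # Edge 2: tip-tip, weak (gamma 0.10).
    age2, (r2, s2) = next(c for c in cherries[1:] if not set(c[1]) & used)
    used |= {r2, s2}
    d2 = _deep_partner(tree, ages, tipsets, r2, used)
    used.add(d2)
    t2 = 0.5 * min(age2, float(ages[tree.parent[tree.tip_node(d2)]]))
    edges.append(HybridEdge(donor=d2, recipient=r2, time=t2, gamma=_PRESET_GAMMAS[1]))

    # Edge 3: ancestral recipient (gamma 0.22): the recipient is the stem
    # branch of a cherry, the donor a member of another sister pair whose
    # divergence is old enough that the pulse time fits inside the donor's
    # tip branch.  Pick the (recipient, donor) cherry pair maximizing the
    # temporal overlap window, deterministically.
    # The triplet-gamma expectation for this edge is gamma * (1 - exp(-t'))
    # with t' = donor sister-pair age - pulse time, so place the pulse early
    # in the recipient stem's span and prefer a donor whose own sister
    # divergence is deep.
    best = None
    for rc_age, rpair in cherries:
        if set(rpair) & used:
            continue
        stem_node = tree.mrca(rpair[0], rpair[1])
        stem_hi = float(ages[tree.parent[stem_node]])
        for dp_age, dpair in cherries:
            if set(dpair) & used or set(dpair) == set(rpair):
                continue
            window = min(stem_hi, dp_age) - rc_age
            if window <= 0:
                continue
            pulse = rc_age + 0.1 * window
            key = (round(dp_age - pulse, 9), rpair[0], dpair[0])
            if best is None or key > best[0]:
                best = (key, rc_age, rpair, dpair, stem_hi, dp_age)
    if best is None:
        raise ConfigError("preset construction failed: no ancestral-edge placement")
    _, rc_age, (c1, c2), dpair, stem_hi, dp_age = best
    used |= {c1, c2} | set(dpair)
    d3 = dpair[0]
    t3 = rc_age + 0.1 * (min(stem_hi, dp_age) - rc_age)
    edges.append(
        HybridEdge(donor=d3, recipient=f"{c1}|{c2}", time=t3, gamma=_PRESET_GAMMAS[2])
    )

    network = SpeciesNetwork(tree, edges)
    config = SimulationConfig(n_loci=756, locus_length=1951, subst_rate=0.01, seed=0, preset="costus_like")
    return config, network


# ------------------------------------------------------------- expectations
def expected_rt_gamma(network: SpeciesNetwork, edge: HybridEdge) -> float:
    """Closed-form expectation of the triplet gamma estimator for one edge,
    evaluated for the canonical detection triplet.

    An introgressed recipient lineage rides the donor's history from the
    pulse time tau_m and yields an excess minor topology only while the
    donor lineage is the sole triplet member it is co-resident with; once a
    second triplet taxon joins the pool, further coalescences are symmetric
    between the two minor pairings.  Over that window of length t',
    E[(minor2 - minor1) / total] = gamma * (1 - exp(-t')).

    For a tip recipient the detection test is (recipient, its sister,
    donor): the window ends at the donor/recipient species MRCA.  For an
    internal (ancestral) recipient branch the detection test places the
    donor inside the sister pair, so the window ends where the donor branch
    itself ends.
    """
    tree = network.tree
    ages = network.ages
    d_node = network.branch_node(edge.donor)
    r_node = network.branch_node(edge.recipient)
    if tree.is_tip(r_node):
        tipsets = tree.clade_tipsets()
        d_tip = sorted(tipsets[d_node])[0]
        r_tip = sorted(tipsets[r_node])[0]
        t_end = float(ages[tree.mrca(d_tip, r_tip)])
    else:
        t_end = float(ages[tree.parent[d_node]])
    return edge.gamma * (1.0 - math.exp(-(t_end - edge.time)))
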