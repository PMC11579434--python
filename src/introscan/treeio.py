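"""Rooted trees, triplet topologies, and gene concordance factors.

The scan pipeline manipulates two kinds of trees: a rooted species tree
(branch lengths in coalescent units) and per-locus gene trees (lengths in
substitutions/site, optional bootstrap supports on internal nodes).  Both are
held in :class:`RootedTree`, a light array-backed structure built for the
operations the introgression tests need — MRCA depth lookups, support
collapsing, outgroup rooting — rather than general tree editing.  Newick
parsing is delegated to dendropy; supports are read from internal-node labels
(the IQ-TREE / RAxML convention).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .errors import MissingTaxonError, NewickParseError

__all__ = [
    "RootedTree",
    "GeneTreeSet",
    "TripletSpec",
    "parse_newick",
    "write_newick",
    "root_with_outgroup",
    "collapse_low_support",
    "triplet_topology",
    "sister_pairs",
    "gene_concordance_factor",
    "read_tree",
    "read_gene_trees",
    "read_taxon_map",
    "select_representatives",
]

P1P2, P2P3, P1P3, UNRESOLVED = "P1P2", "P2P3", "P1P3", "UNRESOLVED"


@dataclass(frozen=True)
class TripletSpec:
    """One rooted-triplet test: putative sister pair (P1, P2), third taxon P3,
    and the outgroup used to root gene trees."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        labels = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(labels)) != 4:
            raise ValueError(f"triplet labels must be distinct, got {labels}")

    @property
    def ingroup(self) -> Tuple[str, str, str]:
        return (self.p1, self.p2, self.p3)

    @property
    def all_taxa(self) -> Tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.outgroup)


class RootedTree:
    """Rooted, labeled tree with branch lengths and optional per-edge support.

    Nodes are integer indices; ``parent[root] == -1``.  Tips carry labels,
    internal nodes may carry a raw label whose numeric value (if any) is the
    support of the edge above them, in [0, 100].
    """

    __slots__ = (
        "parent",
        "children",
        "length",
        "support",
        "label",
        "root",
        "_tip_index",
        "_tips",
    )

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        label: Sequence[Optional[str]],
        support: Optional[Sequence[float]] = None,
    ) -> None:
        n = len(parent)
        self.parent = np.asarray(parent, dtype=np.int32)
        self.length = np.asarray(length, dtype=np.float64)
        self.label: List[Optional[str]] = list(label)
        if support is None:
            self.support = np.full(n, np.nan)
        else:
            self.support = np.asarray(support, dtype=np.float64)
        self.children: List[List[int]] = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                if root >= 0:
                    raise ValueError("tree has more than one root")
                root = i
            else:
                self.children[p].append(i)
        if root < 0:
            raise ValueError("tree has no root")
        self.root = root
        self._tips = [i for i in range(n) if not self.children[i]]
        self._tip_index: Dict[str, int] = {}
        for i in self._tips:
            lab = self.label[i]
            if lab is None:
                raise ValueError(f"tip node {i} has no label")
            if lab in self._tip_index:
                raise NewickParseError(f"duplicate tip label {lab!r}")
            self._tip_index[lab] = i

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tips(self) -> List[int]:
        return list(self._tips)

    @property
    def taxa(self) -> List[str]:
        return [self.label[i] for i in self._tips]  # type: ignore[misc]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._tip_index

    def tip_node(self, taxon: str) -> int:
        try:
            return self._tip_index[taxon]
        except KeyError:
            raise MissingTaxonError(f"taxon {taxon!r} not in tree") from None

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def postorder(self) -> List[int]:
        order: List[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def preorder(self) -> List[int]:
        order: List[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children[node]))
        return order

    def topo_depth(self) -> np.ndarray:
        """Number of edges from the root, per node."""
        d = np.zeros(self.n_nodes, dtype=np.int32)
        for node in self.preorder():
            if node != self.root:
                d[node] = d[self.parent[node]] + 1
        return d

    def node_times(self) -> np.ndarray:
        """Cumulative branch length from the root, per node (missing lengths
        count as 0)."""
        t = np.zeros(self.n_nodes)
        lengths = np.nan_to_num(self.length, nan=0.0)
        for node in self.preorder():
            if node != self.root:
                t[node] = t[self.parent[node]] + lengths[node]
        return t

    def node_ages(self) -> np.ndarray:
        """Time before the most recent tip, per node (ultrametric trees)."""
        t = self.node_times()
        return t[self._tips].max() - t

    def clade_tipsets(self) -> List[frozenset]:
        """Descendant tip-label set per node."""
        sets: List[Optional[frozenset]] = [None] * self.n_nodes
        for node in self.postorder():
            if self.is_tip(node):
                sets[node] = frozenset([self.label[node]])
            else:
                acc: set = set()
                for c in self.children[node]:
                    acc |= sets[c]  # type: ignore[arg-type]
                sets[node] = frozenset(acc)
        return sets  # type: ignore[return-value]

    def copy(self) -> "RootedTree":
        return RootedTree(
            self.parent.copy(), self.length.copy(), list(self.label), self.support.copy()
        )

    # ------------------------------------------------------------- MRCA math
    def mrca(self, a: str, b: str) -> int:
        """MRCA node of two tip labels, by parent walking."""
        na, nb = self.tip_node(a), self.tip_node(b)
        seen = set()
        while na >= 0:
            seen.add(na)
            na = self.parent[na]
        while nb not in seen:
            nb = self.parent[nb]
        return int(nb)

    def mrca_depth_matrix(self) -> Tuple[np.ndarray, List[str]]:
        """Topological depth of the MRCA for every pair of tips.

        Returns ``(M, taxa)`` where ``M[i, j]`` is the number of edges between
        the root and the MRCA of ``taxa[i]`` and ``taxa[j]``.  The diagonal
        holds tip depths.  A deeper (larger) entry for one pair of a triplet
        means that pair is sister within the triplet.
        """
        taxa = self.taxa
        k = len(taxa)
        pos = {t: i for i, t in enumerate(taxa)}
        M = np.zeros((k, k), dtype=np.int16)
        depth = self.topo_depth()
        below: List[Optional[np.ndarray]] = [None] * self.n_nodes
        for node in self.postorder():
            if self.is_tip(node):
                idx = np.array([pos[self.label[node]]], dtype=np.intp)
                M[idx, idx] = depth[node]
                below[node] = idx
            else:
                kids = [below[c] for c in self.children[node]]
                d = depth[node]
                for x, y in itertools.combinations(kids, 2):
                    M[np.ix_(x, y)] = d  # type: ignore[arg-type]
                    M[np.ix_(y, x)] = d  # type: ignore[arg-type]
                below[node] = np.concatenate(kids)  # type: ignore[arg-type]
        return M, taxa

    # ---------------------------------------------------------------- output
    def to_newick(self, include_lengths: bool = True, include_support: bool = True) -> str:
        return write_newick(self, include_lengths=include_lengths, include_support=include_support)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<RootedTree {len(self._tips)} tips, {self.n_nodes} nodes>"


def _format_length(x: float) -> str:
    return repr(round(float(x), 10))


def _node_newick(tree: RootedTree, node: int, include_lengths: bool, include_support: bool) -> str:
    if tree.is_tip(node):
        s = tree.label[node] or ""
    else:
        inner = ",".join(
            _node_newick(tree, c, include_lengths, include_support) for c in tree.children[node]
        )
        lab = ""
        if include_support and node != tree.root:
            if tree.label[node] is not None:
                lab = str(tree.label[node])
            elif not math.isnan(tree.support[node]):
                lab = _format_length(tree.support[node])
        s = f"({inner}){lab}"
    if include_lengths and node != tree.root and not math.isnan(tree.length[node]):
        s += f":{_format_length(tree.length[node])}"
    return s


def write_newick(tree: RootedTree, include_lengths: bool = True, include_support: bool = True) -> str:
    """Serialize a tree to a single Newick statement (supports as internal
    node labels)."""
    return _node_newick(tree, tree.root, include_lengths, include_support) + ";"


# ---------------------------------------------------------------------- parse
def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = []
    length = []
    label: List[Optional[str]] = []
    support = []
    for nd in nodes:
        parent.append(index[id(nd.parent_node)] if nd.parent_node is not None else -1)
        length.append(nd.edge.length if nd.edge.length is not None else np.nan)
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None:
                raise NewickParseError("unlabeled tip in Newick input")
            label.append(str(lab))
            support.append(np.nan)
        else:
            raw = nd.label
            label.append(str(raw) if raw is not None else None)
            try:
                support.append(float(raw))  # type: ignore[arg-type]
            except (TypeError, ValueError):
                support.append(np.nan)
    return RootedTree(parent, length, label, support)


def parse_newick(text: str) -> RootedTree:
    """Parse a single Newick statement into a :class:`RootedTree`.

    Support values are read from internal-node labels; quoted labels and
    underscored labels are preserved verbatim.  Malformed input raises
    :class:`NewickParseError` naming the offending position.
    """
    if text is None or not text.strip():
        raise NewickParseError("empty Newick input")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick statement must end with ';'")
    depth = 0
    for pos, ch in enumerate(stripped):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '(' in Newick statement")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except NewickParseError:
        raise
    except Exception as exc:  # dendropy reader errors carry position info
        raise NewickParseError(f"Newick parse failure: {exc}") from None
    return _from_dendropy(dtree)


def read_tree(path: str) -> RootedTree:
    with open(path) as fh:
        return parse_newick(fh.read())


# -------------------------------------------------------------------- rooting
def root_with_outgroup(tree: RootedTree, outgroup: str) -> RootedTree:
    """Root (or re-root) a tree so the outgroup tip is one child of the root.

    The unrooted topology is preserved; if the tree is already rooted in
    outgroup position it is returned unchanged.
    """
    og = tree.tip_node(outgroup)  # raises MissingTaxonError when absent
    if tree.parent[og] == tree.root and len(tree.children[tree.root]) == 2:
        return tree
    dtree = dendropy.Tree.get(
        data=write_newick(tree),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    og_node = None
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == outgroup:
            og_node = leaf

    assert og_node is not None
    half = (og_node.edge.length or 0.0) / 2.0
    dtree.reroot_at_edge(
        og_node.edge,
        length1=half,
        length2=half if og_node.edge.length is not None else None,
        update_bipartitions=False,
    )
    dtree.suppress_unifurcations()
    return _from_dendropy(dtree)


# ----------------------------------------------------------- support collapse
def collapse_low_support(tree: RootedTree, threshold: float) -> RootedTree:
    """Contract internal edges whose support is strictly below ``threshold``.

    Edges without a support annotation are kept: absence of evidence is not
    low support.  Idempotent at a fixed threshold.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("support threshold must be in [0, 100]")
    drop = np.zeros(tree.n_nodes, dtype=bool)
    for node in range(tree.n_nodes):
        if (
            node != tree.root
            and not tree.is_tip(node)
            and not math.isnan(tree.support[node])
            and tree.support[node] < threshold
        ):
            drop[node] = True
    if not drop.any():
        return tree
    keep = [n for n in range(tree.n_nodes) if not drop[n]]
    remap = {old: new for new, old in enumerate(keep)}
    parent, length, label, support = [], [], [], []
    for old in keep:
        p = tree.parent[old]
        while p >= 0 and drop[p]:
            p = tree.parent[p]
        parent.append(remap[int(p)] if p >= 0 else -1)
        length.append(tree.length[old])
        label.append(tree.label[old])
        support.append(tree.support[old])
    return RootedTree(parent, length, label, support)


# --------------------------------------------------------- triplet topologies
def _triplet_from_depths(d12: int, d13: int, d23: int) -> str:
    top = max(d12, d13, d23)
    hits = [lab for d, lab in ((d12, P1P2), (d13, P1P3), (d23, P2P3)) if d == top]
    return hits[0] if len(hits) == 1 else UNRESOLVED


def triplet_topology(gene_tree: RootedTree, spec: TripletSpec) -> str:
    """Classify a gene tree's rooted-triplet topology for one test.

    The tree is rooted on the outgroup; the label names the ingroup pair that
    is sister after pruning to the four taxa (pruning is implicit: MRCA
    relations among retained taxa are pruning-invariant).  A polytomy joining
    all three ingroup taxa yields ``UNRESOLVED``.
    """
    for taxon in spec.all_taxa:
        if taxon not in gene_tree:
            raise MissingTaxonError(f"taxon {taxon!r} not in gene tree")
    rooted = root_with_outgroup(gene_tree, spec.outgroup)
    depth = rooted.topo_depth()
    d12 = depth[rooted.mrca(spec.p1, spec.p2)]
    d13 = depth[rooted.mrca(spec.p1, spec.p3)]
    d23 = depth[rooted.mrca(spec.p2, spec.p3)]
    return _triplet_from_depths(int(d12), int(d13), int(d23))


def sister_pairs(species_tree: RootedTree) -> List[Tuple[str, str]]:
    """All unordered tip pairs whose parent has exactly those two tips as its
    only descendants."""
    pairs = []
    for node in range(species_tree.n_nodes):
        kids = species_tree.children[node]
        if len(kids) == 2 and all(species_tree.is_tip(c) for c in kids):
            a, b = sorted(species_tree.label[c] for c in kids)  # type: ignore[type-var]
            pairs.append((a, b))
    return sorted(pairs)


# ------------------------------------------------------------------ gene sets
class GeneTreeSet:
    """Ordered collection of per-locus rooted gene trees.

    Locus ids are unique; a taxon-coverage map (taxon -> number of loci
    containing it) is kept consistent with the stored trees.
    """

    def __init__(self, items: Iterable[Tuple[str, RootedTree]]) -> None:
        self.items: List[Tuple[str, RootedTree]] = list(items)
        ids = [lid for lid, _ in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids must be unique")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def locus_ids(self) -> List[str]:
        return [lid for lid, _ in self.items]

    @property
    def trees(self) -> List[RootedTree]:
        return [t for _, t in self.items]

    def coverage(self) -> Dict[str, int]:
        cov: Dict[str, int] = {}
        for _, tree in self.items:
            for taxon in tree.taxa:
                cov[taxon] = cov.get(taxon, 0) + 1
        return cov

    def all_taxa(self) -> List[str]:
        return sorted(self.coverage())

    def rooted_on(self, outgroup: str) -> "GeneTreeSet":
        """Root every tree containing the outgroup; loci lacking it are
        dropped (they cannot be polarized)."""
        out = []
        for lid, tree in self.items:
            if outgroup in tree:
                out.append((lid, root_with_outgroup(tree, outgroup)))
        return GeneTreeSet(out)

    def mrca_depth_tensor(self, taxa: Sequence[str]) -> np.ndarray:
        """Stacked per-locus MRCA-depth matrices over a fixed taxon order.

        Entry ``[l, i, j]`` is the root-to-MRCA edge count of taxa ``i, j`` in
        locus ``l``; -1 where either taxon is missing from the locus.  This is
        the workhorse for vectorized triplet counting across many tests.
        """
        pos = {t: i for i, t in enumerate(taxa)}
        k = len(taxa)
        T = np.full((len(self.items), k, k), -1, dtype=np.int16)
        for l, (_, tree) in enumerate(self.items):
            M, tree_taxa = tree.mrca_depth_matrix()
            idx = np.array([pos[t] for t in tree_taxa if t in pos], dtype=np.intp)
            own = np.array([i for i, t in enumerate(tree_taxa) if t in pos], dtype=np.intp)
            T[l][np.ix_(idx, idx)] = M[np.ix_(own, own)]
        return T

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for _, tree in self.items:
                fh.write(write_newick(tree) + "\n")


def read_gene_trees(path: str, locus_ids: Optional[Sequence[str]] = None) -> GeneTreeSet:
    """Read one Newick gene tree per line; locus ids default to L0000..."""
    items = []
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    if locus_ids is None:
        locus_ids = [f"L{i:04d}" for i in range(len(lines))]
    if len(locus_ids) != len(lines):
        raise ValueError("locus_ids length does not match number of trees")
    for lid, line in zip(locus_ids, lines):
        items.append((lid, parse_newick(line)))
    return GeneTreeSet(items)


# ----------------------------------------------------------------- taxon maps
def read_taxon_map(path: str) -> Dict[str, str]:
    """Two-column TSV (sample, species) -> sample-to-species mapping."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, species = line.split("\t")[:2]
            mapping[sample] = species
    return mapping


def select_representatives(taxon_map: Dict[str, str]) -> Dict[str, str]:
    """Pick one representative sample per species: the lexicographically
    first sample label (deterministic)."""
    best: Dict[str, str] = {}
    for sample, species in taxon_map.items():
        if species not in best or sample < best[species]:
            best[species] = sample
    return best


# --------------------------------------------------------- concordance factor
def gene_concordance_factor(
    species_tree: RootedTree, gene_trees: GeneTreeSet
) -> pd.DataFrame:
    """Gene concordance factor (gCF) for each internal branch.

    gCF = 100 x (decisive gene trees containing the branch bipartition) /
    (decisive gene trees).  A gene tree is decisive for a branch iff it has at
    least one taxon in each of the four taxon groups the branch induces (the
    two child clades below it, its sister clade, and everything else).
    Branches with zero decisive trees get NaN and ``defined = False``.
    """
    tipsets = species_tree.clade_tipsets()
    all_taxa = tipsets[species_tree.root]
    gene_info = []
    for _, gt in gene_trees:
        gtaxa = frozenset(gt.taxa) & all_taxa  # restrict to species-tree taxa
        gclades = {g & all_taxa for g in gt.clade_tipsets()}
        gene_info.append((gtaxa, gclades))

    rows = []
    for node in range(species_tree.n_nodes):
        if node == species_tree.root or species_tree.is_tip(node):
            continue
        parent = int(species_tree.parent[node])
        groups = [tipsets[c] for c in species_tree.children[node]]
        groups += [tipsets[s] for s in species_tree.children[parent] if s != node]
        outside = all_taxa - tipsets[parent]
        if outside:
            groups.append(outside)
        clade = tipsets[node]
        n_decisive = 0
        n_concordant = 0
        for gtaxa, gclades in gene_info:
            if any(not (g & gtaxa) for g in groups):
                continue
            n_decisive += 1
            restricted = clade & gtaxa
            if any((c & gtaxa) == restricted for c in gclades):
                n_concordant += 1
        gcf = 100.0 * n_concordant / n_decisive if n_decisive else np.nan
        rows.append(
            {
                "branch": "|".join(sorted(clade)),
                "n_decisive": n_decisive,
                "n_concordant": n_concordant,
                "gCF": gcf,
                "defined": bool(n_decisive),
            }
        )
    return pd.DataFrame(rows)
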