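"""Rooted-triplet (RT) introgression tests.

For every sister pair (P1, P2) in the species tree and every other ingroup
taxon P3, gene trees rooted on the outgroup are classified into the three
possible triplet topologies.  Under incomplete lineage sorting alone the two
minor topologies are equally frequent; an excess of one minor pairing is
evidence of gene flow between P3 and the pair member it groups with.  The
test is an exact two-sided binomial on (minor1, minor2) with p = 0.5,
Holm-Bonferroni corrected across the whole scan, and the introgressed
genome proportion is estimated as

    gamma = (minor2 - minor1) / (major + minor1 + minor2).

Correlated significant tests that implicate a clade are collapsed into
single ancestral hybridization events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyCountsError, UndefinedStatisticError
from .treeio import (
    GeneTreeSet,
    RootedTree,
    TripletSpec,
    sister_pairs,
    triplet_topology,
)

__all__ = [
    "TripletCounts",
    "RTResult",
    "enumerate_triplets",
    "count_topologies",
    "binomial_minor_test",
    "holm_adjust",
    "gamma_from_counts",
    "rt_scan",
    "collapse_to_events",
    "results_to_frame",
]


@dataclass
class TripletCounts:
    """Locus tallies for one rooted triplet.

    ``minor2 >= minor1`` by convention; ``minor2_with`` records which member
    of the sister pair the excess minor topology groups with P3 (ties keep
    P2 for bookkeeping but carry no signal).  ``n_loci_used`` counts loci
    containing all four taxa; unresolved loci are excluded from the binomial
    denominator but tallied.
    """

    major: int
    minor1: int
    minor2: int
    n_unresolved: int
    n_loci_used: int
    minor2_with: str = ""

    def __post_init__(self) -> None:
        if min(self.major, self.minor1, self.minor2, self.n_unresolved) < 0:
            raise ValueError("counts must be nonnegative")
        if self.minor2 < self.minor1:
            raise ValueError("minor2 must be >= minor1")
        if self.major + self.minor1 + self.minor2 + self.n_unresolved != self.n_loci_used:
            raise ValueError("counts do not sum to n_loci_used")


@dataclass
class RTResult:
    spec: TripletSpec
    counts: TripletCounts
    p_raw: float
    p_adj: float = np.nan
    gamma: float = np.nan

    @property
    def donor_partner(self) -> str:
        """Ingroup tip implicated with P3 by the excess minor topology."""
        return self.counts.minor2_with

    @property
    def test_id(self) -> str:
        s = self.spec
        return f"{s.p1},{s.p2},{s.p3}"


def enumerate_triplets(species_tree: RootedTree, outgroup: str) -> List[TripletSpec]:
    """One spec per (sister pair) x (remaining ingroup tip).

    The count is (#sister pairs) x (#ingroup tips - 2).
    """
    ingroup = [t for t in species_tree.taxa if t != outgroup]
    pairs = [p for p in sister_pairs(species_tree) if outgroup not in p]
    if not pairs:
        warnings.warn("species tree has no sister pairs; empty triplet list")
        return []
    specs = []
    for p1, p2 in pairs:
        for p3 in ingroup:
            if p3 in (p1, p2):
                continue
            specs.append(TripletSpec(p1, p2, p3, outgroup))
    return specs


def count_topologies(gene_trees: GeneTreeSet, spec: TripletSpec) -> TripletCounts:
    """Tally triplet topologies across loci; loci lacking any of the four
    taxa are skipped."""
    major = c13 = c23 = unresolved = 0
    for _, tree in gene_trees:
        if any(t not in tree for t in spec.all_taxa):
            continue
        label = triplet_topology(tree, spec)
        if label == "P1P2":
            major += 1
        elif label == "P1P3":
            c13 += 1
        elif label == "P2P3":
            c23 += 1
        else:
            unresolved += 1
    used = major + c13 + c23 + unresolved
    if used == 0:
        raise EmptyCountsError(f"no usable loci for triplet {spec}")
    return _assemble_counts(spec, major, c13, c23, unresolved)


def _assemble_counts(spec: TripletSpec, major: int, c13: int, c23: int, unresolved: int) -> TripletCounts:
    if c23 >= c13:
        minor1, minor2, with_tip = c13, c23, spec.p2
    else:
        minor1, minor2, with_tip = c23, c13, spec.p1
    return TripletCounts(
        major=major,
        minor1=minor1,
        minor2=minor2,
        n_unresolved=unresolved,
        n_loci_used=major + c13 + c23 + unresolved,
        minor2_with=with_tip,
    )


def binomial_minor_test(counts: TripletCounts) -> float:
    """Exact two-sided binomial probability of a minor-topology split at
    least as extreme as observed under Binomial(minor1+minor2, 0.5); 1 when
    there are no minor loci."""
    n = counts.minor1 + counts.minor2
    if n == 0:
        return 1.0
    return float(stats.binomtest(counts.minor1, n, 0.5).pvalue)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, order-preserving and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def gamma_from_counts(counts: TripletCounts) -> float:
    """Introgressed genome proportion (minor2 - minor1)/(major + minor1 + minor2)."""
    denom = counts.major + counts.minor1 + counts.minor2
    if denom == 0:
        raise UndefinedStatisticError("gamma undefined: no resolved loci")
    return (counts.minor2 - counts.minor1) / denom


# ------------------------------------------------------------------ the scan
def rt_scan(
    gene_trees: GeneTreeSet,
    species_tree: RootedTree,
    outgroup: str,
    alpha: float = 0.001,
) -> List[RTResult]:
    """Run the full rooted-triplet scan.

    Gene trees are rooted on the outgroup once (loci lacking it are
    dropped), triplet topologies are read off MRCA-depth comparisons for
    every enumerated test, and Holm correction is applied jointly across the
    scan family.  Results keep the enumeration order.
    """
    specs = enumerate_triplets(species_tree, outgroup)
    if not specs or len(gene_trees) == 0:
        if len(gene_trees) == 0:
            warnings.warn("empty gene-tree set: no RT tests run")
        return []
    rooted = gene_trees.rooted_on(outgroup)
    taxa = [t for t in species_tree.taxa if t != outgroup]
    pos = {t: i for i, t in enumerate(taxa)}
    T = rooted.mrca_depth_tensor(taxa)

    results: List[RTResult] = []
    for spec in specs:
        i1, i2, i3 = pos[spec.p1], pos[spec.p2], pos[spec.p3]
        d12, d13, d23 = T[:, i1, i2], T[:, i1, i3], T[:, i2, i3]
        present = (d12 >= 0) & (d13 >= 0) & (d23 >= 0)
        major = int(np.sum(present & (d12 > d13) & (d12 > d23)))
        c13 = int(np.sum(present & (d13 > d12) & (d13 > d23)))
        c23 = int(np.sum(present & (d23 > d12) & (d23 > d13)))
        unresolved = int(present.sum()) - major - c13 - c23
        if present.sum() == 0:
            warnings.warn(f"no usable loci for {spec}; skipped")
            continue
        counts = _assemble_counts(spec, major, c13, c23, unresolved)
        results.append(RTResult(spec, counts, p_raw=binomial_minor_test(counts)))

    adj = holm_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
        r.gamma = gamma_from_counts(r.counts) if r.counts.major + r.counts.minor1 + r.counts.minor2 else np.nan
    return results


def results_to_frame(results: Sequence[RTResult]) -> pd.DataFrame:
    """One row per test, Dsuite-style column naming where applicable."""
    rows = []
    for r in results:
        rows.append(
            {
                "P1": r.spec.p1,
                "P2": r.spec.p2,
                "P3": r.spec.p3,
                "outgroup": r.spec.outgroup,
                "major": r.counts.major,
                "minor1": r.counts.minor1,
                "minor2": r.counts.minor2,
                "n_unresolved": r.counts.n_unresolved,
                "n_loci_used": r.counts.n_loci_used,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "gamma": r.gamma,
                "partner": r.donor_partner,
            }
        )
    return pd.DataFrame(rows)


def results_from_frame(frame: pd.DataFrame) -> List[RTResult]:
    """Rebuild RTResult objects from a results TSV (inverse of
    :func:`results_to_frame`)."""
    out = []
    for row in frame.itertuples(index=False):
        spec = TripletSpec(row.P1, row.P2, row.P3, row.outgroup)
        counts = TripletCounts(
            major=int(row.major),
            minor1=int(row.minor1),
            minor2=int(row.minor2),
            n_unresolved=int(row.n_unresolved),
            n_loci_used=int(row.n_loci_used),
            minor2_with=str(row.partner),
        )
        out.append(
            RTResult(spec, counts, p_raw=float(row.p_raw), p_adj=float(row.p_adj), gamma=float(row.gamma))
        )
    return out


# ------------------------------------------------------------ event collapse
def _complete_block(links: Dict[frozenset, float], tips_a: Sequence[str], tips_b: Sequence[str]) -> bool:
    return all(frozenset((a, b)) in links for a in tips_a for b in tips_b)


def collapse_to_events(
    results: Sequence[RTResult],
    species_tree: RootedTree,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Collapse correlated significant tests into hybridization events.

    Each significant test links the implicated pair member with P3.  Links
    are grouped into maximal (clade x clade) blocks of the species tree in
    which every cross pair is significantly linked; a clade-level event
    needs at least two linked descendant tips on the clade side.  The event
    gamma is an f-branch-style summary: the median over one side's tips of
    the minimum gamma across the other side's tips.
    """
    links: Dict[frozenset, float] = {}
    support: Dict[frozenset, List[str]] = {}
    for r in results:
        if not (r.p_adj < alpha) or not r.counts.minor2_with:
            continue
        key = frozenset((r.counts.minor2_with, r.spec.p3))
        if len(key) != 2:
            continue
        # keep the largest gamma when several tests hit the same pair
        if key not in links or r.gamma > links[key]:
            links[key] = r.gamma
        support.setdefault(key, []).append(r.test_id)

    columns = [
        "recipient",
        "partner",
        "direction",
        "gamma",
        "n_supporting",
        "supporting_tests",
    ]
    if not links:
        return pd.DataFrame(columns=columns)

    tipsets = species_tree.clade_tipsets()
    nodes = [
        (node, sorted(tipsets[node]))
        for node in range(species_tree.n_nodes)
        if node != species_tree.root
    ]
    blocks = []
    for ia, (na, ta) in enumerate(nodes):
        for nb, tb in nodes[ia + 1 :]:
            if set(ta) & set(tb):
                continue
            if (len(ta) > 1 or len(tb) > 1) and min(len(ta), len(tb)) < 1:
                continue
            if _complete_block(links, ta, tb):
                blocks.append((len(ta) * len(tb), ta, tb))
    blocks.sort(key=lambda b: (-b[0], b[1], b[2]))

    covered: set = set()
    events = []
    for size, ta, tb in blocks:
        pairs = [frozenset((a, b)) for a in ta for b in tb]
        if all(p in covered for p in pairs):
            continue
        if any(p in covered for p in pairs):
            continue  # partial overlap with an accepted larger event
        # recipient side for the gamma summary: the larger clade
        if (len(ta), ta) >= (len(tb), tb):
            rec, par = ta, tb
        else:
            rec, par = tb, ta
        gammas = [min(links[frozenset((r, p))] for p in par) for r in rec]
        event_gamma = float(np.median(gammas))
        tests: List[str] = []
        for p in pairs:
            covered.add(p)
            tests.extend(support[p])
        events.append(
            {
                "recipient": "|".join(rec),
                "partner": "|".join(par),
                "direction": "<->",
                "gamma": event_gamma,
                "n_supporting": len(tests),
                "supporting_tests": ";".join(sorted(set(tests))),
            }
        )
    frame = pd.DataFrame(events, columns=columns)
    return _flag_bridges(frame)


def _flag_bridges(events: pd.DataFrame) -> pd.DataFrame:
    """Mark candidate bridge events: A-B and B-C detected, and a weaker A-C
    event that may be an indirect signal through B."""
    events = events.copy()
    flags = [False] * len(events)
    parties = [
        (set(r.recipient.split("|")), set(r.partner.split("|")), r.gamma)
        for r in events.itertuples()
    ]
    for i, (ai, bi, gi) in enumerate(parties):
        for j, (aj, bj, gj) in enumerate(parties):
            if i == j:
                continue
            for k, (ak, bk, gk) in enumerate(parties):
                if k in (i, j):
                    continue
                # i = A-C candidate, j = A-B, k = B-C with shared bridge taxon set
                shared_j = aj | bj
                shared_k = ak | bk
                bridge = (shared_j & shared_k) - (ai | bi)
                if not bridge:
                    continue
                if (ai <= shared_j or bi <= shared_j) and (ai <= shared_k or bi <= shared_k):
                    if gi < min(gj, gk):
                        flags[i] = True
    events["bridge_candidate"] = flags
    return events
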