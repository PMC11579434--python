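"""The f-branch summary: assigning gene-flow signal to tree branches.

Correlated trio signals make it hard to tell which branch — possibly an
internal, ancestral one — exchanged genes with a given taxon.  The f-branch
metric fb(b, P3) summarizes a per-trio score over the species tree: for
branch b with sister branch s(b),

    fb(b, P3) = median over A in tips(s(b)) of
                [ min over B in tips(b) of score(A, B, P3) ]

The minimum damps signals that only some descendants of b carry (those are
better explained by a shallower branch); the median aggregates over the
sister clade's vantage points.  Cells where P3 falls inside b's clade or
its sister clade play no valid trio role and are NA; missing trio scores
are skipped inside the min/median and a cell with no defined term is NA.

The score provider here substitutes rooted-triplet gamma estimates for the
f4-ratios of the original metric: scans with one haploid sequence per taxon
have no allele frequencies for f4-ratios to use.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .rttest import RTResult
from .treeio import RootedTree

__all__ = [
    "Branch",
    "FBranchMatrix",
    "expand_branches",
    "fbranch_matrix",
    "gamma_score_provider",
]

ScoreFn = Callable[[str, str, str], Optional[float]]


@dataclass(frozen=True)
class Branch:
    """One species-tree branch: the edge above ``node``."""

    node: int
    tips: Tuple[str, ...]
    sister_tips: Tuple[str, ...]
    label: str

    @property
    def is_tip(self) -> bool:
        return len(self.tips) == 1


def _branch_label(tips: Sequence[str]) -> str:
    if len(tips) == 1:
        return tips[0]
    digest = hashlib.sha1("|".join(sorted(tips)).encode()).hexdigest()[:6]
    ordered = sorted(tips)
    return f"mrca({ordered[0]}..{ordered[-1]},n={len(tips)})#{digest}"


def expand_branches(species_tree: RootedTree) -> List[Branch]:
    """All branches (tip and internal) in depth-first preorder, each with
    its descendant tip set and sister branch tips.

    The root itself has no branch and is excluded; the root's two child
    branches are each other's sisters.
    """
    tipsets = species_tree.clade_tipsets()
    branches = []
    for node in species_tree.preorder():
        if node == species_tree.root:
            continue
        parent = int(species_tree.parent[node])
        sisters: List[str] = []
        for sib in species_tree.children[parent]:
            if sib != node:
                sisters.extend(sorted(tipsets[sib]))
        tips = tuple(sorted(tipsets[node]))
        branches.append(
            Branch(node=node, tips=tips, sister_tips=tuple(sorted(sisters)), label=_branch_label(tips))
        )
    return branches


@dataclass
class FBranchMatrix:
    """fb values for every branch (rows) x candidate P3 taxon (columns).

    ``reasons`` holds an NA code per cell: '' (defined), 'role' (P3 inside
    the branch or sister clade), 'no_data' (no scored trio survived)."""

    branches: List[Branch]
    taxa: List[str]
    values: np.ndarray
    reasons: np.ndarray
    n_trios: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=[b.label for b in self.branches], columns=self.taxa
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.branches):
            for j, t in enumerate(self.taxa):
                rows.append(
                    {
                        "branch": b.label,
                        "branch_tips": "|".join(b.tips),
                        "P3": t,
                        "fb": self.values[i, j],
                        "n_trios": int(self.n_trios[i, j]),
                        "na_reason": self.reasons[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def cell(self, branch_tips: Sequence[str], p3: str) -> float:
        want = tuple(sorted(branch_tips))
        for i, b in enumerate(self.branches):
            if b.tips == want:
                return float(self.values[i, self.taxa.index(p3)])
        return math.nan


def fbranch_matrix(
    score: ScoreFn,
    species_tree: RootedTree,
    taxa: Optional[Sequence[str]] = None,
) -> FBranchMatrix:
    """Evaluate fb(b, P3) for every branch and candidate P3.

    ``score(A, B, P3)`` returns the per-trio signal of excess sharing
    between B and P3 (A is the in-pair control), or None/NaN when the trio
    was never scored.
    """
    branches = expand_branches(species_tree)
    if taxa is None:
        taxa = species_tree.taxa
    taxa = list(taxa)
    values = np.full((len(branches), len(taxa)), np.nan)
    reasons = np.full((len(branches), len(taxa)), "", dtype=object)
    n_trios = np.zeros((len(branches), len(taxa)), dtype=np.int64)
    for i, b in enumerate(branches):
        excluded = set(b.tips) | set(b.sister_tips)
        for j, p3 in enumerate(taxa):
            if p3 in excluded:
                reasons[i, j] = "role"
                continue
            minima = []
            n_used = 0
            for a in b.sister_tips:
                terms = []
                for t in b.tips:
                    s = score(a, t, p3)
                    if s is not None and not (isinstance(s, float) and math.isnan(s)):
                        terms.append(float(s))
                if terms:
                    minima.append(min(terms))
                    n_used += len(terms)
            if minima:
                values[i, j] = float(np.median(minima))
                n_trios[i, j] = n_used
            else:
                reasons[i, j] = "no_data"
    return FBranchMatrix(branches, taxa, values, reasons, n_trios)


def gamma_score_provider(
    rt_results: Sequence[RTResult],
    alpha: float = 0.001,
    nonsignificant: str = "zero",
) -> ScoreFn:
    """Per-trio score function backed by rooted-triplet gamma estimates.

    score(A, B, P3) is +gamma when the RT test on sister pair {A, B} with
    third taxon P3 significantly implicates B with P3, -gamma when it
    implicates A, and for non-significant tests either 0 (default;
    conservative, keeps medians grounded) or NA (``nonsignificant='na'``).
    Untested trios are NA.
    """
    if nonsignificant not in ("zero", "na"):
        raise ValueError("nonsignificant must be 'zero' or 'na'")
    table: Dict[Tuple[frozenset, str], Tuple[float, float, str]] = {}
    for r in rt_results:
        key = (frozenset((r.spec.p1, r.spec.p2)), r.spec.p3)
        table[key] = (r.p_adj, r.gamma, r.donor_partner)

    def score(a: str, b: str, p3: str) -> Optional[float]:
        entry = table.get((frozenset((a, b)), p3))
        if entry is None:
            return None
        p_adj, gamma, partner = entry
        if not (p_adj < alpha):
            return 0.0 if nonsignificant == "zero" else None
        return gamma if partner == b else -gamma

    return score
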