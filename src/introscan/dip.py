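"""Divergence-based introgression polarization (DIP).

For a triplet (P1, P2) sister + P3 with established gene flow between P3
and P2, the direction of that flow leaves a footprint in pairwise sequence
divergences stratified by gene-tree topology class:

    C    concordant loci, (P1, P2) sister
    D23  discordant loci grouping (P2, P3)
    D13  discordant loci grouping (P1, P3)

Under pure incomplete lineage sorting the D23 and D13 strata are
exchangeable images of each other under the P1 <-> P2 relabeling, so any
contrast between them has expectation zero.  The statistics:

    delta12       = mean_D23[d12] - mean_C[d12]        (uncorrected, 1x)
    delta12_corr  = mean_D23[d12] - mean_D13[d12]      (ILS-corrected)
    delta13_corr  = mean_D23[d13] - mean_D13[d23]      (auxiliary mirror)
    delta_gap     = mean_D23[d12 - d23] - mean_D13[d12 - d13]

The uncorrected contrast is positive under ILS alone (discordant loci
coalesce deeper than concordant ones), which is why the corrected contrasts
exist.  In the pulse-admixture coalescent the two flow directions separate
as follows.  Flow P3 -> P2 reroutes P2's lineages, so the D13 stratum stays
exactly at its ILS distribution while introgressed D23 loci pair a recent
P2/P3 coalescence with a deep P1 join: delta_gap goes strongly positive and
delta12_corr only mildly negative.  Flow P2 -> P3 funnels introgressed P3
lineages through P2's ancestral populations, producing shallow-d12 D23 loci
and shallow-d13 D13 loci: delta12_corr goes strongly negative while
delta_gap stays near zero.  ``polarize`` encodes that asymmetry; all three
corrected statistics are exactly antisymmetric under P1 <-> P2.
Significance comes from a locus bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignio import Alignment
from .treeio import GeneTreeSet, RootedTree, TripletSpec, triplet_topology

__all__ = [
    "DivergenceRecord",
    "DipResult",
    "locus_divergences",
    "dip_statistics",
    "dip_corrected",
    "dip_bootstrap",
    "polarize",
    "dip_results_to_frame",
]

CLASS_C, CLASS_D23, CLASS_D13, CLASS_UNRES = "C", "D23", "D13", "UNRESOLVED"
_TOPO_TO_CLASS = {"P1P2": CLASS_C, "P2P3": CLASS_D23, "P1P3": CLASS_D13, "UNRESOLVED": CLASS_UNRES}
_CLASS_CODE = {CLASS_C: 0, CLASS_D23: 1, CLASS_D13: 2, CLASS_UNRES: 3}


@dataclass
class DivergenceRecord:
    """Pairwise p-distances for one locus and its gene-tree topology class."""

    locus_id: str
    d12: float
    d13: float
    d23: float
    topo_class: str


@dataclass
class DipResult:
    spec: TripletSpec
    n_per_class: Dict[str, int]
    delta12: float = np.nan
    delta13: float = np.nan
    delta12_corr: float = np.nan
    delta13_corr: float = np.nan
    delta_gap: float = np.nan
    delta_shallow: float = np.nan
    p12: float = np.nan
    p13: float = np.nan
    p_gap: float = np.nan
    p_shallow: float = np.nan
    z_gap: float = np.nan
    z_shallow: float = np.nan
    direction: str = "none"


def _p_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Proportion of differing sites over columns ungapped in both."""
    ok = (x <= 3) & (y <= 3)
    n = int(ok.sum())
    if n == 0:
        return math.nan
    return float((x[ok] != y[ok]).sum() / n)


def locus_divergences(
    alignments: Sequence[Tuple[str, Alignment]],
    spec: TripletSpec,
    gene_trees: GeneTreeSet,
) -> List[DivergenceRecord]:
    """Per-locus p-distances among the triplet taxa, with topology classes
    read from the matching gene trees.

    Loci lacking any of the four taxa in the gene tree, missing an ingroup
    sequence, or with zero comparable sites for some pair are dropped.
    """
    trees = dict(gene_trees.items)
    records = []
    for lid, aln in alignments:
        tree = trees.get(lid)
        if tree is None or any(t not in aln for t in spec.ingroup):
            continue
        if any(t not in tree for t in spec.all_taxa):
            continue
        x1, x2, x3 = (aln.row(t) for t in spec.ingroup)
        d12 = _p_distance(x1, x2)
        d13 = _p_distance(x1, x3)
        d23 = _p_distance(x2, x3)
        if any(math.isnan(v) for v in (d12, d13, d23)):
            continue
        topo = _TOPO_TO_CLASS[triplet_topology(tree, spec)]
        records.append(DivergenceRecord(lid, d12, d13, d23, topo))
    return records


# ----------------------------------------------------------- array internals
def _as_arrays(records: Sequence[DivergenceRecord]):
    d12 = np.array([r.d12 for r in records])
    d13 = np.array([r.d13 for r in records])
    d23 = np.array([r.d23 for r in records])
    cls = np.array([_CLASS_CODE[r.topo_class] for r in records], dtype=np.int8)
    return d12, d13, d23, cls


def _mean(x: np.ndarray, mask: np.ndarray) -> float:
    n = int(mask.sum())
    return float(x[mask].sum() / n) if n else math.nan


def _corrected_stats(d12, d13, d23, cls) -> Tuple[float, float, float, float]:
    """(delta12_corr, delta13_corr, delta_gap, delta_shallow) from
    stratified arrays.

    delta_shallow contrasts the fraction of discordant loci whose d12 falls
    below the concordant-stratum median: under ILS or P3 -> P2 flow,
    discordant loci always join P1 deeper than the species split and the
    contrast vanishes; P2 -> P3 flow routes introgressed P3 lineages through
    P2's ancestral populations, creating genuinely shallow-d12 discordant
    loci, predominantly in the D23 stratum.
    """
    in23 = cls == 1
    in13 = cls == 2
    if not in23.any() or not in13.any():
        return math.nan, math.nan, math.nan, math.nan
    in_c = cls == 0
    if in_c.any():
        q = float(np.median(d12[in_c]))
        shallow = (
            float((d12[in23] < q).mean()) - float((d12[in13] < q).mean())
        )
    else:
        shallow = math.nan
    return (
        _mean(d12, in23) - _mean(d12, in13),
        _mean(d13, in23) - _mean(d23, in13),
        _mean(d12 - d23, in23) - _mean(d12 - d13, in13),
        shallow,
    )


def _class_counts(cls: np.ndarray) -> Dict[str, int]:
    return {name: int((cls == code).sum()) for name, code in _CLASS_CODE.items()}


# ------------------------------------------------------------ the statistics
def dip_statistics(
    records: Sequence[DivergenceRecord], spec: TripletSpec, min_loci: int = 20
) -> DipResult:
    """Uncorrected (1x) contrasts against the concordant stratum."""
    d12, d13, d23, cls = _as_arrays(records)
    res = DipResult(spec, _class_counts(cls))
    if res.n_per_class[CLASS_C] >= min_loci and res.n_per_class[CLASS_D23] >= min_loci:
        in_c, in23 = cls == 0, cls == 1
        res.delta12 = _mean(d12, in23) - _mean(d12, in_c)
        res.delta13 = _mean(d13, in_c) - _mean(d13, in23)
    return res


def dip_corrected(
    records: Sequence[DivergenceRecord],
    spec: TripletSpec,
    min_loci: int = 20,
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> DipResult:
    """ILS-corrected contrasts, bootstrap p-values, and a direction call.

    Requires at least ``min_loci`` loci in each discordant stratum; one set
    of locus resamples drives the bootstrap of all three statistics.
    """
    d12, d13, d23, cls = _as_arrays(records)
    res = DipResult(spec, _class_counts(cls))
    if res.n_per_class[CLASS_D23] < min_loci or res.n_per_class[CLASS_D13] < min_loci:
        return res
    (
        res.delta12_corr,
        res.delta13_corr,
        res.delta_gap,
        res.delta_shallow,
    ) = _corrected_stats(d12, d13, d23, cls)

    rng = np.random.default_rng(seed)
    n = len(records)
    observed = np.array(
        [res.delta12_corr, res.delta13_corr, res.delta_gap, res.delta_shallow]
    )
    reps = np.full((n_reps, 4), np.nan)
    for b in range(n_reps):
        idx = rng.integers(0, n, n)
        reps[b] = _corrected_stats(d12[idx], d13[idx], d23[idx], cls[idx])
    defined = np.isfinite(reps).sum(axis=0)
    opp = np.nansum(reps * observed < 0, axis=0)
    ps = np.where(
        defined > 0,
        np.maximum(2.0 * opp / np.maximum(defined, 1), 1.0 / n_reps),
        np.nan,
    )
    ps[observed == 0.0] = 1.0
    res.p12, res.p13, res.p_gap, res.p_shallow = (float(p) for p in ps)
    with np.errstate(invalid="ignore"):
        ses = np.nanstd(reps, axis=0, ddof=1)
    res.z_gap = float(observed[2] / ses[2]) if ses[2] > 0 else np.nan
    res.z_shallow = float(observed[3] / ses[3]) if ses[3] > 0 else np.nan
    res.direction = polarize(res, alpha=alpha)
    return res


def dip_bootstrap(
    records: Sequence[DivergenceRecord],
    statistic: Callable[[Sequence[DivergenceRecord]], float],
    n_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided locus bootstrap for an arbitrary record-level statistic.

    p = fraction of resamples whose statistic falls on the opposite side of
    zero from the observed value, doubled, floored at 1/n_reps.
    """
    observed = statistic(records)
    if not np.isfinite(observed):
        return math.nan
    if observed == 0.0:
        return 1.0
    rng = np.random.default_rng(seed)
    n = len(records)
    opposite = 0
    n_defined = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n, n)
        val = statistic([records[i] for i in idx])
        if np.isfinite(val):
            n_defined += 1
            if val * observed < 0:
                opposite += 1
    if n_defined == 0:
        return math.nan
    return float(max(2.0 * opposite / n_defined, 1.0 / n_reps))


def polarize(result: DipResult, alpha: float = 0.05) -> str:
    """Direction call for flow between P3 and P2.

    delta_gap significantly positive is the signature of P3 -> P2 (recent
    P2/P3 coalescences paired with deep P1 joins, clean D13 stratum);
    delta12_corr significantly negative is the signature of P2 -> P3
    (shallow d12 at introgressed discordant loci).  When both fire, the
    larger-magnitude signal wins and a tie is reported as bidirectional or
    unresolved.  Without any significant contrast the call is 'none'
    (rendered as a bidirectional arrow in event tables).
    """
    into_p2 = (
        np.isfinite(result.p_gap) and result.p_gap < alpha and result.delta_gap > 0
    )
    into_p3 = (
        np.isfinite(result.p_shallow)
        and result.p_shallow < alpha
        and result.delta_shallow > 0
    )
    fwd = f"{result.spec.p3}->{result.spec.p2}"
    rev = f"{result.spec.p2}->{result.spec.p3}"
    if into_p2 and into_p3:
        if np.isfinite(result.z_gap) and np.isfinite(result.z_shallow):
            if result.z_gap > result.z_shallow:
                return fwd
            if result.z_gap < result.z_shallow:
                return rev
        return "bidirectional/unresolved"
    if into_p2:
        return fwd
    if into_p3:
        return rev
    # weak fallback: the mean-shift contrast alone
    if np.isfinite(result.p12) and result.p12 < alpha and result.delta12_corr < 0:
        return rev
    return "none"


def dip_results_to_frame(results: Sequence[DipResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "P1": r.spec.p1,
                "P2": r.spec.p2,
                "P3": r.spec.p3,
                "n_C": r.n_per_class[CLASS_C],
                "n_D23": r.n_per_class[CLASS_D23],
                "n_D13": r.n_per_class[CLASS_D13],
                "n_unresolved": r.n_per_class[CLASS_UNRES],
                "delta12": r.delta12,
                "delta13": r.delta13,
                "delta12_corr": r.delta12_corr,
                "delta13_corr": r.delta13_corr,
                "delta_gap": r.delta_gap,
                "delta_shallow": r.delta_shallow,
                "p12": r.p12,
                "p13": r.p13,
                "p_gap": r.p_gap,
                "p_shallow": r.p_shallow,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)
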