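"""ABBA-BABA D-statistics from concatenated alignments.

Per-locus alignments are concatenated; for every trio of ingroup taxa plus
the outgroup, biallelic sites (exactly two alleles among the four sequences,
no gaps or ambiguity) are extracted, thinned to at most one per 500 bp to
damp linkage, and classified by the outgroup-polarized site pattern:

    ABBA  (A, B, B, A)      BABA  (B, A, B, A)      BBAA  (B, B, A, A)

with 'A' the outgroup (ancestral) allele and 'B' the derived allele.  The
statistic D = (ABBA - BABA)/(ABBA + BABA) is zero in expectation without
gene flow; significance comes from a delete-one block jackknife over
contiguous SNP blocks, with Holm correction across the scan.  Trios are
arranged so the species-tree sister pair occupies the (P1, P2) slots and
D >= 0, making P2 the taxon sharing excess derived alleles with P3.

Single haploid sequences per taxon are assumed: pattern counts are integer
tallies, and sites where the outgroup carries a globally minor allele still
polarize by the outgroup state.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .alignio import Alignment
from .errors import AlignmentFormatError, BlockCountError, MissingTaxonError, UndefinedStatisticError
from .rttest import holm_adjust
from .treeio import RootedTree, TripletSpec

__all__ = [
    "ConcatenatedAlignment",
    "SNPTable",
    "PatternCounts",
    "DStatResult",
    "concatenate",
    "extract_biallelic_snps",
    "thin_snps",
    "count_patterns",
    "d_statistic",
    "block_jackknife",
    "arrange_trio",
    "dstat_scan",
    "dstat_results_to_frame",
]


class ConcatenatedAlignment:
    """All loci side by side: taxon -> one long sequence, plus a partition
    map of half-open 0-based column intervals per locus."""

    def __init__(self, taxa: Sequence[str], data: np.ndarray, partitions: List[Tuple[str, int, int]]):
        self.taxa = list(taxa)
        self.data = np.asarray(data, dtype=np.uint8)
        self.partitions = list(partitions)
        self._index = {t: i for i, t in enumerate(self.taxa)}
        total = self.data.shape[1]
        stops = [s for _, _, s in partitions]
        starts = [s for _, s, _ in partitions]
        if partitions and (starts[0] != 0 or stops[-1] != total or any(
            stops[i] != starts[i + 1] for i in range(len(partitions) - 1)
        )):
            raise AlignmentFormatError("partition intervals must tile [0, total)")

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.data[self._index[taxon]]
        except KeyError:
            raise MissingTaxonError(f"taxon {taxon!r} not in alignment") from None


def concatenate(loci: Sequence[Tuple[str, Alignment]]) -> ConcatenatedAlignment:
    """Concatenate per-locus alignments; taxa absent from a locus are padded
    with gaps across that locus's interval."""
    from .alignio import GAP

    taxa: List[str] = []
    seen = set()
    for lid, aln in loci:
        if aln.data.shape[1] == 0 and aln.data.shape[0] == 0:
            raise AlignmentFormatError(f"locus {lid} is empty")
        for t in aln.taxa:
            if t not in seen:
                seen.add(t)
                taxa.append(t)
    total = sum(aln.length for _, aln in loci)
    data = np.full((len(taxa), total), GAP, dtype=np.uint8)
    partitions = []
    offset = 0
    index = {t: i for i, t in enumerate(taxa)}
    for lid, aln in loci:
        stop = offset + aln.length
        for t in aln.taxa:
            data[index[t], offset:stop] = aln.row(t)
        partitions.append((lid, offset, stop))
        offset = stop
    return ConcatenatedAlignment(taxa, data, partitions)


@dataclass
class SNPTable:
    """Biallelic sites for four selected taxa: strictly increasing
    concatenated positions and a (4, n) allele matrix in (P1, P2, P3, O)
    row order."""

    taxa: Tuple[str, str, str, str]
    positions: np.ndarray
    alleles: np.ndarray

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class PatternCounts:
    abba: int
    baba: int
    bbaa: int
    n_snps_used: int


@dataclass
class DStatResult:
    spec: TripletSpec
    d: float
    se: float
    z: float
    p_raw: float
    counts: PatternCounts
    n_blocks: int
    p_adj: float = np.nan

    @property
    def abba_gt_bbaa(self) -> bool:
        return self.counts.abba > self.counts.bbaa


# ------------------------------------------------------------- SNP machinery
def extract_biallelic_snps(concat: ConcatenatedAlignment, taxa: Sequence[str]) -> SNPTable:
    """Columns with exactly two distinct alleles among the four taxa and no
    gap or ambiguity in any of them."""
    if len(taxa) != 4:
        raise ValueError("exactly four taxa required")
    rows = np.vstack([concat.row(t) for t in taxa])
    valid = (rows <= 3).all(axis=0)
    a, b, c, o = rows
    eq = (
        (a == b).astype(np.uint8)
        + (a == c)
        + (a == o)
        + (b == c)
        + (b == o)
        + (c == o)
    )
    mask = valid & (eq >= 2) & (eq <= 3)  # exactly two distinct alleles
    pos = np.flatnonzero(mask)
    return SNPTable(tuple(taxa), pos.astype(np.int64), rows[:, pos])


def thin_snps(table: SNPTable, min_spacing: int = 500) -> SNPTable:
    """Greedy left-to-right thinning: keep a row iff its position is at
    least ``min_spacing`` beyond the last kept position."""
    keep = []
    last = -min_spacing - 1
    for i, p in enumerate(table.positions):
        if p >= last + min_spacing:
            keep.append(i)
            last = int(p)
    idx = np.asarray(keep, dtype=np.intp)
    return SNPTable(table.taxa, table.positions[idx], table.alleles[:, idx])


def _classify(alleles: np.ndarray) -> np.ndarray:
    """Pattern code per SNP column: 1=ABBA, 2=BABA, 3=BBAA, 0=other."""
    a, b, c, o = alleles
    code = np.zeros(a.shape, dtype=np.uint8)
    code[(a == o) & (b == c) & (b != o)] = 1
    code[(b == o) & (a == c) & (a != o)] = 2
    code[(c == o) & (a == b) & (a != o)] = 3
    return code


def count_patterns(table: SNPTable, spec: Optional[TripletSpec] = None) -> PatternCounts:
    """Tally outgroup-polarized ABBA/BABA/BBAA patterns; remaining biallelic
    configurations (derived singletons) are ignored but counted in
    ``n_snps_used``."""
    code = _classify(table.alleles)
    return PatternCounts(
        abba=int((code == 1).sum()),
        baba=int((code == 2).sum()),
        bbaa=int((code == 3).sum()),
        n_snps_used=len(table),
    )


def d_statistic(counts: PatternCounts) -> float:
    denom = counts.abba + counts.baba
    if denom == 0:
        raise UndefinedStatisticError("D undefined: ABBA + BABA = 0")
    return (counts.abba - counts.baba) / denom


def _block_sizes(n: int, n_blocks: int) -> np.ndarray:
    base = n // n_blocks
    sizes = np.full(n_blocks, base, dtype=np.int64)
    sizes[: n % n_blocks] += 1
    return sizes


def _jackknife_from_codes(code: np.ndarray, n_blocks: int) -> Tuple[float, float, float, float]:
    """(D, SE, Z, p) from per-SNP pattern codes split into contiguous,
    near-equal blocks (sizes differ by at most one SNP)."""
    n = code.size
    if n < n_blocks:
        raise BlockCountError(f"{n} SNPs < {n_blocks} jackknife blocks")
    abba_tot = int((code == 1).sum())
    baba_tot = int((code == 2).sum())
    if abba_tot + baba_tot == 0:
        raise UndefinedStatisticError("D undefined: ABBA + BABA = 0")
    d = (abba_tot - baba_tot) / (abba_tot + baba_tot)
    bounds = np.concatenate([[0], np.cumsum(_block_sizes(n, n_blocks))])
    d_del = np.empty(n_blocks)
    for j in range(n_blocks):
        blk = code[bounds[j] : bounds[j + 1]]
        a = abba_tot - int((blk == 1).sum())
        b = baba_tot - int((blk == 2).sum())
        d_del[j] = (a - b) / (a + b) if a + b else 0.0
    var = (n_blocks - 1) / n_blocks * np.sum((d_del - d_del.mean()) ** 2)
    se = math.sqrt(var)
    if se == 0.0:
        z = math.copysign(math.inf, d) if d != 0 else 0.0
        p = 0.0 if d != 0 else 1.0
    else:
        z = d / se
        p = 2.0 * stats.norm.sf(abs(z))
    return d, se, z, float(p)


def block_jackknife(
    table: SNPTable, spec: Optional[TripletSpec] = None, n_blocks: int = 40
) -> Tuple[float, float, float]:
    """Delete-one block jackknife on a (thinned) SNP table.

    Returns (SE, Z, two-sided normal p).  Jackknife variance is
    ((n-1)/n) * sum_j (D_-j - mean(D_-j))^2 over n contiguous blocks.
    """
    code = _classify(table.alleles)
    _, se, z, p = _jackknife_from_codes(code, n_blocks)
    return se, z, p


# ------------------------------------------------------------- arrangement
def arrange_trio(spec: TripletSpec, species_tree: RootedTree) -> TripletSpec:
    """Reorder a trio so the species-tree sister pairing occupies (P1, P2).

    Within the pair, order is alphabetical at this stage; the scan flips
    (P1, P2) after counting so that D >= 0 and P2 names the taxon sharing
    excess derived alleles with P3.
    """
    trio = sorted((spec.p1, spec.p2, spec.p3))
    depth = species_tree.topo_depth()
    d = {
        (x, y): depth[species_tree.mrca(x, y)]
        for x, y in itertools.combinations(trio, 2)
    }
    (x, y), _ = max(d.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1]))
    p3 = next(t for t in trio if t not in (x, y))
    return TripletSpec(x, y, p3, spec.outgroup)


def enumerate_trios(ingroup: Sequence[str]) -> List[Tuple[str, str, str]]:
    """All unordered ingroup trios, sorted; the scan's enumeration order."""
    return list(itertools.combinations(sorted(ingroup), 3))


# ------------------------------------------------------------ the fast path
@njit(cache=True)
def _trio_kernel(s1, s2, s3, so, spacing, pos_out, code_out):  # pragma: no cover
    n = s1.shape[0]
    kept = 0
    last = -spacing - 1
    for i in range(n):
        a = s1[i]
        b = s2[i]
        c = s3[i]
        o = so[i]
        if a > 3 or b > 3 or c > 3 or o > 3:
            continue
        eq = 0
        if a == b:
            eq += 1
        if a == c:
            eq += 1
        if a == o:
            eq += 1
        if b == c:
            eq += 1
        if b == o:
            eq += 1
        if c == o:
            eq += 1
        if eq < 2 or eq > 3:
            continue
        if i < last + spacing:
            continue
        last = i
        if a == o and b == c:
            code_out[kept] = 1
        elif b == o and a == c:
            code_out[kept] = 2
        elif c == o and a == b:
            code_out[kept] = 3
        else:
            code_out[kept] = 0
        pos_out[kept] = i
        kept += 1
    return kept


def _thinned_codes(
    concat: ConcatenatedAlignment, spec: TripletSpec, min_spacing: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Thinned biallelic SNP codes and positions for one trio, in one pass."""
    max_keep = concat.length // max(min_spacing, 1) + 2
    pos_out = np.empty(max_keep, dtype=np.int64)
    code_out = np.empty(max_keep, dtype=np.uint8)
    kept = _trio_kernel(
        concat.row(spec.p1),
        concat.row(spec.p2),
        concat.row(spec.p3),
        concat.row(spec.outgroup),
        min_spacing,
        pos_out,
        code_out,
    )
    return pos_out[:kept], code_out[:kept]


def dstat_scan(
    concat: ConcatenatedAlignment,
    species_tree: RootedTree,
    outgroup: str,
    alpha: float = 0.001,
    min_spacing: int = 500,
    n_blocks: int = 40,
) -> List[DStatResult]:
    """D-statistics for every unordered ingroup trio.

    Each trio is tree-arranged, its SNPs extracted and thinned, D and the
    block-jackknife Z computed, and (P1, P2) oriented so D >= 0.  Holm
    correction is applied across the whole scan.  Per-trio failures (e.g.
    too few SNPs) are warned about and skipped.
    """
    ingroup = sorted(
        t for t in concat.taxa if t in species_tree and t != outgroup
    )
    if outgroup not in concat.taxa:
        raise MissingTaxonError(f"outgroup {outgroup!r} not in alignment")
    results: List[DStatResult] = []
    n_failed = 0
    for trio in enumerate_trios(ingroup):
        spec = arrange_trio(TripletSpec(trio[0], trio[1], trio[2], outgroup), species_tree)
        _, code = _thinned_codes(concat, spec, min_spacing)
        try:
            d, se, z, p = _jackknife_from_codes(code, n_blocks)
        except (BlockCountError, UndefinedStatisticError):
            n_failed += 1
            continue
        abba = int((code == 1).sum())
        baba = int((code == 2).sum())
        bbaa = int((code == 3).sum())
        if d < 0:  # orient so P2 shares the excess derived alleles with P3
            spec = TripletSpec(spec.p2, spec.p1, spec.p3, spec.outgroup)
            d, z = -d, -z
            abba, baba = baba, abba
        counts = PatternCounts(abba, baba, bbaa, int(code.size))
        results.append(DStatResult(spec, d, se, z, p, counts, n_blocks))
    if n_failed:
        warnings.warn(f"{n_failed} trios skipped (insufficient usable SNPs)")
    adj = holm_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


def dstat_results_to_frame(results: Sequence[DStatResult]) -> pd.DataFrame:
    """Dsuite-compatible trio table."""
    rows = []
    for r in results:
        rows.append(
            {
                "P1": r.spec.p1,
                "P2": r.spec.p2,
                "P3": r.spec.p3,
                "Dstatistic": r.d,
                "Z-score": r.z,
                "p-value": r.p_raw,
                "p-adj": r.p_adj,
                "ABBA": r.counts.abba,
                "BABA": r.counts.baba,
                "BBAA": r.counts.bbaa,
                "nSNPs": r.counts.n_snps_used,
                "ABBA>BBAA": r.abba_gt_bbaa,
            }
        )
    return pd.DataFrame(rows)
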