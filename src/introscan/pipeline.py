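"""End-to-end scan orchestration.

``run_scan`` ties the stages together on one dataset: rooted-triplet scan,
event collapse, D-statistic scan, gamma-based f-branch, DIP polarization of
significant pairs, and a cross-method concordance table — writing one TSV
per stage plus a YAML manifest (config, seed, package versions, stage
status) that suffices to reproduce every output byte-for-byte.
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignio import Alignment
from .dip import DipResult, dip_corrected, dip_results_to_frame, dip_statistics, locus_divergences
from .dstat import concatenate, dstat_results_to_frame, dstat_scan
from .errors import ConfigError
from .fbranch import FBranchMatrix, fbranch_matrix, gamma_score_provider
from .rttest import RTResult, collapse_to_events, results_to_frame, rt_scan
from .treeio import (
    GeneTreeSet,
    RootedTree,
    TripletSpec,
    collapse_low_support,
    read_gene_trees,
    read_taxon_map,
    read_tree,
    select_representatives,
)

logger = logging.getLogger("introscan")

__all__ = ["ScanConfig", "run_scan", "run_scan_data", "cross_method_concordance"]

_FLOAT_FORMAT = "%.10g"


@dataclass
class ScanConfig:
    """Everything one scan needs; serializes losslessly to YAML."""

    species_tree: str = ""
    gene_trees: str = ""
    alignments: str = ""  # directory of per-locus FASTA files, or empty
    taxon_map: str = ""
    outgroup: str = ""
    outdir: str = "scan_out"
    alpha_rt: float = 0.001
    alpha_d: float = 0.001
    thinning_bp: int = 500
    jackknife_blocks: int = 40
    support_collapse: float = -1.0  # <0 disables support collapsing
    dip_min_loci: int = 20
    dip_n_reps: int = 1000
    dip_alpha: float = 0.05
    fbranch_threshold: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("alpha_rt", 0.0, 1.0),
            ("alpha_d", 0.0, 1.0),
            ("dip_alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.thinning_bp < 1 or self.jackknife_blocks < 2:
            raise ConfigError("thinning_bp >= 1 and jackknife_blocks >= 2 required")
        if self.support_collapse > 100:
            raise ConfigError("support_collapse must be <= 100")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "ScanConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write(frame: pd.DataFrame, outdir: str, name: str) -> None:
    frame.to_csv(os.path.join(outdir, name), sep="\t", index=False, float_format=_FLOAT_FORMAT)


def run_scan(config: ScanConfig) -> Dict[str, object]:
    """Load inputs named in ``config`` and run the full scan."""
    species_tree = read_tree(config.species_tree)
    gene_trees = read_gene_trees(config.gene_trees)
    alignments: Optional[List[Tuple[str, Alignment]]] = None
    if config.alignments:
        alignments = []
        for lid in gene_trees.locus_ids:
            for ext in (".fasta", ".fa"):
                path = os.path.join(config.alignments, lid + ext)
                if os.path.exists(path):
                    alignments.append((lid, Alignment.from_fasta(path)))
                    break
    if config.taxon_map:
        mapping = read_taxon_map(config.taxon_map)
        keep = set(select_representatives(mapping).values())
        keep.add(config.outgroup)
        drop = [t for t in species_tree.taxa if t not in keep]
        if drop:
            logger.info("taxon map: dropping %d non-representative samples", len(drop))
            import dendropy

            dtree = dendropy.Tree.get(
                data=species_tree.to_newick(), schema="newick", preserve_underscores=True
            )
            dtree.retain_taxa_with_labels([t for t in species_tree.taxa if t in keep])
            from .treeio import _from_dendropy

            species_tree = _from_dendropy(dtree)
    return run_scan_data(
        species_tree, gene_trees, alignments, config.outgroup, config
    )


def run_scan_data(
    species_tree: RootedTree,
    gene_trees: GeneTreeSet,
    alignments: Optional[Sequence[Tuple[str, Alignment]]],
    outgroup: str,
    config: Optional[ScanConfig] = None,
) -> Dict[str, object]:
    """Run every stage on in-memory inputs; write TSVs under
    ``config.outdir`` and return the result objects."""
    config = config or ScanConfig(outgroup=outgroup)
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    status: Dict[str, str] = {}
    out: Dict[str, object] = {"config": config}

    if config.support_collapse >= 0:
        gene_trees = GeneTreeSet(
            [(lid, collapse_low_support(t, config.support_collapse)) for lid, t in gene_trees]
        )

    # ---- stage: rooted-triplet scan -------------------------------------
    rt_results: List[RTResult] = []
    try:
        logger.info("RT scan: %d loci", len(gene_trees))
        rt_results = rt_scan(gene_trees, species_tree, outgroup, alpha=config.alpha_rt)
        _write(results_to_frame(rt_results), outdir, "rt_tests.tsv")
        status["rt_scan"] = "ok"
    except Exception as exc:  # noqa: BLE001 — stage isolation by design
        logger.error("RT scan failed: %s", exc)
        status["rt_scan"] = f"failed: {exc}"
    out["rt_results"] = rt_results

    # ---- stage: event collapse ------------------------------------------
    events = pd.DataFrame()
    try:
        events = collapse_to_events(rt_results, species_tree, alpha=config.alpha_rt)
        _write(events, outdir, "rt_events.tsv")
        status["collapse"] = "ok"
    except Exception as exc:  # noqa: BLE001
        logger.error("event collapse failed: %s", exc)
        status["collapse"] = f"failed: {exc}"
    out["events"] = events

    # ---- stage: D-statistics --------------------------------------------
    dstat_results = []
    if alignments:
        try:
            concat = concatenate(list(alignments))
            logger.info(
                "D-statistic scan: %d taxa, %d concatenated sites",
                len(concat.taxa),
                concat.length,
            )
            dstat_results = dstat_scan(
                concat,
                species_tree,
                outgroup,
                alpha=config.alpha_d,
                min_spacing=config.thinning_bp,
                n_blocks=config.jackknife_blocks,
            )
            _write(dstat_results_to_frame(dstat_results), outdir, "dstat_trios.tsv")
            status["dstat"] = "ok"
        except Exception as exc:  # noqa: BLE001
            logger.error("D-statistic scan failed: %s", exc)
            status["dstat"] = f"failed: {exc}"
    else:
        status["dstat"] = "skipped: no alignments"
    out["dstat_results"] = dstat_results

    # ---- stage: f-branch --------------------------------------------------
    fbm: Optional[FBranchMatrix] = None
    try:
        ingroup_tree = species_tree
        score = gamma_score_provider(rt_results, alpha=config.alpha_rt)
        taxa = [t for t in species_tree.taxa if t != outgroup]
        fbm = fbranch_matrix(score, ingroup_tree, taxa=taxa)
        fbm.to_frame().to_csv(
            os.path.join(outdir, "fbranch.tsv"), sep="\t", float_format=_FLOAT_FORMAT
        )
        _write(fbm.to_long(), outdir, "fbranch_long.tsv")
        status["fbranch"] = "ok"
    except Exception as exc:  # noqa: BLE001
        logger.error("f-branch failed: %s", exc)
        status["fbranch"] = f"failed: {exc}"
    out["fbranch"] = fbm

    # ---- stage: DIP -------------------------------------------------------
    dip_results: List[DipResult] = []
    if alignments:
        try:
            seen = set()
            pairs = []
            for r in rt_results:
                if not (r.p_adj < config.alpha_rt):
                    continue
                partner = r.donor_partner
                key = frozenset((partner, r.spec.p3))
                if len(key) != 2 or key in seen:
                    continue
                seen.add(key)
                other = r.spec.p1 if partner == r.spec.p2 else r.spec.p2
                pairs.append(TripletSpec(other, partner, r.spec.p3, outgroup))
            logger.info("DIP: %d significant pairs", len(pairs))
            for i, spec in enumerate(sorted(pairs, key=lambda s: (s.p1, s.p2, s.p3))):
                records = locus_divergences(list(alignments), spec, gene_trees)
                res = dip_corrected(
                    records,
                    spec,
                    min_loci=config.dip_min_loci,
                    n_reps=config.dip_n_reps,
                    seed=(config.seed * 100003 + i) % (2**31 - 1),
                    alpha=config.dip_alpha,
                )
                basic = dip_statistics(records, spec, min_loci=config.dip_min_loci)
                res.delta12, res.delta13 = basic.delta12, basic.delta13
                dip_results.append(res)
            _write(dip_results_to_frame(dip_results), outdir, "dip.tsv")
            status["dip"] = "ok"
        except Exception as exc:  # noqa: BLE001
            logger.error("DIP failed: %s", exc)
            status["dip"] = f"failed: {exc}"
    else:
        status["dip"] = "skipped: no alignments"
    out["dip_results"] = dip_results

    # ---- stage: concordance ----------------------------------------------
    summary = pd.DataFrame()
    try:
        summary = cross_method_concordance(
            events, fbm, dip_results, threshold=config.fbranch_threshold
        )
        _write(summary, outdir, "events_summary.tsv")
        status["concordance"] = "ok"
    except Exception as exc:  # noqa: BLE001
        logger.error("concordance failed: %s", exc)
        status["concordance"] = f"failed: {exc}"
    out["summary"] = summary

    manifest = {
        "config": asdict(config),
        "stages": status,
        "versions": {
            "introscan": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_loci": len(gene_trees),
        "n_rt_tests": len(rt_results),
        "n_rt_significant": sum(1 for r in rt_results if r.p_adj < config.alpha_rt),
        "n_events": int(len(events)),
        "n_dstat_trios": len(out["dstat_results"]),  # type: ignore[arg-type]
    }
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    out["manifest"] = manifest
    return out


def cross_method_concordance(
    events: pd.DataFrame,
    fb: Optional[FBranchMatrix],
    dip_results: Sequence[DipResult],
    threshold: float = 0.04,
) -> pd.DataFrame:
    """Per-event cross-method summary.

    f-branch column: 'Yes' when every defined branch x partner cell for the
    event exceeds ``threshold``, 'Partial' when some do, 'No' when none do,
    'No (NA)' when no cell is defined.  The DIP consensus direction over
    the event's tip pairs is appended.
    """
    if events.empty:
        return events.assign(fbranch_detected=pd.Series(dtype=str), dip_direction=pd.Series(dtype=str))

    dip_by_pair: Dict[frozenset, DipResult] = {}
    for r in dip_results:
        dip_by_pair[frozenset((r.spec.p2, r.spec.p3))] = r

    det_col, dip_col = [], []
    for row in events.itertuples(index=False):
        rec = row.recipient.split("|")
        par = row.partner.split("|")
        cells: List[float] = []
        if fb is not None:
            for p in par:
                v = fb.cell(rec, p)
                if not np.isnan(v):
                    cells.append(v)
            for p in rec:
                v = fb.cell(par, p)
                if not np.isnan(v):
                    cells.append(v)
        if not cells:
            det_col.append("No (NA)")
        else:
            n_hit = sum(1 for v in cells if v > threshold)
            det_col.append("Yes" if n_hit == len(cells) else ("Partial" if n_hit else "No"))

        directions = set()
        for a in rec:
            for b in par:
                res = dip_by_pair.get(frozenset((a, b)))
                if res is not None and res.direction not in ("none",):
                    # orient as recipient-side vs partner-side
                    if res.direction == f"{res.spec.p3}->{res.spec.p2}":
                        flow = (
                            "partner->recipient"
                            if res.spec.p2 in rec
                            else "recipient->partner"
                        )
                    elif res.direction == f"{res.spec.p2}->{res.spec.p3}":
                        flow = (
                            "recipient->partner"
                            if res.spec.p2 in rec
                            else "partner->recipient"
                        )
                    else:
                        flow = "bidirectional/unresolved"
                    directions.add(flow)
        if not directions:
            dip_col.append("unpolarized")
        elif len(directions) == 1:
            dip_col.append(directions.pop())
        else:
            dip_col.append("mixed")
    frame = events.copy()
    frame["fbranch_detected"] = det_col
    frame["dip_direction"] = dip_col
    return frame
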