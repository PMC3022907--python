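"""Pipeline configuration and orchestration.

``run_pipeline`` executes the requested stages — catalog, duplication,
co-expression, artificial mutant — over the configured inputs, writing JSON
and TSV reports, Newick trees and a run manifest (parameters, input
checksums, package version).  Outputs carry no timestamps, so a rerun with
identical inputs and configuration is checksum-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from . import io as kio
from .artificial_mutant import DeletionSpec, redundancy_screen
from .catalog import family_counts, parse_catalog, scan_catalytic_motif
from .coexpression import (
    cut_tree,
    hcluster,
    log_transform,
    marker_coexpression,
    two_level_labels,
)
from .duplication import (
    DuplicationCatalog,
    assign_segmental_sets,
    call_tandem,
    chain_collinear,
    classify_fate,
    duplication_summary,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys."""


@dataclass
class PipelineConfig:
    """All pipeline inputs and stage parameters, with documented defaults."""

    # inputs
    catalog: str | None = None
    expression: str | None = None
    gff: str | None = None
    anchors: str | None = None
    proteins: str | None = None
    ground_truth: str | None = None
    # stage parameters
    max_intervening: int = 5
    max_gap: int = 100_000
    min_anchors: int = 5
    k_major: int = 3
    k_sub: int = 10
    marker_threshold: float = 0.9
    marker_prefix: str = "SynBC1L"
    slack: int = 1
    low_quantile: float = 0.25
    expressed_quantile: float = 0.6
    overlap_cut: float = 0.5
    alpha: float = 0.05
    # artificial-mutant screen (optional)
    mutant_target: str | None = None
    mutant_candidates: tuple[str, ...] = ()
    mutant_complex: tuple[str, ...] = ()
    mutant_tissues: tuple[str, ...] = ()
    # misc
    seed: int = 0
    outdir: str = "cslkit_out"

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
        d = dict(d)
        for key in ("mutant_candidates", "mutant_complex", "mutant_tissues"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("mutant_candidates", "mutant_complex", "mutant_tissues"):
            d[key] = list(d[key])
        return d


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``).  On a
    stage failure a ``<stage>.failed`` marker is left next to the partial
    outputs and the exception propagates.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "inputs": {},
        "stages": [],
        "outputs": {},
    }
    for name in ("catalog", "expression", "gff", "anchors", "proteins", "ground_truth"):
        path = getattr(cfg, name)
        if path:
            manifest["inputs"][name] = {
                "path": str(path),
                "sha256": kio.sha256_of(path),
            }

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": kio.sha256_of(path),
        }

    catalog = parse_catalog(cfg.catalog) if cfg.catalog else None
    matrix = kio.read_expression(cfg.expression) if cfg.expression else None
    ground_truth = None
    if cfg.ground_truth:
        import json

        from .synthetic_data import GroundTruth

        ground_truth = GroundTruth.from_dict(
            json.loads(Path(cfg.ground_truth).read_text(encoding="utf-8"))
        )

    # ---- catalog stage ----------------------------------------------------
    if catalog is not None:
        stage = "catalog"
        try:
            counts = family_counts(catalog)
            report = {
                "n_genes": counts.total,
                "per_family": dict(sorted(counts.per_family.items())),
                "per_cluster": dict(sorted(counts.per_cluster.items())),
                "csl_total": counts.csl_total,
            }
            if cfg.proteins:
                proteins = kio.read_fasta_proteins(cfg.proteins)
                report["motifs"] = {
                    name: dataclasses.asdict(scan_catalytic_motif(seq))
                    for name, seq in sorted(proteins.items())
                }
            path = outdir / "catalog_report.json"
            kio.write_json(report, path)
            emit("catalog_report", path)
            manifest["stages"].append(stage)
        except Exception:
            (outdir / f"{stage}.failed").touch()
            raise

    # ---- duplication stage ------------------------------------------------
    if catalog is not None:
        stage = "duplication"
        try:
            tandem = call_tandem(catalog, cfg.max_intervening)
            dup = DuplicationCatalog(tandem=tandem)
            if cfg.anchors and cfg.gff:
                anchors, chrom_pairs = kio.read_anchors(cfg.anchors)
                positions = kio.read_gff_positions(cfg.gff)
                blocks = []
                by_pair: dict[tuple[int, int], list] = {}
                for anchor, pair in zip(anchors, chrom_pairs):
                    by_pair.setdefault(pair, []).append(anchor)
                for (ca, cb), group in sorted(by_pair.items()):
                    blocks.extend(
                        chain_collinear(
                            group,
                            max_gap=cfg.max_gap,
                            min_anchors=cfg.min_anchors,
                            chrom_a=ca,
                            chrom_b=cb,
                        )
                    )
                dup.segmental = assign_segmental_sets(
                    catalog, blocks, positions, tandem
                )
            report = dup.to_dict()
            report["summary"] = duplication_summary(dup, catalog)
            if matrix is not None:
                theta = float(np.quantile(matrix.values, cfg.expressed_quantile))
                fates = []
                gene_set = set(matrix.genes)
                for pair in [(p.gene_a, p.gene_b) for p in dup.segmental]:
                    if set(pair) <= gene_set:
                        profile = matrix.tissue_profile("mean")
                        call = classify_fate(
                            profile.loc[pair[0]],
                            profile.loc[pair[1]],
                            expressed_threshold=theta,
                            overlap_cut=cfg.overlap_cut,
                            tissues=list(profile.columns),
                            pair=pair,
                            alpha=cfg.alpha,
                        )
                        fates.append(call.to_dict())
                report["fates"] = fates
                report["expressed_threshold"] = theta
            path = outdir / "duplication_report.json"
            kio.write_json(report, path)
            emit("duplication_report", path)
            manifest["stages"].append(stage)
        except Exception:
            (outdir / f"{stage}.failed").touch()
            raise

    # ---- co-expression stage ----------------------------------------------
    tree = None
    if matrix is not None:
        stage = "coexpress"
        try:
            tree = hcluster(log_transform(matrix))
            groups = two_level_labels(tree, cfg.k_major, cfg.k_sub, m=matrix)
            markers = [g for g in matrix.genes if g.startswith(cfg.marker_prefix)]
            links = (
                marker_coexpression(matrix, markers, threshold=cfg.marker_threshold)
                if markers
                else []
            )
            report: dict = {
                "n_genes": matrix.n_genes,
                "n_samples": matrix.n_samples,
                "groups": [g.to_dict() for g in groups],
                "marker_links": [dataclasses.asdict(l) for l in links],
                "constant_genes": matrix.constant_genes,
            }
            if ground_truth is not None and ground_truth.group_of:
                grouped = [
                    g for g in matrix.genes if g in ground_truth.group_of
                ]
                sub = cut_tree(tree, cfg.k_sub)
                label_of = {}
                for gi, grp in enumerate(sub):
                    for gene in grp.members:
                        label_of[gene] = gi
                report["ari_vs_ground_truth"] = float(
                    adjusted_rand_score(
                        [ground_truth.group_of[g] for g in grouped],
                        [label_of[g] for g in grouped],
                    )
                )
            path = outdir / "coexpression_report.json"
            kio.write_json(report, path)
            emit("coexpression_report", path)
            tsv = outdir / "groups.tsv"
            with tsv.open("w", encoding="utf-8") as fh:
                fh.write("group_id\tgene\n")
                for g in groups:
                    for gene in g.members:
                        fh.write(f"{g.group_id}\t{gene}\n")
            emit("groups_tsv", tsv)
            nwk = outdir / "tree.nwk"
            kio.write_newick(tree, nwk)
            emit("tree_newick", nwk)
            manifest["stages"].append(stage)
        except Exception:
            (outdir / f"{stage}.failed").touch()
            raise

    # ---- artificial-mutant stage ------------------------------------------
    if matrix is not None and cfg.mutant_target:
        stage = "mutant"
        try:
            gene_subset = None
            if cfg.mutant_complex:
                # cluster the family sub-matrix named by the complex genes'
                # catalog families when a catalog is present
                if catalog is not None:
                    fams = {
                        rec.family
                        for rec in catalog
                        if rec.gene_name in set(cfg.mutant_complex) | {cfg.mutant_target}
                    }
                    gene_subset = [
                        rec.gene_name
                        for rec in catalog
                        if rec.family in fams and rec.gene_name in set(matrix.genes)
                    ]
                    gene_subset += [
                        c for c in cfg.mutant_candidates if c not in gene_subset
                    ]
            call = redundancy_screen(
                matrix,
                complex_genes=set(cfg.mutant_complex) | {cfg.mutant_target},
                target=cfg.mutant_target,
                candidates=cfg.mutant_candidates,
                tissues_suspected=cfg.mutant_tissues,
                genes=gene_subset,
                slack=cfg.slack,
                low_quantile=cfg.low_quantile,
            )
            path = outdir / "mutant_report.json"
            kio.write_json(call.to_dict(), path)
            emit("mutant_report", path)
            manifest["stages"].append(stage)
        except Exception:
            (outdir / f"{stage}.failed").touch()
            raise

    path = outdir / "manifest.json"
    kio.write_json(manifest, path)
    return manifest
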