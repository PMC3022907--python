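"""In-silico deletion ("artificial mutant") analysis of co-expression trees.

Genetic redundancy between cellulose-synthase isoforms leaves a footprint in
co-expression data: if gene T is a complex member that is silent in a few
tissues where candidate substitutes are highly expressed, then deleting T's
expression row and re-clustering should pull the candidates into the cluster
formed by the remaining complex members — and that absorption should vanish
when the supporting tissues are also removed.  This module implements that
screen:

1. ``apply_deletion`` removes genes and/or tissue samples from a matrix,
2. ``minimal_subtree`` finds the smallest dendrogram node spanning a focal
   gene set (the operational meaning of "clustered together"),
3. ``deletion_recluster`` composes deletion -> log transform -> complete-
   linkage clustering -> minimal-subtree query,
4. ``redundancy_screen`` runs the full three-step inference and returns a
   verdict: ``supported``, ``not_supported`` or ``tissue_dependent``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .coexpression import (
    ClusterTree,
    CoexpressionError,
    ExpressionMatrix,
    hcluster,
    log_transform,
)

logger = logging.getLogger(__name__)


class MutantError(ValueError):
    """Raised on invalid deletion or screen input."""


@dataclass(frozen=True)
class DeletionSpec:
    """Genes and/or samples (by tissue label or sample id) to delete."""

    genes_removed: frozenset = frozenset()
    samples_removed: frozenset = frozenset()

    @classmethod
    def of(
        cls, genes: Iterable[str] = (), samples: Iterable[str] = ()
    ) -> "DeletionSpec":
        return cls(frozenset(genes), frozenset(samples))

    @property
    def empty(self) -> bool:
        return not self.genes_removed and not self.samples_removed


@dataclass(frozen=True)
class PartnerReport:
    """Minimal-subtree query result for a focal gene set.

    ``minimal_cluster_members`` is the leaf set of the lowest merge node
    whose subtree contains every focal leaf; ``extra_members`` counts the
    non-focal leaves in it, and ``passed`` records whether that count is
    within the configured slack.
    """

    focal: frozenset
    minimal_cluster_members: frozenset
    extra_members: int
    passed: bool

    def to_dict(self) -> dict:
        return {
            "focal": sorted(self.focal),
            "minimal_cluster_members": sorted(self.minimal_cluster_members),
            "extra_members": self.extra_members,
            "passed": self.passed,
        }


@dataclass(frozen=True)
class RedundancyCall:
    target: str
    candidates: frozenset
    complex_partners: frozenset
    supporting_tissues: frozenset
    verdict: str
    reason: str = ""
    absorbed_candidates: frozenset = frozenset()
    evidence: tuple = ()  # (all-tissues PartnerReport, tissues-excluded PartnerReport)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "candidates": sorted(self.candidates),
            "complex_partners": sorted(self.complex_partners),
            "supporting_tissues": sorted(self.supporting_tissues),
            "verdict": self.verdict,
            "reason": self.reason,
            "absorbed_candidates": sorted(self.absorbed_candidates),
            "evidence": [rep.to_dict() for rep in self.evidence],
        }


def apply_deletion(m: ExpressionMatrix, spec: DeletionSpec) -> ExpressionMatrix:
    """Delete the specified genes/samples; the original matrix is untouched."""
    if spec.empty:
        return m.copy()
    known_tissues = set(m.tissues)
    known_ids = set(m.sample_ids)
    tissues = {s for s in spec.samples_removed if s in known_tissues}
    sample_ids = {s for s in spec.samples_removed if s in known_ids}
    unknown = spec.samples_removed - tissues - sample_ids
    unknown |= spec.genes_removed - set(m.genes)
    if unknown:
        raise MutantError(f"unknown id(s) in deletion spec: {', '.join(sorted(unknown))}")
    return m.drop(genes=spec.genes_removed, samples=sample_ids, tissues=tissues)


def minimal_subtree(
    tree: ClusterTree, focal: Iterable[str], slack: int = 1
) -> PartnerReport:
    """Lowest merge node whose subtree contains all focal leaves.

    Because agglomerative clusters are laminar and created in nondecreasing
    height order, the first merge (in merge order) whose member set contains
    the focal set is the minimal one.  ``passed`` is true when at most
    ``slack`` non-focal leaves ride along.
    """
    focal = frozenset(focal)
    if not focal:
        raise MutantError("focal set must not be empty")
    missing = focal - set(tree.leaves)
    if missing:
        raise MutantError(f"focal leaf absent from tree: {', '.join(sorted(missing))}")
    n = tree.n_leaves
    if len(focal) == n:
        members = frozenset(tree.leaves)
        return PartnerReport(focal, members, 0, True)
    for k in range(len(tree.merges)):
        members = tree.members(n + k)
        if focal <= members:
            extra = len(members) - len(focal)
            return PartnerReport(focal, members, extra, extra <= slack)
    raise MutantError("tree does not contain the focal set")  # pragma: no cover


def deletion_recluster(
    m: ExpressionMatrix,
    spec: DeletionSpec,
    focal: Iterable[str],
    metric: str = "euclidean",
    linkage: str = "complete",
    slack: int = 1,
) -> tuple[ClusterTree, PartnerReport]:
    """Delete, log-transform, re-cluster and query the focal minimal subtree."""
    mutant = apply_deletion(m, spec)
    if mutant.n_genes < 2:
        raise MutantError("post-deletion matrix has fewer than 2 genes")
    tree = hcluster(log_transform(mutant), metric=metric, linkage=linkage)
    return tree, minimal_subtree(tree, focal, slack=slack)


def _absorption(
    tree: ClusterTree,
    focal: frozenset,
    candidates: frozenset,
    slack: int,
) -> tuple[frozenset, PartnerReport]:
    """Which candidates join the focal cluster with at most ``slack`` strangers.

    Candidate c is absorbed when the minimal subtree spanning focal + {c}
    contains at most ``slack`` leaves that are neither focal nor candidates
    (other candidates riding along are expected, not strangers).  The report
    returned covers the best candidate (fewest strangers, ties by name).
    """
    best_report: PartnerReport | None = None
    best_key = None
    absorbed = set()
    for cand in sorted(candidates):
        if cand not in tree.leaves:
            continue
        rep = minimal_subtree(tree, focal | {cand}, slack=slack)
        strangers = rep.minimal_cluster_members - focal - candidates
        rep = PartnerReport(
            focal=rep.focal,
            minimal_cluster_members=rep.minimal_cluster_members,
            extra_members=len(strangers),
            passed=len(strangers) <= slack,
        )
        if rep.passed:
            absorbed.add(cand)
        key = (len(strangers), cand)
        if best_key is None or key < best_key:
            best_key = key
            best_report = rep
    if best_report is None:
        raise MutantError("no candidate present in the tree")
    return frozenset(absorbed), best_report


def redundancy_screen(
    m: ExpressionMatrix,
    complex_genes: Iterable[str],
    target: str,
    candidates: Iterable[str],
    tissues_suspected: Iterable[str],
    genes: Sequence[str] | None = None,
    slack: int = 1,
    low_quantile: float = 0.25,
    metric: str = "euclidean",
) -> RedundancyCall:
    """Three-step in-silico test of partial redundancy.

    1. *Gating*: in every suspected tissue the target's mean signal must fall
       below the ``low_quantile`` quantile of its own cross-tissue profile,
       and at least one candidate must exceed its own median there.
    2. *Deletion*: remove the target, re-cluster (genes restricted to
       ``genes`` when given) and test whether the remaining complex members'
       cluster absorbs at least one candidate.
    3. *Tissue exclusion*: repeat with the suspected tissues also removed.
       Absorption that disappears marks the redundancy as tissue-dependent.

    Double deletions are supported by passing a matrix from which further
    genes were already removed via :func:`apply_deletion`.
    """
    complex_genes = frozenset(complex_genes)
    candidates = frozenset(candidates)
    tissues_suspected = frozenset(tissues_suspected)
    if target not in complex_genes:
        raise MutantError(f"target {target!r} must be a complex member")
    if candidates & complex_genes:
        raise MutantError("candidates must be disjoint from the complex")
    missing_t = tissues_suspected - set(m.tissues)
    if missing_t:
        raise MutantError(
            f"suspected tissue(s) absent from matrix: {', '.join(sorted(missing_t))}"
        )
    for gene in sorted(complex_genes | candidates):
        if gene not in m.genes:
            raise MutantError(f"gene {gene!r} absent from matrix")

    focal = complex_genes - {target}
    if not focal:
        raise MutantError("complex must retain at least one member besides the target")

    # Step 1: expression gating on the per-tissue profile (raw scale).
    profile = m.tissue_profile("mean")
    target_profile = profile.loc[target]
    low_cut = float(target_profile.quantile(low_quantile))
    target_low = all(float(target_profile[t]) < low_cut for t in tissues_suspected)
    candidate_high = any(
        all(
            float(profile.loc[c][t]) > float(profile.loc[c].median())
            for t in tissues_suspected
        )
        for c in sorted(candidates)
    )
    if not (target_low and candidate_high):
        reason = (
            "precondition_low_expression"
            if not target_low
            else "precondition_candidate_high"
        )
        return RedundancyCall(
            target=target,
            candidates=candidates,
            complex_partners=focal,
            supporting_tissues=tissues_suspected,
            verdict="not_supported",
            reason=reason,
        )

    work = m.subset_genes(list(genes)) if genes is not None else m

    # Step 2: delete the target, re-cluster on all tissues.
    tree_all, _ = deletion_recluster(
        work, DeletionSpec.of(genes=[target]), focal, metric=metric, slack=slack
    )
    absorbed_all, report_all = _absorption(tree_all, focal, candidates, slack)

    # Step 3: delete the target and the suspected tissues.
    tree_excl, _ = deletion_recluster(
        work,
        DeletionSpec.of(genes=[target], samples=tissues_suspected),
        focal,
        metric=metric,
        slack=slack,
    )
    absorbed_excl, report_excl = _absorption(tree_excl, focal, candidates, slack)

    if absorbed_all and not absorbed_excl:
        verdict, reason = "tissue_dependent", "absorption_lost_without_tissues"
    elif absorbed_all:
        verdict, reason = "supported", "absorption_persists"
    else:
        verdict, reason = "not_supported", "no_coclustering"

    return RedundancyCall(
        target=target,
        candidates=candidates,
        complex_partners=focal,
        supporting_tissues=tissues_suspected,
        verdict=verdict,
        reason=reason,
        absorbed_candidates=absorbed_all,
        evidence=(report_all, report_excl),
    )
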