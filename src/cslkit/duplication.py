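"""Tandem and segmental duplication calling and duplicate-fate classification.

Gene families expand mainly through tandem duplication (paralogs lying next
to each other on a chromosome) and segmental duplication (paralogs sitting in
large collinear duplicated blocks).  This module implements both callers for
a gene-family catalog:

* tandem clusters: family members on one chromosome separated by at most a
  configurable number of intervening gene models (default five),
* collinear blocks: dynamic-programming chaining of pre-scored homologous
  anchor pairs with a maximum per-axis gap (default 100 kb), from which
  family pairs spanning the two block regions are called segmental,

plus the downstream summaries: how many unique family genes are involved in
any duplication event, and the expression fate of a duplicate pair
(nonfunctionalization / subfunctionalization / neofunctionalization
candidate / conserved) from the two genes' expressed-tissue sets and their
expression correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .catalog import GeneRecord

logger = logging.getLogger(__name__)

#: Duplication sets reported for the rice CESA/CSL superfamily: the six-member
#: CSLF tandem array on chromosome 7, two further tandem pairs, and seven
#: segmental pairs assigned to collinear duplication blocks.  Kept as data so
#: the involvement arithmetic can be recomputed from the published sets.
REPORTED_TANDEM_SETS: tuple[tuple[str, ...], ...] = (
    ("OsCSLF9", "OsCSLF8", "OsCSLF2", "OsCSLF1", "OsCSLF4", "OsCSLF3"),
    ("OsCSLH2", "OsCSLH3"),
    ("OsCSLE1", "OsCSLE6"),
)

REPORTED_SEGMENTAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("OsCESA2", "OsCESA8"),
    ("OsCSLA1", "OsCSLA9"),
    ("OsCSLA2", "OsCSLA4"),
    ("OsCSLA5", "OsCSLA7"),
    ("OsCSLA6", "OsCSLA3"),
    ("OsCSLC9", "OsCSLC10"),
    ("OsCSLE2", "OsCSLE6"),
)


class DuplicationError(ValueError):
    """Raised on invalid duplication-caller inputs."""


@dataclass(frozen=True)
class TandemCluster:
    chromosome: int
    members: tuple[str, ...]  # ordered by position along the chromosome
    max_intervening_used: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise DuplicationError("a tandem cluster needs at least two members")


class Anchor(NamedTuple):
    """A scored collinear anchor: homologous gene pair with bp positions."""

    gene_a: str
    gene_b: str
    pos_a: int
    pos_b: int
    score: float = 1.0


@dataclass(frozen=True)
class CollinearBlock:
    region_a: tuple[int, int, int]  # chromosome, start bp, end bp
    region_b: tuple[int, int, int]
    anchors: tuple[Anchor, ...]
    chain_score: float
    orientation: int = 1  # +1 ascending pos_b, -1 descending


@dataclass(frozen=True)
class SegmentalPair:
    gene_a: str
    gene_b: str
    block_id: int


@dataclass
class DuplicationCatalog:
    tandem: list[TandemCluster] = field(default_factory=list)
    segmental: list[SegmentalPair] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tandem": [
                {
                    "chromosome": c.chromosome,
                    "members": list(c.members),
                    "max_intervening_used": c.max_intervening_used,
                }
                for c in self.tandem
            ],
            "segmental": [
                {"gene_a": p.gene_a, "gene_b": p.gene_b, "block_id": p.block_id}
                for p in self.segmental
            ],
        }


# ---------------------------------------------------------------------------
# Tandem calling
# ---------------------------------------------------------------------------


def call_tandem(
    catalog: Sequence[GeneRecord], max_intervening: int = 5
) -> list[TandemCluster]:
    """Call tandem duplicate clusters.

    Two members of one family on the same chromosome are linked when at most
    ``max_intervening`` gene models (by ordinal index) lie between them; the
    transitive closure of links forms the clusters.  Clusters are returned
    sorted by chromosome then position.
    """
    if max_intervening < 0:
        raise DuplicationError("max_intervening must be >= 0")
    groups: dict[tuple[int, str], list[GeneRecord]] = {}
    for rec in catalog:
        groups.setdefault((rec.chromosome, rec.family), []).append(rec)

    runs: list[tuple[int, list[GeneRecord]]] = []
    for (chrom, _family), recs in groups.items():
        recs = sorted(recs, key=lambda r: r.ordinal_index)
        run: list[GeneRecord] = [recs[0]]
        for rec in recs[1:]:
            intervening = rec.ordinal_index - run[-1].ordinal_index - 1
            if intervening <= max_intervening:
                run.append(rec)
            else:
                if len(run) >= 2:
                    runs.append((chrom, run))
                run = [rec]
        if len(run) >= 2:
            runs.append((chrom, run))

    runs.sort(key=lambda item: (item[0], item[1][0].ordinal_index))
    return [_make_cluster(chrom, run, max_intervening) for chrom, run in runs]


def _make_cluster(
    chrom: int, run: Sequence[GeneRecord], max_intervening: int
) -> TandemCluster:
    return TandemCluster(
        chromosome=chrom,
        members=tuple(r.gene_name for r in run),
        max_intervening_used=max_intervening,
    )


# ---------------------------------------------------------------------------
# Collinear chaining
# ---------------------------------------------------------------------------


def _as_anchor(item, index: int) -> Anchor:
    if isinstance(item, Anchor):
        return item
    if len(item) == 5:
        return Anchor(*item)
    if len(item) == 3:
        pos_a, pos_b, score = item
        return Anchor(f"a{index}", f"b{index}", int(pos_a), int(pos_b), float(score))
    raise DuplicationError(
        "anchors must be Anchor tuples, (gene_a, gene_b, pos_a, pos_b, score) "
        "or (pos_a, pos_b, score)"
    )


def _gap_penalty(gap_a: int, gap_b: int, score_unit: float, max_gap: int) -> float:
    return score_unit * ((gap_a + gap_b) / 2.0) / max_gap


def _chain_dp(
    anchors: Sequence[Anchor], max_gap: int, score_unit: float, orientation: int
) -> tuple[float, list[int]]:
    """Best chain (score, anchor indices) for one pos_b orientation."""
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].pos_a, anchors[i].pos_b))
    best = [anchors[i].score for i in order]
    back = [-1] * len(order)
    for ii, i in enumerate(order):
        ai = anchors[i]
        for jj in range(ii):
            aj = anchors[order[jj]]
            if aj.pos_a >= ai.pos_a:
                continue
            if orientation * (ai.pos_b - aj.pos_b) <= 0:
                continue
            gap_a = ai.pos_a - aj.pos_a
            gap_b = abs(ai.pos_b - aj.pos_b)
            if gap_a > max_gap or gap_b > max_gap:
                continue
            cand = best[jj] + ai.score - _gap_penalty(gap_a, gap_b, score_unit, max_gap)
            if cand > best[ii] + 1e-12:
                best[ii] = cand
                back[ii] = jj
    if not order:
        return 0.0, []
    end = max(range(len(order)), key=lambda ii: (best[ii], -order[ii]))
    chain: list[int] = []
    ii = end
    while ii != -1:
        chain.append(order[ii])
        ii = back[ii]
    chain.reverse()
    return best[end], chain


def best_chain_score(
    anchors: Sequence, max_gap: int = 100_000, score_unit: float = 1.0
) -> float:
    """Score of the single best collinear chain over both orientations."""
    items = [_as_anchor(a, i) for i, a in enumerate(anchors)]
    if not items:
        return 0.0
    fwd, _ = _chain_dp(items, max_gap, score_unit, +1)
    rev, _ = _chain_dp(items, max_gap, score_unit, -1)
    return max(fwd, rev)


def chain_collinear(
    anchors: Sequence,
    max_gap: int = 100_000,
    min_anchors: int = 5,
    score_unit: float = 1.0,
    chrom_a: int = 0,
    chrom_b: int = 0,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks.

    Dynamic programming maximizes summed anchor scores minus a gap penalty
    ``score_unit * mean(gap_a, gap_b) / max_gap`` per link; links spanning
    more than ``max_gap`` on either axis are forbidden, which splits chains
    at large gaps.  Both pos_b orientations are tried and blocks are
    extracted best-first until no chain with at least ``min_anchors``
    anchors remains.
    """
    if max_gap <= 0:
        raise DuplicationError("max_gap must be positive")
    if min_anchors < 1:
        raise DuplicationError("min_anchors must be >= 1")
    remaining = [_as_anchor(a, i) for i, a in enumerate(anchors)]
    blocks: list[CollinearBlock] = []
    while len(remaining) >= min_anchors:
        fwd_score, fwd_chain = _chain_dp(remaining, max_gap, score_unit, +1)
        rev_score, rev_chain = _chain_dp(remaining, max_gap, score_unit, -1)
        if (fwd_score, len(fwd_chain)) >= (rev_score, len(rev_chain)):
            score, chain, orient = fwd_score, fwd_chain, +1
        else:
            score, chain, orient = rev_score, rev_chain, -1
        if len(chain) < min_anchors:
            break
        picked = [remaining[i] for i in chain]
        blocks.append(
            CollinearBlock(
                region_a=(chrom_a, min(a.pos_a for a in picked), max(a.pos_a for a in picked)),
                region_b=(chrom_b, min(a.pos_b for a in picked), max(a.pos_b for a in picked)),
                anchors=tuple(picked),
                chain_score=score,
                orientation=orient,
            )
        )
        chain_set = set(chain)
        remaining = [a for i, a in enumerate(remaining) if i not in chain_set]
    return blocks


# ---------------------------------------------------------------------------
# Segmental assignment and summary
# ---------------------------------------------------------------------------


def assign_segmental_sets(
    catalog: Sequence[GeneRecord],
    blocks: Sequence[CollinearBlock],
    positions: Mapping[str, tuple[int, int, int]],
    tandem: Sequence[TandemCluster] = (),
) -> list[SegmentalPair]:
    """Call segmental duplicate pairs from collinear blocks.

    A same-family pair is segmental when one member lies inside ``region_a``
    and the other inside ``region_b`` of a block.  Pairs already joined in a
    tandem cluster are excluded (with a logged reason), and each unordered
    pair is reported at most once.
    """
    missing = sorted(
        rec.gene_name for rec in catalog if rec.gene_name not in positions
    )
    if missing:
        raise DuplicationError(
            f"missing positions for gene(s): {', '.join(missing)}"
        )
    tandem_mates = set()
    for cluster in tandem:
        ms = sorted(cluster.members)
        for i, g in enumerate(ms):
            for h in ms[i + 1 :]:
                tandem_mates.add((g, h))

    def inside(gene: str, region: tuple[int, int, int]) -> bool:
        chrom, start, end = positions[gene]
        rchrom, rstart, rend = region
        return chrom == rchrom and start >= rstart and end <= rend

    pairs: list[SegmentalPair] = []
    seen: set[tuple[str, str]] = set()
    for block_id, block in enumerate(blocks):
        in_a = [r for r in catalog if inside(r.gene_name, block.region_a)]
        in_b = [r for r in catalog if inside(r.gene_name, block.region_b)]
        for ra in in_a:
            for rb in in_b:
                if ra.gene_name == rb.gene_name or ra.family != rb.family:
                    continue
                key = tuple(sorted((ra.gene_name, rb.gene_name)))
                if key in seen:
                    continue
                if key in tandem_mates:
                    logger.info(
                        "pair %s/%s excluded from segmental sets: already a "
                        "tandem cluster pair",
                        key[0],
                        key[1],
                    )
                    continue
                seen.add(key)
                pairs.append(SegmentalPair(ra.gene_name, rb.gene_name, block_id))
    return pairs


def duplication_summary(
    dup: DuplicationCatalog, catalog: Sequence[GeneRecord] | None = None
) -> dict:
    """Summarize duplication involvement.

    ``unique_genes_involved`` is the size of the union of all tandem members
    and segmental pair members.  When a catalog is supplied the per-family
    breakdown also carries family totals.
    """
    involved: set[str] = set()
    for cluster in dup.tandem:
        involved.update(cluster.members)
    for pair in dup.segmental:
        involved.update((pair.gene_a, pair.gene_b))

    per_family: dict[str, dict] = {}
    if catalog is not None:
        fam_of = {rec.gene_name: rec.family for rec in catalog}
        for gene in involved:
            fam = fam_of.get(gene)
            if fam is None:
                continue
            per_family.setdefault(fam, {"involved": 0})["involved"] += 1
        for rec in catalog:
            per_family.setdefault(rec.family, {"involved": 0})
            per_family[rec.family]["total"] = sum(
                1 for r in catalog if r.family == rec.family
            )
    return {"unique_genes_involved": len(involved), "per_family": per_family}


def reported_duplication_catalog() -> DuplicationCatalog:
    """The duplication sets reported for the rice superfamily, as a catalog.

    Tandem chromosome numbers follow the TIGR loci of the member genes.
    """
    chrom_of = {"OsCSLF9": 7, "OsCSLH2": 4, "OsCSLE1": 9}
    tandem = [
        TandemCluster(
            chromosome=chrom_of[members[0]], members=members, max_intervening_used=5
        )
        for members in REPORTED_TANDEM_SETS
    ]
    segmental = [
        SegmentalPair(a, b, block_id=i)
        for i, (a, b) in enumerate(REPORTED_SEGMENTAL_PAIRS)
    ]
    return DuplicationCatalog(tandem=tandem, segmental=segmental)


# ---------------------------------------------------------------------------
# Duplicate-pair expression fate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FateCall:
    pair: tuple[str, str]
    fate: str
    expressed_tissues_a: frozenset
    expressed_tissues_b: frozenset
    jaccard_overlap: float
    corr_r: float
    corr_significant: bool

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "fate": self.fate,
            "expressed_tissues_a": sorted(map(str, self.expressed_tissues_a)),
            "expressed_tissues_b": sorted(map(str, self.expressed_tissues_b)),
            "jaccard_overlap": self.jaccard_overlap,
            "corr_r": self.corr_r,
            "corr_significant": self.corr_significant,
        }


def corr_significance(r: float, n: int, alpha: float = 0.05) -> bool:
    """Two-sided t test for a Pearson correlation coefficient.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of freedom;
    returns True when ``p < alpha``.  ``|r| = 1`` is significant by
    convention (p -> 0).
    """
    if n < 3:
        raise DuplicationError("corr_significance requires n >= 3")
    if abs(r) > 1 + 1e-12:
        raise DuplicationError("|r| must be <= 1")
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return True
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return bool(p < alpha)


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at ``alpha`` for sample size ``n``."""
    if n < 3:
        raise DuplicationError("critical_r requires n >= 3")
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(tcrit / math.sqrt(n - 2 + tcrit * tcrit))


def classify_fate(
    expr_a: Sequence[float],
    expr_b: Sequence[float],
    expressed_threshold: float,
    overlap_cut: float = 0.5,
    tissues: Sequence | None = None,
    pair: tuple[str, str] = ("gene_a", "gene_b"),
    alpha: float = 0.05,
    min_strong: int = 3,
) -> FateCall:
    """Classify the expression fate of a duplicate gene pair.

    A tissue is *expressed* when the signal exceeds ``expressed_threshold``.
    Decision table (evaluated in order, symmetric in the two genes):

    * both silent everywhere -> ``ambiguous``;
    * one silent everywhere, the other expressed in at least ``min_strong``
      tissues -> ``nonfunctionalization`` (one copy lost expression while
      the other retains strong expression);
    * one silent everywhere but the other weakly expressed -> ``ambiguous``;
    * Jaccard overlap >= ``overlap_cut`` with a significant correlation ->
      ``conserved``;
    * overlap < ``overlap_cut`` with each gene holding exclusive tissues ->
      ``subfunctionalization`` (domains partitioned);
    * overlap < ``overlap_cut`` with one expression domain nested in the
      other -> ``neofunctionalization_candidate`` (one copy gained tissues);
    * otherwise -> ``ambiguous``.
    """
    va = np.asarray(expr_a, dtype=float)
    vb = np.asarray(expr_b, dtype=float)
    if va.shape != vb.shape:
        raise DuplicationError("expression vectors differ in length")
    if va.size < 3:
        raise DuplicationError("classify_fate requires vectors of length >= 3")
    labels = list(tissues) if tissues is not None else list(range(va.size))
    if len(labels) != va.size:
        raise DuplicationError("tissue labels differ in length from vectors")

    set_a = frozenset(l for l, x in zip(labels, va) if x > expressed_threshold)
    set_b = frozenset(l for l, x in zip(labels, vb) if x > expressed_threshold)
    union = set_a | set_b
    jac = len(set_a & set_b) / len(union) if union else 1.0

    if va.std() == 0 or vb.std() == 0:
        r, sig = 0.0, False
    else:
        r = float(np.corrcoef(va, vb)[0, 1])
        sig = corr_significance(r, va.size, alpha)

    if not set_a and not set_b:
        fate = "ambiguous"
    elif not set_a or not set_b:
        bigger = set_b if not set_a else set_a
        fate = "nonfunctionalization" if len(bigger) >= min_strong else "ambiguous"
    elif jac >= overlap_cut and sig:
        fate = "conserved"
    elif jac < overlap_cut and (set_a - set_b) and (set_b - set_a):
        fate = "subfunctionalization"
    elif jac < overlap_cut:
        fate = "neofunctionalization_candidate"
    else:
        fate = "ambiguous"

    return FateCall(
        pair=pair,
        fate=fate,
        expressed_tissues_a=set_a,
        expressed_tissues_b=set_b,
        jaccard_overlap=jac,
        corr_r=r,
        corr_significant=sig,
    )
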