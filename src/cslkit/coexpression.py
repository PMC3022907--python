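"""Co-expression clustering of gene-family expression matrices.

The workflow mirrors the classic microarray analysis of a gene family
across a tissue panel: signals are log-transformed (log2(x+1)), genes are
clustered by agglomerative complete linkage on Euclidean distances, the
dendrogram is cut into major groups and subgroups, and per-family
accumulative profiles, tissue-specificity scores (tau), marker-gene links
and cross-species group matching are derived.

The complete-linkage agglomeration is implemented here (rather than wrapped)
because deterministic, lexicographic tie-breaking and an explicit merge
history are part of the contract: downstream minimal-subtree queries of the
in-silico deletion analysis must be reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")
LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class CoexpressionError(ValueError):
    """Raised on invalid expression-matrix input."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue: str
    variety: str = ""
    stage: int = 0


class ExpressionMatrix:
    """Nonnegative gene x sample signal matrix with sample metadata.

    ``genes`` and sample ids must be unique; all signals must be finite and
    >= 0.  Genes with constant signal are flagged (Pearson correlation is
    undefined for them) but kept.
    """

    def __init__(
        self,
        genes: Sequence[str],
        samples: Sequence[SampleMeta],
        values,
        check: bool = True,
    ) -> None:
        self.genes = list(genes)
        self.samples = list(samples)
        self.values = np.asarray(values, dtype=float)
        if check:
            self._validate()

    def _validate(self) -> None:
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise CoexpressionError(
                f"signal shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise CoexpressionError("duplicate gene ids")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise CoexpressionError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise CoexpressionError("signals must be finite")
        if np.any(self.values < 0):
            raise CoexpressionError("signals must be nonnegative")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.tissue, None)
        return list(seen)

    @property
    def constant_genes(self) -> list[str]:
        std = self.values.std(axis=1)
        return [g for g, s in zip(self.genes, std) if s == 0.0]

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise CoexpressionError(f"unknown gene {gene!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.genes), list(self.samples), self.values.copy(), check=False
        )

    def equals(self, other: "ExpressionMatrix", atol: float = 0.0) -> bool:
        return (
            self.genes == other.genes
            and self.samples == other.samples
            and np.allclose(self.values, other.values, atol=atol, rtol=0)
        )

    # -- subsetting ---------------------------------------------------------

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = []
        for g in genes:
            if g not in self.genes:
                raise CoexpressionError(f"unknown gene {g!r}")
            idx.append(self.genes.index(g))
        return ExpressionMatrix(
            [self.genes[i] for i in idx],
            list(self.samples),
            self.values[idx],
            check=False,
        )

    def drop(
        self,
        genes: Iterable[str] = (),
        samples: Iterable[str] = (),
        tissues: Iterable[str] = (),
    ) -> "ExpressionMatrix":
        """Remove genes and/or samples (by id or tissue label); order preserved."""
        genes = set(genes)
        samples = set(samples)
        tissues = set(tissues)
        unknown = (
            (genes - set(self.genes))
            | (samples - set(self.sample_ids))
            | (tissues - set(t for s in self.samples for t in [s.tissue]))
        )
        if unknown:
            raise CoexpressionError(
                f"unknown id(s) to remove: {', '.join(sorted(unknown))}"
            )
        gene_keep = [i for i, g in enumerate(self.genes) if g not in genes]
        samp_keep = [
            j
            for j, s in enumerate(self.samples)
            if s.sample_id not in samples and s.tissue not in tissues
        ]
        return ExpressionMatrix(
            [self.genes[i] for i in gene_keep],
            [self.samples[j] for j in samp_keep],
            self.values[np.ix_(gene_keep, samp_keep)],
            check=False,
        )

    # -- aggregation --------------------------------------------------------

    def tissue_profile(self, agg: str = "mean") -> pd.DataFrame:
        """Genes x tissues frame aggregating samples sharing a tissue label."""
        frame = self.to_dataframe()
        tissue_of = {s.sample_id: s.tissue for s in self.samples}
        grouped = frame.T.groupby([tissue_of[c] for c in frame.columns], sort=False)
        agg_frame = grouped.mean() if agg == "mean" else grouped.sum()
        return agg_frame.T[self.tissues]


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply ``x -> log2(x + 1)`` to every signal; metadata unchanged."""
    if np.any(m.values < 0):
        raise CoexpressionError("log_transform requires nonnegative signals")
    return ExpressionMatrix(
        list(m.genes), list(m.samples), np.log2(m.values + 1.0), check=False
    )


def pearson_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """Gene x gene Pearson correlation matrix.

    Genes with constant signal are excluded with a warning (their correlation
    is undefined).  The result is symmetric with unit diagonal and entries
    clipped to [-1, 1].
    """
    if m.n_samples < 3:
        raise CoexpressionError("pearson_matrix requires at least 3 samples")
    constant = m.constant_genes
    if constant:
        logger.warning(
            "excluding %d constant gene(s) from correlation: %s",
            len(constant),
            ", ".join(constant),
        )
    keep = [g for g in m.genes if g not in set(constant)]
    sub = m.subset_genes(keep)
    corr = np.corrcoef(sub.values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=keep, columns=keep)


# ---------------------------------------------------------------------------
# Agglomerative complete-linkage clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge history.

    Nodes ``0 .. n-1`` are leaves in ``leaves`` order; merge ``k`` creates
    node ``n + k``.  Complete linkage guarantees nondecreasing heights.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise CoexpressionError(
                f"{self.n_leaves} leaves require {self.n_leaves - 1} merges, "
                f"got {len(self.merges)}"
            )

    def members(self, node: int) -> frozenset:
        """Leaf-name set of a node's subtree."""
        n = self.n_leaves
        if node < n:
            return frozenset((self.leaves[node],))
        stack = [node]
        out = []
        while stack:
            cur = stack.pop()
            if cur < n:
                out.append(self.leaves[cur])
            else:
                a, b, _ = self.merges[cur - n]
                stack.extend((a, b))
        return frozenset(out)

    def node_height(self, node: int) -> float:
        return 0.0 if node < self.n_leaves else self.merges[node - self.n_leaves][2]

    def leaf_order(self) -> list[str]:
        """Dendrogram leaf order (children visited lower/lexicographic first)."""
        n = self.n_leaves

        def key(node: int):
            return (self.node_height(node), min(self.members(node)))

        out: list[str] = []
        stack = [self.root]
        while stack:
            cur = stack.pop()
            if cur < n:
                out.append(self.leaves[cur])
            else:
                a, b, _ = self.merges[cur - n]
                first, second = sorted((a, b), key=key)
                stack.append(second)
                stack.append(first)
        return out

    def to_newick(self, digits: int = 6) -> str:
        """Newick string with merge heights rendered as branch lengths."""
        n = self.n_leaves

        def render(node: int, parent_height: float) -> str:
            length = parent_height - self.node_height(node)
            if node < n:
                return f"{self.leaves[node]}:{length:.{digits}f}"
            a, b, h = self.merges[node - n]
            inner = ",".join(render(c, h) for c in (a, b))
            return f"({inner}):{length:.{digits}f}"

        if n == 1:
            return f"({self.leaves[0]}:0.0);"
        a, b, h = self.merges[-1]
        inner = ",".join(render(c, h) for c in (a, b))
        return f"({inner});"

    def to_linkage(self) -> np.ndarray:
        """SciPy-style linkage matrix (for plotting or cross-checks)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        out = np.zeros((len(self.merges), 4))
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + k] = size
            out[k] = (a, b, h, size)
        return out


def hcluster(
    m: ExpressionMatrix, metric: str = "euclidean", linkage: str = "complete"
) -> ClusterTree:
    """Agglomerative clustering of genes.

    Repeatedly merges the pair of clusters at the smallest complete-linkage
    distance (the maximum pairwise distance between members).  Ties are
    broken by the lexicographically smallest combined member-name tuple, so
    the merge history is fully deterministic.
    """
    if linkage != "complete":
        raise CoexpressionError("only complete linkage is supported")
    if m.n_genes < 2:
        raise CoexpressionError("hcluster requires at least 2 genes")
    if not np.all(np.isfinite(m.values)):
        raise CoexpressionError("matrix contains NaN or infinite values")

    n = m.n_genes
    dist = squareform(pdist(m.values, metric=metric))
    # active cluster id -> (node id, sorted member-name tuple)
    active: dict[int, tuple[int, tuple[str, ...]]] = {
        i: (i, (m.genes[i],)) for i in range(n)
    }
    cluster_dist: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    ids = sorted(active)
    for _ in range(n - 1):
        best_key = None
        best = None
        for x in range(len(ids)):
            i = ids[x]
            for y in range(x + 1, len(ids)):
                j = ids[y]
                d = cluster_dist[(i, j) if i < j else (j, i)]
                names = tuple(sorted(active[i][1] + active[j][1]))
                key = (d, names)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best
        d = best_key[0]
        merges.append((active[i][0], active[j][0], d))
        merged_names = best_key[1]
        # Lance-Williams update for complete linkage: max of the two.
        for k in ids:
            if k in (i, j):
                continue
            dik = cluster_dist[(i, k) if i < k else (k, i)]
            djk = cluster_dist[(j, k) if j < k else (k, j)]
            cluster_dist[(k, next_id)] = max(dik, djk)
        active[next_id] = (next_id, merged_names)
        del active[i], active[j]
        ids = [k for k in ids if k not in (i, j)] + [next_id]
        next_id += 1
    return ClusterTree(leaves=tuple(m.genes), merges=tuple(merges))


# ---------------------------------------------------------------------------
# Dendrogram cuts and group reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoexpressionGroup:
    group_id: str
    members: tuple[str, ...]
    signature: Mapping[str, float] = field(default_factory=dict)
    top_tissues: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "members": list(self.members),
            "signature": dict(self.signature),
            "top_tissues": list(self.top_tissues),
        }


def cut_tree(
    tree: ClusterTree, k: int, m: ExpressionMatrix | None = None
) -> list[CoexpressionGroup]:
    """Cut the dendrogram into exactly ``k`` groups.

    Applying the first ``n - k`` merges yields the partition.  Groups are
    ordered (and numbered ``G1..Gk``) by dendrogram leaf order.  When the
    matrix is supplied each group carries its signature: the per-tissue mean
    of member log2(x+1) signals, with tissues ranked into ``top_tissues``.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise CoexpressionError(f"k={k} outside 1..{n}")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx in range(n - k):
        a, b, _ = tree.merges[idx]
        node = n + idx
        parent[find(a)] = node
        parent[find(b)] = node

    clusters: dict[int, list[str]] = {}
    for i, name in enumerate(tree.leaves):
        clusters.setdefault(find(i), []).append(name)

    order = {name: pos for pos, name in enumerate(tree.leaf_order())}
    ordered = sorted(clusters.values(), key=lambda ms: min(order[g] for g in ms))

    signatures: Mapping[str, Mapping[str, float]] = {}
    if m is not None:
        logged = log_transform(m)
        profile = logged.tissue_profile("mean")
        signatures = {g: profile.loc[g] for g in m.genes}

    groups = []
    for gi, members in enumerate(ordered, start=1):
        members = tuple(sorted(members, key=lambda g: order[g]))
        sig: dict[str, float] = {}
        top: tuple[str, ...] = ()
        if signatures:
            acc = pd.DataFrame([signatures[g] for g in members]).mean(axis=0)
            sig = {t: float(v) for t, v in acc.items()}
            top = tuple(
                sorted(sig, key=lambda t: (-sig[t], t))
            )
        groups.append(
            CoexpressionGroup(
                group_id=f"G{gi}", members=members, signature=sig, top_tissues=top
            )
        )
    return groups


def two_level_labels(
    tree: ClusterTree,
    k_major: int = 3,
    k_sub: int = 10,
    m: ExpressionMatrix | None = None,
) -> list[CoexpressionGroup]:
    """Label subgroups hierarchically, e.g. ``IA .. IIIE``.

    Two cuts of the same tree: ``k_major`` major groups get roman numerals in
    dendrogram order; the ``k_sub`` subgroups nested in each major group get
    letters, again in dendrogram order.
    """
    majors = cut_tree(tree, k_major)
    subs = cut_tree(tree, k_sub, m=m)
    major_of: dict[str, str] = {}
    for mi, major in enumerate(majors):
        for gene in major.members:
            major_of[gene] = ROMAN[mi]
    labelled = []
    counter: dict[str, int] = {}
    for sub in subs:
        roman = major_of[sub.members[0]]
        counter[roman] = counter.get(roman, 0) + 1
        labelled.append(
            CoexpressionGroup(
                group_id=f"{roman}{LETTERS[counter[roman] - 1]}",
                members=sub.members,
                signature=sub.signature,
                top_tissues=sub.top_tissues,
            )
        )
    return labelled


# ---------------------------------------------------------------------------
# Profiles, specificity, markers, cross-species matching
# ---------------------------------------------------------------------------


def family_accumulative_profile(
    m: ExpressionMatrix, catalog, family: str
) -> tuple[pd.Series, set]:
    """Per-tissue summed raw signal of a family plus the argmax tissue set.

    Samples sharing a tissue label are first averaged, then member signals
    are summed on the raw scale.  Ties at the maximum are all reported.
    """
    members = [rec.gene_name for rec in catalog if rec.family == family]
    members = [g for g in members if g in m.genes]
    if not members:
        raise CoexpressionError(f"family {family!r} has no member in the matrix")
    profile = m.subset_genes(members).tissue_profile("mean").sum(axis=0)
    peak = profile.max()
    argmax = {t for t, v in profile.items() if v == peak}
    return profile, argmax


def specificity_score(profile: Sequence[float], log_scale: bool = True) -> float:
    """Tissue-specificity index tau in [0, 1].

    ``tau = sum(1 - x_i / x_max) / (n - 1)`` computed on log2(x+1) signals by
    default; 0 means uniform expression, 1 means expression confined to a
    single tissue.
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise CoexpressionError("specificity_score requires >= 2 tissues")
    if np.any(x < 0):
        raise CoexpressionError("profile must be nonnegative")
    if np.all(x == 0):
        raise CoexpressionError("profile is all zero; tau undefined")
    if log_scale:
        x = np.log2(x + 1.0)
    xmax = x.max()
    if xmax == 0:
        raise CoexpressionError("profile is all zero on the log scale")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


@dataclass(frozen=True)
class MarkerLink:
    marker: str
    best_partner: str
    r: float
    passed: bool


def marker_coexpression(
    m: ExpressionMatrix,
    marker_genes: Iterable[str],
    threshold: float = 0.9,
    use_log: bool = False,
) -> list[MarkerLink]:
    """Best co-expression partner for each marker gene.

    For every marker the non-marker gene with the highest Pearson r is
    reported; links at or above ``threshold`` are flagged as co-expression
    links.  Correlation is computed on raw signals by default (``use_log``
    switches to log2(x+1)).  Constant markers are excluded with a warning.
    """
    markers = sorted(set(marker_genes))
    missing = [g for g in markers if g not in m.genes]
    if missing:
        raise CoexpressionError(f"marker(s) not in matrix: {', '.join(missing)}")
    work = log_transform(m) if use_log else m
    constant = set(work.constant_genes)
    links = []
    others = [g for g in m.genes if g not in set(markers) and g not in constant]
    for marker in markers:
        if marker in constant:
            logger.warning("marker %s has constant signal; excluded", marker)
            continue
        mrow = work.row(marker)
        best_gene, best_r = None, -2.0
        for gene in others:
            r = float(np.corrcoef(mrow, work.row(gene))[0, 1])
            if r > best_r or (r == best_r and gene < best_gene):
                best_gene, best_r = gene, r
        if best_gene is None:
            continue
        links.append(
            MarkerLink(
                marker=marker,
                best_partner=best_gene,
                r=best_r,
                passed=best_r >= threshold,
            )
        )
    return links


def match_groups(
    groups_a: Sequence[CoexpressionGroup],
    groups_b: Sequence[CoexpressionGroup],
    tissue_map: Mapping[str, str],
) -> dict[str, list[tuple[str, float]]]:
    """Rank groups of study B against each group of study A.

    Signatures are restricted to the mapped tissue concepts (A-tissue ->
    B-tissue); similarity is the cosine of the two restricted signature
    vectors.  Unmapped tissues are ignored.
    """
    if not tissue_map:
        raise CoexpressionError("tissue_map must not be empty")
    pairs = [
        (ta, tb)
        for ta, tb in tissue_map.items()
    ]

    def vec(group: CoexpressionGroup, side: int) -> np.ndarray:
        return np.array(
            [group.signature.get(p[side], 0.0) for p in pairs], dtype=float
        )

    out: dict[str, list[tuple[str, float]]] = {}
    for ga in groups_a:
        va = vec(ga, 0)
        ranked = []
        for gb in groups_b:
            vb = vec(gb, 1)
            denom = np.linalg.norm(va) * np.linalg.norm(vb)
            sim = float(va @ vb / denom) if denom > 0 else 0.0
            ranked.append((gb.group_id, sim))
        ranked.sort(key=lambda t: (-t[1], t[0]))
        out[ga.group_id] = ranked
    return out
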