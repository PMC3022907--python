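"""Shared fixtures: the packaged catalog and small synthetic matrices."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cslkit.catalog import load_packaged_catalog
from cslkit.coexpression import ExpressionMatrix, SampleMeta


@pytest.fixture(scope="session")
def rice_catalog():
    return load_packaged_catalog()


@pytest.fixture()
def small_matrix():
    """Deterministic 6-gene x 6-sample matrix with two tissue labels."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = [
        SampleMeta(f"s{j}", tissue="root" if j < 3 else "leaf", variety="V", stage=j)
        for j in range(6)
    ]
    values = rng.uniform(1.0, 500.0, size=(6, 6))
    return ExpressionMatrix(genes, samples, values)


def random_matrix(rng: np.random.Generator, n_genes: int, n_samples: int) -> ExpressionMatrix:
    genes = [f"g{i:02d}" for i in range(n_genes)]
    samples = [SampleMeta(f"s{j}", tissue=f"t{j}") for j in range(n_samples)]
    return ExpressionMatrix(genes, samples, rng.uniform(0.0, 100.0, (n_genes, n_samples)))


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive re-implementations)
# ---------------------------------------------------------------------------


def brute_force_alignment(a: str, b: str) -> tuple[int, int, int]:
    """Enumerate every global alignment; return the best
    (score, matches, -length) under match +1 / mismatch 0 / gap -1."""

    best = [None]

    def walk(i: int, j: int, score: int, matches: int, length: int) -> None:
        if i == len(a) and j == len(b):
            key = (score, matches, -length)
            if best[0] is None or key > best[0]:
                best[0] = key
            return
        if i < len(a) and j < len(b):
            m = 1 if a[i] == b[j] else 0
            walk(i + 1, j + 1, score + m, matches + m, length + 1)
        if i < len(a):
            walk(i + 1, j, score - 1, matches, length + 1)
        if j < len(b):
            walk(i, j + 1, score - 1, matches, length + 1)

    walk(0, 0, 0, 0, 0)
    return best[0]


def brute_force_motif(seq: str, g_min: int = 5):
    """Exhaustive sliding-window search over all index triples, applying the
    leftmost-first preference independently of the scanner."""
    seq = seq.upper()
    n = len(seq)
    dxd_sites = [i for i in range(n - 2) if seq[i] == "D" and seq[i + 2] == "D"]
    if not dxd_sites:
        return None, None, None
    i = min(dxd_sites)
    lone_sites = [
        j
        for j in range(n)
        if seq[j] == "D"
        and j >= i + 2 + g_min
        and (j == 0 or seq[j - 1] != "D")
        and (j == n - 1 or seq[j + 1] != "D")
    ]
    if not lone_sites:
        return i, None, None
    j = min(lone_sites)
    motif_sites = [
        k for k in range(j + 1, n - 4) if seq[k + 3] == "R" and seq[k + 4] == "W"
    ]
    if not motif_sites:
        return i, j, None
    return i, j, min(motif_sites)


def brute_force_best_chain(anchors, max_gap: int, score_unit: float = 1.0) -> float:
    """Exhaustive enumeration over all monotone anchor subsequences."""
    best = 0.0
    n = len(anchors)
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            pts = [anchors[i] for i in subset]
            for orient in (1, -1):
                order = sorted(pts, key=lambda a: a.pos_a)
                score = order[0].score
                ok = True
                for p, q in zip(order, order[1:]):
                    if q.pos_a <= p.pos_a or orient * (q.pos_b - p.pos_b) <= 0:
                        ok = False
                        break
                    ga, gb = q.pos_a - p.pos_a, abs(q.pos_b - p.pos_b)
                    if ga > max_gap or gb > max_gap:
                        ok = False
                        break
                    score += q.score - score_unit * ((ga + gb) / 2.0) / max_gap
                if ok and score > best:
                    best = score
    return best


def brute_force_complete_linkage(values: np.ndarray, names: list[str]):
    """Re-scan oracle: recomputes every inter-cluster maximum over leaf
    pairs at each step instead of using the max-of-max update."""
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(values))
    clusters: dict[int, frozenset[int]] = {
        i: frozenset([i]) for i in range(len(names))
    }
    merges = []
    next_id = len(names)
    while len(clusters) > 1:
        best_key, best = None, None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            key = (
                d,
                tuple(sorted(names[i] for i in clusters[a] | clusters[b])),
            )
            if best_key is None or key < best_key:
                best_key, best = key, (a, b)
        a, b = best
        merges.append((a, b, best_key[0]))
        clusters[next_id] = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        next_id += 1
    return merges


def brute_force_minimal_subtree(tree, focal: frozenset):
    """Scan every merge node; the containing node with fewest members wins."""
    n = tree.n_leaves
    candidates = []
    for k in range(len(tree.merges)):
        members = tree.members(n + k)
        if focal <= members:
            candidates.append(members)
    return min(candidates, key=len)
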