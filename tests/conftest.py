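"""Shared fixtures and independent brute-force oracles.

The oracles here recompute semantic contributions and within/between scores
by direct enumeration (explicit loops over paths and groups), independent of
the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from wbsmda.dag import DiseaseDAG
from wbsmda.network import MiRNADiseaseNetwork
from wbsmda.similarity import SimilarityMatrix


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def toy_network() -> MiRNADiseaseNetwork:
    """2 diseases x 3 miRNAs: d1-{m1,m2}, d2-{m2}."""
    A = np.array([[1, 1, 0], [0, 1, 0]])
    return MiRNADiseaseNetwork(["d1", "d2"], ["m1", "m2", "m3"], A)


@pytest.fixture
def chain_dag() -> DiseaseDAG:
    """Chain d -> a -> r with one anchored disease."""
    return DiseaseDAG(
        terms=set(), edges={("d", "a"), ("a", "r")}, anchors={"x": "d"}
    )


@pytest.fixture
def sibling_dag() -> DiseaseDAG:
    """Two sibling terms under a common root."""
    return DiseaseDAG(
        terms=set(),
        edges={("a", "r"), ("b", "r")},
        anchors={"d1": "a", "d2": "b"},
    )


def random_network(
    rng: np.random.Generator, nd: int, nm: int, density: float = 0.3
) -> MiRNADiseaseNetwork:
    """Random binary network guaranteed to contain >= 1 association."""
    A = (rng.random((nd, nm)) < density).astype(np.int8)
    if A.sum() == 0:
        A[rng.integers(nd), rng.integers(nm)] = 1
    return MiRNADiseaseNetwork(
        [f"d{i}" for i in range(nd)], [f"m{j}" for j in range(nm)], A
    )


def random_similarity(rng: np.random.Generator, ids: list[str]) -> SimilarityMatrix:
    n = len(ids)
    vals = rng.random((n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix.from_values(ids, vals)


# ----------------------------------------------------------------- oracles


def brute_force_components(net, SM, SD, i, j):
    """(ws_m, bs_m, ws_d, bs_d) for pair (i, j) by explicit set enumeration."""
    within_m = [k for k in range(net.nm) if net.A[i, k] == 1 and k != j]
    between_m = [k for k in range(net.nm) if net.A[i, k] == 0 and k != j]
    within_d = [k for k in range(net.nd) if net.A[k, j] == 1 and k != i]
    between_d = [k for k in range(net.nd) if net.A[k, j] == 0 and k != i]
    mx = lambda vals, grp, row: max((vals[row][g] for g in grp), default=0.0)
    return (
        mx(SM.values, within_m, j),
        mx(SM.values, between_m, j),
        mx(SD.values, within_d, i),
        mx(SD.values, between_d, i),
    )


def brute_force_score_matrix(net, SM, SD, mode="ratio"):
    """O(nd*nm*(nd+nm)) score matrix by direct loops."""

    def contrast(w, b):
        return w / (w + b) if (w + b) > 0 else 0.0

    S = np.zeros((net.nd, net.nm))
    for i in range(net.nd):
        for j in range(net.nm):
            ws_m, bs_m, ws_d, bs_d = brute_force_components(net, SM, SD, i, j)
            if mode == "ratio":
                S[i, j] = (contrast(ws_m, bs_m) + contrast(ws_d, bs_d)) / 2
            else:
                S[i, j] = ((ws_m - bs_m) + (ws_d - bs_d)) / 2
    return S


def brute_force_semantic_contributions(dag: DiseaseDAG, disease: str, delta: float):
    """Contribution map by enumerating every ascending path from the anchor.

    Each term in the closure gets delta ** (length of the shortest
    child-to-parent path from the anchor).
    """
    anchor = dag.anchors[disease]
    best: dict[str, int] = {}

    def walk(term: str, dist: int, seen: frozenset) -> None:
        if term not in best or dist < best[term]:
            best[term] = dist
        for parent in dag.parents(term):
            if parent not in seen:
                walk(parent, dist + 1, seen | {parent})

    walk(anchor, 0, frozenset({anchor}))
    return {t: delta**k for t, k in best.items()}
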