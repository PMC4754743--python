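"""Disease semantic similarity from DAG term overlap.

Each disease D anchored in the ontology has a semantic value built from term
contributions: its own term contributes 1, and every ancestor term t
contributes ``delta ** k`` where ``k`` is the minimum number of edges from
D's term up to t (terms in the same layer contribute equally, and the
contribution decays with distance).  Equivalently, by topological recursion,

    contribution(t) = delta * max over children c of t within T(D)
                      of contribution(c),   contribution(D's term) = 1.

The semantic value DV(D) is the sum of contributions over T(D).  The
similarity of two diseases is the contribution mass they share relative to
their total semantic values:

    SS(d1, d2) = sum_{t in T(d1) & T(d2)} (C_d1(t) + C_d2(t))
                 / (DV(d1) + DV(d2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dag import DiseaseDAG
from .similarity import SimilarityMatrix

DEFAULT_DELTA = 0.5


@dataclass(frozen=True)
class SemanticValueEntry:
    """Term contributions and semantic value of one disease."""

    disease: str
    contribution: dict[str, float]
    dv: float


def _check_delta(delta: float) -> None:
    if not (0.0 < delta < 1.0):
        raise ValueError(f"semantic contribution factor must be in (0, 1), got {delta}")


def semantic_contributions(
    dag: DiseaseDAG, disease: str, delta: float = DEFAULT_DELTA
) -> SemanticValueEntry:
    """Contribution of every term in T(disease), and the semantic value.

    Computed by breadth-first ascent from the anchor term, so each term's
    contribution is ``delta ** (shortest ascending distance)``.
    """
    _check_delta(delta)
    if not dag.is_anchored(disease):
        raise KeyError(f"disease {disease!r} is not anchored in the DAG")
    anchor = dag.anchors[disease]
    contribution: dict[str, float] = {anchor: 1.0}
    frontier = [anchor]
    level = 1.0
    while frontier:
        level *= delta
        nxt: list[str] = []
        for term in frontier:
            for parent in dag.parents(term):
                if parent not in contribution:
                    contribution[parent] = level
                    nxt.append(parent)
        frontier = nxt
    return SemanticValueEntry(
        disease=disease, contribution=contribution, dv=float(sum(contribution.values()))
    )


def semantic_similarity_matrix(
    dag: DiseaseDAG, diseases: Sequence[str], delta: float = DEFAULT_DELTA
) -> SimilarityMatrix:
    """Pairwise DAG-overlap semantic similarity over a disease registry.

    Diseases without an ontology anchor get ``mask=False`` off the diagonal,
    so downstream integration falls back to the interaction-profile kernel
    for them instead of treating them as dissimilar to everything.
    """
    _check_delta(delta)
    diseases = list(diseases)
    n = len(diseases)
    entries: dict[str, SemanticValueEntry] = {}
    for d in diseases:
        if dag.is_anchored(d):
            entries[d] = semantic_contributions(dag, d, delta)
    values = np.eye(n)
    mask = np.eye(n, dtype=bool)
    for i in range(n):
        ei = entries.get(diseases[i])
        if ei is None:
            continue
        for j in range(i + 1, n):
            ej = entries.get(diseases[j])
            if ej is None:
                continue
            shared = ei.contribution.keys() & ej.contribution.keys()
            num = sum(ei.contribution[t] + ej.contribution[t] for t in shared)
            values[i, j] = values[j, i] = num / (ei.dv + ej.dv)
            mask[i, j] = mask[j, i] = True
    return SimilarityMatrix(diseases, values, mask)
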