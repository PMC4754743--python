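"""Within-score / between-score association scoring.

For a candidate pair (disease i, miRNA j) the network splits each axis into
two groups.  On the miRNA axis: miRNAs with a known association to disease i
(the *within* group) and those without (the *between* group); on the disease
axis likewise with respect to miRNA j.  The candidate itself is excluded
from both of its own groups — without that exclusion the between-score of
every unknown pair would be the candidate's self-similarity of 1 and the
score would degenerate.

    ws_m(i, j) = max_{k in within miRNAs of i, k != j}  SM(j, k)
    bs_m(i, j) = max_{k in between miRNAs of i, k != j} SM(j, k)

and symmetrically ws_d / bs_d over diseases with SD.  A maximum over an
empty group is 0 and flagged.  The four components combine into one score:

* ``ratio`` (default): S = (ws_m/(ws_m+bs_m) + ws_d/(ws_d+bs_d)) / 2,
  a probability-like value in [0, 1] (a zero-sum contrast counts as 0);
* ``difference``: S = ((ws_m - bs_m) + (ws_d - bs_d)) / 2 in [-1, 1].

New entities (all-zero interaction profile) have both groups on their own
axis undefined, so they are scored from the other axis's contrast alone;
that single-view score is the limit of the general formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import MiRNADiseaseNetwork
from .similarity import SimilarityMatrix

COMBINE_MODES = ("ratio", "difference")


@dataclass(frozen=True)
class ScoreComponents:
    """Within/between maxima for one candidate pair, with empty-group flags."""

    ws_m: float
    bs_m: float
    ws_d: float
    bs_d: float
    ws_m_empty: bool = False
    bs_m_empty: bool = False
    ws_d_empty: bool = False
    bs_d_empty: bool = False


def _check_inputs(
    net: MiRNADiseaseNetwork, SM: SimilarityMatrix, SD: SimilarityMatrix
) -> None:
    if SM.ids != net.mirna_ids:
        raise ValueError("miRNA similarity registry does not match the network")
    if SD.ids != net.disease_ids:
        raise ValueError("disease similarity registry does not match the network")


def _group_max(values: np.ndarray, members: np.ndarray) -> tuple[float, bool]:
    if not members.any():
        return 0.0, True
    return float(values[members].max()), False


def within_between_components(
    net: MiRNADiseaseNetwork,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    disease: str,
    mirna: str,
) -> ScoreComponents:
    """The four within/between maxima for one (disease, miRNA) pair."""
    _check_inputs(net, SM, SD)
    i = net.disease_index(disease)
    j = net.mirna_index(mirna)
    mirna_assoc = net.A[i, :] == 1
    disease_assoc = net.A[:, j] == 1
    not_self_m = np.arange(net.nm) != j
    not_self_d = np.arange(net.nd) != i
    ws_m, ws_m_empty = _group_max(SM.values[j], mirna_assoc & not_self_m)
    bs_m, bs_m_empty = _group_max(SM.values[j], ~mirna_assoc & not_self_m)
    ws_d, ws_d_empty = _group_max(SD.values[i], disease_assoc & not_self_d)
    bs_d, bs_d_empty = _group_max(SD.values[i], ~disease_assoc & not_self_d)
    return ScoreComponents(
        ws_m, bs_m, ws_d, bs_d, ws_m_empty, bs_m_empty, ws_d_empty, bs_d_empty
    )


def _contrast(w: np.ndarray, b: np.ndarray) -> np.ndarray:
    total = w + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, w / np.where(total > 0, total, 1.0), 0.0)
    return out


def combine_components(c: ScoreComponents, mode: str = "ratio") -> float:
    """Combine the four within/between components into one score."""
    if mode not in COMBINE_MODES:
        raise ValueError(f"mode must be one of {COMBINE_MODES}, got {mode!r}")
    if mode == "ratio":
        cm = c.ws_m / (c.ws_m + c.bs_m) if (c.ws_m + c.bs_m) > 0 else 0.0
        cd = c.ws_d / (c.ws_d + c.bs_d) if (c.ws_d + c.bs_d) > 0 else 0.0
        return (cm + cd) / 2.0
    return ((c.ws_m - c.bs_m) + (c.ws_d - c.bs_d)) / 2.0


def _component_matrices(
    net: MiRNADiseaseNetwork, SM: SimilarityMatrix, SD: SimilarityMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (ws_m, bs_m, ws_d, bs_d), each of shape (nd, nm).

    Self-exclusion is implemented by masking the similarity diagonals to
    -inf before the group maxima; empty groups come out as -inf and are
    mapped to 0 afterwards.
    """
    A = net.A.astype(bool)
    SMx = SM.values.copy()
    np.fill_diagonal(SMx, -np.inf)
    SDx = SD.values.copy()
    np.fill_diagonal(SDx, -np.inf)

    neg_inf = -np.inf
    ws_m = np.empty((net.nd, net.nm))
    bs_m = np.empty((net.nd, net.nm))
    for i in range(net.nd):
        assoc = A[i]  # miRNAs of disease i
        within = np.where(assoc[None, :], SMx, neg_inf).max(axis=1)
        between = np.where(assoc[None, :], neg_inf, SMx).max(axis=1)
        ws_m[i] = within
        bs_m[i] = between

    ws_d = np.empty((net.nd, net.nm))
    bs_d = np.empty((net.nd, net.nm))
    for j in range(net.nm):
        assoc = A[:, j]  # diseases of miRNA j
        within = np.where(assoc[None, :], SDx, neg_inf).max(axis=1)
        between = np.where(assoc[None, :], neg_inf, SDx).max(axis=1)
        ws_d[:, j] = within
        bs_d[:, j] = between

    for arr in (ws_m, bs_m, ws_d, bs_d):
        arr[~np.isfinite(arr)] = 0.0
    return ws_m, bs_m, ws_d, bs_d


def score_matrix(
    net: MiRNADiseaseNetwork,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    mode: str = "ratio",
) -> np.ndarray:
    """Score every (disease, miRNA) pair; returns an nd x nm matrix.

    Known pairs (A == 1) are scored too; ranking utilities exclude them
    from candidate lists.
    """
    if mode not in COMBINE_MODES:
        raise ValueError(f"mode must be one of {COMBINE_MODES}, got {mode!r}")
    _check_inputs(net, SM, SD)
    ws_m, bs_m, ws_d, bs_d = _component_matrices(net, SM, SD)
    if mode == "ratio":
        return (_contrast(ws_m, bs_m) + _contrast(ws_d, bs_d)) / 2.0
    return ((ws_m - bs_m) + (ws_d - bs_d)) / 2.0


def score_new_disease(
    net: MiRNADiseaseNetwork,
    SD: SimilarityMatrix,
    disease: str,
    mode: str = "ratio",
) -> np.ndarray:
    """Scores for all miRNAs against a disease with no known associations.

    The disease may be a zero row of the network or absent from it entirely
    (in which case it must appear in the SD registry).  Only the disease-view
    contrast is available.
    """
    if mode not in COMBINE_MODES:
        raise ValueError(f"mode must be one of {COMBINE_MODES}, got {mode!r}")
    missing = [d for d in net.disease_ids if d not in SD._index]
    if missing or disease not in SD._index:
        raise ValueError("disease similarity registry does not cover the network")
    self_idx: int | None = None
    if disease in net._disease_index:
        self_idx = net.disease_index(disease)
        if net.A[self_idx].any():
            raise ValueError(
                f"disease {disease!r} has known associations; use score_matrix"
            )
    row = SD.values[SD.index(disease)]
    sd_row = np.array([row[SD.index(d)] for d in net.disease_ids], dtype=float)
    if self_idx is not None:
        sd_row[self_idx] = -np.inf

    A = net.A.astype(bool)
    scores = np.empty(net.nm)
    for j in range(net.nm):
        assoc = A[:, j]
        ws = np.where(assoc, sd_row, -np.inf).max(initial=-np.inf)
        bs = np.where(assoc, -np.inf, sd_row).max(initial=-np.inf)
        ws = 0.0 if not np.isfinite(ws) else ws
        bs = 0.0 if not np.isfinite(bs) else bs
        if mode == "ratio":
            scores[j] = ws / (ws + bs) if (ws + bs) > 0 else 0.0
        else:
            scores[j] = ws - bs
    return scores


def score_new_mirna(
    net: MiRNADiseaseNetwork,
    SM: SimilarityMatrix,
    mirna: str,
    mode: str = "ratio",
) -> np.ndarray:
    """Scores for all diseases against a miRNA with no known associations.

    Mirror of :func:`score_new_disease` on the transposed network.
    """
    if mirna in net._mirna_index:
        j = net.mirna_index(mirna)
        if net.A[:, j].any():
            raise ValueError(
                f"miRNA {mirna!r} has known associations; use score_matrix"
            )
    return score_new_disease(net.transpose(), SM, mirna, mode=mode)
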