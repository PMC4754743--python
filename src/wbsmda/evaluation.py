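"""Cross-validation of the within/between scorer: LOOCV, repeated k-fold, ROC.

Each known association is held out (alone for LOOCV, in groups for k-fold),
the interaction-profile kernels are refreshed on the reduced network, and
the held-out miRNA is ranked against the disease's candidate miRNAs — all
miRNAs with no known evidence of association to that disease.  Because
candidate counts differ per disease, the pooled ROC is swept over
normalized-rank thresholds; its trapezoidal area equals the pairwise
statistic (fraction of test-vs-candidate comparisons won, ties half credit).

The kernel bandwidths are estimated once on the full network and held fixed
during refreshes, so removing a fold perturbs exactly the kernel rows and
columns of the entities it touches; the semantic and functional similarity
matrices do not depend on the association matrix and are computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dag import DiseaseDAG
from .integration import integrate_similarity
from .kernel import gaussian_profile_kernel, kernel_bandwidth
from .network import MiRNADiseaseNetwork
from .scoring import COMBINE_MODES, _contrast
from .semantic import semantic_similarity_matrix
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class EvalOptions:
    """All tunable parameters of the scoring pipeline, echoed into outputs."""

    delta: float = 0.5
    gamma_prime_d: float = 1.0
    gamma_prime_m: float = 1.0
    integration_mode: str = "fallback"
    combine_mode: str = "ratio"
    refresh_kernels: str = "fold"  # "fold" or "never"

    def __post_init__(self) -> None:
        if self.combine_mode not in COMBINE_MODES:
            raise ValueError(f"unknown combine mode {self.combine_mode!r}")
        if self.refresh_kernels not in ("fold", "never"):
            raise ValueError("refresh_kernels must be 'fold' or 'never'")


@dataclass(frozen=True)
class RankRecord:
    """Rank of one held-out association among its disease's candidates.

    ``n_above`` candidates scored strictly higher than the test miRNA and
    ``n_tied`` scored equal, out of ``candidate_count`` candidates; the
    conventional average rank is ``n_above + n_tied / 2 + 1``.
    """

    disease: str
    mirna: str
    n_above: int
    n_tied: int
    candidate_count: int

    @property
    def rank(self) -> float:
        return self.n_above + self.n_tied / 2.0 + 1.0


@dataclass
class EvaluationResult:
    """Per-test ranks, pooled ROC points, AUC, and per-repeat statistics."""

    records: list[RankRecord]
    roc: np.ndarray  # (FPR, TPR) points
    auc: float
    per_repeat_auc: list[float] = field(default_factory=list)
    auc_mean: float = float("nan")
    auc_sd: float = float("nan")
    settings: dict = field(default_factory=dict)


def roc_from_ranks(
    ranks: list,
) -> tuple[np.ndarray, float]:
    """Pooled ROC over normalized-rank thresholds and its pairwise AUC.

    Accepts :class:`RankRecord` objects or plain ``(rank, candidate_count)``
    tuples (integer rank, no ties).  A test at normalized position
    ``n_above / candidate_count`` is retrieved once the acceptance threshold
    passes it; ties spread the retrieval linearly over the tied block.  The
    trapezoidal area of this curve equals the mean pairwise win fraction
    exactly.
    """
    if not ranks:
        raise ValueError("no ranks to evaluate")
    recs: list[RankRecord] = []
    for r in ranks:
        if isinstance(r, RankRecord):
            recs.append(r)
        else:
            rank, cc = r
            if not (1 <= rank <= cc + 1):
                raise ValueError(f"rank {rank} out of range for {cc} candidates")
            recs.append(RankRecord("", "", int(rank) - 1, 0, int(cc)))

    n = len(recs)
    lo = np.array([r.n_above / r.candidate_count for r in recs])
    hi = np.array([(r.n_above + r.n_tied) / r.candidate_count for r in recs])
    is_step = hi == lo

    def tpr(theta: float, side: str) -> float:
        total = 0.0
        for k in range(n):
            if is_step[k]:
                if theta > lo[k] or (side == "right" and theta == lo[k]):
                    total += 1.0
            else:
                total += min(max((theta - lo[k]) / (hi[k] - lo[k]), 0.0), 1.0)
        return total / n

    grid = np.unique(np.concatenate(([0.0, 1.0], lo, hi)))
    points: list[tuple[float, float]] = []
    for theta in grid:
        left = tpr(float(theta), "left")
        right = tpr(float(theta), "right")
        points.append((float(theta), left))
        if right != left:
            points.append((float(theta), right))
    roc = np.array(points)
    auc = float(np.mean(1.0 - lo - (hi - lo) / 2.0))
    return roc, auc


def _score_disease_row(
    net: MiRNADiseaseNetwork,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    i: int,
    mode: str,
) -> np.ndarray:
    """Row ``i`` of the score matrix, vectorized over miRNAs."""
    A = net.A.astype(bool)
    SMx = SM.values.copy()
    np.fill_diagonal(SMx, -np.inf)
    assoc_m = A[i]
    ws_m = np.where(assoc_m[None, :], SMx, -np.inf).max(axis=1)
    bs_m = np.where(assoc_m[None, :], -np.inf, SMx).max(axis=1)

    sd_row = SD.values[i].copy()
    sd_row[i] = -np.inf
    # disease view per miRNA j: max of sd_row over diseases (not) linked to j
    masked_w = np.where(A, sd_row[:, None], -np.inf)
    masked_b = np.where(A, -np.inf, sd_row[:, None])
    ws_d = masked_w.max(axis=0)
    bs_d = masked_b.max(axis=0)

    comp = [np.where(np.isfinite(c), c, 0.0) for c in (ws_m, bs_m, ws_d, bs_d)]
    ws_m, bs_m, ws_d, bs_d = comp
    if mode == "ratio":
        return (_contrast(ws_m, bs_m) + _contrast(ws_d, bs_d)) / 2.0
    return ((ws_m - bs_m) + (ws_d - bs_d)) / 2.0


def _prepare_similarities(
    net: MiRNADiseaseNetwork,
    dag: DiseaseDAG | None,
    FS: SimilarityMatrix | None,
    options: EvalOptions,
) -> tuple[SimilarityMatrix, SimilarityMatrix, float, float]:
    """Fold-independent inputs: FS, SS and the fixed kernel bandwidths."""
    if FS is None:
        FS = SimilarityMatrix.identity(net.mirna_ids)
    if dag is not None:
        SS = semantic_similarity_matrix(dag, net.disease_ids, options.delta)
    else:
        SS = SimilarityMatrix.identity(net.disease_ids)
    gamma_d = kernel_bandwidth(net, "disease", options.gamma_prime_d).gamma
    gamma_m = kernel_bandwidth(net, "mirna", options.gamma_prime_m).gamma
    return FS, SS, gamma_d, gamma_m


def _integrated(
    net: MiRNADiseaseNetwork,
    FS: SimilarityMatrix,
    SS: SimilarityMatrix,
    gamma_d: float,
    gamma_m: float,
    options: EvalOptions,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    KD = gaussian_profile_kernel(net, "disease", gamma=gamma_d)
    KM = gaussian_profile_kernel(net, "mirna", gamma=gamma_m)
    SM = integrate_similarity(FS, KM, options.integration_mode)
    SD = integrate_similarity(SS, KD, options.integration_mode)
    return SM, SD


def _rank_test(
    scores: np.ndarray, full_row: np.ndarray, j: int
) -> tuple[int, int, int]:
    """(n_above, n_tied, candidate_count) of test miRNA j among candidates.

    Candidates are the miRNAs never known to associate with the disease in
    the full dataset (``full_row == 0``), excluding the test miRNA itself.
    """
    cand = (full_row == 0) & (np.arange(full_row.size) != j)
    cand_scores = scores[cand]
    test_score = scores[j]
    n_above = int((cand_scores > test_score).sum())
    n_tied = int((cand_scores == test_score).sum())
    return n_above, n_tied, int(cand.sum())


def _evaluate_folds(
    net: MiRNADiseaseNetwork,
    folds: list[list[tuple[int, int]]],
    FS: SimilarityMatrix,
    SS: SimilarityMatrix,
    gamma_d: float,
    gamma_m: float,
    options: EvalOptions,
) -> list[RankRecord]:
    full_A = net.A.copy()
    records: list[RankRecord] = []
    if options.refresh_kernels == "never":
        SM_full, SD_full = _integrated(net, FS, SS, gamma_d, gamma_m, options)
    for fold in folds:
        reduced = net.copy()
        for i, j in fold:
            reduced.A[i, j] = 0
        if options.refresh_kernels == "fold":
            SM, SD = _integrated(reduced, FS, SS, gamma_d, gamma_m, options)
        else:
            SM, SD = SM_full, SD_full
        by_disease: dict[int, list[int]] = {}
        for i, j in fold:
            by_disease.setdefault(i, []).append(j)
        for i, tests in by_disease.items():
            scores = _score_disease_row(reduced, SM, SD, i, options.combine_mode)
            for j in tests:
                n_above, n_tied, cc = _rank_test(scores, full_A[i], j)
                records.append(
                    RankRecord(
                        net.disease_ids[i], net.mirna_ids[j], n_above, n_tied, cc
                    )
                )
    return records


def loocv(
    net: MiRNADiseaseNetwork,
    dag: DiseaseDAG | None = None,
    FS: SimilarityMatrix | None = None,
    options: EvalOptions = EvalOptions(),
) -> EvaluationResult:
    """Leave-one-out cross-validation over all known associations.

    Each association is removed in turn, the kernels are refreshed on the
    reduced network, and the held-out miRNA is ranked among the disease's
    candidate miRNAs.  All test-vs-candidate comparisons pool into one
    ROC/AUC.
    """
    if net.n_associations == 0:
        raise ValueError("network has no associations to evaluate")
    FS, SS, gamma_d, gamma_m = _prepare_similarities(net, dag, FS, options)
    folds = [[edge] for edge in net.associations()]
    records = _evaluate_folds(net, folds, FS, SS, gamma_d, gamma_m, options)
    roc, auc = roc_from_ranks(records)
    return EvaluationResult(
        records=records, roc=roc, auc=auc, settings=asdict(options)
    )


def kfold_cv(
    net: MiRNADiseaseNetwork,
    dag: DiseaseDAG | None = None,
    FS: SimilarityMatrix | None = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    options: EvalOptions = EvalOptions(),
) -> EvaluationResult:
    """Repeated k-fold cross-validation over known associations.

    Per repeat, the associations are randomly split into ``k`` near-equal
    groups; each group is held out together, kernels refreshed once per
    fold, and one pooled AUC computed per repeat.  Reproducible from the
    single seed via per-repeat substreams.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    n_assoc = net.n_associations
    if n_assoc < k:
        raise ValueError(f"cannot split {n_assoc} associations into {k} folds")
    FS, SS, gamma_d, gamma_m = _prepare_similarities(net, dag, FS, options)
    edges = net.associations()
    per_repeat_auc: list[float] = []
    all_records: list[RankRecord] = []
    for rep in range(repeats):
        rng = np.random.default_rng([int(seed), rep])
        order = rng.permutation(len(edges))
        folds = [[edges[idx] for idx in order[g::k]] for g in range(k)]
        records = _evaluate_folds(net, folds, FS, SS, gamma_d, gamma_m, options)
        _, auc = roc_from_ranks(records)
        per_repeat_auc.append(auc)
        all_records.extend(records)
    roc, auc_pooled = roc_from_ranks(all_records)
    return EvaluationResult(
        records=all_records,
        roc=roc,
        auc=auc_pooled,
        per_repeat_auc=per_repeat_auc,
        auc_mean=float(np.mean(per_repeat_auc)),
        auc_sd=float(np.std(per_repeat_auc, ddof=1)) if repeats > 1 else 0.0,
        settings={**asdict(options), "k": k, "repeats": repeats, "seed": int(seed)},
    )


def partition_sizes(n: int, k: int) -> list[int]:
    """Sizes of the k near-equal groups a set of n items splits into."""
    base = n // k
    extra = n % k
    return [base + (1 if g < extra else 0) for g in range(k)]
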