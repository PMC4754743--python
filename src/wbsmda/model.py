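"""Model/Results interface over the full scoring pipeline.

:class:`WBSMDA` bundles the association network with the optional curated
similarity inputs (miRNA functional similarity, disease ontology) and the
pipeline parameters.  ``fit()`` builds the interaction-profile kernels,
integrates the similarity matrices and scores every candidate pair,
returning a :class:`WBSMDAResults` that carries the score matrix, the
integrated similarities, ranked predictions, and evaluation helpers.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .dag import DiseaseDAG, read_disease_dag
from .evaluation import EvalOptions, EvaluationResult, kfold_cv, loocv
from .integration import integrate_similarity
from .kernel import gaussian_profile_kernel, kernel_bandwidth
from .network import (
    MiRNADiseaseNetwork,
    rank_candidates,
    read_association_list,
    write_predictions,
)
from .scoring import score_matrix, score_new_disease, score_new_mirna
from .semantic import semantic_similarity_matrix
from .similarity import SimilarityMatrix, read_similarity_matrix


class WBSMDA:
    """Within/between-score association model over a bipartite network.

    Parameters
    ----------
    network : MiRNADiseaseNetwork
        Known binary associations.
    mirna_similarity : SimilarityMatrix, optional
        Curated (masked) miRNA functional similarity; missing entries fall
        back to the miRNA interaction-profile kernel.
    dag : DiseaseDAG, optional
        Disease ontology for semantic similarity; unanchored diseases fall
        back to the disease interaction-profile kernel.
    options : EvalOptions
        Pipeline parameters (semantic decay, kernel bandwidths, integration
        and combination modes).
    """

    def __init__(
        self,
        network: MiRNADiseaseNetwork,
        mirna_similarity: SimilarityMatrix | None = None,
        dag: DiseaseDAG | None = None,
        options: EvalOptions = EvalOptions(),
    ) -> None:
        self.network = network
        self.mirna_similarity = (
            mirna_similarity
            if mirna_similarity is not None
            else SimilarityMatrix.identity(network.mirna_ids)
        )
        if self.mirna_similarity.ids != network.mirna_ids:
            raise ValueError(
                "miRNA similarity registry does not match the network"
            )
        self.dag = dag
        self.options = options

    @classmethod
    def from_files(
        cls,
        associations: str,
        mirna_similarity: str | None = None,
        dag: str | None = None,
        options: EvalOptions = EvalOptions(),
    ) -> "WBSMDA":
        """Build the model from the three standard TSV files."""
        net = read_association_list(associations)
        fs = (
            read_similarity_matrix(mirna_similarity, net.mirna_ids)
            if mirna_similarity
            else None
        )
        ontology = read_disease_dag(dag) if dag else None
        return cls(net, fs, ontology, options)

    def fit(self) -> "WBSMDAResults":
        """Run the full pipeline and score every (disease, miRNA) pair."""
        net = self.network
        opts = self.options
        semantic = (
            semantic_similarity_matrix(self.dag, net.disease_ids, opts.delta)
            if self.dag is not None
            else SimilarityMatrix.identity(net.disease_ids)
        )
        gamma_d = kernel_bandwidth(net, "disease", opts.gamma_prime_d)
        gamma_m = kernel_bandwidth(net, "mirna", opts.gamma_prime_m)
        KD = gaussian_profile_kernel(net, "disease", gamma=gamma_d.gamma)
        KM = gaussian_profile_kernel(net, "mirna", gamma=gamma_m.gamma)
        SM = integrate_similarity(self.mirna_similarity, KM, opts.integration_mode)
        SD = integrate_similarity(semantic, KD, opts.integration_mode)
        scores = score_matrix(net, SM, SD, opts.combine_mode)
        return WBSMDAResults(
            model=self,
            scores=scores,
            SM=SM,
            SD=SD,
            KD=KD,
            KM=KM,
            semantic=semantic,
            bandwidths={"gamma_d": gamma_d.gamma, "gamma_m": gamma_m.gamma},
        )

    def loocv(self) -> EvaluationResult:
        """Leave-one-out cross-validation under this model's options."""
        return loocv(self.network, self.dag, self.mirna_similarity, self.options)

    def kfold_cv(
        self, k: int = 5, repeats: int = 100, seed: int = 0
    ) -> EvaluationResult:
        """Repeated k-fold cross-validation under this model's options."""
        return kfold_cv(
            self.network,
            self.dag,
            self.mirna_similarity,
            k=k,
            repeats=repeats,
            seed=seed,
            options=self.options,
        )


class WBSMDAResults:
    """Fitted scores and the similarity matrices behind them."""

    def __init__(
        self,
        model: WBSMDA,
        scores: np.ndarray,
        SM: SimilarityMatrix,
        SD: SimilarityMatrix,
        KD: SimilarityMatrix,
        KM: SimilarityMatrix,
        semantic: SimilarityMatrix,
        bandwidths: dict[str, float],
    ) -> None:
        self.model = model
        self.scores = scores
        self.SM = SM
        self.SD = SD
        self.KD = KD
        self.KM = KM
        self.semantic = semantic
        self.bandwidths = bandwidths

    @property
    def network(self) -> MiRNADiseaseNetwork:
        return self.model.network

    def predictions(self) -> pd.DataFrame:
        """Ranked candidate pairs (known associations excluded)."""
        rows = rank_candidates(self.network, self.scores)
        return pd.DataFrame(rows, columns=["disease", "miRNA", "score", "rank"])

    def top_candidates(self, disease: str, n: int = 50) -> pd.DataFrame:
        df = self.predictions()
        return df[df["disease"] == disease].nsmallest(n, "rank").reset_index(
            drop=True
        )

    def predict_new_disease(self, disease: str) -> pd.DataFrame:
        """Single-view scores for a disease with no known associations."""
        scores = score_new_disease(
            self.network, self.SD, disease, self.model.options.combine_mode
        )
        order = np.lexsort((self.network.mirna_ids, -scores))
        return pd.DataFrame(
            {
                "miRNA": [self.network.mirna_ids[j] for j in order],
                "score": scores[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )

    def predict_new_mirna(self, mirna: str) -> pd.DataFrame:
        """Single-view scores for a miRNA with no known associations."""
        scores = score_new_mirna(
            self.network, self.SM, mirna, self.model.options.combine_mode
        )
        order = np.lexsort((self.network.disease_ids, -scores))
        return pd.DataFrame(
            {
                "disease": [self.network.disease_ids[i] for i in order],
                "score": scores[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )

    def write_predictions(self, path: str) -> None:
        rows = rank_candidates(self.network, self.scores)
        write_predictions(rows, path, header_comments=[self._settings_line()])

    def _settings_line(self) -> str:
        opts = asdict(self.model.options)
        opts.update(self.bandwidths)
        return "settings: " + ", ".join(f"{k}={v}" for k, v in sorted(opts.items()))

    def summary(self) -> str:
        """Human-readable account of the fit."""
        net = self.network
        opts = self.model.options
        cand = (net.A == 0).sum()
        lines = [
            "Within/between miRNA-disease association scores",
            "=" * 48,
            f"diseases:            {net.nd}",
            f"miRNAs:              {net.nm}",
            f"known associations:  {net.n_associations}",
            f"candidate pairs:     {int(cand)}",
            f"semantic decay:      {opts.delta}",
            f"gamma'_d / gamma'_m: {opts.gamma_prime_d} / {opts.gamma_prime_m}",
            f"gamma_d / gamma_m:   {self.bandwidths['gamma_d']:.6g} / "
            f"{self.bandwidths['gamma_m']:.6g}",
            f"integration mode:    {opts.integration_mode}",
            f"combination mode:    {opts.combine_mode}",
            f"score range:         [{self.scores.min():.4f}, "
            f"{self.scores.max():.4f}]",
        ]
        return "\n".join(lines)
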