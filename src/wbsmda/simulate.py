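"""Synthetic miRNA-disease data with planted cluster structure.

The generator instantiates the guilt-by-association assumption the scorer
relies on: diseases and miRNAs carry latent cluster labels; associations are
dense within a cluster (``p_in``) and sparse across (``p_out``); functional
similarity is high within a miRNA cluster (mean ``s_in``) and low across
(``s_out``); and the disease ontology is one root with a subtree per
cluster, diseases anchored to leaves of their own cluster's subtree.  Signal
strength is set by the gaps ``p_in - p_out`` and ``s_in - s_out``; with both
gaps zero the dataset is an exchangeable null.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .dag import DiseaseDAG, write_disease_dag
from .network import MiRNADiseaseNetwork, write_association_list
from .similarity import SimilarityMatrix, write_similarity_matrix


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-cluster generator."""

    n_diseases: int = 30
    n_mirnas: int = 40
    n_clusters: int = 4
    p_in: float = 0.6
    p_out: float = 0.05
    s_in: float = 0.9
    s_out: float = 0.1
    sim_noise: float = 0.05
    fs_coverage: float = 0.8
    dag_depth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "s_in", "s_out", "fs_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_in < self.p_out:
            raise ValueError("no planted signal: p_in < p_out")
        if self.s_in < self.s_out:
            raise ValueError("no planted signal: s_in < s_out")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be non-negative")
        if min(self.n_diseases, self.n_mirnas, self.n_clusters) < 1:
            raise ValueError("sizes must be positive")
        if self.dag_depth < 1:
            raise ValueError("dag_depth must be at least 1")


@dataclass
class SyntheticData:
    network: MiRNADiseaseNetwork
    dag: DiseaseDAG
    fs: SimilarityMatrix
    disease_clusters: np.ndarray
    mirna_clusters: np.ndarray
    config: SyntheticConfig


def _cluster_dag(cfg: SyntheticConfig, disease_ids, d_clusters) -> DiseaseDAG:
    # one root; per cluster a chain of internal terms of length dag_depth-1
    # ending in per-disease leaf terms
    edges: set[tuple[str, str]] = set()
    terms: set[str] = {"root"}
    anchors: dict[str, str] = {}
    for c in range(cfg.n_clusters):
        parent = "root"
        for depth in range(1, cfg.dag_depth):
            node = f"c{c}_l{depth}"
            edges.add((node, parent))
            parent = node
        for d, disease in enumerate(disease_ids):
            if d_clusters[d] == c:
                leaf = f"t_{disease}"
                edges.add((leaf, parent))
                anchors[disease] = leaf
    return DiseaseDAG(terms=terms, edges=edges, anchors=anchors)


def generate(cfg: SyntheticConfig) -> SyntheticData:
    """Draw one synthetic dataset; byte-reproducible from ``cfg.seed``.

    Degenerate draws with an empty network or an all-zero disease row/miRNA
    column are repaired minimally by adding one within-cluster association,
    so every entity is connected and the kernel bandwidth is defined.
    """
    rng = np.random.default_rng(cfg.seed)
    disease_ids = [f"disease{d:03d}" for d in range(cfg.n_diseases)]
    mirna_ids = [f"mir{m:03d}" for m in range(cfg.n_mirnas)]
    d_clusters = rng.integers(0, cfg.n_clusters, size=cfg.n_diseases)
    m_clusters = rng.integers(0, cfg.n_clusters, size=cfg.n_mirnas)

    same = d_clusters[:, None] == m_clusters[None, :]
    prob = np.where(same, cfg.p_in, cfg.p_out)
    A = (rng.random((cfg.n_diseases, cfg.n_mirnas)) < prob).astype(np.int8)
    # guarantee every disease and miRNA has at least one association
    for i in range(cfg.n_diseases):
        if A[i].sum() == 0:
            pool = np.where(m_clusters == d_clusters[i])[0]
            if pool.size == 0:
                pool = np.arange(cfg.n_mirnas)
            A[i, rng.choice(pool)] = 1
    for j in range(cfg.n_mirnas):
        if A[:, j].sum() == 0:
            pool = np.where(d_clusters == m_clusters[j])[0]
            if pool.size == 0:
                pool = np.arange(cfg.n_diseases)
            A[rng.choice(pool), j] = 1
    net = MiRNADiseaseNetwork(disease_ids, mirna_ids, A)

    same_m = m_clusters[:, None] == m_clusters[None, :]
    means = np.where(same_m, cfg.s_in, cfg.s_out)
    noise = rng.normal(0.0, cfg.sim_noise, size=(cfg.n_mirnas, cfg.n_mirnas))
    fs_vals = np.clip(means + noise, 0.0, 1.0)
    fs_vals = (fs_vals + fs_vals.T) / 2.0
    np.fill_diagonal(fs_vals, 1.0)
    n_covered = int(round(cfg.fs_coverage * cfg.n_mirnas))
    covered = np.zeros(cfg.n_mirnas, dtype=bool)
    covered[rng.choice(cfg.n_mirnas, size=n_covered, replace=False)] = True
    mask = covered[:, None] & covered[None, :]
    np.fill_diagonal(mask, True)
    fs = SimilarityMatrix(mirna_ids, np.where(mask, fs_vals, 0.0), mask)

    dag = _cluster_dag(cfg, disease_ids, d_clusters)
    return SyntheticData(net, dag, fs, d_clusters, m_clusters, cfg)


def null_config(seed: int = 0) -> SyntheticConfig:
    """Exchangeable no-signal configuration on the default geometry."""
    return SyntheticConfig(
        p_in=0.15, p_out=0.15, s_in=0.5, s_out=0.5, sim_noise=0.05, seed=seed
    )


def strong_signal_config(seed: int = 0) -> SyntheticConfig:
    """Default strong planted-cluster signal configuration."""
    return SyntheticConfig(seed=seed)


def write_dataset(data: SyntheticData, out_dir: str | Path) -> dict[str, str]:
    """Write the three standard TSV files; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": str(out_dir / "associations.tsv"),
        "mirna_similarity": str(out_dir / "mirna_similarity.tsv"),
        "disease_dag": str(out_dir / "disease_dag.tsv"),
    }
    write_association_list(data.network, paths["associations"])
    write_similarity_matrix(data.fs, paths["mirna_similarity"])
    write_disease_dag(data.dag, paths["disease_dag"])
    return paths
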