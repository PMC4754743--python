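"""Bipartite miRNA-disease association network and its file formats.

The association data are a curated edge list of experimentally verified
(disease, miRNA) pairs.  Internally they live in a dense binary adjacency
matrix ``A`` of shape ``nd x nm`` whose rows are diseases and columns are
miRNAs; ``A[i, j] == 1`` iff disease ``i`` and miRNA ``j`` are known to be
associated.  Row ``i`` of ``A`` is the interaction profile of disease ``i``,
column ``j`` the interaction profile of miRNA ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


def _normalize_name(name: str) -> str:
    """Trim whitespace and case-fold an identifier.

    Curated resources frequently carry the same disease or miRNA under
    variants that differ only in case or surrounding whitespace; those must
    collapse to one registry entry.
    """
    return name.strip().casefold()


@dataclass
class MiRNADiseaseNetwork:
    """Binary disease x miRNA association matrix with identifier registries.

    Parameters
    ----------
    disease_ids : sequence of str
        Unique disease identifiers, one per row of ``A``.
    mirna_ids : sequence of str
        Unique miRNA identifiers, one per column of ``A``.
    A : ndarray of shape (nd, nm)
        Binary adjacency matrix.
    """

    disease_ids: list[str]
    mirna_ids: list[str]
    A: np.ndarray
    _disease_index: dict[str, int] = field(init=False, repr=False)
    _mirna_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.disease_ids = list(self.disease_ids)
        self.mirna_ids = list(self.mirna_ids)
        self.A = np.asarray(self.A, dtype=np.int8)
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        if self.A.shape != (len(self.disease_ids), len(self.mirna_ids)):
            raise ValueError(
                f"adjacency shape {self.A.shape} does not match registries "
                f"({len(self.disease_ids)} diseases, {len(self.mirna_ids)} miRNAs)"
            )
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self._disease_index = {d: i for i, d in enumerate(self.disease_ids)}
        self._mirna_index = {m: j for j, m in enumerate(self.mirna_ids)}

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    @property
    def nm(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def disease_index(self, disease: str) -> int:
        try:
            return self._disease_index[disease]
        except KeyError:
            raise KeyError(f"unknown disease identifier: {disease!r}") from None

    def mirna_index(self, mirna: str) -> int:
        try:
            return self._mirna_index[mirna]
        except KeyError:
            raise KeyError(f"unknown miRNA identifier: {mirna!r}") from None

    def associations(self) -> list[tuple[int, int]]:
        """All known (disease index, miRNA index) pairs in row-major order."""
        rows, cols = np.nonzero(self.A)
        return list(zip(rows.tolist(), cols.tolist()))

    def transpose(self) -> "MiRNADiseaseNetwork":
        """Swap the two axes: diseases become miRNAs and vice versa."""
        return MiRNADiseaseNetwork(
            disease_ids=self.mirna_ids,
            mirna_ids=self.disease_ids,
            A=self.A.T.copy(),
        )

    def copy(self) -> "MiRNADiseaseNetwork":
        return MiRNADiseaseNetwork(
            list(self.disease_ids), list(self.mirna_ids), self.A.copy()
        )


def read_association_list(path: str | Path) -> MiRNADiseaseNetwork:
    """Read a tab-separated (disease, miRNA) edge list into a network.

    Lines starting with ``#`` are comments.  Names are trimmed and
    case-folded; duplicate pairs collapse to a single association.  The
    registries are sorted lexicographically so the matrix layout is
    deterministic regardless of input line order.

    Raises
    ------
    ValueError
        If the file contains no associations, or a non-comment line has
        fewer than two tab-separated fields (the error names the line).
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected at least two "
                    f"tab-separated fields (disease, miRNA)"
                )
            pairs.add((_normalize_name(fields[0]), _normalize_name(fields[1])))
    if not pairs:
        raise ValueError(f"{path}: no associations")
    disease_ids = sorted({d for d, _ in pairs})
    mirna_ids = sorted({m for _, m in pairs})
    d_index = {d: i for i, d in enumerate(disease_ids)}
    m_index = {m: j for j, m in enumerate(mirna_ids)}
    A = np.zeros((len(disease_ids), len(mirna_ids)), dtype=np.int8)
    for d, m in pairs:
        A[d_index[d], m_index[m]] = 1
    return MiRNADiseaseNetwork(disease_ids, mirna_ids, A)


def write_association_list(net: MiRNADiseaseNetwork, path: str | Path) -> None:
    """Write the network back to the two-column edge-list format."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# disease\tmiRNA\n")
        for i, j in net.associations():
            fh.write(f"{net.disease_ids[i]}\t{net.mirna_ids[j]}\n")


def write_predictions(
    ranked: Iterable[tuple[str, str, float, int]], path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write ranked candidate pairs as a TSV file.

    One row per (disease, miRNA, score, rank), sorted per disease by
    descending score with ties broken by ascending miRNA identifier.
    ``header_comments`` lines (without leading ``#``) are echoed at the top,
    so every output records the configuration that produced it.
    """
    rows = list(ranked)
    for _, _, score, _ in rows:
        if not np.isfinite(score):
            raise ValueError("prediction scores must be finite")
    rows.sort(key=lambda r: (r[0], -r[2], r[1]))
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("disease\tmiRNA\tscore\trank\n")
        for disease, mirna, score, rank in rows:
            fh.write(f"{disease}\t{mirna}\t{score:.10g}\t{rank}\n")


def rank_candidates(
    net: MiRNADiseaseNetwork, scores: np.ndarray
) -> list[tuple[str, str, float, int]]:
    """Rank unknown pairs per disease by descending score.

    Known associations (``A == 1``) are excluded from the candidate list;
    ties share order by ascending miRNA identifier and get distinct ranks
    in that order.
    """
    out: list[tuple[str, str, float, int]] = []
    for i, disease in enumerate(net.disease_ids):
        cands = [
            (net.mirna_ids[j], float(scores[i, j]))
            for j in range(net.nm)
            if net.A[i, j] == 0
        ]
        cands.sort(key=lambda t: (-t[1], t[0]))
        for rank, (mirna, score) in enumerate(cands, start=1):
            out.append((disease, mirna, score, rank))
    return out
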