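"""Masked symmetric similarity matrices and their TSV formats.

A :class:`SimilarityMatrix` holds pairwise similarities in ``[0, 1]``
together with an availability mask.  The mask distinguishes "no score is
known for this pair" (e.g. a miRNA absent from the functional-similarity
download, or a disease with no ontology anchor) from "the similarity is
zero" — a distinction the integration step relies on to decide when to fall
back to the interaction-profile kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

SYMMETRY_TOL = 1e-8


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over an ordered identifier list."""

    ids: list[str]
    values: np.ndarray
    mask: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.ids)
        if self.values.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("values/mask must be square over the identifier list")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        if not np.allclose(
            self.values[self.mask], self.values.T[self.mask], atol=SYMMETRY_TOL
        ):
            raise ValueError("values must be symmetric where masked true")
        if not self.mask.diagonal().all():
            raise ValueError("diagonal must be defined (mask true)")
        if not np.allclose(self.values.diagonal(), 1.0):
            raise ValueError("diagonal must be 1")
        masked_vals = self.values[self.mask]
        if masked_vals.size and (
            masked_vals.min() < -1e-12 or masked_vals.max() > 1 + 1e-12
        ):
            raise ValueError("similarity values must lie in [0, 1]")
        self._index = {x: i for i, x in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, identifier: str) -> int:
        return self._index[identifier]

    def fully_defined(self) -> bool:
        return bool(self.mask.all())

    @classmethod
    def identity(cls, ids: Sequence[str]) -> "SimilarityMatrix":
        """All-masked matrix: only the unit diagonal is defined."""
        n = len(ids)
        return cls(list(ids), np.eye(n), np.eye(n, dtype=bool))

    @classmethod
    def from_values(
        cls, ids: Sequence[str], values: np.ndarray, mask: np.ndarray | None = None
    ) -> "SimilarityMatrix":
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.ones_like(values, dtype=bool)
        return cls(list(ids), values, np.asarray(mask, dtype=bool))


def _finalize(ids, values, counts) -> SimilarityMatrix:
    # average the two triangles where both were given; enforce tolerance
    n = len(ids)
    mask = counts > 0
    both = (counts == 1) & (counts.T == 1)
    diff = np.abs(np.where(both, values - values.T, 0.0))
    if diff.max(initial=0.0) > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(diff), diff.shape)
        raise ValueError(
            f"asymmetric similarity beyond tolerance for ({ids[i]}, {ids[j]}): "
            f"{values[i, j]!r} vs {values[j, i]!r}"
        )
    sym = np.where(both, (values + values.T) / 2.0, 0.0)
    sym = np.where(mask & ~both, values, sym)
    sym = np.where(mask.T & ~mask, values.T, sym)
    full_mask = mask | mask.T
    np.fill_diagonal(sym, 1.0)
    np.fill_diagonal(full_mask, True)
    if sym[full_mask].size and (sym[full_mask].min() < 0 or sym[full_mask].max() > 1):
        raise ValueError("similarity value outside [0, 1]")
    return SimilarityMatrix(list(ids), sym, full_mask)


def read_similarity_matrix(
    path: str | Path, ids: Sequence[str]
) -> SimilarityMatrix:
    """Read a similarity matrix aligned to a supplied identifier registry.

    Two TSV layouts are accepted and auto-detected: a labelled square matrix
    (header row of identifiers, label column) or a three-column edge list
    ``id <TAB> id <TAB> value``.  ``NA`` cells denote unavailable scores.
    Identifiers in the registry but absent from the file get ``mask=False``
    everywhere off the diagonal.  Identifiers in the file but not in the
    registry are ignored.  If both triangles are present they must agree to
    ``1e-8`` and are averaged.
    """
    path = Path(path)
    ids = [s.strip().casefold() for s in ids]
    index = {x: i for i, x in enumerate(ids)}
    n = len(ids)
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int8)

    lines: list[tuple[int, list[str]]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            lines.append((lineno, line.split("\t")))
    if not lines:
        raise ValueError(f"{path}: empty similarity file")

    def _is_edge_list() -> bool:
        first = lines[0][1]
        if len(first) != 3:
            return False
        try:
            float(first[2])
            return True
        except ValueError:
            return False

    def _record(a: str, b: str, v: float, lineno: int) -> None:
        if not (0.0 <= v <= 1.0):
            raise ValueError(
                f"{path}: line {lineno}: similarity {v} outside [0, 1]"
            )
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            return
        values[ia, ib] = v
        counts[ia, ib] = 1

    if _is_edge_list():
        for lineno, fields in lines:
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed line {lineno}")
            a = fields[0].strip().casefold()
            b = fields[1].strip().casefold()
            if fields[2].strip() == "NA":
                continue
            _record(a, b, float(fields[2]), lineno)
    else:
        _, header = lines[0]
        col_ids = [c.strip().casefold() for c in header[1:]]
        for lineno, fields in lines[1:]:
            if len(fields) != len(col_ids) + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(col_ids) + 1} fields"
                )
            row_id = fields[0].strip().casefold()
            for b, cell in zip(col_ids, fields[1:]):
                if cell.strip() == "NA":
                    continue
                _record(row_id, b, float(cell), lineno)

    return _finalize(ids, values, counts)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write as a labelled square matrix; masked-false entries print ``NA``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for i, row_id in enumerate(sim.ids):
            cells = [
                f"{sim.values[i, j]:.10g}" if sim.mask[i, j] else "NA"
                for j in range(sim.n)
            ]
            fh.write(row_id + "\t" + "\t".join(cells) + "\n")


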