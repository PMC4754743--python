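"""Integrated similarity: fill gaps in a curated matrix with the GIP kernel.

The functional (miRNA) and semantic (disease) similarity matrices cover only
entities present in their source resources; the interaction-profile kernel
covers everybody.  Integration produces one fully defined matrix per axis:

* ``fallback`` (default) — keep the curated similarity wherever it is
  defined, use the kernel only for missing entries;
* ``average`` — average curated and kernel similarity where both are
  defined, kernel alone otherwise.
"""

from __future__ import annotations

import numpy as np

from .similarity import SimilarityMatrix

INTEGRATION_MODES = ("fallback", "average")


def integrate_similarity(
    primary: SimilarityMatrix,
    kernel: SimilarityMatrix,
    mode: str = "fallback",
) -> SimilarityMatrix:
    """Combine a masked curated matrix with a fully defined kernel matrix.

    Both matrices must share the same identifier registry; the kernel must
    have no masked entries.  The result is fully defined, symmetric and has
    unit diagonal.
    """
    if mode not in INTEGRATION_MODES:
        raise ValueError(f"mode must be one of {INTEGRATION_MODES}, got {mode!r}")
    if primary.ids != kernel.ids:
        raise ValueError("identifier registries of the two matrices differ")
    if not kernel.fully_defined():
        raise ValueError("kernel matrix must be fully defined (no masked entries)")
    if mode == "fallback":
        values = np.where(primary.mask, primary.values, kernel.values)
    else:
        values = np.where(
            primary.mask, (primary.values + kernel.values) / 2.0, kernel.values
        )
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix.from_values(primary.ids, values)
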