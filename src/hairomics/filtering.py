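"""Protein-level inclusion rules.

Two rules are applied before any statistics: a minimum spectral-count
threshold, and removal of structural hair-shaft proteins (keratins and
keratin-associated proteins), which dominate raw hair digests but carry
little biological signal.

The source protocol is ambiguous about whether the count threshold is
"3 or higher" or "strictly greater than 3"; both readings are supported
(``exclusive=True`` for the strict one) with the inclusive rule as the
default.  The threshold is applied per subject — a protein is retained
if any single subject reaches it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import SpectralCountMatrix

__all__ = ["filter_proteins", "boolean_profile"]


def filter_proteins(
    matrix: SpectralCountMatrix,
    min_count: int = 3,
    exclusive: bool = False,
    exclude_structural: bool = True,
) -> SpectralCountMatrix:
    """Drop proteins below the count threshold and, optionally, structural ones.

    A protein survives iff its maximum per-subject count is ``>= min_count``
    (``> min_count`` when ``exclusive``) and, when ``exclude_structural``,
    it is not flagged structural.  Subjects and surviving counts are left
    untouched; the operation is idempotent.
    """
    maxima = matrix.counts.max(axis=1)
    keep = maxima > min_count if exclusive else maxima >= min_count
    if exclude_structural:
        keep &= ~matrix.structural
    if not keep.any():
        warnings.warn("no proteins survive filtering", stacklevel=2)
    kept = matrix.counts.loc[keep]
    return SpectralCountMatrix(kept, matrix.structural.loc[keep.index])


def boolean_profile(matrix: SpectralCountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Presence/absence (Boolean) profiles: 1 where count > 0.

    Accepts a count matrix or a plain DataFrame (so it is idempotent on
    its own output); returns an integer 0/1 DataFrame of the same shape.
    """
    counts = matrix.counts if isinstance(matrix, SpectralCountMatrix) else matrix
    return (counts > 0).astype(np.int8)
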