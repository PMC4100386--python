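"""Quantile normalization of probe-intensity matrices to a shared baseline."""

from __future__ import annotations

import numpy as np

from .types import IntensityMatrix


def quantile_normalize(matrices: list[IntensityMatrix] | IntensityMatrix) -> list[IntensityMatrix]:
    """Quantile-normalize one or more intensity matrices to one baseline.

    All individuals across all input matrices are pooled; the reference
    quantile vector is the across-individual mean of the per-individual
    sorted intensity vectors. Each individual's values are then replaced
    by the reference quantiles at their within-individual ranks, so
    every individual ends up with exactly the same marginal distribution
    while per-individual rank order is preserved. The operation is
    idempotent.

    Returns a list of normalized matrices in the input order (a single
    matrix input still yields a one-element list).
    """
    single = isinstance(matrices, IntensityMatrix)
    mats = [matrices] if single else list(matrices)
    if len(mats) == 0:
        raise ValueError("quantile_normalize requires at least one matrix")
    n_snps = mats[0].n_snps
    if any(m.n_snps != n_snps for m in mats):
        raise ValueError("all matrices must share the SNP dimension")

    pooled = np.vstack([m.signal for m in mats])
    order = np.argsort(pooled, axis=1, kind="stable")
    reference = np.take_along_axis(pooled, order, axis=1).mean(axis=0)

    out = np.empty_like(pooled)
    np.put_along_axis(out, order, np.broadcast_to(reference, pooled.shape), axis=1)

    result = []
    row = 0
    for m in mats:
        result.append(IntensityMatrix(signal=out[row : row + m.n_individuals]))
        row += m.n_individuals
    return result
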