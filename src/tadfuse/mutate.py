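"""Predict contact frequencies of the genome carrying a homozygous deletion.

A deletion of bins x..y leaves all parameters untouched: it only shortens the
genomic distance between loci flanking it and removes the insulation carried
by the deleted bins.  For i < x and j > y the predicted frequency is

    G_{i,j} = exp((alpha_i + alpha_j)/2) * d_new^beta
              / exp(sum_{i<k<=x-1} r_k + sum_{y<k<=j} r_k)

with d_new = (j - i) - (y - x + 1) >= 1 the post-deletion distance.  Pairs on
the same side of the deletion are assumed unchanged and keep their fitted
model value.  Because d_new < j - i and the surviving insulation is a subset
of the original, G_{i,j} >= H'_{i,j} always — deletions can only create
interactions under this model, never destroy them.
"""

from __future__ import annotations

import numpy as np

from tadfuse.genome_io import Deletion
from tadfuse.model import ModelParams


def predict_after_deletion(p: ModelParams, d: Deletion, i: int, j: int) -> float:
    """Predicted post-deletion contact frequency G_{i,j} for a cross pair.

    Requires i strictly upstream (i < x) and j strictly downstream (j > y)
    of the deleted bins; same-side pairs are by assumption unchanged — use
    :func:`tadfuse.model.model_frequency` for those.
    """
    if not d.is_mapped:
        raise ValueError("deletion must be mapped to bins first")
    x, y = d.x, d.y
    n = p.n_bins
    if not (1 <= i <= n and 1 <= j <= n):
        raise ValueError(f"bin pair ({i}, {j}) outside [1, {n}]")
    if i >= j:
        raise ValueError(f"need i < j, got ({i}, {j})")
    if x <= i <= y or x <= j <= y:
        raise ValueError(f"bin inside deleted range [{x}, {y}]")
    if not (i < x and j > y):
        raise ValueError(
            f"pair ({i}, {j}) does not cross the deletion [{x}, {y}]; "
            "same-side contacts are unchanged (use model_frequency)"
        )
    d_new = (j - i) - (y - x + 1)
    R = p.r_cumsum
    surviving = (R[x - 1] - R[i]) + (R[j] - R[y])
    log_g = (
        0.5 * (p.alpha[i - 1] + p.alpha[j - 1])
        + p.pair_beta(i, j) * np.log(d_new)
        - surviving
    )
    return float(np.exp(log_g))
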