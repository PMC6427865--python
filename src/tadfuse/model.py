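"""Parametric Hi-C contact model and its log-scale residual.

The expected contact frequency between bins i < j is

    H'_{i,j} = exp((alpha_i + alpha_j)/2) * (j - i)^beta / exp(sum_{i<k<=j} r_k)

with per-bin bias ``alpha`` (log scale, absorbs mappability/GC effects),
distance-decay exponent ``beta`` in [-2, -1], and non-negative per-bin
insulation ``r`` attenuating every contact that crosses the bin.  The fit
minimises |log H - log H'| over observed pairs, so residuals live on the log
(ratio) scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Optional, Union

import numpy as np
import pandas as pd

from tadfuse.genome_io import BinScheme, ContactMatrix

BETA_BOUNDS = (-2.0, -1.0)


@dataclass(frozen=True)
class SegmentRecord:
    """Provenance of one fitted segment: bins covered, its beta, and the
    disjoint core of bins whose parameters it owns."""

    start_bin: int
    end_bin: int
    beta: float
    core_start: int
    core_end: int


@dataclass
class ModelParams:
    """Fitted model parameters for one chromosome.

    ``alpha``, ``r`` and ``beta`` are length-n arrays indexed by bin-1; beta
    is stored per bin (constant within each fitted segment) with provenance in
    ``segment_table``.
    """

    scheme: BinScheme
    alpha: np.ndarray
    r: np.ndarray
    beta: np.ndarray
    segment_table: list[SegmentRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.scheme.n_bins
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.r = np.asarray(self.r, dtype=np.float64)
        beta = np.asarray(self.beta, dtype=np.float64)
        if beta.ndim == 0:
            beta = np.full(n, float(beta))
        self.beta = beta
        for name, arr in (("alpha", self.alpha), ("r", self.r), ("beta", self.beta)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha must be finite")
        if np.any(self.r < 0):
            raise ValueError("insulation r must be non-negative")
        if np.any(self.beta > 0):
            raise ValueError("beta must be <= 0")
        self._r_cum: Optional[np.ndarray] = None

    @property
    def n_bins(self) -> int:
        return self.scheme.n_bins

    @property
    def r_cumsum(self) -> np.ndarray:
        """R with R[k] = sum of r over bins 1..k; R[0] = 0 (length n+1)."""
        if self._r_cum is None:
            self._r_cum = np.concatenate([[0.0], np.cumsum(self.r)])
        return self._r_cum

    def insulation_between(self, i, j):
        """sum_{i < k <= j} r_k, vectorised over bin indices."""
        R = self.r_cumsum
        return R[np.asarray(j)] - R[np.asarray(i)]

    def pair_beta(self, i, j):
        """Distance-decay exponent applied to the pair (i, j).

        Beta is fitted per segment; pairs spanning a seam take the mean of
        the two bins' values, which is continuous across seams and reduces to
        the segment beta for within-segment pairs.
        """
        b = self.beta
        return 0.5 * (b[np.asarray(i) - 1] + b[np.asarray(j) - 1])


def _check_pair(p: ModelParams, i: int, j: int) -> None:
    n = p.n_bins
    if not (1 <= i <= n and 1 <= j <= n):
        raise ValueError(f"bin pair ({i}, {j}) outside [1, {n}]")
    if i >= j:
        raise ValueError(f"need i < j, got ({i}, {j})")


def model_frequency(p: ModelParams, i: int, j: int) -> float:
    """Model contact frequency H'_{i,j} for bins i < j."""
    _check_pair(p, i, j)
    log_h = (
        0.5 * (p.alpha[i - 1] + p.alpha[j - 1])
        + p.pair_beta(i, j) * np.log(j - i)
        - p.insulation_between(i, j)
    )
    return float(np.exp(log_h))


def log_residual(p: ModelParams, H: ContactMatrix, i: int, j: int) -> float:
    """log(H_{i,j} / H'_{i,j}); the fit objective sums its absolute value.

    Pairs with H_{i,j} = 0 have no finite log ratio and must be excluded
    upstream (they never enter the objective).
    """
    _check_pair(p, i, j)
    h = H.get(i, j)
    if h <= 0:
        raise ValueError(f"H[{i},{j}] = {h}: zero/negative pairs are excluded from the fit")
    return float(
        np.log(h)
        - 0.5 * (p.alpha[i - 1] + p.alpha[j - 1])
        - p.pair_beta(i, j) * np.log(j - i)
        + p.insulation_between(i, j)
    )


def normalized_frequency(p: ModelParams, value: float, i: int, j: int) -> float:
    """Divide out the per-bin bias: value / exp((alpha_i + alpha_j)/2).

    Normalised frequencies are what the interaction threshold delta is
    compared against, so scores are comparable across datasets.
    """
    if value <= 0:
        raise ValueError(f"value must be positive, got {value}")
    return float(value * np.exp(-0.5 * (p.alpha[i - 1] + p.alpha[j - 1])))


def write_params(p: ModelParams, table_path: str, sidecar_path: Optional[str] = None) -> None:
    """Serialise as a TSV (bin, alpha, r, beta, segment_id) + JSON sidecar."""
    n = p.n_bins
    seg_id = np.zeros(n, dtype=int)
    for si, seg in enumerate(p.segment_table):
        seg_id[seg.core_start - 1 : seg.core_end] = si
    df = pd.DataFrame(
        {
            "bin": np.arange(1, n + 1),
            "alpha": p.alpha,
            "r": p.r,
            "beta": p.beta,
            "segment_id": seg_id,
        }
    )
    df.to_csv(table_path, sep="\t", index=False, float_format="%.17g")
    if sidecar_path is None:
        sidecar_path = table_path + ".json"
    sidecar = {
        "chrom": p.scheme.chrom,
        "bin_size": p.scheme.bin_size,
        "n_bins": p.scheme.n_bins,
        "segments": [
            {
                "start_bin": s.start_bin,
                "end_bin": s.end_bin,
                "beta": s.beta,
                "core_start": s.core_start,
                "core_end": s.core_end,
            }
            for s in p.segment_table
        ],
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_params(table_path: str, sidecar_path: Optional[str] = None) -> ModelParams:
    if sidecar_path is None:
        sidecar_path = table_path + ".json"
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    scheme = BinScheme(
        chrom=sidecar["chrom"], bin_size=sidecar["bin_size"], n_bins=sidecar["n_bins"]
    )
    df = pd.read_csv(table_path, sep="\t", float_precision="round_trip")
    if len(df) != scheme.n_bins:
        raise ValueError(
            f"parameter table has {len(df)} rows, scheme declares {scheme.n_bins} bins"
        )
    segments = [SegmentRecord(**s) for s in sidecar["segments"]]
    return ModelParams(
        scheme=scheme,
        alpha=df["alpha"].to_numpy(),
        r=df["r"].to_numpy(),
        beta=df["beta"].to_numpy(),
        segment_table=segments,
    )
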