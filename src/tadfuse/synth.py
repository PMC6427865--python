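"""Synthetic Hi-C matrices drawn from the contact model itself.

The generator instantiates the fitted model generatively: choose per-bin
biases, a distance-decay exponent and a sparse set of insulator bins, emit
H_{i,j} = count_scale * H'_{i,j} * exp(eps), eps ~ Normal(0, sigma^2)
i.i.d. per pair.  Noise is multiplicative log-normal because the fit is L1
on the log scale; sigma = 0 reproduces the model exactly, so noiseless
fixtures must fit to objective zero.  Ground-truth parameters are always
returned beside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from tadfuse.genome_io import (
    BinScheme,
    ContactMatrix,
    Deletion,
    LoopAnchorSet,
    write_contact_matrix,
    write_deletions_bed,
)
from tadfuse.model import ModelParams, write_params


@dataclass
class SynthSpec:
    """Ground-truth parameter specification for one synthetic chromosome.

    ``alpha`` is a per-bin array, or a scalar sigma from which biases are
    drawn Normal(0, sigma); ``insulators`` lists (bin, strength r > 0);
    ``noise`` is the log-normal sd (0 = noiseless); ``count_scale`` maps
    model frequency to expected counts; ``max_distance`` limits generated
    pairs (None = every pair).
    """

    scheme: BinScheme
    alpha: Union[float, np.ndarray] = 0.0
    beta: float = -1.5
    insulators: Sequence[tuple[int, float]] = field(default_factory=list)
    noise: float = 0.0
    count_scale: float = 1.0
    seed: int = 0
    max_distance: Optional[int] = None

    def __post_init__(self) -> None:
        lo, hi = -2.0, -1.0
        if not lo <= self.beta <= hi:
            raise ValueError(f"beta {self.beta} outside [{lo}, {hi}]")
        if self.noise < 0:
            raise ValueError("noise sd must be >= 0")
        for b, s in self.insulators:
            if not 1 <= b <= self.scheme.n_bins:
                raise ValueError(f"insulator bin {b} outside scheme")
            if s <= 0:
                raise ValueError(f"insulator strength must be > 0, got {s}")

    def truth_params(self, rng: Optional[np.random.Generator] = None) -> ModelParams:
        n = self.scheme.n_bins
        if np.isscalar(self.alpha):
            sigma_a = float(self.alpha)
            if sigma_a == 0.0:
                alpha = np.zeros(n)
            else:
                if rng is None:
                    rng = np.random.default_rng(self.seed)
                alpha = rng.normal(0.0, sigma_a, size=n)
        else:
            alpha = np.asarray(self.alpha, dtype=np.float64)
        r = np.zeros(n)
        for b, s in self.insulators:
            r[b - 1] += s
        return ModelParams(scheme=self.scheme, alpha=alpha, r=r, beta=np.full(n, self.beta))


def generate_matrix(spec: SynthSpec) -> tuple[ContactMatrix, ModelParams]:
    """Draw one matrix; returns (matrix, ground-truth parameters)."""
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth_params(rng)
    n = spec.scheme.n_bins
    max_d = spec.max_distance if spec.max_distance is not None else n - 1
    R = truth.r_cumsum
    H = ContactMatrix(spec.scheme)
    for dist in range(1, max_d + 1):
        i = np.arange(1, n - dist + 1)
        j = i + dist
        log_h = (
            0.5 * (truth.alpha[i - 1] + truth.alpha[j - 1])
            + spec.beta * np.log(dist)
            - (R[j] - R[i])
            + np.log(spec.count_scale)
        )
        if spec.noise > 0:
            log_h = log_h + rng.normal(0.0, spec.noise, size=len(i))
        vals = np.exp(log_h)
        for a, b, v in zip(i, j, vals):
            H.set(int(a), int(b), float(v))
    return H, truth


@dataclass
class BenchmarkBundle:
    """End-to-end fixture: matrix + truth + deletion sets + calibration loops."""

    matrix: ContactMatrix
    truth: ModelParams
    covering: list[Deletion]   # each covers >= 1 insulator bin
    sparing: list[Deletion]    # matched length, avoids all insulator bins
    loops: LoopAnchorSet

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_contact_matrix(self.matrix, str(out / "matrix.tsv"))
        write_params(self.truth, str(out / "truth_params.tsv"))
        write_deletions_bed(self.covering, str(out / "deletions_covering.bed"))
        write_deletions_bed(self.sparing, str(out / "deletions_sparing.bed"))
        bs = self.matrix.scheme.bin_size
        chrom = self.matrix.scheme.chrom
        with open(out / "loops.bedpe", "w") as fh:
            for i, j in self.loops:
                fh.write(
                    f"{chrom}\t{(i - 1) * bs}\t{i * bs}\t{chrom}\t{(j - 1) * bs}\t{j * bs}\n"
                )


def generate_benchmark(
    spec: SynthSpec,
    n_covering: int = 5,
    n_sparing: int = 5,
    deletion_bins: int = 4,
    n_loops: int = 30,
    loop_distances: tuple[int, int] = (2, 10),
    margin_bins: int = 2,
) -> BenchmarkBundle:
    """Matrix plus matched deletion sets and calibration loops.

    Covering deletions are centred on insulator bins (cycling through them);
    sparing deletions have identical bin length but are placed, uniformly at
    random, so that their deleted range stays ``margin_bins`` away from every
    insulator.  Loops are the highest-frequency short-range pairs
    (anchor distance within ``loop_distances``), mimicking loop calls used to
    calibrate the interaction threshold.
    """
    if not spec.insulators and n_covering > 0:
        raise ValueError("cannot place covering deletions without insulators")
    matrix, truth = generate_matrix(spec)
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.scheme.n_bins
    bs = spec.scheme.bin_size
    chrom = spec.scheme.chrom
    ins_bins = sorted(b for b, _ in spec.insulators)

    def _mk(x: int) -> Deletion:
        y = x + deletion_bins - 1
        return Deletion(
            chrom=chrom, start_bp=(x - 1) * bs, end_bp=y * bs, x=x, y=y
        )

    covering: list[Deletion] = []
    for k in range(n_covering):
        b = ins_bins[k % len(ins_bins)]
        # jitter the placement within the deletion so repeats of the same
        # insulator are not identical intervals, while always covering bin b
        offset = (k // len(ins_bins)) % deletion_bins
        x = int(np.clip(b - offset, 1, n - deletion_bins + 1))
        covering.append(_mk(x))

    sparing: list[Deletion] = []
    tries = 0
    while len(sparing) < n_sparing:
        tries += 1
        if tries > 100000:
            raise RuntimeError("cannot place sparing deletions away from insulators")
        x = int(rng.integers(1, n - deletion_bins + 2))
        y = x + deletion_bins - 1
        if all(b < x - margin_bins or b > y + margin_bins for b in ins_bins):
            sparing.append(_mk(x))

    from tadfuse.model import model_frequency

    # take the top pairs per anchor distance so the loop set spans the whole
    # distance range, like real loop calls; within a distance the highest
    # model frequencies win (these avoid insulators automatically)
    lo_d, hi_d = loop_distances
    ranked: list[list[tuple[int, int]]] = []
    for dist in range(lo_d, hi_d + 1):
        cand = [
            (model_frequency(truth, i, i + dist), i, i + dist)
            for i in range(1, n - dist + 1)
        ]
        cand.sort(key=lambda t: (-t[0], t[1]))
        ranked.append([(i, j) for _, i, j in cand])
    pairs: list[tuple[int, int]] = []
    rank = 0
    while len(pairs) < n_loops and any(rank < len(r) for r in ranked):
        for r in ranked:  # interleave so every distance stays represented
            if rank < len(r) and len(pairs) < n_loops:
                pairs.append(r[rank])
        rank += 1
    loops = LoopAnchorSet(pairs=pairs)

    return BenchmarkBundle(
        matrix=matrix, truth=truth, covering=covering, sparing=sparing, loops=loops
    )
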