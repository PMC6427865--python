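"""I/O and coordinate arithmetic for bins, contact matrices, deletions and loops.

Conventions: bins are 1-based and inclusive internally (bin ``k`` covers the
0-based half-open bp interval ``[(k-1)*bin_size, k*bin_size)``); all BED/BEDPE
input is 0-based half-open and converted at this boundary.  Contact matrices
are exchanged as whitespace-delimited triplet text ``i j count``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Optional, Union

import numpy as np

TextSource = Union[str, IO[str]]


@dataclass(frozen=True)
class BinScheme:
    """Fixed-width binning of one chromosome.

    ``n_bins`` bins of ``bin_size`` bp each; bin ``k`` (1-based) covers
    ``[(k-1)*bin_size, k*bin_size)``.
    """

    chrom: str
    bin_size: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")

    @property
    def chrom_length(self) -> int:
        return self.bin_size * self.n_bins

    def bin_of_bp(self, pos: int) -> int:
        """1-based bin containing 0-based bp position ``pos`` (rounding down)."""
        if not 0 <= pos < self.chrom_length:
            raise ValueError(
                f"position {pos} outside chromosome {self.chrom} "
                f"[0, {self.chrom_length})"
            )
        return pos // self.bin_size + 1

    def bin_span_bp(self, k: int) -> tuple[int, int]:
        """0-based half-open bp interval covered by bin ``k``."""
        if not 1 <= k <= self.n_bins:
            raise ValueError(f"bin {k} outside [1, {self.n_bins}]")
        return (k - 1) * self.bin_size, k * self.bin_size


class ContactMatrix:
    """Symmetric non-negative Hi-C contact counts over a :class:`BinScheme`.

    Entries are stored once per unordered pair; ``get(i, j)`` is symmetric and
    returns 0.0 for absent pairs.
    """

    def __init__(self, scheme: BinScheme):
        self.scheme = scheme
        self._data: dict[tuple[int, int], float] = {}

    @property
    def n_bins(self) -> int:
        return self.scheme.n_bins

    def _key(self, i: int, j: int) -> tuple[int, int]:
        n = self.scheme.n_bins
        if not (1 <= i <= n and 1 <= j <= n):
            raise ValueError(f"bin pair ({i}, {j}) outside [1, {n}]")
        return (i, j) if i <= j else (j, i)

    def set(self, i: int, j: int, count: float, *, allow_overwrite: bool = True) -> None:
        if count < 0:
            raise ValueError(f"negative count {count} at ({i}, {j})")
        key = self._key(i, j)
        if not allow_overwrite and key in self._data:
            raise ValueError(f"duplicate entry for bin pair {key}")
        self._data[key] = float(count)

    def get(self, i: int, j: int) -> float:
        return self._data.get(self._key(i, j), 0.0)

    def items(self) -> Iterator[tuple[int, int, float]]:
        """Yield (i, j, count) with i <= j, sorted."""
        for (i, j) in sorted(self._data):
            yield i, j, self._data[(i, j)]

    def nonzero_pairs(
        self, lo: int, hi: int, max_distance: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (i, j, count) for stored pairs with lo <= i < j <= hi,
        1 <= j - i <= max_distance and count > 0."""
        ii, jj, cc = [], [], []
        for (i, j), c in self._data.items():
            if c > 0 and lo <= i and j <= hi and 1 <= j - i <= max_distance:
                ii.append(i)
                jj.append(j)
                cc.append(c)
        order = np.lexsort((jj, ii)) if ii else np.array([], dtype=int)
        return (
            np.asarray(ii, dtype=np.int64)[order],
            np.asarray(jj, dtype=np.int64)[order],
            np.asarray(cc, dtype=np.float64)[order],
        )

    def to_dense(self) -> np.ndarray:
        """Dense symmetric (n, n) array; row/col 0 corresponds to bin 1."""
        n = self.n_bins
        out = np.zeros((n, n))
        for (i, j), c in self._data.items():
            out[i - 1, j - 1] = c
            out[j - 1, i - 1] = c
        return out

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactMatrix):
            return NotImplemented
        return self.scheme == other.scheme and self._data == other._data


@dataclass(frozen=True)
class Deletion:
    """Genomic deletion interval, optionally mapped to fully-deleted bins.

    ``start_bp``/``end_bp`` are 0-based half-open; ``x``/``y`` (1-based,
    inclusive) are the first and last bins lying entirely inside the interval,
    set by :func:`map_deletion_to_bins`.
    """

    chrom: str
    start_bp: int
    end_bp: int
    x: Optional[int] = None
    y: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"empty interval [{self.start_bp}, {self.end_bp}) on {self.chrom}"
            )
        if (self.x is None) != (self.y is None):
            raise ValueError("x and y must be set together")
        if self.x is not None and self.x > self.y:
            raise ValueError(f"x={self.x} > y={self.y}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def is_mapped(self) -> bool:
        return self.x is not None

    @property
    def n_deleted_bins(self) -> int:
        if not self.is_mapped:
            raise ValueError("deletion not mapped to bins")
        return self.y - self.x + 1


@dataclass
class LoopAnchorSet:
    """Bin-index pairs (i, j), i < j, derived from chromatin-loop anchors."""

    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.pairs)


def _lines(source: TextSource) -> Iterator[str]:
    if isinstance(source, str):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def read_contact_matrix(
    source: TextSource, scheme: BinScheme, *, coords: str = "bin1"
) -> ContactMatrix:
    """Parse triplet text ``i j count`` into a symmetric matrix.

    ``coords`` selects the index dialect: ``bin1`` (1-based bins, default),
    ``bin0`` (0-based bins) or ``bp`` (bp coordinates, binned by rounding
    down).  Duplicate entries for the same unordered pair are an error.
    """
    if coords not in ("bin1", "bin0", "bp"):
        raise ValueError(f"unknown coords dialect {coords!r}")
    H = ContactMatrix(scheme)
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 'i j count', got {line!r}")
        try:
            a, b = int(parts[0]), int(parts[1])
            count = float(parts[2])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        if coords == "bin0":
            i, j = a + 1, b + 1
        elif coords == "bp":
            i, j = scheme.bin_of_bp(a), scheme.bin_of_bp(b)
        else:
            i, j = a, b
        try:
            H.set(i, j, count, allow_overwrite=False)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return H


def write_contact_matrix(H: ContactMatrix, dest: TextSource) -> None:
    """Write triplet text ``i j count`` (1-based, i <= j, sorted)."""

    def _emit(fh: IO[str]) -> None:
        for i, j, c in H.items():
            fh.write(f"{i}\t{j}\t{c!r}\n")

    if isinstance(dest, str):
        with open(dest, "w") as fh:
            _emit(fh)
    else:
        _emit(dest)


def map_deletion_to_bins(d: Deletion, scheme: BinScheme) -> Optional[Deletion]:
    """Attach the fully-deleted bin range [x, y]; None if no bin is covered.

    A bin counts as deleted only when it lies entirely inside
    ``[start_bp, end_bp)`` — coordinates are rounded down to whole bins.
    """
    if d.chrom != scheme.chrom:
        raise ValueError(f"deletion on {d.chrom}, scheme is {scheme.chrom}")
    if d.start_bp < 0 or d.end_bp > scheme.chrom_length:
        raise ValueError(
            f"deletion [{d.start_bp}, {d.end_bp}) outside chromosome extent "
            f"[0, {scheme.chrom_length})"
        )
    # first bin starting at or after start_bp; last bin ending at or before end_bp
    x = -(-d.start_bp // scheme.bin_size) + 1
    y = d.end_bp // scheme.bin_size
    if x > y:
        return None
    return replace(d, x=int(x), y=int(y))


def _overlaps(a: Deletion, b: Deletion) -> bool:
    return a.chrom == b.chrom and a.start_bp < b.end_bp and b.start_bp < a.end_bp


def filter_deletions(
    ds: Iterable[Deletion],
    scheme: BinScheme,
    exclusion: Optional[Iterable[Deletion]] = None,
) -> list[Deletion]:
    """Keep deletions that fully cover >= 1 bin and miss every exclusion interval.

    The covered-bin criterion implements the usual minimum-length rule at the
    matrix resolution: a deletion shorter than one bin can never satisfy it,
    while one of at least two bin-lengths always does.  Returned deletions are
    mapped (x, y set).
    """
    excl = list(exclusion) if exclusion is not None else []
    kept: list[Deletion] = []
    for d in ds:
        if any(_overlaps(d, e) for e in excl):
            continue
        mapped = map_deletion_to_bins(d, scheme)
        if mapped is not None:
            kept.append(mapped)
    return kept


def read_deletions_bed(source: TextSource, chrom: Optional[str] = None) -> list[Deletion]:
    """Read BED3 intervals; restrict to ``chrom`` if given."""
    out: list[Deletion] = []
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected BED3, got {line!r}")
        c, s, e = parts[0], int(parts[1]), int(parts[2])
        if chrom is not None and c != chrom:
            continue
        out.append(Deletion(chrom=c, start_bp=s, end_bp=e))
    return out


def write_deletions_bed(ds: Iterable[Deletion], dest: TextSource) -> None:
    def _emit(fh: IO[str]) -> None:
        for d in ds:
            fh.write(f"{d.chrom}\t{d.start_bp}\t{d.end_bp}\n")

    if isinstance(dest, str):
        with open(dest, "w") as fh:
            _emit(fh)
    else:
        _emit(dest)


def read_loop_anchors(source: TextSource, scheme: BinScheme) -> LoopAnchorSet:
    """Read BEDPE loops; map each anchor to the bin of its midpoint.

    Inter-chromosomal records and records on other chromosomes are skipped
    with a warning; loops whose two anchors land in the same bin are dropped.
    """
    pairs: list[tuple[int, int]] = []
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(f"line {lineno}: expected BEDPE (6+ cols), got {line!r}")
        c1, s1, e1, c2, s2, e2 = (
            parts[0], int(parts[1]), int(parts[2]),
            parts[3], int(parts[4]), int(parts[5]),
        )
        if c1 != c2:
            warnings.warn(f"line {lineno}: inter-chromosomal loop skipped")
            continue
        if c1 != scheme.chrom:
            warnings.warn(f"line {lineno}: loop on {c1} not on {scheme.chrom}, skipped")
            continue
        i = scheme.bin_of_bp((s1 + e1) // 2)
        j = scheme.bin_of_bp((s2 + e2) // 2)
        if i == j:
            continue
        pairs.append((min(i, j), max(i, j)))
    return LoopAnchorSet(pairs=pairs)
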