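"""Signal-track I/O and synthetic fixture generation.

Consensus peak calling operates on a chromosome partitioned into ``n``
consecutive fixed-width loci of ``L`` bp each.  Each of ``K`` samples
contributes one nonnegative enrichment value per locus, giving a K x n
signal matrix.  This module reads per-sample fixed-step signal tracks
(bedGraph or fixedStep wiggle), assembles the matrix on a shared locus
grid, and generates synthetic multi-sample signals with planted enriched
blocks for testing.

Coordinates are BED-style: 0-based, half-open.  Wiggle ``fixedStep``
declarations use the format's native 1-based starts and are converted on
read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LociGrid",
    "SignalMatrix",
    "read_fixed_step_track",
    "build_signal_matrix",
    "generate_synthetic_signals",
    "write_bedgraph",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class LociGrid:
    """A chromosome segment partitioned into ``n`` fixed-width loci.

    Locus ``i`` (1-indexed, ``1 <= i <= n``) spans the half-open interval
    ``[origin + (i-1)*L, origin + i*L)``; loci are disjoint, consecutive,
    and cover exactly ``n*L`` bp.
    """

    chrom: str
    origin: int = 0
    L: int = 50
    n: int = 1

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"locus width L must be positive, got {self.L}")
        if self.n <= 0:
            raise ValueError(f"locus count n must be positive, got {self.n}")
        if self.origin < 0:
            raise ValueError(f"origin must be >= 0, got {self.origin}")

    @classmethod
    def from_chrom_size(
        cls, chrom: str, size: int, L: int = 50, origin: int = 0
    ) -> "LociGrid":
        """Grid covering ``[origin, size)``; a trailing partial locus
        (< L bp) is truncated so all loci have identical width."""
        span = size - origin
        if span < L:
            raise ValueError(
                f"{chrom}: region [{origin}, {size}) shorter than one locus (L={L})"
            )
        n, rem = divmod(span, L)
        if rem:
            logger.info(
                "%s: truncating trailing %d bp (< L=%d) at the 3' end", chrom, rem, L
            )
        return cls(chrom=chrom, origin=origin, L=L, n=n)

    @property
    def end(self) -> int:
        return self.origin + self.n * self.L

    def locus_starts(self) -> np.ndarray:
        return self.origin + self.L * np.arange(self.n, dtype=np.int64)


@dataclass
class SignalMatrix:
    """K x n matrix of nonnegative per-sample signals on a locus grid.

    Row k holds sample ``sample_ids[k]``; column i is the cross-sample
    signal vector at locus i.
    """

    grid: LociGrid
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("signal values must be a 2-D array")
        K, n = self.values.shape
        if K < 1:
            raise ValueError("signal matrix needs at least one sample row")
        if len(self.sample_ids) != K:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {K} rows"
            )
        if n != self.grid.n:
            raise ValueError(
                f"matrix has {n} columns but grid declares {self.grid.n} loci"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")
        if np.any(self.values < 0):
            raise ValueError("signal values must be nonnegative")

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def _assign_interval(
    out: np.ndarray, grid: LociGrid, start: int, end: int, value: float
) -> None:
    """Write ``value`` into every locus the half-open interval touches.

    A record spanning multiple loci is replicated to each; on conflicting
    overlaps the last record in file order wins.
    """
    if end <= grid.origin or start >= grid.end:
        return
    lo = max(0, (start - grid.origin) // grid.L)
    hi = min(grid.n - 1, (end - 1 - grid.origin) // grid.L)
    if hi >= lo:
        out[lo : hi + 1] = value


def read_fixed_step_track(path, grid: LociGrid) -> np.ndarray:
    """Read one sample's signal track onto a locus grid.

    Accepts 4-column bedGraph (chrom start end value, whitespace-delimited)
    and fixedStep wiggle with ``step == span == grid.L``.  Loci with no
    record get 0.  If the requested chromosome never appears, an all-zero
    vector is returned with a logged warning.

    Raises
    ------
    ValueError
        On a malformed line (message names the line number), a negative
        signal value, or a fixedStep step/span mismatching the grid.
    """
    out = np.zeros(grid.n, dtype=np.float64)
    seen_chrom = False
    # state for an active fixedStep block (None when in bedGraph mode)
    fs_chrom: str | None = None
    fs_pos = 0
    fs_step = fs_span = 0
    in_fixed_block = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = {}
                for tok in line.split()[1:]:
                    if "=" not in tok:
                        raise ValueError(
                            f"{path}:{lineno}: malformed fixedStep token {tok!r}"
                        )
                    k, v = tok.split("=", 1)
                    kv[k] = v
                try:
                    fs_chrom = kv["chrom"]
                    fs_pos = int(kv["start"]) - 1  # wiggle starts are 1-based
                    fs_step = int(kv.get("step", 1))
                    fs_span = int(kv.get("span", fs_step))
                except (KeyError, ValueError) as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed fixedStep declaration"
                    ) from exc
                if fs_chrom == grid.chrom and (
                    fs_step != grid.L or fs_span != grid.L
                ):
                    raise ValueError(
                        f"{path}:{lineno}: fixedStep step/span "
                        f"({fs_step}/{fs_span}) != grid L ({grid.L})"
                    )
                in_fixed_block = True
                continue
            fields = line.split()
            if in_fixed_block and len(fields) == 1:
                try:
                    value = float(fields[0])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed wiggle value {fields[0]!r}"
                    ) from exc
                if value < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative signal value {value}"
                    )
                if fs_chrom == grid.chrom:
                    seen_chrom = True
                    _assign_interval(out, grid, fs_pos, fs_pos + fs_span, value)
                fs_pos += fs_step
                continue
            in_fixed_block = False
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, got "
                    f"{len(fields)}"
                )
            chrom, s, e, v = fields
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed bedGraph record"
                ) from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative signal value {value}")
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval [{start},{end})"
                )
            if chrom != grid.chrom:
                continue
            seen_chrom = True
            _assign_interval(out, grid, start, end, value)

    if not seen_chrom:
        logger.warning(
            "%s: no records for chromosome %s; using all-zero signal",
            path,
            grid.chrom,
        )
    return out


def build_signal_matrix(
    paths, grid: LociGrid, sample_ids: list[str] | None = None
) -> SignalMatrix:
    """Stack K per-sample tracks into a SignalMatrix; rows keep input order."""
    paths = list(paths)
    if not paths:
        raise ValueError("at least one sample track is required")
    if sample_ids is None:
        sample_ids = [str(p) for p in paths]
    rows = [read_fixed_step_track(p, grid) for p in paths]
    return SignalMatrix(grid=grid, sample_ids=list(sample_ids), values=np.vstack(rows))


def generate_synthetic_signals(
    n: int,
    K: int,
    blocks,
    dispersion: float = 0.1,
    noise: float = 0.5,
    seed: int = 0,
    chrom: str = "chrSim",
    L: int = 50,
    origin: int = 0,
) -> SignalMatrix:
    """Synthetic multi-sample enrichment signal with planted blocks.

    ``blocks`` is a list of ``(start_locus, end_locus, amplitude)`` with
    1-indexed inclusive locus bounds.  Background loci draw
    ``|N(0, noise)|``; block loci draw ``amplitude + N(0,
    dispersion*amplitude)`` per sample, clipped at 0.  Defaults model a
    modestly dispersed cohort over a noisy open-chromatin background.
    Reproducible under ``seed``.
    """
    if K < 1 or n < 1:
        raise ValueError("n and K must be positive")
    if dispersion < 0 or noise < 0:
        raise ValueError("dispersion and noise must be nonnegative")
    spans = sorted((int(s), int(e), float(a)) for s, e, a in blocks)
    prev_end = 0
    for s, e, a in spans:
        if not (1 <= s <= e <= n):
            raise ValueError(f"block ({s},{e}) outside [1, {n}]")
        if a <= 0:
            raise ValueError(f"block amplitude must be > 0, got {a}")
        if s <= prev_end:
            raise ValueError("overlapping planted blocks")
        prev_end = e
    rng = np.random.default_rng(seed)
    values = np.abs(rng.normal(0.0, noise, size=(K, n))) if noise > 0 else np.zeros((K, n))
    for s, e, a in spans:
        width = e - s + 1
        block = a + rng.normal(0.0, dispersion * a, size=(K, width))
        values[:, s - 1 : e] = np.clip(block, 0.0, None)
    grid = LociGrid(chrom=chrom, origin=origin, L=L, n=n)
    ids = [f"synthetic_{k}" for k in range(K)]
    return SignalMatrix(grid=grid, sample_ids=ids, values=values)


def write_bedgraph(values: np.ndarray, grid: LociGrid, path) -> None:
    """Write one signal row as 4-column bedGraph at step L (one record per
    nonzero locus; zero loci are omitted, matching sparse track practice)."""
    starts = grid.locus_starts()
    with open(path, "w") as fh:
        for s, v in zip(starts, np.asarray(values, dtype=float)):
            if v != 0.0:
                fh.write(f"{grid.chrom}\t{s}\t{s + grid.L}\t{v:.10g}\n")


def write_matrix(matrix: SignalMatrix, path) -> None:
    """Debug dump: TSV with a header row of locus start coordinates and one
    row per sample (first column = sample id)."""
    starts = matrix.grid.locus_starts()
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(str(s) for s in starts) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix(path, chrom: str = "matrix", L: int = 50) -> SignalMatrix:
    """Read a matrix dump produced by :func:`write_matrix` (or any TSV of the
    same shape) back into a SignalMatrix."""
    with open(path) as fh:
        header = fh.readline().split()
        starts = [int(s) for s in header[1:]]
        ids, rows = [], []
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    if not rows:
        raise ValueError(f"{path}: no sample rows")
    if len(starts) >= 2:
        L = starts[1] - starts[0]
    origin = starts[0] if starts else 0
    grid = LociGrid(chrom=chrom, origin=origin, L=L, n=len(starts))
    return SignalMatrix(grid=grid, sample_ids=ids, values=np.asarray(rows))
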