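"""Convert binary locus decisions into merged consensus peaks (BED6).

Maximal runs of selected loci become single half-open intervals
[origin + (i_first-1)*L, origin + i_last*L); BED column 5 carries the run's
mean locus score rescaled to the 0-1000 BED convention.  The assay is
unstranded, so column 6 is ".".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import LociGrid

__all__ = [
    "PeakSet",
    "decisions_to_peaks",
    "peak_score",
    "write_bed",
    "read_bed",
]


@dataclass
class PeakSet:
    """Sorted, non-overlapping half-open intervals:
    (chrom, start, end, name, score) with 0 <= score <= 1000."""

    records: list[tuple[str, int, int, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_chrom: str | None = None
        prev_end = 0
        for chrom, start, end, _name, score in self.records:
            if start < 0 or end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            if not 0 <= score <= 1000:
                raise ValueError(f"BED score {score} outside [0, 1000]")
            if prev_chrom is not None:
                if chrom < prev_chrom:
                    raise ValueError("peak records not sorted by chromosome")
                if chrom == prev_chrom and start < prev_end:
                    raise ValueError(
                        f"overlapping/unsorted peaks at {chrom}:{start}"
                    )
            prev_chrom, prev_end = chrom, end

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.records == other.records

    def total_bp(self) -> int:
        return sum(end - start for _, start, end, _, _ in self.records)

    @staticmethod
    def concat(parts: list["PeakSet"]) -> "PeakSet":
        recs = sorted(
            (r for p in parts for r in p.records), key=lambda r: (r[0], r[1])
        )
        return PeakSet(records=recs)


def peak_score(
    run_slice: slice, S, norm: float | None = None
) -> int:
    """BED column-5 score for one run of loci: mean S over the run, scaled
    so the maximum score in the vector maps to 1000, clamped to [0, 1000].
    """
    s = np.asarray(getattr(S, "S", S), dtype=np.float64)
    mean = float(np.mean(s[run_slice]))
    if norm is None:
        norm = float(np.max(s)) if s.size else 0.0
    if norm <= 0:
        return 0
    return int(max(0, min(1000, round(1000.0 * mean / norm))))


def decisions_to_peaks(ell: np.ndarray, grid: LociGrid, S=None) -> PeakSet:
    """Merge maximal runs of consecutive selected loci into peaks.

    ``S`` (optional score vector) populates the BED score column; without
    it every peak scores 0.
    """
    ell = np.asarray(ell)
    if ell.shape[0] != grid.n:
        raise ValueError(
            f"decision vector length {ell.shape[0]} != grid.n {grid.n}"
        )
    sel = (ell > 0.5).astype(np.int8)
    # run boundaries: transitions in the 0-padded vector
    padded = np.concatenate([[0], sel, [0]])
    d = np.diff(padded)
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive
    norm = None
    if S is not None:
        s = np.asarray(getattr(S, "S", S), dtype=np.float64)
        norm = float(np.max(s)) if s.size else 0.0
    records = []
    for lo, hi in zip(run_starts, run_ends):
        start = grid.origin + int(lo) * grid.L
        end = grid.origin + int(hi) * grid.L
        sc = peak_score(slice(lo, hi), S, norm=norm) if S is not None else 0
        records.append(
            (grid.chrom, start, end, f"{grid.chrom}_{start}_{end}", sc)
        )
    return PeakSet(records=records)


def write_bed(peaks: PeakSet, path) -> None:
    """Write BED6 (tab-separated, LF, no header); byte-identical for
    identical input."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score in peaks.records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t.\n")


def read_bed(path) -> PeakSet:
    """Parse a BED file written by :func:`write_bed` back into a PeakSet."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}_{start}_{end}"
            score = int(fields[4]) if len(fields) > 4 else 0
            records.append((chrom, start, end, name, score))
    return PeakSet(records=records)
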