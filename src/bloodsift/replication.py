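"""Coverage breadth, peak-to-trough replication ratio and GC-skew Ori/Ter.

In a replicating bacterial population, bidirectional replication from a
single origin means sequencing depth decays roughly log-linearly from
the origin (Ori) to the terminus (Ter) around the circular chromosome;
the ratio of coverage at the peak to coverage at the trough (PTR) then
exceeds 1 and scales with growth rate.  The same Ori/Ter geometry leaves
a compositional footprint: the leading strand is G-enriched, so the
cumulative GC skew ((G-C)/(G+C) summed over windows) attains its minimum
at Ori and maximum at Ter — in anti-phase with the coverage sinusoid,
providing an alignment-free cross-check of the coverage-derived
positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import DataError

BIN_SIZE = 10_000
MEDIAN_WINDOW_BINS = 11
SKEW_WINDOW = 10_000
MIN_ASSIGNED_READS = 1000
PTR_THRESHOLD = 1.1
SKEW_DEGENERACY_FACTOR = 4.0


@dataclass
class CoverageTrack:
    """Sequencing depth along a (by default circular) genome.

    ``bin_size is None`` means per-position depth; otherwise ``depth``
    holds per-bin values for consecutive *bin_size*-bp bins.
    """

    genome_id: str
    length: int
    depth: np.ndarray
    circular: bool = True
    bin_size: int | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.length <= 0:
            raise DataError(f"{self.genome_id}: genome length must be positive")
        if (self.depth < 0).any():
            raise DataError(f"{self.genome_id}: negative depth values")
        expected = self.length if self.bin_size is None else self.length // self.bin_size
        if len(self.depth) != expected:
            raise DataError(
                f"{self.genome_id}: depth array length {len(self.depth)} does not "
                f"match genome length {self.length} (bin_size={self.bin_size})"
            )


@dataclass
class PTRResult:
    """Peak-to-trough ratio estimate with Ori/Ter localisation."""

    genome_id: str
    ptr: float
    ori_position: float            # bp, bin midpoint of the coverage peak
    ter_position: float            # bp, bin midpoint of the coverage trough
    peak_coverage: float
    trough_coverage: float
    fit_r2: float                  # piecewise-linear log2 model quality
    degenerate: bool = False       # flat coverage: Ori/Ter arbitrary
    coverage_breadth: float | None = None
    assigned_reads: int | None = None
    eligible: bool = False
    replicating: bool = False
    evidence: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "ptr": self.ptr,
            "ori_position": self.ori_position,
            "ter_position": self.ter_position,
            "peak_coverage": self.peak_coverage,
            "trough_coverage": self.trough_coverage,
            "fit_r2": self.fit_r2,
            "degenerate": self.degenerate,
            "coverage_breadth": self.coverage_breadth,
            "assigned_reads": self.assigned_reads,
            "eligible": self.eligible,
            "replicating": self.replicating,
        }


@dataclass
class SkewResult:
    """Ori/Ter from the detrended cumulative GC-skew curve."""

    genome_id: str
    ori_position: float
    ter_position: float
    cumulative_skew: np.ndarray    # detrended, one value per window
    window: int
    degenerate: bool               # skew range within the random-walk floor


def coverage_breadth(track: CoverageTrack) -> float:
    """Fraction of genome positions covered by at least one read."""
    if track.bin_size is not None:
        raise DataError("coverage_breadth requires per-position depth")
    if track.length == 0:
        raise DataError("zero-length genome")
    return float(np.mean(track.depth >= 1))


def bin_and_smooth(
    track: CoverageTrack,
    bin_size: int = BIN_SIZE,
    median_window_bins: int = MEDIAN_WINDOW_BINS,
) -> CoverageTrack:
    """Mean depth per bin, then a circular running median over bins.

    The median window wraps around the origin (the genome is circular).
    A trailing partial bin is dropped.  Tracks that are already binned at
    *bin_size* skip straight to the smoothing step.
    """
    if track.length < 2 * bin_size * median_window_bins:
        raise DataError(
            f"{track.genome_id}: genome too short for bin_size={bin_size} and a "
            f"{median_window_bins}-bin median window; use smaller bins"
        )
    if track.bin_size is None:
        n_bins = track.length // bin_size
        binned = track.depth[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    elif track.bin_size == bin_size:
        binned = track.depth.copy()
    else:
        raise DataError(
            f"{track.genome_id}: track already binned at {track.bin_size} bp, "
            f"cannot re-bin to {bin_size} bp"
        )
    mode = "wrap" if track.circular else "nearest"
    smoothed = median_filter(binned, size=median_window_bins, mode=mode)
    return CoverageTrack(
        genome_id=track.genome_id,
        length=track.length,
        depth=smoothed,
        circular=track.circular,
        bin_size=bin_size,
        smoothed=True,
    )


def _piecewise_log2_r2(bins: np.ndarray, ori_idx: int, ter_idx: int) -> float:
    """R^2 of the two-arc linear log2-coverage model between Ori and Ter."""
    n = len(bins)
    log2b = np.log2(bins)
    peak, trough = log2b[ori_idx], log2b[ter_idx]
    arc = (ter_idx - ori_idx) % n
    pred = np.empty(n)
    for k in range(n):
        fwd = (k - ori_idx) % n
        if fwd <= arc:
            frac = fwd / arc if arc else 0.0
        else:
            back = n - fwd
            frac = back / (n - arc) if n != arc else 0.0
        pred[k] = peak + (trough - peak) * frac
    ss_res = float(np.sum((log2b - pred) ** 2))
    ss_tot = float(np.sum((log2b - log2b.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def estimate_ptr(track: CoverageTrack) -> PTRResult:
    """PTR and Ori/Ter from a binned, median-smoothed coverage track.

    The peak (Ori) is the global maximum of the smoothed bins and the
    trough (Ter) the global minimum, each reported at its bin midpoint;
    ``ptr = peak / trough``.  Entirely flat coverage yields ptr = 1 with
    the degeneracy flag set (first-occurrence argmax/argmin).  A
    piecewise-linear log2-coverage fit quality (R^2) is recorded so
    callers can reject tracks that merely have a noisy extreme bin.
    """
    if track.bin_size is None:
        raise DataError("estimate_ptr expects a binned track (run bin_and_smooth)")
    bins = track.depth
    trough_val = float(bins.min())
    if trough_val <= 0.0:
        raise DataError(
            f"{track.genome_id}: zero smoothed coverage in the trough; "
            "insufficient coverage for PTR estimation"
        )
    ori_idx = int(np.argmax(bins))
    ter_idx = int(np.argmin(bins))
    peak_val = float(bins[ori_idx])
    degenerate = peak_val == trough_val
    ptr = peak_val / trough_val
    r2 = 0.0 if degenerate else _piecewise_log2_r2(bins, ori_idx, ter_idx)
    return PTRResult(
        genome_id=track.genome_id,
        ptr=ptr,
        ori_position=(ori_idx + 0.5) * track.bin_size,
        ter_position=(ter_idx + 0.5) * track.bin_size,
        peak_coverage=peak_val,
        trough_coverage=trough_val,
        fit_r2=r2,
        degenerate=degenerate,
        evidence={"n_bins": int(len(bins)), "bin_size": int(track.bin_size)},
    )


def gc_skew_windows(sequence: str, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window GC skew ``(G - C)/(G + C)`` and per-window G+C counts.

    Windows with no G or C get skew 0; a trailing partial window is
    dropped; non-ACGT characters are ignored in the counts.
    """
    seq = str(sequence).upper()
    if len(seq) < window:
        raise DataError("sequence shorter than one window")
    n_win = len(seq) // window
    arr = np.frombuffer(seq.encode("ascii", "replace"), dtype="S1")
    arr = arr[: n_win * window].reshape(n_win, window)
    g = (arr == b"G").sum(axis=1).astype(float)
    c = (arr == b"C").sum(axis=1).astype(float)
    gc = g + c
    skew = np.where(gc > 0, (g - c) / np.where(gc > 0, gc, 1.0), 0.0)
    return skew, gc


def gc_skew_ori_ter(
    sequence: str,
    window: int = SKEW_WINDOW,
    genome_id: str = "",
    degeneracy_factor: float = SKEW_DEGENERACY_FACTOR,
) -> SkewResult:
    """Locate Ori/Ter from the cumulative GC skew of a circular genome.

    Per-window skew is ``(G - C) / (G + C)`` (0 where a window has no G
    or C); the cumulative sum is detrended by the straight line implied
    by circularity (so the series closes on itself), and Ori is placed at
    the cumulative minimum, Ter at the maximum.  When the detrended range
    is within *degeneracy_factor* standard deviations of a pure
    random-walk excursion the positions are still reported but flagged
    unreliable.  Non-ACGT characters are ignored in the counts; a
    trailing partial window is dropped.
    """
    seq = str(sequence).upper()
    if len(seq) < window:
        raise DataError(f"{genome_id or 'sequence'}: shorter than one window")
    n_win = len(seq) // window
    if n_win < 10:
        raise DataError(
            f"{genome_id or 'sequence'}: need at least 10 windows "
            f"({n_win} at window={window})"
        )
    skew, gc = gc_skew_windows(seq, window)
    cum = np.cumsum(skew)
    # circular detrend: subtract the line through (0, 0) and (n, cum[-1])
    detrended = cum - cum[-1] * (np.arange(1, n_win + 1) / n_win)
    ori_idx = int(np.argmin(detrended))
    ter_idx = int(np.argmax(detrended))
    # the extremum marks the window boundary where the skew changes sign
    ori = float(((ori_idx + 1) * window) % len(seq))
    ter = float(((ter_idx + 1) * window) % len(seq))
    # random-walk noise floor from the binomial sampling variance of the
    # per-window skew
    sigma0 = float(np.sqrt(np.mean(1.0 / np.maximum(gc, 1.0))))
    floor = degeneracy_factor * sigma0 * np.sqrt(n_win)
    degenerate = float(np.ptp(detrended)) < floor
    return SkewResult(
        genome_id=genome_id,
        ori_position=ori,
        ter_position=ter,
        cumulative_skew=detrended,
        window=window,
        degenerate=degenerate,
    )


def call_replicating(
    ptr_result: PTRResult,
    assigned_reads: int,
    min_assigned_reads: int = MIN_ASSIGNED_READS,
    ptr_threshold: float = PTR_THRESHOLD,
) -> PTRResult:
    """Flag a PTR result as eligible and (if so) replicating.

    A sample/species pair is eligible when the species received at least
    *min_assigned_reads* read pairs in that sample and the coverage was
    not degenerate; it is called replicating when additionally
    ``ptr > ptr_threshold``.  The default threshold keeps a small guard
    band above 1; set ``ptr_threshold=1.0`` for the literal PTR > 1 rule.
    """
    eligible = assigned_reads >= min_assigned_reads and not ptr_result.degenerate
    replicating = eligible and ptr_result.ptr > ptr_threshold
    return replace(
        ptr_result,
        assigned_reads=int(assigned_reads),
        eligible=eligible,
        replicating=replicating,
    )


# ---------------------------------------------------------------- I/O

def read_depth_tsv(
    path: str, genome_id: str = "", length: int | None = None
) -> CoverageTrack:
    """Read per-position depth from a 2-column (position, depth) TSV.

    Positions are 0-based; positions absent from the file get depth 0.
    """
    tab = pd.read_csv(path, sep="\t", header=None, comment="#")
    if tab.shape[1] == 2:
        pos = tab[0].to_numpy(dtype=np.int64)
        dep = tab[1].to_numpy(dtype=float)
    elif tab.shape[1] >= 4:          # bedGraph: chrom start end value
        return read_bedgraph(path, genome_id=genome_id, length=length)
    else:
        raise DataError(f"{path}: expected 2-column depth TSV or bedGraph")
    n = length if length is not None else int(pos.max()) + 1
    depth = np.zeros(n)
    depth[pos] = dep
    return CoverageTrack(genome_id=genome_id, length=n, depth=depth)


def read_bedgraph(
    path: str, genome_id: str = "", length: int | None = None
) -> CoverageTrack:
    """Read per-position depth from a bedGraph (chrom, start, end, depth)."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#")
    if tab.shape[1] < 4:
        raise DataError(f"{path}: bedGraph needs 4 columns")
    start = tab[1].to_numpy(dtype=np.int64)
    end = tab[2].to_numpy(dtype=np.int64)
    val = tab[3].to_numpy(dtype=float)
    n = length if length is not None else int(end.max())
    depth = np.zeros(n)
    for s, e, v in zip(start, end, val):
        depth[s:e] = v
    if not genome_id:
        genome_id = str(tab[0].iloc[0])
    return CoverageTrack(genome_id=genome_id, length=n, depth=depth)


def write_ptr_json(results: list[PTRResult], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2, sort_keys=True)


def write_smoothed_tsv(track: CoverageTrack, path: str) -> None:
    if track.bin_size is None:
        raise DataError("write_smoothed_tsv expects a binned track")
    starts = np.arange(len(track.depth)) * track.bin_size
    pd.DataFrame(
        {"bin_start": starts, "bin_end": starts + track.bin_size,
         "depth": track.depth}
    ).to_csv(path, sep="\t", index=False)
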