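"""Sliding-window scan of linkage posteriors and interval calling.

Single-SNP posteriors are noisy, so the chromosome is scanned with a
window of ``window_size`` SNPs slid in steps of ``step`` SNPs (defaults
100 and 20) and the *median* posterior of each window is plotted against
the window's middle physical position.  The median is robust: a single
aberrant SNP cannot move it.  The mapping interval is the maximal
contiguous run of windows whose median clears a threshold tau and that
contains the peak window; its end points are translated to centimorgans by
linear interpolation on the genetic map, giving the interval width in cM.

The companion :func:`genetic_physical_profile` computes the local cM/Mb
slope between adjacent markers, the standard way to visualise suppressed
recombination around a centromere (a flat genetic-vs-physical curve).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .synthetic import GeneticMap

SCAN_COLUMNS = ["window", "start_bp", "end_bp", "mid_bp", "median_posterior"]


def sliding_window_scan(
    posteriors: pd.DataFrame, window_size: int = 100, step: int = 20
) -> pd.DataFrame:
    """Median posterior in sliding windows of SNPs along one chromosome.

    ``posteriors`` must cover a single chromosome, sorted by position,
    with at least ``window_size`` SNPs.  Windows start at SNP offsets
    0, step, 2*step, ... giving ``floor((S - window_size) / step) + 1``
    windows; the middle position is that of the ``ceil(window_size/2)``-th
    SNP of the window, and the median of an even-sized window is the mean
    of its two central order statistics.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    chroms = posteriors["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"scan one chromosome at a time (got {list(chroms)})")
    pos = posteriors["pos"].to_numpy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("posteriors must be sorted by position")
    post = posteriors["posterior"].to_numpy(dtype=float)
    s = len(post)
    if s < window_size:
        raise ValueError(f"need at least {window_size} SNPs, got {s}")
    starts = np.arange(0, s - window_size + 1, step)
    windows = np.lib.stride_tricks.sliding_window_view(post, window_size)[starts]
    medians = np.median(windows, axis=1)
    mid_off = (window_size + 1) // 2 - 1
    return pd.DataFrame(
        {
            "window": np.arange(len(starts)),
            "start_bp": pos[starts],
            "end_bp": pos[starts + window_size - 1],
            "mid_bp": pos[starts + mid_off],
            "median_posterior": medians,
        }
    )


@dataclass(frozen=True)
class MappingInterval:
    """The called candidate region, in physical and genetic coordinates."""

    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    width_cm: float
    peak_window: int

    def __post_init__(self):
        if self.start_bp > self.end_bp or self.width_cm < 0:
            raise ValueError("degenerate mapping interval")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_bed(self, path) -> None:
        """BED output, converted to 0-based half-open coordinates."""
        with open(path, "w") as fh:
            fh.write(f"{self.chrom}\t{self.start_bp - 1}\t{self.end_bp}\tmapping_interval\n")


@dataclass(frozen=True)
class NoLinkageSignal:
    """Returned when no window clears the threshold."""

    reason: str
    peak_median: float
    tau: float


def call_interval(
    scan: pd.DataFrame,
    gmap: GeneticMap,
    chrom: str,
    tau: float | None = None,
) -> MappingInterval | NoLinkageSignal:
    """Call the mapping interval from a window scan.

    The interval is the maximal contiguous run of windows with median
    posterior >= tau containing the peak window; its physical bounds are
    the first SNP of the run's first window and the last SNP of its last
    window.  When ``tau`` is None it defaults to
    ``max(0.95, 0.5 * peak median)`` — conservative, and never triggered
    by a flat profile at the prior.  If the peak itself is below tau the
    result is :class:`NoLinkageSignal`.
    """
    if scan.empty:
        raise ValueError("empty scan")
    med = scan["median_posterior"].to_numpy(dtype=float)
    peak = int(np.argmax(med))
    peak_median = float(med[peak])
    if tau is None:
        tau = max(0.95, 0.5 * peak_median)
    if peak_median < tau:
        return NoLinkageSignal("no window median reaches tau", peak_median, float(tau))
    lo = peak
    while lo > 0 and med[lo - 1] >= tau:
        lo -= 1
    hi = peak
    while hi < len(med) - 1 and med[hi + 1] >= tau:
        hi += 1
    start_bp = int(scan["start_bp"].iloc[lo])
    end_bp = int(scan["end_bp"].iloc[hi])
    start_cm = float(gmap.interpolate_cm(chrom, start_bp))
    end_cm = float(gmap.interpolate_cm(chrom, end_bp))
    return MappingInterval(
        chrom, start_bp, end_bp, start_cm, end_cm, end_cm - start_cm, peak
    )


def genetic_physical_profile(gmap: GeneticMap) -> pd.DataFrame:
    """Local recombination rate (cM/Mb) between adjacent map markers.

    One row per consecutive marker pair and chromosome: the bp midpoint of
    the pair and the slope ``delta cM / (delta bp / 1e6)``.  Duplicate
    physical positions are an error; a monotone map yields slopes >= 0.
    """
    frames = []
    for chrom in gmap.chroms:
        bp, cm = gmap.chrom_markers(chrom)
        if len(bp) < 2:
            raise ValueError(f"{chrom}: need at least 2 markers for a profile")
        dbp = np.diff(bp)
        if np.any(dbp == 0):
            raise ValueError(f"{chrom}: duplicate physical positions")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "mid_bp": (bp[:-1] + bp[1:]) / 2.0,
                    "cm_per_mb": np.diff(cm) / (dbp / 1e6),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_scan_tsv(scan: pd.DataFrame, path) -> None:
    scan[SCAN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_scan_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
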