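"""Read-depth copy-number pipeline for single-cell whole-genome data.

Counts are collected in small native bins (10 kb), re-binned to the working
granularity (50 kb for deep sequencing; 250 kb or coarser for low-pass),
median-normalized per sample, cleaned of systematically low-coverage bins,
aggregated with a cross-sample median correction for locus-specific bias,
corrected for replication-timing bias with LOESS, and finally segmented
(see :mod:`embryocn.segment`).  Sample quality is gated on the median
absolute deviation (MAD) of bin-level copy number.

All genomic intervals are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

#: platform regimes and their default MAD thresholds.  The deep regime is
#: noisier per 50 kb bin than low-pass per 250 kb bin, hence the larger
#: threshold.
DEFAULT_MAD_THRESHOLDS = {"low_pass": 0.15, "deep": 0.3}

BIN_COLUMNS = ["chrom", "start", "end"]


def _check_bins(bins: pd.DataFrame) -> None:
    for chrom, grp in bins.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if np.any(e <= s):
            raise ValueError(f"empty or inverted bin on {chrom}")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"bins overlap or are unsorted on {chrom}")


@dataclass
class BinCountMatrix:
    """Raw read counts per (sample, genomic bin).

    ``bins`` holds ordered, non-overlapping ``chrom/start/end`` rows;
    ``counts`` is positionally aligned with one integer column per sample.
    """

    bins: pd.DataFrame
    counts: pd.DataFrame
    bin_size: int

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.counts):
            raise ValueError("bins and counts are not aligned")
        _check_bins(self.bins)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class NormalizedCNMatrix:
    """Relative copy number per bin (sample median ~ 1) with an exclusion mask.

    ``mask`` is True for bins removed from all downstream statistics.
    Values may be NaN where a sample has no usable data for a bin.
    """

    bins: pd.DataFrame
    values: pd.DataFrame
    mask: np.ndarray
    bin_size: int

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def unmasked(self, sample: str) -> np.ndarray:
        v = self.values[sample].to_numpy()[~self.mask]
        return v[~np.isnan(v)]


@dataclass
class RepliSeqTrack:
    """Per-bin replication-timing statistic (early/late), aligned to a bin
    index.  Positive values mean earlier replication on the simulated scale."""

    bins: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bins):
            raise ValueError("track not aligned to bin index")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track contains non-finite values")

    def project(self, bins: pd.DataFrame) -> np.ndarray:
        """Overlap-weighted average of the track onto another bin grid.

        Assumes the track bins tile each chromosome contiguously (which
        :meth:`GenomeModel.bins` guarantees); target bins outside the
        track's extent get NaN.
        """
        if len(bins) == len(self.bins) and (
            bins[BIN_COLUMNS].reset_index(drop=True).equals(
                self.bins[BIN_COLUMNS].reset_index(drop=True)
            )
        ):
            return self.values.copy()
        out = np.full(len(bins), np.nan)
        tchrom = bins["chrom"].to_numpy()
        tstart = bins["start"].to_numpy(dtype=np.int64)
        tend = bins["end"].to_numpy(dtype=np.int64)
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            sel = np.flatnonzero(tchrom == chrom)
            if sel.size == 0:
                continue
            edges = np.append(grp["start"].to_numpy(), grp["end"].to_numpy()[-1])
            vals = self.values[grp.index.to_numpy()]
            # piecewise-linear integral of the step function
            integral = np.concatenate(([0.0], np.cumsum(vals * np.diff(edges))))

            def interp(x):
                j = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                            len(vals) - 1)
                return integral[j] + vals[j] * (np.clip(x, edges[0], edges[-1])
                                                - edges[j])

            lo = np.clip(tstart[sel], edges[0], edges[-1])
            hi = np.clip(tend[sel], edges[0], edges[-1])
            width = (hi - lo).astype(float)
            ok = width > 0
            out[sel[ok]] = (interp(hi) - interp(lo))[ok] / width[ok]
        return out


@dataclass
class SampleQC:
    sample: str
    platform: str
    mad: float
    threshold: float
    passed: bool
    reason: str = ""


def rebin(counts: BinCountMatrix, target_bin_size: int) -> BinCountMatrix:
    """Sum counts into larger bins.

    ``target_bin_size`` must be an integer multiple of the source bin size.
    The trailing bin of each chromosome keeps its true end coordinate.
    """
    if target_bin_size == counts.bin_size:
        return replace(counts, bins=counts.bins.copy(), counts=counts.counts.copy())
    if target_bin_size % counts.bin_size != 0:
        raise ValueError(
            f"target bin size {target_bin_size} is not a multiple of {counts.bin_size}"
        )
    key = counts.bins["start"].to_numpy() // target_bin_size
    grouper = [counts.bins["chrom"].to_numpy(), key]
    new_bins = counts.bins.groupby(grouper, sort=False).agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    new_counts = counts.counts.groupby(grouper, sort=False).sum()
    return BinCountMatrix(
        bins=new_bins.reset_index(drop=True),
        counts=new_counts.reset_index(drop=True),
        bin_size=target_bin_size,
    )


def normalize_depth(
    counts: BinCountMatrix,
    low_coverage_fraction: float = 0.25,
    sample_fraction: float = 0.80,
) -> NormalizedCNMatrix:
    """Median-normalize per sample and mask systematically low bins.

    Steps: (i) drop samples whose median raw coverage across all bins is 0;
    (ii) divide each remaining sample by its median; (iii) mask bins whose
    coverage is below ``low_coverage_fraction`` of the sample median in more
    than ``sample_fraction`` of samples; (iv) re-center each sample so the
    median over unmasked bins is exactly 1.
    """
    raw = counts.counts
    medians = raw.median(axis=0)
    keep = medians[medians > 0].index
    if len(keep) == 0:
        raise ValueError("no usable samples: all per-sample medians are zero")
    dropped = [s for s in raw.columns if s not in set(keep)]
    if dropped:
        warnings.warn(f"dropped zero-median samples: {dropped}", stacklevel=2)
    norm = raw[keep] / medians[keep]
    low = (norm < low_coverage_fraction).to_numpy()
    mask = low.mean(axis=1) > sample_fraction
    # re-center on the surviving bins so the stated invariant holds exactly
    surviving = norm.loc[~mask]
    norm = norm / surviving.median(axis=0)
    return NormalizedCNMatrix(
        bins=counts.bins.copy(), values=norm, mask=mask, bin_size=counts.bin_size
    )


def aggregate_bins(norm: NormalizedCNMatrix, target_bin_size: int) -> NormalizedCNMatrix:
    """Combine normalized bins into a coarser grid and remove locus bias.

    Per large bin, the mean of unmasked constituent values is taken, then
    every bin is divided by its median across samples so that shared
    locus-specific coverage biases cancel.  Large bins whose constituents
    are all masked stay masked.
    """
    if target_bin_size % norm.bin_size != 0 or target_bin_size <= norm.bin_size:
        raise ValueError("target bin size must be a larger multiple of the current size")
    key = norm.bins["start"].to_numpy() // target_bin_size
    grouper = [norm.bins["chrom"].to_numpy(), key]
    keep = np.broadcast_to(~norm.mask[:, None], norm.values.shape)
    vals = norm.values.where(keep)
    new_bins = norm.bins.groupby(grouper, sort=False).agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    new_vals = vals.groupby(grouper, sort=False).mean()
    new_mask = new_vals.isna().all(axis=1).to_numpy()
    cross = new_vals.median(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        new_vals = new_vals.div(cross, axis=0)
    new_mask |= ~(cross > 0).to_numpy()
    return NormalizedCNMatrix(
        bins=new_bins.reset_index(drop=True),
        values=new_vals.reset_index(drop=True),
        mask=new_mask,
        bin_size=target_bin_size,
    )


def correct_replication_timing(
    norm: NormalizedCNMatrix,
    track: RepliSeqTrack,
    span: float = 0.3,
) -> NormalizedCNMatrix:
    """Remove replication-timing coverage bias by LOESS.

    Per sample, bin CN is regressed on the timing value with locally
    weighted smoothing (``span`` = fraction of points per local fit), the
    fitted trend is divided out, and the sample is re-centered to median 1.
    A constant track carries no information and yields the identity
    transform with a warning.
    """
    t = track.project(norm.bins)
    usable = ~norm.mask & np.isfinite(t)
    if np.ptp(t[usable]) < 1e-12:
        warnings.warn("replication-timing track is constant; no correction applied",
                      stacklevel=2)
        return replace(norm, values=norm.values.copy(), mask=norm.mask.copy())
    out = norm.values.copy()
    for sample in norm.samples:
        y = norm.values[sample].to_numpy()
        ok = usable & np.isfinite(y)
        if ok.sum() < 10:
            continue
        fit = lowess(y[ok], t[ok], frac=span, return_sorted=False)
        fit = np.where(fit > 1e-6, fit, np.nan)
        corrected = y[ok] / fit
        corrected = corrected / np.nanmedian(corrected)
        col = out[sample].to_numpy()
        col[ok] = corrected
        out[sample] = col
    return replace(norm, values=out, mask=norm.mask.copy())


def qc_sample(
    norm: NormalizedCNMatrix,
    sample: str,
    platform: str,
    thresholds: dict[str, float] | None = None,
    min_bins: int = 10,
) -> SampleQC:
    """Gate a sample on the MAD of its unmasked bin copy numbers."""
    thresholds = thresholds or DEFAULT_MAD_THRESHOLDS
    if platform not in thresholds:
        raise ValueError(f"unknown platform {platform!r}")
    threshold = thresholds[platform]
    v = norm.unmasked(sample)
    if v.size < min_bins:
        return SampleQC(sample, platform, float("nan"), threshold, False,
                        reason=f"only {v.size} usable bins (<{min_bins})")
    mad = float(np.median(np.abs(v - np.median(v))))
    passed = mad <= threshold
    return SampleQC(sample, platform, mad, threshold, passed,
                    reason="" if passed else f"MAD {mad:.3f} > {threshold}")


def qc_all(
    norm: NormalizedCNMatrix, platform: str, **kwargs
) -> pd.DataFrame:
    rows = [qc_sample(norm, s, platform, **kwargs) for s in norm.samples]
    return pd.DataFrame(
        {
            "sample": [r.sample for r in rows],
            "platform": [r.platform for r in rows],
            "mad": [r.mad for r in rows],
            "threshold": [r.threshold for r in rows],
            "pass": [r.passed for r in rows],
            "reason": [r.reason for r in rows],
        }
    )
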