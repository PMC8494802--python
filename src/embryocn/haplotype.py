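"""Haplotype-resolved copy number from SNP allelic depths.

Bin-level VAF is computed with a two-level aggregation: allelic depths are
first averaged within 5 kb micro-bins, so that dense clusters of SNPs with
correlated coverage cannot dominate, and the micro-bin averages are then
summed across each copy-number bin.  Ploidy is estimated from the
genome-wide mean VAF (the digyny signature is a 1/3 : 2/3 allelic balance);
triploid samples have their copy number multiplied by 1.5.  Haplotype copy
number is VAF (or 1-VAF) times the depth-based copy number, scaled so a
balanced diploid bin reads (1, 1).  Segments whose haplotype mean sits near
k + 1/2 while the other haplotype is integral carry the micronucleus
underreplication signature and are flagged ``half_copy``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depth import NormalizedCNMatrix

logger = logging.getLogger(__name__)

MICRO_BIN = 5_000
TRIPLOID_WINDOW = (2.5, 3.5)
TRIPLOID_FACTOR = 1.5


@dataclass
class PloidyCall:
    sample: str
    mean_vaf: float
    statistic: float  # min(VAF, 1-VAF)^-1
    call: str  # diploid / triploid / indeterminate
    factor: float
    embryo_consistent: bool = True


def bin_vaf(
    depths: pd.DataFrame,
    panel_sites: pd.DataFrame,
    bins: pd.DataFrame,
    micro_bin: int = MICRO_BIN,
) -> pd.DataFrame:
    """Bin-level VAF per sample on a CN bin grid.

    Only sites present in ``panel_sites`` (chrom, pos) contribute.  Within
    each ``micro_bin`` window the ref and alt depths are averaged over its
    SNPs; the micro-bin averages are summed over the CN bin and
    VAF = alt_sum / (alt_sum + ref_sum).  Returns a long table
    (sample, bin_index, vaf, n_snps); bins without covered SNPs are absent.
    """
    keyed = depths.merge(panel_sites[["chrom", "pos"]], on=["chrom", "pos"], how="inner")
    if keyed.empty:
        return pd.DataFrame(columns=["sample", "bin_index", "vaf", "n_snps"])
    keyed = keyed[(keyed["ref_count"] + keyed["alt_count"]) > 0].copy()
    bin_index = _assign_bins(keyed, bins)
    keyed["bin_index"] = bin_index
    keyed = keyed[keyed["bin_index"] >= 0]
    keyed["micro"] = keyed["pos"] // micro_bin
    micro = keyed.groupby(["sample", "bin_index", "micro"], sort=False).agg(
        ref=("ref_count", "mean"), alt=("alt_count", "mean"), n=("pos", "size")
    )
    agg = micro.groupby(["sample", "bin_index"]).agg(
        ref=("ref", "sum"), alt=("alt", "sum"), n_snps=("n", "sum")
    )
    total = agg["ref"] + agg["alt"]
    agg["vaf"] = agg["alt"].where(total > 0) / total.where(total > 0)
    out = agg.reset_index()[["sample", "bin_index", "vaf", "n_snps"]]
    return out.dropna(subset=["vaf"]).reset_index(drop=True)


def _assign_bins(table: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Map (chrom, pos) rows to row indices of a sorted bin table (-1 = none)."""
    out = np.full(len(table), -1, dtype=np.int64)
    pos = table["pos"].to_numpy()
    for chrom, grp in bins.groupby("chrom", sort=False):
        sel = (table["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        j = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (j >= 0) & (pos[sel] < ends[np.clip(j, 0, len(ends) - 1)])
        res = np.where(ok, grp.index.to_numpy()[np.clip(j, 0, len(ends) - 1)], -1)
        out[sel] = res
    return out


def estimate_ploidy(
    vaf_track: pd.DataFrame, sample: str, min_bins: int = 20
) -> PloidyCall:
    """Triploidy rule: statistic = 1 / min(mean VAF, 1 - mean VAF); the call
    is triploid (factor 1.5) iff the statistic lies in the closed window
    [2.5, 3.5], otherwise diploid (factor 1.0).  Tetraploid or haploid
    regimes are outside the rule and fall back to diploid."""
    v = vaf_track.loc[vaf_track["sample"] == sample, "vaf"].dropna()
    if len(v) < min_bins:
        return PloidyCall(sample, float("nan"), float("nan"), "indeterminate", 1.0)
    mean_vaf = float(v.mean())
    lo = min(mean_vaf, 1.0 - mean_vaf)
    statistic = float("inf") if lo == 0 else 1.0 / lo
    if TRIPLOID_WINDOW[0] <= statistic <= TRIPLOID_WINDOW[1]:
        return PloidyCall(sample, mean_vaf, statistic, "triploid", TRIPLOID_FACTOR)
    if statistic > 3.5:
        logger.warning("sample %s: allelic balance %.3f outside the di/triploid "
                       "rule; assuming diploid", sample, mean_vaf)
    return PloidyCall(sample, mean_vaf, statistic, "diploid", 1.0)


def flag_ploidy_outliers(calls: list[PloidyCall]) -> list[PloidyCall]:
    """Flag blastomeres whose ploidy differs from the embryo's modal call.

    Expects the calls of one embryo; requires >=3 determinate calls.  A tie
    for the mode marks every call indeterminate-consistent (False).
    """
    determinate = [c for c in calls if c.call in ("diploid", "triploid")]
    if len(determinate) < 3:
        for c in calls:
            c.embryo_consistent = False
        return calls
    counts = pd.Series([c.call for c in determinate]).value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        for c in calls:
            c.embryo_consistent = False
        return calls
    modal = counts.index[0]
    for c in calls:
        c.embryo_consistent = c.call == modal
    return calls


def compute_haplotype_cn(
    vaf_track: pd.DataFrame,
    depth_cn: NormalizedCNMatrix,
    ploidy: dict[str, PloidyCall],
    baseline_cn: float = 2.0,
) -> pd.DataFrame:
    """Per-bin haplotype copy number.

    Relative depth CN (sample median 1) is scaled by the diploid baseline
    (2) and the ploidy factor, then split by VAF:
    cn_129 = VAF * total, cn_b6 = (1 - VAF) * total.  Bins without VAF keep
    total_cn with missing haplotype values.  Returns a long table
    (sample, bin_index, chrom, start, end, total_cn, cn_129, cn_b6).
    """
    frames = []
    bins = depth_cn.bins.reset_index(drop=True)
    for sample in depth_cn.samples:
        factor = ploidy[sample].factor if sample in ploidy else 1.0
        rel = depth_cn.values[sample].to_numpy()
        total = rel * baseline_cn * factor
        df = bins.copy()
        df["sample"] = sample
        df["bin_index"] = np.arange(len(bins))
        df["total_cn"] = np.where(depth_cn.mask, np.nan, total)
        v = vaf_track[vaf_track["sample"] == sample].set_index("bin_index")["vaf"]
        vaf = df["bin_index"].map(v).to_numpy()
        df["cn_129"] = vaf * df["total_cn"]
        df["cn_b6"] = (1.0 - vaf) * df["total_cn"]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["sample", "bin_index", "chrom", "start", "end",
                "total_cn", "cn_129", "cn_b6"]]


def attach_haplotype_means(
    segments: pd.DataFrame, hap_track: pd.DataFrame
) -> pd.DataFrame:
    """Depth-weighted per-segment means of cn_129 / cn_b6 joined onto a
    segment table (weights: number of contributing SNP micro-bins is not
    retained at this level, so bins count equally; missing-VAF bins are
    skipped)."""
    seg = segments.copy()
    seg["cn_129"] = np.nan
    seg["cn_b6"] = np.nan
    for i, row in seg.iterrows():
        sel = hap_track[
            (hap_track["sample"] == row["sample"])
            & (hap_track["chrom"] == row["chrom"])
            & (hap_track["start"] < row["end"])
            & (hap_track["end"] > row["start"])
        ]
        if sel["cn_129"].notna().any():
            seg.loc[i, "cn_129"] = sel["cn_129"].mean()
            seg.loc[i, "cn_b6"] = sel["cn_b6"].mean()
    return seg


def detect_half_copy_segments(
    hap_segments: pd.DataFrame, tolerance: float = 0.15
) -> pd.DataFrame:
    """Flag segments carrying the micronucleus underreplication signature.

    A segment is ``half_copy`` when one haplotype mean lies within
    ``tolerance`` of k + 1/2 for some integer k >= 0 while the other lies
    within ``tolerance`` of an integer.
    """
    seg = hap_segments.copy()

    def near_half(x: float) -> bool:
        return np.isfinite(x) and abs(x - (np.floor(x) + 0.5)) <= tolerance

    def near_int(x: float) -> bool:
        return np.isfinite(x) and abs(x - np.round(x)) <= tolerance

    flags = []
    for a, b in zip(seg["cn_129"], seg["cn_b6"]):
        flags.append((near_half(a) and near_int(b)) or (near_half(b) and near_int(a)))
    seg["half_copy"] = flags
    return seg
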