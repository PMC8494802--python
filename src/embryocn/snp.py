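"""Selection of cross-informative SNPs.

In a C57BL/6J x 129/SvJae hybrid cross, every truly heterozygous SNP should
sit near 50% variant allele fraction (VAF) when read depth is pooled over
many diploid cells.  Sites are kept when their across-sample median VAF
falls inside a closed window (default [0.40, 0.60]); the reference allele
is oriented to C57BL/6J (maternal) and the alternate to 129/SvJae
(paternal).
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

DEPTH_COLUMNS = ["chrom", "pos", "sample", "ref_count", "alt_count"]


def site_vaf(depths: pd.DataFrame) -> pd.DataFrame:
    """Per-(site, sample) VAF = alt / (ref + alt); NaN where depth is 0."""
    total = depths["ref_count"] + depths["alt_count"]
    vaf = depths["alt_count"].where(total > 0) / total.where(total > 0)
    return depths[["chrom", "pos", "sample"]].assign(depth=total, vaf=vaf)


def filter_informative_snps(
    depths: pd.DataFrame,
    min_vaf: float = 0.40,
    max_vaf: float = 0.60,
    min_covered_samples: int = 3,
) -> pd.DataFrame:
    """Keep sites whose median per-sample VAF lies in [min_vaf, max_vaf].

    The median is taken over samples with nonzero depth only, and a site
    needs at least ``min_covered_samples`` such samples before the median
    is trusted.  Returns a panel table (chrom, pos, median_vaf, n_covered,
    kept) sorted by position; window endpoints are inclusive.
    """
    v = site_vaf(depths)
    covered = v[v["depth"] > 0]
    n_sites_total = v.groupby(["chrom", "pos"]).ngroups
    stats = covered.groupby(["chrom", "pos"], sort=True).agg(
        median_vaf=("vaf", "median"), n_covered=("vaf", "size")
    )
    dropped_uncovered = n_sites_total - len(stats)
    if dropped_uncovered:
        logger.info("dropped %d sites with no covered sample", dropped_uncovered)
    stats["kept"] = (
        (stats["n_covered"] >= min_covered_samples)
        & (stats["median_vaf"] >= min_vaf)
        & (stats["median_vaf"] <= max_vaf)
    )
    return stats.reset_index()


def informative_sites(panel: pd.DataFrame) -> pd.DataFrame:
    return panel[panel["kept"]][["chrom", "pos"]].reset_index(drop=True)
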