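"""Structural-variant candidate filtering and joint genotyping.

SV discovery is external; this module consumes a BEDPE-like candidate table
(one row per junction, per-sample split/discordant tallies in
``split:<sample>`` / ``disc:<sample>`` columns) and applies the de novo
filter chain: drop strain-background calls, calls supported by fewer than
3 reads in the discovery sample, calls without a supporting pair above
mapping quality 30, and intra-chromosomal calls spanning <= 1 Mb.  Filtered
candidates are genotyped jointly across all blastomeres by tallying
split + discordant reads, and only junctions confined to a single embryo
are retained as de novo events.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_SUPPORT_READS = 3
MIN_MAPQ = 30  # strict: requires mapq > 30
MIN_SPAN = 1_000_000  # strict: requires span > 1 Mb (intra-chromosomal only)


def _tally_columns(svs: pd.DataFrame, prefix: str) -> list[str]:
    return [c for c in svs.columns if c.startswith(prefix + ":")]


def sample_names(svs: pd.DataFrame) -> list[str]:
    return [c.split(":", 1)[1] for c in _tally_columns(svs, "split")]


def filter_candidates(
    svs: pd.DataFrame,
    min_support: int = MIN_SUPPORT_READS,
    min_mapq: int = MIN_MAPQ,
    min_span: int = MIN_SPAN,
) -> pd.DataFrame:
    """Apply the four candidate filters; each is independent of the others,
    so their order is immaterial.  Survivor counts are logged per filter."""
    n0 = len(svs)
    not_background = ~svs["in_strain_background"].astype(bool)
    supported = svs["support_reads"] >= min_support
    mapq_ok = svs["max_mapq"] > min_mapq
    intra = svs["chrom_a"] == svs["chrom_b"]
    span = (svs["pos_b"] - svs["pos_a"]).abs()
    span_ok = ~intra | (span > min_span)
    keep = not_background & supported & mapq_ok & span_ok
    logger.info(
        "SV filters on %d candidates: background %d, support %d, mapq %d, "
        "span %d survive; %d pass all",
        n0, int(not_background.sum()), int(supported.sum()),
        int(mapq_ok.sum()), int(span_ok.sum()), int(keep.sum()),
    )
    return svs[keep].reset_index(drop=True)


def joint_genotype(svs: pd.DataFrame, presence_threshold: int = 1) -> pd.DataFrame:
    """Presence matrix per (SV, sample): present when split + discordant
    tallies reach ``presence_threshold`` reads."""
    samples = sample_names(svs)
    if not samples:
        raise ValueError("candidate table has no per-sample tally columns")
    out = pd.DataFrame(index=svs["id"], columns=samples, dtype=bool)
    for s in samples:
        split_col, disc_col = f"split:{s}", f"disc:{s}"
        if disc_col not in svs.columns:
            raise ValueError(f"missing tally column {disc_col!r}")
        total = svs[split_col].to_numpy() + svs[disc_col].to_numpy()
        out[s] = total >= presence_threshold
    return out


def select_embryo_specific(
    presence: pd.DataFrame, embryo_map: dict[str, str]
) -> pd.DataFrame:
    """Keep SVs whose presence calls all fall within a single embryo.

    ``embryo_map`` maps each sample to its embryo; an SV present in no
    sample, or in samples of more than one embryo, is dropped.  Returns a
    table (id, embryo, n_blastomeres, blastomeres).
    """
    unmapped = [s for s in presence.columns if s not in embryo_map]
    if unmapped:
        raise ValueError(f"samples not mapped to an embryo: {unmapped}")
    rows = []
    for sv_id, row in presence.iterrows():
        hit = [s for s in presence.columns if row[s]]
        embryos = {embryo_map[s] for s in hit}
        if len(embryos) == 1:
            rows.append(
                {
                    "id": sv_id,
                    "embryo": next(iter(embryos)),
                    "n_blastomeres": len(hit),
                    "blastomeres": ",".join(hit),
                }
            )
    return pd.DataFrame(rows, columns=["id", "embryo", "n_blastomeres", "blastomeres"])


def genotype_pipeline(
    svs: pd.DataFrame,
    embryo_map: dict[str, str],
    min_support: int = MIN_SUPPORT_READS,
    min_mapq: int = MIN_MAPQ,
    min_span: int = MIN_SPAN,
    presence_threshold: int = 1,
) -> pd.DataFrame:
    """Filter chain -> joint genotyping -> embryo-specific selection."""
    kept = filter_candidates(svs, min_support, min_mapq, min_span)
    if kept.empty:
        return pd.DataFrame(columns=["id", "embryo", "n_blastomeres", "blastomeres"])
    presence = joint_genotype(kept, presence_threshold)
    return select_embryo_specific(presence, embryo_map)
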