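"""Rule-based reconstruction of karyotype history in 8-cell embryos.

Input is a per-blastomere haplotype segment table (columns: sample, chrom,
start, end, n_bins, mean_cn, cn_129, cn_b6 and optionally half_copy).
Per-blastomere rules call whole-chromosome monosomy/trisomy, arm-level
(distal) gains and losses anchored at the Cas9 cut site, and half-copy
micronucleus signatures.  Embryo-level rules then (i) pair reciprocal
gains and losses of the same haplotype segment across blastomeres and read
off the division at which the missegregation happened from the group sizes
(4+4 -> division 1, 2+2 -> 2, 1+1 -> 3 in a full 8-cell complement),
(ii) recognize the dicentric-bridge monosomy pattern (one lineage holding
all copies of the cut homolog, the sister lineage monosomic), and
(iii) attribute alterations shared by every blastomere to meiosis
(trisomy) or digyny.

Copy numbers are interpreted on the half-integer grid; chromosomes are
telocentric, so the centric side of a cut is always the interval below the
cut coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel, MATERNAL, PATERNAL

HAP_COLS = {MATERNAL: "cn_b6", PATERNAL: "cn_129"}  # B6 is maternal in the cross
ARM_LEVEL_FRACTION = 0.30  # minimum chromosome fraction for "arm-level"
CN_TOL = 0.3  # distance to the nearest integer state when rounding


@dataclass(frozen=True)
class TargetSite:
    """gRNA cut site with the breakpoint-match tolerance."""

    name: str
    chromosome: str
    cut_position: int
    tolerance: int = 1_000_000


@dataclass
class KaryotypeEvent:
    embryo: str
    blastomeres: tuple[str, ...]
    chromosome: str
    haplotype: str | None
    event_class: str
    on_target: bool = False
    division_inferred: object = "unknown"  # 1..3, "meiosis", "unknown", or range
    start: int | None = None
    end: int | None = None
    details: str = ""
    ambiguous_alternatives: tuple[str, ...] = field(default_factory=tuple)


def events_table(events: list[KaryotypeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "embryo": e.embryo,
                "blastomeres": ",".join(e.blastomeres),
                "chrom": e.chromosome,
                "haplotype": e.haplotype,
                "event_class": e.event_class,
                "on_target": e.on_target,
                "division_inferred": str(e.division_inferred),
                "start": e.start,
                "end": e.end,
                "details": e.details,
            }
            for e in events
        ]
    )


def match_on_target(segments: pd.DataFrame, site: TargetSite) -> pd.DataFrame:
    """Flag CN breakpoints lying within tolerance of the cut position.

    Every internal segment boundary on the targeted chromosome is tested;
    the returned table (sample, chrom, pos, on_target) lists all arm-level
    breakpoints so that off-target cross-checks can consume the rest.
    """
    rows = []
    for sample, grp in segments.groupby("sample", sort=False):
        for chrom, cgrp in grp.groupby("chrom", sort=False):
            cgrp = cgrp.sort_values("start")
            bounds = cgrp["start"].to_numpy()[1:]  # internal boundaries
            for pos in bounds:
                on = (
                    chrom == site.chromosome
                    and abs(int(pos) - site.cut_position) <= site.tolerance
                )
                rows.append({"sample": sample, "chrom": chrom, "pos": int(pos),
                             "on_target": on})
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "on_target"])


def _round_state(x: float) -> float | None:
    """Snap a haplotype mean to the nearest half-integer state (None if far)."""
    if not np.isfinite(x):
        return None
    state = np.round(x * 2) / 2
    return float(state) if abs(x - state) <= CN_TOL else None


def classify_blastomere(
    hap_segments: pd.DataFrame,
    site: TargetSite | None,
    genome: GenomeModel,
    embryo: str = "E",
    baseline: dict[str, float] | None = None,
) -> list[KaryotypeEvent]:
    """Per-blastomere event calls from ploidy-corrected haplotype segments.

    ``baseline`` gives the expected per-haplotype copy number (default 1
    maternal + 1 paternal; a digynic embryo uses 2 maternal + 1 paternal).
    """
    baseline = baseline or {MATERNAL: 1.0, PATERNAL: 1.0}
    events: list[KaryotypeEvent] = []
    sample = hap_segments["sample"].iloc[0]
    for chrom, grp in hap_segments.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        length = genome.lengths[chrom]
        covered = (grp["end"] - grp["start"]).sum()
        if covered < 0.95 * length:
            raise ValueError(f"segments do not tile {chrom} for {sample}")
        for hap in (MATERNAL, PATERNAL):
            col = HAP_COLS[hap]
            if grp[col].isna().all():
                continue
            states = [_round_state(v) for v in grp[col]]
            base = baseline[hap]
            # whole-chromosome states first
            if all(s == 0.0 for s in states):
                events.append(KaryotypeEvent(
                    embryo, (sample,), chrom, hap, "whole_chromosome_monosomy",
                    start=0, end=length))
                continue
            if all(s == base + 1 for s in states):
                events.append(KaryotypeEvent(
                    embryo, (sample,), chrom, hap, "whole_chromosome_trisomy",
                    start=0, end=length))
                continue
            if all(s == base for s in states):
                continue
            events.extend(
                _segment_events(grp, col, states, base, hap, chrom, length,
                                site, embryo, sample)
            )
    # half-copy flags computed upstream ride along as micronucleus calls
    if "half_copy" in hap_segments.columns:
        for _, row in hap_segments[hap_segments["half_copy"]].iterrows():
            hap = _half_copy_haplotype(row)
            on = _on_target(row, site)
            events.append(KaryotypeEvent(
                embryo, (sample,), row["chrom"], hap, "half_copy_micronucleus",
                on_target=on, start=int(row["start"]), end=int(row["end"]),
                details="haplotype mean near k + 1/2: micronucleus underreplication"))
    return events


def _segment_events(grp, col, states, base, hap, chrom, length, site, embryo, sample):
    events = []
    for (_, row), state in zip(grp.iterrows(), states):
        if state is None or state == base:
            continue
        if bool(row.get("half_copy", False)):
            continue  # reported as a micronucleus signature, not a gain/loss
        span = row["end"] - row["start"]
        arm_level = span >= ARM_LEVEL_FRACTION * length
        if not arm_level:
            continue
        direction = "gain" if state > base else "loss"
        distal = row["end"] >= 0.99 * length  # runs to the telomere-distal end
        on = _on_target(row, site)
        if distal and abs(state - base) in (0.5, 1.0):
            cls = "reciprocal_gain_loss"
            details = f"distal (acentric-side) {direction} to {state:g}"
        else:
            cls = "unclassified"
            details = f"arm-level {direction} to {state:g}"
        events.append(KaryotypeEvent(
            embryo, (sample,), chrom, hap, cls, on_target=on,
            start=int(row["start"]), end=int(row["end"]), details=details))
    return events


def _on_target(row, site: TargetSite | None) -> bool:
    if site is None or row["chrom"] != site.chromosome:
        return False
    return (abs(int(row["start"]) - site.cut_position) <= site.tolerance
            or abs(int(row["end"]) - site.cut_position) <= site.tolerance)


def _half_copy_haplotype(row) -> str:
    frac129 = abs(row["cn_129"] - np.round(row["cn_129"]))
    fracb6 = abs(row["cn_b6"] - np.round(row["cn_b6"]))
    return PATERNAL if frac129 >= fracb6 else MATERNAL


_DIVISION_BY_GROUP = {4: 1, 2: 2, 1: 3}


def pair_reciprocal_events(
    events: list[KaryotypeEvent], n_blastomeres: int = 8
) -> list[KaryotypeEvent]:
    """Group reciprocal gains and losses across an embryo's blastomeres.

    Gains and losses of the same haplotype over the same region pair into
    one missegregation; with the full 8-cell complement the group size
    fixes the division (4+4 -> 1, 2+2 -> 2, 1+1 -> 3).  With missing
    blastomeres the division degrades to a range.  Unpairable events are
    returned unchanged.
    """
    singles = [e for e in events if e.event_class in
               ("reciprocal_gain_loss", "whole_chromosome_monosomy",
                "whole_chromosome_trisomy")]
    other = [e for e in events if e not in singles]
    grouped: list[KaryotypeEvent] = []
    used: set[int] = set()
    keyfn = lambda e: (e.chromosome, e.haplotype, e.start // 10**6 if e.start else 0)
    by_key: dict[tuple, list[KaryotypeEvent]] = {}
    for e in singles:
        by_key.setdefault(keyfn(e), []).append(e)
    for key, group in by_key.items():
        gains = [e for e in group if "gain" in e.details or "trisomy" in e.event_class]
        losses = [e for e in group if "loss" in e.details or "monosomy" in e.event_class]
        if gains and losses:
            n_g, n_l = len(gains), len(losses)
            if n_g == n_l and n_g in _DIVISION_BY_GROUP and n_blastomeres == 8:
                division = _DIVISION_BY_GROUP[n_g]
            elif n_blastomeres < 8:
                division = f"{_DIVISION_BY_GROUP.get(max(n_g, n_l), 'unknown')}" \
                           f"-{_DIVISION_BY_GROUP.get(min(n_g, n_l), 'unknown')}"
            else:
                division = "unknown"
            blasts = tuple(b for e in gains + losses for b in e.blastomeres)
            merged = KaryotypeEvent(
                gains[0].embryo, blasts, key[0], key[1], "reciprocal_gain_loss",
                on_target=any(e.on_target for e in gains + losses),
                division_inferred=division,
                start=gains[0].start, end=gains[0].end,
                details=f"{n_g} gain + {n_l} loss blastomeres")
            grouped.append(merged)
            for e in gains + losses:
                used.add(id(e))
    leftovers = [e for e in singles if id(e) not in used]
    return grouped + leftovers + other


def infer_bridge_monosomy(
    events: list[KaryotypeEvent],
    hap_segments: pd.DataFrame,
    site: TargetSite,
    embryo: str = "E",
) -> KaryotypeEvent | None:
    """Dicentric-bridge monosomy: a blastomere with zero copies of one
    haplotype of the whole targeted chromosome, plus a sibling lineage
    whose centric portion (below the cut) of the same haplotype carries
    surplus copies.  The acentric portion of the surplus lineage may sit at
    replicated or half-copy dosage and does not enter the rule."""
    monosomies = [
        e for e in events
        if e.event_class == "whole_chromosome_monosomy"
        and e.chromosome == site.chromosome
    ]
    if not monosomies:
        return None
    hap = monosomies[0].haplotype
    col = HAP_COLS[hap]
    chrom = site.chromosome
    surplus = []
    mono_samples = {b for e in monosomies for b in e.blastomeres}
    seg = hap_segments[(hap_segments["chrom"] == chrom)]
    for sample, grp in seg.groupby("sample", sort=False):
        if sample in mono_samples:
            continue
        centric = grp[grp["start"] < site.cut_position]
        if centric.empty or centric[col].isna().all():
            continue
        w = (centric["end"].clip(upper=site.cut_position) - centric["start"]).to_numpy()
        mean_centric = float(np.average(centric[col].fillna(0), weights=w))
        if mean_centric >= 1.5:  # >= one surplus copy of the cut homolog
            surplus.append(sample)
    if not surplus:
        return None
    n_mono = len(mono_samples)
    division = 3 - int(np.log2(n_mono)) if n_mono in (1, 2, 4) else "unknown"
    return KaryotypeEvent(
        embryo, tuple(sorted(mono_samples) + sorted(surplus)), chrom, hap,
        "bridge_monosomy", on_target=True, division_inferred=division,
        details=f"{n_mono} monosomic blastomere(s); centric surplus in "
                f"{','.join(sorted(surplus))}",
        ambiguous_alternatives=("independent whole-chromosome loss and gain",),
    )


def infer_meiotic_and_digyny(
    hap_segments: pd.DataFrame,
    genome: GenomeModel,
    embryo: str = "E",
    ploidy_calls: dict[str, str] | None = None,
) -> list[KaryotypeEvent]:
    """Embryo-wide alterations are meiotic: a whole-chromosome gain of one
    haplotype in every QC-passing blastomere is a meiotic trisomy; uniform
    triploidy with doubled maternal dosage is digyny."""
    events: list[KaryotypeEvent] = []
    samples = sorted(hap_segments["sample"].unique())
    if not samples:
        return events
    if ploidy_calls and all(ploidy_calls.get(s) == "triploid" for s in samples):
        m = hap_segments["cn_b6"].mean()
        p = hap_segments["cn_129"].mean()
        if abs(m - 2.0) <= 0.35 and abs(p - 1.0) <= 0.35:
            events.append(KaryotypeEvent(
                embryo, tuple(samples), "genome-wide", MATERNAL, "digyny",
                division_inferred="meiosis",
                details=f"mean maternal CN {m:.2f}, paternal {p:.2f}"))
            return events
    # a trisomy shared by every blastomere shows a chromosome-wide 2:1
    # allelic imbalance; the ratio form is robust even when cross-sample
    # median normalization has flattened the total-depth signal
    for chrom, _ in genome.chromosomes:
        for hap, col in ((MATERNAL, "cn_b6"), (PATERNAL, "cn_129")):
            other = "cn_129" if col == "cn_b6" else "cn_b6"
            shared = True
            for s in samples:
                grp = hap_segments[(hap_segments["sample"] == s)
                                   & (hap_segments["chrom"] == chrom)]
                if grp.empty or grp[col].isna().all():
                    shared = False
                    break
                w = (grp["end"] - grp["start"]).to_numpy()
                hi = np.average(grp[col].fillna(0), weights=w)
                lo = np.average(grp[other].fillna(0), weights=w)
                if not (lo > 0 and 1.6 <= hi / lo <= 2.5):
                    shared = False
                    break
            if shared:
                events.append(KaryotypeEvent(
                    embryo, tuple(samples), chrom, hap, "meiotic_trisomy",
                    division_inferred="meiosis",
                    start=0, end=genome.lengths[chrom]))
    return events


def classify_embryo(
    hap_segments: pd.DataFrame,
    genome: GenomeModel,
    site: TargetSite | None = None,
    embryo: str = "E",
    ploidy_calls: dict[str, str] | None = None,
) -> list[KaryotypeEvent]:
    """Full embryo-level classification.

    Meiotic/digynic signatures are removed from the per-blastomere baseline
    first; remaining per-blastomere events are paired across the lineage,
    and the bridge-monosomy rule is applied last, replacing the plain
    monosomy/surplus calls it explains (most parsimonious history).
    """
    meiotic = infer_meiotic_and_digyny(hap_segments, genome, embryo, ploidy_calls)
    baseline = {MATERNAL: 1.0, PATERNAL: 1.0}
    if any(e.event_class == "digyny" for e in meiotic):
        baseline = {MATERNAL: 2.0, PATERNAL: 1.0}
    # chromosomes explained by a meiotic trisomy are excluded from the
    # per-blastomere rules: their haplotype means are distorted whenever
    # the cross-sample median has absorbed part of the shared gain
    trisomic_chroms = {e.chromosome for e in meiotic
                       if e.event_class == "meiotic_trisomy"}
    per_cell: list[KaryotypeEvent] = []
    for sample, grp in hap_segments.groupby("sample", sort=False):
        cell_events = classify_blastomere(grp, site, genome, embryo, baseline)
        per_cell.extend(
            e for e in cell_events if e.chromosome not in trisomic_chroms
        )
    n_samples = hap_segments["sample"].nunique()
    bridge = None
    if site is not None:
        bridge = infer_bridge_monosomy(per_cell, hap_segments, site, embryo)
        if bridge is not None:
            # the bridge explains the whole-chromosome calls it covers;
            # remove them before reciprocal pairing (parsimony)
            explained = set(bridge.blastomeres)
            per_cell = [
                e for e in per_cell
                if not (e.chromosome == site.chromosome
                        and e.haplotype == bridge.haplotype
                        and e.event_class in ("whole_chromosome_monosomy",
                                              "whole_chromosome_trisomy",
                                              "unclassified")
                        and set(e.blastomeres) <= explained)
            ]
        else:
            for e in per_cell:
                if (e.event_class == "whole_chromosome_monosomy"
                        and e.chromosome == site.chromosome):
                    e.details = "monosomy without sibling centric surplus; flagged for review"
    paired = pair_reciprocal_events(per_cell, n_blastomeres=n_samples)
    out = meiotic + paired
    if bridge is not None:
        out = out + [bridge]
    return out
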