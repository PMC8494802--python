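"""Synthetic embryo lineages with implanted mitotic-error events.

A zygote undergoes three cleavage divisions into 8 blastomeres.  Events are
implanted at a chosen division (or, for meiotic errors, in the zygote) and
propagate through the lineage, producing per-blastomere haplotype
karyotypes with ground truth.  From the realized karyotypes the module
emits sequencing-like observables: binned read counts, per-SNP allelic
depths, candidate structural-variant tables, and two-channel EdU/DAPI
images.

Event mechanics (telocentric chromosomes; centric fragment = [0, cut),
acentric fragment = [cut, length)):

* ``acentric_missegregation`` — the Cas9-induced acentric fragment
  missegregates: both copies go to one daughter (distal gain, CN 2) while
  the sister loses it (distal CN 0, LOH): a reciprocal gain/loss pattern.
* ``micronucleus_underreplication`` — the acentric fragment stays with the
  centric fragment in one daughter but is partitioned into a micronucleus,
  where it fails to replicate; harvested in G2 it carries half the DNA
  mass of the replicated centric fragment (~0.5 CN).
* ``bridge_monosomy`` — fusion of the broken sister-chromatid ends forms a
  dicentric chromosome; at division one daughter receives all copies of
  the cut homolog (centric surplus, with the acentric fragment either
  replicated or micronucleated) and its sister is left monosomic for the
  whole chromosome.
* ``whole_chromosome_missegregation`` — spontaneous nondisjunction:
  reciprocal whole-chromosome gain/loss between sisters.
* ``meiotic_trisomy`` — an extra copy of one homolog inherited from
  meiosis, present in every blastomere.
* ``digyny`` — retention of a second maternal genome complement: every
  blastomere is triploid with 2 maternal : 1 paternal dosage.

Copy numbers are tracked separately for the primary nucleus and for
micronuclei, because the latter underreplicate: in a G2 harvest a nuclear
copy contributes 2 units of DNA mass but a micronuclear copy only 1.

All coordinates 0-based, half-open.  Every emitter is deterministic for a
fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .depth import BinCountMatrix, RepliSeqTrack
from .genome import HAPLOTYPES, MATERNAL, PATERNAL, GenomeModel

MITOTIC_EVENTS = {
    "acentric_missegregation",
    "micronucleus_underreplication",
    "bridge_monosomy",
    "whole_chromosome_missegregation",
}
MEIOTIC_EVENTS = {"meiotic_trisomy", "digyny"}
EVENT_CLASSES = MITOTIC_EVENTS | MEIOTIC_EVENTS | {"none"}
CUT_EVENTS = {
    "acentric_missegregation",
    "micronucleus_underreplication",
    "bridge_monosomy",
}


@dataclass(frozen=True)
class EventSpec:
    """One implanted segregation error.

    ``division_index`` (1..3) selects the cleavage division at which a
    mitotic error occurs and must be absent for meiotic events;
    ``mother_index`` selects which cell of that generation missegregates
    (0 = leftmost).  ``acentric_fate`` applies to ``bridge_monosomy`` only
    and controls whether the surplus acentric fragment is replicated
    normally or held in a micronucleus.
    """

    event_class: str
    target_chromosome: str | None = None
    cut_position: int | None = None
    division_index: int | None = None
    affected_haplotype: str | None = None
    mother_index: int = 0
    acentric_fate: str = "replicated"

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.event_class == "none":
            return
        if self.event_class in MITOTIC_EVENTS:
            if self.division_index not in (1, 2, 3):
                raise ValueError(
                    f"{self.event_class} requires division_index in {{1,2,3}}"
                )
        else:
            if self.division_index is not None:
                raise ValueError(f"{self.event_class} is meiotic: no division_index")
        if self.affected_haplotype not in HAPLOTYPES and self.event_class != "digyny":
            raise ValueError("affected_haplotype must be 'maternal' or 'paternal'")
        if self.event_class in CUT_EVENTS and self.cut_position is None:
            raise ValueError(f"{self.event_class} requires cut_position")
        if self.acentric_fate not in ("replicated", "micronucleus"):
            raise ValueError("acentric_fate must be 'replicated' or 'micronucleus'")


@dataclass
class CoverageModel:
    """Sequencing-depth model for the count emitters.

    mean_depth: genome-wide haploid coverage (0.15 for low-pass, 9.45 deep).
    dispersion: negative-binomial overdispersion alpha (var = mu(1+alpha*mu));
        0 gives Poisson counts.
    bias_profile: optional strictly positive per-bin multiplicative bias.
    repli_bias_strength: log-linear coupling of bin counts to the
        replication-timing value (0 = unbiased).
    read_length: bp per read, converting coverage into expected read counts.
    """

    mean_depth: float
    dispersion: float = 0.05
    bias_profile: np.ndarray | None = None
    repli_bias_strength: float = 0.0
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.bias_profile is not None:
            self.bias_profile = np.asarray(self.bias_profile, dtype=float)
            if (self.bias_profile <= 0).any():
                raise ValueError("bias_profile must be strictly positive")


LOW_PASS = CoverageModel(mean_depth=0.15)
DEEP = CoverageModel(mean_depth=9.45)


@dataclass
class HapSeg:
    """One karyotype segment: copies per haplotype, split between the
    primary nucleus (``*_nuc``, replicate normally) and micronuclei
    (``*_mn``, underreplicated in G2)."""

    start: int
    end: int
    m_nuc: int = 1
    m_mn: int = 0
    p_nuc: int = 1
    p_mn: int = 0

    def cn(self, hap: str) -> int:
        return (self.m_nuc + self.m_mn) if hap == MATERNAL else (self.p_nuc + self.p_mn)

    def mass(self, hap: str, phase: str) -> float:
        nuc, mn = (self.m_nuc, self.m_mn) if hap == MATERNAL else (self.p_nuc, self.p_mn)
        return 2.0 * nuc + 1.0 * mn if phase == "G2" else float(nuc + mn)

    def underreplicated(self) -> bool:
        return self.m_mn > 0 or self.p_mn > 0


class Karyotype:
    """Per-chromosome list of :class:`HapSeg`, tiling each chromosome."""

    def __init__(self, genome: GenomeModel, maternal: int = 1, paternal: int = 1):
        self.segments: dict[str, list[HapSeg]] = {
            chrom: [HapSeg(0, length, m_nuc=maternal, p_nuc=paternal)]
            for chrom, length in genome.chromosomes
        }

    def clone(self) -> "Karyotype":
        new = object.__new__(Karyotype)
        new.segments = {c: copy.deepcopy(segs) for c, segs in self.segments.items()}
        return new

    def split(self, chrom: str, pos: int) -> None:
        segs = self.segments[chrom]
        out = []
        for s in segs:
            if s.start < pos < s.end:
                left = copy.deepcopy(s)
                right = copy.deepcopy(s)
                left.end = pos
                right.start = pos
                out.extend([left, right])
            else:
                out.append(s)
        self.segments[chrom] = out

    def apply(self, chrom: str, start: int, end: int, fn) -> None:
        """Apply ``fn(seg)`` to every segment fully inside [start, end)."""
        self.split(chrom, start)
        self.split(chrom, end)
        for s in self.segments[chrom]:
            if s.start >= start and s.end <= end:
                fn(s)

    def adjust(self, chrom: str, start: int, end: int, hap: str,
               d_nuc: int = 0, d_mn: int = 0) -> None:
        def fn(s: HapSeg) -> None:
            if hap == MATERNAL:
                s.m_nuc = max(0, s.m_nuc + d_nuc)
                s.m_mn = max(0, s.m_mn + d_mn)
            else:
                s.p_nuc = max(0, s.p_nuc + d_nuc)
                s.p_mn = max(0, s.p_mn + d_mn)

        self.apply(chrom, start, end, fn)


@dataclass
class EmbryoGroundTruth:
    """Realized lineage: 8 blastomeres, their karyotypes and event labels."""

    genome: GenomeModel
    blastomeres: list[str]
    lineage: dict[str, str]  # blastomere -> L/R path through 3 divisions
    karyotypes: dict[str, Karyotype]
    events: list[EventSpec]
    phase: str = "G1"  # harvest phase: G1 or G2

    def table(self) -> pd.DataFrame:
        rows = []
        for b in self.blastomeres:
            for chrom, segs in self.karyotypes[b].segments.items():
                for s in segs:
                    rows.append(
                        {
                            "blastomere": b,
                            "chrom": chrom,
                            "start": s.start,
                            "end": s.end,
                            "maternal_cn": s.cn(MATERNAL),
                            "paternal_cn": s.cn(PATERNAL),
                            "replication_state": (
                                "underreplicated" if s.underreplicated() else "replicated"
                            ),
                        }
                    )
        return pd.DataFrame(rows)

    def mass_arrays(self, bins: pd.DataFrame, blastomere: str) -> dict[str, np.ndarray]:
        """Per-bin DNA mass (overlap-weighted) for each haplotype at the
        harvest phase."""
        kar = self.karyotypes[blastomere]
        width = (bins["end"] - bins["start"]).to_numpy(dtype=float)
        out = {h: np.zeros(len(bins)) for h in HAPLOTYPES}
        bstart = bins["start"].to_numpy()
        bend = bins["end"].to_numpy()
        bchrom = bins["chrom"].to_numpy()
        for chrom, segs in kar.segments.items():
            on = bchrom == chrom
            for s in segs:
                ov = np.clip(
                    np.minimum(bend, s.end) - np.maximum(bstart, s.start), 0, None
                )
                ov = np.where(on, ov, 0)
                for h in HAPLOTYPES:
                    out[h] += ov * s.mass(h, self.phase)
        for h in HAPLOTYPES:
            out[h] /= width
        return out

    def point_mass(self, blastomere: str, chrom: str, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Maternal and paternal DNA mass at point positions on one chromosome."""
        segs = self.karyotypes[blastomere].segments[chrom]
        starts = np.array([s.start for s in segs])
        idx = np.searchsorted(starts, pos, side="right") - 1
        m = np.array([s.mass(MATERNAL, self.phase) for s in segs])[idx]
        p = np.array([s.mass(PATERNAL, self.phase) for s in segs])[idx]
        return m, p


def _apply_mitotic(event: EventSpec, left: Karyotype, right: Karyotype,
                   genome: GenomeModel) -> None:
    chrom = event.target_chromosome
    length = genome.lengths[chrom]
    hap = event.affected_haplotype
    cut = event.cut_position
    if event.event_class in CUT_EVENTS and not (0 < cut < length):
        raise ValueError(f"cut_position {cut} outside {chrom} (length {length})")
    if event.event_class == "acentric_missegregation":
        left.adjust(chrom, cut, length, hap, d_nuc=+1)
        right.adjust(chrom, cut, length, hap, d_nuc=-1)
    elif event.event_class == "micronucleus_underreplication":
        # acentric fragment stays with its centric fragment but in a
        # micronucleus: move the nuclear copy into the micronucleus
        left.adjust(chrom, cut, length, hap, d_nuc=-1, d_mn=+1)
    elif event.event_class == "bridge_monosomy":
        # dicentric resolution: right daughter keeps all copies of the cut
        # homolog; left daughter is monosomic for the whole chromosome
        left.adjust(chrom, 0, length, hap, d_nuc=-10**9, d_mn=-10**9)
        right.adjust(chrom, 0, cut, hap, d_nuc=+1)
        if event.acentric_fate == "replicated":
            right.adjust(chrom, cut, length, hap, d_nuc=+1)
        else:
            right.adjust(chrom, cut, length, hap, d_nuc=-1, d_mn=+2)
    elif event.event_class == "whole_chromosome_missegregation":
        left.adjust(chrom, 0, length, hap, d_nuc=+1)
        right.adjust(chrom, 0, length, hap, d_nuc=-1)


def simulate_embryo(
    genome: GenomeModel,
    events: list[EventSpec],
    coverage: CoverageModel,
    phase: str = "G1",
    track: RepliSeqTrack | None = None,
    bin_size: int = 10_000,
    with_svs: bool = True,
) -> tuple[EmbryoGroundTruth, BinCountMatrix, pd.DataFrame, pd.DataFrame]:
    """Run the full generative model for one embryo.

    Returns (ground truth, bin counts, allelic depths, candidate SVs).
    """
    truth = realize_lineage(genome, events, phase=phase)
    rng = np.random.default_rng(coverage.seed)
    counts = simulate_bin_counts(truth, genome, coverage, bin_size=bin_size,
                                 track=track, rng=rng)
    depths = simulate_allelic_depths(truth, genome, coverage, rng=rng)
    svs = simulate_sv_candidates(truth, genome, rng=rng) if with_svs else pd.DataFrame()
    return truth, counts, depths, svs


def realize_lineage(
    genome: GenomeModel, events: list[EventSpec], phase: str = "G1"
) -> EmbryoGroundTruth:
    """Propagate events through a 3-division lineage tree."""
    if phase not in ("G1", "G2"):
        raise ValueError("phase must be 'G1' or 'G2'")
    events = [e for e in events if e.event_class != "none"]
    cut_chroms = [e.target_chromosome for e in events if e.event_class in CUT_EVENTS]
    if len(cut_chroms) != len(set(cut_chroms)):
        raise ValueError("conflicting events: more than one Cas9 cut on one chromosome")
    for e in events:
        if e.event_class in CUT_EVENTS:
            if not (0 < e.cut_position < genome.lengths[e.target_chromosome]):
                raise ValueError(
                    f"cut_position {e.cut_position} outside {e.target_chromosome}"
                )

    zygote = Karyotype(genome)
    for e in events:
        if e.event_class == "digyny":
            for chrom, length in genome.chromosomes:
                zygote.adjust(chrom, 0, length, MATERNAL, d_nuc=+1)
        elif e.event_class == "meiotic_trisomy":
            length = genome.lengths[e.target_chromosome]
            zygote.adjust(e.target_chromosome, 0, length, e.affected_haplotype, d_nuc=+1)

    cells: list[tuple[str, Karyotype]] = [("", zygote)]
    for division in (1, 2, 3):
        todays = [e for e in events
                  if e.event_class in MITOTIC_EVENTS and e.division_index == division]
        nxt: list[tuple[str, Karyotype]] = []
        for idx, (path, kar) in enumerate(cells):
            left, right = kar.clone(), kar.clone()
            for e in todays:
                if e.mother_index % len(cells) == idx:
                    _apply_mitotic(e, left, right, genome)
            nxt.append((path + "L", left))
            nxt.append((path + "R", right))
        cells = nxt

    names = [f"b{i + 1}" for i in range(len(cells))]
    return EmbryoGroundTruth(
        genome=genome,
        blastomeres=names,
        lineage={n: path for n, (path, _) in zip(names, cells)},
        karyotypes={n: kar for n, (_, kar) in zip(names, cells)},
        events=list(events),
        phase=phase,
    )


def simulate_repliseq_track(
    genome: GenomeModel, bin_size: int = 10_000, seed: int = 0, smooth_bins: float = 50.0
) -> RepliSeqTrack:
    """Smooth, autocorrelated early/late replication-timing surrogate.

    White noise is smoothed per chromosome with a Gaussian kernel of
    ``smooth_bins`` bins, then standardized genome-wide and clipped to
    [-3, 3]; positive values = earlier replication.
    """
    bins = genome.bins(bin_size)
    rng = np.random.default_rng(seed)
    vals = np.empty(len(bins))
    for chrom in bins["chrom"].unique():
        on = (bins["chrom"] == chrom).to_numpy()
        vals[on] = gaussian_filter1d(rng.standard_normal(on.sum()), smooth_bins)
    vals = (vals - vals.mean()) / vals.std()
    return RepliSeqTrack(bins=bins, values=np.clip(vals, -3.0, 3.0))


def simulate_bin_counts(
    truth: EmbryoGroundTruth,
    genome: GenomeModel,
    coverage: CoverageModel,
    bin_size: int = 10_000,
    track: RepliSeqTrack | None = None,
    rng: np.random.Generator | None = None,
) -> BinCountMatrix:
    """Draw negative-binomial read counts per bin from the true karyotypes.

    Expected count = mean_depth * bin_width / read_length * DNA mass *
    bias * replication-timing modulation; micronuclear (underreplicated)
    copies contribute half the G2 mass of nuclear ones.
    """
    rng = rng if rng is not None else np.random.default_rng(coverage.seed)
    bins = genome.bins(bin_size)
    width = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    base = coverage.mean_depth * width / coverage.read_length
    bias = np.ones(len(bins))
    if coverage.bias_profile is not None:
        if len(coverage.bias_profile) != len(bins):
            raise ValueError("bias_profile length does not match bin count")
        bias = bias * coverage.bias_profile
    if track is not None and coverage.repli_bias_strength != 0.0:
        t = track.project(bins)
        mod = np.exp(coverage.repli_bias_strength * np.nan_to_num(t))
        bias = bias * (mod / mod.mean())
    cols = {}
    for b in truth.blastomeres:
        masses = truth.mass_arrays(bins, b)
        mu = base * (masses[MATERNAL] + masses[PATERNAL]) * bias
        cols[b] = _nb_draw(rng, mu, coverage.dispersion)
    return BinCountMatrix(bins=bins, counts=pd.DataFrame(cols), bin_size=bin_size)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.clip(mu, 0.0, None)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def simulate_allelic_depths(
    truth: EmbryoGroundTruth,
    genome: GenomeModel,
    coverage: CoverageModel,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-SNP allelic depths: reference reads from the maternal (C57BL/6J)
    haplotype, alternate reads from the paternal (129/SvJae) haplotype,
    each Poisson with mean = mean_depth * haplotype DNA mass.  Optional
    homozygous-reference decoy sites emit reference reads only."""
    rng = rng if rng is not None else np.random.default_rng(coverage.seed)
    frames = []
    panels = [(genome.snp_panel, True)]
    if genome.hom_sites is not None and len(genome.hom_sites):
        panels.append((genome.hom_sites, False))
    for panel, het in panels:
        for chrom, grp in panel.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            for b in truth.blastomeres:
                m_mass, p_mass = truth.point_mass(b, chrom, pos)
                lam_m = coverage.mean_depth * m_mass
                lam_p = coverage.mean_depth * p_mass
                if het:
                    ref = rng.poisson(lam_m)
                    alt = rng.poisson(lam_p)
                else:
                    ref = rng.poisson(lam_m + lam_p)
                    alt = np.zeros(pos.size, dtype=np.int64)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "ref": grp["ref"].to_numpy(),
                            "alt": grp["alt"].to_numpy(),
                            "sample": b,
                            "ref_count": ref,
                            "alt_count": alt,
                        }
                    )
                )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(drop=True)


def simulate_sv_candidates(
    truth: EmbryoGroundTruth,
    genome: GenomeModel,
    rng: np.random.Generator | None = None,
    embryo: str = "E1",
    n_artifacts: int = 20,
    artifact_embryos: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Candidate SV table in a BEDPE-like layout with per-sample tallies.

    Each Cas9 cut event yields a well-supported de novo junction confined
    to the blastomeres that inherited it; artifacts (low support, low
    mapping quality, short span, strain-background, or shared across
    embryos) are sprinkled in to exercise the filter chain.  Columns:
    id, chrom_a, pos_a, strand_a, chrom_b, pos_b, strand_b, support_reads,
    max_mapq, in_strain_background, then ``split:<sample>`` and
    ``disc:<sample>`` tally columns.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    samples = [f"{embryo}.{b}" for b in truth.blastomeres]
    rows = []
    sv_id = 0
    for e in truth.events:
        if e.event_class not in CUT_EVENTS:
            continue
        chrom = e.target_chromosome
        length = genome.lengths[chrom]
        partner = min(e.cut_position + 5_000_000, length - 1)
        carriers = _event_carriers(truth, e)
        tallies = {}
        for b, s in zip(truth.blastomeres, samples):
            hit = b in carriers
            tallies[f"split:{s}"] = int(rng.poisson(6)) + 2 if hit else 0
            tallies[f"disc:{s}"] = int(rng.poisson(4)) + 1 if hit else 0
        rows.append(
            {
                "id": f"sv{sv_id}",
                "chrom_a": chrom, "pos_a": e.cut_position, "strand_a": "+",
                "chrom_b": chrom, "pos_b": partner, "strand_b": "-",
                "support_reads": 3 + int(rng.poisson(8)),
                "max_mapq": 60,
                "in_strain_background": False,
                **tallies,
            }
        )
        sv_id += 1
    chroms = [c for c, _ in genome.chromosomes]
    for _ in range(n_artifacts):
        chrom = chroms[rng.integers(len(chroms))]
        length = genome.lengths[chrom]
        pos_a = int(rng.integers(1, length - 1))
        kind = rng.integers(4)
        support = int(rng.integers(1, 3)) if kind == 0 else 3 + int(rng.integers(10))
        mapq = int(rng.integers(0, 31)) if kind == 1 else 60
        span = int(rng.integers(1_000, 900_000)) if kind == 2 else 2_000_000
        strain = kind == 3
        tallies = {f"{p}:{s}": 0 for s in samples for p in ("split", "disc")}
        hit = samples[rng.integers(len(samples))]
        tallies[f"split:{hit}"] = max(1, support // 2)
        rows.append(
            {
                "id": f"sv{sv_id}",
                "chrom_a": chrom, "pos_a": pos_a, "strand_a": "+",
                "chrom_b": chrom, "pos_b": min(pos_a + span, length - 1), "strand_b": "-",
                "support_reads": support,
                "max_mapq": mapq,
                "in_strain_background": strain,
                **tallies,
            }
        )
        sv_id += 1
    return pd.DataFrame(rows)


def _event_carriers(truth: EmbryoGroundTruth, event: EventSpec) -> set[str]:
    """Blastomeres descended from a daughter altered by the event."""
    div = event.division_index or 1
    carriers = set()
    for b, path in truth.lineage.items():
        prefix = path[: div - 1]
        # rank of the mother cell within its generation (L=0, depth-first order)
        mother_rank = sum((1 if c == "R" else 0) << (div - 2 - i)
                         for i, c in enumerate(prefix)) if prefix else 0
        if mother_rank == event.mother_index % (2 ** (div - 1)):
            carriers.add(b)
    return carriers


# ---------------------------------------------------------------------------
# EdU / DAPI image synthesis


def simulate_edu_image(
    shape: tuple[int, int] = (256, 256),
    pn: tuple[int, int, int] = (110, 128, 55),
    mn: tuple[int, int, int] = (210, 80, 14),
    dapi_rate: float = 2_000.0,
    edu_rate_pn: float = 1_500.0,
    edu_rate_mn: float = 1_500.0,
    background: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Synthesize a two-channel (DAPI, EdU) blastomere image.

    The primary nucleus and micronucleus are uniform discs (``(cy, cx, r)``)
    on a flat background; DAPI intensity tracks DNA density and the EdU
    channel tracks the per-structure replication rate.  Returns a dict with
    ``dapi``/``edu`` uint16 arrays, boolean ground-truth masks and a
    background rectangle (y, x, h, w) guaranteed free of foreground.
    """
    (py, px, pr), (my, mx, mr) = pn, mn
    h, w = shape
    for cy, cx, r, name in ((py, px, pr, "primary"), (my, mx, mr, "micronucleus")):
        if not (r <= cy < h - r and r <= cx < w - r):
            raise ValueError(f"{name} disc outside image bounds")
    if np.hypot(py - my, px - mx) <= pr + mr:
        raise ValueError("primary nucleus and micronucleus overlap")
    yy, xx = np.mgrid[0:h, 0:w]
    pn_mask = (yy - py) ** 2 + (xx - px) ** 2 <= pr**2
    mn_mask = (yy - my) ** 2 + (xx - mx) ** 2 <= mr**2
    dapi = np.full(shape, background, dtype=float)
    edu = np.full(shape, background, dtype=float)
    dapi[pn_mask | mn_mask] += dapi_rate
    edu[pn_mask] += edu_rate_pn
    edu[mn_mask] += edu_rate_mn
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dapi += rng.normal(0, noise_sd, shape)
        edu += rng.normal(0, noise_sd, shape)
    bg = _free_corner(pn_mask | mn_mask, size=32)
    to_u16 = lambda a: np.clip(np.round(a), 0, 65535).astype(np.uint16)
    return {
        "dapi": to_u16(dapi),
        "edu": to_u16(edu),
        "pn_mask": pn_mask,
        "mn_mask": mn_mask,
        "background_region": bg,
    }


def _free_corner(fg: np.ndarray, size: int) -> tuple[int, int, int, int]:
    h, w = fg.shape
    for y, x in ((0, 0), (0, w - size), (h - size, 0), (h - size, w - size)):
        if not fg[y : y + size, x : x + size].any():
            return (y, x, size, size)
    raise ValueError("no background corner free of foreground")
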