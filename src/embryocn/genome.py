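"""Genome model for the hybrid-cross embryo pipeline.

The reference organism is the laboratory mouse: all chromosomes are
telocentric (centromere at coordinate 0), so a double-strand break at
position ``x`` always yields a centric fragment ``[0, x)`` and an acentric
fragment ``[x, length)``.  Embryos come from a C57BL/6J (dam) x 129/SvJae
(sire) cross, so every SNP in the panel is heterozygous with the reference
allele on the maternal (B6) haplotype and the alternate allele on the
paternal (129) haplotype.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MATERNAL = "maternal"  # C57BL/6J, carries the reference allele
PATERNAL = "paternal"  # 129/SvJae, carries the alternate allele
HAPLOTYPES = (MATERNAL, PATERNAL)


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes plus the cross-informative SNP panel.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    snp_panel
        DataFrame with columns ``chrom, pos, ref, alt``; positions strictly
        increasing within each chromosome.  Heterozygous in the cross.
    hom_sites
        Optional DataFrame (same columns) of homozygous-reference decoy
        sites, useful for exercising the informative-SNP filter.
    telocentric
        Per-chromosome flag; mouse autosomes are all telocentric.
    """

    chromosomes: tuple[tuple[str, int], ...]
    snp_panel: pd.DataFrame
    hom_sites: pd.DataFrame | None = None
    telocentric: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if any(length <= 0 for length in lengths.values()):
            raise ValueError("all chromosome lengths must be > 0")
        for chrom, grp in self.snp_panel.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"SNP panel references unknown chromosome {chrom!r}")
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"SNP positions not strictly increasing on {chrom}")
            if pos.min() < 0 or pos.max() >= lengths[chrom]:
                raise ValueError(f"SNP outside chromosome bounds on {chrom}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def is_telocentric(self, chrom: str) -> bool:
        return self.telocentric.get(chrom, True)

    def bins(self, bin_size: int) -> pd.DataFrame:
        """Tile every chromosome with fixed-size bins.

        The trailing bin of each chromosome keeps its true (shorter) end.
        """
        rows = []
        for chrom, length in self.chromosomes:
            starts = np.arange(0, length, bin_size, dtype=np.int64)
            ends = np.minimum(starts + bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


def toy_genome(
    n_chromosomes: int = 3,
    chrom_lengths: tuple[int, ...] | None = None,
    snp_spacing: int = 8_000,
    n_hom_sites: int = 0,
    seed: int = 0,
) -> GenomeModel:
    """Desk-scale genome: a few ~50-60 Mb telocentric chromosomes with a
    dense heterozygous SNP panel (one SNP every ``snp_spacing`` bp with
    jitter).  Full mm10 sizes are supported by :class:`GenomeModel` but not
    needed for testing."""
    if chrom_lengths is None:
        chrom_lengths = tuple(60_000_000 - 5_000_000 * i for i in range(n_chromosomes))
    rng = np.random.default_rng(seed)
    chroms = tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(chrom_lengths))
    bases = np.array(list("ACGT"))
    panel_rows = []
    for chrom, length in chroms:
        pos = np.arange(snp_spacing // 2, length, snp_spacing, dtype=np.int64)
        pos = pos + rng.integers(-snp_spacing // 4, snp_spacing // 4, size=pos.size)
        pos = np.unique(np.clip(pos, 0, length - 1))
        ref_idx = rng.integers(0, 4, size=pos.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4
        panel_rows.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": bases[ref_idx], "alt": bases[alt_idx]}
            )
        )
    panel = pd.concat(panel_rows, ignore_index=True)
    hom = None
    if n_hom_sites > 0:
        take = rng.choice(len(panel), size=min(n_hom_sites, len(panel)), replace=False)
        hom = panel.iloc[np.sort(take)].reset_index(drop=True)
        hom["pos"] = hom["pos"] + 1  # offset so decoys never collide with panel sites
    return GenomeModel(chromosomes=chroms, snp_panel=panel, hom_sites=hom)
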