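"""Plain-text readers and writers for the pipeline's tables.

All files are TSV with a header; genomic intervals are 0-based, half-open,
stated in a leading comment line of every file this module writes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .depth import BinCountMatrix, NormalizedCNMatrix, RepliSeqTrack

COORD_COMMENT = "# coordinates: 0-based, half-open\n"


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bin_counts(counts: BinCountMatrix, path: str | Path) -> None:
    """Long TSV: sample, chrom, start, end, count."""
    long = counts.bins.join(counts.counts).melt(
        id_vars=["chrom", "start", "end"], var_name="sample", value_name="count"
    )
    _write_tsv(long[["sample", "chrom", "start", "end", "count"]], path)


def read_bin_counts(path: str | Path) -> BinCountMatrix:
    long = _read_tsv(path)
    wide = long.pivot_table(
        index=["chrom", "start", "end"], columns="sample", values="count",
        aggfunc="first", sort=False,
    )
    bins = wide.index.to_frame(index=False)
    order = np.lexsort((bins["start"], bins["chrom"]))
    bins = bins.iloc[order].reset_index(drop=True)
    mat = wide.reset_index(drop=True).iloc[order].reset_index(drop=True)
    mat.columns.name = None
    size = int((bins["end"] - bins["start"]).max())
    return BinCountMatrix(bins=bins, counts=mat.astype(np.int64), bin_size=size)


def write_allelic_depths(depths: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(depths, path)


read_allelic_depths = _read_tsv


def write_repliseq(track: RepliSeqTrack, path: str | Path) -> None:
    """bedGraph-like TSV: chrom, start, end, value."""
    df = track.bins.assign(value=track.values)
    _write_tsv(df, path)


def read_repliseq(path: str | Path) -> RepliSeqTrack:
    df = _read_tsv(path)
    return RepliSeqTrack(bins=df[["chrom", "start", "end"]], values=df["value"].to_numpy())


def write_norm_cn(norm: NormalizedCNMatrix, path: str | Path) -> None:
    df = norm.bins.assign(masked=norm.mask).join(norm.values)
    _write_tsv(df, path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df, path)


read_table = _read_tsv


def write_ground_truth(truth, path: str | Path) -> None:
    """Structured YAML: lineage, events, and the per-blastomere karyotype."""
    import yaml

    doc = {
        "coordinates": "0-based, half-open",
        "phase": truth.phase,
        "lineage": truth.lineage,
        "events": [
            {k: v for k, v in vars(e).items() if v is not None}
            for e in truth.events
        ],
        "karyotypes": truth.table().to_dict(orient="records"),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    import tifffile

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), image)


def read_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))
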