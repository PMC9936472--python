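"""Plain-text readers and writers for every pipeline format.

All tabular files are TSV with an optional block of ``#``-prefixed header
comment lines carrying provenance (seed, parameters).  Coverage is
exchanged as 4-column bedGraph (0-based half-open) and gene annotation as
BED6 with the TSS at ``start`` for + genes and ``end - 1`` for - genes.
Floats are written with a fixed general format so identical data produces
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .occupancy import CoverageTrack

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_bedgraph",
    "read_bedgraph",
    "write_bed6",
    "read_bed6",
    "write_config",
    "read_config",
]

_FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path, header_comments: "list[str] | None" = None,
              index: bool = False) -> None:
    """Write a DataFrame as TSV with optional ``#`` comment header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=_FLOAT_FMT,
                  lineterminator="\n")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_bedgraph(track: CoverageTrack, path,
                   header_comments: "list[str] | None" = None) -> None:
    """Write a dense track as run-length-compressed 4-column bedGraph."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        for chrom in sorted(track.data):
            arr = track.chrom(chrom)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{s}\t{e}\t{_FLOAT_FMT % arr[s]}\n"
                )


def read_bedgraph(path, chrom_lengths: "dict[str, int] | None" = None
                  ) -> CoverageTrack:
    """Read a bedGraph into a dense per-chromosome track.

    Lengths default to the maximum interval end seen per chromosome.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"])
    lengths = dict(chrom_lengths or {})
    for chrom, sub in df.groupby("chrom"):
        lengths.setdefault(chrom, int(sub["end"].max()))
    data = {c: np.zeros(n, dtype=float) for c, n in lengths.items()}
    for chrom, s, e, v in df.itertuples(index=False):
        data[chrom][int(s):int(e)] = float(v)
    return CoverageTrack(data)


def write_bed6(annotation: pd.DataFrame, path, gene_length: int = 1000) -> None:
    """Write gene annotation (gene, chrom, tss, strand) as BED6."""
    with open(Path(path), "w") as fh:
        for _, g in annotation.iterrows():
            if g["strand"] == "+":
                start, end = int(g["tss"]), int(g["tss"]) + gene_length
            else:
                end = int(g["tss"]) + 1
                start = max(end - gene_length, 0)
            fh.write(f"{g['chrom']}\t{start}\t{end}\t{g['gene']}\t0\t"
                     f"{g['strand']}\n")


def read_bed6(path) -> pd.DataFrame:
    """Read BED6 into the annotation frame (TSS derived from strand)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "gene", "score",
                            "strand"])
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"invalid strand value(s) at line(s) {list(df.index[bad] + 1)}"
        )
    tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return pd.DataFrame(
        {"gene": df["gene"], "chrom": df["chrom"], "tss": tss,
         "strand": df["strand"]}
    )


def write_config(params: dict, path) -> None:
    """Write a flat key=value config file (sorted keys, lossless round-trip)."""
    with open(Path(path), "w") as fh:
        for key in sorted(params):
            fh.write(f"{key} = {params[key]!r}\n")


def read_config(path) -> dict:
    """Read a key=value config written by :func:`write_config`."""
    import ast

    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        out[key.strip()] = ast.literal_eval(raw.strip())
    return out
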