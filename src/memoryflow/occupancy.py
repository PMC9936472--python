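"""TSS-relative, strand-aware coverage features and CRAC normalization.

Region features are defined in transcription-direction offsets around each
gene's transcription start site (TSS), 0-based half-open:

* ``promoter_sense``    [-150, -50)  read on the gene's own strand
* ``promoter_antisense``[-150, +50)  read on the opposite strand
* ``plus1_nucleosome``  [0, +150)    unstranded (both strands summed)
* ``ndr``               [-150, 0)    unstranded

Offsets map to genomic coordinates as TSS+o on the + strand and TSS-o on
the - strand.  Coverage is consumed as dense per-base tracks (bedGraph in,
counts-per-million scale).  Metagene profiles align per-gene windows on the
TSS in transcription direction, average across genes and smooth with a
centered 5-bp moving mean.

CRAC occupancy: per-gene factor counts are library-normalized and divided
by the equally normalized RNA Pol II counts, after discarding genes with
fewer than 20 counts, giving a per-gene association score relative to
polymerase engagement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .turnover import group_shift_test

__all__ = [
    "REGIONS",
    "RegionSpec",
    "CoverageTrack",
    "region_coords",
    "mean_region_coverage",
    "condition_ratio",
    "metagene_profile",
    "crac_normalize",
    "group_compare_scores",
    "OccupancyAnalysis",
]


@dataclass(frozen=True)
class RegionSpec:
    """A TSS-relative offset window and the strand rule used to read it."""

    name: str
    start_offset: int  # inclusive, transcription-direction offset
    end_offset: int    # exclusive
    strand_rule: str   # "sense" | "antisense" | "unstranded"

    def __post_init__(self):
        if self.start_offset >= self.end_offset:
            raise ValueError("region window start must be < end")


REGIONS = {
    "promoter_sense": RegionSpec("promoter_sense", -150, -50, "sense"),
    "promoter_antisense": RegionSpec("promoter_antisense", -150, 50, "antisense"),
    "plus1_nucleosome": RegionSpec("plus1_nucleosome", 0, 150, "unstranded"),
    "ndr": RegionSpec("ndr", -150, 0, "unstranded"),
}


@dataclass
class CoverageTrack:
    """Dense per-base coverage per chromosome (one strand, cpm scale)."""

    data: dict[str, np.ndarray] = field(default_factory=dict)

    def chrom(self, name: str) -> np.ndarray:
        return self.data[name]

    def __eq__(self, other):
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return set(self.data) == set(other.data) and all(
            np.array_equal(self.data[c], other.data[c]) for c in self.data
        )


def region_coords(
    gene: pd.Series, spec: RegionSpec, chrom_length: int | None = None
) -> tuple[str, int, int, str]:
    """Genomic half-open interval for a TSS-relative region of one gene.

    ``gene`` carries ``chrom, tss, strand`` (TSS 0-based; strand + or -).
    Offsets o in [a, b) map to TSS+o on the + strand and TSS-o on the -
    strand, then the position set is expressed half-open.  Returns
    (chrom, start, end, strand_to_read) where strand_to_read is '+', '-',
    or '.' for unstranded regions.  Intervals reaching past the chromosome
    edge are clipped with a warning when ``chrom_length`` is given.
    """
    strand = gene["strand"]
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    tss = int(gene["tss"])
    a, b = spec.start_offset, spec.end_offset
    if strand == "+":
        start, end = tss + a, tss + b
    else:
        # offsets a..b-1 map to tss-a .. tss-(b-1): interval [tss-b+1, tss-a+1)
        start, end = tss - b + 1, tss - a + 1

    if spec.strand_rule == "sense":
        read_strand = strand
    elif spec.strand_rule == "antisense":
        read_strand = "-" if strand == "+" else "+"
    else:
        read_strand = "."

    clipped_start, clipped_end = start, end
    if start < 0:
        clipped_start = 0
    if chrom_length is not None and end > chrom_length:
        clipped_end = chrom_length
    if (clipped_start, clipped_end) != (start, end):
        warnings.warn(
            f"region {spec.name} of gene {gene.get('gene', '?')} clipped to "
            f"[{clipped_start}, {clipped_end})",
            stacklevel=2,
        )
    return gene["chrom"], clipped_start, clipped_end, read_strand


def mean_region_coverage(
    track: CoverageTrack, chrom: str, start: int, end: int
) -> float:
    """Arithmetic mean per-base coverage over [start, end); NaN when empty."""
    arr = track.chrom(chrom)
    start = max(start, 0)
    end = min(end, arr.size)
    if end <= start:
        return float("nan")
    return float(arr[start:end].mean())


def condition_ratio(cov_primed: float, cov_naive: float,
                    pseudo: float = 0.01) -> float:
    """Primed/naive coverage ratio with a pseudocount guard:
    (cov_primed + pseudo) / (cov_naive + pseudo)."""
    if cov_primed < 0 or cov_naive < 0:
        raise ValueError("coverage must be non-negative")
    return (cov_primed + pseudo) / (cov_naive + pseudo)


def _smooth_centered(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving mean with edge truncation (window shrinks at edges)."""
    if width <= 1:
        return x.copy()
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def metagene_profile(
    tracks: "CoverageTrack | dict[str, CoverageTrack]",
    annotation: pd.DataFrame,
    flank: int = 500,
    smooth_bp: int = 5,
) -> pd.DataFrame:
    """TSS-aligned average coverage profile across genes.

    ``tracks`` is either a single (unstranded) track or ``{'+': ..., '-':
    ...}``, in which case each gene reads its own strand's track.  Windows
    span offsets [-flank, flank) in transcription direction; genes whose
    window exits the chromosome are excluded (their number is reported in
    the ``n_excluded`` attribute of the returned frame).  The cross-gene
    mean is smoothed with a centered ``smooth_bp`` moving mean.

    Returns a DataFrame with columns ``offset`` and ``mean``.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    stranded = isinstance(tracks, dict)
    rows = []
    n_excluded = 0
    for _, gene in annotation.iterrows():
        track = tracks[gene["strand"]] if stranded else tracks
        arr = track.chrom(gene["chrom"])
        tss = int(gene["tss"])
        if gene["strand"] == "+":
            start, end = tss - flank, tss + flank
            if start < 0 or end > arr.size:
                n_excluded += 1
                continue
            rows.append(arr[start:end])
        else:
            # offset o reads position tss - o; offsets -flank..flank-1
            start, end = tss - flank + 1, tss + flank + 1
            if start < 0 or end > arr.size:
                n_excluded += 1
                continue
            rows.append(arr[start:end][::-1])
    if not rows:
        raise ValueError("no gene with a complete window")
    mean = np.mean(rows, axis=0)
    out = pd.DataFrame(
        {"offset": np.arange(-flank, flank),
         "mean": _smooth_centered(mean, smooth_bp)}
    )
    out.attrs["n_excluded"] = n_excluded
    out.attrs["n_genes"] = len(rows)
    return out


def crac_normalize(
    table: pd.DataFrame,
    factor_col: str = "factor_count",
    polii_col: str = "polii_count",
    min_counts: int = 20,
    filter_both: bool = True,
) -> pd.Series:
    """Per-gene CRAC association score relative to RNA Pol II.

    score_g = (factor_g / total factor) / (polII_g / total polII), computed
    over genes passing the minimum-count filter.  By default a gene needs
    >= ``min_counts`` in *both* libraries (``filter_both=False`` applies the
    filter to the factor library only).
    """
    t = table.set_index("gene") if "gene" in table.columns else table
    f = t[factor_col].astype(float)
    p = t[polii_col].astype(float)
    if (f < 0).any() or (p < 0).any():
        raise ValueError("negative counts")
    keep = f >= min_counts
    if filter_both:
        keep &= p >= min_counts
    f, p = f[keep], p[keep]
    if f.empty:
        raise ValueError("no gene passes the count filter")
    score = (f / f.sum()) / (p / p.sum())
    return score.rename("association_score")


def group_compare_scores(
    scores: pd.Series, groups: dict[str, "list[str]"]
) -> pd.DataFrame:
    """Pairwise rank-sum comparison of association scores between gene groups.

    Delegates to :func:`memoryflow.turnover.group_shift_test`; returns one
    row per unordered group pair with the U statistic and two-sided p.
    """
    names = list(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            u, p = group_shift_test(scores, groups[a], groups[b])
            rows.append({"group_a": a, "group_b": b, "statistic": u, "p": p})
    return pd.DataFrame(rows)


class OccupancyAnalysis:
    """Convenience wrapper: region features for a gene annotation over
    strand-specific coverage tracks.

    Parameters
    ----------
    plus, minus : CoverageTrack
        Per-strand dense coverage (cpm).
    annotation : DataFrame
        Columns ``gene, chrom, tss, strand`` (one row per gene).
    """

    def __init__(self, plus: CoverageTrack, minus: CoverageTrack,
                 annotation: pd.DataFrame):
        self.plus = plus
        self.minus = minus
        self.annotation = annotation

    def _track_for(self, read_strand: str):
        if read_strand == "+":
            return [self.plus]
        if read_strand == "-":
            return [self.minus]
        return [self.plus, self.minus]

    def region_means(self, regions: "list[str] | None" = None) -> pd.DataFrame:
        """Mean coverage per gene and region (unstranded regions sum both
        strand tracks)."""
        specs = [REGIONS[r] for r in (regions or REGIONS)]
        rows = []
        for _, gene in self.annotation.iterrows():
            chrom_len = self.plus.chrom(gene["chrom"]).size
            for spec in specs:
                chrom, start, end, read_strand = region_coords(
                    gene, spec, chrom_length=chrom_len
                )
                vals = [
                    mean_region_coverage(t, chrom, start, end)
                    for t in self._track_for(read_strand)
                ]
                rows.append(
                    {"gene": gene["gene"], "region": spec.name,
                     "mean_cpm": float(np.sum(vals))}
                )
        return pd.DataFrame(rows)

    def metagene(self, flank: int = 500, smooth_bp: int = 5,
                 stranded: bool = False) -> pd.DataFrame:
        """Combined-strand (default) or sense-strand metagene profile."""
        if stranded:
            tracks = {"+": self.plus, "-": self.minus}
        else:
            combined = CoverageTrack(
                {c: self.plus.chrom(c) + self.minus.chrom(c)
                 for c in self.plus.data}
            )
            tracks = combined
        return metagene_profile(tracks, self.annotation, flank=flank,
                                smooth_bp=smooth_bp)
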