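"""Memory gene classification from RNA-seq time courses.

Cells are sampled along a galactose induction in the naive state (t0, t30,
t60, t180), returned to glucose (t0'), and re-induced in the primed state
(t15', t30', t60').  All log2 fold changes (lfc) are taken against naive t0
of the same strain.  A gene shows *induction memory* when it is induced and
its primed-state response exceeds the naive response by more than 1.5-fold
at 30 or 60 minutes; *repression memory* is the mirrored rule.  The
gene-level memory index is

    TM_score = lfc(t15') - lfc(t180)

i.e. the early primed response relative to the late naive maximum, and the
effect of a mutant strain on a gene's memory is judged by
dTM = TM_mutant - TM_wildtype against a +/-0.58 band.

The differential-expression engine here is a light negative-binomial Wald
test (method-of-moments dispersion, t reference with pooled df); externally
produced lfc tables (e.g. from DESeq2) can be supplied instead through
:meth:`ExpressionMemoryModel.from_lfc_table`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NAIVE_TIMEPOINTS",
    "PRIMED_TIMEPOINTS",
    "TIMEPOINTS",
    "CATEGORIES",
    "normalize_by_coding_sum",
    "estimate_lfc",
    "classify_base",
    "classify_memory",
    "tm_score",
    "mutant_effect",
    "eight_category_label",
    "hypergeometric_overlap",
    "benjamini_hochberg",
    "ExpressionMemoryModel",
    "ExpressionMemoryResults",
]

NAIVE_TIMEPOINTS = ("t0", "t30", "t60", "t180")
PRIMED_TIMEPOINTS = ("t0'", "t15'", "t30'", "t60'")
TIMEPOINTS = NAIVE_TIMEPOINTS + PRIMED_TIMEPOINTS
REFERENCE_TIMEPOINT = "t0"

CATEGORIES = (
    "induction memory enhanced in mutant",
    "induction memory unchanged in mutant",
    "induction memory attenuated in mutant",
    "induced no memory",
    "repressed no memory",
    "repression memory attenuated in mutant",
    "repression memory unchanged in mutant",
    "repression memory enhanced in mutant",
    "no-change",
)


def normalize_by_coding_sum(
    counts: pd.DataFrame, coding: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize a genes x samples count matrix by the coding-transcriptome sum.

    Size factor of sample s = (coding sum of s) / (geometric mean of coding
    sums); normalized count = count / size factor.  After scaling, every
    sample has the same coding sum.
    """
    coding = coding.reindex(counts.index).fillna(False).astype(bool)
    if not coding.any():
        raise ValueError("no coding gene flagged")
    sums = counts.loc[coding].sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero coding sum in sample(s): {list(zero.index)}")
    size_factors = sums / np.exp(np.mean(np.log(sums)))
    return counts / size_factors, size_factors


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def estimate_lfc(
    normalized: pd.DataFrame,
    sample_info: pd.DataFrame,
    timepoint: str,
    strain: str | None = None,
    pseudocount: float = 0.5,
    min_dispersion: float = 1e-8,
    dispersion: str = "pooled",
) -> pd.DataFrame:
    """Per-gene lfc and Wald p for one timepoint vs the naive t0 reference.

    lfc = log2((mean_t + pseudocount) / (mean_ref + pseudocount)).  The p
    value comes from a negative-binomial Wald test on the log2 means.  With
    ``dispersion="pooled"`` (default) one method-of-moments dispersion is
    shared across all genes of the contrast — information sharing in the
    spirit of DESeq2, which is what makes small-replicate designs able to
    reach small p — and the reference is normal.  ``"per_gene"`` keeps each
    gene's own (noisy) estimate with a t reference on n1+n2-2 df.  The
    dispersion is floored at ``min_dispersion``; padj is
    Benjamini-Hochberg within the contrast.  With a single replicate in
    either group the lfc is returned and p is NaN.
    """
    info = sample_info
    if strain is not None:
        info = info[info["strain"] == strain]
    ref_samples = info.loc[info["timepoint"] == REFERENCE_TIMEPOINT, "sample"]
    tp_samples = info.loc[info["timepoint"] == timepoint, "sample"]
    if len(ref_samples) == 0 or len(tp_samples) == 0:
        raise ValueError(f"missing samples for {timepoint!r} vs reference")

    a = normalized[list(tp_samples)].to_numpy(dtype=float)
    b = normalized[list(ref_samples)].to_numpy(dtype=float)
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    lfc = np.log2((ma + pseudocount) / (mb + pseudocount))

    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        p = np.full(lfc.shape, np.nan)
    else:
        def _alpha_raw(x, m):
            # untruncated moment estimate (v - m) / m^2; negative values
            # carry information and are only clipped after pooling
            v = x.var(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2,
                                np.nan)

        da, db = _alpha_raw(a, ma), _alpha_raw(b, mb)
        if dispersion == "pooled":
            per_gene = np.nanmean(np.vstack([da, db]), axis=0)
            alpha = max(float(np.nanmean(per_gene)), min_dispersion)
        elif dispersion == "per_gene":
            alpha = np.maximum(
                np.maximum(np.nan_to_num(da), np.nan_to_num(db)),
                min_dispersion,
            )
        else:
            raise ValueError(f"unknown dispersion mode {dispersion!r}")
        var_ma = (ma + alpha * ma**2) / n1
        var_mb = (mb + alpha * mb**2) / n2
        ln2sq = np.log(2.0) ** 2
        se = np.sqrt(
            var_ma / np.maximum(ma + pseudocount, pseudocount) ** 2 / ln2sq
            + var_mb / np.maximum(mb + pseudocount, pseudocount) ** 2 / ln2sq
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf))
        if dispersion == "pooled":
            p = 2.0 * stats.norm.sf(np.abs(tstat))
        else:
            p = 2.0 * stats.t.sf(np.abs(tstat), df=n1 + n2 - 2)

    return pd.DataFrame(
        {
            "gene": normalized.index,
            "timepoint": timepoint,
            "lfc": lfc,
            "pvalue": p,
            "padj": benjamini_hochberg(p),
        }
    )


def _wide(lfc_table: pd.DataFrame, field: str) -> pd.DataFrame:
    return lfc_table.pivot(index="gene", columns="timepoint", values=field)


def classify_base(lfc_table: pd.DataFrame, alpha: float = 0.001) -> pd.Series:
    """Assign induced / repressed / no-change per gene.

    Induced: lfc(t180) > 0, lfc(t60') > 0, lfc(t180) > lfc(t60),
    lfc(t180) > lfc(t30), and padj < alpha at both the t180 and t60'
    contrasts.  Repressed is the mirrored rule.  All inequalities strict.
    """
    lfc = _wide(lfc_table, "lfc")
    padj = _wide(lfc_table, "padj")
    needed = {"t30", "t60", "t180", "t30'", "t60'"}
    missing = needed - set(lfc.columns)
    if missing:
        raise ValueError(f"missing timepoint(s) in lfc table: {sorted(missing)}")

    sig = (padj["t180"] < alpha) & (padj["t60'"] < alpha)
    induced = (
        (lfc["t180"] > 0) & (lfc["t60'"] > 0)
        & (lfc["t180"] > lfc["t60"]) & (lfc["t180"] > lfc["t30"]) & sig
    )
    repressed = (
        (lfc["t180"] < 0) & (lfc["t60'"] < 0)
        & (lfc["t180"] < lfc["t60"]) & (lfc["t180"] < lfc["t30"]) & sig
    )
    out = pd.Series("no-change", index=lfc.index, name="base")
    out[induced] = "induced"
    out[repressed] = "repressed"
    return out


def classify_memory(
    lfc_table: pd.DataFrame, base: pd.Series, ratio: float = 1.5
) -> pd.Series:
    """Memory flag per gene (NaN-like pd.NA for no-change genes).

    Induction memory: base induced and lfc(t30')-lfc(t30) > log2(ratio) or
    lfc(t60')-lfc(t60) > log2(ratio).  Repression memory mirrors with < -log2.
    Strict inequalities: a difference exactly at the threshold is not memory.
    """
    lfc = _wide(lfc_table, "lfc")
    thr = np.log2(ratio)
    d30 = lfc["t30'"] - lfc["t30"]
    d60 = lfc["t60'"] - lfc["t60"]
    mem_ind = (d30 > thr) | (d60 > thr)
    mem_rep = (d30 < -thr) | (d60 < -thr)
    base = base.reindex(lfc.index)
    out = pd.Series(pd.NA, index=lfc.index, dtype="object", name="memory")
    out[base == "induced"] = mem_ind[base == "induced"]
    out[base == "repressed"] = mem_rep[base == "repressed"]
    return out


def tm_score(lfc_table: pd.DataFrame) -> pd.Series:
    """TM_score = lfc(t15') - lfc(t180) per gene (NaN when either missing)."""
    lfc = _wide(lfc_table, "lfc")
    if "t15'" not in lfc.columns or "t180" not in lfc.columns:
        raise ValueError("TM_score needs the t15' and t180 contrasts")
    return (lfc["t15'"] - lfc["t180"]).rename("tm_score")


def mutant_effect(
    tm_wt: "float | pd.Series",
    tm_mut: "float | pd.Series",
    base: "str | pd.Series",
    delta: float = 0.58,
):
    """Classify the mutant's effect on a gene's memory from dTM = tm_mut - tm_wt.

    Induced genes: enhanced iff dTM > delta; attenuated iff dTM < -delta.
    Repressed genes: enhanced iff dTM < -delta; attenuated iff dTM > delta.
    Otherwise unchanged.  Strict inequalities; dTM exactly at +/-delta is
    unchanged.
    """
    scalar = np.isscalar(tm_wt) or isinstance(tm_wt, float)
    tm_wt = pd.Series(tm_wt) if scalar else tm_wt
    tm_mut = pd.Series(tm_mut) if np.isscalar(tm_mut) else tm_mut
    base_s = pd.Series(base, index=tm_wt.index) if isinstance(base, str) else base
    if (base_s == "no-change").any():
        raise ValueError("mutant_effect undefined for no-change genes")
    dtm = tm_mut - tm_wt
    out = pd.Series("unchanged", index=tm_wt.index, dtype="object")
    ind = base_s == "induced"
    rep = base_s == "repressed"
    out[ind & (dtm > delta)] = "enhanced"
    out[ind & (dtm < -delta)] = "attenuated"
    out[rep & (dtm < -delta)] = "enhanced"
    out[rep & (dtm > delta)] = "attenuated"
    if scalar:
        return out.iloc[0]
    return out.rename("effect")


def eight_category_label(base: str, memory, effect: "str | None") -> str:
    """Map (base, memory flag, mutant effect) to one of the nine categories."""
    if base == "no-change":
        return "no-change"
    if base not in ("induced", "repressed"):
        raise ValueError(f"unknown base class {base!r}")
    if memory is pd.NA or memory is None:
        raise ValueError("memory flag required for induced/repressed genes")
    kind = "induction" if base == "induced" else "repression"
    if not memory:
        return f"{base} no memory"
    if effect not in ("enhanced", "unchanged", "attenuated"):
        raise ValueError(f"invalid mutant effect {effect!r} for a memory gene")
    return f"{kind} memory {effect} in mutant"


def hypergeometric_overlap(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric p of the overlap of two gene sets.

    P(X >= |a & b|) with X ~ Hypergeom(N=|universe|, K=|a|, n=|b|).
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))


class ExpressionMemoryModel:
    """Memory classification of a two-strain RNA-seq induction time course.

    Parameters
    ----------
    counts : DataFrame
        Raw genes x samples counts.
    sample_info : DataFrame
        Columns ``sample, strain, state, timepoint, replicate``.
    coding : Series
        Boolean coding-gene flag indexed by gene.
    wildtype, mutant : str
        Strain labels; TM_score comparison is mutant minus wildtype.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        sample_info: pd.DataFrame,
        coding: pd.Series,
        wildtype: str = "wildtype",
        mutant: str = "mutant",
    ):
        self.counts = counts
        self.sample_info = sample_info
        self.coding = coding
        self.wildtype = wildtype
        self.mutant = mutant
        self._lfc_tables: dict[str, pd.DataFrame] | None = None

    @classmethod
    def from_lfc_table(
        cls, lfc_table: pd.DataFrame, wildtype: str = "wildtype",
        mutant: str = "mutant",
    ) -> "ExpressionMemoryModel":
        """Build the model from an externally computed lfc table.

        ``lfc_table`` is long format with columns
        ``gene, strain, timepoint, lfc, padj`` (e.g. exported from DESeq2).
        """
        obj = cls(pd.DataFrame(), pd.DataFrame(), pd.Series(dtype=bool),
                  wildtype, mutant)
        tables = {}
        for strain, sub in lfc_table.groupby("strain"):
            t = sub[["gene", "timepoint", "lfc", "padj"]].copy()
            t["pvalue"] = np.nan
            tables[strain] = t
        obj._lfc_tables = tables
        return obj

    def _compute_lfc_tables(self, pseudocount: float) -> dict[str, pd.DataFrame]:
        normalized, self.size_factors_ = normalize_by_coding_sum(
            self.counts, self.coding
        )
        tables = {}
        for strain in (self.wildtype, self.mutant):
            rows = []
            for tp in TIMEPOINTS:
                if tp == REFERENCE_TIMEPOINT:
                    continue
                info = self.sample_info[self.sample_info["strain"] == strain]
                if not (info["timepoint"] == tp).any():
                    continue
                rows.append(
                    estimate_lfc(normalized, self.sample_info, tp,
                                 strain=strain, pseudocount=pseudocount)
                )
            tables[strain] = pd.concat(rows, ignore_index=True)
        return tables

    def fit(
        self,
        alpha: float = 0.001,
        ratio: float = 1.5,
        delta: float = 0.58,
        pseudocount: float = 0.5,
        require_memory_flag: bool = True,
    ) -> "ExpressionMemoryResults":
        """Classify every gene and score the mutant's effect on memory.

        The base class (induced/repressed/no-change) is taken from the
        wildtype strain; the memory flag is set when either strain passes
        the log2(ratio) rule (``require_memory_flag`` keeps the effect
        categories restricted to such genes).
        """
        if self._lfc_tables is None:
            self._lfc_tables = self._compute_lfc_tables(pseudocount)
        lfc_wt = self._lfc_tables[self.wildtype]
        lfc_mut = self._lfc_tables[self.mutant]

        def _as_bool(s: pd.Series) -> pd.Series:
            return s.apply(lambda v: v is not pd.NA and bool(v))

        base = classify_base(lfc_wt, alpha=alpha)
        mem_wt = _as_bool(classify_memory(lfc_wt, base, ratio=ratio))
        mem_mut = _as_bool(classify_memory(lfc_mut, base, ratio=ratio))
        changed = base != "no-change"
        memory = pd.Series(pd.NA, index=base.index, dtype="object",
                           name="memory")
        memory[changed] = (mem_wt | mem_mut)[changed].astype(bool)

        tm_wt = tm_score(lfc_wt)
        tm_mut = tm_score(lfc_mut).reindex(tm_wt.index)
        dtm = (tm_mut - tm_wt).rename("delta_tm")

        effects = pd.Series(pd.NA, index=base.index, dtype="object")
        if changed.any():
            eff_all = mutant_effect(tm_wt[changed], tm_mut[changed],
                                    base[changed], delta=delta)
            has_mem = memory[changed].astype(bool)
            if require_memory_flag:
                effects[changed] = eff_all.where(has_mem, pd.NA)
            else:
                effects[changed] = eff_all

        kind = base.map({"induced": "induction", "repressed": "repression"})
        labels = pd.Series("no-change", index=base.index)
        mem_mask = changed & _as_bool(memory)
        nomem_mask = changed & ~_as_bool(memory)
        labels[nomem_mask] = base[nomem_mask] + " no memory"
        labels[mem_mask] = (
            kind[mem_mask] + " memory " + effects[mem_mask].astype(str)
            + " in mutant"
        )

        annotation = pd.DataFrame(
            {
                "base": base,
                "memory": memory,
                "tm_wt": tm_wt,
                "tm_mut": tm_mut,
                "delta_tm": dtm,
                "effect": effects,
                "label": labels,
            }
        )
        return ExpressionMemoryResults(self, annotation, self._lfc_tables,
                                       alpha, ratio, delta)


class ExpressionMemoryResults:
    """Gene-level memory annotation and per-strain lfc tables."""

    def __init__(self, model, annotation, lfc_tables, alpha, ratio, delta):
        self.model = model
        self.annotation = annotation
        self.lfc_tables = lfc_tables
        self.alpha = alpha
        self.ratio = ratio
        self.delta = delta

    def category_counts(self) -> pd.Series:
        counts = self.annotation["label"].value_counts()
        return counts.reindex(CATEGORIES, fill_value=0)

    def summary(self) -> str:
        counts = self.category_counts()
        lines = [
            "Transcriptional memory gene classification",
            "=" * 45,
            f"genes                 {len(self.annotation)}",
            f"padj threshold        {self.alpha}",
            f"memory ratio          {self.ratio} (log2 = {np.log2(self.ratio):.3f})",
            f"dTM band              +/-{self.delta}",
            "",
        ]
        lines += [f"{name:45s} {int(n):6d}" for name, n in counts.items()]
        return "\n".join(lines)
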