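"""Pooled FACS/barcode screen statistics for transcriptional memory.

The screen follows a pooled, barcoded yeast deletion collection carrying a
galactose-inducible GFP reporter through two rounds of galactose induction.
Cells are FACS-sorted into four GFP gates (R5 = no expression .. R8 = high
expression) at each timepoint and strain barcodes are sequenced per gate.

For a given strain and GFP window, the change in barcode abundance relative
to pooled wildtype controls across a timepoint transition is modelled with a
quasibinomial GLM (logit link)::

    logit( Counts_strain / (Counts_strain + Counts_wildtype) )
        ~ biological_replicate + timepoint

The timepoint coefficient is the log odds-ratio of the strain-vs-wildtype
composition across the transition.  A strain has altered transcriptional
memory when its response across the primed transition (beta_2) differs from
the naive transition (beta_1); per window this is scored as

    z = (beta_1 - beta_2) / sqrt(se_1 + se_2)

with the standard errors inflated by the square root of the Pearson
dispersion (quasibinomial).  Per-window z-scores are combined with a
weighted Stouffer statistic on |z| (weights = FACS sorted-cell counts), and
a strain is only called when the per-window z signs, read in gate order
R5..R8, change at most once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TransitionFit",
    "MemoryCall",
    "filter_abundant_strains",
    "fit_transition_glm",
    "memory_z",
    "combine_windows_stouffer",
    "sign_change_filter",
    "call_memory_strains",
    "gfp_score",
    "ScreenMemoryModel",
    "ScreenMemoryResults",
]

WINDOW_ORDER = ("R5", "R6", "R7", "R8")
GFP_WINDOW_SCORES = {"R5": 1.0, "R6": 2.0, "R7": 3.0, "R8": 4.0}

#: cap on |beta| used when the MLE is infinite (complete separation)
_BETA_CAP = 15.0


@dataclass
class TransitionFit:
    """Timepoint coefficient of a strain-vs-wildtype transition GLM.

    Attributes
    ----------
    beta : float
        Log odds-ratio of the strain/wildtype composition between the two
        transition timepoints (dimensionless).
    se : float
        Standard error of ``beta``, already scaled by
        ``sqrt(max(dispersion, 1))`` (see ``floor_dispersion``).
    dispersion : float
        Pearson X²/df_resid estimate; 1.0 when df_resid <= 0.
    df_resid : int
    converged : bool
        False when complete separation forced a capped estimate.
    """

    beta: float
    se: float
    dispersion: float
    df_resid: int
    converged: bool = True
    #: unscaled (binomial-model) standard error, kept so that a dispersion
    #: estimate pooled across many fits can be applied instead
    se_unscaled: float = float("nan")

    def rescaled(self, dispersion: float, floor: bool = True) -> "TransitionFit":
        """Return a copy whose se uses the given (e.g. pooled) dispersion."""
        scale = max(dispersion, 1.0) if floor else dispersion
        se0 = self.se_unscaled if np.isfinite(self.se_unscaled) else self.se
        return TransitionFit(
            beta=self.beta, se=float(se0 * np.sqrt(scale)),
            dispersion=dispersion, df_resid=self.df_resid,
            converged=self.converged, se_unscaled=se0,
        )


@dataclass
class MemoryCall:
    strain: str
    z_by_window: dict[str, float]
    stouffer_z: float
    sign_consistent: bool
    direction: str  # "decreased" | "enhanced" | "NA"
    significant: bool
    reason: str = ""


def filter_abundant_strains(
    counts: pd.DataFrame, min_mean: float = 5.0
) -> pd.DataFrame:
    """Keep strains whose mean raw count across all samples is > ``min_mean``.

    ``counts`` is the long-format barcode table with columns
    ``strain, timepoint, window, replicate, count`` (extra columns pass
    through).  The mean is over every (timepoint, window, replicate) sample
    in the table, with missing cells counted as zero.
    """
    n_samples = (
        counts[["timepoint", "window", "replicate"]].drop_duplicates().shape[0]
    )
    totals = counts.groupby("strain", sort=False)["count"].sum()
    means = totals / n_samples
    keep = means.index[means > min_mean]
    if len(keep) == 0:
        warnings.warn("no strain passes the abundance filter", stacklevel=2)
    return counts[counts["strain"].isin(keep)].copy()


def _closed_form_two_cell(sa: float, wa: float, sb: float, wb: float) -> TransitionFit:
    """Saturated single-replicate fit: beta is the closed-form log odds-ratio.

    Haldane–Anscombe 0.5 correction is applied only when a cell is zero.
    """
    cells = [sa, wa, sb, wb]
    if any(c == 0 for c in cells):
        cells = [c + 0.5 for c in cells]
        converged = False
    else:
        converged = True
    sa_, wa_, sb_, wb_ = cells
    beta = float(np.log((sb_ / wb_) / (sa_ / wa_)))
    se = float(np.sqrt(1.0 / sa_ + 1.0 / wa_ + 1.0 / sb_ + 1.0 / wb_))
    beta = float(np.clip(beta, -_BETA_CAP, _BETA_CAP))
    return TransitionFit(beta=beta, se=se, dispersion=1.0, df_resid=0,
                         converged=converged, se_unscaled=se)


def fit_transition_glm(
    strain_counts: pd.DataFrame,
    wildtype_counts: pd.DataFrame,
    transition: tuple[str, str],
    floor_dispersion: bool = True,
) -> TransitionFit:
    """Fit the strain-vs-wildtype transition GLM for one GFP window.

    Parameters
    ----------
    strain_counts, wildtype_counts : DataFrame
        Columns ``timepoint, replicate, count`` restricted to one window;
        wildtype counts are typically the pooled control strains.
    transition : (tp_a, tp_b)
        The two ordered timepoint labels; ``beta`` is the log-odds change
        from tp_a to tp_b.
    floor_dispersion : bool
        When True (default) the SE scaling uses ``max(dispersion, 1)`` so
        underdispersion never shrinks the error estimate.

    Replicates where strain+wildtype counts are both zero at a timepoint are
    dropped with a warning.  Complete separation returns ``converged=False``
    with ``|beta|`` capped at 15.
    """
    tp_a, tp_b = transition
    s = strain_counts.set_index(["timepoint", "replicate"])["count"]
    w = wildtype_counts.groupby(["timepoint", "replicate"])["count"].sum()

    reps = sorted(
        set(strain_counts["replicate"]) & set(wildtype_counts["replicate"])
    )
    rows = []
    for rep in reps:
        try:
            cells = [
                (float(s.loc[(tp, rep)]), float(w.loc[(tp, rep)]), tp)
                for tp in (tp_a, tp_b)
            ]
        except KeyError:
            warnings.warn(f"replicate {rep!r} missing a timepoint; dropped",
                          stacklevel=2)
            continue
        if any(sc + wc <= 0 for sc, wc, _ in cells):
            warnings.warn(
                f"replicate {rep!r} has a zero strain+wildtype total; dropped",
                stacklevel=2,
            )
            continue
        for sc, wc, tp in cells:
            rows.append((rep, tp, sc, wc))
    if not rows:
        raise ValueError(
            f"no usable replicate for transition {tp_a}->{tp_b}"
        )

    df = pd.DataFrame(rows, columns=["replicate", "timepoint", "succ", "fail"])
    if df["replicate"].nunique() == 1:
        r = df.sort_values("timepoint", key=lambda c: c.map({tp_a: 0, tp_b: 1}))
        sa, wa = r.iloc[0][["succ", "fail"]]
        sb, wb = r.iloc[1][["succ", "fail"]]
        return _closed_form_two_cell(sa, wa, sb, wb)

    X = pd.get_dummies(
        df[["replicate", "timepoint"]].astype(str), drop_first=True, dtype=float
    )
    tp_col = f"timepoint_{tp_b}" if f"timepoint_{tp_b}" in X.columns else None
    if tp_col is None:
        # tp_b was the dropped level; rebuild with tp_a dropped instead
        X = pd.get_dummies(
            df[["replicate", "timepoint"]].astype(str), dtype=float
        ).drop(columns=[f"timepoint_{tp_a}", f"replicate_{df['replicate'].astype(str).iloc[0]}"])
        tp_col = f"timepoint_{tp_b}"
    X = sm.add_constant(X)
    endog = df[["succ", "fail"]].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200, tol=1e-12)
        except Exception:
            return _separation_fallback(df, tp_a, tp_b)

    beta = float(res.params[tp_col])
    df_resid = int(res.df_resid)
    if df_resid > 0:
        dispersion = float(res.pearson_chi2 / df_resid)
    else:
        dispersion = 1.0
    scale = max(dispersion, 1.0) if floor_dispersion else dispersion
    se0 = float(res.bse[tp_col])
    se = se0 * float(np.sqrt(scale))

    if not np.isfinite(beta) or abs(beta) > _BETA_CAP or not np.isfinite(se):
        return _separation_fallback(df, tp_a, tp_b)
    return TransitionFit(beta=beta, se=se, dispersion=dispersion,
                         df_resid=df_resid, converged=True, se_unscaled=se0)


def _separation_fallback(df: pd.DataFrame, tp_a: str, tp_b: str) -> TransitionFit:
    """Pool replicates and use the corrected closed form when the MLE diverges."""
    g = df.groupby("timepoint")[["succ", "fail"]].sum()
    fit = _closed_form_two_cell(
        g.loc[tp_a, "succ"], g.loc[tp_a, "fail"],
        g.loc[tp_b, "succ"], g.loc[tp_b, "fail"],
    )
    fit.converged = False
    return fit


def memory_z(
    fit_naive: TransitionFit,
    fit_primed: TransitionFit,
    se_combine: str = "as_printed",
) -> float:
    """Per-window z comparing the primed transition response to the naive one.

    ``as_printed`` uses ``(b1 - b2) / sqrt(se1 + se2)`` — the sum of the
    standard errors under the root.  ``quadrature`` uses the conventional
    ``sqrt(se1**2 + se2**2)`` denominator, which is the calibrated choice
    (unit-variance z under the null).
    """
    b1, b2 = fit_naive.beta, fit_primed.beta
    s1, s2 = fit_naive.se, fit_primed.se
    if se_combine == "as_printed":
        denom_sq = s1 + s2
    elif se_combine == "quadrature":
        denom_sq = s1**2 + s2**2
    else:
        raise ValueError(f"unknown se_combine {se_combine!r}")
    if denom_sq <= 0:
        raise ValueError("non-positive combined standard error")
    return float((b1 - b2) / np.sqrt(denom_sq))


def combine_windows_stouffer(
    z_by_window: dict[str, float], weights: dict[str, float]
) -> float:
    """Weighted Stouffer combination of absolute per-window z-scores.

    Z = sum(w_i * |z_i|) / sqrt(sum(w_i**2)).  Windows with missing
    (non-finite) z are dropped together with their weights.
    """
    zs, ws = [], []
    for win, z in z_by_window.items():
        if win in weights and np.isfinite(z):
            zs.append(abs(z))
            ws.append(float(weights[win]))
    if not zs:
        raise ValueError("no window with finite z and a weight")
    ws = np.asarray(ws)
    if not np.any(ws > 0):
        raise ValueError("all Stouffer weights are zero")
    zs = np.asarray(zs)
    return float(np.sum(ws * zs) / np.sqrt(np.sum(ws**2)))


def sign_change_filter(z_ordered: "list[float] | np.ndarray") -> bool:
    """True iff the signs of z, read in gate order with zeros skipped,
    change at most once."""
    signs = [np.sign(z) for z in z_ordered if np.isfinite(z) and z != 0]
    changes = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
    return changes <= 1


def null_calibrated_threshold(null_calls: pd.DataFrame, fpr: float = 0.01) -> float:
    """Combined-Z significance threshold from a null (delta = 0) screen run.

    Returns the (1 - fpr) quantile of the null strains' Stouffer Z, i.e.
    the cutoff at which the expected false-call rate is ``fpr``.
    """
    z = null_calls["stouffer_z"].dropna()
    if z.empty:
        raise ValueError("no finite null Z values")
    return float(np.quantile(z, 1.0 - fpr))


def _call_direction(windows_used: "list[str]", z_ordered: "list[float]") -> str:
    """Direction of a memory change from per-window z in gate order.

    z > 0 means beta_1 > beta_2, a weaker primed response in that window.
    When all nonzero z share one sign the call is that sign (decreased for
    positive).  When the sign flips once — cells redistributing between low
    and high GFP gates — the call follows the gate trend: a strain whose
    primed response is weaker in the *high* gates (z > 0 there, z < 0 in
    low gates) has decreased memory, and conversely.
    """
    nz = [(GFP_WINDOW_SCORES.get(w, i + 1.0), z)
          for i, (w, z) in enumerate(zip(windows_used, z_ordered)) if z != 0]
    if not nz:
        return "NA"
    signs = {np.sign(z) for _, z in nz}
    if len(signs) == 1:
        return "decreased" if signs.pop() > 0 else "enhanced"
    scores = np.array([s for s, _ in nz])
    zs = np.array([z for _, z in nz])
    trend = float(np.sum((scores - scores.mean()) * zs))
    if trend == 0:
        return "NA"
    return "decreased" if trend > 0 else "enhanced"


def gfp_score(
    counts: pd.DataFrame,
    facs: pd.DataFrame,
    scores: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Average GFP expression score per strain and timepoint, on a 1–4 scale.

    Per sample, strain reads are normalized by the sample total; that
    relative abundance is multiplied by the window's share of FACS sorting
    events at the timepoint; the score is the weight-average of the window
    scores (R5=1 .. R8=4) under those adjusted masses.

    Returns a strain x timepoint DataFrame; NaN where a strain has zero
    adjusted mass at a timepoint.
    """
    scores = dict(GFP_WINDOW_SCORES) if scores is None else scores
    df = counts.copy()
    sample_tot = df.groupby(["timepoint", "window", "replicate"])["count"].transform("sum")
    df["rel"] = np.where(sample_tot > 0, df["count"] / sample_tot, 0.0)

    fr = facs.copy()
    fr["facs_frac"] = fr["events"] / fr.groupby("timepoint")["events"].transform("sum")
    df = df.merge(fr[["timepoint", "window", "facs_frac"]],
                  on=["timepoint", "window"], how="left")
    df["mass"] = df["rel"] * df["facs_frac"].fillna(0.0)
    df["weighted"] = df["mass"] * df["window"].map(scores)

    g = df.groupby(["strain", "timepoint"])[["mass", "weighted"]].sum()
    out = (g["weighted"] / g["mass"].where(g["mass"] > 0)).unstack("timepoint")
    out.columns.name = None
    return out


def call_memory_strains(
    counts: pd.DataFrame,
    facs: pd.DataFrame,
    naive_transition: tuple[str, str],
    primed_transition: tuple[str, str],
    control_strains: "list[str] | None" = None,
    z_threshold: float = 4.0,
    windows: "tuple[str, ...]" = WINDOW_ORDER,
    se_combine: str = "as_printed",
    floor_dispersion: bool = True,
    dispersion_pooling: str = "global",
) -> pd.DataFrame:
    """Call strains with altered transcriptional memory.

    For every strain: per-window GLM fits for the naive and primed
    transitions against the pooled controls, per-window ``memory_z``,
    FACS-weighted Stouffer combination of |z|, and the sign-change filter.
    Direction follows :func:`_call_direction` (weaker primed response =
    decreased memory).

    ``dispersion_pooling="global"`` (default) applies a single Pearson
    dispersion pooled over every fit of the screen to all standard errors;
    ``"per_fit"`` keeps each fit's own estimate (R quasibinomial
    behaviour, noisy at few replicates).

    Returns a DataFrame indexed by strain with per-window z columns,
    ``stouffer_z``, ``sign_consistent``, ``direction``, ``significant`` and
    a ``reason`` column for strains whose fits failed.
    """
    if control_strains is None:
        if "is_control" not in counts.columns:
            raise ValueError("control_strains or an is_control column required")
        control_strains = sorted(
            counts.loc[counts["is_control"].astype(bool), "strain"].unique()
        )
    if not control_strains:
        raise ValueError("at least one control strain required")

    wt = counts[counts["strain"].isin(control_strains)]
    test_strains = [
        s for s in counts["strain"].unique() if s not in set(control_strains)
    ]

    tps = set(naive_transition) | set(primed_transition)
    weights = {
        win: float(facs.loc[(facs["window"] == win)
                            & (facs["timepoint"].isin(tps)), "events"].sum())
        for win in windows
    }

    # first pass: all per-window transition fits
    fits: dict[str, dict[str, tuple]] = {}
    fail_reason: dict[str, str] = {}
    for strain in test_strains:
        sc = counts[counts["strain"] == strain]
        fits[strain] = {}
        for win in windows:
            s_w = sc[sc["window"] == win]
            wt_w = wt[wt["window"] == win]
            try:
                fn = fit_transition_glm(s_w, wt_w, naive_transition,
                                        floor_dispersion=floor_dispersion)
                fp = fit_transition_glm(s_w, wt_w, primed_transition,
                                        floor_dispersion=floor_dispersion)
                fits[strain][win] = (fn, fp)
            except (ValueError, KeyError) as exc:
                fits[strain][win] = None
                fail_reason[strain] = f"{win}: {exc}"

    pooled = np.nan
    if dispersion_pooling == "global":
        # Pearson X^2 / df pooled over every fit in the screen: the
        # overdispersion is a property of the assay, and per-fit estimates
        # at 1-2 residual df are too noisy to calibrate z against
        num = den = 0.0
        for per_win in fits.values():
            for pair in per_win.values():
                if pair is None:
                    continue
                for f in pair:
                    if f.df_resid > 0 and f.converged:
                        num += f.dispersion * f.df_resid
                        den += f.df_resid
        pooled = num / den if den > 0 else 1.0

    records = []
    for strain in test_strains:
        z_by_window: dict[str, float] = {}
        reason = fail_reason.get(strain, "")
        for win in windows:
            pair = fits[strain][win]
            if pair is None:
                z_by_window[win] = np.nan
                continue
            fn, fp = pair
            if dispersion_pooling == "global":
                fn = fn.rescaled(pooled, floor=floor_dispersion)
                fp = fp.rescaled(pooled, floor=floor_dispersion)
            try:
                z_by_window[win] = memory_z(fn, fp, se_combine=se_combine)
            except ValueError as exc:
                z_by_window[win] = np.nan
                reason = f"{win}: {exc}"
        finite = {w: z for w, z in z_by_window.items() if np.isfinite(z)}
        if finite:
            stz = combine_windows_stouffer(finite, weights)
            ordered = [z_by_window[w] for w in windows if np.isfinite(z_by_window[w])]
            consistent = sign_change_filter(ordered)
            direction = _call_direction(
                [w for w in windows if np.isfinite(z_by_window[w])], ordered
            )
            significant = bool(stz > z_threshold and consistent
                               and direction != "NA")
        else:
            stz, consistent, direction, significant = np.nan, False, "NA", False
            reason = reason or "all window fits failed"
        rec = {"strain": strain}
        rec.update({f"z_{w}": z_by_window.get(w, np.nan) for w in windows})
        rec.update(
            stouffer_z=stz, sign_consistent=consistent, direction=direction,
            significant=significant, reason=reason,
        )
        records.append(rec)
    return pd.DataFrame(records).set_index("strain")


class ScreenMemoryModel:
    """Transcriptional-memory screen analysis as a fitted model.

    Parameters
    ----------
    counts : DataFrame
        Long-format barcode counts: ``strain, timepoint, window, replicate,
        count`` and optionally ``is_control``.
    facs : DataFrame
        Sorted-cell events: ``timepoint, window, events``.
    naive_transition, primed_transition : (str, str)
        Timepoint pairs, e.g. ``("TP3", "TP4")`` and ``("TP5", "TP6")``.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        facs: pd.DataFrame,
        naive_transition: tuple[str, str] = ("TP3", "TP4"),
        primed_transition: tuple[str, str] = ("TP5", "TP6"),
        control_strains: "list[str] | None" = None,
        windows: "tuple[str, ...]" = WINDOW_ORDER,
        min_mean: float = 5.0,
    ):
        self.counts = counts
        self.facs = facs
        self.naive_transition = tuple(naive_transition)
        self.primed_transition = tuple(primed_transition)
        self.control_strains = control_strains
        self.windows = tuple(windows)
        self.min_mean = min_mean

    def fit(
        self,
        z_threshold: float = 4.0,
        se_combine: str = "as_printed",
        floor_dispersion: bool = True,
        dispersion_pooling: str = "global",
    ) -> "ScreenMemoryResults":
        filtered = filter_abundant_strains(self.counts, self.min_mean)
        calls = call_memory_strains(
            filtered, self.facs, self.naive_transition, self.primed_transition,
            control_strains=self.control_strains, z_threshold=z_threshold,
            windows=self.windows, se_combine=se_combine,
            floor_dispersion=floor_dispersion,
            dispersion_pooling=dispersion_pooling,
        )
        scores = gfp_score(filtered, self.facs)
        return ScreenMemoryResults(self, calls, scores, z_threshold, se_combine)


class ScreenMemoryResults:
    """Results of :class:`ScreenMemoryModel.fit`."""

    def __init__(self, model, calls, gfp_scores, z_threshold, se_combine):
        self.model = model
        self.calls = calls
        self.gfp_scores = gfp_scores
        self.z_threshold = z_threshold
        self.se_combine = se_combine

    @property
    def significant_strains(self) -> pd.DataFrame:
        return self.calls[self.calls["significant"]]

    def summary(self) -> str:
        n = len(self.calls)
        sig = self.significant_strains
        n_dec = int((sig["direction"] == "decreased").sum())
        n_enh = int((sig["direction"] == "enhanced").sum())
        lines = [
            "Transcriptional memory screen",
            "=" * 35,
            f"strains tested        {n}",
            f"naive transition      {'->'.join(self.model.naive_transition)}",
            f"primed transition     {'->'.join(self.model.primed_transition)}",
            f"Stouffer Z threshold  {self.z_threshold}",
            f"z denominator         {self.se_combine}",
            f"significant strains   {len(sig)}",
            f"  decreased memory    {n_dec}",
            f"  enhanced memory     {n_enh}",
        ]
        return "\n".join(lines)
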