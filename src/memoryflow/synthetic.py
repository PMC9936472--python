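"""Synthetic data generators with planted ground truth.

Every input the analysis consumes can be generated here with the
statistical structure the estimators assume, plus a machine-readable truth
table for recovery testing:

* :func:`simulate_screen` — pooled sort-seq barcode counts across GFP gates
  and timepoints.  Cells move between gates as the reporter is induced; a
  strain with altered memory shifts its gate occupancy differently from the
  pooled wildtype controls across the primed transition only.
* :func:`simulate_expression` — negative-binomial RNA-seq count
  trajectories for the nine memory categories.
* :func:`simulate_slam` — SLAM-seq per-gene read summaries given true
  turnover fractions.
* :func:`simulate_coverage` — strand-specific per-base tracks with planted
  promoter ncRNA rectangles and Gaussian nucleosome peaks.
* :func:`simulate_crac` — factor and RNA Pol II counts given true
  association ratios.

Identical config + seed gives bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import NAIVE_TIMEPOINTS, PRIMED_TIMEPOINTS, TIMEPOINTS
from .screen import WINDOW_ORDER

__all__ = [
    "ScreenSimConfig",
    "ExpressionSimConfig",
    "SlamSimConfig",
    "CoverageSignalSpec",
    "simulate_screen",
    "simulate_expression",
    "simulate_slam",
    "simulate_coverage",
    "simulate_crac",
    "default_category_trajectories",
]

TIMEPOINT_LABELS = tuple(f"TP{i}" for i in range(9))

#: linear gate scores used to tilt window occupancy (R5 low .. R8 high)
_GATE_SCORES = np.array([-1.5, -0.5, 0.5, 1.5])

#: wildtype occupancy tilt along the experiment: induction TP0..TP3, glucose
#: TP4..TP5 (protein still accumulating at TP4), re-induction TP6..TP8.
#: Magnitudes on the analyzed transitions (TP3-TP6) are kept moderate so
#: every gate retains enough reads for a calibrated Wald z at screen depth.
_WT_TILT = {
    "TP0": -0.8, "TP1": -0.2, "TP2": 0.1, "TP3": 0.3, "TP4": 0.6,
    "TP5": -0.3, "TP6": 0.3, "TP7": 0.6, "TP8": 0.8,
}


@dataclass
class ScreenSimConfig:
    """Study conditions for the pooled reporter screen.

    ``effect_table`` maps strain name -> memory effect delta: the log-odds
    tilt of the strain's gate occupancy applied across the primed
    transition (positive = enhanced memory response, negative = decreased).
    Controls always have delta = 0.
    """

    n_strains: int = 40
    n_controls: int = 8
    timepoints: tuple = TIMEPOINT_LABELS
    windows: tuple = WINDOW_ORDER
    replicates: int = 2
    reads_per_strain_window: float = 50.0
    cells_sorted: float = 1e6
    effect_table: dict = field(default_factory=dict)
    dispersion_inflation: float = 1.0
    library_sigma: float = 0.2
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_strains <= 0 or self.reads_per_strain_window <= 0:
            raise ValueError("non-positive strain count or depth")
        if self.dispersion_inflation < 1.0:
            raise ValueError("dispersion_inflation must be >= 1")

    @property
    def strain_names(self) -> list[str]:
        return [f"strain_{i:04d}" for i in range(self.n_strains)]

    @property
    def control_names(self) -> list[str]:
        return [f"control_{i}" for i in range(self.n_controls)]


def _window_probs(tilt: float) -> np.ndarray:
    w = np.exp(tilt * _GATE_SCORES)
    return w / w.sum()


def simulate_screen(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate barcode counts, FACS events and the strain truth table.

    Gate occupancy of strain k at timepoint t is
    softmax((tau_t + theta_k(t)) * gate_scores) where tau_t is the shared
    wildtype tilt and theta_k jumps by delta_k at the primed re-induction
    (TP6 onward).  Per sample each strain's total reads are Poisson and
    split across gates multinomially; ``dispersion_inflation`` > 1 switches
    the split to a Dirichlet-multinomial whose Pearson dispersion matches.
    ``noiseless=True`` writes expected counts directly (no sampling).

    Returns ``(counts, facs, truth)`` long-format DataFrames.
    """
    if not config.timepoints:
        raise ValueError("empty timepoint list")
    unknown = set(config.effect_table) - set(config.strain_names)
    if unknown:
        raise ValueError(f"effect_table names unknown strains: {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    strains = config.strain_names + config.control_names
    is_control = {s: s.startswith("control_") for s in strains}
    deltas = {
        s: (0.0 if is_control[s] else float(config.effect_table.get(s, 0.0)))
        for s in strains
    }
    primed_tps = {"TP6", "TP7", "TP8"}

    n_total = len(strains)
    per_strain_sample = config.reads_per_strain_window * len(config.windows)

    count_rows = []
    for tp in config.timepoints:
        tau = _WT_TILT.get(tp, 0.0)
        for rep in range(1, config.replicates + 1):
            if config.noiseless:
                lib = 1.0
            else:
                lib = float(np.exp(rng.normal(0.0, config.library_sigma)))
            for s in strains:
                theta = deltas[s] if tp in primed_tps else 0.0
                probs = _window_probs(tau + theta)
                mean_total = per_strain_sample * lib
                if config.noiseless:
                    counts = mean_total * probs
                else:
                    total = rng.poisson(mean_total)
                    if config.dispersion_inflation > 1.0 and total > 0:
                        # Dirichlet-multinomial with concentration chosen so
                        # the Pearson dispersion ~ dispersion_inflation
                        phi = config.dispersion_inflation
                        c = max((mean_total - phi) / (phi - 1.0), 1e-3)
                        p = rng.dirichlet(c * probs)
                        counts = rng.multinomial(total, p)
                    else:
                        counts = rng.multinomial(total, probs)
                for w, cnt in zip(config.windows, counts):
                    count_rows.append((s, tp, w, rep, float(cnt),
                                       is_control[s]))

    counts = pd.DataFrame(
        count_rows,
        columns=["strain", "timepoint", "window", "replicate", "count",
                 "is_control"],
    )
    if not config.noiseless:
        counts["count"] = counts["count"].astype(int)

    facs_rows = []
    for tp in config.timepoints:
        probs = _window_probs(_WT_TILT.get(tp, 0.0))
        for w, pr in zip(config.windows, probs):
            mean_ev = config.cells_sorted * pr
            ev = mean_ev if config.noiseless else float(rng.poisson(mean_ev))
            facs_rows.append((tp, w, ev))
    facs = pd.DataFrame(facs_rows, columns=["timepoint", "window", "events"])

    truth = pd.DataFrame(
        {
            "strain": strains,
            "delta": [deltas[s] for s in strains],
            "is_control": [is_control[s] for s in strains],
            "direction": [
                "none" if deltas[s] == 0
                else ("enhanced" if deltas[s] > 0 else "decreased")
                for s in strains
            ],
        }
    )
    return counts, facs, truth


# --------------------------------------------------------------------------
# expression


def default_category_trajectories(margin: float = 0.5) -> dict:
    """True lfc trajectories per memory category, wildtype and mutant.

    Each trajectory maps timepoint -> true log2 fold change vs naive t0.
    ``margin`` is how far beyond every classification threshold the planted
    differences sit (log2(1.5) for memory, 0.58 for the dTM band).
    """
    mem = float(np.log2(1.5)) + margin   # memory-rule difference
    dtm = 0.58 + margin                  # mutant-effect shift

    def traj(t30, t60, t180, t15p, t30p, t60p):
        return {"t30": t30, "t60": t60, "t180": t180,
                "t0'": 0.0, "t15'": t15p, "t30'": t30p, "t60'": t60p}

    # induced base: 1 -> 2 -> 3 over the naive course
    ind_mem_wt = traj(1.0, 2.0, 3.0, 2.0, 1.0 + mem, 2.0 + mem)
    ind_nomem = traj(1.0, 2.0, 3.0, 0.5, 1.0, 2.0)
    # repressed base mirrors
    rep_mem_wt = traj(-1.0, -2.0, -3.0, -2.0, -1.0 - mem, -2.0 - mem)
    rep_nomem = traj(-1.0, -2.0, -3.0, -0.5, -1.0, -2.0)
    flat = traj(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def shift_t15(base, by):
        out = dict(base)
        out["t15'"] = out["t15'"] + by
        return out

    return {
        "induction memory enhanced in mutant":
            (ind_mem_wt, shift_t15(ind_mem_wt, +dtm)),
        "induction memory unchanged in mutant":
            (ind_mem_wt, dict(ind_mem_wt)),
        "induction memory attenuated in mutant":
            (ind_mem_wt, shift_t15(ind_mem_wt, -dtm)),
        "induced no memory": (ind_nomem, dict(ind_nomem)),
        "repressed no memory": (rep_nomem, dict(rep_nomem)),
        "repression memory attenuated in mutant":
            (rep_mem_wt, shift_t15(rep_mem_wt, +dtm)),
        "repression memory unchanged in mutant":
            (rep_mem_wt, dict(rep_mem_wt)),
        "repression memory enhanced in mutant":
            (rep_mem_wt, shift_t15(rep_mem_wt, -dtm)),
        "no-change": (flat, dict(flat)),
    }


@dataclass
class ExpressionSimConfig:
    """Study conditions for the RNA-seq memory time course.

    ``ballast_factor`` sizes an extra pool of genes whose abundance absorbs
    the composition shift of the signal genes, so that the planted lfc are
    exactly the relative-abundance changes that coding-sum normalization
    measures (see :func:`simulate_expression`).
    """

    genes_per_category: int = 100
    baseline_mean: float = 200.0
    margin: float = 0.5
    nb_dispersion: float = 0.05
    replicates: int = 3
    library_sigma: float = 0.2
    trajectories: dict | None = None
    ballast_factor: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.nb_dispersion < 0:
            raise ValueError("negative NB dispersion")
        if self.genes_per_category <= 0 or self.replicates < 1:
            raise ValueError("invalid gene or replicate count")


def _ballast_trajectories(
    trajectories: dict, genes_per_category: int, n_ballast_units: float
) -> dict:
    """Per-strain lfc of a ballast class that keeps the total transcriptome
    constant across timepoints.

    Coding-sum normalization measures *relative* abundance, so planted lfc
    are only recoverable when the summed abundance 2**lfc over all genes is
    the same at every timepoint.  The ballast class takes up the slack:
    with S_strain(t) the signal genes' summed fold change (in t0 gene
    units), ballast lfc(t) = log2((S(t0) + N_b - S(t)) / N_b).
    """
    out = {}
    for si, strain in enumerate(("wildtype", "mutant")):
        s_t = {}
        for tp in TIMEPOINTS:
            total = 0.0
            for wt_traj, mut_traj in trajectories.values():
                traj = (wt_traj, mut_traj)[si]
                lfc = 0.0 if tp == "t0" else traj[tp]
                total += genes_per_category * 2.0**lfc
            s_t[tp] = total
        slack = {tp: s_t["t0"] + n_ballast_units - s_t[tp] for tp in TIMEPOINTS}
        if min(slack.values()) <= 0:
            raise ValueError(
                "ballast_factor too small for the signal trajectories"
            )
        out[strain] = {
            tp: float(np.log2(slack[tp] / n_ballast_units)) for tp in TIMEPOINTS
        }
    return out


def _ballast_truth_label(ballast: dict, alpha_ok: bool = True) -> str:
    """Category the classifier assigns to the exact ballast trajectories."""
    from .expression import (
        classify_base,
        classify_memory,
        eight_category_label,
        mutant_effect,
    )

    tables = {}
    for strain in ("wildtype", "mutant"):
        rows = [
            {"gene": "ballast", "timepoint": tp,
             "lfc": ballast[strain][tp], "pvalue": 0.0,
             "padj": 0.0 if alpha_ok else 1.0}
            for tp in TIMEPOINTS if tp != "t0"
        ]
        tables[strain] = pd.DataFrame(rows)
    base = classify_base(tables["wildtype"]).iloc[0]
    if base == "no-change":
        return "no-change"
    mem = False
    for strain in ("wildtype", "mutant"):
        flag = classify_memory(
            tables[strain], pd.Series([base], index=["ballast"])
        ).iloc[0]
        mem = mem or (flag is not pd.NA and bool(flag))
    if not mem:
        return f"{base} no memory"
    tm = {
        s: tables[s].set_index("timepoint")["lfc"]["t15'"]
        - tables[s].set_index("timepoint")["lfc"]["t180"]
        for s in ("wildtype", "mutant")
    }
    eff = mutant_effect(tm["wildtype"], tm["mutant"], base)
    return eight_category_label(base, True, eff)


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples count matrix for both strains.

    Counts are negative binomial with mean = baseline * 2**lfc scaled by a
    log-normal per-sample size factor; ``nb_dispersion = 0`` disables all
    sampling (expected counts written directly, size factors 1) so that
    downstream classification recovers the planted labels exactly.  A
    ballast gene class (``ballast_factor`` x genes_per_category genes)
    keeps the summed transcriptome constant across timepoints so the
    planted lfc survive coding-sum normalization; ballast genes carry the
    category their own trajectory implies.

    Returns ``(counts, sample_info, truth)``; all genes are flagged coding.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    trajectories = config.trajectories or default_category_trajectories(
        config.margin
    )
    noiseless = config.nb_dispersion == 0

    n_ballast = int(round(config.ballast_factor * config.genes_per_category
                          * len(trajectories)))
    ballast = _ballast_trajectories(trajectories, config.genes_per_category,
                                    n_ballast)
    ballast_label = _ballast_truth_label(ballast)

    genes, categories, lfc_by_strain = [], [], {"wildtype": [], "mutant": []}
    for cat, (wt_traj, mut_traj) in trajectories.items():
        for i in range(config.genes_per_category):
            gene = f"{cat.replace(' ', '_')}_{i:04d}"
            genes.append(gene)
            categories.append(cat)
            lfc_by_strain["wildtype"].append(wt_traj)
            lfc_by_strain["mutant"].append(mut_traj)
    for i in range(n_ballast):
        genes.append(f"ballast_{i:04d}")
        categories.append(ballast_label)
        lfc_by_strain["wildtype"].append(ballast["wildtype"])
        lfc_by_strain["mutant"].append(ballast["mutant"])

    samples, info_rows = [], []
    data = {}
    for strain in ("wildtype", "mutant"):
        for tp in TIMEPOINTS:
            state = "naive" if tp in NAIVE_TIMEPOINTS else "primed"
            for rep in range(1, config.replicates + 1):
                sample = f"{strain}_{tp}_r{rep}"
                samples.append(sample)
                info_rows.append((sample, strain, state, tp, rep))
                if noiseless:
                    sf = 1.0
                else:
                    sf = float(np.exp(rng.normal(0.0, config.library_sigma)))
                lfcs = np.array(
                    [
                        0.0 if tp == "t0" else traj[tp]
                        for traj in lfc_by_strain[strain]
                    ]
                )
                mu = config.baseline_mean * 2.0**lfcs * sf
                if noiseless:
                    data[sample] = mu
                else:
                    # NB via gamma-Poisson; alpha = nb_dispersion
                    shape = 1.0 / config.nb_dispersion
                    lam = rng.gamma(shape, mu / shape)
                    data[sample] = rng.poisson(lam).astype(float)

    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    sample_info = pd.DataFrame(
        info_rows, columns=["sample", "strain", "state", "timepoint",
                            "replicate"],
    )
    truth = pd.DataFrame(
        {"gene": genes, "category": categories,
         "is_ballast": [g.startswith("ballast_") for g in genes]}
    )
    return counts, sample_info, truth


# --------------------------------------------------------------------------
# SLAM-seq


@dataclass
class SlamSimConfig:
    """Study conditions for SLAM-seq read summaries.

    ``turnover_truth`` maps condition -> per-gene true new-read fraction
    (scalar or array of length n_genes).
    """

    n_genes: int = 500
    turnover_truth: dict = field(
        default_factory=lambda: {"naive": 0.3, "primed": 0.2}
    )
    reads_per_gene: float = 1000.0
    detection_efficiency: float = 1.0
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.detection_efficiency <= 1):
            raise ValueError("detection_efficiency must lie in (0, 1]")
        for cond, th in self.turnover_truth.items():
            arr = np.atleast_1d(np.asarray(th, dtype=float))
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"theta outside [0, 1] for {cond!r}")


def simulate_slam(config: SlamSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-gene SLAM-seq totals and >=2 T>C converted read counts.

    total ~ Poisson(reads_per_gene); converted ~ Binomial(total,
    theta * detection_efficiency).  Returns ``(counts, truth)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    rows, truth_rows = [], []
    for cond, th in config.turnover_truth.items():
        theta = np.broadcast_to(
            np.asarray(th, dtype=float), (config.n_genes,)
        ).copy()
        p = theta * config.detection_efficiency
        if config.noiseless:
            total = np.full(config.n_genes, config.reads_per_gene)
            conv = total * p
        else:
            total = rng.poisson(config.reads_per_gene, size=config.n_genes)
            conv = rng.binomial(total, p)
        for g, t, c, th_g in zip(genes, total, conv, theta):
            rows.append((g, cond, t, c))
            truth_rows.append((g, cond, th_g))
    counts = pd.DataFrame(
        rows, columns=["gene", "condition", "total_reads", "converted_reads"]
    )
    truth = pd.DataFrame(truth_rows, columns=["gene", "condition", "theta"])
    return counts, truth


# --------------------------------------------------------------------------
# coverage and CRAC


@dataclass
class CoverageSignalSpec:
    """Planted signal for synthetic coverage tracks.

    ``nucleosome_peaks`` is a list of (dyad_offset_bp, amplitude_cpm,
    sd_bp) Gaussians in transcription-direction offsets, split equally
    between the two strand tracks.  Promoter rectangles are placed on the
    gene's own strand at [-150, -50) and the opposite strand at [-150, 50).
    """

    background: float = 5.0
    nucleosome_peaks: list = field(
        default_factory=lambda: [(75, 20.0, 20.0), (240, 12.0, 25.0),
                                 (-180, 12.0, 25.0)]
    )
    promoter_sense_height: float = 0.0
    promoter_antisense_height: float = 0.0


def simulate_coverage(
    n_genes: int,
    signal_spec: CoverageSignalSpec | None = None,
    seed: int = 0,
    gene_spacing: int = 2000,
    gene_length: int = 1000,
    noise_sd: float = 0.0,
):
    """Build strand-specific tracks with planted signal on one chromosome.

    Genes alternate strands along a single linear chromosome, spaced
    ``gene_spacing`` bp apart (>= 2 kb keeps regions non-overlapping by
    construction).  Per-base coverage = background + planted Gaussians +
    promoter rectangles (+ optional Gaussian noise).

    Returns ``(plus_track, minus_track, annotation, truth)`` where truth
    holds the analytic per-gene region means.
    """
    from .occupancy import REGIONS, CoverageTrack, region_coords

    if gene_spacing < 2000:
        raise ValueError("genes must be spaced >= 2 kb")
    spec = signal_spec or CoverageSignalSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    chrom = "chrS"
    margin = 3000
    length = margin * 2 + n_genes * gene_spacing
    plus = np.full(length, spec.background / 2.0)
    minus = np.full(length, spec.background / 2.0)

    ann_rows = []
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        anchor = margin + i * gene_spacing
        tss = anchor if strand == "+" else anchor + gene_length - 1
        ann_rows.append((f"gene_{i:04d}", chrom, tss, strand))
    annotation = pd.DataFrame(ann_rows, columns=["gene", "chrom", "tss",
                                                 "strand"])

    pos = np.arange(length)
    for _, gene in annotation.iterrows():
        tss, strand = gene["tss"], gene["strand"]
        sign = 1 if strand == "+" else -1
        # offsets of every base relative to the TSS, transcription direction
        off = sign * (pos - tss)
        for dyad, amp, sd in spec.nucleosome_peaks:
            bump = amp * np.exp(-0.5 * ((off - dyad) / sd) ** 2)
            plus += bump / 2.0
            minus += bump / 2.0
        if spec.promoter_sense_height:
            mask = (off >= -150) & (off < -50)
            (plus if strand == "+" else minus)[mask] += spec.promoter_sense_height
        if spec.promoter_antisense_height:
            mask = (off >= -150) & (off < 50)
            (minus if strand == "+" else plus)[mask] += spec.promoter_antisense_height

    if noise_sd > 0:
        plus = np.maximum(plus + rng.normal(0, noise_sd, length), 0.0)
        minus = np.maximum(minus + rng.normal(0, noise_sd, length), 0.0)

    plus_track = CoverageTrack({chrom: plus})
    minus_track = CoverageTrack({chrom: minus})

    truth_rows = []
    for _, gene in annotation.iterrows():
        for name, rspec in REGIONS.items():
            _, start, end, read_strand = region_coords(gene, rspec,
                                                       chrom_length=length)
            tracks = (
                [plus] if read_strand == "+" else
                [minus] if read_strand == "-" else [plus, minus]
            )
            mean = float(np.sum([t[start:end].mean() for t in tracks]))
            truth_rows.append((gene["gene"], name, mean))
    truth = pd.DataFrame(truth_rows, columns=["gene", "region",
                                              "expected_mean"])
    return plus_track, minus_track, annotation, truth


def simulate_crac(
    n_genes: int,
    association_truth,
    polii_mean: float = 200.0,
    seed: int = 0,
    noiseless: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-gene decay-factor and RNA Pol II CRAC counts.

    ``association_truth`` is the true per-gene association ratio a_g
    (scalar or length-n array, > 0).  Pol II counts ~ Poisson(polii_mean)
    and factor counts ~ Poisson(a_g * polii_mean); ``noiseless`` writes the
    expected values so that normalization returns a_g (up to the shared
    library totals) exactly.

    Returns ``(table, truth)``.
    """
    a = np.broadcast_to(np.asarray(association_truth, dtype=float),
                        (n_genes,)).copy()
    if np.any(a <= 0):
        raise ValueError("association_truth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    lam_p = np.full(n_genes, float(polii_mean))
    lam_f = a * lam_p
    if noiseless:
        polii, factor = lam_p, lam_f
    else:
        polii = rng.poisson(lam_p).astype(float)
        factor = rng.poisson(lam_f).astype(float)
    table = pd.DataFrame(
        {"gene": genes, "factor_count": factor, "polii_count": polii}
    )
    truth = pd.DataFrame({"gene": genes, "association": a})
    return table, truth
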