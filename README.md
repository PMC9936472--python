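# memoryflow

Analysis toolkit for **transcriptional memory** in budding yeast: the
phenomenon whereby cells previously exposed to a stimulus (galactose,
"primed" cells) respond faster or stronger on re-exposure than naive
cells.  The package implements four bespoke analyses around this
phenotype, each paired with a synthetic-data generator carrying planted
ground truth:

1. **Pooled reporter screen** (`memoryflow.screen`).  A barcoded deletion
   collection carrying a pGAL1-GFP reporter is FACS-sorted into four GFP
   gates (R5 = none … R8 = high) along two induction rounds, and strain
   barcodes are sequenced per gate.  For strain *k* and gate *w*, the
   change in barcode abundance relative to pooled wildtype controls
   across a timepoint transition is a quasibinomial GLM

   logit(Counts_k / (Counts_k + Counts_wt)) ~ replicate + timepoint,

   giving a log odds-ratio β per transition with standard error scaled by
   the Pearson dispersion.  Memory is scored per gate as
   z = (β₁ − β₂) / √(se₁ + se₂) (naive vs primed transition), gates are
   combined with a FACS-event-weighted Stouffer statistic on |z|, and a
   strain is called only when the gate-ordered z signs change at most
   once.  A 1–4 GFP expression score per strain and timepoint is also
   computed.
2. **Memory gene classification** (`memoryflow.expression`).  From
   coding-sum-normalized RNA-seq counts along naive induction (t0, t30,
   t60, t180) and primed re-induction (t0′, t15′, t30′, t60′), genes are
   classified induced / repressed / no-change, flagged as *induction* or
   *repression memory* when the primed response beats the naive response
   by more than 1.5-fold at 30 or 60 min, and scored with
   TM_score = lfc(t15′) − lfc(t180).  A mutant's effect on memory is
   judged from ΔTM = TM_mut − TM_wt against a ±0.58 band, yielding eight
   memory categories plus no-change.
3. **SLAM-seq turnover** (`memoryflow.turnover`).  Per-gene turnover
   θ = (reads with ≥2 T>C conversions) / (total reads) after a 10-min
   4-thiouracil pulse, for genes with ≥20 reads; first-order decay maps
   θ to k = −ln(1−θ)/t_label, t½ = ln2/k and a degradation rate of
   60·ln2/t½ per hour; pulse-chase time courses are fitted by log-linear
   regression; condition shifts are compared between gene sets with a
   two-sided rank-sum test (exact for ≤8 per group).
4. **Occupancy features** (`memoryflow.occupancy`).  Strand-aware
   TSS-relative region means (promoter sense −150..−50, promoter
   antisense −150..+50, +1 nucleosome 0..150, NDR −150..0), primed/naive
   coverage ratios, 5-bp-smoothed metagene profiles, and CRAC
   decay-factor association scores normalized to RNA Pol II binding
   (genes under 20 counts discarded).

## Worked example

```python
import pandas as pd
from memoryflow.synthetic import ScreenSimConfig, simulate_screen
from memoryflow import ScreenMemoryModel

effects = {"strain_0003": 1.5, "strain_0007": -1.5}   # planted memory strains
counts, facs, truth = simulate_screen(
    ScreenSimConfig(n_strains=12, effect_table=effects, seed=1))
res = ScreenMemoryModel(counts, facs).fit(z_threshold=1.5)
print(res.summary())
```

```
Transcriptional memory screen
===================================
strains tested        12
naive transition      TP3->TP4
primed transition     TP5->TP6
Stouffer Z threshold  1.5
z denominator         as_printed
significant strains   2
  decreased memory    1
  enhanced memory     1
```

Both planted strains are recovered with the right direction; a null
strain is shown for comparison:

```
             z_R5  z_R6  z_R7  z_R8  stouffer_z  sign_consistent  direction  significant
strain_0003  3.71  3.48  1.57 -1.87        4.81             True   enhanced         True
strain_0007 -2.75 -0.21  2.56  4.32        5.28             True  decreased         True
strain_0000 -0.22 -0.03  0.26 -0.17        0.34            False  decreased        False
```

The per-gate z of a memory strain changes sign once — cells
redistributing between low and high GFP gates — which is exactly what the
sign-change filter admits, and the direction is read from the gate trend
(a weaker primed response in the high gates means decreased memory).

Every stage is also exposed on the command line:

```sh
memoryflow run --out-dir demo --seed 7          # synthetic end-to-end run
memoryflow screen --counts counts.tsv --facs facs.tsv --naive TP3,TP4 --primed TP5,TP6
memoryflow classify --counts expr.tsv --design design.tsv --ratio 1.5 --delta 0.58
memoryflow turnover --slam slam.tsv --min-reads 20 --t-label 10
memoryflow crac --counts crac.tsv --min-counts 20
```

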