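# barriertrace

Quantification of lateral diffusion barriers in the budding-yeast
endoplasmic reticulum from photobleaching and pedigree data, together
with a synthetic-data generator that simulates the compartment-exchange
physics the analysis assumes.

## The problem

During budding, the yeast ER is one continuous organelle, yet membrane
proteins exchange only slowly between mother and bud: a lateral
diffusion barrier at the bud neck compartmentalizes the ER membrane.
The strength of that barrier is measured by live-cell photobleaching:

- **FLIP** (fluorescence loss in photobleaching): a small region of the
  mother's cortical ER is bleached repeatedly while whole-compartment
  fluorescence is monitored.  The **Barrier Index** is
  `BI = t50(bud) / t50(mother)`, the ratio of the times at which bud and
  mother have lost 50 % of their fluorescence.  Free exchange gives
  BI ≈ 1; an intact barrier gives BI ≈ 7–8.
- **FRAP**: a single bleach of a region, with the recovery half-time
  `t1/2` (time to recover half of the plateau) reporting reporter
  mobility — a chaperone reporter slows down as misfolded clients
  accumulate.
- **Photoconversion**: a green→red converted pool in the mother is
  chased; red signal appearing in the bud reports leakage through the
  neck.
- **Asymmetry index** `(Im − Ib)/(Im + Ib)` of mean cortical-ER
  intensity: 0 for symmetric partitioning, 1 for full mother retention.
- **Bud-neck exclusion**: ER membrane markers are depleted at the neck;
  cells are classified total / partial / no exclusion from the
  neck-to-flank intensity ratio of a cortical transect.
- **Replicative lifespan**: per-mother division counts from pedigree
  dissection, summarized as survival curves and medians and compared
  with the Gehan–Breslow–Wilcoxon (generalized Wilcoxon) test.

Because the underlying imaging data are not published as raw traces, the
package ships a generator (`barriertrace.simkit`) that produces
FLIP/FRAP/photoconversion bundles, neck profiles, spot images and
pedigrees with known ground truth, so every estimator can be validated
by closed-form oracles and parameter recovery.

## The model

Between acquisitions the mobile reporter concentrations in three
well-mixed states — the bleach ROI, the rest of its cell body, and the
other cell body — evolve as a linear system `dc/dt = A c` built from two
conductances: `intra_mixing_rate` (ROI ↔ rest) and `exchange_rate`
(mother ↔ bud, proportional to barrier permeability).  The system is
propagated exactly with the matrix exponential; bleach pulses are
instantaneous multiplicative events on the ROI; every acquisition itself
bleaches all compartments by a small fraction, which is why traces are
normalized per frame to the mean of five unbleached neighbor cells
before fitting.  FLIP loss is fit with
`y(t) = plateau + (100 − plateau)·exp(−k t)` (first bleaching point
pinned to 100 %), FRAP recovery with one or two recovering exponentials.

## Worked example

```sh
barriertrace demo --seed 1 --outdir demo_out
```

simulates two strains (20 FLIP cells each at the shipped wild-type-like
calibration, and with a 5-fold more permeable neck), runs
quantification → fitting → Barrier Index → group tests plus a simulated
pedigree comparison, and prints:

```json
{
  "barrier_index": [
    {"strain": "wild_type_like",   "exchange_factor": 1.0, "n_fit": 20,
     "bi_mean": 7.492634498720181, "bi_sd": 0.5182491108675242},
    {"strain": "barrier_weakened", "exchange_factor": 5.0, "n_fit": 20,
     "bi_mean": 2.1018021179978437, "bi_sd": 0.15915961720313232}
  ],
  "tests": {
    "wild_type_like_vs_barrier_weakened": {"t": 44.47, "p": 1.81e-23}
  },
  "lifespan": {
    "unstressed":  {"median": 32, "n": 60},
    "er_stressed": {"median": 12, "n": 60},
    "gbw_chi2": 10.46, "gbw_p": 0.0012
  }
}
```

The intact-barrier strain keeps its bud fluorescence ~7.5× longer than
its mother during mother-side FLIP, while opening the neck 5-fold
collapses the index towards 2, and the Welch test separates the strains
decisively.  The pedigree block compares 60 simulated mothers per group
(medians at this sample size fluctuate by a few generations, as in real
dissection experiments); the Gehan–Breslow–Wilcoxon chi-square flags the
shortened lifespan of the ER-stressed group.

The same stages are available separately (`simulate`, `quantify`,
`fit`, `stats bi|asym|exclusion`, `lifespan`) and as library functions;
all randomness flows from one seed, and every output file carries the
config hash and seed in a header comment.

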