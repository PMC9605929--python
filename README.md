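# gliodx

Quantitative diagnostics for suspected recurrent high-grade glioma from
simultaneously acquired **DCE-MRI perfusion** (two-compartment exchange
model, 2CXM) and **amino-acid PET**.

After radio-chemotherapy, conventional MRI cannot reliably separate true
tumour progression from pseudo-progression and radiation necrosis. Two
quantitative modalities help: tumour blood volume from dynamic
contrast-enhanced T1 MRI, and amino-acid tracer uptake on PET. This package
implements the full analysis chain for both, and the statistics for
comparing and combining them — for imaging scientists who want a tested,
reproducible reference pipeline that runs end to end on synthetic digital
phantoms with known ground truth.

**Stages** (each usable on its own):

1. `relaxometry` — variable-flip-angle T1/M0 mapping (SPGR,
   `S = M0 sin α (1−E1)/(1−E1 cos α)`, `E1 = e^(−TR/T1)`) and conversion of
   the dynamic signal to gadolinium concentration,
   `C(t) = (1/T1(t) − 1/T1(0))/r1`.
2. `perfusion` — model-free blood-flow estimation by Tikhonov-regularised
   deconvolution, `min ‖Ah − c‖² + λ²‖Lh‖²` with `h ≥ 0` and
   `F = 6000·max h`, then voxel-wise bounded least-squares fitting of the
   2CXM for BV, Ki (unidirectional clearance) and Ve with flow held fixed —
   exposed as `TwoCompartmentExchangeModel(...).fit()` with a statsmodels-
   style results object.
3. `lesions` — isocontour delineation of the metabolically active PET volume
   (uptake > 1.6 × contralateral-cortex background), the increased-BV volume
   (> factor × NAWM reference), and per-lesion metrics TBR_max, BV_max,
   nBV_max and contrast-enhancing-volume medians, with the documented
   fallback chains for PET- or BV-negative lesions.
4. `outcomes` — deterministic modified-RANO adjudication (histology > MRI
   ±25%/−50% bidimensional-product rules > clinical flag) at 6 months ± 2
   weeks.
5. `diagnostics` — rank/logistic ROC AUC, DeLong paired-AUC test,
   Youden-optimal cut-offs, exact (Clopper–Pearson / conditional) confidence
   intervals, concordant-AND and sequential-BV-first combination rules,
   concordance matrices and patient-wise aggregation.
6. `phantoms` / `cohort` — digital DCE and PET phantoms and lesion-level
   cohorts with known truth, so every stage is verifiable without patient
   data.

## Worked example

Simulate a digital phantom (tumour-like lesion in white-matter-like
background), run the whole chain, and inspect the lesion table:

```python
from gliodx.pipeline import simulate_phantom_inputs, RunConfig, run_end_to_end
import pandas as pd

d = simulate_phantom_inputs("phantom_demo", seed=1)   # NIfTI + AIF + config
out = run_end_to_end(RunConfig.from_yaml(d / "config.yaml"))
print(pd.read_csv(out / "lesions.csv")
        [["tbr_max", "bv_max", "f_med", "bv_med", "ki_med", "outcome"]])
```

prints

```
   tbr_max  bv_max  f_med  bv_med  ki_med      outcome
0      2.8    4.01  59.67    4.01    5.99  progressive
```

The lesion was synthesised with PET peak-to-background ratio 2.8 and tissue
parameters F = 60 mL/100 g/min, BV = 4 mL/100 g, Ki = 6 mL/100 g/min — the
chain recovers them to within a percent at zero noise (`tbr_max` is the
measured ratio; `outcome` comes from the follow-up table's tumour
histology).

Per-voxel kinetic fits are ordinary model objects:

```python
import numpy as np
from gliodx import (AifParams, TissueParams, TwoCompartmentExchangeModel,
                    forward_2cxm, make_aif)

aif = make_aif(AifParams(), np.arange(300.0))
curve = forward_2cxm(TissueParams(F=60, BV=4, Ki=6, Ve=20), aif)
res = TwoCompartmentExchangeModel(curve, aif).fit()   # F via deconvolution
print(res.summary())
```

```
Two-compartment exchange model fit
  converged: True   RMS residual: 3.057e-05 mM
  param   estimate    std err  unit
  F         59.67      fixed  mL/100g/min
  BV        4.007   0.000453  mL/100g
  Ki        5.996  0.0006211  mL/100g/min
  Ve           20   0.002045  mL/100g
```

Cohort-level diagnostics on a simulated 76-lesion / 60-patient cohort:

```bash
gliodx simulate cohort --out cohort.csv --seed 1
gliodx diagnostics --lesions cohort.csv --out report/ \
    --modes single,concordant,sequential
```

`report/roc_table.csv` then holds one row per parameter (AUC, Youden
cut-off, sensitivity/specificity/OR/PPV/NPV with exact 95% CIs), e.g. for
seed 1: TBR_max AUC 0.95 at cut-off 2.10, BV_max AUC 0.88 at 5.90 —
simulated cohorts reproduce the qualitative ordering (PET above BV) by
construction of the group distributions, not any published numbers.

The CLI also exposes the individual stages: `gliodx fit-t1`, `to-conc`,
`fit-dce`, `lesion-metrics`, `adjudicate`, and `run` for a full YAML-driven
pipeline with a reproducibility manifest.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline computations from scratch: zero-noise and
SNR-20 phantom parameter recovery through the full relaxometry →
deconvolution → 2CXM chain; the two-by-two diagnostic summaries
(sensitivity, specificity, odds ratio, correctly-classified fraction and the
second-test-avoided fraction) for single, concordant and sequential
classification strategies on a concordance-cell cohort; and ROC / Youden /
DeLong / patient-wise diagnostics on a simulated cohort. Progress and the
computed numbers are printed to stdout; the JSON results file is written to
`--out`.

## Documentation

`docs/methods.md` describes the model conventions (blood-equivalent units
and where hematocrit enters), the deconvolution numerics (hat-function
quadrature, discrepancy-principle λ selection, non-negativity), the
delineation surrogates, what the phantoms do and do not emulate, and all
numerical defaults.
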