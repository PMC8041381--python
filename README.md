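# colonsim

Mechanistic prediction of regional and colon drug absorption in fasted Beagle
dogs, and fold-error evaluation of how well such predictions match observed
colon-administration outcomes.

## Why

Colon absorption determines whether a modified-release (MR) formulation is
viable: once a dosage form leaves the small intestine, continued release only
helps if the drug is still absorbed from the colon. The colon is a hostile
absorption site — roughly 3.5 % of the GI tract's absorptive surface, no bile
salt micelles, long and variable residence. The standard preclinical readout
is a dog regional-absorption study (oral/duodenal reference vs direct colon
administration). This package implements the in-silico counterpart: a
physiologically based biopharmaceutics model (PBBM) of the dog GI tract that
predicts the colonic fraction absorbed and plasma exposure *a priori* (no
fitting to the observations), plus the statistics used to judge whether such
predictions are accurate enough to replace the in-vivo study.

## What is in the box

- **`colonsim.physiology`** — two nine-compartment fasted-Beagle GI
  physiologies: an *area-based* dialect (per-compartment absorptive surface
  area; colon area scaled so colon/total = 3.5 %, giving 17 cm²) and a
  *geometry-based* dialect (cylindrical segments with surface-enhancement
  factors, cecum + ascending colon), each with its dose-to-colon protocol.
- **`colonsim.params`** — parameter harmonization: CL_R = fu·GFR with a
  zero-clamp when inconsistent with total clearance, well-stirred hepatic
  extraction E_H = CL_H/(Q_H·B/P), Stokes–Einstein diffusion D = kT/(6πηr),
  ρ = M_W/V_M, Henderson–Hasselbalch pH-dependent solubility, FaSSIF micellar
  solubilization, and three dog-Peff estimation strategies (identity, uniform
  3×, and the permeability-class split at human Peff ≤ 1.34).
- **`colonsim.simulator`** — a compartmental absorption/transit (CAT) ODE
  model: first-order transit `k_t = 1/T_i`, absorption
  `ka_i = Peff·A_i/V_i`, Nernst–Brunner dissolution
  `dM/dt = −3DM/(ρrh)·(C_s−C)` with `h = min(r, 30 μm)` and cube-root particle
  shrinkage, coupled to a linear 1–3-compartment disposition model with
  first-pass loss (1−E_H). Mass balance is enforced to 0.1 % of dose.
- **`colonsim.metrics` / `colonsim.evaluation`** — AUC_0–t (linear
  trapezoid), C_max/t_max, dose-normalized F_rel,colon, and the prediction
  statistics AAFE = 10^(mean |log₁₀(pred/obs)|), AFE = 10^(mean
  log₁₀(pred/obs)), and % within 2-fold, grouped per metric × formulation ×
  software with the AAFE ≤ 2 accuracy criterion.
- **`colonsim.synthetic`** — synthetic drugs spanning the BCS quadrants with
  paired oral/colon arms and arm-level multiplicative lognormal noise, for
  closed-loop calibration of the whole pipeline.
- **`colonsim/data/`** — the study tables as plain TSV: 14 drugs
  (physicochemistry + systemic PK) and 19 colon arms (13 solutions,
  6 suspensions) with observed and vendor-engine-predicted AUC_0–t,
  F_rel,colon and colonic f_abs.
- **`analysis/01…04_*.py`** — numbered drivers: regenerate the performance
  summary, run the open model on every arm, tabulate accuracy-vs-covariate
  trends, calibrate the metrics on synthetic data.

## Worked example

Simulate ketoprofen (2.5 mg solution) dosed directly to the colon:

```bash
colonsim simulate --drug Ketoprofen --dose-mg 2.5 --route colon --formulation solution
```

```json
{
  "f_abs": 0.8905813545052619,
  "f_abs_colon": 0.8905813545052619,
  "auc_0t": 1.1285266189677559,
  "cmax": 0.19852202336647212,
  "tmax": 1.0828628771677595
}
```

With colon surface area 17 cm², volume 78.5 mL and Peff 8.7 × 10⁻⁴ cm/s, the
absorption rate constant is ka = 0.678 h⁻¹ against a transit rate of
k_t = 1/12 h⁻¹, so the competing-rates limit ka/(ka+k_t) = 0.891 — the
simulated f_abs,colon of 89.1 % is the mechanistic consequence, and the
observed colon AUC for this arm was 0.29 µg·h/mL vs 1.13 simulated over the
full 48 h window (the observed window is shorter).

Regenerate the grouped performance summary from the packaged tables:

```bash
python analysis/01_reproduce_performance.py
```

```
metric     formulation software    within-2-fold    AAFE    AFE  accurate
auc_0t     solution    gastroplus   38% ( 5/13)     2.87   0.72  no
auc_0t     solution    gisim        69% ( 9/13)     1.89   1.06  yes
auc_0t     suspension  gastroplus   33% ( 2/6 )     3.14   2.49  no
auc_0t     suspension  gisim        67% ( 4/6 )     1.53   0.67  yes
frel_colon solution    gastroplus   62% ( 8/13)     2.85   0.55  no
frel_colon solution    gisim        85% (11/13)     1.48   1.10  yes
frel_colon suspension  gastroplus   67% ( 4/6 )     2.13   2.02  no
frel_colon suspension  gisim        33% ( 2/6 )     1.89   0.81  yes
```

Reading: the first engine predicts colon exposure of solutions within the
2-fold accuracy criterion (AAFE 1.89/1.48) with no directional bias
(AFE ≈ 1), the second does not (AAFE 2.87/2.85, AFE ≈ 0.6 — systematic
underprediction, driven by the low-permeability drugs).

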