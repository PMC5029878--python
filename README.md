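# musclefat

Quantitative muscle MRI for longitudinal studies of Duchenne muscular
dystrophy (DMD) and similar myopathies: three-point Dixon fat–water
separation, muscle fat-fraction mapping, ROI/compartment summary measures,
mixed-model change-from-baseline estimation, and trial sample-size
calculation — exercised end to end on synthetic forearm phantoms and
simulated cohorts, so every stage is testable against known ground truth
without any patient data.

The intended users are imaging scientists and trialists who need a
reproducible reference implementation of the fat-fraction endpoint chain:
from raw complex echoes to the per-visit adjusted mean changes that power
calculations are built on.

## The method

**Acquisition model.** Three gradient echoes are acquired with echo times
chosen so the fat–water chemical-shift phase advances by π per echo
(TE = 3.45/4.60/5.75 ms at 3 T, single-peak fat model). At a pixel with
water and fat magnitudes *W*, *F*:

    S_k = (W + F·e^{i(k−1)π}) · e^{i(φ₀ + (k−1)φ)},   k = 1, 2, 3

where φ₀ is the receiver phase and φ the field-inhomogeneity phase accrued
per echo spacing.

**Reconstruction.** `arg(conj(S₁)·S₃)` yields 2φ wrapped into (−π, π],
free of both φ₀ and the fat modulation. The 2φ map is unwrapped in 2D by
quality-guided region growing (quality |S₁·S₃|), halved, and used to
phase-correct the opposed-phase echo. With the in-phase channel
`A = |(S₁ + S₃e^{−2iφ})/2|` and the signed opposed-phase projection
`d = Re(û*·S₂e^{−iφ})` (û the in-phase unit phasor):

    water = (A + d)/2,   fat = (A − d)/2,
    f.f.  = fat/(water + fat) × 100 %

The π-branch ambiguity of φ (a global water–fat swap per slice) is
resolved by maximizing total water over the muscle compartment. Keeping
*d* signed rather than taking magnitudes is what keeps ROI-mean fat
fractions unbiased near 0% — see `docs/methods.md`.

**Summary measures.** Per muscle-group ROI (ten forearm muscle groups,
dorsal and volar compartments): mean f.f. and cross-sectional area
CSA = pixel count × pixel area. Per analysis slice: the CSA-weighted
total compartment f.f. `Σ f.f._r·CSA_r / Σ CSA_r`, total CSA, and the
remaining (non-fat) area `CSA_total·(100 − f.f._total)/100`. Analysis
slices are the central slice plus the slices nearest ±74 mm from it.

**Statistics.** Changes from baseline are estimated with a linear mixed
model — visit as categorical fixed effect, adjustment for time
non-ambulant, subject random intercept, REML — which handles the
unbalanced visit structure left by dropout. Normality is screened with
the Shapiro–Francia W′ test; baseline group contrasts use Welch t-tests;
two-group sample size uses `n = ⌈2σ²(z_{1−α/2}+z_{power})²/δ²⌉`.

## Worked example

```bash
python examples/reconstruct_phantom.py
```

builds a 320×320 single-slice forearm phantom whose true CSA-weighted
compartment fat fraction is 14.1% (a typical non-ambulant patient
baseline), simulates the echoes at magnitude SNR 50, reconstructs, and
prints:

```
true total compartment f.f.   : 14.100 %
recovered total compartment   : 14.104 %
dorsal / volar compartment    : 14.27 / 13.85 %
total compartment CSA         : 2678.1 mm^2
remaining (non-fat) area      : 2300.4 mm^2
```

The recovered total sits within a few hundredths of a percentage point of
the truth; per-muscle recovered means (also printed) agree with the
generating values to similar accuracy. The other examples cover the
longitudinal mixed model (`longitudinal_analysis.py`), the sample-size
calculation (`trial_power.py`, which prints `16 subjects per group` for a
4% vs 0.5% change at SD 3%), and the full simulate→reconstruct→
summarize→analyze pipeline (`full_pipeline.py`).

A thin CLI wraps the same functions:

```bash
musclefat power --delta-control 4 --delta-treated 0.5 --sd 3
musclefat run-all --seed 1 --out runs/demo
```

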