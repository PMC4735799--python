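# Methods

## Receptor model

The model is a deterministic mass-action description of ligand-driven EGFR
activation and trafficking with five pools: free surface receptor (Rs),
unphosphorylated surface complex (Cs), phosphorylated surface complex (Ps),
internalized phosphorylated receptor (Pi), internalized non-phosphorylated
receptor (Ri). Assumptions:

- **Ligand is not depleted.** The medium volume vastly exceeds cellular
  binding capacity at nanomolar doses, so `L` is a constant input.
- **Ligand identity enters only through affinity.** Both ligands share
  `kon`; `koff = kon·kd`, and kd(AREG) = 10 × kd(EGF) is fixed. Every
  EGF/AREG difference the model produces is therefore a consequence of
  affinity alone.
- **Receptor units are relative.** Western blots measure relative amounts,
  so absolute receptor numbers are unidentifiable; the ligand-free surface
  pool of baseline (EGF-cultured, "E") cells defines 1 unit. `r_scale`
  multiplies the pre-stimulation pools (10 for the surface-receptor-rich
  AREG-cultured, "A" state).
- **No downstream kinase cascade.** The ODE stops at receptor
  phosphorylation; ERK curves are handled phenomenologically by the data
  generator (below). No receptor dimerization and no other ErbB family
  members are modeled.
- **Whole-lysate phospho readout.** `pEGFR_total = Ps + Pi`, because lysates
  capture all compartments; `surface_EGFR = Rs + Cs + Ps`; `total_EGFR` sums
  all five pools.

Stimulation always starts from the ligand-free steady state (cells deprived
of growth factor), obtained in closed form from the linear Rs/Ri balance;
with `vs = 0` the closed pool is initialized at the unit-pool convention.
Integration uses LSODA with rtol 1e-8 / atol 1e-10: binding equilibrates in
minutes while trafficking acts over hours, so a stiff-capable integrator is
appropriate. Output states are clipped at zero; a negative excursion beyond
1e-9 raises an error naming the offending time.

### Default parameters (per minute; kon per nM per minute)

| parameter | value | meaning |
|---|---|---|
| kon | 0.1 | association rate, both ligands |
| kd (EGF / AREG) | 20 / 200 nM | dissociation constants, ratio fixed at 10 |
| kp / kdp | 0.05 / 0.3 | surface phosphorylation / dephosphorylation |
| ke0 / ke1 | 0.02 / 0.1 | constitutive / phospho-induced internalization |
| kdpi | 0.1 | internal dephosphorylation |
| kr | 0.05 | recycling |
| kdeg / kdegP | 0.02 / 0.1 | degradation, non-phospho / phospho |
| vs | ke0·kdeg/(kr+kdeg) ≈ 0.00571 | synthesis, sets ligand-free Rs = 1 |

No published rate constants exist for this exact scheme, so the defaults are
a calibration with two targets: (i) at equimolar 1.8 nM and baseline
receptor levels, the 0–60 min integrated pEGFR ratio EGF:AREG is ≈ 10, and
(ii) AREG with a 10-fold receptor excess comes within 20% of the EGF
response. The binding/phosphorylation regime matters for (i): the ratio
approaches the occupancy ratio (kd+L)ᴬᴿᴱᴳ/(kd+L)ᴱᴳᶠ ≈ 9.3 only when
phosphorylation does not outpace dissociation (`kp ≪ koff`); if `kp` is
large, every complex is phosphorylated before it can dissociate and the two
ligands converge (ratio → association-limited, ≈ 3). Hence the deliberately
small `kp = 0.05` and moderate `ke1 = 0.1`. With these defaults the measured
ratio is 9.10 and the compensation ratio 0.97. Compensation is not exactly
10/ratio because synthesis `vs` does not scale with `r_scale`: the receptor
pool is scaled, the production line is not.

## Estimation

The objective is the plain sum of squared residuals over all series and time
points; each series is simulated from its own ligand-free steady state at
its own `r_scale`. When the data are normalized to a reference band, model
predictions are divided by the predicted value at the declared (condition,
time) reference point, so model and data share one relative scale. A failed
integration returns the documented penalty 1e12 — large but finite, keeping
the global search totally ordered without exception handling in the hot
loop.

The global stage is classic self-adaptive ("meta") evolutionary programming
in log10 parameter space (default box [−4, 2] per rate; log space equalizes
mutation scales across rates spanning orders of magnitude). Each individual
carries per-coordinate step sizes σ; offspring are xᵢ′ = xᵢ + σᵢ·N(0,1),
σᵢ′ = σᵢ·exp(τ′·N(0,1) + τ·Nᵢ(0,1)) with τ = 1/√(2√n), τ′ = 1/√(2n), a σ
floor of 1e-12, and (μ+μ) survival by q = 10 round stochastic tournament.
The local stage is Nelder-Mead (reflection 1, expansion 2, contraction 0.5,
shrink 0.5, via `scipy.optimize.minimize`) bounded to the same box; the
returned objective never exceeds the starting one. `multistart_fit` runs
n_restarts independent chains seeded `seed + i` and keeps the minimum —
200 restarts by default, matching the estimation protocol the model
supports; the test suite and fitting examples use 10–20 restarts with
pop 20 / 25 generations, a scaled-down setting that already recovers the
identifiable quantities (kd, kp, ke1) to machine precision on noise-free
data.

`ModelObjective` exposes which coordinates are searched; the special name
`kd_egf` fits the EGF dissociation constant with AREG's kd slaved at 10×,
preserving the model's core assumption during fitting.

## Signal quantification

Normalization divides every intensity by a declared reference band
(replicate-matched when replicate structures align, else the replicate
mean); the reference point maps to 1 and normalization is idempotent.
Integration is trapezoidal on the observed points, with linear interpolation
to the window edges when sampling extends beyond them — exact for piecewise
linear signals and standard for sparse densitometry sampling. AUC is
computed per replicate first, then summarized as mean ± SD (ddof = 1),
preserving replicate variance. Fold change is the ratio of mean AUCs over
matching windows.

Re-activation onset is an operationalization of what is usually read off a
plot: on the replicate-mean curve, find the global peak, the subsequent
trough, and the earliest post-trough sample strictly above
trough + rise_fraction·(peak − trough) that stays above that level at the
next sample (the final sample counts as sustained). `rise_fraction` defaults
to 0.2 and is exposed; monotone curves return a reason code instead of a
time. With 10-min sampling and a pulse programmed at 160 min the detector
reports 170 min — within one sampling interval, the resolution this
definition can promise.

## Clustering index

Segmentation: Otsu global threshold (strictly above), hole filling
(4-connected background, the complement convention of 8-connected
foreground), one 3×3 opening. Counting uses 8-connectivity. Dilation is
`distance_px` iterations of the 3×3 element — Chebyshev radius, matching
ImageJ binary-dilate semantics, not a Euclidean disk; the radius is a
parameter with default 5. Consequently two nuclei merge iff their
edge-to-edge Chebyshev gap is ≤ 2·distance_px. Border-touching nuclei are
counted; there is no area filter beyond the opening and deliberately no
watershed: touching nuclei merging into one N0 object is part of the
statistic's behavior. N0 = 0 yields a flagged undefined index, never a
division by zero.

One subtlety the test oracles account for: a rasterized Euclidean disk is
not invariant under 3×3 opening (its four single-pixel tips are shaved), so
the brute-force geometry oracle in the tests computes each nucleus's opened
footprint independently, from the definition of erosion/dilation, before
deciding merges by pairwise Chebyshev distances.

## Synthetic data

The image generator emulates Hoechst-stained nuclei: uniform cluster
centers, Gaussian nucleus scatter (`cluster_sd`) around them, solid disks of
radius 5 px (≈ half a cell diameter) at a bright level on a flat background,
optional Gaussian camera noise (default SD 2 on 8-bit), and an optional
enforced minimum edge gap implemented by rejection sampling with a bounded
retry budget (a conservative center-separation criterion guarantees the
gap). It does not emulate PSF blur, vignetting, intensity heterogeneity or
out-of-focus light — so passing tests demonstrate correctness of the
morphology pipeline on ideal geometry, not robustness to real microscopy
artifacts.

The time-course generator emulates quantified western blots: pEGFR comes
from the mechanistic model; pERK is phenomenological because the ODE
excludes the kinase cascade — an alpha-shaped immediate pulse (zero at t=0,
peak at 10 min) plus, for the ligand-switch scenario, a re-activation pulse
that is exactly zero before its programmed 160-min onset and rises with a
10-min saturating time constant to half the first-pulse amplitude. The
sharp-onset form was chosen over a smooth second bump so the generator's
ground-truth onset is unambiguous for testing the detector. Noise is
multiplicative lognormal with unit mean (default CV 10%, 3 replicates,
mimicking densitometry variability between blots). Scenario presets encode
the study conditions: equimolar 1.8 nM doses, r_scale 10 for the
AREG-cultured state, 0–60 and 0–310 min grids sampled every 10 min, and the
E-AREG immediate ERK pulse set 2.1-fold below the EGF one. All generators
use numpy's PCG64 (`default_rng`) and are bit-reproducible per seed.

## Numerical choices and limitations

- Problem sizes: simulations run on 1-min grids over 60–310 min (48 h at
  30-min steps for chronic stimulation); fitting examples use two series of
  seven points, 20 restarts. These sizes make the whole suite run in about
  two minutes while leaving every qualitative conclusion unchanged at larger
  sizes.
- The objective weights all series and time points equally; no per-blot
  weighting or heteroscedastic error model.
- Identifiability is not analyzed; with relative data, only ratios and a
  few rates (kd, kp, ke1) are well determined, which is what the recovery
  tests assert.
- The clustering index is resolution-dependent (5 px ≈ half a cell at the
  emulated magnification); images at other pixel sizes need a rescaled
  dilation radius.
- The ERK re-activation machinery (transcriptional feedback) is represented
  only as a programmed pulse shape, not mechanistically.
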