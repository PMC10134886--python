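# Methods

This note documents the model assumptions, the parameterization and its
calibration targets, the numerical choices, and what the synthetic data
generator does and does not emulate.

## Growth dynamics

Batch growth follows a Moser-type model with nutrient-dependent growth and
death/sporulation Hill terms (`growth.GrowthParams`):

    dC/dt = C ( a·k_g·N^h1/(N^h1+K1^h1) − k_d·N^h2/(N^h2+K2^h2) )
    dN/dt = −γ C ( k_g·N^h1/(N^h1+K1^h1) − ψ·k_d·N^h2/(N^h2+K2^h2) )

with cell density `C` in OD units, `C(0)=0.1`, and nutrient normalized to
`N(0)=1`. The population growth rate is `μ = k_g N^h1/(N^h1+K1^h1)`. The
growth-term prefactor `a` is carried explicitly and defaults to 1; the
death term uses its own half-saturation `K2` (switchable to `K1`).

Defaults (`k_g=0.8 h⁻¹`, `k_d=0.18 h⁻¹`, `K1=0.65`, `K2=0.05`, `h1=2`,
`h2=4`, `γ=0.55`, `ψ=0.3`) were chosen so that μ starts near 0.56 h⁻¹,
declines smoothly through the 0.17 h⁻¹ sporulation threshold at about 9 h,
and reaches ≈0.13 h⁻¹ by 10 h — a typical biofilm-medium starvation
course. The "slow" (nitrogen-reduced) scenario keeps `N(0)=1` and scales
the effective yield γ by 3, i.e. the same biomass drains a threefold
smaller usable stock: the initial growth rate is unchanged but the
slowdown arrives ~3.5 h earlier. A K-rescaling representation of the
reduced medium was rejected because, with the fitted `K1`, it suppresses
growth from time zero instead of accelerating the decline.

Integration uses LSODA with rtol 1e-8 / atol 1e-10 on a uniform output
grid; μ(t) lookups interpolate linearly.

### Generation times

Single-cell cycle lengths are Normal(mean, CV 0.25), resampled (not
discarded as lineages) until ≥ 0.2 h. Because a cycle's length is drawn
at its start while the population mean describes cycles *alive* at a
time, the mean is taken at a shifted time
`τ_cyc(t) = ln2/μ(t + ε·ln2/μ(t))`. The shift factor is phenomenological
and must be calibrated against the reconstruction target (the average
growth rate of cycles alive at *t* should match μ(t)); for the default
growth course this gives `ε = 0.65` (maximum reconstruction error 4–5%
over 1–10 h at 1000 lineages). Smaller values (e.g. 0.2) undercorrect
here, leaving a +20–28% bias late in starvation, because the mean cycle
age grows to several hours while μ keeps falling; ε is therefore tied to
the growth parameterization and should be recalibrated if the growth
scenario changes materially.

## Gene dosage

Replication is assumed to start at division and proceed at constant
speed, so a locus at normalized origin distance `p` (0 = oriC,
1 = terminus) doubles at `p·τ_c` after birth, with
`τ_c = 0.78 h + 0.15/μ`. Multifork replication is not modeled; if
`p·τ_c` exceeds the cycle the schedule clamps at copy number 1 with a
warning. The deterministic engine uses the cycle-averaged copy number
generalized to arbitrary position, `n = 2^(1 − p·τ_c/τ_cyc)`, which is
exact under an exponential cell-age distribution; the arithmetic
time-average over a single cycle is `2 − p·τ_c/τ_cyc`, and the two agree
within 10% over μ ∈ [0.1, 0.7]. Default positions: *slrR* p=0.05
(ori-proximal), *sinI* = *sinR* p=0.95, *tapA* p=0.90 (all ori-distal);
all are configurable.

## Spo0A~P map

The phosphorelay is wrapped as a pluggable `(strain, μ) → [Spo0A~P]`
contract. The default implementation is a per-strain decreasing sigmoid
`S(μ) = floor + A/(1 + (μ/K_μ)^m)` with `m = 5`, floor 0.02 μM and

| strain | A (μM) | K_μ (h⁻¹) | sporulation threshold (h⁻¹) |
|--------|--------|-----------|------------------------------|
| WT     | 2.2    | 0.38      | 0.17 |
| ΔkinA  | 1.1    | 0.40      | 0.17 |
| ΔkinC  | 2.8    | 0.30      | 0.17 |
| Δsda   | 3.4    | 0.63      | 0.17 |

These satisfy the qualitative phosphorelay behavior: Spo0A~P rises as
growth slows in every strain; ΔkinA sits below WT throughout; Δsda above
WT throughout; ΔkinC crosses WT exactly once (lower at fast growth,
higher at slow growth — KinC acting as a phosphate sink late in
starvation); and every curve clears the switch's Spo0A~P threshold while
growth still permits bistability, so all strains leave the bistable
region at a similar growth rate. The sporulation threshold is 0.17 h⁻¹
for every strain (a per-strain override hook exists on the presets for
scenarios with shifted sporulation onset). A `TabulatedMap` can replace the sigmoids
with an externally computed phosphorelay solution (delimited columns
`strain, mu, spo0a`); quantitative strain-level targets are only
meaningful with such a quantitative map.

## The SinI–SinR–SlrR network

Species: mRNAs for *sinI*, *sinR*, *slrR*, *tapA*; SinI monomer/dimer;
SinR dimer (R₂) and tetramer (R₄); SlrR dimer (L₂); the SinI·SinR
heterodimer; the SlrR₂·SinR₂ heterotetramer; and the TapA reporter.
Promoters: *sinI* activated by Spo0A~P (Hill n=2, K=0.25 μM), *sinR*
constitutive, *slrR* and *tapA* repressed by R₄ (Hill n=2). Translation
200 h⁻¹ per mRNA; mRNA turnover 8.3 h⁻¹ (5-min half-life); SlrR-containing
species decay at 0.6 h⁻¹, other proteins at 0.2 h⁻¹. The deterministic
engine adds growth dilution μ to every species; the stochastic engine
realizes dilution through division and binomial partitioning instead.

Default stoichiometry choices (all switchable):

* SinI·SinR forms by I₂ + R₂ ⇌ 2 I·R (heterodimer product); the
  alternative single-complex I₂R₂ variant is available.
* SlrR is produced directly as a dimer ("predominately dimeric"); a
  monomer-with-dimerization variant is available.
* Proteolysis of the SlrR moiety inside SlrR₂·SinR₂ removes the whole
  complex (co-degradation). Releasing SinR₂ instead
  (`lr_releases_sinr=True`) makes SlrR sequestration increasingly leaky
  at slow growth and moves the loss of the matrix-on state to much
  faster growth rates, inconsistent with the observed late decline of
  matrix-gene expression; co-degradation is the default.
* The TapA readout models the proteolytically unstable reporter used to
  follow promoter activity (ssrA-tagged GFP), with `k_deg = 3.0 h⁻¹` and
  a repression constant (K = 0.008 μM in R₄) placed between the
  matrix-on and matrix-off R₄ levels, so the reporter is saturated along
  the whole on-branch yet shuts off within about an hour of the cell
  leaving the bistable region, instead of lagging by many hours.

### Calibration

The supplementary reaction table underlying the original parameterization
is not redistributed here; transcription rates and promoter constants are
therefore calibrated, following the same procedure the source model used:
*relative* transcription rates are set so that the mono- to bistable
transitions occur at realistic Spo0A~P levels and growth rates, and
*absolute* rates are set low enough that intrinsic noise can switch the
network state. Calibration anchors (all verified by tests):

* at μ = 0.6 h⁻¹ the switch is monostable-low at 0.05 μM Spo0A~P and
  bistable at 1 μM, with the high branch saturating above ~0.4 μM;
* at 2 μM Spo0A~P the system is bistable at moderate growth rates and
  monostable-low below a critical growth rate near 0.18 h⁻¹ (adiabatic
  continuation of the matrix-on branch);
* the matrix-on state exceeds 500 TapA reporter molecules per cell
  (≈2200), the matrix-off state stays far below (≈30–160);
* the total-SinR / total-SlrR ratio, with *slrR* repression disabled,
  decreases with growth rate.

Resulting defaults (concentration units, per gene copy): transcription
a_sinI = 0.0065, a_sinR = 0.0052, a_slrR = 0.00475, a_tapA = 0.13
μM h⁻¹; binding kon = 384.6 μM⁻¹h⁻¹ with dissociation constants 0.013 μM
(I₂, R₄ assembly) and ~0.0013 μM (sequestration complexes);
K_rep(slrR) = 0.0065 μM, K_rep(tapA) = 0.008 μM. At the 4 fL cell volume
(2409 molecules per μM) this puts SinR₂ at tens of molecules and mRNAs at
single molecules — a deliberately small-copy-number regime; the absolute
scale is a similarity transform of the deterministic model (scaling all
transcription rates by f and association constants by 1/f leaves every
concentration and bifurcation anchor unchanged while setting the noise
level), so the deterministic results do not depend on this choice.

## Deterministic engine

Steady states are found by relaxing the ODE from corner initial
conditions (a vegetative high-SinR state, a SlrR-loaded matrix-on state,
the empty state, plus optional random or continuation seeds), polishing
with a hybrid root finder, clustering endpoints (relative distance 1e-6)
and classifying stability by Jacobian eigenvalues (margin 1e-8; modes
with |Re λ| below the margin, e.g. from dynamically inert species, count
as neutral). In bistable cells the separating unstable state is located
by bisection along the segment between the stable states; if the polish
slides off the saddle the basin-boundary point is reported instead.
Two-parameter scans seed each grid cell with its neighbors' states
(piecewise grid-seeded continuation). One-parameter cuts default to
μ = 0.6 h⁻¹. Note that the low-TapA state never disappears at high
Spo0A~P in this parameterization — activation is strictly
fluctuation-driven — so hysteresis sweeps start the descending pass from
the matrix-on state at the top of the path.

## Stochastic engine

Next-reaction method: each reaction keeps a putative firing time; after a
firing, the fired reaction redraws and dependent reactions rescale their
putative times by the old/new propensity ratio. At discontinuous
parameter changes (cycle start, replication, division) all putative times
are redrawn. Propensities use the fixed 4 fL volume throughout the cycle
(no volume growth). Samples record the state immediately before any event
scheduled at the same instant. Negative counts are asserted against at
every event.

The starvation protocol follows one cell per lineage: at each cycle start
draw τ_cyc from the corrected truncated normal, set μ = ln2/τ_cyc and
Spo0A~P = map(strain, μ) for the whole cycle, schedule gene doublings at
p·τ_c(μ), split every species Binomial(n, 1/2) at division and follow one
daughter. Initial state: the deterministic matrix-off steady state at
μ(0), rounded to counts. Per-lineage child seeds derive from the root
seed by a fixed affine scheme; a growth/partition stream (NumPy
generator) and a reaction-timing stream (kernel RNG) are both seeded from
the lineage seed. The growth-arrest counterfactual clamps μ(t) at its
value at the freeze time (the time-shift lookup then saturates there).

Problem sizes: the packaged analyses and tests use ensembles of a few
hundred to 1000 lineages over 14 h sampled every 0.5 h; fixed-condition
distributions sample a single long lineage (>100 h) on the same 0.5 h
grid.

## Fate statistics

At the 8 h observation point a cell is *sporulating* if the growth rate
of its current cycle is below the strain's threshold and *matrix-on* if
its TapA reporter count strictly exceeds 500 molecules (the first
histogram bin, width 500, holds the non-expressing cells). Summaries
report the law-of-total-probability decompositions exactly; conditional
means over empty subgroups are NaN, never zero. Peak times of noisy mean
curves use the argmax of a centered 3-point moving average.

Because growth-rate noise is resampled independently each cycle, the
single-cell anticorrelation between sporulation and matrix expression
emerges from two channels only: cells in slow cycles sit below the
bistable exit and their (unstable) reporter decays, and late stochastic
activation happens preferentially in currently fast cycles. Both
channels are weak for strains that finished switching early; with the
default map the wild-type non-spo/spo fold change is ≈1.5–2 while
Δsda's is ≈1.2, reproducing the direction (Δsda weakens mutual
exclusivity) rather than the exact magnitudes.

## Synthetic reporter tables

The generator emulates segmented dual-reporter microscopy output: 9
images (3 images × 3 cultures) of 600–1600 cells, each cell carrying GFP
and mCherry mean intensities drawn from log-normal on/off mixture
components on top of Gaussian background, with the two fates coupled
through an odds ratio. It reproduces the statistical structure the
thresholding analysis assumes — it does not emulate segmentation errors,
shading, bleed-through, or spatial correlation within images, so passing
recovery tests validates the analysis pipeline, not image processing.
"Significantly above background" is operationalized as mean + 3 SD of the
no-cell background (configurable); strain comparisons use per-image
non-spo/spo fold changes and Welch's t-test (n = images per group),
pooled-variance optionally.

## Known limitations

* Holding the population growth rate fixed from 6 h onward slows the
  decline of the expressing fraction but does not make it rise again:
  at the frozen growth rate (≈0.32 h⁻¹) the intrinsic-noise escape rate
  of this parameterization is already negligible, while occasional
  slow cycles below the bistable exit keep eroding the expressing pool.
  A growth-arrest counterfactual that keeps activating therefore lies
  outside this calibration (the corresponding test documents this).

* The Spo0A~P map is phenomenological; quantitative strain dynamics
  (absolute fractions, Miller-unit curves) require an external
  phosphorelay solution.
* Switch-off relaxation below the bistable exit takes hours at slow
  growth (the SinR rebuild is slow when dilution is weak), so
  observation-time statistics depend on how long cells have been slow.
* One daughter is followed per division (no population tree), and the
  growth-rate noise is white across cycles; mother-daughter growth
  correlations are not modeled.
* The eps operon is not modeled separately; the *tapA* promoter logic
  stands for both.
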