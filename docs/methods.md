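# Methods

## The model system

All estimators in this package are exercised on analytic 1D free-energy
profiles U(d₁) along the ligand–active-site distance d₁ (Å), built as sums
of Gaussian wells and barrier bumps plus harmonic walls (default onset
2.5 Å and 25 Å, 10 kcal·mol⁻¹·Å⁻² — the upper wall mirrors the 23 Å
distance restraint used in funnel-restrained sampling of real systems).
Amplitudes are calibrated by a small fixed-point solve so that the
numerically measured extrema hit the nominal feature values to better than
10⁻⁴ kcal/mol:

* `dhaa31like` — bound well at 5.94 Å (shifted to 0), one barrier of
  4.81 kcal/mol, tunnel-mouth minimum at 12.14 Å placed 1.5 kcal/mol above
  the global minimum, unbound plateau 2.5 kcal/mol up.  The mouth-minimum
  and plateau offsets are not published quantities; they were chosen once
  to make release thermally accessible while keeping the bound basin
  dominant.
* `dhaawtlike` — bound well at 5.9 Å, two barriers of 2.26 and
  1.46 kcal/mol with intermediate minima at 10 and 13 Å (0.9 and
  1.2 kcal/mol up), plateau 2.0 kcal/mol up.
* `doublewell` — symmetric wells at 8 and 16 Å, barrier 5 k_BT
  (2.98 kcal/mol at 300 K) at 12 Å; the workhorse for oracle cross-checks.
* `flat` — zero potential between the walls.

A 2D variant adds an orthogonal "tunnel width" coordinate confined
harmonically, stiff inside the tunnel and soft outside (funnel-like
widening); the quantitative analyses all run on the 1D profiles, matching
the fact that release surfaces are reported projected on d₁.

Units are kcal/mol, Å, ps and amu throughout; k_BT(300 K) =
0.5962 kcal/mol (2.494 kJ/mol).  Conversions from the kJ/nm conventions of
MD input files live only at I/O boundaries (`units.py`).

## Langevin dynamics

The integrator is BAOAB splitting for underdamped Langevin dynamics
(timestep 0.02 ps by default, stable and configurationally accurate at
this step), with overdamped Euler–Maruyama as an option.  The effective
mass (40 amu) and friction are free parameters of the synthetic model —
nothing in the real-system literature pins an effective-coordinate
friction.  The default friction of 20 ps⁻¹ is chosen so that γ exceeds
the barrier curvature frequencies (ω_b ≈ 5 ps⁻¹), putting barrier
crossing in the overdamped Kramers regime; this makes the 1D
mean-first-passage-time closed form

    MFPT(x₀→b) = D⁻¹ ∫_{x₀}^{b} dy e^{U(y)/k_BT} ∫_{a}^{y} dz e^{−U(z)/k_BT},
    D = k_BT/(mγ)

an accurate independent oracle for the dynamics actually simulated (the
medium-friction Kramers correction at these parameters is ≈6%).  The
oracle has two implementations — trapezoidal quadrature of the double
integral on a 40 001-point grid, and a brute-force average of ≥500
overdamped first-passage simulations — which agree within a few percent on
all presets; every k_off estimator is validated against them.

Configurational sampling of the integrator is itself validated: on the
double well, occupancy ratios match the exact Boltzmann integrals, and
−k_BT ln(histogram) reproduces the potential with RMSE < 0.1 kcal/mol over
well-visited regions.

## Metadynamics engine

Hills (default 0.60 kcal/mol initial height, bias factor γ = 10) are
deposited on the d₁ coordinate every 50 ps for rate runs and every 2 ps
for free-energy runs.  The hill width (0.25 Å) is set to a fraction of the
model well widths (~1 Å); the much narrower widths used with atomistic
path CVs would be numerically wasteful here.  The bias and its force are
accumulated on a grid (spacing ≤ σ/4), so the per-step cost is independent
of the number of hills; the full hill list is also recorded and emitted in
a HILLS-style dialect.

Release runs stop depositing at the first crossing of the release
threshold (22 Å for the enzyme-like presets, 20 Å for the double well);
t_biased and the acceleration factor α = ⟨e^{V/k_BT}⟩ (a running average
over every integration step, evaluated at the instantaneous position) are
both taken at that first crossing.  "Without immediate rebinding" is
operationalized as a commit criterion: the run counts as released only
once the coordinate has stayed above a rebind floor (threshold − 4 Å) for
a 100 ps commit window; runs that never commit within max_time are
excluded from the fit and counted.  A diagnostic counts hills deposited
within 2σ of a barrier top and warns, since such depositions degrade the
validity of the time rescaling.  On the 5 k_BT double well the rescaled
release times converge to the MFPT oracle as deposition slows (ratio
0.97 at 1 ns stride) and sit within ~35% at the default 50 ps stride.

## Poisson analysis

τ_off minimizes Σᵢ (ECDF(tᵢ) − (1 − e^{−tᵢ/τ}))² over the sorted sample
with the midpoint plotting convention (i − ½)/n (less biased than either
step-plateau choice; the evaluation grid is otherwise arbitrary).  The
minimum is located on a 200-point log-spaced τ grid and refined by bounded
Brent iteration (relative tolerance 10⁻⁶).  The KS statistic compares the
full step ECDF with the fitted TCDF.  Two p-values are available:

* *asymptotic* (default) — the Kolmogorov distribution at √n·D.  Because τ
  is fitted from the same data this is conservative: under the null it
  essentially never rejects at 0.05.
* *parametric* — D is referred to its true null distribution, estimated
  from 500 simulated exponential samples refitted the same way
  (vectorized, ~10 ms per fit).  This gate is calibrated: under repeated
  exponential simulation (200 replicates, n = 25) it rejects 5.5% of the
  time at p < 0.05.

Ensembles failing the p > 0.05 gate are discarded, not reported (exit
code 3 in the pipeline driver).  Errors come from an n-of-n bootstrap with
replacement (500 resamples), reported as the SD of the refitted k_off.
The conformational-selection helper implements
k_obs = k₁ + k₋₁·K_d/([L] + K_d), the standard pre-equilibrium form whose
limits are k₁ at saturating ligand and k₁ + k₋₁ at zero ligand.

## Markov state models

Microstates come from mini-batch k-means (scikit-learn) on the 1D distance
feature, 200 clusters by default; trajectories shorter than a minimum
length are excluded at featurization.  Transition counts use a sliding
window at the chosen lag; the default estimator symmetrizes (C + Cᵀ)/2 to
enforce detailed balance (plain MLE is available), with unvisited states
dropped and indices remapped.  Macrostates (bound / tunnel / unbound) are
distance-threshold groups of cluster centres.  Rates are
stationary-weighted mean first-passage times from the microstate linear
system; affinities are reported two ways, since they differ in general:
k_off/k_on (an identity with the reported rates) and
K_d = C·π_unbound/π_bound from the stationary distribution, with
ΔG = −k_BT ln(π_bound/π_unbound) (standard-state term optional).  The
effective concentration C — one ligand per sampled volume — has no
defensible default in molar units and is a required input (the analysis
uses a nominal 0.05 M).

Lag choice: MSM mean first-passage times acquire an O(lag) positive bias
once the lag is comparable to the relaxation time.  The model landscapes
relax three orders of magnitude faster than the μs-scale systems whose
analysis conventions (0.1 ns frames, 15 ns lag, 20 ns trajectories) they
emulate, so the drivers use the correspondingly scaled 0.01 ns frames,
0.02 ns lag and 10 ns trajectories, 60 trajectories per system.  The
Chapman–Kolmogorov test (macrostate self-transition probabilities,
T(lag)^k vs re-estimated T(k·lag), stationary-weighted) validates the lag:
deviations stay below 0.02 on Markovian data and on the double-well swarm.
Bootstrap errors resample 80% of the trajectory list without replacement
(500 replicates in convention, 100 in the driver), keeping the microstate
definition fixed; replicates with an empty macrostate are skipped and
counted.

## Free-energy surfaces

Frame weights follow the Tiwary–Parrinello estimator,
log w = (V(s_t, t) − c(t))/k_BT with

    c(t) = k_BT ln [ ∫ e^{γV(s,t)/((γ−1)k_BT)} ds / ∫ e^{V(s,t)/((γ−1)k_BT)} ds ]

computed on the running bias grid after each hill ("final-bias" reweighting
is available as a cross-check).  Restraint handling: by default the
funnel/wall Boltzmann factor is divided out (frames get an extra
e^{+U_rest/k_BT}), and surfaces are reported only up to the wall onset,
where that correction is meaningful; ignoring the restraint entirely is an
option.  F = −k_BT ln(weighted histogram) on 0.1 Å bins, min-shifted to
zero, unvisited bins +∞.

Stationary points are located by an alternating-extrema scan with a
prominence threshold (hysteresis): an extremum is accepted only once the
surface moves away from it by more than the threshold.  The default
(10⁻⁴ kcal/mol) suppresses floating-point plateau noise on exact
surfaces; for statistically noisy reweighted surfaces the analyses use
0.3 kcal/mol (≈ k_BT/2, the scale of residual histogram noise), and state
searches are restricted to the pre-release region (≤ 20 Å), beyond which
the wall distorts the surface.  Barriers are max-between-adjacent-minima
minus the preceding minimum.  Convergence is tracked by recomputing the
FES from truncated data at checkpoints and integrating two basins:
ΔG(A,B) = −k_BT ln(Σ_A e^{−F/k_BT}/Σ_B e^{−F/k_BT}), plus the barrier
between them; a basin not yet visited yields a missing value.  On 50 ns
well-tempered runs (2 ps deposition) all preset barriers are recovered
within ~0.1 kcal/mol and the surface RMSE on visited regions is
≈ 0.1 kcal/mol.

State ensembles are frame-index lists within |d₁ − center| ≤ tolerance.
The ±0.01 Å convention used for dense atomistic trajectories is far too
narrow for coarsely saved model runs; the drivers use 0.05 Å.

## Hot-spot statistic

ΔΔG_bind = mean ΔG^min − mean ΔG^TS1 per residue, over per-frame
interaction-energy tables for the two state ensembles; more negative
means stronger retention in the bound minimum (the mutagenesis
candidates), ranked ascending.  The display rule flags residues with
|ΔΔG| ≥ 0.5 kcal/mol or pooled SD ≥ 0.5 kcal/mol; "pooled" is the max of
the two state SDs (the conservative reading of an SD-based rule that does
not name a state).  Strong TS1 binders (mean ΔG below a threshold) are
reported separately as transition-state stabilization targets.

## What the synthetic data does and does not show

The generator emulates the statistical structure of the inference problem:
barrier-controlled exponential release times, recrossing free-energy
sampling, swarm data with state mixing, and per-residue energy tables with
planted effect sizes and Gaussian noise.  Passing tests therefore
demonstrate the correctness and internal consistency of the estimators —
time rescaling, CDF fitting, MSM algebra, reweighting, ranking — at known
ground truth.  They do not probe the hard parts of the atomistic problem:
collective-variable suboptimality (hidden barriers orthogonal to the
biased CV), force-field error, path-CV construction from structures,
non-Markovian memory in real distance coordinates, or MM/GBSA energy
accuracy.  Quantitative agreement with experiment is out of scope by
construction; the published kinetic table enters only as input to the
reporting layer.

## Problem sizes

Defaults in the drivers and acceptance script: 25 release runs per system
(max 1 μs biased time each), 60 × 10 ns swarm trajectories (0.01 ns
frames), 50–80 ns well-tempered runs at 2 ps deposition, 500 bootstrap
resamples (100 for MSM replicates), 200 null replicates for gate
calibration.  These sizes give sub-minute stages on one CPU while leaving
all statistical tolerances comfortably resolved.

## Known limitations

* The fast engine biases only the 1D coordinate; path-CV and funnel
  machinery are exact but integrate through the slower generic stepper.
* The symmetrized count estimator is biased toward the empirical visit
  distribution when swarms are far from equilibrium; the MLE option
  trades that for non-reversibility.  Spectral (PCCA-like) coarse-graining
  is not implemented.
* K_d and k_on in molar units inherit the arbitrariness of the effective
  concentration C; only ratios and ΔG differences are
  concentration-independent.
* The parametric KS gate refits with a grid (not Brent) inside the null
  simulation; the residual discreteness is far below the gate's 3%
  tolerance band.
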