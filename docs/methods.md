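# Methods

This note records the models implemented in riboflex, the conventions and
numerical choices behind them, and what the synthetic-data generators do
and do not emulate.

## Spin relaxation (module `relaxation`)

Peak heights of imino ¹H–¹⁵N correlations are fit to I(t) = A·e^(−R·t) by
nonlinear least squares (trust-region reflective, rate constrained ≥ 0).
Starting rates come from a two-point log estimate between the first and
last positive intensities, repeated at 0.5× and 2× that estimate; the
best χ² start wins.  The default delay lists mirror the acquisition
design being emulated: longitudinal delays 100(×2), 200, 400, 700, 1000,
1300, 1700, 2100 ms and spin-lock durations 1, 10(×2), 20, 40, 60, 100,
160, 220 ms under a 1.5 kHz spin-lock.

Rate uncertainties are Monte-Carlo: the best-fit curve is resampled
`mc_iters` times (default 500) with Gaussian noise and refit; σ_R is the
SD of the refitted rates.  The noise SD comes from replicate-delay pairs
as the RMS of |ΔI|/√2 pooled over series; when no replicates exist the
fallback is the fit's residual RMS, and the fit is flagged.  Covariance-
based errors would also have been defensible; Monte-Carlo was chosen
because it handles the rate-amplitude correlation without linearization
and the replicate pairs give a noise scale that is independent of the
model.

R2 is derived from the rotating-frame rate by the tilt-angle relation.
The two textbook forms R2 = R1ρ/sin²θ − R1·tan²θ and
tanθ = Δν/ν₁ are combined in the algebraically equivalent form

    R2 = R1ρ·(1 + tan²θ) − R1·tan²θ,

which reproduces the on-resonance limit R2 = R1ρ exactly at Δν = 0 (the
regime in which on-resonance spin-lock data are recorded; a literal
R1ρ/sin²θ with tanθ → 0 diverges).  σ_R2 is propagated linearly.  The
hetNOE is I_sat/I_unsat with relative errors added in quadrature; when
I_sat = 0 an absolute fallback σ = σ_sat/|I_unsat| is used and flagged.

R2/R1 and R2·R1 summaries use single-pass outlier exclusion: mean and SD
(population SD, ddof = 0) over all residues, then residues deviating by
more than k·SD (default k = 1.5) are dropped and the retained mean ± SD
reported.  The pass is deliberately not iterated — iterating k·SD
trimming changes the retained set on synthetic data and there is no
basis for preferring any particular fixed point.

## CPMG dispersion (module `dispersion`)

Effective rates come from constant-time intensities,
R2eff = (−1/T)·ln(I/I₀), with T = 50 ms for the main frequency block
(80–800 Hz) and 60 ms for the 66.67/133.33 Hz block; ν = 0 rows are
reference spectra, averaged into I₀ and never fitted.  Point errors are
σ = ΔI/(T·I) with ΔI the replicate difference at 640 Hz; residues
without a replicate receive the pooled ΔI of the others and are flagged.
σ values below 2% of the median σ are raised to that floor so no single
point acquires effectively infinite weight.

The two-site fast-exchange model is

    R2(1/τcp) = R2⁰ + Rex·[1 − 2·tanh(kex·τcp/2)/(kex·τcp)],
    Rex = pa·pb·Δω²/kex.

pa, pb and Δω are not separately identifiable from this expression, so
the package reports only Rex and the composite Φ = Rex·kex.

**τcp convention.** The model's abscissa is the pulsing rate 1/τcp, and
by default the listed ν_cpmg values are read as exactly that rate
(τcp = 1/ν_cpmg, `tau_convention="reciprocal"`).  The also-common
counting of full echo cycles (τcp = 1/(2·ν_cpmg), `"half"`) is
selectable everywhere; the two differ only by a factor-of-two rescaling
of kex.  The reciprocal reading is the default because it is the direct
reading of the model as written and because, at the exchange rates of
interest here (~80–450 s⁻¹) and this frequency grid, it places the
dispersion roll-off inside the sampled window.

**Grouped fits.** In individual (one residue), segmental (one secondary-
structure element) and global scope the fit shares one kex across all
member residues and both fields.  R2⁰ is free per (residue, field) and
shared between the 50 ms and 60 ms constant-time blocks — the block
length does not change the intrinsic rate, and giving the two-point
60 ms block its own baseline would absorb precisely the low-frequency
points that carry most of the kex information.  Each residue has one
exchange amplitude referenced to the lowest field; at other fields it is
scaled by the squared field ratio, since Δω in rad/s is proportional to
B₀ and Rex is quadratic in Δω.

**Optimization.** For fixed kex the model is linear in every remaining
parameter, so χ²(kex) is profiled exactly by small weighted linear
solves (one per residue; negative amplitudes are clamped to zero and the
baselines re-solved) and minimized in one dimension: a 121-point log
grid over kex ∈ [1, 10⁵] s⁻¹ plus bounded refinement seeded at the grid
minimum and at 50, 200, 800 and 3200 s⁻¹.  This is equivalent to the
full joint weighted least squares but immune to poor starting values,
and it is verified in the tests against brute-force grids over
(kex, Rex, R2⁰).  Parameter errors and the 95% kex interval are
Monte-Carlo (default 200 resamples of the best-fit curve at the point
σ's, percentile interval).  A residue whose amplitude is statistically
indistinguishable from zero (Rex 95% bound reaches 0 and Δχ² against a
flat profile < 2) is flagged `no_detectable_exchange`.

**Identifiability.** When kex·τcp ≲ 1 over the whole grid the bracket
approaches its fast-pulsing expansion ∝ (kex·τcp)²/12 and only the
product Rex·kex² is constrained; the profile likelihood in kex is then
nearly flat and the point estimate can collapse toward the flat-profile
branch.  This happens by construction for slow exchange (~80 s⁻¹) with
small amplitudes (Rex ≈ 1–4 s⁻¹) at σ ≈ 0.3 s⁻¹ noise.  The Monte-Carlo
interval remains honest in this regime — it widens to span the weakly
constrained range — which is why interval coverage, not point accuracy,
is the meaningful recovery statement there.

## Chemical-shift perturbations (module `csp`)

Δδ_comp = √(Δδ_H² + (Δδ_N/6.5)²) in ppm, the 6.5 divisor compressing
the nitrogen scale; the same formula is applied to imino and long-range
(N1/N3/N7/N9) data.  Flagging uses a strict > 0.05 ppm threshold; ties
are not flagged.  Peaks present in only one state carry no shift
difference and are reported as categorical appeared/lost lists rather
than being given a pseudo-perturbation.

## Guinier analysis (module `guinier`)

ln I = ln I₀ − Rg²q²/3 is fit by weighted linear regression of ln I on
q², weights 1/σ(ln I)² with σ(ln I) = σ_I/I (unweighted when errors are
absent).  The window starts at the lowest min(15, n/3) points and
iterates: fit, compute R̂g = √(−3·slope), keep exactly the points with
q·R̂g < 1.3, refit, until the window repeats (≤ 20 iterations).
Non-decaying data raise a no-Guinier-region error; a window below 5
points raises an insufficient-data error.  Parameter errors come from
the regression covariance scaled by reduced χ².  No beamstop/low-q
exclusion heuristic is applied; flagging bad leading points is left to
input preparation.

## B-factors (module `bfactor`)

Coordinate files are parsed with gemmi.  Per residue, the mean B is
occupancy-weighted over non-hydrogen atoms, so alternate conformers
contribute in proportion to occupancy.  Waters are dropped; non-RNA
residues (ligands, ions) are kept in a separate `hetero` list.  Region
averages are unweighted means of residue means; overall averages are
likewise means of residue means over all RNA residues of the selected
chain(s) — averaging over atoms instead would weight large residues
more and is deliberately not the default.  The shipped region map
(P1/P2/P3, L2/L3, J1/2, J2/3, J3/1 over residues 13–84) reconstructs the
secondary structure from the residue-level assignments available for
this construct and is user-overridable JSON; all region-level numbers
are only as exact as that map.

## Four-state kinetics (module `kinetics`)

The scheme apo1 ⇌ apo2 + ade ⇌ IB·ade ⇌ B·ade is integrated as mass-
action ODEs with an explicit free-ligand pool (no pseudo-first-order
approximation), LSODA with analytic Jacobian, rtol 1e−8 / atol 1e−12.
Units are fixed to µM and seconds; k_on is in µM⁻¹s⁻¹.  Defaults are
the stopped-flow regression constants k_op = 2.1, k_cl = 0.53 s⁻¹,
k_on = 0.37 µM⁻¹s⁻¹, k_off = 45, k_f = 132, k_r = 5.8 s⁻¹ and
observable scaling sc = 2.58.  RNA and adenine totals are conserved
exactly by the dynamics and to integrator tolerance numerically.  The
fluorescence-like observable is sc·Σwᵢ·stateᵢ(t) with user weights,
defaulting to an indicator on the docked state; which states carry
reporter intensity is not determined by the scheme itself, so the
weights are an explicit input.  Fitting rate constants to data is out
of scope — only forward simulation is provided.

## Synthetic data (module `synthdata`)

One global seed fans out to independent per-generator streams keyed by
generator name (CRC32 of the name as a spawn key), so adding a generator
never shifts existing draws and identical specs are byte-reproducible.
The generators emulate the statistical structure the analyses assume:
exponential decays with Gaussian intensity noise and duplicated delays;
dispersion profiles drawn from the two-site model on the nine-point
frequency grid with its repeated 640 Hz point, the 50/60 ms block split
and squared-field-ratio amplitude scaling; Guinier-form curves with
multiplicative noise; and minimal synthetic PDB text with prescribed
B/occupancy columns.  They do not emulate spectral artifacts (overlap,
baseline distortion, solvent exchange line broadening), non-Gaussian or
correlated noise, deviations from two-site exchange, or non-Guinier
scattering at higher q — so passing recovery tests demonstrates
correctness of the estimators under the stated noise model, not
robustness to everything real spectra contain.

## Problem sizes

Default problem sizes were chosen to match the emulated acquisition
designs: 9 CPMG frequencies × 2 fields per residue, 9 relaxation
delays, 60-point scattering curves, 200-sample Monte-Carlo intervals
(500 for exponential rates).  Recovery statements in the tests use
100-instance ensembles for interval coverage and 20-instance ensembles
for oracle agreement.

## Known limitations

* Only the fast-exchange (tanh-bracket) dispersion model is implemented;
  no Carver–Richards slow-exchange treatment, so populations and Δω are
  never separated.
* No model-free (Lipari–Szabo) analysis of R1/R2/NOE; R2/R1 and R2·R1
  are reported as semi-quantitative summaries only.
* The Guinier window rule assumes a clean low-q region; systematically
  bad leading points must be removed upstream.
* B-factor comparisons across crystal forms are raw (no resolution or
  TLS normalization).
* The kinetics module simulates; it does not estimate rates from traces.
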