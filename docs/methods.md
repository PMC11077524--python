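# Methods

## Units and conventions

Internal units are eV (energies and frequency quanta), fs (time) and K
(temperature), with ħ = 0.6582119569 eV·fs, k_B = 8.617333262×10⁻⁵ eV/K and
1 eV = 8065.544 cm⁻¹.  Wavenumbers appear only at I/O boundaries.  The gap
coordinate is ΔV = V_B − V_A, so a downhill process has ΔA = A_B − A_A < 0,
the mean vertical gap on the initial surface is ΔA + λ, and the two
diabatic free-energy curves cross at ΔV = 0.  The default temperature is
298.15 K everywhere; the β-reduced parameters of the coarse-grained
recombination bath are converted at this temperature (βλ_total = 18.8239
gives λ = 0.4836 eV, consistent with the tabulated 0.483 ± 0.003 eV for the
¹CT → S0 process), which fixes the otherwise free absolute energy scale.

## Bath description

A transition's nuclear environment is a harmonic bath with unit-area
spectral distribution ρ(ω) and reorganization energy λ; the conventional
spectral density is J(ω) = πλωρ(ω).  Two analytic families are provided —
overdamped Debye, ρ_D ∝ 1/(1 + (ω/ω_D)²), and underdamped Brownian
oscillator, ρ_BO ∝ γΩ²/((ω²−Ω²)² + γ²ω²) — plus densities fitted from
trajectories.  Printed prefactor conventions of the analytic forms are
shape-only: every density is renormalised on its grid and λ carries all
scale.  Both families admit exact exponential decompositions C(t) =
Σ_j c_j e^(−ν_j t/ħ) (pole residues plus Matsubara terms), computed here by
residue arithmetic and validated against direct quadrature of C(t); the
identity Im Σ c_j/ν_j = −λ holds exactly and is tested.

## Synthetic data

The generators replace molecular-dynamics and quantum-chemistry inputs with
exactly solvable surrogates, so every estimator can be validated against
closed forms:

* **Gap trajectories** are mode superpositions: frequencies drawn from ρ by
  inverse-CDF sampling, each mode carrying a fixed thermal amplitude with a
  random phase.  The total variance is pinned to the linear-response value
  2λk_BT (no chi-squared spread between realisations) and the process is
  Gaussian to central-limit accuracy for the enforced minimum of 100 modes;
  the expected autocovariance is 2λk_BT ∫ρ(ω)cos(ωt/ħ)dω exactly.
* **Two-state samples** follow the shifted-harmonic model: Gaussian gaps
  with means ΔA ± λ and variance 2λk_BT under either surface, with reduced
  energies u_B = u_A + βε so multistate reweighting sees the exact model.
* **Umbrella windows** sample the harmonic-plus-bias Gaussian exactly for
  any window center and curvature.
* The **parameter table** transcribes the eight tabulated BD-An processes.
  Two reorganization energies are printed with negative signs in the
  source; λ is nonnegative by definition, so they are stored positive with
  a provenance flag rather than silently corrected.

What the generators do not emulate: anharmonicity, non-Gaussian gap
statistics, slow conformational drift, and surface-dependent spectral
densities.  Passing tests therefore certify the estimators and rate
theories on their stated model class, not force-field realism.

## Spectral-density fitting

The fitted shape is the Hann-tapered cosine transform of the stationary
autocovariance of δΔV, clipped at zero and renormalised (clipped mass is
reported as a diagnostic); λ comes from the classical variance σ²/(2k_BT)
unless overridden by the resonance-density calibration.  Trajectories whose
half-means differ by more than 3σ (block estimate) are rejected as
drifting.  The default transform window of 150 fs trades frequency
resolution against mode-sampling noise; the default grid spans 0–0.75 eV
(≈6000 cm⁻¹, covering aromatic C=C stretches) with 4096 points.  The
inner/outer/cross decomposition transforms the component auto- and
symmetrised cross-covariances separately; bilinearity guarantees the λ
contributions sum to the total, and an optional scalar rescales the
outer-sphere part when it must represent a different solvent model.

λ calibration solves p^Gauss(0; m, 2λk_BT) = p̂(0) for λ with the sample
mean m fixed, by bracketed root search; with two roots the one nearest the
variance-based estimate is returned.  p̂(0) defaults to the quadratic-CDF
extrapolation below.

## Free-energy estimation

MBAR is solved by self-consistent iteration interleaved with Newton steps
on the gradient (a Newton step that worsens the self-consistency residual
is rejected), to a relative tolerance of 1e-12; uncertainties come from the
standard asymptotic covariance evaluated through the thin SVD of the weight
matrix.  Curves are histogrammed from MBAR weights with bins reported only
where the Kish effective sample count is at least 50.  WHAM is the binned
self-consistent counterpart for umbrella windows; the two agree pointwise
on shared inputs.  The quadratic extrapolation fits a Gaussian (quadratic
free energy) by minimising the Cramér–von Mises distance to the empirical
CDF — chosen over moment matching for robustness to sparse tails and over
maximum likelihood for determinism — and reads the barrier off as
k_BT·m²/(2σ²); even polynomial degrees above 2 are supported through a
numerically normalised density.

## Golden-rule rates

Two independent evaluations of the quantum FGR integral are implemented
and cross-checked:

1. **Gridded densities** (fitted or tabulated analytic): the contour is
   shifted through the imaginary-time saddle τ\*, found by minimising the
   always-convex Re G(−iτ) inside a bracket around the classical saddle
   βħ(ΔA+λ)/2λ, and the integral is accumulated relative to e^{G(−iτ\*)} in
   logs.  A compactly supported (gridded) density makes the integrand
   entire, so the shift is legitimate for either sign of τ\*; rates from
   1e-17 to 1e15 s⁻¹ evaluate without cancellation.  Adaptive span
   extension continues until the shifted integrand decays below 1e-10, and
   a ×2 grid-refinement check is available (observed changes ~1e-11).
2. **Exponential-mode baths** (the HEOM's own representation): g(t) is
   closed-form in the mode sum, and the integral is taken on the real axis
   by uniform trapezoid with dt = 0.02 fs — spectrally accurate for a
   smooth decaying integrand, resolving cancellation to ~1e-12 of the
   integrand scale.  Lorentzian-tailed baths are not compactly supported
   (upward analytic continuation diverges), so the real-axis route is the
   correct one there; it covers every case this bath family produces
   because the same tails lift deep-inverted rates far above the
   cancellation floor.

Both routes agree to 0.1% on shared baths, match Marcus in the classical
limit, match the Marcus–Levich–Jortner sum for a single underdamped mode
plus slow solvent, and satisfy detailed balance k_f/k_b = e^{−βΔA} to
numerical precision.  A practical caveat surfaced by the cross-checks: in
the deep inverted regime the rate is dominated by the high-frequency tails
of the spectral distribution, so Lorentzian-tailed model baths can give
rates orders of magnitude above a compact-support density with the same λ
and peak structure.  Ratios of rates on the *same* bath (as in the
recrossing analysis) are robust; absolute deep-inverted rates are only as
good as the density's tails.  The A/B-surface average is the arithmetic
mean of the two rates, not of the densities.

## Spectra and radiative rates

Lineshapes are Fourier transforms of e^{G(t)} on a time grid that runs
until the correlation function has decayed (a resolution warning fires
otherwise), with absorption using the initial-surface density (drift
ΔA + λ) and emission the final-surface density conjugated (drift ΔA − λ),
giving mirror symmetry about ΔA and a first-moment Stokes shift of exactly
2λ.  A rigid 805 cm⁻¹ shift of all excited states — the global offset that
aligns the computed absorption maximum with experiment — is applied as a
frequency offset.  Composite emission weights are p_state·μ²_state with
populations from K_CS = e^{−βΔA_CS}; the Weller estimate ΔA_CS = +0.13 eV
is available as a named alternative and suppresses the CT band essentially
completely.  Radiative rates use the vacuum prefactor k_r =
(4/3)α³⟨(E/E_h)³⟩μ²/t_au with no refractive-index correction; evaluated on
the ¹BD\* emission lineshape this reproduces the tabulated 1.0747×10⁸ s⁻¹
to 0.3%.

The ¹CT radiative rate printed in the source is internally inconsistent
(its exponent disagrees with the printed ground-state-reformation
branching); the kinetic network therefore defaults to the μ²ω³-scaled
value k_F(¹CT) = k_F(¹BD\*)·(μ²_CT/μ²_BD)·(|ΔA_CT|/|ΔA_BD|)³ = 7.1×10⁶
s⁻¹, switchable to any user value.

## HEOM and the recrossing factor

The coarse-grained ¹CT → S0 model is a donor/acceptor two-level system
(δE = −2.397 eV, H = 1904 cm⁻¹) coupled to one Debye and one underdamped
Brownian-oscillator bath (βω_D = 0.1831, βλ_D = 10.1459; βγ = 4, βΩ = 6.76,
βλ_BO = 8.6780).  The system-bath coupling operator is the *acceptor*
projector, i.e. the bath displaces on the acceptor surface: "donor-localised
with the bath equilibrated to the donor" is then exactly the factorised
initial condition with all auxiliaries zero, eliminating any
pre-equilibration transient and the numerically hostile coherent-amplitude
auxiliary ladder of the donor-displaced frame.  The donor level sits at
−(δE + λ), making the donor→acceptor free energy change δE and the mean
vertical gap δE + λ, consistent with the golden-rule conventions above.

Scaled auxiliaries are truncated with per-mode caps on the three resonant
modes (the slow Debye mode needs depth ≈ 20–30 while the oscillator pair
needs ≤ 6; a total-order cap at the Debye depth would be ruinously large)
and a total-order simplex cap (default 2) across the weakly excited
Matsubara modes; the truncated Matsubara tail enters as the Markovian
correction −(δ/ħ²)[Q,[Q,·]] with δ = Σ_{k>K} c_k ħ/ν_k.  Propagation uses a
sparse Krylov/Taylor matrix exponential with trace and Hermiticity
monitored (conserved to ~1e-12 and ~1e-7 respectively).

Rates are read from the side flux k(t) = (2H/ħ)·Im ρ_DA/P_D once it
plateaus (<2% drift over the trailing quarter of the run; 300 fs suffices
for this bath), or from a log-linear fit of the donor decay; the two agree
within 5%.  The recrossing factor is k_HEOM/k_FGR with the golden-rule
denominator evaluated on the *identical* truncated bath (same Matsubara
count and Markovian tail), so bath-representation error cancels between
numerator and denominator.  At weak coupling (H/20) the two agree to
0.03%, confirming the machinery; at the full coupling the ratio is 0.87,
essentially converged against hierarchy depth (+8), Matsubara count
(2→8) and simplex order (2→3), quantifying a ~13% recrossing reduction of
the golden-rule recombination rate.  Whether flux-plateau or decay-fit
extraction is used changes the ratio by under 5%.

## Kinetic network

The pre-equilibrium expressions (populations from K_CS, k_CR as the sum of
the four ¹CT decay channels, k_CR,eff as the population-weighted total
decay) give Φ_T = 0.795, Φ_F = 0.0454, φ_CRT = Φ_T/(1−Φ_F) = 0.833,
pathway fractions 14/47/39% over (³CT, ³An\*, ³BD\*), ground-state
reformation branching 64/14/22% over (direct nonradiative, radiative ¹CT,
delayed ¹BD\* fluorescence), and τ_T = 95.7 µs.  The exact master equation
over all six states — with detailed-balance reverse rates and the fast
spin-allowed ³CT relaxation represented explicitly at 10⁴ times its
spin-forbidden counterparts — is solved spectrally (eigendecomposition;
population conserved to ~1e-12 across rates spanning seven decades) and
its first-passage triplet yield agrees with the pre-equilibrium value to
0.1%, justifying the approximation whenever k_CS,eff/k_CR,eff ≳ 100.

## Problem sizes and numerical defaults

Synthetic studies use 5×10⁴ samples per state for MBAR (uncertainty ~4 meV,
matching the tabulated <5 meV claim), 12 umbrella windows of 2×10⁴ samples,
2×10⁵-step gap trajectories with 400–1000 modes, and HEOM hierarchies of
~2×10⁴ auxiliaries (caps [24, 6, 6], K = 4 Matsubara terms, simplex order
2) for the production recrossing number.  These sizes were chosen so each
estimate's sampling error sits well inside the tolerances asserted in the
test suite.

## Known limitations

Condon approximation throughout (coordinate-independent couplings); no
spin-vibronic corrections; the spin-boson mapping assumes Gaussian gap
statistics, which the source analysis itself flags as its main uncertainty
for the triplet-lifetime process; absolute deep-inverted FGR rates are
sensitive to spectral-density tails (see above); the HEOM covers only the
two-state, Debye + Brownian-oscillator family needed here; and the quantum
detailed-balance weighting of the fitted spectral distribution is the bare
second-order-cumulant form — classical shape with quantum propagation —
which the Marcus and MLJ limit checks validate but which is not unique.
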