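# Methods

This note documents the models implemented in `deerkin`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations of the analysis.

## DEER forward model

A doubly nitroxide-labelled DNA duplex produces the dipolar signal

    V(t) = V(0) · exp(−α t^ξ) · (1 − λ ⟨cos(D r⁻³ (1 − 3cos²θ) t)⟩)

* `D = μ₀ g_A g_B μ_B² / (4π ħ)`, stored in rad·MHz·nm³; with the
  nitroxide g-value 2.0060 for both spins, D/2π = 52.23 MHz·nm³, so a
  3.94 nm pair has its perpendicular Pake edge at 0.854 MHz.  Units are
  fixed package-wide: t in µs, r in nm, frequencies in MHz.
* The angular average runs over θ ∈ [0, π/2] with the sin θ weight.  The
  reference evaluation is fixed-order Gauss–Legendre quadrature with 512
  nodes (converged to well below 1e-6 for r ≥ 1.8 nm, t ≤ 10 µs, checked
  against a 4096-node oracle in the tests); a closed form in Fresnel
  integrals is the fast path and agrees with the quadrature to ~1e-15.
  Tabulated kernels used by the fitters are built with the Fresnel path.
* P(r) is a mixture of Gaussians, each integrated on 64 Gauss–Legendre
  nodes over ±5 standard deviations (clipped to r > 0) against its own
  density and renormalised — exact to machine noise for the analytic
  component structure.
* Sign convention: `V_intra = 1 − λ⟨cos⟩` exactly as written above, under
  which the normalisation step maps V_intra onto ⟨cos⟩ identically:
  V_intra(0) = 1 − λ, V_intra(∞) = 1, and
  (V_intra − V_intra(∞))/(V_intra(0) − V_intra(∞)) = ⟨cos⟩.  This
  self-consistency is the package contract; the more common
  `1 − λ(1 − ⟨cos⟩)` convention differs only by the same normalisation
  and does not change any recovered distribution (λ cancels, which the
  tests verify).
* The background exponent ξ models excluded volume between biradicals;
  the default simulated acquisition is 12 ns steps from 0 to 6.5 µs
  (543 points), with α = 0.1 µs⁻ξ, ξ = 1.03, λ = 0.3 as the standard
  generator conditions.

## DEER inversion

1. **Background tuning.**  For each ξ on the grid 0.80–1.50 (step 0.01),
   α and an amplitude factor are fitted by linear least squares on
   log V over the final 25% of the trace (where the intramolecular
   oscillations have decayed), the background is divided out (the signal
   model is multiplicative), the corrected trace is normalised and
   cosine-transformed, and ξ is chosen by minimising the zero-frequency
   spike metric `|bin₀ − median(bins 2–6)|`.  The fit window, the plateau
   estimator (mean of the final 15%) and the artifact metric are declared
   choices — the procedure itself only prescribes "minimise the
   zero-frequency artifact".
2. **Cosine Fourier transform.**  Type-I DCT of the 4×-zero-padded trace;
   frequency resolution 1/(2·padded span) ≈ 0.019 MHz.
3. **Monte Carlo multi-Gaussian fit.**  2×10⁵ uniform random draws —
   means on [2, 6] nm, widths on [0.05, 1] nm, fractions uniform on the
   simplex — scored by the frequency-domain χ² over [0, 8] MHz, followed
   by one local least-squares polish of the best draw (fractions
   parameterised as squared weights normalised to the simplex).  Draws
   use a 0.02 nm × 0.025 nm lattice of candidate spectra precomputed from
   the kernel table, so the search costs one gather-and-add per batch;
   the polish is continuous, so the lattice only sets the polish start.
   Default seed 20230714; fixed seeds give identical results.
4. **Joint refinement.**  The tail-window background estimate leaves a
   percent-level multiplicative distortion in V_n that measurably biases
   the fractions of overlapping components.  `invert_trace` therefore
   refines (V(0), α, ξ, λ, all component parameters) jointly against the
   raw trace, repeats the global Monte Carlo search on the refined
   background, refines again, and keeps the lower raw-trace residual.
   Noiseless round trips are then exact to the optimiser tolerance
   (~1e-4 nm).
5. **χ² scale and uncertainties.**  For white V_n noise of std 1/SNR the
   spectral bins have std (1/SNR)·Δt·√(N/2).  Dispersion (δr)
   uncertainties come from scanning each component width on a grid with
   all other parameters re-optimised; the reported uncertainty is the
   half-width of the χ² ≤ χ²_min + 1 region.  A fit is flagged
   unconverged when χ² exceeds 3× the number of spectral bins.
6. **Artifact handling.**  Components with fraction < 4% or mean in
   2.6–2.8 nm (the residual solvent-deuterium echo-modulation peak) are
   flagged and excluded from headline reporting, with the remaining
   fractions renormalised to 1.  The generator can inject such an
   artifact phenomenologically as an extra sub-4% Gaussian; the raw echo
   physics of ²H modulation is not simulated.
7. **Reporting.**  Components are sorted by descending fraction (ties by
   ascending mean); components closer than 0.05 nm with overlapping
   widths are merged.

### Information limit and the replicate protocol

The fraction split of strongly overlapping components is only weakly
identifiable on a single trace.  For the bimodal 25%/75% distribution at
3.94/4.60 nm (widths 0.36/0.34 nm) at V_n SNR 100 on the 6.5 µs grid,
the Cramér–Rao bound on the minor fraction is ≈12 percentage points,
with fraction and width 0.96-correlated; the maximum-likelihood solution
wanders between statistically equivalent blended and split
representations from one noise realisation to the next.  No unbiased
single-trace estimator can do better, so recovery benchmarks report the
**median over independently generated replicate traces** (median because
the wobble is heavy-tailed).  The recovery tests use 15 replicates,
which puts the median's standard error at roughly half of the ±8-point
recovery tolerance; the benchmark script uses 25 to push the Monte Carlo
error of the reported values further below that tolerance.
Component-level scores use many-to-one mass assignment — every retained
fitted Gaussian contributes its fraction to the nearest truth peak — so
the score does not punish a peak for being represented by two
overlapping Gaussians.  Peak *positions* of dominant components are
precise at the 0.02–0.05 nm level throughout and do not need this care.

## Kinetic models

The minimal incision mechanism is

    E + S ⇌(k1, k−1) ES →(kcat) EP ⇌(Kp) E + P

with mass-action rate equations integrated by a stiff-capable solver
(LSODA, rtol 1e-8, atol 1e-10 µM; conservation of enzyme and DNA holds
to 1e-6 µM).  Units: s, µM, µM⁻¹s⁻¹.  Only the *equilibrium* constant
Kp of the product step is experimentally constrained, so EP dissociation
uses k_off = 50 s⁻¹ (fast relative to kcat ≤ 13 s⁻¹) and
k_on = k_off/Kp.  Sensitivity, measured in the tests: between
k_off = 50 and 200 s⁻¹ the FRET observable changes by < 3% of its
amplitude; at k_off = 10 s⁻¹ (only ~2.5 × kcat) transient deviations
reach ~13%, which bounds how slow an off-rate the default tolerates.

The FRET observable is linear in the species:
`signal = offset + f_S[S] + f_ES[ES] + f_EP[EP] + f_P[P]`.  Because total
DNA is conserved, only differences to f_S are identifiable at a single
substrate concentration; the global fit therefore profiles out the three
differential coefficients (shared across traces) and one baseline per
trace by linear least squares inside the nonlinear optimisation.  The
generator defaults (f_S = 1.0, f_ES = 0.8, f_EP = 0.9, f_P = 1.8) encode
the observed stopped-flow shape — a small quench on complex formation
and a large rise on product formation/release; the true coefficients are
never reported and are treated purely as nuisance parameters.

**Global fit.**  Free nonlinear parameters are k1, kcat and Kp in log
space, with k−1 = k1/Ka constrained by the thermophoresis Ka; eight
log-spaced multi-starts, best χ² wins; asymptotic standard errors from
the Jacobian at the optimum.  **Exponential phases** are fitted by
variable projection (amplitudes and baseline linear in the rates) with
eight log-spaced multi-starts across the resolvable rate window of the
grid; negative amplitudes are allowed (quench phases).  **Product
accumulation** `A(1 − e^(−k_obs t)) + k_lin t` and the **MST isotherm**
`F_backgr + F_ampl[E]/(1/Ka + [E])` are fitted by bounded
Levenberg–Marquardt with data-driven starts.

## Synthetic data: what it does and does not emulate

All generators add Gaussian noise only and are byte-deterministic under
a fixed seed.  Conventions:

* **DEER** — the signal-to-noise ratio refers to the *normalised* trace
  V_n, so raw noise is scaled by λ·V(0)·V_inter(t); after processing,
  V_n carries white noise of std 1/SNR (the study conditions are
  SNR 50–100; benchmarks use 100).
* **Stopped-flow** — noise is 1% of each trace's peak-to-peak amplitude
  (the instrument noise level is not published; 1% is declared, not
  inferred).  Default enzyme series 0.25/0.5/1.0/1.5/2.0 µM over 1.0 µM
  substrate on a log grid 1 ms–200 s.  An optional linear drift term can
  emulate photobleaching (off by default).
* **Steady-state** — noise is a percentage of the burst amplitude,
  clipped to [0, 100]%.  The published experiments report only k_obs, so
  scenario curves use an 80% amplitude and no linear leak.
* **MST** — 12 log-spaced concentrations, 0.1–10 µM; noise is a
  percentage of the isotherm amplitude (background 100, amplitude 50
  signal units — arbitrary, as only Ka is compared).

Not emulated: raw echo signals and instrument response, orientation
selectivity (absent in the modelled experiments), gel images,
inner-filter/photobleaching corrections, and temperature dependence
(rate constants are condition-specific; 25 °C for the abasic substrate).
Passing recovery tests therefore demonstrate correctness of the analysis
chain under the stated noise model, not robustness to instrument
systematics absent from that model.

## Known limitations

* Fractions of overlapping distance components are information-limited
  (see above); single-fit fractions can differ from truth by >10 points
  at SNR 100 even though the replicate median is accurate.
* The Monte Carlo fitter assumes at most three Gaussian components and
  distances in [2, 6] nm, matching the systems modelled here.
* The EP off-rate is an assumption; only Kp is data-constrained.
* The ξ estimate from tail fitting alone is accurate to ~±0.03; the
  joint refinement sharpens it to ~±0.005, and ξ is reported at the
  0.01 resolution of the scan grid.
* Alternative kinetic schemes are not enumerated; the three-stage scheme
  is taken as given, and multi-phase curves of slowly-cleaved substrates
  are not assigned a mechanistic model.
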