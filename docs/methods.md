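# Methods

## The assay model

The dithionite scrambling assay is modelled with three pools of unbleached
NBD label.  In scramblase-containing liposomes the inner pool Li exchanges
with the outer pool Lo at the forward/backward scrambling rates α and β
(s⁻¹), and Lo is destroyed by dithionite at the reduction rate γ (s⁻¹):

    dLi/dt = −α Li + β Lo
    dLo/dt =  α Li − (β + γ) Lo

Protein-free liposomes (population fraction f₀) have no leaflet exchange;
only their outer fraction 1 − Liᴾᶠ is bleached at γ, while the protected
inner fraction decays at the very slow leak rate (dithionite permeation or
spontaneous flip-flop).  Total fluorescence is the f₀-weighted sum of the
two populations, normalised to the pre-addition level.

Assumptions baked into this scheme, and their limits:

* every vesicle is unilamellar and either fully scramblase-active or
  fully protein-free — multilamellarity and low-copy-number heterogeneity
  are lumped into f₀ and Liᴾᶠ;
* dithionite reduction is pseudo-first-order with a single γ shared by all
  vesicles (dithionite is in large excess);
* the scramblase pool starts from its scrambling steady state
  Li(0) = β/(α+β), Lo(0) = α/(α+β).  This is the initial condition under
  which the closed-form expression evaluates to exactly 1 at t = 0, which
  we verified numerically across a random parameter grid (max deviation
  ~1e-15); for the non-scrambling degenerate case α = β = 0 the symmetric
  split (1/2, 1/2) is used;
* the leak is negligible on the scrambling timescale, so it enters the
  simulator and the protein-free calibration but not the closed form used
  for proteoliposome fits.

### Closed form vs ODE

`closed_form_fluorescence` implements the biexponential eigen-expansion
literally, including its singular limits: α + β = 0 or D = 0 (the latter
occurs whenever α = 0) raise a degenerate-model error rather than being
patched algebraically, and callers fall back to `ode_fluorescence`.  One
exception: when f₀ = 1 the scramblase term carries zero weight and the
protein-free term is returned without evaluating the bracket.  The ODE
path integrates the rate equations with DOP853 at rtol = 1e-13,
atol = 1e-14; at these tolerances the two paths agree to better than 1e-8
everywhere (the closed form itself matches a matrix-exponential evaluation
to ~1e-15, so the residual difference is integration error).

## Fitting

* **Normalisation** divides by the mean of the pre-addition samples
  (≥ 10 required).
* **Protein-free calibration**: Liᴾᶠ and γ by bounded least squares of the
  two-exponential protein-free model over the early half of the
  post-addition samples; the leak by ordinary linear regression of
  fluorescence on time over the late half, after subtracting the fitted
  fast component — without that subtraction the residual tail of the γ
  phase inflates the leak estimate roughly two-fold at γ = 0.02 s⁻¹ on a
  400 s window.  The fractional leak rate is −slope divided by the plateau
  level.  Multiple traces are pooled as the across-trace mean with its
  standard error; the t-based confidence interval is exposed.  When the
  fitted Liᴾᶠ is ≈ 1 no label is exposed and γ is flagged unidentifiable.
* **Scrambling fit**: unweighted least squares of the closed form with
  f₀ ∈ [0, 1] and α, β ≥ 0, starting from the deterministic 3×3×3 grid
  α, β ∈ {10⁻³, 10⁻², 10⁻¹} s⁻¹ × f₀ ∈ {0.1, 0.3, 0.5}; the converged
  start with the lowest residual sum of squares wins, ties broken by
  first-found.  Standard errors come from the local curvature at the
  optimum; estimates pinned at a bound are flagged, as the curvature
  approximation is unreliable there.
* **Batch QC**: a batch is discarded when any monitored control parameter
  deviates from the historical control mean by strictly more than 3
  reference standard deviations; a deviation of exactly 3 SD is kept (the
  boundary convention is made explicit because conventions differ).

### Identifiability

The model's information content limits what any fit can recover.  The fast
eigenmode's amplitude scales roughly as [γ/(α+β)]² once scrambling is much
faster than reduction; at α + β = 0.2 s⁻¹ with γ = 0.02 s⁻¹ it is ~0.25%
of the signal — below a 1% noise floor.  In that regime only the slow
eigenvalue and the ratio α/(α+β) are determined, and the fitted α, β can
wander along a flat ridge while f₀ remains precise.  We verified this is
an information limit, not an optimiser artifact: the fitted residual norm
drops below the residual norm at the true parameters, and the Cramér–Rao
bound computed from the model Jacobian gives median relative standard
errors far above 5% for α, β drawn across [10⁻³, 0.3] s⁻¹ at this design.
Recovery benchmarks in the test suite therefore distinguish the
identifiable regime (α, β within roughly an order of magnitude of γ, where
median relative errors at 1% noise are ~3%) from the full range, where
only the identified combinations are meaningful.  Practically: report α, β
magnitudes only when they are comparable to γ; otherwise report α/(α+β)
and the slow rate.

## Synthetic data

The generator reproduces the assay design: 100 s flat unit baseline, a
dithionite step, 3 Hz sampling to 500 s total, the ODE model (leak applied
to the protein-free protected pool) and i.i.d. additive Gaussian noise,
default SD 1% of baseline — additive because photomultiplier traces at
fixed gain have signal-independent noise to first approximation, and no
noise model is standard for this assay.  Deterministic given a seed.  It
does not emulate photobleaching, instrument drift, mixing artifacts, or
per-vesicle copy-number variation, so recovery results bound what the
fitting can do on idealised data, not on traces with structured residuals.

The thickness series generator produces α(h) = α₀·e^(−slope·(h − h_ref))
with β = α (the forward and backward constants track each other across
lipid compositions), h_ref = 3.4 nm (the C18 reference bilayer), and
thicknesses restricted to the 3.0–4.2 nm range AFM measurements span.  For
end-to-end recovery demonstrations we use α₀ = 0.01 s⁻¹ at h_ref with
slope 3.5 nm⁻¹ over 3.2–4.0 nm — rates 0.0012–0.02 s⁻¹, the basal
(Ca²⁺-free) activity regime where the rates are identifiable at 1% noise —
with 3 replicates per composition; problem sizes throughout the tests
(≈ 10–20 traces per study, 1200 points per trace) are chosen as the
smallest that leave the statistical assertions comfortably powered.

## Energy barrier and thickness dependence

The Born slab barrier is implemented exactly as the closed form above, in
Gaussian convention: q in elementary charges, lengths in Å, energies in
e²/Å (332.0637 kcal/mol per unit; exposed as a constant).  Defaults
(q = 1 e, r = 4.5 Å, ε_m = 2, ε_w = 80) are conventional illustrative
values, not fitted quantities.  For ε_w > ε_m the logarithm is positive,
so ∂ΔG/∂L > 0 — thinning always lowers the barrier; no claim is made
about the ε_m-dependence away from that regime, which is not monotone in
general.  The thickness–rate regression fits ln(rate) on h by OLS
(reading "exponential inverse dependence on thickness" as rate ∝ e^(−c·h));
ln(rate) on 1/h — the form the slab term itself suggests — is available
via `regressor="inverse"`.  Non-positive rates are excluded with a
warning.  Pairwise fold changes are ratios of per-composition mean rates.
In the end-to-end pipeline the regression is run on per-condition mean
rates rather than per-replicate fits: ln-scale errors are strongly
heteroscedastic across conditions (slow conditions fit noisier), and
averaging within condition first keeps the slope's confidence interval
honestly calibrated at the cost of fewer degrees of freedom.

## AFM mechanics

The pyramidal-tip contact model is linear in E, so the fit is the
through-origin regression of F on δ² — exact, with a standard error from
the residual variance.  ν defaults to 0.5 (incompressible bilayer).  k_A
and k_c follow the plate-theory expressions; their ratio h²/24 is an
algebraic identity the tests assert to machine precision.  Height
distributions are summarised by the mode and full width at half height of
a Gaussian-kernel density estimate with Silverman bandwidth on a 2048-point
grid with interpolated half-maximum crossings; a warning is emitted when a
secondary peak also exceeds half height.  Caveat: Silverman's rule uses
the full-sample standard deviation, so strongly multimodal samples (e.g.
membrane plus bare-mica populations) are oversmoothed and the FWHH of the
dominant peak is then biased upward — segment the populations before
summarising in that case.  Degenerate (effectively constant) samples are
rejected via a relative spread threshold of 1e-9.

## Known limitations

* Each trace is fit independently; no hierarchical pooling across
  replicates and no Bayesian uncertainty.
* The leak window and fast-fit window are fixed fractions (50%) of the
  post-addition samples by default; very slow γ or short recordings need
  the fractions adjusted.
* The Born model is a single-sphere continuum estimate intended for
  trend analysis, not absolute barrier prediction.
* Force curves are assumed pre-processed to (indentation, force) pairs
  with the contact point at δ = 0.
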