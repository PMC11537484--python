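# Methods

## The cascade model and its operating point

The forward model is the standard G-protein cascade description of rod and
cone outer-segment currents: light isomerizes opsin (gain γ, decay rate σ),
active opsin drives phosphodiesterase (decay rate Φ, spontaneous activation
η), PDE hydrolyzes cGMP, cGMP gates the membrane current (I = k·Gⁿ), and
calcium entering through those channels feeds back on the cyclase synthesis
rate through a Hill curve (affinity K_GC, cooperativity m, extrusion rate
β). The transducin step is folded into the opsin→PDE transfer, and
photopigment bleaching/regeneration is outside the model's scope, which
limits cone applicability to means below roughly 50,000 R*/s.

Two constants are never free: `q` and `S_max` are eliminated by requiring
that darkness, with the measured dark current, is a fixed point. The dark
current is therefore an *input* per cell, not a parameter: it pins the dark
cGMP `G_D = (I_D/k)^(1/n)` and through it the cyclase ceiling. A
consequence worth knowing: response *kinetics* are exactly independent of
`I_D` (rescaling G and C by their dark values removes it from the
equations), so the built-in representative dark currents (300, 60, 28,
20 pA for primate cone, mouse cone, primate rod, mouse rod) affect only
absolute amplitudes.

The model current is a positive magnitude. Recording conventions report
dark currents as negative; constructors accept either sign.

σ and Φ are tied in all consensus sets. They are interchangeable *as fit
parameters* — refitting after exchanging their roles reaches the same fit
quality — but not as a fixed-parameter symmetry: with `S_max` pinned by the
dark current, the dark PDE activity η/Φ enters the operating point, so
naively swapping σ and Φ in a fitted model shifts the response. The tie can
be relaxed (`FitSpec(tie_sigma_phi=False)`) for experimentation.

## Integration

The reference integrator is forward Euler at 0.1 ms for cones and 1 ms for
rods, with the stimulus held constant over each step. Euler is deliberate
rather than lazy: the inversion below mirrors its difference equations
exactly, making invert∘simulate an identity to machine precision. A
classical Runge–Kutta integrator (`method="rk4"`) is provided as an
independent convergence check; halving the Euler step changes the current
by <0.5% RMS on the variable-mean fixture, and Euler vs RK4 agree to the
same order. Euler stability bounds the usable stimulus range at the rod
step size (the PDE rate must satisfy P·dt ≲ 1, violated only far beyond rod
saturation). Simulations at a background start from the root-found steady
state (`brentq` on the cGMP balance, which is monotone and so has a unique
fixed point) rather than a burn-in run, which removes onset transients
deterministically.

## Exact inversion

Inversion maps a current trace to the stimulus that produced it in three
steps: (1) `G = (I/k)^(1/n)` pointwise and calcium by integrating
`dC/dt = qI − βC` (a frequency-domain division `C(f) = qI(f)/(β + 2πif)` is
available and agrees to first order in dt; the sign convention is fixed by
requiring that agreement); (2) `P = (S(C) − dG/dt)/G`; (3)
`R = dP/dt + Φ·P − η`, then `Stim = (dR/dt + σ·R)/γ`.

The default derivative scheme is the forward difference that exactly
inverts the Euler update, so noise-free round trips are exact apart from
the last three samples (extrapolated, since forward differences look one
step ahead). Central and spectral schemes are provided for externally
sampled data; they are accurate on band-limited signals but mis-handle
frequencies near Nyquist, where only the Euler mirror is exact.

Differentiation amplifies noise as f² per step, which is why inversion of
measured responses needs regularization: a hard low-pass at the per-type
recoverable band (60 Hz primate cone, 30 Hz mouse cone, 15 Hz rods) and,
optionally, rescaling of the estimate's Fourier amplitude spectrum to a
reference stimulus spectrum with phases preserved (the constraint is
bin-wise exact by construction). Negative recovered intensities are kept in
the mathematical estimate and clipped only at export, with the clipped
fraction reported — clipping is the physical feasibility boundary, not a
numerical detail.

## The linear model and the clamp

The small-signal filter is
`L(t) = α·(t/τ_R)³/(1+(t/τ_R)³)·exp(−t/τ_D)`: a cubed-sigmoid rise with
time constant τ_R and an exponential decay with time constant τ_D. It is
fit to the full model's response to low-contrast Gaussian noise at a single
adapting mean (defaults: 5% RMS contrast, white at the integration step,
30 s for cones / 60 s for rods, fixed seed; α is profiled out analytically
and the two time constants are optimized in log space by Nelder–Mead from a
dim-flash time-to-peak initialization). The linear response is
`baseline − (L ⊛ ΔStim)·dt`, signed so light increments shrink the current
magnitude.

Two honest limitations of this filter form. First, it is monophasic: the
full model's linearization is mildly band-pass at low frequency because of
the calcium feedback (corner near β), so the fitted filter misses slow
(~2 Hz) modulations by ~10–20% even at vanishing contrast; it is most
faithful in the band above the adaptation corner and below the response
cutoff. Second, the fit valley in (τ_R, τ_D) is sloppy — rise and decay
trade off — so the individual constants are configuration-dependent at the
~10% level for rods even when the overall filter shape is stable. Fitted
rod time constants move substantially (and α several-fold) with the
adapting mean, so a filter is only meaningful together with its
`mean_level` tag.

The clamp chains the pieces: linear target from the original stimulus →
inversion of the target through the full model → clip at zero light →
verify by forward simulation. For feasible designs (nothing clipped) the
achieved response equals the target to machine precision, by construction.
The `ClampResult` keeps all five traces and the clipping report. Design
conventions: the filter fit at the pre-step mean is used for step stimuli;
linear targets must stay strictly positive in current (otherwise no light
stimulus exists and the design raises as infeasible); speeding kinetics
(scale < 1) pushes the stimulus decrement against zero, so achieved-change
diagnostics accompany any clipped design. `size_step_flash_protocol`
chooses flash strengths and step sizes from the linear gain (default: the
flash transiently dips the linear target by 5% of the baseline current, the
step by 40% sustained — producing roughly the twofold gain change in the
full model that the clamp then negates); these are protocol defaults of
this package, settable per experiment.

## Fitting, sensitivity, and sloppiness

`PhototransductionModel` pools any number of cells, each with paired
stimulus/response traces and a measured dark current. Free parameters
follow the field's convention: σ (=Φ), η, K_GC shared — plus β for cones,
it being fixed from prior measurements for rods — and γ free per cell to
absorb sensitivity differences; `G_D` is always derived from each cell's
dark current. The objective is the pooled per-sample MSE; optimization is
Nelder–Mead on log parameters (which enforces positivity), with restart
runs that re-expand the simplex from the incumbent. Simulations inside the
objective equilibrate at the first stimulus sample, matching how the
synthetic-recording generator initializes — a convention, but a consistent
one.

`sensitivity_range` brackets, by bisection on a log grid, the interval over
which varying one parameter (others fixed) doubles the optimal MSE; an
unreached side within a 50-fold span is returned as an open bound.
`sloppy_hessian` builds the central finite-difference Hessian of the MSE
over the natural parameters (step: 1% of each parameter), symmetrizes it,
and eigendecomposes; on synthetic rod data the eigenvalue spectrum spans
several decades, the classic stiff/sloppy pattern. The same
finite-difference kernel is exposed as `finite_difference_hessian` for
arbitrary costs; where a parameter is zero the relative step falls back to
an absolute one.

## Synthetic data

The generators reproduce the stimulus families used to constrain such
models: flash families (weakest ~3 R*, doubling), steps with superimposed
flashes, sinusoids, and the variable-mean noise stimulus — Gaussian noise
segments whose means step over up to a 30-fold range. Defaults not fixed by
the protocol descriptions are package choices: 5 log-spaced mean levels
topping out at 30,000 R*/s (cones) or 75 R*/s (rods), 2–5 s segments, 50%
RMS contrast, truncation at zero, seeded shuffling of segment order.
Synthetic recordings add white Gaussian current noise of settable SD; real
recording noise is neither white nor stationary, so parameter-recovery
results on these fixtures demonstrate correctness of the machinery, not
expected performance on electrode data. Likewise the generators draw noise
at the integration step, whereas experimental stimulators hold values over
a refresh interval; the filter fits proved insensitive to this choice over
refresh intervals from one step to 50 ms.

## Numerical conventions and edge cases

- Traces are uniformly sampled; stimulus traces must be nonnegative and all
  samples finite. Time in seconds, intensity in R*/s, current in pA at
  every interface.
- Steady-state root-finding tolerances: `xtol=1e-14` on cGMP; fixed-point
  drift from a steady start is below 10⁻³ relative over 10 s (in practice
  ~10⁻¹⁵).
- Inversion refuses nonpositive currents (channels closed ⇒ cGMP
  unrecoverable) and near-zero cGMP (division blow-up), naming the first
  offending time.
- `time_to_peak` uses a pre-onset baseline window (default 100 ms) and
  quadratic sub-sample refinement; it raises on monotone traces. Rod peaks
  are broad, so time-to-peak carries a few-percent strength dependence even
  for dim flashes.
- `best_fit_sinusoid` normalizes its MSE by trace variance, making the
  metric contrast-independent; `loop_area` normalizes both axes to unit
  peak-to-peak before the shoelace sum, for the same reason.
- The residual-spectrum convergence frequency is defined as the lowest
  frequency where residual power sustains ≥50% of stimulus power over
  3 Welch bins.
- Calibration integrates photon flux (not energy) against per-photon
  sensitivity curves, on the overlapping wavelength support, by the
  trapezoid rule; collecting areas are 1/0.37 µm² (primate rod/cone) and
  0.5/0.2 µm² (mouse), with a 600 µm illuminated spot as default.

## Problem sizes

Defaults used by the test suite and the acceptance script: 30–60 s noise
simulations for filter fits; 6–12 s variable-mean segments per synthetic
cell for fitting experiments (three cells for consensus recovery); 4 s
(cones) or 16 s (rods) step+flash protocols. These sizes give
seed-to-seed variation of a few percent on fitted time constants and
sub-percent parameter-recovery error, which is adequate for the package's
reference checks.

## Known limitations

- No bleaching, no inner-segment conductances, no synaptic output, no
  horizontal-cell feedback: the model stops at the outer-segment current.
- The parametric linear filter is an approximation of the model's
  linearization (see above); clamp targets built from it inherit its
  low-frequency bias. This is a property of the published filter form, kept
  for comparability.
- Speeding responses is bounded by the no-negative-light constraint;
  roughly 20–30% speeding is achievable before clipping dominates.
- The Euler-mirror inversion is exact only for traces produced (or
  resampled) at the reference step; externally recorded currents should be
  inverted with the central or spectral scheme plus band limiting.
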