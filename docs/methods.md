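# Methods

`fmbayes` infers empirical forward-model parameters — the coefficients of
Karplus relations J(φ) = A·cos²(φ+φ₀) + B·cos(φ+φ₀) + C, or the weights of a
small neural network — jointly with conformational populations and error
nuisance parameters, from ensemble-averaged scalar couplings.  This note
records the model as implemented, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Posterior model

The data are N_d ensemble-averaged couplings d_j (Hz), grouped into
observable types k (one Karplus relation and one pair of error parameters
per type).  A conformational ensemble supplies per-state, per-observable
torsions φ_{X,j}; predictions are averaged over the ensemble by one of two
mechanisms:

* **replica averaging** — N replicas each occupy one state; the prediction
  is the replica mean and the finite-sampling error σ_SEM,j is the
  population SD across replicas divided by √N;
* **population averaging** — the deterministic prior-weighted average over
  all states (the large-ensemble limit of replica averaging, with N kept as
  the restraint multiplier).  This is the default for the synthetic studies:
  at toy scale (32 replicas choosing among 100 states, one independent
  torsion per state and observable) free replica configurations can
  reproduce the data under badly wrong coefficients, because the entropy
  cost of a population tilt (≈ N·KL against the prior) is too weak at
  N = 32 to pin θ.  The deterministic average removes that degeneracy while
  preserving the restraint scaling.

Each observable type carries a sampled uncertainty σ_B (Hz) and, under the
Good–Bad model, a variance inflator φ ≥ 1.  The per-observable width is
σ0,j = √(σ_B² + σ_SEM,j²).  The two-component ("Good–Bad") likelihood of a
datum is a gated Gaussian scale mixture,

    L_j = ½·N(d_j | g_j, σ0,j²)^N + (1/2φ)·N(d_j | g_j, φ²σ0,j²)^N ,

whose weights come from analytic marginalization of the unknown outlier
fraction, and whose Heaviside gates drop a component when φ_m·σ0,j would
fall below σ_SEM,j (open by construction with the quadrature width).  A
multi-level severity variant with inflators φ₁=1 < … < φ_M and equal 1/M
weights is also provided.

**Replica counting.**  How the replica factor N enters is the one place the
energy written as “−N·Σ_j ln L_j” and the posterior it is derived from
disagree with each other.  Both conventions are implemented:
`counting="evidence"` multiplies each observable's whole log-mixture by N;
`counting="restraint"` (the sampler default, shown above) replicates the
Gaussian components N-fold while counting the good/bad class weight once —
the class of a datum is a single latent property of the datum, not of each
replica.  The distinction is behaviorally decisive and each study uses the
convention matched to its error model: with systematic outliers present,
only restraint counting engages the mixture (under evidence counting,
declaring a point bad costs N·ln 2 against it and the fit absorbs the
shifts), so the robustness study uses it; on outlier-free data restraint
counting instead trims legitimate noise tails (a redescending-estimator
efficiency loss of ~1.5×), so the network benchmark — training loss and
Karplus refit alike — uses evidence counting.  The two coincide at N = 1,
and for the single-component Gaussian model they give identical θ marginals
(an exact rescaling of σ under the log-uniform prior).

**Width convention.**  Similarly configurable (`sem_in_width`): the
quadrature width above is the default, but in population mode the SEM is a
deterministic function of θ and the N·ln σ0 normalizer then *rewards*
flat curves through their smaller prediction spread (≈ 86 nats at
σ_data = 1 on the 100-observable toy).  The 100-state studies (robustness,
convergence) therefore use the sampled σ_B alone as the width, with the
per-observable SEMs acting through the gates; the 5-state benchmark keeps
the quadrature, where the large SEM (≈ 0.45 Hz at N = 4) is a beneficial
width floor.

**Priors.**  State priors p(X) come from the ensemble table (uniform when
absent).  σ_B and φ carry truncated Jeffreys priors, realized as log-spaced
grids (128 points) over [10⁻³, 10] Hz and [1, 20] respectively; sampling in
log-grid index space makes the flat-in-log prior exact.

## Sampling

One composite sweep updates, in order: one replica's state (uniform
proposal; plus a periodic rejection-free heat-bath draw over all states —
with N replicas the data term scales single-replica moves by N and plain
Metropolis freezes), σ_B and φ (grid index walks, width 0.1 in log units,
plus periodic heat-bath draws over the full grid), and each type's θ.
θ proposals are gradient-informed during burn-in
(θ' = θ − l_rate·∇u + η·z, defaults 10⁻⁴ and 0.01) and symmetric random
walks (width 0.02 Hz) in production, so the production kernel is exactly
reversible.  Two additional devices deal with the multi-modality that the
engaged mixture creates (locally tight basins along the curve-equivalent
ridge of (A, B, C)):

* the restraint exponent anneals from 0 to ξ over the first half of
  burn-in, funneling chains from any start into the high-mass region;
* in population mode, a Hastings-corrected independence proposal drawn from
  the local responsibility-weighted least-squares Gaussian of θ's
  conditional fires every 50 sweeps, alternating tight and wide (×30)
  scales; the wide draws hop between separated basins.

With these, chains from (9,−1,1), (4,0,3) and (0,0,0) give Gelman–Rubin
statistics of 1.00–1.03 per coefficient on the noisy toy.  The default
protocol is 32 replicas, 10k burn-in, 50k production sweeps.

## Evidence score

A fixed parameterization θ is scored by f(θ) = −ln Z(θ)/Z₀, the free energy
of switching the experimental restraint on (data exponent ξ: 0 → 1) with θ
pinned and a uniform state prior in the reference.  Per-ξ chains are thinned
by the integrated autocorrelation of their own energy; the affine form
u_ξ = u_prior + ξ·u_data lets every sample be re-evaluated in every state,
and free energies come from MBAR (self-consistent iteration to 10⁻⁸, at most
10⁴ iterations; asymptotic uncertainties from the SVD form of the estimator
covariance; implemented in `fmbayes._mbar`).  Because the restraint grows
linearly with the replica count, the reduced score f/N_r is reported
alongside.  Bridge schedules: uniform, power-law (denser near ξ = 0, where
the thermodynamic length concentrates), or optimized from a pilot run by
equal arc-length in the metric dL = std[u_data](ξ)·dξ.  Scoring uses a pilot
(9 power-spaced states, ~500 sweeps each) followed by the optimized
schedule; MBAR failure names the worst-overlap pair.

The score gradient is the Boltzmann average of ∂u/∂θ over the ξ = 1
ensemble; variational optimization runs L-BFGS-B on (A, B, C) in a
[−15, 15] Hz box, with every objective evaluation re-sampling the bridge
under common random numbers (fixed seed within a start, distinct across
starts) so line searches see a deterministic function.  Uncertainties come
from the inverse Hessian (finite differences of the gradient) when the
landscape is locally convex, else from the dispersion across starts.

## Synthetic data

Torsions are drawn from a three-mode Gaussian mixture over φ (degrees):
β-sheet (−110, sd 20, weight 0.35), right-handed helix (−60, sd 10, 0.50),
left-handed helix (+60, sd 5, 0.15).  Truth coefficients are
(A*, B*, C*) = (6.51, −1.76, 1.60) Hz with zero phase.  Each observable gets
one angle per state; clean observables are uniform ensemble averages —
uniform weighting is the study condition because it is the only weighting a
single shared population vector can reproduce (per-observable density
weights leave an ~1 Hz misfit floor at the truth for any populations, which
would swamp every benchmark).  Noise: per-observable Gaussian error of SD
σ_data, plus (for the robustness study) +U(2, 4) Hz shifts applied to a
uniformly drawn number of observables up to 20% — the outlier regime.  The
main grid is 100 states × 60 observables; the network benchmark uses
5 states × 60 observables (300 angles).  Prior-quality degradation perturbs
every angle by Gaussian noise of SD σ_prior (≤ 4°), re-wrapped, populations
unchanged.

The generator emulates ensemble-averaged backbone couplings with
uncorrelated angles and noise; it has none of the correlated dynamics,
residue-dependent error structure, or model-form error of real NMR data, so
passing benchmarks demonstrate correct inference under the stated error
model, not accuracy on any particular protein.

## Study protocols and metrics

All study metrics compare *ensemble-averaged couplings*: RMSE over the N_d
observables between the averaged predictions of an estimate and the clean
averaged truth.  (For 3 coefficients fit to 60 noisy averages, any unbiased
per-trial fit is bounded below by σ_data·√(3/60) ≈ 0.22·σ_data — at
σ_data = 1 Hz no method can beat ≈ 0.22 Hz per trial; accuracy claims well
below that refer to aggregated estimates.)

* **Robustness** (`protocols.robustness_study`): ≥10 trials per noise level
  σ_data ∈ {0.1, 0.25, 0.5, 0.75, 1.0} Hz with shifts; per level the
  trial-averaged coefficients are scored.  The Good–Bad aggregate stays
  below 0.1 Hz at every level; Gaussian and SVD fits degrade beyond it from
  0.75 Hz (they absorb the mean outlier shift into C).
* **Convergence** (`convergence_study`): R̂ per coefficient over the three
  standard starts, one noisy dataset, full-length chains.
* **Score vs quality** (`score_quality_study`): ≥50 prior perturbations
  (σ_prior ≤ 4°) each with fresh noise of SD |N(0.68, 0.24)| Hz; quality is
  the RMS deviation between the perturbed ensemble's averaged predictions
  and the experimental data — the operational meaning of ensemble quality,
  and the only reading under which a tight correlation is possible here: 4°
  perturbations move 100-state uniform averages by only ~0.03 Hz, invisible
  next to the noise, while the data-deviation metric spans the full range
  the score responds to.  Systematic shifts are excluded from this study
  (each unfit outlier adds ~N·ln(φσ) of shift-count scatter to f under
  restraint counting, which would cap R² near 0.6).
* **Equivalence** (`equivalence_study`): posterior-sampled and
  variationally minimized coefficients on one dataset, compared within
  combined uncertainties (posterior SD ⊕ multi-start SD); variational runs
  use 4 replicas and 10k MC sweeps per evaluation split over the bridge.
* **Network benchmark** (`nn_benchmark`): the 2→200(GELU)→1 network, LeCun
  initialization, full-batch ADAM at 10⁻³ for 2000 epochs, trained on the
  5-state dataset clean and at σ_data = 0.79 Hz (no shifts: the reported
  SVD and refit errors sit exactly at the no-outlier noise floor), five
  seeds; compared against the regularized SVD fit (ε = 10⁻⁶ on the singular
  values; delete-10% jackknife × 1000 for uncertainties) and the
  Good–Bad refit of the Karplus form (4 replicas — the reduced-cost replica
  count of the variational protocol; the count is otherwise unstated for
  this study).

## Neural-network training

The angle is embedded as (cos φ, sin φ); the loss is the Good–Bad energy of
the ensemble-averaged predictions under evidence counting with the width
σ_B alone (floored at 0.05 Hz) — three deliberate differences from the
sampler's likelihood, each load-bearing for a free-form model: folding the
within-observable prediction spread into the width hands the network a
self-inflating error bar (constant-truth recovery then fails by >1 Hz);
per-observable gates would make the loss discontinuous in the weights; and
under restraint counting the σ ratchet sharpens the loss until the network
exploits cluster-allocation slack in the averaged data.  Every 10 epochs a
500-step MCMC refreshes (σ_B, φ) at fixed weights; weight gradients use the
posterior means.  With noise present a free-form model keeps a genuine
disadvantage against the Karplus form: the value of the sparsely-populated
+60° mode is only pinned through the cosine symmetry J(+60°) = J(−60°) of
the functional form, which the network does not know — its benchmark error
therefore sits slightly above the parametric fits, dataset-realization
dependent.

## Known limitations

* Replica-mode sampling is validated on small enumerable systems; at toy
  scale it is intentionally bypassed (population mode) for the reasons
  above.  Applications with genuinely few, structurally coherent states —
  where one state's torsions are correlated across observables — do not
  suffer the same degeneracy.
* Individual Karplus coefficients are reported with soft directions: the
  three basis functions are nearly collinear across averaged observables,
  so (A, B, C) can drift along a curve-equivalent ridge while predictions
  barely change.  Curve-level metrics are the meaningful ones; single-run
  coefficient values should be read with the posterior SD.
* The Student's-t likelihood, correlated-error models, the prior-switching
  (λ) leg of the score, and forward models for chemical shifts, HDX, and
  PRE are out of scope.
* Structure-file (PDB) torsion extraction is not shipped; ensembles enter
  as plain tables.
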