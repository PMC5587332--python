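# Methods

## Model

Each of the N input conformations of a fixed residue topology is reduced to
its backbone heavy atoms (N, Cα, C, O per residue), rigidly superposed onto
a common reference with the Kabsch algorithm, and flattened into one row of
a data matrix **Y** ∈ ℝ^{N×D}, D = 12 × n_residues. Superposition removes
the 6 rigid-body degrees of freedom, so **Y** carries internal
(conformational) variation only.

The GP-LVM treats each of the D coordinate columns of the centred data as
an independent Gaussian-process draw with a shared kernel over latent
coordinates **X** ∈ ℝ^{N×L}. The composite kernel is an anisotropic RBF
plus a constant (bias) term,

    k(x_s, x_t) = θ₀ exp(−½ Σ_l θ_l (x_sl − x_tl)²) + θ₃,

and observation noise enters as K + σ²I. The fitted objective is the
negative log posterior: the D-column marginal likelihood plus a standard
normal prior on every latent coordinate,

    L = DN/2·log 2π + D/2·log|K+σ²I| + ½·Tr((K+σ²I)⁻¹ Y_c Y_cᵀ) + ½·Σ_n xₙᵀxₙ.

Noise parameterisation: the model's noise slot is a **variance** σ²
appearing as K + σ²I in both the marginal and the predictive equations.
(Descriptions of this model family sometimes label the same slot a
"precision"; with the matrix written K + βI the equations are only
consistent when the scalar is read as a variance, which is what this
implementation does.)

Reconstruction of a backbone at any latent point x* is the GP predictive
mean computed on centred data with the column means re-added,

    E[y*] = μ_Y + k_{x*,X} (K+σ²I)⁻¹ (Y − μ_Y),
    var(y*) = k(x*,x*) − k_{x*,X}(K+σ²I)⁻¹ k_{X,x*}   (shared across columns).

Centring is required: a zero-mean GP on raw coordinates cannot reproduce
absolute atomic positions. The predictive variance is shared across
coordinate columns, the standard multi-output construction with one kernel.

With `kernel="linear"` (k = θ₀·xᵀx′ + θ₃) the same machinery is
probabilistic PCA: the optimal latent subspace is the span of the top-L
principal components, which the test suite verifies by principal angles.

## Fitting

* Initialisation: latents start at the top-L principal component scores of
  centred **Y**, rescaled to unit per-dimension variance (the scale the
  latent prior prefers); θ₀ starts at the data variance, θ_l at 1, θ₃ at
  0.1 × data variance, σ² at 0.01 × data variance. Degenerate principal
  directions fall back to small random values.
* Joint optimisation of X, log θ and log σ² with L-BFGS-B and analytic
  gradients (positivity is structural in the log parameterisation).
  Gradients are validated against central finite differences to a relative
  1e-5 in the tests.
* If the Cholesky factorisation of K + σ²I fails, a jitter starting at
  1e-8 × mean diagonal escalates tenfold up to six attempts before a
  diagnostic error suggests rescaling.
* Non-convergence within `maxiter` is a warning carrying the final gradient
  norm, not a failure — on near-noiseless data the objective is extremely
  steep in log σ² and the optimum is effectively reached long before the
  gradient test is satisfied.
* Fits are deterministic given the seed; models serialise to a versioned
  JSON archive carrying X, θ, σ², the data, column means and topology.

## Sampling

* Temperature ladder: geometric. The published protocol names 24 chains,
  bounds 0.1–0.5 *and* ratio 1.1, which is overdetermined and mutually
  inconsistent (0.1 × 1.1²³ ≈ 0.9). The default here fits the bounds and
  chain count, giving ratio (T_max/T_min)^{1/(n−1)} = 5^{1/23} ≈ 1.0724; an
  explicit-ratio mode instead grows from T_min and truncates at T_max
  (ratio 1.1 yields 17 chains).
* Moves: side-chain with probability 0.95 (uniform design position, uniform
  choice among the 19 non-proline amino acids, uniform rotamer from the
  loaded set), backbone with probability 0.05 (independent zero-mean
  Gaussian step per latent dimension; the reconstructed backbone keeps the
  current rotamer assignment). Acceptance is Metropolis at the chain's own
  temperature.
* Latent step size: the per-dimension proposal **standard deviation** is
  0.001 × the span of the fitted latents. (Source protocols state the same
  0.001 × range number once as a "variance" and once as a step size; as a
  variance the steps would be ~30× smaller and mixing negligible, so the
  standard-deviation reading is used. `step_scale_is_variance` exposes the
  other reading.)
* Swaps: after all chains move, one attempt per iteration — a uniformly
  random chain, then a fair coin between its neighbours (ends have one) —
  accepted with min(1, exp[(E_i−E_j)(1/T_i−1/T_j)]). States exchange;
  temperatures stay with the chain. Move-then-swap ordering is fixed and
  documented here because the alternative is observationally similar but
  not bit-identical.
* RNG: one master seed spawns an independent stream per chain plus one for
  swap decisions, so per-chain sequences are invariant to chain count and
  runs are byte-reproducible.
* Records (iteration, chain, temperature, sequence, energy, latent point)
  are emitted every `save_stride` iterations for every chain; burn-in is
  applied downstream at merging. Defaults follow the published schedule
  (stride 200; burn-in 20,000 for ensemble runs, 600,000 for design runs at
  the full 2,000,000 iterations). Energies are evaluated on the structure
  the model reconstructs — for design this is the partial structure within
  8 Å of the design positions, which is also what keeps reconstruction
  cheap.

## Scoring and comparison statistics

Poses sharing one sequence merge by Boltzmann weight Σ_p e^{−E_p}. A
printed version of this rule elsewhere carries a stray constant factor N;
a constant cannot change any ranking and is dropped. Ranking uses
log-sum-exp for stability; ties break by lower best-pose energy, then
lexicographically. No temperature enters the exponent by default
(`merge_temperature` provides exp(−E/T) as an option), and records from all
chains pool by default with an optional temperature filter — pooling more
post-equilibration poses only sharpens the weight of repeatedly visited
sequences.

Sequence-identity-to-reference is computed position-wise over an explicit
index list (no alignment; topologies must already correspond), taking each
design's best-matching reference; `position_composition` reports the
percentage of designs carrying a residue from a given set at one position.

## Synthetic systems

The fixture generator builds hinged two-segment ideal helices: rise 1.5 Å
and 100° twist per residue, with N/Cα/C/O placed on cylinders of radius
1.60/2.30/1.70/2.00 Å at phase offsets −28°/0°/+28°/+46° and axial offsets
−0.60/0/+0.60/+1.05 Å (fixture constants, not a physical model). The
second segment rotates about a hinge at the mid-chain Cα — a bend angle
(dimension 1) and optionally a twist (dimension 2) — and isotropic Gaussian
noise is added per coordinate. Defaults: 20 structures, 16 residues, bend
sampled uniformly on ±40°, 0.05 Å noise.

This emulates exactly the situation the model assumes — same-topology
backbones whose variation is governed by 1–2 hidden parameters plus noise —
and returns the true parameters for recovery tests. It does **not** emulate
real structural data in other respects: no side chains, no realistic
backbone geometry or sterics, no heterogeneous per-residue mobility, no
missing density or alternate conformers. Passing tests therefore
demonstrate correctness of the learning/sampling machinery under the
model's own assumptions, not performance on crystallographic ensembles.
The toy energies are likewise analytic stand-ins chosen for checkable
ground truth: a harmonic well in Cartesian space (known Boltzmann density
by quadrature) and a separable per-position sequence table (known global
optimum); production use plugs a real scoring function into the same
`EnergyModel` interface.

## Verification conditions and problem sizes

The test and acceptance runs use desk-scale sizes chosen so every check
completes in minutes on one core: ensembles of 10–20 structures of 12–16
residues; sampler checks with a single chain for 10⁵ iterations (Boltzmann
agreement, total-variation < 0.05 against quadrature with per-bin
integrated model mass) and with 24 chains for 10⁴ iterations repeated 20
times (design recovery). For the single-chain Boltzmann check the proposal
scale is 0.03 × latent range rather than the design default 0.001 — the
check targets the stationary distribution, and a random walk at the design
step size would need orders of magnitude more iterations to traverse the
well; the harmonic force constant (k = 1 Å⁻²) and T = 0.2 confine the
density well inside the region supported by training data, where the GP
mean is trustworthy and the quadrature domain is unambiguous.

## Known limitations

* Backbone heavy atoms only: no side-chain coordinates, no hydrogens; an
  energy model needing them must build them itself.
* Topologies must already correspond residue-by-residue; there is no
  sequence or structural alignment step.
* Exact GP-LVM (no sparse/variational approximation): fitting scales as
  O(N³ + N²D), comfortable for tens of structures, not thousands.
* The GP mean reverts to the column means far from training latents, so
  the effective energy landscape over latent space flattens away from the
  data; samplers run at temperatures where that region is unreachable.
* Chains run serially; the reproducibility contract (per-chain RNG
  streams) is designed so a future concurrent executor can preserve
  identical output.
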