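# flexibal

Flexible-backbone protein design from backbone movements **learned from
multiple structures**, rather than from predefined rigid perturbations.

## The problem

Computational protein design searches over amino acid combinations *and*
backbone conformations. Most flexible-backbone methods perturb a single
template with generic local moves (torsion tweaks, backrub rotations).
But for many systems several structures of the same fold are available —
crystal forms, NMR models, MD snapshots — and together they reveal which
concerted, global movements the backbone actually makes.

`flexibal` exploits that. Given N structurally aligned backbones
(heavy atoms N, Cα, C, O flattened into a data matrix **Y** ∈ ℝ^{N×D}), a
**Gaussian-process latent variable model (GP-LVM)** places each
conformation at a coordinate **x**_n in a low-dimensional latent space
(L = 2 by default) and learns a smooth nonlinear map back to Cartesian
space. The composite RBF + bias kernel

    k(x_s, x_t) = θ₀ exp(−½ Σ_l θ_l (x_sl − x_tl)²) + θ₃

is fitted together with the latents and a noise variance σ² by minimising
the negative log posterior

    L(X, θ, σ²) = DN/2·log 2π + D/2·log|K+σ²I| + ½·Tr((K+σ²I)⁻¹ Y Yᵀ) + ½·Σ_n xₙᵀxₙ.

Any latent point **x*** then reconstructs a full backbone through the GP
predictive mean E[y*] = μ_Y + k_{x*,X}(K+σ²I)⁻¹(Y−μ_Y), so a small Gaussian
step in latent space is a concerted multi-atom backbone movement that stays
close to the observed conformations. With a linear kernel the model reduces
to probabilistic PCA — a useful cross-check.

Design then runs as **parallel-tempered Metropolis–Hastings**: 24 chains on
a geometric temperature ladder over [0.1, 0.5]; each iteration every chain
proposes a side-chain move (95%: uniform design position, uniform
non-proline amino acid, uniform rotamer) or a backbone move (5%: latent
step with σ = 0.001 × latent range per dimension); one swap attempt per
iteration between a random chain and an adjacent neighbour with probability
min(1, exp[(E_i−E_j)(1/T_i−1/T_j)]). Poses sharing a sequence are merged by
Boltzmann weight Σ_p e^{−E_p} (ranked via a stable log-sum-exp), so a
sequence is scored by its pooled statistical weight, not just its best pose.

The energy model is pluggable (`EnergyModel.evaluate(coords, sequence)`);
the package ships analytically tractable toy energies (harmonic-to-reference
and separable per-position sequence weights) so the whole machinery is
testable end to end without an external force field.

## Worked example

```python
import flexibal as fb

# 1. a synthetic ensemble: two helical segments joined by a hinge whose
#    bend angle is the single hidden degree of freedom (+0.05 A noise)
spec = fb.ToyEnsembleSpec(n_structures=20, noise_sigma=0.05, rng_seed=11)
ensemble, true_angles = fb.generate_toy_ensemble(spec)

# 2. superpose, flatten, fit the latent model
data = fb.build_data_matrix(ensemble)
results = fb.GPLVM(data, n_latent=1).fit(seed=0)
print(results.summary())

# 3. design five positions against a separable toy energy
from flexibal.toy import random_sequence_weights
energy = fb.SequenceEnergy(random_sequence_weights(5, seed=7))
config = fb.SamplerConfig(n_chains=24, n_iterations=10_000, save_stride=200,
                          burn_in=2_000, rng_seed=0,
                          design_positions=(0, 1, 2, 3, 4))
records, diag = fb.run_parallel_tempering(results, energy,
                                          fb.generate_toy_rotamer_set(2), config)
table = fb.merge_sequence_scores(records, burn_in=config.burn_in)
print(table.head(3)[["sequence", "log_score", "n_poses", "best_energy"]])
print("known optimum:", energy.optimal_sequence())
```

Output (abridged):

```
Backbone latent-variable model
==============================================
Observations (structures)                   20
Features (coordinates, D)                  192
Latent dimensions (L)                        1
Kernel                                     rbf
Neg. log posterior                  -4249.0592
Converged                                 True
...
  sequence  log_score  n_poses  best_energy
0    YIISL  18.152253      721   -11.571614
1    YIRSL  13.814801       22   -10.723758
2    YIFSL  13.457575       15   -10.749525
known optimum: YIISL
```

The sampler's top-ranked variant is the per-position argmin of the weight
table — the known global optimum. Its log score (18.15) exceeds the weight
of its best pose alone (11.57) by ln 721 ≈ 6.6: the pooled Boltzmann weight
rewards a sequence the sampler revisits often, not just its single best
pose. The fitted 1-D latent coordinate tracks the true hinge angle with
|Spearman ρ| = 0.997.

A command-line interface wraps the same pipeline
(`flexibal simulate | fit | design | ensemble`); every run writes a JSON
manifest with its configuration, seed and input hashes.

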