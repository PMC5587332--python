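"""Temperature ladder, acceptance rules, proposals and the tempered engine."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.stats import chisquare, ks_2samp

import flexibal as fb
from flexibal.sampler import (AMINO_ACIDS_NO_PRO, ChainState, RotamerSet,
                              metropolis_accept, propose_backbone_move,
                              propose_sidechain_move, random_sequence,
                              read_records_tsv, swap_probability,
                              temperature_ladder, write_records_tsv)
from flexibal.toy import random_sequence_weights

from conftest import make_sampler_config


class TestTemperatureLadder:
    def test_two_chains_hit_endpoints(self):
        assert temperature_ladder(0.1, 0.5, 2) == pytest.approx([0.1, 0.5])

    def test_derived_ratio_is_closed_form(self):
        temps = temperature_ladder(0.1, 0.5, 24)
        assert len(temps) == 24
        assert temps[0] == pytest.approx(0.1)
        assert temps[-1] == pytest.approx(0.5)
        ratios = temps[1:] / temps[:-1]
        assert ratios == pytest.approx(np.full(23, 5.0 ** (1 / 23)))

    def test_explicit_ratio_truncates_at_cap(self):
        temps = temperature_ladder(0.1, 0.5, 24, ratio=1.1)
        # direct enumeration of the geometric series 0.1 * 1.1^k <= 0.5
        expected = []
        t = 0.1
        while t <= 0.5 * (1 + 1e-12):
            expected.append(t)
            t *= 1.1
        assert len(temps) == len(expected) == 17
        assert temps == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            temperature_ladder(0.5, 0.1, 4)
        with pytest.raises(ValueError):
            temperature_ladder(0.1, 0.5, 1)
        with pytest.raises(ValueError):
            temperature_ladder(0.1, 0.5, 4, ratio=0.9)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-abs(d), 0.3, rng)
                   for d in np.linspace(0, 10, 50))
        assert metropolis_accept(0.0, 0.3, rng)

    def test_half_acceptance_at_t_ln2(self):
        rng = np.random.default_rng(1)
        T = 0.37
        n = 100_000
        acc = sum(metropolis_accept(T * math.log(2.0), T, rng) for _ in range(n))
        sigma = math.sqrt(n * 0.5 * 0.5)
        assert abs(acc - 0.5 * n) <= 3 * sigma

    def test_cold_limit_rejects_uphill(self):
        rng = np.random.default_rng(2)
        assert not any(metropolis_accept(1.0, 1e-9, rng) for _ in range(100))

    def test_nonfinite_rejected(self):
        rng = np.random.default_rng(3)
        assert not metropolis_accept(float("nan"), 0.3, rng)
        assert not metropolis_accept(float("inf"), 0.3, rng)

    def test_detailed_balance_ratio(self):
        # acceptance ratio p(a->b)/p(b->a) = exp(-dE/T) for symmetric proposals
        rng = np.random.default_rng(4)
        for _ in range(50):
            dE = rng.uniform(-3, 3)
            T = rng.uniform(0.05, 2.0)
            fwd = min(1.0, math.exp(-dE / T))
            bwd = min(1.0, math.exp(dE / T))
            assert fwd / bwd == pytest.approx(math.exp(-dE / T), rel=1e-12)


class TestSwapProbability:
    def test_equal_energy_or_temperature_gives_one(self):
        assert swap_probability(1.3, 1.3, 0.1, 0.4) == 1.0
        assert swap_probability(0.2, 5.0, 0.3, 0.3) == 1.0

    def test_closed_form_value(self):
        # (Ei-Ej)(1/Ti-1/Tj) = -5 -> e^-5
        p = swap_probability(1.0, 0.0, 1.0, 1.0 / 6.0)
        assert p == pytest.approx(math.exp(-5.0), abs=1e-12)
        assert p == pytest.approx(0.006738, abs=1e-6)

    def test_replica_exchange_ratio(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ei, ej = rng.uniform(-5, 5, 2)
            ti, tj = rng.uniform(0.05, 2.0, 2)
            fwd = swap_probability(ei, ej, ti, tj)
            bwd = swap_probability(ej, ei, ti, tj)
            ratio = math.exp((ei - ej) * (1 / ti - 1 / tj))
            assert fwd / bwd == pytest.approx(ratio, rel=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            swap_probability(0.0, 0.0, -0.1, 0.2)
        with pytest.raises(ValueError):
            swap_probability(float("inf"), 0.0, 0.1, 0.2)


class TestRotamerSet:
    def test_tsv_roundtrip(self, tmp_path, rotamers):
        p = tmp_path / "rot.tsv"
        rotamers.write_tsv(p)
        back = RotamerSet.from_tsv(p)
        assert back.rotamers == rotamers.rotamers

    def test_proline_and_missing_rejected(self):
        good = {aa: [(0.0,)] for aa in AMINO_ACIDS_NO_PRO}
        with pytest.raises(ValueError, match="proline"):
            RotamerSet({**good, "P": [(0.0,)]})
        bad = dict(good)
        del bad["W"]
        with pytest.raises(ValueError, match="missing"):
            RotamerSet(bad)
        with pytest.raises(ValueError, match="empty"):
            RotamerSet({**good, "W": []})


class TestProposals:
    def _state(self, fitted):
        res, _ = fitted
        x = res.X[0].copy()
        coords, _ = res.reconstruct(x)
        return ChainState(x=x, sequence=[("A", 0), ("C", 1)], coords=coords,
                          energy=0.0, temperature=0.2)

    def test_zero_sigma_is_identity_in_latent(self, fitted_1d):
        res, _ = fitted_1d
        state = self._state(fitted_1d)
        energy = fb.HarmonicEnergy(res.model.data.topology)
        rng = np.random.default_rng(0)
        cand = propose_backbone_move(state, res, np.zeros(1), rng, energy)
        assert np.array_equal(cand.x, state.x)
        assert cand.sequence is state.sequence  # rotamers retained

    def test_step_magnitude_is_half_normal(self, fitted_1d):
        res, _ = fitted_1d
        state = self._state(fitted_1d)
        energy = fb.HarmonicEnergy(res.model.data.topology)
        rng = np.random.default_rng(1)
        sigma = np.array([0.01])
        n = 20_000
        steps = [abs(propose_backbone_move(state, res, sigma, rng, energy).x[0]
                     - state.x[0]) for _ in range(n)]
        assert np.mean(steps) == pytest.approx(0.01 * math.sqrt(2 / math.pi),
                                               rel=0.02)

    def test_candidate_matches_reconstruction_contract(self, fitted_1d):
        res, _ = fitted_1d
        state = self._state(fitted_1d)
        energy = fb.HarmonicEnergy(res.model.data.topology)
        rng = np.random.default_rng(2)
        cand = propose_backbone_move(state, res, np.array([0.01]), rng, energy)
        expected, _ = res.reconstruct(cand.x)
        assert np.array_equal(cand.coords, expected)
        assert cand.energy == energy.evaluate(expected, cand.sequence)

    def test_amino_acids_uniform_and_proline_free(self, fitted_1d, rotamers):
        res, _ = fitted_1d
        x = res.X[0].copy()
        coords, _ = res.reconstruct(x)
        # sentinel rotamer indices so every proposal is distinguishable
        state = ChainState(x=x, sequence=[("A", 99), ("C", 99)], coords=coords,
                           energy=0.0, temperature=0.2)
        energy = fb.SequenceEnergy(random_sequence_weights(2, seed=0))
        rng = np.random.default_rng(3)
        counts = {aa: 0 for aa in AMINO_ACIDS_NO_PRO}
        n = 200_000
        for _ in range(n):
            cand = propose_sidechain_move(state, rotamers, (0, 1), rng, energy)
            changed = [i for i in range(2) if cand.sequence[i] != state.sequence[i]]
            assert len(changed) == 1  # exactly one position mutates
            counts[cand.sequence[changed[0]][0]] += 1
        assert "P" not in counts or counts.get("P", 0) == 0
        observed = np.array([counts[aa] for aa in AMINO_ACIDS_NO_PRO])
        assert chisquare(observed).pvalue > 0.01

    def test_single_position_always_chosen(self, fitted_1d, rotamers):
        res, _ = fitted_1d
        x = res.X[0].copy()
        coords, _ = res.reconstruct(x)
        state = ChainState(x=x, sequence=[("A", 0)], coords=coords,
                           energy=0.0, temperature=0.2)
        energy = fb.SequenceEnergy(random_sequence_weights(1, seed=0))
        rng = np.random.default_rng(4)
        for _ in range(50):
            cand = propose_sidechain_move(state, rotamers, (0,), rng, energy)
            assert len(cand.sequence) == 1


class TestRunParallelTempering:
    def test_record_count_arithmetic(self, fitted_1d, rotamers):
        res, _ = fitted_1d
        energy = fb.SequenceEnergy(random_sequence_weights(3, seed=1))
        config = make_sampler_config(n_chains=24, n_iterations=10_000,
                                     save_stride=200)
        records, _ = fb.run_parallel_tempering(res, energy, rotamers, config)
        assert len(records) == 24 * 50

    def test_same_seed_identical_streams(self, fitted_1d, rotamers, tmp_path):
        res, _ = fitted_1d
        energy = fb.SequenceEnergy(random_sequence_weights(3, seed=1))
        config = make_sampler_config(n_chains=4, n_iterations=600,
                                     save_stride=100, rng_seed=9)
        out = []
        for run in range(2):
            records, _ = fb.run_parallel_tempering(res, energy, rotamers, config)
            p = tmp_path / f"run{run}.tsv"
            write_records_tsv(records, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_records_tsv_roundtrip(self, fitted_1d, rotamers, tmp_path):
        res, _ = fitted_1d
        energy = fb.SequenceEnergy(random_sequence_weights(3, seed=1))
        config = make_sampler_config(n_chains=2, n_iterations=200, save_stride=100)
        records, _ = fb.run_parallel_tempering(res, energy, rotamers, config)
        p = tmp_path / "records.tsv"
        write_records_tsv(records, p)
        back = read_records_tsv(p)
        assert len(back) == len(records)
        assert back[0].sequence == records[0].sequence
        assert back[-1].energy == pytest.approx(records[-1].energy)

    def test_record_energies_rehydrate(self, fitted_1d, rotamers):
        """Cache coherence: each stored energy equals re-evaluating the
        reconstructed structure with the stored sequence."""
        res, _ = fitted_1d
        ref = res.model.data.topology
        energy = fb.SumEnergy(
            fb.HarmonicEnergy(ref, k=0.1),
            fb.SequenceEnergy(random_sequence_weights(3, seed=1)),
        )
        config = make_sampler_config(n_chains=3, n_iterations=300, save_stride=50)
        records, _ = fb.run_parallel_tempering(res, energy, rotamers, config)
        for r in records[:30]:
            coords, _ = res.reconstruct(r.x)
            seq = [(aa, 0) for aa in r.sequence]  # rotamer index immaterial here
            assert r.energy == pytest.approx(energy.evaluate(coords, seq), rel=1e-12)

    def test_equal_temperatures_always_swap_and_match_single_chain(
            self, fitted_1d):
        res, _ = fitted_1d
        ref_idx = 5
        ensemble_member = res.model.data.unflatten(res.model.Y[ref_idx])
        energy = fb.HarmonicEnergy(ensemble_member, k=1.0)
        base = dict(n_iterations=20_000, save_stride=5, burn_in=2_000,
                    design_positions=(), p_sidechain=0.0, p_backbone=1.0,
                    start_index=ref_idx, latent_step_scale=0.03,
                    t_min=0.2, t_max=0.200000001)
        multi = fb.SamplerConfig(n_chains=3, rng_seed=0, **base)
        single = fb.SamplerConfig(n_chains=1, rng_seed=1, **base)
        rec_m, diag_m = fb.run_parallel_tempering(res, energy, None, multi)
        rec_s, _ = fb.run_parallel_tempering(res, energy, None, single)
        assert diag_m.swap_accepted.sum() == diag_m.swap_proposed.sum()
        lowest = min(r.temperature for r in rec_m)
        xs_m = [r.x[0] for r in rec_m
                if r.temperature == lowest and r.iteration > 2_000]
        xs_s = [r.x[0] for r in rec_s if r.iteration > 2_000]
        assert ks_2samp(xs_m, xs_s).pvalue > 0.01

    def test_single_chain_matches_boltzmann_quadrature(self, fitted_1d):
        """Post-burn-in latent histogram vs exp(-E/T)/Z from quadrature."""
        res, _ = fitted_1d
        ref_idx = 5
        member = res.model.data.unflatten(res.model.Y[ref_idx])
        energy = fb.HarmonicEnergy(member, k=1.0)
        T = 0.2
        config = fb.SamplerConfig(
            n_chains=1, n_iterations=100_000, save_stride=1, burn_in=10_000,
            rng_seed=0, design_positions=(), p_sidechain=0.0, p_backbone=1.0,
            start_index=ref_idx, latent_step_scale=0.03, t_min=T, t_max=0.5)
        records, _ = fb.run_parallel_tempering(res, energy, None, config)
        xs = np.array([r.x[0] for r in records if r.iteration > config.burn_in])
        tv = boltzmann_tv_distance(res, energy, T, xs)
        assert tv < 0.05

    def test_missing_rotamers_fail_fast(self, fitted_1d):
        res, _ = fitted_1d
        energy = fb.SequenceEnergy(random_sequence_weights(2, seed=0))
        config = make_sampler_config(design_positions=(0, 1))
        with pytest.raises(ValueError, match="rotamer"):
            fb.run_parallel_tempering(res, energy, None, config)


def boltzmann_tv_distance(res, energy, T, samples, n_bins=30):
    """Total-variation distance between sampled latents and the Boltzmann
    density computed by trapezoidal quadrature on a fine 1-D grid."""
    R = float(res.X.max() - res.X.min())
    lo, hi = float(res.X.min() - 2 * R), float(res.X.max() + 2 * R)
    grid = np.linspace(lo, hi, 4001)
    E = np.array([energy.evaluate(res.reconstruct(np.array([g]))[0], [])
                  for g in grid])
    logp = -E / T
    logp -= logp.max()
    p = np.exp(logp)
    p /= np.trapezoid(p, grid)
    cdf = np.concatenate([[0.0], cumulative_trapezoid(p, grid)])
    mlo = grid[np.searchsorted(cdf, 0.0005)]
    mhi = grid[np.searchsorted(cdf, 0.9995)]
    pad = 0.1 * (mhi - mlo)
    edges = np.linspace(min(mlo, samples.min()) - pad,
                        max(mhi, samples.max()) + pad, n_bins + 1)
    emp, _ = np.histogram(samples, bins=edges)
    emp = emp / len(samples)
    model_mass = np.clip(np.diff(np.interp(edges, grid, cdf)), 0, None)
    model_mass /= model_mass.sum()
    return 0.5 * float(np.abs(emp - model_mass).sum())


class TestSamplerConfig:
    def test_move_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="equal 1"):
            fb.SamplerConfig(p_sidechain=0.9, p_backbone=0.05)

    def test_temperature_bounds(self):
        with pytest.raises(ValueError):
            fb.SamplerConfig(t_min=0.5, t_max=0.1)

    def test_config_file_roundtrip(self, tmp_path):
        p = tmp_path / "sampler.cfg"
        p.write_text(
            "n_chains = 8\n"
            "t_min = 0.1\n"
            "t_max = 0.5\n"
            "p_sidechain = 0.95\n"
            "p_backbone = 0.05\n"
            "n_iterations = 1000\n"
            "save_stride = 100\n"
            "burn_in = 200\n"
            "rng_seed = 7\n"
            "design_positions = 0 1 2\n"
            "# a comment\n"
            "ladder_ratio = none\n"
        )
        config = fb.SamplerConfig.from_file(p)
        assert config.n_chains == 8
        assert config.design_positions == (0, 1, 2)
        assert config.ladder_ratio is None

    def test_random_sequence_covers_positions(self, rotamers):
        rng = np.random.default_rng(0)
        seq = random_sequence((0, 1, 2, 3), rotamers, rng)
        assert len(seq) == 4
        assert all(aa in AMINO_ACIDS_NO_PRO for aa, _ in seq)
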