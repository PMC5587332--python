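"""Parallel-tempered Metropolis-Hastings design sampler.

Multiple MCMC chains run at temperatures from a geometric ladder.  Each
iteration every chain makes one move — a side-chain move with probability
0.95 (uniform design position, uniform non-proline amino acid, uniform
rotamer) or a backbone move with probability 0.05 (a Gaussian step in the
fitted latent space, reconstructed to Cartesian coordinates while the
current rotamer assignment is retained) — accepted by the Metropolis
criterion at the chain's own temperature.  After the moves, one swap is
attempted between a random chain and a random adjacent neighbour with

    p(i, j) = min(1, exp[(E_i - E_j) (1/T_i - 1/T_j)]),

exchanging states but not temperatures, which lets cold chains escape
local minima of the design energy landscape.
"""

from __future__ import annotations

import logging
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .gplvm import GPLVMResults

logger = logging.getLogger(__name__)

#: The 19 design amino acids: all standard residues except proline, whose
#: rotamers the backbone representation cannot accommodate.
AMINO_ACIDS_NO_PRO = tuple(sorted("ACDEFGHIKLMNQRSTVWY"))


class EnergyModel(ABC):
    """Pluggable scoring function: lower is better, deterministic.

    ``coords`` is the flattened backbone coordinate vector (length D) of the
    current reconstruction; ``sequence`` is the per-design-position list of
    (amino acid, rotamer index) pairs.
    """

    @abstractmethod
    def evaluate(self, coords: np.ndarray, sequence: Sequence[tuple[str, int]]) -> float:
        ...

    def evaluate_structure(self, structure, sequence) -> float:
        """Structure-based adapter around :meth:`evaluate`."""
        return self.evaluate(structure.flatten(), sequence)


class RotamerSet:
    """Discrete side-chain conformers per amino acid.

    TSV format (tab-separated, ``#`` comments allowed)::

        aa  rotamer_id  chi1  chi2  chi3  chi4

    with one-letter amino acid codes; proline must be absent.  Shipped toy
    sets carry placeholder chi angles — the sampler only needs the discrete
    index structure, the energy model decides what the angles mean.
    """

    def __init__(self, rotamers: dict[str, list[tuple[float, ...]]]):
        missing = set(AMINO_ACIDS_NO_PRO) - set(rotamers)
        if missing:
            raise ValueError(f"rotamer set missing amino acids: {sorted(missing)}")
        if "P" in rotamers:
            raise ValueError("proline rotamers are not allowed")
        for aa, rots in rotamers.items():
            if not rots:
                raise ValueError(f"empty rotamer list for amino acid {aa}")
        self.rotamers = {aa: list(rots) for aa, rots in rotamers.items()}

    def n_rotamers(self, aa: str) -> int:
        return len(self.rotamers[aa])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RotamerSet":
        rotamers: dict[str, list[tuple[float, ...]]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("aa\t"):
                continue
            parts = line.split("\t")
            aa = parts[0]
            chis = tuple(float(x) for x in parts[2:])
            rotamers.setdefault(aa, []).append(chis)
        return cls(rotamers)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["aa\trotamer_id\tchi1\tchi2\tchi3\tchi4"]
        for aa in sorted(self.rotamers):
            for i, chis in enumerate(self.rotamers[aa]):
                chi_cols = "\t".join(f"{c:.1f}" for c in chis)
                lines.append(f"{aa}\t{i}\t{chi_cols}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ChainState:
    """One tempered chain: latent point, sequence assignment, energy.

    The temperature belongs to the chain; replica-exchange swaps exchange
    states between chains, never temperatures.
    """

    x: np.ndarray
    sequence: list[tuple[str, int]]
    coords: np.ndarray
    energy: float
    temperature: float

    def sequence_string(self) -> str:
        return "".join(aa for aa, _ in self.sequence)


@dataclass
class SamplerConfig:
    """Run conditions for the design sampler.

    Defaults are the published protocol: 24 chains over a geometric
    temperature ladder on [0.1, 0.5], a 95%/5% side-chain/backbone move
    mix, 2,000,000 iterations with records kept every 200.
    """

    n_chains: int = 24
    t_min: float = 0.1
    t_max: float = 0.5
    ladder_ratio: float | None = None
    p_sidechain: float = 0.95
    p_backbone: float = 0.05
    n_iterations: int = 2_000_000
    save_stride: int = 200
    burn_in: int = 600_000
    rng_seed: int = 0
    design_positions: tuple[int, ...] = ()
    start_index: int = 0
    latent_step_scale: float = 0.001
    step_scale_is_variance: bool = False

    def __post_init__(self) -> None:
        if abs(self.p_sidechain + self.p_backbone - 1.0) > 1e-9:
            raise ValueError("p_sidechain + p_backbone must equal 1")
        if not (0 <= self.p_backbone <= 1):
            raise ValueError("move probabilities must lie in [0, 1]")
        if not 0 < self.t_min < self.t_max:
            raise ValueError("need 0 < t_min < t_max")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.save_stride < 1 or self.n_iterations < 1:
            raise ValueError("n_iterations and save_stride must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "SamplerConfig":
        """Read a plain ``key = value`` config file mirroring the fields."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line (expected key = value): {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key == "design_positions":
                kwargs[key] = tuple(int(v) for v in value.split()) if value else ()
            elif key in ("ladder_ratio",):
                kwargs[key] = None if value.lower() == "none" else float(value)
            elif key in ("step_scale_is_variance",):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in ("t_min", "t_max", "p_sidechain", "p_backbone",
                         "latent_step_scale"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
        return cls(**kwargs)


@dataclass
class DesignRecord:
    """One saved sample: emitted every ``save_stride`` iterations per chain."""

    iteration: int
    chain: int
    temperature: float
    sequence: str
    energy: float
    x: np.ndarray


@dataclass
class SamplerDiagnostics:
    """Acceptance bookkeeping, resolved by move type and adjacent pair."""

    sidechain_proposed: np.ndarray
    sidechain_accepted: np.ndarray
    backbone_proposed: np.ndarray
    backbone_accepted: np.ndarray
    swap_proposed: np.ndarray
    swap_accepted: np.ndarray

    def acceptance_rates(self) -> dict[str, np.ndarray]:
        def rate(acc, prop):
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(prop > 0, acc / np.maximum(prop, 1), np.nan)

        return {
            "sidechain": rate(self.sidechain_accepted, self.sidechain_proposed),
            "backbone": rate(self.backbone_accepted, self.backbone_proposed),
            "swap": rate(self.swap_accepted, self.swap_proposed),
        }


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------


def temperature_ladder(t_min: float, t_max: float, n_chains: int,
                       ratio: float | None = None) -> np.ndarray:
    """Geometric temperature ladder.

    With ``ratio`` omitted the ladder hits both bounds exactly using ratio
    (t_max/t_min)^(1/(n-1)).  With an explicit ratio it starts at ``t_min``
    and grows geometrically, truncated at ``t_max`` (the requested chain
    count is then an upper bound).
    """
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    if n_chains < 2:
        raise ValueError("a ladder needs at least 2 chains")
    if ratio is None:
        r = (t_max / t_min) ** (1.0 / (n_chains - 1))
        return t_min * r ** np.arange(n_chains)
    if ratio <= 1:
        raise ValueError("explicit ladder ratio must exceed 1")
    temps = [t_min]
    while len(temps) < n_chains:
        t = temps[-1] * ratio
        if t > t_max * (1 + 1e-12):
            break
        temps.append(t)
    return np.asarray(temps)


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dE/T))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not math.isfinite(delta_e):
        logger.warning("non-finite energy change %r: move rejected", delta_e)
        return False
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / temperature)


def swap_probability(e_i: float, e_j: float, t_i: float, t_j: float) -> float:
    """Replica-exchange swap probability min(1, exp[(Ei-Ej)(1/Ti-1/Tj)])."""
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    if not (math.isfinite(e_i) and math.isfinite(e_j)):
        raise ValueError("energies must be finite")
    exponent = (e_i - e_j) * (1.0 / t_i - 1.0 / t_j)
    if exponent >= 0:
        return 1.0
    return math.exp(exponent)


def random_sequence(design_positions: Sequence[int], rotamers: RotamerSet,
                    rng: np.random.Generator) -> list[tuple[str, int]]:
    """Uniform random (amino acid, rotamer) assignment over design positions."""
    seq = []
    for _ in design_positions:
        aa = AMINO_ACIDS_NO_PRO[rng.integers(len(AMINO_ACIDS_NO_PRO))]
        rot = int(rng.integers(rotamers.n_rotamers(aa)))
        seq.append((aa, rot))
    return seq


def propose_backbone_move(state: ChainState, model: GPLVMResults,
                          sigma: np.ndarray, rng: np.random.Generator,
                          energy: EnergyModel) -> ChainState:
    """Gaussian latent step; rotamer assignment carried over unchanged."""
    x_new = state.x + rng.normal(0.0, sigma)
    coords, _ = model.reconstruct(x_new)
    e = energy.evaluate(coords, state.sequence)
    return ChainState(x=x_new, sequence=state.sequence, coords=coords,
                      energy=e, temperature=state.temperature)


def propose_sidechain_move(state: ChainState, rotamers: RotamerSet,
                           design_positions: Sequence[int],
                           rng: np.random.Generator,
                           energy: EnergyModel) -> ChainState:
    """Uniform position, uniform non-proline amino acid, uniform rotamer."""
    if not design_positions:
        raise ValueError("no design positions configured for side-chain moves")
    slot = int(rng.integers(len(design_positions)))
    aa = AMINO_ACIDS_NO_PRO[rng.integers(len(AMINO_ACIDS_NO_PRO))]
    rot = int(rng.integers(rotamers.n_rotamers(aa)))
    seq = list(state.sequence)
    seq[slot] = (aa, rot)
    e = energy.evaluate(state.coords, seq)
    return ChainState(x=state.x, sequence=seq, coords=state.coords,
                      energy=e, temperature=state.temperature)


# ---------------------------------------------------------------------------
# Main engine
# ---------------------------------------------------------------------------


def run_parallel_tempering(model: GPLVMResults, energy: EnergyModel,
                           rotamers: RotamerSet | None,
                           config: SamplerConfig,
                           log_every: int = 10_000,
                           ) -> tuple[list[DesignRecord], SamplerDiagnostics]:
    """Run the tempered design sampler.

    All chains start at the latent coordinate of the configured input
    structure (``config.start_index``) with independent uniform-random
    initial sequences.  Chains run serially; one master seed spawns an
    independent RNG stream per chain plus one for swap decisions, so runs
    are bit-reproducible and per-chain streams do not depend on chain count.
    """
    temps = temperature_ladder(config.t_min, config.t_max, config.n_chains,
                               config.ladder_ratio) \
        if config.n_chains > 1 else np.array([config.t_min])
    n_chains = len(temps)

    if config.p_backbone > 0:
        sigma = model.latent_step_sigma(scale=config.latent_step_scale)
        if config.step_scale_is_variance:
            sigma = np.sqrt(sigma)
    else:
        sigma = np.zeros(model.X.shape[1])

    if config.p_sidechain > 0:
        if rotamers is None:
            raise ValueError("side-chain moves require a rotamer set")
        if not config.design_positions:
            raise ValueError("side-chain moves require design positions")

    streams = np.random.SeedSequence(config.rng_seed).spawn(n_chains + 1)
    chain_rngs = [np.random.default_rng(s) for s in streams[:n_chains]]
    swap_rng = np.random.default_rng(streams[n_chains])

    x0 = model.X[config.start_index].copy()
    coords0, _ = model.reconstruct(x0)
    chains: list[ChainState] = []
    for c in range(n_chains):
        seq = (random_sequence(config.design_positions, rotamers, chain_rngs[c])
               if config.design_positions and rotamers is not None else [])
        e0 = energy.evaluate(coords0, seq)
        chains.append(ChainState(x=x0.copy(), sequence=seq, coords=coords0,
                                 energy=e0, temperature=float(temps[c])))

    diag = SamplerDiagnostics(
        sidechain_proposed=np.zeros(n_chains, dtype=int),
        sidechain_accepted=np.zeros(n_chains, dtype=int),
        backbone_proposed=np.zeros(n_chains, dtype=int),
        backbone_accepted=np.zeros(n_chains, dtype=int),
        swap_proposed=np.zeros(max(n_chains - 1, 1), dtype=int),
        swap_accepted=np.zeros(max(n_chains - 1, 1), dtype=int),
    )
    records: list[DesignRecord] = []

    for it in range(1, config.n_iterations + 1):
        for c in range(n_chains):
            state = chains[c]
            rng = chain_rngs[c]
            if rng.random() < config.p_backbone:
                cand = propose_backbone_move(state, model, sigma, rng, energy)
                diag.backbone_proposed[c] += 1
                if metropolis_accept(cand.energy - state.energy,
                                     state.temperature, rng):
                    chains[c] = cand
                    diag.backbone_accepted[c] += 1
            else:
                cand = propose_sidechain_move(state, rotamers,
                                              config.design_positions, rng, energy)
                diag.sidechain_proposed[c] += 1
                if metropolis_accept(cand.energy - state.energy,
                                     state.temperature, rng):
                    chains[c] = cand
                    diag.sidechain_accepted[c] += 1

        if n_chains > 1:
            i = int(swap_rng.integers(n_chains))
            if i == 0:
                j = 1
            elif i == n_chains - 1:
                j = n_chains - 2
            else:
                j = i + 1 if swap_rng.random() < 0.5 else i - 1
            lo = min(i, j)
            diag.swap_proposed[lo] += 1
            p = swap_probability(chains[i].energy, chains[j].energy,
                                 chains[i].temperature, chains[j].temperature)
            if p >= 1.0 or swap_rng.random() < p:
                ti, tj = chains[i].temperature, chains[j].temperature
                chains[i], chains[j] = chains[j], chains[i]
                chains[i].temperature, chains[j].temperature = ti, tj
                diag.swap_accepted[lo] += 1

        if it % config.save_stride == 0:
            for c, state in enumerate(chains):
                records.append(DesignRecord(
                    iteration=it, chain=c, temperature=state.temperature,
                    sequence=state.sequence_string(), energy=state.energy,
                    x=state.x.copy(),
                ))

        if log_every and it % log_every == 0:
            rates = diag.acceptance_rates()
            logger.info(
                "iter %d: sidechain acc %s backbone acc %s swap acc %s",
                it,
                np.array2string(rates["sidechain"], precision=2),
                np.array2string(rates["backbone"], precision=2),
                np.array2string(rates["swap"], precision=2),
            )

    return records, diag


# ---------------------------------------------------------------------------
# Record I/O
# ---------------------------------------------------------------------------


def write_records_tsv(records: Sequence[DesignRecord], path: str | Path) -> None:
    """Write design records as TSV (iteration, chain, temperature, sequence,
    energy, latent coordinates)."""
    if not records:
        raise ValueError("no records to write")
    n_latent = len(records[0].x)
    header = ["iteration", "chain", "temperature", "sequence", "energy"]
    header += [f"latent_{l + 1}" for l in range(n_latent)]
    lines = ["\t".join(header)]
    for r in records:
        row = [str(r.iteration), str(r.chain), f"{r.temperature:.10g}",
               r.sequence, f"{r.energy:.10g}"]
        row += [f"{v:.10g}" for v in r.x]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_records_tsv(path: str | Path) -> list[DesignRecord]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    n_latent = sum(1 for h in header if h.startswith("latent_"))
    records = []
    for line in lines[1:]:
        parts = line.split("\t")
        records.append(DesignRecord(
            iteration=int(parts[0]), chain=int(parts[1]),
            temperature=float(parts[2]), sequence=parts[3],
            energy=float(parts[4]),
            x=np.array([float(v) for v in parts[5: 5 + n_latent]]),
        ))
    return records
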