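"""Synthetic test systems: hinged helical ensembles, toy energies, rotamers.

The ensemble generator emulates the situation the latent-variable model is
built for: a set of same-topology backbones whose conformational variation
is governed by one or two hidden parameters (a hinge-bend angle, optionally
a twist) plus isotropic Cartesian noise.  The low-dimensional assumption
therefore holds by construction and the generating parameters are returned
so recovery can be measured.  Geometry is idealised two-segment alpha-helix
backbone (fixture constants below), not a physical model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .sampler import AMINO_ACIDS_NO_PRO, EnergyModel, RotamerSet
from .structures import BackboneStructure, StructureEnsemble

# Idealised alpha-helix fixture constants: rise per residue and twist per
# residue along the helix axis, plus per-atom cylindrical placement
# (radius / phase offset / axial offset relative to the CA of the residue).
HELIX_RISE = 1.5          # Angstrom per residue
HELIX_TWIST_DEG = 100.0   # degrees per residue
_ATOM_CYL = {             # atom -> (radius, phase offset deg, z offset)
    "N": (1.60, -28.0, -0.60),
    "CA": (2.30, 0.0, 0.00),
    "C": (1.70, 28.0, 0.60),
    "O": (2.00, 46.0, 1.05),
}


@dataclass
class ToyEnsembleSpec:
    """Conditions for a synthetic hinged-helix ensemble.

    parameter_range is in degrees and applies to the hinge-bend angle
    (dimension 1) and, if ``generative_dims == 2``, also to the twist about
    the second segment's axis (dimension 2).  ``noise_sigma`` is the
    isotropic per-coordinate Gaussian noise in Angstrom.
    """

    n_structures: int = 20
    n_residues: int = 16
    generative_dims: int = 1
    parameter_range: tuple[float, float] = (-40.0, 40.0)
    noise_sigma: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_structures < 2:
            raise ValueError("n_structures must be >= 2")
        if self.n_residues < 8:
            raise ValueError("n_residues must be >= 8 (two helical segments)")
        if self.generative_dims not in (1, 2):
            raise ValueError("generative_dims must be 1 or 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        lo, hi = self.parameter_range
        if not lo < hi:
            raise ValueError("parameter_range must be an increasing interval")


def _ideal_helix(n_residues: int) -> np.ndarray:
    """(n, 4, 3) idealised helical backbone along +z."""
    coords = np.empty((n_residues, 4, 3))
    for i in range(n_residues):
        base_phase = np.deg2rad(HELIX_TWIST_DEG * i)
        z0 = HELIX_RISE * i
        for j, name in enumerate(("N", "CA", "C", "O")):
            r, dphi, dz = _ATOM_CYL[name]
            phi = base_phase + np.deg2rad(dphi)
            coords[i, j] = (r * np.cos(phi), r * np.sin(phi), z0 + dz)
    return coords


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def hinged_helix(n_residues: int, bend_deg: float, twist_deg: float = 0.0) -> BackboneStructure:
    """Two ideal helical segments joined by a hinge at the midpoint.

    The second segment is first twisted about the helix axis (z) and then
    bent about the x axis, both through the hinge point.
    """
    coords = _ideal_helix(n_residues)
    n1 = n_residues // 2
    hinge_point = coords[n1 - 1, 1].copy()  # CA of the last residue of segment 1

    seg2 = coords[n1:] - hinge_point
    if twist_deg:
        seg2 = seg2 @ _rotation_about_axis([0.0, 0.0, 1.0], np.deg2rad(twist_deg)).T
    if bend_deg:
        seg2 = seg2 @ _rotation_about_axis([1.0, 0.0, 0.0], np.deg2rad(bend_deg)).T
    coords[n1:] = seg2 + hinge_point

    n = n_residues
    return BackboneStructure(
        residue_ids=tuple(str(i + 1) for i in range(n)),
        chain_ids=("A",) * n,
        coords=coords,
        sequence="A" * n,
    )


def generate_toy_ensemble(spec: ToyEnsembleSpec) -> tuple[StructureEnsemble, np.ndarray]:
    """Sample an ensemble of hinged helices with known generating parameters.

    Returns the ensemble and an (n_structures, generative_dims) array of the
    true parameters (degrees), for recovery tests.
    """
    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.parameter_range
    params = rng.uniform(lo, hi, size=(spec.n_structures, spec.generative_dims))
    members = []
    for p in params:
        bend = float(p[0])
        twist = float(p[1]) if spec.generative_dims == 2 else 0.0
        s = hinged_helix(spec.n_residues, bend, twist)
        if spec.noise_sigma > 0:
            noisy = s.coords + rng.normal(0.0, spec.noise_sigma, size=s.coords.shape)
            s = s.with_coords(noisy)
        members.append(s)
    return StructureEnsemble(members), params


# ---------------------------------------------------------------------------
# Toy energies
# ---------------------------------------------------------------------------


class HarmonicEnergy(EnergyModel):
    """E = k * sum_atoms ||r - r_ref||^2, sequence-independent, no superposition."""

    def __init__(self, reference: BackboneStructure, k: float = 1.0):
        if k <= 0:
            raise ValueError("force constant k must be positive")
        self.k = float(k)
        self._ref_flat = reference.flatten()
        self.reference = reference

    def evaluate(self, coords: np.ndarray, sequence) -> float:
        coords = np.asarray(coords, dtype=float).reshape(-1)
        if coords.shape != self._ref_flat.shape:
            raise ValueError(
                f"coordinate length {coords.shape[0]} does not match the "
                f"reference ({self._ref_flat.shape[0]})"
            )
        d = coords - self._ref_flat
        return self.k * float(d @ d)


class SequenceEnergy(EnergyModel):
    """Separable per-position amino acid weights; backbone-independent.

    ``weights`` maps design-position index -> {one-letter aa -> energy} and
    must cover all 19 allowed (non-proline) amino acids at every position.
    The global optimum is the per-position argmin, which makes sampler
    recovery exactly checkable.
    """

    def __init__(self, weights: Mapping[int, Mapping[str, float]]):
        self.weights = {int(p): dict(t) for p, t in weights.items()}
        for p, table in self.weights.items():
            missing = set(AMINO_ACIDS_NO_PRO) - set(table)
            if missing:
                raise ValueError(
                    f"position {p}: weight table missing amino acids {sorted(missing)}"
                )

    def evaluate(self, coords, sequence) -> float:
        total = 0.0
        for slot, (aa, _rot) in enumerate(sequence):
            total += self.weights[slot][aa]
        return total

    def optimal_sequence(self) -> str:
        return "".join(
            min(self.weights[p], key=lambda aa: (self.weights[p][aa], aa))
            for p in sorted(self.weights)
        )


class SumEnergy(EnergyModel):
    """Sum of component energies (e.g. harmonic backbone + sequence terms)."""

    def __init__(self, *components: EnergyModel):
        if not components:
            raise ValueError("at least one component energy required")
        self.components = components

    def evaluate(self, coords, sequence) -> float:
        return sum(c.evaluate(coords, sequence) for c in self.components)


def random_sequence_weights(n_positions: int, seed: int = 0,
                            scale: float = 1.0) -> dict[int, dict[str, float]]:
    """Random separable weight tables with a unique per-position optimum."""
    rng = np.random.default_rng(seed)
    weights: dict[int, dict[str, float]] = {}
    for p in range(n_positions):
        vals = rng.normal(0.0, scale, size=len(AMINO_ACIDS_NO_PRO))
        order = np.argsort(vals)
        vals[order[0]] -= 0.5 * scale  # ensure a clear unique optimum
        weights[p] = {aa: float(v) for aa, v in zip(AMINO_ACIDS_NO_PRO, vals)}
    return weights


def generate_toy_rotamer_set(n_rotamers_per_aa: int = 3,
                             path: str | Path | None = None) -> RotamerSet:
    """Dummy rotamer set: ``n`` placeholder rotamers per non-proline amino acid.

    If ``path`` is given the set is also written in the sampler's TSV rotamer
    format (columns: aa, rotamer_id, chi1..chi4).
    """
    if n_rotamers_per_aa < 1:
        raise ValueError("n_rotamers_per_aa must be >= 1")
    rotamers = {
        aa: [tuple(60.0 * r + 10.0 * k for k in range(4))
             for r in range(n_rotamers_per_aa)]
        for aa in AMINO_ACIDS_NO_PRO
    }
    rset = RotamerSet(rotamers)
    if path is not None:
        rset.write_tsv(path)
    return rset
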