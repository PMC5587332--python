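"""Backbone structure I/O, superposition and ensemble assembly.

The learned representation operates on backbone heavy atoms only (N, CA, C,
O per residue, in that fixed order).  Structures are read from PDB files,
rigidly superposed with the Kabsch algorithm, and flattened into an N x D
data matrix (D = 12 * n_residues) that the latent-variable model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class TopologyError(ValueError):
    """Two structures that must share a topology do not."""


class PDBFormatError(ValueError):
    """A PDB file could not be interpreted as a backbone structure."""


@dataclass(frozen=True)
class BackboneStructure:
    """One conformation of a fixed residue topology.

    Parameters
    ----------
    residue_ids : sequence of str
        PDB residue numbers with any insertion code appended (``"54"``,
        ``"54A"``); strictly increasing within a chain.
    chain_ids : sequence of str
        Per-residue chain label.
    coords : ndarray, shape (n_residues, 4, 3)
        Cartesian coordinates in Angstrom for atoms N, CA, C, O.
    sequence : str
        One-letter amino acid codes, one per residue (``X`` for unknown).
    """

    residue_ids: tuple[str, ...]
    chain_ids: tuple[str, ...]
    coords: np.ndarray
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_ids", tuple(str(r) for r in self.residue_ids))
        object.__setattr__(self, "chain_ids", tuple(self.chain_ids))
        coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_ids)
        if n == 0:
            raise ValueError("empty structure: at least one residue required")
        if coords.shape != (n, 4, 3):
            raise ValueError(
                f"coords must have shape ({n}, 4, 3); got {coords.shape}"
            )
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        if len(self.chain_ids) != n or len(self.sequence) != n:
            raise ValueError("residue_ids, chain_ids and sequence lengths differ")
        object.__setattr__(self, "coords", coords)
        self._check_residue_order()

    def _check_residue_order(self) -> None:
        prev: dict[str, tuple[int, str]] = {}
        for rid, ch in zip(self.residue_ids, self.chain_ids):
            key = _resid_sort_key(rid)
            if ch in prev and key <= prev[ch]:
                raise ValueError(
                    f"residue order not strictly increasing in chain {ch!r} at {rid!r}"
                )
            prev[ch] = key

    # -- topology ----------------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def n_atoms(self) -> int:
        return 4 * self.n_residues

    def topology_key(self) -> tuple:
        return (self.residue_ids, self.chain_ids)

    def same_topology(self, other: "BackboneStructure") -> bool:
        return self.topology_key() == other.topology_key()

    def residue_keys(self) -> list[tuple[str, str]]:
        """(chain_id, residue_id) pairs, one per residue."""
        return list(zip(self.chain_ids, self.residue_ids))

    # -- coordinates -------------------------------------------------------

    def flatten(self) -> np.ndarray:
        """Row-vector of length D = 12 * n_residues (residue-major, atom order
        N, CA, C, O, xyz innermost)."""
        return self.coords.reshape(-1).copy()

    def with_coords(self, coords: np.ndarray) -> "BackboneStructure":
        """Same topology with new coordinates; accepts (n,4,3) or flat (D,)."""
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 1:
            coords = coords.reshape(self.n_residues, 4, 3)
        return replace(self, coords=coords)

    def subset(self, indices: Sequence[int]) -> "BackboneStructure":
        idx = list(indices)
        return BackboneStructure(
            residue_ids=tuple(self.residue_ids[i] for i in idx),
            chain_ids=tuple(self.chain_ids[i] for i in idx),
            coords=self.coords[idx],
            sequence="".join(self.sequence[i] for i in idx),
        )


def _resid_sort_key(rid: str) -> tuple[int, str]:
    num = rid
    icode = ""
    if rid and rid[-1].isalpha():
        num, icode = rid[:-1], rid[-1]
    return int(num), icode


@dataclass
class StructureEnsemble:
    """A set of conformations sharing one residue topology."""

    members: list[BackboneStructure] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.members:
            ref = self.members[0]
            for i, m in enumerate(self.members[1:], start=1):
                _require_same_topology(ref, m, context=f"member {i}")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i: int) -> BackboneStructure:
        return self.members[i]

    @property
    def topology(self) -> BackboneStructure:
        return self.members[0]


def _require_same_topology(a: BackboneStructure, b: BackboneStructure, context: str = "") -> None:
    if a.same_topology(b):
        return
    ka, kb = a.residue_keys(), b.residue_keys()
    detail = f"residue counts differ ({len(ka)} vs {len(kb)})"
    for pa, pb in zip(ka, kb):
        if pa != pb:
            detail = f"first differing residue: {pa} vs {pb}"
            break
    where = f" ({context})" if context else ""
    raise TopologyError(f"topology mismatch{where}: {detail}")


# ---------------------------------------------------------------------------
# PDB I/O (Biopython behind the scenes)
# ---------------------------------------------------------------------------


def read_backbone(path: str | Path, chains: Iterable[str] | None = None,
                  model_index: int = 0) -> BackboneStructure:
    """Read one backbone conformation from a PDB file.

    Only ATOM records are considered; alternate locations resolve to the
    highest-occupancy conformer.  Every residue must provide all four
    backbone heavy atoms or a :class:`PDBFormatError` naming the residue is
    raised.
    """
    models = _read_models(path, chains)
    if model_index >= len(models):
        raise PDBFormatError(f"{path}: model {model_index} not present")
    return models[model_index]


def read_ensemble(source: str | Path | Sequence[str | Path],
                  chains: Iterable[str] | None = None) -> StructureEnsemble:
    """Read an ensemble from a directory of PDBs, a list of PDB paths, or a
    single multi-model PDB file."""
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.is_dir():
            paths = sorted(p.glob("*.pdb"))
            if not paths:
                raise PDBFormatError(f"no .pdb files in directory {p}")
            members = [read_backbone(q, chains) for q in paths]
        else:
            members = _read_models(p, chains)
    else:
        members = [read_backbone(Path(q), chains) for q in source]
    if not members:
        raise PDBFormatError("no structures read")
    return StructureEnsemble(members)


def _read_models(path: str | Path, chains: Iterable[str] | None) -> list[BackboneStructure]:
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise PDBFormatError(f"{path}: not parsable as PDB ({exc})") from exc

    wanted = set(chains) if chains is not None else None
    out: list[BackboneStructure] = []
    for model in structure:
        rids: list[str] = []
        chs: list[str] = []
        seq: list[str] = []
        xyz: list[np.ndarray] = []
        seen_chains = set()
        for chain in model:
            seen_chains.add(chain.id)
            if wanted is not None and chain.id not in wanted:
                continue
            for residue in chain:
                het, resseq, icode = residue.id
                if het.strip():
                    continue  # skip HETATM / waters
                rid = f"{resseq}{icode.strip()}"
                atom_coords = []
                for name in BACKBONE_ATOMS:
                    if name not in residue:
                        raise PDBFormatError(
                            f"{path}: residue {chain.id}:{rid} "
                            f"({residue.get_resname()}) lacks backbone atom {name}"
                        )
                    atom = residue[name]
                    if atom.is_disordered():
                        atom = _highest_occupancy(atom)
                    atom_coords.append(np.asarray(atom.get_coord(), dtype=float))
                rids.append(rid)
                chs.append(chain.id)
                seq.append(_THREE_TO_ONE.get(residue.get_resname(), "X"))
                xyz.append(np.stack(atom_coords))
        if wanted is not None:
            missing = wanted - seen_chains
            if missing:
                raise PDBFormatError(f"{path}: chains {sorted(missing)} not present")
        if not rids:
            raise PDBFormatError(f"{path}: no amino acid residues found")
        out.append(BackboneStructure(tuple(rids), tuple(chs), np.stack(xyz), "".join(seq)))
    if not out:
        raise PDBFormatError(f"{path}: file contains no models")
    return out


def _highest_occupancy(disordered_atom):
    # highest occupancy wins; ties by altloc label order
    best = None
    for alt in sorted(disordered_atom.disordered_get_id_list()):
        a = disordered_atom.disordered_get(alt)
        if best is None or (a.get_occupancy() or 0.0) > (best.get_occupancy() or 0.0):
            best = a
    return best


def write_backbone(structure: BackboneStructure, path: str | Path) -> None:
    """Write a backbone structure as a PDB file (ATOM records only)."""
    _write_models([structure], path)


def write_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file."""
    _write_models(list(ensemble), path)


def _write_models(models: Sequence[BackboneStructure], path: str | Path) -> None:
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("bb")
    for mi, s in enumerate(models):
        builder.init_model(mi)
        current_chain = None
        serial = 1
        for i in range(s.n_residues):
            ch = s.chain_ids[i]
            if ch != current_chain:
                builder.init_chain(ch)
                builder.init_seg("    ")
                current_chain = ch
            rid = s.residue_ids[i]
            num, icode = _resid_sort_key(rid)
            resname = _ONE_TO_THREE.get(s.sequence[i], "UNK")
            builder.init_residue(resname, " ", num, icode or " ")
            for j, name in enumerate(BACKBONE_ATOMS):
                builder.init_atom(
                    name, s.coords[i, j], 0.0, 1.0, " ", f" {name:<3s}"[:4],
                    serial, element=name[0],
                )
                serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


class SuperpositionResult(NamedTuple):
    structure: BackboneStructure  # mobile, transformed onto the reference
    rotation: np.ndarray          # (3, 3) proper rotation, det = +1
    translation: np.ndarray       # (3,) applied after rotation
    rmsd: float                   # Angstrom, over the masked atoms


def kabsch_superpose(mobile: BackboneStructure, reference: BackboneStructure,
                     mask: Sequence[str] | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    ``mask`` optionally restricts the fit (and the reported RMSD) to a
    subset of residue ids; the transform is applied to all atoms of
    ``mobile``.  The returned rotation is always proper (det = +1).
    """
    if mask is None:
        _require_same_topology(mobile, reference)
        idx_m = idx_r = np.arange(mobile.n_residues)
    else:
        wanted = {str(m) for m in mask}
        idx_m = np.array([i for i, r in enumerate(mobile.residue_ids) if r in wanted])
        idx_r = np.array([i for i, r in enumerate(reference.residue_ids) if r in wanted])
        if len(idx_m) != len(wanted) or len(idx_r) != len(wanted):
            raise TopologyError("mask residues missing from one of the structures")
        km = [mobile.residue_keys()[i] for i in idx_m]
        kr = [reference.residue_keys()[i] for i in idx_r]
        if km != kr:
            raise TopologyError("masked residues do not correspond between structures")

    P = mobile.coords[idx_m].reshape(-1, 3)
    Q = reference.coords[idx_r].reshape(-1, 3)
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")

    R, t, rmsd = _kabsch(P, Q)
    moved = mobile.coords.reshape(-1, 3) @ R.T + t
    return SuperpositionResult(mobile.with_coords(moved.reshape(-1, 4, 3)), R, t, rmsd)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t with ``P @ R.T + t ~ Q``."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S = np.diag([1.0, 1.0, d])
    R = Vt.T @ S @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return R, t, rmsd


def pairwise_rmsd(a: BackboneStructure, b: BackboneStructure,
                  mask: Sequence[str] | None = None) -> float:
    """Minimum superposed backbone RMSD between two conformations."""
    return kabsch_superpose(a, b, mask=mask).rmsd


# ---------------------------------------------------------------------------
# Data matrix
# ---------------------------------------------------------------------------


@dataclass
class DataMatrix:
    """Flattened, superposed ensemble coordinates: the model's N x D data.

    ``atom_index`` maps ``(chain_id, residue_id, atom_name)`` to the first of
    the three columns holding that atom's x, y, z.
    """

    values: np.ndarray
    column_means: np.ndarray
    atom_index: dict[tuple[str, str, str], int]
    topology: BackboneStructure

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] % 3:
            raise ValueError("values must be N x D with D divisible by 3")

    @property
    def n_structures(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def unflatten(self, row: np.ndarray) -> BackboneStructure:
        return self.topology.with_coords(np.asarray(row, dtype=float))


def build_data_matrix(ensemble: StructureEnsemble,
                      reference_index: int = 0) -> DataMatrix:
    """Superpose every member onto the reference member and flatten.

    Rigid-body differences between members are removed by the Kabsch
    superposition before flattening, so the matrix captures internal
    (conformational) variation only.
    """
    if len(ensemble) < 2:
        raise ValueError("ensemble must contain at least 2 structures")
    if not 0 <= reference_index < len(ensemble):
        raise ValueError("reference_index out of range")
    ref = ensemble[reference_index]
    rows = []
    aligned = []
    for i, member in enumerate(ensemble):
        _require_same_topology(ref, member, context=f"member {i}")
        if i == reference_index:
            moved = member
        else:
            moved = kabsch_superpose(member, ref).structure
        aligned.append(moved)
        rows.append(moved.flatten())
    values = np.stack(rows)

    atom_index: dict[tuple[str, str, str], int] = {}
    col = 0
    for ch, rid in ref.residue_keys():
        for name in BACKBONE_ATOMS:
            atom_index[(ch, rid, name)] = col
            col += 3

    return DataMatrix(values=values, column_means=values.mean(axis=0),
                      atom_index=atom_index, topology=aligned[reference_index])


# ---------------------------------------------------------------------------
# Partial structures and representatives
# ---------------------------------------------------------------------------


def extract_partial(structure: BackboneStructure,
                    design_positions: Iterable[str],
                    cutoff: float = 8.0) -> BackboneStructure:
    """Residues with any backbone heavy atom within ``cutoff`` Angstrom of
    any backbone heavy atom of a design position.

    Membership is residue-level, so returned topologies stay whole; design
    positions are always included.  The default 8 Angstrom shell is what
    keeps reconstruction and repacking cost manageable during design.
    """
    design = {str(p) for p in design_positions}
    if not design:
        raise ValueError("design position set is empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    present = set(structure.residue_ids)
    missing = design - present
    if missing:
        raise ValueError(f"design positions not in structure: {sorted(missing)}")

    design_idx = [i for i, r in enumerate(structure.residue_ids) if r in design]
    design_idx_set = set(design_idx)
    design_atoms = structure.coords[design_idx].reshape(-1, 3)
    tree = cKDTree(design_atoms)

    keep = []
    for i in range(structure.n_residues):
        if i in design_idx_set:
            keep.append(i)
            continue
        d, _ = tree.query(structure.coords[i].reshape(-1, 3), k=1)
        if float(np.min(d)) <= cutoff:
            keep.append(i)
    return structure.subset(keep)


def rmsd_matrix(ensemble: StructureEnsemble) -> np.ndarray:
    """Symmetric matrix of pairwise superposed backbone RMSDs."""
    n = len(ensemble)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pairwise_rmsd(ensemble[i], ensemble[j])
    return M


def select_representatives(ensemble: StructureEnsemble, k: int,
                           return_indices: bool = False):
    """Pick ``k`` representative conformations by average-link clustering.

    The pairwise superposed-RMSD matrix is clustered with average linkage
    and cut at ``k`` clusters; each cluster contributes the member with the
    smallest mean RMSD to its co-members.
    """
    n = len(ensemble)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]; got {k}")
    M = rmsd_matrix(ensemble)
    if k == n:
        labels = np.arange(n)
    else:
        Z = linkage(squareform(M, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1

    reps: list[int] = []
    for c in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == c)
        if len(members) == 1:
            reps.append(int(members[0]))
            continue
        sub = M[np.ix_(members, members)]
        mean_to_others = sub.sum(axis=1) / (len(members) - 1)
        reps.append(int(members[int(np.argmin(mean_to_others))]))
    reps.sort()
    selected = StructureEnsemble([ensemble[i] for i in reps])
    if return_indices:
        return selected, reps
    return selected
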