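"""Post-processing of design records: Boltzmann merging, ranking, and
sequence-comparison statistics.

Because the tempered sampler draws from the Boltzmann distribution after
equilibration, the several poses (backbone/rotamer states) that share one
amino acid sequence are merged into a single statistical weight
sum_p exp(-E_p).  Ranking uses the numerically stable log-sum-exp of -E_p,
which orders sequences identically whenever the naive sum does not
overflow.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sampler import DesignRecord


def merge_sequence_scores(records: Sequence[DesignRecord],
                          temperature_filter: float | None = None,
                          burn_in: int = 0,
                          merge_temperature: float | None = None) -> pd.DataFrame:
    """Merge pose energies per sequence into Boltzmann weights.

    Parameters
    ----------
    records
        Post-burn-in design records (``burn_in`` trims by iteration).
    temperature_filter
        If given, keep only records from chains at this temperature
        (matched to within 1e-9); default pools all chains.
    merge_temperature
        Optional temperature in the merge exponent, exp(-E/T); the default
        uses exp(-E) with no temperature, as in the published merge rule.

    Returns
    -------
    DataFrame with one row per distinct sequence: ``sequence``,
    ``log_score`` (log sum_p exp(-E_p), the ranking key, larger = better),
    ``merged_score`` (exp of it; may overflow to inf for very low
    energies), ``n_poses`` and ``best_energy``.
    """
    kept = [r for r in records if r.iteration > burn_in]
    if temperature_filter is not None:
        kept = [r for r in kept if abs(r.temperature - temperature_filter) < 1e-9]
    if not kept:
        raise ValueError("no records remain after burn-in/temperature filtering")

    by_seq: dict[str, list[float]] = {}
    for r in kept:
        by_seq.setdefault(r.sequence, []).append(r.energy)

    beta = 1.0 if merge_temperature is None else 1.0 / merge_temperature
    rows = []
    for seq, energies in by_seq.items():
        e = np.asarray(energies)
        log_score = float(logsumexp(-beta * e))
        with np.errstate(over="ignore"):
            merged = float(np.exp(log_score))
        rows.append({
            "sequence": seq,
            "log_score": log_score,
            "merged_score": merged,
            "n_poses": len(energies),
            "best_energy": float(e.min()),
        })
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["log_score", "best_energy", "sequence"],
        ascending=[False, True, True],
    ).reset_index(drop=True)


def top_k_sequences(table: pd.DataFrame, k: int) -> list[str]:
    """Best ``k`` sequences by merged log score.

    Ties break by lower best-pose energy, then lexicographically.  If ``k``
    exceeds the table size all sequences are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = table.sort_values(
        by=["log_score", "best_energy", "sequence"],
        ascending=[False, True, True],
    )
    if k > len(ordered):
        import warnings
        warnings.warn(f"k={k} exceeds table size {len(ordered)}; returning all",
                      stacklevel=2)
        k = len(ordered)
    return ordered["sequence"].head(k).tolist()


def max_identity_to_reference(designs: Sequence[str],
                              reference_set: Sequence[str],
                              positions: Iterable[int] | None = None,
                              ) -> tuple[np.ndarray, float]:
    """Per-design maximum percent identity against a reference sequence set.

    Identity is position-wise over the explicit ``positions`` index list
    (0-based into the compared strings; default: all positions) — no
    alignment is performed, matching topologies are assumed.  Returns the
    per-design maxima (percent) and their mean.
    """
    if not designs:
        raise ValueError("empty design list")
    if not reference_set:
        raise ValueError("empty reference set")
    pos = list(positions) if positions is not None else None

    def identity(a: str, b: str) -> float:
        idx = pos if pos is not None else range(min(len(a), len(b)))
        idx = list(idx)
        if not idx:
            raise ValueError("no positions to compare")
        for i in idx:
            if i >= len(a) or i >= len(b):
                raise IndexError(f"position {i} out of range for compared sequences")
        matches = sum(1 for i in idx if a[i] == b[i])
        return 100.0 * matches / len(idx)

    per_design = np.array([
        max(identity(d, ref) for ref in reference_set) for d in designs
    ])
    return per_design, float(per_design.mean())


def position_composition(designs: Sequence[str], position: int,
                         residue_set: Iterable[str]) -> float:
    """Percent of designs whose residue at ``position`` is in ``residue_set``."""
    if not designs:
        raise ValueError("empty design list")
    allowed = set(residue_set)
    for d in designs:
        if position >= len(d) or position < 0:
            raise IndexError(f"position {position} out of range for {d!r}")
    hits = sum(1 for d in designs if d[position] in allowed)
    return 100.0 * hits / len(designs)


def write_ranked_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_reference_sequences(path) -> list[str]:
    """Reference variants as FASTA or a plain one-sequence-per-line list."""
    text = open(path).read()
    if text.lstrip().startswith(">"):
        seqs, current = [], []
        for line in text.splitlines():
            if line.startswith(">"):
                if current:
                    seqs.append("".join(current))
                    current = []
            else:
                current.append(line.strip())
        if current:
            seqs.append("".join(current))
        return seqs
    return [line.strip() for line in text.splitlines() if line.strip()]
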