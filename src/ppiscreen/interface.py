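"""Inter-chain interface detection, residue contact maps, and steric clash scoring.

A residue pair on different chains is a *contact* when its minimum heavy-atom
distance is strictly below the cutoff (default 4.5 Å). Interface residues are
the union of contact-pair members. The *clash indicator* is the fraction of
interface residues with at least one severely overlapping inter-chain atom
pair; predicted models whose best interface is mostly interpenetration score
near 1 and are rejected upstream of ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import StructureModel

__all__ = ["InterfaceSet", "ClashReport", "find_interface", "contact_map", "clash_indicator"]

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, strict
DEFAULT_CLASH_CUTOFF = 1.6  # Å, deep van der Waals overlap


@dataclass
class InterfaceSet:
    """Interface residues (global indices) and canonical cross-chain contact pairs."""

    residues: frozenset[int]
    pairs: list[tuple[int, int, float]]  # (i, j, min heavy-atom distance), i < j
    cutoff: float

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residues_of_chain(self, model: StructureModel, chain_id: str) -> set[int]:
        chain_idx = model.chain_of()
        k = model.chain_ids.index(chain_id)
        return {i for i in self.residues if chain_idx[i] == k}


@dataclass
class ClashReport:
    indicator: float
    clashing_residues: frozenset[int]
    clash_cutoff: float


def _atom_arrays(model: StructureModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat heavy-atom table: coords (M,3), global residue index and chain index per atom."""
    coords, res_idx, chain_idx = [], [], []
    gi = 0
    for ci, (_, residues) in enumerate(model.chains):
        for r in residues:
            xyz = r.coords()
            coords.append(xyz)
            res_idx.extend([gi] * len(xyz))
            chain_idx.extend([ci] * len(xyz))
            gi += 1
    return np.concatenate(coords), np.asarray(res_idx), np.asarray(chain_idx)


def _residue_pair_minima(
    model: StructureModel, max_distance: float
) -> dict[tuple[int, int], float]:
    """Minimum heavy-atom distance for every cross-chain residue pair closer than
    ``max_distance``; keys are (i, j) with i < j in global-index order."""
    coords, res_idx, chain_idx = _atom_arrays(model)
    minima: dict[tuple[int, int], float] = {}
    n_chains = len(model.chains)
    for a in range(n_chains):
        mask_a = chain_idx == a
        for b in range(a + 1, n_chains):
            mask_b = chain_idx == b
            d = cdist(coords[mask_a], coords[mask_b])
            ia, ib = np.nonzero(d < max_distance)
            ra = res_idx[mask_a][ia]
            rb = res_idx[mask_b][ib]
            for i, j, dist in zip(ra, rb, d[ia, ib]):
                key = (int(i), int(j))
                if dist < minima.get(key, np.inf):
                    minima[key] = float(dist)
    return minima


def find_interface(
    model: StructureModel, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> InterfaceSet:
    """Detect all inter-chain residue contacts below ``cutoff`` (strict).

    A single-chain model yields an empty interface with a warning rather than
    an error, so that monomer controls flow through the same pipeline.
    """
    if len(model.chains) < 2:
        warnings.warn(
            f"model {model.model_id} has a single chain; interface is empty",
            stacklevel=2,
        )
        return InterfaceSet(residues=frozenset(), pairs=[], cutoff=cutoff)
    minima = _residue_pair_minima(model, cutoff)
    pairs = sorted((i, j, d) for (i, j), d in minima.items())
    residues = frozenset(i for i, j, _ in pairs) | frozenset(j for i, j, _ in pairs)
    return InterfaceSet(residues=residues, pairs=pairs, cutoff=cutoff)


def contact_map(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[tuple[int, int, float]]:
    """Residue-level contacts between two named chains.

    Returns (residue_number_a, residue_number_b, min_distance) tuples sorted by
    chain-A residue number, then by distance.
    """
    residues_a = model.get_chain(chain_a)
    residues_b = model.get_chain(chain_b)
    if chain_a == chain_b:
        raise ValueError("contact_map requires two distinct chains")
    out: list[tuple[int, int, float]] = []
    for ra in residues_a:
        ca = ra.coords()
        for rb in residues_b:
            d = float(cdist(ca, rb.coords()).min())
            if d < cutoff:
                out.append((ra.residue_number, rb.residue_number, d))
    out.sort(key=lambda t: (t[0], t[2]))
    return out


def contact_table(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> "pandas.DataFrame":
    """Contact map with residue names, as a DataFrame ready for TSV export."""
    import pandas as pd

    name_a = {r.residue_number: r.residue_name for r in model.get_chain(chain_a)}
    name_b = {r.residue_number: r.residue_name for r in model.get_chain(chain_b)}
    rows = [
        {
            "chain_a": chain_a,
            "resnum_a": na,
            "resname_a": name_a[na],
            "chain_b": chain_b,
            "resnum_b": nb,
            "resname_b": name_b[nb],
            "min_distance_A": d,
        }
        for na, nb, d in contact_map(model, chain_a, chain_b, cutoff)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chain_a", "resnum_a", "resname_a",
            "chain_b", "resnum_b", "resname_b", "min_distance_A",
        ],
    )


def clash_indicator(
    model: StructureModel,
    iface: InterfaceSet,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> ClashReport:
    """Fraction of interface residues involved in inter-chain atomic overlap.

    An interface residue clashes when any of its heavy atoms lies within
    ``clash_cutoff`` of a heavy atom on a different chain. An empty interface
    reports indicator 0.
    """
    if not iface.residues:
        return ClashReport(0.0, frozenset(), clash_cutoff)
    minima = _residue_pair_minima(model, clash_cutoff)
    clashing = set()
    for (i, j), _ in minima.items():
        if i in iface.residues:
            clashing.add(i)
        if j in iface.residues:
            clashing.add(j)
    return ClashReport(
        indicator=len(clashing) / len(iface.residues),
        clashing_residues=frozenset(clashing),
        clash_cutoff=clash_cutoff,
    )
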