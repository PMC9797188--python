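"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain double/triple loops over residues and
atoms so that it shares no code path with the package's vectorized versions.
"""

from __future__ import annotations

import numpy as np

from ppiscreen.model_io import ScoredModel, StructureModel
from ppiscreen.scoring import d0


def brute_force_interface(
    model: StructureModel, cutoff: float
) -> tuple[set[int], dict[tuple[int, int], float]]:
    """All-atom double loop: cross-chain residue pairs with min distance < cutoff."""
    flat = []  # (global_index, chain_position, coords)
    for ci, (_, residues) in enumerate(model.chains):
        for r in residues:
            flat.append((ci, r.coords()))
    pairs: dict[tuple[int, int], float] = {}
    for i, (ci, xyz_i) in enumerate(flat):
        for j in range(i + 1, len(flat)):
            cj, xyz_j = flat[j]
            if ci == cj:
                continue
            dmin = np.inf
            for a in xyz_i:
                for b in xyz_j:
                    dmin = min(dmin, float(np.linalg.norm(a - b)))
            if dmin < cutoff:
                pairs[(i, j)] = dmin
    residues = set()
    for i, j in pairs:
        residues.add(i)
        residues.add(j)
    return residues, pairs


def brute_force_iscore(bound: ScoredModel, iface_residues: set[int]) -> float:
    """Exhaustive-frame iScore: loop every frame, gather cross-chain terms."""
    if not iface_residues:
        return 0.0
    chain_of = bound.model.chain_of()
    members = sorted(iface_residues)
    d = d0(len(members))
    best = 0.0
    for i in members:
        terms = []
        for j in members:
            if chain_of[j] != chain_of[i]:
                terms.append(1.0 / (1.0 + (bound.conf.pae[i, j] / d) ** 2))
        if terms:
            s = np.asarray(terms).sum() / len(terms)
            best = max(best, float(s))
    return best


def brute_force_ptm(bound: ScoredModel) -> float:
    """Exhaustive-frame predicted TM-score over all residues."""
    n = bound.n_residues
    d = d0(n)
    best = 0.0
    for i in range(n):
        terms = [1.0 / (1.0 + (bound.conf.pae[i, j] / d) ** 2) for j in range(n)]
        best = max(best, float(np.asarray(terms).sum() / n))
    return best


def random_bound_model(rng: np.random.Generator, max_n: int = 40) -> ScoredModel:
    """A random two-chain blob with random PAE — small enough for the oracles."""
    from ppiscreen.model_io import Atom, ConfidenceBundle, ResidueRecord, StructureModel, bind

    na = int(rng.integers(3, max_n // 2 + 1))
    nb = int(rng.integers(3, max_n - na + 1))
    chains = []
    for cid, n, offset in (("A", na, 0.0), ("B", nb, rng.uniform(2.0, 8.0))):
        residues = []
        for k in range(n):
            center = rng.uniform(-5, 5, size=3) + np.array([offset, 0, 0])
            atoms = [
                Atom("CA", "C", *(center + rng.uniform(-1, 1, size=3)))
                for _ in range(int(rng.integers(1, 4)))
            ]
            atoms[0] = Atom("CA", "C", *center)
            residues.append(ResidueRecord(k + 1, "GLY", atoms))
        chains.append((cid, residues))
    model = StructureModel("random", chains)
    n = model.n_residues
    pae = rng.uniform(0.0, 25.0, size=(n, n))
    return bind(model, ConfidenceBundle(pae=pae, plddt=rng.uniform(40, 95, size=n)))
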