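"""Synthetic predictor outputs: toy dimers, tunable PAE/pLDDT bundles, proteome
tables, and a seeded mock predictor.

These generators are the offline test surface for the whole pipeline. A toy
dimer is two ideal poly-alanine α-helices on parallel z-axes whose separation
controls whether an interface exists; translating the first few residues of
chain B onto chain A forces steric clashes at will. Confidence bundles use a
two-level PAE model (one value within chains, another across chains) so the
downstream interface score can be predicted in closed form. None of this
emulates real predictor error patterns — it provides controllable geometry
and error levels, nothing more.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .model_io import Atom, ConfidenceBundle, ResidueRecord, ScoredModel, StructureModel, bind

__all__ = [
    "FixtureSpec",
    "make_dimer",
    "make_spaced_dimer",
    "make_confidence",
    "mock_predictor",
    "make_proteome",
]

# ideal α-helix geometry: rise per residue, twist per residue, Cα radius
HELIX_RISE = 1.5  # Å
HELIX_TWIST = 100.0  # degrees
CA_RADIUS = 2.3  # Å

# Backbone/Cβ offsets relative to Cα in the local (radial u, tangential v, axial z)
# frame. Radial components are <= 0 (pointing toward the helix axis) so the
# radial envelope of a chain is exactly CA_RADIUS: two phase-aligned helices at
# axis separation s then have minimum heavy-atom distance s - 2*CA_RADIUS.
_SIDE_ATOMS = (
    ("N", "N", (-0.5, 0.8, -1.0)),
    ("C", "C", (-0.5, -0.8, 1.0)),
    ("O", "O", (-1.2, -1.0, 1.4)),
    ("CB", "C", (0.0, 1.3, 0.6)),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Controls for the toy-dimer and confidence generators.

    ``separation`` is the inter-axis distance of the two helices; with the
    geometry above the closest heavy-atom approach is roughly separation − 5 Å,
    so 7 Å yields a contact-rich, clash-free interface, and 20 Å none at all.
    ``overlap_residues`` copies that many chain-B residues onto chain A to
    force clashes. ``pae_interface``/``pae_intra`` are the cross-/within-chain
    PAE levels; ``pae_jitter`` adds seeded uniform noise of that fractional
    amplitude (0 keeps the matrix exactly two-level for closed-form checks).
    """

    chain_lengths: tuple[int, int] = (25, 25)
    separation: float = 7.0  # Å between helix axes
    overlap_residues: int = 0
    pae_interface: float = 5.0  # Å
    pae_intra: float = 2.0  # Å
    pae_jitter: float = 0.0  # fractional amplitude of seeded uniform noise
    plddt_level: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chain_lengths) != 2 or any(n < 1 for n in self.chain_lengths):
            raise ValueError(f"chain_lengths must be two positive ints: {self.chain_lengths}")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0 <= self.overlap_residues <= min(self.chain_lengths):
            raise ValueError(
                f"overlap_residues {self.overlap_residues} exceeds shortest chain"
            )
        if self.pae_interface < 0 or self.pae_intra < 0:
            raise ValueError("PAE levels must be >= 0")
        if not 0 <= self.plddt_level <= 100:
            raise ValueError("plddt_level must be in [0, 100]")


def _helix_residues(n: int, axis_x: float, phase_deg: float) -> list[ResidueRecord]:
    residues = []
    for t in range(n):
        theta = math.radians(phase_deg + HELIX_TWIST * t)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        v = np.array([-math.sin(theta), math.cos(theta), 0.0])
        z = np.array([0.0, 0.0, 1.0])
        ca = np.array([axis_x, 0.0, 0.0]) + CA_RADIUS * u + HELIX_RISE * t * z
        atoms = [Atom("CA", "C", *ca)]
        for name, element, (du, dv, dz) in _SIDE_ATOMS:
            pos = ca + du * u + dv * v + dz * z
            atoms.append(Atom(name, element, *pos))
        residues.append(ResidueRecord(t + 1, "ALA", atoms))
    return residues


def make_dimer(spec: FixtureSpec) -> StructureModel:
    """Two parallel poly-alanine helices; chain B faces chain A (180° phase).

    The first ``overlap_residues`` residues of chain B are translated onto the
    corresponding chain-A residues, forcing near-zero inter-chain distances.
    """
    na, nb = spec.chain_lengths
    chain_a = _helix_residues(na, 0.0, 0.0)
    chain_b = _helix_residues(nb, spec.separation, 180.0)
    for k in range(spec.overlap_residues):
        src = chain_a[k]
        shifted = [
            Atom(a.name, a.element, a.x + 0.05, a.y, a.z) for a in src.atoms
        ]  # tiny offset keeps distances positive but deep in clash range
        chain_b[k] = ResidueRecord(k + 1, "ALA", shifted)
    return StructureModel(
        model_id=f"dimer_s{spec.separation:g}_o{spec.overlap_residues}",
        chains=[("A", chain_a), ("B", chain_b)],
    )


def make_spaced_dimer(
    pair_distances: Sequence[float], spacing: float = 50.0
) -> StructureModel:
    """A dimer with one residue pair per requested inter-chain distance.

    Pair k sits at z = k*spacing, far from every other pair, so the model has
    exactly ``len(pair_distances)`` cross-chain contacts at exactly the given
    distances — full analytic control for contact-map and clash tests.
    """
    if not pair_distances:
        raise ValueError("need at least one pair distance")
    chain_a, chain_b = [], []
    for k, d in enumerate(pair_distances):
        z = k * spacing
        chain_a.append(ResidueRecord(k + 1, "GLY", [Atom("CA", "C", 0.0, 0.0, z)]))
        chain_b.append(ResidueRecord(k + 1, "GLY", [Atom("CA", "C", float(d), 0.0, z)]))
    return StructureModel("spaced_dimer", [("A", chain_a), ("B", chain_b)])


def make_confidence(model: StructureModel, spec: FixtureSpec) -> ConfidenceBundle:
    """Two-level PAE (intra/inter chain) with optional seeded jitter, flat pLDDT."""
    n = model.n_residues
    chain_idx = model.chain_of()
    cross = chain_idx[:, None] != chain_idx[None, :]
    pae = np.where(cross, spec.pae_interface, spec.pae_intra).astype(float)
    if spec.pae_jitter > 0:
        rng = np.random.default_rng(spec.seed)
        pae *= 1.0 + spec.pae_jitter * rng.uniform(-1.0, 1.0, size=pae.shape)
        pae = np.clip(pae, 0.0, None)
    return ConfidenceBundle(
        pae=pae,
        plddt=np.full(n, spec.plddt_level, dtype=float),
        model_name=model.model_id,
        seed=spec.seed,
        chain_lengths=model.chain_lengths,
    )


def make_bound(spec: FixtureSpec) -> ScoredModel:
    """Convenience: dimer + confidence, bound under the shared index."""
    model = make_dimer(spec)
    return bind(model, make_confidence(model, spec))


def mock_predictor(
    score_schedule: Optional[dict] = None,
    default_spec: FixtureSpec = FixtureSpec(),
) -> Callable:
    """A deterministic stand-in for the structure-prediction step.

    ``score_schedule`` maps either ``(pair, model_name, seed)`` or just
    ``pair`` — where ``pair`` is the tuple of monomer accessions — to a
    :class:`FixtureSpec`; calls not covered fall back to ``default_spec``.
    The returned callable satisfies the predictor-adapter contract:
    ``(features, model_name, seed, max_recycles) -> (StructureModel,
    ConfidenceBundle)`` and is a pure function of its arguments.
    """
    schedule = score_schedule or {}

    def adapter(features, model_name: str, seed: int, max_recycles: int = 8):
        pair = tuple(features.accessions)
        spec = schedule.get((pair, model_name, seed), schedule.get(pair, default_spec))
        model = make_dimer(spec)
        model.model_id = f"{'_'.join(pair)}|{model_name}|s{seed}"
        conf = make_confidence(model, spec)
        conf.model_name = model.model_id
        conf.seed = seed
        conf.recycles = max_recycles
        return model, conf

    return adapter


# ---------------------------------------------------------------------------
# synthetic proteome tables

_ENVELOPE_LOCATIONS = (
    "Cell inner membrane; Multi-pass membrane protein",
    "Periplasm",
    "Cell outer membrane",
    "Secreted",
    "Cell surface",
)


def make_proteome(
    n: int,
    fractions: Optional[dict] = None,
    seed: int = 0,
    length_range: tuple[int, int] = (60, 300),
) -> pd.DataFrame:
    """Synthetic proteome annotation table with a controlled composition.

    ``fractions`` keys: ``cytosolic`` (primary location is the cytoplasm),
    ``signal_peptide`` (fraction of all entries carrying a 1..k signal span;
    assigned to non-cytosolic entries only, since secreted/periplasmic
    proteins are the ones with signals — about 30% is realistic for a cell
    envelope), ``nonstandard`` (fraction containing a non-standard residue).
    Counts are ``round(n * fraction)``; deterministic for a fixed seed.
    """
    fr = {"cytosolic": 0.3, "signal_peptide": 0.3, "nonstandard": 0.0}
    fr.update(fractions or {})
    for key, val in fr.items():
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"fraction {key}={val} outside [0, 1]")
    n_cyt = round(n * fr["cytosolic"])
    n_sig = round(n * fr["signal_peptide"])
    n_bad = round(n * fr["nonstandard"])
    if n_sig > n - n_cyt:
        raise ValueError(
            f"incompatible fractions: {n_sig} signal peptides requested but only "
            f"{n - n_cyt} non-cytosolic entries available"
        )
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    rows = []
    for i in range(n):
        length = int(rng.integers(*length_range))
        seq = "".join(rng.choice(aas, size=length))
        cytosolic = i < n_cyt
        loc = "Cytoplasm" if cytosolic else _ENVELOPE_LOCATIONS[
            int(rng.integers(len(_ENVELOPE_LOCATIONS)))
        ]
        rows.append(
            {
                "accession": f"SYN{i:05d}",
                "gene": f"syn{i}",
                "sequence": seq,
                "locations": loc,
                "signal_peptide": "",
            }
        )
    # signal peptides go to the first n_sig non-cytosolic entries
    for i in range(n_cyt, n_cyt + n_sig):
        k = int(rng.integers(18, 26))  # typical Sec signal length
        rows[i]["signal_peptide"] = f"1..{k}"
    # non-standard residues anywhere
    for i in rng.choice(n, size=n_bad, replace=False):
        seq = rows[int(i)]["sequence"]
        pos = int(rng.integers(len(seq)))
        rows[int(i)]["sequence"] = seq[:pos] + rng.choice(["U", "X"]) + seq[pos + 1 :]
    return pd.DataFrame(rows)
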