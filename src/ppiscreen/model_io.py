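"""Reading, writing and binding of predicted complex structures and confidence files.

The residue-indexing contract established here is shared by every downstream
module: residues are numbered 1-based within each chain (author numbering),
and a 0-based *global index* runs over all residues in chain reading order.
Predicted-aligned-error (PAE) matrices index residues exactly this way, so a
:class:`ScoredModel` — a structure bound to its confidence bundle — is the
unit every scoring operation consumes.

Coordinates are ingested through :mod:`gemmi`; only heavy atoms of standard
polymer residues are kept (hydrogens, waters and hetero-compounds are
irrelevant to interface and clash geometry and are dropped on read).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ResidueRecord",
    "StructureModel",
    "ConfidenceBundle",
    "ScoredModel",
    "ParseError",
    "EmptyModelError",
    "BindingError",
    "read_structure",
    "write_structure",
    "read_confidence",
    "write_confidence",
    "bind",
]


class ParseError(ValueError):
    """A coordinate or confidence file could not be parsed."""


class EmptyModelError(ParseError):
    """The file contained no protein chains."""


class BindingError(ValueError):
    """Structure and confidence bundle disagree on residue bookkeeping."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class ResidueRecord:
    """One amino-acid residue: heavy atoms plus optional per-residue pLDDT."""

    residue_number: int
    residue_name: str
    atoms: list[Atom]
    plddt: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(
                f"residue {self.residue_name}{self.residue_number} has no heavy atoms"
            )
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(
                    f"non-finite coordinates in residue {self.residue_number}"
                )
        if self.plddt is not None and not 0.0 <= self.plddt <= 100.0:
            raise ValueError(f"pLDDT {self.plddt} outside [0, 100]")

    def coords(self) -> np.ndarray:
        """Heavy-atom coordinates, shape (n_atoms, 3)."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """A predicted (multi-)chain structure: ordered chains of ordered residues."""

    model_id: str
    chains: list[tuple[str, list[ResidueRecord]]]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in model {self.model_id}: {ids}")
        for cid, residues in self.chains:
            nums = [r.residue_number for r in residues]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(
                    f"residue numbers not strictly increasing in chain {cid}"
                )

    # -- indexing contract -------------------------------------------------

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    @property
    def chain_lengths(self) -> list[int]:
        return [len(res) for _, res in self.chains]

    @property
    def n_residues(self) -> int:
        return sum(self.chain_lengths)

    def iter_residues(self) -> Iterator[tuple[str, ResidueRecord]]:
        """Residues in chain reading order — the global-index order."""
        for cid, residues in self.chains:
            for r in residues:
                yield cid, r

    def chain_of(self) -> np.ndarray:
        """Chain index (position in ``chains``) per global residue index."""
        return np.repeat(np.arange(len(self.chains)), self.chain_lengths)

    def global_index(self, chain_id: str, residue_number: int) -> int:
        offset = 0
        for cid, residues in self.chains:
            if cid == chain_id:
                for k, r in enumerate(residues):
                    if r.residue_number == residue_number:
                        return offset + k
                raise KeyError(f"residue {residue_number} not in chain {chain_id}")
            offset += len(residues)
        raise KeyError(f"chain {chain_id!r} not in model {self.model_id}")

    def label_of(self, index: int) -> tuple[str, int]:
        """Inverse of :meth:`global_index`: (chain_id, residue_number)."""
        if index < 0:
            raise IndexError(index)
        for cid, residues in self.chains:
            if index < len(residues):
                return cid, residues[index].residue_number
            index -= len(residues)
        raise IndexError("global residue index out of range")

    def get_chain(self, chain_id: str) -> list[ResidueRecord]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"chain {chain_id!r} not in model {self.model_id}")

    def plddt_vector(self) -> Optional[np.ndarray]:
        vals = [r.plddt for _, r in self.iter_residues()]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)


@dataclass
class ConfidenceBundle:
    """Per-model confidence: PAE matrix (Å), pLDDT vector, optional pTM and run metadata.

    ``pae[i, j]`` is the expected positional error (Å) of residue *j* when the
    prediction is aligned to the true structure on the local frame of residue
    *i*; it is not symmetric and is consumed as read.
    """

    pae: np.ndarray
    plddt: Optional[np.ndarray] = None
    ptm: Optional[float] = None
    model_name: str = ""
    seed: Optional[int] = None
    recycles: Optional[int] = None
    chain_lengths: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.pae = np.asarray(self.pae, dtype=float)
        if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
            raise ParseError(f"PAE matrix is not square: shape {self.pae.shape}")
        if np.any(self.pae < 0):
            raise ParseError("PAE matrix contains negative entries")
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if self.plddt.shape != (self.pae.shape[0],):
                raise ParseError(
                    f"pLDDT length {self.plddt.shape[0]} does not match "
                    f"PAE dimension {self.pae.shape[0]}"
                )
            if np.any((self.plddt < 0) | (self.plddt > 100)):
                raise ParseError("pLDDT values outside [0, 100]")
        if self.ptm is not None and not 0.0 <= self.ptm <= 1.0:
            raise ParseError(f"pTM {self.ptm} outside [0, 1]")

    @property
    def n_residues(self) -> int:
        return self.pae.shape[0]


@dataclass
class ScoredModel:
    """A structure bound to its confidence bundle under the shared global index."""

    model: StructureModel
    conf: ConfidenceBundle

    @property
    def n_residues(self) -> int:
        return self.model.n_residues

    def plddt(self) -> np.ndarray:
        """Per-residue pLDDT; the confidence JSON is authoritative over B-factors."""
        if self.conf.plddt is not None:
            return self.conf.plddt
        vec = self.model.plddt_vector()
        if vec is None:
            raise ValueError("no pLDDT available in confidence bundle or structure")
        return vec


# ---------------------------------------------------------------------------
# structure reading


def _best_altloc(atoms: Sequence[gemmi.Atom]) -> list[gemmi.Atom]:
    """Resolve alternate locations by keeping the highest-occupancy copy per atom name."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occ > best[a.name].occ:
            best[a.name] = a
    return [best[name] for name in order]


def read_structure(
    path: str | Path,
    format: Literal["mmcif", "pdb", "auto"] = "auto",
    plddt_from_bfactor: bool = True,
) -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    Only heavy atoms of amino-acid residues are kept; waters, ligands and
    hydrogens are discarded. For NMR-style multi-model files, model 1 is used.
    When ``plddt_from_bfactor`` is true and every per-residue mean B-factor
    lies in [0, 100], the B-factor column is interpreted as pLDDT (the
    AlphaFold deposition convention); otherwise pLDDT is left unset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.remove_hydrogens()
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")

    chains: list[tuple[str, list[ResidueRecord]]] = []
    plddt_like = True
    for chain in st[0]:
        residues: list[ResidueRecord] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            atoms = []
            bsum = 0.0
            for a in _best_altloc(list(res)):
                if a.is_hydrogen():
                    continue
                atoms.append(
                    Atom(a.name, a.element.name, a.pos.x, a.pos.y, a.pos.z)
                )
                bsum += a.b_iso
            if not atoms:
                continue
            bmean = bsum / len(atoms)
            if not 0.0 <= bmean <= 100.0:
                plddt_like = False
            residues.append(
                ResidueRecord(res.seqid.num, res.name, atoms, plddt=bmean)
            )
        if residues:
            chains.append((chain.name, residues))
    if not chains:
        raise EmptyModelError(f"{path}: no protein chains found")
    if not (plddt_from_bfactor and plddt_like):
        for _, residues in chains:
            for r in residues:
                r.plddt = None
    return StructureModel(model_id=path.stem, chains=chains)


def write_structure(
    model: StructureModel,
    path: str | Path,
    format: Literal["mmcif", "pdb", "auto"] = "auto",
) -> None:
    """Write a :class:`StructureModel` as PDB or mmCIF (chosen by extension for auto)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for cid, residues in model.chains:
        ch = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.residue_name
            res.seqid = gemmi.SeqId(r.residue_number, " ")
            for a in r.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(a.x, a.y, a.z)
                at.occ = 1.0
                at.b_iso = r.plddt if r.plddt is not None else 0.0
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# confidence reading


def read_confidence(path: str | Path) -> ConfidenceBundle:
    """Read an AlphaFold-style confidence JSON.

    The PAE matrix is accepted under either the ``predicted_aligned_error``
    or the ``pae`` key (a bare list-of-lists, or the common
    ``[{"predicted_aligned_error": ...}]`` wrapping). Optional keys: ``plddt``,
    ``ptm``, ``model_name``, ``seed``, ``recycles``, ``chain_lengths``.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if isinstance(doc, list):
        if not doc:
            raise ParseError(f"{path}: empty JSON list")
        doc = doc[0]
    pae = doc.get("predicted_aligned_error", doc.get("pae"))
    if pae is None:
        raise ParseError(
            f"{path}: no 'predicted_aligned_error' or 'pae' key present"
        )
    rows = [len(r) for r in pae]
    if len(set(rows)) > 1:
        raise ParseError(f"{path}: ragged PAE matrix, row lengths {sorted(set(rows))}")
    return ConfidenceBundle(
        pae=np.asarray(pae, dtype=float),
        plddt=None if doc.get("plddt") is None else np.asarray(doc["plddt"], float),
        ptm=doc.get("ptm"),
        model_name=doc.get("model_name", path.stem),
        seed=doc.get("seed"),
        recycles=doc.get("recycles"),
        chain_lengths=doc.get("chain_lengths"),
    )


def write_confidence(conf: ConfidenceBundle, path: str | Path) -> None:
    doc: dict = {
        "predicted_aligned_error": conf.pae.tolist(),
        "model_name": conf.model_name,
    }
    if conf.plddt is not None:
        doc["plddt"] = conf.plddt.tolist()
    if conf.ptm is not None:
        doc["ptm"] = conf.ptm
    if conf.seed is not None:
        doc["seed"] = conf.seed
    if conf.recycles is not None:
        doc["recycles"] = conf.recycles
    if conf.chain_lengths is not None:
        doc["chain_lengths"] = list(conf.chain_lengths)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def bind(model: StructureModel, conf: ConfidenceBundle) -> ScoredModel:
    """Pair a structure with its confidence bundle, validating the residue count.

    When the bundle records per-chain lengths, they must match the model's
    chain lengths in reading order — this catches a structure whose chains were
    reordered relative to the PAE matrix even though the total count agrees.
    """
    if model.n_residues != conf.n_residues:
        raise BindingError(
            f"model has {model.n_residues} residues but confidence bundle "
            f"has dimension {conf.n_residues}"
        )
    if conf.chain_lengths is not None and list(conf.chain_lengths) != model.chain_lengths:
        raise BindingError(
            f"per-chain lengths differ: model {model.chain_lengths} vs "
            f"confidence {list(conf.chain_lengths)}"
        )
    return ScoredModel(model=model, conf=conf)
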