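"""Assembly of complex input features from pre-generated monomer features.

A monomer feature bundle carries the query sequence, its multiple sequence
alignment (row 0 is the ungapped query, so aligned columns map one-to-one to
query residues), and structural-template descriptors. Complex features are
built by concatenating monomers, with two MSA pairing modes:

``none``
    block-diagonal MSA — each monomer's rows are padded with gaps across its
    partners' columns (the monomer-model route);
``all_paired``
    rows sharing a species tag across *all* monomers are additionally joined
    into cross-species rows placed before the unpaired block (the multimer
    route). Cyclic, linear and arbitrary pairing are recognised names but
    deliberately unimplemented.

Screening-scale guard rails are applied here: MSA depth capped at 5000 rows
per monomer, at most 4 templates per monomer, and a 1600-residue cap on the
total complex size. Cropping to an arbitrary residue range supports the
mature-chain convention (signal peptides removed before screening) as well as
deliberately shallow-MSA protocols for modelling unfolded substrates.

All operations are pure: inputs are never mutated.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

__all__ = [
    "MsaRow",
    "TemplateDescriptor",
    "MonomerFeatures",
    "ComplexFeatures",
    "SizeCapError",
    "crop",
    "cap_msa",
    "cap_templates",
    "assemble",
    "read_a3m",
    "write_a3m",
    "save_monomer",
    "load_monomer",
    "DEFAULT_MSA_DEPTH",
    "DEFAULT_MAX_TEMPLATES",
    "DEFAULT_SIZE_CAP",
]

DEFAULT_MSA_DEPTH = 5000
DEFAULT_MAX_TEMPLATES = 4
DEFAULT_SIZE_CAP = 1600

PairingMode = Literal["none", "all_paired", "cyclic", "linear", "arbitrary"]


class SizeCapError(ValueError):
    """Total complex length exceeds the imposed size cap."""


@dataclass(frozen=True)
class MsaRow:
    aligned: str
    species_tag: Optional[str] = None
    header: str = ""


@dataclass(frozen=True)
class TemplateDescriptor:
    template_id: str
    start: int  # 1-based, inclusive, in query residue numbering
    end: int


@dataclass(frozen=True)
class MonomerFeatures:
    """Input features for one protein: sequence + MSA + templates + residue range."""

    accession: str
    sequence: str
    msa: tuple[MsaRow, ...]
    templates: tuple[TemplateDescriptor, ...] = ()
    residue_range: tuple[int, int] = (0, 0)  # (start, end), 1-based inclusive

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.residue_range == (0, 0):
            object.__setattr__(self, "residue_range", (1, len(self.sequence)))
        if not self.msa:
            object.__setattr__(self, "msa", (MsaRow(self.sequence),))
        q = self.msa[0].aligned
        if q != self.sequence:
            raise ValueError(
                f"{self.accession}: MSA row 0 must be the ungapped query sequence"
            )
        L = len(q)
        for k, row in enumerate(self.msa):
            if len(row.aligned) != L:
                raise ValueError(
                    f"{self.accession}: MSA row {k} length {len(row.aligned)} != query {L}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def depth(self) -> int:
        return len(self.msa)


def crop(features: MonomerFeatures, start: int, end: int) -> MonomerFeatures:
    """Restrict sequence, MSA columns, template spans and residue range to [start, end].

    ``start`` and ``end`` are 1-based inclusive positions in the current
    sequence. Templates whose span falls entirely outside the window are
    dropped; spans straddling a boundary are truncated.
    """
    L = features.length
    if not 1 <= start <= end <= L:
        raise ValueError(f"crop range ({start}, {end}) outside [1, {L}]")
    lo, hi = start - 1, end  # python slice
    msa = tuple(
        MsaRow(r.aligned[lo:hi], r.species_tag, r.header) for r in features.msa
    )
    templates = tuple(
        TemplateDescriptor(t.template_id, max(t.start, start) - start + 1,
                           min(t.end, end) - start + 1)
        for t in features.templates
        if t.end >= start and t.start <= end
    )
    r0 = features.residue_range[0]
    return replace(
        features,
        sequence=features.sequence[lo:hi],
        msa=msa,
        templates=templates,
        residue_range=(r0 + start - 1, r0 + end - 1),
    )


def cap_msa(features: MonomerFeatures, depth: int = DEFAULT_MSA_DEPTH) -> MonomerFeatures:
    """Keep the first ``depth`` MSA rows (the query row is always retained)."""
    if depth < 1:
        raise ValueError(f"MSA depth must be >= 1, got {depth}")
    return replace(features, msa=features.msa[:depth])


def cap_templates(
    features: MonomerFeatures, max_templates: int = DEFAULT_MAX_TEMPLATES
) -> MonomerFeatures:
    """Keep the first ``max_templates`` template descriptors (0 removes all)."""
    if max_templates < 0:
        raise ValueError(f"max_templates must be >= 0, got {max_templates}")
    return replace(features, templates=features.templates[:max_templates])


@dataclass(frozen=True)
class ComplexFeatures:
    monomers: tuple[MonomerFeatures, ...]
    pairing_mode: PairingMode
    msa: tuple[MsaRow, ...]

    @property
    def total_length(self) -> int:
        return sum(m.length for m in self.monomers)

    @property
    def sequence(self) -> str:
        return "".join(m.sequence for m in self.monomers)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(m.accession for m in self.monomers)


def _paired_rows(monomers: Sequence[MonomerFeatures]) -> tuple[list[MsaRow], set[tuple[int, int]]]:
    """Cross-species joint rows and the (monomer, row) indices they consume.

    A species pairs when every monomer has at least one tagged row for it; the
    first (highest-ranked) such row per monomer is used. Species order follows
    first appearance in the first monomer's MSA. The query rows (row 0) are
    never consumed by pairing.
    """
    per_monomer: list[dict[str, int]] = []
    for m in monomers:
        first: dict[str, int] = {}
        for k, row in enumerate(m.msa[1:], start=1):
            if row.species_tag is not None and row.species_tag not in first:
                first[row.species_tag] = k
        per_monomer.append(first)
    shared = [
        tag for tag in per_monomer[0] if all(tag in d for d in per_monomer[1:])
    ]
    joint: list[MsaRow] = []
    consumed: set[tuple[int, int]] = set()
    for tag in shared:
        parts = []
        for mi, m in enumerate(monomers):
            k = per_monomer[mi][tag]
            parts.append(m.msa[k].aligned)
            consumed.add((mi, k))
        joint.append(MsaRow("".join(parts), tag, f"paired|{tag}"))
    return joint, consumed


def assemble(
    monomers: Sequence[MonomerFeatures],
    pairing: PairingMode = "none",
    size_cap: Optional[int] = DEFAULT_SIZE_CAP,
) -> ComplexFeatures:
    """Concatenate monomer features into complex features under a pairing mode.

    Raises :class:`SizeCapError` when the summed monomer lengths exceed
    ``size_cap`` (pass ``None`` to disable the cap).
    """
    if not monomers:
        raise ValueError("assemble requires at least one monomer")
    if pairing in ("cyclic", "linear", "arbitrary"):
        raise NotImplementedError(f"MSA pairing mode {pairing!r} is not implemented")
    if pairing not in ("none", "all_paired"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    total = sum(m.length for m in monomers)
    if size_cap is not None and total > size_cap:
        raise SizeCapError(
            f"complex size {total} exceeds the {size_cap}-residue cap"
        )
    lengths = [m.length for m in monomers]

    def block_row(mi: int, row: MsaRow) -> MsaRow:
        parts = [
            row.aligned if k == mi else "-" * lengths[k]
            for k in range(len(monomers))
        ]
        return MsaRow("".join(parts), row.species_tag, row.header)

    joint: list[MsaRow] = []
    consumed: set[tuple[int, int]] = set()
    if pairing == "all_paired" and len(monomers) > 1:
        joint, consumed = _paired_rows(monomers)
    unpaired = [
        block_row(mi, row)
        for mi, m in enumerate(monomers)
        for k, row in enumerate(m.msa)
        if (mi, k) not in consumed
    ]
    return ComplexFeatures(
        monomers=tuple(monomers),
        pairing_mode=pairing,
        msa=tuple(joint + unpaired),
    )


# ---------------------------------------------------------------------------
# on-disk formats

_OX_RE = re.compile(r"OX=(\d+)")
_TAXID_RE = re.compile(r"TaxID=(\d+)", re.IGNORECASE)


def parse_species_tag(header: str) -> Optional[str]:
    """Extract a species key (NCBI taxon id) from a UniProt-style FASTA header."""
    m = _OX_RE.search(header) or _TAXID_RE.search(header)
    return m.group(1) if m else None


def read_a3m(path: str | Path) -> list[MsaRow]:
    """Read an A3M/aligned-FASTA alignment; lowercase insertion states are removed."""
    rows: list[MsaRow] = []
    header, seq = "", []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if seq:
                    s = "".join(seq)
                    rows.append(MsaRow(s, parse_species_tag(header), header))
                header, seq = line[1:], []
            elif line:
                seq.append(re.sub(r"[a-z]", "", line))
    if seq:
        rows.append(MsaRow("".join(seq), parse_species_tag(header), header))
    return rows


def write_a3m(rows: Sequence[MsaRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, row in enumerate(rows):
            header = row.header or f"row_{k}"
            fh.write(f">{header}\n{row.aligned}\n")


def save_monomer(features: MonomerFeatures, directory: str | Path) -> None:
    """Store a monomer feature bundle as one directory with a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_a3m(features.msa, directory / "msa.a3m")
    manifest = {
        "accession": features.accession,
        "sequence": features.sequence,
        "msa_file": "msa.a3m",
        "templates": [
            {"id": t.template_id, "start": t.start, "end": t.end}
            for t in features.templates
        ],
        "residue_range": list(features.residue_range),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_monomer(directory: str | Path) -> MonomerFeatures:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    msa = read_a3m(directory / manifest["msa_file"])
    return MonomerFeatures(
        accession=manifest["accession"],
        sequence=manifest["sequence"],
        msa=tuple(msa),
        templates=tuple(
            TemplateDescriptor(t["id"], t["start"], t["end"])
            for t in manifest["templates"]
        ),
        residue_range=tuple(manifest["residue_range"]),
    )
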