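"""Construction of the screening library (the "envelopome") from a proteome table.

The library holds every proteome entry whose *primary* (first-listed)
subcellular location is not cytosolic — inner/outer membrane, periplasm,
secreted and cell-surface proteins all qualify. Known peripheral-membrane
proteins whose UniProt primary location is nominally cytoplasmic (e.g. the
motor ATPase SecA) can be forced in through an explicit allow-list. Sequences
containing non-standard amino acids are removed before prediction. Screening
uses mature chains only: when a signal peptide spanning residues 1..k is
annotated, the mature range is (k+1, L).

Input is a flat TSV (columns: accession, gene, sequence, locations,
signal_peptide) rather than UniProt's native flat-file format, which keeps
the contract testable offline; any UniProt export can be flattened to it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "ProteomeEntry",
    "PairJob",
    "PairList",
    "STANDARD_AA",
    "CYTOSOL_KEYWORDS",
    "parse_proteome",
    "select_envelopome",
    "filter_standard",
    "pair_list",
    "write_library",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

# keywords deciding whether a primary location is cytosolic (case-insensitive
# substring match); config, not biology-complete
CYTOSOL_KEYWORDS = ("cytoplasm", "cytosol")

REQUIRED_COLUMNS = ("accession", "gene", "sequence", "locations")

_SIGNAL_RE = re.compile(r"^\s*(\d+)\s*\.\.\s*(\d+)\s*$")


@dataclass(frozen=True)
class ProteomeEntry:
    accession: str
    gene: str
    sequence: str
    locations: tuple[str, ...]
    signal_peptide: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.signal_peptide is not None:
            s, k = self.signal_peptide
            if s != 1 or not 1 <= k < len(self.sequence):
                raise ValueError(
                    f"{self.accession}: invalid signal peptide span {self.signal_peptide}"
                )

    @property
    def primary_location(self) -> str:
        return self.locations[0] if self.locations else ""

    @property
    def mature_range(self) -> tuple[int, int]:
        """1-based inclusive residue range of the mature chain."""
        if self.signal_peptide is not None:
            return (self.signal_peptide[1] + 1, len(self.sequence))
        return (1, len(self.sequence))

    @property
    def mature_sequence(self) -> str:
        s, e = self.mature_range
        return self.sequence[s - 1 : e]

    @property
    def mature_length(self) -> int:
        s, e = self.mature_range
        return e - s + 1


def parse_proteome(
    path: str | Path,
) -> tuple[list[ProteomeEntry], list[tuple[int, str]]]:
    """Parse a flattened proteome annotation TSV.

    Returns (entries, rejects); a reject is (0-based data row index, reason).
    Malformed rows are collected, never fatal; a missing required column is.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    has_signal = "signal_peptide" in df.columns
    entries: list[ProteomeEntry] = []
    rejects: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            signal = None
            if has_signal and row["signal_peptide"].strip():
                m = _SIGNAL_RE.match(row["signal_peptide"])
                if not m:
                    raise ValueError(
                        f"unparseable signal peptide span {row['signal_peptide']!r}"
                    )
                signal = (int(m.group(1)), int(m.group(2)))
            entries.append(
                ProteomeEntry(
                    accession=row["accession"],
                    gene=row["gene"],
                    sequence=row["sequence"].strip().upper(),
                    locations=tuple(
                        loc.strip()
                        for loc in row["locations"].split(";")
                        if loc.strip()
                    ),
                    signal_peptide=signal,
                )
            )
        except ValueError as exc:
            rejects.append((int(idx), str(exc)))
    return entries, rejects


def select_envelopome(
    entries: Sequence[ProteomeEntry],
    cytosol_keywords: Sequence[str] = CYTOSOL_KEYWORDS,
    allow_list: Sequence[str] = (),
) -> list[ProteomeEntry]:
    """Keep entries whose primary subcellular location is not cytosolic.

    ``allow_list`` accessions are always kept regardless of location (the
    SecA-style peripheral-membrane exception).
    """
    allowed = set(allow_list)
    kept = []
    for e in entries:
        if e.accession in allowed:
            kept.append(e)
            continue
        primary = e.primary_location.lower()
        if any(kw in primary for kw in cytosol_keywords):
            continue
        kept.append(e)
    return kept


def filter_standard(
    entries: Sequence[ProteomeEntry],
) -> tuple[list[ProteomeEntry], list[ProteomeEntry]]:
    """Split entries into (kept, removed) by standard-amino-acid content."""
    kept, removed = [], []
    for e in entries:
        (removed if set(e.sequence) - STANDARD_AA else kept).append(e)
    return kept, removed


@dataclass(frozen=True)
class PairJob:
    query: str
    partner: str
    combined_length: int


@dataclass
class PairList:
    jobs: list[PairJob]
    excluded: list[PairJob]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(j.query, j.partner, j.combined_length) for j in self.jobs],
            columns=["query", "partner", "combined_length"],
        )


def pair_list(
    query: ProteomeEntry,
    library: Sequence[ProteomeEntry],
    size_cap: int = 1600,
) -> PairList:
    """One screening job per library member, including the self pair.

    Combined lengths are mature-chain lengths; jobs over ``size_cap`` total
    residues are excluded and counted rather than silently dropped.
    """
    if not library:
        raise ValueError("pair_list requires a non-empty library")
    jobs, excluded = [], []
    qlen = query.mature_length
    for partner in library:
        job = PairJob(query.accession, partner.accession, qlen + partner.mature_length)
        (excluded if job.combined_length > size_cap else jobs).append(job)
    return PairList(jobs=jobs, excluded=excluded)


def write_library(
    entries: Sequence[ProteomeEntry], fasta_path: str | Path, manifest_path: str | Path
) -> None:
    """Write mature-chain FASTA plus a TSV manifest of the library."""
    with open(fasta_path, "w") as fh:
        for e in entries:
            fh.write(f">{e.accession} GN={e.gene}\n{e.mature_sequence}\n")
    pd.DataFrame(
        [
            {
                "accession": e.accession,
                "gene": e.gene,
                "primary_location": e.primary_location,
                "mature_start": e.mature_range[0],
                "mature_end": e.mature_range[1],
                "mature_length": e.mature_length,
            }
            for e in entries
        ]
    ).to_csv(manifest_path, sep="\t", index=False)
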