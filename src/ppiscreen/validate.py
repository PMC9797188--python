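"""Validation harness for deposited predicted models.

Recomputes the reported confidence numbers (iScore, mean pLDDT) from
coordinate + confidence file pairs on disk, e.g. models deposited alongside a
screening study. Deposits are optional inputs: when the directory is missing,
or contains structures without PAE matrices, the harness degrades gracefully
to an empty result instead of failing, so offline runs and partial deposits
are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .model_io import bind, read_confidence, read_structure
from .scoring import ScoreCard, score_model

__all__ = ["DepositResult", "score_model_files", "validate_deposit"]

_STRUCTURE_SUFFIXES = {".pdb", ".cif", ".mmcif"}


@dataclass
class DepositResult:
    name: str
    card: Optional[ScoreCard]
    error: str = ""

    @property
    def ok(self) -> bool:
        return self.card is not None

    def printed_values(self) -> tuple[float, int]:
        """(iScore to 2 decimals, mean pLDDT to the integer) — reporting style."""
        if self.card is None:
            raise ValueError(f"{self.name}: no score available")
        return round(self.card.iscore, 2), round(self.card.mean_plddt)


def score_model_files(structure_path: str | Path, confidence_path: str | Path) -> ScoreCard:
    """Recompute the full score card for one deposited model pair."""
    bound = bind(read_structure(structure_path), read_confidence(confidence_path))
    return score_model(bound)


def _confidence_for(structure: Path) -> Optional[Path]:
    for candidate in (
        structure.with_suffix(".json"),
        structure.parent / f"{structure.stem}_conf.json",
        structure.parent / f"{structure.stem}_scores.json",
    ):
        if candidate.exists():
            return candidate
    return None


def validate_deposit(directory: str | Path) -> list[DepositResult]:
    """Score every structure/confidence pair found under ``directory``.

    A missing directory yields an empty list; structures lacking a matching
    confidence JSON, or files that fail to parse or bind, yield per-model
    error records rather than raising.
    """
    directory = Path(directory)
    if not directory.is_dir():
        return []
    results: list[DepositResult] = []
    for structure in sorted(
        p for p in directory.rglob("*") if p.suffix.lower() in _STRUCTURE_SUFFIXES
    ):
        conf = _confidence_for(structure)
        if conf is None:
            results.append(
                DepositResult(structure.stem, None, "no matching confidence JSON")
            )
            continue
        try:
            results.append(DepositResult(structure.stem, score_model_files(structure, conf)))
        except Exception as exc:  # noqa: BLE001 — per-model isolation
            results.append(DepositResult(structure.stem, None, str(exc)))
    return results
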