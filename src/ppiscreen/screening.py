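"""Query-vs-library screening orchestration: per-target prediction sweeps,
best-model aggregation, ranking and reporting.

For each (query, partner) job the predictor adapter is invoked over the
model-name × seed grid (10 networks × 2 seeds = 20 predictions by default,
up to 8 recycles each). Every prediction is scored; clash-rejected models are
excluded and the highest surviving iScore represents the target. The whole
screen is ranked by that per-target best score. Per-target results are
persisted as one JSON per pair, making long screens resumable and the desk-
scale tests trivially reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from .envelopome import PairJob
from .features import ComplexFeatures, MonomerFeatures, assemble
from .model_io import ConfidenceBundle, StructureModel, bind
from .scoring import (
    DEFAULT_CLASH_THRESHOLD,
    DEFAULT_TIERS,
    ScoreCard,
    TierScheme,
    score_model,
    select_best,
)

__all__ = [
    "PredictorAdapter",
    "TargetResult",
    "ScreenRecord",
    "DEFAULT_MODEL_NAMES",
    "DEFAULT_SEEDS",
    "run_target",
    "run_screen",
    "report",
    "plot_histogram",
    "stub_features",
]

log = logging.getLogger(__name__)

# ten placeholder network names standing in for the predictor's model set
DEFAULT_MODEL_NAMES = tuple(
    [f"model_{i}_multimer_v2" for i in range(1, 6)]
    + [f"model_{i}_ptm" for i in range(1, 6)]
)
DEFAULT_SEEDS = (0, 1)
DEFAULT_MAX_RECYCLES = 8


class PredictorAdapter(Protocol):
    """Boundary contract for the structure-prediction step.

    Implementations must be deterministic for fixed (features, model_name,
    seed). The neural-network inference itself lives behind this boundary.
    """

    def __call__(
        self,
        features: ComplexFeatures,
        model_name: str,
        seed: int,
        max_recycles: int = DEFAULT_MAX_RECYCLES,
    ) -> tuple[StructureModel, ConfidenceBundle]: ...


@dataclass
class TargetResult:
    best: ScoreCard
    cards: list[ScoreCard]  # audit log, one per successful prediction
    n_models: int  # attempted predictions

    def to_dict(self) -> dict:
        return {
            "best": self.best.to_dict(),
            "cards": [c.to_dict() for c in self.cards],
            "n_models": self.n_models,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetResult":
        return cls(
            best=ScoreCard.from_dict(d["best"]),
            cards=[ScoreCard.from_dict(c) for c in d["cards"]],
            n_models=d["n_models"],
        )


@dataclass
class ScreenRecord:
    partner: str
    best: ScoreCard
    n_models: int
    rank: int = 0


def run_target(
    features: ComplexFeatures,
    adapter: PredictorAdapter,
    model_names: Sequence[str] = DEFAULT_MODEL_NAMES,
    seeds_per_model: int = len(DEFAULT_SEEDS),
    max_recycles: int = DEFAULT_MAX_RECYCLES,
    seeds: Optional[Sequence[int]] = None,
    clash_threshold: float = DEFAULT_CLASH_THRESHOLD,
    scheme: TierScheme = DEFAULT_TIERS,
) -> TargetResult:
    """Score one target over the model × seed grid and select its best model.

    Adapter failures on individual predictions are logged and skipped; the
    target errors out only when every prediction fails.
    """
    if seeds is None:
        seeds = tuple(range(seeds_per_model))
    cards: list[ScoreCard] = []
    attempted = 0
    for model_name in model_names:
        for seed in seeds:
            attempted += 1
            try:
                model, conf = adapter(features, model_name, seed, max_recycles)
                cards.append(score_model(bind(model, conf), scheme=scheme))
            except Exception as exc:  # noqa: BLE001 — per-model isolation
                log.warning(
                    "prediction failed for %s (%s, seed %d): %s",
                    "+".join(features.accessions), model_name, seed, exc,
                )
    if not cards:
        raise RuntimeError(
            f"all {attempted} predictions failed for {'+'.join(features.accessions)}"
        )
    return TargetResult(
        best=select_best(cards, clash_threshold=clash_threshold),
        cards=cards,
        n_models=attempted,
    )


def stub_features(query: str, partner: str) -> ComplexFeatures:
    """Minimal complex features carrying only accessions — enough for a mock
    adapter keyed on the pair identity."""
    mono = [
        MonomerFeatures(accession=acc, sequence="A" * 10, msa=())
        for acc in (query, partner)
    ]
    return assemble(mono, pairing="none", size_cap=None)


def run_screen(
    query: str,
    jobs: Sequence[PairJob],
    adapter: PredictorAdapter,
    features_provider: Callable[[str, str], ComplexFeatures] = stub_features,
    out_dir: Optional[str | Path] = None,
    **target_kwargs,
) -> list[ScreenRecord]:
    """Screen a query against every job partner and rank by best iScore.

    When ``out_dir`` is given, each target's result is stored as
    ``<query>__<partner>.json``; targets with an existing record are loaded
    instead of recomputed, so an interrupted screen resumes where it stopped
    and produces an identical final ranking.
    """
    if not jobs:
        raise ValueError("run_screen requires a non-empty job list")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    records: list[ScreenRecord] = []
    for job in jobs:
        record_path = (
            out_dir / f"{job.query}__{job.partner}.json" if out_dir else None
        )
        if record_path is not None and record_path.exists():
            with open(record_path) as fh:
                result = TargetResult.from_dict(json.load(fh))
        else:
            result = run_target(
                features_provider(job.query, job.partner), adapter, **target_kwargs
            )
            if record_path is not None:
                with open(record_path, "w") as fh:
                    json.dump(result.to_dict(), fh)
        records.append(
            ScreenRecord(partner=job.partner, best=result.best, n_models=result.n_models)
        )
    records.sort(key=lambda r: (-r.best.iscore, -r.best.mean_plddt, r.partner))
    for rank, r in enumerate(records, start=1):
        r.rank = rank
    return records


def report(
    records: Sequence[ScreenRecord],
    scheme: TierScheme = DEFAULT_TIERS,
    bin_width: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, "pandas.DataFrame"]:
    """Histogram of per-target best iScores plus the table of tiered hits.

    Returns (counts, bin_edges, hits) where hits lists every record at tier
    medium or better with its name, rank, iScore and tier.
    """
    import pandas as pd

    scores = np.array([r.best.iscore for r in records], dtype=float)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, edges = np.histogram(scores, bins=edges)
    hits = pd.DataFrame(
        [
            {
                "partner": r.partner,
                "rank": r.rank,
                "iscore": r.best.iscore,
                "tier": r.best.tier,
            }
            for r in records
            if r.best.iscore >= scheme.medium
        ],
        columns=["partner", "rank", "iscore", "tier"],
    )
    return counts, edges, hits


def plot_histogram(records: Sequence[ScreenRecord], path: str | Path) -> None:
    """Save the best-iScore distribution of a screen as a bar chart."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, edges, _ = report(records)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="k")
    ax.set_xlabel("best iScore per target")
    ax.set_ylabel("targets")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
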