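"""Disease (item) selection: score candidates from neighbors' known indications.

Candidate diseases are those indicated by at least one neighbor. Each
candidate c is scored against target t as

    score(c, t) = sum over neighbors n of sim(t, n) * f(n, c)

where f(n, c) in {0, 1} is the golden drug-disease indication. Under the
SUM setting sim(t, n) is dropped (a plain vote count); under WSUM the
neighbor's per-feature similarity profile is collapsed to a scalar
(arithmetic mean of its defined values by default) so more similar
neighbors carry more weight. The output list holds at most k entries, all
with strictly positive score — the method never pads with random guesses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import MethodConfig
from .data_model import Dataset, GoldenAssociations, ValidationError
from .neighbors import NeighborSet, select_neighbors
from .similarity import SimilarityProfile, build_profiles

logger = logging.getLogger(__name__)


@dataclass
class PredictionList:
    """Ranked (disease, score) predictions for one target, at most k entries."""

    target: str
    entries: list[tuple[str, float]] = field(default_factory=list)
    k_limit: int = 1

    @property
    def diseases(self) -> list[str]:
        return [d for d, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": self.target,
                "disease": [d for d, _ in self.entries],
                "score": [s for _, s in self.entries],
                "rank": range(1, len(self.entries) + 1),
            }
        )

    def save(self, path: str | Path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


def score_candidate(
    c: str,
    t: str,
    neighbors: NeighborSet,
    ist: str,
    golden: GoldenAssociations,
    profiles: dict[str, SimilarityProfile],
    collapse: str = "mean",
) -> float:
    """Score one candidate disease from the neighbors' golden indications."""
    score = 0.0
    for n in neighbors.neighbors:
        if n not in golden.values.index:
            continue
        f_nc = float(golden.values.at[n, c]) if c in golden.values.columns else 0.0
        if f_nc == 0.0:
            continue
        if ist == "SUM":
            score += f_nc
        elif ist == "WSUM":
            score += profiles[n].collapse(collapse) * f_nc
        else:
            raise ValidationError(f"unknown IST setting {ist!r}")
    return score


def rank_candidates(
    t: str,
    neighbors: NeighborSet,
    golden: GoldenAssociations,
    profiles: dict[str, SimilarityProfile],
    ist: str,
    collapse: str = "mean",
) -> dict[str, float]:
    """Scores for every disease indicated by at least one neighbor."""
    present = [n for n in neighbors.neighbors if n in golden.values.index]
    if not present:
        return {}
    sub = golden.values.loc[present]
    candidate_mask = sub.sum(axis=0) > 0
    candidates = list(sub.columns[candidate_mask])
    if ist == "SUM":
        scores = sub.loc[:, candidates].sum(axis=0).astype(float)
    else:
        weights = pd.Series({n: profiles[n].collapse(collapse) for n in present})
        scores = sub.loc[:, candidates].mul(weights, axis=0).sum(axis=0)
    return {c: float(s) for c, s in scores.items()}


def predict(
    t: str,
    dataset: Dataset,
    config: MethodConfig,
    matrices: dict[str, pd.DataFrame] | None = None,
    golden: GoldenAssociations | None = None,
    profiles: list[SimilarityProfile] | None = None,
) -> PredictionList:
    """Full pipeline for one target: profiles -> neighbors -> ranked diseases.

    ``golden`` overrides the dataset's golden matrix for the f(n, c) lookups;
    leave-one-out evaluation passes a view with the target's row withheld.
    Entries are sorted by score descending, ties alphabetically by disease,
    truncated to at most k; zero-score diseases are never emitted.
    """
    if profiles is None:
        profiles = build_profiles(dataset, t, config.similarity, matrices=matrices)
    golden = golden if golden is not None else dataset.golden
    neighbors = select_neighbors(profiles, mot=config.mot, n=config.n)
    if not neighbors.neighbors:
        logger.warning("predict: no neighbors for target %r", t)
        return PredictionList(target=t, k_limit=config.k)
    prof_by_name = {p.candidate_drug: p for p in profiles}
    scores = rank_candidates(
        t, neighbors, golden, prof_by_name, config.ist, config.similarity.collapse
    )
    ranked = sorted(
        ((d, s) for d, s in scores.items() if s > 0), key=lambda ds: (-ds[1], ds[0])
    )
    return PredictionList(target=t, entries=ranked[: config.k], k_limit=config.k)
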