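"""Pareto-dominance neighbor selection.

A candidate drug d_i dominates d_j (with respect to one target) when d_i's
similarity to the target is at least d_j's on every feature source and
strictly greater on at least one. Neighbors are taken from successive
non-dominated fronts under one of three collection policies (MOT):

* OD  (Only_Dominates)      - a single front; its size is whatever it is.
* ND  (N_Dominates)         - peel fronts until at least N drugs are
                              collected, then prune the last front so exactly
                              N remain.
* AND (At_Least_N_Dominates)- same peeling, no pruning, so at least N remain
                              (unless the candidate pool is exhausted).

Candidates whose profile is entirely absent or zero carry no evidence of
similarity and are excluded before dominance is evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import ValidationError
from .similarity import SimilarityProfile

logger = logging.getLogger(__name__)

MOT_SETTINGS = ("OD", "ND", "AND")


@dataclass
class NeighborSet:
    """Ordered neighbors of one target with the front index each came from."""

    target: str
    neighbors: list[str] = field(default_factory=list)
    iteration_found: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.neighbors)


def dominates(p: SimilarityProfile, q: SimilarityProfile) -> int:
    """1 iff p >= q on every feature and > on at least one (absent read as 0)."""
    if p.target_drug != q.target_drug:
        raise ValidationError(
            f"profiles target different drugs: {p.target_drug!r} vs {q.target_drug!r}"
        )
    a, b = p.as_array(), q.as_array()
    return int(bool(np.all(a >= b) and np.any(a > b)))


def _profiles_matrix(profiles: list[SimilarityProfile]) -> np.ndarray:
    return np.vstack([p.as_array() for p in profiles])


def _non_dominated_mask(arr: np.ndarray) -> np.ndarray:
    """Boolean mask of rows not dominated by any other row."""
    n = arr.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        ge = np.all(arr >= arr[i], axis=1)
        gt = np.any(arr > arr[i], axis=1)
        if np.any(ge & gt):
            mask[i] = False
    return mask


def non_dominated_set(profiles: list[SimilarityProfile]) -> list[SimilarityProfile]:
    """Candidates not dominated by any other candidate (the first Pareto front)."""
    if not profiles:
        raise ValidationError("non_dominated_set needs at least one profile")
    arr = _profiles_matrix(profiles)
    mask = _non_dominated_mask(arr)
    return [p for p, m in zip(profiles, mask) if m]


def pareto_fronts(profiles: list[SimilarityProfile]) -> list[list[SimilarityProfile]]:
    """Successive non-dominated fronts; disjoint, union = the candidate set."""
    remaining = list(profiles)
    fronts: list[list[SimilarityProfile]] = []
    cap = len(profiles)
    while remaining and len(fronts) < cap:
        front = non_dominated_set(remaining)
        fronts.append(front)
        in_front = {id(p) for p in front}
        remaining = [p for p in remaining if id(p) not in in_front]
    return fronts


def _rank_key(p: SimilarityProfile) -> tuple[float, str]:
    # mean of defined similarities, descending; ties lexicographic by name
    return (-p.collapse("mean"), p.candidate_drug)


def select_neighbors(
    profiles: list[SimilarityProfile], mot: str, n: int = 1
) -> NeighborSet:
    """Collect neighbors under the OD / ND / AND policy.

    Within each front, neighbors are ordered by mean defined similarity
    (descending), ties broken lexicographically by drug name, making the
    output deterministic. ND pruning cuts the final front by the same rank.
    """
    if mot not in MOT_SETTINGS:
        raise ValidationError(f"unknown MOT setting {mot!r}")
    if n < 1:
        raise ValidationError("neighbor count n must be >= 1")
    target = profiles[0].target_drug if profiles else "<unknown>"
    pool = [
        p for p in profiles if any(v for v in p.defined_values())
    ]  # drop all-absent / all-zero evidence
    if not pool:
        logger.warning("select_neighbors: empty candidate pool for %r", target)
        return NeighborSet(target=target)

    ns = NeighborSet(target=target)
    if mot == "OD":
        fronts = [non_dominated_set(pool)]
    else:
        fronts = []
        collected = 0
        remaining = pool
        cap = len(pool)
        while remaining and collected < n and len(fronts) < cap:
            front = non_dominated_set(remaining)
            fronts.append(front)
            collected += len(front)
            in_front = {id(p) for p in front}
            remaining = [p for p in remaining if id(p) not in in_front]
        if collected < n:
            logger.warning(
                "select_neighbors: only %d candidates for %r (n=%d)",
                collected, target, n,
            )

    for it, front in enumerate(fronts, start=1):
        ordered = sorted(front, key=_rank_key)
        if mot == "ND":
            room = n - len(ns.neighbors)
            ordered = ordered[:room]
        for p in ordered:
            ns.neighbors.append(p.candidate_drug)
            ns.iteration_found[p.candidate_drug] = it
    return ns
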