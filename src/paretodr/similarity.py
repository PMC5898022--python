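"""Per-feature drug-drug similarity: cosine, Jaccard/Tanimoto, Smith-Waterman.

Each feature source gets its own measure. Binary incidence vectors are
compared with cosine or Jaccard (Tanimoto) similarity; sources backed by
residue sequences (protein targets) can instead use a Smith-Waterman
local-alignment score averaged over all sequence pairs of the two drugs.
A drug absent from a source has an *absent* (None) similarity there, which
downstream dominance reads as 0.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .data_model import AMINO_ACIDS, Dataset, ValidationError

logger = logging.getLogger(__name__)

MEASURES = ("cosine", "jaccard", "smith_waterman")

#: shorthand letter -> measure; letter order is (chemical, side_effect, protein),
#: i.e. JJC reads "Jaccard chemical, Jaccard side-effect, Cosine protein"
_SHORTHAND_LETTER = {"C": "cosine", "J": "jaccard", "S": "smith_waterman"}
_SHORTHAND_ORDER = ("chemical", "side_effect", "protein")


@dataclass(frozen=True)
class AlignmentParams:
    """Smith-Waterman scoring scheme: match/mismatch substitution, linear gap."""

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -1.0
    alphabet: str = AMINO_ACIDS

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner(mode="local")
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap
        a.extend_gap_score = self.gap
        return a


@dataclass
class SimilarityConfig:
    """Which measure applies to which source, plus alignment settings.

    ``normalize_alignment`` divides each pairwise alignment score by
    sqrt(SW(x,x) * SW(y,y)) so the averaged score lands in [0, 1] and is
    commensurable with cosine/Jaccard inside Pareto comparisons; switch it
    off for the raw mean-of-scores form.
    ``collapse`` is the rule that folds a per-feature similarity profile into
    the single sim(t, n) scalar used by weighted-sum disease scoring.
    """

    measures: dict[str, str]
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    normalize_alignment: bool = True
    collapse: str = "mean"  # mean | sum | max over defined per-feature values

    def __post_init__(self) -> None:
        for src, m in self.measures.items():
            if m not in MEASURES:
                raise ValidationError(f"unknown measure {m!r} for source {src!r}")
        if self.collapse not in ("mean", "sum", "max"):
            raise ValidationError(f"unknown collapse rule {self.collapse!r}")

    @classmethod
    def from_shorthand(cls, code: str, **kwargs) -> "SimilarityConfig":
        """Expand a three-letter setting name (CCC, JJJ, JJC, JJS).

        Letters map to the (chemical, side_effect, protein) sources in that
        order: C = cosine, J = Jaccard, S = Smith-Waterman.
        """
        code = code.upper()
        if len(code) != 3 or any(ch not in _SHORTHAND_LETTER for ch in code):
            raise ValidationError(f"unknown similarity shorthand {code!r}")
        measures = {
            src: _SHORTHAND_LETTER[ch] for src, ch in zip(_SHORTHAND_ORDER, code)
        }
        return cls(measures=measures, **kwargs)

    def validate_for(self, dataset: Dataset) -> None:
        for src in dataset.source_names:
            if src not in self.measures:
                raise ValidationError(f"no measure assigned for source {src!r}")
            if self.measures[src] == "smith_waterman" and dataset.sequences is None:
                raise ValidationError(
                    f"smith_waterman assigned to source {src!r} but the dataset "
                    "carries no sequences"
                )


@dataclass
class SimilarityProfile:
    """Per-feature similarities of one candidate drug to one target drug.

    ``per_feature[source]`` is None when either drug is absent from that
    source — distinct from a measured similarity of 0.
    """

    target_drug: str
    candidate_drug: str
    per_feature: dict[str, float | None]

    def defined_values(self) -> list[float]:
        return [v for v in self.per_feature.values() if v is not None]

    def as_array(self) -> np.ndarray:
        """Values in source order with absent read as 0.0 (the dominance view)."""
        return np.array(
            [0.0 if v is None else v for v in self.per_feature.values()], dtype=float
        )

    def collapse(self, rule: str = "mean") -> float:
        """Fold the profile into one scalar; 0.0 when nothing is defined."""
        vals = self.defined_values()
        if not vals:
            return 0.0
        if rule == "mean":
            return float(np.mean(vals))
        if rule == "sum":
            return float(np.sum(vals))
        if rule == "max":
            return float(np.max(vals))
        raise ValidationError(f"unknown collapse rule {rule!r}")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of two binary incidence vectors; zero vectors give 0, not an error."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("cosine_similarity: vectors differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.debug("cosine_similarity: zero vector, returning 0")
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def jaccard_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard (Tanimoto) index |A∩B| / |A∪B| of two binary vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("jaccard_similarity: vectors differ in length")
    inter = int(np.sum(a & b))
    union = int(np.sum(a)) + int(np.sum(b)) - inter
    if union == 0:
        logger.debug("jaccard_similarity: both vectors all-zero, returning 0")
        return 0.0
    return inter / union


def smith_waterman_score(
    x: str, y: str, params: AlignmentParams | None = None
) -> float:
    """Optimal local-alignment score of two residue strings.

    Scored with the configured match/mismatch substitution and linear gap
    penalty; the empty alignment scores 0, so the result is never negative.
    """
    params = params or AlignmentParams()
    allowed = set(params.alphabet)
    for name, s in (("x", x), ("y", y)):
        if not s:
            raise ValidationError(f"smith_waterman_score: empty sequence {name}")
        for pos, ch in enumerate(s):
            if ch not in allowed:
                raise ValidationError(
                    f"smith_waterman_score: residue {ch!r} at position {pos} "
                    f"of {name} not in alphabet"
                )
    return float(params.aligner().score(x, y))


def sequence_set_similarity(
    va: list[str],
    vb: list[str],
    params: AlignmentParams | None = None,
    normalize: bool = True,
) -> float | None:
    """Mean pairwise alignment score between two drugs' sequence sets.

    sim(A,B) = ΣΣ SW(V_i(A), V_j(B)) / (|V(A)|·|V(B)|). With ``normalize``
    each pairwise score is divided by sqrt(SW(x,x)·SW(y,y)) first, bounding
    the mean in [0, 1]. An empty set yields an absent (None) similarity.
    """
    params = params or AlignmentParams()
    if not va or not vb:
        logger.debug("sequence_set_similarity: empty sequence set, absent")
        return None
    aligner = params.aligner()
    total = 0.0
    if normalize:
        self_a = [aligner.score(s, s) for s in va]
        self_b = [aligner.score(s, s) for s in vb]
        for sa, xa in zip(self_a, va):
            for sb, xb in zip(self_b, vb):
                denom = np.sqrt(sa * sb)
                total += aligner.score(xa, xb) / denom if denom > 0 else 0.0
    else:
        for xa in va:
            for xb in vb:
                total += aligner.score(xa, xb)
    return float(total / (len(va) * len(vb)))


def _binary_similarity_matrix(X: np.ndarray, measure: str) -> np.ndarray:
    """All-pairs cosine or Jaccard over the rows of a binary matrix."""
    X = X.astype(float)
    inter = X @ X.T
    row_sums = X.sum(axis=1)
    if measure == "cosine":
        norms = np.sqrt(row_sums)
        denom = np.outer(norms, norms)
    elif measure == "jaccard":
        denom = row_sums[:, None] + row_sums[None, :] - inter
    else:  # pragma: no cover - guarded by SimilarityConfig
        raise ValidationError(f"unsupported vector measure {measure!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, inter / np.where(denom > 0, denom, 1.0), 0.0)
    return sim


def compute_similarity_matrices(
    dataset: Dataset, config: SimilarityConfig, drugs: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """All-pairs per-source similarity over the golden drugs.

    Returns one drugs x drugs DataFrame per source; cells are NaN when either
    drug is absent from the source (distinct from a measured 0). Computing
    these once makes per-target profile assembly a lookup.
    """
    config.validate_for(dataset)
    drugs = list(drugs) if drugs is not None else dataset.golden.drug_ids
    out: dict[str, pd.DataFrame] = {}
    for src, fm in dataset.feature_matrices.items():
        measure = config.measures[src]
        mat = pd.DataFrame(np.nan, index=drugs, columns=drugs, dtype=float)
        if measure == "smith_waterman":
            seqs = dataset.sequences
            present = [d for d in drugs if seqs.has_drug(d)]
            aligner = config.alignment.aligner()
            per = {d: seqs.sequences_per_drug[d] for d in present}
            selfscore = {
                d: [aligner.score(s, s) for s in per[d]] for d in present
            } if config.normalize_alignment else None
            for i, di in enumerate(present):
                for dj in present[i:]:
                    if config.normalize_alignment:
                        tot = 0.0
                        for sa, xa in zip(selfscore[di], per[di]):
                            for sb, xb in zip(selfscore[dj], per[dj]):
                                denom = np.sqrt(sa * sb)
                                tot += aligner.score(xa, xb) / denom if denom > 0 else 0.0
                        val = tot / (len(per[di]) * len(per[dj]))
                    else:
                        val = sum(
                            aligner.score(xa, xb) for xa in per[di] for xb in per[dj]
                        ) / (len(per[di]) * len(per[dj]))
                    mat.loc[di, dj] = val
                    mat.loc[dj, di] = val
        else:
            present = [d for d in drugs if fm.has_drug(d)]
            if present:
                X = fm.values.loc[present].to_numpy()
                sim = _binary_similarity_matrix(X, measure)
                mat.loc[present, present] = sim
        out[src] = mat
    return out


def build_profiles(
    dataset: Dataset,
    target: str,
    config: SimilarityConfig,
    matrices: dict[str, pd.DataFrame] | None = None,
) -> list[SimilarityProfile]:
    """One similarity profile per candidate drug (every golden drug but the target).

    Sources missing either drug contribute an absent value; the downstream
    dominance comparison reads absent as 0.0.
    """
    if not dataset.has_any_features(target):
        raise ValidationError(f"target drug {target!r} has no feature information")
    if matrices is None:
        matrices = compute_similarity_matrices(dataset, config)
    candidates = [d for d in dataset.golden.drug_ids if d != target]
    profiles = []
    for cand in candidates:
        per_feature: dict[str, float | None] = {}
        for src in dataset.source_names:
            v = matrices[src].loc[target, cand] if target in matrices[src].index else np.nan
            per_feature[src] = None if pd.isna(v) else float(v)
        profiles.append(SimilarityProfile(target, cand, per_feature))
    return profiles
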