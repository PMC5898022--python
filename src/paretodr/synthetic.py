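"""Synthetic planted-cluster datasets for end-to-end testing without downloads.

The generator emulates the structure the repositioning method assumes:
drugs fall into latent clusters that share both features and disease
indications. Each cluster owns a disjoint block of signature features per
source and a disjoint block of signature diseases; a drug's row is its
cluster signature (each signature cell on with the sharing probability)
OR-ed with background Bernoulli noise. Drugs can be missing from individual
sources, and sequence features are mutated copies of per-cluster ancestor
strings. Everything is driven by one seed.

Default parameters mirror the real multi-source data at roughly 1/5 scale:
200 drugs, 150 diseases, and per-source sparsities targeted at 0.86
(chemical), 0.996 (protein) and 0.95 (side-effect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    AMINO_ACIDS,
    Dataset,
    FeatureMatrix,
    GoldenAssociations,
    SequenceFeatureMap,
    ValidationError,
)


@dataclass(frozen=True)
class SourceSpec:
    """One synthetic feature source.

    share_prob: probability a drug carries each of its cluster's signature
    features; background_prob: independent one-probability of any cell
    (noise); missing_prob: probability the drug is absent from this source.
    """

    n_features: int
    signature_size: int
    share_prob: float
    background_prob: float
    missing_prob: float = 0.05

    def validate(self, n_clusters: int) -> None:
        if self.n_features <= 0 or self.signature_size < 0:
            raise ValidationError("feature counts must be positive")
        if n_clusters * self.signature_size > self.n_features:
            raise ValidationError(
                "cluster signatures do not fit: "
                f"{n_clusters} x {self.signature_size} > {self.n_features}"
            )
        for p in (self.share_prob, self.background_prob, self.missing_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")


def _default_sources() -> dict[str, SourceSpec]:
    return {
        "chemical": SourceSpec(200, 20, 0.9, 0.05),
        "protein": SourceSpec(160, 2, 0.3, 0.0005),
        "side_effect": SourceSpec(280, 16, 0.75, 0.008),
    }


@dataclass
class GeneratorSpec:
    """Parameters of the planted-cluster generative model."""

    n_drugs: int = 200
    n_diseases: int = 150
    n_clusters: int = 10
    sources: dict[str, SourceSpec] = field(default_factory=_default_sources)
    indications_per_cluster: int = 5
    indication_share: float = 0.9
    indication_background: float = 0.002
    sequence_source: str = "protein"
    seq_length: tuple[int, int] = (40, 60)
    seqs_per_drug: tuple[int, int] = (1, 2)
    seq_mutation: float = 0.05
    alphabet: str = AMINO_ACIDS
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters > self.n_drugs:
            raise ValidationError("more clusters than drugs")
        if self.n_clusters < 1 or self.n_drugs < 1 or self.n_diseases < 1:
            raise ValidationError("counts must be positive")
        if self.n_clusters * self.indications_per_cluster > self.n_diseases:
            raise ValidationError("cluster disease signatures do not fit")
        for src in self.sources.values():
            src.validate(self.n_clusters)
        for p in (self.indication_share, self.indication_background, self.seq_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted: cluster memberships and signatures."""

    cluster_of: dict[str, int]
    signature_features: dict[str, dict[int, list[str]]]  # source -> cluster -> ids
    signature_diseases: dict[int, list[str]]
    spec: GeneratorSpec

    def cluster_members(self, cluster: int) -> list[str]:
        return [d for d, c in self.cluster_of.items() if c == cluster]

    def to_json(self) -> str:
        payload = {
            "cluster_of": self.cluster_of,
            "signature_features": {
                s: {str(c): ids for c, ids in m.items()}
                for s, m in self.signature_features.items()
            },
            "signature_diseases": {str(c): ids for c, ids in self.signature_diseases.items()},
            "spec": _spec_dict(self.spec),
        }
        return json.dumps(payload, indent=1)


def _spec_dict(spec: GeneratorSpec) -> dict:
    d = asdict(spec)
    d["seq_length"] = list(spec.seq_length)
    d["seqs_per_drug"] = list(spec.seqs_per_drug)
    return d


def expected_sparsity(spec: GeneratorSpec, source: str) -> float:
    """Closed-form expected zero-fraction of one source (or ``"golden"``).

    A signature cell is 1 unless both the sharing draw and the background
    draw miss: P1 = 1 - (1 - share)(1 - background); any other cell is 1
    with the background probability. The expectation averages the two over
    the column blocks and is unaffected by row missingness.
    """
    if source == "golden":
        m, sig = spec.n_diseases, spec.indications_per_cluster
        share, bg = spec.indication_share, spec.indication_background
    else:
        s = spec.sources[source]
        m, sig, share, bg = s.n_features, s.signature_size, s.share_prob, s.background_prob
    frac_sig = sig / m
    p_sig = 1.0 - (1.0 - share) * (1.0 - bg)
    return 1.0 - (frac_sig * p_sig + (1.0 - frac_sig) * bg)


def _mutate(seq: str, rate: float, alphabet: str, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    letters = rng.choice(list(alphabet), size=hits.size)
    for i, ch in zip(hits, letters):
        chars[i] = str(ch)
    return "".join(chars)


def generate(spec: GeneratorSpec) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset from the planted-cluster model; reproducible from seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    drugs = [f"DR{i:04d}" for i in range(spec.n_drugs)]
    diseases = [f"DIS{j:04d}" for j in range(spec.n_diseases)]
    cluster_of = {d: i * spec.n_clusters // spec.n_drugs for i, d in enumerate(drugs)}
    clusters = np.array([cluster_of[d] for d in drugs])

    # per-source binary matrices with planted signature blocks
    feature_matrices: dict[str, FeatureMatrix] = {}
    signature_features: dict[str, dict[int, list[str]]] = {}
    missing_masks: dict[str, np.ndarray] = {}
    for name, src in spec.sources.items():
        feats = [f"{name}_F{j:04d}" for j in range(src.n_features)]
        sig_ids = {
            c: feats[c * src.signature_size : (c + 1) * src.signature_size]
            for c in range(spec.n_clusters)
        }
        signature_features[name] = sig_ids
        mat = (rng.random((spec.n_drugs, src.n_features)) < src.background_prob)
        sig_draw = rng.random((spec.n_drugs, src.n_features)) < src.share_prob
        for c in range(spec.n_clusters):
            lo, hi = c * src.signature_size, (c + 1) * src.signature_size
            rows = clusters == c
            mat[np.ix_(rows, range(lo, hi))] |= sig_draw[np.ix_(rows, range(lo, hi))]
        missing_masks[name] = rng.random(spec.n_drugs) < src.missing_prob
        feature_matrices[name] = (mat, feats)  # finalized after missingness fix-up

    # a drug absent from every source carries no information at all; keep it
    # in one randomly chosen source so harmonization never orphans it
    if missing_masks:
        all_missing = np.logical_and.reduce(list(missing_masks.values()))
        names = list(missing_masks)
        for i in np.nonzero(all_missing)[0]:
            keep = names[int(rng.integers(len(names)))]
            missing_masks[keep][i] = False

    for name, (mat, feats) in feature_matrices.items():
        present = ~missing_masks[name]
        df = pd.DataFrame(
            mat[present].astype(np.int8),
            index=[d for d, p in zip(drugs, present) if p],
            columns=feats,
        )
        feature_matrices[name] = FeatureMatrix(name, df)

    # golden indications: cluster signature diseases plus background
    sig_dis = {
        c: diseases[
            c * spec.indications_per_cluster : (c + 1) * spec.indications_per_cluster
        ]
        for c in range(spec.n_clusters)
    }
    gmat = rng.random((spec.n_drugs, spec.n_diseases)) < spec.indication_background
    ind_draw = rng.random((spec.n_drugs, spec.n_diseases)) < spec.indication_share
    for c in range(spec.n_clusters):
        lo = c * spec.indications_per_cluster
        hi = lo + spec.indications_per_cluster
        rows = clusters == c
        gmat[np.ix_(rows, range(lo, hi))] |= ind_draw[np.ix_(rows, range(lo, hi))]
    golden = GoldenAssociations(
        pd.DataFrame(gmat.astype(np.int8), index=drugs, columns=diseases)
    )

    # sequences: mutated copies of per-cluster ancestors, tied to one source's
    # presence mask so sequence availability matches that source
    sequences = None
    if spec.sequence_source in spec.sources:
        lo_len, hi_len = spec.seq_length
        lo_k, hi_k = spec.seqs_per_drug
        n_anc = hi_k
        ancestors = {
            c: [
                "".join(rng.choice(list(spec.alphabet), size=int(rng.integers(lo_len, hi_len + 1))))
                for _ in range(n_anc)
            ]
            for c in range(spec.n_clusters)
        }
        present = ~missing_masks[spec.sequence_source]
        per_drug = {}
        for i, d in enumerate(drugs):
            if not present[i]:
                continue
            k = int(rng.integers(lo_k, hi_k + 1))
            anc = ancestors[cluster_of[d]]
            per_drug[d] = [
                _mutate(anc[j % n_anc], spec.seq_mutation, spec.alphabet, rng)
                for j in range(k)
            ]
        sequences = SequenceFeatureMap(per_drug, alphabet=spec.alphabet)

    dataset = Dataset(feature_matrices, golden, sequences)
    truth = GroundTruth(cluster_of, signature_features, sig_dis, spec)
    return dataset, truth


def write_dataset(dataset: Dataset, truth: GroundTruth | None, outdir: str | Path) -> None:
    """Write a dataset in the same TSV/FASTA dialect the loaders read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fm in dataset.feature_matrices.items():
        fm.save(outdir / f"{name}.tsv")
    dataset.golden.save(outdir / "golden.tsv")
    if dataset.sequences is not None:
        dataset.sequences.save_fasta(outdir / "sequences.fasta")
    if truth is not None:
        (outdir / "ground_truth.json").write_text(truth.to_json())
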