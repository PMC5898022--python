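"""Binary drug-feature and drug-disease matrices: loading, harmonization, summaries.

All inputs are flat delimited text keyed by drug / disease / feature *names*
(no numeric identifiers). Each feature source (chemical substructures,
protein targets, side-effects, ...) is an independent binary incidence
matrix; a drug may be present in some sources and absent from others, and
absence is distinct from an all-zero row: an absent drug simply has no row
in that source's matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical source labels; arbitrary extra sources are allowed as "custom"
KNOWN_SOURCES = ("chemical", "protein", "side_effect")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """A cell or header in an input file violates the binary-matrix format."""


class ValidationError(ValueError):
    """An in-memory matrix violates a structural invariant (e.g. duplicate ids)."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


def _validate_binary(df: pd.DataFrame, what: str) -> pd.DataFrame:
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"non-binary cell in {what}: row {df.index[r]!r}, "
            f"column {df.columns[c]!r}, value {arr[r, c]!r}"
        )
    return df.astype(np.int8)


@dataclass
class FeatureMatrix:
    """Named binary drug x feature incidence matrix for one data source."""

    source_name: str
    values: pd.DataFrame  # index = drug names, columns = feature names, {0,1}

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "drug")
        _check_unique(self.values.columns, "feature")
        self.values = _validate_binary(self.values, f"source {self.source_name!r}")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def has_drug(self, drug: str) -> bool:
        return drug in self.values.index

    def row(self, drug: str) -> np.ndarray:
        """Binary feature vector of *drug*; KeyError if the drug is absent."""
        return self.values.loc[drug].to_numpy()

    def save(self, path: str | Path, delimiter: str = "\t") -> None:
        self.values.to_csv(path, sep=delimiter)


@dataclass
class GoldenAssociations:
    """The reference binary drug x disease indication matrix (ground truth)."""

    values: pd.DataFrame  # index = drug names, columns = disease names, {0,1}

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "drug")
        _check_unique(self.values.columns, "disease")
        self.values = _validate_binary(self.values, "golden associations")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_positive(self) -> int:
        return int(self.values.to_numpy().sum())

    @property
    def n_negative(self) -> int:
        r, c = self.values.shape
        return r * c - self.n_positive

    def indications(self, drug: str) -> list[str]:
        row = self.values.loc[drug]
        return list(row.index[row == 1])

    def drop_drug(self, drug: str) -> "GoldenAssociations":
        """Golden matrix with *drug*'s row withheld (leave-one-out view)."""
        return GoldenAssociations(self.values.drop(index=drug))

    def save(self, path: str | Path, delimiter: str = "\t") -> None:
        self.values.to_csv(path, sep=delimiter)


@dataclass
class SequenceFeatureMap:
    """Per-drug lists of residue sequences (e.g. target-protein sequences).

    Used by the alignment-based similarity: a drug is a set of sequences and
    two drugs are compared through all pairwise local alignments.
    """

    sequences_per_drug: dict[str, list[str]]
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        allowed = set(self.alphabet)
        for drug, seqs in self.sequences_per_drug.items():
            if not seqs:
                raise ValidationError(f"drug {drug!r} has an empty sequence list")
            for s in seqs:
                if not s:
                    raise ValidationError(f"drug {drug!r} has an empty sequence")
                for pos, ch in enumerate(s):
                    if ch not in allowed:
                        raise ValidationError(
                            f"drug {drug!r}: residue {ch!r} at position {pos} "
                            f"not in alphabet"
                        )

    @property
    def drug_ids(self) -> list[str]:
        return list(self.sequences_per_drug)

    def has_drug(self, drug: str) -> bool:
        return drug in self.sequences_per_drug

    def save_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for drug, seqs in self.sequences_per_drug.items():
                for i, s in enumerate(seqs):
                    fh.write(f">{drug}|seq{i}\n{s}\n")


@dataclass
class SynonymMap:
    """Alias -> canonical drug-name mapping, idempotent after one application."""

    alias: dict[str, str] = field(default_factory=dict)

    def canonical(self, name: str) -> str:
        return self.alias.get(name, name)

    def __len__(self) -> int:
        return len(self.alias)


@dataclass
class Dataset:
    """One or more feature sources plus the golden drug-disease matrix."""

    feature_matrices: dict[str, FeatureMatrix]
    golden: GoldenAssociations
    sequences: SequenceFeatureMap | None = None

    @property
    def source_names(self) -> list[str]:
        return list(self.feature_matrices)

    def sources_with_drug(self, drug: str) -> list[str]:
        out = [s for s, m in self.feature_matrices.items() if m.has_drug(drug)]
        return out

    def has_any_features(self, drug: str) -> bool:
        if any(m.has_drug(drug) for m in self.feature_matrices.values()):
            return True
        return self.sequences is not None and self.sequences.has_drug(drug)


def load_feature_matrix(
    path: str | Path, source_name: str, delimiter: str = "\t"
) -> FeatureMatrix:
    """Read a binary drug x feature matrix from delimited text.

    The first row holds feature names and the first column drug names; cells
    must be 0 or 1. Row and column order are preserved as stored.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureMatrix(source_name=source_name, values=df)


def load_golden(path: str | Path, delimiter: str = "\t") -> GoldenAssociations:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return GoldenAssociations(values=df)


def load_synonyms(path: str | Path, delimiter: str = "\t") -> SynonymMap:
    """Two-column (alias, canonical) table; no header."""
    df = pd.read_csv(path, sep=delimiter, header=None, names=["alias", "canonical"])
    return SynonymMap(alias=dict(zip(df["alias"].astype(str), df["canonical"].astype(str))))


def load_sequences_fasta(path: str | Path, alphabet: str = AMINO_ACIDS) -> SequenceFeatureMap:
    """FASTA keyed by ``drug|anything`` headers; records sharing a drug are grouped."""
    from Bio import SeqIO

    per_drug: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        drug = rec.id.split("|", 1)[0]
        per_drug.setdefault(drug, []).append(str(rec.seq))
    return SequenceFeatureMap(sequences_per_drug=per_drug, alphabet=alphabet)


def _merge_rows(df: pd.DataFrame) -> pd.DataFrame:
    """OR together rows that share an index label, preserving first-seen order."""
    if df.index.is_unique:
        return df
    order = list(dict.fromkeys(df.index))
    merged = df.groupby(level=0, sort=False).max()
    return merged.loc[order]


def harmonize_names(dataset: Dataset, synonyms: SynonymMap) -> Dataset:
    """Canonicalize drug names, merge synonym rows, drop golden orphans.

    Every drug id is replaced by its canonical name; rows that collapse onto
    the same canonical name are merged by elementwise OR (presence in either
    record counts). Golden drugs left without a feature row in *any* source
    are dropped — a drug with no prior information cannot be positioned.
    Idempotent: a second application is a no-op.
    """
    n_merged = 0
    new_sources: dict[str, FeatureMatrix] = {}
    for name, fm in dataset.feature_matrices.items():
        df = fm.values.copy()
        df.index = [synonyms.canonical(d) for d in df.index]
        n_merged += len(df) - len(set(df.index))
        new_sources[name] = FeatureMatrix(name, _merge_rows(df))

    new_seqs = dataset.sequences
    if new_seqs is not None:
        per_drug: dict[str, list[str]] = {}
        for drug, seqs in new_seqs.sequences_per_drug.items():
            per_drug.setdefault(synonyms.canonical(drug), []).extend(seqs)
        new_seqs = SequenceFeatureMap(per_drug, alphabet=new_seqs.alphabet)

    gdf = dataset.golden.values.copy()
    gdf.index = [synonyms.canonical(d) for d in gdf.index]
    gdf = _merge_rows(gdf)

    covered = set()
    for fm in new_sources.values():
        covered.update(fm.drug_ids)
    if new_seqs is not None:
        covered.update(new_seqs.drug_ids)
    keep = [d for d in gdf.index if d in covered]
    n_dropped = len(gdf) - len(keep)
    gdf = gdf.loc[keep]

    logger.info(
        "harmonize_names: merged %d synonym rows, dropped %d golden drugs "
        "with no feature information; golden now %d drugs x %d diseases "
        "with %d positive links",
        n_merged, n_dropped, gdf.shape[0], gdf.shape[1], int(gdf.to_numpy().sum()),
    )
    return Dataset(new_sources, GoldenAssociations(gdf), new_seqs)


def sparsity(matrix: FeatureMatrix | GoldenAssociations | pd.DataFrame) -> float:
    """Fraction of zero cells: ``1 - ones / (rows * columns)``."""
    df = matrix.values if not isinstance(matrix, pd.DataFrame) else matrix
    r, c = df.shape
    if r == 0 or c == 0:
        raise ValidationError("sparsity of a zero-size matrix is undefined")
    return 1.0 - float(df.to_numpy().sum()) / (r * c)


def density(matrix: FeatureMatrix | GoldenAssociations | pd.DataFrame) -> float:
    return 1.0 - sparsity(matrix)
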