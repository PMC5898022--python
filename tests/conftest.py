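import numpy as np
import pandas as pd
import pytest

from paretodr.data_model import Dataset, FeatureMatrix, GoldenAssociations
from paretodr.similarity import SimilarityProfile
from paretodr.synthetic import GeneratorSpec, SourceSpec, generate


def make_matrix(name: str, drugs, data) -> FeatureMatrix:
    data = np.asarray(data)
    cols = [f"{name}_F{j}" for j in range(data.shape[1])]
    return FeatureMatrix(name, pd.DataFrame(data, index=list(drugs), columns=cols))


def make_golden(drugs, diseases, data) -> GoldenAssociations:
    return GoldenAssociations(
        pd.DataFrame(np.asarray(data), index=list(drugs), columns=list(diseases))
    )


def make_profiles(target: str, rows: dict[str, tuple]) -> list[SimilarityProfile]:
    """Profiles from {candidate: (v_f1, v_f2, ...)}; None marks an absent source."""
    out = []
    for cand, vals in rows.items():
        per = {f"f{i}": v for i, v in enumerate(vals)}
        out.append(SimilarityProfile(target, cand, per))
    return out


@pytest.fixture(scope="session")
def tiny_dataset() -> Dataset:
    """Four drugs, two binary sources, golden over four diseases.

    A/B share features and indications; C is a near-duplicate of A; D is
    unrelated and absent from the second source.
    """
    chem = make_matrix(
        "chemical",
        ["A", "B", "C", "D"],
        [[1, 1, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0], [0, 0, 0, 1]],
    )
    side = make_matrix(
        "side_effect",
        ["A", "B", "C"],
        [[1, 0, 1], [1, 0, 1], [1, 0, 0]],
    )
    golden = make_golden(
        ["A", "B", "C", "D"],
        ["d1", "d2", "d3", "d4"],
        [[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1]],
    )
    return Dataset({"chemical": chem, "side_effect": side}, golden)


def noiseless_spec(seed: int = 7) -> GeneratorSpec:
    """Planted clusters with deterministic signatures: no noise, no missingness."""
    return GeneratorSpec(
        n_drugs=60,
        n_diseases=60,
        n_clusters=6,
        sources={
            "chemical": SourceSpec(60, 10, 1.0, 0.0, 0.0),
            "protein": SourceSpec(48, 8, 1.0, 0.0, 0.0),
            "side_effect": SourceSpec(60, 10, 1.0, 0.0, 0.0),
        },
        indications_per_cluster=4,
        indication_share=1.0,
        indication_background=0.0,
        seq_mutation=0.0,
        seed=seed,
    )


def noisy_spec(seed: int, background_scale: float = 1.0) -> GeneratorSpec:
    """Reduced-size planted clusters with realistic noise and missingness.

    ``background_scale`` multiplies every background one-probability, for
    noise-degradation comparisons.
    """
    b = background_scale
    return GeneratorSpec(
        n_drugs=80,
        n_diseases=80,
        n_clusters=8,
        sources={
            "chemical": SourceSpec(80, 8, 0.9, min(0.05 * b, 1.0)),
            "protein": SourceSpec(64, 2, 0.3, min(0.0005 * b, 1.0)),
            "side_effect": SourceSpec(80, 8, 0.75, min(0.008 * b, 1.0)),
        },
        indications_per_cluster=5,
        indication_share=0.9,
        indication_background=0.002,
        seed=seed,
    )


@pytest.fixture(scope="session")
def noiseless_data():
    return generate(noiseless_spec())


@pytest.fixture(scope="session")
def noisy_data():
    return generate(noisy_spec(seed=11))
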