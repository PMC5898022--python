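"""Run configuration shared by prediction, evaluation, and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field

from .data_model import ValidationError
from .similarity import SimilarityConfig

IST_SETTINGS = ("SUM", "WSUM")


@dataclass
class MethodConfig:
    """Full method setting: similarity measures, MOT, IST, N and k.

    ``n`` is the neighbor count target (meaningful for ND/AND); ``k`` caps
    the prediction-list length — the method may return fewer entries and
    never pads with guesses.
    """

    similarity: SimilarityConfig
    mot: str = "ND"
    ist: str = "WSUM"
    n: int = 4
    k: int = 4

    def __post_init__(self) -> None:
        from .neighbors import MOT_SETTINGS

        if self.mot not in MOT_SETTINGS:
            raise ValidationError(f"unknown MOT setting {self.mot!r}")
        if self.ist not in IST_SETTINGS:
            raise ValidationError(f"unknown IST setting {self.ist!r}")
        if self.n < 1 or self.k < 1:
            raise ValidationError("n and k must be >= 1")

    @classmethod
    def from_shorthand(
        cls, sim: str = "CCC", mot: str = "ND", ist: str = "WSUM",
        n: int = 4, k: int = 4, **sim_kwargs,
    ) -> "MethodConfig":
        return cls(
            similarity=SimilarityConfig.from_shorthand(sim, **sim_kwargs),
            mot=mot, ist=ist, n=n, k=k,
        )
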