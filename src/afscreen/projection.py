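"""Population-level projection of a hypothetical national AF screen.

Applies the observed detected prevalence of anticoagulation-eligible
untreated AF to an age/sex population table, then converts each identified
case into strokes prevented over a treatment horizon using the Markov
model's cumulative stroke risk difference (untreated minus DOAC-treated).
Per cell: b = population x prevalence, c = 10-year absolute risk reduction,
d = 1/c (number needed to treat), e = b x c strokes prevented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .markov import Strategy, cumulative_strokes
from .params import ModelConfig, PopulationTable, TransitionTable, ValidationError

__all__ = ["ProjectionResult", "detected_prevalence", "project"]


@dataclass(frozen=True)
class ProjectionResult:
    """Per (sex, single-year age) projection rows plus grand totals.

    ``cells`` columns: sex, age, population (a), identified (b),
    risk_reduction (c), nnt (d), strokes_prevented (e).
    """

    cells: pd.DataFrame
    horizon: int
    prevalence: float

    @property
    def total_identified(self) -> float:
        return float(self.cells["identified"].sum())

    @property
    def total_strokes_prevented(self) -> float:
        return float(self.cells["strokes_prevented"].sum())


def detected_prevalence(
    score_dist: Mapping[int, int], n_screened: int, min_score: int = 1
) -> float:
    """Prevalence of detected untreated AF at or above a risk-score cut.

    ``score_dist`` is the CHADS2 breakdown of the detected untreated-AF
    cases; the default cut of 1 keeps the anticoagulation-eligible cases.
    """
    if n_screened <= 0:
        raise ValidationError("n_screened must be positive")
    if min_score < 0:
        raise ValidationError("min_score must be non-negative")
    eligible = sum(c for s, c in score_dist.items() if s >= min_score)
    return eligible / n_screened


def project(
    pop: PopulationTable,
    prevalence: float,
    transitions: Mapping[str, TransitionTable],
    horizon: int = 10,
    config: ModelConfig | None = None,
    *,
    age_range: tuple[int, int] = (65, 80),
) -> ProjectionResult:
    """Project identified untreated AF and strokes prevented nationally.

    For each sex and single-year age in ``age_range`` (inclusive; band
    headcounts divided by 5), applies the constant detected prevalence and
    the model's per-person cumulative stroke-risk difference over
    ``horizon`` years of treatment.
    """
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    if not (0.0 <= prevalence <= 1.0):
        raise ValidationError("prevalence must be in [0, 1]")
    config = config or ModelConfig()
    rows = []
    for sex in ("men", "women"):
        if sex not in transitions:
            raise ValidationError(f"no transition table supplied for {sex!r}")
        tab = transitions[sex]
        for age in range(age_range[0], age_range[1] + 1):
            a = pop.single_year_count(sex, age)
            b = a * prevalence
            c = cumulative_strokes(
                Strategy.UNTREATED_AF, sex, age, horizon, tab, config
            ) - cumulative_strokes(Strategy.TREATED_AF, sex, age, horizon, tab, config)
            rows.append(
                {
                    "sex": sex,
                    "age": age,
                    "population": a,
                    "identified": b,
                    "risk_reduction": c,
                    "nnt": (1.0 / c) if c > 0 else float("inf"),
                    "strokes_prevented": b * c,
                }
            )
    return ProjectionResult(
        cells=pd.DataFrame(rows), horizon=horizon, prevalence=prevalence
    )
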