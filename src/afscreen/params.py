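"""Parameter tables for the AF screening effectiveness model.

Holds the annual transition probabilities of the three-profile Markov model
(non-AF, DOAC-treated AF, untreated AF), the stroke-related utility
parameters, the run configuration (discount rate, accrual convention), and
the age/sex population table used for the national projection.  Transition
probabilities are stored internally as fractions; CSV files may carry either
percent strings ("1.006%") or plain fractions, resolved per column value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AGE_BANDS",
    "TRANSITION_NAMES",
    "ValidationError",
    "TransitionTable",
    "QolParams",
    "ModelConfig",
    "PopulationTable",
    "band_for_age",
    "load_transition_table",
    "write_transition_table",
    "default_transitions",
    "load_qol",
    "default_qol",
    "load_model_config",
    "load_population",
]

#: Five-year model age bands; the terminal open band forces death.
AGE_BANDS = ("65-69", "70-74", "75-79", "80-84", "85-89", "90-94", "95-99", "100+")

#: Annual transition probabilities, one column per arrow of the state diagram:
#: s0 = alive non-AF, t1 = alive treated AF, t0 = alive untreated AF,
#: e1 = post-stroke, e2 = dead.
TRANSITION_NAMES = (
    "p_s0e1", "p_s0e2", "p_t1e1", "p_t1e2", "p_t0e1", "p_t0e2", "p_e1e2",
)

MODEL_FLOOR_AGE = 65


class ValidationError(ValueError):
    """A parameter table failed a structural or range check."""


def band_for_age(age: float) -> str:
    """Map an age in years to its five-year band label (closed-left bands).

    Ages at or above 100 map to the terminal ``100+`` band.  Ages below the
    model floor of 65 are a domain error: the cohort model starts at 65.
    """
    if age < MODEL_FLOOR_AGE:
        raise ValidationError(f"age {age} is below the model floor of {MODEL_FLOOR_AGE}")
    if age >= 100:
        return "100+"
    return AGE_BANDS[(int(age) - 65) // 5]


def _parse_probability(value, column: str, band: str) -> float:
    """Parse one CSV cell: '1.006%' -> 0.01006, '0.01006' -> 0.01006."""
    if isinstance(value, str) and value.strip().endswith("%"):
        out = float(value.strip().rstrip("%")) / 100.0
    else:
        out = float(value)
    if not (0.0 <= out <= 1.0) or not np.isfinite(out):
        raise ValidationError(
            f"probability {column} in band {band} is {value!r}, outside [0, 1]"
        )
    return out


@dataclass(frozen=True)
class TransitionTable:
    """Annual transition probabilities for one sex, by five-year age band.

    Parameters
    ----------
    sex
        ``"men"`` or ``"women"``.
    probs
        DataFrame indexed by band label with the seven probability columns
        of :data:`TRANSITION_NAMES`, as fractions in ``[0, 1]``.
    acute_fatality_under75, acute_fatality_75plus
        Fraction of incident strokes that die during the acute stage, for
        events at ages 65-74 and 75+ respectively.
    """

    sex: str
    probs: pd.DataFrame
    acute_fatality_under75: float = 0.057
    acute_fatality_75plus: float = 0.101

    def __post_init__(self) -> None:
        if self.sex not in ("men", "women"):
            raise ValidationError(f"sex must be 'men' or 'women', got {self.sex!r}")
        missing_cols = set(TRANSITION_NAMES) - set(self.probs.columns)
        if missing_cols:
            raise ValidationError(f"missing probability columns: {sorted(missing_cols)}")
        missing_bands = [b for b in AGE_BANDS if b not in self.probs.index]
        if missing_bands:
            raise ValidationError(f"missing age bands: {missing_bands}")
        block = self.probs.loc[list(AGE_BANDS), list(TRANSITION_NAMES)].to_numpy(float)
        if not np.isfinite(block).all():
            raise ValidationError("transition table contains NaN or infinite values")
        if (block < 0).any() or (block > 1).any():
            bad = np.argwhere((block < 0) | (block > 1))[0]
            raise ValidationError(
                f"probability {TRANSITION_NAMES[bad[1]]} in band "
                f"{AGE_BANDS[bad[0]]} is outside [0, 1]"
            )
        terminal = self.probs.loc["100+"]
        for col in ("p_s0e2", "p_t1e2", "p_t0e2", "p_e1e2"):
            if terminal[col] != 1.0:
                raise ValidationError(f"terminal band must have {col} = 1.0")
        for col in ("p_s0e1", "p_t1e1", "p_t0e1"):
            if terminal[col] != 0.0:
                raise ValidationError(f"terminal band must have {col} = 0.0")
        for f in (self.acute_fatality_under75, self.acute_fatality_75plus):
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"acute fatality fraction {f} outside [0, 1]")

    def lookup(self, age: float, transition: str) -> float:
        """Probability of ``transition`` for the band containing ``age``."""
        if transition not in TRANSITION_NAMES:
            raise ValidationError(
                f"unknown transition {transition!r}; expected one of {TRANSITION_NAMES}"
            )
        return float(self.probs.at[band_for_age(age), transition])

    def acute_fatality(self, age: float) -> float:
        """Acute-stage stroke case fatality for an event at ``age``.

        Switches exactly at the 75th birthday: 65-74 uses the lower
        fraction, 75 and above the higher one.
        """
        if age < MODEL_FLOOR_AGE:
            raise ValidationError(f"age {age} is below the model floor of {MODEL_FLOOR_AGE}")
        return self.acute_fatality_75plus if age >= 75 else self.acute_fatality_under75


def load_transition_table(path: str | Path, sex: str, **kwargs) -> TransitionTable:
    """Read a transition-probability CSV (percent strings or fractions).

    The file must have an ``age_band`` column and the seven probability
    columns of :data:`TRANSITION_NAMES`.  Extra keyword arguments override
    the acute-fatality fractions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str)
    if "age_band" not in raw.columns:
        raise ValidationError("transition CSV must have an 'age_band' column")
    missing = set(TRANSITION_NAMES) - set(raw.columns)
    if missing:
        raise ValidationError(f"transition CSV missing columns: {sorted(missing)}")
    raw = raw.set_index("age_band")
    probs = pd.DataFrame(index=raw.index, columns=list(TRANSITION_NAMES), dtype=float)
    for band, row in raw.iterrows():
        for col in TRANSITION_NAMES:
            probs.at[band, col] = _parse_probability(row[col], col, band)
    return TransitionTable(sex=sex, probs=probs, **kwargs)


def write_transition_table(table: TransitionTable, path: str | Path) -> None:
    """Write a transition table back to CSV in percent notation (3 dp)."""
    out = table.probs.loc[list(AGE_BANDS), list(TRANSITION_NAMES)] * 100.0
    out = out.map(lambda v: f"{v:.3f}%")
    out.index.name = "age_band"
    out.to_csv(path)


def _data_path(name: str) -> Path:
    return Path(resources.files("afscreen") / "data" / name)


def default_transitions(sex: str) -> TransitionTable:
    """The published transition-probability table shipped with the package."""
    if sex not in ("men", "women"):
        raise ValidationError(f"sex must be 'men' or 'women', got {sex!r}")
    return load_transition_table(_data_path(f"transitions_{sex}.csv"), sex)


@dataclass(frozen=True)
class QolParams:
    """Utility weights for QALY accrual.

    ``u_baseline`` applies to any alive pre-stroke profile.  An incident
    stroke costs ``acute_decrement`` utility for ``acute_duration`` years
    (0.14 for a quarter year, i.e. 0.035 QALY); thereafter survivors carry
    the age-banded post-stroke utility.
    """

    u_baseline: float = 1.0
    acute_decrement: float = 0.14
    acute_duration: float = 0.25
    u_poststroke_65_74: float = 0.68
    u_poststroke_75plus: float = 0.56

    def __post_init__(self) -> None:
        for name in ("u_baseline", "u_poststroke_65_74", "u_poststroke_75plus"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if self.acute_decrement < 0:
            raise ValidationError("acute_decrement must be non-negative")
        if self.acute_duration < 0:
            raise ValidationError("acute_duration must be non-negative")

    def u_poststroke(self, age: float) -> float:
        """Post-stroke utility for the band containing the CURRENT age."""
        return self.u_poststroke_75plus if age >= 75 else self.u_poststroke_65_74

    @property
    def stroke_cycle_penalty(self) -> float:
        """QALY decrement of the acute stage spread over the stroke cycle."""
        return self.acute_decrement * self.acute_duration


_QOL_FIELDS = {
    "u_baseline": "u_baseline",
    "acute_decrement": "acute_decrement",
    "acute_duration_years": "acute_duration",
    "u_poststroke_65_74": "u_poststroke_65_74",
    "u_poststroke_75plus": "u_poststroke_75plus",
}


def load_qol(path: str | Path) -> QolParams:
    """Read utility parameters from a two-column ``parameter,value`` CSV."""
    raw = pd.read_csv(path).set_index("parameter")["value"]
    kwargs = {}
    for key, attr in _QOL_FIELDS.items():
        if key in raw.index:
            kwargs[attr] = float(raw[key])
    return QolParams(**kwargs)


def default_qol() -> QolParams:
    """The published utility parameters shipped with the package."""
    return load_qol(_data_path("qol.csv"))


ACCRUAL_CONVENTIONS = ("cycle_start", "cycle_end", "half_cycle")


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration for the cohort model.

    ``accrual_convention`` decides how much of the cycle members who die
    during it accrue: a full year (``cycle_start``), nothing (``cycle_end``)
    or half a year (``half_cycle``, the default).  ``discount_exponent_base``
    is 0 when the first cycle is undiscounted, 1 when discounting starts at
    the first cycle.
    """

    discount_rate: float = 0.02
    terminal_age: int = 100
    accrual_convention: str = "half_cycle"
    discount_exponent_base: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.discount_rate <= 0.10):
            raise ValidationError(f"discount_rate {self.discount_rate} outside [0, 0.10]")
        if self.accrual_convention not in ACCRUAL_CONVENTIONS:
            raise ValidationError(
                f"accrual_convention must be one of {ACCRUAL_CONVENTIONS}"
            )
        if self.discount_exponent_base not in (0, 1):
            raise ValidationError("discount_exponent_base must be 0 or 1")

    @property
    def death_credit(self) -> float:
        """Fraction of a cycle credited to members dying during it."""
        return {"cycle_start": 1.0, "cycle_end": 0.0, "half_cycle": 0.5}[
            self.accrual_convention
        ]

    def discount_factor(self, cycle: int) -> float:
        return (1.0 + self.discount_rate) ** -(cycle + self.discount_exponent_base)

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


def load_model_config(path: str | Path) -> ModelConfig:
    """Read a ModelConfig from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValidationError(f"config file {path} does not hold a mapping")
    return ModelConfig(**dict(data))


@dataclass(frozen=True)
class PopulationTable:
    """Headcounts by sex and five-year age band (Vital Statistics style).

    Single-year headcounts are the band count divided by 5, the convention
    used when projecting a screen of everyone aged 65-80.
    """

    counts: pd.DataFrame  # columns: sex, age_band, count

    def __post_init__(self) -> None:
        need = {"sex", "age_band", "count"}
        if not need <= set(self.counts.columns):
            raise ValidationError(f"population table needs columns {sorted(need)}")
        if (self.counts["count"] < 0).any():
            raise ValidationError("population counts must be non-negative")
        bad_sex = set(self.counts["sex"]) - {"men", "women"}
        if bad_sex:
            raise ValidationError(f"unknown sex values: {sorted(bad_sex)}")
        for sex in self.counts["sex"].unique():
            bands = set(self.counts.loc[self.counts["sex"] == sex, "age_band"])
            for needed in ("65-69", "70-74", "75-79", "80-84"):
                if needed not in bands:
                    raise ValidationError(
                        f"population table for {sex} missing band {needed} "
                        "(ages 65-80 must be covered)"
                    )

    def single_year_count(self, sex: str, age: int) -> float:
        """Headcount at one single year of age: band count / 5."""
        band = band_for_age(age)
        sel = self.counts[(self.counts["sex"] == sex) & (self.counts["age_band"] == band)]
        if sel.empty:
            raise ValidationError(f"no population row for {sex} band {band}")
        return float(sel["count"].iloc[0]) / 5.0


def load_population(path: str | Path) -> PopulationTable:
    """Read a ``sex,age_band,count`` CSV into a PopulationTable."""
    return PopulationTable(pd.read_csv(path))
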