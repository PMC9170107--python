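"""Statistics of the AF screening campaign.

Detection rates with exact binomial intervals, number needed to screen,
stratified 2x2 comparisons with Fisher's exact test, interobserver kappa,
CHADS2 / CHA2DS2-VASc scoring, score-distribution summaries and diagnostic
accuracy of a rhythm classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .params import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "DetectionRate",
    "detection_rate",
    "nns",
    "fisher_exact",
    "stratified_detection",
    "cohen_kappa",
    "score_summary",
    "diag_accuracy",
    "compute_scores",
    "clopper_pearson",
    "COMORBIDITY_FIELDS",
]

#: Screening-record columns usable as stratification factors.
COMORBIDITY_FIELDS = (
    "chf",
    "hypertension",
    "diabetes",
    "stroke_tia",
    "vascular",
    "age_ge_75",
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = exposed-positive, exposed-negative,
    unexposed-positive, unexposed-negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValidationError(f"2x2 counts must be non-negative integers, got {v}")
        if self.total == 0:
            raise ValidationError("2x2 table must have a positive grand total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class DetectionRate:
    """Point detection rate with an exact (Clopper-Pearson) 95% CI."""

    n_detected: int
    n_screened: int
    rate: float
    ci_low: float
    ci_high: float

    def percent(self, decimals: int = 2) -> float:
        return round(100.0 * self.rate, decimals)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from the beta quantiles."""
    if not (0 <= k <= n) or n <= 0:
        raise ValidationError(f"need 0 <= k <= n with n > 0, got k={k} n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def detection_rate(n_detected: int, n_screened: int) -> DetectionRate:
    """Detected cases per screen with the exact binomial 95% CI."""
    if n_screened <= 0:
        raise ValidationError("n_screened must be positive")
    if not (0 <= n_detected <= n_screened):
        raise ValidationError("need 0 <= n_detected <= n_screened")
    lo, hi = clopper_pearson(n_detected, n_screened)
    return DetectionRate(
        n_detected=n_detected,
        n_screened=n_screened,
        rate=n_detected / n_screened,
        ci_low=lo,
        ci_high=hi,
    )


def nns(n_detected: int, n_screened: int) -> float:
    """Number needed to screen for one detected case: n_screened/n_detected.

    Returned as the raw quotient; round or format at the presentation layer.
    Zero detections give ``inf``.
    """
    if n_screened <= 0:
        raise ValidationError("n_screened must be positive")
    if n_detected < 0:
        raise ValidationError("n_detected must be non-negative")
    if n_detected == 0:
        return math.inf
    return n_screened / n_detected


#: Relative slack when comparing table probabilities to the observed one,
#: so exact ties survive floating-point evaluation (R uses 1e-7 here).
_FISHER_REL_EPS = 1e-10


def _log_hypergeom_weights(n1: int, n2: int, m: int) -> tuple[int, np.ndarray]:
    """Log unnormalised hypergeometric weights C(n1,k)C(n2,m-k) over the
    support of k; returns (support lower bound, log-weight vector)."""
    lo = max(0, m - n2)
    hi = min(m, n1)
    k = np.arange(lo, hi + 1)
    logw = (
        special.gammaln(n1 + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n1 - k + 1)
        + special.gammaln(n2 + 1)
        - special.gammaln(m - k + 1)
        - special.gammaln(n2 - m + k + 1)
    )
    return lo, logw


def fisher_pvalues_by_margins(n1: int, n2: int, m: int) -> tuple[int, np.ndarray]:
    """Two-sided Fisher p for every table in one margin class at once.

    For fixed margins (row sums ``n1``, ``n2``; first column sum ``m``),
    returns the support lower bound and the p-value of every observable
    count ``a`` in the first cell: each p sums the probabilities of all
    tables no more probable than the observed one.
    """
    lo, logw = _log_hypergeom_weights(n1, n2, m)
    w = np.exp(logw - logw.max())
    order = np.argsort(w, kind="stable")
    csum = np.cumsum(w[order])
    # rank of the largest weight still counted as "no more probable"
    idx = np.searchsorted(w[order], w * (1.0 + _FISHER_REL_EPS), side="right")
    pvals = csum[idx - 1] / csum[-1]
    return lo, np.minimum(pvals, 1.0)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums the hypergeometric probabilities, at fixed margins, of every table
    no more probable than the observed one (the convention of mainstream
    statistical software), with a relative slack of 1e-10 so exact ties are
    included.  A zero margin makes every table equally likely, so p = 1 by
    convention.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    n1, n2 = table.a + table.b, table.c + table.d
    m = table.a + table.c
    lo, pvals = fisher_pvalues_by_margins(n1, n2, m)
    return float(pvals[table.a - lo])


def _require_bool_series(records: pd.DataFrame, col: str) -> pd.Series:
    if col not in records.columns:
        raise ValidationError(f"records have no column {col!r}")
    return records[col]


def stratified_detection(
    records: pd.DataFrame,
    factor: str,
    *,
    exclude_treated: bool = False,
    exclude_uninterpretable: bool = False,
) -> dict:
    """Untreated-AF detection compared across presence of one factor.

    Builds the 2x2 of untreated AF by factor status; records whose factor
    status is missing are dropped.  Known treated-AF subjects and
    uninterpretable rhythm reads stay in the denominators by default,
    matching the campaign's published stratum sizes; the ``exclude_*``
    flags restrict to the at-risk / interpretable population instead.

    Returns the table, both stratum rates, and the Fisher two-sided p.
    """
    if factor not in COMORBIDITY_FIELDS:
        raise ValidationError(
            f"unknown factor {factor!r}; expected one of {COMORBIDITY_FIELDS}"
        )
    df = records
    if exclude_uninterpretable and "adjudicated" in df.columns:
        df = df[df["adjudicated"] != "uninterpretable"]
    if exclude_treated and "known_af" in df.columns:
        df = df[~df["known_af"].astype(bool)]
    fac = _require_bool_series(df, factor)
    df = df[fac.notna()]
    fac = df[factor].astype(bool)
    case = df["untreated_af"].astype(bool)
    a = int((fac & case).sum())
    b = int((fac & ~case).sum())
    c = int((~fac & case).sum())
    d = int((~fac & ~case).sum())
    if a + b == 0 or c + d == 0:
        raise ValidationError(f"factor {factor!r} has an empty stratum")
    table = ContingencyTable2x2(a, b, c, d)
    return {
        "table": table,
        "rate_pos": detection_rate(a, a + b),
        "rate_neg": detection_rate(c, c + d),
        "p_value": fisher_exact(table),
    }


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement from the
    product of the raters' marginal frequencies.  Undefined (raises) when
    both raters are constant and identical, since chance agreement is 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValidationError("label sequences must be equal-length and non-empty")
    cats = np.union1d(a, b)
    n = a.size
    p_o = float((a == b).mean())
    p_e = sum(float((a == c).mean()) * float((b == c).mean()) for c in cats)
    if p_e >= 1.0 - 1e-15:
        raise ValidationError("kappa undefined: both raters constant and identical")
    return (p_o - p_e) / (1.0 - p_e)


def score_summary(dist: Mapping[int, int]) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of a score count distribution."""
    total = sum(dist.values())
    if any(c < 0 for c in dist.values()):
        raise ValidationError("score counts must be non-negative")
    if total < 2:
        raise ValidationError("need at least 2 observations for a sample SD")
    values = np.repeat(list(dist.keys()), list(dist.values())).astype(float)
    return float(values.mean()), float(values.std(ddof=1))


def diag_accuracy(
    confusion: ContingencyTable2x2, *, ci_method: str = "clopper_pearson"
) -> dict:
    """Sensitivity and specificity with 95% CIs from a (TP, FP, FN, TN) table.

    The table maps (a, b, c, d) = (TP, FP, FN, TN).  ``ci_method`` is
    ``"clopper_pearson"`` (exact, default) or ``"wilson"``.
    """
    tp, fp, fn, tn = confusion.a, confusion.b, confusion.c, confusion.d
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("need at least one true positive-class and one "
                              "true negative-class subject")

    def ci(k: int, n: int) -> tuple[float, float]:
        if ci_method == "clopper_pearson":
            return clopper_pearson(k, n)
        if ci_method == "wilson":
            lo, hi = stats.binomtest(k, n).proportion_ci(method="wilson")
            return float(lo), float(hi)
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    return {
        "sensitivity": tp / (tp + fn),
        "sensitivity_ci": ci(tp, tp + fn),
        "specificity": tn / (tn + fp),
        "specificity_ci": ci(tn, tn + fp),
    }


def compute_scores(record: Mapping) -> tuple[int, int]:
    """CHADS2 and CHA2DS2-VASc stroke-risk scores of one subject.

    CHADS2 = CHF + hypertension + (age >= 75) + diabetes + 2 * stroke/TIA.
    CHA2DS2-VASc additionally doubles the age-75 point, and adds vascular
    disease, one point for age 65-74 and one for female sex.
    """
    required = ("age", "sex", "chf", "hypertension", "diabetes", "stroke_tia", "vascular")
    for fieldname in required:
        if fieldname not in record or record[fieldname] is None or (
            isinstance(record[fieldname], float) and math.isnan(record[fieldname])
        ):
            raise ValidationError(f"missing score component {fieldname!r}")
    age = float(record["age"])
    if age < 0:
        raise ValidationError("age must be non-negative")
    chf = int(bool(record["chf"]))
    htn = int(bool(record["hypertension"]))
    dm = int(bool(record["diabetes"]))
    stia = int(bool(record["stroke_tia"]))
    vasc = int(bool(record["vascular"]))
    female = int(record["sex"] in ("women", "female", "F", "f"))
    age75 = int(age >= 75)
    age65 = int(65 <= age < 75)
    chads2 = chf + htn + age75 + dm + 2 * stia
    cha2ds2_vasc = chf + htn + 2 * age75 + dm + 2 * stia + vasc + age65 + female
    return chads2, cha2ds2_vasc
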