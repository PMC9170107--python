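"""Individual-level Monte-Carlo cross-check of the cohort recursion.

Simulates n independent subjects through the same per-cycle probabilities
and accrual rules as the deterministic cohort model; the sample means must
agree with the cohort totals within Monte-Carlo error, which is the
package's internal validation of the recursion itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import Strategy
from .params import ModelConfig, QolParams, TransitionTable, ValidationError

__all__ = ["MicrosimResult", "microsim_cohort"]


@dataclass(frozen=True)
class MicrosimResult:
    """Sample means and standard errors over n simulated subjects."""

    n: int
    seed: int
    life_years: float
    life_years_se: float
    qalys: float
    qalys_se: float
    strokes: float
    strokes_se: float


def microsim_cohort(
    strategy: Strategy | str,
    sex: str,
    start_age: int,
    n: int,
    seed: int,
    transitions: TransitionTable,
    qol: QolParams,
    config: ModelConfig | None = None,
) -> MicrosimResult:
    """Simulate ``n`` subjects and return discounted life-year/QALY means.

    Each subject starts alive in the strategy's profile; every cycle,
    death resolves first, stroke strikes survivors, and incident strokes
    are acutely fatal with the age-banded case fatality.  Accrual and
    discounting follow the config exactly as in the cohort model, so the
    estimates are unbiased for the cohort totals.
    """
    strategy = Strategy(strategy)
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if sex != transitions.sex:
        raise ValidationError(
            f"sex {sex!r} does not match transition table sex {transitions.sex!r}"
        )
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    credit = config.death_credit
    pen = qol.stroke_cycle_penalty

    ALIVE, POST_LO, POST_HI, DEAD = 0, 1, 2, 3
    state = np.full(n, ALIVE, dtype=np.int8)
    ly = np.zeros(n)
    qa = np.zeros(n)
    strokes = np.zeros(n)

    k = 0
    while (state != DEAD).any():
        age = start_age + k
        if age > config.terminal_age + 1:
            raise RuntimeError("microsim failed to reach extinction at the terminal age")
        p_death = transitions.lookup(age, strategy.death_col)
        p_stroke = transitions.lookup(age, strategy.stroke_col)
        p_post_death = transitions.lookup(age, "p_e1e2")
        f_acute = transitions.acute_fatality(age)
        u_post_now = qol.u_poststroke(age)
        u_stroke_cycle = u_post_now - pen
        disc = config.discount_factor(k)

        r_death = rng.random(n)
        r_stroke = rng.random(n)
        r_acute = rng.random(n)

        alive = state == ALIVE
        post = (state == POST_LO) | (state == POST_HI)

        dies = alive & (r_death < p_death)
        strk = alive & ~dies & (r_stroke < p_stroke)
        acute = strk & (r_acute < f_acute)
        strk_surv = strk & ~acute
        stays = alive & ~dies & ~strk
        post_dies = post & (r_death < p_post_death)
        post_surv = post & ~post_dies

        cyc_ly = np.zeros(n)
        cyc_qa = np.zeros(n)
        cyc_ly[stays] = 1.0
        cyc_qa[stays] = qol.u_baseline
        cyc_ly[strk_surv] = 1.0
        cyc_qa[strk_surv] = u_stroke_cycle
        cyc_ly[dies] = credit
        cyc_qa[dies] = credit * qol.u_baseline
        cyc_ly[acute] = credit
        cyc_qa[acute] = credit * u_stroke_cycle
        cyc_ly[post_surv] = 1.0
        cyc_ly[post_dies] = credit
        u_post_arr = np.where(state == POST_LO, qol.u_poststroke_65_74,
                              qol.u_poststroke_75plus)
        u_post_arr = np.where(post, u_post_now, u_post_arr)  # current-age convention
        cyc_qa[post_surv] = u_post_arr[post_surv]
        cyc_qa[post_dies] = credit * u_post_arr[post_dies]

        ly += disc * cyc_ly
        qa += disc * cyc_qa
        strokes += strk

        state[dies | acute | post_dies] = DEAD
        state[strk_surv] = POST_LO if age < 75 else POST_HI
        k += 1

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    return MicrosimResult(
        n=n,
        seed=seed,
        life_years=float(ly.mean()),
        life_years_se=se(ly),
        qalys=float(qa.mean()),
        qalys_se=se(qa),
        strokes=float(strokes.mean()),
        strokes_se=se(strokes),
    )
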