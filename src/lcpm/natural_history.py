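"""Lung-cancer natural history and competing other-cause mortality.

A parametric surrogate generates, for each person: onset age from a
proportional-excess-hazard model on pack-years, a preclinical sojourn to
symptomatic ("clinical") detection, histology, stage at detection, and a
stage-specific cure-or-survival outcome.  Screen detection during the
preclinical window redraws stage from a distribution shifted toward early
stage and can convert a fatal case to a cured one; it never moves a death
earlier than the clinical pathway, so earlier diagnosis alone (lead time)
never changes a death age.  Incidental detection during unrelated imaging
moves only the diagnosis age (ending screening eligibility), not the death
age, for the same reason.

Other-cause mortality is a Gompertz-Makeham life table stratified by sex and
smoking-intensity band (never / light / heavy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import (
    AGE_MAX,
    AGE_MIN,
    HISTOLOGIES,
    NaturalHistoryParameters,
    OtherCauseParameters,
    ParameterBundle,
    SEXES,
    STAGES,
    sex_index,
)
from .smoking import NEVER, Person, SmokingHistory, cumulative_cpd, pack_years, smoking_status

__all__ = [
    "Tumor",
    "LifeTable",
    "lung_cancer_hazard",
    "sample_tumor",
    "screen_detect_outcome",
    "incidental_detection",
    "other_cause_death_age",
]

_AGES = np.arange(AGE_MIN, AGE_MAX + 1)


@dataclass
class Tumor:
    """A latent lung cancer and its counterfactual outcomes."""

    onset_age: float
    histology: str
    clinical_detection_age: float
    stage_clinical: str
    #: death age if detected via the clinical route; inf when cured
    lc_death_age_clinical: float
    cured_clinical: bool
    #: filled by screen detection
    detection_age: Optional[float] = None
    stage_screen: Optional[str] = None
    cured_screen: Optional[bool] = None
    lc_death_age_screen: Optional[float] = None
    incidental_age: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.onset_age <= self.clinical_detection_age
                <= self.lc_death_age_clinical):
            raise ValueError("tumor ages must satisfy onset <= detection <= death")


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------


@dataclass
class LifeTable:
    """Annual other-cause death probabilities by (sex, intensity band, age).

    ``q`` has shape (2 sexes, 3 bands, 70 ages) over ages 15..84.
    """

    q: np.ndarray
    ages: np.ndarray = field(default_factory=lambda: _AGES.copy())

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(SEXES), 3, len(self.ages)):
            raise ValueError(f"life table must have shape (2, 3, {len(self.ages)})")
        if (self.q < 0).any() or (self.q > 1).any():
            raise ValueError("life-table probabilities must lie in [0, 1]")

    def annual_probability(self, sex: str, age: float, band: int = 0) -> float:
        idx = int(np.clip(np.floor(age) - AGE_MIN, 0, len(self.ages) - 1))
        return float(self.q[sex_index(sex), band, idx])

    def survival_curve(self, sex: str, band: int = 0) -> np.ndarray:
        """Cumulative P(death age > a) for a = 15..84."""
        return np.cumprod(1.0 - self.q[sex_index(sex), band])

    def life_expectancy(self, sex: str, age: int = 15, band: int = 0) -> float:
        """Expected whole years lived from ``age`` (capped at exit age 85)."""
        idx = age - AGE_MIN
        qs = self.q[sex_index(sex), band, idx:]
        surv = np.cumprod(1.0 - qs)
        return float(surv.sum())

    def to_csv(self, path) -> None:
        rows = []
        for s, sex in enumerate(SEXES):
            for band in range(3):
                for i, age in enumerate(self.ages):
                    rows.append((sex, int(age), band, self.q[s, band, i]))
        pd.DataFrame(rows, columns=["sex", "age", "band", "annual_probability"]) \
            .to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        q = np.zeros((len(SEXES), 3, len(_AGES)))
        for (sex, band), grp in df.groupby(["sex", "band"]):
            grp = grp.sort_values("age")
            q[sex_index(str(sex)), int(band), :] = grp["annual_probability"].to_numpy()
        return cls(q=q)


# ---------------------------------------------------------------------------
# onset hazard
# ---------------------------------------------------------------------------


def lung_cancer_hazard(age: float, history: SmokingHistory,
                       nh: NaturalHistoryParameters,
                       smoking_params=None) -> float:
    """Annual lung-cancer onset hazard for one person at an attained age.

    ``baseline(sex, age) * [1 + beta * pack_years(age)**eta * decay]`` with
    ``decay = exp(-delta * years_since_quit)`` for former smokers and 1
    otherwise; never-smokers are exactly at baseline.
    """
    base = float(nh.baseline_hazard(history.sex, age))
    status = smoking_status(history, age)
    if status == "never":
        return base
    py = pack_years(history, age, smoking_params)
    decay = 1.0
    if status == "former":
        decay = math.exp(-nh.quit_decay_rate * (age - history.quit_age))
    beta = nh.smoking_beta[history.sex]
    return base * (1.0 + beta * py ** nh.smoking_eta * decay)


def unit_hazard_matrix(sex: str, birth_year: int, init: np.ndarray,
                       quit: np.ndarray, bundle: ParameterBundle) -> np.ndarray:
    """Vector kernel: cumulative onset hazard (per-person rows, age columns).

    Row i, column j holds the integrated hazard through age 15+j with the
    per-sex baseline level divided out, so the calibrated level can be
    applied as a pure multiplier (the engine compares these rows against
    exponential draws scaled by 1/level).
    """
    nh = bundle.natural_history
    C = cumulative_cpd(sex, birth_year, bundle.smoking)
    a = np.maximum(_AGES.astype(float) - nh.baseline_age_min, 0.0)
    k, lam_w = nh.baseline_shape, nh.baseline_scale
    base_unit = (k / lam_w) * (a / lam_w) ** (k - 1.0)
    t = _AGES[None, :]
    quit_c = np.minimum(quit, NEVER)[:, None]
    init_c = init[:, None]
    end = np.minimum(t, quit_c)
    py = C[np.clip(end - AGE_MIN, 0, len(C) - 1)] - C[np.clip(init_c - AGE_MIN, 0, len(C) - 1)]
    py = np.where((init_c >= NEVER) | (t < init_c), 0.0, np.maximum(py, 0.0))
    # decay lookup table avoids a large exp() evaluation
    decay_table = np.exp(-nh.quit_decay_rate * np.arange(len(_AGES) + 1))
    qlag = np.clip(t - quit_c, 0, len(_AGES))
    decay = decay_table[qlag]
    beta = nh.smoking_beta[sex]
    if nh.smoking_eta != 1.0:
        py = py ** nh.smoking_eta
    rr = 1.0 + beta * py * decay
    return np.cumsum(rr * base_unit[None, :], axis=1)


def sample_onset_ages(lam_unit: np.ndarray, level: float, exp_draws: np.ndarray,
                      oc_death: np.ndarray) -> np.ndarray:
    """Integer onset ages from cumulative unit-hazard rows; NEVER when none.

    Onset occurs at the first age whose cumulative hazard (times ``level``)
    reaches the person's Exp(1) draw, and must precede both other-cause death
    and the exit age 85.
    """
    if level <= 0.0:
        return np.full(exp_draws.shape, NEVER, dtype=np.int64)
    threshold = exp_draws / level
    onset_idx = (lam_unit < threshold[:, None]).sum(axis=1)
    onset = AGE_MIN + onset_idx
    none = (onset_idx >= lam_unit.shape[1]) | (onset >= np.minimum(oc_death, AGE_MAX + 1))
    return np.where(none, NEVER, onset).astype(np.int64)


# ---------------------------------------------------------------------------
# scalar person-level operations
# ---------------------------------------------------------------------------


def _draw_categorical(probs, u: float) -> int:
    return int(np.searchsorted(np.cumsum(probs), u, side="left"))


def sample_tumor(person: Person, bundle: ParameterBundle,
                 rng: np.random.Generator) -> Optional[Tumor]:
    """Draw the full clinical-pathway tumor outcome for one person.

    Returns None when no onset occurs before other-cause death / exit.  The
    screen-pathway fields are left unset; :func:`screen_detect_outcome`
    fills them when a screening scenario detects the tumor early.
    """
    nh = bundle.natural_history
    history = person.smoking
    init = history.initiation_age if history.initiation_age is not None else NEVER
    quit = history.quit_age if history.quit_age is not None else NEVER
    lam = unit_hazard_matrix(history.sex, history.birth_year,
                             np.array([init]), np.array([quit]), bundle)
    onset = sample_onset_ages(lam, nh.baseline_level[history.sex],
                              rng.exponential(size=1),
                              np.array([person.oc_death_age]))[0]
    if onset == NEVER:
        return None
    sojourn = rng.exponential(nh.sojourn_mean_years)
    detect = onset + sojourn
    period_year = history.birth_year + detect
    histology = HISTOLOGIES[_draw_categorical(
        bundle.histology.distribution(history.sex, int(period_year)), rng.random())]
    stage_idx = _draw_categorical(nh.stage_distribution_clinical, rng.random())
    u_cure = rng.random()
    cured = u_cure < nh.cure_fraction[stage_idx]
    surv = rng.exponential(nh.survival_mean_years[stage_idx])
    death = math.inf if cured else detect + surv
    tumor = Tumor(
        onset_age=float(onset), histology=histology,
        clinical_detection_age=float(detect), stage_clinical=STAGES[stage_idx],
        lc_death_age_clinical=death, cured_clinical=cured,
    )
    # retain the coupling uniform so screen detection can only improve outcome
    tumor._u_cure = u_cure  # type: ignore[attr-defined]
    return tumor


def screen_detect_outcome(tumor: Tumor, detect_age: float,
                          nh: NaturalHistoryParameters,
                          rng: np.random.Generator) -> Tumor:
    """Apply a screen detection during the preclinical window.

    Stage is redrawn from the screen distribution (stochastically earlier),
    and the cure decision reuses the person's clinical-pathway uniform so a
    screen detection can only match or improve the clinical outcome: if not
    cured, the death age stays anchored at the clinical pathway's death age.
    """
    if not (tumor.onset_age <= detect_age < tumor.clinical_detection_age):
        raise ValueError("screen detection must fall in the preclinical window")
    u_cure = getattr(tumor, "_u_cure", None)
    if u_cure is None:
        u_cure = rng.random()
    stage_idx = _draw_categorical(nh.stage_distribution_screen(), rng.random())
    clin_idx = STAGES.index(tumor.stage_clinical)
    cured = u_cure < max(nh.cure_fraction[clin_idx], nh.cure_fraction[stage_idx])
    tumor.detection_age = detect_age
    tumor.stage_screen = STAGES[stage_idx]
    tumor.cured_screen = cured
    tumor.lc_death_age_screen = math.inf if cured else tumor.lc_death_age_clinical
    return tumor


def incidental_detection(person: Person, year: int,
                         nh: NaturalHistoryParameters,
                         rng: np.random.Generator) -> Optional[float]:
    """Bernoulli incidental-imaging detection for one preclinical year.

    Returns the detection age (= attained age in ``year``) when the draw
    fires, else None.  An incidental detection is a clinical-route diagnosis
    at that age: it ends screening eligibility but does not change the death
    age (no stage shift, no lead-time credit).
    """
    tumor = person.tumor
    if tumor is None:
        raise ValueError("person has no tumor")
    age = year - person.birth_year
    if not (tumor.onset_age <= age < tumor.clinical_detection_age):
        return None
    if rng.random() < nh.incidental_detection_rate:
        tumor.incidental_age = float(age)
        return float(age)
    return None


def incidental_delay_years(u: np.ndarray, rate: float) -> np.ndarray:
    """Vector kernel: whole years from onset until incidental detection.

    Geometric with the annual incidental rate; rate 0 never fires (inf),
    rate 1 fires in the first preclinical year (0).
    """
    if rate <= 0.0:
        return np.full(u.shape, np.inf)
    if rate >= 1.0:
        return np.zeros(u.shape)
    return np.floor(np.log(u) / np.log1p(-rate))


def other_cause_death_age(sex: str, history: SmokingHistory | None,
                          life_table: LifeTable, rng: np.random.Generator,
                          band: int | None = None,
                          smoking_params=None,
                          heavy_threshold: float = 20.0) -> int:
    """Sequential annual draws against the person's life-table band.

    Returns the integer age at death, capped at 85 (exit age) when the
    person outlives the table.
    """
    if band is None:
        if history is None or history.initiation_age is None:
            band = 0
        else:
            from .parameters import SmokingParameters
            C = cumulative_cpd(sex, history.birth_year,
                               smoking_params or SmokingParameters())
            from .smoking import smoking_band
            band = int(smoking_band(
                np.array([history.initiation_age]),
                np.array([history.quit_age if history.quit_age is not None else NEVER]),
                C, heavy_threshold)[0])
    for age in range(AGE_MIN, AGE_MAX + 1):
        if rng.random() < life_table.annual_probability(sex, age, band):
            return age
    return AGE_MAX + 1


def sample_oc_death_ages(sex: str, band: np.ndarray, life_table: LifeTable,
                         u: np.ndarray) -> np.ndarray:
    """Vector kernel: other-cause death ages from per-band survival curves.

    Equivalent in distribution to the sequential annual draws: death occurs
    at the first age whose cumulative survival falls strictly below the
    person's uniform; survivors exit at 85.
    """
    out = np.empty(u.shape, dtype=np.int64)
    for b in range(3):
        mask = band == b
        if not mask.any():
            continue
        surv = life_table.survival_curve(sex, b)
        idx = np.searchsorted(-surv, -u[mask], side="right")
        out[mask] = AGE_MIN + idx
    return out
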