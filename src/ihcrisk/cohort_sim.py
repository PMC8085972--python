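"""Synthetic benign-biopsy cohort with configurable marker-driven hazard.

Generates a two-race cohort of men entering follow-up at a benign
prostate biopsy.  Marker expression scores (ln(PPEA x AEI) scale) are
bivariate normal within race with race-specific means — lower in
African-American (AA) men for both markers, matching the magnitudes
observed in benign biopsy series (NF-kB about -5.4 AA vs -4.8 White,
GDF-15 about -7.1 AA vs -6.7 White, cross-marker correlation 0.39).
Prostate-cancer onset follows an exponential (constant-hazard) model
whose log-hazard is linear in NF-kB expression, PSA and inflammation and
optionally quadratic in GDF-15 expression, mirroring the polynomial risk
model

    b0 + PSA*b1 + inflammation*b2 + NFkB*b3 + GDF15*b4 + GDF15^2*b5.

Under incidence-density sampling the matched-pair odds ratio estimates
the hazard ratio, so these coefficients are the recoverable truth for
the downstream conditional-logistic models.

Also provides a direct matched-pair generator (`simulate_matched_pairs`)
for testing the conditional likelihood in isolation, and a bridge
(`expression_to_phantom_spec`) mapping a member's expression score to a
renderable stain phantom.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matched_inference import PairDesign
from .synth_histology import PhantomSpec

__all__ = [
    "AA",
    "WHITE",
    "INFLAMMATION_LEVELS",
    "CohortMember",
    "SimParams",
    "PhantomCalibration",
    "CalibrationError",
    "simulate_cohort",
    "cohort_to_frame",
    "simulate_matched_pairs",
    "expression_to_phantom_spec",
    "write_cohort_csv",
]

AA = "AA"
WHITE = "White"
# inflammation rubric: none (reference), chronic only, chronic and/or acute
INFLAMMATION_LEVELS = ("none", "chronic_only", "chronic_and_or_acute")

_STUDY_END = dt.date(2012, 12, 31)


class CalibrationError(ValueError):
    """Expression score implies a positive-area fraction outside (0, 1]."""


@dataclass(frozen=True)
class CohortMember:
    """One man's entry data, latent marker expressions and outcome."""

    id: int
    race: str
    age_at_entry: float
    entry_date: dt.date
    psa: float
    inflammation: str
    nfkb_expr: float
    gdf15_expr: float
    event_time: float  # years from entry to diagnosis or censoring
    is_case: bool
    prior_cancer: bool = False
    # case-only clinical attributes (NaN / None for non-cases)
    gleason_group: float = float("nan")  # 1-5, NaN when missing
    tumor_stage: float = float("nan")  # 1-4
    batch: int = 0
    platform: int = 0


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the package's study conditions."""

    n: int = 10478
    race_fraction_aa: float = 0.46
    # expression means / SDs on the ln(PPEA x AEI) scale, by race
    nfkb_mean: dict = field(default_factory=lambda: {AA: -5.41, WHITE: -4.79})
    nfkb_sd: dict = field(default_factory=lambda: {AA: 1.59, WHITE: 1.49})
    gdf15_mean: dict = field(default_factory=lambda: {AA: -7.12, WHITE: -6.70})
    gdf15_sd: dict = field(default_factory=lambda: {AA: 1.40, WHITE: 1.38})
    marker_correlation: float = 0.39
    age_mean: float = 64.5
    age_sd: float = 7.3
    psa_log_mean: float = 1.45  # lognormal PSA, median ~4.3 ng/ml
    psa_log_sd: float = 0.60
    inflammation_probs: tuple = (0.392, 0.523, 0.085)
    # hazard coefficients (per unit of the centred covariate)
    beta_nfkb: float = math.log(0.85)
    beta_gdf15: float = math.log(1.06)
    beta_gdf15_sq: float = 0.05
    beta_psa: float = 0.02
    beta_inflammation: tuple = (-0.05, -0.10)  # chronic_only, chronic_and_or_acute
    baseline_hazard: float = 0.006  # events per person-year at covariate means
    entry_start: dt.date = dt.date(1990, 1, 1)
    entry_end: dt.date = dt.date(2011, 12, 31)
    study_end: dt.date = _STUDY_END
    # case-only clinical attribute distributions (grade group 1-5 + missing)
    gleason_probs: tuple = (232, 116, 47, 55, 32, 21)
    stage_probs: tuple = (374, 118, 7, 4)
    n_batches: int = 8
    n_platforms: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.race_fraction_aa <= 1.0:
            raise ValueError("race_fraction_aa must be in [0, 1]")
        if abs(sum(self.inflammation_probs) - 1.0) > 1e-9:
            raise ValueError("inflammation_probs must sum to 1")
        for d in (self.nfkb_sd, self.gdf15_sd):
            if any(s <= 0 for s in d.values()):
                raise ValueError("expression SDs must be > 0")
        if not -1.0 < self.marker_correlation < 1.0:
            raise ValueError("marker_correlation must be in (-1, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")

    @property
    def nfkb_pop_mean(self) -> float:
        f = self.race_fraction_aa
        return f * self.nfkb_mean[AA] + (1 - f) * self.nfkb_mean[WHITE]

    @property
    def gdf15_pop_mean(self) -> float:
        f = self.race_fraction_aa
        return f * self.gdf15_mean[AA] + (1 - f) * self.gdf15_mean[WHITE]

    @property
    def psa_pop_mean(self) -> float:
        return math.exp(self.psa_log_mean + self.psa_log_sd**2 / 2)


def simulate_cohort(params: SimParams) -> list[CohortMember]:
    """Draw a full cohort; deterministic given ``params.seed``.

    Expressions are bivariate normal per race with the configured
    cross-marker correlation; event times are exponential with
    log-hazard linear in the centred covariates (plus an optional
    quadratic GDF-15 term); administrative censoring at study end.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n

    race = np.where(rng.random(n) < params.race_fraction_aa, AA, WHITE)
    age = rng.normal(params.age_mean, params.age_sd, n).clip(40.0, 90.0)
    span_days = (params.entry_end - params.entry_start).days
    entry_offsets = rng.integers(0, span_days + 1, n)
    psa = np.exp(rng.normal(params.psa_log_mean, params.psa_log_sd, n))
    inflam = rng.choice(len(INFLAMMATION_LEVELS), size=n, p=params.inflammation_probs)

    # correlated expressions, race-specific moments
    z = rng.standard_normal((n, 2))
    rho = params.marker_correlation
    z[:, 1] = rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1]
    nfkb = np.empty(n)
    gdf15 = np.empty(n)
    for r in (AA, WHITE):
        m = race == r
        nfkb[m] = params.nfkb_mean[r] + params.nfkb_sd[r] * z[m, 0]
        gdf15[m] = params.gdf15_mean[r] + params.gdf15_sd[r] * z[m, 1]

    g_c = gdf15 - params.gdf15_pop_mean
    lp = (
        params.beta_nfkb * (nfkb - params.nfkb_pop_mean)
        + params.beta_gdf15 * g_c
        + params.beta_gdf15_sq * g_c**2
        + params.beta_psa * (psa - params.psa_pop_mean)
        + np.choose(inflam, (0.0,) + tuple(params.beta_inflammation))
    )
    rate = params.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)

    gleason_p = np.asarray(params.gleason_probs, dtype=float)
    gleason_p /= gleason_p.sum()
    stage_p = np.asarray(params.stage_probs, dtype=float)
    stage_p /= stage_p.sum()

    members: list[CohortMember] = []
    for i in range(n):
        entry = params.entry_start + dt.timedelta(days=int(entry_offsets[i]))
        censor = max((params.study_end - entry).days / 365.25, 1e-6)
        is_case = t_event[i] <= censor
        if is_case:
            g = rng.choice(6, p=gleason_p)  # index 5 = missing grade
            gleason = float("nan") if g == 5 else float(g + 1)
            stage = float(rng.choice(4, p=stage_p) + 1)
        else:
            gleason = float("nan")
            stage = float("nan")
        members.append(
            CohortMember(
                id=i,
                race=str(race[i]),
                age_at_entry=float(age[i]),
                entry_date=entry,
                psa=float(psa[i]),
                inflammation=INFLAMMATION_LEVELS[inflam[i]],
                nfkb_expr=float(nfkb[i]),
                gdf15_expr=float(gdf15[i]),
                event_time=float(t_event[i] if is_case else censor),
                is_case=bool(is_case),
                gleason_group=gleason,
                tumor_stage=stage,
                batch=int(rng.integers(params.n_batches)),
                platform=int(rng.integers(params.n_platforms)),
            )
        )
    return members


def cohort_to_frame(members: list[CohortMember]) -> pd.DataFrame:
    """Tabular view of a cohort (one row per member)."""
    return pd.DataFrame(
        {
            "id": [m.id for m in members],
            "race": [m.race for m in members],
            "age_at_entry": [m.age_at_entry for m in members],
            "entry_date": [m.entry_date.isoformat() for m in members],
            "psa": [m.psa for m in members],
            "inflammation": [m.inflammation for m in members],
            "nfkb_expr": [m.nfkb_expr for m in members],
            "gdf15_expr": [m.gdf15_expr for m in members],
            "event_time": [m.event_time for m in members],
            "is_case": [m.is_case for m in members],
            "gleason_group": [m.gleason_group for m in members],
            "tumor_stage": [m.tumor_stage for m in members],
            "batch": [m.batch for m in members],
            "platform": [m.platform for m in members],
        }
    )


def write_cohort_csv(members: list[CohortMember], path, seed: int | None = None) -> None:
    """Write the cohort as CSV (ISO-8601 dates), seed in a header comment."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# ihcrisk cohort, seed={seed}\n")
        cohort_to_frame(members).to_csv(fh, index=False)


def simulate_matched_pairs(
    n_pairs: int,
    beta: np.ndarray,
    seed: int,
    names: list[str] | None = None,
    sampler=None,
) -> PairDesign:
    """Draw 1:1 matched pairs directly from the conditional model.

    Two candidate members per pair get covariates from ``sampler(rng,
    n, p)`` (standard normal by default); within each pair the case is
    the first member with probability sigmoid(beta . (x1 - x2)) — the
    exact conditional-logistic data-generating process.  Returns the
    case-minus-control difference design, so the fitted coefficients
    target ``beta`` itself.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = beta.size
    rng = np.random.default_rng(seed)
    draw = sampler or (lambda r, n, k: r.standard_normal((n, k)))
    d = draw(rng, n_pairs, p) - draw(rng, n_pairs, p)
    prob_first = 1.0 / (1.0 + np.exp(-(d @ beta)))
    sign = np.where(rng.random(n_pairs) < prob_first, 1.0, -1.0)
    names = names or [f"x{j}" for j in range(p)]
    return PairDesign(d * sign[:, None], names)


@dataclass(frozen=True)
class PhantomCalibration:
    """Mapping from an expression score to a renderable phantom.

    Fixes the mean positive intensity (AEI) per marker and inverts
    expression = ln(PPEA x AEI) for the positive-area fraction.
    """

    aei_brown: float = 0.25  # GDF-15 chromogen
    aei_blue: float = 0.25  # NF-kB chromogen
    width: int = 160
    height: int = 160
    gland_count: int = 8
    gland_radius: float = 20.0
    counterstain_mean_od: float = 0.30


def expression_to_phantom_spec(
    member: CohortMember, calibration: PhantomCalibration | None = None
) -> PhantomSpec:
    """Phantom spec whose ground-truth expression matches the member's.

    GDF-15 maps to the brown chromogen and NF-kB to the blue one.
    Raises :class:`CalibrationError` when an expression score implies a
    positive-area fraction above 1.
    """
    cal = calibration or PhantomCalibration()
    fractions = {}
    for marker, expr, aei in (
        ("brown", member.gdf15_expr, cal.aei_brown),
        ("blue", member.nfkb_expr, cal.aei_blue),
    ):
        f = math.exp(expr) / aei
        if f > 1.0:
            raise CalibrationError(
                f"expression {expr:.3f} with AEI {aei} implies {marker} "
                f"positive fraction {f:.3f} > 1"
            )
        fractions[marker] = f
    if fractions["brown"] + fractions["blue"] > 1.0 + 1e-9:
        raise CalibrationError("combined positive fractions exceed tissue area")
    return PhantomSpec(
        width=cal.width,
        height=cal.height,
        gland_count=cal.gland_count,
        gland_radius=cal.gland_radius,
        brown_positive_fraction=fractions["brown"],
        blue_positive_fraction=fractions["blue"],
        brown_mean_od=cal.aei_brown,
        blue_mean_od=cal.aei_blue,
        counterstain_mean_od=cal.counterstain_mean_od,
        noise_sd=0.0,
        seed=member.id,
    )
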