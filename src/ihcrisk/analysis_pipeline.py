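"""Full study replica: quantification to risk models from one config.

Orchestrates the chain: simulate (or load) a cohort, optionally render
and quantify stain phantoms for a subset of subjects to exercise the
imaging stage, build the incidence-density matched case-control sample,
estimate race-specific control-based quartile cutpoints, and fit the
battery of conditional-logistic models — unadjusted and adjusted
continuous, quartile, and trend models, the same models within strata
defined by case aggressiveness, age and follow-up time, and the nested
polynomial (nonlinear) models selected by likelihood-ratio tests.  Also
provides the unmatched operations: batch/platform-adjusted group
comparisons of expression and the cross-marker correlation, plus a
descriptive baseline table (with a packaged fixture of published
counts for worked examples).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import stain_quant
from .cohort_sim import (
    INFLAMMATION_LEVELS,
    CohortMember,
    PhantomCalibration,
    SimParams,
    expression_to_phantom_spec,
    simulate_cohort,
)
from .matched_inference import (
    FitResult,
    LRTResult,
    NotIdentifiableError,
    PairDesign,
    SeparationError,
    fit_clogit,
    lrt,
    wald_or_ci,
)
from .study_design import (
    MatchCriteria,
    MatchedPair,
    QuartileCuts,
    assign_quartile,
    eligible_cases,
    incidence_density_match,
    quartile_cuts,
)
from .synth_histology import render_phantom

logger = logging.getLogger("ihcrisk")

__all__ = [
    "SAMPLE_FLOW",
    "Table1Fixture",
    "StudyConfig",
    "StudyResults",
    "EmptyStudyError",
    "ConfoundingError",
    "load_table1_fixture",
    "descriptive_table",
    "is_aggressive",
    "case_stratum",
    "build_pair_design",
    "fit_model_table",
    "stratified_models",
    "polynomial_model_search",
    "compare_expression_groups",
    "correlate_markers",
    "run_full_analysis",
]

# Published sample-flow counts of the source study (fixture for worked
# examples; our simulations produce their own flow).
SAMPLE_FLOW = {
    "cohort_size": 10478,
    "potentially_eligible_cases": 725,
    "matched_pairs": 673,
    "unmatched_cases": 52,
    "unmatched_reasons": {
        "malignancy_on_reexamination": 19,
        "prior_prostate_cancer": 5,
        "prior_other_cancer": 4,
        "no_eligible_controls": 14,
        "no_analyzable_tissue": 8,
        "diagnosis_unconfirmed": 2,
    },
    "stained_pairs": 508,
    "removed_incomplete": 5,
    "analytic_pairs": 503,
}

MARKERS = ("nfkb", "gdf15")
ADJUSTED_COVARIATES = ("psa", "inflam_chronic", "inflam_acute")


class EmptyStudyError(RuntimeError):
    """The configuration yields no cases / no matched pairs."""


class ConfoundingError(ValueError):
    """A nuisance factor is perfectly confounded with the grouping."""


# ---------------------------------------------------------------------------
# Table-1 fixture and descriptive table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table1Fixture:
    """Packaged baseline counts of the 503-pair analytic sample."""

    counts: pd.DataFrame
    n_pairs: int = 503

    def __post_init__(self) -> None:
        c = self.counts
        stage = c.loc[c.variable == "tumor_stage", "cases"].sum()
        gleason = c.loc[c.variable == "gleason_group", "cases"].sum()
        inflam = c[c.variable == "inflammation"]
        if stage != self.n_pairs:
            raise ValueError(f"stage counts sum to {stage}, expected {self.n_pairs}")
        if gleason != self.n_pairs - self.gleason_missing:
            raise ValueError("Gleason counts inconsistent with missing-grade count")
        for arm in ("cases", "controls"):
            if inflam[arm].sum() != self.n_pairs:
                raise ValueError(f"inflammation {arm} counts must sum to {self.n_pairs}")

    @property
    def gleason_missing(self) -> int:
        c = self.counts
        return self.n_pairs - int(c.loc[c.variable == "gleason_group", "cases"].sum())


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged baseline-characteristics fixture."""
    with resources.files("ihcrisk.data").joinpath("table1_fixture.csv").open() as fh:
        counts = pd.read_csv(fh)
    return Table1Fixture(counts=counts)


def _round_half_up(x: float, digits: int) -> float:
    factor = 10**digits
    return math.floor(x * factor + 0.5) / factor


def descriptive_table(source: Table1Fixture | list[MatchedPair]) -> pd.DataFrame:
    """Counts and percentages by arm.

    Percent denominators are the arm totals including subjects with a
    missing category (so categories with missing data sum to < 100%).
    Display percentages are rounded half-up to one decimal; the
    unrounded value is retained in ``percent_exact``.
    """
    if isinstance(source, Table1Fixture):
        counts = source.counts.copy()
        n = {"cases": source.n_pairs, "controls": source.n_pairs}
    else:
        counts = _pairs_to_counts(source)
        n = {"cases": len(source), "controls": len(source)}
    rows = []
    for _, r in counts.iterrows():
        for arm in ("cases", "controls"):
            val = r[arm]
            if pd.isna(val):
                continue
            pct = 100.0 * float(val) / n[arm] if n[arm] else 0.0
            rows.append(
                {
                    "variable": r["variable"],
                    "response": r["response"],
                    "arm": arm,
                    "count": int(val),
                    "percent_exact": pct,
                    "percent": _round_half_up(pct, 1),
                }
            )
    return pd.DataFrame(rows)


def _pairs_to_counts(pairs: list[MatchedPair]) -> pd.DataFrame:
    rows = []
    cases = [p.case for p in pairs]
    controls = [p.control for p in pairs]
    for race in sorted({m.race for m in cases}):
        rows.append(
            {
                "variable": "race",
                "response": race,
                "cases": sum(m.race == race for m in cases),
                "controls": sum(m.race == race for m in controls),
            }
        )
    for level in INFLAMMATION_LEVELS:
        rows.append(
            {
                "variable": "inflammation",
                "response": level,
                "cases": sum(m.inflammation == level for m in cases),
                "controls": sum(m.inflammation == level for m in controls),
            }
        )
    for stage in (1, 2, 3, 4):
        rows.append(
            {
                "variable": "tumor_stage",
                "response": str(stage),
                "cases": sum(m.tumor_stage == stage for m in cases),
                "controls": float("nan"),
            }
        )
    for g in (1, 2, 3, 4, 5):
        rows.append(
            {
                "variable": "gleason_group",
                "response": str(g),
                "cases": sum(m.gleason_group == g for m in cases),
                "controls": float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Strata
# ---------------------------------------------------------------------------


def is_aggressive(case: CohortMember) -> bool:
    """Aggressive disease: Gleason group >= 3, or PSA >= 20, or stage >= 3."""
    gleason = case.gleason_group >= 3 if np.isfinite(case.gleason_group) else False
    stage = case.tumor_stage >= 3 if np.isfinite(case.tumor_stage) else False
    return bool(gleason or case.psa >= 20.0 or stage)


def case_stratum(pair: MatchedPair, rule: str) -> str:
    """Stratum label for a pair; both members take the case's stratum."""
    case = pair.case
    if rule == "aggressive":
        return "aggressive" if is_aggressive(case) else "non_aggressive"
    if rule == "age":
        return "old" if case.age_at_entry >= 65.0 else "young"
    if rule == "time":
        return "late" if pair.index_time >= 3.7 else "early"
    raise ValueError(f"unknown stratification rule '{rule}'")


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _member_covariates(
    m: CohortMember,
    cuts: dict[tuple[str, str], QuartileCuts] | None,
    center: dict[str, float],
) -> dict[str, float]:
    cov = {
        "nfkb": m.nfkb_expr,
        "gdf15": m.gdf15_expr,
        "psa": m.psa,
        "inflam_chronic": float(m.inflammation == "chronic_only"),
        "inflam_acute": float(m.inflammation == "chronic_and_or_acute"),
        "gdf15_sq": (m.gdf15_expr - center.get("gdf15", 0.0)) ** 2,
        "gdf15_cub": (m.gdf15_expr - center.get("gdf15", 0.0)) ** 3,
        "nfkb_sq": (m.nfkb_expr - center.get("nfkb", 0.0)) ** 2,
        "nfkb_cub": (m.nfkb_expr - center.get("nfkb", 0.0)) ** 3,
    }
    if cuts is not None:
        for marker in MARKERS:
            q = assign_quartile(cov[marker], cuts[(m.race, marker)])
            cov[f"{marker}_trend"] = float(q)
            for k in (2, 3, 4):
                cov[f"{marker}_q{k}"] = float(q == k)
    return cov


def control_quartile_cuts(
    pairs: list[MatchedPair],
) -> dict[tuple[str, str], QuartileCuts]:
    """Race-specific cutpoints from the control arm of the analytic pairs."""
    cuts: dict[tuple[str, str], QuartileCuts] = {}
    controls = [p.control for p in pairs]
    for race in sorted({c.race for c in controls}):
        for marker in MARKERS:
            values = np.array(
                [getattr(c, f"{marker}_expr") for c in controls if c.race == race]
            )
            cuts[(race, marker)] = quartile_cuts(values, race, marker)
    return cuts


def build_pair_design(
    pairs: list[MatchedPair],
    terms: list[str],
    cuts: dict[tuple[str, str], QuartileCuts] | None = None,
    center: dict[str, float] | None = None,
) -> PairDesign:
    """Case-minus-control difference design for the named terms.

    Polynomial terms (``gdf15_sq`` etc.) are computed on the marker
    centred at ``center[marker]`` (default 0) for numerical stability.
    """
    center = center or {}
    diffs = np.empty((len(pairs), len(terms)))
    for i, p in enumerate(pairs):
        xc = _member_covariates(p.case, cuts, center)
        xk = _member_covariates(p.control, cuts, center)
        diffs[i] = [xc[t] - xk[t] for t in terms]
    return PairDesign(diffs, list(terms))


# ---------------------------------------------------------------------------
# Model batteries
# ---------------------------------------------------------------------------


def _fit(pairs, terms, cuts=None, center=None) -> FitResult:
    return fit_clogit(build_pair_design(pairs, terms, cuts, center))


def fit_model_table(
    pairs: list[MatchedPair],
    cuts: dict[tuple[str, str], QuartileCuts],
    adjusted: bool,
) -> pd.DataFrame:
    """Continuous, quartile and trend models for both markers.

    Adjusted models add PSA, two inflammation indicators and the other
    marker; unadjusted models contain the marker terms alone.  Rows are
    (model, term, OR, lo, hi, p) mirroring the published table layout.
    """
    rows = []
    for marker in MARKERS:
        other = [m for m in MARKERS if m != marker]
        extra = list(ADJUSTED_COVARIATES) + other if adjusted else []

        fit = _fit(pairs, [marker] + extra, cuts)
        rows.append(_row(f"{marker}_continuous", marker, fit))

        qterms = [f"{marker}_q{k}" for k in (2, 3, 4)]
        fit = _fit(pairs, qterms + extra, cuts)
        rows.extend(_row(f"{marker}_quartile", t, fit) for t in qterms)

        fit = _fit(pairs, [f"{marker}_trend"] + extra, cuts)
        rows.append(_row(f"{marker}_trend", f"{marker}_trend", fit))
    return pd.DataFrame(rows)


def _row(model: str, term: str, fit: FitResult) -> dict:
    or_, lo, hi, p = wald_or_ci(fit, term)
    return {
        "model": model,
        "term": term,
        "or": or_,
        "lo": lo,
        "hi": hi,
        "p": p,
        "or_display": _round_half_up(or_, 2),
        "n_pairs": fit.n_pairs,
    }


def stratified_models(
    pairs: list[MatchedPair],
    rule: str,
    cuts: dict[tuple[str, str], QuartileCuts],
    min_pairs: int = 10,
) -> dict[str, pd.DataFrame]:
    """Adjusted model battery within case-defined strata.

    Strata with fewer than ``min_pairs`` informative pairs are skipped
    with a warning.  The union of strata is a partition of the pairs.
    """
    strata: dict[str, list[MatchedPair]] = {}
    for p in pairs:
        strata.setdefault(case_stratum(p, rule), []).append(p)
    out: dict[str, pd.DataFrame] = {}
    for label, sub in sorted(strata.items()):
        if len(sub) < min_pairs:
            logger.warning(
                "stratum %s/%s skipped: only %d pairs (< %d)", rule, label, len(sub), min_pairs
            )
            continue
        try:
            out[label] = fit_model_table(sub, cuts, adjusted=True)
        except (SeparationError, NotIdentifiableError) as exc:
            logger.warning("stratum %s/%s skipped: %s", rule, label, exc)
    return out


def polynomial_model_search(
    pairs: list[MatchedPair],
    marker: str,
    cuts: dict[tuple[str, str], QuartileCuts],
    alpha: float = 0.05,
    max_order: int = 3,
) -> pd.DataFrame:
    """Forward polynomial selection by likelihood-ratio tests.

    Starting from the adjusted linear model, add a second-order then a
    third-order term for the marker, each tested (df = 1) against the
    previous model; stop at the first p >= alpha.  Polynomial terms are
    centred at the control-arm marker mean.
    """
    other = [m for m in MARKERS if m != marker]
    base_terms = [marker] + list(ADJUSTED_COVARIATES) + other
    center = {
        marker: float(
            np.mean([getattr(p.control, f"{marker}_expr") for p in pairs])
        )
    }
    suffix = {2: "_sq", 3: "_cub"}
    fits: list[tuple[int, FitResult, LRTResult | None]] = [
        (1, _fit(pairs, base_terms, cuts, center), None)
    ]
    terms = list(base_terms)
    for order in range(2, max_order + 1):
        terms = terms + [f"{marker}{suffix[order]}"]
        full = _fit(pairs, terms, cuts, center)
        test = lrt(full, fits[-1][1])
        fits.append((order, full, test))
        if test.p_value >= alpha:
            break
    selected = 1
    for order, _, test in fits[1:]:
        if test.p_value < alpha:
            selected = order
        else:
            break
    return pd.DataFrame(
        {
            "order": [o for o, _, _ in fits],
            "loglik": [f.loglik for _, f, _ in fits],
            "lrt_statistic": [t.statistic if t else float("nan") for _, _, t in fits],
            "lrt_p": [t.p_value if t else float("nan") for _, _, t in fits],
            "selected": [o == selected for o, _, _ in fits],
        }
    )


# ---------------------------------------------------------------------------
# Unmatched operations: group comparison and correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    adjusted_means: dict[str, float]
    difference: float  # second group minus first (alphabetical order)
    se: float
    p_value: float
    n: int


def compare_expression_groups(
    df: pd.DataFrame,
    value: str,
    group: str,
    batch: str = "batch",
    platform: str = "platform",
) -> GroupComparison:
    """Linear model ``value ~ group + batch + platform`` (two groups).

    Hand-rolled least squares with indicator coding; adjusted group
    means are predictions at balanced nuisance weights (each batch and
    platform level weighted equally).  Two-sided p for the group effect
    from the t distribution.
    """
    levels = sorted(df[group].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    batches = sorted(df[batch].astype(str).unique())
    platforms = sorted(df[platform].astype(str).unique())
    if len(batches) < 2:
        raise ValueError("need >= 2 batches represented")

    y = df[value].to_numpy(dtype=float)
    cols = [np.ones(len(df)), (df[group].astype(str) == levels[1]).to_numpy(float)]
    names = ["intercept", "group"]
    for b in batches[1:]:
        cols.append((df[batch].astype(str) == b).to_numpy(float))
        names.append(f"batch_{b}")
    for pl in platforms[1:]:
        cols.append((df[platform].astype(str) == pl).to_numpy(float))
        names.append(f"platform_{pl}")
    X = np.column_stack(cols)

    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < X.shape[1]:
        raise ConfoundingError("batch/platform perfectly confounded with group")
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(xtx)

    j = names.index("group")
    se = math.sqrt(cov[j, j])
    t = beta[j] / se
    p = 2.0 * stats.t.sf(abs(t), dof)

    # balanced nuisance weights: average each batch/platform effect
    # (reference level contributes 0)
    nuisance = sum(beta[names.index(f"batch_{b}")] for b in batches[1:]) / len(batches)
    nuisance += sum(
        beta[names.index(f"platform_{pl}")] for pl in platforms[1:]
    ) / len(platforms)
    means = {
        levels[0]: float(beta[0] + nuisance),
        levels[1]: float(beta[0] + beta[j] + nuisance),
    }
    return GroupComparison(means, float(beta[j]), se, float(p), len(y))


def correlate_markers(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of the two markers' expression with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired expression values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a marker; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Everything a full run needs; all randomness flows from the seeds."""

    sim_params: SimParams = field(default_factory=SimParams)
    criteria: MatchCriteria = field(default_factory=MatchCriteria)
    match_seed: int = 1
    phantom_subjects: int = 0  # render+quantify phantoms for this many members
    calibration: PhantomCalibration = field(default_factory=PhantomCalibration)
    out_dir: str | None = None


@dataclass(frozen=True)
class StudyResults:
    """Bundle of every table the pipeline produces."""

    pairs: list[MatchedPair]
    unmatched: list
    cuts: dict[tuple[str, str], QuartileCuts]
    models: dict[str, pd.DataFrame]  # unadjusted / adjusted
    strata: dict[str, dict[str, pd.DataFrame]]
    nonlinear: dict[str, pd.DataFrame]
    correlation: tuple[float, float]
    race_comparisons: dict[str, GroupComparison]
    descriptive: pd.DataFrame
    phantom_roundtrip: pd.DataFrame | None


def _phantom_roundtrip(members, calibration) -> pd.DataFrame:
    """Render phantoms for members and re-quantify them end to end."""
    rows = []
    cfg = stain_quant.QuantConfig()
    for m in members:
        spec = expression_to_phantom_spec(m, calibration)
        rgb, truth = render_phantom(spec, cfg.basis)
        quants = stain_quant.quantify_image(rgb, cfg)
        rows.append(
            {
                "id": m.id,
                "nfkb_true": m.nfkb_expr,
                "nfkb_quantified": quants[stain_quant.BLUE].expression_level,
                "gdf15_true": m.gdf15_expr,
                "gdf15_quantified": quants[stain_quant.BROWN].expression_level,
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(config: StudyConfig) -> StudyResults:
    """Run the whole study replica; byte-identical across re-runs."""
    logger.info("simulating cohort (n=%d)", config.sim_params.n)
    cohort = simulate_cohort(config.sim_params)

    cases = eligible_cases(cohort, config.criteria)
    if not cases:
        raise EmptyStudyError("simulation produced no eligible cases")
    logger.info("matching %d eligible cases", len(cases))
    pairs, unmatched = incidence_density_match(
        cases, cohort, config.criteria, seed=config.match_seed
    )
    if not pairs:
        raise EmptyStudyError("no case could be matched to a control")

    cuts = control_quartile_cuts(pairs)
    models = {
        "unadjusted": fit_model_table(pairs, cuts, adjusted=False),
        "adjusted": fit_model_table(pairs, cuts, adjusted=True),
    }
    strata = {rule: stratified_models(pairs, rule, cuts) for rule in ("aggressive", "age", "time")}
    nonlinear = {m: polynomial_model_search(pairs, m, cuts) for m in MARKERS}

    members = [p.case for p in pairs] + [p.control for p in pairs]
    nfkb = np.array([m.nfkb_expr for m in members])
    gdf15 = np.array([m.gdf15_expr for m in members])
    correlation = correlate_markers(nfkb, gdf15)

    df = pd.DataFrame(
        {
            "race": [m.race for m in members],
            "batch": [m.batch for m in members],
            "platform": [m.platform for m in members],
            "nfkb": nfkb,
            "gdf15": gdf15,
        }
    )
    race_comparisons = {
        m: compare_expression_groups(df, m, "race") for m in MARKERS
    }

    phantom_df = None
    if config.phantom_subjects > 0:
        subset = [p.control for p in pairs[: config.phantom_subjects]]
        phantom_df = _phantom_roundtrip(subset, config.calibration)

    results = StudyResults(
        pairs=pairs,
        unmatched=unmatched,
        cuts=cuts,
        models=models,
        strata=strata,
        nonlinear=nonlinear,
        correlation=correlation,
        race_comparisons=race_comparisons,
        descriptive=descriptive_table(pairs),
        phantom_roundtrip=phantom_df,
    )
    if config.out_dir:
        _write_results(results, Path(config.out_dir))
    return results


def pairs_to_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    """Wide one-row-per-pair table (case_* and control_* columns)."""
    rows = []
    for p in pairs:
        row = {"index_time": p.index_time}
        for prefix, m in (("case", p.case), ("control", p.control)):
            row.update(
                {
                    f"{prefix}_id": m.id,
                    f"{prefix}_race": m.race,
                    f"{prefix}_age": m.age_at_entry,
                    f"{prefix}_entry_date": m.entry_date.isoformat(),
                    f"{prefix}_psa": m.psa,
                    f"{prefix}_inflammation": m.inflammation,
                    f"{prefix}_nfkb": m.nfkb_expr,
                    f"{prefix}_gdf15": m.gdf15_expr,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _write_results(results: StudyResults, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pairs_to_frame(results.pairs).to_csv(out / "pairs.csv", index=False)
    with open(out / "unmatched.log", "w") as fh:
        for u in results.unmatched:
            fh.write(f"{u.case.id}\t{u.reason}\n")
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for name, table in results.models.items():
        table.to_csv(models_dir / f"{name}.csv", index=False)
    strata_dir = out / "strata"
    strata_dir.mkdir(exist_ok=True)
    for rule, tables in results.strata.items():
        for label, table in tables.items():
            table.to_csv(strata_dir / f"{rule}_{label}.csv", index=False)
    for marker, table in results.nonlinear.items():
        table.to_csv(models_dir / f"nonlinear_{marker}.csv", index=False)
    results.descriptive.to_csv(out / "descriptive.csv", index=False)
    if results.phantom_roundtrip is not None:
        results.phantom_roundtrip.to_csv(out / "phantom_roundtrip.csv", index=False)
    report = {
        "n_pairs": len(results.pairs),
        "n_unmatched": len(results.unmatched),
        "correlation_r": results.correlation[0],
        "correlation_p": results.correlation[1],
        "race_comparisons": {
            m: {
                "difference": c.difference,
                "p": c.p_value,
                "adjusted_means": c.adjusted_means,
            }
            for m, c in results.race_comparisons.items()
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def output_checksum(out_dir: str | Path) -> str:
    """SHA-256 over all files in an output directory (re-run check)."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).rglob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
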