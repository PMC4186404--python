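"""Concentration-response modelling and efficacy ranking.

The pharmacodynamic arm of the analysis fits the four-parameter logistic
(4PL, Hill) model to concentration-response measurements,

    E(D) = Emin + (Emax - Emin) / (1 + (EC50 / D) ** slope)

where ``Emax`` is the maximal drug effect (the plateau at saturating
concentration), ``Emin`` the minimal effect, ``EC50`` the concentration
producing the half-maximal change, and ``slope`` the Hill coefficient.
Responses here are signed percent changes (reductions of protein
content/muscle weight, or block of KATP current), so both asymptotes are
typically negative.

Fitting is done by nonlinear least squares in log10-concentration space
with a multi-start grid over (EC50, slope): several of the published
curves have very shallow slopes (n ~ 0.3) for which single-start fits are
fragile.  Drugs are then ranked by potency/efficacy, with a ``>`` between
adjacent drugs when the compared parameter differs significantly (two-
sided z-test on estimate +/- SE at alpha = 0.05) and ``>=`` otherwise.

The module also carries the small viability arithmetic used alongside the
curves: percent change versus contralateral control, the fiber-death
classification (>40% morphology change AND failed contractility), and the
mortality percentage dead/total x 100.
"""

from __future__ import annotations

import enum
import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "HillParams",
    "HillFit",
    "DosePoint",
    "DoseResponseDataset",
    "AnovaResult",
    "EfficacyRanking",
    "CompareOn",
    "hill_4pl",
    "fit_4pl",
    "fit_many",
    "fits_to_frame",
    "one_way_anova",
    "two_way_anova",
    "rank_efficacy",
    "percent_change_vs_control",
    "FiberObservation",
    "classify_fiber_death",
    "mortality_percent",
]


@dataclass(frozen=True)
class HillParams:
    """4PL parameters: asymptotes in %, EC50 in mol/L, Hill slope."""

    emax: float
    emin: float
    ec50: float
    slope: float

    def __post_init__(self) -> None:
        if not (self.ec50 > 0):
            raise ValueError(f"EC50 must be positive, got {self.ec50}")
        if not (self.slope > 0):
            raise ValueError(f"slope must be positive, got {self.slope}")
        if not (math.isfinite(self.emax) and math.isfinite(self.emin)):
            raise ValueError("Emax and Emin must be finite")


@dataclass(frozen=True)
class HillFit:
    """Result of one 4PL fit.

    ``se`` maps parameter name -> standard error (from the inverse
    curvature at the optimum); ``ill_conditioned`` marks degenerate data
    (for example a flat curve, where EC50 is unidentifiable).
    """

    params: HillParams | None
    se: Mapping[str, float]
    rss: float
    converged: bool
    n_points: int
    ill_conditioned: bool = False


@dataclass(frozen=True)
class DosePoint:
    dose: float  # mol/L
    response: float  # percent change
    replicate_id: int = 0


@dataclass
class DoseResponseDataset:
    """Replicated concentration-response measurements for one drug x muscle."""

    drug: str
    muscle: str
    points: list[DosePoint]

    def __post_init__(self) -> None:
        self.points = [p if isinstance(p, DosePoint) else DosePoint(*p) for p in self.points]
        if any(p.dose <= 0 for p in self.points):
            raise ValueError("all doses must be positive (mol/L)")

    @property
    def doses(self) -> np.ndarray:
        return np.array([p.dose for p in self.points], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([p.response for p in self.points], dtype=float)


def hill_4pl(dose: float | np.ndarray, params: HillParams) -> float | np.ndarray:
    """Evaluate the 4PL at ``dose`` (mol/L); dose 0 returns Emin by continuity."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    with np.errstate(divide="ignore"):
        out = params.emin + (params.emax - params.emin) / (
            1.0 + np.power(params.ec50 / np.where(dose > 0, dose, np.inf), params.slope)
        )
    out = np.where(dose > 0, out, params.emin)
    return float(out) if out.ndim == 0 else out


def _model_logx(x: np.ndarray, emin: float, emax: float, log_ec50: float, slope: float) -> np.ndarray:
    # (EC50/D)^slope == 10 ** (slope * (log10 EC50 - log10 D))
    return emin + (emax - emin) / (1.0 + 10.0 ** (slope * (log_ec50 - x)))


class _FitFailure(Exception):
    pass


def _single_fit(x, y, p0, bounds):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        try:
            popt, pcov = optimize.curve_fit(
                _model_logx, x, y, p0=p0, bounds=bounds, maxfev=20000, method="trf"
            )
        except (RuntimeError, ValueError) as exc:
            raise _FitFailure(str(exc)) from exc
    resid = y - _model_logx(x, *popt)
    return popt, pcov, float(resid @ resid)


def fit_4pl(data: DoseResponseDataset, init: HillParams | None = None) -> HillFit:
    """Nonlinear least-squares 4PL fit in log10-dose space.

    Initialization is data-driven (Emin from the lowest-dose mean, Emax
    from the highest, EC50 at the geometric mid-dose, slope 1) and is
    supplemented by a 5x5 multi-start grid over (EC50, slope).  A fit that
    fails everywhere is returned with ``converged=False`` rather than
    raising.
    """
    doses = data.doses
    y = data.responses
    if len(np.unique(doses)) < 4:
        raise ValueError("at least 4 distinct doses are required for a 4-parameter fit")
    x = np.log10(doses)

    order = np.argsort(x)
    lo_mask = x == x.min()
    hi_mask = x == x.max()
    emin0 = float(y[lo_mask].mean())
    emax0 = float(y[hi_mask].mean())
    mid0 = float((x.min() + x.max()) / 2.0)

    span = x.max() - x.min()
    bounds = (
        [-1e4, -1e4, x.min() - 3.0, 1e-3],
        [1e4, 1e4, x.max() + 3.0, 50.0],
    )

    starts = [(emin0, emax0, mid0, 1.0)]
    ec50_grid = np.linspace(x.min() + 0.1 * span, x.max() - 0.1 * span, 5)
    slope_grid = (0.25, 0.5, 1.0, 2.0, 4.0)
    starts += [(emin0, emax0, g, s) for g, s in itertools.product(ec50_grid, slope_grid)]
    if init is not None:
        starts.insert(0, (init.emin, init.emax, math.log10(init.ec50), init.slope))

    best = None
    for p0 in starts:
        p0 = list(np.clip(p0, bounds[0], bounds[1]))
        try:
            popt, pcov, rss = _single_fit(x, y, p0, bounds)
        except _FitFailure:
            continue
        if best is None or rss < best[2] - 1e-12:
            best = (popt, pcov, rss)

    if best is None:
        return HillFit(params=None, se={}, rss=math.nan, converged=False, n_points=len(y))

    popt, pcov, rss = best
    emin, emax, log_ec50, slope = popt
    ec50 = 10.0 ** log_ec50
    diag = np.diag(pcov)
    ill = bool(not np.all(np.isfinite(diag)) or np.any(diag < 0))
    se_log = np.sqrt(np.abs(diag))
    se = {
        "emin": float(se_log[0]),
        "emax": float(se_log[1]),
        # delta method: SE(EC50) = ln(10) * EC50 * SE(log10 EC50)
        "ec50": float(math.log(10.0) * ec50 * se_log[2]),
        "slope": float(se_log[3]),
    }
    # a flat curve leaves EC50/slope unidentifiable
    if abs(emax - emin) < 1e-8 * max(1.0, abs(emax) + abs(emin)) or se["slope"] > 1e3:
        ill = True
    params = HillParams(emax=float(emax), emin=float(emin), ec50=float(ec50), slope=float(slope))
    return HillFit(params=params, se=se, rss=rss, converged=True, n_points=len(y), ill_conditioned=ill)


def fit_many(datasets: Iterable[DoseResponseDataset]) -> dict[tuple[str, str], HillFit]:
    """Fit each dataset; keys are (drug, muscle). Per-curve failures yield
    ``converged=False`` entries and do not stop the batch."""
    out: dict[tuple[str, str], HillFit] = {}
    for data in datasets:
        try:
            out[(data.drug, data.muscle)] = fit_4pl(data)
        except ValueError:
            out[(data.drug, data.muscle)] = HillFit(
                params=None, se={}, rss=math.nan, converged=False, n_points=len(data.points)
            )
    return out


def fits_to_frame(fits: Mapping[tuple[str, str], HillFit]) -> pd.DataFrame:
    """Tabulate a batch of fits (one row per drug x muscle)."""
    rows = []
    for (drug, muscle), fit in fits.items():
        p = fit.params
        rows.append(
            {
                "drug": drug,
                "muscle": muscle,
                "emax_pct": p.emax if p else np.nan,
                "emin_pct": p.emin if p else np.nan,
                "ec50_mol_per_L": p.ec50 if p else np.nan,
                "slope": p.slope if p else np.nan,
                "se_emax": fit.se.get("emax", np.nan),
                "se_emin": fit.se.get("emin", np.nan),
                "se_ec50": fit.se.get("ec50", np.nan),
                "se_slope": fit.se.get("slope", np.nan),
                "rss": fit.rss,
                "n_points": fit.n_points,
                "converged": fit.converged,
                "ill_conditioned": fit.ill_conditioned,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    """Variance-ratio test: F = MS(treatments) / MS(residuals)."""

    ms_treatment: float
    ms_residual: float
    f_ratio: float
    df: tuple[int, int]
    p_value: float
    significant: bool  # at alpha = 0.05


def one_way_anova(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """Standard one-way ANOVA decomposition across treatment groups.

    A degenerate layout with zero within-group variance everywhere is
    flagged with an infinite F ratio rather than an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_obs = np.concatenate(arrays)
    grand = all_obs.mean()
    k = len(arrays)
    n_total = len(all_obs)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f = math.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        ms_treatment=float(ms_b),
        ms_residual=float(ms_w),
        f_ratio=float(f),
        df=(df_b, df_w),
        p_value=p,
        significant=p < alpha,
    )


def two_way_anova(
    data: pd.DataFrame,
    response: str = "response",
    treatment: str = "treatment",
    time: str = "time",
    alpha: float = 0.05,
    max_empty_cell_fraction: float = 0.2,
) -> dict[str, AnovaResult]:
    """Two-way additive ANOVA (treatment + time main effects, no interaction).

    Matches comparing drug treatments across incubation times; returns one
    :class:`AnovaResult` per factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data.rename(columns={response: "_y", treatment: "_trt", time: "_time"}).copy()
    cells = df.groupby(["_trt", "_time"], observed=True).size()
    n_levels = df["_trt"].nunique() * df["_time"].nunique()
    if n_levels == 0:
        raise ValueError("empty design")
    empty_frac = 1.0 - len(cells) / n_levels
    if empty_frac > max_empty_cell_fraction:
        raise ValueError(f"{empty_frac:.0%} of treatment x time cells are empty")

    model = smf.ols("_y ~ C(_trt) + C(_time)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ms_resid = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    out: dict[str, AnovaResult] = {}
    for factor, row_name in (("treatment", "C(_trt)"), ("time", "C(_time)")):
        row = table.loc[row_name]
        ms = row["sum_sq"] / row["df"]
        p = float(row["PR(>F)"])
        out[factor] = AnovaResult(
            ms_treatment=float(ms),
            ms_residual=float(ms_resid),
            f_ratio=float(row["F"]),
            df=(int(row["df"]), int(table.loc["Residual", "df"])),
            p_value=p,
            significant=p < alpha,
        )
    return out


# ---------------------------------------------------------------------------
# Efficacy ranking
# ---------------------------------------------------------------------------

class CompareOn(enum.Enum):
    EC50 = "ec50"
    EMAX = "emax"
    BOTH = "both"


@dataclass(frozen=True)
class EfficacyRanking:
    """Ordered drugs with '>' / '>=' relations between neighbours."""

    order: tuple[str, ...]
    relations: tuple[str, ...]  # length len(order) - 1, each ">" or "≥"
    anova: AnovaResult | None = None
    warnings: tuple[str, ...] = ()

    def format(self, labels: Mapping[str, str] | None = None) -> str:
        labels = labels or {}
        parts = []
        for i, drug in enumerate(self.order):
            parts.append(labels.get(drug, drug))
            if i < len(self.relations):
                parts.append(self.relations[i])
        return "".join(parts)


def _z_significant(e1: float, se1: float, e2: float, se2: float, alpha: float) -> bool:
    denom = math.hypot(se1, se2)
    if denom == 0:
        return e1 != e2
    z = abs(e1 - e2) / denom
    return z > stats.norm.ppf(1 - alpha / 2)


def rank_efficacy(
    fits: Mapping[str, HillFit],
    compare_on: CompareOn = CompareOn.EC50,
    alpha: float = 0.05,
    anova: AnovaResult | None = None,
) -> EfficacyRanking:
    """Order drugs by potency/efficacy and assign '>' / '>=' relations.

    Potency ranking (EC50): smaller EC50 first.  Efficacy ranking (EMAX):
    larger absolute maximal effect first.  BOTH orders by EC50 and calls a
    pair significant when either parameter differs by z-test.  Drugs whose
    fit did not converge rank last; relations involving a missing SE fall
    back to '>=' with a warning.  The output is invariant to input order
    (alphabetical tie-break).
    """
    compare_on = CompareOn(compare_on)
    if not fits:
        raise ValueError("need at least one fit to rank")

    def sort_key(item):
        drug, fit = item
        p = fit.params
        if compare_on is CompareOn.EMAX:
            primary = -abs(p.emax) if p is not None else math.inf
        else:
            primary = p.ec50 if (p is not None and fit.converged) else math.inf
        return (primary, drug)

    ordered = sorted(fits.items(), key=sort_key)
    order = tuple(drug for drug, _ in ordered)

    relations: list[str] = []
    warns: list[str] = []
    for (d1, f1), (d2, f2) in zip(ordered, ordered[1:]):
        tests: list[bool] = []
        for param, attr in (("ec50", "ec50"), ("emax", "emax")):
            if compare_on is CompareOn.EC50 and param != "ec50":
                continue
            if compare_on is CompareOn.EMAX and param != "emax":
                continue
            p1, p2 = f1.params, f2.params
            se1, se2 = f1.se.get(param), f2.se.get(param)
            if p1 is None or p2 is None or se1 is None or se2 is None:
                warns.append(f"{d1} vs {d2}: missing {param} estimate or SE; using '≥'")
                continue
            tests.append(_z_significant(getattr(p1, attr), se1, getattr(p2, attr), se2, alpha))
        relations.append(">" if any(tests) else "≥")

    return EfficacyRanking(order=order, relations=tuple(relations), anova=anova, warnings=tuple(warns))


# ---------------------------------------------------------------------------
# Viability arithmetic
# ---------------------------------------------------------------------------

def percent_change_vs_control(treated: float, control: float) -> float:
    """100 x (treated - control) / control, versus the contralateral control."""
    if control <= 0:
        raise ValueError("control measurement must be positive")
    return 100.0 * (treated - control) / control


@dataclass(frozen=True)
class FiberObservation:
    """Morphology deltas (fractional change from baseline) + contractility."""

    length_change: float
    diameter_change: float
    contractile_response: bool


def classify_fiber_death(fiber: FiberObservation) -> bool:
    """Dead iff a marked (>40%) morphology change AND failed contractility.

    The conjunction matters: a shrunken fiber that still twitches on
    ATP/KCl challenge is counted alive.
    """
    marked = abs(fiber.length_change) > 0.40 or abs(fiber.diameter_change) > 0.40
    return marked and not fiber.contractile_response


def mortality_percent(dead: int, total: int) -> float:
    """Number of dead cells / number of total cells in the plate x 100."""
    if total <= 0:
        raise ValueError("total must be positive")
    if dead < 0 or dead > total:
        raise ValueError("dead must be between 0 and total")
    return 100.0 * dead / total
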