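"""Disproportionality analysis of spontaneous-report corpora.

The proportional reporting ratio (PRR) compares how often a reaction of
interest is reported for an index drug with how often it is reported in a
comparator set of reports:

    PRR = [a / (a + c)] / [b / (b + d)]

where ``a`` counts reports of the reaction of interest for the index drug,
``c`` all other reports for the index drug, and ``b``/``d`` the same split
for the comparator.  A drug-event pair is flagged as a screening signal
when PRR >= 2, the reaction was reported at least 3 times, and the 2x2
chi-square is >= 4; a PRR of exactly 1 is never a signal.

Two comparator conventions are supported.  ``ALL_REPORTS_BACKGROUND``
measures the index drug against the whole corpus (index reports included),
which is the convention under which the published glyburide/muscle-atrophy
worked example (4/1,460 vs 373/1,697,582, PRR = 12) reproduces;
``EXCLUSIVE_BACKGROUND`` removes the index drug's reports from the
comparator.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .report_store import DEFAULT_ATROPHY_TERMS, ReportStore, match_atrophy_terms, normalize_term

__all__ = [
    "BackgroundVariant",
    "ContingencyTable",
    "SignalThresholds",
    "SignalStats",
    "UndefinedStatisticError",
    "build_contingency",
    "compute_prr",
    "compute_chi2",
    "classify_signal",
    "reporting_proportion",
    "scan_all_drugs",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given table (zero marginal)."""


class BackgroundVariant(enum.Enum):
    ALL_REPORTS_BACKGROUND = "all"
    EXCLUSIVE_BACKGROUND = "exclusive"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug x reaction-set pair.

    a: reaction of interest, index drug; b: reaction of interest,
    comparator; c: other reports, index drug; d: other reports, comparator.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_index(self) -> int:
        return self.a + self.c

    @property
    def n_comparator(self) -> int:
        return self.b + self.d

    @classmethod
    def from_marginals(
        cls,
        reaction_index: int,
        total_index: int,
        reaction_comparator: int,
        total_comparator: int,
    ) -> "ContingencyTable":
        """Build the table from the counts a tabulation typically prints:
        reaction/total for the index drug and reaction/total for the
        comparator scope."""
        return cls(
            a=reaction_index,
            b=reaction_comparator,
            c=total_index - reaction_index,
            d=total_comparator - reaction_comparator,
        )


@dataclass(frozen=True)
class SignalThresholds:
    """Screening thresholds: PRR >= 2, >= 3 reports, chi-square >= 4."""

    prr_min: float = 2.0
    n_min: int = 3
    chi2_min: float = 4.0


@dataclass(frozen=True)
class SignalStats:
    drug: str
    prr: float
    chi2: float
    n_reaction_reports: int
    proportion_index_pct: float
    proportion_background_pct: float
    is_signal: bool
    variant: BackgroundVariant


def build_contingency(
    store: ReportStore,
    drug: str,
    term_set: Iterable[str] = DEFAULT_ATROPHY_TERMS,
    variant: BackgroundVariant = BackgroundVariant.ALL_REPORTS_BACKGROUND,
    serious_background: bool = False,
) -> ContingencyTable:
    """Count the 2x2 cells for ``drug`` against ``term_set``.

    A report is "exposed" when it names the drug in any role, suspect or
    concomitant (concomitant-only cases are counted, as in the glyburide
    worked example).  ``serious_background=True`` restricts the comparator
    to serious reports.
    """
    variant = BackgroundVariant(variant)
    canonical = store.canonical(drug)
    terms = {normalize_term(t) for t in term_set}

    a = c = b = d = 0
    for rec in store:
        exposed = canonical in store.canonical_drugs(rec)
        matches = bool(rec.reactions & terms)
        if exposed:
            if matches:
                a += 1
            else:
                c += 1
        if variant is BackgroundVariant.ALL_REPORTS_BACKGROUND:
            in_background = True
        else:
            in_background = not exposed
        if in_background and serious_background and not rec.serious:
            in_background = False
        if in_background:
            if matches:
                b += 1
            else:
                d += 1
    if a + c == 0:
        raise UndefinedStatisticError(f"no exposure reports for drug {canonical!r}")
    return ContingencyTable(a=a, b=b, c=c, d=d)


def compute_prr(table: ContingencyTable) -> float:
    """Proportional reporting ratio [a/(a+c)] / [b/(b+d)].

    Returns 0.0 when a = 0 and +inf when b = 0 with a > 0.
    """
    if table.n_index == 0 or table.n_comparator == 0:
        raise UndefinedStatisticError("PRR undefined: empty index or comparator scope")
    if table.a == 0:
        return 0.0
    if table.b == 0:
        return math.inf
    return (table.a / table.n_index) / (table.b / table.n_comparator)


def compute_chi2(table: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the 2x2 table, Yates-corrected by default.

    The Yates continuity correction is the convention for the sparse cells
    typical of pharmacovigilance screening (the chi-square >= 4 criterion
    corresponds to p < 0.05 at 1 df).
    """
    obs = np.array([[table.a, table.c], [table.b, table.d]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("chi-square undefined: zero marginal")
    stat, _, _, _ = stats.chi2_contingency(obs, correction=yates)
    return float(stat)


def classify_signal(
    prr: float,
    n_reaction_reports: int,
    chi2: float,
    thresholds: SignalThresholds = SignalThresholds(),
) -> bool:
    """Apply the screening rule literally.

    True iff PRR >= prr_min AND n >= n_min AND chi2 >= chi2_min, with the
    explicit exclusion that PRR exactly 1 is never a signal.
    """
    if prr == 1.0:
        return False
    return (
        prr >= thresholds.prr_min
        and n_reaction_reports >= thresholds.n_min
        and chi2 >= thresholds.chi2_min
    )


def reporting_proportion(
    store: ReportStore,
    drug: str | None = None,
    term_set: Iterable[str] = DEFAULT_ATROPHY_TERMS,
) -> float:
    """Percentage of the scope's reports that match ``term_set``.

    ``drug=None`` scopes to the whole store; otherwise to reports naming
    the drug in any role.
    """
    terms = {normalize_term(t) for t in term_set}
    if drug is None:
        scope = list(store)
    else:
        canonical = store.canonical(drug)
        scope = [rec for rec in store if canonical in store.canonical_drugs(rec)]
    if not scope:
        raise UndefinedStatisticError("zero reports in scope")
    matching = sum(1 for rec in scope if rec.reactions & terms)
    return 100.0 * matching / len(scope)


def scan_all_drugs(
    store: ReportStore,
    term_set: Iterable[str] = DEFAULT_ATROPHY_TERMS,
    variant: BackgroundVariant = BackgroundVariant.ALL_REPORTS_BACKGROUND,
    thresholds: SignalThresholds = SignalThresholds(),
    yates: bool = True,
    serious_background: bool = False,
) -> pd.DataFrame:
    """One SignalStats row per canonical drug with at least one report.

    Drugs whose reaction-of-interest count is zero are retained with
    PRR = 0 and is_signal False.  Rows are sorted by descending PRR.
    """
    variant = BackgroundVariant(variant)
    drugs = sorted({name for rec in store for name in store.canonical_drugs(rec)})
    rows = []
    for drug in drugs:
        table = build_contingency(store, drug, term_set, variant, serious_background)
        prr = compute_prr(table)
        try:
            chi2 = compute_chi2(table, yates=yates)
        except UndefinedStatisticError:
            chi2 = float("nan")
        prop_index = 100.0 * table.a / table.n_index
        prop_bg = 100.0 * table.b / table.n_comparator if table.n_comparator else float("nan")
        rows.append(
            {
                "drug": drug,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "prr": prr,
                "chi2": chi2,
                "n_reaction_reports": table.a,
                "proportion_index_pct": prop_index,
                "proportion_background_pct": prop_bg,
                "is_signal": classify_signal(prr, table.a, chi2 if math.isfinite(chi2) else 0.0, thresholds),
                "variant": variant.value,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "drug", "a", "b", "c", "d", "prr", "chi2", "n_reaction_reports",
            "proportion_index_pct", "proportion_background_pct", "is_signal", "variant",
        ],
    )
    return df.sort_values("prr", ascending=False, kind="mergesort").reset_index(drop=True)
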