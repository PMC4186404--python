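"""Data model and I/O for spontaneous adverse-event reports.

A spontaneous-reporting database such as the FDA Adverse Event Reporting
System (AERS) is, at its core, a relational dump: one demographic row per
report, one row per reported drug (with a suspect/concomitant role), and
one row per coded reaction term.  This module provides an in-memory store
of such reports plus the bookkeeping steps that precede any
disproportionality analysis:

* reading/writing a simplified three-table ``$``-delimited layout
  (``DEMO``/``DRUG``/``REAC``, keyed by the ISR report identifier) and a
  flat one-row-per-report CSV dialect;
* drug-name canonicalization through a synonym map (glyburide and
  glibenclamide are the same molecule and are counted as one drug);
* deterministic deduplication;
* coded-term matching for the atrophy term list; and
* identification of positive rechallenge/dechallenge reports from the
  structured code or from narrative phrases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "DrugRole",
    "ChallengeCode",
    "ChallengeKind",
    "Dialect",
    "DrugEntry",
    "ReportRecord",
    "ReportStore",
    "LoadReport",
    "FormatError",
    "DEFAULT_ATROPHY_TERMS",
    "DEFAULT_SYNONYMS",
    "DEFAULT_RECHALLENGE_PHRASES",
    "DEFAULT_DECHALLENGE_PHRASES",
    "read_reports",
    "write_reports",
    "deduplicate",
    "match_atrophy_terms",
    "find_challenge_reports",
]


class FormatError(ValueError):
    """Raised when an input file does not conform to the declared dialect."""


class DrugRole(enum.Enum):
    """Role of a drug on a report, most to least suspect."""

    PRIMARY_SUSPECT = "PS"
    SECONDARY_SUSPECT = "SS"
    CONCOMITANT = "C"


#: precedence used when one report lists the same drug under several roles
_ROLE_RANK = {
    DrugRole.PRIMARY_SUSPECT: 0,
    DrugRole.SECONDARY_SUSPECT: 1,
    DrugRole.CONCOMITANT: 2,
}


class ChallengeCode(enum.Enum):
    """Structured rechallenge/dechallenge outcome recorded on a report."""

    POS = "POS"
    NEG = "NEG"
    UNKNOWN = "UNKNOWN"
    ABSENT = "ABSENT"


class ChallengeKind(enum.Enum):
    RECHALLENGE = "rechallenge"
    DECHALLENGE = "dechallenge"


class Dialect(enum.Enum):
    """On-disk layout for a report store."""

    AERS_DOLLAR = "aers"
    CSV = "csv"


#: The five coded terms used to retrieve atrophy-related reports.
DEFAULT_ATROPHY_TERMS = frozenset(
    {
        "MUSCLE ATROPHY",
        "MUSCULAR ATROPHY",
        "MUSCULOSKELETAL ATROPHY",
        "PERONEAL ATROPHY",
        "PROGRESSIVE MUSCULAR ATROPHY",
    }
)

#: Glyburide is the USAN name for glibenclamide; the two are one drug.
DEFAULT_SYNONYMS: Mapping[str, str] = {"GLYBURIDE": "GLIBENCLAMIDE"}

DEFAULT_RECHALLENGE_PHRASES = (
    "recurred after rechallenge",
    "reappeared on readministration",
)
DEFAULT_DECHALLENGE_PHRASES = (
    "resolved after discontinuation",
    "disappeared after withdrawal",
)


def normalize_drug_name(name: str) -> str:
    """Uppercase, whitespace-collapsed drug name."""
    return " ".join(name.strip().upper().split())


def normalize_term(term: str) -> str:
    """Uppercase, whitespace-collapsed reaction coding term."""
    return " ".join(term.strip().upper().split())


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report."""

    name: str
    role: DrugRole = DrugRole.PRIMARY_SUSPECT

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("drug name must be non-empty")
        object.__setattr__(self, "name", normalize_drug_name(self.name))
        if not isinstance(self.role, DrugRole):
            object.__setattr__(self, "role", DrugRole(self.role))


@dataclass
class ReportRecord:
    """One spontaneous adverse-event report.

    ``reactions`` are uppercase-normalized coded terms; ``serious``
    mirrors the regulatory seriousness flag (hospitalization,
    life-threatening illness, disability, ...), with the codes kept in
    ``outcome_codes``.
    """

    report_id: str
    receive_date: str
    drugs: list[DrugEntry]
    reactions: set[str]
    serious: bool = False
    outcome_codes: set[str] = field(default_factory=set)
    rechallenge_code: ChallengeCode = ChallengeCode.ABSENT
    dechallenge_code: ChallengeCode = ChallengeCode.ABSENT
    narrative: str = ""

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.reactions:
            raise ValueError("a report must carry at least one reaction term")
        self.reactions = {normalize_term(t) for t in self.reactions}
        self.drugs = list(self.drugs)
        if not all(isinstance(code, ChallengeCode) for code in (self.rechallenge_code, self.dechallenge_code)):
            self.rechallenge_code = ChallengeCode(self.rechallenge_code)
            self.dechallenge_code = ChallengeCode(self.dechallenge_code)


@dataclass
class LoadReport:
    """Bookkeeping from one :func:`read_reports` call."""

    n_read: int = 0
    n_dropped_no_reaction: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class ReportStore:
    """A corpus of reports with its term dictionary and drug synonym map."""

    records: list[ReportRecord] = field(default_factory=list)
    term_dictionary: set[str] = field(default_factory=set)
    synonym_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        # idempotent map: canonical names map to themselves
        self.synonym_map = {
            normalize_drug_name(k): normalize_drug_name(v) for k, v in self.synonym_map.items()
        }
        for canonical in list(self.synonym_map.values()):
            self.synonym_map.setdefault(canonical, canonical)
        seen: set[str] = set()
        for rec in self.records:
            if rec.report_id in seen:
                raise ValueError(f"duplicate report_id {rec.report_id!r} in store")
            seen.add(rec.report_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReportRecord]:
        return iter(self.records)

    def canonical(self, drug_name: str) -> str:
        """Canonical form of ``drug_name`` under the synonym map."""
        name = normalize_drug_name(drug_name)
        return self.synonym_map.get(name, name)

    def canonical_drugs(self, record: ReportRecord) -> set[str]:
        return {self.canonical(d.name) for d in record.drugs}

    def dedup_key(self, record: ReportRecord):
        """Deterministic duplicate key: canonical drug multiset, reaction set, date.

        The key deliberately excludes challenge codes, seriousness and the
        narrative; it is a reproducible stand-in for case-by-case manual
        duplicate review.
        """
        drug_multiset = tuple(sorted(self.canonical(d.name) for d in record.drugs))
        return (drug_multiset, frozenset(record.reactions), record.receive_date)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DEMO_COLS = [
    "ISR",
    "RECEIVE_DATE",
    "SERIOUS",
    "OUTCOME_CODES",
    "RECHALLENGE",
    "DECHALLENGE",
    "NARRATIVE",
]
_DRUG_COLS = ["ISR", "DRUGNAME", "ROLE_COD"]
_REAC_COLS = ["ISR", "PT"]

_CSV_COLS = [
    "report_id",
    "receive_date",
    "drugs",
    "reactions",
    "serious",
    "outcome_codes",
    "rechallenge",
    "dechallenge",
    "narrative",
]


def _merge_roles(entries: Iterable[DrugEntry]) -> list[DrugEntry]:
    """Collapse repeated mentions of one drug to its most suspect role."""
    best: dict[str, DrugEntry] = {}
    order: list[str] = []
    for e in entries:
        if e.name not in best:
            best[e.name] = e
            order.append(e.name)
        elif _ROLE_RANK[e.role] < _ROLE_RANK[best[e.name].role]:
            best[e.name] = e
    return [best[name] for name in order]


def _read_table(path: Path, name: str, required: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"missing {name} table: {path}")
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{name} table {path} lacks required column {col!r}")
    return df


def read_reports(
    source: str | Path,
    dialect: Dialect = Dialect.AERS_DOLLAR,
    synonym_map: Mapping[str, str] | None = None,
) -> ReportStore:
    """Read a report store from disk.

    ``AERS_DOLLAR`` expects a directory holding ``DEMO.txt``, ``DRUG.txt``
    and ``REAC.txt``, ``$``-delimited with header rows and a shared ``ISR``
    report-id column.  ``CSV`` expects a single flat file with ``;``-joined
    list cells.  Reports with no reaction rows are dropped and counted in
    ``store.load_report``; DRUG/REAC rows whose ISR has no DEMO row are
    collected as warnings, not errors.
    """
    dialect = Dialect(dialect)
    source = Path(source)
    synonyms = dict(DEFAULT_SYNONYMS if synonym_map is None else synonym_map)
    load = LoadReport()

    if dialect is Dialect.AERS_DOLLAR:
        demo = _read_table(source / "DEMO.txt", "DEMO", _DEMO_COLS[:2])
        drug = _read_table(source / "DRUG.txt", "DRUG", _DRUG_COLS)
        reac = _read_table(source / "REAC.txt", "REAC", _REAC_COLS)

        known = set(demo["ISR"])
        for tbl_name, tbl in (("DRUG", drug), ("REAC", reac)):
            dangling = sorted(set(tbl["ISR"]) - known)
            for isr in dangling:
                load.warnings.append(f"{tbl_name} row(s) for unknown report id {isr!r}")

        drugs_by_isr: dict[str, list[DrugEntry]] = {}
        for row in drug.itertuples(index=False):
            if row.ISR not in known:
                continue
            drugs_by_isr.setdefault(row.ISR, []).append(
                DrugEntry(row.DRUGNAME, DrugRole(row.ROLE_COD))
            )
        reac_by_isr: dict[str, set[str]] = {}
        for row in reac.itertuples(index=False):
            if row.ISR not in known:
                continue
            reac_by_isr.setdefault(row.ISR, set()).add(normalize_term(row.PT))

        records: list[ReportRecord] = []
        for row in demo.itertuples(index=False):
            load.n_read += 1
            reactions = reac_by_isr.get(row.ISR, set())
            if not reactions:
                load.n_dropped_no_reaction += 1
                continue
            records.append(
                ReportRecord(
                    report_id=row.ISR,
                    receive_date=getattr(row, "RECEIVE_DATE", ""),
                    drugs=_merge_roles(drugs_by_isr.get(row.ISR, [])),
                    reactions=reactions,
                    serious=str(getattr(row, "SERIOUS", "0")) in ("1", "True", "Y"),
                    outcome_codes={c for c in str(getattr(row, "OUTCOME_CODES", "")).split(";") if c},
                    rechallenge_code=ChallengeCode(getattr(row, "RECHALLENGE", "ABSENT") or "ABSENT"),
                    dechallenge_code=ChallengeCode(getattr(row, "DECHALLENGE", "ABSENT") or "ABSENT"),
                    narrative=str(getattr(row, "NARRATIVE", "")),
                )
            )
    elif dialect is Dialect.CSV:
        if not source.exists():
            raise FormatError(f"missing CSV file: {source}")
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
        for col in ("report_id", "reactions"):
            if col not in df.columns:
                raise FormatError(f"CSV table {source} lacks required column {col!r}")
        records = []
        for row in df.itertuples(index=False):
            load.n_read += 1
            reactions = {normalize_term(t) for t in str(row.reactions).split(";") if t.strip()}
            if not reactions:
                load.n_dropped_no_reaction += 1
                continue
            drugs = []
            for item in str(getattr(row, "drugs", "")).split(";"):
                if not item.strip():
                    continue
                name, _, role = item.partition(":")
                drugs.append(DrugEntry(name, DrugRole(role or "PS")))
            records.append(
                ReportRecord(
                    report_id=str(row.report_id),
                    receive_date=str(getattr(row, "receive_date", "")),
                    drugs=_merge_roles(drugs),
                    reactions=reactions,
                    serious=str(getattr(row, "serious", "0")) in ("1", "True", "Y"),
                    outcome_codes={c for c in str(getattr(row, "outcome_codes", "")).split(";") if c},
                    rechallenge_code=ChallengeCode(getattr(row, "rechallenge", "ABSENT") or "ABSENT"),
                    dechallenge_code=ChallengeCode(getattr(row, "dechallenge", "ABSENT") or "ABSENT"),
                    narrative=str(getattr(row, "narrative", "")),
                )
            )
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(dialect)

    store = ReportStore(records=records, synonym_map=synonyms)
    store.term_dictionary = {t for rec in records for t in rec.reactions}
    store.load_report = load
    return store


def write_reports(store: ReportStore, sink: str | Path, dialect: Dialect = Dialect.AERS_DOLLAR) -> None:
    """Write ``store`` so that :func:`read_reports` round-trips all modeled fields.

    The ``$`` and ``;`` delimiters are reserved; they are stripped from
    narratives on write.
    """
    dialect = Dialect(dialect)
    sink = Path(sink)

    def clean(text: str) -> str:
        return text.replace("$", " ").replace("\n", " ")

    if dialect is Dialect.AERS_DOLLAR:
        sink.mkdir(parents=True, exist_ok=True)
        demo_rows, drug_rows, reac_rows = [], [], []
        for rec in store:
            demo_rows.append(
                {
                    "ISR": rec.report_id,
                    "RECEIVE_DATE": rec.receive_date,
                    "SERIOUS": int(rec.serious),
                    "OUTCOME_CODES": ";".join(sorted(rec.outcome_codes)),
                    "RECHALLENGE": rec.rechallenge_code.name,
                    "DECHALLENGE": rec.dechallenge_code.name,
                    "NARRATIVE": clean(rec.narrative),
                }
            )
            for d in rec.drugs:
                drug_rows.append({"ISR": rec.report_id, "DRUGNAME": d.name, "ROLE_COD": d.role.value})
            for term in sorted(rec.reactions):
                reac_rows.append({"ISR": rec.report_id, "PT": term})
        pd.DataFrame(demo_rows, columns=_DEMO_COLS).to_csv(sink / "DEMO.txt", sep="$", index=False)
        pd.DataFrame(drug_rows, columns=_DRUG_COLS).to_csv(sink / "DRUG.txt", sep="$", index=False)
        pd.DataFrame(reac_rows, columns=_REAC_COLS).to_csv(sink / "REAC.txt", sep="$", index=False)
    elif dialect is Dialect.CSV:
        sink.parent.mkdir(parents=True, exist_ok=True)
        rows = []
        for rec in store:
            rows.append(
                {
                    "report_id": rec.report_id,
                    "receive_date": rec.receive_date,
                    "drugs": ";".join(f"{d.name}:{d.role.value}" for d in rec.drugs),
                    "reactions": ";".join(sorted(rec.reactions)),
                    "serious": int(rec.serious),
                    "outcome_codes": ";".join(sorted(rec.outcome_codes)),
                    "rechallenge": rec.rechallenge_code.name,
                    "dechallenge": rec.dechallenge_code.name,
                    "narrative": clean(rec.narrative).replace(";", ","),
                }
            )
        pd.DataFrame(rows, columns=_CSV_COLS).to_csv(sink, index=False)
    else:  # pragma: no cover
        raise ValueError(dialect)


# ---------------------------------------------------------------------------
# Corpus operations
# ---------------------------------------------------------------------------

def deduplicate(store: ReportStore) -> tuple[ReportStore, int]:
    """Drop duplicate reports, keeping the smallest report_id per key.

    Two reports are duplicates when they agree on the canonical drug-name
    multiset, the reaction-term set and the receive date.  Returns the
    deduplicated store and the number of records removed.
    """
    best: dict[object, ReportRecord] = {}
    for rec in store:
        key = store.dedup_key(rec)
        incumbent = best.get(key)
        if incumbent is None or rec.report_id < incumbent.report_id:
            best[key] = rec
    keep_ids = {rec.report_id for rec in best.values()}
    kept = [rec for rec in store if rec.report_id in keep_ids]
    removed = len(store) - len(kept)
    out = ReportStore(
        records=kept,
        term_dictionary=set(store.term_dictionary),
        synonym_map=dict(store.synonym_map),
    )
    return out, removed


def match_atrophy_terms(
    store: ReportStore,
    term_set: Iterable[str] = DEFAULT_ATROPHY_TERMS,
    substring: bool = False,
) -> set[str]:
    """Report ids whose reaction set intersects ``term_set``.

    Matching is case-insensitive exact term equality by default because
    reactions are coded dictionary terms, not free text; ``substring=True``
    switches to case-insensitive containment of any term in any reaction.
    """
    terms = {normalize_term(t) for t in term_set}
    if not terms:
        raise ValueError("term_set must be non-empty")
    if not substring:
        return {rec.report_id for rec in store if rec.reactions & terms}
    return {
        rec.report_id
        for rec in store
        if any(t in reaction for t in terms for reaction in rec.reactions)
    }


def find_challenge_reports(
    store: ReportStore,
    kind: ChallengeKind,
    phrases: Sequence[str] | None = None,
) -> set[str]:
    """Report ids with a positive rechallenge/dechallenge.

    A report qualifies when its structured code is POS (the "POS RECHAL"
    coding-term route) or when its narrative contains any of the phrase
    list, case-insensitively.
    """
    kind = ChallengeKind(kind)
    if phrases is None:
        phrases = (
            DEFAULT_RECHALLENGE_PHRASES
            if kind is ChallengeKind.RECHALLENGE
            else DEFAULT_DECHALLENGE_PHRASES
        )
    phrases_lc = [p.lower() for p in phrases]
    out: set[str] = set()
    for rec in store:
        code = rec.rechallenge_code if kind is ChallengeKind.RECHALLENGE else rec.dechallenge_code
        if code is ChallengeCode.POS:
            out.add(rec.report_id)
        elif rec.narrative and any(p in rec.narrative.lower() for p in phrases_lc):
            out.add(rec.report_id)
    return out
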