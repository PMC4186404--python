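"""Synthetic-data generators with planted ground truth.

No public adverse-event extract or wet-lab measurement ships with this
package; instead every pipeline input is simulated with known truth so
that recovery can be tested end to end:

* :func:`gen_reports` builds an AERS-like spontaneous-report corpus:
  per-report drug exposures are independent Bernoulli draws, reaction
  terms are independent Bernoulli draws at their background rate, and a
  planted (drug, term) signal multiplies that term's rate by a relative
  reporting rate rho for exposed reports - so the PRR estimated
  downstream should recover rho.  A configurable fraction of reports are
  exact duplicates (fresh ids) and a fraction carry a positive
  rechallenge code.  Every generated store carries a ledger of what was
  planted.
* :func:`gen_dose_response` draws replicated 4PL responses with Gaussian
  noise around a known parameter set.
* :func:`gen_fiber_observations` emits fiber morphology/contractility
  observations with a planted death rate.

All generators are deterministic given (config, seed).  Reaction terms
are sampled independently (no between-term correlation) - adequate for
testing counting statistics, not a model of real co-reporting structure.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dose_response import DosePoint, DoseResponseDataset, FiberObservation, HillParams, hill_4pl
from .report_store import ChallengeCode, DrugEntry, DrugRole, ReportRecord, ReportStore

__all__ = [
    "ReportSimConfig",
    "ReportSimLedger",
    "CurveSimConfig",
    "gen_reports",
    "gen_dose_response",
    "gen_fiber_observations",
    "log_spaced_doses",
    "DEFAULT_BACKGROUND_REACTIONS",
    "DEFAULT_DRUG_PANEL",
]

#: default reaction background: a spread of common coded terms that keeps
#: reports non-empty and the dedup key space large (a narrow vocabulary
#: makes genuinely distinct reports collide on the drug/reaction/date
#: key), plus the muscle-atrophy term at its corpus-wide rate of 2.2e-4
#: (0.022% of reports)
DEFAULT_BACKGROUND_REACTIONS: tuple[tuple[str, float], ...] = (
    ("NAUSEA", 0.15),
    ("HEADACHE", 0.12),
    ("DIZZINESS", 0.10),
    ("RASH", 0.08),
    ("FATIGUE", 0.10),
    ("VOMITING", 0.08),
    ("DIARRHOEA", 0.08),
    ("PRURITUS", 0.06),
    ("DYSPNOEA", 0.06),
    ("INSOMNIA", 0.05),
    ("ARTHRALGIA", 0.05),
    ("MYALGIA", 0.05),
    ("PYREXIA", 0.05),
    ("CONSTIPATION", 0.04),
    ("HYPOTENSION", 0.04),
    ("PALPITATIONS", 0.04),
    ("ANXIETY", 0.04),
    ("OEDEMA PERIPHERAL", 0.04),
    ("COUGH", 0.04),
    ("ABDOMINAL PAIN", 0.06),
    ("HYPOGLYCAEMIA", 0.02),
    ("MUSCLE WEAKNESS", 0.02),
    ("TREMOR", 0.03),
    ("MUSCLE ATROPHY", 2.2e-4),
)

#: default exposure panel: a spread of commonly reported drugs; every
#: report names at least one drug (drug-less spontaneous reports are not
#: meaningful and would collide under the dedup key)
DEFAULT_DRUG_PANEL: tuple[tuple[str, float], ...] = (
    ("GLIBENCLAMIDE", 0.01),
    ("METFORMIN", 0.05),
    ("ASPIRIN", 0.07),
    ("PARACETAMOL", 0.07),
    ("SIMVASTATIN", 0.05),
    ("ATORVASTATIN", 0.05),
    ("LISINOPRIL", 0.05),
    ("ENALAPRIL", 0.03),
    ("OMEPRAZOLE", 0.05),
    ("PANTOPRAZOLE", 0.03),
    ("AMLODIPINE", 0.04),
    ("WARFARIN", 0.04),
    ("CLOPIDOGREL", 0.03),
    ("PREDNISONE", 0.04),
    ("DEXAMETHASONE", 0.02),
    ("LEVOTHYROXINE", 0.04),
    ("IBUPROFEN", 0.07),
    ("NAPROXEN", 0.04),
    ("FUROSEMIDE", 0.04),
    ("HYDROCHLOROTHIAZIDE", 0.04),
    ("SERTRALINE", 0.04),
    ("FLUOXETINE", 0.03),
    ("GABAPENTIN", 0.04),
    ("TRAMADOL", 0.04),
    ("INSULIN GLARGINE", 0.03),
    ("RAMIPRIL", 0.03),
    ("METOPROLOL", 0.04),
    ("BISOPROLOL", 0.03),
    ("SALBUTAMOL", 0.03),
    ("MONTELUKAST", 0.02),
    ("ALLOPURINOL", 0.03),
    ("CELECOXIB", 0.02),
    ("DULOXETINE", 0.03),
    ("QUETIAPINE", 0.02),
    ("RISPERIDONE", 0.02),
    ("DIGOXIN", 0.02),
    ("SPIRONOLACTONE", 0.03),
    ("TAMSULOSIN", 0.03),
    ("LOSARTAN", 0.04),
    ("ESOMEPRAZOLE", 0.03),
)

_WINDOW_START = datetime.date(2011, 10, 6)
_WINDOW_DAYS = 240  # ~8-month observation window


@dataclass(frozen=True)
class ReportSimConfig:
    """Conditions for one simulated spontaneous-report corpus."""

    n_reports: int
    drugs: tuple[tuple[str, float], ...] = DEFAULT_DRUG_PANEL
    reactions: tuple[tuple[str, float], ...] = DEFAULT_BACKGROUND_REACTIONS
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    duplicate_fraction: float = 0.0
    pos_rechallenge_fraction: float = 0.0
    serious_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        for _, p in self.drugs:
            if not 0 <= p <= 1:
                raise ValueError("exposure probabilities must be in [0, 1]")
        for _, r in self.reactions:
            if not 0 <= r <= 1:
                raise ValueError("background rates must be in [0, 1]")
        for _, _, rho in self.planted_signals:
            if rho < 0:
                raise ValueError("relative reporting rate must be >= 0")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        if self.n_reports > 0 and all(r == 0 for _, r in self.reactions):
            raise ValueError("infeasible config: all reaction background rates are zero")


@dataclass
class ReportSimLedger:
    """Planted truth for one generated corpus."""

    config: ReportSimConfig
    planted_duplicates: list[tuple[str, str]] = field(default_factory=list)  # (dup_id, source_id)
    pos_rechallenge_ids: list[str] = field(default_factory=list)

    @property
    def n_planted_duplicates(self) -> int:
        return len(self.planted_duplicates)


def gen_reports(config: ReportSimConfig) -> tuple[ReportStore, ReportSimLedger]:
    """Simulate a spontaneous-report corpus; returns (store, planted-truth ledger)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    ledger = ReportSimLedger(config=config)
    if n == 0:
        return ReportStore(records=[]), ledger

    drug_names = [name for name, _ in config.drugs]
    drug_p = np.array([p for _, p in config.drugs])
    term_names = [t for t, _ in config.reactions]
    base_rate = np.array([r for _, r in config.reactions])

    exposed = rng.random((n, len(drug_names))) < drug_p  # (n, D)
    # every report names >= 1 drug (unless the panel has no exposure at all)
    if drug_p.sum() > 0:
        none = ~exposed.any(axis=1)
        tries = 0
        while none.any():
            tries += 1
            if tries > 10_000:
                raise RuntimeError("drug-exposure resampling did not converge")
            m = int(none.sum())
            exposed[none] = rng.random((m, len(drug_names))) < drug_p
            none = ~exposed.any(axis=1)

    # per-report, per-term rate with the planted multipliers applied
    rate = np.broadcast_to(base_rate, (n, len(term_names))).copy()
    term_index = {t: i for i, t in enumerate(term_names)}
    drug_index = {d: i for i, d in enumerate(drug_names)}
    for drug, term, rho in config.planted_signals:
        ti = term_index[term]
        di = drug_index[drug]
        rate[exposed[:, di], ti] = np.minimum(1.0, base_rate[ti] * rho)

    reactions = rng.random((n, len(term_names))) < rate
    # every report must carry >= 1 reaction: redraw empty rows
    empty = ~reactions.any(axis=1)
    tries = 0
    while empty.any():
        tries += 1
        if tries > 10_000:
            raise RuntimeError("reaction resampling did not converge; rates too small")
        m = int(empty.sum())
        reactions[empty] = rng.random((m, len(term_names))) < rate[empty]
        empty = ~reactions.any(axis=1)

    dates = rng.integers(0, _WINDOW_DAYS, size=n)
    serious = rng.random(n) < config.serious_fraction
    rechal = rng.random(n) < config.pos_rechallenge_fraction
    dup_flags = rng.random(n) < config.duplicate_fraction
    dup_flags[0] = False
    dup_source = rng.integers(0, np.maximum(np.arange(n), 1))  # j < i for i >= 1

    width = len(str(n))
    ids = [f"R{i:0{width}d}" for i in range(n)]

    records: list[ReportRecord] = []
    for i in range(n):
        if dup_flags[i]:
            src = records[int(dup_source[i])]
            ledger.planted_duplicates.append((ids[i], src.report_id))
            rec = ReportRecord(
                report_id=ids[i],
                receive_date=src.receive_date,
                drugs=list(src.drugs),
                reactions=set(src.reactions),
                serious=src.serious,
                outcome_codes=set(src.outcome_codes),
                rechallenge_code=src.rechallenge_code,
                dechallenge_code=src.dechallenge_code,
                narrative=src.narrative,
            )
        else:
            names = [drug_names[j] for j in np.nonzero(exposed[i])[0]]
            drugs = [
                DrugEntry(name, DrugRole.PRIMARY_SUSPECT if k == 0 else DrugRole.CONCOMITANT)
                for k, name in enumerate(names)
            ]
            date = (_WINDOW_START + datetime.timedelta(days=int(dates[i]))).isoformat()
            code = ChallengeCode.POS if rechal[i] else ChallengeCode.ABSENT
            if rechal[i]:
                ledger.pos_rechallenge_ids.append(ids[i])
            rec = ReportRecord(
                report_id=ids[i],
                receive_date=date,
                drugs=drugs,
                reactions={term_names[j] for j in np.nonzero(reactions[i])[0]},
                serious=bool(serious[i]),
                outcome_codes={"HO"} if serious[i] else set(),
                rechallenge_code=code,
            )
        records.append(rec)

    store = ReportStore(records=records)
    store.term_dictionary = {t for rec in records for t in rec.reactions}
    return store, ledger


@dataclass(frozen=True)
class CurveSimConfig:
    """Conditions for one simulated concentration-response dataset."""

    true_params: HillParams
    doses: tuple[float, ...]
    n_replicates: int = 5
    noise_sd: float = 3.0  # response %, Gaussian
    seed: int = 0
    drug: str = "drug"
    muscle: str = "FDB"

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if list(self.doses) != sorted(self.doses):
            raise ValueError("doses must be ascending")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def log_spaced_doses(low: float, high: float, n: int = 12) -> tuple[float, ...]:
    """n log10-spaced concentrations from low to high (mol/L), inclusive."""
    return tuple(np.logspace(np.log10(low), np.log10(high), n))


def gen_dose_response(config: CurveSimConfig) -> DoseResponseDataset:
    """Replicated 4PL responses with additive Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    points = []
    for dose in config.doses:
        mu = hill_4pl(dose, config.true_params)
        noise = rng.normal(0.0, config.noise_sd, size=config.n_replicates) if config.noise_sd > 0 else np.zeros(config.n_replicates)
        for rep in range(config.n_replicates):
            points.append(DosePoint(dose=float(dose), response=float(mu + noise[rep]), replicate_id=rep))
    return DoseResponseDataset(drug=config.drug, muscle=config.muscle, points=points)


def gen_fiber_observations(
    n_fibers: int,
    death_rate: float,
    seed: int = 0,
) -> tuple[list[FiberObservation], int]:
    """Fiber morphology/contractility table with a planted death rate.

    Dead fibers get >40% morphology loss and no contractile response.
    Alive fibers either stay under the 40% threshold or, occasionally,
    exceed it while retaining contractility (exercising the conjunction in
    the death rule).  Returns (observations, planted dead count).
    """
    if not 0 <= death_rate <= 1:
        raise ValueError("death_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dead = rng.random(n_fibers) < death_rate
    out: list[FiberObservation] = []
    for is_dead in dead:
        if is_dead:
            out.append(
                FiberObservation(
                    length_change=-float(rng.uniform(0.45, 0.80)),
                    diameter_change=-float(rng.uniform(0.45, 0.80)),
                    contractile_response=False,
                )
            )
        elif rng.random() < 0.1:  # shrunken but still contracting
            out.append(
                FiberObservation(
                    length_change=-float(rng.uniform(0.41, 0.60)),
                    diameter_change=-float(rng.uniform(0.0, 0.35)),
                    contractile_response=True,
                )
            )
        else:
            out.append(
                FiberObservation(
                    length_change=-float(rng.uniform(0.0, 0.35)),
                    diameter_change=-float(rng.uniform(0.0, 0.35)),
                    contractile_response=bool(rng.random() < 0.95),
                )
            )
    return out, int(dead.sum())
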