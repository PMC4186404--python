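"""End-to-end orchestration: ingest -> dedup -> scan, and simulate -> fit -> rank.

Each run writes plain TSV/JSON outputs plus a ``manifest.json`` recording
the command, the configuration snapshot, the seed, input checksums and
the package version; identical manifest inputs reproduce identical result
files for the deterministic stages (the manifest's own timestamp is the
only field that differs between reruns).
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .disproportionality import (
    BackgroundVariant,
    SignalThresholds,
    build_contingency,
    compute_prr,
    scan_all_drugs,
)
from .dose_response import CompareOn, DoseResponseDataset, fit_many, fits_to_frame, rank_efficacy
from .report_store import (
    DEFAULT_ATROPHY_TERMS,
    ChallengeKind,
    Dialect,
    ReportStore,
    deduplicate,
    find_challenge_reports,
    read_reports,
)
from .synthetic import CurveSimConfig, ReportSimConfig, gen_dose_response, gen_reports

__all__ = [
    "RunManifest",
    "PharmacovigilanceConfig",
    "PharmacodynamicsConfig",
    "run_pharmacovigilance",
    "run_pharmacodynamics",
]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every run's outputs."""

    command: str
    config: dict
    seed: int | None
    input_checksums: dict[str, str]
    version: str = __version__
    timestamp: str = field(default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat())

    def write(self, out_dir: Path) -> Path:
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(_jsonable(dataclasses.asdict(self)), indent=2, sort_keys=True))
        return path


@dataclass
class PharmacovigilanceConfig:
    """Inputs for a disproportionality run: a store on disk or a simulation."""

    input_path: Path | None = None
    dialect: Dialect = Dialect.AERS_DOLLAR
    sim: ReportSimConfig | None = None
    dedup: bool = True
    term_set: frozenset[str] = DEFAULT_ATROPHY_TERMS
    variant: BackgroundVariant = BackgroundVariant.ALL_REPORTS_BACKGROUND
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    yates: bool = True
    serious_background: bool = False
    drugs_of_interest: tuple[str, ...] = ()


@dataclass
class PharmacodynamicsConfig:
    """Inputs for a dose-response run: a curve CSV or simulation configs."""

    input_path: Path | None = None
    sims: tuple[CurveSimConfig, ...] = ()
    compare_on: CompareOn = CompareOn.EC50
    labels: Mapping[str, str] = field(default_factory=dict)


def _load_store(config: PharmacovigilanceConfig) -> tuple[ReportStore, dict[str, str]]:
    checksums: dict[str, str] = {}
    if config.input_path is not None:
        path = Path(config.input_path)
        if not path.exists():
            raise FileNotFoundError(f"[ingest] input path does not exist: {path}")
        store = read_reports(path, config.dialect)
        files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
        checksums = {f.name: _checksum(f) for f in files}
    elif config.sim is not None:
        store, _ = gen_reports(config.sim)
    else:
        raise ValueError("[ingest] config needs input_path or sim")
    return store, checksums


def run_pharmacovigilance(config: PharmacovigilanceConfig, out_dir: str | Path) -> dict:
    """Ingest (or simulate), deduplicate, scan every drug, and summarise.

    Writes ``signals.tsv``/``signals.json`` (one row per drug),
    ``challenge_reports.json`` (positive rechallenge/dechallenge ids),
    ``summary.json`` (per drug of interest: counts and PRR) and
    ``manifest.json``.  Returns the scan table and paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    store, checksums = _load_store(config)
    removed = 0
    if config.dedup:
        store, removed = deduplicate(store)

    scan = scan_all_drugs(
        store,
        term_set=config.term_set,
        variant=config.variant,
        thresholds=config.thresholds,
        yates=config.yates,
        serious_background=config.serious_background,
    )
    scan.to_csv(out_dir / "signals.tsv", sep="\t", index=False)
    (out_dir / "signals.json").write_text(scan.to_json(orient="records", indent=2))

    challenge = {
        "rechallenge_pos": sorted(find_challenge_reports(store, ChallengeKind.RECHALLENGE)),
        "dechallenge_pos": sorted(find_challenge_reports(store, ChallengeKind.DECHALLENGE)),
    }
    (out_dir / "challenge_reports.json").write_text(json.dumps(challenge, indent=2))

    summary_rows = []
    for drug in config.drugs_of_interest:
        table = build_contingency(store, drug, config.term_set, config.variant, config.serious_background)
        summary_rows.append(
            {
                "drug": store.canonical(drug),
                "reaction_reports": table.a,
                "total_reports": table.n_index,
                "prr": compute_prr(table),
            }
        )
    summary = {
        "n_reports": len(store),
        "n_duplicates_removed": removed,
        "drugs_of_interest": summary_rows,
    }
    (out_dir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))

    seed = config.sim.seed if config.sim is not None else None
    manifest = RunManifest(
        command="run_pharmacovigilance",
        config=_jsonable(config),
        seed=seed,
        input_checksums=checksums,
    )
    manifest.write(out_dir)

    return {"scan": scan, "summary": summary, "challenge": challenge, "out_dir": out_dir}


def _load_curves(config: PharmacodynamicsConfig) -> tuple[list[DoseResponseDataset], dict[str, str]]:
    checksums: dict[str, str] = {}
    datasets: list[DoseResponseDataset] = []
    if config.input_path is not None:
        path = Path(config.input_path)
        if not path.exists():
            raise FileNotFoundError(f"[fit] input path does not exist: {path}")
        df = pd.read_csv(path)
        required = {"drug", "muscle", "dose_mol_per_L", "response_pct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"[fit] curve CSV lacks columns: {sorted(missing)}")
        if "replicate" not in df.columns:
            df["replicate"] = 0
        for (drug, muscle), grp in df.groupby(["drug", "muscle"]):
            points = list(zip(grp["dose_mol_per_L"], grp["response_pct"], grp["replicate"]))
            datasets.append(DoseResponseDataset(drug=drug, muscle=muscle, points=points))
        checksums[path.name] = _checksum(path)
    for sim in config.sims:
        datasets.append(gen_dose_response(sim))
    if not datasets:
        return [], checksums
    return datasets, checksums


def run_pharmacodynamics(config: PharmacodynamicsConfig, out_dir: str | Path) -> dict:
    """Fit every concentration-response curve and rank drugs per muscle.

    Writes ``fits.tsv`` (one row per drug x muscle, in the style of a
    fitting-parameters table), ``rankings.json`` (one potency-ranking
    string per muscle) and ``manifest.json``.  Curves that cannot be fit
    are reported with ``converged=False``; the run continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    datasets, checksums = _load_curves(config)
    fits = fit_many(datasets)
    frame = fits_to_frame(fits)
    frame.to_csv(out_dir / "fits.tsv", sep="\t", index=False)

    rankings: dict[str, dict] = {}
    muscles = sorted({muscle for _, muscle in fits})
    for muscle in muscles:
        per_drug = {drug: fit for (drug, m), fit in fits.items() if m == muscle}
        if len(per_drug) < 2:
            continue
        ranking = rank_efficacy(per_drug, compare_on=config.compare_on)
        rankings[muscle] = {
            "order": list(ranking.order),
            "relations": list(ranking.relations),
            "string": ranking.format(config.labels),
            "warnings": list(ranking.warnings),
        }
    (out_dir / "rankings.json").write_text(json.dumps(rankings, indent=2, ensure_ascii=False))

    seeds = [sim.seed for sim in config.sims]
    manifest = RunManifest(
        command="run_pharmacodynamics",
        config=_jsonable(config),
        seed=seeds[0] if seeds else None,
        input_checksums=checksums,
    )
    manifest.write(out_dir)

    return {"fits": fits, "frame": frame, "rankings": rankings, "out_dir": out_dir}
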