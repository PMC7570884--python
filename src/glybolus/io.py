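"""Serialization: subjects, scenarios, checkpoints and reports as versioned
JSON; traces and logs as tidy CSV."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from .config import SCHEMA_VERSION
from .metrics import GlycemicReport
from .patient import PatientParams
from .scenario import MealEvent, Scenario
from .therapy import TherapyParams

__all__ = ["save_json", "load_json", "save_subject", "load_subject",
           "save_scenario", "load_scenario", "save_checkpoint",
           "load_checkpoint", "save_report", "load_report"]


def save_json(obj: dict, path: str | Path, kind: str) -> None:
    payload = {"schema_version": SCHEMA_VERSION, "kind": kind, **obj}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_json(path: str | Path, kind: str) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != kind:
        raise ValueError(f"expected a {kind!r} file, got {payload.get('kind')!r}")
    return payload


def save_subject(path: str | Path, params: PatientParams,
                 therapy: TherapyParams | None = None) -> None:
    obj = {"patient": asdict(params)}
    if therapy is not None:
        obj["therapy"] = asdict(therapy)
    save_json(obj, path, "subject")


def load_subject(path: str | Path) -> tuple[PatientParams, TherapyParams | None]:
    payload = load_json(path, "subject")
    params = PatientParams(**payload["patient"])
    therapy = TherapyParams(**payload["therapy"]) if "therapy" in payload else None
    return params, therapy


def save_scenario(path: str | Path, scenario: Scenario) -> None:
    save_json({"days": scenario.days, "rng_seed": scenario.rng_seed,
               "meals": [asdict(m) for m in scenario.meals]}, path, "scenario")


def load_scenario(path: str | Path) -> Scenario:
    payload = load_json(path, "scenario")
    return Scenario(days=payload["days"], rng_seed=payload["rng_seed"],
                    meals=[MealEvent(**m) for m in payload["meals"]])


def save_checkpoint(path: str | Path, checkpoint: dict) -> None:
    save_json({"model": checkpoint}, path, "checkpoint")


def load_checkpoint(path: str | Path) -> dict:
    return load_json(path, "checkpoint")["model"]


def save_report(path: str | Path, report: GlycemicReport,
                extra: dict | None = None) -> None:
    save_json({"report": report.to_dict(), **(extra or {})}, path, "report")


def load_report(path: str | Path) -> GlycemicReport:
    return GlycemicReport(**load_json(path, "report")["report"])
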