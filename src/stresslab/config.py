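"""Run configuration, log serialization and reproducibility plumbing.

A :class:`RunConfig` fully determines a run: two runs with the same
config produce identical trial logs and identical stimulus-bank WAV
checksums.  The single seed is expanded into named substreams (synthesis,
schedule, observer) so each pipeline stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .lexicon import IAMBIC, TROCHAIC
from .observer import PRESETS, ObserverProfile
from .schedule import BUDGERIGAR, HUMAN, PhaseOutcome, SpeciesProfile, TrialRecord

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "resolve_observer",
    "resolve_species",
    "named_rng",
    "write_subject_log",
    "read_subject_log",
    "SubjectLog",
]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    species: str = "human"  # "human" | "budgerigar"
    observer: str | dict = "human_like"  # preset name or inline parameters
    training_set: int = 1
    splus_pattern: str = TROCHAIC
    sample_rate: int = 44100
    n_subjects: int = 1
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.training_set not in (1, 2):
            raise ValueError("training_set must be 1 or 2")
        if self.splus_pattern not in (TROCHAIC, IAMBIC):
            raise ValueError(f"unknown splus_pattern {self.splus_pattern!r}")
        if self.species not in ("human", "budgerigar"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def resolve_species(config: RunConfig) -> SpeciesProfile:
    return HUMAN if config.species == "human" else BUDGERIGAR


def resolve_observer(config: RunConfig) -> ObserverProfile:
    if isinstance(config.observer, str):
        try:
            return PRESETS[config.observer]
        except KeyError:
            raise ValueError(
                f"unknown observer preset {config.observer!r}; "
                f"available: {sorted(PRESETS)}"
            ) from None
    params = dict(config.observer)
    params.setdefault("name", "inline")
    return ObserverProfile(**params)


def named_rng(seed: int, name: str) -> np.random.Generator:
    """A named substream of the global seed (stable across runs)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# JSONL trial logs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectLog:
    meta: dict
    outcomes: list[PhaseOutcome]
    records: list[TrialRecord]


def _record_to_json(rec: TrialRecord) -> dict:
    d = dataclasses.asdict(rec)
    if isinstance(d.get("latency"), float) and math.isnan(d["latency"]):
        d["latency"] = None
    return d


def _record_from_json(d: dict) -> TrialRecord:
    return TrialRecord(**d)


def write_subject_log(path: str | Path, result) -> None:
    """Write one subject's run as JSONL: a metadata line, one line per
    phase outcome, then one line per trial record."""
    with open(path, "w") as fh:
        meta = {
            "type": "meta",
            "subject_id": result.subject_id,
            "observer": result.observer,
            "species": result.species,
            "trained_set_id": result.trained_set_id,
            "splus_pattern": result.splus_pattern,
            "seed": result.seed,
            "completed": result.completed,
        }
        fh.write(json.dumps(meta) + "\n")
        for outcome in result.outcomes:
            fh.write(
                json.dumps({"type": "outcome", **dataclasses.asdict(outcome)}) + "\n"
            )
        for rec in result.records:
            fh.write(json.dumps({"type": "trial", **_record_to_json(rec)}) + "\n")


def read_subject_log(path: str | Path) -> SubjectLog:
    meta: dict = {}
    outcomes: list[PhaseOutcome] = []
    records: list[TrialRecord] = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            kind = d.pop("type")
            if kind == "meta":
                meta = d
            elif kind == "outcome":
                outcomes.append(PhaseOutcome(**d))
            elif kind == "trial":
                records.append(_record_from_json(d))
            else:
                raise ValueError(f"unknown log line type {kind!r}")
    if not meta:
        raise ValueError(f"log {path} has no metadata line")
    return SubjectLog(meta, outcomes, records)
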