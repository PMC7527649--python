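"""Interchange formats, run configuration, and the end-to-end pipeline.

The single interchange format is a flat CSV of trial rows (the schema in
:data:`confbayes.simulate.TRIAL_COLUMNS`, optionally plus
``believes_worse``).  Configuration is YAML, validated strictly —
unknown keys are rejected with their location.  ``run_pipeline`` chains
design -> simulate -> analyze and writes a report directory with the
summary tables, the test battery, and a metadata sidecar carrying the
master seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .analysis import compare_to_bne, run_test_battery, summarize
from .simulate import (
    GROUPS,
    TRIAL_COLUMNS,
    GroupSpec,
    default_group_specs,
    simulate_experiment,
)

logger = logging.getLogger("confbayes")

__all__ = [
    "RunConfig",
    "GroupConfig",
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "run_pipeline",
]

_COLOR_SET = {"blue", "orange"}
_FLAG_SET = {0, 1}


class TrialValidationError(ValueError):
    """Raised when trial rows violate the schema; carries per-row messages."""

    def __init__(self, errors: List[str]):
        self.errors = errors
        preview = "\n".join(errors[:10])
        more = f"\n... and {len(errors) - 10} more" if len(errors) > 10 else ""
        super().__init__(f"{len(errors)} invalid trial rows:\n{preview}{more}")


class GroupConfig(BaseModel):
    """One study arm's simulator parameters (see ``GroupSpec``)."""

    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(ge=1)
    p_true: float = Field(gt=0, lt=1)
    p_est: float = Field(gt=0, lt=1, default=0.5524)
    beta: float = Field(gt=0)
    beta_log_sd: float = Field(ge=0, default=0.35)
    p_true_logit_sd: float = Field(ge=0, default=0.15)
    p_est_logit_sd: float = Field(ge=0, default=0.15)
    stay_prob_npi3: float = Field(gt=0, le=1, default=0.996)
    stay_prob_npi1: float = Field(gt=0, le=1, default=0.973)
    rt_log_mu: float = 1.05
    rt_log_sigma: float = Field(gt=0, default=0.35)
    rt_incongruent_shift: float = 0.04
    believes_worse_prob: float = Field(ge=0, le=1, default=0.25)


class RunConfig(BaseModel):
    """Validated end-to-end run configuration."""

    model_config = ConfigDict(extra="forbid")

    master_seed: int = 0
    n_trials: int = 60
    p_c_for_bne: float = Field(gt=0, lt=1, default=0.5524)
    shared_schedule: bool = False
    groups: Optional[Dict[str, GroupConfig]] = None
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except ValidationError as e:
            locs = "; ".join(
                f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                for err in e.errors()
            )
            raise ValueError(f"invalid config {path}: {locs}") from e

    def group_specs(self) -> Dict[str, GroupSpec]:
        if self.groups is None:
            return default_group_specs()
        specs = {}
        for name, g in self.groups.items():
            if name not in GROUPS:
                raise ValueError(f"unknown group {name!r}; expected one of {GROUPS}")
            specs[name] = GroupSpec(name=name, **g.model_dump())
        return specs

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_trials(data: pd.DataFrame, path) -> None:
    """Write trial rows to CSV; RTs rounded to 3 decimal places."""
    out = data.copy()
    for col in ("rt_first", "rt_second"):
        out[col] = out[col].round(3)
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    Row-level problems (illegal colors or flags, NPI inconsistent with
    the recorded responses, shift/conformity flags inconsistent with the
    responses) are collected with line numbers and raised together as a
    :class:`TrialValidationError`.
    """
    data = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in data.columns]
    if missing:
        raise TrialValidationError([f"missing columns: {', '.join(missing)}"])

    errors: List[str] = []

    def check(mask: pd.Series, msg: str) -> None:
        for idx in data.index[mask]:
            errors.append(f"line {idx + 2}: {msg} ({_row_brief(data.loc[idx])})")

    for col in ("true_color", "first_response", "second_response", "peer1", "peer2", "peer3"):
        check(~data[col].isin(_COLOR_SET), f"illegal color in {col!r}")
    for col in ("first_correct", "majority_correct", "conformed", "shifted"):
        check(~data[col].isin(_FLAG_SET), f"illegal flag in {col!r}")
    check(~data["npi"].isin((-3, -1, 1, 3)), "npi outside {-3, -1, 1, 3}")

    colors_ok = data[["first_response", "peer1", "peer2", "peer3"]].isin(_COLOR_SET).all(axis=1)
    agree = sum(
        (data[p] == data["first_response"]).astype(int) for p in ("peer1", "peer2", "peer3")
    )
    recomputed = 2 * agree - 3
    bad_npi = colors_ok & data["npi"].isin((-3, -1, 1, 3)) & (recomputed != data["npi"])
    for idx in data.index[bad_npi]:
        errors.append(
            f"line {idx + 2}: stored npi {data.loc[idx, 'npi']} != recomputed "
            f"{recomputed[idx]} ({_row_brief(data.loc[idx])})"
        )
    shift_ok = (data["second_response"] != data["first_response"]).astype(int)
    check(colors_ok & (data["shifted"] != shift_ok), "shifted flag inconsistent with responses")

    if errors:
        raise TrialValidationError(errors)
    return data


def _row_brief(row: pd.Series) -> str:
    return f"subject={row.get('subject_id')!r} trial={row.get('trial_index')!r}"


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Design -> simulate -> analyze end to end; writes a report directory.

    Writes ``data.csv`` (trial rows), ``summary_by_npi.csv`` and
    ``summary_by_condition.csv`` (group mean/SE tables), ``rt.csv``,
    ``subjects.csv``, ``tests.csv`` (the battery), ``bne_comparison.csv``,
    and ``metadata.json`` (seed, config hash, version, record counts).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage design+simulate: %d trials/subject", config.n_trials)
    data = simulate_experiment(
        group_specs=config.group_specs(),
        n_trials=config.n_trials,
        seed=config.master_seed,
        shared_schedule=config.shared_schedule,
    )
    logger.info("stage simulate: %d trial records", len(data))
    write_trials(data, out / "data.csv")

    tables = summarize(data)
    tables["by_npi"].round(3).to_csv(out / "summary_by_npi.csv", index=False)
    tables["by_condition"].round(3).to_csv(out / "summary_by_condition.csv", index=False)
    tables["rt"].round(3).to_csv(out / "rt.csv", index=False)
    tables["subjects"].round(6).to_csv(out / "subjects.csv", index=False)

    battery = run_test_battery(data)
    pd.DataFrame([t.to_dict() for t in battery]).to_csv(out / "tests.csv", index=False)
    logger.info("stage analyze: %d tests", len(battery))

    compare_to_bne(data, p_c=config.p_c_for_bne).round(6).to_csv(
        out / "bne_comparison.csv", index=False
    )

    meta = {
        "master_seed": config.master_seed,
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "version": __version__,
        "n_records": int(len(data)),
        "n_subjects": int(data["subject_id"].nunique()),
        "n_tests": len(battery),
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out
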