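"""Configuration parsing, dataset/result serialization and test fixtures."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import TRIAL_COLUMNS, TrialData

__all__ = [
    "RunConfig",
    "parse_config",
    "read_trial_csv",
    "write_trial_csv",
    "write_json",
    "write_table_csv",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with all defaults resolved."""

    family: str
    tau: float
    p1: float
    pi_admin: float
    pi_net: float
    beta1: float
    beta2: float
    c_admin: float = 1.0
    p_treat: float = 0.5
    level: float = 0.95
    m: int | None = None
    reps: int | None = None
    seed: int | None = None
    analysis: str = "composite"
    out: str | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.pi_net < self.pi_admin:
            raise ValueError(
                f"pi_net={self.pi_net} < pi_admin={self.pi_admin}: designs "
                "require π_A ≤ π (administrative censoring "
                "cannot exceed net censoring)"
            )
        for name, lo, hi in (("p1", 0, 1), ("pi_admin", 0, 1),
                             ("pi_net", 0, 1), ("p_treat", 0, 1),
                             ("level", 0, 1)):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}), got {v}")
        if self.analysis not in ("composite", "wlw"):
            raise ValueError("analysis must be 'composite' or 'wlw'")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_REQUIRED_KEYS = ("family", "tau", "p1", "pi_admin", "pi_net", "beta1", "beta2")


def parse_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file and/or keyword overrides.

    Flags (keyword overrides) take precedence over file values.  Unknown
    keys are rejected with a field-level message.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML superset also parses JSON
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})

    allowed = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(values) - allowed)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    missing = [k for k in _REQUIRED_KEYS if k not in values]
    if missing:
        raise ValueError(f"missing required config keys: {missing}")
    return RunConfig(**values)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def read_trial_csv(path: str | Path) -> TrialData:
    return TrialData.from_frame(pd.read_csv(path))


def write_trial_csv(data: TrialData, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False, columns=TRIAL_COLUMNS,
                           float_format="%.10g")


def _round_floats(obj):
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.10g}")
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_json(record: dict, path: str | Path) -> None:
    """JSON with deterministic key order and floats at 10 significant digits."""
    Path(path).write_text(
        json.dumps(_round_floats(record), indent=2, sort_keys=True) + "\n"
    )


def write_table_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("symmetric6", "separated", "wlw-toy")


def make_fixture(name: str) -> TrialData:
    """Small deterministic datasets with hand-checkable fits.

    ``symmetric6``: arm-exchangeable 6-subject trial (Cox estimate 0).
    ``separated``: all composite events in the control arm (fit diverges).
    ``wlw-toy``: 12 subjects with events in both arms for both components.
    """
    if name == "symmetric6":
        per_arm = dict(
            x1=[0.3, 0.5, 0.8], d1=[1, 1, 0],
            x2=[0.6, 0.9, 0.4], d2=[1, 0, 1],
            x=[0.3, 0.5, 0.4], d=[1, 1, 1],
        )
        return TrialData(
            id=np.arange(1, 7),
            z=np.array([0, 0, 0, 1, 1, 1]),
            **{k: np.array(v * 2, dtype=float if k.startswith("x") else int)
               for k, v in per_arm.items()},
        )
    if name == "separated":
        return TrialData(
            id=np.arange(1, 7),
            z=np.array([0, 0, 0, 1, 1, 1]),
            x1=np.array([0.2, 0.4, 0.6, 1.0, 1.0, 1.0]),
            d1=np.array([1, 1, 1, 0, 0, 0]),
            x2=np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0]),
            d2=np.array([0, 0, 0, 0, 0, 0]),
            x=np.array([0.2, 0.4, 0.6, 1.0, 1.0, 1.0]),
            d=np.array([1, 1, 1, 0, 0, 0]),
        )
    if name == "wlw-toy":
        x1 = np.array([0.11, 0.35, 0.62, 0.80, 1.0, 0.55,
                       0.21, 0.45, 0.90, 1.0, 0.70, 0.30])
        d1 = np.array([1, 1, 1, 1, 0, 1,
                       1, 1, 1, 0, 1, 1])
        x2 = np.array([0.50, 0.25, 1.0, 0.40, 0.75, 0.95,
                       0.60, 0.33, 0.85, 0.95, 1.0, 0.48])
        d2 = np.array([1, 1, 0, 1, 1, 1,
                       1, 1, 1, 1, 0, 1])
        x = np.minimum(x1, x2)
        d = np.where(x < 1.0, 1, 0)
        return TrialData(
            id=np.arange(1, 13),
            z=np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1]),
            x1=x1, d1=d1, x2=x2, d2=d2, x=x, d=d,
        )
    raise KeyError(
        f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
    )
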