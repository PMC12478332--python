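"""Configuration, fixtures-on-disk, logging and output writers.

Ties the library together for scripted use: scenario YAML round-trip,
canonical fixture generation (adult / pediatric / two-drug / parameter
sweep), and CSV/JSON writers with units in the column headers.  A run is
fully reproducible from its echoed configuration and seed; one global
seed fans out to named substreams for the environment, the agent and
fixture randomization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fixtures import carrier_rate, default_drug
from .scenarios import ScenarioSpec
from .transport import DrugSpec

__all__ = [
    "RunConfig",
    "substreams",
    "load_scenario",
    "save_scenario",
    "generate_fixtures",
    "write_timeseries",
    "write_metrics",
]

#: units appended to time-series columns on export
_UNITS = {
    "time_s": "time [s]",
    "carrier_mlh": "carrier flow [mL/h]",
    "total_flow_mlh": "total flow [mL/h]",
    "dispensed_ml": "dispensed volume [mL]",
}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    scenario_path: str
    out_dir: str
    seed: int = 0
    verbosity: int = 1


def substreams(seed: int, names: tuple[str, ...] = ("env", "agent", "fixtures")):
    """Fan a global seed out to named independent random streams."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def load_scenario(path: str | Path) -> ScenarioSpec:
    with open(path) as fh:
        return ScenarioSpec.from_dict(yaml.safe_load(fh))


def save_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def _scenario(kind: str, **kw) -> ScenarioSpec:
    if kind == "adult":
        return ScenarioSpec(
            name="adult_single_drug", fixture="adult",
            carrier_mlh=carrier_rate("adult"),
            drugs={4: (default_drug("propofol"), 1.0)},
            horizon_min=25.0, **kw,
        )
    if kind == "pediatric":
        return ScenarioSpec(
            name="pediatric_single_drug", fixture="pediatric",
            carrier_mlh=carrier_rate("pediatric"),
            drugs={4: (default_drug("propofol"), 0.5)},
            horizon_min=60.0, **kw,
        )
    if kind == "two_drug":
        return ScenarioSpec(
            name="pediatric_two_drug", fixture="pediatric",
            carrier_mlh=carrier_rate("pediatric"),
            drugs={4: (default_drug("phenylephrine"), 0.5),
                   3: (default_drug("norepinephrine"), 0.5)},
            horizon_min=70.0, **kw,
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


def generate_fixtures(kind: str, out_dir: str | Path) -> list[Path]:
    """Write canonical scenario YAMLs; returns the paths written.

    ``kind`` is one of adult, pediatric, two_drug or sweep; ``sweep``
    enumerates the Wt x (Qdmax/Qd) grid of the parameter-sweep study
    (Wt in {0, 0.5, 1} x ratio in {1, 3, 5}).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    if kind == "sweep":
        for wt in (0.0, 0.5, 1.0):
            for ratio in (1.0, 3.0, 5.0):
                spec = _scenario("adult", mode="det", wt=wt, qmax_ratio=ratio)
                spec = ScenarioSpec(**{**_spec_dict(spec), "name": f"sweep_wt{wt}_r{ratio}"})
                p = out / f"sweep_wt{wt}_r{ratio}.yaml"
                save_scenario(spec, p)
                paths.append(p)
        return paths
    spec = _scenario(kind)
    p = out / f"{kind}.yaml"
    save_scenario(spec, p)
    paths.append(p)
    return paths


def _spec_dict(spec: ScenarioSpec) -> dict:
    d = asdict(spec)
    d["drugs"] = spec.drugs
    d["events"] = spec.events
    return d


def write_timeseries(df: pd.DataFrame, path: str | Path) -> None:
    """CSV export with units in every column header."""
    renames = {}
    for col in df.columns:
        if col in _UNITS:
            renames[col] = _UNITS[col]
        elif col.startswith("q_"):
            renames[col] = f"{col[2:-4]} pump flow [mL/h]"
        elif col.startswith("c_tip_"):
            renames[col] = f"{col[6:]} tip concentration [conc]"
        elif col.startswith("chat_"):
            renames[col] = f"{col[5:]} normalized tip concentration [-]"
        elif col.startswith("delivery_"):
            renames[col] = f"{col[9:]} delivery rate [conc*mL/h]"
    df.rename(columns=renames).to_csv(path, index=False)


def write_metrics(metrics_by_drug: dict, path: str | Path, extra: dict | None = None) -> None:
    payload = {
        name: (asdict(m) if hasattr(m, "__dataclass_fields__") else m)
        for name, m in metrics_by_drug.items()
    }
    if extra:
        payload["run"] = extra
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
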