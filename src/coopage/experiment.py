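"""Configuration loading, scenario presets, sweeps and tabular output.

A run is parameterised by an INI-style config file ([model] section) plus
keyword overrides; a sweep varies one model parameter over a list of
values with a fixed number of replicates per value.  Replicate seeds are
derived deterministically from a master seed (master + row index), so a
results table is a pure function of (spec, master seed).

Two scale presets are provided: ``full`` (the reference
parameterisation: N=1000, t_end=80000, n=20 replicates) and ``desk``
(N=200, t_end=20000, n=5), the reduced scale used throughout the test
suite and worked examples.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .demography import SimulationConfig
from .lifecycle import run_replicate

__all__ = [
    "SweepSpec",
    "load_config",
    "run_experiment",
    "run_scenarios",
    "write_results",
    "SCALE_PRESETS",
    "RESULT_COLUMNS",
]

SCALE_PRESETS = {
    "full": {"N": 1000, "t_end": 80_000, "replicates": 20},
    "desk": {"N": 200, "t_end": 20_000, "replicates": 5},
}

_FLOAT_KEYS = {"d", "m", "mu", "sigma", "g", "q", "a", "b"}
_INT_KEYS = {"scenario", "N", "t_end", "c", "f_max", "seed"}

#: fixed column order of results tables
RESULT_COLUMNS = [
    "parameter", "value", "replicate", "seed",
    "scenario", "N", "t_end", "d", "c", "m", "mu", "sigma", "g", "q", "a", "b", "f_max",
    "mean_life_expectancy", "mean_age_first_reproduction", "mean_group_size",
    "relatedness", "population_size", "n_breeders", "n_helpers", "n_floaters",
    "t_final", "extinct", "error",
]


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a file and overrides.

    ``path`` points to an INI file whose ``[model]`` section holds
    ``key = value`` pairs for any config field; keyword ``overrides``
    take precedence over file values, and unset fields fall back to the
    defaults (the reference parameterisation, with ``q`` defaulting per
    scenario).  Unknown keys and out-of-range values raise ``ValueError``
    naming the offending field.
    """
    values: dict = {}
    if path is not None:
        parser = configparser.ConfigParser()
        read = parser.read(str(path))
        if not read:
            raise FileNotFoundError(f"config file not found: {path}")
        section = "model" if parser.has_section("model") else parser.default_section
        for key, raw in parser.items(section):
            values[key.strip()] = raw
    values.update(overrides)

    known = set(SimulationConfig.field_names())
    kwargs: dict = {}
    for key, raw in values.items():
        name = "N" if key in ("n", "N") else key
        if name not in known:
            raise ValueError(f"unknown configuration key: {key!r}")
        if raw is None or (isinstance(raw, str) and raw.strip().lower() in ("", "none")):
            continue
        try:
            if name in _INT_KEYS:
                kwargs[name] = int(raw)
            elif name in _FLOAT_KEYS:
                kwargs[name] = float(raw)
            else:
                raise ValueError
        except (TypeError, ValueError):
            raise ValueError(f"invalid value for {name!r}: {raw!r}") from None
    return SimulationConfig(**kwargs)


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep: run ``replicates`` seeds per parameter value.

    ``parameter`` may be any model parameter (``a``, ``d``, ``q``, ``m``,
    ``mu``, ``sigma``, ``c``, or ``scenario``); ``master_seed`` is the
    root of the deterministic per-replicate seed sequence.
    """

    parameter: str
    values: tuple
    replicates: int
    base: SimulationConfig
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.parameter not in SimulationConfig.field_names():
            raise ValueError(f"unknown sweep parameter: {self.parameter!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.values:
            raise ValueError("sweep needs at least one value")
        object.__setattr__(self, "values", tuple(self.values))


def _summary_row(config: SimulationConfig, parameter: str, value, replicate: int) -> dict:
    row = {"parameter": parameter, "value": value, "replicate": replicate}
    for name in SimulationConfig.field_names():
        row[name] = getattr(config, name)
    row["q"] = config.queue_q
    row["error"] = ""
    try:
        summary = run_replicate(config)
    except Exception as exc:  # pragma: no cover - defensive
        row["error"] = f"{type(exc).__name__}: {exc}"
        for k in ("mean_life_expectancy", "mean_age_first_reproduction",
                  "mean_group_size", "relatedness"):
            row[k] = float("nan")
        row.update(population_size=0, n_breeders=0, n_helpers=0, n_floaters=0,
                   t_final=-1, extinct=True, _schedule=None)
        return row
    row.update(
        mean_life_expectancy=summary.mean_life_expectancy,
        mean_age_first_reproduction=summary.mean_age_first_reproduction,
        mean_group_size=summary.mean_group_size,
        relatedness=summary.relatedness,
        population_size=summary.population_size,
        n_breeders=summary.n_breeders,
        n_helpers=summary.n_helpers,
        n_floaters=summary.n_floaters,
        t_final=summary.t_final,
        extinct=summary.extinct,
        _schedule=summary.age_survival_schedule,
    )
    return row


def run_experiment(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Run a sweep; one row per (parameter value, replicate).

    Replicate seeds are ``master_seed + row_index``.  A failing replicate
    is recorded in its row's ``error`` column and the run continues.  The
    per-age survival schedule of each run is carried in the ``_schedule``
    column (dropped by :func:`write_results`' main table and written to
    the sidecar schedule file instead).
    """
    rows = []
    index = 0
    for value in spec.values:
        for rep in range(spec.replicates):
            cfg = spec.base.with_(
                **{spec.parameter: value}, seed=spec.master_seed + index
            )
            rows.append(_summary_row(cfg, spec.parameter, value, rep))
            index += 1
            if progress:
                print(f"  {spec.parameter}={value} replicate {rep}: done")
    df = pd.DataFrame(rows)
    return df[[c for c in RESULT_COLUMNS if c in df.columns] + ["_schedule"]]


def run_scenarios(
    scenarios: Sequence[int],
    base: SimulationConfig,
    replicates: int,
    master_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Convenience sweep over breeding-system scenarios.

    The queue parameter is reset to each scenario's default (``q=None``).
    """
    spec = SweepSpec(
        parameter="scenario",
        values=tuple(scenarios),
        replicates=replicates,
        base=base.with_(q=None),
        master_seed=master_seed,
    )
    return run_experiment(spec, progress=progress)


def write_results(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a results table as TSV plus sidecar files.

    The main table goes to ``path`` (tab-separated, fixed column order,
    missing statistics as ``NA``).  A ``<path>.schedules.tsv`` sidecar
    holds the per-age survival schedules in long format and a
    ``<path>.config.json`` sidecar the fully resolved base configuration
    of every run.
    """
    if table.empty:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    main = table[[c for c in RESULT_COLUMNS if c in table.columns]]
    main.to_csv(path, sep="\t", index=False, na_rep="NA")

    if "_schedule" in table.columns:
        recs = []
        for i, sched in enumerate(table["_schedule"]):
            if sched is None:
                continue
            for age, s in enumerate(np.asarray(sched)):
                recs.append({"row": i, "age": age, "survival": s})
        if recs:
            pd.DataFrame(recs).to_csv(
                path.with_suffix(path.suffix + ".schedules.tsv"),
                sep="\t", index=False, na_rep="NA",
            )

    configs = table[[c for c in SimulationConfig.field_names() if c in table.columns]]
    sidecar = {
        "columns": list(main.columns),
        "runs": configs.to_dict(orient="records"),
    }
    path.with_suffix(path.suffix + ".config.json").write_text(
        json.dumps(sidecar, indent=2, default=_json_default)
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a TSV results table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
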