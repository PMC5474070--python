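"""Readers/writers for bout and roster tables, and the pipeline runner.

Bout CSV schema (one row per processing attempt):
    day         1-based experimental day (integer)
    seq         1-based order within the day
    actor       individual id
    technique   technique label
    success     0/1
    duration_s  seconds (decimal)
    audience    semicolon-joined individual ids; empty allowed

Roster CSV schema: id, age_years, matriline, alpha (0/1).  Days are
experiment days, not calendar dates; any calendar mapping belongs in the
dataset metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TechniqueSet
from .cues import BoutRecord, RosterInfo

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "read_dataset",
    "write_dataset",
    "run_pipeline",
    "PipelineConfigError",
]

BOUT_COLUMNS = ("day", "seq", "actor", "technique", "success", "duration_s", "audience")
ROSTER_COLUMNS = ("id", "age_years", "matriline", "alpha")


@dataclass
class Dataset:
    """A bout table plus the individual roster and free-form metadata."""

    bouts: list[BoutRecord]
    roster: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        info = RosterInfo(self.roster)
        seen: set[tuple[int, int]] = set()
        for m, b in enumerate(self.bouts):
            if b.actor not in info:
                raise ValueError(f"bout {m}: actor {b.actor!r} not in roster")
            for j in b.audience:
                if j not in info:
                    raise ValueError(
                        f"bout {m}: audience member {j!r} not in roster"
                    )
            key = (b.day, b.seq)
            if key in seen:
                raise ValueError(f"duplicate (day, seq) pair {key}")
            seen.add(key)

    @property
    def techniques(self) -> TechniqueSet:
        names = sorted({b.technique for b in self.bouts})
        return TechniqueSet(tuple(names))

    def sorted_bouts(self) -> list[BoutRecord]:
        return sorted(self.bouts, key=lambda b: (b.day, b.seq))


def write_dataset(dataset: Dataset, bouts_path, roster_path) -> None:
    """Write the bout and roster tables in the documented CSV dialect."""
    rows = [
        {
            "day": b.day, "seq": b.seq, "actor": b.actor,
            "technique": b.technique, "success": int(b.success),
            "duration_s": b.duration_s,
            "audience": ";".join(sorted(b.audience)),
        }
        for b in dataset.sorted_bouts()
    ]
    pd.DataFrame(rows, columns=list(BOUT_COLUMNS)).to_csv(
        bouts_path, index=False, float_format="%.17g")
    roster = dataset.roster.reset_index()
    roster.columns = ["id", *dataset.roster.columns]
    roster["alpha"] = roster["alpha"].astype(int)
    roster.to_csv(roster_path, index=False, float_format="%.17g")


def read_dataset(bouts_path, roster_path) -> Dataset:
    """Read and validate a dataset; raises with row/id context on bad input."""
    roster_df = pd.read_csv(roster_path, float_precision="round_trip")
    missing = set(ROSTER_COLUMNS) - set(roster_df.columns)
    if missing:
        raise ValueError(f"roster {roster_path}: missing columns {sorted(missing)}")
    roster = roster_df.set_index("id")
    roster.index = roster.index.astype(str)
    roster["alpha"] = roster["alpha"].astype(bool)

    bouts_df = pd.read_csv(bouts_path, dtype={"audience": str},
                           keep_default_na=False, float_precision="round_trip")
    missing = set(BOUT_COLUMNS) - set(bouts_df.columns)
    if missing:
        raise ValueError(f"bout table {bouts_path}: missing columns {sorted(missing)}")
    bouts = []
    for m, row in enumerate(bouts_df.itertuples(index=False)):
        audience = frozenset(x for x in str(row.audience).split(";") if x)
        try:
            bouts.append(BoutRecord(
                day=int(row.day), seq=int(row.seq), actor=str(row.actor),
                technique=str(row.technique), success=bool(int(row.success)),
                duration_s=float(row.duration_s), audience=audience,
            ))
        except (ValueError, TypeError) as e:
            raise ValueError(f"bout table row {m}: {e}") from e
    return Dataset(bouts=bouts, roster=roster)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class PipelineConfigError(ValueError):
    """Invalid pipeline configuration; the message names the offending key."""


def _load_config(config_path) -> dict:
    import yaml

    text = Path(config_path).read_text()
    cfg = yaml.safe_load(text)   # YAML is a superset of JSON
    if not isinstance(cfg, dict):
        raise PipelineConfigError(f"config {config_path} must be a mapping")
    return cfg


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise PipelineConfigError(f"config key {key!r} is required")
    return cfg[key]


def _mcmc_from(cfg: dict, seed: int | None):
    from .inference import MCMCConfig

    m = cfg.get("mcmc", {})
    allowed = {"chains", "iterations", "warmup", "seed", "max_draws"}
    bad = set(m) - allowed
    if bad:
        raise PipelineConfigError(f"config key 'mcmc.{sorted(bad)[0]}' is unknown")
    if seed is not None:
        m = {**m, "seed": seed}
    return MCMCConfig(**m)


def _spec_from(cfg: dict, window_days: int | None):
    from .inference import spec_by_label

    label = _require(cfg, "spec")
    kw = {}
    if window_days is not None:
        kw["window_days"] = window_days
    elif "window_days" in cfg:
        kw["window_days"] = int(cfg["window_days"])
    try:
        return spec_by_label(label, **kw)
    except ValueError as e:
        raise PipelineConfigError(f"config key 'spec': {e}") from e


def run_pipeline(
    command: str,
    config_path,
    seed: int | None = None,
    out_dir=None,
    window_days: int | None = None,
) -> int:
    """Run one pipeline stage and write its artifacts to a run directory.

    Commands: simulate, fit, compare, recover, sensitivity.  Returns 0 on
    success, 2 on configuration errors (after logging a message naming the
    offending key).  Identical config and seed reproduce simulate outputs
    exactly.
    """
    from . import __version__
    from .compare import compare_models, window_sensitivity
    from .inference import fit_model, recover
    from .simulate import make_fixture

    try:
        cfg = _load_config(config_path)
        out = Path(out_dir) if out_dir is not None else Path("runs") / command
        out.mkdir(parents=True, exist_ok=True)

        if command == "simulate":
            fixture = _require(cfg, "fixture")
            sim_seed = seed if seed is not None else cfg.get("seed")
            config, bouts = make_fixture(fixture, seed=sim_seed)
            ds = Dataset(bouts=bouts, roster=config.roster,
                         metadata={"fixture": fixture, "seed": config.seed})
            write_dataset(ds, out / "bouts.csv", out / "roster.csv")
            resolved = {"command": command, "fixture": fixture,
                        "seed": config.seed, "n_bouts": len(bouts),
                        "techniques": list(config.technique_set.names)}
        elif command == "fit":
            spec = _spec_from(cfg, window_days)
            mcmc = _mcmc_from(cfg, seed)
            ds = read_dataset(_require(cfg, "bouts"), _require(cfg, "roster"))
            fit = fit_model(ds.sorted_bouts(), ds.roster, ds.techniques, spec,
                            mcmc=mcmc)
            _write_posterior(fit, out / "posterior.csv")
            summary = {
                "spec": spec.label, "seed": mcmc.seed,
                "diagnostics": fit.diagnostics,
                "posterior_median": {
                    k: float(v) for k, v in
                    fit.population_draws().median().items()
                },
            }
            (out / "summary.json").write_text(json.dumps(summary, indent=2))
            resolved = {"command": command, "spec": spec.label,
                        "mcmc": dataclasses.asdict(mcmc)}
        elif command == "compare":
            labels = _require(cfg, "specs")
            mcmc = _mcmc_from(cfg, seed)
            ds = read_dataset(_require(cfg, "bouts"), _require(cfg, "roster"))
            fits = []
            for label in labels:
                spec = _spec_from({"spec": label, **cfg}, window_days)
                fits.append(fit_model(ds.sorted_bouts(), ds.roster,
                                      ds.techniques, spec, mcmc=mcmc))
            table = compare_models(fits)
            table.table.to_csv(out / "model_table.csv", index=False)
            (out / "model_table.json").write_text(
                table.table.to_json(orient="records", indent=2))
            resolved = {"command": command, "specs": list(labels),
                        "mcmc": dataclasses.asdict(mcmc)}
        elif command == "recover":
            fixture = _require(cfg, "fixture")
            config, _ = make_fixture(fixture)
            spec = _spec_from(cfg, window_days)
            mcmc = _mcmc_from(cfg, seed)
            n_rep = int(cfg.get("n_replicates", 3))
            report = recover(config, spec, n_rep, mcmc=mcmc)
            report.drop(columns=["replicate_medians"], errors="ignore").to_csv(
                out / "recovery.csv", index=False)
            (out / "recovery.json").write_text(
                report.to_json(orient="records", indent=2))
            resolved = {"command": command, "fixture": fixture,
                        "spec": spec.label, "n_replicates": n_rep,
                        "mcmc": dataclasses.asdict(mcmc)}
        elif command == "sensitivity":
            ds = read_dataset(_require(cfg, "bouts"), _require(cfg, "roster"))
            spec = _spec_from(cfg, None)
            mcmc = _mcmc_from(cfg, seed)
            widths = tuple(cfg.get("widths", (7, 14, 21, 28)))
            table = window_sensitivity(ds.sorted_bouts(), ds.roster,
                                       ds.techniques, spec, widths=widths,
                                       mcmc=mcmc)
            table.to_csv(out / "sensitivity.csv", index=False)
            (out / "sensitivity.json").write_text(
                table.to_json(orient="records", indent=2))
            resolved = {"command": command, "spec": spec.label,
                        "widths": list(widths), "mcmc": dataclasses.asdict(mcmc)}
        else:
            raise PipelineConfigError(
                f"unknown command {command!r}; valid: simulate, fit, compare, "
                "recover, sensitivity"
            )

        resolved["version"] = __version__
        (out / "config_resolved.json").write_text(json.dumps(resolved, indent=2))
        logger.info("%s: artifacts written to %s", command, out)
        return 0
    except PipelineConfigError as e:
        logger.error("invalid config: %s", e)
        return 2
    except (OSError, ValueError) as e:
        logger.error("pipeline input error: %s", e)
        return 2


def _write_posterior(fit, path) -> None:
    """Flat posterior CSV: parameter, chain, iteration, value."""
    long = fit.draws.reset_index(names="iteration").melt(
        id_vars="iteration", var_name="parameter", value_name="value")
    long["chain"] = 0
    long[["parameter", "chain", "iteration", "value"]].to_csv(path, index=False)
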