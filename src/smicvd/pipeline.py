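"""End-to-end orchestration: simulate -> build -> score -> survival -> calibrate -> describe.

Each stage reads and writes plain CSV/JSON artifacts in a run directory,
so stages can be re-run individually (the CLI exposes them as
subcommands).  A manifest records the configuration, seed, package version
and a SHA-256 digest of every data artifact; re-running from the same
configuration and seed reproduces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import calibration_table
from .cohort import build_eligible_table
from .errors import SmicvdError
from .reporting import descriptive_table
from .risk import RiskEquationSpec, default_equation, load_spec, score_cohort
from .survival import age_adjusted_curves
from .synthetic import SimulationConfig, generate_cohort, write_tables

logger = logging.getLogger(__name__)

MIN_CALIBRATION_N = 10


def _read_persons(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "persons.csv", dtype={"person_id": str},
                       keep_default_na=True)


def stage_simulate(cfg: SimulationConfig, outdir: Path,
                   equation: RiskEquationSpec | None = None) -> None:
    persons, contacts = generate_cohort(cfg, equation)
    write_tables(persons, contacts, outdir)
    logger.info("simulate: wrote %d persons, %d contacts", len(persons), len(contacts))


def stage_build(outdir: Path) -> None:
    persons = _read_persons(outdir)
    contacts = pd.read_csv(outdir / "contacts.csv", dtype={"person_id": str})
    eligible, flow = build_eligible_table(persons, contacts)
    eligible.to_csv(outdir / "eligible.csv", index=False)
    (outdir / "flow.json").write_text(json.dumps(flow.to_dict(), indent=2) + "\n")
    logger.info("build: %d in -> %d eligible", len(persons), len(eligible))


def stage_score(outdir: Path, equation: RiskEquationSpec) -> None:
    eligible = pd.read_csv(outdir / "eligible.csv", dtype={"person_id": str})
    risks = score_cohort(eligible, equation)
    risks.to_csv(outdir / "risks.csv", index=False)
    logger.info("score: %d persons scored", len(risks))


def _exposure_group(eligible: pd.DataFrame) -> pd.Series:
    smi = eligible["smi"].astype(bool)
    psych = eligible["psychosis"].astype(bool)
    return pd.Series(
        np.where(psych, "psychosis_smi", np.where(smi, "non_psychosis_smi", "none")),
        index=eligible.index,
    )


def stage_survival(outdir: Path) -> None:
    eligible = pd.read_csv(outdir / "eligible.csv", dtype={"person_id": str})
    if eligible.empty:
        pd.DataFrame(columns=["group", "time", "estimate", "lower", "upper"]).to_csv(
            outdir / "curves.csv", index=False)
        return
    eligible["is_event"] = eligible["event_type"] == "cvd"
    frames = []
    # overall SMI vs none, then the psychosis split; reference weights are
    # the whole eligible cohort both times, so panels are comparable
    binary = eligible.assign(
        _grp=np.where(eligible["smi"].astype(bool), "smi", "none"))
    frames.append(age_adjusted_curves(binary, "_grp").to_frame())
    three = eligible.assign(_grp=_exposure_group(eligible))
    cur3 = age_adjusted_curves(three, "_grp").to_frame()
    frames.append(cur3[cur3["group"] != "none"])
    curves = pd.concat(frames, ignore_index=True)
    curves.to_csv(outdir / "curves.csv", index=False)
    logger.info("survival: %d curve rows for %d persons", len(curves), len(eligible))


def stage_calibrate(outdir: Path, horizon: float = 5.0) -> None:
    eligible = pd.read_csv(outdir / "eligible.csv", dtype={"person_id": str})
    risks = pd.read_csv(outdir / "risks.csv", dtype={"person_id": str})
    merged = eligible.merge(risks, on="person_id", validate="one_to_one")
    merged["is_event"] = merged["event_type"] == "cvd"

    populations = {
        "smi": merged[merged["smi"].astype(bool)],
        "no_mh": merged[~merged["smi"].astype(bool)],
    }
    for sex, label in (("F", "smi_female"), ("M", "smi_male")):
        populations[label] = merged[
            merged["smi"].astype(bool) & (merged["sex"] == sex)
        ]

    rows, summary = [], {}
    for label, pop in populations.items():
        if len(pop) < MIN_CALIBRATION_N:
            summary[label] = {"mean_ratio": None, "person_weighted_ratio": None,
                              "n": int(len(pop)), "flag": "empty_or_too_small"}
            logger.warning("calibrate: population %s has n=%d, skipped", label, len(pop))
            continue
        tab = calibration_table(
            pop["predicted_risk"], pop["event_time_years"], pop["is_event"],
            person_ids=pop["person_id"], horizon=horizon, population=label,
        )
        t = tab.table.copy()
        t.insert(0, "population", label)
        rows.append(t)
        summary[label] = {
            "mean_ratio": tab.mean_ratio,
            "person_weighted_ratio": tab.person_weighted_ratio,
            "n": int(len(pop)),
        }
    out = (pd.concat(rows, ignore_index=True) if rows else
           pd.DataFrame(columns=["population", "decile", "n", "mean_predicted",
                                 "observed", "lower", "upper", "ratio", "zero_events"]))
    out.to_csv(outdir / "calibration.csv", index=False)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("calibrate: %d populations summarised", len(summary))


def stage_describe(outdir: Path) -> None:
    eligible = pd.read_csv(outdir / "eligible.csv", dtype={"person_id": str})
    table = descriptive_table(eligible)
    table.table.to_csv(outdir / "descriptive.csv", index=False)
    logger.info("describe: %d table rows", len(table.table))


DATA_ARTIFACTS = (
    "persons.csv", "contacts.csv", "eligible.csv", "flow.json", "risks.csv",
    "curves.csv", "calibration.csv", "summary.json", "descriptive.csv",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: SimulationConfig | dict | str | Path,
    outdir: str | Path,
    seed: int | None = None,
    equation: RiskEquationSpec | str | Path | None = None,
) -> dict:
    """Run every stage and write a manifest; returns the manifest dict.

    ``config`` may be a SimulationConfig, a dict, or a JSON/YAML path;
    ``seed`` overrides the config's seed; ``equation`` may be a spec object
    or a JSON/YAML equation document (defaults to the bundled illustrative
    equation).  Identical (config, seed) inputs reproduce byte-identical
    artifacts.
    """
    if isinstance(config, (str, Path)):
        cfg = SimulationConfig.from_file(config)
    elif isinstance(config, dict):
        cfg = SimulationConfig.from_dict(config)
    else:
        cfg = config
    if seed is not None:
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "seed": int(seed)})
    cfg.validate()
    if equation is None:
        eq = default_equation()
    elif isinstance(equation, (str, Path)):
        eq = load_spec(equation)
    else:
        eq = equation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = (
        ("simulate", lambda: stage_simulate(cfg, outdir, eq)),
        ("build", lambda: stage_build(outdir)),
        ("score", lambda: stage_score(outdir, eq)),
        ("survival", lambda: stage_survival(outdir)),
        ("calibrate", lambda: stage_calibrate(outdir, eq.horizon_years)),
        ("describe", lambda: stage_describe(outdir)),
    )
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise SmicvdError(f"pipeline stage {name!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "files": {name: _sha256(outdir / name) for name in DATA_ARTIFACTS
                  if (outdir / name).exists()},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
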