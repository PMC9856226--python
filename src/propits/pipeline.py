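"""End-to-end pipeline: generate (or load) → classify → monthly series →
characteristics → ITS → meta-analysis, with reproducible CSV outputs.

Every output CSV starts with a comment line recording the package version,
seed and bootstrap size, so any table can be traced back to the run that
produced it.  Read them back with ``pd.read_csv(path, comment="#")``.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codemap import load_codemap
from .cohort import (
    ANY_MH,
    FEMALE_SHARE,
    characteristics_table,
    filter_eligible,
    monthly_series,
)
from .errors import ConfigurationError
from .its import FEATURED_CONDITIONS, results_frame, run_all_its
from .meta import MetaInput, forest_table, meta_frame, pool_hierarchy
from .synthetic import SyntheticConfig, default_scenarios, export_ground_truth, generate_records

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" or "real"
    seed: int = 0
    output_dir: str = "propits_output"
    hospitalizations: str | None = None  # real mode inputs
    diagnoses: str | None = None
    codemap: str = "default"
    bootstrap_iterations: int = 10_000
    alpha: float = 0.05
    p_method: str = "z"
    conditions: tuple[str, ...] = FEATURED_CONDITIONS
    monthly_admissions_scale: float = 1.0  # scales synthetic site volumes

    def __post_init__(self) -> None:
        if self.mode not in {"synthetic", "real"}:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            for label, path in (
                ("hospitalizations", self.hospitalizations),
                ("diagnoses", self.diagnoses),
            ):
                if path is None:
                    raise ConfigurationError(f"real mode requires a {label} file")
                if not Path(path).exists():
                    raise ConfigurationError(f"{label} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def write_csv(df: pd.DataFrame, path: Path, *, seed: int, B: int) -> None:
    """Write a CSV with a provenance comment header."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# propits {__version__} seed={seed} B={B}\n")
        df.to_csv(fh, index=False)


def summarize_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Per-site monthly hospitalization counts with simple outlier flags.

    A month is flagged when its count deviates from the site median by more
    than 3 median absolute deviations (an MAD of 0 flags any deviation).
    """
    counts = (
        records.groupby(["site_id", "month"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    out = []
    for site, sub in counts.groupby("site_id", observed=True):
        med = sub["count"].median()
        mad = (sub["count"] - med).abs().median()
        dev = (sub["count"] - med).abs()
        flagged = dev > 3 * mad if mad > 0 else dev > 0
        sub = sub.assign(site_median=med, mad=mad, flagged=flagged)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a run manifest.

    Stages: generate (synthetic mode) or load (real mode), classify and
    filter, monthly series, characteristics, count diagnostics, ITS,
    meta-analysis.  All outputs land in ``config.output_dir``; any stage
    error is logged with its stage name and re-raised after the manifest
    records the failure, preserving partial outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "row_counts": {},
    }
    t0 = time.time()
    stage = "setup"
    try:
        codemap = load_codemap(config.codemap)

        stage = "generate" if config.mode == "synthetic" else "load"
        if config.mode == "synthetic":
            scenarios = tuple(
                dataclasses.replace(
                    s,
                    monthly_admissions_mean=s.monthly_admissions_mean
                    * config.monthly_admissions_scale,
                )
                for s in default_scenarios()
            )
            syn = SyntheticConfig(seed=config.seed, scenarios=scenarios)
            hosp, diag = generate_records(syn)
            write_csv(hosp, out / "hospitalizations.csv", seed=config.seed, B=0)
            write_csv(diag, out / "diagnoses.csv", seed=config.seed, B=0)
            write_csv(
                export_ground_truth(syn), out / "ground_truth.csv", seed=config.seed, B=0
            )
        else:
            hosp = pd.read_csv(config.hospitalizations, comment="#")
            diag = pd.read_csv(config.diagnoses, comment="#")
        manifest["stages"].append(stage)

        stage = "classify"
        records = filter_eligible(hosp, diag, codemap)
        manifest["row_counts"]["eligible_hospitalizations"] = len(records)
        manifest["stages"].append(stage)

        stage = "series"
        outcomes = [ANY_MH, *config.conditions, FEMALE_SHARE]
        series_by_outcome = {o: monthly_series(records, o) for o in outcomes}
        all_series = pd.concat(series_by_outcome.values(), ignore_index=True)
        write_csv(
            all_series.assign(month=all_series["month"].astype(str)),
            out / "monthly_series.csv",
            seed=config.seed,
            B=0,
        )
        manifest["row_counts"]["monthly_series"] = len(all_series)
        manifest["stages"].append(stage)

        stage = "characteristics"
        chars = characteristics_table(records, seed=config.seed)
        write_csv(chars.to_frame(), out / "characteristics.csv", seed=config.seed, B=0)
        manifest["stages"].append(stage)

        stage = "diagnostics"
        diag_counts = summarize_counts(records)
        write_csv(
            diag_counts.assign(month=diag_counts["month"].astype(str)),
            out / "count_diagnostics.csv",
            seed=config.seed,
            B=0,
        )
        manifest["stages"].append(stage)

        stage = "its"
        its_results = run_all_its(
            series_by_outcome,
            B=config.bootstrap_iterations,
            seed=config.seed,
            alpha=config.alpha,
            p_method=config.p_method,
            conditions=config.conditions,
        )
        its_df = results_frame(its_results)
        write_csv(
            its_df, out / "its_results.csv", seed=config.seed, B=config.bootstrap_iterations
        )
        manifest["row_counts"]["its_results"] = len(its_df)
        manifest["stages"].append(stage)

        stage = "meta"
        country_of = records.drop_duplicates("site_id").set_index("site_id")["country"]
        site_rows = its_df[(its_df["outcome"] == ANY_MH) & its_df["delta"].notna()]
        inputs = [
            MetaInput(
                site_id=row.site_id,
                country=str(country_of.get(row.site_id, "?")),
                estimate=row.delta,
                se=row.delta_boot_sd,
            )
            for row in site_rows.itertuples()
        ]
        pools = pool_hierarchy(inputs, alpha=config.alpha)
        write_csv(
            meta_frame(pools),
            out / "meta_results.csv",
            seed=config.seed,
            B=config.bootstrap_iterations,
        )
        write_csv(
            forest_table(inputs, pools),
            out / "forest_table.csv",
            seed=config.seed,
            B=config.bootstrap_iterations,
        )
        manifest["stages"].append(stage)
    except Exception:
        logger.exception("pipeline stage %r failed", stage)
        manifest["failed_stage"] = stage
        manifest["wall_clock_s"] = round(time.time() - t0, 3)
        _write_manifest(manifest, out)
        raise
    manifest["wall_clock_s"] = round(time.time() - t0, 3)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
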