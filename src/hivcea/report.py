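"""Run orchestration and report rendering.

``run`` executes the full pipeline from a config file and writes the result
bundle: the scenario-comparison table replica (CSV + JSON), the waiting
table, the tornado table, an optional microsimulation summary, and a
manifest with the config snapshot, seeds and output checksums so any run
can be reproduced from its own bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Literal

import pandas as pd

from . import __version__
from .cohort import SimulationConfig, microsimulate, sample_cohort
from .engine import CEARow, CEASummary, run_base_case
from .params import ModelParameters, load_parameters
from .sensitivity import TornadoEntry, default_ranges, tornado
from .waiting import cohort_wait_summary, decline_at_percentile, default_bins

logger = logging.getLogger("hivcea")

__all__ = ["render_table2", "table2_frame", "waiting_frame", "tornado_frame", "run"]

_USD_ROWS = {
    "Lifetime Cost, cART + Monitoring",
    "24 Months Hospitalization Cost",
    "Net Cost",
    "Cost per DALY",
}


def _fmt_years(x: float | None) -> str:
    return "" if x is None else f"{x:.2f}"


def _fmt_usd(x: float | None) -> str:
    return "" if x is None else f"${x:,.0f}"


def table2_frame(summary: CEASummary) -> pd.DataFrame:
    """Numeric scenario-comparison table, one record per quantity × row."""
    records = []
    for row in summary.rows:
        icer_cell = row.icer if row.icer is not None else None
        quantities = [
            ("Life Expectancy, in years", row.le_a, row.le_b),
            ("Discounted Life Expectancy, in years", row.dle_a, row.dle_b),
            ("YLL", None, row.yll),
            ("YLD", None, row.yld),
            ("DALY", None, row.daly),
            ("Lifetime Cost, cART + Monitoring", row.cart_monitoring_a, row.cart_monitoring_b),
            ("24 Months Hospitalization Cost", row.hosp_a, row.hosp_b),
            ("Net Cost", row.net_a, row.net_b),
            ("Cost per DALY", icer_cell, None),
        ]
        for name, a, b in quantities:
            records.append(
                {
                    "quantity": name,
                    "baseline_cd4": row.label,
                    "scenario_a": a,
                    "scenario_b": b,
                    "dominance": row.dominance if name == "Cost per DALY" else None,
                }
            )
    return pd.DataFrame(records)


def render_table2(summary: CEASummary) -> pd.DataFrame:
    """Display-formatted replica: years to 2 dp, USD to whole dollars with
    thousands separators; dominance rendered as a label in the ICER cell."""
    if not summary.rows:
        raise ValueError("summary has no rows")
    df = table2_frame(summary)

    def fmt(row: pd.Series, col: str) -> str:
        val = row[col]
        if row["quantity"] == "Cost per DALY" and col == "scenario_a" and pd.isna(val):
            return row["dominance"] or ""
        if val is None or pd.isna(val):
            return ""
        return _fmt_usd(val) if row["quantity"] in _USD_ROWS else _fmt_years(val)

    out = df.copy()
    for col in ("scenario_a", "scenario_b"):
        out[col] = [fmt(row, col) for _, row in df.iterrows()]
    return out.drop(columns=["dominance"])


def waiting_frame(
    params: ModelParameters,
    decline_percentile: Literal["q25", "median", "q75"] = "median",
) -> pd.DataFrame:
    """Per-bin waiting table: wait and CD4 at initiation."""
    decline = decline_at_percentile(params.decline, decline_percentile)
    ws = cohort_wait_summary(
        default_bins(params), decline, params.cd4_threshold, params.decline.period_length
    )
    return pd.DataFrame(
        [
            {
                "bin": label,
                "baseline_cd4": o.cd4_trajectory[0][1],
                "wait_months": o.wait_years * 12.0,
                "cd4_at_initiation": o.cd4_at_initiation,
            }
            for label, o in ws["outcomes"].items()
        ]
    )


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in entries])


def _row_dict(row: CEARow) -> dict:
    d = asdict(row)
    d["dominance"] = row.dominance
    return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(
    config_path: str | Path | None,
    output_dir: str | Path,
    decline_percentile: Literal["q25", "median", "q75"] = "median",
    discount_convention: str | None = None,
    sensitivity: bool = True,
    microsim: bool = False,
    n_patients: int = 10_000,
    seed: int = 1,
) -> dict:
    """Execute the pipeline and write the result bundle; returns the manifest."""
    params = load_parameters(config_path)
    if discount_convention is not None:
        d = params.to_dict()
        d["discount"]["convention"] = discount_convention
        from .params import parameters_from_dict

        params = parameters_from_dict(d)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("cohort model: decline percentile %s", decline_percentile)
    summary = run_base_case(params, decline_percentile)
    files: dict[str, Path] = {}

    files["table2_replica.csv"] = out / "table2_replica.csv"
    render_table2(summary).to_csv(files["table2_replica.csv"], index=False)
    files["table2_replica.json"] = out / "table2_replica.json"
    files["table2_replica.json"].write_text(
        json.dumps(
            {
                "lowest": _row_dict(summary.lowest),
                "mean": _row_dict(summary.mean),
                "highest": _row_dict(summary.highest),
                "classification": summary.classification.value,
            },
            indent=2,
        )
    )
    files["waiting_table.csv"] = out / "waiting_table.csv"
    waiting_frame(params, decline_percentile).to_csv(files["waiting_table.csv"], index=False)

    if sensitivity:
        logger.info("one-way sensitivity analysis over %d parameters", len(default_ranges()))
        files["tornado.csv"] = out / "tornado.csv"
        tornado_frame(tornado(default_ranges(), params)).to_csv(
            files["tornado.csv"], index=False
        )

    if microsim:
        logger.info("microsimulation: n=%d seed=%d", n_patients, seed)
        cohort = sample_cohort(
            SimulationConfig(n_patients=n_patients, seed=seed, params=params)
        )
        sim = microsimulate(cohort)
        files["cohort.csv"] = out / "cohort.csv"
        sim["patients"].to_csv(files["cohort.csv"], index=False)
        files["cohort_summary.json"] = out / "cohort_summary.json"
        files["cohort_summary.json"].write_text(
            json.dumps({k: v for k, v in sim.items() if k != "patients"}, indent=2)
        )

    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "seed": seed,
        "decline_percentile": decline_percentile,
        "config": params.to_dict(),
        "classification": summary.classification.value,
        "outputs": {name: _sha256(path) for name, path in files.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("wrote %d outputs to %s", len(files) + 1, out)
    return manifest
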