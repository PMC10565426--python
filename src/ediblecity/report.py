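"""Scenario-comparison report: build scenarios, run all eight indicators.

The typical workflow is to compare a base city with scenarios converting
an increasing share of gardens, vacant plots and rooftops to urban
agriculture.  ``run_report`` builds each scenario from a shared master
seed (named substreams keep every indicator's draws independent of the
others) and tabulates, per scenario: urban-agriculture element counts and
surfaces, the heat-island summary, the runoff triplet, total NO2
sequestration, jobs/volunteers/food Monte-Carlo intervals, the green
accessibility summary and the green-per-capita equity ratio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .core import (
    AttributeTable,
    CityModel,
    NeighbourhoodLayer,
    SvfGrid,
    substream,
    urban_attribute_table,
)
from .green import green_capita, green_distance
from .runoff import RunoffParams, runoff_prev
from .scenario import ScenarioParams, set_scenario
from .stochastic import edible_jobs, edible_volunteers, food_production, no2_seq
from .uhi import UhiParams, uhi

__all__ = ["run_report", "write_report"]

log = logging.getLogger("ediblecity")

#: Urban-agriculture solution land uses tallied in the report.
UA_LAND_USES = (
    "Community garden",
    "Commercial garden",
    "Edible private garden",
    "Hydroponic rooftop",
    "Rooftop garden",
)


def _ua_tally(city: CityModel) -> dict:
    out = {}
    for lu in UA_LAND_USES:
        mask = city.df["land_use"] == lu
        out[lu] = {
            "n": int(mask.sum()),
            "edible_area": float(city.df.loc[mask, "edible_area"].sum()),
        }
    return out


def run_report(
    city: CityModel,
    svf: SvfGrid,
    neighbourhoods: NeighbourhoodLayer | None,
    scenario_specs: dict[str, ScenarioParams | None],
    seed: int,
    table: AttributeTable | None = None,
    uhi_params: UhiParams | None = None,
    runoff_params: RunoffParams | None = None,
    green_min_area: float = 100.0,
) -> dict:
    """Compute the full indicator battery for every scenario.

    ``scenario_specs`` maps scenario names to :class:`ScenarioParams`
    (None means the unmodified base city).  Returns a JSON-serialisable
    dict keyed by scenario name; identical seeds yield identical reports.
    """
    if not scenario_specs:
        raise ValueError("at least one scenario spec is required")
    table = table if table is not None else urban_attribute_table()
    report: dict = {}
    for name, params in scenario_specs.items():
        if params is None:
            scen, warns = city, []
        else:
            scen, warns = set_scenario(
                city, params, substream(seed, f"scenario:{name}"))
        for w in warns:
            log.warning("[%s] %s", name, w)

        entry: dict = {"warnings": warns, "ua_elements": _ua_tally(scen)}

        entry["uhi"] = uhi(scen, svf, table, uhi_params)._asdict()
        r = runoff_prev(scen, table, runoff_params,
                        substream(seed, f"runoff:{name}"))
        entry["runoff"] = {"runoff_mm": r.runoff, "rainfall_m3": r.rainfall,
                           "rainharvest_m3": r.rainharvest}
        entry["no2_gr_s"] = no2_seq(scen, table,
                                    substream(seed, f"no2:{name}"))
        entry["jobs"] = edible_jobs(
            scen, table, rng=substream(seed, f"jobs:{name}"))._asdict()
        entry["volunteers"] = edible_volunteers(
            scen, table, rng=substream(seed, f"volunteers:{name}"))._asdict()
        entry["food_kg"] = food_production(
            scen, table, rng=substream(seed, f"food:{name}"))._asdict()
        entry["green_distance"] = green_distance(
            scen, table, min_area=green_min_area)._asdict()
        entry["green_percent_out"] = green_distance(
            scen, table, min_area=green_min_area, percent_out=True)
        if neighbourhoods is not None:
            entry["green_capita_ratio"] = green_capita(
                scen, table, neighbourhoods=neighbourhoods, private=True)
            entry["green_capita_by_neighbourhood"] = green_capita(
                scen, table, neighbourhoods=neighbourhoods, private=True,
                verbose=True)
        report[name] = entry
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the report as a JSON bundle plus per-table CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    scenarios = list(report)
    # urban-agriculture tally, one row per solution type
    rows = []
    for lu in UA_LAND_USES:
        row: dict = {"land_use": lu}
        for s in scenarios:
            t = report[s]["ua_elements"][lu]
            row[f"{s} n"] = t["n"]
            row[f"{s} edible_area"] = t["edible_area"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "ua_elements.csv", index=False)

    flat = []
    for s in scenarios:
        e = report[s]
        rec = {"scenario": s}
        rec.update({f"uhi_{k}": v for k, v in e["uhi"].items()})
        rec.update(e["runoff"])
        rec["no2_gr_s"] = e["no2_gr_s"]
        for ind in ("jobs", "volunteers", "food_kg"):
            rec.update({f"{ind}_{k}": v for k, v in e[ind].items()})
        rec["green_percent_out"] = e["green_percent_out"]
        if "green_capita_ratio" in e:
            rec["green_capita_ratio"] = e["green_capita_ratio"]
        flat.append(rec)
    pd.DataFrame(flat).to_csv(out / "indicators.csv", index=False)
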