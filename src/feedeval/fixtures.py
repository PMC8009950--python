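"""Bundled study data: printed composition tables, reference patterns, growth points.

The packaged CSVs hold the published summary values (means, 95% half-widths
and significance letters) for three feed substrates — isopod meal, Antarctic
krill meal and white fish meal — together with the FAO/WHO and whole-egg
amino-acid reference patterns and the printed juvenile growth check points.
Every numeric cell of the source tables appears in exactly one fixture record;
values are stored digit-for-digit as printed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .growth import GrowthSeries
from .panels import (
    AminoAcidProfile,
    AnalyteSeries,
    Censor,
    Measurement,
    NutrientPanel,
    ReferencePattern,
)

SUBSTRATES = ("isopod", "krill", "fish")

#: analytes entering the 8 combined scoring categories
SCORING_CATEGORIES = ("Ile", "Leu", "Lys", "Thr", "Val", "Trp", "Met+Cys", "Phe+Tyr")


def _data(name: str) -> pd.DataFrame:
    with resources.files("feedeval.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _measurement(row) -> Measurement:
    censor = Censor(row.get("censor", "observed") or "observed")
    if censor is Censor.BELOW_LIMIT:
        return Measurement(float(row["value"]), censor, limit=float(row["value"]))
    if censor is Censor.NOT_DETECTED:
        return Measurement(0.0, censor)
    return Measurement(float(row["value"]))


def _summary_panels(
    df: pd.DataFrame, category: str, unit: str, basis: str, value_col: str = "value"
) -> dict[str, NutrientPanel]:
    """Build one single-'replicate' panel per substrate from a printed table."""
    panels: dict[str, NutrientPanel] = {}
    for substrate, sub in df.groupby("substrate", sort=False):
        panel = NutrientPanel(substrate=substrate, category=category, unit=unit, basis=basis)
        for _, row in sub.iterrows():
            m = _measurement({**row, "value": row[value_col]})
            hw = row.get("ci95")
            series = AnalyteSeries(
                [m],
                unit=str(row["unit"]) if "unit" in row and pd.notna(row["unit"]) else unit,
                printed_half_width=float(hw) if pd.notna(hw) else None,
                letter=str(row["letter"]) if pd.notna(row.get("letter")) else None,
            )
            if row.get("aggregate", 0) == 1:
                panel.aggregates[row["analyte"]] = series
            else:
                panel.analytes[row["analyte"]] = series
        panels[substrate] = panel
    return panels


def load_fixture(name: str):
    """Load a bundled fixture by name.

    ================  =====================================================
    name              returns
    ================  =====================================================
    table2            dict substrate -> amino-acid NutrientPanel (g/100 g)
    table3_patterns   dict {'fao_who', 'egg'} -> ReferencePattern (mg/g N)
    table3_scores     DataFrame of the printed AAS/CS/EAAI values
    table4            dict substrate -> fatty-acid NutrientPanel (% of total FA)
    table5            dict substrate -> vitamin NutrientPanel (mixed units)
    table6            dict substrate -> mineral NutrientPanel (mg/kg)
    growth_points     GrowthSeries of the printed body-weight means
    ================  =====================================================
    """
    if name == "table2":
        df = _data("table2_amino_acids.csv").assign(censor="observed", unit="g/100g")
        df = df.rename(columns={"mean": "value"})
        return _summary_panels(df, "amino_acid", "g/100g", "dry_weight")
    if name == "table3_patterns":
        df = _data("table3_reference_patterns.csv")
        return {
            pat: ReferencePattern(pat, dict(zip(sub["category"], sub["mg_per_gN"])))
            for pat, sub in df.groupby("pattern", sort=False)
        }
    if name == "table3_scores":
        return _data("table3_printed_scores.csv")
    if name == "table4":
        return _summary_panels(
            _data("table4_fatty_acids.csv").assign(unit="% of total FA"),
            "fatty_acid", "% of total FA", "percent_of_total_FA",
        )
    if name == "table5":
        return _summary_panels(_data("table5_vitamins.csv"), "vitamin", "mg/100g", "dry_weight")
    if name == "table6":
        return _summary_panels(_data("table6_minerals.csv"), "mineral", "mg/kg", "dry_weight")
    if name == "growth_points":
        df = _data("growth_checkpoints.csv")
        return GrowthSeries(
            time=df["dah"].to_numpy(),
            group_weights=df["mean_mg"].to_numpy()[:, None],
            ci95=df["ci95"].to_numpy(),
        )
    raise KeyError(f"unknown fixture {name!r}")


def table2_profiles(include_taurine_in_faa: bool = True) -> dict[str, AminoAcidProfile]:
    """Amino-acid profiles per substrate with essential/flavor flags.

    Taurine carries the flavor flag by default (its inclusion in the flavor
    and total sums matches the printed aggregates); pass
    ``include_taurine_in_faa=False`` for the convention that drops it.
    """
    df = _data("table2_amino_acids.csv")
    df = df[df["aggregate"] == 0]
    out: dict[str, AminoAcidProfile] = {}
    for substrate, sub in df.groupby("substrate", sort=False):
        flavor = set(sub.loc[sub["flavor"] == 1, "analyte"])
        if not include_taurine_in_faa:
            flavor.discard("Tau")
        out[substrate] = AminoAcidProfile(
            contents=dict(zip(sub["analyte"], sub["mean"])),
            essential=frozenset(sub.loc[sub["essential"] == 1, "analyte"]),
            flavor=frozenset(flavor),
        )
    return out


def printed_aggregates(name: str = "table2") -> pd.DataFrame:
    """The printed sum/ratio rows (value, half-width, letter) of a table fixture."""
    panels = load_fixture(name)
    rows = []
    for substrate, panel in panels.items():
        for agg, series in panel.aggregates.items():
            rows.append(
                {
                    "substrate": substrate,
                    "aggregate": agg,
                    "value": series.measurements[0].numeric,
                    "ci95": series.printed_half_width,
                    "letter": series.letter,
                }
            )
    return pd.DataFrame(rows)


def growth_endpoints() -> dict[str, float]:
    """Printed trial endpoints: initial/final mean weight (mg) and duration (d)."""
    series = load_fixture("growth_points")
    return {
        "initial_mg": float(series.mean_weights[0]),
        "final_mg": float(series.mean_weights[-1]),
        "days": float(series.time[-1] - series.time[0]),
    }
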