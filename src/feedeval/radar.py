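"""Comparative radar scoring of substrates across nutrient categories.

Four factors enter the radar table as actual values (flavor and essential
amino-acid proportions, EAAI, total PUFA); the vitamin and mineral factors
are rank scores: within each category the comparable parameters are counted
as "wins" (strictly highest mean) per substrate, the substrates are ranked
by win count, and the ranks 1/2/3 map to scores 50/40/30.  Ties share the
average of the scores they span and are flagged rather than broken
arbitrarily.

Whether a parameter is *comparable* is a filtering decision: parameters
censored in every substrate carry no ranking information, parameters absent
(never measured) in most substrates cannot be compared, and parameters
reported on a bulk percentage scale are incommensurable with the trace
concentrations making up the rest of a category.  The thresholds and the
excluded-unit set are exposed as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .panels import NutrientPanel
from .protein import ProteinQualityReport

RANK_SCORES = (50.0, 40.0, 30.0)


@dataclass(frozen=True)
class ComparabilityRules:
    """Filtering configuration for cross-substrate parameter comparison."""

    drop_all_censored: bool = True  # censored/ND in every substrate -> out
    max_missing: int = 1  # absent (no measurement) in more substrates -> out
    excluded_units: tuple[str, ...] = ("%",)  # bulk-percentage parameters -> out


DEFAULT_RULES = ComparabilityRules()


def comparable_parameters(
    panels: Mapping[str, NutrientPanel],
    rules: ComparabilityRules = DEFAULT_RULES,
) -> list[str]:
    """Parameters of a category that can be ranked across all substrates."""
    if not panels:
        raise ValueError("no panels supplied")
    categories = {p.category for p in panels.values()}
    if len(categories) > 1:
        raise ValueError(f"panels span multiple categories: {sorted(categories)}")
    all_names: list[str] = []
    for panel in panels.values():
        for name in panel.analytes:
            if name not in all_names:
                all_names.append(name)
    kept: list[str] = []
    for name in all_names:
        present = [p for p in panels.values() if name in p.analytes]
        missing = len(panels) - len(present)
        if missing > rules.max_missing:
            continue
        if rules.drop_all_censored and all(
            p.analytes[name].fully_censored for p in present
        ):
            continue
        units = {p.analyte_unit(name) for p in present}
        if units & set(rules.excluded_units):
            continue
        kept.append(name)
    if not kept:
        raise ValueError("no comparable parameters after filtering")
    return kept


def win_counts(
    panels: Mapping[str, NutrientPanel], parameters: Sequence[str]
) -> dict[str, float]:
    """Per-substrate count of parameters whose mean is strictly highest.

    Censored values count as zero; an absent parameter counts as zero for
    that substrate.  Ties split the win equally (fractional credit), so the
    counts always sum to the number of parameters.
    """
    counts = {s: 0.0 for s in panels}
    for name in parameters:
        means = {
            s: (p.analytes[name].mean if name in p.analytes else 0.0)
            for s, p in panels.items()
        }
        top = max(means.values())
        winners = [s for s, m in means.items() if m == top]
        for s in winners:
            counts[s] += 1.0 / len(winners)
    return counts


@dataclass(frozen=True)
class RankScore:
    scores: dict[str, float]
    tied: bool


def rank_scores(counts: Mapping[str, float]) -> RankScore:
    """Map win counts of 3 substrates onto the 50/40/30 rank scores.

    Substrates tied on count share the arithmetic mean of the scores their
    ranks would have received, and the result is flagged.
    """
    if len(counts) != len(RANK_SCORES):
        raise ValueError(f"rank scoring expects {len(RANK_SCORES)} substrates")
    ordered = sorted(counts, key=lambda s: counts[s], reverse=True)
    scores: dict[str, float] = {}
    tied = False
    i = 0
    while i < len(ordered):
        j = i
        while j + 1 < len(ordered) and counts[ordered[j + 1]] == counts[ordered[i]]:
            j += 1
        block = ordered[i : j + 1]
        share = sum(RANK_SCORES[i : j + 1]) / len(block)
        if len(block) > 1:
            tied = True
        for s in block:
            scores[s] = share
        i = j + 1
    return RankScore(scores=scores, tied=tied)


@dataclass
class RadarTable:
    """factor x substrate score table with per-cell provenance."""

    table: pd.DataFrame  # index: factor, columns: substrates
    provenance: dict[str, str]  # factor -> 'actual value (<unit>)' | 'rank score'
    flags: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["provenance"] = [self.provenance[f] for f in out.index]
        out.to_csv(path, index_label="factor")


def build_radar(
    reports: Mapping[str, ProteinQualityReport],
    pufa_totals: Mapping[str, float],
    vitamin_counts: Mapping[str, float],
    mineral_counts: Mapping[str, float],
) -> RadarTable:
    """Assemble the six-factor radar table.

    ``reports`` supply the amino-acid factors per substrate, ``pufa_totals``
    the total-PUFA percentages, and the two count mappings come from
    :func:`win_counts` on the vitamin and mineral panels.
    """
    substrates = list(reports)
    for name, mapping in (("pufa_totals", pufa_totals),
                          ("vitamin_counts", vitamin_counts),
                          ("mineral_counts", mineral_counts)):
        missing = [s for s in substrates if s not in mapping]
        if missing:
            raise KeyError(f"{name} lacks substrates {missing}")
    vit = rank_scores(vitamin_counts)
    mine = rank_scores(mineral_counts)
    rows = {
        "FAA/AA (%)": {s: reports[s].summary.faa_over_aa_pct for s in substrates},
        "EAA/AA (%)": {s: reports[s].summary.eaa_over_aa_pct for s in substrates},
        "EAAI": {s: reports[s].eaai for s in substrates},
        "PUFA (% of total FA)": {s: float(pufa_totals[s]) for s in substrates},
        "vitamins": vit.scores,
        "minerals": mine.scores,
    }
    provenance = {
        "FAA/AA (%)": "actual value (%)",
        "EAA/AA (%)": "actual value (%)",
        "EAAI": "actual value (index)",
        "PUFA (% of total FA)": "actual value (% of total FA)",
        "vitamins": "rank score",
        "minerals": "rank score",
    }
    flags = []
    if vit.tied:
        flags.append("vitamin rank tie: averaged scores")
    if mine.tied:
        flags.append("mineral rank tie: averaged scores")
    table = pd.DataFrame(rows).T[substrates]
    return RadarTable(table=table, provenance=provenance, flags=flags)


def plot_radar(radar: RadarTable, path=None):
    """Optional polar plot of the radar table (each factor min-max scaled)."""
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = radar.table
    scaled = table.sub(table.min(axis=1), axis=0)
    rng = table.max(axis=1) - table.min(axis=1)
    scaled = scaled.div(rng.replace(0, 1.0), axis=0) * 0.8 + 0.2
    angles = [2 * math.pi * i / len(table.index) for i in range(len(table.index))]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for sub in table.columns:
        vals = scaled[sub].tolist()
        ax.plot(angles + angles[:1], vals + vals[:1], label=sub)
    ax.set_xticks(angles)
    ax.set_xticklabels(table.index, fontsize=7)
    ax.set_yticklabels([])
    ax.legend(loc="lower right", fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
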