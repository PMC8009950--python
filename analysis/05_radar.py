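"""Assemble the six-factor radar comparison of the three substrates.

Amino-acid factors and EAAI come from the protein-quality reports, total
PUFA from the fatty-acid table; the vitamin and mineral factors are rank
scores (50/40/30) from win counts over the comparable parameters of each
category.
"""

from pathlib import Path

from feedeval import fixtures
from feedeval.protein import evaluate_protein_quality
from feedeval.radar import (build_radar, comparable_parameters, plot_radar,
                            win_counts)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    patterns = fixtures.load_fixture("table3_patterns")
    profiles = fixtures.table2_profiles()
    reports = {
        s: evaluate_protein_quality(s, p, patterns["fao_who"], patterns["egg"])
        for s, p in profiles.items()
    }
    fatty = fixtures.load_fixture("table4")
    pufa = {s: p.aggregates["SumPUFA"].mean for s, p in fatty.items()}
    vitamins = fixtures.load_fixture("table5")
    minerals = fixtures.load_fixture("table6")
    vit_params = comparable_parameters(vitamins)
    min_params = comparable_parameters(minerals)
    vit_wins = win_counts(vitamins, vit_params)
    min_wins = win_counts(minerals, min_params)
    print(f"comparable vitamins ({len(vit_params)}): {vit_params}; wins {vit_wins}")
    print(f"comparable minerals ({len(min_params)}): {min_params}; wins {min_wins}")
    radar = build_radar(reports, pufa, vit_wins, min_wins)
    print(radar.table.round(2).to_string())
    OUT.mkdir(exist_ok=True)
    radar.to_csv(OUT / "radar_table.csv")
    plot_radar(radar, OUT / "radar.png")
    print(f"wrote {OUT / 'radar_table.csv'} and radar.png — isopod leads on "
          "vitamins, minerals and flavor amino acids; fish meal on EAAI and PUFA.")


if __name__ == "__main__":
    main()
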