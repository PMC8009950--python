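# feedeval

Nutritional evaluation of candidate feed substrates — built around a case
study comparing meal from the semiterrestrial isopod *Ligia exotica* with
Antarctic krill meal and white fish meal as aquaculture feed ingredients.

Assessing whether a novel ingredient can replace an established one requires
several unrelated pieces of machinery at once: protein-quality indices
against reference amino-acid patterns, growth-curve fitting for the
candidate organism, replicated composition panels compared across substrates
with post-hoc letters, a multi-criteria synthesis of expert judgment, and a
final comparative summary.  `feedeval` implements that full stack as a
tested library, with the study's published tables bundled as fixtures and
synthetic-data generators for every stage.

## What it computes

**Protein quality.**  Amino-acid contents (g/100 g dry weight) are converted
to mg per g nitrogen (× 62.5) and scored per category *a* against a
reference pattern *R*:

- amino acid score AAS(a) = sample(a) / R_FAO/WHO(a)
- chemical score CS(a) = sample(a) / R_egg(a); the minimum CS names the
  limiting amino acid
- essential amino acid index
  EAAI = (∏_a 100·sample(a)/R_egg(a))^(1/n), the geometric mean over the
  n = 8 scoring categories (Met+Cys and Phe+Tyr pooled); EAAI = 100 means
  egg-equivalent protein.

Plus ΣAA/ΣEAA/ΣNEAA/ΣFAA totals and their percentage ratios.

**Growth kinetics.**  Body weight vs age is fitted as BW = a·t^b by OLS on
(ln t, ln BW) (the spreadsheet power-trendline convention, r² reported on
that scale), with WGR = (W_T − W_0)/W_0 × 100 % and
SGR = (ln W_T − ln W_0)/T × 100 %/day, and a Shapiro–Wilk residual check.

**Group statistics.**  Per analyte: Shapiro–Wilk, Levene (mean-centered);
homogeneous variances → one-way ANOVA + Duncan's multiple range test,
heterogeneous → Welch's ANOVA + Dunnett's T3; Fisher's LSD against a control
substrate as a reference.  Pairwise decisions become a compact letter
display ('a' = smallest mean by default; groups sharing a letter do not
differ at α = 0.05).

**AHP synthesis.**  Saaty-scale reciprocal judgment matrices per expert,
principal-eigenvector priorities (power iteration), consistency ratio
CR = CI/RI with CI = (λ_max − n)/(n − 1), arithmetic averaging of expert
priority vectors, and hierarchical synthesis
global(alt) = Σ_c w(c)·w(alt | c).

**Radar ranking.**  Four factors scored by actual value (ΣFAA/ΣAA %,
ΣEAA/ΣAA %, EAAI, ΣPUFA); vitamins and minerals by rank: comparable
parameters are filtered (all-censored, mostly-absent and off-unit parameters
dropped), substrates counted by strictly-highest means, and ranks 1/2/3
scored 50/40/30.

## Worked example

```python
import feedeval as fe

patterns = fe.load_fixture("table3_patterns")   # FAO/WHO and whole-egg, mg/g N
profiles = fe.table2_profiles()                 # bundled composition table
rep = fe.evaluate_protein_quality("isopod", profiles["isopod"],
                                  patterns["fao_who"], patterns["egg"])
print(round(rep.eaai, 2), rep.limiting, rep.cs_rounded["Met+Cys"])
```

prints `34.14 ['Met+Cys'] 0.1`: isopod meal reaches about a third of
egg-protein quality, and its pooled sulfur amino acids — at a tenth of the
egg reference — are the first-limiting category (krill and fish meal score
45.16 and 55.93).  The analysis drivers narrate the full study:

```sh
python analysis/01_protein_quality.py   # score tables -> results/
python analysis/02_growth.py            # BW = a*t^b fit, WGR, SGR
python analysis/03_group_comparison.py  # letter displays from printed CIs
python analysis/04_ahp.py               # synthetic expert committee synthesis
python analysis/05_radar.py             # six-factor radar table
```

For instance `02_growth.py` prints

```
power fit on 5 printed check points: BW = 0.001914 * t^2.213, r2(log-log) = 0.9739
WGR = 12841.67% over 70 d; SGR = 6.95%/d from printed endpoints, 6.97%/d from
the WGR-implied initial weight 0.2366 mg
```

i.e. the juveniles grow four orders of magnitude in 70 days, about 7 %/day.
There is also a CLI (`feedeval protein-quality|growth|compare|ahp|radar|simulate`)
exposing the same operations on user CSV/YAML files.

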