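"""Protein-quality scoring: AAS, CS, EAAI, limiting amino acids, sum/ratio summaries.

Scores compare a sample's essential amino-acid contents, expressed in mg per
gram of nitrogen, with a reference pattern:

* AAS (amino acid score)   = sample / FAO-WHO pattern, per category
* CS  (chemical score)     = sample / whole-egg pattern, per category;
  its minimum names the limiting amino acid
* EAAI (essential amino acid index) = geometric mean over the scoring
  categories of 100 x (sample / egg); 100 means egg-equivalent protein.

Contents printed as g/100 g dry weight convert to mg/g N with the factor
62.5 (nitrogen-to-protein factor 6.25 x 10).  Sulfur (Met+Cys) and aromatic
(Phe+Tyr) amino acids are pooled before conversion.  By default scoring runs
over the 8 pooled categories; the category list is a parameter, so an
unpooled 9-acid variant can be computed as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .panels import AminoAcidProfile, ReferencePattern

#: g/100 g dry weight -> mg per g nitrogen
MG_PER_GN_FACTOR = 62.5

#: the 8 scoring categories and their member amino acids
CATEGORY_MEMBERS: dict[str, tuple[str, ...]] = {
    "Ile": ("Ile",),
    "Leu": ("Leu",),
    "Lys": ("Lys",),
    "Thr": ("Thr",),
    "Val": ("Val",),
    "Trp": ("Trp",),
    "Met+Cys": ("Met", "Cys"),
    "Phe+Tyr": ("Phe", "Tyr"),
}

SCORING_CATEGORIES: tuple[str, ...] = tuple(CATEGORY_MEMBERS)


def round2(x: float) -> float:
    """Round half-up to 2 decimal places (display convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def to_mg_per_gN(
    profile: AminoAcidProfile | Mapping[str, float],
    categories: Sequence[str] = SCORING_CATEGORIES,
    factor: float = MG_PER_GN_FACTOR,
) -> dict[str, float]:
    """Pool category members and convert g/100 g contents to mg/g N."""
    contents = profile.contents if isinstance(profile, AminoAcidProfile) else dict(profile)
    out: dict[str, float] = {}
    for cat in categories:
        members = CATEGORY_MEMBERS.get(cat, (cat,))
        missing = [m for m in members if m not in contents]
        if missing:
            raise KeyError(f"profile lacks amino acid(s) {missing} for category {cat!r}")
        out[cat] = sum(contents[m] for m in members) * factor
    return out


def amino_acid_score(
    sample: Mapping[str, float], pattern: ReferencePattern
) -> dict[str, float]:
    """Per-category ratio sample / pattern (both mg/g N), unrounded."""
    scores = {}
    for cat, content in sample.items():
        ref = pattern[cat]
        if ref <= 0:
            raise ZeroDivisionError(f"pattern content for {cat!r} is not positive")
        scores[cat] = content / ref
    return scores


def chemical_score(
    sample: Mapping[str, float], egg: ReferencePattern
) -> dict[str, float]:
    """AAS computed against the whole-egg pattern."""
    return amino_acid_score(sample, egg)


def eaai(
    sample: Mapping[str, float],
    egg: ReferencePattern,
    categories: Sequence[str] | None = None,
) -> float:
    """Geometric mean of 100 x (sample/egg) over the scoring categories.

    A zero content in any category sends the index to 0 (the geometric mean
    of a set containing zero).
    """
    cats = tuple(categories) if categories is not None else tuple(sample)
    missing = [c for c in cats if c not in sample]
    if missing:
        raise KeyError(f"sample lacks categories {missing}")
    ratios = [100.0 * sample[c] / egg[c] for c in cats]
    if any(r == 0 for r in ratios):
        return 0.0
    return math.exp(sum(math.log(r) for r in ratios) / len(ratios))


def limiting_categories(scores: Mapping[str, float]) -> list[str]:
    """Categories with the smallest score; alphabetical on ties (co-limiting)."""
    lo = min(scores.values())
    return sorted(c for c, s in scores.items() if s == lo)


@dataclass(frozen=True)
class AASummary:
    """Sum/ratio summary of an amino-acid profile (g/100 g and %)."""

    sum_aa: float
    sum_eaa: float
    sum_neaa: float
    sum_faa: float
    eaa_over_aa_pct: float
    eaa_over_neaa_pct: float
    faa_over_aa_pct: float


def aa_summaries(profile: AminoAcidProfile) -> AASummary:
    """Totals of all / essential / non-essential / flavor amino acids and ratios."""
    total = sum(profile.contents.values())
    eaa = sum(profile.contents[a] for a in profile.essential)
    faa = sum(profile.contents[a] for a in profile.flavor)
    neaa = total - eaa
    pct = lambda num, den: 100.0 * num / den if den > 0 else 0.0
    return AASummary(
        sum_aa=total,
        sum_eaa=eaa,
        sum_neaa=neaa,
        sum_faa=faa,
        eaa_over_aa_pct=pct(eaa, total),
        eaa_over_neaa_pct=pct(eaa, neaa),
        faa_over_aa_pct=pct(faa, total),
    )


@dataclass
class ProteinQualityReport:
    """Full scoring report for one substrate."""

    substrate: str
    aas: dict[str, float]
    cs: dict[str, float]
    eaai: float
    limiting: list[str]  # argmin of CS; first entry is the primary limiting category
    second_limiting: list[str]
    summary: AASummary
    categories: tuple[str, ...] = SCORING_CATEGORIES
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def aas_rounded(self) -> dict[str, float]:
        return {c: round2(v) for c, v in self.aas.items()}

    @property
    def cs_rounded(self) -> dict[str, float]:
        return {c: round2(v) for c, v in self.cs.items()}


def evaluate_protein_quality(
    substrate: str,
    profile: AminoAcidProfile,
    fao_pattern: ReferencePattern,
    egg_pattern: ReferencePattern,
    categories: Sequence[str] = SCORING_CATEGORIES,
) -> ProteinQualityReport:
    """Compute the complete protein-quality report for one substrate."""
    sample = to_mg_per_gN(profile, categories)
    aas = amino_acid_score(sample, fao_pattern)
    cs = chemical_score(sample, egg_pattern)
    lim = limiting_categories(cs)
    rest = {c: v for c, v in cs.items() if c not in lim}
    second = limiting_categories(rest) if rest else []
    return ProteinQualityReport(
        substrate=substrate,
        aas=aas,
        cs=cs,
        eaai=eaai(sample, egg_pattern, categories),
        limiting=lim,
        second_limiting=second,
        summary=aa_summaries(profile),
        categories=tuple(categories),
        notes={
            "eaai_categories": (
                f"{len(tuple(categories))} pooled scoring categories "
                "(sulfur and aromatic pairs combined)"
            )
        },
    )
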