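"""Replicate nutrient-panel data model and delimited-table I/O.

A *panel* holds replicate measurements of many analytes for a single feed
substrate (e.g. the amino-acid panel of isopod meal).  Analytical chemistry
panels routinely contain left-censored entries: an analyte may be reported
"ND" (not detected) or "<x" (below the limit of quantification x).  Both are
carried as explicit censoring states; group statistics treat them as zero,
while reports keep the original "<x" string.

Units are recorded per analyte (vitamin tables mix mg/100 g, µg/100 g and
mg/kg); a panel additionally declares its dominant unit.
"""

from __future__ import annotations

import csv
import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats


class Censor(str, enum.Enum):
    """Censoring state of a single measurement."""

    OBSERVED = "observed"
    NOT_DETECTED = "not_detected"
    BELOW_LIMIT = "below_limit"


class PanelParseError(ValueError):
    """Raised when a delimited panel file cannot be parsed."""


class CensoredSummaryError(ValueError):
    """Raised when a summary is requested for a fully censored analyte."""


@dataclass(frozen=True)
class Measurement:
    """One replicate measurement, possibly left-censored.

    ``value`` is the measured value for observed entries, 0 for ND entries
    and the quantification limit for below-limit entries (the numeric value
    used downstream is always :attr:`numeric`).
    """

    value: float
    censor: Censor = Censor.OBSERVED
    limit: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"negative measurement value {self.value!r}")
        if self.censor is Censor.BELOW_LIMIT:
            if self.limit is None or self.limit <= 0:
                raise ValueError("below_limit measurement requires a positive limit")
        elif self.limit is not None:
            raise ValueError("limit is only meaningful for below_limit measurements")

    @property
    def numeric(self) -> float:
        """Value entering statistics: censored entries count as zero."""
        return self.value if self.censor is Censor.OBSERVED else 0.0

    @property
    def display(self) -> str:
        if self.censor is Censor.NOT_DETECTED:
            return "ND"
        if self.censor is Censor.BELOW_LIMIT:
            return f"<{_fmt(self.limit)}"
        return _fmt(self.value)


@dataclass
class AnalyteSeries:
    """All replicates of one analyte, plus optional printed summary metadata."""

    measurements: list[Measurement]
    unit: str = ""
    printed_half_width: float | None = None
    letter: str | None = None

    def observed(self) -> list[float]:
        return [m.value for m in self.measurements if m.censor is Censor.OBSERVED]

    def numeric(self) -> list[float]:
        return [m.numeric for m in self.measurements]

    @property
    def fully_censored(self) -> bool:
        return all(m.censor is not Censor.OBSERVED for m in self.measurements)

    @property
    def mean(self) -> float:
        """Mean over replicates with censored entries as zero."""
        vals = self.numeric()
        return sum(vals) / len(vals)


@dataclass
class NutrientPanel:
    """Replicate analyte measurements for one substrate and category."""

    substrate: str
    category: str  # amino_acid | fatty_acid | vitamin | mineral | proximate
    analytes: dict[str, AnalyteSeries] = field(default_factory=dict)
    unit: str = ""
    basis: str = "dry_weight"  # dry_weight | wet_weight | percent_of_total_FA
    aggregates: dict[str, AnalyteSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, series in self.analytes.items():
            if not series.measurements:
                raise ValueError(f"analyte {name!r} has no replicates")

    def analyte_unit(self, name: str) -> str:
        return self.analytes[name].unit or self.unit


@dataclass(frozen=True)
class SummaryStat:
    """Mean with a t-based 95% confidence half-width."""

    mean: float
    n: int
    half_width_ci95: float


@dataclass(frozen=True)
class ReferencePattern:
    """Amino-acid scoring pattern: category -> reference content in mg/g N."""

    name: str
    contents: Mapping[str, float]

    def __post_init__(self) -> None:
        for cat, v in self.contents.items():
            if v <= 0:
                raise ValueError(f"pattern {self.name!r}: non-positive content for {cat!r}")

    def __getitem__(self, category: str) -> float:
        return self.contents[category]

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.contents)


@dataclass
class AminoAcidProfile:
    """Amino-acid contents in g/100 g dry weight with essential/flavor flags."""

    contents: dict[str, float]
    essential: frozenset[str] = frozenset()
    flavor: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for aa, v in self.contents.items():
            if v < 0:
                raise ValueError(f"negative content for {aa!r}")
        self.essential = frozenset(self.essential) & set(self.contents)
        self.flavor = frozenset(self.flavor) & set(self.contents)

    def __getitem__(self, aa: str) -> float:
        return self.contents[aa]


# ---------------------------------------------------------------------------
# Controlled vocabulary

#: Synonym map normalising analyte names to 3-letter amino-acid codes.
AA_SYNONYMS: dict[str, str] = {
    "aspartate": "Asp", "aspartic acid": "Asp",
    "threonine": "Thr", "serine": "Ser",
    "glutamate": "Glu", "glutamic acid": "Glu",
    "glycine": "Gly", "alanine": "Ala", "valine": "Val",
    "methionine": "Met", "isoleucine": "Ile", "leucine": "Leu",
    "tyrosine": "Tyr", "phenylalanine": "Phe", "lysine": "Lys",
    "histidine": "His", "arginine": "Arg", "proline": "Pro",
    "cysteine": "Cys", "cystine": "Cys", "tryptophan": "Trp",
    "taurine": "Tau",
}

_KNOWN_CODES = set(AA_SYNONYMS.values())


def normalize_analyte(name: str, category: str = "amino_acid") -> str:
    """Map an analyte name onto the controlled vocabulary.

    Amino acids become 3-letter codes.  Unknown names pass through verbatim
    with a warning, so user panels with exotic analytes still load.
    """
    stripped = name.strip()
    if category != "amino_acid":
        return stripped
    if stripped in _KNOWN_CODES:
        return stripped
    key = stripped.lower()
    if key in AA_SYNONYMS:
        return AA_SYNONYMS[key]
    if stripped.capitalize() in _KNOWN_CODES:
        return stripped.capitalize()
    warnings.warn(f"unknown analyte name {name!r} kept verbatim", stacklevel=2)
    return stripped


# ---------------------------------------------------------------------------
# Summaries


def summarize(panel: NutrientPanel, analyte: str) -> SummaryStat:
    """Mean and t-based 95% half-width over the observed replicates.

    Raises :class:`CensoredSummaryError` when every replicate is censored —
    a censored analyte has no meaningful mean, only a reporting string.
    """
    series = panel.analytes[analyte]
    obs = series.observed()
    if not obs:
        raise CensoredSummaryError(f"analyte {analyte!r} is fully censored")
    n = len(obs)
    mean = sum(obs) / n
    if n < 2:
        return SummaryStat(mean=mean, n=n, half_width_ci95=0.0)
    sd = math.sqrt(sum((x - mean) ** 2 for x in obs) / (n - 1))
    hw = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return SummaryStat(mean=mean, n=n, half_width_ci95=hw)


def sd_from_half_width(half_width: float, n: int) -> float:
    """Back out a replicate standard deviation from a printed 95% half-width.

    Inverse of the t-interval construction: sd = hw * sqrt(n) / t(0.975, n-1).
    Intended for demonstration fixtures built from printed tables only.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    return half_width * math.sqrt(n) / stats.t.ppf(0.975, n - 1)


# ---------------------------------------------------------------------------
# Delimited-table I/O
#
# Panel CSV layout: substrate,category,analyte,rep1..repK,unit,basis
# Censoring tokens in replicate cells: "ND" and "<x".


def parse_token(token: str) -> Measurement:
    """Parse one replicate cell into a :class:`Measurement`."""
    tok = token.strip()
    if tok.upper() == "ND":
        return Measurement(0.0, Censor.NOT_DETECTED)
    if tok.startswith("<"):
        limit = float(tok[1:])
        return Measurement(limit, Censor.BELOW_LIMIT, limit=limit)
    value = float(tok)
    if value < 0:
        raise ValueError(f"negative value {tok!r}")
    return Measurement(value)


def read_panel(path: str | Path, schema: str | None = None) -> NutrientPanel:
    """Read a replicate panel CSV.

    The header must contain ``substrate``, ``category``, ``analyte``, one or
    more ``rep*`` columns, ``unit`` and ``basis``.  ``schema`` optionally
    asserts the expected category.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        rep_cols = [c for c in header if c.lower().startswith("rep")]
        required = {"substrate", "category", "analyte", "unit", "basis"}
        if not required.issubset(header) or not rep_cols:
            raise PanelParseError(
                f"{path}: header must declare {sorted(required)} and rep1..repK, got {header}"
            )
        panel: NutrientPanel | None = None
        for lineno, row in enumerate(reader, start=2):
            try:
                category = row["category"].strip()
                if schema and category != schema:
                    raise ValueError(f"expected category {schema!r}, found {category!r}")
                name = normalize_analyte(row["analyte"], category)
                reps = [parse_token(row[c]) for c in rep_cols if row[c] and row[c].strip()]
                if not reps:
                    raise ValueError("no replicate values")
                series = AnalyteSeries(reps, unit=row["unit"].strip())
            except (ValueError, KeyError) as exc:
                raise PanelParseError(f"{path}: row {lineno}: {exc}") from exc
            if panel is None:
                panel = NutrientPanel(
                    substrate=row["substrate"].strip(),
                    category=category,
                    unit=row["unit"].strip(),
                    basis=row["basis"].strip(),
                )
            panel.analytes[name] = series
        if panel is None:
            raise PanelParseError(f"{path}: no data rows")
        return panel


def write_panel(panel: NutrientPanel, path: str | Path) -> None:
    """Write a panel in the replicate CSV layout (round-trips read_panel)."""
    path = Path(path)
    k = max(len(s.measurements) for s in panel.analytes.values())
    rep_cols = [f"rep{i + 1}" for i in range(k)]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["substrate", "category", "analyte", *rep_cols, "unit", "basis"])
        for name, series in panel.analytes.items():
            cells = [m.display for m in series.measurements]
            cells += [""] * (k - len(cells))
            writer.writerow(
                [panel.substrate, panel.category, name, *cells,
                 series.unit or panel.unit, panel.basis]
            )


def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    return f"{x:g}"


def panels_from_profiles(
    profiles: Mapping[str, AminoAcidProfile], basis: str = "dry_weight"
) -> dict[str, NutrientPanel]:
    """Wrap single-value amino-acid profiles as one-replicate panels."""
    out = {}
    for substrate, prof in profiles.items():
        panel = NutrientPanel(substrate=substrate, category="amino_acid",
                              unit="g/100g", basis=basis)
        for aa, v in prof.contents.items():
            panel.analytes[aa] = AnalyteSeries([Measurement(v)], unit="g/100g")
        out[substrate] = panel
    return out
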