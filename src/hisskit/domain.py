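"""Canonical domain types shared across the package.

Five biomarkers describe one patient snapshot: glucose (mg/dL), lactate
(mmol/L), pH (dimensionless), potassium (mmol/L) and oxygen tension
(mmHg).  Each analyte has a closed "normal" band; values strictly below
it are *low*, strictly above it are *high*.  Severity scores are ordinal
integers 0 (LOW) through 4 (SEVERE).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

ANALYTES: tuple[str, ...] = ("glucose", "lactate", "ph", "potassium", "po2")

REGIMES: tuple[str, ...] = ("low", "normal", "high")

SEVERITY_LEVELS: tuple[int, ...] = (0, 1, 2, 3, 4)

SEVERITY_NAMES: dict[int, str] = {
    0: "LOW",
    1: "GUARDED",
    2: "ELEVATED",
    3: "HIGH",
    4: "SEVERE",
}

#: molar mass of glucose, g/mol; 1 mmol/L = 18.016 mg/dL
GLUCOSE_MG_DL_PER_MMOL_L = 18.016

#: hard plausibility gate on pH, deliberately wider than the normal band
PH_GATE = (6.5, 8.0)


class UnknownAnalyteError(ValueError):
    """Raised when an analyte name is not one of the five panel analytes."""


def check_score(value: int) -> int:
    """Validate an ordinal severity score, returning it as an ``int``."""
    iv = int(value)
    if iv != value or iv not in SEVERITY_LEVELS:
        raise ValueError(f"severity score must be an integer in 0..4, got {value!r}")
    return iv


@dataclass(frozen=True)
class AnalytePanel:
    """One patient's five biomarker values in canonical units."""

    glucose: float   # mg/dL
    lactate: float   # mmol/L
    ph: float        # dimensionless
    potassium: float # mmol/L
    po2: float       # mmHg

    def as_dict(self) -> dict[str, float]:
        return {a: getattr(self, a) for a in ANALYTES}

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, a) for a in ANALYTES)


def validate_panel(panel: AnalytePanel) -> list[str]:
    """Return one violation descriptor per broken panel invariant.

    Never raises; an empty list means the panel is plausible.
    """
    violations: list[str] = []
    for name in ANALYTES:
        v = getattr(panel, name)
        if not isinstance(v, (int, float)) or not math.isfinite(v):
            violations.append(f"{name}: value {v!r} is not finite")
    if violations:
        return violations
    if panel.glucose <= 0:
        violations.append(f"glucose: must be > 0, got {panel.glucose}")
    if panel.lactate < 0:
        violations.append(f"lactate: must be >= 0, got {panel.lactate}")
    if panel.potassium <= 0:
        violations.append(f"potassium: must be > 0, got {panel.potassium}")
    if panel.po2 <= 0:
        violations.append(f"po2: must be > 0, got {panel.po2}")
    lo, hi = PH_GATE
    if not (lo <= panel.ph <= hi):
        violations.append(f"ph: outside plausibility gate [{lo}, {hi}], got {panel.ph}")
    return violations


@dataclass(frozen=True)
class RegimeTable:
    """Per-analyte normal bands and pathological regime labels.

    ``bands[a] = (low_max, high_min)`` is the closed normal interval for
    analyte ``a``; boundary values classify as normal.
    """

    bands: dict[str, tuple[float, float]]
    labels: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"{a}: normal band must have low bound < high bound, got [{lo}, {hi}]")

    def band(self, analyte: str) -> tuple[float, float]:
        _require_analyte(analyte)
        return self.bands[analyte]

    @classmethod
    def default(cls) -> "RegimeTable":
        """The shipped default table (see ``data/regimes.json``)."""
        text = resources.files("hisskit.data").joinpath("regimes.json").read_text()
        return cls.from_json(text)

    @classmethod
    def from_json(cls, text: str) -> "RegimeTable":
        doc = json.loads(text)
        bands = {}
        labels = {}
        for a in ANALYTES:
            if a not in doc:
                raise ValueError(f"regime table JSON missing analyte {a!r}")
            entry = doc[a]
            bands[a] = (float(entry["low_max"]), float(entry["high_min"]))
            labels[a] = (entry.get("low_label", "low"), entry.get("high_label", "high"))
        return cls(bands=bands, labels=labels)

    def to_json(self) -> str:
        doc = {}
        for a in ANALYTES:
            lo, hi = self.bands[a]
            low_label, high_label = self.labels.get(a, ("low", "high"))
            doc[a] = {"low_max": lo, "high_min": hi,
                      "low_label": low_label, "high_label": high_label}
        return json.dumps(doc, indent=2)

    def shifted(self, shifts: dict[str, float]) -> "RegimeTable":
        """A copy with each analyte's normal band translated by ``shifts[a]``."""
        bands = dict(self.bands)
        for a, s in shifts.items():
            _require_analyte(a)
            lo, hi = bands[a]
            bands[a] = (lo + s, hi + s)
        return RegimeTable(bands=bands, labels=dict(self.labels))


def _require_analyte(analyte: str) -> None:
    if analyte not in ANALYTES:
        raise UnknownAnalyteError(
            f"unknown analyte {analyte!r}; valid analytes are {', '.join(ANALYTES)}"
        )


def classify_regime(analyte: str, value: float, table: RegimeTable | None = None) -> str:
    """Classify ``value`` as ``low``/``normal``/``high`` for ``analyte``.

    The normal band is closed: boundary values classify as normal.
    """
    _require_analyte(analyte)
    if not math.isfinite(value):
        raise ValueError(f"{analyte}: cannot classify non-finite value {value!r}")
    table = table if table is not None else RegimeTable.default()
    lo, hi = table.band(analyte)
    if value < lo:
        return "low"
    if value > hi:
        return "high"
    return "normal"


def convert_glucose_units(value: float, direction: str) -> float:
    """Convert glucose between mg/dL and mmol/L.

    ``direction`` is ``"to_mmol_l"`` (input mg/dL) or ``"to_mg_dl"``
    (input mmol/L).  Round-trips are exact to within 1e-9 relative.
    """
    if value <= 0:
        raise ValueError(f"glucose concentration must be positive, got {value}")
    if direction == "to_mmol_l":
        return value / GLUCOSE_MG_DL_PER_MMOL_L
    if direction == "to_mg_dl":
        return value * GLUCOSE_MG_DL_PER_MMOL_L
    raise ValueError(f"direction must be 'to_mmol_l' or 'to_mg_dl', got {direction!r}")
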