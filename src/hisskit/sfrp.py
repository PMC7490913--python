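"""Synthetic patient generator.

A cohort is produced by seeding each synthetic patient with a hidden
severity level 0-4, sampling every biomarker uniformly from a
level-specific interval, and then passing the draws through noise
filters that let values bleed into neighbouring regimes:

* glucose/lactate may drift one regime step (``p_drift``);
* glucose may be forced hyperglycemic — a stress ("adrenergic") response
  confounding lower severity levels (``p_adrenergic``);
* pH may stay normal at any non-zero seed, acidosis being a late sign
  (``p_ph_normal``);
* pO2 may normalise under acidosis — respiratory compensation through
  hyperventilation (``p_resp_comp``) — and always receives a small
  additive jitter.

Potassium is never sampled directly: it is a eukalemic baseline draw
adjusted by the empirical acid-base relation (a 0.1-unit drop in pH
raises potassium by 0.6 mmol/L), applied unconditionally in pH.

The hidden seed is retained on each record but withheld from default
exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

from .domain import (
    ANALYTES,
    PH_GATE,
    SEVERITY_LEVELS,
    AnalytePanel,
    RegimeTable,
    check_score,
    classify_regime,
    validate_panel,
)

#: slope of the potassium/pH relation: mmol/L potassium per pH unit
K_PER_PH_UNIT = 6.0

#: pH pivot below which potassium rises
K_PH_PIVOT = 7.35

# sampling windows used when a draw drifts into (or is forced into) a
# pathological regime; Table-style bands are open-ended so a finite
# window is needed for uniform draws
_DRIFT_WINDOWS: dict[str, dict[str, tuple[float, float]]] = {
    "glucose": {"low": (30.0, 70.0), "high": (99.0, 180.0)},
    "lactate": {"low": (0.05, 0.5), "high": (2.0, 4.0)},
}

Interval = tuple[float, float]


@dataclass(frozen=True)
class SeverityProfile:
    """Per-level, per-analyte target sampling intervals.

    ``intervals[level][analyte]`` is a list of (lo, hi) windows; when an
    analyte has several windows (e.g. hypo- vs hyper-glycemia) one is
    chosen uniformly before drawing.  Potassium is absent by design: it
    is derived from pH.
    """

    intervals: dict[int, dict[str, list[Interval]]]

    _SAMPLED = ("glucose", "lactate", "ph", "po2")

    def __post_init__(self) -> None:
        table = RegimeTable.default()
        for level in SEVERITY_LEVELS:
            if level not in self.intervals:
                raise ValueError(f"severity profile missing level {level}")
            for a in self._SAMPLED:
                windows = self.intervals[level].get(a)
                if not windows:
                    raise ValueError(f"severity profile level {level} missing analyte {a!r}")
                for lo, hi in windows:
                    if not lo <= hi:
                        raise ValueError(f"level {level} {a}: bad interval [{lo}, {hi}]")
        # level 0 must lie inside the normal bands
        for a in self._SAMPLED:
            band_lo, band_hi = table.band(a)
            for lo, hi in self.intervals[0][a]:
                if lo < band_lo or hi > band_hi:
                    raise ValueError(
                        f"level-0 interval [{lo}, {hi}] for {a} leaves the normal band"
                    )
        lac_means = [self.mean_value(level, "lactate") for level in SEVERITY_LEVELS]
        if any(b < a for a, b in zip(lac_means, lac_means[1:])):
            raise ValueError("mean lactate must be non-decreasing in severity level")
        ph_means = [self.mean_value(level, "ph") for level in SEVERITY_LEVELS]
        if any(b > a for a, b in zip(ph_means, ph_means[1:])):
            raise ValueError("mean pH must be non-increasing in severity level")

    def mean_value(self, level: int, analyte: str) -> float:
        """Expected draw for ``analyte`` at ``level`` (windows equi-probable)."""
        windows = self.intervals[level][analyte]
        return float(np.mean([(lo + hi) / 2 for lo, hi in windows]))

    def windows(self, level: int, analyte: str) -> list[Interval]:
        return self.intervals[level][analyte]

    @classmethod
    def default(cls) -> "SeverityProfile":
        text = resources.files("hisskit.data").joinpath("severity_profile.json").read_text()
        return cls.from_json(text)

    @classmethod
    def from_json(cls, text: str) -> "SeverityProfile":
        doc = json.loads(text)
        intervals = {
            int(level): {a: [tuple(map(float, w)) for w in windows]
                         for a, windows in entry.items()}
            for level, entry in doc.items()
        }
        return cls(intervals=intervals)

    def to_json(self) -> str:
        doc = {
            str(level): {a: [list(w) for w in windows]
                         for a, windows in entry.items()}
            for level, entry in self.intervals.items()
        }
        return json.dumps(doc, indent=2)


@dataclass(frozen=True)
class NoiseConfig:
    """Probabilities of the regime-bleed noise scenarios."""

    p_drift: float = 0.10
    p_adrenergic: float = 0.10
    p_ph_normal: float = 0.25
    p_resp_comp: float = 0.30
    po2_jitter: float = 5.0  # mmHg, additive uniform half-width

    def __post_init__(self) -> None:
        for name in ("p_drift", "p_adrenergic", "p_ph_normal", "p_resp_comp"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.po2_jitter < 0:
            raise ValueError(f"po2_jitter must be >= 0, got {self.po2_jitter}")

    @classmethod
    def quiet(cls) -> "NoiseConfig":
        """All noise scenarios disabled."""
        return cls(p_drift=0.0, p_adrenergic=0.0, p_ph_normal=0.0,
                   p_resp_comp=0.0, po2_jitter=0.0)


@dataclass(frozen=True)
class SFRPRecord:
    """One synthetic patient: id, biomarker panel, withheld severity seed."""

    patient_id: int
    panel: AnalytePanel
    hidden_seed: int

    def baseline_potassium(self) -> float:
        """Recover the eukalemic baseline draw behind the potassium value."""
        return self.panel.potassium - K_PER_PH_UNIT * (K_PH_PIVOT - self.panel.ph)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to regenerate a cohort deterministically."""

    profile: SeverityProfile = field(default_factory=SeverityProfile.default)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    class_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "profile": json.loads(self.profile.to_json()),
            "noise": {
                "p_drift": self.noise.p_drift,
                "p_adrenergic": self.noise.p_adrenergic,
                "p_ph_normal": self.noise.p_ph_normal,
                "p_resp_comp": self.noise.p_resp_comp,
                "po2_jitter": self.noise.po2_jitter,
            },
            "class_weights": list(self.class_weights),
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CohortConfig":
        profile = (SeverityProfile.from_json(json.dumps(doc["profile"]))
                   if "profile" in doc else SeverityProfile.default())
        noise = NoiseConfig(**doc.get("noise", {}))
        weights = tuple(doc.get("class_weights", (1.0,) * 5))
        return cls(profile=profile, noise=noise, class_weights=weights,
                   rng_seed=int(doc.get("rng_seed", 0)))


def generate_hidden_seeds(
    n: int,
    weights: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` hidden severity seeds.

    With equal weights and ``n`` divisible by 5 the allocation is exactly
    stratified (n/5 per level, shuffled); otherwise a multinomial draw by
    the normalized weights is used.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if weights is None:
        weights = (1.0,) * len(SEVERITY_LEVELS)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(SEVERITY_LEVELS),) or np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be 5 non-negative numbers, not all zero")
    rng = rng if rng is not None else np.random.default_rng()
    equal = np.allclose(w, w[0]) and w[0] > 0
    if equal and n % len(SEVERITY_LEVELS) == 0:
        seeds = np.repeat(np.array(SEVERITY_LEVELS), n // len(SEVERITY_LEVELS))
        rng.shuffle(seeds)
        return seeds
    probs = w / w.sum()
    return rng.choice(len(SEVERITY_LEVELS), size=n, p=probs)


def compute_potassium(ph: float, baseline: float) -> float:
    """Potassium from a eukalemic baseline and the acid-base relation.

    Applied unconditionally in pH: acidosis raises potassium, alkalosis
    lowers it (0.6 mmol/L per 0.1 pH unit).
    """
    if not 3.5 <= baseline <= 5.5:
        raise ValueError(
            f"baseline potassium must be a eukalemic draw in [3.50, 5.50], got {baseline}"
        )
    lo, hi = PH_GATE
    if not lo <= ph <= hi:
        raise ValueError(f"pH {ph} outside plausibility gate [{lo}, {hi}]")
    return baseline + (K_PH_PIVOT - ph) * K_PER_PH_UNIT


def _draw_from_windows(windows: list[Interval], rng: np.random.Generator) -> float:
    if len(windows) > 1:
        idx = int(rng.integers(len(windows)))
    else:
        idx = 0
    lo, hi = windows[idx]
    return float(rng.uniform(lo, hi)) if lo < hi else lo


def _drift_adjacent(analyte: str, value: float, table: RegimeTable,
                    rng: np.random.Generator) -> float:
    """Replace ``value`` with a draw from an adjacent regime (one step)."""
    regime = classify_regime(analyte, value, table)
    band = table.band(analyte)
    if regime == "normal":
        side = "low" if rng.random() < 0.5 else "high"
        lo, hi = _DRIFT_WINDOWS[analyte][side]
        return float(rng.uniform(lo, hi))
    # from a pathological regime the only adjacent regime is normal
    return float(rng.uniform(*band))


def sample_panel(
    seed: int,
    profile: SeverityProfile,
    noise: NoiseConfig,
    table: RegimeTable | None = None,
    rng: np.random.Generator | None = None,
) -> AnalytePanel:
    """Sample one biomarker panel for a hidden severity ``seed``."""
    seed = check_score(seed)
    table = table if table is not None else RegimeTable.default()
    rng = rng if rng is not None else np.random.default_rng()

    glucose = _draw_from_windows(profile.windows(seed, "glucose"), rng)
    if rng.random() < noise.p_drift:
        glucose = _drift_adjacent("glucose", glucose, table, rng)
    if rng.random() < noise.p_adrenergic:
        glucose = float(rng.uniform(*_DRIFT_WINDOWS["glucose"]["high"]))

    lactate = _draw_from_windows(profile.windows(seed, "lactate"), rng)
    if rng.random() < noise.p_drift:
        lactate = _drift_adjacent("lactate", lactate, table, rng)

    ph = _draw_from_windows(profile.windows(seed, "ph"), rng)
    if seed > 0 and rng.random() < noise.p_ph_normal:
        ph = float(rng.uniform(*table.band("ph")))

    # restrict the eukalemic baseline so a normal-pH patient stays
    # eukalemic after the (unconditional) acid-base adjustment
    baseline_lo = min(3.5 + max(0.0, (ph - K_PH_PIVOT) * K_PER_PH_UNIT), 5.5)
    baseline = float(rng.uniform(baseline_lo, 5.5))
    potassium = compute_potassium(ph, baseline)

    po2 = _draw_from_windows(profile.windows(seed, "po2"), rng)
    if ph < table.band("ph")[0] and rng.random() < noise.p_resp_comp:
        po2 = float(rng.uniform(*table.band("po2")))
    if noise.po2_jitter > 0:
        po2 += float(rng.uniform(-noise.po2_jitter, noise.po2_jitter))
    po2 = max(po2, 1.0)

    panel = AnalytePanel(glucose=glucose, lactate=lactate, ph=ph,
                         potassium=potassium, po2=po2)
    problems = validate_panel(panel)
    if problems:  # pragma: no cover - profiles inside the gate cannot trip this
        raise ValueError(f"sampled implausible panel: {problems}")
    return panel


def generate_cohort(n: int, config: CohortConfig | None = None) -> list[SFRPRecord]:
    """Generate ``n`` records with ids 1..n, reproducible from the config seed."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    config = config if config is not None else CohortConfig()
    rng = np.random.default_rng(config.rng_seed)
    table = RegimeTable.default()
    seeds = generate_hidden_seeds(n, config.class_weights, rng)
    records = []
    for i, seed in enumerate(seeds, start=1):
        panel = sample_panel(int(seed), config.profile, config.noise, table, rng)
        records.append(SFRPRecord(patient_id=i, panel=panel, hidden_seed=int(seed)))
    return records
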