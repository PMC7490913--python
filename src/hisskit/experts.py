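"""Simulated physician committee and label fusion.

A deterministic core rubric maps a biomarker panel to a severity score
by grading each analyte's derangement (distance beyond its normal band)
and thresholding the weighted sum.  Individual committee members deviate
from the core rubric through per-analyte importance weights, shifted
regime boundaries, a score ceiling, and a per-scoring-act perturbation
probability.  Fusion covers both the crisp consensus (mode, ties broken
toward higher severity) and graded possibility labels (vote counts
normalised by the largest count).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .domain import (
    ANALYTES,
    AnalytePanel,
    RegimeTable,
    classify_regime,
)
from .sfrp import SFRPRecord

N_CLASSES = 5

# per-(analyte, side) grade steps: derangement distance d maps to grade
# 1 if d <= step1, 2 if d <= step2, else 3
_GRADE_STEPS: dict[tuple[str, str], tuple[float, float]] = {
    ("glucose", "low"): (15.0, 35.0),
    ("glucose", "high"): (30.0, 80.0),
    ("lactate", "low"): (0.2, 0.4),
    ("lactate", "high"): (1.0, 4.0),
    ("ph", "low"): (0.05, 0.10),
    ("ph", "high"): (0.05, 0.10),
    ("potassium", "low"): (0.5, 1.5),
    ("potassium", "high"): (0.5, 1.5),
    ("po2", "low"): (20.0, 40.0),
    ("po2", "high"): (30.0, 80.0),
}

# weighted derangement sum s maps to score k where s >= _CUTS[k-1];
# half-integer cuts keep unit-weight sums (integers) away from the
# boundaries so small expert weight biases do not flip every score;
# calibrated so the rubric reproduces the committee consensus on
# reference panels (see tests)
_CUTS = (0.5, 3.5, 6.5, 12.5)


def derangement_grade(analyte: str, value: float, table: RegimeTable) -> int:
    """Grade one analyte 0 (normal) to 3 (severely deranged)."""
    regime = classify_regime(analyte, value, table)
    if regime == "normal":
        return 0
    lo, hi = table.band(analyte)
    d = lo - value if regime == "low" else value - hi
    step1, step2 = _GRADE_STEPS[(analyte, regime)]
    if d <= step1:
        return 1
    if d <= step2:
        return 2
    return 3


def core_policy_score(
    panel: AnalytePanel,
    table: RegimeTable | None = None,
    weights: dict[str, float] | None = None,
) -> int:
    """Deterministic rubric score in 0..4 for a panel."""
    table = table if table is not None else RegimeTable.default()
    s = 0.0
    for a in ANALYTES:
        w = 1.0 if weights is None else weights.get(a, 1.0)
        s += w * derangement_grade(a, getattr(panel, a), table)
    score = 0
    for k, cut in enumerate(_CUTS, start=1):
        if s >= cut:
            score = k
    return score


@dataclass(frozen=True)
class ExpertProfile:
    """Behavioural parameters of one simulated committee member."""

    name: str = "D?"
    rubric_weights: dict[str, float] = field(default_factory=dict)
    threshold_shift: dict[str, float] = field(default_factory=dict)
    score_ceiling: int = 4
    intra_noise: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.intra_noise <= 1.0:
            raise ValueError(f"intra_noise must lie in [0, 1], got {self.intra_noise}")
        if self.score_ceiling not in range(N_CLASSES):
            raise ValueError(f"score_ceiling must be in 0..4, got {self.score_ceiling}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "rubric_weights": dict(self.rubric_weights),
            "threshold_shift": dict(self.threshold_shift),
            "score_ceiling": self.score_ceiling,
            "intra_noise": self.intra_noise,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ExpertProfile":
        return cls(
            name=doc.get("name", "D?"),
            rubric_weights=dict(doc.get("rubric_weights", {})),
            threshold_shift=dict(doc.get("threshold_shift", {})),
            score_ceiling=int(doc.get("score_ceiling", 4)),
            intra_noise=float(doc.get("intra_noise", 0.0)),
        )


def default_committee(intra_noise: float = 0.08) -> list[ExpertProfile]:
    """The shipped five-member committee (see ``data/committee.json``).

    ``intra_noise`` overrides every member's per-act perturbation rate.
    """
    text = resources.files("hisskit.data").joinpath("committee.json").read_text()
    committee = committee_from_json(text)
    return [ExpertProfile(name=p.name, rubric_weights=p.rubric_weights,
                          threshold_shift=p.threshold_shift,
                          score_ceiling=p.score_ceiling, intra_noise=intra_noise)
            for p in committee]


def committee_from_json(text: str) -> list[ExpertProfile]:
    return [ExpertProfile.from_dict(doc) for doc in json.loads(text)]


def committee_to_json(committee: Sequence[ExpertProfile]) -> str:
    return json.dumps([p.to_dict() for p in committee], indent=2)


def simulate_expert_score(
    panel: AnalytePanel,
    profile: ExpertProfile,
    rng: np.random.Generator,
    table: RegimeTable | None = None,
    reference: int | None = None,
) -> int:
    """One scoring act by one expert.

    ``reference`` is the expert's own previously recorded score for the
    same panel (duplicate presentation); the act then wobbles around that
    anchor instead of re-deriving the rubric.  Deviations are +/-1 with
    probability ``intra_noise``; a deviation that would leave
    [0, score_ceiling] takes the opposite direction instead.
    """
    table = table if table is not None else RegimeTable.default()
    if reference is not None:
        base = min(int(reference), profile.score_ceiling)
    else:
        shifted = table.shifted(profile.threshold_shift) if profile.threshold_shift else table
        base = core_policy_score(panel, shifted, profile.rubric_weights or None)
        base = min(base, profile.score_ceiling)
    if profile.intra_noise > 0 and rng.random() < profile.intra_noise:
        step = 1 if rng.random() < 0.5 else -1
        if not 0 <= base + step <= profile.score_ceiling:
            step = -step
        if 0 <= base + step <= profile.score_ceiling:
            base += step
    return base


@dataclass
class ScoreMatrix:
    """Committee scores, originals first, probe duplicates appended."""

    scores: np.ndarray           # (n_rows, n_experts) int
    expert_ids: list[str]
    patient_ids: list[int]       # per row; probe rows repeat a patient id
    n_patients: int              # number of original rows
    probe_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.expert_ids):
            raise ValueError("score matrix shape inconsistent with expert ids")
        if len(self.patient_ids) != self.scores.shape[0]:
            raise ValueError("patient id list inconsistent with score rows")
        if np.any((self.scores < 0) | (self.scores >= N_CLASSES)):
            raise ValueError("scores must lie in 0..4")

    @property
    def n_experts(self) -> int:
        return len(self.expert_ids)

    def originals(self) -> np.ndarray:
        return self.scores[: self.n_patients]


def score_cohort(
    records: Sequence[SFRPRecord],
    committee: Sequence[ExpertProfile],
    rng: np.random.Generator | None = None,
    probe_fraction: float = 0.0,
    table: RegimeTable | None = None,
) -> ScoreMatrix:
    """Score every record with every expert; optionally re-present probes.

    A ``probe_fraction`` of patients is silently shown a second time and
    the duplicate rows recorded in ``probe_pairs`` for intra-expert
    variability measurement.
    """
    if len(committee) == 0:
        raise ValueError("committee must contain at least one expert")
    if not 0.0 <= probe_fraction <= 1.0:
        raise ValueError(f"probe_fraction must lie in [0, 1], got {probe_fraction}")
    rng = rng if rng is not None else np.random.default_rng()
    table = table if table is not None else RegimeTable.default()
    n = len(records)
    scores = np.zeros((n, len(committee)), dtype=int)
    for i, rec in enumerate(records):
        for j, prof in enumerate(committee):
            scores[i, j] = simulate_expert_score(rec.panel, prof, rng, table)
    patient_ids = [rec.patient_id for rec in records]
    probe_pairs: list[tuple[int, int]] = []
    n_probe = int(round(probe_fraction * n))
    if n_probe > 0:
        chosen = rng.choice(n, size=n_probe, replace=False)
        probe_rows = []
        for row, i in enumerate(chosen, start=n):
            rescores = [
                simulate_expert_score(records[i].panel, prof, rng, table,
                                      reference=int(scores[i, j]))
                for j, prof in enumerate(committee)
            ]
            probe_rows.append(rescores)
            patient_ids.append(records[i].patient_id)
            probe_pairs.append((int(i), row))
        scores = np.vstack([scores, np.asarray(probe_rows, dtype=int)])
    return ScoreMatrix(
        scores=scores,
        expert_ids=[p.name for p in committee],
        patient_ids=patient_ids,
        n_patients=n,
        probe_pairs=probe_pairs,
    )


def majority_vote(scores: Sequence[int]) -> int:
    """Modal score; ties broken toward the higher (more severe) score."""
    scores = np.asarray(scores, dtype=int)
    if scores.size == 0:
        raise ValueError("majority_vote requires at least one score")
    counts = np.bincount(scores, minlength=N_CLASSES)
    best = counts.max()
    return int(np.flatnonzero(counts == best).max())


def possibility_labels(scores: Sequence[int], c: int = N_CLASSES) -> np.ndarray:
    """Vote-count possibility vector: count per class over the max count."""
    scores = np.asarray(scores, dtype=int)
    if scores.size == 0:
        raise ValueError("possibility_labels requires at least one score")
    if np.any(scores >= c) or np.any(scores < 0):
        raise ValueError(f"scores must lie in 0..{c - 1}")
    counts = np.bincount(scores, minlength=c).astype(float)
    return counts / counts.max()


def intra_expert_variability(matrix: ScoreMatrix) -> float:
    """Percent of probe re-scorings that differ from the original act."""
    if not matrix.probe_pairs:
        raise ValueError("no probe pairs recorded; score with probe_fraction > 0")
    discordant = 0
    total = 0
    for i, j in matrix.probe_pairs:
        discordant += int(np.sum(matrix.scores[i] != matrix.scores[j]))
        total += matrix.n_experts
    return 100.0 * discordant / total


def inter_expert_variability(matrix: ScoreMatrix) -> float:
    """Mean over patients of the pairwise expert disagreement rate, in percent."""
    k = matrix.n_experts
    if k < 2:
        raise ValueError("inter-expert variability requires at least two experts")
    rows = matrix.originals()
    n_pairs = k * (k - 1) / 2
    disagreements = []
    for row in rows:
        d = sum(row[a] != row[b] for a in range(k) for b in range(a + 1, k))
        disagreements.append(d / n_pairs)
    return 100.0 * float(np.mean(disagreements))
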