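"""Fatigue-index fusion: normalisation, weighted sum, and grading.

Each sliding window's four behavioural indicators — blink frequency
(BF), PERCLOS, yawn frequency (YF), nod frequency (NF) — are mapped to
[0, 1] by clamped min-max normalisation against fixed baseline / maximum
reference values, then fused::

    F_i = clamp((X_i - X_i0) / (X_im - X_i0), 0, 1)
    F   = sum_i W_i * F_i,     sum_i W_i = 1

with default weights (0.10, 0.40, 0.30, 0.20) — PERCLOS dominant, YF and
NF supporting, BF de-emphasised.  F grades into four levels (awake,
mild, moderate, severe at boundaries 0.25 / 0.45 / 0.65) and an
independent sleep warning fires when PERCLOS exceeds 0.4.

Unit note: the PERCLOS normalisation bounds are percentages (5, 50), so
the fraction-valued PERCLOS is multiplied by 100 before normalising; the
sleep warning compares the fraction against 0.4 directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .temporal import WindowSummary

__all__ = [
    "FusionConfig", "FatigueAssessment", "LEVELS",
    "normalize_feature", "fatigue_index", "classify_fatigue",
    "assess_windows", "default_config", "round_half_up",
]

LEVELS = ("awake", "mild", "moderate", "severe")


@dataclass(frozen=True)
class FusionConfig:
    """Normalisation bounds, fusion weights and grading boundaries.

    Order of the four features everywhere: (BF, PERCLOS[%], YF, NF).
    ``use_rates``: normalise per-minute rates instead of raw window
    counts (the bounds are per-minute figures; for the default 30 s
    window the raw counts reproduce the reference worked examples, so
    counts are the default).
    """

    baselines: Tuple[float, float, float, float] = (15.0, 5.0, 1.0, 3.0)
    maxima: Tuple[float, float, float, float] = (40.0, 50.0, 5.0, 10.0)
    weights: Tuple[float, float, float, float] = (0.10, 0.40, 0.30, 0.20)
    level_boundaries: Tuple[float, float, float] = (0.25, 0.45, 0.65)
    sleep_perclos: float = 0.4
    use_rates: bool = False

    def __post_init__(self) -> None:
        for lo, hi in zip(self.baselines, self.maxima):
            if not lo < hi:
                raise ValueError(f"baseline {lo} must be below maximum {hi}")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")
        b = self.level_boundaries
        if not (0 < b[0] < b[1] < b[2] < 1):
            raise ValueError("level boundaries must be strictly increasing in (0, 1)")


def default_config() -> FusionConfig:
    """The reference configuration (Group-G4 weights, standard bounds)."""
    return FusionConfig()


@dataclass(frozen=True)
class FatigueAssessment:
    """One window's normalised features, fused index and grade."""

    window_index: int
    f1: float   # BF
    f2: float   # PERCLOS
    f3: float   # YF
    f4: float   # NF
    f: float
    level: str
    sleeping_warning: bool


def normalize_feature(x: float, baseline: float, maxref: float) -> float:
    """Clamped min-max normalisation of one indicator to [0, 1]."""
    if not math.isfinite(x):
        raise ValueError(f"non-finite monitored value {x!r}")
    if not baseline < maxref:
        raise ValueError("baseline must be below the maximum reference")
    return min(1.0, max(0.0, (x - baseline) / (maxref - baseline)))


def fatigue_index(fi: Sequence[float],
                  weights: Sequence[float] = (0.10, 0.40, 0.30, 0.20)) -> float:
    """Weighted fusion of normalised features into the scalar index F."""
    if len(fi) != len(weights):
        raise ValueError("feature/weight length mismatch")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(weights)}")
    for v in fi:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"normalised feature {v} outside [0, 1]")
    return float(sum(w * v for w, v in zip(weights, fi)))


def classify_fatigue(f: float, perclos: float,
                     config: FusionConfig = FusionConfig()) -> Tuple[str, bool]:
    """Grade the fused index and raise the sleep warning.

    The level is read off the F boundaries (upper boundary of 'severe'
    inclusive so F = 1 grades severe); the warning is an independent
    flag (perclos > sleep threshold) that never suppresses the level —
    a sleeping driver still receives a fatigue grade.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"F must lie in [0, 1], got {f}")
    if not 0.0 <= perclos <= 1.0:
        raise ValueError(f"perclos must lie in [0, 1], got {perclos}")
    b1, b2, b3 = config.level_boundaries
    if f < b1:
        level = "awake"
    elif f < b2:
        level = "mild"
    elif f < b3:
        level = "moderate"
    else:
        level = "severe"
    return level, perclos > config.sleep_perclos


def assess_window_values(bf: float, perclos_fraction: float, yf: float,
                         nf: float, config: FusionConfig = FusionConfig(),
                         window_index: int = 0) -> FatigueAssessment:
    """Assess one window given its raw indicator values.

    ``perclos_fraction`` is in [0, 1]; it is put on the percent scale
    for normalisation and kept as a fraction for the sleep warning.
    """
    xs = (bf, perclos_fraction * 100.0, yf, nf)
    fis = tuple(normalize_feature(x, lo, hi)
                for x, lo, hi in zip(xs, config.baselines, config.maxima))
    f = fatigue_index(fis, config.weights)
    level, warning = classify_fatigue(f, perclos_fraction, config)
    return FatigueAssessment(window_index, *fis, f=f, level=level,
                             sleeping_warning=warning)


def assess_windows(summaries: Sequence[WindowSummary],
                   config: FusionConfig = FusionConfig()
                   ) -> List[FatigueAssessment]:
    """Assess every window summary produced by the temporal pipeline."""
    out: List[FatigueAssessment] = []
    for s in summaries:
        if config.use_rates:
            bf, yf, nf = s.bf_per_min, s.yf_per_min, s.nf_per_min
        else:
            bf, yf, nf = s.bf, s.yf, s.nf
        out.append(assess_window_values(bf, s.perclos, yf, nf, config,
                                        window_index=s.window_index))
    return out


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal display rounding (0.375 -> 0.38), for reports only."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def assessments_to_dataframe(assessments: Sequence[FatigueAssessment]):
    """Assessment table: window, F1..F4, F, level, sleeping_warning."""
    import pandas as pd

    rows = [{
        "window": a.window_index, "F1": a.f1, "F2": a.f2, "F3": a.f3,
        "F4": a.f4, "F": a.f, "level": a.level,
        "sleeping_warning": a.sleeping_warning,
    } for a in assessments]
    cols = ["window", "F1", "F2", "F3", "F4", "F", "level", "sleeping_warning"]
    return pd.DataFrame(rows, columns=cols)
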