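"""The two ECG detection systems built on the backprop network.

1.  A whole-cycle diagnosis net with topology 101-10-1: each 101-sample ECG
    cycle is min-max normalized and mapped to a single output encoding
    0 = healthy, 1 = sick.

2.  A sliding-window pattern-recognition net with topology 10-10-8: every
    contiguous 10-sample window of a cycle is min-max normalized onto [0, 1]
    and presented to a net trained on eight reference wave patterns
    (H1-H4 for healthy morphology, S1-S4 for sick morphology, one output
    unit each).  A pattern counts as recognized when its unit's activation
    reaches the decision threshold p (70% by default).  The diagnosis policy
    tests the sick patterns first: if any S pattern is recognized the series
    is called sick; otherwise if any H pattern is recognized it is called
    healthy; otherwise it stays unspecified.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .bp_core import (
    LabeledSample,
    NetParameters,
    NetTopology,
    TrainingConfig,
    TrainingReport,
    forward,
    forward_batch,
    train,
)

__all__ = [
    "EcgSeries",
    "Window",
    "PatternLibrary",
    "RecognitionResult",
    "DiagnosisPolicy",
    "Diagnosis",
    "PATTERN_NAMES",
    "PATTERN_TOPOLOGY",
    "CYCLE_TOPOLOGY",
    "CYCLE_LENGTH",
    "WINDOW_LENGTH",
    "normalize_window",
    "extract_windows",
    "build_pattern_library",
    "train_pattern_net",
    "recognize_patterns",
    "diagnose_by_patterns",
    "diagnose_series",
    "train_cycle_classifier",
    "classify_cycle",
]

PATTERN_NAMES = ("H1", "H2", "H3", "H4", "S1", "S2", "S3", "S4")
PATTERN_TOPOLOGY = NetTopology(10, 10, 8)
CYCLE_TOPOLOGY = NetTopology(101, 10, 1)
CYCLE_LENGTH = 101
WINDOW_LENGTH = 10

_LABELS = ("healthy", "sick", "unknown")


@dataclass
class EcgSeries:
    """A univariate ECG-like series with an optional class label."""

    values: np.ndarray
    label: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("series must be a nonempty 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.id!r} contains non-finite values")
        if self.label is not None and self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Window:
    """One contiguous window [start, start+n) of a series, raw and normalized."""

    start_index: int
    values_raw: np.ndarray
    values_norm: np.ndarray


@dataclass
class PatternLibrary:
    """The eight labeled reference windows and their class assignment."""

    patterns: list[LabeledSample]
    names: tuple[str, ...] = PATTERN_NAMES
    class_of: dict[str, str] = field(
        default_factory=lambda: {n: ("healthy" if n.startswith("H") else "sick") for n in PATTERN_NAMES}
    )

    def input_of(self, name: str) -> np.ndarray:
        return self.patterns[self.names.index(name)].input


@dataclass
class DiagnosisPolicy:
    """Decision thresholds: p for pattern recognition, cutoff for the cycle net."""

    p_threshold: float = 0.70
    cycle_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if not (0.0 < self.cycle_cutoff < 1.0):
            raise ValueError(f"cycle_cutoff must be in (0, 1), got {self.cycle_cutoff}")


@dataclass
class RecognitionResult:
    """Per-pattern recognition probabilities over all windows of one series."""

    per_pattern_max: dict[str, float]
    detections: list[tuple[int, str, float]]

    @property
    def p_S(self) -> float:
        return max(v for k, v in self.per_pattern_max.items() if k.startswith("S"))

    @property
    def p_H(self) -> float:
        return max(v for k, v in self.per_pattern_max.items() if k.startswith("H"))


@dataclass
class Diagnosis:
    verdict: str  # "sick" | "healthy" | "unspecified"
    evidence: object = None


def normalize_window(raw) -> np.ndarray:
    """Min-max map onto [0, 1]: x' = (x - min) / (max - min).

    A degenerate all-equal window (max = min) maps to all zeros so that the
    pipeline stays total.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or len(raw) == 0:
        raise ValueError("window must be a nonempty 1-D vector")
    lo = raw.min()
    span = raw.max() - lo
    if span == 0:
        return np.zeros_like(raw)
    return (raw - lo) / span


def extract_windows(series: EcgSeries | np.ndarray, n: int = WINDOW_LENGTH, stride: int = 1) -> list[Window]:
    """All contiguous n-sample windows (stride 1 by default), normalized."""
    values = series.values if isinstance(series, EcgSeries) else np.asarray(series, dtype=float)
    L = len(values)
    if L < n:
        raise ValueError(f"series of length {L} is shorter than the window length {n}")
    windows = []
    for start in range(0, L - n + 1, stride):
        raw = values[start : start + n]
        windows.append(Window(start_index=start, values_raw=raw.copy(), values_norm=normalize_window(raw)))
    return windows


def build_pattern_library() -> PatternLibrary:
    """Load the eight packaged reference patterns with one-hot targets."""
    text = resources.files("ecgdx.data").joinpath("table1.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    patterns = []
    names = []
    for row in rows:
        names.append(row["name"])
        inp = np.array([float(row[f"x{i}"]) for i in range(1, 11)])
        tgt = np.array([float(row[f"t{i}"]) for i in range(1, 9)])
        patterns.append(LabeledSample(input=inp, target=tgt))
    lib = PatternLibrary(patterns=patterns, names=tuple(names))
    return lib


def train_pattern_net(
    config: TrainingConfig | None = None,
    library: PatternLibrary | None = None,
) -> tuple[NetParameters, TrainingReport]:
    """Train the 10-10-8 recognition net on the eight reference patterns."""
    if library is None:
        library = build_pattern_library()
    return train(PATTERN_TOPOLOGY, library.patterns, config)


def recognize_patterns(
    series: EcgSeries,
    net: NetParameters,
    policy: DiagnosisPolicy | None = None,
    library: PatternLibrary | None = None,
) -> RecognitionResult:
    """Slide the recognition net over every normalized window of a series.

    The recognition probability p of a pattern is the maximum activation of
    its output unit across all windows; detections are the (window, pattern)
    pairs whose activation reaches the policy threshold.
    """
    if net.topology != PATTERN_TOPOLOGY:
        raise ValueError(
            f"pattern recognition requires topology {PATTERN_TOPOLOGY.as_tuple()}, "
            f"got {net.topology.as_tuple()}"
        )
    if policy is None:
        policy = DiagnosisPolicy()
    names = library.names if library is not None else PATTERN_NAMES
    windows = extract_windows(series)
    W = np.stack([w.values_norm for w in windows])
    Z = forward_batch(net, W)  # (n_windows, 8)
    per_pattern_max = {name: float(Z[:, k].max()) for k, name in enumerate(names)}
    detections = [
        (windows[t].start_index, names[k], float(Z[t, k]))
        for t, k in zip(*np.nonzero(Z >= policy.p_threshold))
    ]
    return RecognitionResult(per_pattern_max=per_pattern_max, detections=detections)


def diagnose_by_patterns(result: RecognitionResult, policy: DiagnosisPolicy | None = None) -> Diagnosis:
    """Sick-first threshold policy on the recognition probabilities.

    If any sick pattern reaches the threshold the verdict is sick (the sick
    test takes strict precedence); otherwise a healthy pattern at threshold
    gives healthy; otherwise the series stays unspecified.
    """
    if policy is None:
        policy = DiagnosisPolicy()
    if result.p_S >= policy.p_threshold:
        return Diagnosis(verdict="sick", evidence=result)
    if result.p_H >= policy.p_threshold:
        return Diagnosis(verdict="healthy", evidence=result)
    return Diagnosis(verdict="unspecified", evidence=result)


def diagnose_series(
    series: EcgSeries, net: NetParameters, policy: DiagnosisPolicy | None = None
) -> Diagnosis:
    """Convenience: recognize_patterns followed by diagnose_by_patterns."""
    return diagnose_by_patterns(recognize_patterns(series, net, policy), policy)


def train_cycle_classifier(
    cohort: Sequence[EcgSeries],
    config: TrainingConfig | None = None,
    normalize: bool = True,
) -> tuple[NetParameters, TrainingReport]:
    """Train the 101-10-1 whole-cycle net on labeled series.

    Targets are 0 for healthy and 1 for sick.  Each series is min-max
    normalized per series before presentation (the same convention as the
    window normalization); disable with ``normalize=False``.
    """
    samples = []
    for s in cohort:
        if len(s) != CYCLE_LENGTH:
            raise ValueError(
                f"series {s.id!r} has {len(s)} samples; the cycle net requires {CYCLE_LENGTH}"
            )
        if s.label not in ("healthy", "sick"):
            raise ValueError(f"series {s.id!r} needs a healthy/sick label, got {s.label!r}")
        x = normalize_window(s.values) if normalize else s.values
        samples.append(LabeledSample(input=x, target=np.array([0.0 if s.label == "healthy" else 1.0])))
    return train(CYCLE_TOPOLOGY, samples, config)


def classify_cycle(
    series: EcgSeries,
    net: NetParameters,
    policy: DiagnosisPolicy | None = None,
    normalize: bool = True,
) -> Diagnosis:
    """Whole-cycle verdict: sick iff the single output reaches the cutoff."""
    if net.topology != CYCLE_TOPOLOGY:
        raise ValueError(
            f"cycle classification requires topology {CYCLE_TOPOLOGY.as_tuple()}, "
            f"got {net.topology.as_tuple()}"
        )
    if len(series) != CYCLE_LENGTH:
        raise ValueError(
            f"series {series.id!r} has {len(series)} samples; expected {CYCLE_LENGTH}"
        )
    if policy is None:
        policy = DiagnosisPolicy()
    x = normalize_window(series.values) if normalize else series.values
    z = float(forward(net, x).z[0])
    verdict = "sick" if z >= policy.cycle_cutoff else "healthy"
    return Diagnosis(verdict=verdict, evidence=z)
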