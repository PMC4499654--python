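"""Synthetic one-cycle ECG generator with healthy and sick morphologies.

Each 101-sample cycle is a sum of five signed Gaussian deflections (P, Q,
R, S, T in temporal order) plus white noise.  The healthy defaults follow a
textbook lead-II cycle: a small P wave, a narrow dominant R spike flanked
by small negative Q and S dips, and a broader T wave.  The sick morphology
keeps the same landmarks but lowers and widens the R complex and enlarges
and widens the T wave, so the two class-mean curves are clearly separated
while individual draws still overlap through noise.

The generator also builds the 1010-sample learning series used by the
SMAPE-comparison classifier (ten cycles concatenated) and can plant an
exact raw pre-image of one of the eight reference windows into a series,
which supports recognition-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classifiers import CYCLE_LENGTH, EcgSeries, build_pattern_library

__all__ = [
    "Deflection",
    "MorphologyParams",
    "CohortSpec",
    "healthy_morphology",
    "sick_morphology",
    "generate_cycle",
    "generate_cohort",
    "build_learning_series",
    "plant_pattern",
]


@dataclass(frozen=True)
class Deflection:
    """One Gaussian bump: center (sample index), signed amplitude, width (sd, samples)."""

    center: float
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"deflection width must be positive, got {self.width}")


@dataclass(frozen=True)
class MorphologyParams:
    """The five deflections of one cycle plus the additive noise level."""

    p: Deflection
    q: Deflection
    r: Deflection
    s: Deflection
    t: Deflection
    noise_sd: float = 0.02
    class_tag: str = "healthy"

    def __post_init__(self) -> None:
        centers = [self.p.center, self.q.center, self.r.center, self.s.center, self.t.center]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError(f"deflection centers must be ordered P < Q < R < S < T, got {centers}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")

    @property
    def deflections(self) -> tuple[Deflection, ...]:
        return (self.p, self.q, self.r, self.s, self.t)


def healthy_morphology(noise_sd: float = 0.02) -> MorphologyParams:
    """Default healthy cycle: narrow dominant R, modest P and T waves."""
    return MorphologyParams(
        p=Deflection(20.0, 0.17, 3.0),
        q=Deflection(38.0, -0.10, 1.2),
        r=Deflection(42.0, 1.00, 1.2),
        s=Deflection(46.0, -0.14, 1.4),
        t=Deflection(70.0, 0.35, 5.0),
        noise_sd=noise_sd,
        class_tag="healthy",
    )


def sick_morphology(noise_sd: float = 0.02) -> MorphologyParams:
    """Default sick cycle: reduced and widened R complex, enlarged wide T."""
    return MorphologyParams(
        p=Deflection(18.0, 0.10, 3.5),
        q=Deflection(38.0, -0.06, 1.6),
        r=Deflection(42.0, 0.62, 1.5),
        s=Deflection(47.0, -0.08, 2.0),
        t=Deflection(72.0, 0.48, 7.0),
        noise_sd=noise_sd,
        class_tag="sick",
    )


@dataclass(frozen=True)
class CohortSpec:
    """How many series of each class to draw, and from which master seed.

    The study-scale preset is 36 healthy / 34 sick with 25 + 25 used for
    training; ``sick_deformation`` can override the sick morphology.
    """

    n_healthy: int
    n_sick: int
    cycle_length: int = CYCLE_LENGTH
    rng_seed: int = 0
    noise_sd: float = 0.02
    sick_deformation: MorphologyParams | None = None

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_sick < 0:
            raise ValueError("cohort counts must be nonnegative")
        if self.cycle_length < 1:
            raise ValueError("cycle_length must be positive")


def generate_cycle(
    params: MorphologyParams, seed: int, cycle_length: int = CYCLE_LENGTH, id: str = ""
) -> EcgSeries:
    """One noisy cycle: sum of the five Gaussian bumps plus white noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(cycle_length, dtype=float)
    signal = np.zeros(cycle_length)
    for d in params.deflections:
        signal += d.amplitude * np.exp(-0.5 * ((t - d.center) / d.width) ** 2)
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=cycle_length)
    return EcgSeries(values=signal, label=params.class_tag, id=id)


def generate_cohort(spec: CohortSpec) -> list[EcgSeries]:
    """Labeled healthy + sick series with per-series seeds from the master seed."""
    master = np.random.default_rng(spec.rng_seed)
    # 2**31 keeps derived seeds reproducible across platforms and small
    seeds = master.integers(0, 2**31, size=spec.n_healthy + spec.n_sick)
    healthy = healthy_morphology(spec.noise_sd)
    sick = spec.sick_deformation or sick_morphology(spec.noise_sd)
    cohort = []
    for i in range(spec.n_healthy):
        cohort.append(
            generate_cycle(healthy, int(seeds[i]), spec.cycle_length, id=f"H{i + 1:03d}")
        )
    for i in range(spec.n_sick):
        cohort.append(
            generate_cycle(sick, int(seeds[spec.n_healthy + i]), spec.cycle_length, id=f"S{i + 1:03d}")
        )
    return cohort


def build_learning_series(series_list: list[EcgSeries]) -> np.ndarray:
    """Concatenate exactly ten 101-sample cycles into one 1010-sample series."""
    if len(series_list) != 10:
        raise ValueError(f"a learning series takes exactly 10 cycles, got {len(series_list)}")
    for s in series_list:
        if len(s) != CYCLE_LENGTH:
            raise ValueError(
                f"series {s.id!r} has {len(s)} samples; each cycle must have {CYCLE_LENGTH}"
            )
    return np.concatenate([s.values for s in series_list])


def plant_pattern(series: EcgSeries, pattern_name: str, at: int, seed: int = 0) -> EcgSeries:
    """Replace a 10-sample window with a raw pre-image of a reference pattern.

    The pre-image is an affine image (positive scale, arbitrary offset) of
    the normalized reference window; min-max normalization is affine
    invariant, so normalizing the planted window recovers the reference
    pattern exactly.  Samples outside [at, at+10) are untouched.
    """
    library = build_pattern_library()
    if pattern_name not in library.names:
        raise ValueError(f"unknown pattern {pattern_name!r}; choose from {library.names}")
    pattern = library.input_of(pattern_name)
    n = len(pattern)
    if at < 0 or at + n > len(series):
        raise ValueError(
            f"window [{at}, {at + n}) does not fit in a series of length {len(series)}"
        )
    rng = np.random.default_rng(seed)
    scale = rng.uniform(0.5, 2.0)
    offset = rng.uniform(-1.0, 1.0)
    values = series.values.copy()
    values[at : at + n] = offset + scale * pattern
    return EcgSeries(values=values, label=series.label, id=series.id)
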