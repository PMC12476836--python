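"""Calibration of the adaptive MiniPAE threshold from a non-binder pool.

The adaptive threshold tracks how the minimum MiniPAE among n non-binders
shifts as n grows: subsample n scores from the non-binder pool, record the
minimum, repeat (default 100 iterations), average — giving one curve point
(n, avg_min) per subsample size — then fit the three-parameter power law

    y = a * x**-b + c

by non-linear least squares (``scipy.optimize.curve_fit``).  ``predict(n)``
of the fitted model is the screen-size-dependent MiniPAE cutoff.

The module follows the Model/Results idiom: build a
:class:`PowerLawThreshold` model from a score pool (or pre-computed curve
points), call :meth:`~PowerLawThreshold.fit`, and read estimates,
diagnostics and ``summary()`` off the returned
:class:`PowerLawThresholdResults`.  Functional wrappers
(:func:`subsample_minima`, :func:`fit_power_law`,
:func:`predict_threshold`) expose the same steps individually.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateInputError,
    DomainError,
    FitFailureError,
    SamplingError,
    UnderdeterminedError,
)

__all__ = [
    "MinimaCurvePoint",
    "PowerLawThreshold",
    "PowerLawThresholdResults",
    "ThresholdModel",
    "subsample_minima",
    "fit_power_law",
    "predict_threshold",
    "DEFAULT_SIZE_GRID",
]

#: Log-spaced subsample sizes covering the screening-scale axis.
DEFAULT_SIZE_GRID = (1, 2, 5, 10, 25, 50, 100, 250, 500, 1000)

#: Subsampling repeats per size.
DEFAULT_ITERATIONS = 100


@dataclass(frozen=True)
class MinimaCurvePoint:
    """One point of the minima curve: mean (and sd) of the per-iteration
    minimum MiniPAE over subsamples of size ``n``."""

    n: int
    avg_min: float
    iterations: int
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1 or self.iterations < 1:
            raise DomainError("n and iterations must be >= 1")
        if self.avg_min < 0:
            raise DomainError("avg_min must be non-negative")


def _power_law(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.power(x, -b) + c


def subsample_minima(
    scores: Sequence[float],
    sizes: Sequence[int] | None = None,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    with_replacement: bool = False,
) -> list[MinimaCurvePoint]:
    """Minima curve of a score pool by repeated random subsampling.

    For each size n: draw n scores without replacement (``with_replacement``
    flips this), record the minimum, repeat ``iterations`` times; report the
    mean and standard deviation of the minima.  Fully reproducible: each
    size gets its own random stream spawned deterministically from ``seed``,
    so adding sizes does not perturb existing points.
    """
    pool = np.asarray(scores, dtype=float)
    if pool.size == 0:
        raise DegenerateInputError("empty score pool")
    if iterations < 1:
        raise DomainError(f"iterations must be >= 1, got {iterations}")
    if sizes is None:
        sizes = [n for n in DEFAULT_SIZE_GRID if n <= pool.size]
    points: list[MinimaCurvePoint] = []
    streams = np.random.SeedSequence(seed).spawn(len(sizes))
    for size, stream in zip(sizes, streams):
        size = int(size)
        if size < 1:
            raise DomainError(f"subsample size must be >= 1, got {size}")
        if not with_replacement and size > pool.size:
            raise SamplingError(
                f"subsample size {size} exceeds pool size {pool.size}"
            )
        rng = np.random.default_rng(stream)
        minima = np.empty(iterations)
        for it in range(iterations):
            draw = rng.choice(pool, size=size, replace=with_replacement)
            minima[it] = draw.min()
        points.append(
            MinimaCurvePoint(
                n=size,
                avg_min=float(minima.mean()),
                iterations=iterations,
                sd=float(minima.std(ddof=0)),
            )
        )
    return points


class PowerLawThreshold:
    """Adaptive-threshold model y = a*x^-b + c for a minima curve.

    Construct from pre-computed curve points, or from a raw non-binder score
    pool with :meth:`from_scores` (which runs the subsampling step).  Call
    :meth:`fit` to estimate (a, b, c).
    """

    def __init__(self, points: Sequence[MinimaCurvePoint], seed: int | None = None):
        points = list(points)
        if len(points) < 4:
            raise UnderdeterminedError(
                f"need >= 4 curve points for a 3-parameter fit, got "
                f"{len(points)}"
            )
        if len({p.n for p in points}) < 3:
            raise UnderdeterminedError("need >= 3 distinct subsample sizes")
        self.points = sorted(points, key=lambda p: p.n)
        self.seed = seed

    @classmethod
    def from_scores(
        cls,
        scores: Sequence[float],
        sizes: Sequence[int] | None = None,
        iterations: int = DEFAULT_ITERATIONS,
        seed: int = 0,
        with_replacement: bool = False,
    ) -> "PowerLawThreshold":
        points = subsample_minima(
            scores, sizes=sizes, iterations=iterations, seed=seed,
            with_replacement=with_replacement,
        )
        return cls(points, seed=seed)

    @property
    def x(self) -> np.ndarray:
        return np.array([p.n for p in self.points], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([p.avg_min for p in self.points])

    def fit(self, maxfev: int = 20000) -> "PowerLawThresholdResults":
        """Non-linear least squares estimate of (a, b, c).

        Start values: a = range of y, b = 0.3, c = min(y) — a decreasing
        curve of the observed span, which converges robustly for minima
        curves.  A flat curve (zero span) short-circuits to the exact
        degenerate solution a=0, c=mean(y).
        """
        x, y = self.x, self.y
        span = float(np.ptp(y))
        if span < 1e-12:
            return PowerLawThresholdResults(
                model=self, a=0.0, b=0.3, c=float(y.mean()),
                rss=float(((y - y.mean()) ** 2).sum()), converged=True,
            )
        p0 = (span, 0.3, float(y.min()))
        try:
            popt, _ = curve_fit(_power_law, x, y, p0=p0, maxfev=maxfev)
        except RuntimeError as exc:
            raise FitFailureError(
                f"power-law fit did not converge: {exc}",
                diagnostics={"p0": p0, "x": x.tolist(), "y": y.tolist()},
            ) from exc
        a, b, c = (float(v) for v in popt)
        rss = float(((y - _power_law(x, a, b, c)) ** 2).sum())
        return PowerLawThresholdResults(
            model=self, a=a, b=b, c=c, rss=rss, converged=True
        )


@dataclass
class PowerLawThresholdResults:
    """Fitted adaptive-threshold parameters with fit provenance."""

    model: PowerLawThreshold
    a: float
    b: float
    c: float
    rss: float
    converged: bool

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def fit_points(self) -> list[MinimaCurvePoint]:
        return self.model.points

    @property
    def seed(self) -> int | None:
        return self.model.seed

    def predict(self, n: int | Sequence[int] | np.ndarray) -> float | np.ndarray:
        """Threshold a*n^-b + c at screen size n (n >= 1)."""
        arr = np.asarray(n, dtype=float)
        if np.any(arr < 1):
            raise DomainError(f"screen size must be >= 1, got {n}")
        out = _power_law(arr, self.a, self.b, self.c)
        return float(out) if out.ndim == 0 else out

    def summary(self) -> str:
        lines = [
            "Adaptive MiniPAE threshold: power-law fit y = a*x^-b + c",
            "=" * 56,
            f"  points: {len(self.fit_points)}   iterations/point: "
            f"{self.fit_points[0].iterations}   seed: {self.seed}",
            f"  a = {self.a:10.4f}",
            f"  b = {self.b:10.4f}",
            f"  c = {self.c:10.4f}",
            f"  RSS = {self.rss:.6g}   converged: {self.converged}",
            "-" * 56,
            f"{'n':>8} {'avg_min':>10} {'sd':>8} {'fitted':>10}",
        ]
        for p in self.fit_points:
            lines.append(
                f"{p.n:>8d} {p.avg_min:>10.4f} {p.sd:>8.4f} "
                f"{self.predict(p.n):>10.4f}"
            )
        return "\n".join(lines)


#: Alias matching the field's naming for the fitted threshold object.
ThresholdModel = PowerLawThresholdResults


def fit_power_law(points: Sequence[MinimaCurvePoint]) -> PowerLawThresholdResults:
    """Fit y = a*x^-b + c to pre-computed minima-curve points."""
    return PowerLawThreshold(points).fit()


def predict_threshold(model: PowerLawThresholdResults, n: int) -> float:
    """Evaluate a fitted threshold model at screen size n."""
    return float(model.predict(n))
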