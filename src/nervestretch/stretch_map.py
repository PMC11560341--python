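"""Smooth per-specimen maps between stretch ratio and CAP reduction.

A cubic smoothing spline is fitted to (stretch, % reduction) points for
each nerve; inverting it gives the stretch needed to produce a given
reduction, and pooling those inversions across a cohort at 2.5%-reduction
increments yields Student-t 95% confidence intervals for the stretch at
each functional deficit level.

Smoothing convention: ``smoothing`` is the csaps-style parameter p in
[0, 1] trading off data fidelity (p -> 1) against curvature penalty
(p -> 0); p = 1 interpolates the data exactly. Internally p is mapped to
the roughness weight lam = (1 - p)/p of a penalised regression spline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline, PPoly, make_smoothing_spline
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CAPStretchCurve",
    "StretchReductionCurve",
    "CohortCI",
    "fit_reduction_spline",
    "stretch_at_reduction",
    "cohort_ci",
]


class StretchReductionCurve(RegressorMixin, BaseEstimator):
    """Cubic (smoothing) spline regression of % CAP reduction on stretch.

    Parameters
    ----------
    smoothing : float in [0, 1]
        csaps-style smoothing parameter; 1 -> interpolating spline.

    Attributes
    ----------
    spline_ : PPoly
        Fitted piecewise-cubic in stretch ratio.
    domain_ : (float, float)
        Stretch range covered by the data; no inversion outside it.
    knots_ : ndarray of shape (n, 2)
        The (stretch, reduction) pairs the curve was fitted to.
    """

    def __init__(self, smoothing: float = 1.0):
        self.smoothing = smoothing

    def fit(self, X, y):
        lam = np.asarray(X, dtype=float)
        if lam.ndim == 2 and lam.shape[1] == 1:
            lam = lam[:, 0]
        red = np.asarray(y, dtype=float)
        if lam.ndim != 1 or red.shape != lam.shape:
            raise ValueError("expect matching 1-D stretch and reduction vectors")
        if lam.size < 3:
            raise ValueError("need at least 3 points to fit a spline")
        if np.unique(lam).size != lam.size:
            raise ValueError("stretch values must be distinct")
        if not 0.0 <= self.smoothing <= 1.0:
            raise ValueError("smoothing must lie in [0, 1]")
        order = np.argsort(lam)
        lam, red = lam[order], red[order]
        if self.smoothing == 1.0:
            # natural interpolating cubic (the lam->0 limit of the penalty)
            bspl = CubicSpline(lam, red, bc_type="natural")
            self.spline_ = PPoly(bspl.c, bspl.x)
        else:
            rough = (1.0 - self.smoothing) / self.smoothing
            bspl = make_smoothing_spline(lam, red, lam=rough)
            self.spline_ = PPoly.from_spline(bspl)
        self.domain_ = (float(lam[0]), float(lam[-1]))
        self.knots_ = np.column_stack([lam, red])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        lam = np.asarray(X, dtype=float)
        if lam.ndim == 2 and lam.shape[1] == 1:
            lam = lam[:, 0]
        return self.spline_(lam)

    def inverse(self, target: float) -> float:
        """Smallest stretch in the fitted domain with curve == target."""
        lo, hi = self.domain_
        roots = self.spline_.solve(target, extrapolate=False)
        roots = roots[(roots >= lo - 1e-12) & (roots <= hi + 1e-12)]
        roots = np.real(roots[np.isreal(roots)])
        if roots.size == 0:
            raise ValueError(
                f"target reduction {target}% is outside the curve's range on "
                f"stretch domain [{lo}, {hi}]"
            )
        return float(np.clip(roots.min(), lo, hi))

    def to_curve(self, specimen_id: str = "") -> "CAPStretchCurve":
        return CAPStretchCurve(
            specimen_id=specimen_id,
            knots=self.knots_,
            smoothing=self.smoothing,
            spline=self.spline_,
            domain=self.domain_,
        )


@dataclass
class CAPStretchCurve:
    """Per-specimen smooth stretch -> % CAP reduction map."""

    specimen_id: str
    knots: np.ndarray          # (n, 2): stretch, reduction
    smoothing: float
    spline: PPoly
    domain: tuple[float, float]

    def __call__(self, lam):
        return self.spline(np.asarray(lam, dtype=float))

    def sample(self, step: float = 1e-3) -> np.ndarray:
        """Dense (stretch, reduction) table over the domain, for linear
        interpolation consumers (the FE mapping)."""
        lo, hi = self.domain
        n = max(int(round((hi - lo) / step)), 1)
        lam = np.linspace(lo, hi, n + 1)
        return np.column_stack([lam, self.spline(lam)])


@dataclass
class CohortCI:
    """Stretch confidence intervals on a grid of reduction levels."""

    reduction_grid: np.ndarray
    mean_stretch: np.ndarray   # NaN where < 2 curves contribute
    half_width: np.ndarray
    n_contributing: np.ndarray
    level: float


def fit_reduction_spline(points, smoothing: float = 1.0, specimen_id: str = "") -> CAPStretchCurve:
    """Fit one specimen's stretch -> reduction curve.

    ``points`` is a sequence of (stretch, reduction%) pairs; at least three
    distinct stretches are required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (stretch, reduction) pairs")
    est = StretchReductionCurve(smoothing=smoothing).fit(pts[:, 0], pts[:, 1])
    return est.to_curve(specimen_id)


def stretch_at_reduction(curve: CAPStretchCurve, target: float) -> float:
    """First (lowest-stretch) crossing of the curve with ``target`` %.

    Raises when the target lies outside the values the curve attains on its
    fitted domain; the curve is never extrapolated for inversion.
    """
    lo, hi = curve.domain
    roots = curve.spline.solve(target, extrapolate=False)
    roots = np.real(roots[np.isreal(roots)])
    roots = roots[(roots >= lo - 1e-12) & (roots <= hi + 1e-12)]
    if roots.size == 0:
        raise ValueError(
            f"target reduction {target}% outside curve range for specimen "
            f"{curve.specimen_id!r}"
        )
    return float(np.clip(roots.min(), lo, hi))


def cohort_ci(
    curves,
    grid_step: float = 2.5,
    max_reduction: float = 50.0,
    level: float = 0.95,
) -> CohortCI:
    """Student-t confidence intervals for stretch at each reduction level.

    At each grid value r the stretches ``stretch_at_reduction(curve_i, r)``
    are pooled over the curves whose range covers r; grid points with fewer
    than two contributors are reported as missing (NaN), never fabricated.
    """
    n_pts = int(round(max_reduction / grid_step)) + 1
    grid = np.linspace(0.0, max_reduction, n_pts)
    mean = np.full(n_pts, np.nan)
    hw = np.full(n_pts, np.nan)
    n_contrib = np.zeros(n_pts, dtype=int)
    for k, r in enumerate(grid):
        vals = []
        for c in curves:
            try:
                vals.append(stretch_at_reduction(c, r))
            except ValueError:
                continue
        n = len(vals)
        n_contrib[k] = n
        if n < 2:
            continue
        v = np.asarray(vals)
        mean[k] = v.mean()
        tcrit = stats.t.ppf((1.0 + level) / 2.0, n - 1)
        hw[k] = tcrit * v.std(ddof=1) / np.sqrt(n)
    return CohortCI(
        reduction_grid=grid,
        mean_stretch=mean,
        half_width=hw,
        n_contributing=n_contrib,
        level=level,
    )
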