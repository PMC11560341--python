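"""Uniaxial hyperelastic mechanics of peripheral nerve.

Cauchy stress is computed from peak force and reference geometry under the
incompressible uniaxial convention (current area ``A0/lam``), and the
stress–stretch response is fitted with the two-parameter polynomial
strain-energy model of Raghavan & Vorp,

    W = alpha * (I1 - 3) + beta * (I1 - 3)**2,

whose uniaxial incompressible Cauchy stress is

    T11(lam) = [2*alpha + 4*beta*(lam**2 + 2/lam - 3)] * (lam**2 - 1/lam).

``alpha`` and ``beta`` carry units of MPa; internally forces are N, lengths
mm and stresses MPa (N/mm^2 == MPa, so no numeric conversion is needed).

The model is linear in (alpha, beta), so the nonnegatively-constrained
least-squares fit has a unique global optimum; :class:`RaghavanVorpModel`
computes it with a bounded linear solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import lsq_linear
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "StretchTrial",
    "NerveSpecimen",
    "ConstitutiveFit",
    "cauchy_stress",
    "model_stress",
    "fit_constitutive",
    "extrapolate_curve",
    "circular_area",
    "RaghavanVorpModel",
]


def circular_area(d0_mm: float) -> float:
    """Reference cross-sectional area (mm^2) of a circular section."""
    return np.pi * (d0_mm / 2.0) ** 2


@dataclass
class StretchTrial:
    """One stretch increment: peak force and derived Cauchy stress.

    ``reduction`` is the percent CAP amplitude reduction measured at this
    stretch, or None when electrophysiology is unavailable.
    """

    lam: float
    force: float
    stress: float = 0.0
    reduction: float | None = None

    def __post_init__(self):
        if self.lam < 1.0:
            raise ValueError(f"stretch ratio must be >= 1, got {self.lam}")
        if self.force < 0.0:
            raise ValueError(f"force must be >= 0, got {self.force}")


@dataclass
class NerveSpecimen:
    """Metadata, geometry and ordered stretch trials for one nerve.

    ``d0`` is the mean of repeated diameter measurements along the nerve;
    the cross-section is assumed circular, so ``A0 = pi*(d0/2)**2``.
    """

    id: str
    sex: str
    side: str
    L0: float
    d0: float
    trials: list[StretchTrial] = field(default_factory=list)

    def __post_init__(self):
        if self.L0 <= 0 or self.d0 <= 0:
            raise ValueError("L0 and d0 must be positive")
        lams = [t.lam for t in self.trials]
        if lams:
            if any(b <= a for a, b in zip(lams, lams[1:])):
                raise ValueError("trials must be strictly increasing in lam")
            if abs(lams[0] - 1.0) > 1e-12:
                raise ValueError("first trial must be the unstretched state (lam=1)")

    @property
    def A0(self) -> float:
        return circular_area(self.d0)


@dataclass
class ConstitutiveFit:
    """Fitted material parameters (MPa) with goodness of fit."""

    alpha: float
    beta: float
    r2: float
    residuals: np.ndarray
    converged: bool = True
    lam_max_data: float = 1.0


def cauchy_stress(force, A0: float, lam) -> np.ndarray | float:
    """Axial Cauchy stress T11 = force * lam / A0 (N, mm^2 -> MPa).

    Incompressibility makes the current area ``A0/lam``, hence the factor
    of ``lam`` relative to the engineering stress.
    """
    if A0 <= 0:
        raise ValueError(f"A0 must be positive, got {A0}")
    force = np.asarray(force, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(force < 0):
        raise ValueError("force must be >= 0")
    if np.any(lam < 1):
        raise ValueError("stretch ratio must be >= 1")
    out = force * lam / A0
    return float(out) if out.ndim == 0 else out


def model_stress(alpha: float, beta: float, lam) -> np.ndarray | float:
    """Raghavan–Vorp uniaxial incompressible Cauchy stress (MPa).

    T11 = [2*alpha + 4*beta*(lam^2 + 2/lam - 3)] * (lam^2 - 1/lam);
    identically zero at the reference state lam=1.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch ratio must be positive")
    i1m3 = lam**2 + 2.0 / lam - 3.0
    out = (2.0 * alpha + 4.0 * beta * i1m3) * (lam**2 - 1.0 / lam)
    return float(out) if out.ndim == 0 else out


def _design_matrix(lam: np.ndarray) -> np.ndarray:
    # T11 = 2*(lam^2 - 1/lam) * alpha + 4*(I1-3)*(lam^2 - 1/lam) * beta
    x = lam**2 - 1.0 / lam
    i1m3 = lam**2 + 2.0 / lam - 3.0
    return np.column_stack([2.0 * x, 4.0 * i1m3 * x])


class RaghavanVorpModel(RegressorMixin, BaseEstimator):
    """Nonnegative least-squares regressor for the two-parameter model.

    Parameters
    ----------
    weight_by_stretch : bool, default False
        If True, residuals are weighted by the stretch ratio.

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted material parameters (MPa), constrained >= 0.
    r2_ : float
        Coefficient of determination on the fitted Cauchy stresses.
    residuals_ : ndarray
        Per-point misfit ``observed - model`` (MPa).
    lam_max_data_ : float
        Largest stretch seen during fitting; larger evaluations are
        extrapolations.
    """

    def __init__(self, weight_by_stretch: bool = False):
        self.weight_by_stretch = weight_by_stretch

    @staticmethod
    def _validate_lam(X) -> np.ndarray:
        lam = np.asarray(X, dtype=float)
        if lam.ndim == 2 and lam.shape[1] == 1:
            lam = lam[:, 0]
        if lam.ndim != 1:
            raise ValueError("stretch input must be 1-D or a single column")
        if np.any(~np.isfinite(lam)) or np.any(lam <= 0):
            raise ValueError("stretch ratios must be finite and positive")
        return lam

    def fit(self, X, y):
        """Fit (alpha, beta) to Cauchy stress ``y`` (MPa) at stretches ``X``."""
        lam = self._validate_lam(X)
        stress = np.asarray(y, dtype=float)
        if stress.shape != lam.shape:
            raise ValueError("X and y must have matching lengths")
        if lam.size < 3:
            raise ValueError("need at least 3 stretch levels to fit two parameters")
        if np.unique(lam).size != lam.size:
            raise ValueError("stretch levels must be distinct")

        A = _design_matrix(lam)
        b = stress.copy()
        if self.weight_by_stretch:
            A = A * lam[:, None]
            b = b * lam
        res = lsq_linear(A, b, bounds=(0.0, np.inf), tol=1e-14)
        self.alpha_, self.beta_ = map(float, res.x)
        self.residuals_ = stress - model_stress(self.alpha_, self.beta_, lam)
        sstot = float(np.sum((stress - stress.mean()) ** 2))
        ssres = float(np.sum(self.residuals_**2))
        # all-zero (or constant) data: a zero-parameter model is an exact fit
        self.r2_ = 1.0 if sstot == 0.0 and ssres <= 1e-24 else 1.0 - ssres / sstot if sstot > 0 else 0.0
        self.converged_ = bool(res.success)
        self.lam_max_data_ = float(lam.max())
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        lam = self._validate_lam(X)
        return model_stress(self.alpha_, self.beta_, lam)

    def to_fit(self) -> ConstitutiveFit:
        return ConstitutiveFit(
            alpha=self.alpha_,
            beta=self.beta_,
            r2=self.r2_,
            residuals=self.residuals_,
            converged=self.converged_,
            lam_max_data=self.lam_max_data_,
        )


def fit_constitutive(trials: Sequence[StretchTrial]) -> ConstitutiveFit:
    """Fit (alpha, beta) to the Cauchy stresses of ordered stretch trials.

    Requires at least three distinct stretch levels including the reference
    state. Stresses must already be populated (see :func:`cauchy_stress`).
    """
    if len(trials) < 3:
        raise ValueError("need at least 3 trials to fit the constitutive model")
    lam = np.array([t.lam for t in trials])
    stress = np.array([t.stress for t in trials])
    if not np.any(np.isclose(lam, 1.0)):
        raise ValueError("trials must include the unstretched reference state")
    model = RaghavanVorpModel().fit(lam, stress)
    return model.to_fit()


def extrapolate_curve(
    fit: ConstitutiveFit, lam_max: float, step: float = 1e-3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the fitted model densely on [1, lam_max].

    Returns ``(lam_grid, stress, extrapolated)`` where ``extrapolated`` marks
    grid points beyond the stretch range covered by the fitted data.
    """
    if lam_max < 1.0:
        raise ValueError("lam_max must be >= 1")
    n = int(round((lam_max - 1.0) / step))
    lam_grid = np.linspace(1.0, lam_max, n + 1)
    stress = np.asarray(model_stress(fit.alpha, fit.beta, lam_grid))
    extrapolated = lam_grid > fit.lam_max_data + 1e-12
    return lam_grid, np.atleast_1d(stress), extrapolated
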