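"""Collagen fiber-angle distribution analysis.

Angles extracted from second-harmonic-generation sections are normalised
to zero mean per section, pooled per nerve, binned into 1-degree
histograms, and summarised by the full width at half maximum (FWHM) of
the binned distribution. Group comparisons (stretched vs control) use
Tukey-fence outlier exclusion, an F-test on variances, and a pooled- or
Welch-variance t-test depending on the F-test outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FiberAngleSet",
    "AngleHistogram",
    "normalize_angles",
    "bin_histogram",
    "fwhm",
    "iqr_outliers",
    "compare_groups",
]


@dataclass
class FiberAngleSet:
    """Zero-mean pooled fiber angles for one specimen."""

    specimen_id: str
    group: str
    angles: np.ndarray       # degrees, mean 0
    sections: np.ndarray     # section label per angle

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and abs(self.angles.mean()) > 1e-9:
            raise ValueError("angles must be normalized to zero mean")


@dataclass
class AngleHistogram:
    """1-degree-bin histogram in percent of fibers."""

    bin_edges: np.ndarray
    pct: np.ndarray

    def __post_init__(self):
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, 1.0, atol=1e-9):
            raise ValueError("bin width must be exactly 1 degree")
        if abs(self.pct.sum() - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def normalize_angles(
    angles, sections=None, specimen_id: str = "", group: str = "control"
) -> FiberAngleSet:
    """Zero the arithmetic mean angle of each section, then pool.

    Angles are assumed already within +/-90 deg of the nerve axis, so no
    circular wrapping is applied; the mean direction along the nerve is
    taken as the zero reference.
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle list")
    sec = (
        np.zeros(a.size, dtype=int)
        if sections is None
        else np.asarray(sections)
    )
    if sec.shape != a.shape:
        raise ValueError("sections must label every angle")
    out = a.copy()
    for s in np.unique(sec):
        m = sec == s
        if not m.any():
            raise ValueError(f"empty section {s!r}")
        out[m] -= out[m].mean()
    # pooling reintroduces a tiny nonzero mean only at float precision
    out -= out.mean()
    return FiberAngleSet(specimen_id=specimen_id, group=group, angles=out, sections=sec)


def bin_histogram(fiber_set: FiberAngleSet | np.ndarray) -> AngleHistogram:
    """1-degree half-open bins [edge, edge+1) covering the angle range.

    Accepts a normalized :class:`FiberAngleSet` or a raw angle array. An
    angle exactly on an interior edge counts toward the upper bin; the
    final bin's upper edge is closed.
    """
    a = fiber_set.angles if isinstance(fiber_set, FiberAngleSet) else np.asarray(
        fiber_set, dtype=float
    )
    if a.size < 10:
        raise ValueError("need at least 10 angles to histogram")
    lo = np.floor(a.min())
    hi = np.ceil(a.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.arange(lo, hi + 0.5, 1.0)
    counts, _ = np.histogram(a, bins=edges)
    return AngleHistogram(bin_edges=edges, pct=100.0 * counts / a.size)


def fwhm(hist: AngleHistogram) -> float:
    """Full width at half maximum of the binned distribution (degrees).

    The half-max level is half the peak bin percentage; left and right
    crossings are located by linear interpolation between adjacent bin
    centers. Peak ties are broken toward the distribution's centroid.
    Raises when the distribution never falls below half max on one side.
    """
    pct, centers = hist.pct, hist.centers
    peak_val = pct.max()
    if peak_val <= 0:
        raise ValueError("empty histogram")
    half = peak_val / 2.0
    ties = np.flatnonzero(pct == peak_val)
    centroid = float(np.sum(pct * centers) / pct.sum())
    i_peak = int(ties[np.argmin(np.abs(centers[ties] - centroid))])

    def crossing(direction: int) -> float:
        i = i_peak
        while 0 <= i + direction < pct.size and pct[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= pct.size:
            side = "left" if direction < 0 else "right"
            raise ValueError(
                f"distribution never falls below half maximum on the {side} side"
            )
        # interpolate between (inside, >= half) and (outside, < half)
        x_in, y_in = centers[i], pct[i]
        x_out, y_out = centers[j], pct[j]
        return float(x_in + (half - y_in) / (y_out - y_in) * (x_out - x_in))

    return crossing(+1) - crossing(-1)


def iqr_outliers(values) -> np.ndarray:
    """Tukey-fence inclusion mask: keep Q1-1.5*IQR <= x <= Q3+1.5*IQR.

    Quartiles use linear interpolation of order statistics (numpy's
    default quantile convention).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for quartile fences")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    return (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)


def compare_groups(fwhm_a, fwhm_b, f_alpha: float = 0.05) -> dict:
    """F-test on variances, then pooled or Welch t-test on FWHM values.

    Returns a dict with F statistic and p, t statistic and p, and the
    t-test ``variant`` used ('pooled' when the F-test does not reject equal
    variances at ``f_alpha``, else 'welch').
    """
    a = np.asarray(fwhm_a, dtype=float)
    b = np.asarray(fwhm_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups: F-test undefined")
    if vb == 0 or va == 0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = va / vb
        cdf = stats.f.cdf(f_stat, a.size - 1, b.size - 1)
        f_p = 2.0 * min(cdf, 1.0 - cdf)
    variant = "pooled" if f_p >= f_alpha else "welch"
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return {
        "F_stat": float(f_stat),
        "F_p": float(f_p),
        "t_stat": float(t_stat),
        "t_p": float(t_p),
        "variant": variant,
    }
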