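"""Topography comparison statistics.

Two potential topographies sampled at the same m points are compared with
the relative difference measure

    RDM* = sqrt( sum_k ( v_RM_k / ||v_RM|| - v_TM_k / ||v_TM|| )^2 )

which isolates differences in spatial shape (0 = identical shape, 2 =
sign-flipped), and the magnification factor

    MAG = ||v_TM|| / ||v_RM||

which isolates differences in magnitude (1 = equal RMS magnitude).  ||.||
is the Euclidean norm, RM the reference model and TM the test model.

Distribution-level differences are summarized with histograms, empirical
CDFs and the two-sample Kolmogorov-Smirnov test (asymptotic p-value with
effective sample size n_x*n_y/(n_x+n_y)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "ComparisonResult",
    "DistributionSummary",
    "rdm_star",
    "mag",
    "percent_peak_reduction",
    "distribution_summary",
    "ks_two_sample",
    "compare_topographies",
]


def _as_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name} is empty")
    return arr


def rdm_star(v_rm, v_tm) -> float:
    """Relative difference measure between two equal-length topographies.

    Symmetric in its arguments and invariant to positive rescaling of
    either; ranges over [0, 2].

    Raises
    ------
    ValidationError
        On length mismatch or a zero-norm input (normalization undefined).
    """
    a = _as_vector(v_rm, "reference topography")
    b = _as_vector(v_tm, "test topography")
    if a.size != b.size:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("zero-norm topography: RDM* undefined")
    return float(np.linalg.norm(a / na - b / nb))


def mag(v_rm, v_tm) -> float:
    """Magnification factor: Euclidean norm of test over reference.

    Raises
    ------
    ValidationError
        On length mismatch or zero-norm reference.
    """
    a = _as_vector(v_rm, "reference topography")
    b = _as_vector(v_tm, "test topography")
    if a.size != b.size:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    na = np.linalg.norm(a)
    if na == 0:
        raise ValidationError("zero-norm reference: MAG undefined")
    return float(np.linalg.norm(b) / na)


def percent_peak_reduction(peak_without_layer: float, peak_with_layer: float) -> float:
    """Percent reduction of a peak potential caused by adding a layer.

    ``100 * (1 - peak_with_layer / peak_without_layer)``; e.g. a 12.5 uV
    peak dropping to 7.5 uV is a 40% reduction.
    """
    if peak_without_layer == 0:
        raise ValidationError("zero reference peak: reduction undefined")
    return 100.0 * (1.0 - peak_with_layer / peak_without_layer)


@dataclass
class DistributionSummary:
    """Histogram + empirical CDF summary of a sample.

    The standard deviation is the population value (whole surfaces are
    enumerated, not sampled).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    sorted_values: np.ndarray
    cumulative_fractions: np.ndarray
    mean: float
    std: float
    n: int

    def cdf(self, x: float) -> float:
        """Empirical CDF F(x) = fraction of values <= x."""
        return float(np.searchsorted(self.sorted_values, x, side="right")) / self.n

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
            "mean": self.mean,
            "std": self.std,
            "n": self.n,
        }


def distribution_summary(values, n_bins: int = 50) -> DistributionSummary:
    """Summarize a sample with an equal-width histogram and empirical CDF."""
    v = _as_vector(values, "sample")
    counts, edges = np.histogram(v, bins=n_bins)
    sv = np.sort(v)
    return DistributionSummary(
        bin_edges=edges,
        counts=counts,
        sorted_values=sv,
        cumulative_fractions=np.arange(1, v.size + 1) / v.size,
        mean=float(v.mean()),
        std=float(v.std()),  # population std
        n=v.size,
    )


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns (D, p) where D = sup |F_x - F_y| over the pooled values and p
    is the asymptotic approximation with effective sample size
    n_x*n_y/(n_x+n_y).
    """
    a = _as_vector(x, "first sample")
    b = _as_vector(y, "second sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonResult:
    """Shape, magnitude and distribution comparison of two topographies."""

    rdm_star: float
    mag: float
    ks_statistic: float
    ks_p: float
    n_points: int
    mean_rm: float
    std_rm: float
    mean_tm: float
    std_tm: float
    summary_rm: DistributionSummary | None = field(default=None, repr=False)
    summary_tm: DistributionSummary | None = field(default=None, repr=False)

    @property
    def ks_rejects_equality(self) -> bool:
        """K-S decision at alpha = 0.05."""
        return self.ks_p < 0.05

    def to_dict(self) -> dict:
        return {
            "rdm_star": self.rdm_star,
            "mag": self.mag,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "n_points": self.n_points,
            "mean_rm": self.mean_rm,
            "std_rm": self.std_rm,
            "mean_tm": self.mean_tm,
            "std_tm": self.std_tm,
        }


def compare_topographies(v_rm, v_tm, n_bins: int = 50) -> ComparisonResult:
    """Full comparison of a test topography against a reference one."""
    a = _as_vector(v_rm, "reference topography")
    b = _as_vector(v_tm, "test topography")
    if a.size != b.size:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    d, p = ks_two_sample(a, b)
    return ComparisonResult(
        rdm_star=rdm_star(a, b),
        mag=mag(a, b),
        ks_statistic=d,
        ks_p=p,
        n_points=a.size,
        mean_rm=float(a.mean()),
        std_rm=float(a.std()),
        mean_tm=float(b.mean()),
        std_tm=float(b.std()),
        summary_rm=distribution_summary(a, n_bins),
        summary_tm=distribution_summary(b, n_bins),
    )
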