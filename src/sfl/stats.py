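"""Group statistics on spectral fluorescence lifetime curves.

Compares SFL curves between tissue groups three ways: channel-wise
two-sample t-tests (magnitude, pooled groups), a paired t-test across
channels (magnitude, per-sample means), and Procrustes shape disparity
(shape, independent of absolute lifetime).  Also provides the
sample-size/power computation for a two-sample lifetime comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import procrustes as _scipy_procrustes

__all__ = [
    "SFLCurve",
    "DisparityResult",
    "procrustes_disparity",
    "pairwise_disparity_matrix",
    "channelwise_ttest",
    "paired_channel_ttest",
    "required_sample_size",
]


@dataclass
class SFLCurve:
    """A spectral fluorescence lifetime curve: lifetime vs wavelength."""

    wavelengths_nm: np.ndarray
    sfl_ns: np.ndarray
    label: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.sfl_ns = np.asarray(self.sfl_ns, dtype=float)
        if self.wavelengths_nm.shape != self.sfl_ns.shape:
            raise ValueError("wavelengths and lifetimes must align")
        if self.wavelengths_nm.size < 4:
            raise ValueError("curve needs at least 4 channels")
        if not np.all(np.isfinite(self.sfl_ns)):
            raise ValueError("curve contains non-finite lifetimes")

    @property
    def n_channels(self) -> int:
        return self.wavelengths_nm.size


@dataclass
class DisparityResult:
    """Pairwise Procrustes disparities and per-group medians."""

    labels: list[str]
    groups: list[str]
    matrix: np.ndarray
    group_medians: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _embed(curve: SFLCurve) -> np.ndarray:
    """Embed a 1-D curve as P points (channel coordinate, z-scored lifetime).

    The channel axis is mapped to [0, 1] so the comparison does not depend on
    physical wavelength units, and the lifetime coordinate is z-scored so any
    affine change of the lifetime values (a uniform scale plus an offset)
    leaves the embedded shape unchanged — the disparity measures shape only,
    never magnitude.
    """
    p = curve.n_channels
    x = np.arange(p, dtype=float) / (p - 1)
    y = curve.sfl_ns
    spread = y.std()
    if spread == 0:
        raise ValueError(
            "degenerate (constant) curve: no shape after standardization"
        )
    return np.column_stack([x, (y - y.mean()) / spread])


def procrustes_disparity(a: SFLCurve, b: SFLCurve) -> float:
    """Shape dissimilarity of two SFL curves, independent of magnitude.

    Each curve becomes a point set (standardized channel coordinate,
    lifetime); both sets are translated to zero centroid, scaled to unit
    Frobenius norm, and optimally rotated onto each other.  The disparity is
    the remaining sum of squared pointwise differences: zero for curves that
    coincide up to translation, uniform scaling and rotation, symmetric in
    its arguments.
    """
    if a.n_channels != b.n_channels:
        raise ValueError("curves must have equal length")
    if not np.allclose(a.wavelengths_nm, b.wavelengths_nm):
        raise ValueError("curves must share the wavelength grid")
    try:
        _, _, disparity = _scipy_procrustes(_embed(a), _embed(b))
    except ValueError as err:
        raise ValueError(f"degenerate curve in Procrustes comparison: {err}")
    return float(disparity)


def pairwise_disparity_matrix(curves: list[SFLCurve]) -> DisparityResult:
    """All-pairs Procrustes disparity with per-group median summaries.

    The matrix is symmetric with a zero diagonal.  Each group's median is
    taken over its unordered within-group pairs, quantifying shape
    variability inside that group.
    """
    n = len(curves)
    if n < 2:
        raise ValueError("need at least 2 curves")
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = procrustes_disparity(curves[i], curves[j])
        mat[i, j] = mat[j, i] = d
    groups = [c.group for c in curves]
    medians: dict[str, float] = {}
    for g in dict.fromkeys(groups):  # preserve first-seen order
        idx = [i for i, gi in enumerate(groups) if gi == g]
        pairs = [mat[i, j] for i, j in itertools.combinations(idx, 2)]
        if pairs:
            medians[g] = float(np.median(pairs))
    return DisparityResult(
        labels=[c.label for c in curves],
        groups=groups,
        matrix=mat,
        group_medians=medians,
    )


def channelwise_ttest(
    group_a: list[SFLCurve],
    group_b: list[SFLCurve],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sided two-sample t-test at every spectral channel.

    Pools the curves of each group and tests the lifetime difference channel
    by channel.  Raw p-values are returned without multiplicity correction;
    channels with zero variance in both groups get NaN p-values rather than
    a fabricated significance.  Set ``equal_var=False`` for Welch's test.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 curves per group")
    w = group_a[0].wavelengths_nm
    for c in group_a + group_b:
        if not np.allclose(c.wavelengths_nm, w):
            raise ValueError("all curves must share the wavelength grid")
    a = np.array([c.sfl_ns for c in group_a])
    b = np.array([c.sfl_ns for c in group_b])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, pval = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    return pd.DataFrame(
        {
            "wavelength_nm": w,
            "t_statistic": tstat,
            "p_value": pval,
            "mean_a": a.mean(axis=0),
            "mean_b": b.mean(axis=0),
        }
    )


def paired_channel_ttest(mean_a: SFLCurve, mean_b: SFLCurve) -> dict:
    """Paired two-sided t-test over the channel-wise lifetime differences.

    Treats the channels of the two mean curves as paired observations.  When
    every difference is identical (zero spread) the statistic is degenerate
    and reported as such instead of a p-value.
    """
    if mean_a.n_channels != mean_b.n_channels:
        raise ValueError("curves must have equal length")
    if not np.allclose(mean_a.wavelengths_nm, mean_b.wavelengths_nm):
        raise ValueError("curves must share the wavelength grid")
    diff = mean_a.sfl_ns - mean_b.sfl_ns
    if np.isclose(diff.std(ddof=1), 0.0):
        # constant difference: no spread to test against.  Zero difference
        # means no effect (p = 1); a non-zero constant shift is arbitrarily
        # significant (p = 0).  Both are flagged as degenerate.
        zero = bool(np.allclose(diff, 0.0))
        return {
            "t_statistic": 0.0 if zero else np.inf,
            "p_value": 1.0 if zero else 0.0,
            "mean_difference_ns": float(diff.mean()),
            "degenerate": True,
        }
    tstat, pval = sps.ttest_rel(mean_a.sfl_ns, mean_b.sfl_ns)
    return {
        "t_statistic": float(tstat),
        "p_value": float(pval),
        "mean_difference_ns": float(diff.mean()),
        "degenerate": False,
    }


def _two_sample_t_power(
    n_per_group: int, delta: float, sd: float, alpha: float
) -> float:
    """Exact power of the equal-variance two-sample t-test (noncentral t)."""
    df = 2 * n_per_group - 2
    ncp = delta / (sd * np.sqrt(2.0 / n_per_group))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    # two-sided rejection region; the lower tail is negligible for ncp > 0
    return float(
        sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    )


def required_sample_size(
    delta_ns: float,
    sd_ns: float,
    alpha: float = 0.05,
    power: float = 0.8,
    method: str = "noncentral_t",
    n_max: int = 1_000_000,
) -> int:
    """Smallest per-group n detecting a lifetime difference at given power.

    Uses the exact noncentral-t power function of the two-sided,
    equal-variance two-sample t-test and searches over integers; a
    normal-approximation mode is available (it can differ by one sample near
    power boundaries).
    """
    if delta_ns <= 0:
        raise ValueError("delta must be positive (zero effect is undetectable)")
    if sd_ns <= 0:
        raise ValueError("sd must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if method == "normal_approx":
        za = sps.norm.ppf(1.0 - alpha / 2.0)
        zb = sps.norm.ppf(power)
        n = 2.0 * ((za + zb) * sd_ns / delta_ns) ** 2
        return max(2, int(np.ceil(n)))
    if method != "noncentral_t":
        raise ValueError(f"unknown method {method!r}")
    # bracket with the normal approximation, then walk to the exact answer
    guess = required_sample_size(delta_ns, sd_ns, alpha, power,
                                 method="normal_approx")
    n = max(2, guess - 5)
    while n <= n_max and _two_sample_t_power(n, delta_ns, sd_ns, alpha) < power:
        n += 1
    if n > n_max:
        raise ValueError("required sample size exceeds n_max")
    while n > 2 and _two_sample_t_power(n - 1, delta_ns, sd_ns, alpha) >= power:
        n -= 1
    return n
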