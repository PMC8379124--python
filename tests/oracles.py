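"""Independent brute-force oracles used to check the package's algorithms.

Nothing here imports the implementation paths it validates.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def blurred_disk_fwhm_area(
    radius_mm: float, psf_sigma_mm: float, fine_step_mm: float
) -> float:
    """Area enclosed at half maximum of an analytic Gaussian-blurred disk.

    The blurred unit disk evaluated at distance r from the centre equals
    the probability that an isotropic 2-D Gaussian centred at r lands
    inside the disk, i.e. the Rice CDF at the disk radius.  The profile is
    evaluated on a fine 2-D grid and thresholded at half its maximum; the
    area is the count of grid cells above threshold.
    """
    extent = radius_mm + 4.0 * psf_sigma_mm
    g = np.arange(-extent, extent + fine_step_mm, fine_step_mm)
    rr = np.hypot(g[:, None], g[None, :])
    prof_r = np.linspace(0.0, rr.max() + fine_step_mm, 4000)
    prof = sps.rice.cdf(
        radius_mm, b=np.maximum(prof_r, 1e-12) / psf_sigma_mm, scale=psf_sigma_mm
    )
    vals = np.interp(rr, prof_r, prof)
    half = 0.5 * vals.max()
    return float(np.count_nonzero(vals >= half)) * fine_step_mm**2


def accuracy_precision_bruteforce(
    measured: np.ndarray, true: np.ndarray
) -> tuple[float, float, float]:
    """Direct recomputation of the segmentation quality definitions.

    accuracy = |mean(measured - true)|;
    precision = mean over distinct true areas of the sample SD of the
    measured areas sharing that true area (>= 2 repeats);
    dispersion = sample SD of the per-hole differences.
    """
    measured = np.asarray(measured, float)
    true = np.asarray(true, float)
    diffs = measured - true
    accuracy = abs(float(np.mean(diffs)))
    dispersion = float(np.std(diffs, ddof=1))
    sds = []
    for t in np.unique(true):
        group = measured[true == t]
        if group.size >= 2:
            sds.append(np.std(group, ddof=1))
    precision = float(np.mean(sds)) if sds else float(np.std(measured, ddof=1))
    return accuracy, precision, dispersion


def wald_diff_ci_bruteforce(
    x_a: int, n_a: int, x_b: int, n_b: int, conf: float
) -> tuple[float, float]:
    """Literal evaluation of the unadjusted Wald difference interval."""
    p_a, p_b = x_a / n_a, x_b / n_b
    se = np.sqrt(p_a * (1 - p_a) / n_a + p_b * (1 - p_b) / n_b)
    z = sps.norm.ppf((1 + conf) / 2)
    return (p_a - p_b) - z * se, (p_a - p_b) + z * se


def pearson_chi2_bruteforce(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared for a 2x2 table via the closed N(ad-bc)^2 form."""
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return stat, float(sps.chi2.sf(stat, df=1))


def holm_bruteforce(p_values) -> list[float]:
    """Hand-stepped Holm adjustment: sort, multiply by decreasing factor,
    enforce monotonicity, cap at 1."""
    p = list(map(float, p_values))
    order = sorted(range(len(p)), key=lambda i: p[i])
    m = len(p)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * p[idx])
        running = max(running, value)
        adjusted[idx] = running
    return adjusted
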