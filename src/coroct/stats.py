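"""Clinical statistics: noninferiority design and inference, group
comparisons with multiplicity control, and inter-rater agreement.

Conventions are fixed by numeric reproduction of the study's printed
results: the difference CI is an unadjusted Wald interval (no continuity
correction), the 2x2 test is Pearson's chi-squared without Yates
correction, and the sample-size formula is the equal-rate normal
approximation for two proportions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import ROISample, cnr

__all__ = [
    "NoninferiorityResult",
    "SampleSizeResult",
    "KappaResult",
    "diff_ci_wald",
    "sample_size_noninferiority",
    "chisq_2x2",
    "weighted_kappa",
    "kappa_from_table",
    "kappa_band",
    "holm_adjust",
    "kruskal_holm",
    "proportion_pct",
    "analyze_cohort",
    "CohortReport",
]


# -- noninferiority -------------------------------------------------------


@dataclass(frozen=True)
class NoninferiorityResult:
    rate_a: float
    rate_b: float
    diff: float
    ci_low: float
    ci_high: float
    margin: float
    noninferior: bool
    conf: float = 0.95
    degenerate: bool = False  # a rate hit 0 or 1; Wald CI collapses


def diff_ci_wald(
    x_a: int, n_a: int, x_b: int, n_b: int, conf: float = 0.95, margin: float = 0.10
) -> NoninferiorityResult:
    """Wald CI for the difference of two independent proportions.

    Noninferiority is declared when the two-sided CI lies entirely within
    (-margin, margin).
    """
    for x, n in [(x_a, n_a), (x_b, n_b)]:
        if n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    p_a, p_b = x_a / n_a, x_b / n_b
    diff = p_a - p_b
    se = math.sqrt(p_a * (1 - p_a) / n_a + p_b * (1 - p_b) / n_b)
    z = sps.norm.ppf(0.5 + conf / 2.0)
    lo, hi = diff - z * se, diff + z * se
    degenerate = p_a in (0.0, 1.0) or p_b in (0.0, 1.0)
    if degenerate:
        warnings.warn(
            "a proportion is 0 or 1: the Wald interval is degenerate",
            stacklevel=2,
        )
    return NoninferiorityResult(
        rate_a=p_a,
        rate_b=p_b,
        diff=diff,
        ci_low=lo,
        ci_high=hi,
        margin=margin,
        noninferior=bool(lo > -margin and hi < margin),
        conf=conf,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class SampleSizeResult:
    n_per_group: int
    total: int
    expected_rate: float
    margin: float
    alpha_one_sided: float
    power: float


def sample_size_noninferiority(
    expected_rate: float,
    margin: float = 0.10,
    alpha_one_sided: float = 0.05,
    power: float = 0.80,
    rounding: str = "nearest",
) -> SampleSizeResult:
    """Per-group n for noninferiority of two proportions (equal-rate normal
    approximation):

        n = (z_{1-alpha} + z_{power})^2 * 2 p (1 - p) / margin^2

    ``rounding='nearest'`` reproduces the published practice of reporting
    the rounded normal-approximation value; ``'ceil'`` always rounds up.
    """
    for v, name in [
        (expected_rate, "expected_rate"),
        (alpha_one_sided, "alpha_one_sided"),
        (power, "power"),
    ]:
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    if margin <= 0:
        raise ValueError("margin must be positive")
    z_a = sps.norm.ppf(1.0 - alpha_one_sided)
    z_b = sps.norm.ppf(power)
    p = expected_rate
    n_exact = (z_a + z_b) ** 2 * 2.0 * p * (1.0 - p) / margin**2
    if rounding == "nearest":
        n = int(math.floor(n_exact + 0.5))
    elif rounding == "ceil":
        n = int(math.ceil(n_exact))
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    n = max(n, 1)
    return SampleSizeResult(
        n_per_group=n,
        total=2 * n,
        expected_rate=expected_rate,
        margin=margin,
        alpha_one_sided=alpha_one_sided,
        power=power,
    )


# -- contingency ----------------------------------------------------------


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) on [[a,b],[c,d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-squared undefined with a zero margin")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def proportion_pct(x: int, n: int, decimals: int = 1) -> float:
    """Percentage 100*x/n rounded half-up to ``decimals``."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * x / n
    scale = 10.0**decimals
    return math.floor(pct * scale + 0.5) / scale


# -- agreement ------------------------------------------------------------

#: interpretation bands for kappa
_KAPPA_BANDS = [
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "excellent"),
]


def kappa_band(kappa: float) -> str:
    """Map a kappa value to its interpretation band."""
    for upper, name in _KAPPA_BANDS[:-1]:
        if kappa <= upper + 1e-12:
            return name
    return "excellent"


def _weight_matrix(k: int, weights: str) -> np.ndarray:
    idx = np.arange(k)
    dist = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    if weights == "linear":
        return 1.0 - dist
    if weights == "quadratic":
        return 1.0 - dist**2
    raise ValueError(f"unknown weights {weights!r}")


def kappa_from_table(table: np.ndarray, weights: str = "linear") -> float:
    """Weighted kappa from a square joint count/probability table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1] or table.shape[0] < 2:
        raise ValueError("table must be square, at least 2x2")
    total = table.sum()
    if total <= 0:
        raise ValueError("empty table")
    p = table / total
    w = _weight_matrix(table.shape[0], weights)
    po = float((w * p).sum())
    marg_r, marg_c = p.sum(axis=1), p.sum(axis=0)
    pe = float((w * np.outer(marg_r, marg_c)).sum())
    if abs(1.0 - pe) < 1e-12:
        raise ValueError(
            "expected agreement is 1 (constant ratings): kappa undefined"
        )
    return (po - pe) / (1.0 - pe)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    weights: str
    band: str
    n_pairs: int


def weighted_kappa(
    ratings_r1: Sequence[int],
    ratings_r2: Sequence[int],
    weights: str = "linear",
    categories: Sequence[int] | None = None,
) -> KappaResult:
    """Weighted kappa between two raters' paired ordinal scores.

    ``categories`` fixes the ordinal scale (defaults to the union of
    observed scores, ascending); unused categories still shape the
    disagreement weights.
    """
    r1 = np.asarray(ratings_r1)
    r2 = np.asarray(ratings_r2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D sequences")
    if r1.size < 2:
        raise ValueError("need at least two rating pairs")
    if categories is None:
        categories = sorted(set(r1.tolist()) | set(r2.tolist()))
    cats = list(categories)
    if len(cats) < 2:
        raise ValueError("constant ratings in both raters: kappa undefined")
    pos = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(r1.tolist(), r2.tolist()):
        if a not in pos or b not in pos:
            raise ValueError(f"score {a if a not in pos else b} outside categories")
        table[pos[a], pos[b]] += 1
    k = kappa_from_table(table, weights=weights)
    return KappaResult(kappa=k, weights=weights, band=kappa_band(k), n_pairs=r1.size)


# -- rank tests with multiplicity control ---------------------------------


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    _, adj, _, _ = multipletests(p, method="holm")
    return [float(v) for v in adj]


def kruskal_holm(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis across ``groups`` plus Holm-adjusted pairwise
    rank-sum post hoc tests.

    Returns ``(H, p_raw, pairwise)`` where ``pairwise`` has columns
    group1, group2, p_raw, p_holm.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if any(s.size < 1 for s in samples):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups", stacklevel=2)
        pairs = [
            (names[i], names[j], 1.0)
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        df = pd.DataFrame(pairs, columns=["group1", "group2", "p_raw"])
        df["p_holm"] = 1.0
        return 0.0, 1.0, df
    h_stat, p_raw = sps.kruskal(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            _, p_ij = sps.mannwhitneyu(
                samples[i], samples[j], alternative="two-sided"
            )
            rows.append((names[i], names[j], float(p_ij)))
    df = pd.DataFrame(rows, columns=["group1", "group2", "p_raw"])
    df["p_holm"] = holm_adjust(df["p_raw"].tolist())
    return float(h_stat), float(p_raw), df


# -- full cohort analysis -------------------------------------------------


@dataclass
class CohortReport:
    rates: pd.DataFrame
    noninferiority: NoninferiorityResult
    segment_scores: pd.DataFrame
    attenuation_tests: pd.DataFrame
    cnr_summary: pd.DataFrame
    kappa: dict[str, KappaResult] = field(default_factory=dict)

    def summary_json(self) -> dict:
        ni = self.noninferiority
        return {
            "rate_a": ni.rate_a,
            "rate_b": ni.rate_b,
            "diff": ni.diff,
            "ci_low": ni.ci_low,
            "ci_high": ni.ci_high,
            "margin": ni.margin,
            "noninferior": ni.noninferior,
            "kappa": {g: k.kappa for g, k in self.kappa.items()},
        }


def analyze_cohort(cohort, margin: float = 0.10) -> CohortReport:
    """End-to-end analysis of a simulated cohort table.

    Computes per-group diagnostic rates and the noninferiority decision,
    per-segment score comparisons (rank-sum, Holm-adjusted), the
    attenuation-by-energy Kruskal-Wallis test within group B, per-patient
    CNR summaries for the three plaque scenarios, and weighted kappa per
    group.
    """
    patients: pd.DataFrame = cohort.patients
    if set(patients["group"].unique()) != {"A", "B"}:
        raise ValueError("cohort must contain both groups A and B")

    grp = patients.groupby("group")["diagnostic"]
    x = grp.sum()
    n = grp.count()
    rates = pd.DataFrame(
        {
            "group": ["A", "B"],
            "n": [int(n["A"]), int(n["B"])],
            "diagnostic": [int(x["A"]), int(x["B"])],
            "rate_pct": [
                proportion_pct(int(x["A"]), int(n["A"])),
                proportion_pct(int(x["B"]), int(n["B"])),
            ],
        }
    )
    ni = diff_ci_wald(int(x["A"]), int(n["A"]), int(x["B"]), int(n["B"]), margin=margin)

    # per-segment score comparison A vs B on rater-1 scores
    seg_rows = []
    scores: pd.DataFrame = cohort.scores
    for seg, sub in scores.groupby("segment"):
        a = sub.loc[sub["group"] == "A", "rater1"].to_numpy()
        b = sub.loc[sub["group"] == "B", "rater1"].to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        if np.all(np.r_[a, b] == a[0]):
            p_val = 1.0
        else:
            _, p_val = sps.mannwhitneyu(a, b, alternative="two-sided")
        seg_rows.append(
            {
                "segment": seg,
                "mean_score_a": float(a.mean()),
                "mean_score_b": float(b.mean()),
                "p_raw": float(p_val),
            }
        )
    segment_scores = pd.DataFrame(seg_rows)
    if not segment_scores.empty:
        segment_scores["p_holm"] = holm_adjust(segment_scores["p_raw"].tolist())

    # attenuation vs energy (group B spans the VMI grid)
    atten: pd.DataFrame = cohort.attenuations
    att_rows = []
    b_att = atten[atten["group"] == "B"]
    for seg, sub in b_att.groupby("segment"):
        by_energy = {e: s["hu"].to_numpy() for e, s in sub.groupby("energy")}
        if len(by_energy) < 2:
            continue
        h_stat, p_raw, _ = kruskal_holm(by_energy)
        att_rows.append({"segment": seg, "H": h_stat, "p_raw": p_raw})
    attenuation_tests = pd.DataFrame(att_rows)

    # per-patient CNR for the three clinical scenarios
    cnr_rows = []
    for _, row in patients.iterrows():
        lumen = ROISample(row["lumen_hu"], row["roi_sd_hu"], label="lumen")
        for scenario, col in [
            ("lumen_vs_fat", "fat_hu"),
            ("lumen_vs_muscle", "muscle_hu"),
            ("lumen_vs_bone", "bone_hu"),
        ]:
            tissue = ROISample(row[col], row["roi_sd_hu"], label=scenario)
            cnr_rows.append(
                {
                    "patient_id": row["patient_id"],
                    "group": row["group"],
                    "scenario": scenario,
                    "cnr": cnr(lumen, tissue),
                }
            )
    cnr_long = pd.DataFrame(cnr_rows)
    cnr_summary = (
        cnr_long.groupby(["group", "scenario"])["cnr"]
        .agg(
            median="median",
            iqr=lambda v: float(np.subtract(*np.percentile(v, [75, 25]))),
        )
        .reset_index()
    )

    # inter-rater agreement per group
    kappas: dict[str, KappaResult] = {}
    if {"rater1", "rater2"}.issubset(scores.columns):
        for g, sub in scores.groupby("group"):
            kappas[str(g)] = weighted_kappa(
                sub["rater1"].to_numpy(),
                sub["rater2"].to_numpy(),
                categories=sorted(set(scores["rater1"]) | set(scores["rater2"])),
            )
    else:
        warnings.warn("rater columns missing: kappa skipped", stacklevel=2)

    return CohortReport(
        rates=rates,
        noninferiority=ni,
        segment_scores=segment_scores,
        attenuation_tests=attenuation_tests,
        cnr_summary=cnr_summary,
        kappa=kappas,
    )
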