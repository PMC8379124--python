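"""Synthetic patient cohort with the structure of the clinical comparison.

Generates per-patient records for two injection protocols: group A
(regular dose, conventional images only) and group B (reduced dose, VMI at
all seven energy levels).  Each patient carries a diagnostic flag, a
non-diagnostic cause, a catheter insertion site, two raters' 4-point
quality scores over coronary segments, per-segment lumen attenuation and
tissue ROI summaries.

Attenuations are log-normal, parameterised by (median, IQR) anchors with a
patient-level random effect on the log scale (exchangeable within-patient
correlation).  The second rater repeats the first rater's score with
probability ``rater_agreement`` and otherwise moves to an adjacent score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .spectral import CONVENTIONAL, EnergySpec, VMI_LEVELS, load_calibration

__all__ = [
    "LIKERT_SCORES",
    "CohortParams",
    "CohortTable",
    "simulate_cohort",
    "implied_kappa",
    "lognormal_from_median_iqr",
]

#: 4 = excellent ... 1 = poor / non-evaluable
LIKERT_SCORES = (4, 3, 2, 1)

# score distributions from the qualitative per-segment counts, normalised
_LIKERT_A = {4: 1220 / 1384, 3: 74 / 1384, 2: 35 / 1384, 1: 55 / 1384}
_LIKERT_B = {4: 949 / 1310, 3: 267 / 1310, 2: 31 / 1310, 1: 63 / 1310}

_CATHETER_SITES = ("antecubital", "forearm", "hand_wrist")
_CATHETER_A = (89 / 103, 12 / 103, 2 / 103)
_CATHETER_B = (64 / 100, 19 / 100, 17 / 100)

_Q75 = 0.6744897501960817  # standard normal upper quartile


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and IQR.

    IQR/median = 2*sinh(q*sigma) with q the normal upper quartile, so
    sigma = asinh(IQR / (2*median)) / q.  Negative medians are handled by
    the caller via sign flipping.
    """
    if median <= 0 or iqr <= 0:
        raise ValueError("median and IQR must be positive")
    sigma = math.asinh(iqr / (2.0 * median)) / _Q75
    return math.log(median), sigma


def _default_attenuation_params() -> dict[str, dict[str, tuple[float, float]]]:
    cal = load_calibration()
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for seg, tab in cal.lumen_segments.items():
        out[seg] = {
            e: (tab["median"][e], tab["iqr"][e]) for e in tab["median"]
        }
    return out


def _default_tissue_params() -> dict[str, dict[str, tuple[float, float]]]:
    cal = load_calibration()
    return {
        t: {e: (tab["median"][e], tab["iqr"][e]) for e in tab["median"]}
        for t, tab in cal.tissues.items()
    }


def _check_dist(probs, name: str) -> None:
    p = np.asarray(list(probs), dtype=float)
    if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be probabilities summing to 1")


@dataclass(frozen=True)
class CohortParams:
    n_a: int = 103
    n_b: int = 100
    p_diag_a: float = 0.884
    p_diag_b: float = 0.89
    likert_probs_a: Mapping[int, float] = field(default_factory=lambda: dict(_LIKERT_A))
    likert_probs_b: Mapping[int, float] = field(default_factory=lambda: dict(_LIKERT_B))
    rater_agreement: float = 0.84  # implies weighted kappa ~0.69 (A) / ~0.76 (B)
    n_score_segments: int = 14
    segment_attenuation_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=_default_attenuation_params
    )
    tissue_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=_default_tissue_params
    )
    catheter_probs_a: tuple[float, ...] = _CATHETER_A
    catheter_probs_b: tuple[float, ...] = _CATHETER_B
    motion_fraction_nondx_a: float = 0.833
    motion_fraction_nondx_b: float = 0.909
    patient_effect_share: float = 0.3  # share of log-variance between patients
    roi_sd_median_hu: float = 25.0  # per-patient ROI noise level, group A
    roi_sd_iqr_hu: float = 8.0
    vmi_sd_factor: float = 0.8  # spectral noise reduction on VMI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("group sizes must be positive")
        for p, name in [
            (self.p_diag_a, "p_diag_a"),
            (self.p_diag_b, "p_diag_b"),
            (self.rater_agreement, "rater_agreement"),
            (self.motion_fraction_nondx_a, "motion_fraction_nondx_a"),
            (self.motion_fraction_nondx_b, "motion_fraction_nondx_b"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for probs, name in [
            (self.likert_probs_a.values(), "likert_probs_a"),
            (self.likert_probs_b.values(), "likert_probs_b"),
            (self.catheter_probs_a, "catheter_probs_a"),
            (self.catheter_probs_b, "catheter_probs_b"),
        ]:
            _check_dist(probs, name)
        if not 0.0 <= self.patient_effect_share < 1.0:
            raise ValueError("patient_effect_share must lie in [0, 1)")


@dataclass
class CohortTable:
    """Tidy frames: one row per patient / per segment score / per attenuation."""

    patients: pd.DataFrame
    scores: pd.DataFrame
    attenuations: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "patients.csv", index=False)
        self.scores.to_csv(out / "segment_scores.csv", index=False)
        self.attenuations.to_csv(out / "attenuations.csv", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "CohortTable":
        p = Path(in_dir)
        return cls(
            patients=pd.read_csv(p / "patients.csv"),
            scores=pd.read_csv(p / "segment_scores.csv"),
            attenuations=pd.read_csv(p / "attenuations.csv"),
        )


def _adjacent_transition(agreement: float) -> dict[int, dict[int, float]]:
    """Rater-2 mechanism: repeat rater 1 or move to an adjacent score."""
    t: dict[int, dict[int, float]] = {}
    lo, hi = min(LIKERT_SCORES), max(LIKERT_SCORES)
    for s in LIKERT_SCORES:
        neighbours = [v for v in (s - 1, s + 1) if lo <= v <= hi]
        row = {s: agreement}
        for v in neighbours:
            row[v] = (1.0 - agreement) / len(neighbours)
        t[s] = row
    return t


def implied_kappa(
    likert_probs: Mapping[int, float], agreement: float, weights: str = "linear"
) -> float:
    """Population weighted kappa implied by the rating mechanism.

    Builds the expected rater-1 x rater-2 joint distribution and evaluates
    weighted kappa on it directly (no sampling).
    """
    from .stats import kappa_from_table  # local import, avoids cycle at import time

    scores = sorted(LIKERT_SCORES)
    trans = _adjacent_transition(agreement)
    joint = np.zeros((len(scores), len(scores)))
    for i, si in enumerate(scores):
        for j, sj in enumerate(scores):
            joint[i, j] = likert_probs.get(si, 0.0) * trans[si].get(sj, 0.0)
    return kappa_from_table(joint, weights=weights)


def _draw_lognormal(
    rng: np.random.Generator,
    median: float,
    iqr: float,
    patient_z: np.ndarray,
    resid_share: float,
    effect_share: float,
) -> np.ndarray:
    """Log-normal draws whose marginal matches (median, IQR), with a
    patient-level random effect carrying ``effect_share`` of the variance."""
    sign = 1.0
    if median < 0:
        sign, median = -1.0, -median
    mu, sigma = lognormal_from_median_iqr(median, iqr)
    z = patient_z * math.sqrt(effect_share) + rng.standard_normal(
        patient_z.shape
    ) * math.sqrt(resid_share)
    return sign * np.exp(mu + sigma * z)


def simulate_cohort(params: CohortParams | None = None) -> CohortTable:
    """Draw one synthetic cohort; deterministic for a fixed ``params.seed``."""
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)

    patient_rows = []
    score_rows = []
    atten_rows = []
    pid = 0
    for group, n, p_diag, likert, cath_p, motion_p in [
        ("A", params.n_a, params.p_diag_a, params.likert_probs_a,
         params.catheter_probs_a, params.motion_fraction_nondx_a),
        ("B", params.n_b, params.p_diag_b, params.likert_probs_b,
         params.catheter_probs_b, params.motion_fraction_nondx_b),
    ]:
        energies = (
            [CONVENTIONAL]
            if group == "A"
            else [EnergySpec.vmi(e) for e in VMI_LEVELS]
        )
        scores = sorted(likert)
        score_p = np.array([likert[s] for s in scores])
        trans = _adjacent_transition(params.rater_agreement)
        effect = params.patient_effect_share
        resid = 1.0 - effect

        for _ in range(n):
            diagnostic = bool(rng.random() < p_diag)
            if diagnostic:
                cause = "none"
            else:
                cause = "motion" if rng.random() < motion_p else "enhancement"
            site = _CATHETER_SITES[rng.choice(len(cath_p), p=np.asarray(cath_p))]

            # two raters over the scored segments
            r1 = rng.choice(scores, size=params.n_score_segments, p=score_p)
            r2 = np.empty_like(r1)
            for k, s1 in enumerate(r1):
                opts = sorted(trans[int(s1)])
                pr = np.array([trans[int(s1)][o] for o in opts])
                r2[k] = opts[rng.choice(len(opts), p=pr)]
            for k in range(params.n_score_segments):
                score_rows.append(
                    {
                        "patient_id": pid,
                        "group": group,
                        "segment": f"seg{k + 1:02d}",
                        "rater1": int(r1[k]),
                        "rater2": int(r2[k]),
                    }
                )

            # attenuation draws share one patient-level effect
            patient_z = np.array(rng.standard_normal())
            for seg, per_energy in params.segment_attenuation_params.items():
                for e in energies:
                    med, iqr = per_energy[e.key]
                    hu = _draw_lognormal(
                        rng, med, iqr, patient_z, resid, effect
                    )
                    atten_rows.append(
                        {
                            "patient_id": pid,
                            "group": group,
                            "segment": seg,
                            "energy": e.key,
                            "hu": float(hu),
                        }
                    )

            # tissue ROI means at the group's qualitative-analysis energy
            quality_energy = CONVENTIONAL if group == "A" else EnergySpec.vmi(55)
            tissue_hu = {}
            for tissue, per_energy in params.tissue_params.items():
                med, iqr = per_energy[quality_energy.key]
                tissue_hu[tissue] = float(
                    _draw_lognormal(rng, med, iqr, patient_z, resid, effect)
                )

            # per-patient ROI noise level (SD), lower on VMI
            mu_sd, sig_sd = lognormal_from_median_iqr(
                params.roi_sd_median_hu, params.roi_sd_iqr_hu
            )
            roi_sd = float(np.exp(mu_sd + sig_sd * rng.standard_normal()))
            if group == "B":
                roi_sd *= params.vmi_sd_factor

            lumen_med, lumen_iqr = params.segment_attenuation_params[
                "ascending_aorta"
            ][quality_energy.key]
            lumen_hu = float(
                _draw_lognormal(rng, lumen_med, lumen_iqr, patient_z, resid, effect)
            )

            patient_rows.append(
                {
                    "patient_id": pid,
                    "group": group,
                    "diagnostic": diagnostic,
                    "nondx_cause": cause,
                    "catheter_site": site,
                    "quality_energy": quality_energy.key,
                    "lumen_hu": lumen_hu,
                    "fat_hu": tissue_hu["fat"],
                    "muscle_hu": tissue_hu["muscle"],
                    "bone_hu": tissue_hu["trabecular_bone"],
                    "roi_sd_hu": roi_sd,
                }
            )
            pid += 1

    return CohortTable(
        patients=pd.DataFrame(patient_rows),
        scores=pd.DataFrame(score_rows),
        attenuations=pd.DataFrame(atten_rows),
    )
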