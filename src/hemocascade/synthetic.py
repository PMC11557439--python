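"""Phantom head-CT slices and synthetic msTBI cohorts with known truth.

The phantom generator draws a stylized axial head slice — bright
elliptical skull ring, mid-gray parenchyma, a darker central ventricle —
and paints 0–3 hemorrhage lesions whose geometry encodes their subtype
the way the subtypes present on real CT:

* EDH: thick biconvex lens pressed against the inner skull table;
* SDH: thin, wide crescent hugging the inner skull;
* IPH: compact elliptical blob inside the parenchyma;
* IVH: blob confined to the dark central ventricle;
* SAH: thin curvilinear streaks at mid-radius (sulcal blood).

Lesion pixels sit ``lesion_intensity_contrast`` above the tissue they
replace, before additive Gaussian noise, and the returned masks are
exact by construction (subtype-coded 1–5).  Subtype is therefore
inferable from shape and local context alone, which is what the fusion
classifier needs as a learnable signal.

The cohort generator draws patients satisfying the msTBI inclusion
criteria (GCS 3–12, age 18–80) with CRASH-CT covariates, hematoma
volume and subtype indicators, then samples two binary outcomes from
stated logistic models: ``death14`` (scheme A: death vs. other) and
``death_or_coma14`` (scheme B: death-or-coma vs. other).  The true
linear predictors are stored per row so estimation code can be checked
against the generating truth.  Coefficients are expressed in the same
units as the outcome model's design matrix (ln-age via the Box-Cox
transform at lambda = 0, raw GCS, raw volume in mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .image_io import SUBTYPE_CODES, SUBTYPE_NAMES, CTSeries, LabelMask, SubtypeLabels

# physical field of view kept constant so pixel spacing scales with resolution
_FOV_MM = 230.4
_DEFAULT_THICKNESS_MM = 5.0

# tissue intensities in [0,1] (unit-scale phantoms, no HU involved)
_I_BACKGROUND = 0.02
_I_SKULL = 0.95
_I_PARENCHYMA = 0.35
_I_VENTRICLE = 0.18

# geometry fractions of the image side
_R_OUTER = 0.46
_R_INNER = 0.40
_VENT_RX = 0.13
_VENT_RY = 0.09

# per-subtype shape parameter ranges (fractions of image side / radians)
_EDH_HALFWIDTH = (0.35, 0.50)
_EDH_THICK = (0.07, 0.12)
_SDH_HALFWIDTH = (0.90, 1.30)
_SDH_THICK = (0.028, 0.042)
_IPH_RADIUS = (0.05, 0.10)
_IPH_DIST = (0.15, 0.26)
_IVH_RADIUS = (0.035, 0.060)
_SAH_R0 = (0.28, 0.36)
_SAH_HALFARC = (0.20, 0.40)
_SAH_THICK_FRAC = 0.013


@dataclass
class PhantomSpec:
    """Conditions for one phantom series."""

    image_side: int = 64
    n_slices: int = 10
    subtype_mix: Dict[str, float] = field(
        default_factory=lambda: {n: 0.2 for n in SUBTYPE_NAMES}
    )
    lesion_intensity_contrast: float = 0.35
    noise_sd: float = 0.05
    fraction_empty_slices: float = 0.3
    seed: int = 0
    patient_id: str = "phantom"

    def __post_init__(self):
        if self.image_side < 32:
            raise ValueError("image_side must be >= 32")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if not 0.0 < self.lesion_intensity_contrast <= 1.0:
            raise ValueError("lesion_intensity_contrast must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.fraction_empty_slices <= 1.0:
            raise ValueError("fraction_empty_slices must be in [0, 1]")
        for k, v in self.subtype_mix.items():
            if k not in SUBTYPE_NAMES:
                raise ValueError(f"unknown subtype {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError("subtype probabilities must be in [0, 1]")
        if sum(self.subtype_mix.values()) <= 0:
            raise ValueError("subtype_mix must have positive total mass")


def _polar(side: int) -> Tuple[np.ndarray, np.ndarray]:
    c = (side - 1) / 2.0
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    dy, dx = rr - c, cc - c
    return np.hypot(dy, dx), np.arctan2(dy, dx)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _paint_mural(r, phi, side, theta0, halfwidth, t0_frac, profile) -> np.ndarray:
    """Lesion band against the inner skull with an angular thickness profile."""
    r_in = _R_INNER * side
    dphi = _wrap_angle(phi - theta0)
    u = np.clip(np.abs(dphi) / halfwidth, 0.0, 1.0)
    if profile == "lens":  # biconvex: elliptic thickness profile
        t = t0_frac * side * np.sqrt(np.clip(1.0 - u**2, 0.0, 1.0))
    else:  # crescent: parabolic, thinner profile
        t = t0_frac * side * np.clip(1.0 - u**2, 0.0, 1.0)
    t = np.where(np.abs(dphi) < halfwidth, np.maximum(t, 1.2), 0.0)
    return (r < r_in - 0.5) & (r >= r_in - 0.5 - t)


def _paint_ellipse(side, center, radii, angle) -> np.ndarray:
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    dy, dx = rr - center[0], cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = (ca * dy + sa * dx) / radii[0]
    v = (-sa * dy + ca * dx) / radii[1]
    return u**2 + v**2 <= 1.0


def _sample_lesion(
    subtype: str, side: int, rng: np.random.Generator, r: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    c = (side - 1) / 2.0
    if subtype == "edh":
        return _paint_mural(
            r, phi, side,
            rng.uniform(-np.pi, np.pi),
            rng.uniform(*_EDH_HALFWIDTH),
            rng.uniform(*_EDH_THICK),
            "lens",
        )
    if subtype == "sdh":
        return _paint_mural(
            r, phi, side,
            rng.uniform(-np.pi, np.pi),
            rng.uniform(*_SDH_HALFWIDTH),
            rng.uniform(*_SDH_THICK),
            "crescent",
        )
    if subtype == "iph":
        d = rng.uniform(*_IPH_DIST) * side
        theta = rng.uniform(-np.pi, np.pi)
        center = (c + d * math.sin(theta), c + d * math.cos(theta))
        radii = rng.uniform(*_IPH_RADIUS, size=2) * side
        # keep the blob strictly interior to the skull
        max_r = _R_INNER * side - d - 2.0
        radii = np.minimum(radii, max(max_r, 2.0))
        blob = _paint_ellipse(side, center, radii, rng.uniform(0, np.pi))
        return blob & (r < _R_INNER * side - 1.5)
    if subtype == "ivh":
        off = rng.uniform(-0.03, 0.03, size=2) * side
        radii = rng.uniform(*_IVH_RADIUS, size=2) * side
        blob = _paint_ellipse(side, (c + off[0], c + off[1]), radii, rng.uniform(0, np.pi))
        vent = _paint_ellipse(side, (c, c), (_VENT_RY * side, _VENT_RX * side), 0.0)
        return blob & vent
    if subtype == "sah":
        out = np.zeros((side, side), dtype=bool)
        for _ in range(int(rng.integers(1, 3))):
            r0 = rng.uniform(*_SAH_R0) * side
            theta0 = rng.uniform(-np.pi, np.pi)
            half = rng.uniform(*_SAH_HALFARC)
            thick = max(_SAH_THICK_FRAC * side, 1.0)
            dphi = _wrap_angle(phi - theta0)
            out |= (np.abs(r - r0) < thick) & (np.abs(dphi) < half)
        return out & (r < _R_INNER * side - 1.5)
    raise ValueError(f"unknown subtype {subtype!r}")


def expected_mean_area(subtype: str, image_side: int) -> float:
    """Analytic mean lesion area (pixels) under the shape samplers.

    Serves as the oracle for area checks on generated sets.  Exact for
    the continuous geometry; pixelization adds O(perimeter) error.
    """
    s = image_side
    r_in = _R_INNER * s
    if subtype == "edh":
        t0 = 0.5 * sum(_EDH_THICK) * s
        alpha = 0.5 * sum(_EDH_HALFWIDTH)
        # band area = integral of sqrt-profile thickness along the arc
        return t0 * r_in * alpha * (np.pi / 2)
    if subtype == "sdh":
        t0 = 0.5 * sum(_SDH_THICK) * s
        alpha = 0.5 * sum(_SDH_HALFWIDTH)
        return t0 * r_in * alpha * (4.0 / 3.0)
    if subtype == "iph":
        # E[pi a b] for independent uniform radii
        m = 0.5 * sum(_IPH_RADIUS) * s
        return np.pi * m * m
    if subtype == "ivh":
        m = 0.5 * sum(_IVH_RADIUS) * s
        return np.pi * m * m
    if subtype == "sah":
        r0 = 0.5 * sum(_SAH_R0) * s
        half = 0.5 * sum(_SAH_HALFARC)
        thick = max(_SAH_THICK_FRAC * s, 1.0)
        return 1.5 * (2 * half * r0) * (2 * thick)  # mean 1.5 arcs
    raise ValueError(f"unknown subtype {subtype!r}")


def _base_slice(side: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    r, phi = _polar(side)
    img = np.full((side, side), _I_BACKGROUND, dtype=np.float64)
    img[r < _R_OUTER * side] = _I_SKULL
    brain = r < _R_INNER * side
    img[brain] = _I_PARENCHYMA
    vent = _paint_ellipse(side, ((side - 1) / 2.0,) * 2, (_VENT_RY * side, _VENT_RX * side), 0.0)
    img[vent] = _I_VENTRICLE
    return img, r, phi


def generate_phantom_series(
    spec: PhantomSpec,
) -> Tuple[CTSeries, List[LabelMask], List[SubtypeLabels]]:
    """Draw a phantom series with exact masks and slice-level labels."""
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    base, r, phi = _base_slice(side)

    names = list(spec.subtype_mix)
    probs = np.array([spec.subtype_mix[n] for n in names], dtype=float)
    probs = probs / probs.sum()

    slices, masks, labels = [], [], []
    for _ in range(spec.n_slices):
        img = base.copy()
        mask = np.zeros((side, side), dtype=np.int16)
        if rng.random() >= spec.fraction_empty_slices:
            n_lesions = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
            for _ in range(n_lesions):
                subtype = str(rng.choice(names, p=probs))
                region = _sample_lesion(subtype, side, rng, r, phi)
                # keep lesions disjoint so masks and labels stay exact
                for _retry in range(5):
                    if region.any() and not (region & (mask > 0)).any():
                        break
                    region = _sample_lesion(subtype, side, rng, r, phi)
                if not region.any() or (region & (mask > 0)).any():
                    continue
                img[region] = np.clip(
                    img[region] + spec.lesion_intensity_contrast, 0.0, 1.0
                )
                mask[region] = SUBTYPE_CODES[subtype]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        lm = LabelMask(mask, encoding="subtype")
        slices.append(np.clip(img, 0.0, 1.0).astype(np.float32))
        masks.append(lm)
        labels.append(lm.subtype_labels())

    spacing = _FOV_MM / side
    series = CTSeries(
        patient_id=spec.patient_id,
        slices=slices,
        pixel_spacing_mm=(spacing, spacing),
        slice_thickness_mm=_DEFAULT_THICKNESS_MM,
    )
    return series, masks, labels


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

# design-matrix column order shared with the outcome model
COHORT_FEATURES = [
    "age_bc",
    "gcs",
    "pupils_one_reactive",
    "pupils_both_nonreactive",
    "major_extracranial_injury",
    "petechiae",
    "effaced_basal_cistern",
    "sah_present",
    "midline_shift",
    "nonevacuated_hematoma",
    "volume_ml",
    "edh",
    "iph",
    "ivh",
    "sah",
    "sdh",
]

# preset mirroring the study cohort's marginals qualitatively
# (median age ~57.5, GCS median ~6.5, ~30% 14-day mortality,
#  ~47% death-or-coma); coefficients in design units, ln-age for age.
DEFAULT_COEF_A: Dict[str, float] = {
    "age_bc": 0.9,
    "gcs": -0.25,
    "pupils_one_reactive": 0.5,
    "pupils_both_nonreactive": 1.2,
    "major_extracranial_injury": 0.5,
    "petechiae": 0.3,
    "effaced_basal_cistern": 0.8,
    "sah_present": 0.4,
    "midline_shift": 0.6,
    "nonevacuated_hematoma": 0.4,
    "volume_ml": 0.08,
    "edh": -0.3,
    "iph": 0.7,
    "ivh": 0.6,
    "sah": 0.3,
    "sdh": 0.2,
    "intercept": -6.45,
}
DEFAULT_COEF_B: Dict[str, float] = {
    **{k: v for k, v in DEFAULT_COEF_A.items()},
    "gcs": -0.35,
    "intercept": -4.70,
}

_PUPIL_PROBS = {"both_reactive": 0.503, "one_reactive": 0.166, "both_nonreactive": 0.331}
_BINARY_PREVALENCE = {
    "major_extracranial_injury": 0.119,
    "petechiae": 0.815,
    "effaced_basal_cistern": 0.093,
    "midline_shift": 0.185,
    "sah_present": 0.901,
    "evacuated_hematoma": 0.629,
}
_SUBTYPE_PREVALENCE = {"edh": 0.311, "iph": 0.053, "ivh": 0.093, "sah": 0.901, "sdh": 0.940}


@dataclass
class CohortSpec:
    """Conditions for one synthetic msTBI cohort."""

    n_patients: int = 151
    coefficients: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEF_A))
    coefficients_b: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEF_B))
    age_log_mean: float = math.log(57.5)
    age_log_sd: float = 0.18
    age_bounds: Tuple[float, float] = (18.0, 80.0)
    gcs_bounds: Tuple[int, int] = (3, 12)
    volume_log_mean: float = math.log(15.0)
    volume_log_sd: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        lo, hi = self.gcs_bounds
        if not (3 <= lo < hi <= 12):
            raise ValueError("GCS bounds must stay within the msTBI range 3-12")
        lo, hi = self.age_bounds
        if not (18.0 <= lo < hi <= 80.0):
            raise ValueError("age bounds must stay within the msTBI range 18-80")
        for c in (self.coefficients, self.coefficients_b):
            unknown = set(c) - set(COHORT_FEATURES) - {"intercept"}
            if unknown:
                raise ValueError(f"unknown coefficient names: {sorted(unknown)}")

    @staticmethod
    def null(n_patients: int = 10000, seed: int = 0) -> "CohortSpec":
        """All coefficients zero: outcomes are fair coin flips."""
        zero = {k: 0.0 for k in COHORT_FEATURES}
        zero["intercept"] = 0.0
        return CohortSpec(
            n_patients=n_patients,
            coefficients=dict(zero),
            coefficients_b=dict(zero),
            seed=seed,
        )


def _truncated_lognormal(rng, n, mu, sd, lo, hi):
    from scipy.stats import norm

    a = norm.cdf((math.log(lo) - mu) / sd)
    b = norm.cdf((math.log(hi) - mu) / sd)
    u = rng.uniform(a, b, size=n)
    return np.exp(mu + sd * norm.ppf(u))


def _gcs_probs(lo: int, hi: int) -> np.ndarray:
    # mild skew toward low scores so the median lands near 6.5
    vals = np.arange(lo, hi + 1)
    w = np.exp(-0.05 * (vals - lo))
    return w / w.sum()


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per patient; outcomes drawn from the stated logistic truth.

    Columns: demographics/CRASH predictors, ``volume_ml``, the five
    subtype indicators, outcomes ``death14`` / ``death_or_coma14`` and
    the true linear predictors ``true_lp_a`` / ``true_lp_b``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    age = _truncated_lognormal(
        rng, n, spec.age_log_mean, spec.age_log_sd, *spec.age_bounds
    )
    lo, hi = spec.gcs_bounds
    gcs = rng.choice(np.arange(lo, hi + 1), size=n, p=_gcs_probs(lo, hi))
    pupil_names = list(_PUPIL_PROBS)
    pupils = rng.choice(pupil_names, size=n, p=list(_PUPIL_PROBS.values()))
    binaries = {
        k: (rng.random(n) < p).astype(int) for k, p in _BINARY_PREVALENCE.items()
    }
    subtype_ind = {
        k: (rng.random(n) < p).astype(int) for k, p in _SUBTYPE_PREVALENCE.items()
    }
    volume = np.exp(rng.normal(spec.volume_log_mean, spec.volume_log_sd, size=n))

    design = {
        "age_bc": np.log(age),  # Box-Cox transform at lambda = 0
        "gcs": gcs.astype(float),
        "pupils_one_reactive": (pupils == "one_reactive").astype(float),
        "pupils_both_nonreactive": (pupils == "both_nonreactive").astype(float),
        "major_extracranial_injury": binaries["major_extracranial_injury"].astype(float),
        "petechiae": binaries["petechiae"].astype(float),
        "effaced_basal_cistern": binaries["effaced_basal_cistern"].astype(float),
        "sah_present": binaries["sah_present"].astype(float),
        "midline_shift": binaries["midline_shift"].astype(float),
        "nonevacuated_hematoma": 1.0 - binaries["evacuated_hematoma"],
        "volume_ml": volume,
        **{k: subtype_ind[k].astype(float) for k in SUBTYPE_NAMES},
    }

    def linpred(coefs: Dict[str, float]) -> np.ndarray:
        lp = np.full(n, coefs.get("intercept", 0.0), dtype=float)
        for name, beta in coefs.items():
            if name != "intercept" and beta != 0.0:
                lp += beta * design[name]
        return lp

    lp_a = linpred(spec.coefficients)
    lp_b = linpred(spec.coefficients_b)
    p_a = 1.0 / (1.0 + np.exp(-lp_a))
    p_b = 1.0 / (1.0 + np.exp(-lp_b))
    death14 = (rng.random(n) < p_a).astype(int)
    death_or_coma14 = (rng.random(n) < p_b).astype(int)

    df = pd.DataFrame(
        {
            "patient_id": [f"synth-{i:05d}" for i in range(n)],
            "age_years": age,
            "gcs": gcs,
            "pupils": pupils,
            "major_extracranial_injury": binaries["major_extracranial_injury"],
            "petechiae": binaries["petechiae"],
            "effaced_basal_cistern": binaries["effaced_basal_cistern"],
            "midline_shift": binaries["midline_shift"],
            "sah_present": binaries["sah_present"],
            "evacuated_hematoma": binaries["evacuated_hematoma"],
            "volume_ml": volume,
            **{k: subtype_ind[k] for k in SUBTYPE_NAMES},
            "death14": death14,
            "death_or_coma14": death_or_coma14,
            "true_lp_a": lp_a,
            "true_lp_b": lp_b,
        }
    )
    return df
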