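"""Synthetic phantoms and cohorts with known ground truth.

Three generators make every downstream stage testable without patient data:

* diffusion phantoms — voxel grids with a spherical "lesion" region whose
  true (Dapp, Kapp) differ from the background; noiseless signals follow the
  kurtosis model exactly, and Gaussian or Rician (magnitude-MR) noise can be
  layered on at a chosen SNR = S0/sigma.  Rician is the realistic default
  for magnitude MR data and exercises the fitter's noise-floor behaviour;
* PET phantoms — explicit SUV assignments per lesion voxel (plateaus and
  gradients both expressible) over a uniform background, returned together
  with analytically computed SUVmax/MTV/TLG ground truth;
* patient cohorts — per-group Gaussian draws of the six imaging parameters
  (ADC, MD, MK in their usual reporting units of 1e-3 mm^2/s for the
  diffusion pair; SUVmax, MTV, TLG unitless/mL/g), demographics, pathology
  labels with grades, and two reader columns for the hand-measured diffusion
  parameters with controllable additive reader noise.

The cohort defaults encode the published two-group statistics of a 73-patient
solitary-pulmonary-lesion study (58 malignant of which 31 high-grade, 15
benign).  Malignant patients' parameters are drawn from the grade-specific
distributions, so the pooled malignant group is the implied mixture.
Negative draws for physically nonnegative quantities are floored at 1e-6
rather than redrawn, which keeps random streams aligned across parameter
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .diffusion_models import (
    BValueProtocol,
    DiffusionVolumeStack,
    ParameterMap,
    dki_signal,
)
from .pet_metrics import LesionROI, MetabolicMetrics, SUVVolume

__all__ = [
    "DiffusionPhantomSpec",
    "PETPhantomSpec",
    "CohortSpec",
    "make_diffusion_phantom",
    "make_pet_phantom",
    "make_cohort",
    "DEFAULT_GROUP_STATS",
    "DEFAULT_EXCLUSION_COUNTS",
    "EXCLUSION_FLAGS",
    "NONNEGATIVE_FLOOR",
]

NONNEGATIVE_FLOOR = 1e-6

# Published per-group (mean, SD).  Malignant patients are generated from the
# grade-specific columns; the pooled malignant column is implied (e.g. MD:
# 31/58 x N(2.11, .51^2) + 27/58 x N(2.46, .46^2) has mean 2.27, matching the
# printed pooled cell).  The source table's pooled malignant cells for ADC
# (1.35 +/- 0.33) and MTV (20.17 +/- 32.34) are inconsistent with this
# pooling and are retained here only as a record, not used for generation.
DEFAULT_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "adc": {  # 1e-3 mm^2/s
        "benign": (1.67, 0.33),
        "high_grade": (1.35, 0.33),
        "non_high_grade": (1.67, 0.33),
    },
    "md": {  # 1e-3 mm^2/s; pooled malignant (2.27, 0.51)
        "benign": (2.85, 0.60),
        "high_grade": (2.11, 0.51),
        "non_high_grade": (2.46, 0.46),
    },
    "mk": {
        "benign": (0.47, 0.08),
        "high_grade": (0.60, 0.13),
        "non_high_grade": (0.59, 0.12),
    },
    "suvmax": {
        "benign": (5.49, 4.05),
        "high_grade": (11.14, 4.20),
        "non_high_grade": (9.22, 4.08),
    },
    "mtv": {  # mL
        "benign": (35.87, 42.24),
        "high_grade": (35.87, 42.24),
        "non_high_grade": (20.17, 32.34),
    },
    "tlg": {  # g
        "benign": (119.58, 163.65),
        "high_grade": (119.58, 163.65),
        "non_high_grade": (114.20, 178.68),
    },
}

EXCLUSION_FLAGS = (
    "no_histopathology",
    "solid_component_lt_10mm",
    "multiple_lesions",
    "poor_image_quality",
)

# Screening-cascade tallies: 121 screened minus these disjoint counts = 73.
DEFAULT_EXCLUSION_COUNTS: dict[str, int] = {
    "no_histopathology": 13,
    "solid_component_lt_10mm": 11,
    "multiple_lesions": 15,
    "poor_image_quality": 9,
}

# Reader-noise SDs (additive, homoscedastic, independent across readers)
# sized so two-reader ICC(2,1) on the default cohort sits near the reported
# inter-reader agreement (ADC 0.836, MD 0.897, MK 0.867).
DEFAULT_READER_NOISE_SD: dict[str, float] = {"adc": 0.15, "md": 0.19, "mk": 0.05}

_PATHOLOGY_CHOICES = {
    "benign": (
        ["granuloma", "hamartoma", "inflammatory pseudotumor", "tuberculoma"],
        [0.4, 0.2, 0.2, 0.2],
    ),
    "high_grade": (
        [
            "adenocarcinoma (poorly differentiated)",
            "squamous cell carcinoma (poorly differentiated)",
            "small cell lung cancer",
        ],
        [0.6, 0.25, 0.15],
    ),
    "non_high_grade": (
        [
            "adenocarcinoma (well differentiated)",
            "adenocarcinoma (moderately differentiated)",
            "squamous cell carcinoma (moderately differentiated)",
            "bronchial adenoma",
        ],
        [0.3, 0.5, 0.1, 0.1],
    ),
}

_GRADE_FROM_PATHOLOGY = {
    "adenocarcinoma (poorly differentiated)": 3,
    "squamous cell carcinoma (poorly differentiated)": 3,
    "small cell lung cancer": 3,
    "adenocarcinoma (well differentiated)": 1,
    "adenocarcinoma (moderately differentiated)": 2,
    "squamous cell carcinoma (moderately differentiated)": 2,
    "bronchial adenoma": 1,
}


# ---------------------------------------------------------------------------
# Diffusion phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionPhantomSpec:
    """Ground truth for a two-region diffusion phantom.

    The lesion is a sphere (``lesion_radius`` voxels around ``lesion_center``,
    defaulting to the grid centre); everything else is background.  ``snr``
    is S0/sigma and only read when ``noise_model != 'none'``.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lesion_radius: float = 4.0
    lesion_center: tuple[float, float, float] | None = None
    dapp_lesion: float = 1.2e-3  # mm^2/s
    dapp_background: float = 2.5e-3
    kapp_lesion: float = 0.9
    kapp_background: float = 0.4
    s0: float = 1000.0
    noise_model: Literal["none", "gaussian", "rician"] = "rician"
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 1 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 1")
        if self.dapp_lesion <= 0 or self.dapp_background <= 0:
            raise ValueError("Dapp values must be positive")
        if self.kapp_lesion < 0 or self.kapp_background < 0:
            raise ValueError("Kapp values must be nonnegative")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise_model: {self.noise_model!r}")
        if self.noise_model != "none" and self.snr <= 0:
            raise ValueError("snr must be positive when noise is applied")

    def lesion_mask(self) -> np.ndarray:
        center = self.lesion_center or tuple((g - 1) / 2 for g in self.grid_shape)
        grids = np.ogrid[tuple(slice(0, g) for g in self.grid_shape)]
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        return dist2 <= self.lesion_radius**2


def make_diffusion_phantom(
    spec: DiffusionPhantomSpec, protocol: BValueProtocol | None = None
) -> tuple[DiffusionVolumeStack, dict[str, ParameterMap]]:
    """Simulate a multi-b-value stack plus its true MD/MK maps.

    Noiseless voxel signals satisfy the kurtosis signal equation exactly for
    that voxel's true (Dapp, Kapp); noise is then applied per ``noise_model``
    with ``sigma = s0 / snr`` under the spec's seed.
    """
    protocol = protocol or BValueProtocol.dki_default()
    lesion = spec.lesion_mask()
    dapp = np.where(lesion, spec.dapp_lesion, spec.dapp_background)
    kapp = np.where(lesion, spec.kapp_lesion, spec.kapp_background)

    b = protocol.as_array()
    signal = dki_signal(
        b[None, None, None, :], spec.s0, dapp[..., None], kapp[..., None]
    )

    if spec.noise_model != "none":
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        if spec.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, sigma, signal.shape)
        else:  # rician: magnitude of a complex signal with iid Gaussian parts
            re = signal + rng.normal(0.0, sigma, signal.shape)
            im = rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt(re**2 + im**2)

    stack = DiffusionVolumeStack(
        data=signal, protocol=protocol, voxel_size=spec.voxel_size
    )
    full = np.ones(spec.grid_shape, dtype=bool)
    truth = {
        "MD": ParameterMap(name="MD", values=dapp.astype(float), mask=full),
        "MK": ParameterMap(name="MK", values=kapp.astype(float), mask=full.copy()),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# PET phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PETPhantomSpec:
    """Explicit SUV assignments for lesion voxels over a uniform background."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    lesion_voxel_values: Mapping[tuple[int, int, int], float]
    background_suv: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lesion_voxel_values) < 1:
            raise ValueError("lesion must contain at least one voxel")
        if self.background_suv < 0 or any(
            v < 0 for v in self.lesion_voxel_values.values()
        ):
            raise ValueError("SUV values must be nonnegative")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


def make_pet_phantom(
    spec: PETPhantomSpec, threshold_fraction: float = 0.40
) -> tuple[SUVVolume, LesionROI, MetabolicMetrics]:
    """Build the SUV volume, its lesion ROI, and analytic ground-truth metrics.

    Ground truth is computed directly from the voxel assignment table by
    explicit enumeration (strict > threshold inclusion), independent of the
    array-based metric implementations.
    """
    values = np.full(spec.grid_shape, float(spec.background_suv))
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for idx, suv in spec.lesion_voxel_values.items():
        values[idx] = float(suv)
        mask[idx] = True

    suvs = [float(v) for v in spec.lesion_voxel_values.values()]
    suvmax = max(suvs)
    thr = threshold_fraction * suvmax
    included = [v for v in suvs if v > thr]
    mtv = len(included) * spec.voxel_volume / 1000.0
    suvmean = sum(included) / len(included) if included else 0.0
    truth = MetabolicMetrics(
        suvmax=suvmax,
        mtv=mtv,
        tlg=mtv * suvmean,
        suvmean_included=suvmean,
        threshold_fraction=threshold_fraction,
    )
    vol = SUVVolume(values=values, voxel_volume=spec.voxel_volume)
    roi = LesionROI(mask=mask, provenance="synthetic")
    return vol, roi, truth


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study-conditions generator for a two-contrast lesion cohort.

    ``group_sizes`` gives benign and the two malignant grade strata (their
    sum is the malignant group); ``group_stats[param][group]`` holds
    (mean, SD) of the Gaussian each stratum's true parameter values are
    drawn from.  ``reader_noise_sd`` maps each hand-measured parameter to
    the SD of its additive per-reader error.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"benign": 15, "high_grade": 31, "non_high_grade": 27}
    )
    group_stats: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_GROUP_STATS
    )
    age_mean: float = 60.0
    age_sd: float = 10.41
    male_fraction: float = 53 / 73
    smoking_fraction: float = 0.45
    diameter_mean: float = 3.68  # cm
    diameter_sd: float = 1.77
    reader_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_READER_NOISE_SD
    )
    include_excluded: bool = False
    exclusion_counts: Mapping[str, int] = field(
        default_factory=lambda: DEFAULT_EXCLUSION_COUNTS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs size >= 2, got {n}")
        for param, groups in self.group_stats.items():
            for g, (_, sd) in groups.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {param}/{g}")
        for p, sd in self.reader_noise_sd.items():
            if sd < 0:
                raise ValueError(f"negative reader noise SD for {p}")


_READ_PARAMS = ("adc", "md", "mk")  # measured by two readers
_AUTO_PARAMS = ("suvmax", "mtv", "tlg")  # workstation-computed, single value


def _floored_normal(rng: np.random.Generator, mean, sd, n) -> np.ndarray:
    return np.maximum(rng.normal(mean, sd, n), NONNEGATIVE_FLOOR)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a per-patient cohort table.

    Columns: patient_id, age, sex, smoking, diameter_cm, pathology, grade,
    group, {adc,md,mk}_reader{1,2}, suvmax, mtv, tlg, exclusion_flags (empty
    string = retained).  Reader columns are true value + independent
    homoscedastic Gaussian reader noise.  Bit-reproducible under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for stratum in ("benign", "high_grade", "non_high_grade"):
        n = int(spec.group_sizes.get(stratum, 0))
        if n == 0:
            continue
        rec: dict[str, object] = {}
        rec["age"] = np.round(_floored_normal(rng, spec.age_mean, spec.age_sd, n), 1)
        rec["sex"] = np.where(
            rng.random(n) < spec.male_fraction, "male", "female"
        )
        rec["smoking"] = rng.random(n) < spec.smoking_fraction
        rec["diameter_cm"] = np.round(
            _floored_normal(rng, spec.diameter_mean, spec.diameter_sd, n), 2
        )
        labels, probs = _PATHOLOGY_CHOICES[stratum]
        rec["pathology"] = rng.choice(labels, size=n, p=probs)
        if stratum == "benign":
            rec["grade"] = [""] * n
        else:
            rec["grade"] = [str(_GRADE_FROM_PATHOLOGY[p]) for p in rec["pathology"]]
        rec["group"] = "benign" if stratum == "benign" else "malignant"

        for param in _READ_PARAMS:
            mean, sd = spec.group_stats[param][stratum]
            true = _floored_normal(rng, mean, sd, n)
            noise_sd = float(spec.reader_noise_sd.get(param, 0.0))
            for reader in (1, 2):
                noisy = true + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else true
                rec[f"{param}_reader{reader}"] = np.maximum(noisy, NONNEGATIVE_FLOOR)
        for param in _AUTO_PARAMS:
            mean, sd = spec.group_stats[param][stratum]
            rec[param] = _floored_normal(rng, mean, sd, n)
        rec["exclusion_flags"] = [""] * n
        frames.append(pd.DataFrame(rec))

    df = pd.concat(frames, ignore_index=True)

    if spec.include_excluded:
        ex_frames = []
        for flag in EXCLUSION_FLAGS:
            n = int(spec.exclusion_counts.get(flag, 0))
            if n == 0:
                continue
            ex = pd.DataFrame(
                {
                    "age": np.round(
                        _floored_normal(rng, spec.age_mean, spec.age_sd, n), 1
                    ),
                    "sex": np.where(
                        rng.random(n) < spec.male_fraction, "male", "female"
                    ),
                    "smoking": rng.random(n) < spec.smoking_fraction,
                    "diameter_cm": np.round(
                        _floored_normal(rng, spec.diameter_mean, spec.diameter_sd, n), 2
                    ),
                    "pathology": [""] * n,
                    "grade": [""] * n,
                    "group": ["unknown"] * n,
                    "exclusion_flags": [flag] * n,
                }
            )
            ex_frames.append(ex)
        if ex_frames:
            df = pd.concat([df] + ex_frames, ignore_index=True)

    df.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(len(df))])
    cols = (
        ["patient_id", "age", "sex", "smoking", "diameter_cm", "pathology",
         "grade", "group"]
        + [f"{p}_reader{r}" for p in _READ_PARAMS for r in (1, 2)]
        + list(_AUTO_PARAMS)
        + ["exclusion_flags"]
    )
    return df.reindex(columns=cols)
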