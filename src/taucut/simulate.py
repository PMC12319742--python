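"""Synthetic multi-ethnoracial tau-PET cohort generator.

Emulates the statistical structure the cut-point analysis assumes, so every
downstream stage is testable without restricted study data:

* participants belong to strata of diagnosis (CU/MCI/AD) x amyloid status x
  ethnoracial group, with configurable cell counts;
* each participant carries a single latent tau state (normal / abnormal)
  drawn with a per-(diagnosis, amyloid) prevalence that rises with diagnostic
  severity — tau staging is spatially coherent, so the state is shared across
  regions, making composite-level SUVR distributions remain two-component;
* given the latent state, regional mean SUVRs are the component value (a
  participant-level Gaussian draw) plus independent per-region jitter;
  median SUVRs add zero-mean noise to the means; volumes are log-normal
  around per-region typical values;
* global amyloid SUVR is drawn per amyloid status from truncated normals on
  either side of the 1.08 positivity threshold, so the drawn value always
  agrees with the stratum's amyloid label.

Two optional "planted-effect" dials exist for validation studies:
``region_shift_scale`` multiplies the abnormal-component shift in named
regions, and ``group_separation_scale`` attenuates (or amplifies) the
abnormal shift within an ethnoracial group — emulating a subgroup in which
tau separates cases from controls less cleanly.

Fixing the seed fixes every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    AMYLOID_POSITIVITY_THRESHOLD,
    Cohort,
    SUVR_MEAN_PREFIX,
    SUVR_MEDIAN_PREFIX,
    VOLUME_PREFIX,
)

__all__ = [
    "RegionSpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "default_habs_like_config",
    "default_full_spectrum_config",
    "DEFAULT_REGIONS",
]


@dataclass(frozen=True)
class RegionSpec:
    """A region's name and the typical scale of its volume (mm^3)."""

    name: str
    mean_volume: float
    volume_sd: float


#: The nine evaluated ROIs with plausible FreeSurfer-scale bilateral volumes.
#: (The hippocampus volume scale matches the cohort-table convention of
#: reporting it in the ~3200 mm^3 range.)
DEFAULT_REGIONS: tuple[RegionSpec, ...] = (
    RegionSpec("entorhinal", 3500.0, 400.0),
    RegionSpec("fusiform", 17000.0, 1800.0),
    RegionSpec("inferior_temporal", 20000.0, 2200.0),
    RegionSpec("middle_temporal", 20500.0, 2200.0),
    RegionSpec("parahippocampal", 4100.0, 450.0),
    RegionSpec("amygdala", 3100.0, 350.0),
    RegionSpec("hippocampus", 3200.0, 400.0),
    RegionSpec("posterior_cingulate", 6200.0, 700.0),
    RegionSpec("lateral_parietal", 15500.0, 1700.0),
)

# Demographic defaults: per-diagnosis age mean/SD and female fraction, and
# per-ethnoracial-group education mean/SD, matched to the study-like cohort
# composition the default configs emulate.
_AGE_BY_DX = {"CU": (64.62, 8.12), "MCI": (70.73, 9.33), "AD": (72.25, 9.81)}
_FEMALE_FRAC_BY_DX = {"CU": 0.65, "MCI": 0.52, "AD": 0.46}
_EDU_BY_GROUP = {
    "Hispanic": (11.32, 4.04),
    "NHB": (14.98, 2.71),
    "NHW": (15.87, 2.36),
    "other": (14.34, 3.56),
}


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    ``group_sizes`` maps (diagnosis, amyloid-status, ethnoracial-group) to a
    cell count; ``abnormal_prevalence`` maps (diagnosis, amyloid-status) to
    the probability that a participant in that stratum is latently
    tau-abnormal. SUVR units are dimensionless ratios.
    """

    group_sizes: Mapping[tuple[str, str, str], int]
    regions: tuple[RegionSpec, ...] = DEFAULT_REGIONS
    normal_component: tuple[float, float] = (1.10, 0.07)    # (mu0, sigma0)
    abnormal_component: tuple[float, float] = (1.50, 0.10)  # (mu1, sigma1)
    abnormal_prevalence: Mapping[tuple[str, str], float] = field(default_factory=dict)
    amyloid_distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"negative": (0.98, 0.04), "positive": (1.35, 0.20)}
    )
    median_noise_sd: float = 0.02
    region_jitter_sd: float = 0.03
    region_shift_scale: Mapping[str, float] = field(default_factory=dict)
    group_separation_scale: Mapping[str, float] = field(default_factory=dict)
    age_by_diagnosis: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_AGE_BY_DX)
    )
    female_fraction_by_diagnosis: Mapping[str, float] = field(
        default_factory=lambda: dict(_FEMALE_FRAC_BY_DX)
    )
    education_by_group: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_EDU_BY_GROUP)
    )
    amyloid_threshold: float = AMYLOID_POSITIVITY_THRESHOLD
    seed: int = 0

    def validate(self) -> None:
        mu0, s0 = self.normal_component
        mu1, s1 = self.abnormal_component
        if mu1 <= mu0:
            raise ValueError(f"abnormal mean {mu1} must exceed normal mean {mu0}")
        for name, s in (("sigma0", s0), ("sigma1", s1),
                        ("median_noise_sd", self.median_noise_sd),
                        ("region_jitter_sd", self.region_jitter_sd)):
            if s < 0 or (name in ("sigma0", "sigma1") and s == 0):
                raise ValueError(f"{name} must be positive, got {s}")
        for key, p in self.abnormal_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {key} must lie in [0, 1], got {p}")
        for key, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group size for {key} must be >= 0, got {n}")
        for status, (mu, sd) in self.amyloid_distributions.items():
            if sd <= 0:
                raise ValueError(f"amyloid sd for {status!r} must be positive")


@dataclass
class GroundTruth:
    """Latent per-participant tau states plus the config that produced them."""

    frame: pd.DataFrame  # participant_id, diagnosis, amyloid, ethnoracial_group, latent_state
    config: GeneratorConfig

    def abnormal_fraction(self, diagnosis: str, amyloid: str) -> float:
        sel = self.frame[
            (self.frame["diagnosis"] == diagnosis) & (self.frame["amyloid"] == amyloid)
        ]
        if sel.empty:
            raise ValueError(f"no participants in stratum ({diagnosis}, {amyloid})")
        return float((sel["latent_state"] == "abnormal").mean())


def _truncnorm_rvs(rng, mu, sd, low, high, size):
    a = (low - mu) / sd
    b = (high - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def generate(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a synthetic cohort and its latent ground truth from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mu0, s0 = config.normal_component
    mu1, s1 = config.abnormal_component
    eps = 1e-9  # keep amyloid draws strictly on their side of the threshold
    thr = config.amyloid_threshold

    rows: list[dict] = []
    truth_rows: list[dict] = []
    pid = 0
    # Deterministic stratum order: sorted keys.
    for (dx, amy, group) in sorted(config.group_sizes):
        n = int(config.group_sizes[(dx, amy, group)])
        if n == 0:
            continue
        prevalence = float(config.abnormal_prevalence.get((dx, amy), 0.0))
        sep = float(config.group_separation_scale.get(group, 1.0))
        amu, asd = config.amyloid_distributions[amy]
        if amy == "negative":
            amyloid_draws = _truncnorm_rvs(rng, amu, asd, 1e-6, thr - eps, n)
        else:
            amyloid_draws = _truncnorm_rvs(rng, amu, asd, thr, np.inf, n)
        abnormal = rng.random(n) < prevalence
        zeta = rng.standard_normal(n)  # shared latent level across regions
        age_mu, age_sd = config.age_by_diagnosis[dx]
        ages = np.clip(rng.normal(age_mu, age_sd, n), 0.0, 120.0)
        female = rng.random(n) < config.female_fraction_by_diagnosis[dx]
        edu_mu, edu_sd = config.education_by_group[group]
        education = np.clip(rng.normal(edu_mu, edu_sd, n), 0.0, None)
        for i in range(n):
            pid += 1
            row = {
                "participant_id": f"S{pid:06d}",
                "diagnosis": dx,
                "ethnoracial_group": group,
                "age": round(float(ages[i]), 2),
                "sex": "F" if female[i] else "M",
                "education": round(float(education[i]), 1),
                "global_amyloid_suvr": float(amyloid_draws[i]),
            }
            rows.append(row)
            truth_rows.append(
                {
                    "participant_id": row["participant_id"],
                    "diagnosis": dx,
                    "amyloid": amy,
                    "ethnoracial_group": group,
                    "latent_state": "abnormal" if abnormal[i] else "normal",
                }
            )
            for spec in config.regions:
                if abnormal[i]:
                    shift = (mu1 - mu0) * sep * float(
                        config.region_shift_scale.get(spec.name, 1.0)
                    )
                    center = mu0 + shift + s1 * zeta[i]
                else:
                    center = mu0 + s0 * zeta[i]
                suvr_mean = center + rng.normal(0.0, config.region_jitter_sd)
                suvr_mean = max(suvr_mean, 1e-3)
                suvr_median = max(suvr_mean + rng.normal(0.0, config.median_noise_sd), 1e-3)
                cv = spec.volume_sd / spec.mean_volume
                vol = float(
                    np.exp(rng.normal(np.log(spec.mean_volume) - 0.5 * cv**2, cv))
                )
                row[SUVR_MEAN_PREFIX + spec.name] = suvr_mean
                row[SUVR_MEDIAN_PREFIX + spec.name] = suvr_median
                row[VOLUME_PREFIX + spec.name] = vol

    df = pd.DataFrame(rows)
    cohort = Cohort(df, provenance="synthetic", seed=config.seed)
    truth = GroundTruth(frame=pd.DataFrame(truth_rows), config=config)
    return cohort, truth


def default_habs_like_config(seed: int = 0) -> GeneratorConfig:
    """Default amyloid-stratified cohort: 675 participants.

    Cell counts reproduce the study-like composition: 599 amyloid-negative
    CU, 48 amyloid-positive MCI, and 28 amyloid-positive AD, cross-classified
    by ethnoracial group (186 Hispanic / 209 non-Hispanic Black / 280
    non-Hispanic White in total). Latent abnormal-tau prevalences rise with
    severity (0.05 / 0.70 / 0.80); these are the latent rates obtained by
    inverting typical observed tau-positivity (roughly two thirds of
    amyloid-positive MCI and three quarters of amyloid-positive dementia
    classified positive at a medial-temporal cut-point near 1.26) through the
    mixture's classification error, so the generated cohort reproduces
    operating characteristics of that magnitude rather than the raw rates.
    """
    group_sizes = {
        ("CU", "negative", "Hispanic"): 167,
        ("CU", "negative", "NHB"): 183,
        ("CU", "negative", "NHW"): 249,
        ("MCI", "positive", "Hispanic"): 12,
        ("MCI", "positive", "NHB"): 17,
        ("MCI", "positive", "NHW"): 19,
        ("AD", "positive", "Hispanic"): 7,
        ("AD", "positive", "NHB"): 9,
        ("AD", "positive", "NHW"): 12,
    }
    prevalence = {
        ("CU", "negative"): 0.05,
        ("MCI", "positive"): 0.70,
        ("AD", "positive"): 0.80,
    }
    return GeneratorConfig(
        group_sizes=group_sizes, abnormal_prevalence=prevalence, seed=int(seed)
    )


def default_full_spectrum_config(seed: int = 0) -> GeneratorConfig:
    """Full-spectrum cohort: 879 participants regardless of amyloid status.

    Adds to the amyloid-stratified cells 130 amyloid-positive CU, 72
    amyloid-negative MCI, and 2 amyloid-negative dementia participants,
    apportioned across ethnoracial groups so that dementia is almost entirely
    amyloid positive while MCI is mixed — the composition under which
    continuous amyloid discriminates CU from dementia better than tau does.
    """
    base = default_habs_like_config(seed)
    sizes = dict(base.group_sizes)
    sizes.update(
        {
            ("CU", "positive", "Hispanic"): 27,
            ("CU", "positive", "NHB"): 30,
            ("CU", "positive", "NHW"): 73,
            ("MCI", "negative", "Hispanic"): 32,
            ("MCI", "negative", "NHB"): 19,
            ("MCI", "negative", "NHW"): 21,
            ("AD", "negative", "Hispanic"): 1,
            ("AD", "negative", "NHW"): 1,
        }
    )
    prevalence = dict(base.abnormal_prevalence)
    prevalence.update(
        {
            ("CU", "positive"): 0.25,
            ("MCI", "negative"): 0.10,
            ("AD", "negative"): 0.50,
        }
    )
    base.group_sizes = sizes
    base.abnormal_prevalence = prevalence
    return base
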