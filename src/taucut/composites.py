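"""Composite ROIs, region-diagnosis correlation ranking, and mean/median QC.

A composite ROI combines several FreeSurfer-style regions into one SUVR by a
volume-weighted average: sum_r(vol_r * suvr_r) / sum_r(vol_r), using each
participant's own region volumes. Two composites are built in:

* ``temporal_composite`` — entorhinal, fusiform, inferior temporal, middle
  temporal, parahippocampal, amygdala, hippocampus.
* ``mtl_composite`` — the medial temporal lobe subset (entorhinal,
  parahippocampal, amygdala), the regions most positively correlated with
  diagnostic severity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    Cohort,
    ParticipantRecord,
    SUVR_MEAN_PREFIX,
    SUVR_MEDIAN_PREFIX,
    VOLUME_PREFIX,
)

__all__ = [
    "CompositeDefinition",
    "RegionDiagnosisCorrelation",
    "TEMPORAL_COMPOSITE",
    "MTL_COMPOSITE",
    "BUILTIN_COMPOSITES",
    "ORDINAL_DIAGNOSIS_CODING",
    "BINARY_DIAGNOSIS_CODING",
    "MissingRegionError",
    "UndefinedCorrelationError",
    "composite_suvr",
    "composite_series",
    "roi_scores",
    "correlate_region_with_diagnosis",
    "rank_regions",
    "mean_median_qc",
    "merge_bilateral",
]


class MissingRegionError(KeyError):
    """A composite references a region absent from the record/cohort."""


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: one of the variables is constant."""


@dataclass(frozen=True)
class CompositeDefinition:
    """A named set of regions combined into one SUVR.

    ``weighting='volume'`` weights each region by the participant's own
    region volume; ``'equal'`` takes the plain arithmetic mean.
    """

    name: str
    regions: tuple[str, ...]
    weighting: str = "volume"

    def __post_init__(self):
        if not self.regions:
            raise ValueError("a composite needs at least one region")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError(f"composite {self.name!r} lists a region twice")
        if self.weighting not in ("volume", "equal"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


TEMPORAL_COMPOSITE = CompositeDefinition(
    "temporal_composite",
    (
        "entorhinal",
        "fusiform",
        "inferior_temporal",
        "middle_temporal",
        "parahippocampal",
        "amygdala",
        "hippocampus",
    ),
)

MTL_COMPOSITE = CompositeDefinition(
    "mtl_composite", ("entorhinal", "parahippocampal", "amygdala")
)

BUILTIN_COMPOSITES: dict[str, CompositeDefinition] = {
    c.name: c for c in (TEMPORAL_COMPOSITE, MTL_COMPOSITE)
}

#: Ordinal severity coding CU=0, MCI=1, AD=2 (default for region ranking).
ORDINAL_DIAGNOSIS_CODING: Mapping[str, float] = {"CU": 0.0, "MCI": 1.0, "AD": 2.0}
#: Binary CU-vs-impaired coding (point-biserial correlation).
BINARY_DIAGNOSIS_CODING: Mapping[str, float] = {"CU": 0.0, "MCI": 1.0, "AD": 1.0}


def composite_suvr(record: ParticipantRecord, definition: CompositeDefinition) -> float:
    """Composite SUVR for one participant.

    Volume weighting uses the participant's own region volumes. The result
    always lies within [min, max] of the member-region SUVRs.
    """
    suvrs, vols = [], []
    for region in definition.regions:
        if region not in record.regional_suvr_mean:
            raise MissingRegionError(f"region {region!r} missing from record {record.id}")
        suvrs.append(record.regional_suvr_mean[region])
        if definition.weighting == "volume":
            if region not in record.regional_volume:
                raise MissingRegionError(f"volume for region {region!r} missing from record {record.id}")
            vols.append(record.regional_volume[region])
    suvrs = np.asarray(suvrs, float)
    if definition.weighting == "equal":
        return float(suvrs.mean())
    vols = np.asarray(vols, float)
    total = vols.sum()
    if total <= 0:
        raise ValueError(f"total volume for composite {definition.name!r} is not positive")
    return float((vols * suvrs).sum() / total)


def composite_series(cohort: Cohort, definition: CompositeDefinition) -> np.ndarray:
    """Vectorised composite SUVR across a cohort (one value per participant)."""
    available = set(cohort.regions)
    missing = [r for r in definition.regions if r not in available]
    if missing:
        raise MissingRegionError(
            f"composite {definition.name!r} needs region(s) {missing} absent from cohort"
        )
    suvr = np.column_stack([cohort.suvr_mean(r) for r in definition.regions])
    if definition.weighting == "equal":
        return suvr.mean(axis=1)
    vol = np.column_stack([cohort.volume(r) for r in definition.regions])
    total = vol.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError(f"non-positive total volume in composite {definition.name!r}")
    return (vol * suvr).sum(axis=1) / total


def roi_scores(
    cohort: Cohort,
    roi: str | CompositeDefinition,
    composites: Mapping[str, CompositeDefinition] | None = None,
) -> np.ndarray:
    """Resolve an ROI name to per-participant scores.

    ``roi`` may be a :class:`CompositeDefinition`, the name of a built-in or
    user-supplied composite, or a plain region name.
    """
    if isinstance(roi, CompositeDefinition):
        return composite_series(cohort, roi)
    registry = dict(BUILTIN_COMPOSITES)
    if composites:
        registry.update(composites)
    if roi in registry:
        return composite_series(cohort, registry[roi])
    if roi in cohort.regions:
        return cohort.suvr_mean(roi)
    raise MissingRegionError(f"ROI {roi!r} is neither a known composite nor a cohort region")


@dataclass(frozen=True)
class RegionDiagnosisCorrelation:
    region: str
    r: float
    n: int


def correlate_region_with_diagnosis(
    cohort: Cohort,
    region: str,
    coding: Mapping[str, float] = ORDINAL_DIAGNOSIS_CODING,
    method: str = "pearson",
) -> RegionDiagnosisCorrelation:
    """Correlation between a region's SUVR and numerically coded diagnosis.

    Pearson by default (for a binary coding this is the point-biserial
    correlation); ``method='spearman'`` available.
    """
    suvr = roi_scores(cohort, region)
    dx = cohort.df["diagnosis"].map(coding).to_numpy(float)
    if np.any(np.isnan(dx)):
        raise ValueError("diagnosis coding does not cover all labels present")
    if len(suvr) < 3:
        raise ValueError("need at least 3 participants for a correlation")
    if np.ptp(suvr) == 0 or np.ptp(dx) == 0:
        raise UndefinedCorrelationError(
            f"correlation undefined for region {region!r}: constant variable"
        )
    if method == "pearson":
        r = stats.pearsonr(suvr, dx).statistic
    elif method == "spearman":
        r = stats.spearmanr(suvr, dx).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return RegionDiagnosisCorrelation(region=str(region), r=float(r), n=len(suvr))


def rank_regions(
    cohort: Cohort,
    regions: Sequence[str] | None = None,
    coding: Mapping[str, float] = ORDINAL_DIAGNOSIS_CODING,
    method: str = "pearson",
) -> list[RegionDiagnosisCorrelation]:
    """Rank regions by correlation with diagnosis, descending.

    Ties (to float equality) break alphabetically by region name.
    """
    regions = list(regions) if regions is not None else cohort.regions
    results = [
        correlate_region_with_diagnosis(cohort, r, coding=coding, method=method)
        for r in regions
    ]
    return sorted(results, key=lambda c: (-c.r, c.region))


def mean_median_qc(
    cohort: Cohort,
    regions: Sequence[str] | None = None,
    flag_below: float = 0.96,
) -> pd.DataFrame:
    """Per-region Pearson r between mean and median SUVR across participants.

    Mean SUVRs can be inflated by off-target signal (meninges, venous
    sinuses); medians are robust to it, so a low mean/median correlation
    flags a region whose mean may be contaminated. Returns a DataFrame with
    columns ``region``, ``r``, ``flagged`` (r < ``flag_below``).

    Raises if the cohort carries no median SUVRs — an absent QC input is an
    explicit not-available condition, never a silent pass.
    """
    if not cohort.has_median_suvr:
        raise ValueError("cohort has no median SUVR columns; mean/median QC not available")
    regions = list(regions) if regions is not None else cohort.regions
    rows = []
    for region in regions:
        med = cohort.suvr_median(region)
        if med is None:
            raise ValueError(f"region {region!r} has no median SUVR column")
        mean = cohort.suvr_mean(region)
        if np.ptp(mean) == 0 or np.ptp(med) == 0:
            raise UndefinedCorrelationError(f"constant SUVRs in region {region!r}")
        r = float(stats.pearsonr(mean, med).statistic)
        rows.append({"region": region, "r": r, "flagged": r < flag_below})
    return pd.DataFrame(rows)


def merge_bilateral(df: pd.DataFrame) -> pd.DataFrame:
    """Merge ``lh_``/``rh_`` region column pairs by volume weighting.

    For every region appearing as both ``suvr_mean__lh_<r>`` and
    ``suvr_mean__rh_<r>`` (with matching ``vol__`` columns), emits merged
    ``suvr_mean__<r>`` = volume-weighted average and ``vol__<r>`` = summed
    volume, dropping the hemispheric columns. Non-paired columns pass through.
    """
    out = df.copy()
    lh = {
        c[len(SUVR_MEAN_PREFIX) + 3:]
        for c in df.columns
        if c.startswith(SUVR_MEAN_PREFIX + "lh_")
    }
    rh = {
        c[len(SUVR_MEAN_PREFIX) + 3:]
        for c in df.columns
        if c.startswith(SUVR_MEAN_PREFIX + "rh_")
    }
    for region in sorted(lh & rh):
        cols = {}
        for side in ("lh_", "rh_"):
            cols[side] = (
                SUVR_MEAN_PREFIX + side + region,
                VOLUME_PREFIX + side + region,
            )
            if cols[side][1] not in df.columns:
                raise MissingRegionError(f"missing volume column {cols[side][1]!r}")
        vl = df[cols["lh_"][1]].to_numpy(float)
        vr = df[cols["rh_"][1]].to_numpy(float)
        sl = df[cols["lh_"][0]].to_numpy(float)
        sr = df[cols["rh_"][0]].to_numpy(float)
        out[SUVR_MEAN_PREFIX + region] = (vl * sl + vr * sr) / (vl + vr)
        out[VOLUME_PREFIX + region] = vl + vr
        out = out.drop(columns=[cols["lh_"][0], cols["lh_"][1], cols["rh_"][0], cols["rh_"][1]])
    return out
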