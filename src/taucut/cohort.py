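"""Cohort data model, I/O, amyloid classification, and Centiloid conversion.

The cohort is a participant-level wide table: one row per participant with
identifiers, cognitive diagnosis (CU / MCI / AD), self-identified ethnoracial
group, demographics, a global amyloid-PET SUVR, and per-region tau-PET SUVRs
and volumes stored in three column families::

    suvr_mean__<region>     mean tau SUVR in <region> (required per region)
    suvr_median__<region>   median tau SUVR (optional, for off-target QC)
    vol__<region>           region volume in mm^3 (required per region)

SUVR = standardized uptake value ratio, tracer uptake in a target region
divided by a reference region (inferior cerebellar gray matter for tau,
whole cerebellum for amyloid). Amyloid positivity uses a global SUVR
threshold of 1.08 (inclusive), and Centiloids are the standard linear
rescaling of the florbetaben global SUVR.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Diagnosis",
    "EthnoracialGroup",
    "Sex",
    "AmyloidStatus",
    "ParticipantRecord",
    "Cohort",
    "SchemaError",
    "ValidationError",
    "SpecificationError",
    "AMYLOID_POSITIVITY_THRESHOLD",
    "classify_amyloid",
    "centiloid",
    "read_cohort",
    "write_cohort",
    "stratify",
    "select_contrast",
    "BUILTIN_RULES",
    "SUVR_MEAN_PREFIX",
    "SUVR_MEDIAN_PREFIX",
    "VOLUME_PREFIX",
    "CORE_COLUMNS",
]


class Diagnosis(str, enum.Enum):
    """Consensus cognitive diagnosis."""

    CU = "CU"   #: cognitively unimpaired
    MCI = "MCI"  #: mild cognitive impairment
    AD = "AD"   #: Alzheimer's-type dementia


class EthnoracialGroup(str, enum.Enum):
    """Self-identified ethnoracial group."""

    Hispanic = "Hispanic"
    NHB = "NHB"   #: non-Hispanic Black
    NHW = "NHW"   #: non-Hispanic White
    other = "other"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


#: Global amyloid SUVR at or above which a participant is amyloid positive.
AMYLOID_POSITIVITY_THRESHOLD = 1.08

# Centiloid linear map for florbetaben global SUVR (ADNI3-style processing).
_CENTILOID_SLOPE = 159.08
_CENTILOID_INTERCEPT = -151.65

SUVR_MEAN_PREFIX = "suvr_mean__"
SUVR_MEDIAN_PREFIX = "suvr_median__"
VOLUME_PREFIX = "vol__"

#: Canonical non-region columns of the cohort table, in storage order.
CORE_COLUMNS = (
    "participant_id",
    "diagnosis",
    "ethnoracial_group",
    "age",
    "sex",
    "education",
    "global_amyloid_suvr",
)

_IMPAIRED = frozenset({Diagnosis.MCI.value, Diagnosis.AD.value})


class SchemaError(ValueError):
    """A required column is missing or cannot be mapped."""


class ValidationError(ValueError):
    """The table violates a cohort invariant (duplicate ids, bad labels ...)."""


class SpecificationError(ValueError):
    """A stratification rule references an unknown field or cannot be parsed."""


@dataclass(frozen=True)
class AmyloidStatus:
    """Dichotomised amyloid status together with the threshold that produced it."""

    status: str  # "positive" | "negative"
    threshold_used: float

    @property
    def positive(self) -> bool:
        return self.status == "positive"


def classify_amyloid(
    global_amyloid_suvr: float, threshold: float = AMYLOID_POSITIVITY_THRESHOLD
) -> AmyloidStatus:
    """Classify a global amyloid SUVR as positive/negative.

    The threshold is inclusive: a SUVR exactly at the threshold is positive.

    Parameters
    ----------
    global_amyloid_suvr
        Global amyloid SUVR (dimensionless, must be > 0).
    threshold
        Positivity threshold, default 1.08.
    """
    if not np.isfinite(global_amyloid_suvr) or global_amyloid_suvr <= 0:
        raise ValueError(f"global amyloid SUVR must be positive, got {global_amyloid_suvr!r}")
    status = "positive" if global_amyloid_suvr >= threshold else "negative"
    return AmyloidStatus(status=status, threshold_used=float(threshold))


def centiloid(suvr_fbb):
    """Convert a florbetaben global SUVR to the Centiloid scale.

    CL = 159.08 * SUVR - 151.65, the linear anchor mapping the amyloid SUVR
    onto the common 0-100 Centiloid scale. Accepts scalars or arrays.
    """
    arr = np.asarray(suvr_fbb, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("SUVR values must be positive and finite")
    out = _CENTILOID_SLOPE * arr + _CENTILOID_INTERCEPT
    return float(out) if np.isscalar(suvr_fbb) or arr.ndim == 0 else out


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: identifiers, diagnosis, demographics, and regional data."""

    id: str
    diagnosis: Diagnosis
    ethnoracial_group: EthnoracialGroup
    age: float
    sex: Sex
    education: float
    global_amyloid_suvr: float
    regional_suvr_mean: Mapping[str, float]
    regional_volume: Mapping[str, float]
    regional_suvr_median: Mapping[str, float] | None = None

    def amyloid_status(self, threshold: float = AMYLOID_POSITIVITY_THRESHOLD) -> AmyloidStatus:
        return classify_amyloid(self.global_amyloid_suvr, threshold)


class Cohort:
    """An ordered participant-level cohort table.

    Thin wrapper over a :class:`pandas.DataFrame` in the canonical wide
    format; validates invariants on construction (unique ids, recognised
    diagnosis / sex / group labels, positive SUVRs and volumes, ages in
    [0, 120], volume columns present for every mean-SUVR region).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        provenance: str = "file",
        seed: int | None = None,
        validate: bool = True,
    ):
        self._df = df.reset_index(drop=True)
        self.provenance = provenance
        self.seed = seed
        if validate:
            self._validate()

    # -- container basics -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def regions(self) -> list[str]:
        """Region names present (from the ``suvr_mean__`` column family), sorted."""
        return sorted(
            c[len(SUVR_MEAN_PREFIX):] for c in self._df.columns if c.startswith(SUVR_MEAN_PREFIX)
        )

    @property
    def has_median_suvr(self) -> bool:
        return any(c.startswith(SUVR_MEDIAN_PREFIX) for c in self._df.columns)

    def suvr_mean(self, region: str) -> np.ndarray:
        col = SUVR_MEAN_PREFIX + region
        if col not in self._df.columns:
            raise KeyError(f"region {region!r} has no mean-SUVR column")
        return self._df[col].to_numpy(float)

    def suvr_median(self, region: str) -> np.ndarray | None:
        col = SUVR_MEDIAN_PREFIX + region
        if col not in self._df.columns:
            return None
        return self._df[col].to_numpy(float)

    def volume(self, region: str) -> np.ndarray:
        col = VOLUME_PREFIX + region
        if col not in self._df.columns:
            raise KeyError(f"region {region!r} has no volume column")
        return self._df[col].to_numpy(float)

    def amyloid_status(self, threshold: float = AMYLOID_POSITIVITY_THRESHOLD) -> pd.Series:
        """Per-participant 'positive'/'negative' amyloid status (threshold inclusive)."""
        suvr = self._df["global_amyloid_suvr"]
        return pd.Series(
            np.where(suvr >= threshold, "positive", "negative"),
            index=self._df.index,
            name="amyloid",
        )

    def impaired(self) -> np.ndarray:
        """Boolean array: diagnosis is MCI or AD (CI = cognitively impaired)."""
        return self._df["diagnosis"].isin(_IMPAIRED).to_numpy()

    # -- record view -------------------------------------------------------
    def iter_records(self) -> Iterator[ParticipantRecord]:
        regions = self.regions
        has_median = self.has_median_suvr
        for _, row in self._df.iterrows():
            median = None
            if has_median:
                median = {
                    r: float(row[SUVR_MEDIAN_PREFIX + r])
                    for r in regions
                    if SUVR_MEDIAN_PREFIX + r in row.index
                }
            yield ParticipantRecord(
                id=str(row["participant_id"]),
                diagnosis=Diagnosis(row["diagnosis"]),
                ethnoracial_group=EthnoracialGroup(row["ethnoracial_group"]),
                age=float(row["age"]),
                sex=Sex(row["sex"]),
                education=float(row["education"]),
                global_amyloid_suvr=float(row["global_amyloid_suvr"]),
                regional_suvr_mean={r: float(row[SUVR_MEAN_PREFIX + r]) for r in regions},
                regional_volume={r: float(row[VOLUME_PREFIX + r]) for r in regions},
                regional_suvr_median=median,
            )

    def subset(self, mask) -> "Cohort":
        sub = Cohort(self._df.loc[np.asarray(mask)], provenance=self.provenance,
                     seed=self.seed, validate=False)
        return sub

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        df = self._df
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if df["participant_id"].duplicated().any():
            dups = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
            raise ValidationError(f"duplicate participant id(s): {dups[:5]}")
        bad_dx = set(df["diagnosis"]) - {d.value for d in Diagnosis}
        if bad_dx:
            raise ValidationError(
                f"unrecognised diagnosis label(s) {sorted(bad_dx)}; expected CU/MCI/AD"
            )
        bad_grp = set(df["ethnoracial_group"]) - {g.value for g in EthnoracialGroup}
        if bad_grp:
            raise ValidationError(f"unrecognised ethnoracial group label(s) {sorted(bad_grp)}")
        bad_sex = set(df["sex"]) - {s.value for s in Sex}
        if bad_sex:
            raise ValidationError(f"unrecognised sex label(s) {sorted(bad_sex)}")
        ages = df["age"].to_numpy(float)
        if np.any(~np.isfinite(ages)) or np.any(ages < 0) or np.any(ages > 120):
            raise ValidationError("ages must be finite and within [0, 120]")
        amy = df["global_amyloid_suvr"].to_numpy(float)
        if np.any(~np.isfinite(amy)) or np.any(amy <= 0):
            raise ValidationError("global amyloid SUVRs must be positive")
        for region in self.regions:
            vcol = VOLUME_PREFIX + region
            if vcol not in df.columns:
                raise SchemaError(f"region {region!r} has SUVR but no volume column {vcol!r}")
            for col in (SUVR_MEAN_PREFIX + region, vcol):
                vals = df[col].to_numpy(float)
                if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
                    raise ValidationError(f"column {col!r} must be strictly positive")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> Cohort:
    """Read a cohort CSV, optionally remapping core column names.

    Parameters
    ----------
    path
        CSV with a header row; UTF-8.
    schema
        Optional mapping ``canonical_name -> column_name_in_file`` for the
        core columns (see :data:`CORE_COLUMNS`). Region column families must
        follow the ``suvr_mean__`` / ``suvr_median__`` / ``vol__`` prefix
        convention.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if schema:
        rename = {}
        for canonical, actual in schema.items():
            if canonical not in CORE_COLUMNS:
                raise SchemaError(f"schema maps unknown canonical column {canonical!r}")
            if actual not in df.columns:
                raise SchemaError(f"schema column {actual!r} (for {canonical!r}) not in file")
            rename[actual] = canonical
        df = df.rename(columns=rename)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df["participant_id"] = df["participant_id"].astype(str)
    return Cohort(df, provenance="file")


def write_cohort(cohort: Cohort, path: str | Path, sidecar: bool = True) -> Path:
    """Write the cohort to CSV, with a JSON provenance sidecar by default."""
    path = Path(path)
    cohort.df.to_csv(path, index=False)
    if sidecar:
        meta = {"provenance": cohort.provenance, "seed": cohort.seed,
                "n": cohort.n, "regions": cohort.regions}
        path.with_suffix(".provenance.json").write_text(json.dumps(meta, indent=2))
    return path


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

def _rule_cu_abneg(df: pd.DataFrame, amyloid: pd.Series) -> pd.Series:
    return (df["diagnosis"] == "CU") & (amyloid == "negative")


def _rule_ci_abpos(df: pd.DataFrame, amyloid: pd.Series) -> pd.Series:
    return df["diagnosis"].isin(_IMPAIRED) & (amyloid == "positive")


def _rule_primary(df: pd.DataFrame, amyloid: pd.Series) -> pd.Series:
    return _rule_cu_abneg(df, amyloid) | _rule_ci_abpos(df, amyloid)


#: Named built-in stratification rules. "primary" is the amyloid-stratified
#: analysis set: amyloid-negative CU plus amyloid-positive CI participants.
BUILTIN_RULES: dict[str, Callable[[pd.DataFrame, pd.Series], pd.Series]] = {
    "cu_amyloid_negative": _rule_cu_abneg,
    "ci_amyloid_positive": _rule_ci_abpos,
    "primary": _rule_primary,
}


def stratify(
    cohort: Cohort,
    rule,
    threshold: float = AMYLOID_POSITIVITY_THRESHOLD,
) -> Cohort:
    """Return the sub-cohort satisfying a stratification rule.

    ``rule`` may be the name of a built-in rule (:data:`BUILTIN_RULES`), a
    pandas-eval expression over the cohort columns plus a derived ``amyloid``
    column ('positive'/'negative'), or a callable mapping the augmented
    DataFrame to a boolean mask. Complement counts are logged.
    """
    df = cohort.df
    amyloid = cohort.amyloid_status(threshold)
    if callable(rule):
        mask = np.asarray(rule(df.assign(amyloid=amyloid.to_numpy())), dtype=bool)
    elif isinstance(rule, str) and rule in BUILTIN_RULES:
        mask = BUILTIN_RULES[rule](df, amyloid).to_numpy()
    elif isinstance(rule, str):
        try:
            mask = df.assign(amyloid=amyloid.to_numpy()).eval(rule)
        except Exception as exc:  # unknown columns, syntax errors
            raise SpecificationError(f"cannot evaluate stratification rule {rule!r}: {exc}") from exc
        mask = np.asarray(mask, dtype=bool)
    else:
        raise SpecificationError(f"unsupported rule type: {type(rule).__name__}")
    n_in = int(mask.sum())
    logger.info("stratify: %d selected, %d in complement", n_in, cohort.n - n_in)
    return cohort.subset(mask)


def select_contrast(
    cohort: Cohort,
    contrast: str,
    amyloid_stratified: bool = True,
    threshold: float = AMYLOID_POSITIVITY_THRESHOLD,
) -> tuple[Cohort, np.ndarray]:
    """Select the participants for a diagnostic contrast and label them.

    Contrasts: ``cu-vs-mci``, ``cu-vs-ad`` (alias ``cu-vs-dementia``),
    ``cu-vs-ci``. Controls are CU participants and cases the impaired group
    named by the contrast. With ``amyloid_stratified`` (the primary analysis),
    controls must be amyloid negative and cases amyloid positive; without it
    the full spectrum of participants enters regardless of amyloid status.

    Returns the selected sub-cohort and a boolean label array (True = case).
    """
    key = contrast.lower().replace("_", "-")
    case_dx = {
        "cu-vs-mci": {"MCI"},
        "cu-vs-ad": {"AD"},
        "cu-vs-dementia": {"AD"},
        "cu-vs-ci": _IMPAIRED,
    }.get(key)
    if case_dx is None:
        raise SpecificationError(f"unknown contrast {contrast!r}")
    df = cohort.df
    is_cu = (df["diagnosis"] == "CU").to_numpy()
    is_case = df["diagnosis"].isin(case_dx).to_numpy()
    if amyloid_stratified:
        positive = (cohort.amyloid_status(threshold) == "positive").to_numpy()
        is_cu &= ~positive
        is_case &= positive
    keep = is_cu | is_case
    sub = cohort.subset(keep)
    labels = is_case[keep]
    return sub, labels
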