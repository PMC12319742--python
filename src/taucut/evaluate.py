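"""Cut-point application, subgroup evaluation, full-spectrum comparison,
descriptive tables, and deterministic report rendering.

Applying a cut-point uses strict "greater than" tau positivity: a case is a
true positive when its ROI SUVR exceeds the cut-point. Cut-points derived by
the ROC machinery sit at midpoints between observed scores, so the strict
convention never disagrees with the ">=" convention used during derivation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, select_contrast
from .composites import CompositeDefinition, roi_scores
from .cutpoints import RocAnalysis, roc

logger = logging.getLogger(__name__)

__all__ = [
    "CutpointEvaluation",
    "ContrastComparison",
    "DescriptiveTable",
    "metrics_from_rates",
    "apply_cutpoint",
    "subgroup_evaluation",
    "full_spectrum_comparison",
    "descriptive_table",
    "dunn_posthoc",
    "render_metrics_table",
    "render_evaluations",
]


@dataclass(frozen=True)
class CutpointEvaluation:
    """Confusion counts and derived metrics for one fixed cut-point.

    Invariants: tp + fn == n_case, tn + fp == n_control, sens == tp/n_case,
    spec == tn/n_control, accuracy == (tp+tn)/n, youden == sens + spec - 1.
    ``flagged`` marks subgroups below the minimum per-class size.
    """

    cutpoint: float
    subgroup: str
    n_case: int
    n_control: int
    tp: int
    fp: int
    tn: int
    fn: int
    sens: float
    spec: float
    accuracy: float
    youden: float
    flagged: bool = False


def metrics_from_rates(
    sens: float, spec: float, n_case: int, n_control: int
) -> tuple[float, float]:
    """Youden index and accuracy implied by sensitivity, specificity and sizes.

    youden = sens + spec - 1;
    accuracy = (sens * n_case + spec * n_control) / (n_case + n_control).
    Useful for checking published tables whose Youden/accuracy rows are
    arithmetic consequences of the printed operating points.
    """
    youden = sens + spec - 1.0
    accuracy = (sens * n_case + spec * n_control) / (n_case + n_control)
    return float(youden), float(accuracy)


def _case_labels(cohort: Cohort, labels) -> np.ndarray:
    if labels is None:
        return cohort.impaired()
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != (cohort.n,):
        raise ValueError("labels must align with the cohort (one per participant)")
    return labels


def apply_cutpoint(
    cohort: Cohort,
    roi: str | CompositeDefinition,
    cutpoint: float,
    labels=None,
    subgroup: str = "all",
    positivity: str = ">",
    composites: Mapping[str, CompositeDefinition] | None = None,
    flagged: bool = False,
) -> CutpointEvaluation:
    """Classify a cohort at a fixed cut-point and tabulate the confusion.

    ``labels`` is a boolean case indicator aligned with the cohort; by
    default cases are the cognitively impaired (MCI or AD). ``positivity``
    selects the tau-positive convention: strict ``'>'`` (default) or
    ``'>='``; the two differ only when scores tie the cut-point exactly.
    """
    labels = _case_labels(cohort, labels)
    scores = np.asarray(roi_scores(cohort, roi, composites=composites), float)
    if positivity == ">":
        predicted = scores > cutpoint
    elif positivity == ">=":
        predicted = scores >= cutpoint
    else:
        raise ValueError(f"positivity must be '>' or '>=', got {positivity!r}")
    n_case = int(labels.sum())
    n_control = int((~labels).sum())
    if n_case == 0:
        raise ValueError(f"no cases in stratum {subgroup!r}")
    if n_control == 0:
        raise ValueError(f"no controls in stratum {subgroup!r}")
    tp = int((predicted & labels).sum())
    fn = n_case - tp
    fp = int((predicted & ~labels).sum())
    tn = n_control - fp
    sens = tp / n_case
    spec = tn / n_control
    return CutpointEvaluation(
        cutpoint=float(cutpoint),
        subgroup=subgroup,
        n_case=n_case,
        n_control=n_control,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sens=sens,
        spec=spec,
        accuracy=(tp + tn) / (n_case + n_control),
        youden=sens + spec - 1.0,
        flagged=flagged,
    )


def subgroup_evaluation(
    cohort: Cohort,
    roi: str | CompositeDefinition,
    cutpoint: float,
    by: str,
    labels=None,
    min_per_class: int = 5,
    composites: Mapping[str, CompositeDefinition] | None = None,
) -> list[CutpointEvaluation]:
    """Evaluate a pooled cut-point within each level of a grouping column.

    Returns the whole-cohort evaluation (subgroup "all") followed by one
    evaluation per level of ``by`` (sorted). Levels with fewer than
    ``min_per_class`` cases or controls are flagged, not dropped — small
    subgroups are informative but fragile.
    """
    if by not in cohort.df.columns:
        raise KeyError(f"grouping column {by!r} not in cohort")
    labels = _case_labels(cohort, labels)
    out = [
        apply_cutpoint(cohort, roi, cutpoint, labels=labels, subgroup="all",
                       composites=composites)
    ]
    values = cohort.df[by]
    for level in sorted(values.unique()):
        mask = (values == level).to_numpy()
        sub = cohort.subset(mask)
        sub_labels = labels[mask]
        ev = apply_cutpoint(sub, roi, cutpoint, labels=sub_labels,
                            subgroup=str(level), composites=composites)
        small = ev.n_case < min_per_class or ev.n_control < min_per_class
        if small:
            logger.warning("subgroup %r has <%d cases or controls", level, min_per_class)
            ev = CutpointEvaluation(**{**ev.__dict__, "flagged": True})
        out.append(ev)
    return out


@dataclass(frozen=True)
class ContrastComparison:
    """Tau vs continuous-amyloid ROC results for one diagnostic contrast."""

    contrast: str
    tau: RocAnalysis
    amyloid: RocAnalysis

    @property
    def winner(self) -> str:
        if self.tau.youden > self.amyloid.youden:
            return "tau"
        if self.amyloid.youden > self.tau.youden:
            return "amyloid"
        return "tie"


def full_spectrum_comparison(
    cohort: Cohort,
    roi: str | CompositeDefinition,
    contrasts: Sequence[str] = ("cu-vs-mci", "cu-vs-dementia", "cu-vs-ci"),
    composites: Mapping[str, CompositeDefinition] | None = None,
) -> list[ContrastComparison]:
    """Compare the tau ROI against continuous global amyloid, full spectrum.

    Runs identical ROC machinery on the tau ROI SUVR and on the continuous
    global amyloid SUVR for each contrast, without amyloid stratification;
    the per-contrast winner is the predictor with the higher Youden index.
    """
    out = []
    for contrast in contrasts:
        sub, labels = select_contrast(cohort, contrast, amyloid_stratified=False)
        tau = roc(roi_scores(sub, roi, composites=composites), labels)
        amyloid = roc(sub.df["global_amyloid_suvr"].to_numpy(float), labels)
        out.append(ContrastComparison(contrast=contrast, tau=tau, amyloid=amyloid))
    return out


# ---------------------------------------------------------------------------
# Descriptive tables
# ---------------------------------------------------------------------------

@dataclass
class DescriptiveTable:
    """Per-variable per-group summaries with group-comparison tests."""

    frame: pd.DataFrame          # rows: variables; columns: group levels + p-value + test
    grouping: str
    n_missing: dict[str, int]
    dunn: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_tsv(self) -> str:
        return self.frame.to_csv(sep="\t", index=True)

    def to_markdown(self) -> str:
        return self.frame.to_markdown()


def dunn_posthoc(values: np.ndarray, groups: np.ndarray, adjust: str | None = None) -> pd.DataFrame:
    """Dunn's rank-based pairwise post-hoc test after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)) with
    the tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal
    p-values, optionally Bonferroni adjusted (``adjust='bonferroni'``).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    n_total = len(values)
    ranks = stats.rankdata(values)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    n_pairs = len(levels) * (len(levels) - 1) // 2
    for i, gi in enumerate(levels):
        for gj in levels[i + 1:]:
            ri = ranks[groups == gi]
            rj = ranks[groups == gj]
            se = np.sqrt(var_base * (1.0 / len(ri) + 1.0 / len(rj)))
            z = (ri.mean() - rj.mean()) / se
            p = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * n_pairs)
            rows.append({"group_a": gi, "group_b": gj, "z": float(z), "p": float(p)})
    return pd.DataFrame(rows)


def descriptive_table(
    cohort: Cohort,
    variables: Sequence[str],
    grouping: str,
    dunn: bool = False,
    dunn_adjust: str | None = None,
) -> DescriptiveTable:
    """Group-comparison summary table.

    Continuous variables: mean (SD) per group plus a Kruskal-Wallis p-value
    (Dunn pairwise tests on request). Categorical variables: count (percent)
    per level per group plus a chi-square p-value. Missing values are
    excluded per variable, with counts reported.
    """
    df = cohort.df
    if grouping not in df.columns:
        raise KeyError(f"grouping column {grouping!r} not in cohort")
    levels = sorted(df[grouping].unique().tolist())
    if len(levels) < 2:
        raise ValueError("grouping needs at least two levels")
    rows: dict[str, dict] = {}
    n_missing: dict[str, int] = {}
    dunn_results: dict[str, pd.DataFrame] = {}
    for var in variables:
        if var not in df.columns:
            raise KeyError(f"variable {var!r} not in cohort")
        col = df[var]
        miss = int(col.isna().sum())
        n_missing[var] = miss
        valid = df.loc[col.notna(), [var, grouping]]
        if valid.empty:
            rows[var] = {lvl: "NA" for lvl in levels} | {"p": np.nan, "test": "none (all missing)"}
            continue
        if pd.api.types.is_numeric_dtype(col):
            cells = {}
            samples = []
            for lvl in levels:
                x = valid.loc[valid[grouping] == lvl, var].to_numpy(float)
                samples.append(x)
                cells[lvl] = f"{x.mean():.2f} ({x.std(ddof=1):.2f})" if x.size else "NA"
            nonempty = [s for s in samples if s.size > 0]
            if len(nonempty) < 2:
                p = np.nan
            elif np.ptp(np.concatenate(nonempty)) == 0:
                p = 1.0  # kruskal rejects all-identical input; no evidence of difference
            else:
                p = float(stats.kruskal(*nonempty).pvalue)
            rows[var] = cells | {"p": p, "test": "Kruskal-Wallis"}
            if dunn and len(nonempty) >= 2 and np.isfinite(p):
                dunn_results[var] = dunn_posthoc(
                    valid[var].to_numpy(float), valid[grouping].to_numpy(), adjust=dunn_adjust
                )
        else:
            table = pd.crosstab(valid[var], valid[grouping])
            table = table.reindex(columns=levels, fill_value=0)
            if table.shape[0] < 2:
                p = np.nan
            else:
                p = float(stats.chi2_contingency(table.to_numpy()).pvalue)
            for cat in table.index:
                cells = {}
                for lvl in levels:
                    count = int(table.loc[cat, lvl])
                    total = int(table[lvl].sum())
                    pct = 100.0 * count / total if total else 0.0
                    cells[lvl] = f"{count} ({pct:.0f}%)"
                rows[f"{var}={cat}"] = cells | {
                    "p": p if cat == table.index[0] else np.nan,
                    "test": "chi-square" if cat == table.index[0] else "",
                }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "variable"
    return DescriptiveTable(frame=frame, grouping=grouping, n_missing=n_missing,
                            dunn=dunn_results)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_METRIC_ROWS = ("Optimal cut-point", "Youden", "Sensitivity", "Specificity", "Accuracy", "AUC")


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return "—"
    return f"{value:.2f}"


def render_metrics_table(columns: Mapping[str, Mapping[str, float | None]], fmt: str = "tsv") -> str:
    """Render a deterministic cut-point metrics table (2-decimal style).

    ``columns`` maps a column label (e.g. a contrast or subgroup) to a dict
    with any of the keys ``cutpoint``, ``youden``, ``sens``, ``spec``,
    ``accuracy``, ``auc``; missing entries render as an em dash. ``fmt`` is
    ``'tsv'`` or ``'markdown'``. Rendering is idempotent and byte-stable for
    identical inputs.
    """
    keys = {"Optimal cut-point": "cutpoint", "Youden": "youden", "Sensitivity": "sens",
            "Specificity": "spec", "Accuracy": "accuracy", "AUC": "auc"}
    header = ["metric"] + list(columns.keys())
    body = [[row] + [_fmt(columns[col].get(keys[row])) for col in columns] for row in _METRIC_ROWS]
    if fmt == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in body]
        return "\n".join(lines) + "\n"
    if fmt == "markdown":
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "|".join(["---"] * len(header)) + "|"]
        lines += ["| " + " | ".join(r) + " |" for r in body]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def render_evaluations(evaluations: Sequence[CutpointEvaluation], fmt: str = "tsv") -> str:
    """Render a list of :class:`CutpointEvaluation` as a metrics table."""
    columns = {
        ev.subgroup + (" *" if ev.flagged else ""): {
            "cutpoint": ev.cutpoint,
            "youden": ev.youden,
            "sens": ev.sens,
            "spec": ev.spec,
            "accuracy": ev.accuracy,
        }
        for ev in evaluations
    }
    return render_metrics_table(columns, fmt=fmt)
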