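"""Differential testing, FDR control, ROC evaluation and stratified analyses.

Markers (glyco-compounds or aggregated glycan features) are compared between
clinical groups with two-sided Wilcoxon rank-sum (Mann-Whitney U) tests,
corrected with Benjamini-Hochberg at a 20% FDR. Diagnostic performance is
summarized by the ROC AUC together with the two fixed operating points the
field reports: sensitivity at 90% specificity and specificity at 90%
sensitivity, both on empirical thresholds without interpolation.

AUC orientation: the primary AUC scores cases (HCC) as the positive class, so
down-regulated markers fall below 0.5; an auto-oriented companion
max(AUC, 1-AUC) is also reported, matching the convention of ROC software
that picks the direction automatically.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "MarkerResult",
    "ROCCurve",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "roc_auc",
    "roc_curve",
    "operating_point",
    "evaluate_markers",
    "tier_counts",
    "stratified_evaluate",
    "markers_to_frame",
]

EXACT_MAX_N = 8  # exact Mann-Whitney null when min(n1, n2) <= this and no ties


@dataclass(frozen=True)
class TestResult:
    p_value: float
    u_statistic: float  # U of the first sample, midrank-based
    direction: int  # +1 first sample larger, -1 smaller, 0 no shift


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when min(n1, n2) <= 8 and the pooled
    sample is tie-free; otherwise the normal approximation with tie and
    continuity corrections. Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(1.0, n1 * n2 / 2.0, 0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(n1, n2) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u1 = float(res.statistic)
    auc = u1 / (n1 * n2)
    direction = 0 if auc == 0.5 else (1 if auc > 0.5 else -1)
    return TestResult(float(min(res.pvalue, 1.0)), u1, direction)


def bh_adjust(p_values: Sequence[float], fdr: float = 0.20) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags.

    q_i = min over j >= rank(i) of m * p_(j) / j, clipped at 1;
    flag = (q <= fdr).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= fdr


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC by rank statistic: (#(case > control) + 0.5 #ties) / (n1 n2).

    `labels` are True for cases (the positive class). Down-regulated markers
    legitimately yield AUC < 0.5 under this fixed orientation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_case = int(labels.sum())
    n_ctrl = int((~labels).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("need at least one case and one control")
    ranks = sps.rankdata(scores)  # midranks
    u_case = ranks[labels].sum() - n_case * (n_case + 1) / 2.0
    return float(u_case / (n_case * n_ctrl))


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC: rule 'score >= threshold' calls a case."""

    thresholds: np.ndarray  # descending; +inf first, -inf last
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_label: str = "case"


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_case = labels.sum()
    n_ctrl = (~labels).sum()
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("need at least one case and one control")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]])
    sens = np.array([(scores[labels] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~labels] < t).mean() for t in thresholds])
    return ROCCurve(thresholds, sens, spec)


def operating_point(
    roc: ROCCurve,
    fix: Literal["sensitivity", "specificity"],
    level: float = 0.90,
) -> float:
    """Best complementary metric subject to the fixed one being >= level.

    Empirical thresholds only, no interpolation; 0.0 when no threshold
    attains the constraint.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if fix == "specificity":
        ok = roc.specificity >= level
        return float(roc.sensitivity[ok].max()) if ok.any() else 0.0
    if fix == "sensitivity":
        ok = roc.sensitivity >= level
        return float(roc.specificity[ok].max()) if ok.any() else 0.0
    raise ValueError(f"fix must be 'sensitivity' or 'specificity', got {fix!r}")


@dataclass(frozen=True)
class MarkerResult:
    marker: str
    contrast: str
    n_case: int
    n_control: int
    p: float
    q: float
    significant: bool
    auc_fixed: float  # cases positive; may be < 0.5
    auc_oriented: float  # max(auc, 1 - auc)
    orientation: int  # +1 up in cases, -1 down in cases
    sens_at_90spec: float
    spec_at_90sens: float
    stratum: str = "all"


def _contrast_groups(meta: pd.DataFrame, contrast: tuple[str, str]) -> tuple[pd.Index, pd.Index]:
    ctrl_name, case_name = contrast
    grp = meta["group"]
    ctrl = meta.index[grp == ctrl_name] if ctrl_name != "hcc" else meta.index[grp.isin(["early", "late"])]
    case = meta.index[grp == case_name] if case_name != "hcc" else meta.index[grp.isin(["early", "late"])]
    return ctrl, case


def evaluate_markers(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    fdr: float = 0.20,
    op_level: float = 0.90,
    stratum: str = "all",
) -> list[MarkerResult]:
    """Per-marker differential test + ROC summary for one group contrast.

    `contrast` is (control-group, case-group); the pseudo-group "hcc" pools
    early and late. BH adjustment is applied across all rows of `matrix`
    jointly (one family per contrast). Operating points are computed on the
    auto-oriented score direction so down-regulated markers are summarized by
    the rule that actually separates the groups.
    """
    ctrl_ids, case_ids = _contrast_groups(meta, contrast)
    ctrl_ids = ctrl_ids.intersection(matrix.columns)
    case_ids = case_ids.intersection(matrix.columns)
    if len(ctrl_ids) == 0 or len(case_ids) == 0 or set(ctrl_ids) == set(case_ids):
        raise ValueError(f"degenerate contrast {contrast}: "
                         f"{len(ctrl_ids)} control / {len(case_ids)} case samples")
    contrast_name = f"{contrast[0]} vs {contrast[1]}"
    rows = []
    for marker in matrix.index:
        xs = matrix.loc[marker, case_ids].to_numpy(dtype=float)
        ys = matrix.loc[marker, ctrl_ids].to_numpy(dtype=float)
        keep_x, keep_y = ~np.isnan(xs), ~np.isnan(ys)
        xs, ys = xs[keep_x], ys[keep_y]
        test = wilcoxon_rank_sum(xs, ys)
        scores = np.concatenate([xs, ys])
        labels = np.concatenate([np.ones(len(xs), bool), np.zeros(len(ys), bool)])
        auc = roc_auc(scores, labels)
        # rank-statistic identity: U1/(n1 n2) is the AUC with cases positive
        assert abs(test.u_statistic / (len(xs) * len(ys)) - auc) < 1e-9
        orientation = 1 if auc >= 0.5 else -1
        oriented_scores = scores if orientation == 1 else -scores
        curve = roc_curve(oriented_scores, labels)
        rows.append(
            dict(marker=marker, test=test, auc=auc, orientation=orientation,
                 n_case=len(xs), n_control=len(ys),
                 sens=operating_point(curve, "specificity", op_level),
                 spec=operating_point(curve, "sensitivity", op_level))
        )
    q, flags = bh_adjust([r["test"].p_value for r in rows], fdr)
    results = [
        MarkerResult(
            marker=r["marker"], contrast=contrast_name,
            n_case=r["n_case"], n_control=r["n_control"],
            p=r["test"].p_value, q=float(qi), significant=bool(fi),
            auc_fixed=r["auc"], auc_oriented=max(r["auc"], 1 - r["auc"]),
            orientation=r["orientation"],
            sens_at_90spec=r["sens"], spec_at_90sens=r["spec"],
            stratum=stratum,
        )
        for r, qi, fi in zip(rows, q, flags)
    ]
    results.sort(key=lambda m: (m.q, m.marker))
    return results


TIER_EDGES = (0.90, 0.80, 0.75, 0.70)


def tier_counts(results: Sequence[MarkerResult], oriented: bool = True) -> dict[str, dict[str, int]]:
    """AUC tier tallies, both banded ((0.70,0.75], ..., >0.90) and nested
    (>0.70, >0.75, ...), on the oriented AUC by default."""
    aucs = [r.auc_oriented if oriented else r.auc_fixed for r in results]
    banded = {
        ">0.90": sum(a > 0.90 for a in aucs),
        "0.80-0.90": sum(0.80 < a <= 0.90 for a in aucs),
        "0.75-0.80": sum(0.75 < a <= 0.80 for a in aucs),
        "0.70-0.75": sum(0.70 < a <= 0.75 for a in aucs),
    }
    nested = {f">{e:.2f}": sum(a > e for a in aucs) for e in TIER_EDGES}
    return {"banded": banded, "nested": nested}


@dataclass
class StratifiedResult:
    per_stratum: dict[str, list[MarkerResult]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    comparison: pd.DataFrame | None = None  # per-stratum vs whole-cohort AUC


def stratified_evaluate(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    stratum: Literal["phenotype", "etiology", "cirrhosis"],
    min_n: int = 10,
    fdr: float = 0.20,
    op_level: float = 0.90,
) -> StratifiedResult:
    """Run `evaluate_markers` separately within each stratum.

    Strata with fewer than `min_n` patients in the contrast's analysis set
    are skipped with a logged reason. A comparison table of per-stratum vs
    whole-cohort oriented AUC is attached.
    """
    if stratum == "phenotype":
        labels = meta["phenotype"]
    elif stratum == "cirrhosis":
        labels = meta["cirrhosis"].map(lambda v: "cirrhotic" if _truthy(v) else "non-cirrhotic")
    elif stratum == "etiology":
        labels = None  # handled below: one stratum per flag, overlapping
    else:
        raise ValueError(f"unknown stratum {stratum!r}")

    ctrl_ids, case_ids = _contrast_groups(meta, contrast)
    analysis = meta.loc[ctrl_ids.union(case_ids)]

    if stratum == "etiology":
        strata = {
            flag: analysis.index[analysis[flag].map(_truthy)]
            for flag in ("HBV", "HCV", "ASH", "NASH")
            if flag in analysis.columns
        }
    else:
        strata = {
            str(val): analysis.index[labels.loc[analysis.index] == val]
            for val in sorted(labels.loc[analysis.index].dropna().unique())
        }

    whole = evaluate_markers(matrix, meta.loc[analysis.index], contrast, fdr, op_level)
    whole_auc = {m.marker: m.auc_oriented for m in whole}
    out = StratifiedResult()
    comp_rows = []
    for name, ids in strata.items():
        if len(ids) < min_n:
            reason = f"only {len(ids)} patients in analysis set (< {min_n})"
            logger.warning("skipping stratum %s=%s: %s", stratum, name, reason)
            out.skipped[name] = reason
            continue
        try:
            res = evaluate_markers(matrix[ids.intersection(matrix.columns)],
                                   meta.loc[ids], contrast, fdr, op_level,
                                   stratum=f"{stratum}={name}")
        except ValueError as exc:  # e.g. one contrast arm empty in stratum
            out.skipped[name] = str(exc)
            logger.warning("skipping stratum %s=%s: %s", stratum, name, exc)
            continue
        out.per_stratum[name] = res
        for m in res:
            comp_rows.append(
                dict(stratum=name, marker=m.marker,
                     auc_stratum=m.auc_oriented,
                     auc_whole=whole_auc[m.marker],
                     delta=m.auc_oriented - whole_auc[m.marker])
            )
    out.comparison = pd.DataFrame(comp_rows)
    return out


def _truthy(v) -> bool:
    return str(v).strip().lower() in {"1", "true", "yes", "y"}


def markers_to_frame(results: Sequence[MarkerResult]) -> pd.DataFrame:
    """Marker report as a DataFrame, ordered by (q, marker id)."""
    from .quant import split_row_id

    recs = []
    for m in sorted(results, key=lambda r: (r.q, r.marker)):
        try:
            site, comp = split_row_id(m.marker)
        except ValueError:
            site, comp = "", m.marker
        recs.append(
            dict(marker=m.marker, site=site, composition=comp, contrast=m.contrast,
                 n_case=m.n_case, n_control=m.n_control, p=m.p, q=m.q,
                 significant=m.significant, auc_fixed=m.auc_fixed,
                 auc_oriented=m.auc_oriented, orientation=m.orientation,
                 sens_at_90spec=m.sens_at_90spec, spec_at_90sens=m.spec_at_90sens,
                 stratum=m.stratum)
        )
    return pd.DataFrame(recs)
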