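"""Quantification: internal-standard normalization, left-censored imputation,
QC coefficients of variation, and glycan-feature aggregation.

The central object is the quant matrix, a pandas DataFrame of XIC peak areas
with glyco-compound rows (site label + canonical composition string, joined
by ``|``) and sample columns; missing observations are NaN. The processing
order is fixed: normalize to the spiked heavy-protein internal standard,
impute missing values with the per-glycopeptide minimum, then aggregate into
glycan feature classes (fucosylation and sialylation degree, antennarity,
high-mannose).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .glyco import GlycanClassification, classify, parse_composition

logger = logging.getLogger(__name__)

__all__ = [
    "ROW_ID_SEP",
    "make_row_id",
    "split_row_id",
    "read_quant_matrix",
    "read_heavy_table",
    "read_sample_meta",
    "classify_rows",
    "select_top3_heavy",
    "normalize",
    "impute_min",
    "qc_cv",
    "CVReport",
    "aggregate_features",
    "collapse_charge_states",
]

ROW_ID_SEP = "|"

GROUPS = ("control", "early", "late")
PHENOTYPES = ("1-1", "2-1", "2-2", "unknown")
META_COLUMNS = ("group", "phenotype", "HBV", "HCV", "ASH", "NASH", "cirrhosis", "AFP")


def make_row_id(site_label: str, composition: str) -> str:
    return f"{site_label}{ROW_ID_SEP}{composition}"


def split_row_id(row_id: str) -> tuple[str, str]:
    site, _, comp = row_id.partition(ROW_ID_SEP)
    if not comp:
        raise ValueError(f"row id {row_id!r} is not 'site{ROW_ID_SEP}composition'")
    return site, comp


def _read_table(path, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA"], comment="#")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {index_col} ids in {path}: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample columns in {path}")
    return df


def read_quant_matrix(path) -> pd.DataFrame:
    """Read a glyco-compound x sample XIC-area table (TSV, NaN = missing)."""
    df = _read_table(path, "glyco-compound").astype(float)
    neg = df.lt(0)
    if neg.any().any():
        r, c = np.argwhere(neg.values)[0]
        raise ValueError(
            f"negative XIC area at row {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    for rid in df.index:
        split_row_id(rid)  # validates shape, raises with the offending id
    return df

def read_heavy_table(path) -> pd.DataFrame:
    """Read the heavy internal-standard peptide abundance table."""
    df = _read_table(path, "heavy-peptide").astype(float)
    if df.le(0).any().any():
        raise ValueError("heavy-standard abundances must be > 0 where present")
    return df

def read_sample_meta(path) -> pd.DataFrame:
    """Read sample metadata; validates group and phenotype vocabularies."""
    df = _read_table(path, "sample")
    if "group" not in df.columns:
        raise ValueError("metadata must have a 'group' column")
    bad = set(df["group"].dropna()) - set(GROUPS)
    if bad or df["group"].isna().any():
        raise ValueError(
            f"every sample needs a group in {GROUPS}; offending values: "
            f"{sorted(map(str, bad)) or 'missing'}"
        )
    if "phenotype" in df.columns:
        df["phenotype"] = df["phenotype"].fillna("unknown")
        bad = set(df["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotypes {sorted(bad)}")
    return df


def classify_rows(matrix: pd.DataFrame) -> dict[str, GlycanClassification]:
    """Classify every glyco-compound row by its composition part."""
    out = {}
    for rid in matrix.index:
        _site, comp = split_row_id(rid)
        out[rid] = classify(parse_composition(comp))
    return out


def collapse_charge_states(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sum rows sharing a site+composition id (charge states observed
    separately upstream); NaN + NaN stays NaN, NaN + x = x."""
    return matrix.groupby(level=0, sort=False).sum(min_count=1)


def select_top3_heavy(heavy: pd.DataFrame) -> list[str]:
    """The 3 heavy peptides with highest mean abundance over all samples.

    Only rows with complete observations are eligible; ties at the cut are
    broken by lexicographic peptide id. Fewer than 3 complete rows is an
    error — the internal standard cannot anchor normalization.
    """
    complete = heavy.dropna(axis=0)
    if len(complete) < 3:
        raise ValueError(
            f"need >= 3 heavy peptides with complete observations, have {len(complete)}"
        )
    ranked = sorted(complete.index, key=lambda p: (-complete.loc[p].mean(), p))
    top3 = ranked[:3]
    logger.info("top-3 heavy peptides selected for normalization: %s", top3)
    return top3


def normalize(matrix: pd.DataFrame, heavy: pd.DataFrame) -> pd.DataFrame:
    """Normalize XIC areas to the summed top-3 heavy-peptide abundance.

    value'(g, s) = value(g, s) / T(s) * mean_s T(s), where T(s) is the top-3
    heavy sum in sample s. The rescale by mean T keeps the output on the
    input intensity scale. Missing values stay missing.
    """
    missing = set(matrix.columns) - set(heavy.columns)
    if missing:
        raise ValueError(f"samples absent from heavy table: {sorted(missing)}")
    top3 = select_top3_heavy(heavy[list(matrix.columns)])
    t = heavy.loc[top3, list(matrix.columns)].sum(axis=0)
    if (t == 0).any():
        bad = t.index[t == 0].tolist()
        raise ValueError(f"zero heavy-standard sum in sample(s) {bad}")
    return matrix.div(t, axis=1) * t.mean()


def impute_min(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values with the row's minimum observed value.

    The minimum is global across all samples (left-censoring floor for that
    glycopeptide). Rows with no observed value at all cannot be imputed and
    are dropped with a warning.
    """
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        dropped = matrix.index[all_missing].tolist()
        logger.warning("dropping %d all-missing row(s): %s", len(dropped), dropped)
    kept = matrix.loc[~all_missing]
    row_min = kept.min(axis=1)
    return kept.apply(lambda col: col.fillna(row_min))


@dataclass(frozen=True)
class CVReport:
    cvs: pd.Series  # CV% per aggregate unit (may contain NaN for mean 0)
    mean: float
    range: tuple[float, float]


def qc_cv(
    matrix: pd.DataFrame,
    control_columns: Sequence[str],
    level: Literal["protein", "peptide-set"] = "protein",
    peptide_sets: Mapping[str, Sequence[str]] | None = None,
) -> CVReport:
    """Coefficients of variation (%) across repeated control injections.

    protein level: CV of the column sums over all rows (one CV). peptide-set
    level: one CV per named row set. CV% = 100 * sd / mean (sample sd);
    mean 0 yields a missing CV.
    """
    if len(control_columns) < 2:
        raise ValueError("need >= 2 control columns for a CV")
    sub = matrix[list(control_columns)]
    if level == "protein":
        series = pd.Series({"protein": _cv(sub.sum(axis=0, skipna=True))})
    elif level == "peptide-set":
        if not peptide_sets:
            raise ValueError("peptide-set level requires peptide_sets")
        series = pd.Series(
            {name: _cv(sub.loc[list(rows)].sum(axis=0, skipna=True))
             for name, rows in peptide_sets.items()}
        )
    else:
        raise ValueError(f"unknown level {level!r}")
    finite = series.dropna()
    rng = (float(finite.min()), float(finite.max())) if len(finite) else (np.nan, np.nan)
    return CVReport(series, float(finite.mean()) if len(finite) else np.nan, rng)


def _cv(values: pd.Series) -> float:
    m = values.mean()
    if m == 0:
        return np.nan
    return float(100.0 * values.std(ddof=1) / m)


# Feature-class vocabulary for aggregation. Degree features cover complex
# glycans only, so each degree axis partitions the complex set exactly.
MAX_DEGREE = 4


def _feature_classes(cls: GlycanClassification, pool_high_degrees: bool) -> list[str]:
    feats = []
    if cls.family == "high-mannose":
        return ["high-mannose"]
    if cls.family == "complex":
        fd, sd = cls.fucosylation_degree, cls.sialylation_degree
        if pool_high_degrees:
            fd, sd = min(fd, MAX_DEGREE), min(sd, MAX_DEGREE)
        if 1 <= fd <= MAX_DEGREE:
            feats.append(f"fucosylation-{fd}")
        if 1 <= sd <= MAX_DEGREE:
            feats.append(f"sialylation-{sd}")
        if cls.antennae in (2, 3, 4):
            feats.append(f"antennae-{cls.antennae}")
    return feats


def aggregate_features(
    matrix: pd.DataFrame,
    classifications: Mapping[str, GlycanClassification],
    scope: Literal["global", "per-site"] = "global",
    pool_high_degrees: bool = True,
) -> pd.DataFrame:
    """Sum glyco-compound intensities into glycan feature classes.

    Features: fucosylation degree 1-4, sialylation degree 1-4, antennarity
    2/3/4 (complex glycans), and high-mannose. A row contributes to every
    feature class it belongs to. `per-site` scope prefixes features with the
    glycosite label. Degrees above 4 pool into the "4" class when
    `pool_high_degrees` (a 4+ bucket).
    """
    missing = [r for r in matrix.index if r not in classifications]
    if missing:
        raise ValueError(f"unclassified rows: {missing[:5]}")
    feature_order = (
        [f"fucosylation-{d}" for d in range(1, MAX_DEGREE + 1)]
        + [f"sialylation-{d}" for d in range(1, MAX_DEGREE + 1)]
        + [f"antennae-{a}" for a in (2, 3, 4)]
        + ["high-mannose"]
    )
    buckets: dict[str, list[str]] = {}
    for rid in matrix.index:
        site, _comp = split_row_id(rid)
        for feat in _feature_classes(classifications[rid], pool_high_degrees):
            key = f"{site}{ROW_ID_SEP}{feat}" if scope == "per-site" else feat
            buckets.setdefault(key, []).append(rid)
    if scope == "per-site":
        sites = sorted({split_row_id(r)[0] for r in matrix.index})
        keys = [f"{s}{ROW_ID_SEP}{f}" for s in sites for f in feature_order]
    else:
        keys = feature_order
    data = {
        key: matrix.loc[buckets[key]].sum(axis=0, skipna=True)
        if key in buckets
        else pd.Series(0.0, index=matrix.columns)
        for key in keys
    }
    return pd.DataFrame(data).T[matrix.columns]
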