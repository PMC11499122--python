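"""Normalization, feature filtering, responder calls, design matrices.

Counts are normalized to log2 counts-per-million with a 0.5 pseudocount
(the standard companion to trend-moderated linear modeling).  Feature
filtering removes non-coding and LOC-prefixed transcripts and then keeps
the top-K genes by variance.  Responder classification applies the
trial endpoint: a >= 2-fold rise in IgG titer from baseline to week 12,
with high responders (HR) defined by an OD450 >= 0.4 at 1:80 dilution.
Design matrices always include biological sex and trial batch as
blocking factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    ExpressionMatrix,
    LOG_NORMALIZED,
    RAW_COUNTS,
    ResponseLabels,
)

CONTRASTS = ("baseline_RvsNR", "week2_RvsNR", "delta_RvsNR", "HRvsNR")


def normalize(expr: ExpressionMatrix, pseudocount: float = 0.5) -> ExpressionMatrix:
    """Raw counts -> log2 counts-per-million.

    Uses log2((count + pseudocount) / (libsize + 2*pseudocount) * 1e6) per
    sample, so each column of 2**value sums to ~1e6.
    """
    if expr.scale != RAW_COUNTS:
        raise ValueError("normalize expects raw counts")
    libsize = expr.values.sum(axis=0)
    zero = libsize.index[libsize <= 0].tolist()
    if zero:
        raise ValueError(f"zero-sum sample column(s): {zero}")
    cpm = (expr.values + pseudocount) / (libsize + 2.0 * pseudocount) * 1e6
    return ExpressionMatrix(np.log2(cpm), LOG_NORMALIZED)


def filter_features(
    expr: ExpressionMatrix,
    annotations: dict[str, str] | None = None,
    variance_top_k: int = 8000,
) -> ExpressionMatrix:
    """Drop non-coding / LOC features, keep the top-K by variance.

    ``annotations`` maps gene id -> biotype; genes with a biotype other
    than ``protein_coding`` are removed (genes absent from the map are
    kept).  Gene ids starting with ``LOC`` are removed regardless.  Ties
    in variance are broken by lexicographic gene id.  Sample order is
    preserved.
    """
    if expr.scale != LOG_NORMALIZED:
        raise ValueError("filter_features expects log-normalized input")
    keep = []
    for g in expr.gene_ids:
        if g.startswith("LOC"):
            continue
        if annotations is not None and annotations.get(g, "protein_coding") != "protein_coding":
            continue
        keep.append(g)
    sub = expr.values.loc[keep]
    if variance_top_k > len(keep):
        warnings.warn(
            f"variance_top_k={variance_top_k} exceeds {len(keep)} remaining "
            "genes; keeping all"
        )
        variance_top_k = len(keep)
    if variance_top_k == 0:
        warnings.warn("variance_top_k=0: returning an empty matrix")
    variances = sub.var(axis=1, ddof=1) if sub.shape[1] > 1 else pd.Series(0.0, index=sub.index)
    order = pd.DataFrame({"var": variances, "gene": sub.index}).sort_values(
        ["var", "gene"], ascending=[False, True]
    )
    top = order["gene"].head(variance_top_k).tolist()
    # preserve original gene order among the survivors
    top_set = set(top)
    kept = [g for g in keep if g in top_set]
    return ExpressionMatrix(sub.loc[kept], LOG_NORMALIZED)


def classify_response(
    samples: pd.DataFrame,
    hr_threshold: float = 0.4,
    fold_threshold: float = 2.0,
) -> ResponseLabels:
    """Responder (R) iff week-12 / week-0 IgG >= fold_threshold.

    Among responders, tier HR iff OD450 at 1:80 >= hr_threshold, else
    LR; non-responders get tier NR.  Both boundaries are inclusive.
    Labels are scale-invariant in the titers.
    """
    response: dict[str, str] = {}
    tier: dict[str, str] = {}
    per_subject = samples.drop_duplicates("subject_id").set_index("subject_id")
    has_od = "od450_1to80" in per_subject.columns
    for subj, row in per_subject.iterrows():
        ratio = row["igg_week12"] / row["igg_week0"]
        if ratio >= fold_threshold:
            response[subj] = "R"
            od = row["od450_1to80"] if has_od else np.nan
            if pd.isna(od):
                warnings.warn(f"responder {subj} has no OD450; recording tier LR")
                tier[subj] = "LR"
            else:
                tier[subj] = "HR" if od >= hr_threshold else "LR"
        else:
            response[subj] = "NR"
            tier[subj] = "NR"
    return ResponseLabels(response=response, tier=tier)


@dataclass
class DesignInfo:
    """A full-rank design matrix plus the contrast selecting the group effect.

    ``mode`` is ``"samples"`` (rows are samples at one timepoint) or
    ``"delta"`` (rows are subjects; the response is week2 - week0).
    ``column_ids`` gives the expression columns to model; for delta mode
    ``pair_columns`` maps each subject row to its (week0, week2) columns.
    """

    design: pd.DataFrame
    contrast: np.ndarray
    group: pd.Series
    mode: str
    column_ids: list[str]
    pair_columns: dict[str, tuple[str, str]] | None = None


def _dummies(series: pd.Series) -> pd.Series:
    levels = sorted(series.dropna().unique())
    if len(levels) > 2:
        raise ValueError(f"expected a two-level factor, got levels {levels}")
    return (series == levels[-1]).astype(float)


def build_design(
    samples: pd.DataFrame,
    labels: ResponseLabels,
    contrast: str,
) -> DesignInfo:
    """Design with columns {intercept, group, sex, batch} for a contrast.

    Constant blocking columns are dropped with a warning; a group column
    aliased with a blocking factor raises (confounded design).  For
    ``delta_RvsNR`` only subjects with both timepoints are kept and the
    design has one row per subject.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    resp = pd.Series(labels.response)
    tier = pd.Series(labels.tier)

    if contrast == "delta_RvsNR":
        counts = samples.groupby("subject_id")["timepoint"].nunique()
        unpaired = counts.index[counts < 2].tolist()
        if unpaired:
            warnings.warn(f"excluding unpaired subject(s): {unpaired}")
        paired = [s for s in counts.index if counts[s] == 2]
        sub = samples[samples["subject_id"].isin(paired)]
        per_subject = sub.drop_duplicates("subject_id").set_index("subject_id")
        group = resp.loc[per_subject.index].map({"NR": 0.0, "R": 1.0})
        sex = _dummies(per_subject["sex"])
        batch = _dummies(per_subject["batch"])
        pair_columns = {}
        for subj in per_subject.index:
            rows = sub[sub["subject_id"] == subj].set_index("timepoint")
            pair_columns[subj] = (
                rows.loc["week0", "sample_id"],
                rows.loc["week2", "sample_id"],
            )
        design = pd.DataFrame(
            {"intercept": 1.0, "group": group.values, "sex": sex.values,
             "batch": batch.values},
            index=per_subject.index,
        )
        mode, column_ids = "delta", list(per_subject.index)
    else:
        tp = "week2" if contrast == "week2_RvsNR" else "week0"
        sub = samples[samples["timepoint"] == tp].set_index("sample_id")
        if contrast == "HRvsNR":
            keep = sub["subject_id"].map(tier).isin(["HR", "NR"])
            sub = sub[keep]
            group = sub["subject_id"].map(tier).map({"NR": 0.0, "HR": 1.0})
        else:
            group = sub["subject_id"].map(resp).map({"NR": 0.0, "R": 1.0})
        if group.isna().any():
            missing = sub.index[group.isna()].tolist()
            raise ValueError(f"samples without response labels: {missing}")
        design = pd.DataFrame(
            {"intercept": 1.0, "group": group.values,
             "sex": _dummies(sub["sex"]).values,
             "batch": _dummies(sub["batch"]).values},
            index=sub.index,
        )
        mode, column_ids, pair_columns = "samples", list(sub.index), None

    n_groups = design["group"].nunique()
    if n_groups < 2:
        raise ValueError("need samples from both groups for a contrast")

    # drop constant blocking columns; then demand full rank
    for col in ("sex", "batch"):
        if design[col].nunique() == 1:
            warnings.warn(f"blocking factor {col!r} is constant; dropping it")
            design = design.drop(columns=col)
    X = design.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # group must carry information beyond the blocking factors
        without_group = design.drop(columns="group").to_numpy()
        if np.linalg.matrix_rank(X) == np.linalg.matrix_rank(without_group):
            raise ValueError(
                "confounded design: group is aliased with blocking factors"
            )
        # otherwise a blocking column is redundant; drop it
        for col in ("sex", "batch"):
            if col in design.columns:
                reduced = design.drop(columns=col).to_numpy()
                if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(X):
                    warnings.warn(f"blocking factor {col!r} is redundant; dropping it")
                    design = design.drop(columns=col)
                    X = design.to_numpy()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix remains rank-deficient")

    contrast_vec = (design.columns == "group").astype(float)
    return DesignInfo(
        design=design,
        contrast=contrast_vec,
        group=design["group"],
        mode=mode,
        column_ids=column_ids,
        pair_columns=pair_columns,
    )


def delta_matrix(values: pd.DataFrame | ExpressionMatrix, info: DesignInfo) -> pd.DataFrame:
    """Within-subject week2 - week0 values for a delta design."""
    if info.mode != "delta":
        raise ValueError("delta_matrix requires a delta design")
    if isinstance(values, ExpressionMatrix):
        values = values.values
    cols = {}
    for subj, (wk0, wk2) in info.pair_columns.items():
        cols[subj] = values[wk2] - values[wk0]
    return pd.DataFrame(cols).loc[:, info.column_ids]
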