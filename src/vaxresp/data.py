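"""Core data containers shared across the pipeline.

The pipeline operates on three tabular objects: a genes x samples
expression matrix carrying a value-scale tag, a per-sample covariate
table (subject, timepoint, sex, trial batch, IgG titers), and a named
collection of gene sets.  All are thin, validated wrappers around
pandas objects so that every downstream stage can rely on consistent
identifiers and dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
LOG_NORMALIZED = "log_normalized"

TIMEPOINTS = ("week0", "week2")

REQUIRED_SAMPLE_COLUMNS = (
    "sample_id",
    "subject_id",
    "timepoint",
    "sex",
    "batch",
    "igg_week0",
    "igg_week12",
)


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a value-scale tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.
    scale : str
        Either ``"raw_counts"`` or ``"log_normalized"``.
    """

    values: pd.DataFrame
    scale: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if self.scale not in (RAW_COUNTS, LOG_NORMALIZED):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValueError("expression values must be numeric")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.scale)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids), :], self.scale)


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample covariate table.

    Requires columns ``sample_id, subject_id, timepoint, sex, batch,
    igg_week0, igg_week12`` (an optional ``od450_1to80`` is carried
    through).  Each (subject, timepoint) pair must be unique and titers
    strictly positive.
    """
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    bad_tp = set(samples["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    pairs = samples[["subject_id", "timepoint"]]
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].to_records(index=False).tolist()
        raise ValueError(f"duplicate (subject, timepoint) pairs: {dup}")
    if (samples[["igg_week0", "igg_week12"]] <= 0).any().any():
        raise ValueError("IgG titers must be strictly positive")
    return samples


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. Hallmark pathways."""

    sets: dict[str, list[str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        # de-duplicate members while preserving order
        self.sets = {name: list(dict.fromkeys(genes)) for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe, min_size: int = 5) -> "GeneSetCollection":
        """Intersect each set with ``universe``; drop sets below ``min_size``."""
        uni = set(universe)
        kept = {}
        for name, genes in self.sets.items():
            inter = [g for g in genes if g in uni]
            if len(inter) >= min_size:
                kept[name] = inter
        return GeneSetCollection(kept, self.source_tag)


@dataclass
class ResponseLabels:
    """Per-subject responder calls.

    ``response`` maps subject -> {"R", "NR"}; ``tier`` maps subject ->
    {"HR", "LR", "NR"} with tier == "NR" exactly for non-responders.
    """

    response: dict[str, str] = field(default_factory=dict)
    tier: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sub, resp in self.response.items():
            t = self.tier.get(sub)
            if resp == "NR" and t != "NR":
                raise ValueError(f"subject {sub}: NR response requires NR tier")
            if resp == "R" and t not in ("HR", "LR"):
                raise ValueError(f"subject {sub}: responder tier must be HR or LR")

    def subjects(self) -> list[str]:
        return list(self.response)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": list(self.response),
                "response": list(self.response.values()),
                "tier": [self.tier[s] for s in self.response],
            }
        )
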