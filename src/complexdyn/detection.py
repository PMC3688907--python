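"""Expression matrices and posterior-SD detection calls.

Consumes MMSEQ-style per-sample quantification tables (one TSV per sample:
``feature_id<TAB>estimate<TAB>sd`` with log-scale expression estimates and
their posterior standard deviations) and produces boolean detection calls.
A feature is *detected* in a sample when it is present in that sample's file
and its posterior SD does not exceed the threshold (default 1.5, the point
beyond which estimates come from features without unique read support).
The expression estimate itself is never thresholded by default.

Gene-level calls can either be loaded from native gene-level quantifications
or rolled up from transcript calls (a gene is detected iff any of its
transcripts is); rollup makes the gene-superset relation to transcript-level
results exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

DEFAULT_SD_MAX = 1.5

EXPRESSION_COLUMNS = ("feature_id", "estimate", "sd")


@dataclass
class ExpressionMatrix:
    """Feature-by-sample estimates with per-cell posterior SDs.

    Missing cells (feature absent from a sample's file) are NaN in both
    matrices and are never detected.
    """

    level: str
    estimate: pd.DataFrame
    sd: pd.DataFrame

    def __post_init__(self) -> None:
        if self.level not in ("transcript", "gene"):
            raise ConfigError(f"level must be 'transcript' or 'gene', got {self.level!r}")
        if not self.estimate.index.equals(self.sd.index) or not self.estimate.columns.equals(
            self.sd.columns
        ):
            raise FormatError("estimate and sd matrices must share index and columns")
        if self.estimate.index.has_duplicates:
            raise FormatError("duplicate feature ids")
        if self.estimate.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        if (self.sd.to_numpy() < 0).any():
            raise FormatError("posterior SD values must be non-negative")

    @property
    def features(self) -> list[str]:
        return list(self.estimate.index)

    @property
    def samples(self) -> list[str]:
        return list(self.estimate.columns)


@dataclass
class DetectionCall:
    """Boolean feature-by-sample detection matrix at one level."""

    level: str
    detected: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.detected.columns)

    def detected_features(self, sample: str) -> frozenset[str]:
        col = self.detected[sample]
        return frozenset(col.index[col])


def _read_sample_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"feature_id": str})
    for col in EXPRESSION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise FormatError(f"{path}: duplicate feature {dup!r}")
    return df.set_index("feature_id")[["estimate", "sd"]].astype(float)


def load_expression(
    paths: Sequence[str | Path],
    level: str,
    sample_names: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Assemble one expression matrix from per-sample TSV files.

    Column order equals input path order; sample names default to file stems.
    The feature universe is the union across samples in first-seen order, with
    absent cells left missing (NaN).
    """
    paths = [Path(p) for p in paths]
    if sample_names is None:
        sample_names = [p.stem for p in paths]
    if len(sample_names) != len(paths):
        raise ConfigError("sample_names must match paths one-to-one")
    if len(set(sample_names)) != len(sample_names):
        raise FormatError("duplicate sample names")
    tables = [_read_sample_table(p) for p in paths]
    features: list[str] = []
    seen: set[str] = set()
    for table in tables:
        for f in table.index:
            if f not in seen:
                seen.add(f)
                features.append(f)
    index = pd.Index(features, name="feature_id")
    estimate = pd.DataFrame(
        {s: t["estimate"].reindex(index) for s, t in zip(sample_names, tables)}
    )
    sd = pd.DataFrame({s: t["sd"].reindex(index) for s, t in zip(sample_names, tables)})
    return ExpressionMatrix(level=level, estimate=estimate, sd=sd)


def call_detection(
    expr: ExpressionMatrix,
    sd_max: float = DEFAULT_SD_MAX,
    min_estimate: float | None = None,
) -> DetectionCall:
    """Call detection: present cell with SD <= ``sd_max`` (boundary inclusive).

    ``min_estimate`` optionally adds an expression floor; it is off by default
    because the SD rule alone defines reliable detection here.
    """
    if sd_max <= 0:
        raise ConfigError(f"sd_max must be positive, got {sd_max}")
    detected = expr.sd.notna() & (expr.sd <= sd_max)
    if min_estimate is not None:
        detected &= expr.estimate >= min_estimate
    return DetectionCall(level=expr.level, detected=detected)


def rollup_gene_detection(
    tx_call: DetectionCall, transcript_to_gene: Mapping[str, str]
) -> DetectionCall:
    """Roll transcript calls up to genes: detected iff any transcript is.

    Every called transcript must have a gene mapping; offenders are listed in
    the error.  Gene order follows first occurrence in transcript order.
    """
    if tx_call.level != "transcript":
        raise ConfigError("rollup requires a transcript-level call")
    features = list(tx_call.detected.index)
    missing = [t for t in features if t not in transcript_to_gene]
    if missing:
        head = ", ".join(missing[:5])
        raise FormatError(
            f"{len(missing)} transcript(s) without a gene mapping: {head}"
        )
    genes = pd.Series([transcript_to_gene[t] for t in features], index=features)
    rolled = tx_call.detected.groupby(genes).any()
    order = list(dict.fromkeys(genes))
    rolled = rolled.loc[order]
    rolled.index.name = "feature_id"
    return DetectionCall(level="gene", detected=rolled)


def write_detection(call: DetectionCall, path: str | Path) -> None:
    """Write a 0/1 feature-by-sample detection TSV."""
    call.detected.astype(int).to_csv(path, sep="\t", index_label="feature_id")


def read_detection(path: str | Path, level: str) -> DetectionCall:
    """Read a 0/1 detection TSV written by :func:`write_detection`."""
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return DetectionCall(level=level, detected=df.astype(bool))
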