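"""Nonparametric (M, D) differential-expression probability for transcripts.

Given normalized transcript abundances for case and control samples, each
transcript gets a signal pair: M = log2 ratio of group means and D = absolute
difference of group means.  A noise distribution of (M*, D*) pairs is built
from all within-group sample-pair comparisons pooled across both groups
(replicate mode); when no group has replicates, technical replicates are
simulated by multinomial resampling of each sample's counts at its observed
depth.  The probability of differential expression is

    q_t = fraction of noise pairs with |M*| < |M_t| and D* < D_t

(strict domination; boundary ties do not count).  Transcripts with
q > q_min are called differentially expressed; per-dataset defaults follow
replicate availability — fewer replicates demand a stricter threshold
(breast 0.9, colon 0.9, lung 0.99 with no replicates, prostate 0.8).

Normalization follows the median-deviation-from-the-mean convention: each
sample's log-abundances are shifted so that all per-sample medians (over
expressed transcripts) coincide, with the shifts summing to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

#: Per-dataset default q thresholds, stricter where replication is weaker.
DEFAULT_Q_MIN: dict[str, float] = {
    "breast": 0.9,
    "colon": 0.9,
    "lung": 0.99,
    "prostate": 0.8,
}

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    """Per-transcript (M, D, q) with the explicit noise pool used for q."""

    table: pd.DataFrame
    noise_m: np.ndarray
    noise_d: np.ndarray
    groups: pd.Series
    mode: str

    @property
    def q(self) -> pd.Series:
        return self.table["q"]


def normalize_median_deviation(counts: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-sample medians of log-abundance over expressed transcripts.

    For sample s, offset_s = median_s - mean of medians, where median_s is the
    median natural-log abundance of the sample's nonzero transcripts; the
    sample is rescaled by exp(-offset_s).  Offsets sum to zero, zeros stay
    zero, and a single-sample matrix is returned unchanged.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise FormatError("abundances must be non-negative")
    medians = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        nonzero = values[:, j][values[:, j] > 0]
        if nonzero.size == 0:
            raise FormatError(
                f"sample {counts.columns[j]!r} has no nonzero abundance"
            )
        medians[j] = np.median(np.log(nonzero))
    offsets = medians - medians.mean()
    normalized = values * np.exp(-offsets)[None, :]
    return pd.DataFrame(normalized, index=counts.index, columns=counts.columns)


def _group_columns(counts: pd.DataFrame, groups: Mapping[str, str]):
    missing = [s for s in counts.columns if s not in groups]
    if missing:
        raise ConfigError(f"samples without a group label: {missing}")
    labels = pd.Series({s: groups[s] for s in counts.columns})
    bad = sorted(set(labels) - {"case", "control"})
    if bad:
        raise ConfigError(f"group labels must be 'case'/'control', got {bad}")
    case = [s for s in counts.columns if labels[s] == "case"]
    control = [s for s in counts.columns if labels[s] == "control"]
    if not case or not control:
        raise ConfigError("both groups need at least one sample")
    return labels, case, control


def _log2_ratio(a: np.ndarray, b: np.ndarray, pseudo: float) -> np.ndarray:
    a = np.where(a == 0, pseudo, a)
    b = np.where(b == 0, pseudo, b)
    return np.log2(a / b)


def _simulate_replicates(
    column: np.ndarray, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial technical replicates of one sample at its observed depth."""
    total = column.sum()
    if total <= 0:
        raise FormatError("cannot simulate replicates for an all-zero sample")
    depth = int(round(total))
    p = column / total
    return rng.multinomial(depth, p, size=n_sim).T.astype(float)


def noiseq_probability(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    simulate: bool | None = None,
    n_sim: int = 5,
    seed: int | None = None,
) -> DEResult:
    """Compute per-transcript (M, D, q) against a within-group noise pool.

    ``simulate=None`` auto-selects: replicate mode when at least one group has
    >=2 samples, simulation otherwise.  ``simulate=False`` with two singleton
    groups raises, explaining the replicate requirement.  ``seed`` drives the
    replicate simulation only.
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be positive")
    labels, case, control = _group_columns(counts, groups)
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise FormatError("abundances must be non-negative")
    col_idx = {s: i for i, s in enumerate(counts.columns)}
    groups_cols = {"case": [col_idx[s] for s in case], "control": [col_idx[s] for s in control]}

    replicated = [g for g, cols in groups_cols.items() if len(cols) >= 2]
    if simulate is None:
        simulate = not replicated
    if not replicated and not simulate:
        raise ConfigError(
            "both groups are singletons: the noise pool needs within-group "
            "replicates; enable replicate simulation or provide replicates"
        )

    mean_case = values[:, groups_cols["case"]].mean(axis=1)
    mean_control = values[:, groups_cols["control"]].mean(axis=1)
    m = _log2_ratio(mean_case, mean_control, pseudocount)
    d = np.abs(mean_case - mean_control)

    noise_m_parts: list[np.ndarray] = []
    noise_d_parts: list[np.ndarray] = []

    def add_pairs(columns: np.ndarray) -> None:
        k = columns.shape[1]
        for i in range(k):
            for j in range(i + 1, k):
                noise_m_parts.append(
                    _log2_ratio(columns[:, i], columns[:, j], pseudocount)
                )
                noise_d_parts.append(np.abs(columns[:, i] - columns[:, j]))

    if simulate:
        rng = np.random.default_rng(seed)
        mode = "simulated"
        for g in ("case", "control"):
            for c in groups_cols[g]:
                add_pairs(_simulate_replicates(values[:, c], n_sim, rng))
    else:
        mode = "replicate"
        for g in replicated:
            add_pairs(values[:, groups_cols[g]])

    noise_m = np.concatenate(noise_m_parts)
    noise_d = np.concatenate(noise_d_parts)
    q = _dominated_fraction(np.abs(m), d, np.abs(noise_m), noise_d)
    table = pd.DataFrame({"M": m, "D": d, "q": q}, index=counts.index)
    table.index.name = "transcript_id"
    return DEResult(
        table=table, noise_m=noise_m, noise_d=noise_d, groups=labels, mode=mode
    )


def _dominated_fraction(
    abs_m: np.ndarray,
    d: np.ndarray,
    noise_abs_m: np.ndarray,
    noise_d: np.ndarray,
    chunk: int = 256,
) -> np.ndarray:
    """Fraction of noise pairs strictly dominated by each signal pair."""
    n_noise = noise_abs_m.size
    if n_noise == 0:
        raise ConfigError("empty noise pool")
    out = np.empty(abs_m.size)
    for start in range(0, abs_m.size, chunk):
        stop = min(start + chunk, abs_m.size)
        dominated = (noise_abs_m[None, :] < abs_m[start:stop, None]) & (
            noise_d[None, :] < d[start:stop, None]
        )
        out[start:stop] = dominated.mean(axis=1)
    return out


def de_call(
    result: DEResult,
    q_min: float | None = None,
    dataset: str | None = None,
) -> frozenset[str]:
    """Threshold q into a DE transcript set.

    ``q_min`` defaults from the dataset name when it matches a known dataset;
    otherwise it must be given explicitly.
    """
    if q_min is None:
        if dataset is None or dataset not in DEFAULT_Q_MIN:
            raise ConfigError(
                "q_min required (no default threshold for dataset "
                f"{dataset!r}; known: {sorted(DEFAULT_Q_MIN)})"
            )
        q_min = DEFAULT_Q_MIN[dataset]
    if not 0 < q_min < 1:
        raise ConfigError(f"q_min must be in (0, 1), got {q_min}")
    q = result.table["q"]
    return frozenset(q.index[q > q_min])


def read_counts(path) -> pd.DataFrame:
    """Read a transcripts-by-samples counts TSV (first column transcript_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df.astype(float)


def read_groups(path) -> dict[str, str]:
    """Read a ``sample<TAB>group`` table into a dict."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return dict(zip(df["sample"], df["group"]))
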