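"""Dominant (major) isoforms, their involvement in complexes, and switching.

The major isoform of a gene in a sample is its highest-expressed *detected*
transcript (ties broken by lexicographically smallest transcript id); genes
with no detected transcript have no major isoform in that sample.

Involvement asks how often the complex machinery runs on dominant isoforms:
(a) the fraction of formable complexes with at least one subunit whose
transcript set contains a major isoform, and (b) the fraction of expressed
subunit proteins whose transcript set contains the major isoform of one of
their genes.

Switching compares two samples: among eligible complex constituents (proteins
with >=2 associated transcripts from a single gene) whose evaluation gene has
a major isoform defined in *both* samples, the switch fraction is the share
whose major isoform differs.  Denominators are pair-specific and reported; a
pair with an empty denominator has an undefined (NaN) fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .complex_map import ComplexRecord, MappingTable
from .detection import DetectionCall, ExpressionMatrix
from .errors import ConfigError
from .pfpc import PFPCResult


@dataclass
class MajorIsoformAssignment:
    """Per-sample gene-to-dominant-transcript maps."""

    samples: list[str]
    by_sample: dict[str, dict[str, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s, g, t)
            for s in self.samples
            for g, t in sorted(self.by_sample[s].items())
        ]
        return pd.DataFrame(rows, columns=["sample", "gene_id", "major_transcript"])


@dataclass
class SwitchMatrix:
    """Pairwise major-isoform switch fractions over eligible constituents."""

    fractions: pd.DataFrame
    denominators: pd.DataFrame
    n_eligible: int
    overall_switch_fraction: float


def assign_major_isoforms(
    expr: ExpressionMatrix,
    call: DetectionCall,
    transcript_to_gene: Mapping[str, str],
) -> MajorIsoformAssignment:
    """Pick, per gene and sample, the detected transcript with maximal estimate.

    Transcripts missing from the gene map are ignored (they cannot be assigned
    to any gene).  Ties go to the lexicographically smallest transcript id.
    """
    if expr.level != "transcript":
        raise ConfigError("major-isoform assignment requires a transcript-level matrix")
    features = [t for t in expr.features if t in transcript_to_gene]
    genes = pd.Series([transcript_to_gene[t] for t in features], index=features)
    by_sample: dict[str, dict[str, str]] = {}
    for s in expr.samples:
        est = expr.estimate.loc[features, s].where(call.detected.loc[features, s])
        est = est.dropna()
        if est.empty:
            by_sample[s] = {}
            continue
        df = pd.DataFrame(
            {"gene": genes.loc[est.index], "est": est.to_numpy()},
            index=est.index,
        )
        # stable sort after lexicographic index ordering: the first row per
        # gene is the max-estimate transcript, min-id under ties
        df = df.loc[sorted(df.index)].sort_values(
            by=["gene", "est"], ascending=[True, False], kind="mergesort"
        )
        first = df[~df["gene"].duplicated()]
        by_sample[s] = {g: t for t, g in first["gene"].items()}
    return MajorIsoformAssignment(samples=list(expr.samples), by_sample=by_sample)


def eligible_components(
    proteins: Iterable[str],
    mapping: MappingTable,
    min_transcripts: int = 2,
) -> dict[str, str]:
    """Map each eligible constituent protein to its evaluation gene.

    A protein is eligible when some single gene contributes at least
    ``min_transcripts`` of its associated transcripts; switching is evaluated
    on that gene (the lexicographically smallest qualifying one, for
    determinism, if several qualify).
    """
    if min_transcripts < 2:
        raise ConfigError("min_transcripts must be >= 2")
    out: dict[str, str] = {}
    for p in proteins:
        per_gene: dict[str, int] = {}
        for t in mapping.protein_to_transcripts.get(p, frozenset()):
            g = mapping.transcript_to_gene[t]
            per_gene[g] = per_gene.get(g, 0) + 1
        qualifying = sorted(g for g, n in per_gene.items() if n >= min_transcripts)
        if qualifying:
            out[p] = qualifying[0]
    return out


def switch_matrix(
    assignment: MajorIsoformAssignment, eligible: Mapping[str, str]
) -> SwitchMatrix:
    """Pairwise switch fractions between all sample pairs.

    The overall fraction is the share of eligible constituents whose gene's
    major isoform takes at least two distinct values across the samples where
    it is defined.
    """
    samples = assignment.samples
    if len(samples) < 2:
        raise ConfigError("switch matrix requires at least 2 samples")
    comps = sorted(eligible)
    genes = [eligible[p] for p in comps]
    # major[i][k] = major isoform of component k's gene in sample i (None if undefined)
    major = [
        [assignment.by_sample[s].get(g) for g in genes] for s in samples
    ]
    n = len(samples)
    frac = np.full((n, n), np.nan)
    denom = np.zeros((n, n), dtype=int)
    np.fill_diagonal(frac, 0.0)
    for i in range(n):
        denom[i, i] = sum(m is not None for m in major[i])
    for i in range(n):
        for j in range(i + 1, n):
            both = [
                (a, b)
                for a, b in zip(major[i], major[j])
                if a is not None and b is not None
            ]
            denom[i, j] = denom[j, i] = len(both)
            if both:
                switched = sum(a != b for a, b in both)
                frac[i, j] = frac[j, i] = switched / len(both)
    ever = 0
    for k in range(len(comps)):
        defined = {major[i][k] for i in range(n) if major[i][k] is not None}
        if len(defined) >= 2:
            ever += 1
    overall = ever / len(comps) if comps else 0.0
    idx = pd.Index(samples, name="sample")
    return SwitchMatrix(
        fractions=pd.DataFrame(frac, index=idx, columns=idx),
        denominators=pd.DataFrame(denom, index=idx, columns=idx),
        n_eligible=len(comps),
        overall_switch_fraction=overall,
    )


def major_involvement(
    assignment: MajorIsoformAssignment,
    pfpc: PFPCResult,
    complexes: Iterable[ComplexRecord],
    mapping: MappingTable,
) -> pd.DataFrame:
    """Per-sample major-isoform involvement fractions.

    Columns: ``pfpc_major_fraction`` (share of formable complexes with >=1
    subunit carrying a major isoform) and ``subunit_major_fraction`` (share of
    expressed subunit proteins carrying one).  Undefined fractions (empty
    denominator) are NaN.
    """
    if pfpc.level != "transcript":
        raise ConfigError("involvement requires transcript-level formability calls")
    recs = {rec.complex_id: rec for rec in complexes}
    rows = []
    for s in assignment.samples:
        majors = frozenset(assignment.by_sample[s].values())
        expressed = pfpc.expressed_subunits[s]
        has_major = {
            p
            for p in expressed
            if mapping.protein_to_transcripts[p] & majors
        }
        sub_frac = len(has_major) / len(expressed) if expressed else np.nan
        formable = pfpc.formable[s]
        hit = sum(
            1
            for c in formable
            if any(
                mapping.protein_to_transcripts[p] & majors
                for p in recs[c].subunit_set
            )
        )
        pf_frac = hit / len(formable) if formable else np.nan
        rows.append((s, pf_frac, sub_frac))
    return pd.DataFrame(
        rows, columns=["sample", "pfpc_major_fraction", "subunit_major_fraction"]
    ).set_index("sample")
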