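"""Possible formable protein complexes (PFPCs).

A complex is *possibly formable* in a sample when every one of its subunit
proteins is expressed there, where a protein counts as expressed if at least
one of its associated features (transcripts at transcript level, genes at
gene level) is detected.  PFPC status is a transcript-presence proxy for
assemblability, not evidence of physical assembly.

Besides the per-sample PFPC sets this module reports the per-sample expressed
subunit fraction, the PFPC fraction and their gap, the "missing-one"
diagnostic (complexes failing because exactly one subunit is unexpressed —
the dominant failure mode), and cross-sample summaries (common PFPCs, and the
case/control intersection decomposition for two-group designs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .complex_map import ComplexRecord, MappingTable
from .detection import DetectionCall
from .errors import ConfigError


@dataclass
class PFPCResult:
    """Per-sample formability calls and derived ratios at one level."""

    level: str
    samples: list[str]
    complex_ids: list[str]
    formable: dict[str, frozenset[str]]
    expressed_subunits: dict[str, frozenset[str]]
    missing_one: dict[str, frozenset[str]]
    summary: pd.DataFrame
    n_complexes: int
    n_subunit_proteins: int


def _features_of(protein: str, mapping: MappingTable, level: str) -> frozenset[str]:
    table = (
        mapping.protein_to_transcripts if level == "transcript" else mapping.protein_to_genes
    )
    if protein not in table:
        raise ConfigError(
            f"protein {protein} absent from mapping; unmappable subunits must be "
            "dropped during resolution"
        )
    return table[protein]


def protein_expressed(
    protein: str, call: DetectionCall, mapping: MappingTable
) -> pd.Series:
    """Per-sample boolean: does any associated feature of ``protein`` get detected?"""
    features = _features_of(protein, mapping, call.level)
    present = [f for f in features if f in call.detected.index]
    if not present:
        return pd.Series(False, index=call.detected.columns)
    return call.detected.loc[present].any(axis=0)


def _expressed_matrix(
    proteins: Sequence[str], call: DetectionCall, mapping: MappingTable
) -> pd.DataFrame:
    rows = {p: protein_expressed(p, call, mapping) for p in proteins}
    return pd.DataFrame(rows).T.reindex(list(proteins))


def call_pfpc(
    complexes: Sequence[ComplexRecord],
    call: DetectionCall,
    mapping: MappingTable,
) -> PFPCResult:
    """Call PFPCs: a complex is formable in a sample iff all subunits are expressed.

    The summary carries, per sample: PFPC count and fraction of all complexes,
    expressed-subunit count and fraction of all subunit proteins, the gap
    between the two fractions, and the missing-one count.
    """
    samples = call.samples
    proteins = sorted({p for rec in complexes for p in rec.subunit_set})
    expressed = _expressed_matrix(proteins, call, mapping)
    formable: dict[str, frozenset[str]] = {}
    missing_one: dict[str, frozenset[str]] = {}
    expressed_subunits: dict[str, frozenset[str]] = {}
    for s in samples:
        col = expressed[s]
        expressed_subunits[s] = frozenset(col.index[col])
        form = []
        miss1 = []
        for rec in complexes:
            n_expr = sum(bool(col[p]) for p in rec.subunit_set)
            if n_expr == len(rec.subunit_set):
                form.append(rec.complex_id)
            elif n_expr == len(rec.subunit_set) - 1:
                miss1.append(rec.complex_id)
        formable[s] = frozenset(form)
        missing_one[s] = frozenset(miss1)
    n_complexes = len(complexes)
    n_proteins = len(proteins)
    summary = pd.DataFrame(
        {
            "n_pfpc": [len(formable[s]) for s in samples],
            "pfpc_fraction": [
                len(formable[s]) / n_complexes if n_complexes else 0.0 for s in samples
            ],
            "n_expressed_subunits": [len(expressed_subunits[s]) for s in samples],
            "expressed_subunit_fraction": [
                len(expressed_subunits[s]) / n_proteins if n_proteins else 0.0
                for s in samples
            ],
            "n_missing_one": [len(missing_one[s]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    summary["fraction_gap"] = (
        summary["expressed_subunit_fraction"] - summary["pfpc_fraction"]
    )
    return PFPCResult(
        level=call.level,
        samples=list(samples),
        complex_ids=[rec.complex_id for rec in complexes],
        formable=formable,
        expressed_subunits=expressed_subunits,
        missing_one=missing_one,
        summary=summary,
        n_complexes=n_complexes,
        n_subunit_proteins=n_proteins,
    )


def pfpc_cross_sample(
    result: PFPCResult,
    groups: Mapping[str, Sequence[str]] | None = None,
    group_reduce: str = "intersection",
) -> dict:
    """Cross-sample PFPC summary.

    Returns per-sample counts, the samples with the most and fewest PFPCs, the
    common-PFPC set (intersection across all samples) and its fraction of the
    complex universe.  With ``groups`` mapping exactly two group names to
    sample lists (a case/control design), additionally returns each group's
    PFPC set (reduced across its samples by intersection, or union if
    ``group_reduce='union'``), the shared set, and each group's private set.
    """
    if len(result.samples) < 2:
        raise ConfigError("cross-sample summary requires at least 2 samples")
    counts = result.summary["n_pfpc"]
    common = frozenset.intersection(*(result.formable[s] for s in result.samples))
    out: dict = {
        "per_sample_counts": counts,
        "max_sample": str(counts.idxmax()),
        "min_sample": str(counts.idxmin()),
        "common_pfpcs": common,
        "n_common": len(common),
        "common_fraction": len(common) / result.n_complexes
        if result.n_complexes
        else 0.0,
    }
    if groups is not None:
        if len(groups) != 2:
            raise ConfigError("group decomposition requires exactly 2 groups")
        if group_reduce not in ("intersection", "union"):
            raise ConfigError(f"unknown group_reduce {group_reduce!r}")
        reduce = (
            frozenset.intersection if group_reduce == "intersection" else frozenset.union
        )
        group_sets = {}
        for gname, members in groups.items():
            if not members:
                raise ConfigError(f"group {gname!r} has no samples")
            group_sets[gname] = reduce(*(result.formable[s] for s in members))
        (g1, s1), (g2, s2) = group_sets.items()
        out["group_sets"] = group_sets
        out["shared"] = s1 & s2
        out["only"] = {g1: s1 - s2, g2: s2 - s1}
    return out


def write_pfpc_matrix(result: PFPCResult, path) -> None:
    """Write the complex-by-sample 0/1 formability TSV (full complex universe)."""
    rows = {
        s: [1 if c in result.formable[s] else 0 for c in result.complex_ids]
        for s in result.samples
    }
    df = pd.DataFrame(rows, index=pd.Index(result.complex_ids, name="complex_id"))
    df.to_csv(path, sep="\t")
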