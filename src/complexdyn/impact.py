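"""Propagation of differentially expressed transcripts to affected complexes.

A DE transcript impacts a complex when some subunit of the complex has that
transcript in its associated set; a complex is *affected* when at least one
subunit has at least one associated DE transcript.  Because subunits are
shared across complexes and each subunit carries several transcripts, small
DE-transcript overlaps between datasets typically amplify into much larger
affected-complex overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .complex_map import ComplexRecord, MappingTable
from .errors import ConfigError


@dataclass
class ComplexImpact:
    """DE transcripts restricted to the complex universe and their reach."""

    dataset: str
    de_in_complex: frozenset[str]
    affected_complexes: frozenset[str]
    per_complex: dict[str, frozenset[str]]
    universe: frozenset[str]


def map_de_to_complexes(
    de_set: Iterable[str],
    complexes: Sequence[ComplexRecord],
    mapping: MappingTable,
    dataset: str = "",
) -> ComplexImpact:
    """Reachability from DE transcripts to complexes through subunit transcript sets.

    DE transcripts outside every subunit's transcript set simply do not appear
    in ``de_in_complex``.
    """
    de = frozenset(de_set)
    per_complex: dict[str, frozenset[str]] = {}
    de_in_complex: set[str] = set()
    for rec in complexes:
        hits = frozenset(
            t
            for p in rec.subunit_set
            for t in mapping.protein_to_transcripts[p] & de
        )
        if hits:
            per_complex[rec.complex_id] = hits
            de_in_complex |= hits
    return ComplexImpact(
        dataset=dataset,
        de_in_complex=frozenset(de_in_complex),
        affected_complexes=frozenset(per_complex),
        per_complex=per_complex,
        universe=frozenset(rec.complex_id for rec in complexes),
    )


@dataclass
class OverlapResult:
    """Pairwise and global overlaps of DE transcripts and affected complexes."""

    transcript_overlap: pd.DataFrame
    complex_overlap: pd.DataFrame
    combined: pd.DataFrame
    amplification: pd.DataFrame
    common_complexes: frozenset[str]
    common_transcripts: frozenset[str]


def cross_dataset_overlap(impacts: Sequence[ComplexImpact]) -> OverlapResult:
    """Pairwise overlap matrices across datasets sharing one complex universe.

    ``transcript_overlap``/``complex_overlap`` carry intersection counts
    (diagonal = own set size).  ``combined`` mirrors the one-matrix layout:
    upper triangle = shared affected complexes, lower = shared in-complex DE
    transcripts, diagonal 0.  ``amplification`` is the complex/transcript
    overlap ratio per pair, NaN where the transcript overlap is zero.
    """
    if len(impacts) < 2:
        raise ConfigError("overlap requires at least 2 datasets")
    universes = {imp.universe for imp in impacts}
    if len(universes) != 1:
        raise ConfigError("impacts were computed over different complex universes")
    names = [imp.dataset for imp in impacts]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate dataset names")
    n = len(impacts)
    tx = np.zeros((n, n), dtype=int)
    cx = np.zeros((n, n), dtype=int)
    for i, a in enumerate(impacts):
        for j, b in enumerate(impacts):
            tx[i, j] = len(a.de_in_complex & b.de_in_complex)
            cx[i, j] = len(a.affected_complexes & b.affected_complexes)
    idx = pd.Index(names, name="dataset")
    combined = np.where(np.triu(np.ones((n, n), dtype=bool), k=1), cx, tx)
    np.fill_diagonal(combined, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = np.where(tx > 0, cx / np.where(tx > 0, tx, 1), np.nan)
    np.fill_diagonal(amp, np.nan)
    return OverlapResult(
        transcript_overlap=pd.DataFrame(tx, index=idx, columns=idx),
        complex_overlap=pd.DataFrame(cx, index=idx, columns=idx),
        combined=pd.DataFrame(combined, index=idx, columns=idx),
        amplification=pd.DataFrame(amp, index=idx, columns=idx),
        common_complexes=frozenset.intersection(
            *(imp.affected_complexes for imp in impacts)
        ),
        common_transcripts=frozenset.intersection(
            *(imp.de_in_complex for imp in impacts)
        ),
    )
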