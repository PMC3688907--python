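"""Protein-complex tables: parsing, de-duplication, and ID resolution.

A complex table is a CORUM-style TSV (``complex_id<TAB>name<TAB>subunits``,
subunits semicolon-separated Uniprot-style accessions).  A mapping table is a
Uniprot-to-Ensembl-style TSV (``protein_id<TAB>transcript_id<TAB>gene_id``,
one association per row) encoding the many-to-many relation between proteins
and the transcripts that can encode them; each transcript belongs to exactly
one gene.

Loading removes redundant complexes (identical subunit membership, first
record kept) and complexes containing uncertain subunits (tokens carrying a
configurable ambiguity marker, CORUM-style ``(P1|P2)`` alternatives).
Resolution keeps only complexes whose every subunit has at least one
associated transcript, yielding the analysis universe of complexes, proteins,
genes and transcripts.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Substrings that flag a subunit token as ambiguous (CORUM-style alternatives).
UNCERTAINTY_MARKERS: tuple[str, ...] = ("(", "|")

COMPLEX_COLUMNS = ("complex_id", "name", "subunits")
MAPPING_COLUMNS = ("protein_id", "transcript_id", "gene_id")


@dataclass(frozen=True)
class ComplexRecord:
    """A named protein complex and, after resolution, its gene/transcript sets.

    ``subunits`` preserves file order (duplicates within a row collapsed);
    identity for de-duplication is the *set* of accessions.
    """

    complex_id: str
    name: str
    subunits: tuple[str, ...]
    resolved_genes: frozenset[str] = frozenset()
    resolved_transcripts: frozenset[str] = frozenset()

    @property
    def subunit_set(self) -> frozenset[str]:
        return frozenset(self.subunits)

    @property
    def size(self) -> int:
        return len(self.subunits)


@dataclass(frozen=True)
class MappingTable:
    """Many-to-many protein/transcript and protein/gene association maps.

    ``protein_to_genes`` is derived as the image of ``protein_to_transcripts``
    under ``transcript_to_gene``.
    """

    protein_to_transcripts: Mapping[str, frozenset[str]]
    transcript_to_gene: Mapping[str, str]
    protein_to_genes: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_associations(cls, rows: Iterable[tuple[str, str, str]]) -> "MappingTable":
        """Build a table from (protein, transcript, gene) association triples."""
        p2t: dict[str, set[str]] = {}
        t2g: dict[str, str] = {}
        for protein, transcript, gene in rows:
            if not protein or not transcript or not gene:
                raise FormatError(
                    f"empty field in association ({protein!r}, {transcript!r}, {gene!r})"
                )
            prev = t2g.get(transcript)
            if prev is not None and prev != gene:
                raise FormatError(
                    f"transcript {transcript} mapped to two genes: {prev}, {gene}"
                )
            t2g[transcript] = gene
            p2t.setdefault(protein, set()).add(transcript)
        p2t_frozen = {p: frozenset(ts) for p, ts in p2t.items()}
        p2g = {p: frozenset(t2g[t] for t in ts) for p, ts in p2t_frozen.items()}
        return cls(p2t_frozen, t2g, p2g)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.protein_to_transcripts)


def _read_tsv_rows(path: Path, n_fields: int, header: Sequence[str]):
    """Yield (line_number, fields) for a '#'-commented TSV, checking the header."""
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header_seen = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header_seen is None:
                header_seen = [c.strip() for c in row]
                for col in header:
                    if col not in header_seen:
                        raise FormatError(
                            f"{path}: missing required column {col!r} in header"
                        )
                idx = [header_seen.index(c) for c in header]
                continue
            if len(row) < len(header_seen):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header_seen)} fields, got {len(row)}"
                )
            yield lineno, [row[i].strip() for i in idx]
        if header_seen is None:
            raise FormatError(f"{path}: empty file, header required")


def load_complexes(
    path: str | Path,
    uncertainty_markers: Sequence[str] = UNCERTAINTY_MARKERS,
) -> tuple[list[ComplexRecord], list[tuple[str, str]]]:
    """Parse a complex table, dropping uncertain and redundant records.

    Returns ``(records, rejects)`` where ``rejects`` is a list of
    ``(complex_id, reason)`` rows for the rejects report.  Records with
    identical subunit sets are collapsed to the first occurrence; records with
    an ambiguous subunit token or an empty subunit list are rejected, not
    fatal.  Survivor order follows the input file.
    """
    records: list[ComplexRecord] = []
    rejects: list[tuple[str, str]] = []
    seen_sets: set[frozenset[str]] = set()
    for lineno, (complex_id, name, subunit_field) in _read_tsv_rows(
        Path(path), 3, COMPLEX_COLUMNS
    ):
        tokens = [t.strip() for t in subunit_field.split(";")]
        tokens = [t for t in tokens if t]
        if not tokens:
            rejects.append((complex_id, "empty subunit list"))
            continue
        uncertain = next(
            (t for t in tokens if any(m in t for m in uncertainty_markers)), None
        )
        if uncertain is not None:
            rejects.append((complex_id, f"uncertain subunit: {uncertain}"))
            continue
        # collapse duplicate tokens within a row, keeping first occurrence
        unique: list[str] = []
        for t in tokens:
            if t not in unique:
                unique.append(t)
        key = frozenset(unique)
        if key in seen_sets:
            logger.debug("line %d: duplicate subunit set for %s", lineno, complex_id)
            continue
        seen_sets.add(key)
        records.append(ComplexRecord(complex_id, name, tuple(unique)))
    return records, rejects


def write_rejects(rejects: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write the rejects report (``complex_id<TAB>reason``)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("complex_id\treason\n")
        for complex_id, reason in rejects:
            handle.write(f"{complex_id}\t{reason}\n")


def write_complexes(records: Sequence[ComplexRecord], path: str | Path) -> None:
    """Serialize complex records back to the complex-table TSV format."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("complex_id\tname\tsubunits\n")
        for rec in records:
            handle.write(f"{rec.complex_id}\t{rec.name}\t{';'.join(rec.subunits)}\n")


def load_mapping(path: str | Path) -> MappingTable:
    """Parse a protein-to-transcript/gene mapping table."""
    rows: list[tuple[str, str, str]] = []
    for lineno, (protein, transcript, gene) in _read_tsv_rows(
        Path(path), 3, MAPPING_COLUMNS
    ):
        if not protein or not transcript or not gene:
            raise FormatError(f"{path}: line {lineno}: empty field in mapping row")
        rows.append((protein, transcript, gene))
    try:
        return MappingTable.from_associations(rows)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def resolve_complexes(
    complexes: Sequence[ComplexRecord], mapping: MappingTable
) -> tuple[list[ComplexRecord], list[tuple[str, str]]]:
    """Keep complexes whose every subunit has at least one mapped transcript.

    Returns ``(kept, dropped)``; ``dropped`` names each eliminated complex with
    its first unmapped subunit.  Kept records carry the union of their
    subunits' transcript and gene sets.
    """
    kept: list[ComplexRecord] = []
    dropped: list[tuple[str, str]] = []
    for rec in complexes:
        missing = next(
            (
                p
                for p in rec.subunits
                if not mapping.protein_to_transcripts.get(p)
            ),
            None,
        )
        if missing is not None:
            dropped.append((rec.complex_id, missing))
            continue
        transcripts = frozenset().union(
            *(mapping.protein_to_transcripts[p] for p in rec.subunits)
        )
        genes = frozenset().union(*(mapping.protein_to_genes[p] for p in rec.subunits))
        kept.append(replace(rec, resolved_transcripts=transcripts, resolved_genes=genes))
    return kept, dropped


@dataclass
class ComplexStats:
    """Summary statistics of a resolved complex universe."""

    per_protein: pd.DataFrame
    n_complexes: int
    n_proteins: int
    n_genes: int
    n_transcripts: int
    mean_transcripts_per_subunit: float
    mean_genes_per_subunit: float
    multi_transcript_fraction: float
    shared_fraction: float
    max_complexes_per_protein: int
    top_shared_protein: str | None
    size_histogram: pd.Series
    transcripts_per_subunit_histogram: pd.Series

    def to_dict(self) -> dict:
        return {
            "n_complexes": self.n_complexes,
            "n_proteins": self.n_proteins,
            "n_genes": self.n_genes,
            "n_transcripts": self.n_transcripts,
            "mean_transcripts_per_subunit": self.mean_transcripts_per_subunit,
            "mean_genes_per_subunit": self.mean_genes_per_subunit,
            "multi_transcript_fraction": self.multi_transcript_fraction,
            "shared_fraction": self.shared_fraction,
            "max_complexes_per_protein": self.max_complexes_per_protein,
            "top_shared_protein": self.top_shared_protein,
            "size_histogram": {int(k): int(v) for k, v in self.size_histogram.items()},
            "transcripts_per_subunit_histogram": {
                int(k): int(v)
                for k, v in self.transcripts_per_subunit_histogram.items()
            },
        }


def complex_stats(kept: Sequence[ComplexRecord], mapping: MappingTable) -> ComplexStats:
    """Summarise a resolved universe: per-protein transcript/gene counts, the
    fraction of subunits with >=2 transcripts, the protein-sharing fraction and
    maximum, and the complex-size and transcripts-per-subunit histograms.
    """
    if not kept:
        logger.warning("complex_stats called on an empty complex list")
        empty = pd.DataFrame(columns=["n_transcripts", "n_genes", "n_complexes"])
        return ComplexStats(
            per_protein=empty,
            n_complexes=0,
            n_proteins=0,
            n_genes=0,
            n_transcripts=0,
            mean_transcripts_per_subunit=0.0,
            mean_genes_per_subunit=0.0,
            multi_transcript_fraction=0.0,
            shared_fraction=0.0,
            max_complexes_per_protein=0,
            top_shared_protein=None,
            size_histogram=pd.Series(dtype=int),
            transcripts_per_subunit_histogram=pd.Series(dtype=int),
        )
    complexes_per_protein: dict[str, int] = {}
    for rec in kept:
        for p in rec.subunit_set:
            complexes_per_protein[p] = complexes_per_protein.get(p, 0) + 1
    proteins = sorted(complexes_per_protein)
    n_tx = {p: len(mapping.protein_to_transcripts[p]) for p in proteins}
    n_genes = {p: len(mapping.protein_to_genes[p]) for p in proteins}
    per_protein = pd.DataFrame(
        {
            "n_transcripts": [n_tx[p] for p in proteins],
            "n_genes": [n_genes[p] for p in proteins],
            "n_complexes": [complexes_per_protein[p] for p in proteins],
        },
        index=pd.Index(proteins, name="protein_id"),
    )
    all_transcripts = frozenset().union(*(r.resolved_transcripts for r in kept))
    all_genes = frozenset().union(*(r.resolved_genes for r in kept))
    top = per_protein["n_complexes"].idxmax()
    sizes = pd.Series([r.size for r in kept])
    return ComplexStats(
        per_protein=per_protein,
        n_complexes=len(kept),
        n_proteins=len(proteins),
        n_genes=len(all_genes),
        n_transcripts=len(all_transcripts),
        mean_transcripts_per_subunit=float(per_protein["n_transcripts"].mean()),
        mean_genes_per_subunit=float(per_protein["n_genes"].mean()),
        multi_transcript_fraction=float((per_protein["n_transcripts"] >= 2).mean()),
        shared_fraction=float((per_protein["n_complexes"] >= 2).mean()),
        max_complexes_per_protein=int(per_protein["n_complexes"].max()),
        top_shared_protein=str(top),
        size_histogram=sizes.value_counts().sort_index(),
        transcripts_per_subunit_histogram=per_protein["n_transcripts"]
        .value_counts()
        .sort_index(),
    )
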