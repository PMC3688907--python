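"""End-to-end orchestration: map -> detect -> pfpc -> isoform -> de -> impact.

Each stage is an independently callable function writing its outputs under
the run's output directory; :func:`run_pipeline` chains them and writes a
top-level ``summary.json`` with the counts a reader would pull from the
figure-analogue tables (size histograms, per-sample formability counts at
both levels, involvement fractions, the switch matrix range, DE counts and
overlap matrices).  Outputs are a deterministic function of the input files
and the run configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import complex_map, de, detection, impact, isoform, pfpc
from .errors import ComplexdynError, ConfigError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class DatasetInput:
    """One case/control dataset: counts, group labels, optional q threshold."""

    counts: Path
    groups: Path
    q_min: float | None = None


@dataclass
class RunConfig:
    """Validated inputs and parameters of one pipeline run."""

    complexes: Path
    mapping: Path
    expression: list[Path] = field(default_factory=list)
    datasets: dict[str, DatasetInput] = field(default_factory=dict)
    sd_max: float = detection.DEFAULT_SD_MAX
    min_estimate: float | None = None
    outdir: Path = Path("results")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        base = Path(path).parent
        resolve = lambda p: (base / p) if not Path(p).is_absolute() else Path(p)
        datasets = {
            name: DatasetInput(
                counts=resolve(d["counts"]),
                groups=resolve(d["groups"]),
                q_min=d.get("q_min"),
            )
            for name, d in (raw.get("datasets") or {}).items()
        }
        return cls(
            complexes=resolve(raw["complexes"]),
            mapping=resolve(raw["mapping"]),
            expression=[resolve(p) for p in raw.get("expression", [])],
            datasets=datasets,
            sd_max=float(raw.get("sd_max", detection.DEFAULT_SD_MAX)),
            min_estimate=raw.get("min_estimate"),
            outdir=resolve(raw.get("outdir", "results")),
            seed=int(raw.get("seed", 0)),
        )

    def validate(self) -> None:
        for path in [self.complexes, self.mapping, *self.expression] + [
            p for d in self.datasets.values() for p in (d.counts, d.groups)
        ]:
            if not Path(path).is_file():
                raise ConfigError(f"input file not found: {path}")
        if self.sd_max <= 0:
            raise ConfigError("sd_max must be positive")


def _json_default(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(data: Mapping, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(data, handle, indent=2, sort_keys=True, default=_json_default)
        handle.write("\n")


# ---------------------------------------------------------------------------
# stages


def stage_map(config: RunConfig):
    """Load, de-duplicate and resolve the complex universe; write reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, rejects = complex_map.load_complexes(config.complexes)
    complex_map.write_rejects(rejects, outdir / "rejects.tsv")
    mapping = complex_map.load_mapping(config.mapping)
    kept, dropped = complex_map.resolve_complexes(records, mapping)
    complex_map.write_complexes(kept, outdir / "complexes_kept.tsv")
    with open(outdir / "complexes_dropped.tsv", "w", encoding="utf-8") as handle:
        handle.write("complex_id\tfirst_unmapped_subunit\n")
        for cid, subunit in dropped:
            handle.write(f"{cid}\t{subunit}\n")
    stats = complex_map.complex_stats(kept, mapping)
    stats.per_protein.to_csv(outdir / "per_protein_stats.tsv", sep="\t")
    summary = {
        "n_input_records": len(records) + len(rejects),
        "n_deduplicated": len(records),
        "n_rejected": len(rejects),
        "n_kept": len(kept),
        "n_dropped": len(dropped),
        **stats.to_dict(),
    }
    del summary["top_shared_protein"]
    summary["top_shared_protein"] = stats.top_shared_protein
    _write_json(summary, outdir / "complex_stats.json")
    return kept, mapping, summary


def stage_detect(config: RunConfig, mapping: complex_map.MappingTable):
    """Assemble the transcript matrix, call detection, roll up to genes."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = detection.load_expression(config.expression, level="transcript")
    tx_call = detection.call_detection(
        expr, sd_max=config.sd_max, min_estimate=config.min_estimate
    )
    gene_call = detection.rollup_gene_detection(tx_call, mapping.transcript_to_gene)
    detection.write_detection(tx_call, outdir / "detection_transcript.tsv")
    detection.write_detection(gene_call, outdir / "detection_gene.tsv")
    return expr, tx_call, gene_call


def stage_pfpc(config: RunConfig, kept, mapping, tx_call, gene_call):
    """Formability calls at both levels plus the cross-sample summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {}
    summary = {}
    for level, call in (("transcript", tx_call), ("gene", gene_call)):
        res = pfpc.call_pfpc(kept, call, mapping)
        pfpc.write_pfpc_matrix(res, outdir / f"pfpc_{level}.tsv")
        frag = {
            "per_sample": res.summary.round(6).to_dict(orient="index"),
        }
        if len(res.samples) >= 2:
            cross = pfpc.pfpc_cross_sample(res)
            frag["n_common"] = cross["n_common"]
            frag["common_fraction"] = round(cross["common_fraction"], 6)
            frag["max_sample"] = cross["max_sample"]
            frag["min_sample"] = cross["min_sample"]
        results[level] = res
        summary[level] = frag
    _write_json(summary, outdir / "pfpc_summary.json")
    return results, summary


def stage_isoform(config: RunConfig, kept, mapping, expr, tx_call, pfpc_tx):
    """Major-isoform assignment, involvement fractions and the switch matrix."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assignment = isoform.assign_major_isoforms(
        expr, tx_call, mapping.transcript_to_gene
    )
    assignment.to_frame().to_csv(
        outdir / "major_isoforms.tsv", sep="\t", index=False
    )
    proteins = sorted({p for rec in kept for p in rec.subunit_set})
    eligible = isoform.eligible_components(proteins, mapping)
    involvement = isoform.major_involvement(assignment, pfpc_tx, kept, mapping)
    involvement.round(6).to_csv(outdir / "involvement.tsv", sep="\t")
    summary = {
        "n_eligible": len(eligible),
        "involvement": involvement.round(6).to_dict(orient="index"),
    }
    switches = None
    if len(assignment.samples) >= 2:
        switches = isoform.switch_matrix(assignment, eligible)
        switches.fractions.round(6).to_csv(outdir / "switch_matrix.tsv", sep="\t")
        switches.denominators.to_csv(
            outdir / "switch_denominators.tsv", sep="\t"
        )
        values = switches.fractions.to_numpy().copy()
        np.fill_diagonal(values, np.nan)
        flat = values[~np.isnan(values)]
        summary.update(
            {
                "overall_switch_fraction": round(switches.overall_switch_fraction, 6),
                "switch_fraction_min": round(float(flat.min()), 6) if flat.size else None,
                "switch_fraction_max": round(float(flat.max()), 6) if flat.size else None,
            }
        )
    _write_json(summary, outdir / "isoform_summary.json")
    return assignment, eligible, switches, summary


def stage_de(config: RunConfig):
    """Normalize each dataset, compute (M, D, q) and call DE sets."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    de_sets: dict[str, frozenset[str]] = {}
    summary = {}
    for idx, (name, ds) in enumerate(sorted(config.datasets.items())):
        counts = de.read_counts(ds.counts)
        groups = de.read_groups(ds.groups)
        normalized = de.normalize_median_deviation(counts)
        child_seed = (config.seed * 100003 + idx) % (2**31)
        result = de.noiseq_probability(normalized, groups, seed=child_seed)
        q_min = ds.q_min
        if q_min is None and name in de.DEFAULT_Q_MIN:
            q_min = de.DEFAULT_Q_MIN[name]
        called = de.de_call(result, q_min=q_min, dataset=name)
        table = result.table.copy()
        table["de_flag"] = table.index.isin(called).astype(int)
        table.round(6).to_csv(outdir / f"de_{name}.tsv", sep="\t")
        de_sets[name] = called
        summary[name] = {
            "q_min": q_min,
            "mode": result.mode,
            "n_transcripts": int(len(table)),
            "n_de": len(called),
        }
    _write_json(summary, outdir / "de_summary.json")
    return de_sets, summary


def stage_impact(config: RunConfig, de_sets, kept, mapping):
    """Propagate DE sets to affected complexes and compute overlaps."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    impacts = [
        impact.map_de_to_complexes(s, kept, mapping, dataset=name)
        for name, s in sorted(de_sets.items())
    ]
    summary = {
        "per_dataset": {
            imp.dataset: {
                "n_de_in_complex": len(imp.de_in_complex),
                "n_affected_complexes": len(imp.affected_complexes),
            }
            for imp in impacts
        }
    }
    if len(impacts) >= 2:
        overlap = impact.cross_dataset_overlap(impacts)
        overlap.transcript_overlap.to_csv(
            outdir / "overlap_transcripts.tsv", sep="\t"
        )
        overlap.complex_overlap.to_csv(outdir / "overlap_complexes.tsv", sep="\t")
        overlap.combined.to_csv(outdir / "overlap_combined.tsv", sep="\t")
        summary["n_common_complexes"] = len(overlap.common_complexes)
        summary["n_common_transcripts"] = len(overlap.common_transcripts)
        summary["common_complexes"] = sorted(overlap.common_complexes)
    _write_json(summary, outdir / "impact_summary.json")
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write ``summary.json``; stage failures name the stage."""
    config.validate()
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    def run(name, fn, *args):
        logger.info("stage %s", name)
        try:
            return fn(config, *args)
        except ComplexdynError as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    kept, mapping, summary["map"] = run("map", stage_map)
    if config.expression:
        expr, tx_call, gene_call = run("detect", stage_detect, mapping)
        pfpc_results, summary["pfpc"] = run(
            "pfpc", stage_pfpc, kept, mapping, tx_call, gene_call
        )
        _, _, _, summary["isoform"] = run(
            "isoform", stage_isoform, kept, mapping, expr, tx_call,
            pfpc_results["transcript"],
        )
    if config.datasets:
        de_sets, summary["de"] = run("de", stage_de)
        summary["impact"] = run("impact", stage_impact, de_sets, kept, mapping)
    _write_json(summary, Path(config.outdir) / "summary.json")
    return summary
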