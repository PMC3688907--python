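"""Synthetic universes for the complex-expression pipeline, with ground truth.

The generator emulates the statistical structure of a curated complex
resource mapped onto a reference transcriptome and profiled across tissues
and case/control cohorts: complex sizes concentrated on 2-4 subunits, about
half of subunit proteins shared across >=2 complexes, subunits carrying ~2.3
transcripts on average (vs ~1.35 for non-complex proteins), co-expressed
complex members with planted absent subunits, planted dominant isoforms with
exact switch planting between tissues, and negative-binomial case/control
count matrices with planted fold-changes.

Everything planted is recorded in a :class:`GroundTruth` ledger consistent
with the emitted files by construction, so downstream modules can be tested
for exact recovery in the zero-noise limit without any external downloads.
Identical configurations (including the seed) yield byte-identical output
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .complex_map import ComplexRecord, MappingTable
from .errors import ConfigError

_DEFAULT_SIZE_PROBS = {2: 0.45, 3: 0.25, 4: 0.15, 5: 0.07, 6: 0.04, 7: 0.02, 8: 0.02}


@dataclass
class DatasetConfig:
    """Replicate structure and planting for one case/control count dataset."""

    n_case: int = 5
    n_control: int = 5
    de_fraction: float = 0.05
    fold_change: float = 4.0


def default_datasets() -> dict[str, DatasetConfig]:
    """Four cancer-style datasets mirroring typical replicate availability."""
    return {
        "breast": DatasetConfig(n_case=2, n_control=2),
        "colon": DatasetConfig(n_case=2, n_control=2),
        "lung": DatasetConfig(n_case=1, n_control=1),
        "prostate": DatasetConfig(n_case=12, n_control=9),
    }


@dataclass
class SynthConfig:
    """All knobs of the generator; defaults are the emulation targets.

    Rates are probabilities in [0, 1].  ``tx_per_gene_mean`` targets the
    ~2.26 transcripts per complex subunit of curated complexes, while decoy
    (non-complex) genes use the lower proteome-wide mean; ``sharing_rate``
    targets the ~0.49 fraction of subunits shared across complexes and is
    realized exactly up to rounding.  ``dominance_margin`` is the planted
    log-expression gap between a gene's dominant transcript and its runners-up;
    recovery of planted structure is exact whenever ``noise_sd`` stays below
    half that margin.
    """

    seed: int = 0
    n_complexes: int = 500
    complex_size_probs: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_SIZE_PROBS)
    )
    sharing_rate: float = 0.49
    tx_per_gene_mean: float = 2.26
    decoy_tx_per_gene_mean: float = 1.35
    n_decoy_genes: int = 200
    min_tx_per_gene: int = 1
    max_tx_per_gene: int = 10
    # tissue expression
    n_samples: int = 16
    coexpression: float = 0.94
    absent_rate: float = 0.06
    variable_subunit_fraction: float = 0.21
    involvement_rate: float = 0.8
    switch_rate: float = 0.11
    switch_pool_fraction: float = 0.35
    dominance_margin: float = 1.0
    noise_sd: float = 0.1
    base_log_mean: float = 3.0
    base_log_sd: float = 1.0
    sd_low: tuple[float, float] = (0.05, 0.6)
    sd_high: tuple[float, float] = (1.8, 3.0)
    # case/control count datasets
    datasets: dict[str, DatasetConfig] = field(default_factory=default_datasets)
    count_mean_log: float = 5.0
    count_mean_sd: float = 1.0
    nb_dispersion: float = 0.1
    library_size_sd: float = 0.1

    def validate(self) -> None:
        rates = {
            "sharing_rate": self.sharing_rate,
            "coexpression": self.coexpression,
            "absent_rate": self.absent_rate,
            "variable_subunit_fraction": self.variable_subunit_fraction,
            "involvement_rate": self.involvement_rate,
            "switch_rate": self.switch_rate,
            "switch_pool_fraction": self.switch_pool_fraction,
        }
        if self.switch_rate > self.switch_pool_fraction:
            raise ConfigError(
                "switch_rate cannot exceed switch_pool_fraction"
            )
        if self.absent_rate > 0 and self.absent_rate > self.variable_subunit_fraction:
            raise ConfigError(
                "absent_rate (the marginal per-sample absence rate) cannot "
                "exceed variable_subunit_fraction"
            )
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_complexes < 0 or self.n_decoy_genes < 0 or self.n_samples < 1:
            raise ConfigError("counts must be non-negative (and n_samples >= 1)")
        probs = self.complex_size_probs
        if not probs or any(s < 1 for s in probs) or any(p < 0 for p in probs.values()):
            raise ConfigError("invalid complex size distribution")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigError("complex size probabilities must sum to 1")
        if self.n_complexes == 1 and self.sharing_rate > 0:
            raise ConfigError("subunit sharing requires at least 2 complexes")
        if self.dominance_margin <= 0:
            raise ConfigError("dominance_margin must be positive")
        if not 1 <= self.min_tx_per_gene <= self.max_tx_per_gene:
            raise ConfigError("need 1 <= min_tx_per_gene <= max_tx_per_gene")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        for name, ds in self.datasets.items():
            if ds.n_case < 1 or ds.n_control < 1:
                raise ConfigError(f"dataset {name}: both groups need >= 1 sample")
            if not 0 <= ds.de_fraction <= 1 or ds.fold_change <= 0:
                raise ConfigError(f"dataset {name}: invalid DE planting")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SynthConfig":
        data = dict(data)
        if "complex_size_probs" in data:
            data["complex_size_probs"] = {
                int(k): float(v) for k, v in data["complex_size_probs"].items()
            }
        if "datasets" in data:
            data["datasets"] = {
                str(k): DatasetConfig(**v) for k, v in data["datasets"].items()
            }
        for key in ("sd_low", "sd_high"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


@dataclass
class Universe:
    """A generated complex/mapping universe plus generator-side bookkeeping."""

    complexes: list[ComplexRecord]
    mapping_rows: list[tuple[str, str, str]]
    mapping: MappingTable
    complex_proteins: list[str]
    protein_gene: dict[str, str]
    gene_transcripts: dict[str, tuple[str, ...]]
    noninvolved: frozenset[str]
    eligible: dict[str, str]
    sharing_fraction: float
    transcripts: list[str]


@dataclass
class GroundTruth:
    """Planted structure, consistent with the emitted files by construction."""

    sharing_fraction: float = 0.0
    complexes_per_protein: dict[str, int] = field(default_factory=dict)
    eligible: dict[str, str] = field(default_factory=dict)
    noninvolved_proteins: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)
    absent: dict[str, list[str]] = field(default_factory=dict)
    formable: dict[str, list[str]] = field(default_factory=dict)
    expressed_subunits: dict[str, list[str]] = field(default_factory=dict)
    major: dict[str, dict[str, str]] = field(default_factory=dict)
    switch_fractions: dict = field(default_factory=dict)
    involvement: dict[str, dict[str, float]] = field(default_factory=dict)
    de_truth: dict[str, list[str]] = field(default_factory=dict)


def _assign_slots(
    sizes: np.ndarray, slots: list[str], rng: np.random.Generator
) -> list[list[str]] | None:
    """Greedy assignment of protein slots to complexes, distinct within each."""
    pool = list(slots)
    rng.shuffle(pool)
    out: list[list[str]] = []
    for size in sizes:
        chosen: list[str] = []
        deferred: list[str] = []
        while len(chosen) < size and pool:
            x = pool.pop()
            if x in chosen:
                deferred.append(x)
            else:
                chosen.append(x)
        pool.extend(deferred)
        if len(chosen) < size:
            return None
        out.append(chosen)
    seen = set()
    for members in out:
        key = frozenset(members)
        if key in seen:
            return None
        seen.add(key)
    return out


def generate_universe(config: SynthConfig) -> Universe:
    """Generate the complex table, mapping table and structural ground truth.

    The sharing fraction is realized exactly (up to rounding): shared proteins
    appear in exactly two complexes, private ones in exactly one.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    size_values = np.array(sorted(config.complex_size_probs))
    size_probs = np.array(
        [config.complex_size_probs[s] for s in size_values], dtype=float
    )

    if config.n_complexes == 0:
        sizes = np.array([], dtype=int)
        membership: list[list[str]] = []
        n_proteins = 0
        sharing = 0.0
        proteins: list[str] = []
    else:
        sizes = rng.choice(size_values, size=config.n_complexes, p=size_probs)
        total_slots = int(sizes.sum())
        n_proteins = max(int(round(total_slots / (1.0 + config.sharing_rate))),
                         int(sizes.max()))
        n_shared = total_slots - n_proteins
        if n_shared < 0:
            n_proteins = total_slots
            n_shared = 0
        if n_shared > n_proteins:
            raise ConfigError(
                "infeasible sharing rate for the drawn complex sizes"
            )
        proteins = [f"P{i:05d}" for i in range(n_proteins)]
        shared = list(rng.choice(proteins, size=n_shared, replace=False))
        slots = proteins + shared
        membership = None
        for _ in range(100):
            membership = _assign_slots(sizes, slots, rng)
            if membership is not None:
                break
        if membership is None:
            raise ConfigError("could not assign subunits to complexes; retry budget exhausted")
        used = {p for members in membership for p in members}
        assert used == set(proteins)
        sharing = n_shared / n_proteins if n_proteins else 0.0

    complexes = [
        ComplexRecord(
            complex_id=f"CPX{i:04d}",
            name=f"synthetic complex {i}",
            subunits=tuple(sorted(members)),
        )
        for i, members in enumerate(membership)
    ]

    # genes and transcripts: one gene per complex protein
    gene_transcripts: dict[str, tuple[str, ...]] = {}
    protein_gene: dict[str, str] = {}
    mapping_rows: list[tuple[str, str, str]] = []
    tx_counter = 0
    gene_counter = 0

    def new_gene(mean_tx: float) -> tuple[str, list[str]]:
        nonlocal tx_counter, gene_counter
        gene = f"G{gene_counter:05d}"
        gene_counter += 1
        k = int(np.clip(rng.geometric(1.0 / mean_tx), config.min_tx_per_gene,
                        config.max_tx_per_gene))
        txs = [f"T{tx_counter + i:06d}" for i in range(k)]
        tx_counter += k
        return gene, txs

    for p in proteins:
        gene, txs = new_gene(config.tx_per_gene_mean)
        protein_gene[p] = gene
        gene_transcripts[gene] = tuple(txs)
        for t in txs:
            mapping_rows.append((p, t, gene))

    # non-involved subunits: the gene gains one extra transcript carried by a
    # decoy protein; that transcript is planted as the constant dominant isoform
    n_noninv = int(round((1.0 - config.involvement_rate) * len(proteins)))
    noninvolved = (
        list(rng.choice(proteins, size=n_noninv, replace=False)) if n_noninv else []
    )
    decoy_counter = 0
    for p in sorted(noninvolved):
        gene = protein_gene[p]
        extra = f"T{tx_counter:06d}"
        tx_counter += 1
        gene_transcripts[gene] = gene_transcripts[gene] + (extra,)
        decoy = f"Q{decoy_counter:05d}"
        decoy_counter += 1
        mapping_rows.append((decoy, extra, gene))

    for _ in range(config.n_decoy_genes):
        gene, txs = new_gene(config.decoy_tx_per_gene_mean)
        gene_transcripts[gene] = tuple(txs)
        decoy = f"Q{decoy_counter:05d}"
        decoy_counter += 1
        for t in txs:
            mapping_rows.append((decoy, t, gene))

    mapping = MappingTable.from_associations(mapping_rows)
    eligible = {
        p: protein_gene[p]
        for p in proteins
        if len(mapping.protein_to_transcripts[p]) >= 2
    }
    transcripts = [t for g in gene_transcripts.values() for t in g]
    return Universe(
        complexes=complexes,
        mapping_rows=mapping_rows,
        mapping=mapping,
        complex_proteins=proteins,
        protein_gene=protein_gene,
        gene_transcripts=gene_transcripts,
        noninvolved=frozenset(noninvolved),
        eligible=eligible,
        sharing_fraction=sharing,
        transcripts=transcripts,
    )


@dataclass
class TissuePanel:
    """Per-tissue expression matrices plus the planted detection mask."""

    samples: list[str]
    estimate: pd.DataFrame
    sd: pd.DataFrame
    detected: pd.DataFrame


def generate_expression(
    config: SynthConfig, universe: Universe, truth: GroundTruth | None = None
) -> tuple[TissuePanel, GroundTruth]:
    """Generate tissue expression with planted absences, dominance and switches.

    Dominant isoforms are planted with a fixed expression margin; switches
    relative to the first sample are planted as exact-count flips among free
    eligible constituents.  Absent subunits get every transcript of their
    gene(s) pushed above the detection SD threshold.  The returned ground
    truth records realized per-sample formable sets, major-isoform maps,
    pairwise switch fractions and involvement fractions, all derived from the
    planted matrices.
    """
    config.validate()
    if truth is None:
        truth = GroundTruth()
    rng = np.random.default_rng([config.seed, 1])
    samples = [f"tissue{i + 1:02d}" for i in range(config.n_samples)]
    genes = sorted(universe.gene_transcripts)
    transcripts = [t for g in genes for t in universe.gene_transcripts[g]]
    tx_gene = {
        t: g for g in genes for t in universe.gene_transcripts[g]
    }
    n_tx = len(transcripts)
    tx_idx = {t: i for i, t in enumerate(transcripts)}

    base = {g: rng.normal(config.base_log_mean, config.base_log_sd) for g in genes}

    # reference dominant isoform per gene
    noninv_genes = {universe.protein_gene[p]: p for p in universe.noninvolved}
    ref_dom: dict[str, str] = {}
    for g in genes:
        txs = universe.gene_transcripts[g]
        if g in noninv_genes:
            ref_dom[g] = txs[-1]  # the extra, non-subunit transcript
        else:
            ref_dom[g] = txs[int(rng.integers(len(txs)))]

    # exact-count switch planting relative to the first sample.  Flips are
    # drawn from a fixed switch-prone subpool of the involved eligible
    # constituents, so that per-pair rates stay near switch_rate while the
    # fraction of constituents ever switching saturates near the pool size.
    eligible_all = sorted(universe.eligible)
    free = [p for p in eligible_all if p not in universe.noninvolved]
    n_flip = int(round(config.switch_rate * len(eligible_all)))
    pool_size = min(
        max(int(round(config.switch_pool_fraction * len(eligible_all))), n_flip),
        len(free),
    )
    if n_flip > len(free):
        raise ConfigError(
            "switch_rate infeasible: not enough involved eligible constituents"
        )
    pool = (
        list(rng.choice(free, size=pool_size, replace=False)) if pool_size else []
    )
    dominant: dict[str, dict[str, str]] = {}
    for i, s in enumerate(samples):
        dom = dict(ref_dom)
        if i > 0 and n_flip:
            flips = rng.choice(pool, size=n_flip, replace=False)
            for p in flips:
                g = universe.eligible[p]
                options = sorted(
                    set(universe.mapping.protein_to_transcripts[p])
                    & set(universe.gene_transcripts[g])
                )
                alts = [t for t in options if t != ref_dom[g]]
                if not alts:
                    alts = options
                dom[g] = alts[int(rng.integers(len(alts)))]
        dominant[s] = dom

    # absences and co-detection.  Absences are confined to a tissue-variable
    # subset of subunits (the rest form a constitutive core present in every
    # sample), with the conditional rate chosen so the marginal per-sample
    # absence rate equals absent_rate
    complex_tx = {
        t
        for p in universe.complex_proteins
        for t in universe.mapping.protein_to_transcripts[p]
    }
    detected = np.ones((n_tx, len(samples)), dtype=bool)
    n_variable = int(
        round(config.variable_subunit_fraction * len(universe.complex_proteins))
    )
    variable = (
        list(rng.choice(universe.complex_proteins, size=n_variable, replace=False))
        if n_variable
        else []
    )
    conditional_rate = (
        min(config.absent_rate * len(universe.complex_proteins) / n_variable, 1.0)
        if n_variable
        else 0.0
    )
    absent: dict[str, frozenset[str]] = {}
    for j, s in enumerate(samples):
        abs_p = frozenset(
            p for p in variable if rng.random() < conditional_rate
        )
        absent[s] = abs_p
        absent_genes = {universe.protein_gene[p] for p in abs_p}
        for g in absent_genes:
            for t in universe.gene_transcripts[g]:
                detected[tx_idx[t], j] = False
        if config.coexpression < 1.0:
            # dropout spares each gene's dominant isoform: the highest-expressed
            # transcript is the one reliably quantified in practice
            for t in complex_tx:
                i = tx_idx[t]
                if (
                    detected[i, j]
                    and t != dominant[s][tx_gene[t]]
                    and rng.random() > config.coexpression
                ):
                    detected[i, j] = False

    # expression values: dominant at the gene base level, runners-up spaced
    # one margin (plus rank spacing) below
    est = np.empty((n_tx, len(samples)))
    for j, s in enumerate(samples):
        for g in genes:
            txs = universe.gene_transcripts[g]
            dom = dominant[s][g]
            rank = 0
            for t in txs:
                i = tx_idx[t]
                if t == dom:
                    offset = 0.0
                else:
                    offset = -(config.dominance_margin + 0.25 * rank)
                    rank += 1
                est[i, j] = base[g] + offset + rng.normal(0.0, config.noise_sd)
    sd = np.where(
        detected,
        rng.uniform(config.sd_low[0], config.sd_low[1], size=detected.shape),
        rng.uniform(config.sd_high[0], config.sd_high[1], size=detected.shape),
    )

    idx = pd.Index(transcripts, name="feature_id")
    panel = TissuePanel(
        samples=samples,
        estimate=pd.DataFrame(est, index=idx, columns=samples),
        sd=pd.DataFrame(sd, index=idx, columns=samples),
        detected=pd.DataFrame(detected, index=idx, columns=samples),
    )

    # ---- ground-truth bookkeeping, derived from the planted matrices ----
    det_sets = {
        s: frozenset(idx[panel.detected[s].to_numpy()]) for s in samples
    }
    truth.samples = samples
    truth.absent = {s: sorted(absent[s]) for s in samples}
    truth.sharing_fraction = universe.sharing_fraction
    counts: dict[str, int] = {}
    for rec in universe.complexes:
        for p in rec.subunit_set:
            counts[p] = counts.get(p, 0) + 1
    truth.complexes_per_protein = counts
    truth.eligible = dict(universe.eligible)
    truth.noninvolved_proteins = sorted(universe.noninvolved)

    p2t = universe.mapping.protein_to_transcripts
    for s in samples:
        det = det_sets[s]
        expressed = frozenset(
            p for p in universe.complex_proteins if p2t[p] & det
        )
        formable = [
            rec.complex_id
            for rec in universe.complexes
            if all(p in expressed for p in rec.subunit_set)
        ]
        truth.expressed_subunits[s] = sorted(expressed)
        truth.formable[s] = sorted(formable)
        # realized major isoform: planted dominant if detected, else the
        # highest planted runner-up among detected transcripts
        major: dict[str, str] = {}
        for g in genes:
            cands = [t for t in universe.gene_transcripts[g] if t in det]
            if not cands:
                continue
            col = panel.estimate[s]
            best = max(cands, key=lambda t: (col[t], t))
            ties = [t for t in cands if col[t] == col[best]]
            major[g] = min(ties)
        truth.major[s] = major
        majors = frozenset(major.values())
        has_major = frozenset(p for p in expressed if p2t[p] & majors)
        sub_frac = len(has_major) / len(expressed) if expressed else float("nan")
        recs = {rec.complex_id: rec for rec in universe.complexes}
        hit = sum(
            1
            for c in formable
            if any(p2t[p] & majors for p in recs[c].subunit_set)
        )
        pf_frac = hit / len(formable) if formable else float("nan")
        truth.involvement[s] = {
            "pfpc_major_fraction": pf_frac,
            "subunit_major_fraction": sub_frac,
        }

    pair_fracs = {}
    for i, si in enumerate(samples):
        for sj in samples[i + 1 :]:
            both = [
                p
                for p in eligible_all
                if universe.eligible[p] in truth.major[si]
                and universe.eligible[p] in truth.major[sj]
            ]
            if both:
                switched = sum(
                    truth.major[si][universe.eligible[p]]
                    != truth.major[sj][universe.eligible[p]]
                    for p in both
                )
                pair_fracs[f"{si}|{sj}"] = {
                    "fraction": switched / len(both),
                    "n": len(both),
                }
            else:
                pair_fracs[f"{si}|{sj}"] = {"fraction": None, "n": 0}
    truth.switch_fractions = pair_fracs
    return panel, truth


def generate_counts(
    config: SynthConfig, universe: Universe, truth: GroundTruth | None = None
) -> tuple[dict[str, tuple[pd.DataFrame, dict[str, str]]], GroundTruth]:
    """Generate negative-binomial case/control count matrices per dataset.

    Planted DE transcripts have their case-group mean multiplied (or divided,
    half each) by the configured fold change; per-sample library-size factors
    exercise the normalization step.  Truth records each dataset's planted DE
    transcript set.
    """
    config.validate()
    if truth is None:
        truth = GroundTruth()
    out: dict[str, tuple[pd.DataFrame, dict[str, str]]] = {}
    transcripts = sorted(universe.transcripts)
    n_tx = len(transcripts)
    size = 1.0 / config.nb_dispersion
    for d_idx, (name, ds) in enumerate(sorted(config.datasets.items())):
        rng = np.random.default_rng([config.seed, 2, d_idx])
        mu = rng.lognormal(config.count_mean_log, config.count_mean_sd, size=n_tx)
        n_de = int(round(ds.de_fraction * n_tx))
        de_idx = rng.choice(n_tx, size=n_de, replace=False) if n_de else np.array([], dtype=int)
        up = rng.random(n_de) < 0.5
        case_mu = mu.copy()
        case_mu[de_idx[up]] *= ds.fold_change
        case_mu[de_idx[~up]] /= ds.fold_change
        cols = [f"control{i + 1:02d}" for i in range(ds.n_control)] + [
            f"case{i + 1:02d}" for i in range(ds.n_case)
        ]
        groups = {c: ("control" if c.startswith("control") else "case") for c in cols}
        data = np.empty((n_tx, len(cols)))
        for j, c in enumerate(cols):
            lib = rng.lognormal(0.0, config.library_size_sd)
            mean = (case_mu if groups[c] == "case" else mu) * lib
            p = size / (size + mean)
            data[:, j] = rng.negative_binomial(size, p)
        counts = pd.DataFrame(
            data, index=pd.Index(transcripts, name="transcript_id"), columns=cols
        )
        out[name] = (counts, groups)
        truth.de_truth[name] = sorted(transcripts[i] for i in de_idx)
    return out, truth


# ---------------------------------------------------------------------------
# serialization


def write_universe(universe: Universe, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    complexes_path = outdir / "complexes.tsv"
    with open(complexes_path, "w", encoding="utf-8") as handle:
        handle.write("complex_id\tname\tsubunits\n")
        for rec in universe.complexes:
            handle.write(
                f"{rec.complex_id}\t{rec.name}\t{';'.join(rec.subunits)}\n"
            )
    mapping_path = outdir / "mapping.tsv"
    with open(mapping_path, "w", encoding="utf-8") as handle:
        handle.write("protein_id\ttranscript_id\tgene_id\n")
        for p, t, g in universe.mapping_rows:
            handle.write(f"{p}\t{t}\t{g}\n")
    return {"complexes": complexes_path, "mapping": mapping_path}


def write_expression(panel: TissuePanel, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in panel.samples:
        path = outdir / f"{s}.tsv"
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("feature_id\testimate\tsd\n")
            est = panel.estimate[s]
            sd = panel.sd[s]
            for t in panel.estimate.index:
                handle.write(f"{t}\t{est[t]:.6f}\t{sd[t]:.6f}\n")
        paths.append(path)
    return paths


def write_counts(
    datasets: Mapping[str, tuple[pd.DataFrame, dict[str, str]]], outdir: str | Path
) -> dict[str, dict[str, Path]]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, Path]] = {}
    for name, (counts, groups) in sorted(datasets.items()):
        cpath = outdir / f"{name}_counts.tsv"
        with open(cpath, "w", encoding="utf-8") as handle:
            handle.write("transcript_id\t" + "\t".join(counts.columns) + "\n")
            values = counts.to_numpy()
            for i, t in enumerate(counts.index):
                row = "\t".join(f"{v:.0f}" for v in values[i])
                handle.write(f"{t}\t{row}\n")
        gpath = outdir / f"{name}_groups.tsv"
        with open(gpath, "w", encoding="utf-8") as handle:
            handle.write("sample\tgroup\n")
            for s in counts.columns:
                handle.write(f"{s}\t{groups[s]}\n")
        paths[name] = {"counts": cpath, "groups": gpath}
    return paths


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(asdict(truth), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return path


@dataclass
class SimulationOutput:
    """Paths and in-memory objects of one full simulation."""

    universe: Universe
    panel: TissuePanel
    truth: GroundTruth
    complexes_path: Path
    mapping_path: Path
    expression_paths: list[Path]
    count_paths: dict[str, dict[str, Path]]
    truth_path: Path


def simulate(config: SynthConfig, outdir: str | Path) -> SimulationOutput:
    """Generate and write a complete synthetic study into ``outdir``."""
    outdir = Path(outdir)
    universe = generate_universe(config)
    truth = GroundTruth()
    panel, truth = generate_expression(config, universe, truth)
    datasets, truth = generate_counts(config, universe, truth)
    upaths = write_universe(universe, outdir)
    epaths = write_expression(panel, outdir / "expression")
    cpaths = write_counts(datasets, outdir / "counts")
    tpath = write_truth(truth, outdir / "truth" / "truth.json")
    return SimulationOutput(
        universe=universe,
        panel=panel,
        truth=truth,
        complexes_path=upaths["complexes"],
        mapping_path=upaths["mapping"],
        expression_paths=epaths,
        count_paths=cpaths,
        truth_path=tpath,
    )
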