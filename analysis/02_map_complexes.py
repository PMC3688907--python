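"""Resolve the complex universe and summarise its structure.

De-duplicates the complex table, drops uncertain records, keeps complexes
whose every subunit maps to at least one transcript, and reports the
size and transcripts-per-subunit histograms, the multi-transcript fraction
and the subunit-sharing fraction.
"""

from pathlib import Path

from complexdyn.pipeline import RunConfig, stage_map

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUTDIR = ROOT / "results" / "analysis"


def main() -> None:
    config = RunConfig(
        complexes=DATA / "complexes.tsv",
        mapping=DATA / "mapping.tsv",
        outdir=OUTDIR,
    )
    kept, mapping, summary = stage_map(config)
    print(f"kept {summary['n_kept']} / {summary['n_deduplicated']} complexes "
          f"({summary['n_rejected']} rejected, {summary['n_dropped']} unmappable)")
    print(f"transcripts per subunit: {summary['mean_transcripts_per_subunit']:.2f}")
    print(f"genes per subunit:       {summary['mean_genes_per_subunit']:.2f}")
    print(f"subunits with >=2 transcripts: {summary['multi_transcript_fraction']:.1%}")
    print(f"subunits shared across >=2 complexes: {summary['shared_fraction']:.1%}")
    print(f"complex size histogram: {summary['size_histogram']}")
    print(f"-> {OUTDIR}/complex_stats.json")


if __name__ == "__main__":
    main()
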