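"""Propagate DE transcripts to affected complexes and overlap the datasets.

A complex is affected when any subunit carries any DE transcript.  Because
subunits are shared and carry multiple transcripts, the affected-complex
overlap between two datasets is typically several-fold larger than their
DE-transcript overlap (the amplification the combined matrix displays:
upper triangle = shared affected complexes, lower = shared in-complex DE
transcripts).
"""

from pathlib import Path

import pandas as pd

from complexdyn.pipeline import RunConfig, stage_impact, stage_map

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUTDIR = ROOT / "results" / "analysis"


def main() -> None:
    config = RunConfig(
        complexes=DATA / "complexes.tsv",
        mapping=DATA / "mapping.tsv",
        outdir=OUTDIR,
    )
    kept, mapping, _ = stage_map(config)
    de_sets = {}
    for path in sorted(OUTDIR.glob("de_*.tsv")):
        name = path.stem.replace("de_", "")
        table = pd.read_csv(path, sep="\t", index_col=0)
        de_sets[name] = frozenset(table.index[table["de_flag"] == 1].astype(str))
    if len(de_sets) < 2:
        raise SystemExit("run 05_differential_expression.py first")
    summary = stage_impact(config, de_sets, kept, mapping)
    for name, frag in summary["per_dataset"].items():
        print(f"{name:>9}: {len(de_sets[name])} DE -> "
              f"{frag['n_de_in_complex']} in complexes -> "
              f"{frag['n_affected_complexes']} affected complexes")
    print(f"common affected complexes across all datasets: "
          f"{summary['n_common_complexes']}; "
          f"common in-complex DE transcripts: {summary['n_common_transcripts']}")
    combined = pd.read_csv(OUTDIR / "overlap_combined.tsv", sep="\t", index_col=0)
    print("combined overlap matrix (upper = complexes, lower = transcripts):")
    print(combined.to_string())
    print(f"-> {OUTDIR}/overlap_combined.tsv, {OUTDIR}/impact_summary.json")


if __name__ == "__main__":
    main()
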