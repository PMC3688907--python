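"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over Python sets and dicts, with no
reliance on the package's own code paths, so agreement with the library is a
meaningful check rather than a tautology.
"""

from __future__ import annotations

import numpy as np


def brute_detected(sd: dict, sd_max: float) -> set:
    """(feature, sample) pairs with a present SD not exceeding the threshold."""
    return {
        (f, s)
        for (f, s), value in sd.items()
        if value is not None and not np.isnan(value) and value <= sd_max
    }


def brute_protein_expressed(protein_features: set, detected: set) -> bool:
    return any(f in detected for f in protein_features)


def brute_pfpc(
    complexes: dict, protein_features: dict, detected_per_sample: dict
) -> dict:
    """Per-sample formable complex-id sets via exhaustive enumeration."""
    out = {}
    for sample, detected in detected_per_sample.items():
        formable = set()
        for cid, subunits in complexes.items():
            if all(
                brute_protein_expressed(protein_features[p], detected)
                for p in subunits
            ):
                formable.add(cid)
        out[sample] = formable
    return out


def brute_major(
    estimates: dict, detected_per_sample: dict, tx_gene: dict
) -> dict:
    """Per-sample gene -> argmax-detected-transcript maps (min-id ties)."""
    out = {}
    for sample, detected in detected_per_sample.items():
        best: dict[str, tuple[float, str]] = {}
        for (t, s), value in estimates.items():
            if s != sample or t not in detected or t not in tx_gene:
                continue
            g = tx_gene[t]
            if g not in best:
                best[g] = (value, t)
            else:
                bv, bt = best[g]
                if value > bv or (value == bv and t < bt):
                    best[g] = (value, t)
        out[sample] = {g: t for g, (_, t) in best.items()}
    return out


def brute_switch_fraction(major_i: dict, major_j: dict, eligible: dict):
    """(switch fraction, denominator) between two samples; None when empty."""
    denom = 0
    switched = 0
    for protein, gene in eligible.items():
        if gene in major_i and gene in major_j:
            denom += 1
            if major_i[gene] != major_j[gene]:
                switched += 1
    return (switched / denom if denom else None), denom


def brute_reach(de_set: set, complexes: dict, protein_transcripts: dict):
    """(in-complex DE transcripts, affected complexes) by graph walking."""
    de_in_complex = set()
    affected = set()
    for cid, subunits in complexes.items():
        for p in subunits:
            hits = protein_transcripts[p] & de_set
            if hits:
                affected.add(cid)
                de_in_complex |= hits
    return de_in_complex, affected


def brute_overlap(sets: list) -> list:
    """Pairwise intersection counts via fold-left set logic."""
    n = len(sets)
    return [[len(sets[i] & sets[j]) for j in range(n)] for i in range(n)]


def brute_q(abs_m, d, noise_abs_m, noise_d):
    """q per signal: fraction of noise pairs strictly dominated, by loops."""
    out = []
    for am, dd in zip(abs_m, d):
        count = 0
        for nm, nd in zip(noise_abs_m, noise_d):
            if nm < am and nd < dd:
                count += 1
        out.append(count / len(noise_abs_m))
    return out
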