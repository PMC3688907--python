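from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from complexdyn.complex_map import ComplexRecord, MappingTable
from complexdyn.detection import DetectionCall, ExpressionMatrix
from complexdyn.synth import SynthConfig, generate_expression, generate_universe

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def small_mapping() -> MappingTable:
    """Handcrafted many-to-many mapping, including a multi-gene protein (P4)
    and two proteins sharing a gene (P5, P6 on G5)."""
    rows = [
        ("P1", "T1", "G1"),
        ("P2", "T2", "G2"),
        ("P2", "T3", "G2"),
        ("P3", "T4", "G3"),
        ("P3", "T5", "G3"),
        ("P3", "T6", "G3"),
        ("P4", "T7", "G4a"),
        ("P4", "T8", "G4b"),
        ("P5", "T9", "G5"),
        ("P6", "T10", "G5"),
    ]
    return MappingTable.from_associations(rows)


@pytest.fixture
def small_complexes() -> list[ComplexRecord]:
    return [
        ComplexRecord("C1", "one", ("P1", "P2")),
        ComplexRecord("C2", "two", ("P1", "P3")),
        ComplexRecord("C3", "three", ("P2", "P3", "P4")),
        ComplexRecord("C4", "shared gene", ("P5", "P6")),
    ]


def make_expression(
    values: dict, samples: list[str], level: str = "transcript"
) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {feature: {sample: (estimate, sd)}}."""
    features = list(values)
    est = pd.DataFrame(np.nan, index=features, columns=samples)
    sd = pd.DataFrame(np.nan, index=features, columns=samples)
    for f, cells in values.items():
        for s, (e, d) in cells.items():
            est.loc[f, s] = e
            sd.loc[f, s] = d
    return ExpressionMatrix(level=level, estimate=est, sd=sd)


def make_call(detected: dict, samples: list[str], level: str = "transcript") -> DetectionCall:
    """Build a DetectionCall from {feature: set of detected samples}."""
    features = list(detected)
    df = pd.DataFrame(
        [[s in detected[f] for s in samples] for f in features],
        index=features,
        columns=samples,
    )
    return DetectionCall(level=level, detected=df)


@pytest.fixture
def make_study():
    """Factory for small synthetic studies: (config, universe, panel, truth)."""

    def _make(seed: int, **overrides):
        defaults = dict(
            seed=seed,
            n_complexes=30,
            n_decoy_genes=15,
            n_samples=4,
            datasets={},
        )
        defaults.update(overrides)
        cfg = SynthConfig(**defaults)
        universe = generate_universe(cfg)
        panel, truth = generate_expression(cfg, universe)
        return cfg, universe, panel, truth

    return _make
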