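"""Shared fixtures.

The expensive objects — a full 42-chemical synthetic screen and its fitted
POD table — are session-scoped and computed once; most tests that need
realistic data share them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from namscreen import conc_response as cr
from namscreen.io import load_reference_classing
from namscreen.synthetic import (
    ClassPotencyProfile,
    CellTypePotency,
    ScreenDesign,
    simulate_screen,
)

#: One fixed seed for the planted-structure screen used across the suite.
SCREEN_SEED = 11


@pytest.fixture(scope="session")
def reference_classing() -> pd.DataFrame:
    return load_reference_classing()


@pytest.fixture(scope="session")
def screen():
    """Default 42-chemical, five-cell-type screen at 10% well noise."""
    return simulate_screen(noise_sd=10.0, seed=SCREEN_SEED)


@pytest.fixture(scope="session")
def pods_bundle(screen):
    """(normalized measurements, vehicle stats, POD table) for `screen`."""
    normalized, vstats = cr.normalize_to_vehicle(screen.measurements)
    pods = cr.pod_table(normalized, vstats)
    return normalized, vstats, pods


@pytest.fixture(scope="session")
def pods(pods_bundle) -> pd.DataFrame:
    return pods_bundle[2]


@pytest.fixture()
def small_design() -> ScreenDesign:
    """A 6-chemical, 2-cell-type design for fast unit tests."""
    return ScreenDesign(
        chemicals={
            "chemA1": "alpha",
            "chemA2": "alpha",
            "chemA3": "alpha",
            "chemB1": "beta",
            "chemB2": "beta",
            "chemB3": "beta",
        },
        phenotypes={
            "hepatocyte": (
                ("p1", "functional"),
                ("p2", "cytotoxicity"),
            ),
            "cardiomyocyte": (
                ("p1", "functional"),
                ("p2", "cytotoxicity"),
            ),
        },
    )


@pytest.fixture()
def small_profiles() -> list[ClassPotencyProfile]:
    pot = CellTypePotency(0.0, 0.3, 1.0)
    off = CellTypePotency(2.0, 0.3, 0.0)
    return [
        ClassPotencyProfile("alpha", {"hepatocyte": pot, "cardiomyocyte": off}),
        ClassPotencyProfile("beta", {"hepatocyte": off, "cardiomyocyte": pot}),
    ]


def make_pod_frame(records) -> pd.DataFrame:
    """Build a minimal POD table from (chemical, cell_type, phenotype,
    category, pod, censored) tuples."""
    return pd.DataFrame(
        records,
        columns=["chemical", "cell_type", "phenotype", "category", "pod_uM", "censored"],
    )
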