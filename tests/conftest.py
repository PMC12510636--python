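"""Shared fixtures: small generated families and a calibrated panel.

Session-scoped so the profile calibration cost is paid once; sizes are
kept modest (120-residue masters, 8 members, 400 calibration sequences)
for speed without losing the planted-vs-decoy score separation the tests
rely on.
"""

from __future__ import annotations

import numpy as np
import pytest

import coconserve as cc


@pytest.fixture(scope="session")
def marker_families():
    return cc.generate_marker_families(
        seed=42, master_length=120, n_members=8, divergence=0.2, indel_rate=0.01
    )


@pytest.fixture(scope="session")
def calibrated_panel(marker_families):
    return cc.build_marker_profiles(marker_families, n_random=400, db_size=400, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_tiny_profile(rng: np.random.Generator, max_L: int = 3) -> cc.ProfileHMM:
    """A valid random profile with L <= max_L match states, built from a
    small random alignment so transitions/emissions are realistic."""
    AA = "ACDEFGHIKLMNPQRSTVWY"
    while True:
        L_target = int(rng.integers(1, max_L + 1))
        n_seq = int(rng.integers(1, 4))
        width = L_target + int(rng.integers(0, 3))
        rows = []
        for s in range(n_seq):
            row = "".join(
                AA[rng.integers(0, 20)] if rng.random() > 0.25 else "-"
                for _ in range(width)
            )
            if row.count("-") == width:
                row = AA[rng.integers(0, 20)] + row[1:]
            rows.append((f"s{s}", row))
        try:
            profile = cc.build_profile(
                rows, pseudocount=1.0, gap_fraction_cutoff=0.75, name="tiny"
            )
        except ValueError:
            continue
        if profile.L <= max_L:
            return profile


def random_peptide(rng: np.random.Generator, length: int) -> str:
    AA = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(AA[rng.integers(0, 20)] for _ in range(length))
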