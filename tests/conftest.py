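from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from mrpipe.harmonize import HarmonizationStatus, HarmonizedInstrument

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from mrpipe.summary_io import Role, SnpAssociation, StudySet


def make_instruments(bx, by, sy, sx=None, ids=None) -> list[HarmonizedInstrument]:
    """Build harmonized instruments from plain effect arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    ids = ids or [f"rs{i + 1}" for i in range(bx.size)]
    return [
        HarmonizedInstrument(
            variant_id=ids[i],
            beta_exposure=float(bx[i]),
            se_exposure=float(sx[i]),
            beta_outcome=float(by[i]),
            se_outcome=float(sy[i]),
            effect_allele="A",
            status=HarmonizationStatus.KEPT,
        )
        for i in range(bx.size)
    ]


def random_instruments(rng: np.random.Generator, k: int) -> list[HarmonizedInstrument]:
    """Random instrument sets for oracle cross-checks (betas can be negative)."""
    bx = rng.uniform(0.03, 0.3, k) * rng.choice([-1.0, 1.0], k)
    by = rng.normal(0.0, 0.05, k)
    sy = rng.uniform(0.005, 0.05, k)
    sx = rng.uniform(0.005, 0.02, k)
    return make_instruments(bx, by, sy, sx)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def glycine_like_exposure() -> StudySet:
    """A small exposure StudySet with a mix of allele configurations."""
    recs = [
        SnpAssociation("rs1", "A", "G", 0.10, 0.01, 1e-12, eaf=0.30),
        SnpAssociation("rs2", "C", "T", -0.08, 0.012, 4e-10, eaf=0.55),
        SnpAssociation("rs3", "G", "C", 0.12, 0.015, 3e-9, eaf=0.20),  # palindromic
        SnpAssociation("rs4", "T", "A", 0.07, 0.011, 2e-8, eaf=0.48),  # palindromic, ambiguous
        SnpAssociation("rs5", "A", "C", 0.09, 0.013, 6e-8, eaf=0.70),
    ]
    return StudySet("glycine_like", Role.EXPOSURE, recs)


@pytest.fixture
def published_summary_path() -> Path:
    return Path(__file__).resolve().parents[1] / "data" / "published_summary.tsv"
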