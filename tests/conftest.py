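"""Shared fixtures.

The expensive end-to-end objects (the full synthetic bundle, its screen and
validation outputs) are session-scoped so the planted-truth recovery tests
and the unit tests share one computation.
"""

from __future__ import annotations

import pytest

from hgtscreen.pipeline import run_screen, run_validate
from hgtscreen.simulate import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle42():
    """The reference synthetic bundle: 50 intrinsic genes, 6 bacterial +
    4 fungal planted HGTs at 0.2 divergence, 1 fusion, 1 co-transfer pair,
    1 truncated-duplicate pair."""
    return generate_bundle(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def screen42(bundle42):
    return run_screen(bundle42)


@pytest.fixture(scope="session")
def validate42(bundle42, screen42):
    return run_validate(bundle42, screen42.candidates, seed=42)


@pytest.fixture(scope="session")
def small_cfg():
    """A light bundle configuration for CLI and determinism tests."""
    return dict(n_intrinsic_genes=10, n_hgt_bacterial=2, n_hgt_fungal=1,
                n_fusions=0, n_cotransfer_pairs=1, n_truncated_dup_pairs=0,
                n_domains=60, n_expanded_domains=2)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return generate_bundle(SynthConfig(seed=5, **small_cfg))
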