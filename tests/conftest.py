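"""Shared fixtures: small STFT geometries and one session-scoped cohort.

The session cohort (2 groups x 6 samples at full acquisition size) is
simulated once and reused by the feature, chemometrics, pipeline and
acceptance tests, so the expensive stages run a single time.
"""

from __future__ import annotations

import numpy as np
import pytest

import nmrmodal as nm

COHORT_SEED = 11


@pytest.fixture(scope="session")
def small_params() -> nm.STFTParams:
    return nm.STFTParams(window_length=8, overlap=4, n_fft=16, n_frames_out=4)


@pytest.fixture(scope="session")
def demo_design() -> nm.CohortDesign:
    return nm.two_state_design(n_per_group=6, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def demo_records(demo_design):
    return nm.simulate_cohort(demo_design)


@pytest.fixture(scope="session")
def demo_spectrograms(demo_records):
    return [nm.fid_to_spectrogram(r) for r in demo_records]


@pytest.fixture(scope="session")
def demo_matrices(demo_spectrograms):
    """(raw, snv) feature-matrix pair for the session cohort."""
    raw = nm.assemble(demo_spectrograms)
    return raw, nm.snv(raw)


@pytest.fixture(scope="session")
def demo_pca(demo_matrices):
    return nm.pca_fit(demo_matrices[1], n_components=5)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240308)
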