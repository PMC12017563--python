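"""Shared fixtures: synthetic campaigns and a pipeline run reused across tests."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

import reefscape as rs
from reefscape import synthetic


@pytest.fixture(scope="session")
def mini_campaign(tmp_path_factory):
    """A generated 3-site, 1-hour synthetic campaign (13 files per site)."""
    out = tmp_path_factory.mktemp("mini_campaign")
    config = synthetic.mini_campaign_config(seed=1)
    csv_path = synthetic.generate_campaign(config, out)
    return config, csv_path


@pytest.fixture(scope="session")
def mini_run_config():
    """Reduced pipeline settings for the mini campaign (20 UMAP repeats)."""
    return rs.RunConfig(
        n_repeats=20,
        min_cluster_size=20,
        trajectory_k=20,
        diagnostics_k=20,
        diagnostics_triplets=10_000,
    )


@pytest.fixture(scope="session")
def mini_bundle(mini_campaign, mini_run_config):
    """Full pipeline results on the mini campaign."""
    _, csv_path = mini_campaign
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="skipping silhouette")
        return rs.run(mini_run_config, csv_path)


@pytest.fixture(scope="session")
def tiny_campaign(tmp_path_factory):
    """A 2-site, 3-file-per-site campaign for fast pipeline contract tests."""
    out = tmp_path_factory.mktemp("tiny_campaign")
    sites = synthetic.default_sites()
    config = dataclasses.replace(
        synthetic.mini_campaign_config(seed=3),
        sites={"quiet": sites["quiet"], "boat": sites["boat"]},
        schedule_hours=600 / 3600,
    )
    csv_path = synthetic.generate_campaign(config, out)
    return config, csv_path


def make_segment(samples: np.ndarray, sample_rate: int = 44100) -> rs.AudioSegment:
    return rs.AudioSegment(samples=np.asarray(samples, dtype=np.float64), sample_rate=sample_rate)


@pytest.fixture
def tone_segment():
    """A 1-s, 44.1 kHz unit sine at 500 Hz."""
    sr = 44100
    t = np.arange(sr) / sr
    return make_segment(np.sin(2 * np.pi * 500.0 * t), sr)
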