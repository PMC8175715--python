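"""Shared fixtures: small integer fixtures for oracle tests and one
session-scoped default synthetic run reused by the heavier checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import emtscreen as es

# small deterministic genes-by-samples integer matrix ("FIXTURE-A")
FIXTURE_A_VALUES = np.array(
    [
        [1, 3, 2, 5, 4, 6],
        [2, 2, 3, 1, 5, 4],
        [9, 7, 8, 6, 5, 4],
        [1, 1, 2, 2, 3, 3],
        [4, 6, 5, 7, 6, 8],
    ],
    dtype=float,
)
FIXTURE_A_L = pd.Series(
    [0.5, -1.0, 2.0, -0.3, 1.2],
    index=[f"G{i}" for i in range(1, 6)],
    name="log2_stroma_epi",
)


@pytest.fixture
def fixture_a() -> pd.DataFrame:
    return pd.DataFrame(
        FIXTURE_A_VALUES,
        index=[f"G{i}" for i in range(1, 6)],
        columns=[f"S{i}" for i in range(1, 7)],
    )


@pytest.fixture
def fixture_a_logratio() -> pd.Series:
    return FIXTURE_A_L.copy()


@pytest.fixture
def micro_fixture() -> es.MicrodissectionSet:
    """4 genes x 3 pairs, linear scale, integer values."""
    genes = [f"G{i}" for i in range(1, 5)]
    epi = pd.DataFrame(
        [[1, 2, 3], [4, 4, 4], [2, 1, 3], [8, 6, 10]],
        index=genes,
        columns=["E1", "E2", "E3"],
        dtype=float,
    )
    stro = pd.DataFrame(
        [[2, 4, 6], [1, 2, 3], [2, 1, 3], [16, 12, 20]],
        index=genes,
        columns=["T1", "T2", "T3"],
        dtype=float,
    )
    return es.MicrodissectionSet(
        epithelium=epi,
        stroma=stro,
        pairing=[("E1", "T1"), ("E2", "T2"), ("E3", "T3")],
        log2=False,
    )


@pytest.fixture(scope="session")
def default_cfg() -> es.SimConfig:
    return es.SimConfig(seed=11)


@pytest.fixture(scope="session")
def default_run(default_cfg):
    """Full default-condition synthetic run shared across tests."""
    bulk, truth = es.generate_cohort(default_cfg)
    micro = es.generate_microdissection(default_cfg, truth)
    survival = es.generate_survival(default_cfg, truth)
    log_ratio = es.stroma_epithelium_logfc(micro)
    scores = es.mesenchymal_score_all(bulk, log_ratio)
    z_table = es.prognostic_z_all(bulk, survival, transform="raw")
    candidates = es.select_candidates(scores, z_table)
    return {
        "config": default_cfg,
        "bulk": bulk,
        "truth": truth,
        "micro": micro,
        "survival": survival,
        "log_ratio": log_ratio,
        "scores": scores,
        "z_table": z_table,
        "candidates": candidates,
    }


@pytest.fixture(scope="session")
def small_cfg() -> es.SimConfig:
    """Desk-scale configuration for fast end-to-end tests."""
    return es.SimConfig(
        n_genes=200,
        n_bulk_samples=80,
        n_stromal_archetype=30,
        n_planted_mediators=12,
        n_celllines=16,
        n_emt_prone=5,
        seed=5,
    )
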