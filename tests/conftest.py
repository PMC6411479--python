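"""Shared fixtures.

The expensive ground-truth studies (seed-varied default scenarios, the
pure-host control, the decoy-paralog and truncation scenarios) are session
fixtures so the evaluation suite computes each condition exactly once.
"""

from __future__ import annotations

import warnings

import pytest

from egt_screen.evaluation import (
    run_decoy_scenario,
    run_default_study,
    run_pure_host_study,
    run_scenario,
    run_truncation_scenario,
)
from egt_screen.seqio import Alignment, ProteinRecord
from egt_screen.synthetic_data import ScenarioConfig

BASE_SEED = 0


def make_alignment(family: str, rows: list[tuple[str, str]],
                   taxon: str = "taxon") -> Alignment:
    """rows: (id, gapped string)."""
    return Alignment(
        family,
        [(ProteinRecord(rid, taxon, g.replace("-", "")), g) for rid, g in rows],
    )


@pytest.fixture(scope="session")
def default_study():
    """25 seed-varied runs of the standard condition (12 families, 20 taxa,
    Nup98/Rae1-analog EGT with signal peptides)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_default_study(n_seeds=25, base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def pure_host_runs():
    """5 seed-varied runs with no EGT: the false-positive control."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pure_host_study(n_seeds=5, base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def decoy_run():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_decoy_scenario(base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def truncation_run():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_truncation_scenario(base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def small_run():
    """A reduced scenario for fast integration tests (not the standard
    acceptance condition)."""
    cfg = ScenarioConfig(
        seed=11,
        families=["Nup98", "Rae1", "Sec13", "Nup62"],
        length_range=(150, 250),
        n_query=4, n_host_outgroup=3, n_algal=4, n_other=3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_scenario(cfg)
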