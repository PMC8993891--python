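"""Shared fixtures: each miniature simulated session is analyzed once per run."""

from __future__ import annotations

import warnings

import pytest

from ecogseq.pipeline import analyze_session
from ecogseq.simulate import make_fixture

_CACHE: dict = {}


def _analyzed(name: str):
    if name not in _CACHE:
        rec, events, truth = make_fixture(name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            epochs, metrics, estimates, labels = analyze_session(rec, events)
        _CACHE[name] = dict(
            recording=rec, events=events, truth=truth, epochs=epochs,
            metrics=metrics, estimates=estimates, labels=labels,
        )
    return _CACHE[name]


@pytest.fixture(scope="session")
def single_burst_run():
    return _analyzed("single_burst")


@pytest.fixture(scope="session")
def null_run():
    return _analyzed("null_no_signal")


@pytest.fixture(scope="session")
def two_roi_run():
    return _analyzed("two_roi_lag")


@pytest.fixture(scope="session")
def specificity_run():
    return _analyzed("specificity_grid")


@pytest.fixture(scope="session")
def selectivity_run():
    return _analyzed("selectivity_grid")
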