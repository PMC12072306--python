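"""Shared fixtures: tiny scaffolds/substituent sets and a session-scoped
full benchmark pipeline run reused by the slower integration checks."""

from __future__ import annotations

import pytest

from simplihit import benchmark as bm
from simplihit import enumeration as en
from simplihit.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def kinase_scaffold() -> en.AttachmentScaffold:
    return en.parse_scaffold(bm.KINASE_SCAFFOLD_SMILES, bm.KINASE_SCAFFOLD_POSITIONS)


@pytest.fixture(scope="session")
def tiny_benchmark() -> bm.Benchmark:
    """3 positions x (2, 3, 2) substituents -> 12-molecule library."""
    return bm.make_benchmark(seed=11, n_positions=3, substituents_per_position=(2, 3, 2))


@pytest.fixture(scope="session")
def default_benchmark() -> bm.Benchmark:
    return bm.make_benchmark(seed=0)


def paper_scale_substituents() -> en.SubstituentSet:
    """A substituent set with the per-position counts of a realistic
    5-point campaign: 30/14/12/27/5 including the hydrogen entry."""
    counts = {"C2": 30, "C4": 14, "C5": 12, "C6": 27, "N8": 5}
    per_position = {}
    for pos, c in counts.items():
        frags = [en.HYDROGEN_FRAGMENT] + list(bm.FRAGMENT_POOL[: c - 1])
        per_position[pos] = frags
    return en.SubstituentSet(per_position)


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory) -> dict:
    """One full pipeline run on the default synthetic benchmark.

    Shared across integration and acceptance tests: runs once per session
    (a few minutes), everything downstream reads the artifacts.
    """
    outdir = tmp_path_factory.mktemp("benchmark_run")
    config = RunConfig(
        outdir=str(outdir),
        seed=0,
        benchmark={},
        n_train=400,
        top_n=400,
        top_threshold=7.0,
        quota=17,
    )
    report = run_pipeline(config)
    return {"config": config, "report": report, "outdir": outdir}
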