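import dendropy
import numpy as np
import pandas as pd
import pytest

import avabund as av
from avabund.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def tiny_world():
    """Small but fully featured world used by several modules' tests."""
    cfg = av.WorldConfig(n_species=40, n_grid_rows=3, n_grid_cols=4)
    return av.generate_world(cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_checklists(tiny_world):
    effort = av.default_effort(tiny_world, seed=12)
    return av.simulate_checklists(tiny_world, effort, seed=13)


@pytest.fixture(scope="session")
def tiny_result(tiny_world):
    """A fast full-pipeline run (short chains, few imputations)."""
    cfg = PipelineConfig(mcmc_iterations=1000, mcmc_warmup=400,
                         m_imputations=4, n_draws=2000)
    return run_pipeline(tiny_world, seed=21, config=cfg)


@pytest.fixture(scope="session")
def balanced_tree():
    """4-tip balanced tree, unit branch lengths."""
    return dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1);",
                             schema="newick")


@pytest.fixture(scope="session")
def star_tree():
    return dendropy.Tree.get(data="(a:2,b:2,c:2,d:2,e:2);", schema="newick")


def make_checklist_table(durations, distances, complete, months=None,
                         lat=0.0, lon=0.0, counts=None):
    n = len(durations)
    events = pd.DataFrame({
        "checklist_id": np.arange(n),
        "lat": np.full(n, lat), "lon": np.full(n, lon),
        "month": months if months is not None else np.ones(n, dtype=int),
        "duration_min": durations, "distance_km": distances,
        "complete": complete,
    })
    counts = counts if counts is not None else pd.DataFrame(
        columns=["checklist_id", "species_id", "count"])
    return av.ChecklistTable(events, counts)
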