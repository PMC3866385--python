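import numpy as np
import pytest

import gsrnet as g


@pytest.fixture(scope="session")
def small_phantom():
    return g.generate_phantom((6, 6, 6), 4, 0.2, seed=7)


@pytest.fixture(scope="session")
def plain_model():
    """Signal model with the structural extras switched off, so the
    closed-form correlation identities hold exactly."""
    return g.SignalModel(var_module=1.0, var_local=0.0, var_noise=1.0,
                         var_global=1.0, var_wm=0.0, var_vent=0.5,
                         module_loading_spread=0.0, parent_mixing=0.0,
                         hub_global_loading=1.0, hub_module_factor=1.0,
                         seed=11)


@pytest.fixture(scope="session")
def shared_signal_dataset(small_phantom, plain_model):
    """G + noise only: every pair has population correlation 0.5."""
    import dataclasses
    model = dataclasses.replace(plain_model, var_module=0.0)
    return g.simulate_timeseries(small_phantom, model)


def two_cliques_bridge():
    """Two 4-cliques joined by a single bridge edge (8 nodes, m=13)."""
    a = np.zeros((8, 8))
    for blk in (range(4), range(4, 8)):
        for i in blk:
            for j in blk:
                if i != j:
                    a[i, j] = 1
    a[3, 4] = a[4, 3] = 1
    return g.network_from_adjacency(a)


@pytest.fixture(scope="session")
def clique_bridge_network():
    return two_cliques_bridge()


@pytest.fixture(scope="session")
def study_report():
    """The default-scale phantom study shared by the slower tests."""
    return g.run_study(g.StudyConfig(n_subjects=10, base_seed=1))


@pytest.fixture(scope="session")
def study_pivot(study_report):
    return study_report.metrics.pivot_table(
        index="subject", columns="method",
        values=["mean_corr", "C", "L", "Nc", "connected_fraction",
                "max_degree", "Q", "n_modules", "n_junk",
                "n_junk_wm_adjacent", "L_without_wm_adjacent"])
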