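import numpy as np
import pandas as pd
import pytest

from venticomp import (ResuscitatorSettings, RunConfig, run_full_study,
                       simulate_scenario, simulate_study)


@pytest.fixture(scope="session")
def settings():
    return ResuscitatorSettings()


@pytest.fixture(scope="session")
def study():
    """Full 18-provider synthetic study (episodes only, analysis separate)."""
    return simulate_study(n_providers=18, seed=1)


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Complete pipeline run at study scale, small bootstrap for speed."""
    out = tmp_path_factory.mktemp("run")
    return run_full_study(RunConfig(seed=1, n_providers=18, n_bootstrap=100,
                                    make_figures=False, out_dir=str(out)))


@pytest.fixture(scope="session")
def manikin_short_episodes(study):
    return [ep for ep in study.manikin_episodes if ep.scenario == "S1"]


def make_panel(curves: dict, parameter: str = "x", group: str = "M",
               duration_class: str = "S") -> pd.DataFrame:
    """Long-format panel from {subject: values} with 1-based breath index."""
    rows = []
    for sid, vals in curves.items():
        for t, v in enumerate(np.atleast_1d(vals), start=1):
            rows.append((sid, t, parameter, float(v), group, duration_class))
    return pd.DataFrame(rows, columns=["subject_id", "breath_index",
                                       "parameter", "value", "group",
                                       "duration_class"])


def make_xy_panel(x_curves: dict, y_curves: dict) -> pd.DataFrame:
    px = make_panel(x_curves, parameter="x")
    py = make_panel(y_curves, parameter="y")
    return pd.concat([px, py], ignore_index=True)
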