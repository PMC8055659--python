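import numpy as np
import pandas as pd
import pytest

import mifspat as m


def make_frame(
    cells,
    markers,
    sample_id="S01",
    roi_id="R1",
    timepoint="week1",
    width=931.0,
    height=698.0,
):
    """Build an ROIFrame from (cell_id, x, y, {marker: bool}) tuples."""
    rows = []
    for cid, x, y, calls in cells:
        rows.append(
            {"cell_id": cid, "x_um": x, "y_um": y,
             **{mk: bool(calls.get(mk, False)) for mk in markers}}
        )
    df = pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", *markers])
    for mk in markers:
        df[mk] = df[mk].astype(bool)
    return m.ROIFrame(sample_id, roi_id, timepoint, width=width, height=height, cells=df)


@pytest.fixture(scope="session")
def panel1():
    return m.default_panels()["1"]


@pytest.fixture(scope="session")
def panel2():
    return m.default_panels()["2"]


@pytest.fixture(scope="session")
def small_cohort():
    """2 samples x 3 ROIs x 2 timepoints — cheap shared cohort."""
    cfg = m.SimConfig(n_samples=2, n_rois_per_sample=3, seed=11)
    return m.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study design: 10 samples x 5 ROIs x 2 timepoints, seed 1."""
    cfg = m.SimConfig(seed=1)
    return m.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort_repro(default_cohort, panel1):
    """Density table + reproducibility battery of the default cohort."""
    frames, _ = default_cohort
    dens = m.density_table(frames, panel1)
    stats, excluded = m.summarize_repro(dens)
    return dens, stats, excluded
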