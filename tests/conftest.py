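import numpy as np
import pandas as pd
import pytest

from stith.dsp_io import DSPExperiment, ROIRecord


@pytest.fixture
def toy_experiment():
    """3 patients x 2 ROIs, 20 genes, 5 negprobes; deterministic counts."""
    rng = np.random.default_rng(42)
    roi_ids = [f"P{p}_R{r}" for p in (1, 2, 3) for r in (1, 2)]
    counts = pd.DataFrame(
        rng.integers(1, 200, size=(20, 6)),
        index=[f"G{i:03d}" for i in range(20)],
        columns=roi_ids,
    )
    negprobes = pd.DataFrame(
        rng.integers(1, 10, size=(5, 6)),
        index=[f"N{i}" for i in range(5)],
        columns=roi_ids,
    )
    rois = [
        ROIRecord(roi_id=rid, patient_id=rid.split("_")[0],
                  x_um=float(100 * i), y_um=float(50 * (i % 3)))
        for i, rid in enumerate(roi_ids)
    ]
    return DSPExperiment(counts=counts, negprobes=negprobes, rois=rois)


@pytest.fixture
def small_cohort():
    """Default-condition synthetic experiment at desk scale (60 ROIs)."""
    from stith.synthetic_data import SimulationConfig, generate_experiment

    cfg = SimulationConfig(n_patients=20, roi_count_range=(3, 3), n_genes=500, seed=1)
    exp, truth = generate_experiment(cfg)
    return cfg, exp, truth
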