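import numpy as np
import pandas as pd
import pytest

from metabofuse import fusion, ms, mvda, nmr
from metabofuse.synthetic import StudyDesign, generate_study


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study (4 seasons x 3 harvests x 3 reps)."""
    return generate_study(StudyDesign(seed=1))


@pytest.fixture(scope="session")
def fused_study(study):
    """Binned + curated + fused matrices with class labels for the study."""
    binned = nmr.stack_binned(study.projections)
    curated = ms.remove_blank_features(study.features, study.blank_ids)
    fused = fusion.fuse(binned, curated)
    labels = [m.season for m in study.metadata]
    design = mvda.ClassDesign([m.sample_id for m in study.metadata], labels)
    return {
        "study": study,
        "binned": binned,
        "curated": curated,
        "fused": fused,
        "labels": labels,
        "design": design,
    }


@pytest.fixture(scope="session")
def fitted_model(fused_study):
    X_scaled, _, _ = mvda.pareto_scale(fused_study["fused"].values)
    model = mvda.fit_plsda(X_scaled, fused_study["design"], n_components=2)
    return {"X_scaled": X_scaled, "model": model, **fused_study}


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def toy_feature_table(rows, sample_ids):
    """Build a FeatureTable from (id, mz, rt, polarity, areas-list) tuples."""
    feats = [
        ms.Feature(fid, mz, rt, pol, dict(zip(sample_ids, areas)))
        for fid, mz, rt, pol, areas in rows
    ]
    return ms.FeatureTable(features=feats, sample_ids=list(sample_ids))
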