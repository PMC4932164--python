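import numpy as np
import pandas as pd
import pytest

from svmpanel import (
    BandedMarker,
    ExpressionDataset,
    SyntheticSpec,
    TransformState,
    floor_log_transform,
    generate_cohort,
)


def make_dataset(values, diagnosis, *, age=None, gender=None, group=None,
                 gene_symbols=None, state=TransformState.LOG2):
    """Build an ExpressionDataset from plain arrays for unit tests."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    sids = [f"S{i+1:03d}" for i in range(n)]
    fids = [f"F{j+1:03d}" for j in range(k)]
    meta = pd.DataFrame({
        "diagnosis": list(diagnosis),
        "age": age if age is not None else [np.nan] * n,
        "gender": gender if gender is not None else [np.nan] * n,
        "cohort": "test",
        "group": group if group is not None else [np.nan] * n,
    }, index=pd.Index(sids, name="sample_id"))
    fmeta = pd.DataFrame(
        {"gene_symbol": gene_symbols if gene_symbols is not None else [np.nan] * k},
        index=pd.Index(fids, name="feature_id"))
    return ExpressionDataset(values=pd.DataFrame(values, index=sids, columns=fids),
                             sample_meta=meta, feature_meta=fmeta,
                             transform_state=state)


@pytest.fixture(scope="session")
def small_spec():
    """A fast synthetic spec: 2 banded markers among 30 noise features."""
    return SyntheticSpec(n_pos=20, n_neg=16, n_noise_features=30,
                         val_n_pos=14, val_n_neg=18)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    ds, truth = generate_cohort(small_spec, seed=11)
    return floor_log_transform(ds), truth


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized cohort (50 AD / 40 healthy, 202 features), log2."""
    spec = SyntheticSpec()
    ds, truth = generate_cohort(spec, seed=7)
    return floor_log_transform(ds), truth, spec
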