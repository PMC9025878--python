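import numpy as np
import pandas as pd
import pytest

from omifuse.types import DEFAULT_CLASSES, ModalityMatrix, ProbabilityTable


def make_matrix(values, labels, feature_names=None, modality="toy",
                classes=DEFAULT_CLASSES) -> ModalityMatrix:
    """Build a ModalityMatrix from plain arrays (one sample per patient)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    idx = pd.Index([f"S{i}" for i in range(len(labels))], name="sample_id")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(values.shape[1])]
    return ModalityMatrix(
        modality=modality,
        values=pd.DataFrame(values, index=idx, columns=feature_names),
        labels=pd.Series(labels, index=idx),
        patient_ids=pd.Series(idx.to_numpy(), index=idx),
        classes=classes,
    )


def make_table(probs, mask=None, classes=DEFAULT_CLASSES, modalities=None) -> ProbabilityTable:
    probs = np.asarray(probs, dtype=float)
    n, m, _ = probs.shape
    if modalities is None:
        modalities = tuple(f"M{j}" for j in range(m))
    if mask is None:
        mask = probs.sum(axis=2) > 0
    return ProbabilityTable(
        sample_ids=[f"s{i}" for i in range(n)],
        classes=tuple(classes),
        modalities=tuple(modalities),
        probs=probs,
        mask=mask,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def shifted_cohort():
    """Small cohort with a clear planted signal, shared across tests."""
    from omifuse.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(
        n_patients_per_class=40,
        modalities=("omics",),
        n_features=100,  # 10 informative at the default 10% fraction
        effect_size=2.0,
        missing_rate=0.0,
        seed=11,
    )
    return generate_cohort(spec)
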