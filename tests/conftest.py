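"""Shared fixtures: one default simulated study, preprocessed, with the
standard contrasts — computed once per session since several modules test
against the same planted ground truth."""

import numpy as np
import pandas as pd
import pytest

import hippocomp as hc
from hippocomp import diffexpr as de


@pytest.fixture(scope="session")
def default_study():
    """Default-condition simulated study (seed 42): raw matrix, phenotypes,
    ground truth."""
    return hc.generate_dataset(hc.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def preprocessed_study(default_study):
    matrix, ph, truth = default_study
    mm, report = hc.preprocess_pipeline(matrix)
    return mm, ph.loc[mm.sample_ids], truth, report


@pytest.fixture(scope="session")
def standard_contrasts(preprocessed_study):
    mm, ph, truth, _ = preprocessed_study
    return {
        "region_control": de.contrast(
            mm, ph, by="region", groups=("CA1", "CA3"),
            subset={"diagnosis": "control"}, paired=True),
        "disease_ca1": de.contrast(
            mm, ph, by="diagnosis", groups=("AD", "control"), subset={"region": "CA1"}),
        "disease_ca3": de.contrast(
            mm, ph, by="diagnosis", groups=("AD", "control"), subset={"region": "CA3"}),
    }


def make_matrix(values, detection=None, symbols=None, prefix="g"):
    """Small ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    idx = [f"{prefix}{i}" for i in range(n)]
    cols = [f"s{j}" for j in range(p)]
    return hc.ExpressionMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        detection_p=None if detection is None else pd.DataFrame(detection, index=idx, columns=cols),
        gene_symbols=None if symbols is None else pd.Series(symbols, index=idx),
    )


def make_phenotypes(n_subjects=12, n_control=6):
    """Minimal paired two-region phenotype table."""
    rows = []
    for i in range(n_subjects):
        dx = "control" if i < n_control else "AD"
        for region in ("CA1", "CA3"):
            rows.append({
                "sample_id": f"u{i}_{region}", "subject_id": f"u{i}", "region": region,
                "diagnosis": dx, "braak": 1 + i % 2 if dx == "control" else 5,
                "plaque": 0 if dx == "control" else 3, "age": 75.0 + i, "sex": "M",
                "pmi": 10.0, "batch": "b1",
            })
    return hc.validate_phenotypes(pd.DataFrame(rows))
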