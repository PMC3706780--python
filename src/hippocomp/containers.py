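"""In-memory containers shared by every analysis stage.

Two tables drive the whole pipeline: an :class:`ExpressionMatrix` holding
probe-level intensities (linear scale, as exported by Illumina BeadStudio-style
software) together with per-probe/sample detection p-values and a probe→gene
symbol annotation, and a per-sample phenotype table (subject, hippocampal
subfield, diagnosis, Braak stage, plaque score, age, sex, PMI, batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PHENOTYPE_COLUMNS",
    "validate_phenotypes",
    "read_phenotypes",
    "write_phenotypes",
]

#: Columns a phenotype table must carry (``brain_bank`` is optional).
PHENOTYPE_COLUMNS = (
    "sample_id",
    "subject_id",
    "region",
    "diagnosis",
    "braak",
    "plaque",
    "age",
    "sex",
    "pmi",
    "batch",
)

REGIONS = ("CA1", "CA3")
DIAGNOSES = ("control", "AD")


@dataclass
class ExpressionMatrix:
    """Probe × sample intensity matrix with detection calls and annotations.

    Parameters
    ----------
    values
        Non-negative linear-scale intensities, probes as rows, samples as
        columns. The index holds unique probe identifiers.
    detection_p
        Optional matrix of detection p-values in ``[0, 1]`` aligned with
        ``values`` (the platform's probability that a probe is
        indistinguishable from background; "present" = small value).
    gene_symbols
        Optional per-probe gene symbol annotation aligned with the probe
        index; missing/empty entries mean "no annotation".
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("probe identifiers must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample identifiers must be unique")
        vals = self.values.to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError("detection_p shape must match values")
            self.detection_p = self.detection_p.set_axis(self.values.index, axis=0)
            self.detection_p = self.detection_p.set_axis(self.values.columns, axis=1)
            dp = self.detection_p.to_numpy(dtype=float)
            if np.any((dp < 0) | (dp > 1)):
                raise ValueError("detection p-values must lie in [0, 1]")
        if self.gene_symbols is not None:
            if len(self.gene_symbols) != len(self.values.index):
                raise ValueError("gene_symbols length must match probe count")
            self.gene_symbols = self.gene_symbols.set_axis(self.values.index)

    # -- basic views ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self, offset: float = 1.0) -> pd.DataFrame:
        """log2(intensity + offset); the scale all test statistics run on."""
        return np.log2(self.values + offset)

    # -- subsetting ----------------------------------------------------
    def subset_probes(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[probes],
            detection_p=None if self.detection_p is None else self.detection_p.loc[probes],
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.loc[probes],
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[:, samples],
            detection_p=None if self.detection_p is None else self.detection_p.loc[:, samples],
            gene_symbols=self.gene_symbols,
        )

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, expr_path, detect_path=None, annot_path=None) -> None:
        self.values.rename_axis("probe_id").to_csv(expr_path, sep="\t")
        if detect_path is not None and self.detection_p is not None:
            self.detection_p.rename_axis("probe_id").to_csv(detect_path, sep="\t")
        if annot_path is not None and self.gene_symbols is not None:
            self.gene_symbols.rename("gene_symbol").rename_axis("probe_id").to_csv(
                annot_path, sep="\t"
            )

    @classmethod
    def from_tsv(cls, expr_path, detect_path=None, annot_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        detection = None
        if detect_path is not None and Path(detect_path).exists():
            detection = pd.read_csv(detect_path, sep="\t", index_col=0)
        symbols = None
        if annot_path is not None and Path(annot_path).exists():
            symbols = pd.read_csv(annot_path, sep="\t", index_col=0)["gene_symbol"]
        return cls(values=values, detection_p=detection, gene_symbols=symbols)


def validate_phenotypes(ph: pd.DataFrame, sample_ids=None) -> pd.DataFrame:
    """Check a phenotype table against the pipeline's contract.

    Returns the table indexed by ``sample_id``. Raises ``ValueError`` on a
    missing column, an unknown region/diagnosis level, a subject with two
    samples in one region, or a mismatch with ``sample_ids``.
    """
    ph = ph.copy()
    if ph.index.name == "sample_id":
        ph = ph.reset_index()
    missing = [c for c in PHENOTYPE_COLUMNS if c not in ph.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if not ph["sample_id"].is_unique:
        raise ValueError("sample_id values must be unique")
    bad_region = set(ph["region"]) - set(REGIONS)
    if bad_region:
        raise ValueError(f"unknown region levels: {sorted(bad_region)}")
    bad_dx = set(ph["diagnosis"]) - set(DIAGNOSES)
    if bad_dx:
        raise ValueError(f"unknown diagnosis levels: {sorted(bad_dx)}")
    dup = ph.groupby(["subject_id", "region"]).size()
    if (dup > 1).any():
        offenders = dup[dup > 1].index.tolist()
        raise ValueError(f"subject has >1 sample in a region: {offenders}")
    ph = ph.set_index("sample_id")
    if sample_ids is not None:
        if set(ph.index) != set(sample_ids):
            raise ValueError("phenotype sample_ids do not match expression matrix")
        ph = ph.loc[list(sample_ids)]
    return ph


def read_phenotypes(path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, sep="\t"))


def write_phenotypes(ph: pd.DataFrame, path) -> None:
    out = ph.reset_index() if ph.index.name == "sample_id" else ph
    out.to_csv(path, sep="\t", index=False)
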