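"""Array-level QC and probe filtering.

The fixed pipeline order is: inter-array-correlation outlier pass ->
quantile normalization -> second outlier pass -> detection/annotation
filters -> duplicate-probe collapse. Outlier removal ignores phenotypes
entirely; filters only change membership, never surviving values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "quantile_normalize",
    "remove_outlier_arrays",
    "filter_probes",
    "collapse_duplicates",
    "preprocess_pipeline",
    "PreprocessReport",
]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share one reference distribution.

    The reference is the across-sample mean of each rank's values; tied
    values within a sample receive the mean of the reference values at
    their tied ranks, so the map is well defined and idempotent up to ties.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    n, p = vals.shape
    reference = np.sort(vals, axis=0).mean(axis=1)

    out = np.empty_like(vals)
    for j in range(p):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # average the assigned reference values over ties
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]

    return ExpressionMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        detection_p=m.detection_p,
        gene_symbols=m.gene_symbols,
    )


def remove_outlier_arrays(
    m: ExpressionMatrix, z_cut: float = -2.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop arrays whose mean inter-array correlation (IAC) is an outlier.

    For each sample the IAC is its mean Pearson correlation with all other
    samples; samples with standardized IAC below ``z_cut`` are removed in a
    single round. The rule never looks at phenotypes. When all IACs are
    equal the z-scores are defined as 0 and nothing is removed.
    """
    if m.n_samples < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    vals = m.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, np.nan)
    iac = np.nanmean(corr, axis=0)
    sd = iac.std(ddof=1)
    z = np.zeros_like(iac) if (sd == 0 or not np.isfinite(sd)) else (iac - iac.mean()) / sd
    flagged = z < z_cut
    if flagged.all():
        raise ValueError("all samples flagged as outliers; check the input matrix")
    removed = list(m.values.columns[flagged])
    kept = m.subset_samples(m.values.columns[~flagged])
    return kept, removed


def filter_probes(
    m: ExpressionMatrix,
    present_p: float = 0.1,
    min_present: int = 3,
    floor_quantile: float = 0.05,
) -> ExpressionMatrix:
    """Drop rarely detected and unannotated probes.

    A probe is "present" in a sample when its detection p-value is below
    ``present_p``; probes present in ``min_present`` or fewer samples are
    dropped, as are probes without a gene symbol. When no detection
    p-values exist, presence falls back to intensity above the sample's
    ``floor_quantile`` quantile.
    """
    if m.detection_p is not None:
        present = (m.detection_p < present_p).to_numpy()
    else:
        floors = np.quantile(m.values.to_numpy(), floor_quantile, axis=0)
        present = m.values.to_numpy() > floors[None, :]
    keep = present.sum(axis=1) > min_present
    if m.gene_symbols is not None:
        annotated = m.gene_symbols.notna() & (m.gene_symbols.astype(str).str.strip() != "")
        keep &= annotated.to_numpy()
    return m.subset_probes(m.values.index[keep])


def collapse_duplicates(
    m: ExpressionMatrix, r_cut: float = 0.8, mode: str = "all_pairs"
) -> ExpressionMatrix:
    """Resolve multiple probes per gene symbol.

    When a gene's probes are mutually consistent (every pairwise Pearson
    correlation above ``r_cut``; ``mode='mean_pairs'`` relaxes this to the
    mean pairwise correlation), only the probe with the highest average
    expression is retained; discordant probe groups are left untouched.
    """
    if m.gene_symbols is None:
        raise ValueError("collapse_duplicates requires gene symbol annotations")
    if mode not in ("all_pairs", "mean_pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = m.values
    drop: list[str] = []
    for _, probes in m.gene_symbols.groupby(m.gene_symbols, sort=False).groups.items():
        if len(probes) < 2:
            continue
        sub = vals.loc[probes]
        corr = np.corrcoef(sub.to_numpy())
        off = corr[np.triu_indices(len(probes), k=1)]
        consistent = (off > r_cut).all() if mode == "all_pairs" else off.mean() > r_cut
        if consistent:
            best = sub.mean(axis=1).idxmax()
            drop.extend(p for p in probes if p != best)
    keep = vals.index.difference(pd.Index(drop), sort=False)
    return m.subset_probes(vals.index[vals.index.isin(keep)])


@dataclass
class PreprocessReport:
    removed_pre_norm: list[str] = field(default_factory=list)
    removed_post_norm: list[str] = field(default_factory=list)
    n_probes_in: int = 0
    n_probes_after_filter: int = 0
    n_probes_after_collapse: int = 0
    n_samples_out: int = 0


def preprocess_pipeline(
    m: ExpressionMatrix,
    present_p: float = 0.1,
    min_present: int = 3,
    r_cut: float = 0.8,
    z_cut: float = -2.0,
    collapse_mode: str = "all_pairs",
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Run the full fixed-order preprocessing chain and report counts."""
    report = PreprocessReport(n_probes_in=m.n_probes)
    m, report.removed_pre_norm = remove_outlier_arrays(m, z_cut=z_cut)
    m = quantile_normalize(m)
    m, report.removed_post_norm = remove_outlier_arrays(m, z_cut=z_cut)
    m = filter_probes(m, present_p=present_p, min_present=min_present)
    report.n_probes_after_filter = m.n_probes
    m = collapse_duplicates(m, r_cut=r_cut, mode=collapse_mode)
    report.n_probes_after_collapse = m.n_probes
    report.n_samples_out = m.n_samples
    return m, report
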