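"""Cell-composition-adjusted differential expression.

Bulk hippocampal tissue mixes neurons and glia, and AD shifts that mixture
(neuron loss, gliosis). To separate intrinsic transcriptional change from
composition change, each gene's log2 profile is regressed on region and
diagnosis indicators plus the standardized log2 profiles of one marker
gene per major cell type (neurons SYT1, astrocytes AQP4, oligodendrocytes
MOG, microglia TYROBP by default). The model deliberately ignores the
within-subject pairing, so its p-values are descriptive, not inferential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = ["AdjustedModelResult", "fit_adjusted_model", "fraction_retained", "DEFAULT_MARKERS"]

DEFAULT_MARKERS = ("SYT1", "AQP4", "MOG", "TYROBP")


@dataclass
class AdjustedModelResult:
    """Per-gene OLS coefficients/t/p for each model term.

    ``coef``, ``t`` and ``p`` are gene × term DataFrames with terms
    ``intercept, region, disease, <marker1..4>``; marker genes themselves
    are excluded from the evaluated gene set. ``descriptive`` flags the
    pairing caveat.
    """

    coef: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    markers: tuple[str, ...]
    df_resid: int
    descriptive: bool = True

    def adjusted_significant(self, term: str = "disease", p_cut: float = 0.05) -> pd.Series:
        return self.p[term] < p_cut


def _marker_probes(m: ExpressionMatrix, markers) -> dict[str, str]:
    if m.gene_symbols is None:
        raise ValueError("marker lookup needs gene symbol annotations")
    symbols = m.gene_symbols.astype(str).str.upper()
    found = {}
    for marker in markers:
        hits = symbols.index[symbols == str(marker).upper()]
        if len(hits) == 0:
            raise ValueError(f"marker gene {marker!r} not present in the matrix")
        # several probes: take the one with the highest mean expression
        found[marker] = m.values.loc[hits].mean(axis=1).idxmax()
    return found


def fit_adjusted_model(
    m: ExpressionMatrix,
    ph: pd.DataFrame,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    include_markers: bool = True,
) -> AdjustedModelResult:
    """OLS of every gene on region, diagnosis, and cell-type markers.

    Marker profiles enter z-scored (mean 0, unit variance across samples)
    so their coefficients are comparable; region/disease are 0/1 indicators
    (CA1 = 1, AD = 1). Coefficient t-tests use n - p degrees of freedom.
    ``include_markers=False`` drops the marker covariates, giving the
    matched unadjusted model on the same gene set.
    """
    if m.n_samples < 10:
        raise ValueError("need at least 10 samples for a stable fit")
    ph = ph.loc[m.sample_ids]
    marker_probes = _marker_probes(m, markers)

    terms = ["intercept", "region", "disease"]
    cols = [
        np.ones(m.n_samples),
        (ph["region"] == "CA1").to_numpy(float),
        (ph["diagnosis"] == "AD").to_numpy(float),
    ]
    log2v = m.log2()
    if include_markers:
        for marker, probe in marker_probes.items():
            profile = log2v.loc[probe].to_numpy(float)
            sd = profile.std(ddof=0)
            if sd <= 1e-10:  # numerically constant on the log2 scale
                raise ValueError(f"marker {marker!r} has a constant profile")
            cols.append((profile - profile.mean()) / sd)
            terms.append(marker)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the first column whose removal restores full rank
        for j in range(X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
                raise ValueError(f"collinear design: column {terms[j]!r}")
        raise ValueError("collinear design matrix")

    eval_probes = m.values.index.difference(pd.Index(marker_probes.values()), sort=False)
    eval_probes = m.values.index[m.values.index.isin(eval_probes)]
    Y = log2v.loc[eval_probes].to_numpy(float).T  # samples × genes

    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # k × genes
    resid = Y - X @ beta
    df_resid = n - k
    sigma2 = (resid**2).sum(axis=0) / df_resid
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    t = np.where(se == 0, 0.0, t)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df_resid), np.finfo(float).tiny, 1.0)

    genes = eval_probes
    return AdjustedModelResult(
        coef=pd.DataFrame(beta.T, index=genes, columns=terms),
        t=pd.DataFrame(t.T, index=genes, columns=terms),
        p=pd.DataFrame(p.T, index=genes, columns=terms),
        markers=tuple(markers) if include_markers else (),
        df_resid=df_resid,
    )


def fraction_retained(
    de_genes: list[str],
    adj: AdjustedModelResult,
    term: str = "disease",
    p_cut: float = 0.05,
    gene_symbols: pd.Series | None = None,
) -> float:
    """Fraction of a DE gene list still significant after adjustment.

    ``de_genes`` may be probe ids or gene symbols (pass ``gene_symbols`` to
    translate). Marker genes, which have no adjusted p, are ignored.
    """
    if len(de_genes) == 0:
        raise ValueError("empty differential-expression gene list")
    pvals = adj.p[term]
    if gene_symbols is not None:
        sym_to_probe = {}
        for probe, sym in gene_symbols.items():
            sym_to_probe.setdefault(str(sym).upper(), probe)
        de_genes = [sym_to_probe.get(str(g).upper(), g) for g in de_genes]
    hits = [g for g in de_genes if g in pvals.index]
    if len(hits) == 0:
        raise ValueError("none of the DE genes appear in the adjusted results")
    return float((pvals.loc[hits] < p_cut).mean())
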