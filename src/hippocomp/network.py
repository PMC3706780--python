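"""Signed weighted co-expression network analysis.

Pairwise Pearson correlations become a signed adjacency
a_ij = ((1 + cor_ij)/2)^beta, from which topological overlap (TOM) measures
shared-neighbor similarity. Modules come from average-linkage clustering on
1 - TOM with a static height cut plus small-branch merging, summarized by
eigengenes (first principal components); every gene — including genes left
out of the connectivity-restricted clustering — is then (re)assigned to the
module whose eigengene it best correlates with (kME), iterated to a fixed
point. Module eigengenes are associated with region/diagnosis (Bayes
ANOVA), early Braak stage in controls (t-test), and age (Pearson r).
Gene-list overlap uses the hypergeometric tail, with the conservative EASE
variant (overlap decremented by one) available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "NetworkConfig",
    "ModuleSet",
    "EnrichmentResult",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_trait_association",
    "extract_hub_edges",
    "list_overlap_enrichment",
    "batch_enrichment",
]

#: Module labels follow the field's color-name convention, ordered by size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
]


@dataclass(frozen=True)
class NetworkConfig:
    beta: float = 12.0
    signed: bool = True
    top_k_connectivity: int = 15_000
    min_module_size: int = 30
    cut_height_quantile: float = 0.99
    edge_count: int = 250
    hub_degree: int = 15
    reciprocal_q: int = 50  # mutual nearest-neighbor depth defining reciprocity
    min_kme_warn: float = 0.3

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")


@dataclass
class ModuleSet:
    """Exhaustive module assignment with eigengenes, kME, hubs and edges."""

    labels: pd.Series  # gene -> module label (every gene labeled)
    eigengenes: pd.DataFrame  # samples × modules
    kme: pd.DataFrame  # genes × modules
    hubs: dict[str, list[str]] = field(default_factory=dict)
    edges: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        return list(self.eigengenes.columns)

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


@dataclass
class EnrichmentResult:
    category: str
    universe_size: int
    list_size: int
    category_size: int
    overlap: int
    p_hypergeometric: float
    p_ease: float
    q: float | None = None


# ---------------------------------------------------------------------------
# adjacency / TOM
# ---------------------------------------------------------------------------

def _gene_correlations(m: ExpressionMatrix) -> np.ndarray:
    x = m.log2().to_numpy()
    sd = x.std(axis=1)
    constant = sd <= 1e-10  # identical values can leave ~1e-16 roundoff
    if np.any(constant):
        offender = m.values.index[int(np.argmax(constant))]
        raise ValueError(f"constant gene profile: {offender!r}")
    cor = np.corrcoef(x)
    return np.clip(cor, -1.0, 1.0)


def adjacency(m: ExpressionMatrix, beta: float = 12.0) -> pd.DataFrame:
    """Signed soft-thresholded adjacency a_ij = ((1 + cor_ij)/2)^beta."""
    cor = _gene_correlations(m)
    a = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=m.values.index, columns=m.values.index)


def topological_overlap(a: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    The numerator sum runs over u distinct from both i and j;
    k_i = sum_{u != i} a_iu is the node connectivity. Requires a symmetric
    adjacency with unit diagonal; the result is symmetric in [0, 1] with
    unit diagonal.
    """
    av = a.to_numpy(dtype=float)
    if not np.allclose(av, av.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    n = av.shape[0]
    k = av.sum(axis=1) - np.diag(av)
    shared = av @ av
    # remove the u = i and u = j terms (diagonal is 1)
    shared = shared - av * np.diag(av)[:, None] - av * np.diag(av)[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - av
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + av) / denom
    tom = np.where(denom == 0, 1.0, tom)
    tom = (tom + tom.T) / 2.0  # enforce exact symmetry against matmul roundoff
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=a.index, columns=a.columns)


def pick_soft_threshold(
    m: ExpressionMatrix,
    candidates: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Smallest power giving approximate scale-free topology (R^2 >= target).

    For each candidate power the connectivity distribution is binned and
    log10(frequency) regressed on log10(mean connectivity); the fit R^2
    measures how scale-free the network is. Falls back, with a warning, to
    the R^2-maximizing power when no candidate reaches the target.
    """
    if m.n_probes < 20:
        raise ValueError("need at least 20 genes to assess scale-free fit")
    cor = _gene_correlations(m)
    rows = []
    for beta in candidates:
        a = ((1.0 + cor) / 2.0) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append({"beta": float(beta), "r2": _scale_free_r2(k, n_bins), "mean_k": float(k.mean())})
    fits = pd.DataFrame(rows)
    ok = fits[fits["r2"] >= r2_target]
    if len(ok):
        chosen = float(ok["beta"].iloc[0])
    else:
        chosen = float(fits.loc[fits["r2"].idxmax(), "beta"])
        warnings.warn(
            f"no candidate power reached scale-free R^2 >= {r2_target}; "
            f"using beta={chosen} (R^2={fits['r2'].max():.3f})",
            stacklevel=2,
        )
    return chosen, fits


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if len(k) < n_bins or np.allclose(k, k[0]):
        return 0.0
    # equal-width bins over the connectivity range (WGCNA's convention);
    # quantile bins would flatten the frequency axis by construction
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-9
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3 or np.allclose(xs, xs[0]) or np.allclose(ys, ys[0]):
        return 0.0
    r = stats.pearsonr(xs, ys)[0]
    if not np.isfinite(r):
        return 0.0
    return float(r**2)


# ---------------------------------------------------------------------------
# eigengenes and module detection
# ---------------------------------------------------------------------------

def module_eigengene(m: ExpressionMatrix, members) -> tuple[pd.Series, float]:
    """First principal component of the gene-standardized module submatrix.

    Returns the unit-norm sample-length eigengene, sign-oriented so its
    correlation with the module's mean standardized expression is
    non-negative, together with the fraction of variance it explains.
    """
    members = pd.Index(members)
    if len(members) < 2:
        raise ValueError("a module needs at least 2 genes")
    x = m.log2().loc[members].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if np.any(sd <= 1e-10):
        raise ValueError("constant gene profile inside the module")
    xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = xs.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=m.sample_ids, name="eigengene"), var_explained


def _kme(m: ExpressionMatrix, eigengenes: pd.DataFrame) -> pd.DataFrame:
    x = m.log2().to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    xn = xc / np.linalg.norm(xc, axis=1, keepdims=True)
    e = eigengenes.to_numpy(dtype=float)
    ec = e - e.mean(axis=0, keepdims=True)
    en = ec / np.linalg.norm(ec, axis=0, keepdims=True)
    kme = np.clip(xn @ en, -1.0, 1.0)
    return pd.DataFrame(kme, index=m.values.index, columns=eigengenes.columns)


def detect_modules(m: ExpressionMatrix, cfg: NetworkConfig = NetworkConfig()) -> ModuleSet:
    """Cluster the co-expression network into modules.

    Initial clustering runs on the ``top_k_connectivity`` most-connected
    genes: average-linkage on 1 - TOM, cut at the ``cut_height_quantile``
    of merge heights, with branches below ``min_module_size`` merged into
    the branch whose eigengene they correlate with best. Final labels come
    from iterated kME reassignment of *all* genes, so reassignment is a
    fixed point of the returned ModuleSet.
    """
    if m.n_probes < cfg.min_module_size:
        raise ValueError("fewer genes than min_module_size")
    a = adjacency(m, beta=cfg.beta)
    k = a.to_numpy().sum(axis=1) - 1.0
    top = min(cfg.top_k_connectivity, m.n_probes)
    keep = m.values.index[np.argsort(k)[::-1][:top]]
    keep = m.values.index[m.values.index.isin(keep)]  # preserve original order
    tom = topological_overlap(a.loc[keep, keep])

    dist = 1.0 - tom.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    # cut at a fraction of the dendrogram height range, the WGCNA static-cut
    # convention (cutHeight = 0.99 of the join range by default)
    h = Z[:, 2]
    cut = h.min() + cfg.cut_height_quantile * (h.max() - h.min())
    initial = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(initial, index=keep)

    labels = _merge_small_branches(m, labels, cfg.min_module_size)

    # iterate: eigengenes -> kME reassignment over all genes -> repeat
    for _ in range(25):
        eigengenes = _cluster_eigengenes(m, labels)
        kme = _kme(m, eigengenes)
        new_labels = kme.abs().idxmax(axis=1)
        if len(labels) == m.n_probes and new_labels.equals(labels):
            break
        labels = new_labels
    eigengenes = _cluster_eigengenes(m, labels)
    kme = _kme(m, eigengenes)
    stranded = ~labels.isin(eigengenes.columns)
    if stranded.any():  # a label can lose all but one member during reassignment
        labels.loc[stranded] = kme.loc[stranded].abs().idxmax(axis=1)
        eigengenes = _cluster_eigengenes(m, labels)
        kme = _kme(m, eigengenes)

    labels, eigengenes, kme = _rename_by_size(labels, eigengenes, kme)
    weak = kme.to_numpy()[np.arange(len(labels)), kme.columns.get_indexer(labels)]
    n_weak = int((np.abs(weak) < cfg.min_kme_warn).sum())
    if n_weak:
        warnings.warn(f"{n_weak} genes assigned with |kME| < {cfg.min_kme_warn}", stacklevel=2)
    return ModuleSet(labels=labels, eigengenes=eigengenes, kme=kme)


def _cluster_eigengenes(m: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    eig = {}
    for lab in pd.unique(labels):
        members = labels.index[labels == lab]
        if len(members) < 2:
            continue
        eig[lab], _ = module_eigengene(m, members)
    if not eig:
        raise ValueError("no cluster with >= 2 genes")
    return pd.DataFrame(eig)


def _merge_small_branches(m: ExpressionMatrix, labels: pd.Series, min_size: int) -> pd.Series:
    """Fold undersized branches into the big branch with the most-correlated
    eigengene; if no branch is big enough, keep the largest as the seed."""
    labels = labels.copy()
    while True:
        sizes = labels.value_counts()
        big = sizes.index[sizes >= min_size]
        small = sizes.index[sizes < min_size]
        if len(small) == 0:
            break
        if len(big) == 0:
            big = sizes.index[:1]
            small = sizes.index[1:]
            if len(small) == 0:
                break
        eigs = _cluster_eigengenes(m, labels[labels.isin(big)])
        x = m.log2()
        moved = False
        for lab in small:
            members = labels.index[labels == lab]
            profile = x.loc[members].mean(axis=0) if len(members) > 1 else x.loc[members[0]]
            cors = eigs.apply(lambda e: np.corrcoef(profile.to_numpy(), e.to_numpy())[0, 1])
            labels.loc[members] = cors.idxmax()
            moved = True
        if not moved:
            break
    return labels


def _rename_by_size(labels, eigengenes, kme):
    order = labels.value_counts().index
    mapping = {}
    for i, old in enumerate(order):
        mapping[old] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
    labels = labels.map(mapping)
    eigengenes = eigengenes.rename(columns=mapping)
    kme = kme.rename(columns=mapping)
    cols = [mapping[o] for o in order if mapping[o] in eigengenes.columns]
    return labels, eigengenes[cols], kme[cols]


# ---------------------------------------------------------------------------
# module-trait association
# ---------------------------------------------------------------------------

def _eigengene_bayes_anova(values: pd.Series, groups: pd.Series, conf: float = 12.0):
    """Four-group Bayes ANOVA on a single eigengene.

    With one profile the expression-rank window degenerates, so the
    background variance is the eigengene's own pooled within-group
    variance and ``conf`` acts as pure degrees-of-freedom inflation.
    """
    levels = sorted(groups.unique())
    k = len(levels)
    xs = [values[groups == lev].to_numpy(dtype=float) for lev in levels]
    ns = [len(x) for x in xs]
    if min(ns) < 2:
        raise ValueError("every group needs >= 2 samples")
    grand = np.concatenate(xs).mean()
    ss_between = sum(n * (x.mean() - grand) ** 2 for n, x in zip(ns, xs))
    pooled = sum((n - 1) * x.var(ddof=1) for n, x in zip(ns, xs)) / (sum(ns) - k)
    ss_within = sum(conf * pooled + (n - 1) * x.var(ddof=1) for n, x in zip(ns, xs))
    df_den = sum(conf + n for n in ns) - k
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / df_den
    if ms_within == 0:
        return (0.0, 1.0) if ms_between == 0 else (float("inf"), float(np.finfo(float).tiny))
    F = ms_between / ms_within
    return float(F), float(np.clip(stats.f.sf(F, k - 1, df_den), np.finfo(float).tiny, 1.0))


def module_trait_association(
    ms: ModuleSet, ph: pd.DataFrame, conf: float = 12.0
) -> pd.DataFrame:
    """Associate every module eigengene with the study's phenotypes.

    Columns: ``group_F``/``group_p`` (Bayes ANOVA over the four
    region-by-diagnosis cells), ``braak_t``/``braak_p`` (Braak 1 vs 2
    within controls), ``age_r``/``age_p`` (Pearson, within controls).
    """
    for col in ("region", "diagnosis", "braak", "age"):
        if col not in ph.columns:
            raise ValueError(f"phenotype table lacks {col!r}")
    ph = ph.loc[ms.eigengenes.index]
    groups = ph["diagnosis"].str[:1].str.upper() + ph["region"].str[-1]
    controls = ph.index[ph["diagnosis"] == "control"]
    rows = {}
    for module in ms.module_names:
        eig = ms.eigengenes[module]
        F, p_group = _eigengene_bayes_anova(eig, groups, conf=conf)
        b1 = eig[controls[ph.loc[controls, "braak"] == 1]]
        b2 = eig[controls[ph.loc[controls, "braak"] == 2]]
        if len(b1) >= 2 and len(b2) >= 2:
            t_b, p_b = stats.ttest_ind(b2, b1, equal_var=True)
        else:
            t_b, p_b = np.nan, np.nan
        r_age, p_age = stats.pearsonr(
            eig[controls].to_numpy(), ph.loc[controls, "age"].to_numpy(dtype=float)
        )
        rows[module] = {
            "group_F": F,
            "group_p": p_group,
            "braak_t": float(t_b),
            "braak_p": float(p_b),
            "age_r": float(r_age),
            "age_p": float(p_age),
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# hubs / edges / enrichment
# ---------------------------------------------------------------------------

def extract_hub_edges(
    tom: pd.DataFrame, ms: ModuleSet, cfg: NetworkConfig = NetworkConfig()
) -> ModuleSet:
    """Per-module strongest reciprocal edges and the hub genes they define.

    Within each module, gene pairs are kept when each gene lies within the
    other's ``reciprocal_q`` strongest TOM neighbors; the ``edge_count``
    strongest such pairs are the depicted edges, and a hub is any gene with
    at least ``hub_degree`` depicted connections.
    """
    ms.edges, ms.hubs = {}, {}
    for module in ms.module_names:
        members = ms.members(module)
        members = members[members.isin(tom.index)]
        if len(members) < 2:
            warnings.warn(f"module {module!r} has <2 genes in the TOM; skipped", stacklevel=2)
            continue
        sub = tom.loc[members, members].to_numpy()
        np.fill_diagonal(sub, -np.inf)
        q = min(cfg.reciprocal_q, len(members) - 1)
        order = np.argsort(-sub, axis=1, kind="mergesort")[:, :q]
        neighbor = np.zeros_like(sub, dtype=bool)
        np.put_along_axis(neighbor, order, True, axis=1)
        mutual = neighbor & neighbor.T
        iu = np.triu_indices(len(members), k=1)
        pair_mask = mutual[iu]
        weights = sub[iu][pair_mask]
        gi = iu[0][pair_mask]
        gj = iu[1][pair_mask]
        top = np.argsort(-weights, kind="mergesort")[: cfg.edge_count]
        edges = pd.DataFrame(
            {
                "gene1": members[gi[top]],
                "gene2": members[gj[top]],
                "tom": weights[top],
            }
        )
        degree = pd.concat([edges["gene1"], edges["gene2"]]).value_counts()
        ms.edges[module] = edges
        ms.hubs[module] = sorted(degree.index[degree >= cfg.hub_degree])
    return ms


def list_overlap_enrichment(
    gene_list, category, universe, mode: str = "hypergeometric", name: str = ""
) -> EnrichmentResult:
    """Hypergeometric over-representation of a category within a gene list.

    ``mode='ease'`` reports the conservative EASE variant as the headline
    p (overlap decremented by one, floored at zero); both are always
    computed and EASE p >= hypergeometric p for every input.
    """
    universe = {str(g).upper() for g in universe}
    gene_list = {str(g).upper() for g in gene_list}
    category = {str(g).upper() for g in category}
    stray = gene_list - universe
    if stray:
        raise ValueError(f"list genes outside the universe: {sorted(stray)[:10]}")
    stray = category - universe
    if stray:
        raise ValueError(f"category genes outside the universe: {sorted(stray)[:10]}")
    N, n, K = len(universe), len(gene_list), len(category)
    k = len(gene_list & category)
    p_hyp = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    k_ease = max(k - 1, 0)
    p_ease = float(stats.hypergeom.sf(k_ease - 1, N, K, n)) if k_ease > 0 else 1.0
    if mode not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    return EnrichmentResult(
        category=name,
        universe_size=N,
        list_size=n,
        category_size=K,
        overlap=k,
        p_hypergeometric=min(p_hyp, 1.0),
        p_ease=min(p_ease, 1.0),
    )


def batch_enrichment(
    gene_list, categories: dict, universe, mode: str = "hypergeometric"
) -> pd.DataFrame:
    """Run list_overlap_enrichment over many categories with BH q-values."""
    results = [
        list_overlap_enrichment(gene_list, cat, universe, mode=mode, name=name)
        for name, cat in categories.items()
    ]
    headline = [r.p_ease if mode == "ease" else r.p_hypergeometric for r in results]
    qs = multipletests(headline, method="fdr_bh")[1] if results else []
    rows = []
    for r, q in zip(results, qs):
        r.q = float(q)
        rows.append(vars(r))
    return pd.DataFrame(rows).set_index("category") if rows else pd.DataFrame()
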