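"""Contrast statistics, gene lists, Bayes-regularized ANOVA, interaction
quadrants, and the regional vulnerability/protection classifier.

Conventions used throughout:

* test statistics run on log2(intensity + 1);
* fold changes are linear-scale group-mean (or group-median) ratios reported
  with the signed convention fc = r if r >= 1 else -1/r, so -1.44 means
  1.44-fold lower in the first-listed group;
* the ranking score is z = sign(t) * Phi^-1(1 - p/2), a signed normal
  quantile of the two-tailed p-value;
* p-values are uncorrected (Benjamini-Hochberg q-values are carried along
  but never drive any threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "ContrastResult",
    "GeneListThresholds",
    "contrast",
    "select_genes",
    "bayes_anova",
    "classify_vulnerability",
    "interaction_quadrants",
    "signed_fc",
    "welchless_t_from_summary",
]

_TINY_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class GeneListThresholds:
    """Significance/fold-change cutoffs for gene-list construction."""

    p_cut: float = 0.05
    fc_cut: float = 1.2
    strict_fc_cut: float = 1.4
    high_expr_cut: float = 1000.0
    very_sig_cut: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must be in (0, 1)")
        if self.fc_cut < 1:
            raise ValueError("fc_cut must be >= 1")


@dataclass
class ContrastResult:
    """Per-gene statistics for one two-group comparison.

    ``table`` is indexed by probe id with columns: gene, t, p, q,
    fc_signed, fc_median_signed, mean_a, mean_b, median_a, median_b, z.
    Group "a" is the first-listed group; positive fold changes mean higher
    in group a.
    """

    table: pd.DataFrame
    label: str
    paired: bool
    groups: tuple

    def __getitem__(self, col):
        return self.table[col]

    @property
    def genes(self) -> pd.Series:
        return self.table["gene"]


def signed_fc(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Linear-ratio fold change with symmetric sign convention."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    if np.any(mean_a <= 0) or np.any(mean_b <= 0):
        raise ValueError("fold changes need strictly positive group means")
    r = mean_a / mean_b
    return np.where(r >= 1, r, -1.0 / r)


def _two_tailed_p(t: np.ndarray, df: float) -> np.ndarray:
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.clip(p, _TINY_P, 1.0)


def _t_from_effect(num: np.ndarray, denom: np.ndarray, df: float):
    """Shared degenerate-variance convention: 0/0 -> t=0, p=1; x/0 -> p=tiny."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    zero_den = denom == 0
    t = np.where(zero_den & (num == 0), 0.0, t)
    t = np.where(zero_den & (num > 0), np.inf, t)
    t = np.where(zero_den & (num < 0), -np.inf, t)
    p = np.where(np.isinf(t), _TINY_P, _two_tailed_p(np.where(np.isinf(t), 0.0, t), df))
    p = np.where(zero_den & (num == 0), 1.0, p)
    return t, p


def contrast(
    m: ExpressionMatrix,
    ph: pd.DataFrame,
    by: str,
    groups: tuple,
    subset: dict | None = None,
    paired: bool = False,
    equal_var: bool = True,
    label: str | None = None,
) -> ContrastResult:
    """Two-group differential expression for every probe.

    ``by`` names the phenotype column defining groups ``(a, b)``;
    ``subset`` restricts samples first (e.g. ``{"diagnosis": "control"}``).
    Region contrasts should set ``paired=True`` to exploit the
    within-subject CA1/CA3 design (a paired t on subject-matched log2
    differences); otherwise a two-sample Student's t (pooled variance by
    default, Welch with ``equal_var=False``) is used.
    """
    samples = ph
    if subset:
        for col, val in subset.items():
            samples = samples[samples[col] == val]
    ids_a = samples.index[samples[by] == groups[0]]
    ids_b = samples.index[samples[by] == groups[1]]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(f"contrast needs >=2 samples per group, got {len(ids_a)}/{len(ids_b)}")

    log2v = m.log2()
    lin = m.values
    xa, xb = log2v[ids_a].to_numpy(), log2v[ids_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]

    if paired:
        subj_a = samples.loc[ids_a, "subject_id"]
        subj_b = samples.loc[ids_b, "subject_id"]
        if subj_a.duplicated().any() or subj_b.duplicated().any():
            raise ValueError("paired contrast found a subject twice within one group")
        shared = subj_a[subj_a.isin(set(subj_b))]
        if len(shared) < 2:
            raise ValueError("paired contrast requires >=2 subjects present in both groups")
        ids_a = shared.index
        xa = log2v[ids_a].to_numpy()
        order = (
            subj_b.reset_index()
            .set_index("subject_id")
            .loc[shared.to_numpy()]
            .iloc[:, 0]
        )
        ids_b = pd.Index(order.to_numpy())
        xb = log2v[ids_b].to_numpy()
        diffs = xa - xb
        n = diffs.shape[1]
        df = n - 1
        num = diffs.mean(axis=1)
        denom = diffs.std(axis=1, ddof=1) / np.sqrt(n)
        t, p = _t_from_effect(num, denom, df)
    else:
        df = na + nb - 2
        num = xa.mean(axis=1) - xb.mean(axis=1)
        va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
        if equal_var:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / df
            denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            t, p = _t_from_effect(num, denom, df)
        else:
            denom = np.sqrt(va / na + vb / nb)
            with np.errstate(divide="ignore", invalid="ignore"):
                df_w = denom**4 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            df_w = np.where(np.isfinite(df_w), df_w, df)
            t, p = _t_from_effect(num, denom, df_w)

    mean_a = lin[ids_a].mean(axis=1).to_numpy()
    mean_b = lin[ids_b].mean(axis=1).to_numpy()
    med_a = lin[ids_a].median(axis=1).to_numpy()
    med_b = lin[ids_b].median(axis=1).to_numpy()
    fc = signed_fc(mean_a, mean_b)
    fc_med = signed_fc(med_a, med_b)

    z = np.sign(t) * stats.norm.isf(p / 2.0)
    z = np.where(t == 0, 0.0, z)
    q = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": m.gene_symbols if m.gene_symbols is not None else m.values.index,
            "t": t,
            "p": p,
            "q": q,
            "fc_signed": fc,
            "fc_median_signed": fc_med,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "median_a": med_a,
            "median_b": med_b,
            "z": z,
        },
        index=m.values.index,
    )
    return ContrastResult(
        table=table,
        label=label or f"{by}:{groups[0]}_vs_{groups[1]}",
        paired=paired,
        groups=groups,
    )


def select_genes(
    r: ContrastResult,
    th: GeneListThresholds = GeneListThresholds(),
    direction: str = "both",
    highly_expressed: bool = False,
    very_significant: bool = False,
    strict_fc: bool = False,
) -> list[str]:
    """Directional differentially-expressed gene lists.

    Baseline rule: p below ``p_cut`` and |fold change| above ``fc_cut``.
    Optional refinements restrict to highly expressed genes (grand linear
    mean above ``high_expr_cut``), the stricter p cutoff, or the stricter
    fold-change cutoff.
    """
    t = r.table
    p_cut = th.very_sig_cut if very_significant else th.p_cut
    fc_cut = th.strict_fc_cut if strict_fc else th.fc_cut
    keep = (t["p"] < p_cut) & (t["fc_signed"].abs() > fc_cut)
    if direction == "up":
        keep &= t["fc_signed"] > 0
    elif direction == "down":
        keep &= t["fc_signed"] < 0
    elif direction != "both":
        raise ValueError(f"unknown direction {direction!r}")
    if highly_expressed:
        keep &= (t["mean_a"] + t["mean_b"]) / 2.0 > th.high_expr_cut
    return list(t.loc[keep, "gene"])


# ---------------------------------------------------------------------------
# Bayes-regularized one-way ANOVA
# ---------------------------------------------------------------------------

def _window_background(s2: np.ndarray, order_stat: np.ndarray, win_size: int) -> np.ndarray:
    """Mean sample variance of the ``win_size`` genes nearest in
    mean-expression rank, window clamped at the edges."""
    n = s2.shape[0]
    order = np.argsort(order_stat, kind="mergesort")
    s2_sorted = s2[order]
    half = win_size // 2
    starts = np.clip(np.arange(n) - half, 0, n - win_size)
    csum = np.concatenate([[0.0], np.cumsum(s2_sorted)])
    windowed = (csum[starts + win_size] - csum[starts]) / win_size
    out = np.empty(n)
    out[order] = windowed
    return out


def bayes_anova(
    m: ExpressionMatrix,
    ph: pd.DataFrame,
    group_labels: pd.Series | None = None,
    conf: float = 12.0,
    win_size: int = 11,
) -> pd.DataFrame:
    """One-way ANOVA with sliding-window Bayesian variance regularization.

    Within each group, every gene's sample variance is shrunk toward a
    background variance estimated from the ``win_size`` genes with the
    nearest group-mean expression, with ``conf`` pseudo-observations of
    weight. The pooled regularized within-group sum of squares is::

        SS~ = sum_g [ conf * s2_bg(g) + (n_g - 1) * s2(g) ]

    with denominator degrees of freedom ``sum_g (conf + n_g) - k``. With
    ``conf = 0`` this reduces exactly to the classical one-way F test.
    Default groups are the four region-by-diagnosis cells (C1/C3/A1/A3).
    """
    if conf < 0:
        raise ValueError("conf must be >= 0")
    if win_size < 1:
        raise ValueError("win_size must be >= 1")
    if win_size > m.n_probes:
        raise ValueError("win_size larger than the number of genes")

    if group_labels is None:
        group_labels = ph["diagnosis"].str[:1].str.upper() + ph["region"].str[-1]
    group_labels = group_labels.loc[m.sample_ids]
    levels = sorted(group_labels.unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")

    x = m.log2().to_numpy()
    n_tot = 0
    grand_num = np.zeros(m.n_probes)
    group_stats = []
    for lev in levels:
        cols = np.flatnonzero((group_labels == lev).to_numpy())
        if len(cols) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")
        xg = x[:, cols]
        ng = xg.shape[1]
        mean_g = xg.mean(axis=1)
        s2_g = xg.var(axis=1, ddof=1)
        s2_bg = _window_background(s2_g, mean_g, min(win_size, m.n_probes))
        group_stats.append((ng, mean_g, s2_g, s2_bg))
        grand_num += ng * mean_g
        n_tot += ng

    grand_mean = grand_num / n_tot
    ss_between = sum(ng * (mg - grand_mean) ** 2 for ng, mg, _, _ in group_stats)
    ms_between = ss_between / (k - 1)
    ss_within = sum(conf * bg + (ng - 1) * s2 for ng, _, s2, bg in group_stats)
    df_den = sum(conf + ng for ng, _, _, _ in group_stats) - k
    ms_within = ss_within / df_den

    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_between / ms_within
    zero_den = ms_within == 0
    F = np.where(zero_den & (ms_between == 0), 0.0, F)
    F = np.where(zero_den & (ms_between > 0), np.inf, F)
    p = np.where(
        np.isinf(F), _TINY_P, np.clip(stats.f.sf(np.where(np.isinf(F), 0, F), k - 1, df_den), _TINY_P, 1.0)
    )
    p = np.where(zero_den & (ms_between == 0), 1.0, p)

    return pd.DataFrame({"F": F, "p": p}, index=m.values.index)


# ---------------------------------------------------------------------------
# vulnerability / protection classifier
# ---------------------------------------------------------------------------

def _fc_criteria_vulnerability(region_fc, ca1_fc, ca3_fc, fc_cut):
    return (region_fc > fc_cut) & (ca1_fc > fc_cut) & (ca1_fc > ca3_fc)


def _fc_criteria_protection(region_fc, ca1_fc, ca3_fc, fc_cut, strict_cut, rule):
    region_ok = region_fc < -fc_cut  # higher in CA3
    up_branch = (ca3_fc > fc_cut) & (ca1_fc < fc_cut)
    # "decreasing" means a material CA1 decrease (beyond the FC cut), not a
    # noise-floor ratio below 1; otherwise every CA3-enriched gene with flat
    # disease response would satisfy the magnitude comparison trivially
    both_down = (ca1_fc < -fc_cut) & (ca3_fc < 0)
    if rule == "lenient":
        down_branch = both_down & (-ca3_fc < strict_cut * -ca1_fc)
    elif rule == "strict":
        down_branch = both_down & (strict_cut * -ca3_fc < -ca1_fc)
    else:
        raise ValueError(f"unknown protection rule {rule!r}")
    return region_ok & (up_branch | down_branch)


def classify_vulnerability(
    region_ctrl: ContrastResult,
    disease_ca1: ContrastResult,
    disease_ca3: ContrastResult,
    bayes_p: pd.Series,
    th: GeneListThresholds = GeneListThresholds(),
    protection_rule: str = "lenient",
) -> pd.DataFrame:
    """Call regional vulnerability and protection genes.

    Vulnerability: significantly CA1-enriched in controls (paired p below
    ``p_cut`` and FC above ``fc_cut``), AD-increased in CA1 (FC above
    ``fc_cut``) with a larger FC in CA1 than CA3, Bayes-ANOVA p below 0.05,
    and every FC criterion holding for both mean- and median-based group
    summaries. Protection mirrors this toward CA3: CA3-enriched at baseline
    and either AD-increased in CA3 only, or decreasing in both regions with
    the CA3 decrease magnitude below ``strict_fc_cut`` times the CA1
    magnitude (``protection_rule='strict'`` flips that inequality).

    ``region_ctrl`` must list CA1 first; the disease contrasts must list AD
    first. Returns a per-gene table of the class and each criterion flag; a
    gene can never carry both labels because the region clause is exclusive.
    """
    idx = region_ctrl.table.index
    for other in (disease_ca1, disease_ca3):
        if not idx.equals(other.table.index):
            raise ValueError("all contrasts must cover the same genes")
    for res in (region_ctrl, disease_ca1, disease_ca3):
        if "fc_median_signed" not in res.table:
            raise ValueError("median-based fold changes are required in every contrast")
    bayes_p = bayes_p.loc[idx]

    def crit(col):
        reg = region_ctrl.table[col].to_numpy()
        ca1 = disease_ca1.table[col].to_numpy()
        ca3 = disease_ca3.table[col].to_numpy()
        vul = _fc_criteria_vulnerability(reg, ca1, ca3, th.fc_cut)
        pro = _fc_criteria_protection(reg, ca1, ca3, th.fc_cut, th.strict_fc_cut, protection_rule)
        return vul, pro

    vul_mean, pro_mean = crit("fc_signed")
    vul_med, pro_med = crit("fc_median_signed")
    region_sig = (region_ctrl.table["p"] < th.p_cut).to_numpy()
    bayes_ok = (bayes_p < 0.05).to_numpy()

    vul = vul_mean & vul_med & region_sig & bayes_ok
    pro = pro_mean & pro_med & region_sig & bayes_ok
    cls = np.where(vul, "vulnerability", np.where(pro, "protection", "none"))

    return pd.DataFrame(
        {
            "gene": region_ctrl.table["gene"],
            "class": cls,
            "region_sig": region_sig,
            "bayes_sig": bayes_ok,
            "vulnerability_fc_mean": vul_mean,
            "vulnerability_fc_median": vul_med,
            "protection_fc_mean": pro_mean,
            "protection_fc_median": pro_med,
        },
        index=idx,
    )


# ---------------------------------------------------------------------------
# region-by-disease interaction quadrants
# ---------------------------------------------------------------------------

def interaction_quadrants(
    region: ContrastResult,
    disease: ContrastResult,
    th: GeneListThresholds = GeneListThresholds(),
) -> dict:
    """Joint region/disease significance structure over the gene universe.

    Reports the Pearson correlation between the two t-statistic vectors and,
    for each of the four sign quadrants of jointly significant genes, the
    count plus a two-sided Fisher exact p for enrichment or depletion of
    joint membership relative to the marginal significance rates.
    """
    idx = region.table.index
    if len(idx) == 0:
        raise ValueError("empty gene universe")
    if not idx.equals(disease.table.index):
        raise ValueError("contrasts must share one gene universe")

    t_r = region.table["t"].to_numpy()
    t_d = disease.table["t"].to_numpy()
    if len(idx) < 3 or t_r.std() == 0 or t_d.std() == 0:
        corr, corr_p = float("nan"), float("nan")
    else:
        corr, corr_p = stats.pearsonr(t_r, t_d)

    sig_r = region.table["p"].to_numpy() < th.p_cut
    sig_d = disease.table["p"].to_numpy() < th.p_cut
    n = len(idx)
    quadrants = {}
    for rs, ds, name in (
        (1, 1, "region_up_disease_up"),
        (1, -1, "region_up_disease_down"),
        (-1, 1, "region_down_disease_up"),
        (-1, -1, "region_down_disease_down"),
    ):
        in_r = sig_r & (np.sign(t_r) == rs)
        in_d = sig_d & (np.sign(t_d) == ds)
        a = int((in_r & in_d).sum())
        b = int((in_r & ~in_d).sum())
        c = int((~in_r & in_d).sum())
        d = n - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        quadrants[name] = {
            "count": a,
            "fisher_p": float(p),
            "odds_ratio": float(odds) if np.isfinite(odds) else float("inf"),
            "direction": "enriched" if (odds > 1 or not np.isfinite(odds)) else "depleted",
        }
    return {"t_correlation": float(corr), "t_correlation_p": float(corr_p), "quadrants": quadrants}


def welchless_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance two-sample t-test from printed summary statistics."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)
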