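"""Rank-based cross-study agreement statistics.

The central quantity is the *mean gene rank* (MGR): genes in an internal
differential-expression ranking get scaled ranks (r - 0.5)/N, and an
external gene list's MGR is the mean scaled rank of its matched genes minus
0.5, so random subsets score exactly 0 and perfectly consistent subsets
approach +0.5. External "down" genes are rank-reflected (r -> N + 1 - r)
before averaging so consistency always points toward the top of the
ranking. Significance comes from the exact without-replacement analytic
null or a permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ContrastResult

__all__ = [
    "RankedUniverse",
    "ExternalGeneList",
    "ConcordanceResult",
    "rank_universe",
    "mean_gene_rank",
    "mgr_significance",
    "sign_agreement",
    "fc_correlation",
    "classify_fc_confirmation",
]


@dataclass
class RankedUniverse:
    """Genes ranked 1..N by a signed score, consistent direction last.

    ``ranks`` maps uppercased gene symbol -> rank; ``orientation`` records
    which direction the top of the ranking means (e.g. "up_with_AD").
    """

    ranks: pd.Series
    orientation: str = ""

    def __post_init__(self) -> None:
        n = len(self.ranks)
        if n == 0:
            raise ValueError("empty universe")
        if sorted(self.ranks) != list(range(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..N")
        self.ranks.index = self.ranks.index.astype(str).str.upper()
        if not self.ranks.index.is_unique:
            raise ValueError("gene symbols in a universe must be unique")

    @property
    def n(self) -> int:
        return len(self.ranks)

    def reversed(self) -> "RankedUniverse":
        return RankedUniverse(
            ranks=self.n + 1 - self.ranks, orientation=f"reversed({self.orientation})"
        )


@dataclass
class ExternalGeneList:
    """Symbols with expected directions from a previous study."""

    symbols: list[str]
    directions: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.directions):
            raise ValueError("symbols and directions must align")
        bad = set(self.directions) - {"up", "down"}
        if bad:
            raise ValueError(f"directions must be 'up'/'down', got {sorted(bad)}")
        if any(not str(s).strip() for s in self.symbols):
            raise ValueError("empty gene symbol in external list")
        # case-insensitive de-duplication, first occurrence wins
        seen, symbols, directions = set(), [], []
        for s, d in zip(self.symbols, self.directions):
            key = str(s).upper()
            if key not in seen:
                seen.add(key)
                symbols.append(key)
                directions.append(d)
        self.symbols, self.directions = symbols, directions

    @classmethod
    def from_tsv(cls, path, source=None) -> "ExternalGeneList":
        df = pd.read_csv(path, sep="\t")
        return cls(
            symbols=list(df.iloc[:, 0].astype(str)),
            directions=list(df.iloc[:, 1].astype(str)),
            source=source or str(path),
        )


@dataclass
class ConcordanceResult:
    m: int
    mgr: float
    mean_rank: float
    n_universe: int
    matched: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    z: float | None = None
    p: float | None = None
    null_type: str | None = None


def rank_universe(result: ContrastResult, orientation: str = "") -> RankedUniverse:
    """Build a gene-level ranked universe from a contrast.

    Genes are ranked by the signed z-score ascending, so the most
    "consistent-direction" genes (largest z) sit at rank N. When several
    probes share a symbol, the probe with the largest |z| represents the
    gene. Ties in z break by table order.
    """
    t = result.table.copy()
    t["gene"] = t["gene"].astype(str).str.upper()
    best = t.sort_values("z", key=np.abs, ascending=False, kind="mergesort").drop_duplicates("gene")
    z = best.set_index("gene")["z"]
    ranks = z.rank(method="first").astype(int)
    return RankedUniverse(ranks=ranks, orientation=orientation or result.label)


def _oriented_ranks(u: RankedUniverse, ext: ExternalGeneList):
    matched, oriented, unmatched = [], [], []
    for sym, direction in zip(ext.symbols, ext.directions):
        if sym in u.ranks.index:
            r = int(u.ranks[sym])
            oriented.append(u.n + 1 - r if direction == "down" else r)
            matched.append(sym)
        else:
            unmatched.append(sym)
    return matched, np.asarray(oriented, dtype=float), unmatched


def mean_gene_rank(u: RankedUniverse, ext: ExternalGeneList) -> ConcordanceResult:
    """MGR of an external list within the universe; chance is exactly 0."""
    matched, oriented, unmatched = _oriented_ranks(u, ext)
    if len(matched) == 0:
        raise ValueError(
            f"no external symbols matched the universe (tried {len(ext.symbols)}; "
            f"first unmatched: {unmatched[:5]})"
        )
    mgr = float(np.mean((oriented - 0.5) / u.n) - 0.5)
    return ConcordanceResult(
        m=len(matched),
        mgr=mgr,
        mean_rank=float(oriented.mean()),
        n_universe=u.n,
        matched=matched,
        unmatched=unmatched,
    )


def mgr_significance(
    res: ConcordanceResult,
    u: RankedUniverse,
    method: str = "analytic",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> ConcordanceResult:
    """Standardize an MGR against its null of random same-size subsets.

    ``analytic`` uses the exact moments of a mean of m ranks drawn without
    replacement from 1..N: Z = (mean rank - (N+1)/2) / sqrt((N+1)(N-m)/(12m)).
    ``permutation`` standardizes against ``n_perm`` random subsets instead.
    The p-value is two-tailed normal either way.
    """
    N, m = res.n_universe, res.m
    if m >= N:
        raise ValueError("list covers the whole universe; the null variance is zero")
    if method == "analytic":
        var = (N + 1) * (N - m) / (12.0 * m)
        z = (res.mean_rank - (N + 1) / 2.0) / math.sqrt(var)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        null_means = np.array(
            [rng.choice(N, size=m, replace=False).mean() + 1.0 for _ in range(n_perm)]
        )
        sd = null_means.std(ddof=1)
        z = (res.mean_rank - null_means.mean()) / sd
    else:
        raise ValueError(f"unknown method {method!r}")
    res.z = float(z)
    res.p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    res.null_type = method
    return res


def sign_agreement(
    internal: ContrastResult,
    ext: ExternalGeneList,
    highly_expressed: bool = False,
    very_significant: bool = False,
    significant: bool = False,
    high_expr_cut: float = 1000.0,
) -> float:
    """Percentage of overlapping genes whose internal fold-change direction
    matches the external expectation, after optional EXP/SIG/VERY-SIG
    subsetting of the internal results."""
    t = internal.table.copy()
    if highly_expressed:
        t = t[(t["mean_a"] + t["mean_b"]) / 2.0 > high_expr_cut]
    if significant:
        t = t[t["p"] < 0.05]
    if very_significant:
        t = t[t["p"] < 0.005]
    t["gene"] = t["gene"].astype(str).str.upper()
    t = t.sort_values("p").drop_duplicates("gene")
    internal_dir = t.set_index("gene")["fc_signed"]
    agree = total = 0
    for sym, direction in zip(ext.symbols, ext.directions):
        if sym in internal_dir.index:
            total += 1
            internal_up = internal_dir[sym] > 0
            if internal_up == (direction == "up"):
                agree += 1
    if total == 0:
        raise ValueError("no overlap between the external list and the filtered results")
    return 100.0 * agree / total


def fc_correlation(a: ContrastResult, b: pd.Series) -> tuple[float, float, int]:
    """Pearson correlation of log2 signed fold changes over shared genes.

    ``b`` maps gene symbol -> signed fold change from an external study.
    """
    fa = a.table.copy()
    fa["gene"] = fa["gene"].astype(str).str.upper()
    fa = fa.sort_values("p").drop_duplicates("gene").set_index("gene")["fc_signed"]
    fb = b.copy()
    fb.index = fb.index.astype(str).str.upper()
    shared = fa.index.intersection(fb.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")

    def log2fc(fc):
        fc = np.asarray(fc, dtype=float)
        return np.sign(fc) * np.log2(np.abs(fc))

    xa, xb = log2fc(fa.loc[shared]), log2fc(fb.loc[shared])
    if np.allclose(xa, xa[0]) or np.allclose(xb, xb[0]):
        raise ValueError("constant fold-change vector; correlation undefined")
    r, p = stats.pearsonr(xa, xb)
    return float(r), float(p), int(len(shared))


def classify_fc_confirmation(microarray_fc: float, validation_fc: float) -> str:
    """Rate an independent validation fold change against the array result.

    Same-direction validation FC magnitudes above 1.2 are ``confirmed``,
    between 1.1 (inclusive) and 1.2 ``marginal``, below 1.1 or opposite in
    direction ``non_confirmed``.
    """
    if np.sign(microarray_fc) != np.sign(validation_fc):
        return "non_confirmed"
    magnitude = abs(validation_fc)
    if magnitude > 1.2:
        return "confirmed"
    if magnitude >= 1.1:
        return "marginal"
    return "non_confirmed"
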