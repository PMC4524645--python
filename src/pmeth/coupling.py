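"""Joint structure of gene-body methylation and gene expression.

The co-independence test bins both axes into a 20 x 20 grid (gene-body
methylation x transformed expression), compares observed joint counts to
the product-of-marginals expectation, and assesses the chi-square
statistic either against its asymptotic distribution or, by default, a
permutation null built by shuffling expression labels across genes.

Expression is transformed as log10(FPKM + eps) + 1 with eps = 0.01, which
makes the conventional 0.56 high/low threshold meaningful near
FPKM ~ 0.36 and handles zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def transform_expression(fpkm, eps: float = 0.01, base: float = 10.0) -> np.ndarray:
    """log(FPKM + eps) + 1 in the given base (default log10)."""
    f = np.asarray(fpkm, dtype=float)
    if (f < 0).any():
        raise ValueError("FPKM must be non-negative")
    return np.log(f + eps) / np.log(base) + 1.0


@dataclass
class QuadrantTable:
    """Binned joint counts with expectations under independence."""

    observed: np.ndarray    # (n_bins_meth, n_bins_expr)
    expected: np.ndarray
    deviation: np.ndarray   # observed - expected
    meth_edges: np.ndarray
    expr_edges: np.ndarray
    statistic: float
    p_value: float
    n_genes: int
    mode: str
    n_perm: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        nb_m, nb_e = self.observed.shape
        for i in range(nb_m):
            for j in range(nb_e):
                rows.append(
                    {
                        "bin_meth": i, "bin_expr": j,
                        "observed": self.observed[i, j],
                        "expected": self.expected[i, j],
                        "deviation": self.deviation[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _equal_spaced_bins(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    return idx, edges

def _rank_bins(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    ranks = stats.rankdata(x, method="average")
    idx = np.minimum((ranks - 1) * n_bins // len(x), n_bins - 1).astype(int)
    return idx, np.quantile(x, np.linspace(0, 1, n_bins + 1))


def _pool_groups(expected: np.ndarray) -> np.ndarray:
    """Group id per cell; cells with expected < 1 are pooled with contiguous
    neighbors along the expression axis (within their methylation row)."""
    nb_m, nb_e = expected.shape
    group = np.zeros((nb_m, nb_e), dtype=np.int64)
    gid = 0
    for i in range(nb_m):
        row_groups: list[tuple[int, float]] = []
        acc = 0.0
        for j in range(nb_e):
            group[i, j] = gid
            acc += expected[i, j]
            if acc >= 1.0 and j < nb_e - 1:
                row_groups.append((gid, acc))
                gid += 1
                acc = 0.0
        row_groups.append((gid, acc))
        gid += 1
        # trailing underfilled group folds into its left neighbor
        if len(row_groups) >= 2 and row_groups[-1][1] < 1.0:
            last, prev = row_groups[-1][0], row_groups[-2][0]
            group[i][group[i] == last] = prev
    _, dense = np.unique(group, return_inverse=True)
    return dense.reshape(group.shape)


def coindependence_test(
    meth,
    fpkm,
    n_bins: int = 20,
    mode: str = "permutation",
    n_perm: int = 999,
    seed: int = 0,
    eps: float = 0.01,
    rank_bins: bool = False,
) -> QuadrantTable:
    """Grid-binned test of independence between gene-body methylation and
    expression.

    Axes are cut into ``n_bins`` equally spaced bins over each axis's
    observed range (rank-based bins optionally).  The chi-square statistic
    is evaluated over cells pooled along the expression axis until every
    group's expected count is at least 1.  ``mode='permutation'`` (default)
    shuffles expression across genes ``n_perm`` times for an empirical p;
    ``mode='chi2'`` uses the asymptotic chi-square distribution.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    m = np.asarray(meth, dtype=float)
    y = transform_expression(fpkm, eps=eps)
    if len(m) != len(y):
        raise ValueError("methylation and expression must be matched by gene")
    ok = ~(np.isnan(m) | np.isnan(y))
    m, y = m[ok], y[ok]
    n = len(m)
    if n < 200:
        warnings.warn(f"only {n} matched genes; the co-independence test is underpowered")

    binner = _rank_bins if rank_bins else _equal_spaced_bins
    mi, m_edges = binner(m, n_bins)
    yi, y_edges = binner(y, n_bins)

    observed = np.zeros((n_bins, n_bins))
    np.add.at(observed, (mi, yi), 1.0)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / n
    deviation = observed - expected

    group = _pool_groups(expected)
    n_groups = group.max() + 1
    flat_cell = mi * n_bins + yi
    grp_of_cell = group.ravel()
    exp_g = np.bincount(grp_of_cell, weights=expected.ravel(), minlength=n_groups)
    nonzero = exp_g > 0

    def chi2_of(y_bins: np.ndarray) -> float:
        cells = np.bincount(mi * n_bins + y_bins, minlength=n_bins * n_bins)
        obs_g = np.bincount(grp_of_cell, weights=cells, minlength=n_groups)
        d = obs_g[nonzero] - exp_g[nonzero]
        return float(np.sum(d * d / exp_g[nonzero]))

    statistic = chi2_of(yi)
    if mode == "chi2":
        rows_used = int((row.ravel() > 0).sum())
        cols_used = int((col.ravel() > 0).sum())
        df = max(1, int(nonzero.sum()) - (rows_used + cols_used - 1))
        p = float(stats.chi2.sf(statistic, df))
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(yi)
            if chi2_of(perm) >= statistic:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
    else:
        raise ValueError("mode must be 'chi2' or 'permutation'")

    return QuadrantTable(
        observed=observed, expected=expected, deviation=deviation,
        meth_edges=m_edges, expr_edges=y_edges,
        statistic=statistic, p_value=p, n_genes=n, mode=mode,
        n_perm=n_perm if mode == "permutation" else 0,
    )


def sector_deviation(
    table: QuadrantTable,
    meth_range: tuple[float, float] = (2 / 3, 1.0),
    expr_range: tuple[float, float] = (1 / 3, 2 / 3),
) -> float:
    """Summed observed-minus-expected over a grid sector.

    Ranges are fractions of the bin grid; the defaults select the
    high-methylation x intermediate-expression sector where positive
    coupling concentrates excess counts.
    """
    nb_m, nb_e = table.deviation.shape
    mi0, mi1 = int(np.floor(meth_range[0] * nb_m)), int(np.ceil(meth_range[1] * nb_m))
    ei0, ei1 = int(np.floor(expr_range[0] * nb_e)), int(np.ceil(expr_range[1] * nb_e))
    return float(table.deviation[mi0:mi1, ei0:ei1].sum())


@dataclass
class ExpressionQuadrants:
    """High/low expression classification of genes across two tissues."""

    classes: pd.Series      # gene_id -> 'high-high' | 'high-low' | 'low-high' | 'low-low'
    counts: dict[str, int]
    threshold: float
    n_excluded: int


def expression_quadrants(
    expr_a: pd.Series, expr_b: pd.Series, threshold: float = 0.56, eps: float = 0.01
) -> ExpressionQuadrants:
    """Classify genes by high/low transformed expression in two tissues.

    Inputs are FPKM Series indexed by gene id; genes absent from either
    tissue are excluded (and counted).  'high' means
    log10(FPKM + eps) + 1 > threshold in that tissue; the class string is
    '<tissue-a>-<tissue-b>'.
    """
    common = expr_a.index.intersection(expr_b.index)
    n_excluded = (len(expr_a) - len(common)) + (len(expr_b) - len(common))
    ta = transform_expression(expr_a.loc[common].to_numpy(), eps=eps)
    tb = transform_expression(expr_b.loc[common].to_numpy(), eps=eps)
    labels = np.where(ta > threshold, "high", "low").astype(object)
    labels = labels + "-" + np.where(tb > threshold, "high", "low")
    classes = pd.Series(labels, index=common, name="class")
    counts = {
        k: int((classes == k).sum())
        for k in ("high-high", "high-low", "low-high", "low-low")
    }
    return ExpressionQuadrants(
        classes=classes, counts=counts, threshold=threshold, n_excluded=n_excluded
    )


def methylation_expression_overlap(**gene_sets: set) -> dict[str, int]:
    """Cardinalities of all pairwise and higher-order intersections.

    Keyword arguments name the gene sets (e.g. high_meth=..., high_expr=...).
    Returns a dict mapping 'name' and 'nameA&nameB' (sorted, ampersand
    joined) to intersection sizes.
    """
    names = sorted(gene_sets)
    out: dict[str, int] = {n: len(set(gene_sets[n])) for n in names}
    from itertools import combinations

    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set(gene_sets[combo[0]])
            for n in combo[1:]:
                inter &= set(gene_sets[n])
            out["&".join(combo)] = len(inter)
    return out
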