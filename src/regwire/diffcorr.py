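"""Between-group differential co-expression of RF / DE-gene pairs.

For every (regulatory factor, DE gene) pair the Pearson correlation is
computed separately within each genetic type, tested against zero within
each group (t-transform, n-2 df), and the two correlations are compared
with the two-sample Fisher r-to-z test.  The family of difference tests is
corrected by Benjamini-Hochberg using the product of the effective numbers
of independent RFs and DE genes as the test count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .errors import DataValidationError
from .preprocess import effective_tests

__all__ = [
    "group_correlations",
    "correlation_difference_test",
    "adjust_with_meff",
    "diffcorr_table",
    "export_edges",
    "read_edges",
]


def _corr_with_p(ds, rf_ids, de_ids, group):
    cols = ds.group_samples(group)
    n = len(cols)
    if n < 4:
        raise DataValidationError(f"group {group!r} has fewer than 4 samples")
    rf = ds.values.loc[rf_ids, cols].to_numpy(dtype=float)
    de = ds.values.loc[de_ids, cols].to_numpy(dtype=float)

    def standardize_rows(arr):
        centered = arr - arr.mean(axis=1, keepdims=True)
        norm = np.sqrt((centered**2).sum(axis=1))
        ok = norm > 0
        centered[ok] = centered[ok] / norm[ok, None]
        return centered, ok

    rf_std, rf_ok = standardize_rows(rf)
    de_std, de_ok = standardize_rows(de)
    r = rf_std @ de_std.T
    defined = rf_ok[:, None] & de_ok[None, :]
    r = np.where(defined, np.clip(r, -1.0, 1.0), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, np.where(defined, 0.0, np.nan))
    return r, p, n, defined


def group_correlations(ds: ExpressionDataset, rf_ids, de_ids) -> pd.DataFrame:
    """Per-pair, per-group Pearson r with within-group p-values.

    Returns one row per (RF, DE gene) pair — ``len(rf_ids) * len(de_ids)``
    rows — with columns ``r_<group>``, ``p_<group>``, ``n_<group>`` for each
    of the two groups and a ``defined`` flag (False where a profile is
    constant within a group, such pairs are excluded from testing).
    """
    rf_ids, de_ids = list(rf_ids), list(de_ids)
    g1, g2 = ds.group_levels
    r1, p1, n1, ok1 = _corr_with_p(ds, rf_ids, de_ids, g1)
    r2, p2, n2, ok2 = _corr_with_p(ds, rf_ids, de_ids, g2)
    pairs = pd.MultiIndex.from_product([rf_ids, de_ids], names=["rf", "de"])
    table = pd.DataFrame(
        {
            f"r_{g1}": r1.ravel(),
            f"p_{g1}": p1.ravel(),
            f"r_{g2}": r2.ravel(),
            f"p_{g2}": p2.ravel(),
            "defined": (ok1 & ok2).ravel(),
        },
        index=pairs,
    )
    table.attrs["n_per_group"] = {g1: n1, g2: n2}
    table.attrs["group_levels"] = (g1, g2)
    n_undefined = int((~table["defined"]).sum())
    if n_undefined:
        table.attrs["n_undefined"] = n_undefined
    return table


def correlation_difference_test(r1, n1: int, r2, n2: int):
    """Two-sided p-value for a difference between two independent correlations.

    Fisher r-to-z transform in each group, then a normal test on
    ``(z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))``.  ``|r| = 1`` gives an
    infinite transform and returns NaN (the pair must be flagged and
    excluded by the caller).
    """
    if n1 < 4 or n2 < 4:
        raise DataValidationError("need at least 4 samples per group")
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z1 = np.arctanh(r1)
        z2 = np.arctanh(r2)
        se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        stat = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    p = np.where(np.isfinite(stat), p, np.nan)
    if p.ndim == 0:
        return float(p)
    return p


def adjust_with_meff(p_diff, rf_matrix, de_matrix, q: float = 0.10):
    """BH step-up on difference p-values with a two-way effective test count.

    The test count is ``m_eff(RF set) * m_eff(DE set)`` — the product of
    the effective numbers of independent items on the two axes, each from
    the Moskvina-Schmidt correction on the expression submatrix.  NaN
    p-values (undefined pairs) are excluded from the family.
    """
    meff_rf = effective_tests(rf_matrix)
    meff_de = effective_tests(de_matrix)
    m_eff = meff_rf.m_eff * meff_de.m_eff
    if isinstance(p_diff, pd.Series):
        index = p_diff.index
        vals = p_diff.to_numpy(dtype=float)
    else:
        vals = np.asarray(p_diff, dtype=float)
        index = pd.RangeIndex(len(vals))
    tested = ~np.isnan(vals)
    flags = np.zeros(len(vals), dtype=bool)
    if tested.any():
        pv = vals[tested]
        order = np.argsort(pv, kind="stable")
        k = np.arange(1, len(pv) + 1)
        passing = pv[order] <= k * q / m_eff
        if passing.any():
            threshold = pv[order][np.max(np.flatnonzero(passing))]
            flags[tested] = pv <= threshold
    out = pd.Series(flags, index=index, name="diff_significant")
    info = {
        "m_eff": float(m_eff),
        "m_eff_rf": meff_rf.m_eff,
        "m_eff_de": meff_de.m_eff,
        "q": q,
        "n_tested": int(tested.sum()),
        "n_significant": int(flags.sum()),
    }
    return out, info


def diffcorr_table(
    ds: ExpressionDataset, rf_ids, de_ids, q: float = 0.10
) -> pd.DataFrame:
    """Full differential-correlation analysis for an RF set and a DE set.

    Combines :func:`group_correlations`, the Fisher-z difference test and
    the effective-count BH adjustment into one per-pair table.
    """
    rf_ids, de_ids = list(rf_ids), list(de_ids)
    table = group_correlations(ds, rf_ids, de_ids)
    g1, g2 = table.attrs["group_levels"]
    n1 = table.attrs["n_per_group"][g1]
    n2 = table.attrs["n_per_group"][g2]
    r1 = table[f"r_{g1}"].to_numpy()
    r2 = table[f"r_{g2}"].to_numpy()
    degenerate = np.isclose(np.abs(r1), 1.0) | np.isclose(np.abs(r2), 1.0)
    p_diff = correlation_difference_test(
        np.where(degenerate, np.nan, r1), n1, np.where(degenerate, np.nan, r2), n2
    )
    p_diff = np.where(table["defined"].to_numpy(), p_diff, np.nan)
    table["p_diff"] = p_diff

    # effective counts on the tested items only
    rf_sub = ds.values.loc[rf_ids]
    de_sub = ds.values.loc[de_ids]
    flags, info = adjust_with_meff(table["p_diff"], rf_sub, de_sub, q=q)
    table["diff_significant"] = flags
    table.attrs["adjustment"] = info
    table.attrs["fisher_z_test"] = "two-sample Fisher r-to-z, two-sided normal"
    return table


def export_edges(table: pd.DataFrame, path=None, significant_only: bool = True):
    """Edge list for network rendering tools.

    One row per retained pair with, for each group, the correlation sign
    (``positive``/``negative``) and whether the within-group correlation
    differs from zero at 0.05; plus the between-group difference flag.
    """
    g1, g2 = table.attrs["group_levels"]
    rows = table[table["diff_significant"]] if significant_only else table
    edges = pd.DataFrame(
        {
            "rf": rows.index.get_level_values("rf"),
            "de": rows.index.get_level_values("de"),
            f"sign_{g1}": np.where(rows[f"r_{g1}"] >= 0, "positive", "negative"),
            f"significant_{g1}": rows[f"p_{g1}"] < 0.05,
            f"sign_{g2}": np.where(rows[f"r_{g2}"] >= 0, "positive", "negative"),
            f"significant_{g2}": rows[f"p_{g2}"] < 0.05,
            "diff_significant": rows["diff_significant"].to_numpy(),
        }
    )
    if path is not None:
        edges.to_csv(path, sep="\t", index=False)
    return edges


def read_edges(path) -> pd.DataFrame:
    """Re-parse an edge list written by :func:`export_edges`."""
    return pd.read_csv(path, sep="\t")
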