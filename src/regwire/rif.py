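"""Regulatory impact factor (RIF) scoring with bootstrap null intervals.

RIF assigns importance to a regulatory factor (RF) by how strongly its
co-expression with the differentially expressed (DE) genes changes between
the two conditions.  With ``n_de`` DE genes, and per DE gene ``j`` its
average log2 expression ``a_j``, log2 contrast ``d_j`` and within-group
means ``e1_j``/``e2_j``, and per (RF ``i``, gene ``j``) the within-group
Pearson correlations ``r1_ij``/``r2_ij``:

    RIF1_i = (1/n_de) * sum_j  a_j * d_j * (r1_ij - r2_ij)^2
    RIF2_i = (1/n_de) * sum_j  (e1_j * r1_ij)^2 - (e2_j * r2_ij)^2

RIF1 rewards consistent differential wiring to abundant, strongly DE
genes; RIF2 measures the change in the RF's ability to predict DE-gene
abundance.  Raw scores are standardized to z-scores over the full RF
census, and significance is judged against bootstrap confidence intervals
built by repeatedly drawing random "DE" sets of the same size from the
filtered array and pooling the resulting z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ConfigurationError, DataValidationError

__all__ = [
    "RIFInputs",
    "BootstrapCI",
    "compute_rif_inputs",
    "rif_scores",
    "standardize",
    "rif_table",
    "bootstrap_ci",
    "classify_extreme",
]


@dataclass
class RIFInputs:
    a_bar: pd.Series     # average log2 expression per DE gene
    d: pd.Series         # log2 contrast per DE gene (group2 - group1)
    e1: pd.Series        # mean log2 expression in group 1
    e2: pd.Series        # mean log2 expression in group 2
    r1: pd.DataFrame     # RF x DE within-group-1 Pearson correlations
    r2: pd.DataFrame     # RF x DE within-group-2 Pearson correlations

    @property
    def n_de(self) -> int:
        return len(self.a_bar)

    def __post_init__(self):
        if self.n_de < 2:
            raise DataValidationError("need at least 2 DE genes")
        for name in ("r1", "r2"):
            r = getattr(self, name)
            if np.any(np.abs(r.to_numpy()) > 1 + 1e-9):
                raise DataValidationError(f"{name} outside [-1, 1]")


def _row_standardize(arr: np.ndarray, what: str, ids) -> np.ndarray:
    """Center and scale rows so that cross-products give Pearson r."""
    centered = arr - arr.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    if (norm == 0).any():
        bad = [ids[i] for i in np.flatnonzero(norm == 0)]
        raise DataValidationError(
            f"constant within-group profile, correlation undefined for {what}: {bad[:10]}"
        )
    return centered / norm[:, None]


def compute_rif_inputs(
    ds: ExpressionDataset, rf_ids, de_ids, contrast=None
) -> RIFInputs:
    """Assemble RIF inputs from a dataset and RF / DE probe lists.

    ``contrast`` (log2, group2 - group1) defaults to the difference of group
    means; pass the posterior mean contrast from the Bayesian fit for the
    full pipeline.  A gene appearing in both lists is allowed (the overlap
    is recorded on the result), matching RF censuses that contain DE genes.
    """
    rf_ids, de_ids = list(rf_ids), list(de_ids)
    g1, g2 = ds.group_levels
    sub_de = ds.values.loc[de_ids]
    m1 = sub_de[ds.group_samples(g1)].mean(axis=1)
    m2 = sub_de[ds.group_samples(g2)].mean(axis=1)
    a_bar = sub_de.mean(axis=1)
    if contrast is None:
        d = m2 - m1
    else:
        d = pd.Series(contrast).reindex(de_ids)
        if d.isna().any():
            missing = list(d.index[d.isna()])
            raise DataValidationError(f"contrast missing for DE genes {missing[:5]}")

    r = {}
    for key, group in (("r1", g1), ("r2", g2)):
        cols = ds.group_samples(group)
        rf_std = _row_standardize(
            ds.values.loc[rf_ids, cols].to_numpy(dtype=float), f"RF in {group}", rf_ids
        )
        de_std = _row_standardize(
            ds.values.loc[de_ids, cols].to_numpy(dtype=float), f"DE gene in {group}", de_ids
        )
        r[key] = pd.DataFrame(rf_std @ de_std.T, index=rf_ids, columns=de_ids)

    inputs = RIFInputs(a_bar=a_bar, d=d, e1=m1, e2=m2, r1=r["r1"], r2=r["r2"])
    overlap = sorted(set(rf_ids) & set(de_ids))
    if overlap:
        inputs.overlap = overlap
    return inputs


def rif_scores(inputs: RIFInputs) -> pd.DataFrame:
    """Raw RIF1 and RIF2 per RF (rows follow the RF order of the inputs)."""
    a = inputs.a_bar.to_numpy(dtype=float)
    d = inputs.d.to_numpy(dtype=float)
    e1 = inputs.e1.to_numpy(dtype=float)
    e2 = inputs.e2.to_numpy(dtype=float)
    r1 = inputs.r1.to_numpy(dtype=float)
    r2 = inputs.r2.to_numpy(dtype=float)
    n = inputs.n_de
    rif1 = ((r1 - r2) ** 2) @ (a * d) / n
    rif2 = ((r1 * e1[None, :]) ** 2 - (r2 * e2[None, :]) ** 2).sum(axis=1) / n
    return pd.DataFrame(
        {"rif1_raw": rif1, "rif2_raw": rif2}, index=inputs.r1.index
    )


def standardize(raw) -> pd.Series:
    """z-scores over the RF census: subtract the mean, divide by sample SD."""
    if isinstance(raw, pd.Series):
        index = raw.index
        vals = raw.to_numpy(dtype=float)
    else:
        vals = np.asarray(raw, dtype=float)
        index = pd.RangeIndex(len(vals))
    if len(vals) < 2:
        raise DataValidationError("need at least 2 values to standardize")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise DataValidationError("zero standard deviation, z-scores undefined")
    return pd.Series((vals - vals.mean()) / sd, index=index)


def rif_table(ds, rf_ids, de_ids, contrast=None) -> pd.DataFrame:
    """Raw and standardized RIF scores for an RF census against a DE set."""
    inputs = compute_rif_inputs(ds, rf_ids, de_ids, contrast=contrast)
    table = rif_scores(inputs)
    table["rif1_z"] = standardize(table["rif1_raw"])
    table["rif2_z"] = standardize(table["rif2_raw"])
    return table


@dataclass
class BootstrapCI:
    """Null intervals for RIF z-scores from random DE-set draws.

    ``bounds[metric][level] = (lower, upper)`` where metric is ``rif1`` or
    ``rif2``.  Bounds are quantiles of the z-scores pooled over all
    iterations and all RFs.
    """

    bounds: dict
    n_iterations: int
    n_de: int
    seed: int

    def interval(self, metric: str, level: float) -> tuple:
        try:
            return self.bounds[metric][level]
        except KeyError:
            raise ConfigurationError(
                f"no {metric} interval at level {level}"
            ) from None

    def __post_init__(self):
        for metric, by_level in self.bounds.items():
            if 0.95 in by_level and 0.99 in by_level:
                lo95, hi95 = by_level[0.95]
                lo99, hi99 = by_level[0.99]
                if not (lo99 <= lo95 and hi95 <= hi99):
                    raise DataValidationError(
                        f"99% interval does not contain 95% interval for {metric}"
                    )


def bootstrap_ci(
    ds: ExpressionDataset,
    rf_ids,
    n_de: int,
    n_iterations: int = 10_000,
    levels=(0.95, 0.99),
    seed: int = 0,
    contrast=None,
) -> BootstrapCI:
    """Bootstrap null distribution of RIF z-scores.

    Each iteration draws ``n_de`` probes uniformly without replacement from
    the (filtered) array, treats them as the DE set with their observed
    average expression, contrast and group means, and computes the RIF
    z-scores of the whole RF census.  z-scores are pooled across iterations
    and RFs; CI bounds are the matching quantiles of the pooled
    distribution.  Seed-deterministic.
    """
    rf_ids = list(rf_ids)
    probe_ids = list(ds.values.index)
    if n_de > len(probe_ids):
        raise ConfigurationError(
            f"n_de={n_de} exceeds the {len(probe_ids)} probes of the filtered array"
        )
    g1, g2 = ds.group_levels
    cols1, cols2 = ds.group_samples(g1), ds.group_samples(g2)
    vals = ds.values
    m1 = vals[cols1].mean(axis=1).to_numpy()
    m2 = vals[cols2].mean(axis=1).to_numpy()
    a_bar = vals.mean(axis=1).to_numpy()
    if contrast is None:
        d = m2 - m1
    else:
        d = pd.Series(contrast).reindex(probe_ids).to_numpy(dtype=float)
        if np.isnan(d).any():
            raise DataValidationError("contrast missing for some filtered probes")

    rf_std1 = _row_standardize(vals.loc[rf_ids, cols1].to_numpy(float), f"RF in {g1}", rf_ids)
    rf_std2 = _row_standardize(vals.loc[rf_ids, cols2].to_numpy(float), f"RF in {g2}", rf_ids)
    all_std1 = _row_standardize(vals[cols1].to_numpy(float), f"probe in {g1}", probe_ids)
    all_std2 = _row_standardize(vals[cols2].to_numpy(float), f"probe in {g2}", probe_ids)
    # full RF x probe correlation matrices, sliced per draw
    C1 = rf_std1 @ all_std1.T
    C2 = rf_std2 @ all_std2.T
    D2 = (C1 - C2) ** 2
    C1sq, C2sq = C1**2, C2**2
    ad = a_bar * d
    e1sq, e2sq = m1**2, m2**2

    rng = np.random.default_rng(seed)
    n_rf = len(rf_ids)
    z1 = np.empty((n_iterations, n_rf))
    z2 = np.empty((n_iterations, n_rf))
    for b in range(n_iterations):
        idx = rng.choice(len(probe_ids), size=n_de, replace=False)
        rif1 = D2[:, idx] @ ad[idx] / n_de
        rif2 = (C1sq[:, idx] @ e1sq[idx] - C2sq[:, idx] @ e2sq[idx]) / n_de
        z1[b] = (rif1 - rif1.mean()) / rif1.std(ddof=1)
        z2[b] = (rif2 - rif2.mean()) / rif2.std(ddof=1)

    bounds = {"rif1": {}, "rif2": {}}
    for level in levels:
        alpha = (1.0 - level) / 2.0
        bounds["rif1"][level] = tuple(np.quantile(z1.ravel(), [alpha, 1 - alpha]))
        bounds["rif2"][level] = tuple(np.quantile(z2.ravel(), [alpha, 1 - alpha]))
    return BootstrapCI(
        bounds=bounds, n_iterations=n_iterations, n_de=n_de, seed=seed
    )


def classify_extreme(table: pd.DataFrame, ci, level: float = 0.95):
    """Flag RFs whose z-scores fall outside the bootstrap intervals.

    ``ci`` is a :class:`BootstrapCI` or a mapping
    ``{"rif1": (lo, hi), "rif2": (lo, hi)}``.  Classification uses strict
    inequality: a z-score exactly on a bound is not extreme.  Returns the
    table with ``extreme1``/``extreme2`` flags plus a summary dict with
    counts and the union/intersection gene lists.
    """
    if isinstance(ci, BootstrapCI):
        lo1, hi1 = ci.interval("rif1", level)
        lo2, hi2 = ci.interval("rif2", level)
    else:
        lo1, hi1 = ci["rif1"]
        lo2, hi2 = ci["rif2"]
    out = table.copy()
    z1 = out["rif1_z"].to_numpy(dtype=float)
    z2 = out["rif2_z"].to_numpy(dtype=float)
    out["extreme1"] = (z1 < lo1) | (z1 > hi1)
    out["extreme2"] = (z2 < lo2) | (z2 > hi2)
    both = out["extreme1"] & out["extreme2"]
    either = out["extreme1"] | out["extreme2"]
    summary = {
        "n_extreme1": int(out["extreme1"].sum()),
        "n_extreme2": int(out["extreme2"].sum()),
        "n_union": int(either.sum()),
        "n_intersection": int(both.sum()),
        "union": list(out.index[either]),
        "intersection": list(out.index[both]),
        "level": level,
        "bounds": {"rif1": (lo1, hi1), "rif2": (lo2, hi2)},
    }
    return out, summary
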