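"""Bayesian differential expression by Gibbs sampling.

The model for the log2 intensity of probe ``p`` on array ``s`` is

    y[p, s] = a[s] + mu[p] + t[p] * x_g[s] + sum_c u[p, c] * z[s, c] + e[p, s]

with an overall effect ``a`` of each array (shared across probes), a probe
baseline ``mu``, within-probe discrete effects of genetic type (``x_g``,
centered +/-1/2 coding so that ``t[p]`` is the group-2 minus group-1
contrast) and of hybridization series (centered dummy columns ``z``), and
probe-specific residual variance ``e[p, s] ~ N(0, sigma2[p])``.

Priors are flat on all location effects and scaled-inverse-chi-square
(``nu0`` pseudo-observations at the per-probe empirical residual variance)
on ``sigma2``; all full conditionals are then Gaussian or scaled inverse
chi-square and the joint posterior is explored by Gibbs sampling.

Identifiability: because genetic type and series are properties of arrays,
the array-effect vector is confounded not only with the probe baselines
(its mean) but also with every within-probe factor (its projections onto
the group-contrast and series directions).  Each sweep therefore projects
the sampled array effects onto the orthogonal complement of the span of
{intercept, group contrast, series dummies} — the sum-to-zero constraint
extended to all confounded directions.

Inference per probe: posterior mean and SD of the contrast, and the
posterior tail probability PP — the fraction of retained draws on the
opposite side of zero from the posterior mean (small PP = strong evidence
of differential expression).  PPs are then treated as p-values in a
Benjamini-Hochberg step-up whose denominator is the effective number of
independent tests rather than the raw probe count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ConfigurationError, DataValidationError

__all__ = [
    "ModelSpec",
    "ContrastChains",
    "DECalls",
    "gibbs_fit",
    "posterior_probability",
    "fdr_call",
    "bh_bound",
    "expression_ratio",
    "de_table",
]


@dataclass
class ModelSpec:
    """Chain settings and priors for :func:`gibbs_fit`.

    ``seed`` is required: every fit is reproducible by construction.
    """

    seed: int
    n_iterations: int = 30_000
    burn_in: int = 5_000
    thinning: int = 5
    nu0: float = 2.0
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if self.n_iterations <= self.burn_in:
            raise ConfigurationError("n_iterations must exceed burn_in")
        if self.thinning < 1:
            raise ConfigurationError("thinning must be >= 1")
        if self.nu0 <= 0:
            raise ConfigurationError("nu0 must be > 0")


@dataclass
class ContrastChains:
    """Retained Gibbs draws of the per-probe genetic-type contrast."""

    draws: np.ndarray            # (n_kept, n_probes)
    probe_ids: pd.Index
    spec: ModelSpec
    rhat: pd.Series              # split-chain potential scale reduction

    @property
    def n_kept(self) -> int:
        return self.draws.shape[0]

    def posterior_mean(self) -> pd.Series:
        return pd.Series(self.draws.mean(axis=0), index=self.probe_ids)

    def posterior_sd(self) -> pd.Series:
        return pd.Series(self.draws.std(axis=0, ddof=1), index=self.probe_ids)

    def nonconverged(self) -> list:
        """Probes whose split-Rhat exceeds the spec threshold."""
        bad = self.rhat[self.rhat > self.spec.rhat_threshold]
        return list(bad.index)


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Gelman-style potential scale reduction from the two chain halves."""
    n = draws.shape[0] // 2
    halves = np.stack([draws[:n], draws[n : 2 * n]])  # (2, n, P)
    within = halves.var(axis=1, ddof=1).mean(axis=0)
    between = n * halves.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n - 1) / n * within + between / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / within)
    return np.where(within > 0, rhat, 1.0)


def gibbs_fit(ds: ExpressionDataset, spec: ModelSpec) -> ContrastChains:
    """Sample the joint posterior of the array + within-probe effects model.

    Returns the retained, thinned chains of the genetic-type contrast
    (group 2 minus group 1 of ``ds.group_levels``) for every probe, with
    split-chain convergence diagnostics attached.  Identical seed and data
    give identical chains.
    """
    g1, g2 = ds.group_levels
    y = ds.values.to_numpy(dtype=float)
    n_probes, n_samples = y.shape
    groups = ds.design.loc[list(ds.sample_ids), "group"].to_numpy()
    for g in (g1, g2):
        if (groups == g).sum() < 2:
            raise DataValidationError(f"group {g!r} has fewer than 2 samples")

    xg = np.where(groups == g2, 0.5, -0.5)
    xg = xg - xg.mean()
    sxx = float((xg**2).sum())

    series = ds.design.loc[list(ds.sample_ids), "series"].to_numpy()
    levels = sorted(pd.unique(series))
    z_cols = []
    for lvl in levels[1:]:
        col = (series == lvl).astype(float)
        z_cols.append(col - col.mean())
    Z = np.column_stack(z_cols) if z_cols else np.zeros((n_samples, 0))
    szz = (Z**2).sum(axis=0)

    # empirical residual variance per probe (OLS on the within-probe design)
    X = np.column_stack([np.ones(n_samples), xg, Z])
    # orthonormal basis of the design span, used to constrain array effects
    Q, _ = np.linalg.qr(X)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y.T - X @ beta
    dof = max(n_samples - X.shape[1], 1)
    s0sq = np.maximum((resid**2).sum(axis=0) / dof, 1e-8)

    rng = np.random.default_rng(spec.seed)
    mu = y.mean(axis=1)
    t = y[:, xg > 0].mean(axis=1) - y[:, xg < 0].mean(axis=1)
    u = np.zeros((n_probes, Z.shape[1]))
    a = np.zeros(n_samples)
    sig2 = s0sq.copy()
    U = u @ Z.T

    n_kept = (spec.n_iterations - spec.burn_in) // spec.thinning
    draws = np.empty((n_kept, n_probes))
    kept = 0

    for it in range(spec.n_iterations):
        # array effects (precision-weighted across probes), constrained to
        # the orthogonal complement of the within-probe design span
        R = y - mu[:, None] - t[:, None] * xg[None, :] - U
        w = 1.0 / sig2
        prec = w.sum()
        a = (w @ R) / prec + rng.standard_normal(n_samples) / np.sqrt(prec)
        a -= Q @ (Q.T @ a)
        ya = y - a[None, :]

        # probe baselines
        R = ya - t[:, None] * xg[None, :] - U
        mu = R.mean(axis=1) + rng.standard_normal(n_probes) * np.sqrt(
            sig2 / n_samples
        )

        # genetic-type contrast
        R = ya - mu[:, None] - U
        t = (R @ xg) / sxx + rng.standard_normal(n_probes) * np.sqrt(sig2 / sxx)

        # series effects, one centered dummy column at a time
        for c in range(Z.shape[1]):
            U -= np.outer(u[:, c], Z[:, c])
            R = ya - mu[:, None] - t[:, None] * xg[None, :] - U
            u[:, c] = (R @ Z[:, c]) / szz[c] + rng.standard_normal(
                n_probes
            ) * np.sqrt(sig2 / szz[c])
            U += np.outer(u[:, c], Z[:, c])

        # probe-specific residual variances
        E = ya - mu[:, None] - t[:, None] * xg[None, :] - U
        sse = (E * E).sum(axis=1)
        sig2 = (spec.nu0 * s0sq + sse) / rng.chisquare(spec.nu0 + n_samples, n_probes)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
            if kept < n_kept:
                draws[kept] = t
                kept += 1

    rhat = pd.Series(_split_rhat(draws[:kept]), index=ds.values.index)
    return ContrastChains(
        draws=draws[:kept], probe_ids=ds.values.index, spec=spec, rhat=rhat
    )


def posterior_probability(chains) -> pd.Series:
    """Posterior tail probability opposite the sign of the posterior mean.

    For a probe with positive posterior mean this is the fraction of
    retained draws below zero, and vice versa; capped at 0.5.
    """
    if isinstance(chains, ContrastChains):
        draws, index = chains.draws, chains.probe_ids
    else:
        draws = np.atleast_2d(np.asarray(chains, dtype=float))
        if draws.shape[0] == 1 and draws.shape[1] > 1:
            draws = draws.T
        index = pd.RangeIndex(draws.shape[1])
    if draws.shape[0] == 0:
        raise DataValidationError("no retained draws")
    mean = draws.mean(axis=0)
    below = (draws < 0).mean(axis=0)
    above = (draws > 0).mean(axis=0)
    pp = np.where(mean >= 0, below, above)
    return pd.Series(np.minimum(pp, 0.5), index=index)


def bh_bound(k: int, m_eff: float, q: float = 0.10) -> float:
    """Benjamini-Hochberg step-up bound for the k-th ordered p-value."""
    return k * q / m_eff


@dataclass
class DECalls:
    calls: pd.Series           # boolean per probe
    threshold_pp: float        # largest PP passing the step-up, or nan
    n_called: int
    q: float
    m_eff: float


def fdr_call(pp, m_eff: float, q: float = 0.10) -> DECalls:
    """Benjamini-Hochberg step-up on PPs with an effective test count.

    The denominator of the step-up bound is ``m_eff`` (the effective number
    of independent tests) rather than the length of ``pp``.  Calls are all
    probes with PP at or below the largest ordered PP satisfying
    ``pp_(k) <= k*q/m_eff``.
    """
    if isinstance(pp, pd.Series):
        index = pp.index
        vals = pp.to_numpy(dtype=float)
    else:
        vals = np.asarray(pp, dtype=float)
        index = pd.RangeIndex(len(vals))
    if len(vals) == 0:
        raise DataValidationError("empty PP vector")
    if np.any((vals < 0) | (vals > 0.5)):
        raise DataValidationError("PP values must lie in [0, 0.5]")
    if m_eff < 1:
        raise ConfigurationError("m_eff must be >= 1")
    order = np.argsort(vals, kind="stable")
    sorted_pp = vals[order]
    k = np.arange(1, len(vals) + 1)
    passing = sorted_pp <= k * q / m_eff
    if passing.any():
        k_star = int(np.max(np.flatnonzero(passing))) + 1
        threshold = float(sorted_pp[k_star - 1])
        calls = vals <= threshold
    else:
        threshold = float("nan")
        calls = np.zeros(len(vals), dtype=bool)
    return DECalls(
        calls=pd.Series(calls, index=index),
        threshold_pp=threshold,
        n_called=int(calls.sum()),
        q=q,
        m_eff=float(m_eff),
    )


def expression_ratio(ds: ExpressionDataset) -> pd.Series:
    """Linear-scale expression ratio group2/group1 from mean log2 intensities."""
    g1, g2 = ds.group_levels
    m1 = ds.group_matrix(g1).mean(axis=1)
    m2 = ds.group_matrix(g2).mean(axis=1)
    return pd.Series(2.0 ** (m2 - m1), index=ds.values.index)


def de_table(
    ds: ExpressionDataset,
    chains: ContrastChains,
    m_eff: float,
    q: float = 0.10,
) -> pd.DataFrame:
    """Per-probe differential-expression summary table.

    Columns: gene symbol, posterior mean/SD of the log2 contrast, PP,
    linear expression ratio (group2/group1), DE call at the given FDR, and
    the split-Rhat convergence diagnostic.
    """
    pp = posterior_probability(chains)
    calls = fdr_call(pp, m_eff=m_eff, q=q)
    out = pd.DataFrame(
        {
            "gene_symbol": ds.annotation.loc[ds.values.index, "gene_symbol"],
            "post_mean": chains.posterior_mean(),
            "post_sd": chains.posterior_sd(),
            "pp": pp,
            "ratio": expression_ratio(ds),
            "de_call": calls.calls,
            "rhat": chains.rhat,
        },
        index=ds.values.index,
    )
    out.attrs["threshold_pp"] = calls.threshold_pp
    out.attrs["q"] = q
    out.attrs["m_eff"] = float(m_eff)
    return out
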