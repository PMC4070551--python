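"""Variation filtering and the effective number of independent tests.

Two pre-analysis steps: (i) drop probes showing minimal variation across
arrays — only probes for which more than a given fraction of samples deviate
by at least a given fold from the probe's median expression are kept; and
(ii) reduce the nominal test count for correlated probes to an effective
number of independent tests, used downstream as the Benjamini-Hochberg
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ConfigurationError, DataValidationError

__all__ = ["FilterResult", "MeffResult", "variation_filter", "effective_tests"]


@dataclass
class FilterResult:
    retained: pd.Index
    fraction_deviating: pd.Series
    min_fraction: float
    fold: float
    median_mode: str

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def variation_filter(
    ds: ExpressionDataset,
    min_fraction: float = 0.20,
    fold: float = 1.5,
    median_mode: str = "per_probe",
) -> FilterResult:
    """Keep probes whose expression varies beyond ``fold`` in enough samples.

    A probe is retained iff the fraction of samples with
    ``|log2(x) - log2(median)| >= log2(fold)`` is strictly greater than
    ``min_fraction``.  ``median_mode='per_probe'`` (default) takes the
    probe's own median across arrays; ``'grand'`` uses the single median of
    the whole matrix.
    """
    if not (fold > 1):
        raise ConfigurationError("fold must be > 1")
    if not (0 < min_fraction < 1):
        raise ConfigurationError("min_fraction must be in (0, 1)")
    if median_mode not in ("per_probe", "grand"):
        raise ConfigurationError(f"unknown median_mode {median_mode!r}")

    vals = ds.values.to_numpy(dtype=float)
    if median_mode == "per_probe":
        med = np.median(vals, axis=1, keepdims=True)
    else:
        med = np.median(vals)
    dev = np.abs(vals - med) >= np.log2(fold)
    frac = dev.mean(axis=1)
    keep = frac > min_fraction
    return FilterResult(
        retained=ds.values.index[keep],
        fraction_deviating=pd.Series(frac, index=ds.values.index),
        min_fraction=min_fraction,
        fold=fold,
        median_mode=median_mode,
    )


@dataclass
class MeffResult:
    m: int
    m_eff: float
    item_order: list

    def rounded(self) -> int:
        return int(round(self.m_eff))


def effective_tests(values, method: str = "moskvina-schmidt") -> MeffResult:
    """Effective number of independent tests among correlated items.

    ``values`` is an items x samples array (or DataFrame).  Using the
    item-item Pearson correlation matrix across samples, the count is

        m_eff = 1 + sum_{j=2..m} sqrt(1 - max_{i<j} r_ij^2),

    the alpha-independent form of the Moskvina-Schmidt correction.  Each
    item contributes fully when uncorrelated with all earlier items and
    nothing when perfectly correlated with one of them, so
    ``1 <= m_eff <= m``.  The construction is sequential: the result depends
    on (and records) the item order.
    """
    if method != "moskvina-schmidt":
        raise ConfigurationError(f"unknown method {method!r}")
    if isinstance(values, pd.DataFrame):
        order = list(values.index)
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        order = list(range(arr.shape[0]))
    m, n_samples = arr.shape
    if m < 2:
        raise DataValidationError("need at least 2 items")
    if n_samples < 3:
        raise DataValidationError("need at least 3 samples")
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = [order[i] for i in np.flatnonzero(sd == 0)]
        raise DataValidationError(
            f"constant items have undefined correlations: {bad[:10]}"
        )
    corr = np.corrcoef(arr)
    r2 = np.clip(corr**2, 0.0, 1.0)
    m_eff = 1.0
    for j in range(1, m):
        m_eff += np.sqrt(1.0 - r2[:j, j].max())
    return MeffResult(m=m, m_eff=float(m_eff), item_order=order)
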