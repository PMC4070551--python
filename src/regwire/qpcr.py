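"""Efficiency-corrected qPCR quantification and cross-platform validation.

Chain: mean triplicate Cp -> efficiency-corrected relative quantity
(comparative-Cp with the gene's standard-curve slope, calibrated to the
most abundant sample) -> reference-gene stability (geNorm-style M) and
per-sample normalization factors -> group ratio and t-test -> agreement
with a second platform via per-gene Pearson correlation and a global Lin's
concordance correlation coefficient (CCC) on fold changes.

Orientation of the comparative-Cp formula: with calibrator = the sample
with the lowest mean Cp (highest expression), ``dCp = Cp_sample -
Cp_calibrator >= 0`` and ``Qty = 10**(dCp/slope)`` with ``slope < 0``, so a
later crossing point (less abundant transcript) always yields a smaller
quantity and the calibrator has quantity 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataValidationError

__all__ = [
    "aggregate_triplicates",
    "efficiency_from_curve",
    "relative_quantity",
    "reference_stability",
    "normalize_and_test",
    "platform_correlation",
    "lin_ccc",
    "ConcordanceResult",
    "StabilityResult",
    "validate_platforms",
]


def aggregate_triplicates(cp_long: pd.DataFrame, qc_sd: float = 0.5) -> pd.DataFrame:
    """Mean Cp per gene and sample from long-format replicate data.

    Emits a warning for any (gene, sample) whose replicate SD exceeds
    ``qc_sd`` cycles.  Returns a gene x sample DataFrame of mean Cp.
    """
    grouped = cp_long.groupby(["gene", "sample"])["cp"]
    means = grouped.mean().unstack("sample")
    sds = grouped.std().unstack("sample")
    noisy = sds.stack()[sds.stack() > qc_sd]
    for (gene, sample), sd in noisy.items():
        warnings.warn(
            f"replicate SD {sd:.2f} cycles for gene {gene!r}, sample {sample!r}",
            stacklevel=2,
        )
    return means


def efficiency_from_curve(points) -> tuple:
    """Slope and PCR efficiency (%) from a dilution standard curve.

    ``points`` are (log10 input, Cp) pairs; the slope is the least-squares
    regression of Cp on log10 input and the efficiency is
    ``(10**(-1/slope) - 1) * 100``.  Requires at least 3 points spanning at
    least 2 log10 units of input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise DataValidationError("standard curve needs at least 3 dilution points")
    span = pts[:, 0].max() - pts[:, 0].min()
    if span < 2.0:
        raise DataValidationError(
            f"dilution series spans {span:.2f} log10, need at least 2"
        )
    fit = stats.linregress(pts[:, 0], pts[:, 1])
    slope = float(fit.slope)
    efficiency = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return slope, float(efficiency)


def relative_quantity(cp: pd.Series, slope: float) -> pd.Series:
    """Per-sample quantity relative to the most abundant sample.

    Calibrator = sample with the lowest mean Cp (quantity 1); all
    quantities lie in (0, 1].  Samples with missing Cp are excluded with a
    warning.
    """
    if slope >= 0:
        raise ConfigurationError(f"slope must be < 0, got {slope}")
    cp = pd.Series(cp, dtype=float)
    missing = cp.index[cp.isna()]
    if len(missing):
        warnings.warn(f"excluding samples with missing Cp: {list(missing)}",
                      stacklevel=2)
        cp = cp.dropna()
    if cp.empty:
        raise DataValidationError("no Cp values")
    dcp = cp - cp.min()
    return 10.0 ** (dcp / slope)


@dataclass
class StabilityResult:
    m: pd.Series              # geNorm-style stability per candidate (low = stable)
    selected: tuple           # the two most stable candidates
    normalization_factors: pd.Series  # per-sample geometric mean of the pair


def reference_stability(quantities: pd.DataFrame) -> StabilityResult:
    """geNorm-style reference selection from candidate quantities.

    ``quantities`` is candidates x samples.  For each ordered pair the
    pairwise variation is the SD across samples of log2(Qty_a/Qty_b);
    a candidate's M is its mean pairwise variation against all others.
    The two lowest-M candidates are selected and the per-sample
    normalization factor is the geometric mean of their quantities.
    """
    if quantities.shape[0] < 2:
        raise DataValidationError("need at least 2 reference candidates")
    if quantities.shape[1] < 2:
        raise DataValidationError("need at least 2 samples")
    if (quantities.to_numpy() <= 0).any():
        raise DataValidationError("reference quantities must be positive")
    logq = np.log2(quantities.to_numpy(dtype=float))
    names = list(quantities.index)
    k = len(names)
    m = np.zeros(k)
    for i in range(k):
        vs = [np.std(logq[i] - logq[j], ddof=1) for j in range(k) if j != i]
        m[i] = float(np.mean(vs))
    m_series = pd.Series(m, index=names).sort_values(kind="stable")
    selected = tuple(m_series.index[:2])
    nf = np.sqrt(
        quantities.loc[selected[0]].to_numpy() * quantities.loc[selected[1]].to_numpy()
    )
    return StabilityResult(
        m=pd.Series(m, index=names),
        selected=selected,
        normalization_factors=pd.Series(nf, index=quantities.columns),
    )


def normalize_and_test(
    target_qty: pd.Series, nf: pd.Series, design: pd.DataFrame, group_levels
) -> dict:
    """Normalize a gene's quantities and test the group difference.

    Returns the normalized per-sample values, the group ratio
    (treatment mean / reference mean) and the two-sided two-sample t-test
    p-value.
    """
    g1, g2 = group_levels
    common = target_qty.index.intersection(nf.index)
    normalized = target_qty.loc[common] / nf.loc[common]
    grp = design.loc[common, "group"]
    x1 = normalized[grp == g1].to_numpy(dtype=float)
    x2 = normalized[grp == g2].to_numpy(dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise DataValidationError("need at least 2 samples per group")
    ratio = x2.mean() / x1.mean()
    if np.allclose(np.concatenate([x1, x2]), np.concatenate([x1, x2])[0]):
        p = 1.0
    else:
        p = float(stats.ttest_ind(x2, x1).pvalue)
    return {"normalized": normalized, "ratio": float(ratio), "p_value": p}


def platform_correlation(x, y) -> tuple:
    """Pearson r between per-sample measurements on two platforms, with the
    p-value of the t-transform test of r = 0 (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataValidationError("need equal-length vectors of at least 3 samples")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ConcordanceResult:
    ccc: float
    n: int
    provenance: str = ""


def lin_ccc(x, y, provenance: str = "") -> ConcordanceResult:
    """Lin's concordance correlation coefficient between two measurement sets.

    ``CCC = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with the
    n-denominator (population) moment convention throughout.  CCC penalizes
    both scatter and location/scale shift, so ``|CCC| <= |Pearson r|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataValidationError("inputs differ in length")
    if len(x) < 2:
        raise DataValidationError("need at least 2 pairs")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = x.var() + y.var() + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise DataValidationError("zero denominator: both inputs are constant and equal")
    return ConcordanceResult(ccc=float(2.0 * sxy / denom), n=len(x),
                             provenance=provenance)


def validate_platforms(
    plate,
    ds,
    design: pd.DataFrame = None,
    group_levels=None,
    qc_sd: float = 0.5,
) -> pd.DataFrame:
    """Full qPCR validation of a two-group expression dataset.

    Runs the whole quantification chain on a :class:`~regwire.simulate.QPCRPlate`
    (or any object with ``cp`` long table and ``assays``), normalizes target
    genes by the two most stable reference candidates, tests the group
    difference, correlates per-sample qPCR quantities with the matching
    probe's linear-scale expression, and attaches a CCC comparing the two
    platforms' fold changes (in ``result.attrs['ccc']``).
    """
    if design is None:
        design = ds.design
    if group_levels is None:
        group_levels = ds.group_levels
    mean_cp = aggregate_triplicates(plate.cp, qc_sd=qc_sd)
    assays = plate.assays
    qty = pd.DataFrame(
        {
            gene: relative_quantity(mean_cp.loc[gene], assays.loc[gene, "slope"])
            for gene in mean_cp.index
        }
    ).T
    refs = assays.index[assays["is_reference"]]
    targets = assays.index[~assays["is_reference"]]
    stability = reference_stability(qty.loc[refs])
    nf = stability.normalization_factors

    g1, g2 = group_levels
    micro_ratio = None
    if ds is not None:
        from .bayes_de import expression_ratio

        micro_ratio = expression_ratio(ds)

    rows = []
    for gene in targets:
        res = normalize_and_test(qty.loc[gene], nf, design, group_levels)
        row = {"gene": gene, "ratio_qpcr": res["ratio"], "p_qpcr": res["p_value"]}
        if ds is not None and gene in ds.values.index:
            samples = res["normalized"].index
            micro_linear = 2.0 ** ds.values.loc[gene, samples].to_numpy(dtype=float)
            r, p_r = platform_correlation(
                micro_linear, res["normalized"].to_numpy(dtype=float)
            )
            row["ratio_microarray"] = float(micro_ratio.loc[gene])
            row["r"] = r
            row["p_r"] = p_r
        rows.append(row)
    result = pd.DataFrame(rows).set_index("gene")
    result.attrs["reference_selected"] = stability.selected
    result.attrs["reference_m"] = stability.m.to_dict()
    if "ratio_microarray" in result.columns:
        conc = lin_ccc(
            result["ratio_microarray"], result["ratio_qpcr"],
            provenance="linear-scale fold changes, microarray vs qPCR",
        )
        result.attrs["ccc"] = conc.ccc
        result.attrs["ccc_n"] = conc.n
    return result
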