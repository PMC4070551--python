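"""Published reference values packaged as TSV fixtures.

These tables reproduce printed results from the motivating study — a
muscle-transcriptome contrast between purebred Iberian (IB) piglets and
Duroc x Iberian (DUxIB) crossbreds:

* ``study_qpcr_validation`` — 18 genes with linear fold changes
  (DUxIB/IB) measured on both the microarray and by qPCR, the qPCR t-test
  p-value and the per-gene cross-platform Pearson correlation.  Censored
  entries printed as "< bound" are stored at the bound.
* ``study_rif_zscores`` — the 29 regulatory factors reported with extreme
  RIF1/RIF2 z-scores (out of a census of 310 RFs on the filtered array).
* ``study_rif_ci`` — the 95% and 99% bootstrap confidence intervals for
  the RIF z-scores (10,000 random 256-gene draws from 5,226 filtered
  probes).
* ``study_primer_efficiency`` — per-gene PCR efficiencies (%) from
  four-point standard curves, with amplicon lengths.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_qpcr_validation",
    "load_rif_zscores",
    "load_rif_ci",
    "load_primer_efficiencies",
]


def _load(name: str, **kw) -> pd.DataFrame:
    ref = resources.files("regwire") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", **kw)


def load_qpcr_validation() -> pd.DataFrame:
    """18-gene cross-platform validation table, indexed by gene symbol."""
    return _load("study_qpcr_validation.tsv", index_col="gene")


def load_rif_zscores() -> pd.DataFrame:
    """29 regulatory factors with their reported RIF1/RIF2 z-scores."""
    return _load("study_rif_zscores.tsv", index_col="gene")


def load_rif_ci() -> dict:
    """Bootstrap z-score intervals: ``{level: {metric: (lower, upper)}}``."""
    table = _load("study_rif_ci.tsv")
    out = {}
    for _, row in table.iterrows():
        out.setdefault(float(row["level"]), {})[row["metric"]] = (
            float(row["lower"]),
            float(row["upper"]),
        )
    return out


def load_primer_efficiencies() -> pd.DataFrame:
    """Per-gene PCR efficiencies (%) and amplicon sizes, by gene symbol."""
    return _load("study_primer_efficiency.tsv", index_col="gene")
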