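"""Synthetic two-group expression and qPCR data with known ground truth.

The generator mirrors the structure of the analysis model: each log2
intensity is a probe baseline plus an array (sample) effect, a hybridization
series effect, a group effect on the differentially expressed (DE) probes,
and Gaussian residual noise.  "Differential wiring" — the signal the
regulatory-impact-factor stage is designed to detect — is created by
regressing DE-gene expression on the biological deviation of an assigned
regulatory factor (RF) probe with a group-specific coefficient, so the
RF-DE co-expression differs between the two genetic types while the RF
itself stays non-DE.

Default design follows the emulated study: 14 samples per genetic type,
two hybridization series, DE linear fold changes between 1.2x and 8x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "QPCRPlate",
    "simulate_expression",
    "simulate_qpcr",
]


@dataclass
class SimulationConfig:
    """Parameters of the expression simulator.

    All effect sizes and SDs are in log2-intensity units except
    ``de_fold_range`` (linear-scale fold changes) and ``wiring_strength``
    (dimensionless regression coefficient).  ``wiring_strength`` may be a
    single float ``w`` — interpreted as coefficients ``(+w, -w)`` in the two
    groups, i.e. opposite-sign wiring — or an explicit per-group pair.
    """

    n_probes: int = 2000
    n_rf: int = 100
    n_de: int = 100
    n_wired_rf: int = 2
    samples_per_group: int = 14
    n_series: int = 2
    de_fold_range: tuple = (1.2, 8.0)
    array_effect_sd: float = 0.2
    series_effect_sd: float = 0.1
    residual_sd: float = 0.5
    wiring_strength: object = 0.0
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    n_families: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.n_de + self.n_rf > self.n_probes:
            raise ConfigurationError(
                "n_de + n_rf exceeds n_probes "
                f"({self.n_de} + {self.n_rf} > {self.n_probes})"
            )
        if self.n_wired_rf > self.n_rf:
            raise ConfigurationError("n_wired_rf exceeds n_rf")
        if self.samples_per_group < 3:
            raise ConfigurationError("samples_per_group must be >= 3")
        if self.n_series < 1:
            raise ConfigurationError("n_series must be >= 1")
        for name in ("array_effect_sd", "series_effect_sd", "residual_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        lo, hi = self.de_fold_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"de_fold_range must satisfy 1 <= low <= high, got {self.de_fold_range}"
            )

    @property
    def wiring_coefficients(self) -> tuple:
        w = self.wiring_strength
        if isinstance(w, (tuple, list)):
            if len(w) != 2:
                raise ConfigurationError("wiring_strength pair must have 2 entries")
            return tuple(float(x) for x in w)
        return (float(w), -float(w))


@dataclass
class GroundTruth:
    """Record of every planted signal, for recovery testing."""

    de_effects: pd.Series          # signed log2 group effect, by DE probe id
    wired_rf: pd.DataFrame         # rf_id -> coef_group1, coef_group2
    wiring_targets: dict           # rf_id -> list of DE probe ids it drives
    array_effects: pd.Series       # by sample id
    series: pd.Series              # by sample id
    family: pd.Series              # by sample id (generated, unused downstream)


def simulate_expression(config: SimulationConfig):
    """Generate an :class:`ExpressionDataset` and its :class:`GroundTruth`.

    Probe ids are ``DE####`` (differentially expressed), ``RF####``
    (regulatory factors, flagged ``is_rf``) and ``NP####`` (null probes).
    The group contrast is ``group2 - group1`` with the planted effect split
    symmetrically (+e/2 / -e/2), so the contrast equals the recorded effect.
    Identical seeds give identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.samples_per_group
    groups = ["IB"] * n + ["DUxIB"] * n
    sample_ids = [f"IB_{i+1:02d}" for i in range(n)] + [
        f"DUxIB_{i+1:02d}" for i in range(n)
    ]
    series = [(i % cfg.n_series) + 1 for i in range(n)] * 2
    family = [(i % cfg.n_families) + 1 for i in range(n)] * 2

    de_ids = [f"DE{i+1:04d}" for i in range(cfg.n_de)]
    rf_ids = [f"RF{i+1:04d}" for i in range(cfg.n_rf)]
    np_ids = [f"NP{i+1:04d}" for i in range(cfg.n_probes - cfg.n_de - cfg.n_rf)]
    probe_ids = de_ids + rf_ids + np_ids
    n_samples = 2 * n

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_probes)
    array_eff = rng.normal(0.0, cfg.array_effect_sd, n_samples)
    # per-probe, per-series effects, centered across series levels
    series_eff = rng.normal(0.0, cfg.series_effect_sd, (cfg.n_probes, cfg.n_series))
    series_eff -= series_eff.mean(axis=1, keepdims=True)

    lo, hi = (math.log2(cfg.de_fold_range[0]), math.log2(cfg.de_fold_range[1]))
    magnitudes = rng.uniform(lo, hi, cfg.n_de)
    signs = rng.choice([-1.0, 1.0], cfg.n_de)
    de_effects = magnitudes * signs

    resid = rng.normal(0.0, cfg.residual_sd, (cfg.n_probes, n_samples))

    values = baseline[:, None] + array_eff[None, :] + resid
    series_idx = np.asarray(series) - 1
    values += series_eff[:, series_idx]
    group_sign = np.where(np.asarray(groups) == "DUxIB", 0.5, -0.5)
    values[: cfg.n_de] += de_effects[:, None] * group_sign[None, :]

    # differential wiring: each wired RF drives a coherent program — the DE
    # genes sharing one direction of change — with a group-specific
    # coefficient.  This is the master-regulator scenario the RIF metrics
    # are designed to detect: the regulator's co-expression with abundant,
    # coherently DE targets changes between groups.
    w1, w2 = cfg.wiring_coefficients
    wired_ids = rf_ids[: cfg.n_wired_rf]
    wiring_targets = {}
    if cfg.n_wired_rf and (w1 or w2):
        coef = np.where(np.asarray(groups) == "DUxIB", w2, w1)
        by_direction = {
            1.0: [j for j in range(cfg.n_de) if signs[j] > 0],
            -1.0: [j for j in range(cfg.n_de) if signs[j] < 0],
        }
        for k, rf in enumerate(wired_ids):
            direction = 1.0 if k % 2 == 0 else -1.0
            block = by_direction[direction]
            # same-direction regulators partition the block between them
            share = (k // 2, max(1, (cfg.n_wired_rf + 1) // 2))
            targets = [j for i, j in enumerate(block) if i % share[1] == share[0]]
            wiring_targets[rf] = [de_ids[j] for j in targets]
            rf_row = cfg.n_de + k
            values[targets] += coef[None, :] * resid[rf_row][None, :]
    else:
        wiring_targets = {rf: [] for rf in wired_ids}

    matrix = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    design = pd.DataFrame(
        {"group": groups, "series": series, "family": family},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    annotation = pd.DataFrame(
        {"gene_symbol": probe_ids, "is_rf": [p.startswith("RF") for p in probe_ids]},
        index=probe_ids,
    )
    ds = ExpressionDataset(
        values=matrix,
        design=design,
        annotation=annotation,
        group_levels=("IB", "DUxIB"),
    )
    truth = GroundTruth(
        de_effects=pd.Series(de_effects, index=de_ids),
        wired_rf=pd.DataFrame(
            {"coef_group1": w1, "coef_group2": w2},
            index=pd.Index(wired_ids, name="rf_id"),
        )
        if (w1 or w2)
        else pd.DataFrame(
            columns=["coef_group1", "coef_group2"], index=pd.Index([], name="rf_id")
        ),
        wiring_targets=wiring_targets if (w1 or w2) else {},
        array_effects=pd.Series(array_eff, index=sample_ids),
        series=design["series"],
        family=design["family"],
    )
    return ds, truth


# ----------------------------------------------------------------------
# qPCR plate simulation


@dataclass
class QPCRPlate:
    """Triplicate crossing-point (Cp) measurements plus per-gene assay info.

    ``cp`` is long format (gene, sample, replicate, cp); ``assays`` is
    indexed by gene with columns ``efficiency_pct``, ``slope``,
    ``is_reference``.
    """

    cp: pd.DataFrame
    assays: pd.DataFrame

    def write(self, cp_path, assay_path=None) -> None:
        self.cp.to_csv(cp_path, sep="\t", index=False)
        if assay_path is not None:
            self.assays.to_csv(assay_path, sep="\t", index_label="gene")


def slope_from_efficiency(efficiency_pct: float) -> float:
    """Standard-curve slope (cycles per log10 dilution) for an efficiency.

    100% efficiency gives the textbook -3.3219 cycles/log10.
    """
    return -1.0 / math.log10(1.0 + efficiency_pct / 100.0)


def simulate_qpcr(
    ds: ExpressionDataset,
    truth: GroundTruth,
    gene_ids=None,
    n_genes: int = None,
    n_reference: int = 2,
    efficiencies=None,
    seed: int = 0,
    technical_sd: float = 0.1,
    reference_biological_sd: float = 0.05,
) -> QPCRPlate:
    """Simulate a qPCR plate measuring genes from a simulated dataset.

    Target genes' underlying abundance is the dataset's own per-sample log2
    value, so qPCR and "microarray" measurements of the same gene agree up
    to technical noise.  Reference genes have group-independent abundance
    but share the per-sample loading (the array effect), which is what the
    downstream normalization-factor step removes.  Cp decreases by
    ``1/log10(1+E)`` cycles per log10 of abundance; triplicates are jittered
    with ``technical_sd`` cycles.
    """
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        if n_genes is None:
            n_genes = min(8, len(truth.de_effects))
        gene_ids = list(truth.de_effects.index[:n_genes])
    gene_ids = list(gene_ids)
    ref_ids = [f"REF{i+1}" for i in range(n_reference)]
    all_genes = gene_ids + ref_ids

    if efficiencies is None:
        efficiencies = list(rng.uniform(82.0, 97.0, len(all_genes)))
    efficiencies = [float(e) for e in efficiencies]
    if len(efficiencies) != len(all_genes):
        raise ConfigurationError(
            f"need {len(all_genes)} efficiencies, got {len(efficiencies)}"
        )
    for e in efficiencies:
        if not (60.0 < e <= 110.0):
            raise ConfigurationError(
                f"efficiency {e} outside the plausible (60, 110] percent range"
            )

    samples = list(ds.sample_ids)
    loading = truth.array_effects.reindex(samples).to_numpy()
    rows = []
    assay_rows = []
    for g, eff in zip(all_genes, efficiencies):
        slope = slope_from_efficiency(eff)
        c0 = rng.uniform(26.0, 34.0)
        if g in ref_ids:
            abundance = (
                8.0
                + loading
                + (
                    rng.normal(0.0, reference_biological_sd, len(samples))
                    if reference_biological_sd > 0
                    else 0.0
                )
            )
        else:
            abundance = ds.values.loc[g, samples].to_numpy(dtype=float)
        mean_cp = c0 + slope * (abundance * math.log10(2.0))
        for s, cp in zip(samples, mean_cp):
            jitter = (
                rng.normal(0.0, technical_sd, 3) if technical_sd > 0 else np.zeros(3)
            )
            for rep in range(3):
                rows.append((g, s, rep + 1, cp + jitter[rep]))
        assay_rows.append((g, eff, slope, g in ref_ids))

    cp = pd.DataFrame(rows, columns=["gene", "sample", "replicate", "cp"])
    assays = pd.DataFrame(
        assay_rows, columns=["gene", "efficiency_pct", "slope", "is_reference"]
    ).set_index("gene")
    return QPCRPlate(cp=cp, assays=assays)
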