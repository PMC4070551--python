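"""End-to-end orchestration with a single declarative configuration.

Stage order: simulate/load -> variation filter + effective test count ->
Bayesian differential expression -> RIF scoring with bootstrap intervals ->
differential correlation -> optional qPCR validation.  Every stage writes a
TSV whose first line carries the manifest hash, and the run manifest
records the full configuration, all seeds and per-stage row counts, so a
run can be reproduced bit-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bayes_de import ModelSpec, de_table, gibbs_fit
from .dataset import load_expression
from .diffcorr import diffcorr_table, export_edges
from .errors import ConfigurationError
from .preprocess import effective_tests, variation_filter
from .qpcr import lin_ccc, validate_platforms
from .reference_tables import (
    load_qpcr_validation,
    load_rif_ci,
    load_rif_zscores,
)
from .rif import bootstrap_ci, classify_extreme, rif_table
from .simulate import SimulationConfig, simulate_expression, simulate_qpcr

STAGES = ("simulate", "filter", "de", "rif", "diffcorr", "qpcr")

# design toggles in effect, recorded verbatim in every manifest
DESIGN_TOGGLES = {
    "filter_median": "per_probe",
    "filter_fraction_rule": "strictly greater than min_fraction",
    "m_eff_form": "alpha-independent Moskvina-Schmidt, input row order",
    "pp_definition": "tail opposite the posterior-mean sign, capped at 0.5",
    "rif_formulas": (
        "RIF1 = mean_j a*d*(r1-r2)^2; RIF2 = mean_j (e1*r1)^2 - (e2*r2)^2"
    ),
    "rif_standardization": "sample SD (n-1) over the RF census",
    "rif_bootstrap": "without replacement within iteration, pooled z quantiles",
    "rif_extreme_rule": "strict inequality outside the interval",
    "diffcorr_test": "two-sample Fisher r-to-z, two-sided normal",
    "diffcorr_meff": "multiplicative across RF and DE axes",
    "qty_orientation": "Qty = 10**((Cp - Cp_calibrator)/slope), slope < 0",
    "ccc_scale": "linear fold changes, n-denominator moments",
}


@dataclass
class PipelineConfig:
    """Declarative configuration; exactly one of ``inputs``/``simulation``."""

    outdir: str = "regwire_out"
    simulation: dict = None
    inputs: dict = None
    filter: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    fdr_q: float = 0.10
    rif: dict = field(default_factory=dict)
    diffcorr: dict = field(default_factory=dict)
    qpcr: dict = None
    seed: int = None

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'inputs' and 'simulation' must be given"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def resolved_seeds(self) -> dict:
        base = self.seed if self.seed is not None else 0
        return {
            "simulation": self.simulation.get("seed", base)
            if self.simulation
            else None,
            "model": self.model.get("seed", base + 1),
            "rif_bootstrap": self.rif.get("seed", base + 2),
            "qpcr": (self.qpcr or {}).get("seed", base + 3),
        }


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str
    toggles: dict
    stage_rows: dict
    hash: str = ""

    def finalize(self) -> "RunManifest":
        # outdir does not affect the computation, so it is excluded from
        # the hash: the same analysis in two directories is the same run
        hashed = {k: v for k, v in self.config.items() if k != "outdir"}
        payload = json.dumps(
            {"config": hashed, "seeds": self.seeds, "version": self.version},
            sort_keys=True,
            default=str,
        )
        self.hash = hashlib.sha256(payload.encode()).hexdigest()[:16]
        return self

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _write_tsv(frame: pd.DataFrame, path, manifest_hash: str, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest_hash}\n")
        frame.to_csv(fh, sep="\t", **kw)


def run_pipeline(config: PipelineConfig, stages=STAGES) -> RunManifest:
    """Execute the pipeline, writing stage outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.resolved_seeds()
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seeds=seeds,
        version=__version__,
        toggles=dict(DESIGN_TOGGLES),
        stage_rows={},
    ).finalize()
    h = manifest.hash

    truth = None
    try:
        if config.simulation is not None:
            sim_kw = dict(config.simulation)
            sim_kw["seed"] = seeds["simulation"]
            sim_cfg = SimulationConfig(**sim_kw)
            ds, truth = simulate_expression(sim_cfg)
            if "simulate" in stages:
                _write_tsv(ds.values, outdir / "expression.tsv", h,
                           index_label="probe_id")
                _write_tsv(ds.design, outdir / "design.tsv", h,
                           index_label="sample_id")
                _write_tsv(
                    truth.de_effects.rename("log2_effect").to_frame(),
                    outdir / "truth_de.tsv", h, index_label="probe_id",
                )
                manifest.stage_rows["simulate"] = len(ds.values)
        else:
            ds = load_expression(
                config.inputs["matrix"],
                config.inputs["design"],
                config.inputs.get("rf_list"),
                linear_scale=config.inputs.get("linear_scale", False),
            )
    except (KeyError, OSError) as exc:
        raise ConfigurationError(f"stage simulate/load failed: {exc}") from exc

    if "filter" not in stages:
        manifest.write(outdir / "manifest.json")
        return manifest
    filt = variation_filter(ds, **config.filter)
    filtered = ds.subset(filt.retained)
    meff = effective_tests(filtered.values)
    _write_tsv(
        pd.DataFrame(
            {"retained": 1}, index=pd.Index(filt.retained, name="probe_id")
        ),
        outdir / "filtered_probes.tsv", h,
    )
    manifest.stage_rows["filter"] = filt.n_retained
    manifest.stage_rows["m_eff"] = meff.m_eff

    if "de" not in stages:
        manifest.write(outdir / "manifest.json")
        return manifest
    model_kw = dict(config.model)
    model_kw["seed"] = seeds["model"]
    spec = ModelSpec(**model_kw)
    chains = gibbs_fit(filtered, spec)
    de = de_table(filtered, chains, m_eff=meff.m_eff, q=config.fdr_q)
    _write_tsv(de, outdir / "de_table.tsv", h, index_label="probe_id")
    manifest.stage_rows["de"] = int(de["de_call"].sum())
    nonconv = chains.nonconverged()
    if nonconv:
        manifest.stage_rows["de_nonconverged"] = len(nonconv)

    de_ids = list(de.index[de["de_call"]])
    rf_ids = [p for p in filtered.rf_probes() if p not in set(de_ids)]

    if "rif" in stages:
        if len(de_ids) >= 2 and len(rf_ids) >= 2:
            contrast = de["post_mean"]
            table = rif_table(filtered, rf_ids, de_ids, contrast=contrast)
            ci = bootstrap_ci(
                filtered,
                rf_ids,
                n_de=len(de_ids),
                n_iterations=config.rif.get("n_iterations", 10_000),
                seed=seeds["rif_bootstrap"],
                contrast=contrast,
            )
            level = config.rif.get("level", 0.95)
            table, summary = classify_extreme(table, ci, level=level)
            _write_tsv(table, outdir / "rif_table.tsv", h, index_label="probe_id")
            ci_rows = [
                {"metric": metric, "level": lvl, "lower": lo, "upper": hi}
                for metric, by_level in ci.bounds.items()
                for lvl, (lo, hi) in by_level.items()
            ]
            _write_tsv(pd.DataFrame(ci_rows), outdir / "rif_ci.tsv", h, index=False)
            manifest.stage_rows["rif_extreme"] = summary["n_union"]
        else:
            manifest.stage_rows["rif_extreme"] = "skipped: too few DE genes or RFs"
            table = None

    if "diffcorr" in stages and len(de_ids) >= 1 and len(rf_ids) >= 1:
        dc = diffcorr_table(
            filtered, rf_ids, de_ids, q=config.diffcorr.get("q", 0.10)
        )
        _write_tsv(dc.reset_index(), outdir / "diffcorr_table.tsv", h, index=False)
        edges = export_edges(dc)
        _write_tsv(edges, outdir / "edges.tsv", h, index=False)
        manifest.stage_rows["diffcorr_significant"] = int(
            dc["diff_significant"].sum()
        )
        manifest.stage_rows["edges"] = len(edges)

    if "qpcr" in stages and config.qpcr is not None:
        if truth is None:
            raise ConfigurationError(
                "qpcr stage requires simulation mode (needs ground truth)"
            )
        plate = simulate_qpcr(
            ds,
            truth,
            n_genes=config.qpcr.get("n_genes", 8),
            n_reference=config.qpcr.get("n_reference", 3),
            seed=seeds["qpcr"],
        )
        result = validate_platforms(plate, ds)
        _write_tsv(result, outdir / "qpcr_validation.tsv", h, index_label="gene")
        manifest.stage_rows["qpcr_genes"] = len(result)
        if "ccc" in result.attrs:
            manifest.stage_rows["qpcr_ccc"] = round(result.attrs["ccc"], 4)

    manifest.write(outdir / "manifest.json")
    return manifest


def reproduce_tables(fixtures_dir=None) -> dict:
    """Re-derive the study's printed summary numbers from packaged fixtures.

    Applies the extreme-z classification to the packaged RIF z-score table
    using the published 95% bootstrap intervals, and Lin's CCC to the
    packaged cross-platform fold-change pairs.  Returns a report dict with
    an overall ``passed`` flag comparing against the study's printed
    summary (16 / 16 extreme RFs, union 29, intersection SIX4-EYA2-KLF11,
    CCC 0.863).
    """
    if fixtures_dir is not None:
        fixtures_dir = Path(fixtures_dir)
        if not fixtures_dir.exists():
            raise FileNotFoundError(f"fixtures directory {fixtures_dir} not found")
        zscores = pd.read_csv(
            fixtures_dir / "study_rif_zscores.tsv", sep="\t", index_col="gene"
        )
        ci_table = pd.read_csv(fixtures_dir / "study_rif_ci.tsv", sep="\t")
        ci = {}
        for _, row in ci_table.iterrows():
            ci.setdefault(float(row["level"]), {})[row["metric"]] = (
                row["lower"],
                row["upper"],
            )
        validation = pd.read_csv(
            fixtures_dir / "study_qpcr_validation.tsv", sep="\t", index_col="gene"
        )
    else:
        zscores = load_rif_zscores()
        ci = load_rif_ci()
        validation = load_qpcr_validation()

    flagged, summary = classify_extreme(zscores, ci[0.95], level=0.95)
    conc = lin_ccc(
        validation["ratio_microarray"], validation["ratio_qpcr"],
        provenance="packaged study fold changes",
    )
    expected = {
        "n_extreme1": 16,
        "n_extreme2": 16,
        "n_union": 29,
        "intersection": {"SIX4", "EYA2", "KLF11"},
        "ccc": 0.863,
    }
    observed = {
        "n_extreme1": summary["n_extreme1"],
        "n_extreme2": summary["n_extreme2"],
        "n_union": summary["n_union"],
        "intersection": set(summary["intersection"]),
        "ccc": round(conc.ccc, 3),
    }
    report = {
        "expected": expected,
        "observed": observed,
        "ccc_exact": conc.ccc,
        "n_pairs": conc.n,
        "passed": all(observed[k] == expected[k] for k in expected),
    }
    return report
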