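import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regwire.errors import ConfigurationError, DataValidationError
from regwire.rif import (
    RIFInputs,
    bootstrap_ci,
    classify_extreme,
    compute_rif_inputs,
    rif_scores,
    rif_table,
    standardize,
)
from regwire.simulate import SimulationConfig, simulate_expression

from conftest import make_dataset


def inputs_from_arrays(a, d, e1, e2, r1, r2):
    de = [f"g{j}" for j in range(len(a))]
    rf = [f"rf{i}" for i in range(len(r1))]
    return RIFInputs(
        a_bar=pd.Series(a, index=de),
        d=pd.Series(d, index=de),
        e1=pd.Series(e1, index=de),
        e2=pd.Series(e2, index=de),
        r1=pd.DataFrame(r1, index=rf, columns=de),
        r2=pd.DataFrame(r2, index=rf, columns=de),
    )


class TestRifScores:
    def test_equal_correlations_zero_rif1(self):
        r = [[0.5, -0.3, 0.8]]
        inp = inputs_from_arrays([7, 7, 7], [1, -1, 2], [7, 7, 7], [7, 7, 7], r, r)
        assert rif_scores(inp)["rif1_raw"].iloc[0] == 0.0

    def test_identical_groups_zero_rif2(self):
        r = [[0.5, -0.3, 0.8]]
        inp = inputs_from_arrays([7, 7, 7], [0, 0, 0], [6, 7, 8], [6, 7, 8], r, r)
        assert rif_scores(inp)["rif2_raw"].iloc[0] == 0.0

    def test_hand_evaluated_two_rf_three_gene_case(self):
        # both sums evaluated by hand before implementation
        inp = inputs_from_arrays(
            a=[8.0, 6.0, 7.0],
            d=[1.0, -0.5, 2.0],
            e1=[8.5, 5.75, 8.0],
            e2=[7.5, 6.25, 6.0],
            r1=[[0.9, -0.4, 0.5], [0.1, 0.2, -0.3]],
            r2=[[0.2, -0.4, 0.8], [0.1, 0.6, 0.3]],
        )
        out = rif_scores(inp)
        assert out["rif1_raw"].to_numpy() == pytest.approx([5.18 / 3, 1.52])
        assert out["rif2_raw"].to_numpy() == pytest.approx(
            [48.2725 / 3, -10.06 / 3]
        )

    def test_correlation_out_of_range_rejected(self):
        with pytest.raises(DataValidationError):
            inputs_from_arrays([7, 7], [1, 1], [7, 7], [7, 7],
                               [[1.2, 0.0]], [[0.0, 0.0]])


class TestStandardize:
    def test_one_two_three(self):
        # sample SD (n-1) of (1,2,3) is exactly 1
        z = standardize(pd.Series([1.0, 2.0, 3.0]))
        assert z.to_numpy() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(DataValidationError, match="zero standard deviation"):
            standardize([2.0, 2.0, 2.0])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30))
    def test_zero_mean_unit_sd_identity(self, raw):
        vals = np.asarray(raw)
        # spread below float resolution makes the identity meaningless
        if vals.std(ddof=1) <= 1e-9 * max(1.0, np.abs(vals).max()):
            return
        z = standardize(vals)
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0)


class TestComputeInputs:
    def test_constant_profile_named_in_error(self):
        vals = np.vstack([np.full(8, 3.0), np.arange(8.0), np.arange(8.0) ** 1.5])
        ds = make_dataset(vals)
        with pytest.raises(DataValidationError, match="P1"):
            compute_rif_inputs(ds, ["P1"], ["P2", "P3"])

    def test_overlap_allowed_and_recorded(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(7, 1, (4, 8)))
        inp = compute_rif_inputs(ds, ["P1", "P2"], ["P2", "P3", "P4"])
        assert inp.overlap == ["P2"]


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(
        n_probes=200, n_rf=20, n_de=20, n_wired_rf=2,
        wiring_strength=0.8, seed=17,
    )
    return simulate_expression(cfg)


class TestBootstrapCI:

    def test_same_seed_identical_bounds(self, sim):
        ds, _ = sim
        rf = list(ds.rf_probes())
        ci1 = bootstrap_ci(ds, rf, n_de=20, n_iterations=300, seed=5)
        ci2 = bootstrap_ci(ds, rf, n_de=20, n_iterations=300, seed=5)
        assert ci1.bounds == ci2.bounds

    def test_99_contains_95(self, sim):
        ds, _ = sim
        ci = bootstrap_ci(ds, list(ds.rf_probes()), n_de=20,
                          n_iterations=300, seed=6)
        for metric in ("rif1", "rif2"):
            lo95, hi95 = ci.interval(metric, 0.95)
            lo99, hi99 = ci.interval(metric, 0.99)
            assert lo99 <= lo95 < hi95 <= hi99

    def test_single_level_carries_no_99_bounds(self, sim):
        ds, _ = sim
        ci = bootstrap_ci(ds, list(ds.rf_probes()), n_de=20,
                          n_iterations=100, levels=(0.95,), seed=7)
        with pytest.raises(ConfigurationError):
            ci.interval("rif1", 0.99)

    def test_n_de_larger_than_pool_rejected(self, sim):
        ds, _ = sim
        with pytest.raises(ConfigurationError):
            bootstrap_ci(ds, list(ds.rf_probes()), n_de=10_000, seed=1)

    def test_null_zscores_mostly_inside_95_interval(self):
        """On null data ~95% of RF z-scores fall inside the 95% interval."""
        rates = []
        for rep in range(10):
            cfg = SimulationConfig(
                n_probes=150, n_rf=25, n_de=0, n_wired_rf=0,
                wiring_strength=0.0, seed=300 + rep,
            )
            ds, _ = simulate_expression(cfg)
            rf = list(ds.rf_probes())
            rng = np.random.default_rng(rep)
            fake_de = list(
                ds.values.index[rng.choice(len(ds.values.index), 20, replace=False)]
            )
            rf_use = [r for r in rf if r not in fake_de]
            table = rif_table(ds, rf_use, fake_de)
            ci = bootstrap_ci(ds, rf_use, n_de=20, n_iterations=400,
                              seed=100 + rep)
            _, summary = classify_extreme(table, ci, level=0.95)
            rates.append(1 - summary["n_union"] / len(rf_use))
        # coverage of the union of two 95% intervals; allow MC slack
        assert 0.85 <= np.mean(rates) <= 1.0


class TestClassifyExtreme:
    def make_table(self, z1, z2):
        return pd.DataFrame(
            {"rif1_z": z1, "rif2_z": z2},
            index=[f"rf{i}" for i in range(len(z1))],
        )

    def test_boundary_value_is_not_extreme(self):
        table = self.make_table([2.0, 2.5], [0.0, 0.0])
        ci = {"rif1": (-2.0, 2.0), "rif2": (-2.0, 2.0)}
        out, summary = classify_extreme(table, ci)
        assert not out.loc["rf0", "extreme1"]  # exactly on the bound
        assert out.loc["rf1", "extreme1"]
        assert summary["n_extreme1"] == 1

    def test_all_inside_gives_empty_summary(self):
        table = self.make_table([0.1, -0.5], [0.3, 0.2])
        ci = {"rif1": (-2.0, 2.0), "rif2": (-2.0, 2.0)}
        _, summary = classify_extreme(table, ci)
        assert summary["n_union"] == 0
        assert summary["union"] == []


def test_scale_change_keeps_classification_self_consistent():
    """Multiplying all log2 intensities by a constant rescales raw RIF but
    leaves the extreme classification unchanged when the bootstrap uses the
    same transformed data."""
    cfg = SimulationConfig(
        n_probes=150, n_rf=15, n_de=15, n_wired_rf=2, wiring_strength=0.8,
        seed=23,
    )
    ds, truth = simulate_expression(cfg)
    rf = list(ds.rf_probes())
    de = list(truth.de_effects.index)

    def run(dataset):
        table = rif_table(dataset, rf, de)
        ci = bootstrap_ci(dataset, rf, n_de=len(de), n_iterations=300, seed=9)
        _, summary = classify_extreme(table, ci)
        return table, set(summary["union"])

    t1, u1 = run(ds)
    from regwire.dataset import ExpressionDataset

    scaled = ExpressionDataset(
        values=ds.values * 3.0, design=ds.design, annotation=ds.annotation,
        group_levels=ds.group_levels,
    )
    t2, u2 = run(scaled)
    assert u1 == u2
    # correlations are scale-invariant; raw RIF1 scales deterministically
    # (a*d pick up one factor of c each: c^2)
    assert t2["rif1_raw"].to_numpy() == pytest.approx(
        9.0 * t1["rif1_raw"].to_numpy()
    )
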