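import numpy as np
import pandas as pd
import pytest

from nsum import (
    BootstrapError,
    BootstrapSpec,
    ValidationError,
    bootstrap_general,
    generate_general_survey,
    generate_rds_survey,
    joint_pipeline_ci,
    mean_known_count,
    rds_chain_bootstrap,
)
from nsum.adjustment import mean_known_rowsum
from nsum.scale_up import GeneralSurveyTable

from .conftest import make_general_table, make_rds_table


class TestBootstrapSpec:
    def test_defaults(self):
        spec = BootstrapSpec()
        assert spec.B == 10_000
        assert spec.level == 0.95

    def test_invalid(self):
        with pytest.raises(ValidationError):
            BootstrapSpec(B=0)
        with pytest.raises(ValidationError):
            BootstrapSpec(level=1.0)
        with pytest.raises(ValidationError):
            BootstrapSpec(method="bca")


class TestBootstrapGeneral:
    def test_constant_dataset_zero_width(self):
        table = make_general_table([5, 5, 5, 5])
        est = bootstrap_general(table, mean_known_count, BootstrapSpec(B=200, seed=1))
        assert est.ci_low == est.ci_high == est.point == 5.0

    def test_fixed_seed_reproducible(self, truth, design):
        table = generate_general_survey(truth, 300, design, seed=3)
        spec = BootstrapSpec(B=1000, seed=42)
        a = bootstrap_general(table, mean_known_count, spec)
        b = bootstrap_general(table, mean_known_count, spec)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_coverage_of_mean(self):
        # scaled-down coverage study: Poisson(5) row sums, nominal 95%
        reps, n, B = 300, 300, 400
        true_mean = 5.0
        cover = 0
        master = np.random.SeedSequence(123)
        for i, s in enumerate(master.spawn(reps)):
            rng = np.random.default_rng(s)
            table = make_general_table(rng.poisson(true_mean, n))
            est = bootstrap_general(table, mean_known_count, BootstrapSpec(B=B, seed=i))
            cover += est.ci_low <= true_mean <= est.ci_high
        # 3 binomial SEs at 300 reps is about 3.8 points
        assert abs(cover / reps - 0.95) < 0.04

    def test_cluster_resampling(self, truth, design):
        table = generate_general_survey(truth, 400, design, seed=5)
        est = bootstrap_general(
            table, mean_known_count, BootstrapSpec(B=300, seed=2), cluster_level="department"
        )
        assert est.ci_low <= est.point <= est.ci_high

    def test_unknown_cluster_column(self):
        table = make_general_table([1, 2, 3])
        with pytest.raises(ValidationError, match="cluster column"):
            bootstrap_general(table, mean_known_count, BootstrapSpec(B=10, seed=0),
                              cluster_level="village")

    def test_failing_statistic_aborts(self):
        table = make_general_table([1, 2, 3])
        calls = {"n": 0}

        def bad(t):
            calls["n"] += 1
            if calls["n"] > 1:  # fine on the full table, fails on every resample
                raise RuntimeError("boom")
            return mean_known_count(t)

        with pytest.raises(BootstrapError, match="aborting"):
            bootstrap_general(table, bad, BootstrapSpec(B=500, seed=0))

    def test_endpoint_convergence_in_B(self, truth, design):
        table = generate_general_survey(truth, 300, design, seed=9)
        a = bootstrap_general(table, mean_known_count, BootstrapSpec(B=5000, seed=0))
        b = bootstrap_general(table, mean_known_count, BootstrapSpec(B=10_000, seed=1))
        assert a.ci_low == pytest.approx(b.ci_low, rel=0.01)
        assert a.ci_high == pytest.approx(b.ci_high, rel=0.01)


class TestRDSChainBootstrap:
    def test_single_chain_identical_respondents_zero_width(self):
        n = 6
        table = make_rds_table(
            [[3.0]] * n, [[2.0]] * n,
            recruiter=[None] + [f"r{i}" for i in range(n - 1)],
            wave=list(range(n)),
        )
        est = rds_chain_bootstrap(table, mean_known_rowsum, BootstrapSpec(B=200, seed=0))
        assert est.ci_low == est.ci_high == est.point == 3.0

    def test_fixed_seed_reproducible(self, truth):
        table = generate_rds_survey(truth, n_target=150, seed=8)
        spec = BootstrapSpec(B=400, seed=11)
        a = rds_chain_bootstrap(table, mean_known_rowsum, spec)
        b = rds_chain_bootstrap(table, mean_known_rowsum, spec)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_respondent_flavor_fallback(self, truth):
        table = generate_rds_survey(truth, n_target=150, seed=8)
        est = rds_chain_bootstrap(
            table, mean_known_rowsum, BootstrapSpec(B=400, seed=1), flavor="respondent"
        )
        assert est.ci_low <= est.point <= est.ci_high

    def test_unknown_flavor(self, truth):
        table = generate_rds_survey(truth, n_target=20, seed=8)
        with pytest.raises(ValidationError, match="flavor"):
            rds_chain_bootstrap(table, mean_known_rowsum, BootstrapSpec(B=10, seed=0),
                                flavor="tree")

    def test_invalid_forest_rejected_before_resampling(self):
        df = pd.DataFrame({
            "id": ["a", "b"],
            "recruiter_id": [None, "zz"],
            "wave": [0, 1],
            "name_x": [1.0, 2.0],
            "aware_x": [1.0, 1.0],
        })
        from nsum import RDSTable

        with pytest.raises(ValidationError, match="dangling"):
            RDSTable(df)

    def test_scaled_coverage(self, truth, synth_frame):
        # scaled-down vs the full acceptance run: 50 replications, B=200
        true_mean = truth.c_true * truth.delta_true * synth_frame.e0 / synth_frame.t
        cover = 0
        for i, s in enumerate(np.random.SeedSequence(55).spawn(50)):
            table = generate_rds_survey(truth, seed=np.random.default_rng(s))
            est = rds_chain_bootstrap(table, mean_known_rowsum,
                                      BootstrapSpec(B=200, seed=i))
            cover += est.ci_low <= true_mean <= est.ci_high
        assert cover >= 44  # >= 88% at nominal 95%


class TestJointPipelineCI:
    def test_reproducible(self, truth, synth_frame, design):
        g = generate_general_survey(truth, 800, design, seed=2)
        r = generate_rds_survey(truth, n_target=150, seed=2)
        spec = BootstrapSpec(B=300, seed=7)
        a = joint_pipeline_ci(g, r, synth_frame, design, spec)
        b = joint_pipeline_ci(g, r, synth_frame, design, spec)
        for k in a:
            assert (a[k].ci_low, a[k].ci_high) == (b[k].ci_low, b[k].ci_high)

    def test_identity_world_adjusted_tracks_e1(self, synth_frame, design):
        from nsum import SyntheticTruth

        truth = SyntheticTruth(
            frame=synth_frame, N_H=45_000, c_true=120.0,
            delta_true=1.0, tau_true=1.0, mu_unrelated=2.0, nonresponse_rate=0.0,
        )
        g = generate_general_survey(truth, 4000, design, seed=31)
        r = generate_rds_survey(truth, n_target=300, seed=31)
        out = joint_pipeline_ci(g, r, synth_frame, design, BootstrapSpec(B=400, seed=3))
        e1, adj = out["e1"], out["adjusted"]
        # same world, identity factors: endpoints differ only by the noise of
        # the estimated factors
        assert adj.point == pytest.approx(e1.point / (out["delta"].point * out["tau"].point))
        assert adj.ci_low == pytest.approx(e1.ci_low, rel=0.25)
        assert adj.ci_high == pytest.approx(e1.ci_high, rel=0.25)

    def test_every_chain_quantity_reported_with_ci(self, truth, synth_frame, design):
        from nsum.uncertainty import CHAIN_KEYS

        g = generate_general_survey(truth, 600, design, seed=4)
        r = generate_rds_survey(truth, n_target=120, seed=4)
        out = joint_pipeline_ci(g, r, synth_frame, design, BootstrapSpec(B=200, seed=5))
        assert set(out) == set(CHAIN_KEYS)
        for est in out.values():
            assert est.ci_low <= est.point <= est.ci_high

    def test_percentile_ci_brackets_resample_median(self, truth, synth_frame, design):
        g = generate_general_survey(truth, 600, design, seed=6)
        r = generate_rds_survey(truth, n_target=120, seed=6)
        out = joint_pipeline_ci(g, r, synth_frame, design, BootstrapSpec(B=500, seed=9))
        for est in out.values():
            assert est.ci_low <= est.ci_high
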