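"""Particle engine: stepping, conservation, ergodicity, determinism."""

import numpy as np
import pytest

from nfsim import (
    AxonGeometry,
    EightStateRates,
    KineticRates,
    McConfig,
    Particle,
    PhosphoKinetics,
    build_profile,
    run_axon,
    step_particle,
    steady_state_numeric,
)
from nfsim.kinetics import ConfigurationError
from nfsim.mc import default_burn_in, injection_state_index, transition_tables


def tiny_rate_set(**over):
    """Eight-state rates with negligibly small transition rates."""
    eps = 1e-12
    kw = dict(
        base=KineticRates(
            gamma_10=eps, gamma_01=eps, gamma_off=eps, gamma_ar=eps, gamma_ra=eps
        ),
        gamma_on1=eps,
        gamma_on2=eps,
        phospho=PhosphoKinetics(gamma_ph=eps, gamma_de=eps),
    )
    kw.update(over)
    return EightStateRates(**kw)


@pytest.fixture(scope="module")
def fast_uniform_profile(uniform_fast_profile):
    return uniform_fast_profile


class TestStepParticle:
    def test_running_state_advances_deterministically(self):
        rates = tiny_rate_set()
        profile = build_profile(AxonGeometry(), rates, rates)
        rng = np.random.default_rng(0)
        p = Particle(position=10.0, state=0)  # running anterograde
        for k in range(100):
            p = step_particle(p, profile, dt=0.1, rng=rng)
        assert p.state == 0
        assert p.position == pytest.approx(10.0 + 100 * 0.1 * 0.52)

    def test_particle_leaving_domain_is_removed(self):
        rates = tiny_rate_set()
        profile = build_profile(AxonGeometry(), rates, rates)
        rng = np.random.default_rng(0)
        p = Particle(position=49.99, state=0)
        p = step_particle(p, profile, dt=0.1, rng=rng)
        assert not p.alive

    def test_negligible_on_rate_keeps_phospho_off_track_state(self):
        # with gamma_on1 ~ 0 (and phospho exchange ~ 0) a phosphorylated
        # off-track NF is stuck against the on-track edge
        rates = tiny_rate_set(gamma_on2=5.16e-3)
        profile = build_profile(AxonGeometry(), rates, rates)
        tables = transition_tables(profile)
        labels = tables[0]
        rng = np.random.default_rng(1)
        p = Particle(position=25.0, state=labels.index("Pap1"))
        for _ in range(5000):
            p = step_particle(p, profile, dt=0.1, rng=rng, tables=tables)
            assert labels[p.state] == "Pap1"

    def test_dt_too_large_rejected_at_setup(self, fast_uniform_profile):
        rng = np.random.default_rng(0)
        p = Particle(position=25.0, state=0)
        with pytest.raises(ConfigurationError, match="dt"):
            step_particle(p, fast_uniform_profile, dt=5.0, rng=rng)

    def test_single_particle_occupancy_matches_chain_steady_state(self):
        """Ergodic time-average of one walker against the null-eigenvector
        oracle, using fast rates and negligible run speeds so the walker
        stays in the domain."""
        rates = EightStateRates(
            base=KineticRates(
                gamma_10=0.14,
                gamma_01=0.064,
                gamma_off=0.04,
                gamma_ar=0.01,
                gamma_ra=0.02,
                v_a=1e-9,
                v_r=-1e-9,
            ),
            gamma_on1=0.02,
            gamma_on2=0.08,
            phospho=PhosphoKinetics(gamma_ph=0.8, gamma_de=0.1),
        )
        profile = build_profile(AxonGeometry(), rates, rates)
        tables = transition_tables(profile)
        rng = np.random.default_rng(42)
        p = Particle(position=25.0, state=0)
        n_steps, burn = 200_000, 20_000
        counts = np.zeros(8)
        for k in range(n_steps):
            p = step_particle(p, profile, dt=0.1, rng=rng, tables=tables)
            if k >= burn:
                counts[p.state] += 1
        occupancy = counts / counts.sum()
        expected = steady_state_numeric(rates).probabilities
        # 3 sigma of the correlated time average: the slowest rate here is
        # 0.01/s, so one effective sample per ~2/0.01 s of model time
        tau, dt = 2.0 / 0.01, 0.1
        n_eff = (n_steps - burn) * dt / tau
        sigma3 = 3 * np.sqrt(expected * (1 - expected) / n_eff)
        assert np.all(np.abs(occupancy - expected) < np.maximum(sigma3, 0.01))


class TestRunAxon:
    def test_particle_count_conservation(self, fast_uniform_profile):
        cfg = McConfig(n_replicates=3, burn_in=500.0, t_observe=500.0, seed=5)
        census = run_axon(cfg, fast_uniform_profile)
        assert np.all(census.n_injected == census.n_removed + census.n_alive)
        expected_injections = int(1000.0 / 10.0)
        assert np.all(census.n_injected == expected_injections)

    def test_same_seed_reproduces_census_exactly(self, fast_uniform_profile):
        cfg = McConfig(n_replicates=3, burn_in=300.0, t_observe=300.0, seed=9)
        a = run_axon(cfg, fast_uniform_profile)
        b = run_axon(cfg, fast_uniform_profile)
        np.testing.assert_array_equal(a.bin_counts, b.bin_counts)
        np.testing.assert_array_equal(a.region_state_counts, b.region_state_counts)

    def test_different_seeds_differ(self, fast_uniform_profile):
        cfg_a = McConfig(n_replicates=2, burn_in=300.0, t_observe=300.0, seed=1)
        cfg_b = McConfig(n_replicates=2, burn_in=300.0, t_observe=300.0, seed=2)
        a = run_axon(cfg_a, fast_uniform_profile)
        b = run_axon(cfg_b, fast_uniform_profile)
        assert not np.array_equal(a.bin_counts, b.bin_counts)

    def test_uniform_rates_give_flat_interior_bins(self, fast_uniform_profile):
        cfg = McConfig(n_replicates=12, seed=17)
        census = run_axon(cfg, fast_uniform_profile)
        mean = census.mean_bin_counts()
        interior = mean[2:-2]
        se = census.sd_bin_counts()[2:-2] / np.sqrt(cfg.n_replicates)
        # no spatial trend: every interior bin within 4 SE of the plateau
        assert np.all(np.abs(interior - interior.mean()) < 4 * np.maximum(se, 0.1))

    def test_replicate_scaling_shrinks_standard_error(self, fast_uniform_profile):
        cfg = McConfig(n_replicates=32, burn_in=1000.0, t_observe=2000.0, seed=23)
        census = run_axon(cfg, fast_uniform_profile)
        totals = census.bin_counts.sum(axis=1)
        se_full = totals.std(ddof=1) / np.sqrt(len(totals))
        half = totals[:16]
        se_half = half.std(ddof=1) / np.sqrt(len(half))
        # SE should drop by ~sqrt(2), i.e. the per-replicate sd is stable;
        # the sd ratio itself carries chi-square sampling error (~25% at
        # n=16), so allow a 3-sigma band around 1
        assert 0.6 < (se_half / se_full) / np.sqrt(2) < 1.7

    def test_region_occupancy_converges_to_chain_steady_state(
        self, fast_uniform_profile
    ):
        cfg = McConfig(n_replicates=8, seed=31)
        census = run_axon(cfg, fast_uniform_profile)
        observed = census.region_fractions("internode").probabilities
        expected = steady_state_numeric(
            fast_uniform_profile.internode_rates
        ).probabilities
        # boundary removal depletes the (slow) retrograde family; compare
        # within the anterograde family which dominates the census
        labels = census.labels
        ante = [
            i
            for i, l in enumerate(labels)
            if l in ("Pa", "Pa0") or l.startswith("Pap")
        ]
        obs_a = observed[ante] / observed[ante].sum()
        exp_a = expected[ante] / expected[ante].sum()
        np.testing.assert_allclose(obs_a, exp_a, atol=0.03)

    def test_burn_in_estimator_exceeds_transit_time(self, fast_uniform_profile):
        from nfsim import mean_velocity

        burn = default_burn_in(fast_uniform_profile)
        transit = 50.0 / mean_velocity(fast_uniform_profile.internode_rates)
        assert burn > transit

    def test_injection_state_six_phospho_default_dephosphorylated(self):
        from nfsim import canonical_profile_six_phospho

        profile = canonical_profile_six_phospho()
        idx = injection_state_index(profile, "de")
        assert census_label(profile, idx) == "Pa_de"

    def test_invalid_configs_rejected(self, fast_uniform_profile):
        with pytest.raises(ConfigurationError):
            McConfig(dt=-0.1)
        with pytest.raises(ConfigurationError):
            run_axon(
                McConfig(n_replicates=1, burn_in=10.0, t_observe=10.0, bin_width=3.0),
                fast_uniform_profile,
            )


def census_label(profile, idx):
    from nfsim.kinetics import state_labels

    return state_labels(profile.internode_rates)[idx]


class TestCensusWriter:
    def test_tidy_csv_partitions_bin_counts(self, uniform_fast_profile, tmp_path):
        import pandas as pd
        from nfsim.mc import write_census_csv

        cfg = McConfig(n_replicates=2, burn_in=300.0, t_observe=300.0, seed=13)
        census = run_axon(cfg, uniform_fast_profile)
        out = tmp_path / "census.csv"
        write_census_csv(census, out)
        df = pd.read_csv(out)
        assert list(df.columns) == ["replicate", "bin", "state", "count"]
        assert len(df) == 2 * census.n_bins * len(census.labels)
        per_bin = df.groupby(["replicate", "bin"])["count"].sum().unstack().values
        np.testing.assert_allclose(per_bin, census.bin_counts)
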