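"""Generator contracts: determinism, identifiability, domain safety."""

import numpy as np
import pytest

from laborcast.cohort_engine import N_AGES
from laborcast.labor_supply import fit_lfpr_model
from laborcast.rate_surfaces import DomainError, fit_pca, transform
from laborcast.synthetic_data import (
    ComponentSpec,
    CovariateProcess,
    FactorSpec,
    LFPRTruth,
    PyramidParams,
    SyntheticConfig,
    child_rng,
    generate_base_population,
    generate_immigration_totals,
    generate_lfpr_history,
    generate_rate_history,
)


def one_factor_config(noise_sd=0.0, n_years=30, phi=(0.8,), seed=0):
    ages = np.arange(10)
    spec = ComponentSpec(
        ages=ages,
        transform_kind="logit",
        mean_profile=np.zeros(10),
        loadings=np.linspace(0.5, 1.5, 10)[:, None],
        factors=(FactorSpec(kind="ar", phi=phi, sigma=0.5),),
        noise_sd=noise_sd,
    )
    return SyntheticConfig(
        n_years=n_years, seed=seed, components={"emigration": spec}
    )


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = SyntheticConfig(seed=11)
        a = generate_rate_history(cfg, "fertility", ("f", "german"))
        b = generate_rate_history(cfg, "fertility", ("f", "german"))
        assert np.array_equal(a.values, b.values)

    def test_different_seeds_differ(self):
        a = generate_rate_history(SyntheticConfig(seed=1), "fertility", ("f", "german"))
        b = generate_rate_history(SyntheticConfig(seed=2), "fertility", ("f", "german"))
        assert not np.array_equal(a.values, b.values)

    def test_strata_have_independent_child_streams(self):
        cfg = SyntheticConfig(seed=5)
        a = generate_rate_history(cfg, "fertility", ("f", "german"))
        b = generate_rate_history(cfg, "fertility", ("f", "foreign"))
        assert not np.array_equal(a.values, b.values)

    def test_lfpr_reproducible(self):
        cfg = SyntheticConfig(seed=9)
        g = next(iter(cfg.lfpr_truth))
        s1, p1 = generate_lfpr_history(cfg, g)
        s2, p2 = generate_lfpr_history(cfg, g)
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())


class TestIdentifiability:
    def test_noiseless_single_factor_recovered_by_pca(self):
        cfg = one_factor_config(noise_sd=0.0)
        surface = generate_rate_history(cfg, "emigration", ("m", "german"))
        # regenerate the latent path with the documented child-seed rule
        rng = child_rng(cfg.seed, "emigration", "m", "german")
        truth = cfg.components["emigration"].factors[0].simulate(cfg.n_years, rng)
        d = fit_pca(transform(surface), standardize=False)
        corr = np.corrcoef(truth, d.scores[:, 0])[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_noiseless_surface_has_rank_one_spectrum(self):
        cfg = one_factor_config(noise_sd=0.0)
        surface = generate_rate_history(cfg, "emigration", ("m", "german"))
        d = fit_pca(transform(surface), standardize=False)
        assert d.eigenvalues[0] > 1e-6
        assert np.all(d.eigenvalues[1:] < 1e-8)

    def test_two_factor_spectrum_against_eigendecomposition_oracle(self):
        # two AR(1) factors (phi 0.8 and 0.3) over 200 years with noise 0.05:
        # exactly 2 sample eigenvalues sit above the noise floor
        ages = np.arange(10)
        loadings = np.column_stack(
            [np.linspace(0.5, 1.5, 10), np.r_[np.ones(5), -np.ones(5)]]
        )
        spec = ComponentSpec(
            ages=ages,
            transform_kind="logit",
            mean_profile=np.zeros(10),
            loadings=loadings,
            factors=(
                FactorSpec(kind="ar", phi=(0.8,), sigma=0.5),
                FactorSpec(kind="ar", phi=(0.3,), sigma=0.5),
            ),
            noise_sd=0.05,
        )
        cfg = SyntheticConfig(n_years=200, seed=4, components={"emigration": spec})
        surface = generate_rate_history(cfg, "emigration", ("m", "german"))
        Z = transform(surface)
        # oracle: brute-force eigendecomposition of the sample covariance
        ev = np.sort(np.linalg.eigvalsh(np.cov(Z, rowvar=False, ddof=1)))[::-1]
        noise_floor = 10.0 * 0.05**2
        assert np.sum(ev > noise_floor) == 2
        d = fit_pca(Z, standardize=False)
        assert d.eigenvalues[: ev.size] == pytest.approx(ev, abs=1e-8)


class TestDomainSafety:
    def test_all_default_surfaces_pass_transform_checks(self):
        cfg = SyntheticConfig(seed=21)
        for comp in cfg.components:
            surface = generate_rate_history(cfg, comp, ("f", "foreign"))
            Z = transform(surface)  # raises on any domain violation
            assert np.all(np.isfinite(Z))

    def test_domain_violation_aborts_with_cell(self):
        ages = np.arange(5)
        q = np.full(5, 1e-4)
        spec = ComponentSpec(
            ages=ages,
            transform_kind="log_survival",
            mean_profile=np.log1p(-q),
            loadings=np.full((5, 1), 0.5),
            factors=(FactorSpec(kind="ar", phi=(0.5,), sigma=2.0),),
            noise_sd=0.0,
        )
        cfg = SyntheticConfig(n_years=50, seed=0, components={"mortality": spec})
        with pytest.raises(DomainError, match="age="):
            generate_rate_history(cfg, "mortality", ("f", "german"))

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError, match="n_years"):
            SyntheticConfig(n_years=5)
        ages = np.arange(4)
        with pytest.raises(ValueError, match="rank"):
            ComponentSpec(
                ages=ages,
                transform_kind="logit",
                mean_profile=np.zeros(4),
                loadings=np.ones((4, 2)),  # rank 1
                factors=(FactorSpec(), FactorSpec()),
                noise_sd=0.0,
            ).validate()


class TestBasePopulation:
    def test_uniform_pyramid_cell_totals(self):
        cfg = SyntheticConfig(
            seed=0, pyramid=PyramidParams(total=9100.0, shape="uniform")
        )
        pop = generate_base_population(cfg)
        by_age = pop.counts.sum(axis=(1, 2))
        assert by_age == pytest.approx(np.full(N_AGES, 100.0))

    def test_total_conserved(self):
        cfg = SyntheticConfig(seed=0)
        pop = generate_base_population(cfg)
        assert pop.counts.sum() == pytest.approx(cfg.pyramid.total, rel=1e-12)

    def test_stratum_shares_exact(self):
        cfg = SyntheticConfig(
            seed=0, pyramid=PyramidParams(total=1e6, german_share=0.9)
        )
        pop = generate_base_population(cfg)
        share = pop.total("german") / pop.total()
        assert share == pytest.approx(0.9, abs=1e-9)

    def test_negative_total_rejected(self):
        cfg = SyntheticConfig(seed=0, pyramid=PyramidParams(total=-1.0))
        with pytest.raises(ValueError):
            generate_base_population(cfg)


class TestLFPRGeneration:
    def test_noiseless_recovery_through_regression(self):
        cfg = SyntheticConfig(seed=3, lfpr_noise_sd=0.0)
        group = next(iter(cfg.lfpr_truth))
        truth = cfg.lfpr_truth[group]
        ser, panel = generate_lfpr_history(cfg, group)
        m = fit_lfpr_model(
            ser.to_numpy(),
            panel.drop(columns=["indicator"]),
            panel["indicator"].to_numpy(),
        )
        assert m.b0 == pytest.approx(truth.b0, abs=1e-8)
        assert m.b1[0] == pytest.approx(truth.b1[0], abs=1e-8)
        assert m.c == pytest.approx(truth.c, abs=1e-8)

    def test_zero_indicator_coefficient_makes_series_independent_of_u(self):
        base = dict(seed=6, lfpr_noise_sd=0.01)
        g = ("f", "german", "45-49")
        truth = {g: LFPRTruth(b0=0.2, b1=(0.01,), c=0.0)}
        cfg_a = SyntheticConfig(lfpr_truth=dict(truth), **base)
        cfg_b = SyntheticConfig(
            lfpr_truth=dict(truth),
            indicator_process=CovariateProcess(start=20.0, slope=0.3, phi=0.5, sigma=2.0),
            **base,
        )
        sa, pa = generate_lfpr_history(cfg_a, g)
        sb, pb = generate_lfpr_history(cfg_b, g)
        assert not np.array_equal(pa["indicator"], pb["indicator"])
        assert np.array_equal(sa.to_numpy(), sb.to_numpy())

    def test_all_zero_coefficients_give_one_half(self):
        g = ("m", "german", "15-19")
        cfg = SyntheticConfig(
            seed=1,
            lfpr_noise_sd=0.0,
            lfpr_truth={g: LFPRTruth(b0=0.0, b1=(0.0,), c=0.0)},
        )
        ser, _ = generate_lfpr_history(cfg, g)
        assert ser.to_numpy() == pytest.approx(0.5)

    def test_rates_in_unit_interval(self):
        cfg = SyntheticConfig(seed=8)
        for g in cfg.lfpr_truth:
            ser, _ = generate_lfpr_history(cfg, g)
            assert np.all(ser > 0.0) and np.all(ser < 1.0)


class TestImmigrationTotals:
    def test_positive_and_reproducible(self):
        cfg = SyntheticConfig(seed=2)
        a = generate_immigration_totals(cfg, "foreign")
        b = generate_immigration_totals(cfg, "foreign")
        assert np.array_equal(a.to_numpy(), b.to_numpy())
        assert np.all(a > 0.0)

    def test_level_matches_configuration_scale(self):
        cfg = SyntheticConfig(seed=2)
        ser = generate_immigration_totals(cfg, "foreign")
        level = cfg.immigration_levels["foreign"]
        assert 0.3 * level < ser.mean() < 3.0 * level
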