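import math

import numpy as np
import pytest

from ptscreen import (
    FitResult,
    MixtureSpec,
    ScreeningConfig,
    alpha_validity_filter,
    fit_dataset,
    retention_percentage,
    screen,
    screen_combined,
    screen_conventional,
    simulate_mixture,
    threshold_sweep,
)

from conftest import power_law_curve
from ptscreen.fitting import fit_log_linear


def make_fit(R2=0.9, RSS=1.0, alpha_star=0.8, unfit=False, n=50):
    nan = float("nan")
    return FitResult(
        method="log_linear",
        D_hat=nan if unfit else 0.1,
        alpha_hat=nan if unfit else alpha_star,
        alpha_star=nan if unfit else alpha_star,
        R2=nan if unfit else R2,
        RSS=nan if unfit else RSS,
        TSS=nan if unfit else RSS / max(1e-9, (1 - R2)) if R2 < 1 else RSS,
        RMSE=nan if unfit else math.sqrt(RSS / n),
        n_points=n,
        converged=not unfit,
        unfit=unfit,
    )


def random_fit_set(rng, n=50):
    return [
        make_fit(
            R2=float(rng.uniform(0, 1)),
            RSS=float(rng.lognormal(0.0, 2.0)),
            alpha_star=float(rng.uniform(0, 1.5)),
            unfit=bool(rng.random() < 0.05),
        )
        for _ in range(n)
    ]


class TestConventional:
    def test_threshold_keeps_high_r2(self):
        fits = [make_fit(R2=0.95), make_fit(R2=0.4)]
        out = screen_conventional(fits, ScreeningConfig(r2_min=0.5))
        assert out.n_kept == 1
        assert out.reasons == ["none", "low_r2"]

    def test_zero_threshold_keeps_all_alpha_valid(self):
        fits = [make_fit(R2=0.0, alpha_star=a) for a in (0.1, 0.5, 1.0)]
        fits.append(make_fit(R2=0.9, alpha_star=1.3))
        out = screen_conventional(fits, ScreeningConfig(r2_min=0.0))
        assert out.n_kept == 3
        assert out.reasons[-1] == "alpha_superdiffusive"

    def test_retention_non_increasing_in_r2_min(self, rng):
        fits = random_fit_set(rng, n=200)
        kept = [
            screen_conventional(fits, ScreeningConfig(r2_min=t)).n_kept
            for t in np.linspace(0, 0.9, 10)
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_empty_input(self):
        out = screen_conventional([], ScreeningConfig())
        assert out.n_total == 0 and math.isnan(out.retention_pct)


class TestCombined:
    def test_flat_adhesive_particle_kept_via_rss(self):
        out = screen_combined([make_fit(R2=0.05, RSS=0.3)])
        assert out.n_kept == 1

    def test_erratic_particle_discarded(self):
        out = screen_combined([make_fit(R2=0.2, RSS=20.0)])
        assert out.n_kept == 0
        assert out.reasons == ["erratic_high_rss"]

    def test_diffusive_particle_kept_via_r2(self):
        out = screen_combined([make_fit(R2=0.95, RSS=8.0)])
        assert out.n_kept == 1

    def test_conventional_subset_of_combined(self, rng):
        for _ in range(20):
            fits = random_fit_set(rng)
            cfg = ScreeningConfig(
                r2_min=float(rng.uniform(0, 1)),
                rss_max=float(rng.lognormal(0, 1)),
            )
            conv = screen_conventional(fits, cfg).kept
            comb = screen_combined(fits, cfg).kept
            assert np.all(comb[conv])  # every conventional keep also kept

    def test_retention_non_decreasing_in_rss_max(self, rng):
        fits = random_fit_set(rng, n=200)
        kept = [
            screen_combined(fits, ScreeningConfig(rss_max=m)).n_kept
            for m in (0.1, 1.0, 5.0, 50.0)
        ]
        assert all(a <= b for a, b in zip(kept, kept[1:]))

    def test_rmse_thresholding_option(self):
        fit = make_fit(R2=0.1, RSS=10.0, n=1000)  # RMSE = 0.1
        cfg = ScreeningConfig(rss_max=0.5, rss_metric="rmse")
        assert screen_combined([fit], cfg).n_kept == 1


class TestStrictAnd:
    def test_requires_both(self):
        fits = [
            make_fit(R2=0.9, RSS=1.0),   # both pass
            make_fit(R2=0.9, RSS=20.0),  # RSS fails
            make_fit(R2=0.1, RSS=1.0),   # R2 fails
        ]
        out = screen(fits, ScreeningConfig(mode="strict_and"))
        assert list(out.kept) == [True, False, False]


class TestAlphaValidity:
    def test_superdiffusive_discarded(self):
        flags = alpha_validity_filter([make_fit(alpha_star=1.2)])
        assert not flags[0]

    def test_boundary_inclusive(self):
        flags = alpha_validity_filter([make_fit(alpha_star=1.1)])
        assert flags[0]

    def test_clamped_immobile_kept(self):
        flags = alpha_validity_filter([make_fit(alpha_star=0.0)])
        assert flags[0]

    def test_unfit_counted_separately(self):
        fits = [make_fit(), make_fit(unfit=True)]
        out = screen_combined(fits)
        assert out.reasons == ["none", "unfit"]
        assert out.summary()["discard_counts"] == {"unfit": 1}


class TestRetentionPercentage:
    @pytest.mark.parametrize("kept,total,expected", [
        (6681, 6965, 95.9),
        (1113, 1167, 95.4),
        (0, 100, 0.0),
        (100, 100, 100.0),
    ])
    def test_values(self, kept, total, expected):
        assert retention_percentage(kept, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            retention_percentage(0, 0)
        with pytest.raises(ValueError):
            retention_percentage(5, 4)


class TestThresholdSweep:
    def test_zero_grid_reproduces_unscreened(self):
        # noiseless power laws: all alpha-valid, R2 = 1 everywhere
        curves = [power_law_curve(d, a, particle_id=i)
                  for i, (d, a) in enumerate(
                      [(0.1, 0.3), (0.5, 0.8), (1.0, 1.0)], start=1)]
        fits = [fit_log_linear(c) for c in curves]
        table = threshold_sweep(fits, [0.0], reference_D=1.0)
        row = table.iloc[0]
        assert row["pct"] == 100.0
        assert row["alpha"] == pytest.approx(np.mean([0.3, 0.8, 1.0]),
                                             abs=1e-9)

    def test_mixture_alpha_non_decreasing_and_inclusion(self):
        ds, _ = simulate_mixture(MixtureSpec(n_particles=2000, seed=3))
        fits = fit_dataset(ds)
        grid = [i / 10 for i in range(10)]
        table = threshold_sweep(fits, grid, reference_D=5.0,
                                statistic="mean")
        alphas = table["alpha"].to_numpy()[:10]
        assert np.all(np.diff(alphas) >= 0)
        # combined row retains at least as many as any conventional row
        # with r2_min >= 0.1
        combined_n = table.iloc[-1]["n"]
        assert (table.iloc[1:10]["n"] <= combined_n).all()

    def test_sweep_table_shape(self):
        ds, _ = simulate_mixture(MixtureSpec(n_particles=50, seed=1))
        fits = fit_dataset(ds)
        table = threshold_sweep(fits, [0.0, 0.5], reference_D=5.0)
        assert list(table.columns) == ["approach", "alpha", "D_over_Dref",
                                       "n", "pct"]
        assert list(table["approach"]) == ["R2>=0", "R2>=0.5", "R2+RSS"]


class TestMixtureSubpopulations:
    def test_combined_keeps_adhesive_conventional_drops_them(self):
        ds, labels = simulate_mixture(MixtureSpec(n_particles=400, seed=9))
        fits = fit_dataset(ds)
        lab = labels.set_index(["video_id", "particle_id"])["label"]
        is_adh = np.array(
            [lab.loc[(c.video_id, c.particle_id)] == "adhesive"
             for c in ds.curves]
        )
        cfg = ScreeningConfig(r2_min=0.5, rss_max=5.0)
        comb = screen_combined(fits, cfg).kept
        conv = screen_conventional(fits, cfg).kept
        assert comb[is_adh].mean() >= 0.90
        assert conv[is_adh].mean() <= 0.20


class TestConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ScreeningConfig(r2_min=1.5)
        with pytest.raises(ValueError):
            ScreeningConfig(rss_max=-1.0)
        with pytest.raises(ValueError):
            ScreeningConfig(alpha_max=0.0, alpha_min=0.5)
        with pytest.raises(ValueError):
            ScreeningConfig(mode="bogus")
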