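"""Heritability estimation and variance partitioning against simulation truth."""

import numpy as np
import pandas as pd
import pytest

from rosettrack.devtime import RelativeCurve, assemble_phenotype_table
from rosettrack.genetics import (
    estimate_h2,
    h2_trajectory,
    trait_correlation,
    variance_partition,
)


def one_way_sample(rng, n_geno, n_rep, sigma_g, sigma_e):
    g = np.repeat(rng.normal(0, sigma_g, n_geno), n_rep)
    labels = np.repeat([f"G{i}" for i in range(n_geno)], n_rep)
    return g + rng.normal(0, sigma_e, n_geno * n_rep), labels


class TestEstimateH2:
    def test_no_residual_variance_gives_one(self):
        y = np.repeat([1.0, 2.0, 3.0], 4)
        g = np.repeat(list("abc"), 4)
        assert estimate_h2(y, g).h2 >= 0.999

    def test_null_case_near_zero(self):
        rng = np.random.default_rng(0)
        y, g = one_way_sample(rng, 50, 10, sigma_g=0.0, sigma_e=1.0)
        assert estimate_h2(y, g).h2 <= 0.05

    def test_known_components_recovered(self):
        # sigma2_G = 4, sigma2_E = 1 -> H2 = 0.8
        ests = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            y, g = one_way_sample(rng, 50, 10, sigma_g=2.0, sigma_e=1.0)
            ests.append(estimate_h2(y, g).h2)
        assert abs(np.mean(ests) - 0.80) < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        y, g = one_way_sample(rng, 10, 5, 1.0, 1.0)
        h = estimate_h2(y, g).h2
        assert estimate_h2(7.0 * y - 3.0, g).h2 == pytest.approx(h, abs=1e-6)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            estimate_h2([1.0, 2.0], ["a", "a"])  # single genotype
        with pytest.raises(ValueError):
            estimate_h2([1.0, 2.0], ["a", "b"])  # no replication anywhere


def _table_with_h2(rng, h2, n_geno=20, n_rep=5, grid_size=5):
    sigma_g, sigma_e = np.sqrt(h2), np.sqrt(1 - h2)
    grid = np.linspace(0, 1, grid_size)
    curves, meta = [], {}
    g_eff = rng.normal(0, sigma_g, n_geno)
    for gi in range(n_geno):
        for ri in range(n_rep):
            pid = f"g{gi}r{ri}"
            vals = g_eff[gi] + rng.normal(0, sigma_e, grid_size)
            curves.append(RelativeCurve(pid, "RA", grid, vals))
            meta[pid] = {"accession": f"acc{gi}", "environment": "E"}
    return assemble_phenotype_table(curves, meta)


class TestTrajectory:
    def test_constant_h2_recovered_in_median(self):
        table = _table_with_h2(np.random.default_rng(1), 0.8, n_geno=50, n_rep=10,
                               grid_size=7)
        _, summary = h2_trajectory(table, "RA")
        assert abs(summary["median"] - 0.8) < 0.1

    def test_single_grid_point(self):
        rng = np.random.default_rng(2)
        g_eff = np.repeat(rng.normal(0, 1, 10), 5)
        table = pd.DataFrame({
            "plant_id": [f"p{i}" for i in range(50)],
            "accession": np.repeat([f"acc{i}" for i in range(10)], 5),
            "environment": "E", "trait": "RA",
            "g000": g_eff + rng.normal(0, 1, 50),
        })
        estimates, summary = h2_trajectory(table, "RA")
        assert len(estimates) == 1
        assert summary["median"] == estimates[0].h2

    def test_ramp_tracked_in_rank_order(self):
        rng = np.random.default_rng(4)
        grid_size, n_geno, n_rep = 8, 60, 10
        truth = np.linspace(0.2, 0.9, grid_size)
        grid = np.linspace(0, 1, grid_size)
        curves, meta = [], {}
        g_eff = rng.normal(0, 1, n_geno)
        for gi in range(n_geno):
            for ri in range(n_rep):
                pid = f"g{gi}r{ri}"
                vals = np.array([
                    np.sqrt(h) * g_eff[gi] + np.sqrt(1 - h) * rng.normal()
                    for h in truth
                ])
                curves.append(RelativeCurve(pid, "RA", grid, vals))
                meta[pid] = {"accession": f"acc{gi}", "environment": "E"}
        table = assemble_phenotype_table(curves, meta)
        estimates, _ = h2_trajectory(table, "RA")
        est = np.array([e.h2 for e in estimates])
        rank_corr = pd.Series(est).corr(pd.Series(truth), method="spearman")
        assert rank_corr > 0.9

    def test_unknown_trait_rejected(self):
        table = _table_with_h2(np.random.default_rng(5), 0.5, grid_size=2)
        with pytest.raises(ValueError):
            h2_trajectory(table, "bolting")


def exact_effects(levels, var):
    e = np.arange(levels, dtype=float)
    e -= e.mean()
    return e * np.sqrt(var / np.mean(e ** 2))


def balanced_long(rng, fractions, n_env=2, n_dev=3, n_geno=10, n_rep=20):
    e_eff = exact_effects(n_env, fractions["env"])
    d_eff = exact_effects(n_dev, fractions["dev"])
    g_eff = exact_effects(n_geno, fractions["geno"])
    n = n_env * n_dev * n_geno * n_rep
    resid = rng.normal(size=n)
    resid = (resid - resid.mean()) / resid.std() * np.sqrt(fractions["resid"])
    rows, i = [], 0
    for E in range(n_env):
        for D in range(n_dev):
            for G in range(n_geno):
                for _ in range(n_rep):
                    rows.append({
                        "environment": f"E{E}", "development": f"D{D}",
                        "genotype": f"G{G}",
                        "value": e_eff[E] + d_eff[D] + g_eff[G] + resid[i],
                    })
                    i += 1
    return pd.DataFrame(rows)


class TestVariancePartition:
    def test_pure_genotype_effect(self):
        rows = []
        for E in range(2):
            for D in range(2):
                for G in range(4):
                    for _ in range(3):
                        rows.append({"environment": f"E{E}", "development": f"D{D}",
                                     "genotype": f"G{G}", "value": float(G)})
        vp = variance_partition(pd.DataFrame(rows))
        assert vp.loc["Genotype", "percent_variance"] == pytest.approx(100.0, abs=1e-6)
        others = vp.drop("Genotype")["percent_variance"]
        assert (others.abs() < 1e-6).all()

    def test_known_fractions_recovered(self):
        fr = {"env": 0.05, "dev": 0.40, "geno": 0.35, "resid": 0.20}
        vp = variance_partition(balanced_long(np.random.default_rng(7), fr))
        assert abs(vp.loc["Environment", "percent_variance"] - 5) < 5
        assert abs(vp.loc["Development", "percent_variance"] - 40) < 5
        assert abs(vp.loc["Genotype", "percent_variance"] - 35) < 5
        assert abs(vp.loc["Residual", "percent_variance"] - 20) < 5

    def test_percentages_conserve_total(self):
        fr = {"env": 0.1, "dev": 0.3, "geno": 0.3, "resid": 0.3}
        vp = variance_partition(balanced_long(np.random.default_rng(8), fr, n_rep=5))
        assert vp["percent_variance"].sum() == pytest.approx(100.0, abs=0.1)
        assert (vp["percent_variance"] >= 0).all()

    def test_joint_permutation_invariance(self):
        fr = {"env": 0.1, "dev": 0.3, "geno": 0.3, "resid": 0.3}
        df = balanced_long(np.random.default_rng(9), fr, n_rep=4)
        perm = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        vp1 = variance_partition(df)
        vp2 = variance_partition(perm)
        np.testing.assert_allclose(vp1["percent_variance"], vp2["percent_variance"],
                                   atol=1e-8)

    def test_single_level_factor_rejected(self):
        df = balanced_long(np.random.default_rng(1),
                           {"env": 0.1, "dev": 0.3, "geno": 0.3, "resid": 0.3},
                           n_rep=2)
        df["environment"] = "E0"
        with pytest.raises(ValueError):
            variance_partition(df)


class TestTraitCorrelation:
    def _table(self, rng, rho, n=200, grid_size=4):
        grid = np.linspace(0, 1, grid_size)
        curves, meta = [], {}
        for i in range(n):
            a = rng.normal(size=grid_size)
            noise = rng.normal(size=grid_size)
            b = rho * a + np.sqrt(1 - rho ** 2) * noise
            curves.append(RelativeCurve(f"p{i}", "RA", grid, a))
            curves.append(RelativeCurve(f"p{i}", "CA", grid, b))
            meta[f"p{i}"] = {"accession": "x", "environment": "E"}
        return assemble_phenotype_table(curves, meta)

    def test_self_correlation_is_one(self):
        table = self._table(np.random.default_rng(0), rho=0.5)
        dup = table.copy()
        dup.loc[dup["trait"] == "CA", table.columns[4:]] = \
            table.loc[table["trait"] == "RA", table.columns[4:]].to_numpy()
        out, summary = trait_correlation(dup, "RA", "CA")
        np.testing.assert_allclose(out["r"], 1.0, atol=1e-12)

    def test_independent_traits_near_zero(self):
        table = self._table(np.random.default_rng(1), rho=0.0)
        out, _ = trait_correlation(table, "RA", "CA")
        assert (out["r"].abs() < 0.2).all()

    def test_target_correlation_recovered(self):
        rs = []
        for rep in range(20):
            table = self._table(np.random.default_rng(100 + rep), rho=0.7)
            out, _ = trait_correlation(table, "RA", "CA")
            rs.extend(out["r"].tolist())
        assert abs(np.mean(rs) - 0.7) < 0.05

    def test_zero_variance_point_is_nan(self):
        table = self._table(np.random.default_rng(2), rho=0.5, n=10)
        col = "g000"
        table.loc[table["trait"] == "RA", col] = 1.0
        out, _ = trait_correlation(table, "RA", "CA")
        assert np.isnan(out["r"].iloc[0])
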