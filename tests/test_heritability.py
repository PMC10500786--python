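"""Variance-component heritability: likelihood, oracle equivalence, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import famres as fr
from famres.heritability import (
    HeritabilityError,
    VCModelSpec,
    _design_matrix,
    build_covariance,
    fit_vc,
    h2_table,
    profile_loglik,
)
from famres.pedigree import Individual, Pedigree, kinship
from famres.simulate import SimConfig, simulate_latent, simulate_pedigree
from famres.traits import TraitTable

INT_PROV = [{"step": "inverse_normal_transform"}]


def sib_pair_pedigree(n_pairs):
    inds = []
    for f in range(n_pairs):
        fid = f"F{f}"
        inds += [
            Individual(fid, "p", sex="male"), Individual(fid, "m", sex="female"),
            Individual(fid, "a", "p", "m", "male"),
            Individual(fid, "b", "p", "m", "female"),
        ]
    return Pedigree(inds)


def sib_pair_traits(n_pairs, h2, rng):
    """Values only for the sibs; parents stay unphenotyped."""
    rho = h2 / 2.0
    chol = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
    vals = rng.standard_normal((n_pairs, 2)) @ chol.T
    rows = []
    for f in range(n_pairs):
        rows.append((f"F{f}", "a", "male", 30.0, vals[f, 0]))
        rows.append((f"F{f}", "b", "female", 28.0, vals[f, 1]))
    df = pd.DataFrame(rows, columns=["fid", "iid", "sex", "age", "y"])
    return TraitTable(values=df, units={"y": "sd"}, provenance=list(INT_PROV)), vals


def latent_trait_table(sim, values):
    df = pd.DataFrame({
        "fid": [k[0] for k in sim.index],
        "iid": [k[1] for k in sim.index],
        "sex": sim.sex,
        "age": 2024.0 - sim.birth_year,
        "y": values,
    })
    return TraitTable(values=df, units={"y": "sd"}, provenance=list(INT_PROV))


class TestBuildCovariance:
    def test_unrelated_individuals_scaled_half_diagonal(self):
        ped = Pedigree([Individual("F", str(i)) for i in range(3)])
        cov = build_covariance(kinship(ped), scale=2.0)
        _, a, w, _ = cov.blocks["F"]
        assert np.allclose(a, np.eye(3))  # 2 * 0.5 on the diagonal
        assert np.allclose(sorted(w), 1.0)

    def test_full_sib_off_diagonal(self, nuclear_ped):
        cov = build_covariance(kinship(nuclear_ped), scale=2.0)
        iids, a, _, _ = cov.blocks["N"]
        i, j = iids.index("son"), iids.index("dau")
        assert a[i, j] == pytest.approx(0.5)

    def test_eigendecomposition_reconstructs_block(self, three_gen_ped):
        cov = build_covariance(kinship(three_gen_ped))
        _, a, w, u = cov.blocks["T"]
        assert np.allclose(u @ np.diag(w) @ u.T, a, atol=1e-12)
        assert w.min() >= 0.0

    def test_nonpositive_scale_rejected(self, nuclear_ped):
        with pytest.raises(HeritabilityError):
            build_covariance(kinship(nuclear_ped), scale=0.0)


class TestLikelihood:
    def test_matches_dense_multivariate_normal(self, rng):
        """Block-rotated fast path vs dense MVN log-density, tol 1e-8."""
        cfg = SimConfig(n_families=8, seed=31, singleton_fraction=0.2)
        sim = simulate_pedigree(cfg)
        tt = latent_trait_table(sim, simulate_latent(sim, cfg, 0.3, rng))
        kin = kinship(sim.pedigree)
        spec = VCModelSpec(trait="y")
        for h2 in (0.05, 0.3, 0.7, 0.95):
            ll, beta, s2 = profile_loglik(spec, tt, kin, h2)
            dense = 0.0
            for fid, sub in tt.values.groupby("fid", sort=False):
                iids, phi = kin.block(fid)
                pos = {iid: k for k, iid in enumerate(iids)}
                sel = [pos[i] for i in sub["iid"]]
                a = 2.0 * phi[np.ix_(sel, sel)]
                v = s2 * (h2 * a + (1 - h2) * np.eye(len(sel)))
                x = _design_matrix(sub, spec.fixed)
                dense += multivariate_normal.logpdf(
                    sub["y"].to_numpy(), mean=x @ beta, cov=v
                )
            assert ll == pytest.approx(dense, abs=1e-8)

    def test_h2_invariant_to_affine_trait_rescaling(self, rng):
        cfg = SimConfig(n_families=120, seed=37)
        sim = simulate_pedigree(cfg)
        values = simulate_latent(sim, cfg, cfg.h2, rng)
        kin = kinship(sim.pedigree)
        base = fit_vc(VCModelSpec(trait="y"), latent_trait_table(sim, values), kin)
        scaled = fit_vc(
            VCModelSpec(trait="y"),
            latent_trait_table(sim, 7.3 * values - 2.0),
            kin,
        )
        assert scaled.h2 == pytest.approx(base.h2, abs=1e-5)
        assert scaled.sigma2_g == pytest.approx(7.3**2 * base.sigma2_g, rel=1e-4)

    def test_reml_close_to_ml_at_moderate_n(self, rng):
        cfg = SimConfig(n_families=200, seed=41)
        sim = simulate_pedigree(cfg)
        tt = latent_trait_table(sim, simulate_latent(sim, cfg, cfg.h2, rng))
        kin = kinship(sim.pedigree)
        ml = fit_vc(VCModelSpec(trait="y", estimator="ML"), tt, kin)
        reml = fit_vc(VCModelSpec(trait="y", estimator="REML"), tt, kin)
        assert reml.h2 == pytest.approx(ml.h2, abs=0.02)


class TestFitVC:
    def test_sib_pairs_closed_form_relation(self):
        """ML h2 from sib pairs equals 2 x (sib correlation), recovering 0.4."""
        n_pairs, h2_true = 1000, 0.4
        ped = sib_pair_pedigree(n_pairs)
        kin = kinship(ped)
        ests, icc_relation = [], []
        for s in range(30):
            rng = np.random.default_rng(600 + s)
            tt, vals = sib_pair_traits(n_pairs, h2_true, rng)
            fit = fit_vc(VCModelSpec(trait="y", fixed=()), tt, kin)
            ests.append(fit.h2)
            from oracles import double_entry_pearson

            icc_relation.append(abs(fit.h2 - 2 * double_entry_pearson(
                vals[:, 0], vals[:, 1]
            )))
        assert np.mean(ests) == pytest.approx(h2_true, abs=0.03)
        assert np.mean(icc_relation) < 0.02  # ML ~ 2 x double-entry ICC

    def test_null_trait_estimates_near_zero(self):
        cfg = SimConfig(n_families=1000, seed=43, generations=2,
                        h2=0.0, c_spouse=0.0, c_house=0.0)
        ests = []
        for s in range(20):
            rng = np.random.default_rng(700 + s)
            sim = simulate_pedigree(
                SimConfig(n_families=1000, seed=700 + s, generations=2,
                          h2=0.0, c_spouse=0.0, c_house=0.0))
            tt = latent_trait_table(sim, simulate_latent(sim, cfg, 0.0, rng))
            fit = fit_vc(VCModelSpec(trait="y", fixed=()), tt,
                         kinship(sim.pedigree))
            ests.append(fit.h2)
        assert np.mean(ests) < 0.025

    def test_boundary_fit_flagged_without_se(self):
        """Negative sib resemblance pushes h2 to the 0 boundary."""
        n_pairs = 200
        ped = sib_pair_pedigree(n_pairs)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(n_pairs)
        rows = []
        for f in range(n_pairs):
            rows.append((f"F{f}", "a", "male", 30.0, x[f]))
            rows.append((f"F{f}", "b", "female", 28.0, -x[f] + 0.05 * rng.standard_normal()))
        tt = TraitTable(
            values=pd.DataFrame(rows, columns=["fid", "iid", "sex", "age", "y"]),
            units={"y": "sd"}, provenance=list(INT_PROV),
        )
        fit = fit_vc(VCModelSpec(trait="y", fixed=()), tt, kinship(ped))
        assert fit.boundary and fit.se_h2 is None
        assert fit.h2 == pytest.approx(0.0, abs=1e-5)

    def test_spousal_environment_inflates_h2(self):
        """Shared couple/household environment absent from the model confounds
        upward: family-based h2 exceeds the generating value."""
        ests = []
        for s in range(10):
            cfg = SimConfig(n_families=1000, seed=800 + s, generations=2,
                            h2=0.2, c_spouse=0.3, c_house=0.25)
            rng = np.random.default_rng(900 + s)
            sim = simulate_pedigree(cfg, rng)
            tt = latent_trait_table(sim, simulate_latent(sim, cfg, cfg.h2, rng))
            ests.append(
                fit_vc(VCModelSpec(trait="y", fixed=()), tt,
                       kinship(sim.pedigree)).h2
            )
        assert np.mean(ests) > 0.3  # well above the generating 0.2

    def test_too_few_informative_pairs_rejected(self):
        ped = Pedigree([Individual("A", "1"), Individual("B", "1"),
                        Individual("C", "1")])
        df = pd.DataFrame({
            "fid": ["A", "B", "C"], "iid": ["1", "1", "1"],
            "sex": ["male", "female", "male"], "age": [40.0, 41, 42],
            "y": [0.1, -0.2, 0.3],
        })
        tt = TraitTable(values=df, units={"y": "sd"}, provenance=list(INT_PROV))
        with pytest.raises(HeritabilityError, match="informative"):
            fit_vc(VCModelSpec(trait="y", fixed=()), tt, kinship(ped))


class TestH2Table:
    def test_single_trait_matches_fit(self, rng):
        cfg = SimConfig(n_families=150, seed=47)
        sim = simulate_pedigree(cfg)
        tt = latent_trait_table(sim, simulate_latent(sim, cfg, cfg.h2, rng))
        kin = kinship(sim.pedigree)
        spec = VCModelSpec(trait="y", fixed=())
        fit = fit_vc(spec, tt, kin)
        table = h2_table([spec], tt, kin)
        assert table.loc[0, "h2_percent"] == pytest.approx(100 * fit.h2, abs=0.05)
        assert bool(table.loc[0, "converged"])

    def test_zero_variance_trait_flagged_failed(self):
        ped = sib_pair_pedigree(5)
        rows = [(f"F{f}", m, "male", 30.0, 1.0) for f in range(5) for m in "ab"]
        tt = TraitTable(
            values=pd.DataFrame(rows, columns=["fid", "iid", "sex", "age", "y"]),
            units={"y": "sd"}, provenance=list(INT_PROV),
        )
        table = h2_table([VCModelSpec(trait="y", fixed=())], tt, kinship(ped))
        assert not table.loc[0, "converged"]
        assert "variance" in table.loc[0, "error"]

    def test_well_separated_h2_levels_ordered(self):
        """Estimated h2 preserves the generating order for separated levels."""
        levels = (0.05, 0.2, 0.5)
        monotone = 0
        reps = 10
        for s in range(reps):
            cfg0 = SimConfig(n_families=800, seed=1100 + s, generations=2,
                             c_spouse=0.0, c_house=0.0)
            rng = np.random.default_rng(1200 + s)
            sim = simulate_pedigree(cfg0, rng)
            kin = kinship(sim.pedigree)
            ests = []
            for h2 in levels:
                tt = latent_trait_table(sim, simulate_latent(sim, cfg0, h2, rng))
                ests.append(fit_vc(VCModelSpec(trait="y", fixed=()), tt, kin).h2)
            monotone += ests[0] < ests[1] < ests[2]
        assert monotone >= 8
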