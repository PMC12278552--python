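"""Estimation core: relationship algebra, likelihood, BLUP, REML fit.

Small instances are checked against dense brute-force oracles (tabular
relationship matrix, dense-V likelihood and GLS/BLUP); the fit is checked
against grid search of the restricted likelihood around its optimum.
"""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import igesim
from igesim import (
    a_inverse,
    blup,
    build_design,
    reml_fit,
    restricted_loglik,
)
from igesim.reml import (
    REMLOptions,
    _ArrowFactor,
    _Factor,
    _MMEWorkspace,
    _traces_exact,
)
from igesim.scenarios import ScenarioConfig, VarianceComponents

from conftest import (
    dense_blup,
    dense_restricted_loglik,
    dense_tabular_A,
    psd_candidate,
)


def _small_config(n_herds=2, herd_size=15, **kw):
    """Miniature study design: sparse contacts (mean 5), few sires."""
    vc = kw.pop("vc", igesim.get_scenario(1).vc)
    return ScenarioConfig(
        scenario_id=99,
        n_herds=n_herds,
        herd_size=herd_size,
        vc=vc,
        mean_contacts=5,
        max_contacts=8,
        n_sires=5,
        **kw,
    )


def _toy_fit_config():
    """A 200-cow design in which all five components are well identified:
    denser families (20 sires) and indirect effects carrying the same share
    of phenotypic variance at the toy's contact density (mean 8)."""
    from igesim.scenarios import derive_base_components

    vc = derive_base_components(800, 0.25, 8, 0.20, 0)
    return ScenarioConfig(
        scenario_id=98,
        n_herds=4,
        herd_size=50,
        vc=vc,
        mean_contacts=8,
        max_contacts=12,
        n_sires=20,
    )


class TestAInverse:
    def test_founders_only_identity(self):
        ped = pd.DataFrame(
            {"animal": [1, 2, 3], "sire": 0, "dam": 0, "role": "sire", "herd": 0}
        )
        np.testing.assert_allclose(a_inverse(ped).toarray(), np.eye(3))

    def test_trio(self):
        ped = pd.DataFrame(
            {
                "animal": [1, 2, 3],
                "sire": [0, 0, 1],
                "dam": [0, 0, 2],
                "role": ["sire", "dam", "cow"],
                "herd": [0, 0, 1],
            }
        )
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(a_inverse(ped).toarray(), expected)
        # and the tabular-method A inverts to the same matrix
        np.testing.assert_allclose(
            np.linalg.inv(dense_tabular_A(ped)), expected, atol=1e-12
        )

    def test_henderson_rules_match_tabular_oracle(self, vc1):
        parents, _ = igesim.simulate_parents(80, 20, vc1, 1)
        ped = igesim.assign_matings(parents, 2, 40, 9, 2)
        got = a_inverse(ped).toarray()
        oracle = np.linalg.inv(dense_tabular_A(ped))
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_rejects_child_before_parent(self):
        ped = pd.DataFrame(
            {
                "animal": [1, 2],
                "sire": [2, 0],
                "dam": [0, 0],
                "role": ["cow", "sire"],
                "herd": [1, 0],
            }
        )
        with pytest.raises(ValueError, match="parents-first"):
            a_inverse(ped)


class TestBuildDesign:
    @staticmethod
    def _toy_directed():
        ped = pd.DataFrame(
            {
                "animal": [1, 2, 3],
                "sire": 0,
                "dam": 0,
                "role": "cow",
                "herd": 1,
            }
        )
        phenos = pd.DataFrame({"cow": [1, 2, 3], "herd": 1, "y": [1.0, 2.0, 3.0]})
        edges = pd.DataFrame(
            {
                "herd": [1, 1],
                "source": [2, 3],
                "target": [1, 1],
                "f_true": 1.0,
                "f_analysis": 1.0,
            }
        )
        net = igesim.ContactNetwork(
            directed=True, edges=edges, cow_herd=pd.Series([1, 1, 1], index=[1, 2, 3])
        )
        return phenos, net, ped

    def test_directed_as_simulated(self):
        phenos, net, ped = self._toy_directed()
        spec = build_design(phenos, net, ped, analysis_direction="as_simulated")
        Z = spec.Z_I.toarray()
        np.testing.assert_array_equal(Z, [[0, 1, 1], [0, 0, 0], [0, 0, 0]])
        assert spec.Z_D.toarray().tolist() == np.eye(3).tolist()
        assert (spec.Z_D.toarray().diagonal() == 1).all()

    def test_directed_ignore_direction_symmetrizes(self):
        phenos, net, ped = self._toy_directed()
        spec = build_design(phenos, net, ped, analysis_direction="ignore_direction")
        Z = spec.Z_I.toarray()
        np.testing.assert_array_equal(Z, [[0, 1, 1], [1, 0, 0], [1, 0, 0]])

    def test_row_support_matches_network_degrees(self, tiny_sim, tiny_system):
        spec, _ = tiny_system
        per_row = np.diff(spec.Z_I.tocsr().indptr)
        counts = tiny_sim.network.incoming_counts()
        np.testing.assert_array_equal(
            per_row, counts.loc[tiny_sim.phenotypes["cow"]].to_numpy()
        )

    def test_intensity_selection(self):
        phenos, net, ped = self._toy_directed()
        net.edges["f_true"] = [0.4, 0.8]
        net.edges["f_analysis"] = [0.5, 0.9]
        true_spec = build_design(phenos, net, ped, analysis_intensity="use_true")
        noisy_spec = build_design(phenos, net, ped, analysis_intensity="use_noisy")
        assert sorted(true_spec.Z_I.data.tolist()) == [0.4, 0.8]
        assert sorted(noisy_spec.Z_I.data.tolist()) == [0.5, 0.9]


class TestRestrictedLoglik:
    def test_matches_dense_oracle(self):
        sim = igesim.simulate_replicate(_small_config(), 11)
        spec = build_design(sim.phenotypes, sim.network, sim.pedigree)
        ainv = a_inverse(sim.pedigree)
        for vc in [
            igesim.get_scenario(1).vc,
            VarianceComponents(150000, 5000, 10000, 5000, 80000),
        ]:
            got = restricted_loglik(spec, ainv, vc)
            want = dense_restricted_loglik(spec, ainv, vc)
            assert got == pytest.approx(want, abs=1e-6)

    def test_translation_invariance_within_herd(self):
        sim = igesim.simulate_replicate(_small_config(), 12)
        spec = build_design(sim.phenotypes, sim.network, sim.pedigree)
        ainv = a_inverse(sim.pedigree)
        vc = igesim.get_scenario(1).vc
        base = restricted_loglik(spec, ainv, vc)
        shift = spec.X @ np.array([500.0, -300.0])
        shifted = dataclasses.replace(spec, y=spec.y + shift)
        assert restricted_loglik(shifted, ainv, vc) == pytest.approx(base, abs=1e-6)

    def test_fixed_effects_only_closed_form(self):
        sim = igesim.simulate_replicate(_small_config(), 13)
        spec = build_design(sim.phenotypes, sim.network, sim.pedigree)
        ainv = a_inverse(sim.pedigree)
        s2 = 1.0e5
        got = restricted_loglik(spec, ainv, VarianceComponents(0, 0, 0, 0, s2))
        X = spec.X.toarray()
        beta = np.linalg.lstsq(X, spec.y, rcond=None)[0]
        rss = np.sum((spec.y - X @ beta) ** 2)
        _, ld = np.linalg.slogdet(X.T @ X / s2)
        want = -0.5 * (spec.n * np.log(s2) + ld + rss / s2)
        assert got == pytest.approx(want, abs=1e-8)

    def test_arrow_and_sparse_lu_agree(self, tiny_system):
        spec, ainv = tiny_system
        ws = _MMEWorkspace(spec, ainv)
        assert ws.arrow is not None
        vc = VarianceComponents(150000, 5000, 10000, 5000, 80000)
        f_arrow = _ArrowFactor(ws, vc)
        f_lu = _Factor(ws, vc)
        assert f_arrow.loglik == pytest.approx(f_lu.loglik, abs=1e-6)
        rhs = np.random.default_rng(0).standard_normal(ws.dim)
        np.testing.assert_allclose(f_arrow.solve(rhs), f_lu.solve(rhs), atol=1e-8)

    def test_selected_traces_match_column_solves(self, tiny_system):
        spec, ainv = tiny_system
        ws = _MMEWorkspace(spec, ainv)
        vc = VarianceComponents(150000, 5000, 10000, 5000, 80000)
        fac = _ArrowFactor(ws, vc)
        sel = fac.selected_traces()
        col = _traces_exact(fac)
        for name in ("TDD", "TDI", "TII", "Tee"):
            assert getattr(sel, name) == pytest.approx(getattr(col, name), rel=1e-9)


class TestBlup:
    def test_matches_dense_gls(self):
        sim = igesim.simulate_replicate(_small_config(), 14)
        spec = build_design(sim.phenotypes, sim.network, sim.pedigree)
        ainv = a_inverse(sim.pedigree)
        vc = igesim.get_scenario(1).vc
        ebv, fixed = blup(spec, ainv, vc)
        b, aD, aI, _ = dense_blup(spec, ainv, vc)
        np.testing.assert_allclose(fixed["estimate"], b, atol=1e-6)
        np.testing.assert_allclose(ebv["aD_hat"], aD, atol=1e-6)
        np.testing.assert_allclose(ebv["aI_hat"], aI, atol=1e-6)

    def test_vanishing_genetic_variance_shrinks_ebv_to_zero(self):
        sim = igesim.simulate_replicate(_small_config(), 15)
        spec = build_design(sim.phenotypes, sim.network, sim.pedigree)
        ainv = a_inverse(sim.pedigree)
        tiny = VarianceComponents(1e-6, 1e-6, 0.0, 1e-6, 640_000.0)
        ebv, _ = blup(spec, ainv, tiny)
        assert np.abs(ebv[["aD_hat", "aI_hat"]].to_numpy()).max() < 1e-3

    def test_parents_with_many_offspring_are_predicted_better(self, vc1):
        cfg = igesim.get_scenario(1).scaled(n_herds=10, herd_size=60)
        res = igesim.run_replicate(cfg, 31)
        # sires (~6 offspring each here) must beat dams (single offspring)
        sim = igesim.simulate_replicate(cfg, 31)
        merged = sim.bvs.merge(res.fit.ebv, on="animal").merge(
            sim.pedigree[["animal", "role"]], on="animal"
        )
        dams = merged[merged["role"] == "dam"]
        acc_dam = np.corrcoef(dams["a_D"], dams["aD_hat"])[0, 1]
        assert res.accuracy[("sires", "DGE")] > acc_dam
        assert res.accuracy[("sires", "DGE")] > 0.4


class TestREMLFit:
    @pytest.fixture(scope="class")
    def toy_fit(self):
        cfg = _toy_fit_config()  # 200 phenotyped cows
        sim = igesim.simulate_replicate(cfg, 16)
        spec = build_design(sim.phenotypes, sim.network, sim.pedigree)
        ainv = a_inverse(sim.pedigree)
        fit = reml_fit(spec, ainv)
        return spec, ainv, fit

    def test_converges(self, toy_fit):
        _, _, fit = toy_fit
        assert fit.converged
        assert fit.n_iter <= 120

    def test_argmax_against_grid_search(self, toy_fit):
        spec, ainv, fit = toy_fit
        est = fit.estimates
        # 1-d grids through the optimum: no grid point may beat the argmax
        for name in ("sigma2_aD", "sigma2_aI", "sigma2_eI", "sigma2_e"):
            val = getattr(est, name)
            for fac in (0.7, 0.85, 1.15, 1.3):
                cand = psd_candidate(est, **{name: val * fac})
                assert restricted_loglik(spec, ainv, cand) <= fit.loglik + 1e-6
        # 2-d grid over the weakly identified (sigma2_aI, sigma2_eI) pair
        for fa in (0.6, 1.0, 1.4):
            for fe in (0.6, 1.0, 1.4):
                cand = psd_candidate(
                    est,
                    sigma2_aI=est.sigma2_aI * fa,
                    sigma2_eI=est.sigma2_eI * fe,
                )
                assert restricted_loglik(spec, ainv, cand) <= fit.loglik + 1e-6

    def test_start_invariance(self, toy_fit):
        spec, ainv, fit = toy_fit
        other = reml_fit(spec, ainv, init=igesim.get_scenario(1).vc)
        assert other.loglik == pytest.approx(fit.loglik, abs=1e-4)
        assert other.estimates.sigma2_aI == pytest.approx(
            fit.estimates.sigma2_aI, rel=1e-2
        )

    def test_true_null_indirect_variance_near_boundary(self):
        vc = VarianceComponents(192000, 0.0, 0.0, 0.0, 448000)
        cfg = _small_config(n_herds=6, herd_size=50, vc=vc)
        sim = igesim.simulate_replicate(cfg, 17)
        spec = build_design(sim.phenotypes, sim.network, sim.pedigree)
        fit = reml_fit(spec, a_inverse(sim.pedigree))
        # simulated without indirect effects: their estimates stay small
        assert fit.estimates.sigma2_aI + fit.estimates.sigma2_eI < 0.05 * 640_000

    def test_iteration_cap_returns_unconverged(self, toy_fit):
        spec, ainv, _ = toy_fit
        fit = reml_fit(spec, ainv, options=REMLOptions(max_iter=2))
        assert not fit.converged
        assert fit.n_iter == 2
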