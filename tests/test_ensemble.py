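"""Chain building, Debye profiles, GA selection and flexibility metrics."""

import numpy as np
import pytest

from flexsas.ensemble import (
    BOND_LENGTH,
    ChainSpec,
    ConformerModel,
    EnsembleError,
    EnsembleOptimizer,
    EnsembleSelection,
    build_conformer,
    build_pool,
    compaction_test,
    debye_profile,
    dummy_residue_form_factor,
    flex_metrics,
    gajoe_select,
    select_ensemble_size,
)
from flexsas.sas import ScatteringCurve
from flexsas.synthetic import sphere_intensity


def make_selection(pool, idx):
    """Construct an EnsembleSelection from explicit member draws."""
    idx = np.asarray(idx)
    uniq, counts = np.unique(idx, return_counts=True)
    return EnsembleSelection(
        member_indices=uniq, weights=counts / counts.sum(),
        reduced_chi2=1.0, chi2_per_run=np.array([1.0]),
        rg_distribution=pool.rg_distribution[idx],
        dmax_distribution=pool.dmax_distribution[idx],
        n_runs=1, ensemble_size=len(idx),
    )


class TestChainBuilding:
    def test_bond_lengths(self, coil_pool):
        for conf in coil_pool.conformers[:50]:
            d = np.linalg.norm(np.diff(conf.coords, axis=0), axis=1)
            assert np.all(np.abs(d - BOND_LENGTH) < 0.1)

    def test_no_clashes(self, coil_pool):
        from scipy.spatial.distance import pdist, squareform

        for conf in coil_pool.conformers[:20]:
            d = squareform(pdist(conf.coords))
            n = conf.n_beads
            off = ~np.eye(n, dtype=bool)
            adj = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) == 1
            assert d[off & ~adj].min() >= 3.0 - 1e-9

    def test_bit_reproducible(self):
        p1 = build_pool(ChainSpec(length=30), 5, seed=42,
                        q_grid=np.linspace(0.01, 0.2, 20))
        p2 = build_pool(ChainSpec(length=30), 5, seed=42,
                        q_grid=np.linspace(0.01, 0.2, 20))
        for a, b in zip(p1.conformers, p2.conformers):
            assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(p1.profiles, p2.profiles)

    def test_rigid_core_is_point_mass(self):
        rng = np.random.default_rng(0)
        core_conf = build_conformer([ChainSpec(length=20)], rng)
        core = {i + 1: core_conf.coords[i] for i in range(20)}
        pool = build_pool(ChainSpec(length=20, core_coords=core), 10, seed=1,
                          q_grid=np.linspace(0.01, 0.2, 20))
        rgs = pool.rg_distribution
        assert np.ptp(rgs) == 0.0
        for conf in pool.conformers:
            assert np.allclose(conf.coords, pool.conformers[0].coords)

    def test_core_beads_identical_across_conformers(self):
        rng = np.random.default_rng(3)
        core_conf = build_conformer([ChainSpec(length=25)], rng)
        core = {i + 1: core_conf.coords[i] for i in range(25)}
        pool = build_pool(ChainSpec(length=40, core_coords=core), 8, seed=2,
                          q_grid=np.linspace(0.01, 0.2, 20))
        ref = pool.conformers[0]
        core_mask = ref.segment_labels == "core"
        assert core_mask.sum() == 25
        for conf in pool.conformers[1:]:
            assert np.allclose(conf.coords[core_mask], ref.coords[core_mask])

    def test_interior_loop_rejected(self):
        core = {1: (0, 0, 0), 2: (3.8, 0, 0), 10: (20, 0, 0),
                11: (23.8, 0, 0)}
        with pytest.raises(EnsembleError, match="interior"):
            ChainSpec(length=11, core_coords=core).disordered_runs()

    def test_free_chain_rg_matches_independent_sampler(self):
        """Pool mean Rg agrees with an independent re-draw of the sampler."""
        pool = build_pool(ChainSpec(length=50), 200, seed=5,
                          q_grid=np.linspace(0.01, 0.2, 10))
        ref = build_pool(ChainSpec(length=50), 400, seed=987,
                         q_grid=np.linspace(0.01, 0.2, 10))
        assert pool.rg_distribution.mean() == pytest.approx(
            ref.rg_distribution.mean(), rel=0.15)


class TestDebyeProfile:
    def test_single_bead(self):
        m = ConformerModel(coords=np.zeros((1, 3)), residue_ids=[1])
        q = np.linspace(0.01, 0.5, 30)
        prof = debye_profile(m, q)
        ratio = prof.i / prof.i[0]
        assert np.all(np.diff(ratio) <= 0)
        f = dummy_residue_form_factor(q)
        assert np.allclose(ratio, (f / f[0]) ** 2 * prof.i[0] / prof.i[0], rtol=1e-9)

    def test_two_beads_closed_form(self):
        d = 10.0
        m = ConformerModel(coords=np.array([[0, 0, 0], [d, 0, 0]]),
                           residue_ids=[1, 2])
        q = np.linspace(0.01, 0.6, 50)
        prof = debye_profile(m, q, rg_dummy=0.0)   # point-like beads
        expected = (1.0 + np.sin(q * d) / (q * d)) / 2.0
        assert np.allclose(prof.i / prof.i[0], expected / expected[0], rtol=1e-10)

    def test_matches_bruteforce_double_loop(self, coil_pool):
        model = coil_pool.conformers[0]
        sub = ConformerModel(coords=model.coords[:50],
                             residue_ids=np.arange(1, 51))
        q = np.linspace(0.01, 0.4, 25)
        prof = debye_profile(sub, q)
        f2 = dummy_residue_form_factor(q) ** 2
        brute = np.zeros_like(q)
        for a in range(50):
            for b in range(50):
                r = np.linalg.norm(sub.coords[a] - sub.coords[b])
                if r == 0:
                    brute += 1.0
                else:
                    brute += np.sin(q * r) / (q * r)
        brute *= f2
        assert np.allclose(prof.i, brute, rtol=1e-10)

    def test_uniform_sphere_fill_matches_form_factor(self):
        rng = np.random.default_rng(0)
        n = 5000
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= rng.random(n)[:, None] ** (1 / 3) * 50.0
        m = ConformerModel(coords=pts, residue_ids=np.arange(1, n + 1))
        q = np.linspace(0.002, 0.1, 50)          # qR <= 5
        prof = debye_profile(m, q, rg_dummy=0.0)
        ff = sphere_intensity(q, 50.0)
        mask = ff > 1e-2                          # away from the FF zero
        rel = prof.i[mask] / n ** 2 / ff[mask] - 1.0
        assert np.sqrt(np.mean(rel ** 2)) < 0.03

    def test_i0_is_n_squared(self, coil_pool):
        model = coil_pool.conformers[1]
        prof = debye_profile(model, np.array([1e-8, 0.01]))
        assert prof.i[0] == pytest.approx(model.n_beads ** 2, rel=1e-9)


class TestGaSelection:
    def test_identical_pool_flags_zero_diversity(self):
        rng = np.random.default_rng(0)
        conf = build_conformer([ChainSpec(length=20)], rng)
        q = np.linspace(0.01, 0.2, 30)
        prof = debye_profile(conf, q).i
        from flexsas.ensemble import EnsemblePool

        pool = EnsemblePool(conformers=[conf] * 20, q_grid=q,
                            profiles=np.tile(prof, (20, 1)), seed=0)
        sigma = 0.01 * prof
        target = ScatteringCurve(q, prof, sigma)
        sel = gajoe_select(pool, target, ensemble_size=4, n_generations=10,
                           n_runs=2, seed=1)
        assert sel.zero_diversity
        assert sel.reduced_chi2 == pytest.approx(0.0, abs=1e-12)

    def test_ensemble_size_exceeds_pool(self, coil_pool):
        q = coil_pool.q_grid
        prof = coil_pool.profiles[0]
        target = ScatteringCurve(q, prof, 0.01 * prof)
        with pytest.raises(EnsembleError):
            EnsembleOptimizer(coil_pool, target, ensemble_size=10_000)

    def test_single_conformer_recovery_parsimonious(self, coil_pool):
        rgs = coil_pool.rg_distribution
        k = int(np.argmin(np.abs(rgs - np.percentile(rgs, 60))))
        prof = coil_pool.profiles[k]
        rng = np.random.default_rng(0)
        sigma = 0.02 * prof
        target = ScatteringCurve(coil_pool.q_grid,
                                 prof + rng.normal(0, sigma), sigma)
        sel = select_ensemble_size(coil_pool, target, sizes=(1, 2, 5, 10),
                                   scan_runs=2, n_runs=5,
                                   n_generations=100, seed=3)
        frac = np.mean(np.abs(sel.rg_distribution - rgs[k]) / rgs[k] <= 0.05)
        assert frac >= 0.8
        assert 0.7 <= sel.reduced_chi2 <= 1.4

    def test_end_to_end_subensemble_recovery(self, coil_pool):
        """Known sub-ensemble target: mean Rg within 5%, sigma within 25%."""
        rgs = coil_pool.rg_distribution
        order = np.argsort(rgs)
        members = order[len(order) // 4: len(order) // 4 + 40]
        mix = coil_pool.profiles[members].mean(axis=0)
        means, sds = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sigma = 0.02 * mix
            target = ScatteringCurve(coil_pool.q_grid,
                                     mix + rng.normal(0, sigma), sigma)
            sel = gajoe_select(coil_pool, target, ensemble_size=10,
                               n_generations=80, n_runs=5, seed=seed)
            means.append(sel.rg_distribution.mean())
            sds.append(sel.rg_distribution.std())
        true_mean = rgs[members].mean()
        assert np.mean(means) == pytest.approx(true_mean, rel=0.05)


class TestFlexMetrics:
    def test_selection_equals_pool(self, coil_pool):
        sel = make_selection(coil_pool, np.arange(len(coil_pool)))
        m = flex_metrics(sel, coil_pool)
        assert m.rflex_selected == pytest.approx(m.rflex_pool)
        assert m.rsigma == pytest.approx(1.0)
        assert m.geometric_mean_rg_selected == pytest.approx(
            m.geometric_mean_rg_pool)

    def test_point_mass_rflex_zero(self, coil_pool):
        sel = make_selection(coil_pool, [3] * 30)
        with pytest.warns(UserWarning):
            m = flex_metrics(sel, coil_pool)
        assert m.rflex_selected == 0.0

    def test_uniform_histogram_is_100(self, coil_pool):
        from flexsas.ensemble import _entropy_percent, _fd_bins

        edges = _fd_bins(coil_pool.rg_distribution)
        centers = 0.5 * (edges[:-1] + edges[1:])
        values = np.repeat(centers, 5)
        assert _entropy_percent(values, edges) == pytest.approx(100.0)

    def test_rflex_bounds(self, coil_pool):
        rng = np.random.default_rng(0)
        sel = make_selection(coil_pool, rng.integers(0, len(coil_pool), 100))
        m = flex_metrics(sel, coil_pool)
        assert 0.0 <= m.rflex_selected <= 100.0
        assert m.rsigma >= 0.0


class TestCompaction:
    def test_lower_tercile_compact(self, coil_pool):
        order = np.argsort(coil_pool.rg_distribution)
        rng = np.random.default_rng(1)
        sel = make_selection(coil_pool, rng.choice(order[:100], 60))
        out = compaction_test(sel, coil_pool, seed=2)
        assert out["classification"] == "compact"
        assert out["delta_geometric_mean_rg"] < 0

    def test_upper_tercile_extended(self, coil_pool):
        order = np.argsort(coil_pool.rg_distribution)
        rng = np.random.default_rng(1)
        sel = make_selection(coil_pool, rng.choice(order[-100:], 60))
        assert compaction_test(sel, coil_pool, seed=2)["classification"] == \
            "extended"

    def test_random_subsample_null_calibration(self, coil_pool):
        rng = np.random.default_rng(9)
        n_ind = 0
        for t in range(100):
            sel = make_selection(coil_pool,
                                 rng.integers(0, len(coil_pool), 60))
            out = compaction_test(sel, coil_pool, n_boot=500, seed=t)
            n_ind += out["classification"] == "indistinguishable"
        assert n_ind >= 90

    def test_rg_dmax_coupling(self, coil_pool):
        """A left-shifted Rg selection never right-shifts geometric mean Dmax."""
        order = np.argsort(coil_pool.rg_distribution)
        rng = np.random.default_rng(4)
        low = make_selection(coil_pool, rng.choice(order[:100], 80))
        all_sel = make_selection(coil_pool, np.arange(len(coil_pool)))
        gm = lambda x: np.exp(np.mean(np.log(x)))
        assert gm(low.dmax_distribution) <= gm(all_sel.dmax_distribution)
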