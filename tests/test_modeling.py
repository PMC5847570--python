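"""Rigid-body modelling: restraints, symmetry, annealing mechanics,
3:2 derivation, dummy chains, clustering, ensemble flexibility."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import ks_2samp

from dutstl import hdx, modeling, saxs, synth
from dutstl.io import (CA_BOND, ROLE_DUMMY, ROLE_RIGID, ScatteringCurve,
                       StructureModel)
from dutstl.modeling import _rot_z


class TestBuildRestraints:
    def test_one_restraint_per_copy(self):
        tri = hdx.InterfaceMap("t", eligible=set(range(37, 45)) | set(range(88, 93)))
        mono = hdx.InterfaceMap("m", eligible=set(range(98, 114)))
        rsts = modeling.build_restraints(tri, mono, bound=10.0, copies=3)
        assert len(rsts) == 3
        assert all(r.bound == 10.0 for r in rsts)
        assert set(rsts[0].trimer_residues) == {"A", "B", "C"}

    def test_empty_eligible_set_names_filter(self):
        tri = hdx.InterfaceMap("t", eligible=set())
        mono = hdx.InterfaceMap("m", eligible={98})
        with pytest.raises(ValueError, match="SASA"):
            modeling.build_restraints(tri, mono)


class TestRestraintPenalty:
    def _flat_complex(self, d_min):
        """Core bead at origin, one monomer bead at distance d_min."""
        core = StructureModel(["A"], np.array([1]), ["ALA"], np.zeros((1, 3)),
                              [ROLE_RIGID])
        mono = StructureModel(["S"], np.array([1]), ["ALA"], np.zeros((1, 3)),
                              [ROLE_RIGID])
        model = modeling.ComplexModel(core=core, monomer=mono,
                                      poses=[(np.eye(3), np.array([d_min, 0.0, 0.0]))],
                                      symmetry="P1")
        rst = modeling.AmbiguousRestraint(trimer_residues={"A": [1]},
                                          monomer_residues=[1], copy_index=0,
                                          bound=10.0, weight=1.0)
        return model, [rst]

    def test_inside_bound_costs_nothing(self):
        model, rsts = self._flat_complex(8.0)
        assert modeling.restraint_penalty(model, rsts) == 0.0

    def test_flat_bottom_quadratic_outside(self):
        model, rsts = self._flat_complex(12.0)
        assert modeling.restraint_penalty(model, rsts) == pytest.approx(4.0)

    def test_matches_brute_force_over_random_poses(self, small_complex):
        truth, _, monomer = small_complex
        rsts = truth.meta["restraints"]
        rng = np.random.default_rng(0)
        for _ in range(20):
            ang = rng.uniform(0, 2 * np.pi)
            t = rng.normal(0, 40, 3)
            pose = (modeling._rot_axis(modeling._random_unit(rng), ang), t)
            model = modeling.ComplexModel(core=truth.core, monomer=monomer,
                                          poses=[pose] * 3, symmetry="P3")
            fast = modeling.restraint_penalty(model, rsts)
            # oracle: explicit loop over every eligible cross pair
            brute = 0.0
            copies = model.copy_models()
            for r in rsts:
                cm = copies[r.copy_index]
                d_min = np.inf
                for ch, residues in r.trimer_residues.items():
                    for res in residues:
                        a = truth.core.xyz[truth.core.mask(chain=ch) &
                                           (truth.core.resid == res)]
                        for mres in r.monomer_residues:
                            b = cm.xyz[cm.resid == mres]
                            if len(a) and len(b):
                                d_min = min(d_min, float(cdist(a, b).min()))
                brute += r.weight * max(0.0, d_min - r.bound) ** 2
            assert fast == pytest.approx(brute, rel=1e-9)


class TestSymmetry:
    def test_p3_images_are_rotations_of_pose_one(self, small_complex):
        truth, _, _ = small_complex
        copies = truth.copy_models()
        r120 = copies[0].transformed(_rot_z(2 * np.pi / 3), np.zeros(3))
        assert np.sqrt(np.mean((r120.xyz - copies[1].xyz) ** 2)) < 1e-9

    def test_wrong_copy_count_rejected(self, small_complex):
        truth, _, monomer = small_complex
        target = ScatteringCurve(np.linspace(0.01, 0.3, 60), np.ones(60),
                                 np.full(60, 0.01))
        with pytest.raises(ValueError, match="P3"):
            modeling.anneal_complex(truth.core, monomer, 2, "P3", [], target)


@pytest.fixture(scope="module")
def short_run(small_complex, target_33):
    truth, _, monomer = small_complex
    sched = modeling.SAScedule(t0=None, gamma=None, steps=400,
                               quench_steps=100)
    model = modeling.anneal_complex(truth.core, monomer, 3, "P3",
                                    truth.meta["restraints"], target_33,
                                    schedule=sched, seed=7)
    return model, sched


class TestAnnealingMechanics:

    def test_energy_equals_sum_of_breakdown(self, short_run):
        model, sched = short_run
        e = model.energy
        assert e["total"] == pytest.approx(
            e["chi2"] + sched.w_restraint * e["restraint"]
            + sched.w_clash * e["clash"], rel=1e-12)

    def test_same_seed_is_bit_reproducible(self, small_complex, target_33, short_run):
        truth, _, monomer = small_complex
        model, sched = short_run
        again = modeling.anneal_complex(truth.core, monomer, 3, "P3",
                                        truth.meta["restraints"], target_33,
                                        schedule=sched, seed=7)
        assert again.energy == model.energy
        assert np.array_equal(again.realize().xyz, model.realize().xyz)

    def test_best_energy_trace_non_increasing(self, short_run):
        model, _ = short_run
        trace = np.array(model.meta["best_trace"])
        assert np.all(np.diff(trace) <= 1e-12)

    def test_zero_temperature_keeps_ground_truth(self, small_complex, target_33):
        """Starting from the true pose at T0 = 0 the model stays at the
        generating structure; chi2 sits at the generation-noise level."""
        truth, _, monomer = small_complex
        sched = modeling.SAScedule(t0=0.0, gamma=0.99, steps=300, quench_steps=0)
        model = modeling.anneal_complex(truth.core, monomer, 3, "P3",
                                        truth.meta["restraints"], target_33,
                                        schedule=sched, seed=1,
                                        initial_poses=list(truth.poses))
        assert 0.5 <= model.energy["chi2"] <= 2.0
        drift = np.linalg.norm(model.copy_models()[0].centroid()
                               - truth.copy_models()[0].centroid())
        assert drift < 2.0


class TestDerive32:
    def test_removal_and_restoration_reproduce_33_curve(
            self, small_complex, target_33, s_grid):
        truth, _, _ = small_complex
        m32 = modeling.derive_32_from_33(truth, 2, target_33)
        re_add = truth.copy_models()[1]
        re_add.chain = ["S9"] * len(re_add)
        restored = StructureModel.concatenate(
            [m32.core] + m32.copy_models() + [re_add])
        a = saxs.debye_curve(truth.realize(), s_grid).intensity
        b = saxs.debye_curve(restored, s_grid).intensity
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_32_model_fits_its_own_region(self, small_complex, target_32):
        truth, _, _ = small_complex
        m32 = modeling.derive_32_from_33(truth, 3, target_32)
        assert m32.energy["chi2"] < 2.0
        assert m32.meta["p2_compatible"]

    def test_remove_index_validated(self, small_complex, target_33):
        truth, _, _ = small_complex
        with pytest.raises(ValueError, match="1..3"):
            modeling.derive_32_from_33(truth, 4, target_33)
        p1 = modeling.ComplexModel(core=truth.core, monomer=truth.monomer,
                                   poses=list(truth.poses), symmetry="P1")
        with pytest.raises(ValueError, match="P3"):
            modeling.derive_32_from_33(p1, 1, target_33)


class TestDummyLinkers:
    def test_terminal_extension_geometry(self, small_complex):
        _, _, monomer = small_complex
        ext = modeling.add_dummy_linkers(monomer, [(53, 57)], {(53, 57): 52},
                                         seed=3)
        dummies = np.array([r == ROLE_DUMMY for r in ext.role])
        assert dummies.sum() == 5
        anchor = ext.xyz[(ext.resid == 52) & ~dummies][0]
        pts = np.vstack([anchor, ext.xyz[dummies]])
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        np.testing.assert_allclose(steps, CA_BOND, atol=0.01)

    def test_zero_length_gap_adds_nothing(self, small_complex):
        _, _, monomer = small_complex
        out = modeling.add_dummy_linkers(monomer, [(60, 59)], {(60, 59): 52},
                                         seed=0)
        assert len(out) == len(monomer)

    def test_two_anchor_gap_closes(self):
        xyz = np.array([[0.0, 0, 0], [12.0, 0, 0]])
        m = StructureModel(["A", "A"], np.array([1, 6]), ["ALA"] * 2, xyz,
                           [ROLE_RIGID] * 2)
        out = modeling.add_dummy_linkers(m, [(2, 5)], {(2, 5): (1, 6)}, seed=1,
                                         chain="A")
        dummies = np.array([r == ROLE_DUMMY for r in out.role])
        assert dummies.sum() == 4
        chain_pts = np.vstack([xyz[0], out.xyz[dummies], xyz[1]])
        steps = np.linalg.norm(np.diff(chain_pts, axis=0), axis=1)
        np.testing.assert_allclose(steps[:-1], CA_BOND, atol=0.01)
        assert abs(steps[-1] - CA_BOND) <= 0.5    # closure tolerance

    def test_unbridgeable_gap_rejected(self):
        xyz = np.array([[0.0, 0, 0], [60.0, 0, 0]])
        m = StructureModel(["A", "A"], np.array([1, 6]), ["ALA"] * 2, xyz,
                           [ROLE_RIGID] * 2)
        with pytest.raises(ValueError, match="unbridgeable"):
            modeling.add_dummy_linkers(m, [(2, 5)], {(2, 5): (1, 6)}, seed=0,
                                       chain="A")

    def test_terminal_chains_follow_self_avoiding_walk_statistics(self):
        """End-to-end distances of seeded 12-bead terminal chains match an
        independently coded self-avoiding walk at the same step length."""
        anchor = StructureModel(["A"], np.array([1]), ["ALA"], np.zeros((1, 3)),
                                [ROLE_RIGID])
        ours = []
        for seed in range(500):
            out = modeling.add_dummy_linkers(anchor, [(2, 13)], {(2, 13): 1},
                                             seed=seed)
            dummies = np.array([r == ROLE_DUMMY for r in out.role])
            ours.append(np.linalg.norm(out.xyz[dummies][-1]))

        # oracle: brute-force SAW with uniform sphere steps
        rng = np.random.default_rng(12345)
        oracle = []
        while len(oracle) < 500:
            pts = [np.zeros(3)]
            dead = False
            for _ in range(12):
                for _ in range(30):
                    v = rng.normal(size=3)
                    cand = pts[-1] + CA_BOND * v / np.linalg.norm(v)
                    if all(np.linalg.norm(cand - p) > modeling.SELF_AVOID
                           for p in pts):
                        break
                else:
                    dead = True
                    break
                pts.append(cand)
            if not dead:
                oracle.append(np.linalg.norm(pts[-1]))
        assert ks_2samp(ours, oracle).pvalue > 0.01


class TestClustering:
    def test_identical_models_form_one_cluster(self, small_complex):
        truth, _, _ = small_complex
        a = truth.replace_poses(truth.poses); a.energy = {"chi2": 1.0}
        b = truth.replace_poses(truth.poses); b.energy = {"chi2": 1.2}
        acs = np.array([truth.core.xyz[truth.core.mask(chain=c, residues=(8, 13))]
                        .mean(axis=0) for c in "ABC"])
        labels, clusters = modeling.cluster_models([a, b], acs,
                                                   n_range=(1, 16), c_range=(17, 52))
        assert len(clusters) == 1

    def test_distant_placements_split(self, small_complex):
        truth, _, _ = small_complex
        near = truth.replace_poses(truth.poses); near.energy = {"chi2": 1.0}
        R, t = truth.poses[0]
        far = truth.replace_poses([(R, t + np.array([60.0, 0, 0]))] * 3)
        far.energy = {"chi2": 5.0}
        acs = np.array([truth.core.xyz[truth.core.mask(chain=c, residues=(8, 13))]
                        .mean(axis=0) for c in "ABC"])
        labels, clusters = modeling.cluster_models([near, far], acs, cutoff=10.0,
                                                   n_range=(1, 16), c_range=(17, 52))
        assert len(clusters) == 2
        # ranking: best chi2 cluster first
        assert near in [[near, far][i] for i in clusters[0]]

    def test_two_pose_families_recovered(self, small_complex):
        truth, _, _ = small_complex
        rng = np.random.default_rng(0)
        models, labels_true = [], []
        R, t = truth.poses[0]
        for k in range(20):
            fam = k % 2
            shift = np.array([50.0, 0, 0]) if fam else np.zeros(3)
            jitter = rng.normal(0, 1.0, 3)
            m = truth.replace_poses([(R, t + shift + jitter)] * 3)
            m.energy = {"chi2": 1.0 + 0.01 * k}
            models.append(m)
            labels_true.append(fam)
        acs = np.array([truth.core.xyz[truth.core.mask(chain=c, residues=(8, 13))]
                        .mean(axis=0) for c in "ABC"])
        labels, clusters = modeling.cluster_models(models, acs, cutoff=10.0,
                                                   n_range=(1, 16), c_range=(17, 52))
        # Rand index against generator labels
        n = len(models)
        agree = sum(1 for i in range(n) for j in range(i + 1, n)
                    if (labels[i] == labels[j]) == (labels_true[i] == labels_true[j]))
        rand = agree / (n * (n - 1) / 2)
        assert rand >= 0.9


@pytest.fixture(scope="module")
def flexible_core():
    from dutstl.synth import _assign_patch_residues, _blob_chain
    rng = np.random.default_rng(2)
    core = _blob_chain(30, "S", 31, rng)
    _assign_patch_residues(core, [31], np.array([0.0, 0, 1.0]))
    return core


class TestEnsembleFlexibility:

    def test_rigid_molecule_has_zero_flexibility(self, flexible_core):
        s = np.linspace(0.01, 0.3, 50)
        target = saxs.debye_curve(flexible_core, s)
        res = modeling.ensemble_flexibility(flexible_core, None, 100, target,
                                            seed=3)
        assert res.r_flex_pool == 0.0 and res.r_flex_selected == 0.0
        assert res.weights.sum() == pytest.approx(1.0)

    def test_pool_average_target_keeps_breadth(self, flexible_core):
        s = np.linspace(0.01, 0.3, 50)
        curves = []
        for k in range(60):
            conf = modeling.add_dummy_linkers(flexible_core, [(1, 30)],
                                              {(1, 30): 31}, seed=1000 + k,
                                              chain="S")
            curves.append(saxs.debye_curve(conf, s).intensity)
        avg = np.mean(curves, axis=0)
        target = ScatteringCurve(s, avg, 0.002 * avg + 1e-5 * avg.max())
        res = modeling.ensemble_flexibility(flexible_core, (1, 30), 150, target,
                                            seed=3)
        assert abs(res.r_flex_selected - res.r_flex_pool) <= 10.0
        lo, hi = np.percentile(res.pool_rg, [5, 95])
        assert res.selected_rg.min() <= lo + 0.5
        assert res.selected_rg.max() >= hi - 0.5

    def test_pool_deterministic_under_seed(self, flexible_core):
        s = np.linspace(0.01, 0.3, 50)
        target = saxs.debye_curve(flexible_core, s)
        a = modeling.ensemble_flexibility(flexible_core, (1, 30), 100, target,
                                          seed=5)
        b = modeling.ensemble_flexibility(flexible_core, (1, 30), 100, target,
                                          seed=5)
        np.testing.assert_array_equal(a.pool_rg, b.pool_rg)

    def test_flexible_range_must_not_overlap_core(self, flexible_core):
        s = np.linspace(0.01, 0.3, 50)
        target = saxs.debye_curve(flexible_core, s)
        with pytest.raises(ValueError, match="overlap"):
            modeling.ensemble_flexibility(flexible_core, (31, 40), 100, target)
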