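"""Hybrid rigid-body modelling of trimer:monomer complexes.

A fixed trimer core and k copies of a monomer rigid body are arranged
by Metropolis simulated annealing under an optional cyclic symmetry
(P2/P3), scored by the reduced chi-square of the model's Debye
scattering curve against an experimental target, plus flat-bottom
ambiguous distance restraints derived from HDX-protected surface
segments and a soft-sphere clash penalty.  Supporting operations add
self-avoiding dummy-residue chains for missing termini and linkers,
derive a 3:2 complex from a refined 3:3 one, cluster solutions by the
position of the monomer domains relative to the active sites, and run
a pool/ensemble flexibility analysis of a two-domain monomer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .io import CA_BOND, ROLE_DUMMY, ROLE_RIGID, ScatteringCurve, StructureModel
from .saxs import chi_square, debye_curve

log = logging.getLogger(__name__)

__all__ = [
    "AmbiguousRestraint", "ComplexModel", "SAScedule", "EnsembleResult",
    "build_restraints", "restraint_penalty", "clash_penalty",
    "anneal_complex", "anneal_units", "derive_32_from_33",
    "add_dummy_linkers", "cluster_models", "ensemble_flexibility",
    "align_core_axis",
]

CLASH_FLOOR = 3.5      # Angstrom between beads of different rigid units
SELF_AVOID = 3.0       # Angstrom for dummy-chain growth


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class AmbiguousRestraint:
    """Flat-bottom ambiguous restraint between a trimer-side eligible
    residue set and one monomer copy's eligible segment.

    Satisfied (zero penalty) when ANY eligible cross pair is within
    ``bound``; otherwise penalty = weight * (d_min - bound)^2.
    """

    trimer_residues: dict          # chain -> sorted residue list
    monomer_residues: list         # residue list on the copy
    copy_index: int
    bound: float = 10.0
    weight: float = 1.0


@dataclass
class SAScedule:
    """Geometric-cooling Metropolis schedule and move sizes.

    ``t0=None`` scales the initial temperature to the starting energy
    (a tenth of it) and chooses gamma so the end temperature is ~0.05,
    which keeps the schedule meaningful on the steep chi-square
    landscapes of low-noise targets.
    """

    t0: float | None = 10.0
    gamma: float | None = 0.995
    steps: int = 20000
    sigma_rot_deg: float = 10.0
    sigma_trans: float = 3.0
    w_restraint: float = 10.0
    w_clash: float = 10.0
    linker_move_prob: float = 0.25
    jump_prob: float = 0.08       # chance of re-drawing a pose on the shell
    t_end: float = 0.05
    quench_steps: int = 2000      # greedy small-move descent after cooling

    def resolve(self, e_init: float):
        """(T0, gamma) for a run starting at energy ``e_init``."""
        t0 = self.t0 if self.t0 is not None else max(0.1 * abs(e_init), 1.0)
        gamma = self.gamma
        if gamma is None:
            gamma = float(np.exp(np.log(max(self.t_end, 1e-9) / max(t0, 1e-9))
                                 / max(self.steps, 1)))
        return t0, min(gamma, 1.0)


@dataclass
class ComplexModel:
    """Trimer core plus k monomer poses under a declared symmetry.

    ``poses`` holds one (rotation, translation) per copy; under P3 only
    pose 0 is independent and poses 1, 2 are its 120/240-degree images
    about z (the core's symmetry axis), regenerated on realization.
    """

    core: StructureModel
    monomer: StructureModel
    poses: list                       # [(R 3x3, t 3)]
    symmetry: str = "P1"              # "P1" | "P2" | "P3"
    energy: dict = field(default_factory=dict)
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.poses)

    def symmetry_poses(self):
        """Poses with the symmetry operator applied (pose 0 independent)."""
        if self.symmetry == "P1":
            return list(self.poses)
        n = {"P2": 2, "P3": 3}[self.symmetry]
        if self.k != n:
            raise ValueError(f"symmetry {self.symmetry} requires {n} copies, have {self.k}")
        R0, t0 = self.poses[0]
        out = []
        for j in range(n):
            Rz = _rot_z(2.0 * np.pi * j / n)
            out.append((Rz @ R0, Rz @ t0))
        return out

    def copy_models(self) -> list[StructureModel]:
        out = []
        for j, (R, t) in enumerate(self.symmetry_poses()):
            m = self.monomer.transformed(R, t)
            m.chain = [f"{c}{j + 1}" for c in m.chain]
            out.append(m)
        return out

    def realize(self) -> StructureModel:
        return StructureModel.concatenate([self.core] + self.copy_models())

    def replace_poses(self, poses) -> "ComplexModel":
        return replace(self, poses=list(poses), energy=dict(self.energy),
                       meta=dict(self.meta))


@dataclass
class EnsembleResult:
    pool_rg: np.ndarray
    selected_rg: np.ndarray
    weights: np.ndarray
    r_flex_pool: float       # %
    r_flex_selected: float   # %
    chi2: float


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def align_core_axis(core: StructureModel) -> StructureModel:
    """Center the core and put its pseudo-3-fold axis on z.

    The axis is taken as the normal of the best plane through the chain
    centroids (SVD); for a symmetric trimer this is the symmetry axis.
    """
    cents = np.array([core.xyz[core.mask(chain=c)].mean(axis=0) for c in core.chains])
    cent = cents.mean(axis=0)
    if len(cents) >= 3:
        _, _, vt = np.linalg.svd(cents - cent)
        normal = vt[2]
    else:
        normal = np.array([0.0, 0.0, 1.0])
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3)
    else:
        angle = np.arccos(np.clip(normal @ z, -1, 1))
        R = _rot_axis(v, angle)
    out = core.copy()
    out.xyz = (core.xyz - cent) @ R.T
    return out


# ---------------------------------------------------------------------------
# restraints and penalties
# ---------------------------------------------------------------------------

def build_restraints(trimer_map, monomer_map, bound: float = 10.0,
                     copies: int = 3, trimer_chains=("A", "B", "C"),
                     weight: float = 1.0) -> list[AmbiguousRestraint]:
    """One ambiguous restraint per monomer copy.

    The interface is projected equally across all subunits: every copy
    is restrained against the eligible residues of all trimer chains,
    with ambiguous-minimum semantics, so each monomer effectively binds
    its nearest chain set.
    """
    if not trimer_map.eligible:
        raise ValueError("empty eligible set on the trimer map (after SASA filter?)")
    if not monomer_map.eligible:
        raise ValueError("empty eligible set on the monomer map")
    tri = {c: sorted(trimer_map.eligible) for c in trimer_chains}
    mono = sorted(monomer_map.eligible)
    return [AmbiguousRestraint(trimer_residues=tri, monomer_residues=mono,
                               copy_index=j, bound=bound, weight=weight)
            for j in range(copies)]


def _eligible_coords(core: StructureModel, restraint: AmbiguousRestraint):
    masks = []
    for c, residues in restraint.trimer_residues.items():
        m = core.mask(chain=c) & np.isin(core.resid, residues)
        masks.append(m)
    return core.xyz[np.logical_or.reduce(masks)]


def restraint_penalty(model: ComplexModel,
                      restraints: list[AmbiguousRestraint]) -> float:
    """Sum of flat-bottom penalties; zero when every restraint has at
    least one eligible cross pair within its bound."""
    total = 0.0
    copies = model.copy_models()
    for rst in restraints:
        a = _eligible_coords(model.core, rst)
        cm = copies[rst.copy_index]
        b = cm.xyz[np.isin(cm.resid, rst.monomer_residues)]
        if len(a) == 0 or len(b) == 0:
            raise ValueError("restraint with empty eligible coordinates")
        d_min = float(cdist(a, b).min())
        total += rst.weight * max(0.0, d_min - rst.bound) ** 2
    return total


def clash_penalty(units_xyz: list[np.ndarray], floor: float = CLASH_FLOOR) -> float:
    """Soft-sphere penalty over bead pairs of *different* rigid units:
    sum over pairs closer than the floor of (floor - d)^2."""
    total = 0.0
    for i in range(len(units_xyz)):
        for j in range(i + 1, len(units_xyz)):
            d = cdist(units_xyz[i], units_xyz[j])
            close = d[d < floor]
            if close.size:
                total += float(np.sum((floor - close) ** 2))
    return total


def _model_energy(model: ComplexModel, restraints, target: ScatteringCurve,
                  sched: SAScedule):
    realized = model.realize()
    calc = debye_curve(realized, target.s)
    chi2 = chi_square(calc, target).chi2
    units = [model.core.xyz] + [m.xyz for m in model.copy_models()]
    e_clash = clash_penalty(units)
    e_rst = restraint_penalty(model, restraints) if restraints else 0.0
    breakdown = {"chi2": chi2, "restraint": e_rst, "clash": e_clash,
                 "total": chi2 + sched.w_restraint * e_rst + sched.w_clash * e_clash}
    return breakdown


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------

def _perturb_pose(pose, rng, sched: SAScedule, scale: float = 1.0):
    R, t = pose
    if rng.random() < 0.5:
        ang = np.deg2rad(rng.normal(0.0, scale * sched.sigma_rot_deg))
        R = _rot_axis(_random_unit(rng), ang) @ R
    else:
        t = t + rng.normal(0.0, scale * sched.sigma_trans, size=3)
    return (R, t)


def _linker_move(template: StructureModel, rng, max_angle: float = 0.6) -> StructureModel | None:
    """Crankshaft/tail-pivot move on a contiguous dummy stretch.

    Terminal dummy tails pivot beyond a random bead about a random axis;
    interior (two-anchor) stretches rotate about the axis through two
    pivot beads, preserving all bond lengths.
    """
    dummy = np.array([r == ROLE_DUMMY for r in template.role])
    if not dummy.any():
        return None
    idx = np.flatnonzero(dummy)
    # contiguous runs of dummy beads
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    run = runs[rng.integers(len(runs))]
    out = template.copy()
    lo, hi = run[0], run[-1]
    angle = rng.uniform(-max_angle, max_angle)
    anchored_left = lo > 0
    anchored_right = hi < len(template) - 1
    if anchored_left and anchored_right:
        # interior linker: crankshaft about the anchor-anchor axis
        p1, p2 = template.xyz[lo - 1], template.xyz[hi + 1]
        axis = p2 - p1
        if np.linalg.norm(axis) < 1e-9:
            return None
        R = _rot_axis(axis, angle)
        out.xyz[lo:hi + 1] = (template.xyz[lo:hi + 1] - p1) @ R.T + p1
    else:
        # terminal tail: pivot the stretch beyond a random interior bead
        pivot = int(rng.integers(lo, hi + 1))
        p = template.xyz[pivot]
        R = _rot_axis(_random_unit(rng), angle)
        if anchored_left:
            out.xyz[pivot:hi + 1] = (template.xyz[pivot:hi + 1] - p) @ R.T + p
        else:
            out.xyz[lo:pivot + 1] = (template.xyz[lo:pivot + 1] - p) @ R.T + p
    return out


def anneal_units(core: StructureModel, templates: list[StructureModel],
                 symmetry: str, restraints, target: ScatteringCurve,
                 schedule: SAScedule | None = None, seed: int = 0,
                 initial_poses=None, freeze_poses: bool = False) -> ComplexModel:
    """Metropolis simulated annealing over rigid-unit poses.

    ``templates`` lists the independent rigid bodies; under P2/P3 a
    single template is replicated by the symmetry operator and only
    pose 0 is sampled.  ``freeze_poses`` restricts the search to dummy
    linker moves (used by the 3:2 derivation).  Deterministic for a
    given seed; the best-so-far model with its full energy breakdown is
    returned, with the accepted- and best-energy traces in ``meta``.
    """
    sched = schedule or SAScedule()
    rng = np.random.default_rng(seed)
    if symmetry == "P3" and len(templates) != 1:
        raise ValueError("P3 symmetry expects a single template replicated 3x")
    if symmetry == "P2" and len(templates) != 1:
        raise ValueError("P2 symmetry expects a single template replicated 2x")
    if symmetry not in ("P1", "P2", "P3"):
        raise ValueError(f"unknown symmetry {symmetry!r}")

    n_copies = {"P1": len(templates), "P2": 2, "P3": 3}[symmetry]
    if symmetry == "P1":
        tpls = list(templates)
    else:
        tpls = [templates[0]] * n_copies

    core_r = float(np.linalg.norm(core.xyz - core.centroid(), axis=1).max())

    def shell_pose(tpl):
        """Random orientation, centroid on a shell just outside the core."""
        R = _rot_axis(_random_unit(rng), rng.uniform(0, 2 * np.pi))
        tpl_r = float(np.linalg.norm(tpl.xyz - tpl.centroid(), axis=1).max())
        t = (core.centroid() + _random_unit(rng) * (core_r + 0.7 * tpl_r)
             - R @ tpl.centroid())
        return (R, t)

    if initial_poses is None:
        poses = [shell_pose(templates[min(j, len(templates) - 1)])
                 for j in range(len(templates) if symmetry == "P1" else 1)]
        if symmetry != "P1":
            poses = poses * n_copies
    else:
        poses = list(initial_poses)

    # heterogeneous P1 case: ComplexModel assumes one template; emulate by
    # annealing a wrapper that realizes each template with its own pose.
    hetero = symmetry == "P1" and len(templates) > 1

    def make_model(pose_list, tpl_list):
        if hetero:
            mono = tpl_list[0]
            cm = ComplexModel(core=core, monomer=mono, poses=[pose_list[0]],
                              symmetry="P1", seed=seed)
            cm.meta["extra_units"] = list(zip(tpl_list[1:], pose_list[1:]))
            return cm
        return ComplexModel(core=core, monomer=tpl_list[0], poses=list(pose_list),
                            symmetry=symmetry, seed=seed)

    def energy_of(pose_list, tpl_list):
        model = make_model(pose_list, tpl_list)
        realized_units = [core] + _all_copies(model)
        realized = StructureModel.concatenate(realized_units)
        calc = debye_curve(realized, target.s)
        chi2 = chi_square(calc, target).chi2
        e_clash = clash_penalty([u.xyz for u in realized_units])
        e_rst = _hetero_restraint(model, restraints) if restraints else 0.0
        return {"chi2": chi2, "restraint": e_rst, "clash": e_clash,
                "total": chi2 + sched.w_restraint * e_rst + sched.w_clash * e_clash}

    def _all_copies(model: ComplexModel):
        copies = model.copy_models()
        for j, (tpl, (R, t)) in enumerate(model.meta.get("extra_units", [])):
            m = tpl.transformed(R, t)
            m.chain = [f"{c}x{j + 1}" for c in m.chain]
            copies.append(m)
        return copies

    def _hetero_restraint(model: ComplexModel, rsts):
        copies = _all_copies(model)
        total = 0.0
        for rst in rsts:
            if rst.copy_index >= len(copies):
                continue
            a = _eligible_coords(core, rst)
            cm = copies[rst.copy_index]
            b = cm.xyz[np.isin(cm.resid, rst.monomer_residues)]
            if len(b) == 0:
                continue
            d_min = float(cdist(a, b).min())
            total += rst.weight * max(0.0, d_min - rst.bound) ** 2
        return total

    cur_poses = list(poses)
    cur_tpls = list(tpls)
    cur_e = energy_of(cur_poses, cur_tpls)
    if not np.isfinite(cur_e["total"]):
        raise FloatingPointError(f"non-finite initial energy: {cur_e}")
    best_poses, best_tpls, best_e = list(cur_poses), list(cur_tpls), dict(cur_e)
    best_trace, acc_trace = [cur_e["total"]], [cur_e["total"]]
    n_indep = len(templates) if symmetry == "P1" else 1
    has_dummies = any(ROLE_DUMMY in t.role for t in templates)

    T0, gamma = sched.resolve(cur_e["total"])
    T = T0
    for step in range(sched.steps):
        trial_poses, trial_tpls = list(cur_poses), list(cur_tpls)
        do_linker = has_dummies and (freeze_poses or rng.random() < sched.linker_move_prob)
        if do_linker:
            j = int(rng.integers(len(trial_tpls) if hetero else 1))
            moved = _linker_move(trial_tpls[j], rng)
            if moved is None:
                continue
            if hetero:
                trial_tpls[j] = moved
            else:
                trial_tpls = [moved] * len(trial_tpls)
        elif freeze_poses:
            continue
        else:
            j = int(rng.integers(n_indep))
            u = rng.random()
            if u < sched.jump_prob:
                # large move: re-draw the pose on the shell (escape route
                # out of chi-square traps far from the funnel)
                newp = shell_pose(trial_tpls[min(j, len(trial_tpls) - 1)])
            elif u < 2.0 * sched.jump_prob:
                # spin: new uniform orientation about the unit's own
                # centroid (placement kept, orientation re-sampled)
                tpl = trial_tpls[min(j, len(trial_tpls) - 1)]
                R_old, t_old = trial_poses[j]
                cent = R_old @ tpl.centroid() + t_old
                R_new = _rot_axis(_random_unit(rng), rng.uniform(0, 2 * np.pi))
                newp = (R_new, cent - R_new @ tpl.centroid())
            else:
                # moves shrink with temperature so the search refines as
                # it cools
                scale = max(np.sqrt(T / T0), 0.03) if T0 > 0 else 0.3
                newp = _perturb_pose(trial_poses[j], rng, sched, scale=scale)
            if symmetry == "P1":
                trial_poses[j] = newp
            else:
                trial_poses = [newp] * len(trial_poses)
        trial_e = energy_of(trial_poses, trial_tpls)
        if not np.isfinite(trial_e["total"]):
            raise FloatingPointError(f"non-finite energy at step {step}: {trial_e}")
        dE = trial_e["total"] - cur_e["total"]
        if dE <= 0 or (T > 0 and rng.random() < np.exp(-dE / T)):
            cur_poses, cur_tpls, cur_e = trial_poses, trial_tpls, trial_e
            acc_trace.append(cur_e["total"])
            if cur_e["total"] < best_e["total"]:
                best_poses, best_tpls, best_e = list(cur_poses), list(cur_tpls), dict(cur_e)
        best_trace.append(best_e["total"])
        T *= gamma

    # greedy quench from the best state: small moves, downhill only
    cur_poses, cur_tpls, cur_e = list(best_poses), list(best_tpls), dict(best_e)
    for step in range(sched.quench_steps):
        trial_poses, trial_tpls = list(cur_poses), list(cur_tpls)
        if has_dummies and rng.random() < sched.linker_move_prob:
            j = int(rng.integers(len(trial_tpls) if hetero else 1))
            moved = _linker_move(trial_tpls[j], rng, max_angle=0.1)
            if moved is None:
                continue
            if hetero:
                trial_tpls[j] = moved
            else:
                trial_tpls = [moved] * len(trial_tpls)
        elif freeze_poses:
            continue
        else:
            j = int(rng.integers(n_indep))
            newp = _perturb_pose(trial_poses[j], rng, sched,
                                 scale=float(rng.choice([0.3, 0.1, 0.03])))
            if symmetry == "P1":
                trial_poses[j] = newp
            else:
                trial_poses = [newp] * len(trial_poses)
        trial_e = energy_of(trial_poses, trial_tpls)
        if trial_e["total"] < cur_e["total"]:
            cur_poses, cur_tpls, cur_e = trial_poses, trial_tpls, trial_e
            acc_trace.append(cur_e["total"])
        best_trace.append(cur_e["total"])
    best_poses, best_tpls, best_e = cur_poses, cur_tpls, cur_e

    out = make_model(best_poses, best_tpls)
    out.energy = best_e
    out.meta["best_trace"] = best_trace
    out.meta["accepted_trace"] = acc_trace
    out.meta["schedule"] = sched
    if hetero:
        out.meta["templates"] = best_tpls
    else:
        out.monomer = best_tpls[0]
    return out


def anneal_complex(core: StructureModel, monomer: StructureModel, copies: int,
                   symmetry: str, restraints, target: ScatteringCurve,
                   schedule: SAScedule | None = None, seed: int = 0,
                   initial_poses=None) -> ComplexModel:
    """Anneal ``copies`` rigid copies of one monomer around a fixed core."""
    if symmetry == "P3" and copies != 3:
        raise ValueError("P3 symmetry requires 3 copies")
    if symmetry == "P2" and copies != 2:
        raise ValueError("P2 symmetry requires 2 copies")
    templates = [monomer] if symmetry in ("P2", "P3") else [monomer] * copies
    return anneal_units(core, templates, symmetry, restraints, target,
                        schedule=schedule, seed=seed, initial_poses=initial_poses)


def score_model(model: ComplexModel, restraints, target: ScatteringCurve,
                schedule: SAScedule | None = None) -> dict:
    """Energy breakdown of a realized complex model (no optimization)."""
    sched = schedule or SAScedule()
    e = _model_energy(model, restraints or [], target, sched)
    model.energy = e
    return e


def derive_32_from_33(model33: ComplexModel, remove_index: int,
                      target_region2: ScatteringCurve,
                      schedule: SAScedule | None = None,
                      seed: int = 0) -> ComplexModel:
    """3:2 complex from a refined 3:3 one.

    One monomer (``remove_index`` in 1..3) is deleted; the remaining two
    poses are frozen (interface fixed) and only dummy termini/linkers
    are re-annealed against the region-2 curve.  The result is P1 with
    a P2-compatibility flag.
    """
    if model33.symmetry != "P3":
        raise ValueError("3:2 derivation expects a P3 3:3 model")
    if remove_index not in (1, 2, 3):
        raise ValueError("remove index must be 1..3")
    poses = model33.symmetry_poses()
    kept = [p for j, p in enumerate(poses) if j != remove_index - 1]
    sched = schedule or SAScedule()
    has_dummies = ROLE_DUMMY in model33.monomer.role
    if has_dummies:
        out = anneal_units(model33.core, [model33.monomer, model33.monomer],
                           "P1", [], target_region2, schedule=sched, seed=seed,
                           initial_poses=[kept[0], kept[1]], freeze_poses=True)
        # re-wrap as a plain two-pose P1 model
        tpls = out.meta.get("templates", [out.monomer, out.monomer])
        model = ComplexModel(core=model33.core, monomer=tpls[0],
                             poses=[kept[0]], symmetry="P1", seed=seed)
        model.meta["extra_units"] = [(tpls[1], kept[1])]
        realized = StructureModel.concatenate(
            [model.core] + model.copy_models()
            + [t.transformed(R, tr) for t, (R, tr) in model.meta["extra_units"]])
    else:
        model = ComplexModel(core=model33.core, monomer=model33.monomer,
                             poses=kept, symmetry="P1", seed=seed)
        realized = model.realize()
    calc = debye_curve(realized, target_region2.s)
    fq = chi_square(calc, target_region2)
    model.energy = {"chi2": fq.chi2, "restraint": 0.0, "clash": 0.0,
                    "total": fq.chi2}
    model.meta["p2_compatible"] = True
    model.meta["removed_index"] = remove_index
    return model


# ---------------------------------------------------------------------------
# dummy linkers / termini
# ---------------------------------------------------------------------------

def add_dummy_linkers(model: StructureModel, missing_ranges: list,
                      anchors: dict, seed: int = 0,
                      chain: str | None = None,
                      closure_tol: float = 0.5,
                      max_retries: int = 2000) -> StructureModel:
    """Append self-avoiding dummy-residue chains for missing residues.

    ``missing_ranges`` lists (first, last) residue ranges; ``anchors``
    maps a range to one anchor residue (terminal extension) or a pair
    (two-anchor gap).  Beads are placed 3.8 Angstrom apart; two-anchor
    chains must close onto the far anchor within ``closure_tol`` of a
    bond length (discard-and-retry growth, with a guided bias for the
    closing steps).
    """
    rng = np.random.default_rng(seed)
    out = model.copy()
    for rng_span in missing_ranges:
        first, last = rng_span
        n = last - first + 1
        if n <= 0:
            continue
        anchor = anchors[rng_span]
        two_sided = isinstance(anchor, (tuple, list)) and len(anchor) == 2
        ch = chain or out.chain[0]

        def bead_pos(resid):
            m = out.mask(chain=ch) & (out.resid == resid)
            if not m.any():
                raise ValueError(f"anchor residue {resid} not in model chain {ch}")
            return out.xyz[m][0]

        if two_sided:
            p_start, p_end = bead_pos(anchor[0]), bead_pos(anchor[1])
            span = np.linalg.norm(p_end - p_start)
            if span > CA_BOND * (n + 1) + closure_tol:
                raise ValueError(f"gap {rng_span} unbridgeable: span {span:.1f} A "
                                 f"> {CA_BOND * (n + 1) + closure_tol:.1f} A")
        else:
            p_start = bead_pos(anchor if np.isscalar(anchor) else anchor[0])
            p_end = None

        occupied = out.xyz
        chain_xyz = None
        for _ in range(max_retries):
            trial = _grow_chain(p_start, p_end, n, rng, occupied, closure_tol)
            if trial is not None:
                chain_xyz = trial
                break
        if chain_xyz is None:
            raise ValueError(f"could not grow dummy chain for {rng_span}")

        add = StructureModel([ch] * n, np.arange(first, last + 1),
                             ["DUM"] * n, chain_xyz, [ROLE_DUMMY] * n)
        out = StructureModel.concatenate([out, add])
    return out


def _grow_chain(p_start, p_end, n, rng, occupied, closure_tol):
    """One attempt at a self-avoiding 3.8-Angstrom-step chain."""
    pts = []
    cur = p_start
    for i in range(n):
        remaining = n - i          # steps left including this one
        closing = p_end is not None and remaining == 1
        for _ in range(30):
            if closing:
                # final bead: exact point at bond length from both the
                # chain end and the far anchor (two-sphere intersection)
                axis = p_end - cur
                d = np.linalg.norm(axis)
                if d > 2.0 * CA_BOND - 1e-9 or d < 1e-9:
                    return None
                axis = axis / d
                ring_r = np.sqrt(CA_BOND ** 2 - (d / 2.0) ** 2)
                perp = np.cross(axis, _random_unit(rng))
                nrm = np.linalg.norm(perp)
                if nrm < 1e-9:
                    continue
                perp /= nrm
                cand = cur + 0.5 * d * axis + ring_r * perp
            else:
                step = _random_unit(rng)
                if p_end is not None:
                    # bias toward the far anchor once the leash gets tight
                    to_end = p_end - cur
                    dist = np.linalg.norm(to_end)
                    slack = CA_BOND * remaining - dist
                    bias = np.clip(1.0 - slack / (2.0 * CA_BOND), 0.0, 1.0)
                    direction = ((1.0 - bias) * step
                                 + bias * to_end / max(dist, 1e-9))
                    step = direction / np.linalg.norm(direction)
                cand = cur + CA_BOND * step
            d_model = (np.linalg.norm(occupied - cand, axis=1).min()
                       if len(occupied) else np.inf)
            d_self = (np.linalg.norm(np.array(pts) - cand, axis=1).min()
                      if len(pts) > 1 else np.inf)
            if d_model > SELF_AVOID and d_self > SELF_AVOID:
                break
        else:
            return None
        pts.append(cand)
        cur = cand
    if p_end is not None:
        if abs(np.linalg.norm(cur - p_end) - CA_BOND) > closure_tol:
            return None
    return np.array(pts)


# ---------------------------------------------------------------------------
# clustering and ensemble analysis
# ---------------------------------------------------------------------------

def cluster_models(models: list[ComplexModel], active_site_centroids: np.ndarray,
                   cutoff: float = 10.0,
                   n_range: tuple = (1, 84), c_range: tuple = (85, 267)):
    """Single-linkage clustering of complex models by monomer placement.

    The feature of a model is the pair (distance of the monomer
    N-domain centroid, distance of the C-domain centroid) to the
    nearest active-site centroid, averaged over copies.  Clusters are
    cut at ``cutoff`` (Angstrom) and ranked by the best member chi2.

    Returns ``(labels, clusters)`` where clusters is a list of index
    lists ordered best-first.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    feats = []
    for m in models:
        dn, dc = [], []
        for cm in m.copy_models():
            for rng_, acc in ((n_range, dn), (c_range, dc)):
                sel = (cm.resid >= rng_[0]) & (cm.resid <= rng_[1])
                if not sel.any():
                    continue
                cent = cm.xyz[sel].mean(axis=0)
                acc.append(np.linalg.norm(active_site_centroids - cent, axis=1).min())
        feats.append([np.mean(dn) if dn else 0.0, np.mean(dc) if dc else 0.0])
    feats = np.asarray(feats)
    if len(models) == 2:
        same = np.linalg.norm(feats[0] - feats[1]) <= cutoff
        labels = np.array([1, 1]) if same else np.array([1, 2])
    else:
        Z = linkage(feats, method="single")
        labels = fcluster(Z, t=cutoff, criterion="distance")
    clusters = []
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        best = min(float(models[i].energy.get("chi2", np.inf)) for i in idx)
        clusters.append((best, idx))
    clusters.sort()
    return labels, [idx for _, idx in clusters]


def ensemble_flexibility(core: StructureModel, flexible_range: tuple | None,
                         pool_size: int, target: ScatteringCurve, seed: int = 0,
                         n_select: int = 20, n_bins: int = 20,
                         flexible_chains: list | None = None) -> EnsembleResult:
    """Pool/ensemble flexibility analysis of a two-domain molecule.

    A pool of conformers is built by regrowing the flexible residue
    range of each chain as a self-avoiding random chain anchored at the
    fixed core; a greedy selection (with replacement) picks the
    sub-ensemble whose weight-averaged Debye curve best fits the
    target.  Flexibility is summarized by R_flex, the Shannon entropy
    of the Rg histogram normalized by the uniform-histogram entropy
    (an entropy surrogate for the ensemble-optimization flexibility
    metric): 100% = maximally broad, 0% = rigid.
    """
    if pool_size < 100:
        raise ValueError("pool size must be at least 100")
    rng = np.random.default_rng(seed)
    chains = flexible_chains or core.chains
    if flexible_range is not None:
        lo, hi = flexible_range
        for ch in chains:
            if (core.mask(chain=ch, residues=(lo, hi))).any():
                raise ValueError("flexible range overlaps the fixed core")

    conformers, rgs, curves = [], [], []
    for _ in range(pool_size):
        if flexible_range is None:
            conf = core
        else:
            lo, hi = flexible_range
            conf = core
            for ch in chains:
                ids = core.resid[core.mask(chain=ch)]
                anchor = lo - 1 if (ids == lo - 1).any() else hi + 1
                conf = add_dummy_linkers(conf, [(lo, hi)], {(lo, hi): anchor},
                                         seed=int(rng.integers(2 ** 31)), chain=ch)
        conformers.append(conf)
        rgs.append(conf.rg())
        curves.append(debye_curve(conf, target.s).intensity)
    rgs = np.array(rgs)
    curves = np.array(curves)

    def ens_chi2(idx_list):
        avg = curves[idx_list].mean(axis=0)
        c = ScatteringCurve(target.s, avg, np.full_like(avg, 1.0))
        return chi_square(c, target).chi2

    # genetic subset selection: fixed-size ensembles, swap mutations and
    # uniform crossover; where the data do not discriminate, members stay
    # random, so the selected breadth reflects the data's information
    # content rather than the optimizer's determinism
    pop_size, generations = 40, 60
    population = [list(rng.choice(pool_size, size=n_select, replace=False))
                  for _ in range(pop_size)]
    fitness = [ens_chi2(ind) for ind in population]
    for _ in range(generations):
        order = np.argsort(fitness)
        keep = [population[i] for i in order[:pop_size // 2]]
        children = []
        while len(keep) + len(children) < pop_size:
            pa, pb = keep[rng.integers(len(keep))], keep[rng.integers(len(keep))]
            mix = list({*pa, *pb})
            child = list(rng.choice(mix, size=min(n_select, len(mix)), replace=False))
            while len(child) < n_select:
                c = int(rng.integers(pool_size))
                if c not in child:
                    child.append(c)
            if rng.random() < 0.8:    # swap mutation
                child[rng.integers(n_select)] = int(rng.integers(pool_size))
            children.append(child)
        population = keep + children
        fitness = [ens_chi2(ind) for ind in population]
    selected = population[int(np.argmin(fitness))]
    sel_rg = rgs[selected]
    weights = np.zeros(pool_size)
    for j in selected:
        weights[j] += 1.0 / n_select

    lo_r, hi_r = rgs.min(), rgs.max()
    if hi_r - lo_r < 1e-9:
        r_pool = r_sel = 0.0
    else:
        edges = np.linspace(lo_r, hi_r, n_bins + 1)
        r_pool = _norm_entropy(np.histogram(rgs, bins=edges)[0])
        r_sel = _norm_entropy(np.histogram(sel_rg, bins=edges)[0])
    return EnsembleResult(pool_rg=rgs, selected_rg=sel_rg,
                          weights=weights[weights > 0] if weights.any() else weights,
                          r_flex_pool=r_pool, r_flex_selected=r_sel,
                          chi2=float(ens_chi2(selected)))


def _norm_entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    h = -np.sum(p * np.log(p))
    return float(100.0 * h / np.log(len(counts)))
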