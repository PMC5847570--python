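"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study system — a three-fold-symmetric enzyme
trimer bound by separated copies of a two-domain repressor monomer —
and the four experiment types the pipeline analyzes: noisy buffer-
subtracted SAXS curves, SEC-SAXS frame series with two co-eluting
complex species, triplicate HDX uptake tables with interface
protection, one-site ITC titrations and quadratic tight-binding
inhibition assays.  Every generator is deterministic under a fixed
seed.

Default sizes copy the real system (trimer 3 x 152 residues, monomer
267 residues split into an ~84-residue N domain and an ~183-residue C
domain) so the benchmark segment numbers (34-50, 89-110, 98-113) can be
reused in fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import (CA_BOND, ROLE_RIGID, ItcTable, PeptideUptakeRecord,
                 ScatteringCurve, StructureModel)
from .modeling import AmbiguousRestraint, ComplexModel, _rot_axis, _rot_z
from .saxs import debye_curve
from .thermo import itc_heats, tight_binding_model

log = logging.getLogger(__name__)

__all__ = [
    "ToyComplexSpec", "HdxSimSpec",
    "make_toy_complex", "simulate_saxs", "simulate_sec_saxs_run",
    "simulate_hdx_experiment", "simulate_itc_titration",
    "simulate_inhibition_assay", "default_s_grid",
]

GENERATOR_VERSION = "1"

# random packing density of globular domains, one bead per this volume
BEAD_VOLUME = 120.0   # Angstrom^3


@dataclass
class ToyComplexSpec:
    """Geometry of the synthetic trimer + monomer complex."""

    trimer_chain_residues: int = 152
    monomer_n_domain: int = 84        # residues 1..84
    monomer_c_domain: int = 183       # residues 85..267
    copies: int = 3
    trimer_interface: tuple = (37, 44)    # patch on each trimer chain
    trimer_interface2: tuple = (88, 92)
    monomer_interface: tuple = (98, 113)  # patch on the monomer C domain edge
    contact_distance: float = 6.0         # target closest approach, Angstrom
    seed: int = 0


@dataclass
class HdxSimSpec:
    """Design of a synthetic continuous-labelling HDX experiment."""

    protein: str = "protein"
    length: int = 152
    peptide_length: int = 10
    peptide_step: int = 5          # 2-fold overlap
    times_min: tuple = (1.0, 10.0, 100.0)
    replicates: int = 3
    noise_sd_da: float = 0.05
    rate_median_per_min: float = 1.0
    rate_sigma_log: float = 1.5    # log-normal spread of intrinsic rates
    protection_factor: float = 50.0


# ---------------------------------------------------------------------------
# toy complex geometry
# ---------------------------------------------------------------------------

def _pack_blob(n: int, rng, jitter: float = 0.0) -> np.ndarray:
    """Random packing of n beads in a sphere at protein-like density."""
    radius = (3.0 * n * BEAD_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(cand) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - cand, axis=1)) < 3.4:
            continue
        pts.append(cand)
    return np.array(pts)


def _blob_chain(n: int, chain: str, first_resid: int, rng) -> StructureModel:
    xyz = _pack_blob(n, rng)
    return StructureModel([chain] * n, np.arange(first_resid, first_resid + n),
                          ["ALA"] * n, xyz, [ROLE_RIGID] * n)


def _assign_patch_residues(blob: StructureModel, patch_ids: list,
                           direction: np.ndarray) -> None:
    """Renumber a blob so the patch residues sit on the face toward
    ``direction`` (bead positions are random, so numbering is free)."""
    proj = blob.xyz @ (direction / np.linalg.norm(direction))
    order = np.argsort(-proj)              # face-first
    all_ids = sorted(blob.resid.tolist())
    rest = [i for i in all_ids if i not in set(patch_ids)]
    new = np.empty(len(blob), dtype=int)
    new[order[:len(patch_ids)]] = sorted(patch_ids)
    new[order[len(patch_ids):]] = rest
    blob.resid = new


def make_toy_complex(spec: ToyComplexSpec | None = None):
    """Build a deterministic ground-truth complex.

    Returns ``(truth: ComplexModel, trimer: StructureModel,
    monomer: StructureModel)``.  The trimer's 3-fold axis is on z; the
    monomers are placed radially so the declared interface patches are
    in contact (closest cross pair near ``contact_distance``, at most
    10 Angstrom) without clashes.
    """
    spec = spec or ToyComplexSpec()
    rng = np.random.default_rng(spec.seed)

    # one chain blob, interface patch on the outward (+x) face, centroid
    # pushed off-axis, then 3-fold images
    nres = spec.trimer_chain_residues
    chain_r = (3.0 * nres * BEAD_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
    base = _blob_chain(nres, "A", 1, rng)
    patch_ids = (list(range(spec.trimer_interface[0], spec.trimer_interface[1] + 1))
                 + list(range(spec.trimer_interface2[0], spec.trimer_interface2[1] + 1)))
    _assign_patch_residues(base, patch_ids, np.array([1.0, 0.0, 0.0]))
    base.xyz += np.array([1.05 * chain_r, 0.0, 0.0])
    chains = [base]
    for j, cname in enumerate(("B", "C"), start=1):
        img = base.transformed(_rot_z(2.0 * np.pi * j / 3.0), np.zeros(3))
        img.chain = [cname] * len(img)
        chains.append(img)
    trimer = StructureModel.concatenate(chains)
    trimer.auto_segments()

    # two-domain monomer: the C-domain blob carries the interface patch on
    # its -x face, the N domain sits outward (+x)
    nn, nc = spec.monomer_n_domain, spec.monomer_c_domain
    ndom = _blob_chain(nn, "S", 1, rng)
    cdom = _blob_chain(nc, "S", nn + 1, rng)
    mono_patch = list(range(spec.monomer_interface[0], spec.monomer_interface[1] + 1))
    _assign_patch_residues(cdom, mono_patch, np.array([-1.0, 0.0, 0.0]))
    rn = (3.0 * nn * BEAD_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
    rc = (3.0 * nc * BEAD_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
    ndom.xyz += np.array([rn + rc + 2.0, 0.0, 0.0])
    monomer = StructureModel.concatenate([ndom, cdom])
    monomer.auto_segments()
    mono_cent = monomer.centroid()
    mono0 = monomer.transformed(np.eye(3), -mono_cent)   # centered, patch at -x

    # slide the monomer out along +x until the patches are at contact
    # distance without clashes
    patch_t = trimer.xyz[trimer.mask(chain="A", residues=spec.trimer_interface)]
    patch_t2 = trimer.xyz[trimer.mask(chain="A", residues=spec.trimer_interface2)]
    patch_all = np.vstack([patch_t, patch_t2])
    z_patch = float(patch_all.mean(axis=0)[2])

    pose_t = None
    lo_x, hi_x = chain_r, 10.0 * chain_r
    for _ in range(80):
        mid = 0.5 * (lo_x + hi_x)
        t = np.array([mid, 0.0, z_patch])
        m = mono0.transformed(np.eye(3), t)
        pm_patch = m.xyz[m.mask(residues=spec.monomer_interface)]
        d_patch = cdist(patch_all, pm_patch).min()
        d_all = cdist(trimer.xyz, m.xyz).min()
        if d_all < 3.6:
            lo_x = mid
        elif d_patch > spec.contact_distance:
            hi_x = mid
        else:
            pose_t = t
            break
    if pose_t is None:
        raise ValueError("interface patches unreachable with this spec")

    pose = (np.eye(3), pose_t - mono_cent)
    truth = ComplexModel(core=trimer, monomer=monomer,
                         poses=[pose] * spec.copies,
                         symmetry={3: "P3", 2: "P2"}.get(spec.copies, "P1"),
                         seed=spec.seed)
    truth.meta["spec"] = spec
    truth.meta["generator_version"] = GENERATOR_VERSION
    truth.meta["restraints"] = [AmbiguousRestraint(
        trimer_residues={c: list(range(spec.trimer_interface[0], spec.trimer_interface[1] + 1))
                         + list(range(spec.trimer_interface2[0], spec.trimer_interface2[1] + 1))
                         for c in ("A", "B", "C")},
        monomer_residues=list(range(spec.monomer_interface[0], spec.monomer_interface[1] + 1)),
        copy_index=j, bound=10.0) for j in range(spec.copies)]
    return truth, trimer, monomer


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------

def default_s_grid(n: int = 120, s_max: float = 0.35) -> np.ndarray:
    return np.linspace(0.005, s_max, n)


def simulate_saxs(model, s: np.ndarray, noise: tuple = (0.0, 0.0),
                  seed: int = 0, label: str = "synthetic") -> ScatteringCurve:
    """Noisy Debye curve of a structure or complex model.

    ``noise = (a, b)`` sets the counting-statistics-like uncertainty
    ``sigma(s) = a sqrt(I) + b``; the intensity receives Gaussian noise
    of exactly that sigma and the sigma column is filled truthfully.
    """
    rng = np.random.default_rng(seed)
    structure = model.realize() if isinstance(model, ComplexModel) else model
    base = debye_curve(structure, s, label=label)
    a, b = noise
    if a == 0.0 and b == 0.0:
        return base
    sig = a * np.sqrt(np.abs(base.intensity)) + b
    intensity = base.intensity + rng.normal(0.0, 1.0, size=len(s)) * sig
    return ScatteringCurve(s, intensity, sig, label=label,
                           meta={"noise": noise, "seed": seed})


def simulate_sec_saxs_run(species_curves: list[ScatteringCurve],
                          elution_centers: list[float],
                          elution_widths: list[float],
                          elution_amplitudes: list[float],
                          n_frames: int = 60,
                          buffer_level: float = 5.0,
                          noise: tuple = (0.05, 0.001),
                          seed: int = 0) -> list[ScatteringCurve]:
    """Frame series of an in-line SEC-SAXS run.

    ``frame_t = buffer + sum_k w_k(t) I_k(s) + noise`` with Gaussian
    elution profiles w_k; a leading-edge species is emulated by an
    earlier, smaller Gaussian.  The buffer contribution is flat in s.
    """
    if not any(a > 0 for a in elution_amplitudes):
        raise ValueError("all elution profiles are zero")
    rng = np.random.default_rng(seed)
    s = species_curves[0].s
    frames = []
    a, b = noise
    for t in range(n_frames):
        I = np.full_like(s, buffer_level)
        for curve, c0, w, amp in zip(species_curves, elution_centers,
                                     elution_widths, elution_amplitudes):
            I = I + amp * np.exp(-0.5 * ((t - c0) / w) ** 2) * curve.intensity
        sig = a * np.sqrt(np.abs(I)) + b if (a or b) else np.full_like(s, 1e-6)
        if a or b:
            I = I + rng.normal(0.0, 1.0, size=len(s)) * sig
        frames.append(ScatteringCurve(s, I, sig, label=f"frame{t:04d}"))
    return frames


# ---------------------------------------------------------------------------
# HDX
# ---------------------------------------------------------------------------

def _peptide_map(spec: HdxSimSpec):
    peptides = []
    pid = 1
    start = 1
    while start <= spec.length - 3:
        end = min(start + spec.peptide_length - 1, spec.length)
        peptides.append((pid, start, end))
        pid += 1
        start += spec.peptide_step
    return peptides


def simulate_hdx_experiment(spec: HdxSimSpec, interface: list[tuple],
                            seed: int = 0):
    """Free and bound uptake tables under a two-state uptake model.

    Per-residue uptake at time t is ``1 - exp(-k_int t / P)`` with
    log-normal intrinsic rates; binding multiplies the protection
    factor P on interface residues by ``spec.protection_factor``.  A
    peptide's centroid mass shift sums the uptake of its exchange-
    competent residues (the first two of each peptide excluded) plus
    Gaussian noise.  Returns ``(free_records, bound_records,
    peptide_map)``.
    """
    for lo, hi in interface:
        if lo < 1 or hi > spec.length:
            raise ValueError(f"interface {lo}-{hi} outside protein 1-{spec.length}")
    rng = np.random.default_rng(seed)
    k_int = rng.lognormal(np.log(spec.rate_median_per_min), spec.rate_sigma_log,
                          size=spec.length + 1)
    protected = np.zeros(spec.length + 1, dtype=bool)
    for lo, hi in interface:
        protected[lo:hi + 1] = True
    peptides = _peptide_map(spec)

    free, bound = [], []
    for pid, start, end in peptides:
        residues = np.arange(start + 2, end + 1)
        for t in spec.times_min:
            up_free = np.sum(1.0 - np.exp(-k_int[residues] * t))
            pf = np.where(protected[residues], spec.protection_factor, 1.0)
            up_bound = np.sum(1.0 - np.exp(-k_int[residues] * t / pf))
            for rep in range(1, spec.replicates + 1):
                free.append(PeptideUptakeRecord(
                    spec.protein, pid, start, end, "free", t, rep,
                    float(up_free + rng.normal(0.0, spec.noise_sd_da))))
                bound.append(PeptideUptakeRecord(
                    spec.protein, pid, start, end, "bound", t, rep,
                    float(up_bound + rng.normal(0.0, spec.noise_sd_da))))
    coverage = np.zeros(spec.length + 1)
    for _, start, end in peptides:
        coverage[start:end + 1] += 1
    log.info("HDX simulation: coverage %.1f%%, redundancy %.1f",
             100.0 * np.mean(coverage[1:] > 0), np.mean(coverage[1:]))
    return free, bound, peptides


# ---------------------------------------------------------------------------
# ITC and inhibition
# ---------------------------------------------------------------------------

def simulate_itc_titration(n: float = 1.27, kd_m: float = 0.23e-6,
                           dh: float = -8000.0,
                           cell_conc_um: float = 20.0,
                           syringe_conc_um: float = 200.0,
                           injection_ul: np.ndarray | None = None,
                           cell_volume_ul: float = 200.0,
                           temperature_k: float = 293.15,
                           dilution_heat_ucal: float = 0.0,
                           noise_frac: float = 0.0,
                           seed: int = 0) -> ItcTable:
    """Exact single-site forward titration, optionally with noise.

    The default schedule is the benchmark design: a discarded 0.5 µL
    first injection followed by 19 x 2 µL.  ``noise_frac`` scales
    Gaussian noise by the largest corrected heat.
    """
    if injection_ul is None:
        injection_ul = np.array([0.5] + [2.0] * 19)
    injection_ul = np.asarray(injection_ul, dtype=float)
    c = n * cell_conc_um * 1e-6 / kd_m
    if not (0.1 <= c <= 1e5):
        log.warning("ITC simulation c-value %.3g outside [0.1, 1e5]", c)
    heats = itc_heats(n, kd_m, dh, cell_conc_um, syringe_conc_um, injection_ul,
                      cell_volume_ul=cell_volume_ul,
                      dilution_heat_ucal=dilution_heat_ucal)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_frac * np.abs(heats).max(),
                                   size=len(heats))
    return ItcTable(injection_ul, heats, cell_conc_um=cell_conc_um,
                    syringe_conc_um=syringe_conc_um,
                    cell_volume_ul=cell_volume_ul,
                    temperature_k=temperature_k, discard_first=True)


def simulate_inhibition_assay(ki: float = 6.7e-9, amplitude: float = 0.70,
                              e_total: float = 50e-9,
                              i_conc: np.ndarray | None = None,
                              noise_frac: float = 0.0, seed: int = 0):
    """Fractional-velocity table under the quadratic tight-binding model.

    Default inhibitor series spans the enzyme concentration (50 nM) as
    in the benchmark assay.  Returns ``(i_conc, v_over_v0)``.
    """
    if i_conc is None:
        i_conc = np.array([0.0, 10e-9, 25e-9, 50e-9, 100e-9, 250e-9, 500e-9])
    i_conc = np.asarray(i_conc, dtype=float)
    v = tight_binding_model(i_conc, ki, amplitude, e_total)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_frac, size=len(v))
    return i_conc, v
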