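"""Hydrogen-deuterium exchange difference analysis and interface mapping.

Replicate peptide uptake tables for a free and a bound state are turned
into bound-minus-free mass-shift differences (Woods-plot data), a 95%
confidence band from the pooled replicate scatter, a per-residue
projection of the accumulated differences, maximal runs of significant
protected residues (candidate binding interfaces), and a solvent-
accessibility filter that keeps only surface-exposed residues eligible
for distance restraints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from scipy.stats import norm

from .io import (DEFAULT_BEAD_RADIUS, PeptideUptakeRecord, StructureModel)

log = logging.getLogger(__name__)

__all__ = [
    "PeptideDelta", "ResidueDeltaProfile", "InterfaceMap",
    "peptide_deltas", "confidence_band", "residue_projection",
    "call_interface", "sasa_per_residue", "filter_interface_by_sasa",
]

# the first two residues of a peptide back-exchange too fast to carry signal
N_TERM_EXCLUDED = 2


@dataclass
class PeptideDelta:
    """Bound-minus-free mass shift of one peptide, per labelling time."""

    peptide_id: int
    start: int
    end: int
    times: np.ndarray            # labelling times, minutes
    dmass: np.ndarray            # Da, mean(bound) - mean(free) per time
    sd: np.ndarray               # pooled SD per time
    se: np.ndarray               # pooled SE of the difference per time
    n_free: np.ndarray
    n_bound: np.ndarray
    low_rep: bool = False        # any state/time with < 2 replicates

    @property
    def accumulated(self) -> float:
        """Mass-shift difference summed over all labelling times, Da."""
        return float(np.sum(self.dmass))


@dataclass
class ResidueDeltaProfile:
    residue: int
    mean_dmass: float            # accumulated Δmass averaged over covering peptides
    coverage: int
    band: tuple                  # (lower, upper) symmetric about 0
    call: str                    # "protected" | "deprotected" | "ns" | "no-data"


@dataclass
class InterfaceMap:
    protein: str
    segments: list = field(default_factory=list)   # [(first, last, direction)]
    eligible: set = field(default_factory=set)     # SASA-filtered residue set


# ---------------------------------------------------------------------------

def peptide_deltas(records: list[PeptideUptakeRecord]) -> list[PeptideDelta]:
    """Per-peptide, per-time bound-minus-free differences.

    A peptide/time cell enters only when both states were measured
    there; a cell with fewer than two replicates in either state is
    kept but flagged ``low_rep``.
    """
    table: dict = {}
    for r in records:
        table.setdefault(r.peptide_id, {"span": (r.start, r.end), "cells": {}})
        cell = table[r.peptide_id]["cells"].setdefault((r.state, r.time_min), [])
        cell.append(r.mass_shift_da)

    out = []
    for pid in sorted(table):
        span = table[pid]["span"]
        cells = table[pid]["cells"]
        times = sorted({t for (_, t) in cells})
        dmass, sd, se, nf, nb = [], [], [], [], []
        low_rep = False
        kept_times = []
        for t in times:
            free = cells.get(("free", t))
            bound = cells.get(("bound", t))
            if free is None or bound is None:
                continue
            kept_times.append(t)
            free, bound = np.asarray(free), np.asarray(bound)
            if len(free) < 2 or len(bound) < 2:
                low_rep = True
            dmass.append(bound.mean() - free.mean())
            vf = free.var(ddof=1) if len(free) > 1 else 0.0
            vb = bound.var(ddof=1) if len(bound) > 1 else 0.0
            sd.append(np.sqrt((vf + vb) / 2.0))
            se.append(np.sqrt(vf / len(free) + vb / len(bound)))
            nf.append(len(free))
            nb.append(len(bound))
        if not kept_times:
            continue
        out.append(PeptideDelta(
            peptide_id=pid, start=span[0], end=span[1],
            times=np.array(kept_times, dtype=float), dmass=np.array(dmass),
            sd=np.array(sd), se=np.array(se),
            n_free=np.array(nf), n_bound=np.array(nb), low_rep=low_rep))
    return out


def confidence_band(deltas: list[PeptideDelta], level: float = 0.95):
    """Half-width of the confidence band on a peptide Δmass.

    The pooled standard error of a single difference,
    ``SE = sqrt(SD_free^2/n_free + SD_bound^2/n_bound)``, is averaged in
    quadrature over peptides and scaled by the normal quantile of
    ``level``.  The accumulated band adds the per-time half-widths in
    quadrature.

    Returns ``(per_time: dict time -> half-width, accumulated: float)``.
    """
    if len(deltas) < 5:
        raise ValueError("need at least 5 peptides with replicate SDs")
    z = norm.ppf(0.5 + level / 2.0)
    times = sorted({t for d in deltas for t in d.times})
    per_time = {}
    for t in times:
        ses = [d.se[list(d.times).index(t)] for d in deltas if t in d.times]
        pooled = float(np.sqrt(np.mean(np.square(ses))))
        per_time[t] = z * pooled
    acc = float(np.sqrt(np.sum(np.square(list(per_time.values())))))
    if acc == 0.0:
        log.warning("confidence_band: all replicate SDs are zero, zero-width band")
    return per_time, acc


def residue_projection(deltas: list[PeptideDelta], protein_length: int,
                       accumulated_band: float) -> list[ResidueDeltaProfile]:
    """Project accumulated peptide differences onto residues.

    Each peptide contributes its accumulated Δmass uniformly to residues
    ``start+2 .. end`` (the first two are excluded as fast
    back-exchanging); the per-residue value is the mean over covering
    peptides, and a call is made against the accumulated band.
    """
    acc_sum = np.zeros(protein_length + 1)
    cover = np.zeros(protein_length + 1, dtype=int)
    for d in deltas:
        lo = min(d.start + N_TERM_EXCLUDED, d.end)
        for res in range(lo, d.end + 1):
            if 1 <= res <= protein_length:
                acc_sum[res] += d.accumulated
                cover[res] += 1
    out = []
    for res in range(1, protein_length + 1):
        if cover[res] == 0:
            out.append(ResidueDeltaProfile(res, np.nan, 0,
                                           (-accumulated_band, accumulated_band),
                                           "no-data"))
            continue
        mean = acc_sum[res] / cover[res]
        if mean < -accumulated_band:
            call = "protected"
        elif mean > accumulated_band:
            call = "deprotected"
        else:
            call = "ns"
        out.append(ResidueDeltaProfile(res, float(mean), int(cover[res]),
                                       (-accumulated_band, accumulated_band), call))
    return out


def call_interface(profile: list[ResidueDeltaProfile], protein: str = "",
                   gap_tolerance: int = 2) -> InterfaceMap:
    """Maximal runs of significant same-direction residues.

    Runs of protected (negative, band-exceeding) residues are merged
    when separated by at most ``gap_tolerance`` residues or by residues
    without coverage; deprotected runs are collected the same way.
    Global sub-band shifts never enter a segment.
    """
    imap = InterfaceMap(protein=protein)
    for direction in ("protected", "deprotected"):
        marks = sorted(p.residue for p in profile if p.call == direction)
        nodata = {p.residue for p in profile if p.call == "no-data"}
        if not marks:
            continue
        segs = [[marks[0], marks[0]]]
        for res in marks[1:]:
            gap = range(segs[-1][1] + 1, res)
            n_real_gap = sum(1 for g in gap if g not in nodata)
            if n_real_gap <= gap_tolerance:
                segs[-1][1] = res
            else:
                segs.append([res, res])
        imap.segments.extend((a, b, direction) for a, b in segs)
    imap.segments.sort()
    imap.eligible = {res for a, b, _ in imap.segments for res in range(a, b + 1)}
    return imap


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------

def sasa_per_residue(model: StructureModel, probe: float = 1.4,
                     bead_radius: float = DEFAULT_BEAD_RADIUS,
                     points: int = 960) -> dict:
    """Shrake-Rupley accessible surface per bead, Angstrom^2.

    Each residue bead is a sphere of ``bead_radius`` (effective residue
    radius); the probe radius is added on top.  Returns a mapping
    ``(chain, residue) -> area``.
    """
    xyz = model.xyz
    d2 = np.sum((xyz[None, :, :] - xyz[:, None, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    if np.any(d2 < 1e-12):
        raise ValueError("overlapping identical bead coordinates")
    arr = struc.AtomArray(len(model))
    arr.coord = xyz.astype(np.float32)
    arr.chain_id = np.array(model.chain)
    arr.res_id = model.resid
    arr.res_name = np.array(model.resname)
    arr.atom_name = np.array(["CA"] * len(model))
    arr.element = np.array(["C"] * len(model))
    areas = struc.sasa(arr, probe_radius=probe, point_number=points,
                       vdw_radii=np.full(len(model), bead_radius))
    return {(c, int(r)): float(a)
            for c, r, a in zip(model.chain, model.resid, areas)}


def filter_interface_by_sasa(imap: InterfaceMap, sasa: dict,
                             cutoff: float = 10.0,
                             chain: str | None = None) -> InterfaceMap:
    """Restrict the restraint-eligible residue set to surface residues.

    ``sasa`` maps ``(chain, residue) -> area``; residues at or below
    ``cutoff`` (Angstrom^2) are dropped from the eligible set; the
    reported segments stay untouched.  A residue absent from the table
    is kept with a warning.  With multiple chains the maximum area over
    chains is used unless ``chain`` picks one.
    """
    by_res: dict = {}
    for (c, res), area in sasa.items():
        if chain is not None and c != chain:
            continue
        by_res[res] = max(by_res.get(res, -np.inf), area)
    eligible = set()
    for res in imap.eligible:
        if res not in by_res:
            log.warning("residue %d absent from SASA table, kept", res)
            eligible.add(res)
        elif by_res[res] > cutoff:
            eligible.add(res)
    out = InterfaceMap(protein=imap.protein, segments=list(imap.segments),
                       eligible=eligible)
    return out
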