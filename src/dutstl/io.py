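"""Readers and writers for the file formats the pipeline touches.

Scattering curves travel as 3-column text files (``s  I  sigma``, the
ATSAS/SASBDB convention), structures as PDB, peptide-level deuterium
uptake and ITC injection heats as CSV.  All coordinates are in Angstrom,
momentum transfer in 1/Angstrom, residue spans 1-based inclusive.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ScatteringCurve",
    "StructureModel",
    "PeptideUptakeRecord",
    "ItcTable",
    "read_scattering_dat",
    "write_scattering_dat",
    "read_structure",
    "write_structure",
    "read_peptide_uptake_table",
    "write_peptide_uptake_table",
    "read_itc_table",
    "write_itc_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ScatteringCurve:
    """One buffer-subtracted 1-D SAXS profile with per-point uncertainty.

    Parameters
    ----------
    s : ndarray
        Momentum transfer grid, 1/Angstrom, strictly increasing,
        ``s = 4 pi sin(theta) / lambda``.
    intensity : ndarray
        I(s) on an arbitrary or absolute (1/cm) scale.
    sigma : ndarray
        Per-point uncertainty, same scale as the intensity.
    """

    s: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.s) == len(self.intensity) == len(self.sigma)):
            raise ValueError("s, intensity and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive everywhere")
        if np.any(self.s < 0):
            raise ValueError("momentum transfer must be non-negative")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("momentum transfer grid must be strictly increasing")

    def __len__(self):
        return len(self.s)

    def crop(self, s_min: float = 0.0, s_max: float = np.inf) -> "ScatteringCurve":
        m = (self.s >= s_min) & (self.s <= s_max)
        return ScatteringCurve(self.s[m], self.intensity[m], self.sigma[m],
                               label=self.label, meta=dict(self.meta))


# residue effective radius used for coarse (one bead per residue) models, Angstrom
DEFAULT_BEAD_RADIUS = 3.4
# virtual C-alpha bond length along a pseudo-chain, Angstrom
CA_BOND = 3.8

ROLE_RIGID = "rigid"
ROLE_DUMMY = "dummy"


@dataclass
class StructureModel:
    """Residue-level bead model: chains of (chain, resid, name, xyz, role).

    ``role`` distinguishes beads taken from a rigid body ("rigid") from
    dummy residues added for missing termini or linkers ("dummy").
    ``segments`` holds named residue ranges per chain, e.g.
    ``{"A": {"core": (1, 152)}}``.
    """

    chain: list
    resid: np.ndarray
    resname: list
    xyz: np.ndarray
    role: list
    segments: dict = field(default_factory=dict)

    def __post_init__(self):
        self.resid = np.asarray(self.resid, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.resid)
        if not (len(self.chain) == n == len(self.resname) == len(self.role) == len(self.xyz)):
            raise ValueError("bead attribute arrays must have equal length")
        for c in set(self.chain):
            ids = self.resid[[i for i, ch in enumerate(self.chain) if ch == c]]
            if len(ids) != len(set(ids.tolist())):
                raise ValueError(f"duplicate residue numbers in chain {c}")

    def __len__(self):
        return len(self.resid)

    @property
    def chains(self) -> list:
        seen = []
        for c in self.chain:
            if c not in seen:
                seen.append(c)
        return seen

    def mask(self, chain: str | None = None, residues: tuple[int, int] | None = None) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= np.array([c == chain for c in self.chain])
        if residues is not None:
            lo, hi = residues
            m &= (self.resid >= lo) & (self.resid <= hi)
        return m

    def subset(self, mask: np.ndarray) -> "StructureModel":
        idx = np.flatnonzero(mask)
        return StructureModel(
            [self.chain[i] for i in idx], self.resid[idx],
            [self.resname[i] for i in idx], self.xyz[idx],
            [self.role[i] for i in idx], dict(self.segments))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        out = self.copy()
        out.xyz = self.xyz @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def copy(self) -> "StructureModel":
        return StructureModel(list(self.chain), self.resid.copy(), list(self.resname),
                              self.xyz.copy(), list(self.role),
                              {k: dict(v) for k, v in self.segments.items()})

    def centroid(self) -> np.ndarray:
        return self.xyz.mean(axis=0)

    def rg(self) -> float:
        d = self.xyz - self.centroid()
        return float(np.sqrt((d ** 2).sum(axis=1).mean()))

    @staticmethod
    def concatenate(models: list["StructureModel"]) -> "StructureModel":
        segs: dict = {}
        for m in models:
            segs.update(m.segments)
        return StructureModel(
            sum((list(m.chain) for m in models), []),
            np.concatenate([m.resid for m in models]),
            sum((list(m.resname) for m in models), []),
            np.vstack([m.xyz for m in models]),
            sum((list(m.role) for m in models), []),
            segs)

    def auto_segments(self) -> dict:
        """Register one segment per chain spanning its residue range."""
        segs = {}
        for c in self.chains:
            ids = self.resid[self.mask(chain=c)]
            segs[c] = {"all": (int(ids.min()), int(ids.max()))}
        self.segments = segs
        return segs


@dataclass(frozen=True)
class PeptideUptakeRecord:
    """One replicate centroid mass shift of one peptide in one state/time."""

    protein: str
    peptide_id: int
    start: int
    end: int
    state: str          # "free" | "bound"
    time_min: float
    replicate: int
    mass_shift_da: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"peptide {self.peptide_id}: span start > end")
        if self.state not in ("free", "bound"):
            raise ValueError(f"unknown state {self.state!r}")


@dataclass
class ItcTable:
    """Integrated injection heats of one titration.

    Concentrations are protomer concentrations (µM); volumes µL;
    heats µcal; temperature K.  ``discard_first`` flags the customary
    small first injection.
    """

    injection_ul: np.ndarray
    heat_ucal: np.ndarray
    cell_conc_um: float
    syringe_conc_um: float
    cell_volume_ul: float = 200.0
    temperature_k: float = 293.15
    discard_first: bool = True

    def __post_init__(self):
        self.injection_ul = np.asarray(self.injection_ul, dtype=float)
        self.heat_ucal = np.asarray(self.heat_ucal, dtype=float)
        if len(self.injection_ul) != len(self.heat_ucal):
            raise ValueError("injection and heat columns must align")


# ---------------------------------------------------------------------------
# scattering .dat
# ---------------------------------------------------------------------------

def _parse_numeric_line(line: str):
    parts = line.replace(",", " ").split()
    try:
        vals = [float(p) for p in parts]
    except ValueError:
        return None
    return vals if len(vals) >= 2 else None


def read_scattering_dat(path, unit: str = "auto", sigma_model=None,
                        label: str | None = None) -> ScatteringCurve:
    """Read an ATSAS-style ``s I sigma`` text file.

    Lines that do not parse as numbers are kept verbatim in
    ``meta["header"]``.  Whitespace- and comma-separated columns are both
    accepted.  ``unit`` is one of ``"A-1"``, ``"nm-1"``, ``"auto"``;
    under ``auto`` a grid reaching past 2.0 is taken to be 1/nm and is
    divided by 10 (protein SAXS in 1/Angstrom rarely exceeds 1).

    A file without a third column is rejected unless ``sigma_model`` is
    given, a callable ``sigma_model(s, I) -> sigma``.
    """
    path = Path(path)
    header, rows = [], []
    for line in path.read_text().splitlines():
        vals = _parse_numeric_line(line)
        if vals is None:
            if line.strip():
                header.append(line.rstrip())
        else:
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no numeric data")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    s, i = arr[:, 0], arr[:, 1]
    if ncol >= 3:
        sig = arr[:, 2]
    elif sigma_model is not None:
        sig = np.asarray(sigma_model(s, i), dtype=float)
    else:
        raise ValueError(f"{path}: no uncertainty column and no sigma model supplied")
    if np.any(np.diff(s) <= 0):
        raise ValueError(f"{path}: momentum transfer not strictly increasing")
    meta = {"path": str(path)}
    if header:
        meta["header"] = "\n".join(header)
    if unit == "nm-1" or (unit == "auto" and s.max() > 2.0):
        s = s / 10.0
        meta["unit_converted"] = "nm-1 -> A-1"
    elif unit not in ("auto", "A-1"):
        raise ValueError(f"unknown unit hint {unit!r}")
    return ScatteringCurve(s, i, sig, label=label or path.stem, meta=meta)


def write_scattering_dat(path, curve: ScatteringCurve) -> None:
    path = Path(path)
    lines = []
    if "header" in curve.meta:
        lines.extend(curve.meta["header"].splitlines())
    for s, i, sig in zip(curve.s, curve.intensity, curve.sigma):
        lines.append(f"{s:.6e} {i:.6e} {sig:.6e}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# structures (PDB via gemmi)
# ---------------------------------------------------------------------------

def read_structure(path, coarse: bool = True) -> StructureModel:
    """Read a PDB file into a bead model (one bead per residue at C-alpha).

    Residues without a C-alpha are skipped with a warning; DUM residues
    are flagged as dummy beads.  ``coarse=False`` is reserved: this
    pipeline operates at residue resolution throughout.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    chain_l, resid_l, name_l, xyz_l, role_l = [], [], [], [], []
    for model in st:
        for ch in model:
            for res in ch:
                ca = res.find_atom("CA", "*")
                if ca is None:
                    log.warning("%s: residue %s %d%s has no CA, skipped",
                                path.name, res.name, res.seqid.num, ch.name)
                    continue
                chain_l.append(ch.name)
                resid_l.append(res.seqid.num)
                name_l.append(res.name)
                xyz_l.append([ca.pos.x, ca.pos.y, ca.pos.z])
                role_l.append(ROLE_DUMMY if res.name == "DUM" else ROLE_RIGID)
        break  # first MODEL only
    if not chain_l:
        raise ValueError(f"{path}: no residues with C-alpha found")
    m = StructureModel(chain_l, np.array(resid_l), name_l, np.array(xyz_l), role_l)
    m.auto_segments()
    return m


def write_structure(path, model: StructureModel) -> None:
    """Write a bead model as a PDB of CA atoms (dummy beads as DUM)."""
    st = gemmi.Structure()
    st.name = "beads"
    md = gemmi.Model("1")
    for cname in model.chains:
        ch = gemmi.Chain(cname)
        msk = model.mask(chain=cname)
        order = np.argsort(model.resid[msk])
        idx = np.flatnonzero(msk)[order]
        for i in idx:
            res = gemmi.Residue()
            res.name = "DUM" if model.role[i] == ROLE_DUMMY else model.resname[i]
            res.seqid = gemmi.SeqId(int(model.resid[i]), " ")
            at = gemmi.Atom()
            at.name = "CA"
            at.element = gemmi.Element("C")
            at.pos = gemmi.Position(*model.xyz[i])
            at.occ = 1.0
            res.add_atom(at)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# peptide uptake CSV
# ---------------------------------------------------------------------------

UPTAKE_COLUMNS = ["protein", "peptide_id", "start", "end", "state",
                  "time_min", "replicate", "mass_shift_da"]


def read_peptide_uptake_table(path, protein_length: int | None = None) -> list[PeptideUptakeRecord]:
    """Read an uptake CSV (columns ``protein,peptide_id,start,end,state,
    time_min,replicate,mass_shift_da``) into validated records.

    Rows whose span lies outside ``protein_length`` are rejected with the
    offending line number; a duplicate (peptide, state, time, replicate)
    key rejects the whole file.
    """
    path = Path(path)
    records, seen = [], set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(UPTAKE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = PeptideUptakeRecord(
                    protein=row["protein"], peptide_id=int(row["peptide_id"]),
                    start=int(row["start"]), end=int(row["end"]),
                    state=row["state"], time_min=float(row["time_min"]),
                    replicate=int(row["replicate"]),
                    mass_shift_da=float(row["mass_shift_da"]))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            if protein_length is not None and rec.end > protein_length:
                raise ValueError(f"{path}:{lineno}: span {rec.start}-{rec.end} "
                                 f"outside protein length {protein_length}")
            key = (rec.peptide_id, rec.state, rec.time_min, rec.replicate)
            if key in seen:
                raise ValueError(f"{path}: duplicate record {key}")
            seen.add(key)
            records.append(rec)
    return records


def write_peptide_uptake_table(path, records: list[PeptideUptakeRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(UPTAKE_COLUMNS)
        for r in records:
            w.writerow([r.protein, r.peptide_id, r.start, r.end, r.state,
                        f"{r.time_min:g}", r.replicate, f"{r.mass_shift_da:.6g}"])


def replicate_counts(records: list[PeptideUptakeRecord]) -> dict:
    """Replicate count per (peptide_id, state, time_min)."""
    counts: dict = {}
    for r in records:
        key = (r.peptide_id, r.state, r.time_min)
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# ITC CSV
# ---------------------------------------------------------------------------

def read_itc_table(path) -> ItcTable:
    """Read an ITC CSV (``injection_ul,heat_ucal`` columns, metadata in
    ``# key = value`` header lines)."""
    path = Path(path)
    meta, rows = {}, []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                meta[k.strip()] = float(v)
            continue
        if line.strip().lower().startswith("injection"):
            continue
        if line.strip():
            v, h = line.replace(",", " ").split()[:2]
            rows.append((float(v), float(h)))
    arr = np.array(rows)
    return ItcTable(arr[:, 0], arr[:, 1],
                    cell_conc_um=meta.get("cell_conc_um", np.nan),
                    syringe_conc_um=meta.get("syringe_conc_um", np.nan),
                    cell_volume_ul=meta.get("cell_volume_ul", 200.0),
                    temperature_k=meta.get("temperature_k", 293.15))


def write_itc_table(path, table: ItcTable) -> None:
    lines = [
        f"# cell_conc_um = {table.cell_conc_um:g}",
        f"# syringe_conc_um = {table.syringe_conc_um:g}",
        f"# cell_volume_ul = {table.cell_volume_ul:g}",
        f"# temperature_k = {table.temperature_k:g}",
        "injection_ul,heat_ucal",
    ]
    for v, h in zip(table.injection_ul, table.heat_ucal):
        lines.append(f"{v:.6g},{h:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
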