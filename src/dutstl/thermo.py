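"""Binding and inhibition thermodynamics.

One-set-of-sites fitting of ITC titrations (Wiseman isotherm with
cell-displacement bookkeeping), interpretation of the fitted
stoichiometry in protomers per trimer, initial-velocity extraction from
enzymatic progress curves, the Morrison quadratic tight-binding
inhibition fit, and protein-complex mass determination from native-MS
charge states.

Conventions: concentrations are protomer concentrations; in the
benchmark titration the calorimeter cell holds the inhibitor (Stl) and
the syringe the enzyme (hDUT), so the fitted N counts enzyme protomers
per inhibitor protomer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io import ItcTable

log = logging.getLogger(__name__)

__all__ = [
    "BindingFit", "InhibitionFit",
    "itc_heats", "fit_itc_one_site", "stoichiometry_per_trimer",
    "initial_velocity", "tight_binding_model", "fit_tight_binding",
    "mass_from_charge_states",
]

R_CAL = 1.98720425864083      # gas constant, cal/(mol K)
PROTON_MASS = 1.00728         # Da


@dataclass
class BindingFit:
    n: float                  # titrant protomers per cell-species protomer
    kd: float                 # M
    dh: float                 # cal/mol
    dg: float                 # cal/mol
    tds_neg: float            # -T*dS, cal/mol
    temperature_k: float
    n_err: float = np.nan
    kd_err: float = np.nan
    dh_err: float = np.nan
    dilution_heat_ucal: float = 0.0
    c_value: float = np.nan
    low_confidence: bool = False

    def check_consistency(self, rtol: float = 1e-6) -> bool:
        dg = R_CAL * self.temperature_k * np.log(self.kd)
        return (abs(dg - self.dg) <= rtol * abs(self.dg)
                and abs(self.dh + self.tds_neg - self.dg) <= rtol * max(abs(self.dg), 1.0))


@dataclass
class InhibitionFit:
    ki_app: float             # M
    amplitude: float          # maximal fractional inhibition, 0..1
    e_total: float            # M, fixed
    ki_err: float = np.nan
    amplitude_err: float = np.nan
    amplitude_pinned: bool = False


# ---------------------------------------------------------------------------
# ITC forward model and fit
# ---------------------------------------------------------------------------

def _bound_conc(m_tot, x_tot, n, kd):
    """Complex concentration under one set of N identical sites on M."""
    sites = n * m_tot
    b = sites + x_tot + kd
    return 0.5 * (b - np.sqrt(b * b - 4.0 * sites * x_tot))


def itc_heats(n: float, kd_m: float, dh: float, cell_conc_um: float,
              syringe_conc_um: float, injection_ul: np.ndarray,
              cell_volume_ul: float = 200.0,
              dilution_heat_ucal: float = 0.0) -> np.ndarray:
    """Per-injection heats (µcal) of the single-site total-heat model.

    Injection i displaces a volume fraction of the (pre-injection) cell
    content: ``M_i = M_{i-1}(1 - v_i/V0)``,
    ``X_i = X_{i-1}(1 - v_i/V0) + X_syr v_i/V0``.  The heat of the
    injection is ``V0 ΔH (B_i - B_{i-1}(1 - v_i/V0))`` with B the bound
    complex concentration, i.e. newly formed complex inside the cell.
    """
    v0 = cell_volume_ul
    m = cell_conc_um * 1e-6
    x = 0.0
    b_prev = 0.0
    heats = []
    for v in np.asarray(injection_ul, dtype=float):
        f = 1.0 - v / v0
        m *= f
        x = x * f + syringe_conc_um * 1e-6 * (v / v0)
        b = _bound_conc(m, x, n, kd_m)
        dq = dh * (v0 * 1e-6) * (b - b_prev * f)   # cal
        heats.append(dq * 1e6 + dilution_heat_ucal)
        b_prev = b
    return np.array(heats)


def fit_itc_one_site(table: ItcTable, discard_first: bool | None = None) -> BindingFit:
    """Fit N, Kd, ΔH (one set of independent sites) to integrated heats.

    The apparent dilution heat, estimated as the mean of the last three
    injections, is subtracted before fitting; a small residual constant
    offset remains a nuisance parameter of the fit so an imperfect
    end-of-titration estimate cannot bias the binding parameters.
    ΔG = RT ln Kd and -TΔS = ΔG - ΔH are derived at the table's
    temperature.  A c-value (N·[cell]/Kd) outside [1, 5000] flags the
    fit low-confidence.
    """
    if discard_first is None:
        discard_first = table.discard_first
    vol = table.injection_ul.copy()
    heat = table.heat_ucal.copy()
    use = np.ones(len(vol), dtype=bool)
    if discard_first:
        use[0] = False
    if np.count_nonzero(use) < 10:
        raise ValueError("need at least 10 usable injections")
    if np.allclose(heat, 0.0):
        raise ValueError("all-zero heats")

    dil = float(np.mean(heat[-3:]))
    heat_corr = heat - dil

    def model(params):
        n, log_kd, dh, offset = params
        return itc_heats(n, np.exp(log_kd), dh, table.cell_conc_um,
                         table.syringe_conc_um, vol,
                         cell_volume_ul=table.cell_volume_ul) + offset

    def residuals(params):
        return (model(params) - heat_corr)[use]

    # starting point: total heat ~ dH * V0 * (N * cell conc) at saturation,
    # stoichiometry from the titration midpoint
    x_end = table.syringe_conc_um * vol.sum() / table.cell_volume_ul
    n0 = float(np.clip(x_end / (2.0 * table.cell_conc_um), 0.1, 10.0))
    dh0 = (heat_corr[use].sum() * 1e-6
           / (table.cell_volume_ul * 1e-6 * n0 * table.cell_conc_um * 1e-6))
    lb = [1e-3, np.log(1e-13), -np.inf, -np.inf]
    ub = [100.0, np.log(1e-2), np.inf, np.inf]
    best = None
    for kd0 in (1e-6, 1e-7, 1e-8, 1e-5, 1e-9):
        p0 = np.array([n0, np.log(kd0), dh0, 0.0])
        try:
            sol = optimize.least_squares(residuals, p0, bounds=(lb, ub),
                                         xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                         max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("ITC fit did not converge")
    n, log_kd, dh, offset = best.x
    kd = float(np.exp(log_kd))

    # parameter SEs from the Jacobian
    try:
        _, s, vt = np.linalg.svd(best.jac, full_matrices=False)
        dof = max(np.count_nonzero(use) - 4, 1)
        cov = (vt.T / s ** 2) @ vt * (2.0 * best.cost / dof)
        n_err, kd_err, dh_err = (np.sqrt(cov[0, 0]), kd * np.sqrt(cov[1, 1]),
                                 np.sqrt(cov[2, 2]))
    except np.linalg.LinAlgError:
        n_err = kd_err = dh_err = np.nan

    t = table.temperature_k
    dg = R_CAL * t * np.log(kd)
    fit = BindingFit(n=float(n), kd=kd, dh=float(dh), dg=float(dg),
                     tds_neg=float(dg - dh), temperature_k=t,
                     n_err=float(n_err), kd_err=float(kd_err), dh_err=float(dh_err),
                     dilution_heat_ucal=dil + float(offset))
    fit.c_value = float(n * table.cell_conc_um * 1e-6 / kd)
    if not (1.0 <= fit.c_value <= 5000.0):
        fit.low_confidence = True
        log.warning("ITC fit c-value %.3g outside [1, 5000]: low confidence", fit.c_value)
    return fit


def stoichiometry_per_trimer(n: float):
    """Interpret fitted N (titrant per cell protomer) as inhibitor
    protomers per enzyme trimer: 3/N, also rounded to one decimal."""
    if n <= 0:
        raise ValueError("N must be positive")
    exact = 3.0 / n
    return exact, round(exact, 1)


# ---------------------------------------------------------------------------
# enzyme kinetics
# ---------------------------------------------------------------------------

def initial_velocity(time_s: np.ndarray, signal: np.ndarray,
                     fraction: float = 0.10):
    """Initial slope over the first ``fraction`` of the progress curve.

    The analysis window covers the points up to ``fraction`` of the
    total amplitude change; with fewer than 4 points the window is
    widened to 4 with a warning.  Returns (slope, SE) in signal/s.
    """
    time_s = np.asarray(time_s, dtype=float)
    signal = np.asarray(signal, dtype=float)
    amp = signal[-1] - signal[0]
    if amp == 0.0:
        return 0.0, 0.0
    prog = np.abs(signal - signal[0]) / abs(amp)
    n = int(np.searchsorted(prog, fraction, side="right"))
    if n < 4:
        log.warning("initial_velocity: window widened to 4 points")
        n = min(4, len(time_s))
    res = stats.linregress(time_s[:n], signal[:n])
    return float(res.slope), float(res.stderr if res.stderr is not None else np.nan)


def tight_binding_model(i_conc: np.ndarray, ki: float, amplitude: float,
                        e_total: float) -> np.ndarray:
    """Morrison 1:1 tight-binding fractional activity:

    ``v/v0 = 1 - A ([E]+[I]+Ki - sqrt(([E]+[I]+Ki)^2 - 4[E][I])) / (2[E])``
    """
    i_conc = np.asarray(i_conc, dtype=float)
    b = e_total + i_conc + ki
    frac_bound = (b - np.sqrt(b * b - 4.0 * e_total * i_conc)) / (2.0 * e_total)
    return 1.0 - amplitude * frac_bound


def fit_tight_binding(i_conc: np.ndarray, v_over_v0: np.ndarray,
                      e_total: float) -> InhibitionFit:
    """Fit Ki,app and the maximal inhibition amplitude, E fixed.

    Enzyme concentration is the protomer concentration of the assay and
    is not fitted.  The amplitude is bounded to [0, 1]; a fit pinned at
    either bound is flagged.
    """
    i_conc = np.asarray(i_conc, dtype=float)
    v = np.asarray(v_over_v0, dtype=float)
    if len(i_conc) < 5:
        raise ValueError("need at least 5 inhibitor concentrations")

    def model(x, log_ki, a):
        return tight_binding_model(x, np.exp(log_ki), a, e_total)

    a0 = float(np.clip(1.0 - v.min(), 0.05, 1.0))
    p0 = [np.log(max(e_total, 1e-12)), a0]
    popt, pcov = optimize.curve_fit(model, i_conc, v, p0=p0,
                                    bounds=([-60, 0.0], [10, 1.0]),
                                    xtol=1e-14, ftol=1e-14, max_nfev=20000)
    log_ki, a = popt
    perr = np.sqrt(np.diag(pcov))
    ki = float(np.exp(log_ki))
    pinned = bool(a <= 1e-9 or a >= 1.0 - 1e-9)
    if pinned:
        log.warning("tight-binding amplitude pinned at bound: %.3f", a)
    return InhibitionFit(ki_app=ki, amplitude=float(a), e_total=float(e_total),
                         ki_err=float(ki * perr[0]), amplitude_err=float(perr[1]),
                         amplitude_pinned=pinned)


# ---------------------------------------------------------------------------
# native MS
# ---------------------------------------------------------------------------

def mass_from_charge_states(peaks: list[tuple[float, int]]):
    """Neutral mass from (m/z, z) peaks: M = z·(m/z) - z·m_H.

    Returns (mean, SD) over peaks.
    """
    masses = []
    for mz, z in peaks:
        if z <= 0:
            raise ValueError("charge must be positive")
        masses.append(z * mz - z * PROTON_MASS)
    masses = np.array(masses)
    return float(masses.mean()), float(masses.std(ddof=1) if len(masses) > 1 else 0.0)
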