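"""Primary small-angle scattering analysis.

Covers the standard reduction chain for solution scattering of protein
complexes: Guinier analysis (radius of gyration and forward scattering
from the low-angle limit I(s) = I(0)·exp(-(s·Rg)²/3), valid for
s·Rg <~ 1.3), regularized indirect Fourier transform to the pair
distance distribution p(r), the Porod invariant and volume, molecular
mass estimators, Debye-formula model intensities for residue-level bead
models, the reduced chi-square between a model and an experimental
curve with an analytically optimal scale factor, and frame pooling for
in-line SEC-SAXS runs with co-eluting species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .io import ScatteringCurve, StructureModel

log = logging.getLogger(__name__)

__all__ = [
    "GuinierResult", "PrFunction", "VolumetricEstimates", "FitQuality",
    "guinier_fit", "invert_pr", "porod_volume", "mm_estimates",
    "debye_curve", "chi_square", "select_secsaxs_regions",
]

SRG_LIMIT = 1.3          # Guinier validity bound on s·Rg
SRG_TOL = 0.05


@dataclass
class GuinierResult:
    rg: float                 # Angstrom
    i0: float                 # curve units
    rg_err: float
    i0_err: float
    window: tuple             # (s_min, s_max) used, 1/Angstrom
    n_points: int
    r_squared: float
    srg_max: float            # s_max * Rg at the window end


@dataclass
class PrFunction:
    r: np.ndarray             # Angstrom, 0..Dmax
    p: np.ndarray
    dmax: float
    alpha: float
    rg_real: float
    i0_real: float
    chi2: float = np.nan      # of the forward transform against the input

    def moments(self):
        """Recompute (Rg_real, I0_real) from the stored arrays."""
        w = np.trapezoid(self.p, self.r)
        rg2 = np.trapezoid(self.r ** 2 * self.p, self.r) / (2.0 * w)
        return float(np.sqrt(rg2)), float(4.0 * np.pi * w)

    def forward(self, s: np.ndarray) -> np.ndarray:
        """I(s) corresponding to the stored p(r)."""
        s = np.asarray(s, dtype=float)
        sr = np.outer(s, self.r)
        kern = np.sinc(sr / np.pi)
        return 4.0 * np.pi * np.trapezoid(self.p[None, :] * kern, self.r, axis=1)


@dataclass
class VolumetricEstimates:
    vp: float | None = None           # Porod volume, Angstrom^3
    vex: float | None = None          # excluded volume, Angstrom^3
    mm_from_i0: float | None = None   # Da
    mm_from_vp: float | None = None
    mm_from_vex: float | None = None
    reference: tuple | None = None    # (I0_ref, MM_ref, c_ref)


@dataclass
class FitQuality:
    chi2: float
    scale: float
    n_points: int


# ---------------------------------------------------------------------------
# Guinier
# ---------------------------------------------------------------------------

def _wls_line(x, y, w):
    """Weighted least squares y = a + b x; returns a, b, var_a, var_b, r2."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    b = sxy / sxx
    a = ym - b * xm
    var_b = 1.0 / sxx
    var_a = 1.0 / W + xm ** 2 / sxx
    ss_res = np.sum(w * (y - a - b * x) ** 2)
    ss_tot = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return a, b, var_a, var_b, r2


def _leading_sign_run(res: np.ndarray) -> int:
    """Length of the same-sign residual run starting at the first point."""
    signs = np.sign(res)
    if len(signs) == 0 or signs[0] == 0:
        return 0
    run = 1
    for v in signs[1:]:
        if v == signs[0]:
            run += 1
        else:
            break
    return run


def guinier_fit(curve: ScatteringCurve, window: tuple | None = None,
                max_sign_run: int = 4) -> GuinierResult:
    """Guinier analysis: weighted regression of ln I on s².

    With ``window=(s_min, s_max)`` the fit is taken verbatim.  Otherwise
    the window is searched automatically: starting from the low-angle
    end, the upper bound is iterated until s_max·Rg converges to 1.3,
    and leading points are dropped while the residuals of the first part
    of the window show a systematic same-sign run (aggregation or
    beam-smearing signature) longer than ``max_sign_run``.
    """
    pos = curve.intensity > 0
    if np.count_nonzero(~pos):
        log.warning("guinier_fit: %d non-positive intensities excluded",
                    int(np.count_nonzero(~pos)))
    s, I, sig = curve.s[pos], curve.intensity[pos], curve.sigma[pos]
    if len(s) < 5:
        raise ValueError("no Guinier region: fewer than 5 positive points")
    x_all = s ** 2
    y_all = np.log(I)
    w_all = (I / sig) ** 2      # var(ln I) = (sigma/I)^2

    def fit(lo, hi):
        a, b, va, vb, r2 = _wls_line(x_all[lo:hi], y_all[lo:hi], w_all[lo:hi])
        if b >= 0:
            return None
        rg = np.sqrt(-3.0 * b)
        return a, b, va, vb, r2, rg

    if window is not None:
        lo = int(np.searchsorted(s, window[0]))
        hi = int(np.searchsorted(s, window[1], side="right"))
        if hi - lo < 5:
            raise ValueError("no Guinier region: window holds fewer than 5 points")
        out = fit(lo, hi)
        if out is None:
            raise ValueError("no Guinier region: non-negative slope in window")
    else:
        lo = 0
        out = None
        for _ in range(200):
            # converge the upper bound onto s_max * Rg = 1.3
            hi = min(lo + 10, len(s))
            trial = fit(lo, hi)
            if trial is None:
                lo += 1
                continue
            for _ in range(50):
                rg = trial[5]
                hi_new = int(np.searchsorted(s, SRG_LIMIT / rg, side="right"))
                hi_new = max(hi_new, lo + 5)
                if hi_new == hi:
                    break
                hi = hi_new
                t2 = fit(lo, hi)
                if t2 is None:
                    break
                trial = t2
            if trial is None or hi - lo < 5:
                lo += 1
                continue
            a, b, va, vb, r2, rg = trial
            head = min(15, hi - lo)
            resid = y_all[lo:lo + head] - (a + b * x_all[lo:lo + head])
            run = _leading_sign_run(resid)
            # drop leading points only when the systematic run also exceeds
            # the noise level (aggregation / beam-smearing signature)
            sig_ln = 1.0 / np.sqrt(np.median(w_all[lo:hi]))
            if (run > max_sign_run and hi - (lo + 1) >= 5
                    and np.mean(np.abs(resid[:run])) > sig_ln):
                lo += 1
                continue
            out = trial
            break
        if out is None:
            raise ValueError("no Guinier region: auto-search failed")
        if s[lo] * out[5] > SRG_LIMIT + SRG_TOL:
            raise ValueError("no Guinier region: data start beyond s*Rg = 1.3")

    a, b, va, vb, r2, rg = out
    n = hi - lo
    # scale parameter variances by residual variance (standard WLS practice)
    dof = max(n - 2, 1)
    chi_red = np.sum(w_all[lo:hi] * (y_all[lo:hi] - a - b * x_all[lo:hi]) ** 2) / dof
    rg_err = np.sqrt(3.0 * vb * chi_red) / (2.0 * rg) if rg > 0 else np.nan
    i0 = float(np.exp(a))
    i0_err = float(i0 * np.sqrt(va * chi_red))
    return GuinierResult(rg=float(rg), i0=i0, rg_err=float(rg_err), i0_err=i0_err,
                         window=(float(s[lo]), float(s[hi - 1])), n_points=int(n),
                         r_squared=float(r2), srg_max=float(s[hi - 1] * rg))


# ---------------------------------------------------------------------------
# indirect Fourier transform
# ---------------------------------------------------------------------------

def _ift_design(s, r):
    dr = r[1] - r[0]
    sr = np.outer(s, r)
    T = 4.0 * np.pi * dr * np.sinc(sr / np.pi)
    # trapezoid end-weights (endpoints excluded anyway, kept for clarity)
    return T


def invert_pr(curve: ScatteringCurve, dmax: float, alpha: float | None = None,
              nr: int = 101) -> PrFunction:
    """Regularized indirect Fourier transform of I(s) to p(r).

    Solves the Tikhonov problem
    ``min ||(I - T p)/sigma||^2 + alpha ||D2 p||^2`` with the endpoint
    constraints p(0) = p(Dmax) = 0, where
    ``T_ij = 4 pi dr sin(s_i r_j)/(s_i r_j)``.  When ``alpha`` is not
    given it is chosen at the corner of the L-curve (maximum curvature
    of log residual norm vs log seminorm).
    """
    if dmax <= 0:
        raise ValueError("Dmax must be positive")
    if len(curve) < 50:
        raise ValueError("need at least 50 data points for the inversion")
    try:
        g = guinier_fit(curve)
        if dmax < 2.0 * g.rg / 1.5:
            log.warning("invert_pr: Dmax=%.1f is small vs Guinier Rg=%.1f", dmax, g.rg)
    except ValueError:
        pass

    r = np.linspace(0.0, dmax, nr)
    T = _ift_design(curve.s, r)
    # endpoint constraint: solve for interior points only
    Ti = T[:, 1:-1]
    A = Ti / curve.sigma[:, None]
    b = curve.intensity / curve.sigma
    m = Ti.shape[1]
    # second-difference operator with implicit zero boundaries
    D2 = np.zeros((m, m))
    for k in range(m):
        D2[k, k] = -2.0
        if k > 0:
            D2[k, k - 1] = 1.0
        if k < m - 1:
            D2[k, k + 1] = 1.0

    AtA = A.T @ A
    Atb = A.T @ b
    DtD = D2.T @ D2
    scale0 = np.trace(AtA) / np.trace(DtD)

    def solve(al):
        for boost in range(5):
            try:
                p_int = np.linalg.solve(AtA + al * (10.0 ** boost) * DtD, Atb)
                return p_int
            except np.linalg.LinAlgError:
                continue
        raise np.linalg.LinAlgError("IFT system singular after 5 regularization boosts")

    if alpha is None:
        # L-curve corner, located as the largest regularization that still
        # attains (within 5%) the best achievable residual: the fit stays
        # at the noise level while the solution is as smooth as possible
        alphas = scale0 * np.logspace(-10, 2, 37)
        chi2s = []
        for al in alphas:
            p_int = solve(al)
            chi2s.append(np.sum((A @ p_int - b) ** 2) / max(len(b) - 1, 1))
        chi2s = np.array(chi2s)
        best = float(np.nanmin(chi2s))
        ok = chi2s <= 1.05 * best + 1e-12
        alpha = float(alphas[int(np.flatnonzero(ok)[-1])])

    p_int = solve(alpha)
    p = np.zeros(nr)
    p[1:-1] = p_int

    pr = PrFunction(r=r, p=p, dmax=float(dmax), alpha=float(alpha),
                    rg_real=np.nan, i0_real=np.nan)
    pr.rg_real, pr.i0_real = pr.moments()
    model = ScatteringCurve(curve.s, pr.forward(curve.s),
                            curve.sigma, label="ift-forward")
    pr.chi2 = chi_square(model, curve).chi2
    return pr


# ---------------------------------------------------------------------------
# Porod
# ---------------------------------------------------------------------------

def porod_volume(curve: ScatteringCurve, i0: float) -> float:
    """Porod volume Vp = 2 pi^2 I(0) / Q from the Porod invariant
    Q = int s^2 (I(s) - K) ds.

    The constant background K is a regression of s^4 I on s^4 over the
    high-angle quartile (flattening s^4 (I-K)); the unmeasured range
    below s_min is filled with the Guinier extrapolation.
    """
    s, I = curve.s, curve.intensity
    q4 = len(s) * 3 // 4
    x = s[q4:] ** 4
    y = x * I[q4:]
    K = float(np.polyfit(x, y, 1)[0])     # slope of s^4 I vs s^4
    K = max(K, 0.0)
    g = guinier_fit(curve)
    s_fill = np.linspace(0.0, s[0], 32, endpoint=False)
    i_fill = i0 * np.exp(-(s_fill * g.rg) ** 2 / 3.0)
    s_all = np.concatenate([s_fill, s])
    i_all = np.concatenate([i_fill, I - K])
    q = float(np.trapezoid(s_all ** 2 * i_all, s_all))
    if q <= 0:
        raise ValueError("invalid Porod region: non-positive invariant")
    return float(2.0 * np.pi ** 2 * i0 / q)


def mm_estimates(i0: float | None = None, concentration: float | None = None,
                 reference: tuple | None = None, vp: float | None = None,
                 vex: float | None = None,
                 vp_divisor: float = 1.6,
                 vp_factor: float | None = None) -> VolumetricEstimates:
    """Molecular-mass estimates from forward scattering and volumes.

    ``MM_from_I0 = MM_ref * (I0/c) / (I0_ref/c_ref)`` against a
    reference solution (bovine serum albumin in the benchmark tables);
    ``MM_from_Vp = Vp / 1.6`` by default (``vp_factor=0.588`` switches
    to the multiplicative rule); ``MM_from_Vex = Vex / 2``.
    """
    est = VolumetricEstimates(vp=vp, vex=vex, reference=reference)
    if i0 is not None and reference is not None and concentration is not None:
        i0_ref, mm_ref, c_ref = reference
        est.mm_from_i0 = mm_ref * (i0 / concentration) / (i0_ref / c_ref)
    if vp is not None:
        est.mm_from_vp = vp * vp_factor if vp_factor is not None else vp / vp_divisor
    if vex is not None:
        est.mm_from_vex = vex / 2.0
    return est


# ---------------------------------------------------------------------------
# Debye scattering
# ---------------------------------------------------------------------------

def default_sigma_model(s: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """1% relative + small floor pseudo-uncertainty for model curves."""
    return 0.01 * np.abs(intensity) + 1e-4 * float(np.max(np.abs(intensity)))


def debye_curve(model: StructureModel, s: np.ndarray, bead_sigma: float = 3.0,
                bin_width: float = 0.5, label: str = "debye") -> ScatteringCurve:
    """Model intensity by the Debye formula over residue beads.

    ``I(s) = f(s)^2 [N + 2 sum_pairs sinc(s r_ij)]`` with a Gaussian
    bead form factor ``f(s) = exp(-s^2 sigma_b^2 / 2)``.  Pair distances
    are histogram-binned (default 0.5 Angstrom) so the double sum
    collapses to one term per occupied bin.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    s = np.asarray(s, dtype=float)
    n = len(model)
    d = pdist(model.xyz)
    if len(d):
        nbins = max(int(np.ceil(d.max() / bin_width)) + 1, 1)
        rng = (0.0, nbins * bin_width)
        hist, _ = np.histogram(d, bins=nbins, range=rng)
        dsum, _ = np.histogram(d, bins=nbins, range=rng, weights=d)
        occ = hist > 0
        centers = dsum[occ] / hist[occ]      # mean distance per occupied bin
        sr = np.outer(s, centers)
        pair_term = 2.0 * (np.sinc(sr / np.pi) @ hist[occ])
    else:
        pair_term = 0.0
    f2 = np.exp(-(s * bead_sigma) ** 2)
    intensity = f2 * (n + pair_term)
    return ScatteringCurve(s, intensity, default_sigma_model(s, intensity),
                           label=label)


# ---------------------------------------------------------------------------
# discrepancy (reduced chi-square with optimal scale)
# ---------------------------------------------------------------------------

def chi_square(model_curve: ScatteringCurve, experimental: ScatteringCurve,
               extrapolation_tol: float = 1e-9) -> FitQuality:
    """Reduced discrepancy between a model and an experimental curve:

    ``chi^2 = 1/(N-1) sum_j [(I_exp(s_j) - c I_calc(s_j)) / sigma(s_j)]^2``

    with the analytically optimal scale
    ``c = sum(I_exp I_calc / sigma^2) / sum(I_calc^2 / sigma^2)``.
    The model is interpolated onto the experimental grid; experimental
    points outside the model's s-range are a grid mismatch.
    """
    se, ie, sig = experimental.s, experimental.intensity, experimental.sigma
    sm = model_curve.s
    if se.min() < sm.min() - extrapolation_tol or se.max() > sm.max() + extrapolation_tol:
        raise ValueError("grid mismatch: experimental s-range exceeds model range")
    ic = np.interp(se, sm, model_curve.intensity)
    w = 1.0 / sig ** 2
    c = float(np.sum(w * ie * ic) / np.sum(w * ic ** 2))
    n = len(se)
    chi2 = float(np.sum(((ie - c * ic) / sig) ** 2) / (n - 1))
    return FitQuality(chi2=chi2, scale=c, n_points=n)


# ---------------------------------------------------------------------------
# SEC-SAXS frame pooling
# ---------------------------------------------------------------------------

def select_secsaxs_regions(frames: list[ScatteringCurve],
                           buffer_frames: list[tuple[int, int]],
                           similarity_chi2: float = 1.5,
                           peak_snr: float = 3.0,
                           min_frames: int = 3):
    """Pool consecutive similar elution frames of a SEC-SAXS run.

    The buffer frames (index ranges, inclusive) are averaged and
    subtracted from every frame.  Frames whose integrated signal exceeds
    ``peak_snr`` times the buffer-level noise form the elution peak;
    walking through the peak, a frame joins the current region while its
    scale-free reduced chi-square against the region's first frame stays
    below ``similarity_chi2``, otherwise a new region starts.  Pools
    shorter than ``min_frames`` (transition frames between co-eluting
    species) are dropped; each remaining region is averaged with
    inverse-variance weights.

    Returns a list of ``(label, frame_indices, averaged_curve)`` ordered
    by elution; the averaged curve's meta carries per-frame Guinier
    traces of the region.
    """
    if len(frames) < 20:
        raise ValueError("need at least 20 frames")
    s = frames[0].s
    buf_idx = sorted({i for lo, hi in buffer_frames for i in range(lo, hi + 1)})
    if not buf_idx:
        raise ValueError("no buffer frames given")
    buf_I = np.mean([frames[i].intensity for i in buf_idx], axis=0)
    buf_sig = np.sqrt(np.mean([frames[i].sigma ** 2 for i in buf_idx], axis=0)
                      / len(buf_idx))

    sub = []
    for fr in frames:
        sig = np.sqrt(fr.sigma ** 2 + buf_sig ** 2)
        sub.append(ScatteringCurve(s, fr.intensity - buf_I, sig, label=fr.label))

    totals = np.array([np.trapezoid(np.abs(c.intensity), s) for c in sub])
    noise = np.array([np.trapezoid(c.sigma, s) for c in sub])
    in_peak = totals > peak_snr * noise
    for i in buf_idx:
        in_peak[i] = False
    if not in_peak.any():
        raise ValueError("no elution peak: no frames above buffer signal")

    def pair_chi2(a: ScatteringCurve, b: ScatteringCurve) -> float:
        """Reduced chi-square between two noisy frames, scale absorbed,
        both uncertainty columns propagated."""
        c = 1.0
        for _ in range(3):
            var = a.sigma ** 2 + (c * b.sigma) ** 2
            c = float(np.sum(a.intensity * b.intensity / var)
                      / np.sum(b.intensity ** 2 / var))
        var = a.sigma ** 2 + (c * b.sigma) ** 2
        return float(np.sum((a.intensity - c * b.intensity) ** 2 / var)
                     / (len(a) - 1))

    peak_idx = np.flatnonzero(in_peak)
    regions: list[list[int]] = [[int(peak_idx[0])]]
    for i in peak_idx[1:]:
        anchor = sub[regions[-1][0]]
        if int(i) - regions[-1][-1] > 1:
            regions.append([int(i)])
            continue
        if pair_chi2(sub[int(i)], anchor) < similarity_chi2:
            regions[-1].append(int(i))
        else:
            regions.append([int(i)])

    regions = [r for r in regions if len(r) >= min_frames] or regions[:1]
    out = []
    for k, idxs in enumerate(regions, start=1):
        w = np.array([1.0 / sub[i].sigma ** 2 for i in idxs])
        I = np.array([sub[i].intensity for i in idxs])
        wsum = w.sum(axis=0)
        avg_I = (w * I).sum(axis=0) / wsum
        avg_sig = np.sqrt(1.0 / wsum)
        avg = ScatteringCurve(s, avg_I, avg_sig, label=f"region{k}")
        trace = {}
        for i in idxs:
            try:
                g = guinier_fit(sub[i])
                trace[i] = (g.rg, g.i0)
            except ValueError:
                trace[i] = (np.nan, np.nan)
        avg.meta["frame_guinier"] = trace
        avg.meta["frames"] = list(idxs)
        out.append((f"region{k}", list(idxs), avg))
    return out
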