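"""Small-angle X-ray scattering analytics for 1-D curves.

Covers the standard SEC-SAXS reduction chain: buffer subtraction, iterative
Guinier fitting (Rg, I0), dimensionless Kratky representation, molecular
weight from the correlation volume, the pair-distance distribution P(r) and
maximal extension Dmax by regularized indirect Fourier transform, the
chi-square comparison of an experimental curve against a model curve with
the analytic least-squares scale factor, and selection/averaging of elution
frames with stable Rg.

Conventions: q in 1/A (A = angstrom), distances in A, intensities in
arbitrary units with per-point uncertainties sigma in the same units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

__all__ = [
    "ScatteringCurve",
    "GuinierFit",
    "PairDistribution",
    "CurveComparison",
    "SecSaxsSeries",
    "GuinierError",
    "PrEstimationError",
    "FrameSelectionError",
    "KRATKY_GLOBULAR_PEAK",
    "MW_CALIBRATIONS",
    "buffer_subtract",
    "guinier_fit",
    "dimensionless_kratky",
    "correlation_volume_mw",
    "pair_distribution",
    "optimal_scale",
    "chi_square",
    "select_stable_frames",
]

# (q*Rg, (q*Rg)^2 I/I0) at the maximum for an ideal globular particle obeying
# the Guinier law: u^2 exp(-u^2/3) peaks at u = sqrt(3) with height 3/e.
KRATKY_GLOBULAR_PEAK = (np.sqrt(3.0), 3.0 / np.e)

# Correlation-volume -> molecular weight power laws (QR = Vc^2 / Rg, mass in
# Da).  The protein and RNA calibrations differ; neither is claimed correct
# for mixed protein/nucleic-acid particles.
MW_CALIBRATIONS = {
    "protein": {"divisor": 0.1231, "exponent": 1.0},
    "rna": {"divisor": 0.00934, "exponent": 0.808},
}


class GuinierError(RuntimeError):
    """Guinier analysis cannot produce a valid (Rg, I0)."""


class PrEstimationError(RuntimeError):
    """No candidate Dmax gives an acceptable P(r) back-transform."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FrameSelectionError(RuntimeError):
    """No stable run of elution frames could be selected."""


@dataclass
class ScatteringCurve:
    """A 1-D scattering curve I(q) with optional per-point uncertainties."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.size != self.I.size:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(~np.isfinite(self.q)) or np.any(self.q <= 0):
            raise ValueError("q must be finite and > 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.size != self.q.size:
                raise ValueError("sigma length mismatch")

    @property
    def n_points(self) -> int:
        return int(self.q.size)

    def require_sigma(self) -> np.ndarray:
        if self.sigma is None or np.any(self.sigma <= 0):
            raise ValueError("positive per-point sigma required")
        return self.sigma


def _common_grid(a: ScatteringCurve, b: ScatteringCurve, interpolate: bool):
    if a.q.size == b.q.size and np.allclose(a.q, b.q, rtol=0, atol=1e-12):
        return b.I, b.sigma
    if not interpolate:
        raise ValueError("curves are on different q grids (interpolation off)")
    I = np.interp(a.q, b.q, b.I)
    sigma = np.interp(a.q, b.q, b.sigma) if b.sigma is not None else None
    return I, sigma


def buffer_subtract(
    sample: ScatteringCurve, buffer: ScatteringCurve, interpolate: bool = False
) -> ScatteringCurve:
    """Subtract buffer scattering from a sample curve.

    Uncertainties combine in quadrature.  The buffer may be interpolated onto
    the sample grid when ``interpolate`` is set.
    """
    Ib, sb = _common_grid(sample, buffer, interpolate)
    I = sample.I - Ib
    if sample.sigma is not None and sb is not None:
        sigma = np.sqrt(sample.sigma**2 + sb**2)
    elif sample.sigma is not None:
        sigma = sample.sigma.copy()
    else:
        sigma = None
    return ScatteringCurve(sample.q.copy(), I, sigma, dict(sample.metadata))


@dataclass
class GuinierFit:
    """Result of an iterated Guinier fit: ln I = ln I0 - (Rg^2/3) q^2."""

    Rg: float  # A
    I0: float
    q_min: float
    q_max: float
    qmax_rg: float
    r_squared: float
    n_points: int


def _guinier_window(
    q: np.ndarray, lnI: np.ndarray, limit: float, min_points: int, max_iter: int
) -> int:
    """Iterate (fit -> recompute window from Rg) to a self-consistent size."""
    hi = min(max(min_points, q.size // 10), q.size)
    prev_hi = -1
    for _ in range(max_iter):
        if hi < min_points:
            raise GuinierError(f"only {hi} points satisfy q*Rg <= {limit}")
        slope, _ = np.polyfit(q[:hi] ** 2, lnI[:hi], 1)
        if slope >= 0:
            # a noise-dominated narrow window can masquerade as rising
            # low-q; widen before declaring failure
            if hi < q.size:
                prev_hi = hi
                hi = min(2 * hi, q.size)
                continue
            raise GuinierError("non-negative Guinier slope (rising low-q)")
        Rg = float(np.sqrt(-3.0 * slope))
        new_hi = int(np.searchsorted(q, limit / Rg, side="right"))
        new_hi = min(new_hi, q.size)
        if new_hi == hi or new_hi == prev_hi:  # fixed point (or 2-cycle)
            hi = min(hi, new_hi) if new_hi == prev_hi else hi
            break
        prev_hi = hi
        hi = new_hi
    if hi < min_points:
        raise GuinierError(f"only {hi} points satisfy q*Rg <= {limit}")
    return hi


def guinier_fit(
    curve: ScatteringCurve,
    qmax_rg_limit: float = 1.3,
    min_points: int = 5,
    max_iter: int = 100,
    curvature_tol: float = 0.005,
) -> GuinierFit:
    """Guinier fit iterated to a self-consistent low-q window.

    Starting from the lowest usable q (first positive intensity), a straight
    line is fit to ln I vs q^2; the window upper edge is then recomputed from
    the fitted Rg as q_max = qmax_rg_limit / Rg and the fit repeated until the
    window stops changing.  Rg = sqrt(-3 * slope), I0 = exp(intercept).

    ``qmax_rg_limit`` is an outer bound on the window: if an added quadratic
    term in q^2 shifts Rg by more than ``curvature_tol`` (relative) — i.e.
    the data leave the Guinier regime inside the window, as compact globular
    shapes do near q*Rg = 1.3 — the window is shrunk until the linear law is
    self-consistent or ``min_points`` is reached.
    """
    pos = np.nonzero(curve.I > 0)[0]
    if pos.size < min_points:
        raise GuinierError("fewer than min_points positive intensities")
    i0 = pos[0]
    usable = np.arange(i0, curve.q.size)
    usable = usable[curve.I[usable] > 0]
    q = curve.q[usable]
    lnI = np.log(curve.I[usable])

    limit = qmax_rg_limit
    hi = _guinier_window(q, lnI, limit, min_points, max_iter)
    for _ in range(12):
        x = q[:hi] ** 2
        y = lnI[:hi]
        slope, intercept = np.polyfit(x, y, 1)
        if hi <= max(min_points, 6):
            break
        quad, quad_cov = np.polyfit(x, y, 2, cov=True)
        slope_quad = quad[1]
        if slope_quad >= 0 or slope >= 0:
            break
        # shrink only for curvature that is both material for Rg and clearly
        # above the noise (otherwise the window would chase random wiggles)
        significant = abs(quad[0]) > 2.0 * np.sqrt(quad_cov[0, 0])
        rg_lin = np.sqrt(-3.0 * slope)
        rg_quad = np.sqrt(-3.0 * slope_quad)
        if not significant or abs(rg_lin - rg_quad) <= curvature_tol * rg_quad:
            break
        limit *= 0.9
        hi = _guinier_window(q, lnI, limit, min_points, max_iter)
    x = q[:hi] ** 2
    y = lnI[:hi]
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise GuinierError("non-negative Guinier slope (rising low-q)")
    Rg = float(np.sqrt(-3.0 * slope))
    yhat = intercept + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GuinierFit(
        Rg=Rg,
        I0=float(np.exp(intercept)),
        q_min=float(q[0]),
        q_max=float(q[hi - 1]),
        qmax_rg=float(q[hi - 1] * Rg),
        r_squared=r2,
        n_points=hi,
    )


def dimensionless_kratky(
    curve: ScatteringCurve, g: GuinierFit
) -> dict[str, np.ndarray | tuple[float, float]]:
    """Dimensionless Kratky transform (q*Rg, (q*Rg)^2 * I/I0).

    A compact globular particle peaks at the reference point
    (sqrt(3), 3/e) ~= (1.73, 1.10); flexible or extended particles rise above
    that level at high q*Rg.  The reference point is returned for overlay.
    """
    u = curve.q * g.Rg
    y = u**2 * curve.I / g.I0
    return {"qrg": u, "kratky": y, "reference_peak": KRATKY_GLOBULAR_PEAK}


def correlation_volume_mw(
    curve: ScatteringCurve,
    g: GuinierFit,
    integration_qmax: float | None = None,
    calibration: str = "protein",
) -> tuple[float, float]:
    """Correlation volume Vc (A^2) and molecular-weight estimate (kDa).

    Vc = I(0) / integral_0^qmax q I(q) dq.  The segment below the first
    measured q is filled with the Guinier extrapolation (closed form); the
    rest is integrated by the trapezoid rule.  The default integration limit
    is min(0.3 A^-1, 8/Rg).  MW comes from the correlation-volume power law
    QR = Vc^2/Rg with calibration constants recorded in
    :data:`MW_CALIBRATIONS`.
    """
    if calibration not in MW_CALIBRATIONS:
        raise ValueError(f"unknown calibration {calibration!r}")
    if integration_qmax is None:
        integration_qmax = min(0.3, 8.0 / g.Rg)
    sel = curve.q <= integration_qmax
    if sel.sum() < 2:
        raise ValueError("curve does not extend over the integration range")
    q = curve.q[sel]
    I = curve.I[sel]
    # analytic Guinier fill on [0, q_min]: int q I0 exp(-q^2 Rg^2/3) dq
    a = g.Rg**2 / 3.0
    head = g.I0 / (2.0 * a) * (1.0 - np.exp(-a * q[0] ** 2))
    integral = head + float(np.trapezoid(q * I, q))
    if integral <= 0:
        raise ValueError("non-positive q*I integral: degenerate curve")
    Vc = g.I0 / integral
    cal = MW_CALIBRATIONS[calibration]
    qr = Vc**2 / g.Rg
    mw_da = (qr / cal["divisor"]) ** cal["exponent"]
    return float(Vc), float(mw_da / 1e3)


# ---------------------------------------------------------------------------
# P(r) by regularized indirect Fourier transform


@dataclass
class PairDistribution:
    """Pair-distance distribution with its back-transform diagnostics."""

    r: np.ndarray  # A
    p: np.ndarray
    dmax: float  # A
    alpha: float  # regularization weight
    back_chi2: float
    scan: dict | None = None  # Dmax-scan diagnostics when auto-selected

    def rg(self) -> float:
        """Rg from the second moment: Rg^2 = int r^2 p dr / (2 int p dr)."""
        num = np.trapezoid(self.r**2 * self.p, self.r)
        den = np.trapezoid(self.p, self.r)
        if den <= 0:
            raise ValueError("non-positive p(r) integral")
        return float(np.sqrt(num / (2.0 * den)))

    def i0(self) -> float:
        """Forward intensity I(0) = 4 pi * int p dr."""
        return float(4.0 * np.pi * np.trapezoid(self.p, self.r))


def _ift_design(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Design matrix mapping p(r_i) to I(q_j) = 4 pi sum_i w_i p_i sinc(q r_i)."""
    dr = r[1] - r[0]
    w = np.full(r.size, dr)
    w[0] = w[-1] = dr / 2.0  # trapezoid weights
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr > 0, np.sin(qr) / qr, 1.0)
    return 4.0 * np.pi * sinc * w[None, :]


def _fit_pr_fixed_dmax(
    q: np.ndarray,
    I: np.ndarray,
    sigma: np.ndarray,
    dmax: float,
    n_r: int,
    alphas: np.ndarray,
    positivity: bool,
):
    """Solve the regularized IFT for one Dmax, picking alpha by L-curve corner."""
    r = np.linspace(0.0, dmax, n_r)
    A_full = _ift_design(q, r)
    # endpoints pinned to zero: solve for interior values only
    A = A_full[:, 1:-1] / sigma[:, None]
    b = I / sigma
    m = n_r - 2
    # second-difference operator acting on the full (zero-padded) profile
    D = np.zeros((n_r - 2, m))
    for i in range(n_r - 2):
        if i - 1 >= 0:
            D[i, i - 1] = 1.0
        D[i, i] = -2.0
        if i + 1 < m:
            D[i, i + 1] = 1.0
    scale = np.linalg.norm(A) / max(np.linalg.norm(D), 1e-30)

    results = []
    for alpha in alphas:
        M = np.vstack([A, np.sqrt(alpha) * scale * D])
        rhs = np.concatenate([b, np.zeros(D.shape[0])])
        if positivity:
            sol = lsq_linear(M, rhs, bounds=(0.0, np.inf), tol=1e-10)
            x = sol.x
        else:
            x, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        resid = A @ x - b
        chi2 = float(np.sum(resid**2) / max(q.size - 1, 1))
        rough = float(np.sum((D @ x) ** 2))
        results.append((alpha, x, chi2, rough))

    # L-curve corner: maximize curvature of (log residual, log roughness)
    lr = np.log10([max(c, 1e-300) for _, _, c, _ in results])
    lp = np.log10([max(s, 1e-300) for _, _, _, s in results])
    if len(results) >= 3:
        curv = np.zeros(len(results))
        for i in range(1, len(results) - 1):
            v1 = np.array([lr[i] - lr[i - 1], lp[i] - lp[i - 1]])
            v2 = np.array([lr[i + 1] - lr[i], lp[i + 1] - lp[i]])
            cross = v1[0] * v2[1] - v1[1] * v2[0]
            norm = np.linalg.norm(v1) * np.linalg.norm(v2)
            curv[i] = cross / norm if norm > 0 else 0.0
        best = int(np.argmax(curv))
        # fall back to the smoothest solution whose chi2 is near the minimum
        chis = np.array([c for _, _, c, _ in results])
        if chis[best] > 2.0 * chis.min() + 0.5:
            best = int(np.argmin(chis))
    else:
        best = int(np.argmin([c for _, _, c, _ in results]))
    alpha, x, chi2, rough = results[best]
    p = np.zeros(n_r)
    p[1:-1] = x
    return r, p, alpha, chi2, rough


def pair_distribution(
    curve: ScatteringCurve,
    dmax: float | None = None,
    guinier: GuinierFit | None = None,
    n_r: int = 81,
    positivity: bool = True,
    alphas: np.ndarray | None = None,
    dmax_step: float = 2.0,
) -> PairDistribution:
    """P(r) and Dmax by regularized indirect Fourier transform.

    The distribution is represented on a uniform r grid with p(0) = p(Dmax)
    = 0, second-derivative smoothness regularization (weight chosen by an
    L-curve corner rule) and optional positivity.  When ``dmax`` is not
    given, candidates spanning [2 Rg, 5 Rg] in ``dmax_step`` steps are
    scored by back-transform chi-square plus penalties for oscillation
    (excess total variation of p) and negative lobes, and the selection
    takes the smallest Dmax whose score is within 10% of the best — the knee
    of the score curve, where extending Dmax further no longer improves the
    fit.
    """
    if guinier is None:
        guinier = guinier_fit(curve)
    sigma = (
        curve.sigma
        if curve.sigma is not None and np.all(curve.sigma > 0)
        else np.maximum(np.abs(curve.I), np.max(np.abs(curve.I)) * 1e-6) * 0.01
    )
    if alphas is None:
        alphas = np.logspace(-10, -2, 9)

    if dmax is not None:
        r, p, alpha, chi2, _ = _fit_pr_fixed_dmax(
            curve.q, curve.I, sigma, dmax, n_r, alphas, positivity
        )
        return PairDistribution(r=r, p=p, dmax=float(dmax), alpha=alpha, back_chi2=chi2)

    lo, hi = 2.0 * guinier.Rg, 5.0 * guinier.Rg
    candidates = np.arange(lo, hi + dmax_step / 2, dmax_step)
    # one regularization weight for the whole scan, chosen by L-curve at a
    # mid-range candidate, so chi2 is comparable across candidates
    _, _, alpha_scan, _, _ = _fit_pr_fixed_dmax(
        curve.q, curve.I, sigma, 0.5 * (lo + hi), n_r, alphas, positivity
    )
    records = []
    for d in candidates:
        r, p, alpha, chi2, _rough = _fit_pr_fixed_dmax(
            curve.q, curve.I, sigma, d, n_r, np.array([alpha_scan]), positivity
        )
        pmax = float(np.max(np.abs(p))) or 1.0
        tv = float(np.sum(np.abs(np.diff(p)))) / pmax
        osc = max(tv - 2.0, 0.0)  # a unimodal profile has TV exactly 2*max
        neg = float(-np.sum(p[p < 0])) / pmax
        score = chi2 + 0.1 * osc + 0.5 * neg
        records.append(
            {"dmax": float(d), "chi2": chi2, "osc": osc, "neg": neg,
             "score": score, "r": r, "p": p, "alpha": alpha}
        )
    scores = np.array([rec["score"] for rec in records])
    if not np.any(np.isfinite(scores)):
        raise PrEstimationError("no candidate Dmax produced a fit", {"scores": scores})
    best_score = float(np.nanmin(scores))
    # knee: the smallest Dmax whose score is already within a few percent of
    # the best achievable — beyond it, extending Dmax buys nothing
    cutoff = best_score * 1.05 + 0.05
    idx = int(np.nonzero(scores <= cutoff)[0][0])
    rec = records[idx]
    if rec["chi2"] > 50.0:
        raise PrEstimationError(
            "best back-transform chi2 is unacceptably large",
            {"chi2": rec["chi2"], "scores": scores.tolist()},
        )
    scan = {
        "candidates": [float(d) for d in candidates],
        "chi2": [rec_["chi2"] for rec_ in records],
        "score": scores.tolist(),
    }
    return PairDistribution(
        r=rec["r"], p=rec["p"], dmax=rec["dmax"], alpha=rec["alpha"],
        back_chi2=rec["chi2"], scan=scan,
    )


# ---------------------------------------------------------------------------
# Curve comparison


@dataclass
class CurveComparison:
    chi2: float
    scale_c: float
    n: int


def optimal_scale(exp: ScatteringCurve, theor: ScatteringCurve) -> float:
    """Analytic least-squares scale c minimising chi^2(c):

    c = [sum Iexp Itheor / sigma^2] / [sum Itheor^2 / sigma^2]
    """
    if exp.q.size != theor.q.size or not np.allclose(exp.q, theor.q):
        raise ValueError("curves must share a common q grid")
    sigma = exp.require_sigma()
    denom = float(np.sum(theor.I**2 / sigma**2))
    if denom == 0.0:
        raise ValueError("theoretical curve is identically zero")
    return float(np.sum(exp.I * theor.I / sigma**2) / denom)


def chi_square(
    exp: ScatteringCurve, theor: ScatteringCurve, scale: float | None = None
) -> CurveComparison:
    """Reduced chi-square between experiment and scaled model:

    chi^2 = 1/(N-1) * sum_j [(Iexp(qj) - c Itheor(qj)) / sigma(qj)]^2

    with c the analytic optimal scale unless given explicitly.
    """
    if exp.q.size != theor.q.size or not np.allclose(exp.q, theor.q):
        raise ValueError("curves must share a common q grid")
    if exp.q.size < 2:
        raise ValueError("need at least 2 points")
    sigma = exp.require_sigma()
    c = optimal_scale(exp, theor) if scale is None else float(scale)
    chi2 = float(np.sum(((exp.I - c * theor.I) / sigma) ** 2) / (exp.q.size - 1))
    return CurveComparison(chi2=chi2, scale_c=c, n=int(exp.q.size))


# ---------------------------------------------------------------------------
# SEC-SAXS frame selection


@dataclass
class SecSaxsSeries:
    """Ordered elution frames with per-frame Guinier parameters."""

    frames: list[ScatteringCurve]
    rg: np.ndarray | None = None
    i0: np.ndarray | None = None
    selection_mask: np.ndarray | None = None

    def compute_guinier(self, **kwargs) -> None:
        rg = np.full(len(self.frames), np.nan)
        i0 = np.full(len(self.frames), np.nan)
        for i, fr in enumerate(self.frames):
            try:
                g = guinier_fit(fr, **kwargs)
            except GuinierError:
                continue
            rg[i] = g.Rg
            i0[i] = g.I0
        self.rg = rg
        self.i0 = i0


def select_stable_frames(
    series: SecSaxsSeries, rg_tolerance: float = 0.05
) -> tuple[ScatteringCurve, np.ndarray]:
    """Average the longest contiguous run of frames with stable Rg.

    A run is stable when every frame's Rg deviates from the run median by
    less than ``rg_tolerance`` (relative).  Frames are averaged with
    inverse-variance weights when uncertainties are present, which can only
    reduce the pointwise sigma.  Returns (averaged curve, boolean mask).
    """
    if series.rg is None:
        series.compute_guinier()
    rg = series.rg
    ok = np.isfinite(rg)
    if not np.any(ok):
        raise FrameSelectionError("no frame has a successful Guinier fit")
    n = len(series.frames)
    min_run = min(3, int(np.sum(ok)))
    best: tuple[int, int] | None = None
    for i in range(n):
        if not ok[i]:
            continue
        for j in range(i + min_run, n + 1):
            window = rg[i:j]
            if not np.all(np.isfinite(window)):
                break
            med = np.median(window)
            if np.any(np.abs(window - med) >= rg_tolerance * med):
                break
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
    if best is None:
        raise FrameSelectionError(
            f"no contiguous stable run of >= {min_run} frames"
        )
    i, j = best
    mask = np.zeros(n, dtype=bool)
    mask[i:j] = True
    frames = [series.frames[k] for k in range(i, j)]
    q = frames[0].q
    for fr in frames[1:]:
        if fr.q.size != q.size or not np.allclose(fr.q, q):
            raise ValueError("frames must share a common q grid")
    I_stack = np.stack([fr.I for fr in frames])
    if all(fr.sigma is not None for fr in frames):
        s_stack = np.stack([fr.sigma for fr in frames])
        w = 1.0 / s_stack**2
        I_avg = np.sum(w * I_stack, axis=0) / np.sum(w, axis=0)
        sigma_avg = np.sqrt(1.0 / np.sum(w, axis=0))
    else:
        I_avg = I_stack.mean(axis=0)
        sigma_avg = None
    series.selection_mask = mask
    avg = ScatteringCurve(q.copy(), I_avg, sigma_avg, {"n_frames_averaged": j - i})
    return avg, mask
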