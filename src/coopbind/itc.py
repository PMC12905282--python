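"""Isothermal titration calorimetry: forward heat models and cooperative fits.

Implements the "one set of sites" and "two sets of sites" binding-heat models
used to analyse titrations of an oligonucleotide ligand into a protein cell,
the displaced-volume per-injection heat correction, weighted nonlinear
least-squares fitting with multi-start initialisation, and the cooperativity
index K_D1/K_D2 that quantifies whether the second binding event is tighter
than the first.

Units: volumes in litres, concentrations in molar, heats in kcal, association
constants in 1/M, temperatures in kelvin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

import lmfit

R_KCAL = 1.987204259e-3  # gas constant, kcal/(mol*K)

__all__ = [
    "TitrationProtocol",
    "BindingModelOneSet",
    "BindingModelTwoSets",
    "Isotherm",
    "ItcFitResult",
    "NoBindingSignalError",
    "free_ligand",
    "cumulative_heat",
    "displaced_volume_correction",
    "injection_heats",
    "fit_isotherm",
    "cooperativity_index",
    "thermodynamics",
]


class NoBindingSignalError(ValueError):
    """Raised when an isotherm carries no heat signal to fit."""


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class TitrationProtocol:
    """Cell/syringe geometry and injection schedule of an ITC experiment.

    Parameters
    ----------
    cell_volume : float
        Active cell volume V0 in litres.
    cell_concentration : float
        Total macromolecule (protein) concentration in the cell before the
        first injection, molar.
    syringe_concentration : float
        Ligand (oligonucleotide) concentration in the syringe, molar.
    injection_volumes : array-like
        Volume of each injection dV_i in litres.
    temperature : float
        Experiment temperature in kelvin.
    """

    cell_volume: float
    cell_concentration: float
    syringe_concentration: float
    injection_volumes: np.ndarray
    temperature: float = 298.15

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injection_volumes", np.asarray(self.injection_volumes, dtype=float)
        )
        _require_finite(
            "protocol",
            self.cell_volume,
            self.cell_concentration,
            self.syringe_concentration,
            self.temperature,
        )
        _require_finite("injection_volumes", self.injection_volumes)
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.cell_concentration < 0 or self.syringe_concentration < 0:
            raise ValueError("concentrations must be >= 0")
        if self.injection_volumes.ndim != 1 or self.injection_volumes.size < 1:
            raise ValueError("need at least one injection")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("all injection volumes must be > 0")

    @property
    def n_injections(self) -> int:
        return int(self.injection_volumes.size)

    def cell_concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Total macromolecule and ligand concentration after each injection.

        Uses the perfusion (continuous-displacement) dilution model for an
        overfilled cell: material displaced during injection i has the average
        composition of the cell, so

            Mt_i = Mt0 * exp(-v_i / V0)
            Xt_i = Xs * (1 - exp(-v_i / V0))

        with v_i the cumulative injected volume.  This is the convention
        consistent with the displaced-volume heat correction applied by
        :func:`injection_heats`.
        """
        v = np.cumsum(self.injection_volumes)
        dilution = np.exp(-v / self.cell_volume)
        Mt = self.cell_concentration * dilution
        Xt = self.syringe_concentration * (1.0 - dilution)
        return Mt, Xt


@dataclass(frozen=True)
class BindingModelOneSet:
    """One-set-of-sites model: n identical sites per macromolecule monomer."""

    n: float  # sites per monomer
    K: float  # association constant, 1/M
    dH: float  # binding enthalpy, kcal/mol

    def __post_init__(self) -> None:
        _require_finite("one-set model", self.n, self.K, self.dH)
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if self.K < 0:
            raise ValueError("K must be >= 0")

    @property
    def sites(self) -> tuple[tuple[float, float, float], ...]:
        return ((self.n, self.K, self.dH),)


@dataclass(frozen=True)
class BindingModelTwoSets:
    """Two independent sets of sites, each with its own (n, K, dH)."""

    n1: float
    n2: float
    K1: float
    K2: float
    dH1: float
    dH2: float

    def __post_init__(self) -> None:
        _require_finite(
            "two-sets model", self.n1, self.n2, self.K1, self.K2, self.dH1, self.dH2
        )
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("n1, n2 must be > 0")
        if self.K1 < 0 or self.K2 < 0:
            raise ValueError("K1, K2 must be >= 0")

    @property
    def sites(self) -> tuple[tuple[float, float, float], ...]:
        return ((self.n1, self.K1, self.dH1), (self.n2, self.K2, self.dH2))


BindingModel = BindingModelOneSet | BindingModelTwoSets


@dataclass
class Isotherm:
    """Per-injection record of a titration.

    All arrays are aligned per injection: cumulative injected volume (L),
    ligand:macromolecule molar ratio, cumulative heat Q_i (kcal),
    per-injection heat q_i (kcal) and an optional per-injection noise scale
    sigma_i (kcal).  ``q_per_mol`` reports q_i normalised to kcal per mole of
    injectant, the axis instrument software plots.
    """

    cumulative_volume: np.ndarray
    molar_ratio: np.ndarray
    Q: np.ndarray
    q: np.ndarray
    sigma: np.ndarray | None = None
    injected_moles: np.ndarray | None = None
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.cumulative_volume = np.asarray(self.cumulative_volume, dtype=float)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.injected_moles is not None:
            self.injected_moles = np.asarray(self.injected_moles, dtype=float)
        n = self.q.size
        for name in ("cumulative_volume", "molar_ratio", "Q"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match q")
        if self.sigma is not None and self.sigma.size != n:
            raise ValueError("sigma length does not match q")
        if np.any(np.diff(self.molar_ratio) < -1e-12):
            raise ValueError("molar_ratio must be non-decreasing")

    @property
    def n_injections(self) -> int:
        return int(self.q.size)

    @property
    def q_per_mol(self) -> np.ndarray:
        if self.injected_moles is None:
            raise ValueError("injected moles unknown; cannot normalise")
        return self.q / self.injected_moles


def free_ligand(model: BindingModel, Mt: float, Xt: float) -> float:
    """Free ligand concentration X satisfying the mass balance.

    Solves  Xt = X + Mt * sum_s n_s K_s X / (1 + K_s X)  for the unique root
    X in [0, Xt] by bracketed root finding followed by Newton polishing; the
    mass-balance residual of the returned value is below
    1e-12 * max(Xt, 1e-12).
    """
    _require_finite("Mt", Mt)
    _require_finite("Xt", Xt)
    if Mt < 0 or Xt < 0:
        raise ValueError("concentrations must be >= 0")
    if Xt == 0.0:
        return 0.0
    sites = model.sites
    if Mt == 0.0 or all(K == 0.0 for _, K, _ in sites):
        return Xt

    def bound(X: float) -> float:
        return Mt * sum(n * K * X / (1.0 + K * X) for n, K, _ in sites)

    def f(X: float) -> float:
        return Xt - X - bound(X)

    def fprime(X: float) -> float:
        return -1.0 - Mt * sum(n * K / (1.0 + K * X) ** 2 for n, K, _ in sites)

    # f(0) = Xt > 0, f(Xt) = -bound(Xt) <= 0; f is strictly decreasing.
    X = brentq(f, 0.0, Xt, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    tol = 1e-12 * max(Xt, 1e-12)
    for _ in range(10):
        r = f(X)
        if abs(r) < tol:
            break
        step = r / fprime(X)
        X_new = min(max(X - step, 0.0), Xt)
        if X_new == X:
            break
        X = X_new
    return X


def cumulative_heat(
    model: BindingModel, protocol: TitrationProtocol, Mt: float, Xt: float
) -> float:
    """Cumulative heat Q (kcal) at total concentrations (Mt, Xt).

    One set of sites:   Q = Mt V0 [ n dH K X / (1 + K X) ]
    Two sets of sites:  Q = Mt V0 [ n1 dH1 K1 X/(1+K1 X) + n2 dH2 K2 X/(1+K2 X) ]

    with X the free-ligand concentration from :func:`free_ligand`.
    """
    if Mt < 0 or Xt < 0:
        raise ValueError("concentrations must be >= 0")
    X = free_ligand(model, Mt, Xt)
    per_mol = sum(n * dH * K * X / (1.0 + K * X) for n, K, dH in model.sites)
    return Mt * protocol.cell_volume * per_mol


def displaced_volume_correction(
    Q: np.ndarray, dV: np.ndarray, V0: float
) -> np.ndarray:
    """Per-injection heats from cumulative heats with the displaced-volume
    term:

        q_i = Q_i + (dV_i / V0) * (Q_i + Q_{i-1}) / 2 - Q_{i-1}

    With dV_i = 0 this reduces to the simple difference Q_i - Q_{i-1}.
    """
    Q = np.asarray(Q, dtype=float)
    dV = np.asarray(dV, dtype=float)
    Q_prev = np.concatenate([[0.0], Q[:-1]])
    return Q + (dV / V0) * 0.5 * (Q + Q_prev) - Q_prev


def injection_heats(model: BindingModel, protocol: TitrationProtocol) -> Isotherm:
    """Noise-free per-injection heats for a model under a protocol.

    The observed heat of injection i corrects the cumulative-heat difference
    for the heat carried out with the displaced volume (see
    :func:`displaced_volume_correction`).
    """
    Mt, Xt = protocol.cell_concentrations()
    V0 = protocol.cell_volume
    Q = np.array(
        [cumulative_heat(model, protocol, m, x) for m, x in zip(Mt, Xt)]
    )
    dV = protocol.injection_volumes
    q = displaced_volume_correction(Q, dV, V0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(Mt > 0, Xt / np.where(Mt > 0, Mt, 1.0), np.inf)
    return Isotherm(
        cumulative_volume=np.cumsum(dV),
        molar_ratio=ratio,
        Q=Q,
        q=q,
        injected_moles=protocol.syringe_concentration * dV,
    )


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class ItcFitResult:
    """Point estimates, uncertainties and derived thermodynamics of an ITC fit.

    ``params``/``stderr`` are keyed by model field name.  Derived per-set
    quantities: K_D = 1/K (M), dG = -RT ln K and TdS = dH - dG (kcal/mol).
    ``cooperativity_index`` (two-sets only) is max(K_D)/min(K_D) >= 1; the
    independent two-sets model is invariant under set relabelling, so the
    binding order itself is not identifiable.  ``c_values`` are the Wiseman
    parameters c_s = K_s * Mt0 * n_s per set.
    """

    model_kind: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    kd: tuple[float, ...]
    dG: tuple[float, ...]
    TdS: tuple[float, ...]
    c_values: tuple[float, ...]
    cooperativity_index: float | None
    rss: float
    converged: bool
    n_obs: int
    warnings: list[str] = field(default_factory=list)
    fitted_q: np.ndarray | None = None

    @property
    def model(self) -> BindingModel:
        if self.model_kind == "one_set":
            p = self.params
            return BindingModelOneSet(n=p["n"], K=p["K"], dH=p["dH"])
        p = self.params
        return BindingModelTwoSets(
            n1=p["n1"], n2=p["n2"], K1=p["K1"], K2=p["K2"], dH1=p["dH1"], dH2=p["dH2"]
        )


def _model_from_lmfit(kind: str, params: lmfit.Parameters) -> BindingModel:
    if kind == "one_set":
        return BindingModelOneSet(
            n=params["n"].value, K=10.0 ** params["logK"].value, dH=params["dH"].value
        )
    return BindingModelTwoSets(
        n1=params["n1"].value,
        n2=params["n2"].value,
        K1=10.0 ** params["logK1"].value,
        K2=10.0 ** params["logK2"].value,
        dH1=params["dH1"].value,
        dH2=params["dH2"].value,
    )


def _initial_guesses(
    isotherm: Isotherm, protocol: TitrationProtocol, kind: str
) -> list[lmfit.Parameters]:
    """Multi-start initialisation from the shape of the isotherm.

    The first-plateau heat per mole of injectant approximates dH, the molar
    ratio at the transition midpoint approximates the total stoichiometry,
    and K starts span several decades around a mid-range Wiseman c.
    """
    q = isotherm.q
    dH0 = float(np.sign(q[0]) * max(abs(q[0]) / isotherm.injected_moles[0], 0.1))
    # transition midpoint: molar ratio where |q| first drops below half its
    # early-plateau value
    early = np.median(np.abs(q[: max(3, q.size // 10)]))
    below = np.nonzero(np.abs(q) < 0.5 * early)[0]
    n_tot = float(isotherm.molar_ratio[below[0]]) if below.size else float(
        isotherm.molar_ratio[q.size // 2]
    )
    n_tot = min(max(n_tot, 0.05), 5.0)
    Mt0 = protocol.cell_concentration
    K_mid = 50.0 / max(Mt0 * n_tot, 1e-12)  # c ~ 50 as a central guess

    starts: list[lmfit.Parameters] = []
    if kind == "one_set":
        for K0 in (K_mid / 30, K_mid, K_mid * 30):
            p = lmfit.Parameters()
            p.add("n", value=n_tot, min=1e-3, max=20)
            p.add("logK", value=np.log10(K0), min=0.0, max=14.0)
            p.add("dH", value=dH0, min=-200, max=200)
            starts.append(p)
        return starts
    splits = ((0.5, 0.5), (0.35, 0.65))
    K_pairs = (
        (K_mid / 10, K_mid * 10),
        (K_mid, K_mid),
        (K_mid / 100, K_mid * 10),
        (K_mid * 10, K_mid / 10),
    )
    for f1, f2 in splits:
        for Ka, Kb in K_pairs:
            p = lmfit.Parameters()
            p.add("n1", value=n_tot * f1, min=1e-3, max=20)
            p.add("n2", value=n_tot * f2, min=1e-3, max=20)
            p.add("logK1", value=np.log10(Ka), min=0.0, max=14.0)
            p.add("logK2", value=np.log10(Kb), min=0.0, max=14.0)
            p.add("dH1", value=dH0, min=-200, max=200)
            p.add("dH2", value=dH0, min=-200, max=200)
            starts.append(p)
    return starts[:6]


def fit_isotherm(
    isotherm: Isotherm,
    protocol: TitrationProtocol,
    model_kind: str = "one_set",
    init: BindingModel | None = None,
    exclude_first: bool = False,
) -> ItcFitResult:
    """Weighted least-squares fit of the binding-heat model to an isotherm.

    Parameters
    ----------
    model_kind : {"one_set", "two_sets"}
    init : optional model used as an extra starting point.
    exclude_first : drop the first injection from the residuals (common
        practice for the first-injection artifact); off by default.
    """
    if model_kind not in ("one_set", "two_sets"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    n_free = 3 if model_kind == "one_set" else 6
    mask = np.ones(isotherm.n_injections, dtype=bool)
    if exclude_first:
        mask[0] = False
    if mask.sum() < 2 * n_free:
        raise ValueError("too few injections for the number of free parameters")
    q_obs = isotherm.q
    if np.all(q_obs == 0.0):
        raise NoBindingSignalError("isotherm heats are all zero: no binding signal")
    if isotherm.sigma is not None and np.all(isotherm.sigma > 0):
        weights = 1.0 / isotherm.sigma
    else:
        weights = np.full(q_obs.size, 1.0 / max(np.max(np.abs(q_obs)), 1e-30))

    def residuals(params: lmfit.Parameters) -> np.ndarray:
        model = _model_from_lmfit(model_kind, params)
        pred = injection_heats(model, protocol).q
        return ((pred - q_obs) * weights)[mask]

    starts = _initial_guesses(isotherm, protocol, model_kind)
    if init is not None:
        p = lmfit.Parameters()
        if model_kind == "one_set":
            p.add("n", value=init.n, min=1e-3, max=20)
            p.add("logK", value=np.log10(max(init.K, 1.0)), min=0.0, max=14.0)
            p.add("dH", value=init.dH, min=-200, max=200)
        else:
            p.add("n1", value=init.n1, min=1e-3, max=20)
            p.add("n2", value=init.n2, min=1e-3, max=20)
            p.add("logK1", value=np.log10(max(init.K1, 1.0)), min=0.0, max=14.0)
            p.add("logK2", value=np.log10(max(init.K2, 1.0)), min=0.0, max=14.0)
            p.add("dH1", value=init.dH1, min=-200, max=200)
            p.add("dH2", value=init.dH2, min=-200, max=200)
        starts.insert(0, p)

    fits = []
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = lmfit.minimize(
                    residuals,
                    p0,
                    method="least_squares",
                    ftol=1e-12,
                    xtol=1e-12,
                    gtol=1e-12,
                )
        except Exception:
            continue
        if res.success:
            fits.append(res)
    best = None
    if fits:
        lowest = min(f.chisqr for f in fits)
        # the independent two-sets model is degenerate when the sites are
        # equal: noise can "split" K1/K2 at no cost.  Among starts whose
        # cost is indistinguishable from the best, keep the least
        # cooperative (most parsimonious) solution.
        def _kd_split(res) -> float:
            m = _model_from_lmfit(model_kind, res.params)
            ks = [K for _, K, _ in m.sites if K > 0]
            return max(ks) / min(ks) if len(ks) == 2 and min(ks) > 0 else np.inf

        near = [f for f in fits if f.chisqr <= lowest * 1.005 + 1e-300]
        best = min(near, key=_kd_split) if model_kind == "two_sets" else min(
            near, key=lambda f: f.chisqr
        )
    if best is None or not best.success:
        return ItcFitResult(
            model_kind=model_kind,
            params={},
            stderr={},
            kd=(),
            dG=(),
            TdS=(),
            c_values=(),
            cooperativity_index=None,
            rss=np.inf,
            converged=False,
            n_obs=int(mask.sum()),
            warnings=["fit did not converge from any start"],
        )

    model = _model_from_lmfit(model_kind, best.params)
    T = protocol.temperature
    Mt0 = protocol.cell_concentration

    def _stderr(name: str) -> float | None:
        par = best.params.get(name)
        return float(par.stderr) if par is not None and par.stderr else None

    if model_kind == "one_set":
        params = {"n": model.n, "K": model.K, "dH": model.dH}
        stderr = {"n": _stderr("n"), "K": _k_stderr(best, "logK", model.K), "dH": _stderr("dH")}
    else:
        params = {
            "n1": model.n1,
            "n2": model.n2,
            "K1": model.K1,
            "K2": model.K2,
            "dH1": model.dH1,
            "dH2": model.dH2,
        }
        stderr = {
            "n1": _stderr("n1"),
            "n2": _stderr("n2"),
            "K1": _k_stderr(best, "logK1", model.K1),
            "K2": _k_stderr(best, "logK2", model.K2),
            "dH1": _stderr("dH1"),
            "dH2": _stderr("dH2"),
        }

    kd = tuple(1.0 / K if K > 0 else np.inf for _, K, _ in model.sites)
    dG, TdS = thermodynamics_from_model(model, T)
    c_values = tuple(K * Mt0 * n for n, K, _ in model.sites)
    warn = []
    for i, c in enumerate(c_values, 1):
        if not (1.0 <= c <= 1000.0):
            warn.append(
                f"Wiseman c for set {i} is {c:.3g}, outside [1, 1000]; "
                "parameters may be poorly determined"
            )
    coop = None
    if model_kind == "two_sets":
        coop = max(kd) / min(kd) if min(kd) > 0 and np.isfinite(max(kd)) else np.inf
    fitted_q = injection_heats(model, protocol).q
    rss = float(np.sum((fitted_q - q_obs)[mask] ** 2))
    return ItcFitResult(
        model_kind=model_kind,
        params=params,
        stderr=stderr,
        kd=kd,
        dG=dG,
        TdS=TdS,
        c_values=c_values,
        cooperativity_index=coop,
        rss=rss,
        converged=True,
        n_obs=int(mask.sum()),
        warnings=warn,
        fitted_q=fitted_q,
    )


def _k_stderr(res, log_name: str, K: float) -> float | None:
    par = res.params.get(log_name)
    if par is None or not par.stderr:
        return None
    return float(K * np.log(10.0) * par.stderr)  # delta method from log10 K


def thermodynamics_from_model(
    model: BindingModel, temperature: float
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-set (dG, TdS): dG = -RT ln K, TdS = dH - dG (kcal/mol)."""
    dG = []
    TdS = []
    for _, K, dH in model.sites:
        if K <= 0:
            raise ValueError("K must be > 0 for thermodynamics")
        g = -R_KCAL * temperature * np.log(K)
        dG.append(g)
        TdS.append(dH - g)
    return tuple(dG), tuple(TdS)


def thermodynamics(fit: ItcFitResult, temperature: float):
    """Recompute per-set (dG, TdS) from a fit result at a given temperature."""
    return thermodynamics_from_model(fit.model, temperature)


def cooperativity_index(fit: ItcFitResult) -> float:
    """K_D1/K_D2 under the ordering convention max(K_D)/min(K_D) (>= 1).

    High values mean the second (tighter) binding event has much higher
    affinity than the first — the signature of cooperative assembly on a
    long repeat; values near 1 mean no cooperativity.
    """
    if fit.model_kind != "two_sets":
        raise ValueError("cooperativity index requires a two-sets fit")
    kd = fit.kd
    if min(kd) <= 0:
        raise ValueError("both association constants must be positive")
    return max(kd) / min(kd)
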