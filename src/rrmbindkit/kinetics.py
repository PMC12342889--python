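"""SPR kinetic models: 1:1 Langmuir, bivalent analyte, rate-distribution maps,
and tandem-domain competition.

A surface plasmon resonance sensorgram records bound mass (response units,
RU) on a ligand-coated surface while analyte at concentration C flows over it
(association) and is then washed out (dissociation).  The models here:

* **1:1 (Langmuir)** — A + L ⇌ AL with rates ka1 (M⁻¹s⁻¹), kd1 (s⁻¹); closed
  form R(t) = Req(1 − e^{−(ka1·C+kd1)t}) with Req = Rmax·C/(C+KD1),
  dissociating as R(t_a)·e^{−kd1·t}.  KD1 = kd1/ka1.
* **Bivalent analyte** — a tandem-domain analyte that, once bound through one
  site (AL), can engage a *second* surface ligand (AL + L → AL2, per-RU rate
  ka2, reversal kd2).  The avidity-stabilised AL2 pool dissociates slowly,
  producing the characteristic biphasic wash-out: fast at first, then
  progressively slower.
* **Rate-distribution map** — a regularised nonnegative decomposition of a
  sensorgram set onto a log-spaced grid of 1:1 (ka, kd) basis curves; peaks in
  the weight surface expose coexisting binding modes (e.g. the monovalent and
  bivalent components of a tandem-domain interaction).
* **Tandem competition** — two domains of one analyte competing for a shared
  single-site RNA surface, with optional bridging of two RNA molecules; with
  bridging on, dissociation again turns biphasic.

Global fitting (all concentrations simultaneously) uses bounded least squares
on log-scaled rate constants with multi-start initialisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, nnls

from .errors import DegenerateDataError, InputError, NumericalError

__all__ = [
    "InjectionSchedule",
    "Kinetic1to1Params",
    "BivalentParams",
    "BridgingParams",
    "Sensorgram",
    "CompetitionTrace",
    "FitResult",
    "KineticMapGrid",
    "simulate_1to1",
    "simulate_bivalent",
    "simulate_tandem_competition",
    "fit_1to1",
    "fit_bivalent",
    "kd_from_rates",
    "interaction_map",
    "instantaneous_off_rate",
]

# adaptive-integrator tolerances (stiff-capable LSODA); tight enough that a
# ~100 RU trace is reproduced to well under 1e-6 RU
_ATOL = 1e-12
_RTOL = 1e-10

# rate-constant bounds for fitting, log10 space
_LKA_BOUNDS = (2.0, 9.0)  # ka in [1e2, 1e9] M^-1 s^-1
_LKD_BOUNDS = (-5.0, 1.0)  # kd in [1e-5, 10] s^-1


@dataclass(frozen=True)
class InjectionSchedule:
    """Analyte injection series: concentrations (M), association and
    dissociation durations (s), and sampling interval dt (s)."""

    concentrations: tuple[float, ...]
    t_assoc: float = 120.0
    t_dissoc: float = 300.0
    dt: float = 0.5

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations):
            raise InputError("analyte concentrations must be >= 0")
        if self.t_assoc <= 0 or self.t_dissoc <= 0 or self.dt <= 0:
            raise InputError("t_assoc, t_dissoc and dt must be > 0")

    @property
    def times(self) -> np.ndarray:
        """Sampling grid over the full association + dissociation cycle."""
        n = int(round((self.t_assoc + self.t_dissoc) / self.dt))
        return np.linspace(0.0, self.t_assoc + self.t_dissoc, n + 1)


def _twofold_series(c_min: float = 7.8125e-9, n: int = 6) -> tuple[float, ...]:
    return tuple(c_min * 2**i for i in range(n))


#: the study's standard dilution series: 7.8–250 nM, twofold steps
STANDARD_SCHEDULE = InjectionSchedule(_twofold_series(), t_assoc=120.0, t_dissoc=300.0, dt=0.5)


@dataclass(frozen=True)
class Kinetic1to1Params:
    """1:1 Langmuir parameters; KD1 = kd1/ka1 (M)."""

    ka1: float  # M^-1 s^-1
    kd1: float  # s^-1
    Rmax: float  # RU

    def __post_init__(self) -> None:
        if self.ka1 < 0 or self.kd1 < 0 or self.Rmax < 0:
            raise InputError("ka1, kd1 and Rmax must all be >= 0")

    @property
    def KD1(self) -> float:
        return kd_from_rates(self.ka1, self.kd1)


@dataclass(frozen=True)
class BivalentParams:
    """Bivalent-analyte parameters.

    ka2 is the second-site on-rate per surface density (RU⁻¹ s⁻¹); ``g``
    converts surface density to molar equivalents (M per RU) so that
    KD2 = kd2 / (ka2 / g) can be quoted in molar units.  Ltot is the total
    ligand surface capacity in RU.
    """

    ka1: float  # M^-1 s^-1
    kd1: float  # s^-1
    ka2: float  # RU^-1 s^-1
    kd2: float  # s^-1
    Ltot: float  # RU
    g: float = 1e-8  # M per RU

    def __post_init__(self) -> None:
        if min(self.ka1, self.kd1, self.ka2, self.kd2, self.Ltot) < 0 or self.g <= 0:
            raise InputError("all bivalent parameters must be >= 0 (g > 0)")

    @property
    def KD1(self) -> float:
        return kd_from_rates(self.ka1, self.kd1)

    @property
    def KD2(self) -> float:
        """Second-step dissociation constant in molar equivalents."""
        if self.ka2 == 0:
            raise ZeroDivisionError("KD2 is undefined for ka2 = 0")
        return self.kd2 / (self.ka2 / self.g)


@dataclass(frozen=True)
class Sensorgram:
    """One injection cycle: time (s), response (RU), analyte concentration (M).

    ``t_assoc`` marks the association→dissociation boundary.
    """

    time: np.ndarray
    response: np.ndarray
    concentration: float
    t_assoc: float
    curve_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        r = np.asarray(self.response, float)
        if t.ndim != 1 or t.shape != r.shape:
            raise InputError("time and response must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise InputError("time must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise InputError("response contains non-finite values")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)

    @property
    def phase(self) -> np.ndarray:
        """'assoc' / 'dissoc' flag per sample."""
        return np.where(self.time <= self.t_assoc, "assoc", "dissoc")


def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant KD = kd/ka (M)."""
    if ka == 0:
        raise ZeroDivisionError("KD is undefined for ka = 0")
    return kd / ka


def _closed_form_1to1(
    t: np.ndarray, t_assoc: float, C: float, ka: float, kd: float, Rmax: float
) -> np.ndarray:
    """Analytic 1:1 trace on grid ``t`` (association then dissociation)."""
    r = np.zeros_like(t, dtype=float)
    kobs = ka * C + kd
    denom = C + (kd / ka if ka > 0 else np.inf)
    req = Rmax * C / denom if denom > 0 else 0.0
    assoc = t <= t_assoc
    if kobs > 0:
        r[assoc] = req * (1.0 - np.exp(-kobs * t[assoc]))
        r_end = req * (1.0 - math.exp(-kobs * t_assoc))
    else:
        r_end = 0.0
    r[~assoc] = r_end * np.exp(-kd * (t[~assoc] - t_assoc))
    return r


def simulate_1to1(
    params: Kinetic1to1Params,
    schedule: InjectionSchedule,
    method: str = "closed",
) -> list[Sensorgram]:
    """Simulate 1:1 sensorgrams, one per scheduled concentration.

    ``method='closed'`` evaluates the analytic solution; ``method='ode'``
    integrates dR/dt = ka1·C·(Rmax−R) − kd1·R numerically (the two agree to
    integrator tolerance and the ODE route serves as a cross-check).
    """
    t = schedule.times
    out = []
    for i, C in enumerate(schedule.concentrations):
        if method == "closed":
            r = _closed_form_1to1(t, schedule.t_assoc, C, params.ka1, params.kd1, params.Rmax)
        elif method == "ode":
            r = _ode_1to1(t, schedule.t_assoc, C, params)
        else:
            raise InputError(f"unknown method {method!r}")
        out.append(Sensorgram(t, r, C, schedule.t_assoc, curve_id=f"c{i}"))
    return out


def _integrate_two_phase(rhs, t: np.ndarray, t_assoc: float, y0: list[float], conc: float
                         ) -> np.ndarray:
    """Integrate rhs(t, y, C) over association (C=conc) then wash (C=0).

    The association segment always ends exactly at t_assoc so the
    dissociation phase starts from the true phase-boundary state, whether or
    not t_assoc lies on the sampling grid.  Returns states on grid ``t``.
    """
    assoc = t <= t_assoc
    te_a = t[assoc]
    pad = te_a.size == 0 or te_a[-1] < t_assoc - 1e-12
    te_a_full = np.append(te_a, t_assoc) if pad else te_a
    sol_a = solve_ivp(rhs, (0.0, t_assoc), y0, t_eval=te_a_full, args=(conc,),
                      method="LSODA", atol=_ATOL, rtol=_RTOL)
    if not sol_a.success:
        raise NumericalError(f"association integration failed: {sol_a.message}")
    y_end = sol_a.y[:, -1]
    out = np.zeros((len(y0), t.size))
    out[:, assoc] = sol_a.y[:, : te_a.size]
    te_d = t[~assoc]
    if te_d.size:
        sol_d = solve_ivp(rhs, (t_assoc, t[-1]), list(y_end), t_eval=te_d, args=(0.0,),
                          method="LSODA", atol=_ATOL, rtol=_RTOL)
        if not sol_d.success:
            raise NumericalError(f"dissociation integration failed: {sol_d.message}")
        out[:, ~assoc] = sol_d.y
    return out


def _ode_1to1(t, t_assoc, C, params: Kinetic1to1Params) -> np.ndarray:
    def rhs(_t, y, conc):
        return [params.ka1 * conc * (params.Rmax - y[0]) - params.kd1 * y[0]]

    return _integrate_two_phase(rhs, t, t_assoc, [0.0], C)[0]


def _bivalent_rhs(_t, y, C, p: BivalentParams):
    al, al2 = y
    lfree = p.Ltot - al - 2.0 * al2
    dal = p.ka1 * C * lfree - p.kd1 * al - p.ka2 * al * lfree + p.kd2 * al2
    dal2 = p.ka2 * al * lfree - p.kd2 * al2
    return [dal, dal2]


def simulate_bivalent(
    params: BivalentParams,
    schedule: InjectionSchedule,
    return_states: bool = False,
):
    """Simulate the bivalent-analyte model.

    States: AL (bound through one site) and AL2 (bridging two surface
    ligands); free ligand Lfree = Ltot − AL − 2·AL2.  The response is the
    bound analyte, AL + AL2.  With ka2 = 0 the model reduces exactly to 1:1.
    Returns sensorgrams, plus per-curve state dictionaries when
    ``return_states`` is set.
    """
    t = schedule.times
    grams, states = [], []

    def rhs(_t, y, C):
        return _bivalent_rhs(_t, y, C, params)

    for i, C in enumerate(schedule.concentrations):
        ys = _integrate_two_phase(rhs, t, schedule.t_assoc, [0.0, 0.0], C)
        lfree = params.Ltot - ys[0] - 2.0 * ys[1]
        if np.any(lfree < -1e-6 * max(params.Ltot, 1.0)):
            raise NumericalError(
                "free-ligand concentration went negative during integration "
                "(step-size failure); tighten tolerances or check parameters"
            )
        grams.append(Sensorgram(t, ys[0] + ys[1], C, schedule.t_assoc, curve_id=f"c{i}"))
        states.append({"AL": ys[0], "AL2": ys[1], "Lfree": lfree})
    return (grams, states) if return_states else grams


@dataclass(frozen=True)
class BridgingParams:
    """Cross-linking rates for tandem competition: a singly-anchored protein
    grabbing a second RNA molecule with its free domain.

    ``kb1``: domain 1 bridging from a domain-2-anchored state (RU⁻¹ s⁻¹);
    ``kb2``: domain 2 bridging from a domain-1-anchored state.
    """

    kb1: float = 0.0
    kb2: float = 0.0

    def __post_init__(self) -> None:
        if self.kb1 < 0 or self.kb2 < 0:
            raise InputError("bridging rates must be >= 0")


@dataclass(frozen=True)
class CompetitionTrace:
    sensorgram: Sensorgram
    states: dict[str, np.ndarray]  # B1, B2, X, Lfree over time


def simulate_tandem_competition(
    domain1: tuple[float, float],
    domain2: tuple[float, float],
    bridging: BridgingParams,
    Ltot: float,
    schedule: InjectionSchedule,
) -> list[CompetitionTrace]:
    """Two domains of one analyte competing for a single-site RNA surface.

    States (RU of bound protein): B1 (anchored by domain 1), B2 (anchored by
    domain 2), X (bridged across two RNA molecules, occupying two surface
    sites).  Each domain i has solution-phase rates (ka_i, kd_i); bridging
    converts B1→X at kb2·B1·Lfree (domain 2 engages) and B2→X at
    kb1·B2·Lfree, and X releases back at the corresponding domain off-rate.
    With both bridging rates zero the model is a sum of independent 1:1
    channels and dissociation is monoexponential.
    """
    ka1, kd1 = domain1
    ka2, kd2 = domain2
    if min(ka1, kd1, ka2, kd2) < 0 or Ltot < 0:
        raise InputError("rate constants and Ltot must be >= 0")

    def rhs(_t, y, C):
        b1, b2, x = y
        lfree = Ltot - b1 - b2 - 2.0 * x
        db1 = ka1 * C * lfree - kd1 * b1 - bridging.kb2 * b1 * lfree + kd2 * x
        db2 = ka2 * C * lfree - kd2 * b2 - bridging.kb1 * b2 * lfree + kd1 * x
        dx = bridging.kb2 * b1 * lfree + bridging.kb1 * b2 * lfree - (kd1 + kd2) * x
        return [db1, db2, dx]

    t = schedule.times
    out = []
    for i, C in enumerate(schedule.concentrations):
        ys = _integrate_two_phase(rhs, t, schedule.t_assoc, [0.0] * 3, C)
        lfree = Ltot - ys[0] - ys[1] - 2.0 * ys[2]
        if np.any(lfree < -1e-6 * max(Ltot, 1.0)):
            raise NumericalError("free-site concentration went negative during integration")
        gram = Sensorgram(t, ys.sum(axis=0), C, schedule.t_assoc, curve_id=f"c{i}")
        out.append(CompetitionTrace(gram, {"B1": ys[0], "B2": ys[1], "X": ys[2], "Lfree": lfree}))
    return out


def instantaneous_off_rate(gram: Sensorgram, min_response: float = 1e-9) -> np.ndarray:
    """−d ln R / dt over the dissociation phase, by central finite differences.

    For a single-exponential decay this is constant (= kd); a monotonically
    decreasing profile is the fingerprint of biphasic, avidity-stabilised
    dissociation.
    """
    mask = gram.time > gram.t_assoc
    t = gram.time[mask]
    r = gram.response[mask]
    keep = r > min_response
    t, r = t[keep], r[keep]
    if t.size < 3:
        raise InputError("not enough dissociation samples above the response floor")
    return -np.gradient(np.log(r), t)


@dataclass(frozen=True)
class FitResult:
    """Global-fit output: point estimates, 95% confidence intervals,
    residual sum of squares, and convergence diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rss: float
    n_obs: int
    converged: bool
    message: str = ""
    warnings: tuple[str, ...] = ()


def _stack(sensorgrams: list[Sensorgram]) -> list[Sensorgram]:
    if not sensorgrams:
        raise InputError("no sensorgrams supplied")
    t_assoc = sensorgrams[0].t_assoc
    if any(abs(g.t_assoc - t_assoc) > 1e-9 for g in sensorgrams):
        raise InputError("all sensorgrams must share the association time")
    return sorted(sensorgrams, key=lambda g: g.concentration)


def _ci_from_jac(jac: np.ndarray, residuals: np.ndarray, x: np.ndarray):
    """Linearised standard errors at the optimum (in the fitted coordinates)."""
    n, p = residuals.size, x.size
    dof = max(n - p, 1)
    s2 = float(residuals @ residuals) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


def _tail_kd_estimate(grams: list[Sensorgram]) -> float:
    """kd guess: slope of log-response over the dissociation tail of the
    strongest curve."""
    g = max(grams, key=lambda s: s.response.max())
    mask = (g.time > g.t_assoc) & (g.response > 1e-6 * max(g.response.max(), 1.0))
    t, r = g.time[mask], g.response[mask]
    if t.size < 3:
        return 1e-2
    slope = np.polyfit(t - t[0], np.log(r), 1)[0]
    return float(np.clip(-slope, 10**_LKD_BOUNDS[0], 10**_LKD_BOUNDS[1]))


def fit_1to1(
    sensorgrams: list[Sensorgram],
    n_starts: int = 5,
) -> FitResult:
    """Global bounded least-squares fit of the 1:1 model across all curves.

    Rate constants are fitted on a log10 scale within ka ∈ [1e2, 1e9] M⁻¹s⁻¹
    and kd ∈ [1e-5, 10] s⁻¹; Rmax is shared across curves.  Initialisation is
    multi-start: kd from the dissociation-tail slope, ka log-spaced.  Reports
    ka1, kd1, Rmax and KD1 = kd1/ka1 with linearised 95% CIs.
    """
    grams = _stack(sensorgrams)
    rmax0 = max(g.response.max() for g in grams)
    if rmax0 <= 0:
        raise DegenerateDataError("all responses are zero; nothing to fit")
    warnings = []
    if len({g.concentration for g in grams}) < 2:
        warnings.append("single-concentration fit: ka1 and Rmax are weakly identifiable")
    y = np.concatenate([g.response for g in grams])
    kd0 = _tail_kd_estimate(grams)

    def residual(x):
        lka, lkd, rmax = x
        model = np.concatenate([
            _closed_form_1to1(g.time, g.t_assoc, g.concentration, 10**lka, 10**lkd, rmax)
            for g in grams
        ])
        return model - y

    best = None
    lka_starts = np.linspace(4.0, 8.0, n_starts)
    for lka0 in lka_starts:
        x0 = [lka0, math.log10(kd0), rmax0]
        try:
            res = least_squares(
                residual, x0,
                bounds=([_LKA_BOUNDS[0], _LKD_BOUNDS[0], 0.0],
                        [_LKA_BOUNDS[1], _LKD_BOUNDS[1], 10.0 * rmax0 + 1.0]),
                method="trf", x_scale=[1.0, 1.0, rmax0],
            )
        except Exception:  # a bad start must not kill the multi-start loop
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise NumericalError("1:1 fit failed from every start")
    lka, lkd, rmax = best.x
    se = _ci_from_jac(best.jac, best.fun, best.x)
    z = 1.959963984540054  # normal 97.5% quantile
    ci = {
        "ka1": (10 ** (lka - z * se[0]), 10 ** (lka + z * se[0])),
        "kd1": (10 ** (lkd - z * se[1]), 10 ** (lkd + z * se[1])),
        "Rmax": (rmax - z * se[2], rmax + z * se[2]),
    }
    ka1, kd1 = 10**lka, 10**lkd
    # KD1 CI from the log-space difference (lkd - lka)
    se_kd1 = math.hypot(se[0], se[1])  # conservative: ignores covariance
    ci["KD1"] = (10 ** (lkd - lka - z * se_kd1), 10 ** (lkd - lka + z * se_kd1))
    return FitResult(
        params={"ka1": ka1, "kd1": kd1, "Rmax": float(rmax), "KD1": kd1 / ka1},
        stderr={"log10_ka1": float(se[0]), "log10_kd1": float(se[1]), "Rmax": float(se[2])},
        ci95=ci,
        rss=float(2 * best.cost),
        n_obs=int(y.size),
        converged=bool(best.success),
        message=best.message,
        warnings=tuple(warnings),
    )


def fit_bivalent(
    sensorgrams: list[Sensorgram],
    n_starts: int = 3,
) -> FitResult:
    """Global fit of the bivalent-analyte model.

    ka1/kd1 are seeded from a 1:1 fit; (ka2, kd2) are multi-started on a
    log-spaced grid.  Fitted parameters: ka1, kd1, ka2, kd2, Ltot; also
    reports KD1 = kd1/ka1 and the bivalent fraction AL2/(AL+AL2) at the end
    of association for the strongest curve.
    """
    grams = _stack(sensorgrams)
    rmax0 = max(g.response.max() for g in grams)
    if rmax0 <= 0:
        raise DegenerateDataError("all responses are zero; nothing to fit")
    seed = fit_1to1(grams, n_starts=3)
    y = np.concatenate([g.response for g in grams])
    t_assoc = grams[0].t_assoc
    dt = float(np.median(np.diff(grams[0].time)))
    schedule = InjectionSchedule(
        tuple(g.concentration for g in grams),
        t_assoc=t_assoc, t_dissoc=float(grams[0].time[-1] - t_assoc), dt=dt,
    )

    def residual(x):
        lka1, lkd1, lka2, lkd2, ltot = x
        p = BivalentParams(10**lka1, 10**lkd1, 10**lka2, 10**lkd2, ltot)
        try:
            model_grams = [
                np.interp(g.time, m.time, m.response)
                for g, m in zip(grams, simulate_bivalent(p, schedule))
            ]
        except NumericalError:
            return np.full(y.size, 1e6)
        return np.concatenate(model_grams) - y

    lka1_0 = math.log10(max(seed.params["ka1"], 10 ** _LKA_BOUNDS[0]))
    lkd1_0 = math.log10(max(seed.params["kd1"], 10 ** _LKD_BOUNDS[0]))
    best = None
    lka2_grid = np.linspace(-5.0, -2.0, n_starts)
    for lka2_0 in lka2_grid:
        x0 = [lka1_0, lkd1_0, lka2_0, -2.0, rmax0]
        try:
            res = least_squares(
                residual, x0,
                bounds=([_LKA_BOUNDS[0], _LKD_BOUNDS[0], -8.0, -5.0, 0.0],
                        [_LKA_BOUNDS[1], _LKD_BOUNDS[1], 0.0, 1.0, 10.0 * rmax0 + 1.0]),
                method="trf", x_scale=[1.0, 1.0, 1.0, 1.0, rmax0],
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise NumericalError("bivalent fit failed from every start")
    lka1, lkd1, lka2, lkd2, ltot = best.x
    fitted = BivalentParams(10**lka1, 10**lkd1, 10**lka2, 10**lkd2, float(ltot))
    _, states = simulate_bivalent(fitted, schedule, return_states=True)
    al, al2 = states[-1]["AL"], states[-1]["AL2"]
    i_end = int(np.searchsorted(schedule.times, t_assoc))
    tot = al[i_end] + al2[i_end]
    biv_frac = float(al2[i_end] / tot) if tot > 0 else 0.0
    se = _ci_from_jac(best.jac, best.fun, best.x)
    z = 1.959963984540054
    names = ["ka1", "kd1", "ka2", "kd2"]
    ci = {
        name: (10 ** (lx - z * s), 10 ** (lx + z * s))
        for name, lx, s in zip(names, best.x[:4], se[:4])
    }
    ci["Ltot"] = (ltot - z * se[4], ltot + z * se[4])
    return FitResult(
        params={
            "ka1": fitted.ka1, "kd1": fitted.kd1, "ka2": fitted.ka2,
            "kd2": fitted.kd2, "Ltot": fitted.Ltot,
            "KD1": fitted.kd1 / fitted.ka1, "bivalent_fraction": biv_frac,
        },
        stderr={f"log10_{n}": float(s) for n, s in zip(names, se[:4])} | {"Ltot": float(se[4])},
        ci95=ci,
        rss=float(2 * best.cost),
        n_obs=int(y.size),
        converged=bool(best.success),
        message=best.message,
    )


@dataclass(frozen=True)
class KineticMapGrid:
    """Rate-distribution decomposition: nonnegative weights on a log-spaced
    (ka, kd) grid, plus detected peaks (local maxima above threshold)."""

    ka_nodes: np.ndarray
    kd_nodes: np.ndarray
    weights: np.ndarray  # shape (n_ka, n_kd), >= 0
    peaks: tuple[tuple[int, int], ...]  # (i_ka, j_kd) grid indices

    def peak_rates(self) -> list[tuple[float, float]]:
        return [(float(self.ka_nodes[i]), float(self.kd_nodes[j])) for i, j in self.peaks]


def interaction_map(
    sensorgrams: list[Sensorgram],
    ka_range: tuple[float, float] = (1e4, 1e8),
    kd_range: tuple[float, float] = (1e-4, 1.0),
    n_ka: int = 12,
    n_kd: int = 12,
    lam: float = 1e-3,
    peak_threshold: float = 0.05,
) -> KineticMapGrid:
    """Decompose sensorgrams into a distribution of 1:1 (ka, kd) components.

    Solves  min_{w >= 0} ||B w − y||² + λ ||w||²  where column (i, j) of B is
    the unit-amplitude 1:1 trace at grid node (ka_i, kd_j) evaluated on every
    curve's time base and concentration.  Peaks are grid-local maxima above
    ``peak_threshold`` of the global maximum.  Weights are invariant to curve
    ordering and scale linearly with response amplitude.
    """
    if lam <= 0:
        raise InputError("regularisation lambda must be > 0")
    if peak_threshold <= 0 or peak_threshold >= 1:
        raise InputError("peak_threshold must lie in (0, 1)")
    grams = _stack(sensorgrams)
    ka_nodes = np.geomspace(*ka_range, n_ka)
    kd_nodes = np.geomspace(*kd_range, n_kd)
    y = np.concatenate([g.response for g in grams])
    if not np.any(y):
        return KineticMapGrid(ka_nodes, kd_nodes, np.zeros((n_ka, n_kd)), ())
    cols = []
    for ka in ka_nodes:
        for kd in kd_nodes:
            cols.append(np.concatenate([
                _closed_form_1to1(g.time, g.t_assoc, g.concentration, ka, kd, 1.0)
                for g in grams
            ]))
    B = np.column_stack(cols)
    n_nodes = B.shape[1]
    B_aug = np.vstack([B, math.sqrt(lam) * np.eye(n_nodes)])
    y_aug = np.concatenate([y, np.zeros(n_nodes)])
    w, _ = nnls(B_aug, y_aug)
    weights = w.reshape(n_ka, n_kd)
    peaks = _find_peaks(weights, peak_threshold)
    return KineticMapGrid(ka_nodes, kd_nodes, weights, peaks)


def _find_peaks(w: np.ndarray, frac: float) -> tuple[tuple[int, int], ...]:
    """Local maxima (8-neighbourhood, >=) above frac·max.

    Nonnegative least squares tends to split one broad kinetic component
    across a few nearby nodes, so maxima within two grid cells (Chebyshev) of
    a larger peak are absorbed into it; on the default 12-node / 4-decade
    grids that radius is ~0.7 decades, below the one-decade separation at
    which components are considered resolved."""
    wmax = w.max()
    if wmax <= 0:
        return ()
    n_ka, n_kd = w.shape
    raw = []
    for i in range(n_ka):
        for j in range(n_kd):
            v = w[i, j]
            if v < frac * wmax:
                continue
            neigh = w[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
            if v >= neigh.max():
                raw.append((v, i, j))
    raw.sort(reverse=True)
    kept: list[tuple[int, int]] = []
    for v, i, j in raw:
        if all(max(abs(i - pi), abs(j - pj)) > 2 for pi, pj in kept):
            kept.append((i, j))
    return tuple(sorted(kept))
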