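"""Mass-action binding models and titration/kinetics curve fits.

The ternary system A + B + C with a bispecific bridge B follows six
species (A, B, C, AB, BC, ABC) under mass action, with one rate pair per
interface: A binds B and BC with (k1, k-1); C binds B and AB with
(k2, k-2).  The dissociation constants are K1 = k-1/k1 and K2 = k-2/k2.

Three standard fit models are provided:

* single-exponential kinetics   S = A exp(-k_obs t) + B
* two-state quadratic isotherm  S = S0 + S1 fAB + slope * B_T, with
  fAB = (A_T+B_T+Kd - sqrt((A_T+B_T+Kd)^2 - 4 A_T B_T)) / (2 A_T)
* Hill curve                    S = S0 + (S1-S0) / (1 + (K/L)^n)

All concentrations are molar internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, curve_fit, least_squares

logger = logging.getLogger(__name__)

SPECIES = ("A", "B", "C", "AB", "BC", "ABC")


@dataclass(frozen=True)
class KineticRates:
    k1: float        # M^-1 s^-1, A + B and A + BC association
    k_minus1: float  # s^-1
    k2: float        # M^-1 s^-1, B + C and AB + C association
    k_minus2: float  # s^-1

    def __post_init__(self):
        if min(self.k1, self.k_minus1, self.k2, self.k_minus2) < 0:
            raise ValueError("rates must be non-negative")

    @property
    def K1(self) -> float:
        if self.k1 <= 0:
            raise ValueError("K1 undefined for k1 = 0")
        return self.k_minus1 / self.k1

    @property
    def K2(self) -> float:
        if self.k2 <= 0:
            raise ValueError("K2 undefined for k2 = 0")
        return self.k_minus2 / self.k2


def ternary_odes(state, rates: KineticRates):
    """Time derivatives of (A, B, C, AB, BC, ABC) under mass action."""
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("concentrations must be non-negative")
    A, B, C, AB, BC, ABC = state
    k1, km1, k2, km2 = rates.k1, rates.k_minus1, rates.k2, rates.k_minus2
    dA = -k1 * A * B + km1 * AB - k1 * A * BC + km1 * ABC
    dB = -k1 * A * B + km1 * AB - k2 * B * C + km2 * BC
    dC = -k2 * B * C + km2 * BC - k2 * AB * C + km2 * ABC
    dAB = k1 * A * B - km1 * AB + km2 * ABC - k2 * AB * C
    dBC = k2 * B * C - km2 * BC + km1 * ABC - k1 * A * BC
    dABC = k1 * A * BC - km1 * ABC + k2 * AB * C - km2 * ABC
    return np.array([dA, dB, dC, dAB, dBC, dABC])


def simulate_ternary(
    rates: KineticRates,
    a_total: float,
    b_total: float,
    c_total: float,
    t_grid,
    rtol: float = 1e-8,
):
    """Integrate the ternary system from free monomers at t = 0.

    Returns an (len(t_grid), 6) array of species concentrations.  The
    three conservation totals are preserved to relative 1e-6 and
    non-negativity is enforced (tiny integrator undershoot is clipped).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing and start at 0")
    totals = np.array([a_total, b_total, c_total])
    y0 = np.array([a_total, b_total, c_total, 0.0, 0.0, 0.0])
    atol = 1e-12 * max(totals.max(), 1e-30)

    def rhs(_t, y):
        return ternary_odes(np.clip(y, 0.0, None), rates)

    sol = solve_ivp(
        rhs, (0.0, t_grid[-1]), y0, t_eval=t_grid, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    y = sol.y.T
    if np.any(y < -1e-12 * max(totals.max(), 1e-30) - 1e-20):
        raise RuntimeError("integrator produced significantly negative concentrations")
    return np.clip(y, 0.0, None)


def conserved_totals(y) -> np.ndarray:
    """(A_T, B_T, C_T) of each state row."""
    y = np.atleast_2d(y)
    a = y[:, 0] + y[:, 3] + y[:, 5]
    b = y[:, 1] + y[:, 3] + y[:, 4] + y[:, 5]
    c = y[:, 2] + y[:, 4] + y[:, 5]
    return np.stack([a, b, c], axis=1)


def _equilibrium_root(K1, K2, a_t, b_t, c_t):
    """Solve the mass-action equilibrium by nested 1-D root finding.

    For a trial free-B concentration, free A and C follow in closed form;
    the outer equation is B's own conservation, monotone in free B.
    """

    def free_ac(b):
        # free A and C at fixed free B: A (1 + b/K1) + w A C = a_t and
        # C (1 + b/K2) + w A C = c_t with w = b / (K1 K2); the first,
        # with C eliminated, is monotone in A.
        u, v, w = b / K1, b / K2, b / (K1 * K2)

        def c_of(a):
            return c_t / (1.0 + v + w * a)

        def g(a):
            return a * (1.0 + u) + w * a * c_of(a) - a_t

        if a_t <= 0:
            return 0.0, c_of(0.0)
        a = brentq(g, 0.0, a_t, xtol=1e-300, rtol=1e-14)
        return a, c_of(a)

    def residual(b):
        a, c = free_ac(b)
        bound = a * b / K1 + b * c / K2 + a * b * c / (K1 * K2)
        return b + bound - b_t

    if b_t <= 0:
        b = 0.0
    else:
        b = brentq(residual, 0.0, b_t, xtol=1e-300, rtol=1e-14)
    a, c = free_ac(b)
    ab = a * b / K1
    bc = b * c / K2
    abc = ab * c / K2
    return np.array([a, b, c, ab, bc, abc])


def steady_state(
    rates: KineticRates,
    a_total: float,
    b_total: float,
    c_total: float,
    agree_rtol: float = 1e-6,
):
    """Equilibrium species distribution (kinetic and algebraic routes).

    Integrates to long time until derivatives vanish, solves the
    mass-action equilibrium algebraically, and demands agreement; the
    algebraic solution is returned.
    """
    if min(rates.k1, rates.k2, rates.k_minus1, rates.k_minus2) <= 0:
        raise ValueError("steady_state requires strictly positive rates")
    alg = _equilibrium_root(rates.K1, rates.K2, a_total, b_total, c_total)

    scale = max(a_total, b_total, c_total, 1e-30)
    # characteristic relaxation time; extend until derivatives vanish
    t_end = 10.0 / max(rates.k_minus1, rates.k_minus2, 1e-12)
    y = None
    for _ in range(12):
        y = simulate_ternary(rates, a_total, b_total, c_total, [0.0, t_end])[-1]
        if np.max(np.abs(ternary_odes(y, rates))) < 1e-10 * scale:
            break
        t_end *= 10.0
    else:
        raise RuntimeError("kinetic route did not reach steady state")
    denom = np.maximum(np.abs(alg), 1e-12 * scale)
    if np.max(np.abs(y - alg) / denom) > max(agree_rtol, 1e-4):
        raise RuntimeError("kinetic and algebraic equilibria disagree")
    return alg


def fraction_bound(a_t, b_t, kd):
    """Two-state fAB: bound fraction of A from the quadratic mass-action root.

    Uses the conjugate (numerically stable) form, exact also for kd = 0.
    """
    a_t = np.asarray(a_t, dtype=float)
    b_t = np.asarray(b_t, dtype=float)
    s = a_t + b_t + kd
    disc = np.sqrt(np.maximum(s**2 - 4.0 * a_t * b_t, 0.0))
    return np.where(a_t > 0, 2.0 * b_t / (s + disc), 0.0)


# -- fits --------------------------------------------------------------------


@dataclass
class ExponentialFitResult:
    amplitude: float
    k_obs: float          # s^-1
    baseline: float
    residual_norm: float
    low_confidence: bool = False


@dataclass
class QuadraticBindingFitResult:
    s0: float
    s1: float
    slope: float          # lumped a2 * S2 term (per molar of B_T)
    kd: float             # M
    residual_norm: float
    extrapolated: bool = False


@dataclass
class HillFitResult:
    s0: float
    s1: float
    midpoint: float       # K, M
    hill_n: float
    residual_norm: float


def fit_exponential(t, signal, dead_time: float = 0.0) -> ExponentialFitResult:
    """Least-squares fit of S = A exp(-k_obs (t + dead_time)) + B.

    Initialization: baseline from the tail, rate from a log-linear
    regression of the baseline-subtracted signal.  Degenerate (flat or
    non-decaying) data is fitted anyway but flagged low-confidence.
    """
    t = np.asarray(t, dtype=float) + dead_time
    signal = np.asarray(signal, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 points")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    n_tail = max(2, len(t) // 10)
    b0 = float(np.mean(signal[-n_tail:]))
    resid0 = signal - b0
    a0 = signal[0] - b0
    span = abs(a0)
    low_confidence = False
    scale = max(np.abs(signal).max(), 1e-30)
    if span < 1e-9 * scale:
        return ExponentialFitResult(0.0, 0.0, b0, float(np.linalg.norm(resid0)), True)
    mask = np.sign(a0) * resid0 > 1e-12 * scale
    if mask.sum() >= 2:
        k0 = max(
            1e-12,
            -np.polyfit(t[mask], np.log(np.abs(resid0[mask])), 1)[0],
        )
    else:
        k0 = 1.0 / max(t[-1], 1e-12)
        low_confidence = True

    def model(tt, amp, k, base):
        return amp * np.exp(-k * tt) + base

    # fit on a normalized signal so tolerances behave for any unit scale
    try:
        popt, _ = curve_fit(
            model, t, signal / scale, p0=[a0 / scale, k0, b0 / scale],
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        popt = [popt[0] * scale, popt[1], popt[2] * scale]
    except RuntimeError:
        logger.warning("exponential fit did not converge; reporting initial guess")
        popt = [a0, k0, b0]
        low_confidence = True
    resid = signal - model(t, *popt)
    return ExponentialFitResult(
        float(popt[0]), float(popt[1]), float(popt[2]),
        float(np.linalg.norm(resid)), low_confidence,
    )


def fit_quadratic_kd(b_totals, signal, a_total: float) -> QuadraticBindingFitResult:
    """Fit the two-state titration S = S0 + S1 fAB(A_T, B_T; Kd) + slope B_T.

    The a2 and S2 correction terms of the signal model are not separately
    identifiable (they only enter as a product with B_T) and are fitted as
    one lumped linear slope.
    """
    b_totals = np.asarray(b_totals, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(b_totals) < 6:
        raise ValueError("need at least 6 titration points")

    def model(p):
        s0, s1, slope, log_kd = p
        return s0 + s1 * fraction_bound(a_total, b_totals, 10.0**log_kd) + slope * b_totals

    def residuals(p):
        return model(p) - signal

    positives = b_totals[b_totals > 0]
    kd0 = np.sqrt(positives.min() * positives.max())
    p0 = [signal.min(), signal.max() - signal.min(), 0.0, np.log10(kd0)]
    fit = least_squares(residuals, p0, method="lm", max_nfev=20000)
    s0, s1, slope, log_kd = fit.x
    kd = 10.0**log_kd
    extrapolated = kd > 100.0 * positives.max() or kd < positives.min() / 100.0
    if extrapolated:
        logger.warning("fitted Kd lies far outside the titration range")
    return QuadraticBindingFitResult(
        float(s0), float(s1), float(slope), float(kd),
        float(np.linalg.norm(fit.fun)), extrapolated,
    )


def hill_curve(L, s0, s1, midpoint, n):
    L = np.asarray(L, dtype=float)
    return s0 + (s1 - s0) / (1.0 + (midpoint / L) ** n)


def fit_hill(conc, signal) -> HillFitResult:
    """Fit the Hill equation S = S0 + (S1 - S0) / (1 + (K/L)^n)."""
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(conc) < 6:
        raise ValueError("need at least 6 points")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    smin, smax = signal.min(), signal.max()
    mid_level = 0.5 * (smin + smax)
    k0 = conc[np.argmin(np.abs(signal - mid_level))]

    def model(L, s0, s1, log_k, n):
        return hill_curve(L, s0, s1, 10.0**log_k, n)

    popt, _ = curve_fit(
        model, conc, signal,
        p0=[signal[np.argmin(conc)], signal[np.argmax(conc)], np.log10(k0), 1.0],
        bounds=([-np.inf, -np.inf, -np.inf, 1e-3], [np.inf, np.inf, np.inf, 50.0]),
        maxfev=40000,
    )
    s0, s1, log_k, n = popt
    resid = signal - model(conc, *popt)
    return HillFitResult(
        float(s0), float(s1), float(10.0**log_k), float(n),
        float(np.linalg.norm(resid)),
    )


def pseudo_first_order_kobs(k_on: float, k_off: float, conc_excess: float) -> float:
    """k_obs = k_on [excess] + k_off for two-species binding in excess."""
    return k_on * conc_excess + k_off
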