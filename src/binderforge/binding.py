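"""Binding characterization models: 1:1 kinetics, dose-response, competition.

Three model families cover the standard binder-characterization assays:

* **Biosensor kinetics** (biolayer interferometry): a 1:1 Langmuir scheme
  with association R(t) = R_eq(1 − e^{−(k_on·C + k_off)t}),
  R_eq = R_max·C/(C + K_D), and exponential dissociation; k_on, k_off and
  R_max are fit globally across all traces and K_D = k_off/k_on.
* **Saturation dose-response** (on-cell titration): the three-parameter
  hyperbola MFI(c) = bg + (max − bg)·c/(c + K_D).
* **Global competition**: descending logistic curves with shared
  max/min plateaus and one EC50 per competitor, converted to K_D by the
  ligand-depletion correction K_D = EC50/(1 + C_L/K_D,L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import IdentifiabilityError, InvalidInputError

__all__ = [
    "KineticTrace",
    "KineticFit",
    "DoseResponseFit",
    "CompetitionFit",
    "simulate_1to1_trace",
    "fit_1to1_global",
    "simulate_dose_response",
    "fit_dose_response3",
    "simulate_competition",
    "fit_competition_global",
    "ec50_to_kd",
    "exact_competition_fraction_bound",
]


@dataclass
class KineticTrace:
    """One biosensor phase: time series of response at one concentration."""

    time_s: np.ndarray
    response: np.ndarray
    phase: str  # association | dissociation
    concentration_M: float
    series_id: str = "s1"
    buffer: str = "resting"  # resting | active | inactive | low_pH (metadata)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, float)
        self.response = np.asarray(self.response, float)
        if self.phase not in ("association", "dissociation"):
            raise InvalidInputError(f"unknown phase {self.phase!r}")
        if (np.diff(self.time_s) <= 0).any():
            raise InvalidInputError("time must be strictly increasing")
        if self.phase == "association" and self.concentration_M <= 0:
            raise InvalidInputError("association requires a positive concentration")


@dataclass
class KineticFit:
    """Global 1:1 fit result; K_D = k_off/k_on holds by construction."""

    kon_per_M_s: float
    koff_per_s: float
    rmax: float
    residual_norm: float
    identifiable: bool = True

    def __post_init__(self):
        if min(self.kon_per_M_s, self.koff_per_s, self.rmax) <= 0:
            raise InvalidInputError("rates and Rmax must be positive")

    @property
    def kd_M(self) -> float:
        return self.koff_per_s / self.kon_per_M_s


@dataclass
class DoseResponseFit:
    """Three-parameter saturation fit: K_D, background and maximum MFI."""

    kd_nM: float
    background: float
    maximum: float
    stderr: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kd_nM <= 0:
            raise InvalidInputError("K_D must be positive")
        if self.maximum <= self.background:
            raise InvalidInputError("maximum MFI must exceed the background")


@dataclass
class CompetitionFit:
    """Global competition fit: shared plateaus, per-competitor EC50/K_D."""

    shared_max: float
    shared_min: float
    ec50_nM: dict[str, float]
    kd_nM: dict[str, float]
    labeled_conc_nM: float
    labeled_kd_nM: float
    ec50_is_lower_bound: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.shared_min >= self.shared_max:
            raise InvalidInputError("shared min must be below shared max")


# ---------------------------------------------------------------------------
# forward models

def _association(t, kon, koff, rmax, conc):
    kd = koff / kon
    req = rmax * conc / (conc + kd)
    return req * (1.0 - np.exp(-(kon * conc + koff) * t))


def simulate_1to1_trace(
    kon: float, koff: float, rmax: float, concentration_M: float,
    association_time_s: float, dissociation_time_s: float,
    noise_sd: float = 0.0, seed: int = 0, n_points: int = 120,
    series_id: str = "s1",
) -> tuple[KineticTrace, KineticTrace]:
    """Simulate an association/dissociation trace pair of the 1:1 scheme."""
    if min(kon, koff, rmax, concentration_M,
           association_time_s, dissociation_time_s) <= 0:
        raise InvalidInputError("all kinetic simulation inputs must be positive")
    rng = np.random.default_rng(seed)
    t_a = np.linspace(0.0, association_time_s, n_points)[1:]
    r_a = _association(t_a, kon, koff, rmax, concentration_M)
    r_end = _association(np.array([association_time_s]), kon, koff, rmax,
                         concentration_M)[0]
    t_d = np.linspace(0.0, dissociation_time_s, n_points)[1:]
    r_d = r_end * np.exp(-koff * t_d)
    if noise_sd > 0:
        r_a = r_a + rng.normal(0, noise_sd, r_a.shape)
        r_d = r_d + rng.normal(0, noise_sd, r_d.shape)
    assoc = KineticTrace(t_a, r_a, "association", concentration_M, series_id)
    dissoc = KineticTrace(t_d, r_d, "dissociation", concentration_M, series_id)
    return assoc, dissoc


def fit_1to1_global(traces: list[KineticTrace], n_starts: int = 5) -> KineticFit:
    """Globally fit (k_on, k_off, R_max) to all phases by least squares.

    Dissociation traces start from the model's association end point of
    the same series (matched by ``series_id``); association duration is
    taken as the last association time of that series.  Multistart
    initialization over log-spaced k_on keeps the fit deterministic.
    A single-concentration dataset without dissociation data is flagged
    non-identifiable rather than rejected.
    """
    assoc = [t for t in traces if t.phase == "association"]
    dissoc = [t for t in traces if t.phase == "dissociation"]
    if not assoc or not dissoc:
        raise InvalidInputError("need at least one association and one "
                                "dissociation trace")
    t_assoc_end = {t.series_id: t.time_s[-1] for t in assoc}

    def residuals(params):
        log_kon, log_koff, log_rmax = params
        kon, koff, rmax = 10.0 ** log_kon, 10.0 ** log_koff, 10.0 ** log_rmax
        res = []
        for tr in assoc:
            res.append(_association(tr.time_s, kon, koff, rmax,
                                    tr.concentration_M) - tr.response)
        for tr in dissoc:
            t_end = t_assoc_end.get(tr.series_id, max(t_assoc_end.values()))
            r0 = _association(np.array([t_end]), kon, koff, rmax,
                              tr.concentration_M)[0]
            res.append(r0 * np.exp(-koff * tr.time_s) - tr.response)
        return np.concatenate(res)

    rmax_guess = max(float(np.max(t.response)) for t in assoc)
    best = None
    for log_kon0 in np.linspace(4.0, 7.0, n_starts):
        x0 = np.array([log_kon0, -3.0, math.log10(max(rmax_guess, 1e-6))])
        sol = least_squares(residuals, x0, bounds=([0.0, -8.0, -6.0],
                                                   [10.0, 2.0, 6.0]),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    kon, koff, rmax = (10.0 ** v for v in best.x)

    identifiable = len({t.concentration_M for t in assoc}) >= 2 or bool(dissoc)
    return KineticFit(kon, koff, rmax, float(np.sqrt(2 * best.cost)),
                      identifiable=identifiable)


# ---------------------------------------------------------------------------
# dose-response

def _dose_response(c, kd, bg, mx):
    return bg + (mx - bg) * c / (c + kd)


def simulate_dose_response(
    kd_nM: float, background: float, maximum: float,
    concentrations_nM: np.ndarray, noise_sd: float = 0.0, seed: int = 0,
) -> np.ndarray:
    """MFI values of the three-parameter saturation model."""
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations_nM, float)
    mfi = _dose_response(c, kd_nM, background, maximum)
    if noise_sd > 0:
        mfi = mfi + rng.normal(0, noise_sd, mfi.shape)
    return mfi


def fit_dose_response3(concentrations_nM: np.ndarray, mfi: np.ndarray,
                       ) -> DoseResponseFit:
    """Fit MFI(c) = bg + (max − bg)·c/(c + K_D) by least squares.

    Standard errors come from the curvature (covariance) at the optimum.
    Data without curvature — all points on one plateau — raise an
    identifiability error.
    """
    c = np.asarray(concentrations_nM, float)
    y = np.asarray(mfi, float)
    if len(c) < 4:
        raise InvalidInputError("need at least 4 titration points")
    span = y.max() - y.min()
    if span <= 0 or span < 0.02 * max(abs(y.max()), 1e-12):
        raise IdentifiabilityError("titration shows no curvature to fit")
    p0 = [float(np.median(c)), float(y.min()), float(y.max())]
    try:
        popt, pcov = curve_fit(
            _dose_response, c, y, p0=p0,
            bounds=([c.min() / 1e4, -np.inf, -np.inf],
                    [c.max() * 1e4, np.inf, np.inf]),
            maxfev=20000, xtol=1e-12, ftol=1e-12)
    except RuntimeError as exc:
        raise IdentifiabilityError(f"dose-response fit failed: {exc}") from exc
    if not np.all(np.isfinite(pcov)):
        raise IdentifiabilityError("dose-response parameters are not identifiable")
    se = np.sqrt(np.diag(pcov))
    return DoseResponseFit(
        kd_nM=float(popt[0]), background=float(popt[1]), maximum=float(popt[2]),
        stderr={"kd_nM": float(se[0]), "background": float(se[1]),
                "maximum": float(se[2])})


# ---------------------------------------------------------------------------
# competition

def _competition_mfi(x, ec50, mn, mx):
    return mn + (mx - mn) / (1.0 + x / ec50)


def simulate_competition(
    competitor_kds_nM: dict[str, float], labeled_conc_nM: float,
    labeled_kd_nM: float, shared_max: float, shared_min: float,
    concentrations_nM: np.ndarray, noise_sd: float = 0.0, seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-competitor titration curves of the shared-plateau model.

    True EC50s follow from the competitor K_Ds via the inverse of the
    EC50→K_D correction: EC50 = K_D·(1 + C_L/K_D,L).
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations_nM, float)
    out = {}
    for name, kd in competitor_kds_nM.items():
        ec50 = kd * (1.0 + labeled_conc_nM / labeled_kd_nM)
        y = _competition_mfi(c, ec50, shared_min, shared_max)
        if noise_sd > 0:
            y = y + rng.normal(0, noise_sd, y.shape)
        out[name] = (c.copy(), y)
    return out


def fit_competition_global(
    curves: dict[str, tuple[np.ndarray, np.ndarray]],
    labeled_conc_nM: float,
    labeled_kd_nM: float,
) -> CompetitionFit:
    """Globally fit descending dose-response curves with shared plateaus.

    MFI(x) = min + (max − min)/(1 + x/EC50) with the maximum (no
    competitor) and minimum (background) MFI shared across competitors
    and one free EC50 per competitor; each EC50 is then converted to a
    K_D with :func:`ec50_to_kd`.  A competitor showing no decrease over
    the tested range gets its EC50 reported as a lower bound.
    """
    if min(labeled_conc_nM, labeled_kd_nM) <= 0:
        raise InvalidInputError("labeled-ligand concentration and K_D must be positive")
    names = sorted(curves)
    if not names:
        raise InvalidInputError("no competition curves supplied")
    all_y = np.concatenate([np.asarray(curves[n][1], float) for n in names])
    mx0, mn0 = float(all_y.max()), float(all_y.min())
    if mn0 >= mx0:
        raise IdentifiabilityError("competition curves show no signal decrease")

    def unpack(params):
        mx, mn = params[0], params[1]
        ec50 = {n: 10.0 ** params[2 + i] for i, n in enumerate(names)}
        return mx, mn, ec50

    def residuals(params):
        mx, mn, ec50 = unpack(params)
        res = []
        for n in names:
            x, y = curves[n]
            res.append(_competition_mfi(np.asarray(x, float), ec50[n], mn, mx)
                       - np.asarray(y, float))
        return np.concatenate(res)

    # multistart over per-competitor EC50 initialisation
    x_all = np.concatenate([np.asarray(curves[n][0], float) for n in names])
    x_pos = x_all[x_all > 0]
    log_bounds = (math.log10(x_pos.min()) - 4.0, math.log10(x_pos.max()) + 4.0)
    best = None
    for log_ec0 in np.linspace(log_bounds[0] + 2, log_bounds[1] - 2, 5):
        x0 = np.array([mx0, mn0] + [log_ec0] * len(names))
        lb = [mn0 - abs(mn0) - 1.0, -np.inf] + [log_bounds[0]] * len(names)
        ub = [np.inf, mx0 + abs(mx0) + 1.0] + [log_bounds[1]] * len(names)
        sol = least_squares(residuals, x0, bounds=(lb, ub),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    mx, mn, ec50 = unpack(best.x)
    edge = 0.05
    lower_bound = {
        n: math.log10(ec50[n]) >= log_bounds[1] - edge for n in names}
    kd = {n: ec50_to_kd(ec50[n], labeled_conc_nM, labeled_kd_nM) for n in names}
    return CompetitionFit(float(mx), float(mn), ec50, kd,
                          labeled_conc_nM, labeled_kd_nM, lower_bound)


def ec50_to_kd(ec50: float, labeled_conc: float, labeled_kd: float) -> float:
    """Correct a competitor EC50 for labeled-ligand occupancy:
    K_D = EC50/(1 + C_L/K_D,L).  All quantities share one concentration
    unit."""
    if min(ec50, labeled_conc, labeled_kd) <= 0:
        raise InvalidInputError("ec50_to_kd inputs must be positive")
    return ec50 / (1.0 + labeled_conc / labeled_kd)


def exact_competition_fraction_bound(
    labeled_total: float, competitor_total: float, receptor_total: float,
    labeled_kd: float, competitor_kd: float,
) -> float:
    """Fraction of labeled ligand bound under exact competition.

    Closed-form solution of the coupled equilibria P+L ⇌ PL and
    P+I ⇌ PI without the free≈total approximation (the trigonometric
    root of the ternary-equilibrium cubic).  Useful when receptor or
    labeled-ligand depletion matters, e.g. fluorescence-polarization
    competition at receptor concentrations near K_D; the logistic
    shared-plateau fit remains the default model.
    """
    if min(labeled_total, receptor_total, labeled_kd, competitor_kd) <= 0:
        raise InvalidInputError("concentrations and K_Ds must be positive")
    if competitor_total < 0:
        raise InvalidInputError("competitor concentration must be nonnegative")
    a = labeled_kd + competitor_kd + labeled_total + competitor_total - receptor_total
    b = (competitor_kd * (labeled_total - receptor_total)
         + labeled_kd * (competitor_total - receptor_total)
         + labeled_kd * competitor_kd)
    c = -labeled_kd * competitor_kd * receptor_total
    q = math.sqrt(max(a * a - 3 * b, 0.0))
    theta = math.acos(min(1.0, max(-1.0,
        (-2 * a ** 3 + 9 * a * b - 27 * c) / (2 * max(q, 1e-300) ** 3))))
    root = 2 * q * math.cos(theta / 3) - a
    return root / (3 * labeled_kd + root)
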