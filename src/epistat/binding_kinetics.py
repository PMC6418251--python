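"""SPR binding kinetics and thermodynamics.

Simulates and globally fits 1:1 Langmuir sensorgrams, derives the equilibrium
dissociation constant KD = koff/kon, extracts van't Hoff enthalpy and entropy
from the temperature dependence of KD (ln KD = dH/RT - dS/R, so dG = dH - T*dS
= RT ln KD is the binding free energy), propagates the fitted (dH, dS)
covariance into sd(dG), and picks the apparent melting temperature from a DSC
thermogram as the temperature of maximum heat capacity.

Model and conventions
---------------------
Association phase (analyte at molar concentration C flowed over the surface
from t = 0 to the end of contact):

    R(t) = R_eq * (1 - exp(-(kon*C + koff) * t)),   R_eq = Rmax * kon*C / (kon*C + koff)

Dissociation (buffer only, from t0 = end of contact):

    R(t) = R(t0) * exp(-koff * (t - t0))

Mass transport, baseline drift and bulk refractive-index jumps are not
modelled; residual diagnostics are attached to fits so violations are
visible.  The global fit shares (kon, koff, Rmax) across all concentrations
and works in log10-parameter space for positivity and conditioning, with a
small multi-start over log-spaced initialisations.

Temperatures are Kelvin internally and degrees Celsius at file boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, NoPeakError, UsageError

__all__ = [
    "R_GAS_KJ",
    "PhaseSchedule",
    "Sensorgram",
    "KineticFit",
    "VantHoffFit",
    "TmResult",
    "simulate_sensorgram",
    "fit_kinetics_global",
    "vant_hoff_fit",
    "delta_g_propagated",
    "tm_app",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "read_sensorgram_csv",
    "sensorgrams_to_frame",
    "read_kd_table_csv",
    "read_thermogram_csv",
]

#: Gas constant in kJ/(mol*K).
R_GAS_KJ = 8.314462618e-3

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + CELSIUS_OFFSET


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - CELSIUS_OFFSET


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSchedule:
    """Injection schedule: contact (association) and dissociation durations in s."""

    assoc_s: float = 60.0
    dissoc_s: float = 300.0
    dt_s: float = 1.0

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.assoc_s + self.dissoc_s + 0.5 * self.dt_s, self.dt_s)


@dataclass
class Sensorgram:
    """One SPR curve: response (RU) vs time (s) at a single analyte concentration (M)."""

    times: np.ndarray
    response: np.ndarray
    analyte_conc: float
    assoc_end: float
    dissoc_end: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape:
            raise UsageError("times and response must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise UsageError("sensorgram times must be strictly increasing")
        if not 0 < self.assoc_end <= self.dissoc_end:
            raise UsageError("association must end before dissociation ends")

    @property
    def phase(self) -> np.ndarray:
        """'assoc' or 'dissoc' per time point."""
        return np.where(self.times <= self.assoc_end, "assoc", "dissoc")


@dataclass
class KineticFit:
    """Globally fitted 1:1 Langmuir parameters with sds from the fit covariance.

    ``kd`` is always koff/kon — an identity, never refit independently.
    """

    kon: float        # 1/(M*s)
    koff: float       # 1/s
    rmax: float       # RU
    kon_sd: float
    koff_sd: float
    rmax_sd: float
    kd_sd: float
    rss: float
    n_points: int
    warnings: list[str] = field(default_factory=list)
    residuals_by_conc: dict[float, float] = field(default_factory=dict)

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass
class VantHoffFit:
    """van't Hoff enthalpy/entropy with their covariance and dG at a reference T."""

    dh: float          # kJ/mol
    ds: float          # kJ/(mol*K)
    dh_sd: float
    ds_sd: float
    cov_dh_ds: float   # kJ^2/(mol^2*K)
    ref_temperature: float  # K
    n_points: int

    @property
    def dg_at_ref(self) -> float:
        return self.dh - self.ref_temperature * self.ds


@dataclass
class TmResult:
    """Apparent melting temperature: position of the heat-capacity maximum (deg C)."""

    tm_app: float
    cp_max: float
    multi_peak: bool


# --------------------------------------------------------------------------
# Langmuir model
# --------------------------------------------------------------------------

def _langmuir_response(times: np.ndarray, kon: float, koff: float, rmax: float,
                       conc: float, assoc_end: float) -> np.ndarray:
    kobs = kon * conc + koff
    if kobs <= 0:
        return np.zeros_like(times)
    r_eq = rmax * kon * conc / kobs
    assoc = r_eq * (1.0 - np.exp(-kobs * np.minimum(times, assoc_end)))
    r0 = r_eq * (1.0 - math.exp(-kobs * assoc_end))
    dissoc = r0 * np.exp(-koff * np.maximum(times - assoc_end, 0.0))
    return np.where(times <= assoc_end, assoc, dissoc)


def simulate_sensorgram(kon: float, koff: float, rmax: float, conc: float,
                        schedule: PhaseSchedule = PhaseSchedule(),
                        noise_sd: float = 0.0,
                        rng: np.random.Generator | int | None = None) -> Sensorgram:
    """Closed-form 1:1 Langmuir sensorgram with optional iid Gaussian noise (RU)."""
    if min(kon, koff, rmax, conc) < 0 or noise_sd < 0:
        raise UsageError("rates, Rmax, concentration and noise must be non-negative")
    times = schedule.times()
    response = _langmuir_response(times, kon, koff, rmax, conc, schedule.assoc_s)
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        response = response + rng.normal(0.0, noise_sd, size=times.shape)
    return Sensorgram(times=times, response=response, analyte_conc=conc,
                      assoc_end=schedule.assoc_s,
                      dissoc_end=schedule.assoc_s + schedule.dissoc_s)


# --------------------------------------------------------------------------
# global fit
# --------------------------------------------------------------------------

_LOG10 = math.log(10.0)


def _start_grid(rmax0: float) -> list[np.ndarray]:
    """Eight log-spaced (log10 kon, log10 koff, log10 rmax) initialisations."""
    kons = [1e3, 1e4, 1e5, 1e6]
    koffs = [1e-3, 1e-1]
    return [np.array([math.log10(kon), math.log10(koff), math.log10(rmax0)])
            for kon in kons for koff in koffs]


def fit_kinetics_global(panel: Sequence[Sensorgram], n_starts: int | None = None,
                        ftol: float = 1e-12) -> KineticFit:
    """Global nonlinear least-squares fit of a 1:1 Langmuir model to a panel.

    A single (kon, koff, Rmax) triple is shared across all curves.  The fit is
    parameterised in log10 space and restarted from a grid of log-spaced
    initial guesses; the best converged solution wins.  Parameter sds come
    from the Jacobian-based covariance at the optimum (delta method back to
    natural units); ``kd_sd`` uses the full (log kon, log koff) covariance.
    """
    panel = list(panel)
    if not panel:
        raise UsageError("empty sensorgram panel")
    concs = sorted({s.analyte_conc for s in panel})
    warnings_: list[str] = []
    if len(concs) < 2:
        warnings_.append(
            "single analyte concentration: kon and Rmax are weakly identifiable"
        )

    times = [s.times for s in panel]
    resp = [s.response for s in panel]
    ends = [s.assoc_end for s in panel]
    cs = [s.analyte_conc for s in panel]
    n_points = int(sum(len(t) for t in times))

    def residuals(theta: np.ndarray) -> np.ndarray:
        kon, koff, rmax = 10.0 ** np.clip(theta, -30.0, 30.0)
        parts = [
            _langmuir_response(t, kon, koff, rmax, c, e) - r
            for t, r, c, e in zip(times, resp, cs, ends)
        ]
        return np.concatenate(parts)

    rmax0 = max(1e-6, 1.05 * max(float(r.max()) for r in resp))
    starts = _start_grid(rmax0)
    if n_starts is not None:
        starts = starts[:n_starts]

    best = None
    diagnostics = []
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, method="lm", ftol=ftol, xtol=1e-12,
                                gtol=1e-12, max_nfev=4000)
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(f"start {x0}: {exc}")
            continue
        if not res.success:
            diagnostics.append(f"start {x0}: {res.message}")
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("global Langmuir fit failed from every start: "
                       + "; ".join(diagnostics))

    theta = best.x
    kon, koff, rmax = (float(v) for v in 10.0 ** theta)
    rss = float(2.0 * best.cost)

    # covariance in log10 space
    jac = best.jac
    dof = max(n_points - 3, 1)
    sigma2 = rss / dof
    try:
        cov_log = sigma2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        cov_log = np.full((3, 3), np.nan)
        warnings_.append("singular Jacobian: parameter sds unavailable")
    sd_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
    kon_sd = kon * _LOG10 * sd_log[0]
    koff_sd = koff * _LOG10 * sd_log[1]
    rmax_sd = rmax * _LOG10 * sd_log[2]
    var_log_kd = cov_log[1, 1] + cov_log[0, 0] - 2.0 * cov_log[0, 1]
    kd_sd = (koff / kon) * _LOG10 * math.sqrt(max(var_log_kd, 0.0))

    per_conc = {}
    for t, r, c, e in zip(times, resp, cs, ends):
        model = _langmuir_response(t, kon, koff, rmax, c, e)
        per_conc[c] = float(np.sqrt(np.mean((model - r) ** 2)))

    return KineticFit(kon=kon, koff=koff, rmax=rmax,
                      kon_sd=float(kon_sd), koff_sd=float(koff_sd),
                      rmax_sd=float(rmax_sd), kd_sd=float(kd_sd),
                      rss=rss, n_points=n_points, warnings=warnings_,
                      residuals_by_conc=per_conc)


# --------------------------------------------------------------------------
# van't Hoff thermodynamics
# --------------------------------------------------------------------------

def vant_hoff_fit(kd_by_temperature: Sequence[tuple[float, float]],
                  weights: Sequence[float] | None = None,
                  ref_temperature: float = 298.0) -> VantHoffFit:
    """Linear van't Hoff regression of ln KD on 1/T.

    ``kd_by_temperature`` holds (T in K, KD in M) pairs, KD > 0, at >= 3
    temperatures.  Slope = dH/R and intercept = -dS/R; the (slope, intercept)
    covariance is carried through to (dH, dS).  Unweighted by default;
    optional per-point weights give a weighted regression.
    """
    pairs = [(float(t), float(kd)) for t, kd in kd_by_temperature]
    if len(pairs) < 3:
        raise UsageError(f"need >= 3 temperatures for a van't Hoff fit, got {len(pairs)}")
    if any(kd <= 0 for _, kd in pairs):
        raise UsageError("all KD values must be positive")
    if any(t <= 0 for t, _ in pairs):
        raise UsageError("temperatures must be in Kelvin (> 0)")

    t = np.array([p[0] for p in pairs])
    y = np.log(np.array([p[1] for p in pairs]))
    x = 1.0 / t
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w < 0):
            raise UsageError("weights must be non-negative, one per point")

    design = np.column_stack([x, np.ones_like(x)])
    wsqrt = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design * wsqrt[:, None], y * wsqrt, rcond=None)
    slope, intercept = (float(b) for b in beta)
    resid = y - design @ beta
    dof = len(pairs) - 2
    sigma2 = float(np.sum(w * resid ** 2) / dof) if dof > 0 else 0.0
    xtx_inv = np.linalg.inv((design * w[:, None]).T @ design)
    cov_beta = sigma2 * xtx_inv

    dh = R_GAS_KJ * slope
    ds = -R_GAS_KJ * intercept
    dh_sd = R_GAS_KJ * math.sqrt(max(cov_beta[0, 0], 0.0))
    ds_sd = R_GAS_KJ * math.sqrt(max(cov_beta[1, 1], 0.0))
    cov_dh_ds = -R_GAS_KJ ** 2 * cov_beta[0, 1]
    return VantHoffFit(dh=dh, ds=ds, dh_sd=dh_sd, ds_sd=ds_sd,
                       cov_dh_ds=cov_dh_ds, ref_temperature=float(ref_temperature),
                       n_points=len(pairs))


def delta_g_propagated(fit: VantHoffFit, temperature: float | None = None,
                       use_covariance: bool = True) -> tuple[float, float]:
    """dG = dH - T*dS with error propagation.

    With ``use_covariance`` the (dH, dS) covariance enters:
    var(dG) = var(dH) + T^2 var(dS) - 2 T cov(dH, dS); without it, only the
    two marginal variances are summed.
    """
    t = fit.ref_temperature if temperature is None else float(temperature)
    dg = fit.dh - t * fit.ds
    var = fit.dh_sd ** 2 + t ** 2 * fit.ds_sd ** 2
    if use_covariance:
        var -= 2.0 * t * fit.cov_dh_ds
    return float(dg), float(math.sqrt(max(var, 0.0)))


# --------------------------------------------------------------------------
# DSC apparent melting temperature
# --------------------------------------------------------------------------

def tm_app(temperatures_c: Sequence[float], heat_capacity: Sequence[float],
           smooth_window: int | None = None,
           peak_prominence_frac: float = 0.05) -> TmResult:
    """Apparent Tm: temperature of the global heat-capacity maximum.

    Optional moving-average smoothing (odd ``smooth_window`` points), then a
    quadratic refinement through the three grid points around the maximum.
    Thermograms whose maximum sits on the scan boundary, or that are flat, have
    no interior peak and raise :class:`NoPeakError`.  A ``multi_peak`` flag is
    set when a second peak with prominence above ``peak_prominence_frac`` of
    the signal range is present (broad transitions with shoulders).
    """
    t = np.asarray(temperatures_c, dtype=float)
    cp = np.asarray(heat_capacity, dtype=float)
    if t.shape != cp.shape or t.ndim != 1:
        raise UsageError("temperature and heat-capacity arrays must match in shape")
    if len(t) < 5:
        raise UsageError("need at least 5 thermogram points")
    if not np.all(np.diff(t) > 0):
        raise UsageError("thermogram temperatures must be strictly increasing")

    y = cp
    if smooth_window is not None and smooth_window > 1:
        if smooth_window % 2 == 0:
            raise UsageError("smooth_window must be odd")
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(cp, kernel, mode="same")

    span = float(y.max() - y.min())
    if span <= 0:
        raise NoPeakError("flat thermogram: no heat-capacity maximum")
    imax = int(np.argmax(y))
    if imax in (0, len(y) - 1):
        raise NoPeakError("heat-capacity maximum lies on the scan boundary")

    # quadratic refinement around the grid maximum
    ts, ys = t[imax - 1: imax + 2], y[imax - 1: imax + 2]
    coeffs = np.polyfit(ts, ys, 2)
    if coeffs[0] < 0:
        tm = float(-coeffs[1] / (2.0 * coeffs[0]))
        if not ts[0] <= tm <= ts[2]:
            tm = float(t[imax])
    else:
        tm = float(t[imax])

    from scipy.signal import find_peaks
    peaks, _ = find_peaks(y, prominence=peak_prominence_frac * span)
    return TmResult(tm_app=tm, cp_max=float(y[imax]), multi_peak=len(peaks) >= 2)


# --------------------------------------------------------------------------
# file I/O (CSV boundaries; temperatures in deg C on disk)
# --------------------------------------------------------------------------

def sensorgrams_to_frame(panel: Sequence[Sensorgram]) -> pd.DataFrame:
    """Tidy table with columns time_s, response_RU, conc_M, phase."""
    frames = [
        pd.DataFrame({"time_s": s.times, "response_RU": s.response,
                      "conc_M": s.analyte_conc, "phase": s.phase})
        for s in panel
    ]
    return pd.concat(frames, ignore_index=True)


def read_sensorgram_csv(path) -> list[Sensorgram]:
    """Read a tidy sensorgram table (time_s, response_RU, conc_M, phase)."""
    df = pd.read_csv(path)
    required = {"time_s", "response_RU", "conc_M", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise UsageError(f"sensorgram CSV lacks columns: {sorted(missing)}")
    panel = []
    for conc, grp in df.groupby("conc_M", sort=True):
        grp = grp.sort_values("time_s")
        assoc = grp[grp["phase"] == "assoc"]
        if assoc.empty:
            raise UsageError(f"concentration {conc}: no association-phase points")
        panel.append(Sensorgram(
            times=grp["time_s"].to_numpy(),
            response=grp["response_RU"].to_numpy(),
            analyte_conc=float(conc),
            assoc_end=float(assoc["time_s"].max()),
            dissoc_end=float(grp["time_s"].max()),
        ))
    return panel


def read_kd_table_csv(path) -> list[tuple[float, float]]:
    """Read (T_C, KD_M) rows; returns (T in K, KD in M) pairs."""
    df = pd.read_csv(path)
    missing = {"T_C", "KD_M"} - set(df.columns)
    if missing:
        raise UsageError(f"KD table lacks columns: {sorted(missing)}")
    return [(float(celsius_to_kelvin(row.T_C)), float(row.KD_M))
            for row in df.itertuples(index=False)]


def read_thermogram_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read (T_C, Cp) columns of a DSC thermogram."""
    df = pd.read_csv(path)
    missing = {"T_C", "Cp"} - set(df.columns)
    if missing:
        raise UsageError(f"thermogram lacks columns: {sorted(missing)}")
    df = df.sort_values("T_C")
    return df["T_C"].to_numpy(dtype=float), df["Cp"].to_numpy(dtype=float)
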