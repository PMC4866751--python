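"""H2O2-driven Zn release kinetics reported by the PAR chromophore.

The protein's structural Zn2+ is released when H2O2 oxidizes the
coordinating thiolates; free Zn2+ is captured by the chelator PAR
(4-(2-pyridylazo)resorcinol) whose Zn complex absorbs at 494 nm with
eps = 85,000 M^-1 cm^-1.  With H2O2 in large excess over protein (mM vs uM)
release is pseudo-first-order:

    A(t) = baseline + plateau * (1 - exp(-k_obs * t)),   k_obs = k2 [H2O2]

so each trace yields k_obs and a plateau; a through-origin regression of
k_obs on [H2O2] gives the second-order rate constant k2, and the plateau
divided by eps * l * [protein] gives the Zn stoichiometry per monomer.
PAR binding is assumed instantaneous relative to release (PAR in >=20-fold
excess over Zn).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

#: Zn(PAR) complex molar absorptivity at 494 nm, M^-1 cm^-1.
PAR_EPSILON_494 = 85_000.0


@dataclass(frozen=True)
class KineticTrace:
    time: np.ndarray  # s, strictly increasing
    a494: np.ndarray  # absorbance units
    protein_conc: float  # M
    h2o2_conc: float  # M
    path_length: float = 1.0  # cm

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.a494, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "a494", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("time and a494 must be equal-length 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("a494 must be finite")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive")


@dataclass(frozen=True)
class TraceFit:
    k_obs: float  # s^-1
    plateau: float  # AU
    baseline: float  # AU
    k_obs_se: float
    plateau_se: float
    baseline_se: float
    degenerate: bool = False


@dataclass(frozen=True)
class SecondOrderFit:
    k2: float  # M^-1 s^-1
    k2_se: float


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot converge or is non-identifiable."""


def simulate_trace(
    k2: float,
    h2o2: float,
    zn_content: float,
    protein_conc: float,
    noise_sd: float = 0.0,
    dt: float = 1.0,
    duration: float = 1800.0,
    seed: int | None = None,
    epsilon: float = PAR_EPSILON_494,
    path_length: float = 1.0,
    baseline: float = 0.0,
) -> KineticTrace:
    """Exponential-approach PAR trace with iid Gaussian noise per point.

    A(t) = eps*l*content*P*(1 - exp(-k2*[H2O2]*t)) + baseline + noise.
    Defaults mirror the assay protocol: 1 s sampling for 30 min.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if min(k2, h2o2, zn_content, protein_conc, noise_sd) < 0:
        raise ValueError("parameters must be nonnegative")
    t = np.arange(0.0, duration + dt / 2, dt)
    amplitude = epsilon * path_length * zn_content * protein_conc
    a = baseline + amplitude * (1.0 - np.exp(-k2 * h2o2 * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=t.shape)
    return KineticTrace(
        time=t,
        a494=a,
        protein_conc=protein_conc,
        h2o2_conc=h2o2,
        path_length=path_length,
    )


def _exp_model(t: np.ndarray, baseline: float, plateau: float, k_obs: float) -> np.ndarray:
    return baseline + plateau * (1.0 - np.exp(-k_obs * t))


def fit_single_trace(trace: KineticTrace, flat_threshold: float = 0.0) -> TraceFit:
    """Nonlinear least squares of the single-exponential approach model.

    Initialization: baseline from the first point, plateau from the signal
    range, k_obs from the time to half-plateau (ln 2 / t_half).  A trace with
    signal range <= ``flat_threshold`` (exactly flat by default) is reported
    as degenerate with k_obs = plateau = 0 rather than fitted.
    """
    t, a = trace.time, trace.a494
    if t.size < 10:
        raise ValueError("need at least 10 points to fit")
    span = float(np.ptp(a))
    if span <= flat_threshold:
        return TraceFit(
            k_obs=0.0,
            plateau=0.0,
            baseline=float(a[0]),
            k_obs_se=np.inf,
            plateau_se=np.inf,
            baseline_se=0.0,
            degenerate=True,
        )
    baseline0 = float(a[0])
    plateau0 = float(a.max() - a.min())
    half = baseline0 + 0.5 * plateau0
    above = np.nonzero(a >= half)[0]
    t_half = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1]) / 2
    k0 = np.log(2.0) / max(t_half, float(t[1] - t[0]))
    try:
        popt, pcov = curve_fit(
            _exp_model,
            t,
            a,
            p0=[baseline0, plateau0, k0],
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - pathological inputs
        raise FitError(f"trace fit did not converge: {err}") from err
    se = np.sqrt(np.diag(pcov))
    k_obs_se, plateau_se = float(se[2]), float(se[1])
    # Identifiability guard: when the window never approaches the plateau
    # (k_obs * t_max < 1, i.e. < ~63% of the asymptote reached), plateau and
    # k_obs are jointly unconstrained (only their product is); the linearized
    # covariance is then meaningless, so the uncertainties are reported as
    # unknown rather than trusted.
    if float(popt[2]) * float(t[-1]) < 1.0:
        k_obs_se = plateau_se = np.inf
    return TraceFit(
        k_obs=float(popt[2]),
        plateau=float(popt[1]),
        baseline=float(popt[0]),
        k_obs_se=k_obs_se,
        plateau_se=plateau_se,
        baseline_se=float(se[0]),
        degenerate=False,
    )


def fit_second_order(
    fits_by_h2o2: Sequence[tuple[float, TraceFit]],
) -> SecondOrderFit:
    """Weighted through-origin regression of k_obs on [H2O2].

    Points whose k_obs has a usable uncertainty (finite, positive SE) are
    regressed with weights 1/SE^2; if fewer than two such points exist
    (e.g. only the highest concentration saturates within the window), the
    regression is unweighted over all points.  Forcing the origin encodes
    the no-H2O2 control (no detectable release without peroxide).
    """
    pts = [(c, f) for c, f in fits_by_h2o2 if c > 0 and not f.degenerate]
    if len(pts) < 2:
        raise FitError(
            "need k_obs at >= 2 nonzero H2O2 concentrations; with a single "
            "concentration assume pseudo-first-order and divide k_obs by [H2O2]"
        )
    x = np.array([c for c, _ in pts])
    y = np.array([f.k_obs for _, f in pts])
    se = np.array([f.k_obs_se for _, f in pts])
    usable = np.isfinite(se) & (se > 0)
    if usable.sum() >= 2:
        xw, yw, sew = x[usable], y[usable], se[usable]
        w = 1.0 / sew**2
        sxx = float(np.sum(w * xw * xw))
        slope = float(np.sum(w * xw * yw)) / sxx
        slope_se = float(np.sqrt(1.0 / sxx))
    else:
        slope = float(np.sum(x * y) / np.sum(x * x))
        resid = y - slope * x
        dof = max(len(x) - 1, 1)
        slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(x * x)))
    return SecondOrderFit(k2=slope, k2_se=slope_se)


def estimate_zn_content(
    plateau: float,
    protein_conc: float,
    epsilon: float = PAR_EPSILON_494,
    path_length: float = 1.0,
) -> float:
    """Zn stoichiometry (mol/mol monomer) from the release plateau."""
    if protein_conc <= 0:
        raise ValueError("protein_conc must be positive")
    return plateau / (epsilon * path_length * protein_conc)


@dataclass(frozen=True)
class ReleaseSeriesFit:
    trace_fits: tuple[tuple[float, TraceFit], ...]  # ([H2O2], fit)
    k2: float
    k2_se: float
    zn_content: float


def fit_release_series(traces: Sequence[KineticTrace]) -> ReleaseSeriesFit:
    """Fit every trace, regress k_obs on [H2O2], and read the stoichiometry
    from the plateau of the highest-concentration trace (closest to full
    release within the observation window)."""
    fits = [(tr.h2o2_conc, fit_single_trace(tr)) for tr in traces]
    so = fit_second_order(fits)
    nonzero = [(c, f, tr) for (c, f), tr in zip(fits, traces) if c > 0 and not f.degenerate]
    if not nonzero:
        raise FitError("no nonzero-H2O2 trace to estimate the Zn content from")
    c, f, tr = max(nonzero, key=lambda item: item[0])
    content = estimate_zn_content(f.plateau, tr.protein_conc, path_length=tr.path_length)
    return ReleaseSeriesFit(
        trace_fits=tuple(fits),
        k2=so.k2,
        k2_se=so.k2_se,
        zn_content=content,
    )
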