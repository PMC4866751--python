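"""Apparent-Kd estimation from EMSA titrations.

The shifted fraction of a trace-labelled probe at protein concentration P is
modelled by the single-site isotherm theta(P) = P / (P + Kd): probe well
below Kd (no ligand depletion), Hill coefficient 1.  Kd is "apparent" on
the protein-concentration basis as supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class TitrationPoint:
    protein_conc: float  # M
    fraction_bound: float  # 0..1

    def __post_init__(self) -> None:
        if self.protein_conc < 0:
            raise ValueError("protein_conc must be nonnegative")
        if not 0.0 <= self.fraction_bound <= 1.0:
            raise ValueError("fraction_bound must be in [0, 1]")


@dataclass(frozen=True)
class BindingFit:
    kd_apparent: float  # M
    kd_se: float
    model: str = "single-site"
    assumptions: tuple[str, ...] = (
        "no ligand depletion (probe << Kd)",
        "Hill coefficient fixed at 1",
    )


class BindingFitError(RuntimeError):
    pass


def isotherm(p: np.ndarray, kd: float) -> np.ndarray:
    return p / (p + kd)


def simulate_titration(
    kd: float,
    concs: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    noise_mode: str = "multiplicative",
) -> list[TitrationPoint]:
    """Single-site binding points with clipped Gaussian noise.

    ``multiplicative`` noise scales each theta by (1 + N(0, sd)); ``additive``
    adds N(0, sd).  Either way the result is clipped to [0, 1].
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    p = np.asarray(concs, dtype=float)
    if np.any(p < 0):
        raise ValueError("concentrations must be nonnegative")
    theta = isotherm(p, kd)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=theta.shape)
        if noise_mode == "multiplicative":
            theta = theta * (1.0 + eps)
        elif noise_mode == "additive":
            theta = theta + eps
        else:
            raise ValueError("noise_mode must be 'multiplicative' or 'additive'")
    theta = np.clip(theta, 0.0, 1.0)
    return [TitrationPoint(float(c), float(f)) for c, f in zip(p, theta)]


def fit_kd(points: Sequence[TitrationPoint]) -> BindingFit:
    """Nonlinear least squares of theta(P) = P/(P + Kd).

    Requires >= 4 points; an all-bound or all-free titration is rejected as
    non-identifiable rather than fitted.
    """
    if len(points) < 4:
        raise BindingFitError("need at least 4 titration points")
    p = np.array([pt.protein_conc for pt in points])
    f = np.array([pt.fraction_bound for pt in points])
    if np.all(f >= 0.95):
        raise BindingFitError("all points near saturation: Kd not identifiable")
    if np.all(f <= 0.05):
        raise BindingFitError("all points near zero binding: Kd not identifiable")
    # initialize at the concentration whose fraction is closest to 0.5
    kd0 = float(p[np.argmin(np.abs(f - 0.5))])
    if kd0 <= 0:
        kd0 = float(np.median(p[p > 0]))
    popt, pcov = curve_fit(
        isotherm, p, f, p0=[kd0], bounds=(0.0, np.inf), maxfev=10000
    )
    return BindingFit(
        kd_apparent=float(popt[0]),
        kd_se=float(np.sqrt(pcov[0, 0])),
    )
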