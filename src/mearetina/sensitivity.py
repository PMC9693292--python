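"""Hill-equation intensity–response fits and the half-max sensitivity σ.

Each unit's light response versus flash intensity is fit with the Hill
equation R(I) = R_max·Iⁿ/(Iⁿ+σⁿ) on linear intensity I = 10^(log
intensity); σ — the intensity evoking the half-maximum response — is
reported as sigma_log = log10(σ). A lower σ means higher light
sensitivity. The Hill coefficient is free but bounded to [0.3, 6]:
unbounded n makes σ unidentifiable on a six-point ladder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import ValidationError

HILL_N_BOUNDS = (0.3, 6.0)


class NonresponsiveError(ValueError):
    """All responses are ≤ 0; a Hill fit is meaningless."""


@dataclass
class IntensityResponse:
    """One unit's response (spikes/s, spontaneous-subtracted) per intensity."""

    unit_id: str
    intensities_log: np.ndarray
    responses: np.ndarray
    variant: str = "peak"          # peak | average
    n_trials: int | None = None

    def __post_init__(self) -> None:
        self.intensities_log = np.asarray(self.intensities_log, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.intensities_log.shape != self.responses.shape:
            raise ValidationError("intensities_log and responses must have "
                                  "equal length")
        if np.any(np.diff(self.intensities_log) <= 0):
            raise ValidationError("intensities_log must be strictly "
                                  "increasing")


@dataclass
class HillFit:
    """Fitted Hill parameters for one unit."""

    unit_id: str
    r_max: float
    hill_n: float
    sigma_log: float
    rss: float
    converged: bool
    extrapolated: bool             # sigma_log outside [min−1, max+1]
    variant: str = "peak"

    def predict(self, intensities_log: np.ndarray) -> np.ndarray:
        return hill_curve(np.asarray(intensities_log), self.r_max,
                          self.hill_n, self.sigma_log)


def hill_curve(intensity_log: np.ndarray, r_max: float, n: float,
               sigma_log: float) -> np.ndarray:
    """R(I) on linear intensity, evaluated stably in the log10 domain."""
    return r_max / (1.0 + 10.0 ** (n * (sigma_log - intensity_log)))


def fit_hill(data: IntensityResponse,
             n_bounds: tuple[float, float] = HILL_N_BOUNDS) -> HillFit:
    """Unweighted least-squares Hill fit with a 3×3 multi-start grid.

    Starts span (σ, n) ∈ {low, mid, high intensity} × {0.5, 1, 3}; the
    best converged start wins. Negative response points are kept (they are
    spontaneous-subtracted rates, not clipped). σ outside the sampled
    ladder ± 1 log unit is flagged extrapolated, not an error.
    """
    x, y = data.intensities_log, data.responses
    if x.size < 4:
        raise ValidationError("need at least 4 intensity points")
    if np.all(y <= 0):
        raise NonresponsiveError(f"unit {data.unit_id}: no positive response")

    lo, hi = float(x.min()), float(x.max())
    r0 = float(y.max())
    bounds = ([0.0, n_bounds[0], lo - 3.0],
              [10.0 * r0 + 1e-9, n_bounds[1], hi + 3.0])

    def resid(theta: np.ndarray) -> np.ndarray:
        return hill_curve(x, *theta) - y

    best, best_rss, converged = None, np.inf, False
    for s0 in (lo, 0.5 * (lo + hi), hi):
        for n0 in (0.5, 1.0, 3.0):
            res = least_squares(resid, x0=[r0, n0, s0], bounds=bounds,
                                method="trf", xtol=1e-12, ftol=1e-12)
            rss = float(2.0 * res.cost)
            if rss < best_rss:
                best, best_rss = res, rss
                converged = bool(res.success)
    r_max, n, sigma_log = (float(v) for v in best.x)
    return HillFit(
        unit_id=data.unit_id, r_max=r_max, hill_n=n, sigma_log=sigma_log,
        rss=best_rss, converged=converged,
        extrapolated=not (lo - 1.0 <= sigma_log <= hi + 1.0),
        variant=data.variant,
    )


def hill_grid_search(data: IntensityResponse,
                     sigma_step: float = 0.01, n_step: float = 0.025,
                     n_bounds: tuple[float, float] = HILL_N_BOUNDS,
                     ) -> HillFit:
    """Brute-force Hill fit over a (σ_log, n) lattice.

    For each lattice point R_max has the closed-form least-squares value
    max(0, Σh·y/Σh²) where h is the unit-amplitude Hill curve. Serves as an
    independent check of the gradient-based optimizer.
    """
    x, y = data.intensities_log, data.responses
    if np.all(y <= 0):
        raise NonresponsiveError(f"unit {data.unit_id}: no positive response")
    lo, hi = float(x.min()), float(x.max())

    def scan(sig: np.ndarray, ns: np.ndarray):
        # h: (n_sig, n_n, n_points)
        h = 1.0 / (1.0 + 10.0 ** (ns[None, :, None]
                                  * (sig[:, None, None] - x[None, None, :])))
        num = (h * y[None, None, :]).sum(axis=-1)
        den = (h * h).sum(axis=-1)
        r = np.clip(num / den, 0.0, None)
        rss = ((r[:, :, None] * h - y[None, None, :]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        return i, j, r, rss

    sig = np.arange(lo - 1.5, hi + 1.5 + sigma_step, sigma_step)
    ns = np.arange(n_bounds[0], n_bounds[1] + n_step, n_step)
    i, j, _, _ = scan(sig, ns)
    # local refinement at 1/20 of the coarse steps around the coarse minimum
    sig = np.arange(sig[i] - sigma_step, sig[i] + sigma_step,
                    sigma_step / 20)
    ns = np.clip(np.arange(ns[j] - n_step, ns[j] + n_step, n_step / 20),
                 n_bounds[0], n_bounds[1])
    i, j, r, rss = scan(sig, ns)
    return HillFit(
        unit_id=data.unit_id, r_max=float(r[i, j]), hill_n=float(ns[j]),
        sigma_log=float(sig[i]), rss=float(rss[i, j]), converged=True,
        extrapolated=not (lo - 1.0 <= sig[i] <= hi + 1.0),
        variant=data.variant,
    )


def compare_sensitivity(fits_by_group: dict[str, list[HillFit]],
                        ) -> pd.DataFrame:
    """Per-group mean sigma_log ± SEM, excluding unusable fits.

    Non-converged or extrapolated fits are excluded; exclusion counts are
    reported so group n is auditable. Raises if any group is empty after
    exclusion.
    """
    rows = []
    for group, fits in fits_by_group.items():
        kept = [f for f in fits if f.converged and not f.extrapolated]
        if len(kept) < 2:
            raise ValidationError(
                f"group '{group}': fewer than 2 usable fits "
                f"({len(fits) - len(kept)} of {len(fits)} excluded)")
        for variant in sorted({f.variant for f in kept}):
            vals = np.array([f.sigma_log for f in kept
                             if f.variant == variant])
            rows.append({
                "group": group, "variant": variant,
                "mean_sigma_log": float(vals.mean()),
                "sem_sigma_log": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1 else 0.0,
                "n_units": int(vals.size),
                "n_excluded": len(fits) - len(kept),
            })
    return pd.DataFrame(rows)
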