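"""Nonlinear fits for equilibrium binding and RNA stability.

Binding: fluorescence-anisotropy saturation vs protein concentration fit by
the hyperbolic single-site form y = A_free + (A_bound − A_free)·P/(K_d + P)
(valid in the no-depletion regime, probe ≪ K_d); a quadratic ligand-depletion
variant is available behind a flag. Stability: single-exponential decay
y = y0·2^(−t/t½) with a log-linear seed; series that never drop below 90% of
the initial intensity are reported as censored lower bounds on the half-life
(the ">10 days" situation), not point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .simulate import binding_model, decay_model


@dataclass
class BindingCurve:
    """(protein concentration [nM], anisotropy) measurements."""

    protein_conc: np.ndarray
    anisotropy: np.ndarray
    probe_conc: float = 0.5  # nM

    def __post_init__(self) -> None:
        self.protein_conc = np.asarray(self.protein_conc, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.protein_conc.shape != self.anisotropy.shape:
            raise ValueError("concentration/anisotropy length mismatch")
        if (self.protein_conc < 0).any():
            raise ValueError("concentrations must be nonnegative")
        if len(np.unique(self.protein_conc)) < 5:
            raise ValueError("at least 5 distinct concentrations required")


@dataclass
class DecayCurve:
    """(time [h], intensity) measurements; t[0] must be 0 for normalization."""

    time: np.ndarray
    intensity: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time/intensity length mismatch")
        if (np.diff(self.time) < 0).any():
            raise ValueError("time must be sorted ascending")
        if self.time[0] != 0:
            raise ValueError("first time point must be 0")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be nonnegative")


@dataclass
class FitResult:
    param: float  # K_d [nM] or half-life [h]; a lower bound when censored
    stderr: float
    floor: float
    ceiling: float
    residual_ss: float
    converged: bool
    censored: bool = False
    n_boot: int = 0

    def __post_init__(self) -> None:
        if self.converged and self.param <= 0:
            raise ValueError("fitted parameter must be positive")
        if self.stderr < 0:
            raise ValueError("stderr must be nonnegative")


def _binding_depletion(P, kd, floor, ceiling, probe):
    b = P + probe + kd
    frac = (b - np.sqrt(b * b - 4.0 * P * probe)) / (2.0 * probe)
    return floor + (ceiling - floor) * frac


def fit_kd(
    curve: BindingCurve, depletion: bool = False, n_boot: int = 0, seed: int = 0
) -> FitResult:
    """Least-squares K_d from a saturation binding curve.

    Multi-start initialization over a geometric K_d grid spanning the
    concentration range; stderr from the local curvature (covariance), with
    an optional residual-bootstrap stderr when `n_boot` > 0.
    """
    x, y = curve.protein_conc, curve.anisotropy
    if depletion:
        model = lambda P, kd, lo, hi: _binding_depletion(P, kd, lo, hi, curve.probe_conc)  # noqa: E731
    else:
        model = binding_model
    pos = x[x > 0]
    starts = np.geomspace(pos.min() / 10.0, pos.max() * 10.0, 7)
    lo0, hi0 = float(y.min()), float(y.max())
    best = None
    for kd0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model, x, y, p0=[kd0, lo0, hi0],
                bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10_000,
            )
        except (RuntimeError, ValueError):
            continue
        ss = float(((y - model(x, *popt)) ** 2).sum())
        if best is None or ss < best[2] - 1e-15:
            best = (popt, pcov, ss)
    if best is None:
        return FitResult(np.nan, 0.0, np.nan, np.nan, np.inf, converged=False)
    popt, pcov, ss = best
    stderr = float(np.sqrt(np.diag(pcov))[0]) if np.isfinite(pcov).all() else 0.0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        resid = y - model(x, *popt)
        boot = []
        for _ in range(n_boot):
            yb = model(x, *popt) + rng.choice(resid, size=len(resid), replace=True)
            try:
                pb, _ = optimize.curve_fit(
                    model, x, yb, p0=popt,
                    bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=10_000,
                )
                boot.append(pb[0])
            except (RuntimeError, ValueError):
                continue
        if len(boot) > 1:
            stderr = float(np.std(boot, ddof=1))
    return FitResult(
        param=float(popt[0]), stderr=stderr, floor=float(popt[1]),
        ceiling=float(popt[2]), residual_ss=ss, converged=True, n_boot=n_boot,
    )


def percent_remaining(curve: DecayCurve) -> DecayCurve:
    """Normalize intensities to the t = 0 value, expressed as percent."""
    y0 = curve.intensity[0]
    if y0 <= 0:
        raise ValueError("intensity at t = 0 must be positive")
    return DecayCurve(curve.time.copy(), 100.0 * curve.intensity / y0, normalized=True)


def fit_half_life(curve: DecayCurve, identifiability_drop: float = 0.9) -> FitResult:
    """Half-life from single-exponential decay, with censoring.

    If no observation falls below `identifiability_drop` × y0, the decay is
    not identifiable over the observation window and the result is a censored
    lower bound t½ > max(t) rather than a point estimate. Otherwise a
    log-linear regression seeds a nonlinear least-squares fit; the seed
    solution is kept if the refinement does not reduce the residual sum.
    """
    t, y = curve.time, curve.intensity
    if len(t) < 4:
        raise ValueError("at least 4 time points required")
    y0_obs = y[0]
    if y0_obs <= 0:
        raise ValueError("initial intensity must be positive")
    if y.min() > identifiability_drop * y0_obs:
        return FitResult(
            param=float(t.max()), stderr=0.0, floor=0.0, ceiling=float(y0_obs),
            residual_ss=float(((y - y0_obs) ** 2).sum()), converged=False, censored=True,
        )
    # log-linear seed on strictly positive intensities
    mask = y > 0
    slope, intercept = np.polyfit(t[mask], np.log2(y[mask]), 1)
    if slope >= 0:
        return FitResult(
            param=float(t.max()), stderr=0.0, floor=0.0, ceiling=float(y0_obs),
            residual_ss=float(((y - y0_obs) ** 2).sum()), converged=False, censored=True,
        )
    seed_thalf, seed_y0 = -1.0 / slope, float(2.0**intercept)
    seed_ss = float(((y - decay_model(t, seed_y0, seed_thalf)) ** 2).sum())
    model = lambda tt, y0, th: decay_model(tt, y0, th)  # noqa: E731
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=[seed_y0, seed_thalf],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10_000,
        )
        ss = float(((y - model(t, *popt)) ** 2).sum())
    except (RuntimeError, ValueError):
        popt, pcov, ss = None, None, np.inf
    if popt is None or ss > seed_ss:
        y0_fit, thalf, ss = seed_y0, seed_thalf, seed_ss
        stderr = 0.0
    else:
        y0_fit, thalf = float(popt[0]), float(popt[1])
        stderr = float(np.sqrt(np.diag(pcov))[1]) if np.isfinite(pcov).all() else 0.0
    return FitResult(
        param=thalf, stderr=stderr, floor=0.0, ceiling=y0_fit,
        residual_ss=ss, converged=True,
    )
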