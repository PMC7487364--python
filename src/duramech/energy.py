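"""Global constitutive identification from total strain energy.

Rather than fitting a constitutive law element by element (noisy and hard to
average), the membrane's global response is characterized by its total strain
energy.  The experimental energy accumulates the tensor contraction of the
measured Cauchy stress with the logarithmic strain increment, element by
element and frame by frame (trapezoidal rule), then integrates over the
reference volume.  The model energy evaluates the incompressible plane-stress
Ogden or NeoHookean strain-energy density at the measured principal
stretches.  The parameters minimizing the squared mismatch of the two energy
traces over all frames are found by trust-region nonlinear least squares with
multistart, with asymptotic 95% confidence half-widths.

For incompressible response the accumulated Cauchy-stress/log-strain work
density equals the strain energy per reference volume; the two integrations
are therefore directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "EnergyTrace",
    "ConstitutiveParams",
    "experimental_energy",
    "model_energy",
    "identify_parameters",
]

ALPHA_STARTS = (2.0, 5.0, 10.0, 20.0)


@dataclass
class EnergyTrace:
    """Per-frame total strain energy with its per-element density history."""

    W_exp: np.ndarray      # (n_frames,) total strain energy (J)
    pressures: np.ndarray  # (n_frames,) chamber pressure (Pa)
    w: np.ndarray          # (n_frames, m) strain-energy density (J/m^3)
    volumes: np.ndarray    # (m,) reference element volumes (m^3)


@dataclass
class ConstitutiveParams:
    """Identified hyperelastic parameters and fit quality."""

    model: str                 # "ogden" or "neohookean"
    mu: float | None = None    # Pa (Ogden)
    alpha: float | None = None
    c1: float | None = None    # Pa (NeoHookean)
    r2: float = np.nan
    ci95: dict | None = None   # 95% confidence half-widths per parameter
    shear_modulus: float = np.nan  # mu_s (Pa)
    youngs_modulus: float = np.nan  # E = 3 mu_s (Pa)


def experimental_energy(stress_frames: list[np.ndarray],
                        strain_frames: list[np.ndarray],
                        volumes: np.ndarray,
                        pressures: np.ndarray | None = None) -> EnergyTrace:
    """Accumulate total strain energy from stress and strain histories.

    ``stress_frames[k]`` and ``strain_frames[k]`` are (m, 2, 2) in-plane
    tensors of frame ``k`` (frame 0 is the unloaded reference).  The density
    increment per element is the trapezoidal rule applied to sigma : dE,
    where the contraction counts the off-diagonal term twice; the
    through-thickness direction contributes nothing (sigma_33 = 0).
    """
    n_frames = len(stress_frames)
    if len(strain_frames) != n_frames:
        raise ValueError("stress and strain frame counts differ")
    volumes = np.asarray(volumes, float)
    m = volumes.shape[0]
    for k in range(n_frames):
        if stress_frames[k].shape != (m, 2, 2) \
                or strain_frames[k].shape != (m, 2, 2):
            raise ValueError(f"frame {k}: element count mismatch")
    w = np.zeros((n_frames, m))
    for k in range(1, n_frames):
        dE = strain_frames[k] - strain_frames[k - 1]
        s_mid = 0.5 * (stress_frames[k] + stress_frames[k - 1])
        w[k] = w[k - 1] + np.einsum("mij,mij->m", s_mid, dE)
    W = w @ volumes
    if pressures is None:
        pressures = np.full(n_frames, np.nan)
    return EnergyTrace(W_exp=W, pressures=np.asarray(pressures, float),
                       w=w, volumes=volumes)


def _psi_ogden(lam1, lam2, mu, alpha):
    return (mu / alpha) * (lam1 ** alpha + lam2 ** alpha
                           + (lam1 * lam2) ** (-alpha) - 3.0)


def _psi_neohookean(lam1, lam2, c1):
    return c1 * (lam1 ** 2 + lam2 ** 2 + (lam1 * lam2) ** (-2) - 3.0)


def model_energy(lam1: np.ndarray, lam2: np.ndarray, volumes: np.ndarray,
                 model: str, **params) -> np.ndarray:
    """Per-frame total model strain energy at the measured stretches.

    ``lam1``/``lam2`` are (n_frames, m) principal-stretch histories; the
    incompressible plane-stress strain-energy density is summed over elements
    weighted by the (constant) reference volumes.
    """
    lam1 = np.asarray(lam1, float)
    lam2 = np.asarray(lam2, float)
    volumes = np.asarray(volumes, float)
    if np.any(lam1 <= 0) or np.any(lam2 <= 0):
        raise ValueError("principal stretches must be positive")
    if model == "ogden":
        psi = _psi_ogden(lam1, lam2, params["mu"], params["alpha"])
    elif model == "neohookean":
        psi = _psi_neohookean(lam1, lam2, params["c1"])
    else:
        raise ValueError(f"unknown model {model!r}")
    return psi @ volumes


def _ogden_basis(lam1, lam2, volumes, alpha):
    """W_ogden / mu as a function of alpha (the energy is linear in mu)."""
    return ((lam1 ** alpha + lam2 ** alpha + (lam1 * lam2) ** (-alpha) - 3.0)
            @ volumes) / alpha


def identify_parameters(energy: EnergyTrace, lam1: np.ndarray,
                        lam2: np.ndarray, volumes: np.ndarray,
                        model: str = "ogden") -> ConstitutiveParams:
    """Fit the hyperelastic parameters to the experimental energy trace.

    Minimizes ``sum_i (W_exp_i - W_model_i(theta))**2`` over theta = (mu,
    alpha) or (C1,) by trust-region nonlinear least squares; the Ogden fit is
    multistarted over alpha with mu profiled out (the energy is linear in
    mu).  Confidence half-widths are Student-t asymptotics from the Jacobian
    at the optimum; R^2 is computed about the mean of W_exp.
    """
    W = np.asarray(energy.W_exp, float)
    lam1 = np.asarray(lam1, float)
    lam2 = np.asarray(lam2, float)
    volumes = np.asarray(volumes, float)
    nz = np.count_nonzero(np.abs(W) > 0)
    if np.allclose(W, 0):
        raise ValueError("all-zero energy trace: parameters unidentifiable")
    if nz < 5:
        raise ValueError("need >= 5 frames with nonzero energy")

    if model == "ogden":
        best = None
        for a0 in ALPHA_STARTS:
            g = _ogden_basis(lam1, lam2, volumes, a0)
            denom = g @ g
            if denom <= 0:
                continue
            mu0 = max((W @ g) / denom, 1e-3)
            try:
                res = least_squares(
                    lambda th: _ogden_basis(lam1, lam2, volumes, th[1])
                    * th[0] - W,
                    x0=[mu0, a0], bounds=([1e-12, 0.05], [np.inf, 100.0]),
                    x_scale=[max(mu0, 1e-6), max(a0, 1.0)],
                    method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("Ogden identification failed to start")
        res = best
        mu, alpha = res.x
        params = ConstitutiveParams(model="ogden", mu=float(mu),
                                    alpha=float(alpha))
        params.shear_modulus = float(mu * alpha / 2.0)
        names = ("mu", "alpha")
    elif model == "neohookean":
        g = _psi_neohookean(lam1, lam2, 1.0) @ volumes
        c0 = max((W @ g) / (g @ g), 1e-3)
        res = least_squares(lambda th: g * th[0] - W, x0=[c0],
                            bounds=([1e-12], [np.inf]), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        params = ConstitutiveParams(model="neohookean", c1=float(res.x[0]))
        params.shear_modulus = float(2.0 * res.x[0])
        names = ("c1",)
    else:
        raise ValueError(f"unknown model {model!r}")
    if not res.success:
        raise RuntimeError(
            f"identification did not converge (final cost {res.cost:.3e})")

    params.youngs_modulus = 3.0 * params.shear_modulus
    ssr = 2.0 * res.cost
    sst = float(np.sum((W - W.mean()) ** 2))
    params.r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    params.ci95 = _asymptotic_ci(res, names)
    return params


def _asymptotic_ci(res, names) -> dict:
    """95% half-widths from the HC3 sandwich covariance at the optimum.

    The energy residuals scale with the energy itself (noise is effectively
    multiplicative and the late, high-energy frames carry most leverage), so
    the classic homoscedastic formula badly understates the parameter
    variance; the leverage-corrected sandwich stays calibrated.
    """
    J, r = res.jac, res.fun
    n, p = r.size, res.x.size
    dof = max(n - p, 1)
    try:
        JtJi = np.linalg.inv(J.T @ J)
        lev = np.clip(np.einsum("ij,jk,ik->i", J, JtJi, J), 0.0, 1.0 - 1e-8)
        meat = (J.T * (r ** 2 / (1.0 - lev) ** 2)) @ J
        cov = JtJi @ meat @ JtJi
        half = stats.t.ppf(0.975, dof) * np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        half = np.full(p, np.nan)
    return {name: float(h) for name, h in zip(names, half)}
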