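"""Uniaxial tensile models, curve fitting, moduli conversions, failure metrics.

For an incompressible Ogden solid in uniaxial tension (lam_1 = lam,
lam_2 = lam_3 = lam**-1/2) the engineering (first Piola-Kirchhoff) stress is

    P(lam) = mu (lam**(alpha - 1) - lam**(-alpha/2 - 1)),

the Cauchy stress sigma = lam P, the initial shear modulus mu_s = mu alpha / 2
and the Young's modulus E = 3 mu_s.  The one-parameter NeoHookean law is the
alpha = 2 special case with C1 = mu / 2 (so mu_s = 2 C1, P = 2 C1 (lam -
lam**-2)).

Fitting targets the engineering stress by default (the measure a load cell
and initial cross-section yield); Cauchy-stress fitting is available via
``target="cauchy"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "UniaxialRecord",
    "FitResult",
    "model_stress",
    "fit_curve",
    "derived_moduli",
    "curve_metrics",
    "synthetic_uniaxial_record",
]

ALPHA_STARTS = (2.0, 5.0, 10.0, 20.0)


@dataclass
class UniaxialRecord:
    """One dogbone test: stretch and engineering-stress arrays to failure."""

    stretch: np.ndarray
    stress: np.ndarray       # engineering stress P (Pa)
    gauge_length: float | None = None   # m
    width: float | None = None          # m
    thickness: float | None = None      # m
    orientation: str = "longitudinal"
    strain_rate: float | None = None    # 1/s

    def __post_init__(self) -> None:
        self.stretch = np.asarray(self.stretch, float)
        self.stress = np.asarray(self.stress, float)
        if self.stretch.shape != self.stress.shape or self.stretch.ndim != 1:
            raise ValueError("stretch and stress must be equal-length 1D")
        if self.stretch.size < 3:
            raise ValueError("need at least 3 points")
        if not np.isclose(self.stretch[0], 1.0):
            raise ValueError("record must start at stretch 1")
        if not np.isfinite(self.stress).all():
            raise ValueError("stress must be finite")
        if self.orientation not in ("longitudinal", "transverse"):
            raise ValueError("orientation must be longitudinal|transverse")


@dataclass
class FitResult:
    """Fitted uniaxial constitutive parameters and failure metrics."""

    model: str
    mu: float | None = None
    alpha: float | None = None
    c1: float | None = None
    r2: float = np.nan
    ci95: dict | None = None
    shear_modulus: float = np.nan
    youngs_modulus: float = np.nan
    uts: float = np.nan             # max engineering stress (Pa)
    failure_strain: float = np.nan  # engineering strain at last point (-)


def model_stress(model: str, stretch, **params):
    """Engineering and Cauchy stress of the uniaxial model at ``stretch``.

    Returns the pair ``(P, sigma)`` with ``sigma = stretch * P``.
    """
    lam = np.asarray(stretch, float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    if model == "ogden":
        mu, alpha = params["mu"], params["alpha"]
        P = mu * (lam ** (alpha - 1.0) - lam ** (-alpha / 2.0 - 1.0))
    elif model == "neohookean":
        c1 = params["c1"]
        P = 2.0 * c1 * (lam - lam ** -2.0)
    else:
        raise ValueError(f"unknown model {model!r}")
    return P, lam * P


def fit_curve(record: UniaxialRecord, model: str = "ogden",
              target: str = "engineering") -> FitResult:
    """Least-squares fit of the uniaxial stress model to a test record.

    The Ogden fit profiles mu (the stress is linear in mu) and multistarts
    over alpha; R^2 is reported on the fitted stress measure.
    """
    lam = record.stretch
    if np.any(np.diff(lam) <= 0):
        raise ValueError("stretch must be strictly increasing")
    if np.allclose(record.stress, 0):
        raise ValueError("degenerate all-zero stress record")
    if target == "engineering":
        y = record.stress
        measure = 0
    elif target == "cauchy":
        y = lam * record.stress
        measure = 1
    else:
        raise ValueError("target must be engineering|cauchy")

    if model == "ogden":
        def shape(alpha):
            return model_stress("ogden", lam, mu=1.0, alpha=alpha)[measure]

        best = None
        for a0 in ALPHA_STARTS:
            g = shape(a0)
            mu0 = max((y @ g) / (g @ g), 1e-3)
            try:
                res = least_squares(
                    lambda th: th[0] * shape(th[1]) - y, x0=[mu0, a0],
                    bounds=([1e-12, 0.05], [np.inf, 100.0]), method="trf",
                    x_scale=[max(mu0, 1e-6), max(a0, 1.0)],
                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("Ogden fit failed from every start")
        res = best
        out = FitResult(model="ogden", mu=float(res.x[0]),
                        alpha=float(res.x[1]))
        names = ("mu", "alpha")
    elif model == "neohookean":
        g = model_stress("neohookean", lam, c1=1.0)[measure]
        c0 = max((y @ g) / (g @ g), 1e-3)
        res = least_squares(lambda th: th[0] * g - y, x0=[c0],
                            bounds=([1e-12], [np.inf]), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        out = FitResult(model="neohookean", c1=float(res.x[0]))
        names = ("c1",)
    else:
        raise ValueError(f"unknown model {model!r}")

    ssr = 2.0 * res.cost
    sst = float(np.sum((y - y.mean()) ** 2))
    out.r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    out.ci95 = _asymptotic_ci(res, names)
    out.shear_modulus, out.youngs_modulus = derived_moduli(out)
    out.uts, out.failure_strain = curve_metrics(record)
    return out


def derived_moduli(params) -> tuple[float, float]:
    """Initial shear modulus and Young's modulus from fitted parameters.

    Ogden: ``mu_s = mu alpha / 2``; NeoHookean: ``mu_s = 2 C1``.  For an
    isotropic incompressible solid ``E = 3 mu_s``.
    """
    if getattr(params, "model", None) == "ogden" or (
            getattr(params, "mu", None) is not None
            and getattr(params, "alpha", None) is not None):
        mu_s = params.mu * params.alpha / 2.0
    elif getattr(params, "c1", None) is not None:
        mu_s = 2.0 * params.c1
    else:
        raise ValueError("params must carry (mu, alpha) or c1")
    return float(mu_s), float(3.0 * mu_s)


def curve_metrics(record: UniaxialRecord) -> tuple[float, float]:
    """UTS (max engineering stress) and failure strain (last stretch - 1)."""
    if np.allclose(record.stress, 0):
        raise ValueError("all-zero stress record")
    return (float(record.stress.max()),
            float(record.stretch[-1] - 1.0))


def synthetic_uniaxial_record(mu: float = 450e3, alpha: float = 16.55,
                              n_points: int = 100, lam_max: float = 1.22,
                              noise_rel: float = 0.02,
                              seed: int = 0,
                              orientation: str = "longitudinal"
                              ) -> UniaxialRecord:
    """Dogbone test record from the Ogden model with multiplicative noise.

    Defaults emulate the tensile cohort being studied: mean Ogden parameters
    (450 kPa, 16.55), failure at 22% engineering strain, 2% relative noise.
    """
    lam = np.linspace(1.0, lam_max, n_points)
    P, _ = model_stress("ogden", lam, mu=mu, alpha=alpha)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        P = P * (1.0 + rng.normal(0.0, noise_rel, P.shape))
        P[0] = 0.0
    return UniaxialRecord(stretch=lam, stress=P, orientation=orientation,
                          strain_rate=0.01)


def _asymptotic_ci(res, names) -> dict:
    """95% half-widths, HC3 sandwich (stress noise is near-multiplicative)."""
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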