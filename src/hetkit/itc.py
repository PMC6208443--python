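"""Forward model and least-squares fitting of isothermal titration
calorimetry data for a single class of N identical, independent sites.

Model
-----
After cumulative injected volume v into a perfusion (constant-volume,
overflow) cell of volume V0, concentrations follow the exponential
dilution convention:

    [M]_t = M0 * exp(-v/V0)          macromolecule in the cell
    [X]_t = Xs * (1 - exp(-v/V0))    titrant that has entered and stayed

Bound titrant B solves the one-site-class equilibrium (S = N*[M]_t is the
site concentration):

    B = ( (X + S + Kd) - sqrt((X + S + Kd)^2 - 4*S*X) ) / 2

The cell heat content is Q = V0 * dH * B and the i-th injection heat uses
the displaced-volume correction

    dq_i = Q_i - Q_{i-1} + (dv_i / V0) * (Q_i + Q_{i-1}) / 2

Because B depends on N and [M]_t only through their product S, an
N-identical-sites protein at concentration M is algebraically identical to
a one-site species at concentration N*M — the exact identity used as the
fitting oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingParams",
    "Isotherm",
    "FitResult",
    "NoDetectableBinding",
    "default_injections",
    "molar_ratio",
    "predict_heats",
    "fit_isotherm",
    "compare_affinities",
]


class NoDetectableBinding(ValueError):
    """Raised when an isotherm carries no usable binding signal."""


@dataclass
class BindingParams:
    """One-site-class binding parameters and instrument geometry.

    Units: concentrations in uM, volumes in mL/uL as named, dH in
    kcal per mole of sites.
    """

    kd_uM: float
    dh_kcal: float
    n_sites: float = 1.0
    cell_uM: float = 100.0
    syringe_uM: float = 1200.0
    v0_mL: float = 0.1

    def __post_init__(self) -> None:
        if self.kd_uM <= 0:
            raise ValueError("Kd must be positive")
        if self.n_sites <= 0:
            raise ValueError("N must be positive")
        if self.cell_uM <= 0 or self.syringe_uM <= 0 or self.v0_mL <= 0:
            raise ValueError("concentrations and cell volume must be positive")

    @property
    def c_value(self) -> float:
        """Wiseman c = N * [cell] / Kd, a fit-quality diagnostic."""
        return self.n_sites * self.cell_uM / self.kd_uM


@dataclass
class Isotherm:
    """An injection series: volumes (uL), measured heats (ucal), and the
    molar ratio [X]/[M] reached after each injection."""

    volumes_uL: np.ndarray
    heats_ucal: np.ndarray
    molar_ratio: np.ndarray
    saturation_warning: bool = False

    def __post_init__(self) -> None:
        self.volumes_uL = np.asarray(self.volumes_uL, dtype=np.float64)
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=np.float64)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=np.float64)
        if not (len(self.volumes_uL) == len(self.heats_ucal) == len(self.molar_ratio)):
            raise ValueError("inconsistent isotherm array lengths")


def default_injections(n: int = 19, volume_uL: float = 2.0) -> np.ndarray:
    """The standard schedule: n equal injections."""
    return np.full(n, volume_uL, dtype=np.float64)


def _dilution_state(params: BindingParams, volumes_uL: np.ndarray):
    v0_uL = params.v0_mL * 1000.0
    vcum = np.cumsum(np.asarray(volumes_uL, dtype=np.float64))
    f = np.exp(-vcum / v0_uL)
    mt = params.cell_uM * f          # uM
    xt = params.syringe_uM * (1 - f)  # uM
    return v0_uL, vcum, mt, xt


def molar_ratio(params: BindingParams, volumes_uL: np.ndarray) -> np.ndarray:
    """[X]_t / [M]_t after each injection."""
    _, _, mt, xt = _dilution_state(params, volumes_uL)
    return xt / mt


def _bound_conc(xt: np.ndarray, sites: np.ndarray, kd: float) -> np.ndarray:
    b = xt + sites + kd
    disc = b * b - 4.0 * sites * xt
    return 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))


def predict_heats(params: BindingParams, volumes_uL: np.ndarray) -> np.ndarray:
    """Per-injection heats (ucal) from the one-site-class model."""
    v0_uL, _, mt, xt = _dilution_state(params, volumes_uL)
    sites = params.n_sites * mt
    bound = _bound_conc(xt, sites, params.kd_uM)  # uM
    # Q in ucal: dH[kcal/mol] * V0[L] * B[mol/L] * 1e9 [ucal/kcal]
    v0_L = params.v0_mL / 1000.0
    q = params.dh_kcal * v0_L * (bound * 1e-6) * 1e9
    q_prev = np.concatenate([[0.0], q[:-1]])
    dv = np.asarray(volumes_uL, dtype=np.float64)
    return q - q_prev + (dv / v0_uL) * (q + q_prev) / 2.0


@dataclass
class FitResult:
    """A converged one-site-class fit with approximate standard errors."""

    kd_uM: float
    dh_kcal: float
    n_sites: float
    kd_se: float
    dh_se: float
    n_se: float
    c_value: float
    sse: float
    residuals_kcal_per_mol: np.ndarray = field(repr=False)
    converged: bool = True
    c_flag: str = ""
    message: str = ""


def _heats_per_mole(heats_ucal, volumes_uL, syringe_uM) -> np.ndarray:
    # kcal per mole of injectant: ucal / (uL * uM) = ucal/pmol -> kcal/mol = *1e-3... derive:
    # moles injected = dv[uL]*1e-6 L * syringe[uM]*1e-6 M = dv*syringe*1e-12 mol
    # heat = q[ucal]*1e-6 cal = q*1e-9 kcal
    # kcal/mol = q*1e-9 / (dv*syringe*1e-12) = 1e3 * q / (dv*syringe)
    heats_ucal = np.asarray(heats_ucal, dtype=np.float64)
    dv = np.asarray(volumes_uL, dtype=np.float64)
    return 1e3 * heats_ucal / (dv * syringe_uM)


def fit_isotherm(
    data: Isotherm,
    cell_uM: float = 100.0,
    syringe_uM: float = 1200.0,
    v0_mL: float = 0.1,
    model: str = "one_site",
) -> FitResult:
    """Nonlinear least-squares fit of (Kd, dH, N) to an injection series.

    Residuals are taken in heat-per-mole-of-injectant units (kcal/mol).
    Initialization is a deterministic multi-start over a log-spaced Kd grid
    and stoichiometry guesses that include the molar ratio at the half-heat
    point; the best converged start by SSE wins. Raises
    :class:`NoDetectableBinding` for flat isotherms and ``RuntimeError`` on
    non-convergence.
    """
    if model != "one_site":
        raise ValueError(f"unknown model {model!r}")
    volumes = np.asarray(data.volumes_uL, dtype=np.float64)
    heats = np.asarray(data.heats_ucal, dtype=np.float64)
    if len(volumes) < 8:
        raise ValueError("need at least 8 injections to fit")
    ndh_obs = _heats_per_mole(heats, volumes, syringe_uM)
    if np.max(np.abs(ndh_obs)) < 1e-4:
        raise NoDetectableBinding("no binding detected: all heats are ~zero")

    geometry = dict(cell_uM=cell_uM, syringe_uM=syringe_uM, v0_mL=v0_mL)

    def residuals(x):
        log_kd, dh, n = x
        p = BindingParams(kd_uM=10.0 ** log_kd, dh_kcal=dh, n_sites=max(n, 1e-6), **geometry)
        pred = _heats_per_mole(predict_heats(p, volumes), volumes, syringe_uM)
        return pred - ndh_obs

    # heuristic starts: dH from the first injections, N from the molar
    # ratio at the half-cumulative-heat point
    dh0 = float(np.mean(ndh_obs[:2]))
    ratio = molar_ratio(BindingParams(1.0, -1.0, 1.0, **geometry), volumes)
    cumq = np.cumsum(heats)
    half = 0.5 * cumq[-1]
    k = int(np.argmin(np.abs(cumq - half)))
    n_half = float(np.clip(ratio[k], 0.1, 20.0))

    best = None
    for log_kd0 in (-1.0, 0.0, 1.0, 2.0):
        for n0 in {1.0, round(n_half, 2), 3.0}:
            try:
                res = least_squares(
                    residuals,
                    x0=[log_kd0, dh0 if dh0 != 0 else -1.0, n0],
                    bounds=([-6.0, -1e4, 1e-3], [6.0, 1e4, 100.0]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            sse = float(np.sum(res.fun ** 2))
            if res.success and (best is None or sse < best[0]):
                best = (sse, res)
    if best is None:
        raise RuntimeError("isotherm fit failed to converge from any start")
    sse, res = best
    log_kd, dh, n = res.x
    kd = 10.0 ** log_kd

    # approximate covariance from the Jacobian at the optimum
    dof = max(len(volumes) - 3, 1)
    s2 = sse / dof
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        se = np.sqrt(np.maximum(np.diag(jtj_inv) * s2, 0.0))
        kd_se = float(kd * np.log(10) * se[0])  # delta method for 10**x
        dh_se, n_se = float(se[1]), float(se[2])
    except np.linalg.LinAlgError:
        kd_se = dh_se = n_se = np.nan

    c = n * cell_uM / kd
    c_flag = "low_c" if c < 1 else ("high_c" if c > 1000 else "")
    return FitResult(
        kd_uM=float(kd), dh_kcal=float(dh), n_sites=float(n),
        kd_se=kd_se, dh_se=dh_se, n_se=n_se,
        c_value=float(c), sse=sse, residuals_kcal_per_mol=res.fun,
        converged=True, c_flag=c_flag, message=res.message,
    )


def compare_affinities(fits: dict[str, FitResult], reference: str):
    """Fold-ratio table of fitted Kd values against a reference state.

    ratio = Kd_label / Kd_reference, with first-order propagated
    uncertainty from the fit standard errors.
    """
    import pandas as pd

    if reference not in fits:
        raise KeyError(f"reference state {reference!r} not among fits")
    if len(fits) < 2:
        raise ValueError("compare_affinities needs at least 2 fits")
    ref = fits[reference]
    rows = []
    for label, fit in fits.items():
        ratio = fit.kd_uM / ref.kd_uM
        rel = 0.0
        if np.isfinite(fit.kd_se) and np.isfinite(ref.kd_se):
            rel = np.sqrt(
                (fit.kd_se / fit.kd_uM) ** 2 + (ref.kd_se / ref.kd_uM) ** 2
            )
        rows.append({
            "label": label, "kd_uM": fit.kd_uM, "ratio_vs_ref": ratio,
            "ratio_se": ratio * rel, "ratio_1dp": round(ratio, 1),
            "reference": reference,
        })
    return pd.DataFrame(rows)
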