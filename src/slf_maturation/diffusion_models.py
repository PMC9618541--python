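"""Microstructure model fitting: the diffusion tensor on the b = 0/1000
sub-scheme and a simplified three-compartment NODDI on all shells.

The tensor is fitted by weighted least squares on the log-signal (one WLS
iteration with squared-predicted-signal weights from an OLS start), then
eigen-decomposed into FA / MD / AD / RD.  The NODDI fit estimates
(NDI, ODI, f_iso) by coarse grid search over the forward model of
:mod:`slf_maturation.synthetic_data` followed by bounded Nelder-Mead
refinement; the mean neurite direction is taken from the tensor's
principal eigenvector rather than being optimised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import FitError, GradientError
from .io_formats import SHELL_TOLERANCE, GradientScheme
from .synthetic_data import noddi_signal
from .watson import dispersed_stick_attenuation, kappa_from_odi, watson_tau1

__all__ = [
    "TensorFit",
    "NoddiFit",
    "extract_subscheme",
    "fit_dti",
    "fit_dti_volume",
    "tensor_metrics",
    "fit_noddi",
    "fit_noddi_volume",
]


@dataclass
class TensorFit:
    D: np.ndarray  # symmetric 3x3 diffusion tensor, mm^2/s
    s0: float
    eigenvalues: np.ndarray  # sorted descending
    eigenvectors: np.ndarray  # columns match eigenvalues
    n_negative_eigenvalues: int = 0


@dataclass
class NoddiFit:
    ndi: float
    odi: float
    f_iso: float
    residual: float  # root-mean-square misfit
    mu: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    degenerate: bool = False  # f_iso ~ 1: ndi/odi unidentifiable


def extract_subscheme(
    scheme: GradientScheme, keep_b, tol: float = SHELL_TOLERANCE
) -> tuple[GradientScheme, np.ndarray]:
    """Keep only the volumes whose b-value matches one of ``keep_b`` within
    ``tol``; order preserved.  Raises if a requested shell is absent."""
    keep_b = sorted(float(b) for b in keep_b)
    mask = np.zeros(len(scheme), dtype=bool)
    for b in keep_b:
        sel = np.abs(scheme.bvals - b) <= tol
        if not np.any(sel):
            raise GradientError(f"no volumes at b = {b:g} s/mm^2")
        mask |= sel
    idx = np.nonzero(mask)[0]
    sub = GradientScheme(bvals=scheme.bvals[idx], bvecs=scheme.bvecs[idx])
    return sub, idx


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    g = scheme.bvecs
    b = scheme.bvals
    return np.column_stack(
        [
            np.ones(len(b)),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def _tensor_from_params(p: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [p[1], p[4], p[5]],
            [p[4], p[2], p[6]],
            [p[5], p[6], p[3]],
        ]
    )


def fit_dti(signals: np.ndarray, scheme: GradientScheme) -> TensorFit:
    """Weighted least-squares tensor fit of ln S = ln S0 - b g^T D g.

    Non-positive signals are excluded from the fit (the voxel errors out if
    fewer than 7 usable volumes remain).  One WLS iteration with weights
    equal to the squared OLS-predicted signals follows the OLS start.
    """
    signals = np.asarray(signals, dtype=float).ravel()
    if len(signals) != len(scheme):
        raise FitError("signal length does not match gradient scheme")
    usable = signals > 0
    if np.any(~usable):
        if usable.sum() < 7:
            raise FitError("fewer than 7 positive signals")
        sub = GradientScheme(
            bvals=scheme.bvals[usable], bvecs=scheme.bvecs[usable]
        )
        return fit_dti(signals[usable], sub)
    if len(signals) < 7:
        raise FitError("tensor fit needs >= 7 volumes")
    if len(scheme.b0_indices) < 1:
        raise FitError("tensor fit needs >= 1 b=0 volume")
    X = _design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise FitError("rank-deficient design (gradient directions degenerate)")
    y = np.log(signals)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    # one WLS pass: weights = predicted signal squared
    w = np.exp(X @ beta) ** 2
    Xw = X * w[:, None]
    beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    D = _tensor_from_params(beta)
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return TensorFit(
        D=D,
        s0=float(np.exp(beta[0])),
        eigenvalues=evals,
        eigenvectors=evecs,
        n_negative_eigenvalues=int(np.sum(evals < 0)),
    )


def tensor_metrics(fit: TensorFit) -> dict:
    """FA / MD / AD / RD from the tensor eigenvalues.

    Negative eigenvalues are clamped to zero before computing the metrics;
    an all-zero tensor has FA defined as 0.  FA is clamped into [0, 1].
    """
    lam = np.maximum(np.asarray(fit.eigenvalues, dtype=float), 0.0)
    md = float(lam.mean())
    ad = float(lam[0])
    rd = float((lam[1] + lam[2]) / 2.0)
    norm = float(np.sqrt(np.sum(lam**2)))
    if norm == 0.0:
        fa = 0.0
    else:
        fa = float(np.sqrt(1.5 * np.sum((lam - md) ** 2)) / norm)
    return {"FA": min(max(fa, 0.0), 1.0), "MD": md, "AD": ad, "RD": rd}


def fit_dti_volume(dwi: np.ndarray, scheme: GradientScheme) -> dict:
    """Fit every voxel of a 4-D array; returns metric arrays plus the
    principal-eigenvector field (used to seed the NODDI fit)."""
    dwi = np.asarray(dwi, dtype=float)
    grid = dwi.shape[:-1]
    flat = dwi.reshape(-1, dwi.shape[-1])
    out = {m: np.zeros(flat.shape[0]) for m in ("FA", "MD", "AD", "RD")}
    e1 = np.zeros((flat.shape[0], 3))
    for v in range(flat.shape[0]):
        fit = fit_dti(flat[v], scheme)
        for m, val in tensor_metrics(fit).items():
            out[m][v] = val
        e1[v] = fit.eigenvectors[:, 0]
    result = {m: arr.reshape(grid) for m, arr in out.items()}
    result["e1"] = e1.reshape(grid + (3,))
    return result


# ---------------------------------------------------------------------------
# NODDI


_DEFAULT_NDI_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)
_DEFAULT_ODI_GRID = np.round(np.arange(0.05, 1.0001, 0.05), 10)
_DEFAULT_FISO_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)


def fit_noddi(
    signals: np.ndarray,
    scheme: GradientScheme,
    mu: np.ndarray | None = None,
    d_par: float = 1.7e-3,
    d_iso: float = 3.0e-3,
    ndi_grid: np.ndarray = _DEFAULT_NDI_GRID,
    odi_grid: np.ndarray = _DEFAULT_ODI_GRID,
    fiso_grid: np.ndarray = _DEFAULT_FISO_GRID,
    refine_tol: float = 1e-4,
) -> NoddiFit:
    """Estimate (ndi, odi, f_iso) for one voxel by grid search + refinement.

    ``mu`` is the mean neurite direction; when omitted it is estimated as
    the principal eigenvector of a tensor fitted on the b <= 1000 shells.
    Requires a multi-shell scheme (>= 2 distinct non-zero shells).
    """
    signals = np.asarray(signals, dtype=float).ravel()
    if len(signals) != len(scheme):
        raise FitError("signal length does not match gradient scheme")
    shells = [b for b in scheme.shells() if b > SHELL_TOLERANCE]
    if len(shells) < 2:
        raise FitError("NODDI needs >= 2 non-zero shells (model degenerate)")
    # normalise to the mean b=0 signal
    b0 = scheme.b0_indices
    if len(b0) < 1:
        raise FitError("NODDI needs >= 1 b=0 volume")
    s0 = float(np.mean(signals[b0]))
    if s0 <= 0:
        raise FitError("non-positive b=0 signal")
    y = signals / s0

    if mu is None:
        low_shells = [0.0] + [b for b in shells if b <= 1000 + SHELL_TOLERANCE]
        sub, idx = extract_subscheme(scheme, low_shells)
        tensor = fit_dti(np.clip(signals[idx], 1e-8, None), sub)
        mu = tensor.eigenvectors[:, 0]
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    cos_angle = scheme.bvecs @ mu

    def model(ndi, odi, f_iso):
        return noddi_signal(
            ndi, odi, f_iso, cos_angle, scheme.bvals, d_par=d_par, d_iso=d_iso
        )

    # grid search: the Watson quadrature depends on odi only, so evaluate it
    # once per odi node and sweep the (ndi, f_iso) plane with cheap algebra
    a_iso = np.exp(-scheme.bvals * d_iso)
    bd = scheme.bvals * d_par
    ndi_col = np.asarray(ndi_grid, dtype=float)[:, None]
    best = (np.inf, None)
    for odi in odi_grid:
        kappa = float(kappa_from_odi(odi))
        a_intra = dispersed_stick_attenuation(bd, cos_angle, kappa)
        tau1 = watson_tau1(kappa)
        d_perp = d_par * (1.0 - ndi_col)
        d_ax = d_perp + (d_par - d_perp) * tau1
        d_rad = d_perp + (d_par - d_perp) * (1.0 - tau1) / 2.0
        a_extra = np.exp(
            -scheme.bvals[None, :] * (d_rad + (d_ax - d_rad) * cos_angle[None, :] ** 2)
        )
        tissue = ndi_col * a_intra[None, :] + (1.0 - ndi_col) * a_extra
        for f in fiso_grid:
            pred = (1.0 - f) * tissue + f * a_iso[None, :]
            sse = np.sum((pred - y[None, :]) ** 2, axis=1)
            i = int(np.argmin(sse))
            if sse[i] < best[0]:
                best = (float(sse[i]), (float(ndi_grid[i]), float(odi), float(f)))
    _, (ndi0, odi0, f0) = best

    def objective(p):
        ndi, odi, f = p
        return float(np.sum((model(ndi, odi, f) - y) ** 2))

    res = minimize(
        objective,
        x0=[ndi0, odi0, f0],
        method="Nelder-Mead",
        bounds=[(0.0, 1.0), (0.01, 1.0), (0.0, 1.0)],
        options={"xatol": refine_tol, "fatol": 1e-12, "maxiter": 400},
    )
    ndi, odi, f_iso = (float(v) for v in res.x)
    rms = float(np.sqrt(res.fun / len(y)))
    return NoddiFit(
        ndi=ndi,
        odi=odi,
        f_iso=f_iso,
        residual=rms,
        mu=mu,
        degenerate=f_iso >= 0.95,
    )


def fit_noddi_volume(
    dwi: np.ndarray, scheme: GradientScheme, **kwargs
) -> dict:
    """Fit every voxel of a 4-D array; returns NDI / ODI / f_iso arrays."""
    dwi = np.asarray(dwi, dtype=float)
    grid = dwi.shape[:-1]
    flat = dwi.reshape(-1, dwi.shape[-1])
    out = {m: np.zeros(flat.shape[0]) for m in ("NDI", "ODI", "FISO")}
    for v in range(flat.shape[0]):
        fit = fit_noddi(flat[v], scheme, **kwargs)
        out["NDI"][v] = fit.ndi
        out["ODI"][v] = fit.odi
        out["FISO"][v] = fit.f_iso
    return {m: arr.reshape(grid) for m, arr in out.items()}
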