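"""Classical nucleation theory analysis of cluster excess Gibbs energies.

The excess Gibbs energy of an N-molecule crystallite is modelled as a volume
driving term plus a surface penalty,

    dG_ex(N) = -delta_mu * N + b * N^(2/3),

and the critical nucleus is the point of vanishing chemical potential
mu = d(dG_ex)/dN = 0, i.e. N* = (2b / (3 delta_mu))^3.  The surface
coefficient converts to an interfacial tension through the spherical-cluster
surface factor s = (36 pi)^(1/3) v_m^(2/3): gamma = b / (s N_A).

A ``saturating`` analysis is also provided for restrained-cluster data that
levels off at a 2D-periodic slab reference; there the critical size is
declared where the fitted slope falls below a fraction of its maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .constants import N_AVOGADRO

#: molecular volume of beta-D-mannitol from the crystal structure
#: (M = 182.17 g/mol at crystal density), nm^3 per molecule
V_M_MANNITOL = 0.203


class CNTFitError(RuntimeError):
    """Degenerate or non-convergent CNT fit."""


@dataclass
class ClusterGibbsCurve:
    """Excess Gibbs energy vs cluster size with 1-SD uncertainties."""

    N: np.ndarray  # molecules, strictly increasing
    dG: np.ndarray  # kJ/mol
    sd: np.ndarray  # kJ/mol, >= 0
    slab_reference: float | None = None  # kJ/mol

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N)
        self.dG = np.asarray(self.dG, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.N) == len(self.dG) == len(self.sd)):
            raise ValueError("N, dG, sd length mismatch")
        if np.any(np.diff(self.N) <= 0):
            raise ValueError("N must be strictly increasing")
        if np.any(self.sd < 0):
            raise ValueError("uncertainties must be >= 0")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# N\tdG_ex_kJ_mol\tsd_kJ_mol\n")
            if self.slab_reference is not None:
                fh.write(f"# slab_reference = {self.slab_reference:g}\n")
            for n, g, s in zip(self.N, self.dG, self.sd):
                fh.write(f"{n}\t{g:.6f}\t{s:.6f}\n")

    @classmethod
    def from_tsv(cls, path) -> "ClusterGibbsCurve":
        slab = None
        rows = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                if "slab_reference" in line:
                    slab = float(line.split("=")[1])
                continue
            if line.strip():
                n, g, s = line.split("\t")
                rows.append((int(n), float(g), float(s)))
        arr = np.array(rows)
        return cls(arr[:, 0].astype(int), arr[:, 1], arr[:, 2], slab_reference=slab)


@dataclass
class CNTFit:
    """Fitted CNT coefficients and derived critical size."""

    form: str
    delta_mu: float | None  # kJ/mol per molecule
    b: float | None  # kJ/mol per N^(2/3)
    b_err: float | None
    N_star: int | None  # molecules; None = no finite critical size
    v_m: float = V_M_MANNITOL  # nm^3


def fit_cnt(curve: ClusterGibbsCurve, form: str = "two_term", tol: float = 0.01) -> CNTFit:
    """Fit the excess-Gibbs curve and locate the critical nucleus size.

    ``two_term``: weighted least squares of dG = -delta_mu*N + b*N^(2/3);
    N* = round((2b/(3 delta_mu))^3); delta_mu <= 0 means no finite critical
    size.  ``saturating``: fit an exponential approach to the plateau (the
    slab reference anchors the plateau when provided) and report the smallest
    N whose fitted slope magnitude is at most ``tol`` times the maximum slope.
    """
    if len(curve.N) < 4:
        raise CNTFitError("need at least 4 points to fit")
    n = curve.N.astype(float)
    g = curve.dG
    if np.allclose(g, 0.0) or np.ptp(g) == 0.0:
        raise CNTFitError("degenerate fit: curve has no structure")
    w = np.where(curve.sd > 0, 1.0 / np.maximum(curve.sd, 1e-12), 1.0)

    if form == "two_term":
        design = np.column_stack([-n, n ** (2.0 / 3.0)]) * w[:, None]
        coef, *_ = np.linalg.lstsq(design, g * w, rcond=None)
        delta_mu, b = float(coef[0]), float(coef[1])
        resid = g - (-delta_mu * n + b * n ** (2.0 / 3.0))
        dof = max(len(n) - 2, 1)
        cov = np.linalg.inv(design.T @ design) * float(resid @ (resid * w**2)) / dof
        b_err = float(math.sqrt(max(cov[1, 1], 0.0)))
        if delta_mu <= 0:
            return CNTFit("two_term", delta_mu, b, b_err, None)
        n_star = int(round((2.0 * b / (3.0 * delta_mu)) ** 3))
        return CNTFit("two_term", delta_mu, b, b_err, max(n_star, 2))

    if form == "saturating":
        plateau = curve.slab_reference

        def model(x, amp, lam):
            return amp * (1.0 - np.exp(-x / lam))

        p0_amp = plateau if plateau is not None else g[-1]
        try:
            if plateau is not None:
                popt, _ = curve_fit(
                    lambda x, lam: model(x, plateau, lam), n, g, p0=[10.0], maxfev=10000
                )
                amp, lam = plateau, float(popt[0])
            else:
                popt, _ = curve_fit(model, n, g, p0=[p0_amp, 10.0], maxfev=10000)
                amp, lam = float(popt[0]), float(popt[1])
        except RuntimeError as exc:
            raise CNTFitError(f"saturating fit did not converge: {exc}") from exc
        slope = np.abs(amp / lam * np.exp(-n / lam))
        below = np.flatnonzero(slope <= tol * slope.max())
        n_star = int(n[below[0]]) if len(below) else None
        return CNTFit("saturating", None, None, None, n_star)

    raise ValueError(f"unknown CNT fit form {form!r}")


def surface_factor(v_m: float) -> float:
    """Spherical per-molecule surface factor s = (36 pi)^(1/3) v_m^(2/3), m^2."""
    if v_m <= 0:
        raise ValueError("molecular volume must be > 0")
    return (36.0 * math.pi) ** (1.0 / 3.0) * (v_m * 1e-27) ** (2.0 / 3.0)


def interfacial_tension(
    fit: CNTFit, v_m: float = V_M_MANNITOL, with_uncertainty: bool = False
):
    """Solid/liquid interfacial tension from the CNT surface coefficient.

    gamma = b / (s N_A) with s the spherical surface factor; returned in
    mJ/m^2.  The uncertainty is propagated linearly from the fitted b.
    """
    if fit.b is None or not math.isfinite(fit.b):
        raise ValueError("fit has no finite surface coefficient")
    s = surface_factor(v_m)
    gamma = fit.b * 1000.0 / (N_AVOGADRO * s) * 1000.0  # kJ/mol -> J/mol -> mJ/m^2
    if with_uncertainty:
        err = (fit.b_err or 0.0) * 1000.0 / (N_AVOGADRO * s) * 1000.0
        return gamma, err
    return gamma


def calibrated_surface_coefficient(gamma_mj_m2: float, v_m: float = V_M_MANNITOL) -> float:
    """Inverse of :func:`interfacial_tension`: b (kJ/mol) giving gamma."""
    return gamma_mj_m2 / 1000.0 * N_AVOGADRO * surface_factor(v_m) / 1000.0
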