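"""Quadratic ligand-depletion binding isotherm for MST titrations.

In a microscale-thermophoresis experiment a fluorescently labelled target
at fixed concentration C_T is titrated with a ligand at concentrations C.
Because C_T is not negligible relative to Kd, the free-ligand approximation
(simple hyperbola) is biased, and the exact solution of the 1:1 equilibrium
with ligand depletion is used instead:

    F(C) = U + (B - U) * (C + C_T + Kd - sqrt((C + C_T + Kd)^2 - 4*C*C_T))
                 / (2 * C_T)

where U and B are the responses of the fully unbound and fully bound
states.  The second factor is the bound fraction of the target.  All
concentrations are handled internally in molar units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: Default labelled-target concentration, molar (20 nM).
DEFAULT_C_T = 20e-9

_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6, "nM": 1e-9, "pM": 1e-12}


class FitError(RuntimeError):
    """Nonlinear least squares failed to produce a usable fit."""


def binding_response(C, U: float, B: float, C_T: float, Kd: float):
    """Model response at ligand concentration(s) ``C`` (molar).

    Exact 1:1 bound fraction with ligand depletion; reduces to ``U`` at
    C=0 and approaches ``B`` as C -> infinity.  At Kd=0 it becomes the
    stoichiometric limit: all target bound once C >= C_T.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("ligand concentrations must be >= 0")
    if C_T <= 0:
        raise ValueError("target concentration C_T must be > 0")
    if Kd < 0:
        raise ValueError("Kd must be >= 0")
    s = C + C_T + Kd
    disc = s * s - 4.0 * C * C_T
    # disc = (C - C_T + Kd)^2 + 4*Kd*C_T >= 0 analytically; clip roundoff
    disc = np.maximum(disc, 0.0)
    frac = (s - np.sqrt(disc)) / (2.0 * C_T)
    return U + (B - U) * frac


@dataclass
class TitrationSeries:
    """One titration: ligand concentrations, responses, target concentration.

    Concentrations are molar.  ``concentrations`` must be monotone
    (the usual serial-dilution order) and at least five points are required
    for a three-parameter fit.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    c_t: float = DEFAULT_C_T
    label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentration and response lengths differ")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if self.c_t <= 0:
            raise ValueError("C_T must be > 0")
        d = np.diff(self.concentrations)
        if len(d) and not (np.all(d <= 0) or np.all(d >= 0)):
            raise ValueError("concentrations must be monotone")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class BindingFit:
    """Fitted (U, B, Kd) with standard errors and diagnostics."""

    U: float
    B: float
    Kd: float
    se_U: float
    se_B: float
    se_Kd: float
    rss: float
    n_points: int
    converged: bool
    message: str = ""

    def predict(self, C, c_t: float) -> np.ndarray:
        return binding_response(C, self.U, self.B, c_t, self.Kd)

    def to_dict(self) -> dict:
        return {
            "U": self.U,
            "B": self.B,
            "Kd_M": self.Kd,
            "Kd_uM": self.Kd * 1e6,
            "se_U": self.se_U,
            "se_B": self.se_B,
            "se_Kd_M": self.se_Kd,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "message": self.message,
        }


def _default_init(ts: TitrationSeries) -> tuple[float, float, float]:
    F = ts.responses
    C = ts.concentrations
    U0 = float(F.min())
    B0 = float(F.max())
    span = B0 - U0
    if span > 0:
        half = U0 + 0.5 * span
        # concentration whose response is nearest half-maximal
        kd0 = float(C[np.argmin(np.abs(F - half))])
    else:
        kd0 = 0.0
    if kd0 <= 0:
        pos = C[C > 0]
        kd0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1e-6
    # orient U/B by concentration order rather than min/max
    order = np.argsort(C)
    return float(F[order[0]]), float(F[order[-1]]), kd0


def fit_binding(
    ts: TitrationSeries, init: tuple[float, float, float] | None = None
) -> BindingFit:
    """Fit (U, B, Kd) to a titration by nonlinear least squares.

    Kd is constrained positive.  Default initialisation: U and B from the
    responses at the lowest and highest ligand concentration, Kd from the
    concentration closest to half-maximal response.  The ``converged`` flag
    is cleared when the optimiser fails, the response amplitude is
    negligible (Kd unidentifiable from flat data), or Kd runs away far
    beyond the titrated range.
    """
    if len(ts) < 5:
        raise ValueError(f"need at least 5 titration points, got {len(ts)}")
    C, F = ts.concentrations, ts.responses
    u0, b0, kd0 = init if init is not None else _default_init(ts)
    kd0 = max(kd0, 1e-12)

    def resid(p):
        u, b, log_kd = p
        return binding_response(C, u, b, ts.c_t, np.exp(log_kd)) - F

    # log-parametrisation keeps Kd > 0 without an active bound
    res = least_squares(resid, x0=[u0, b0, np.log(kd0)], method="lm", max_nfev=10000)
    u, b, kd = res.x[0], res.x[1], float(np.exp(res.x[2]))
    rss = float(2.0 * res.cost)

    # covariance from the Jacobian in (U, B, Kd) coordinates
    se = [np.nan] * 3
    dof = len(ts) - 3
    try:
        J = res.jac.copy()
        J[:, 2] *= 1.0 / kd  # d/dlogKd -> d/dKd
        cov = np.linalg.inv(J.T @ J) * (rss / dof if dof > 0 else np.nan)
        se = list(np.sqrt(np.maximum(np.diag(cov), 0.0)))
    except np.linalg.LinAlgError:
        pass

    span = abs(b - u)
    scale = max(np.ptp(F), abs(u), abs(b), 1e-300)
    identifiable = span > 1e-6 * scale
    in_range = kd < 1e3 * max(C.max(), ts.c_t)
    converged = bool(res.success and identifiable and in_range)
    msg = ""
    if not res.success:
        msg = f"optimizer failure: {res.message}"
    elif not identifiable:
        msg = "flat response (B ~ U): Kd unidentifiable"
    elif not in_range:
        msg = "Kd ran far beyond the titrated concentration range"
    return BindingFit(
        U=float(u), B=float(b), Kd=kd,
        se_U=float(se[0]), se_B=float(se[1]), se_Kd=float(se[2]),
        rss=rss, n_points=len(ts), converged=converged, message=msg,
    )


def serial_dilution(top: float, n: int = 16, factor: float = 2.0) -> np.ndarray:
    """Concentration series of ``n`` serial dilutions from ``top`` (molar).

    ``[top, top/factor, ..., top/factor**(n-1)]`` — the standard 1:1 MST
    dilution layout with the default factor of 2.
    """
    if top <= 0:
        raise ValueError("top concentration must be > 0")
    if n < 2:
        raise ValueError("need at least 2 dilution steps")
    if factor <= 1:
        raise ValueError("dilution factor must be > 1")
    return top / factor ** np.arange(n)


def read_titration_csv(
    path: str | Path, c_t: float = DEFAULT_C_T
) -> list[TitrationSeries]:
    """Read titration CSV: columns ``concentration, concentration_unit,
    response`` and optional ``replicate``; returns one series per replicate."""
    df = pd.read_csv(path)
    required = {"concentration", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV missing column(s): {sorted(missing)}")
    if "concentration_unit" in df.columns:
        factors = df["concentration_unit"].map(_UNIT_FACTORS)
        if factors.isna().any():
            bad = df.loc[factors.isna(), "concentration_unit"].unique()
            raise ValueError(f"unknown concentration unit(s): {list(bad)}")
        conc = df["concentration"].to_numpy(float) * factors.to_numpy(float)
    else:
        conc = df["concentration"].to_numpy(float)
    reps = df["replicate"] if "replicate" in df.columns else pd.Series(0, index=df.index)
    series = []
    for rep, idx in reps.groupby(reps).groups.items():
        series.append(
            TitrationSeries(
                concentrations=conc[np.asarray(idx)],
                responses=df.loc[idx, "response"].to_numpy(float),
                c_t=c_t,
                label=str(rep),
            )
        )
    return series


def write_fit_json(fit: BindingFit, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
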