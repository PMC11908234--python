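"""Delayed, feedback-regulated cell-cycle model of HBC activation.

Horizontal basal cells (HBCs) of the olfactory epithelium are quiescent
stem cells that activate after acute injury.  The model tracks the
fractions of HBCs in G1 (``H1``), S (``H2``) and G2/M (``H3``) together
with the abundance ``D`` of differentiated cells they produce:

.. math::

    dH1/dt &= -k_1 H_1 + k_3 H_3 \\\\
    dH2/dt &= k_1 H_1 - k_2 H_2 \\\\
    dH3/dt &= k_2 H_2 - k_3 H_3 \\\\
    dD/dt  &= k_3 H_3 - \\gamma D

The G1->S rate is under negative feedback from the differentiated pool
through a Hill function, ``k1 = kmax / (1 + (D/K)^h)``: as the tissue
regenerates and ``D`` builds up, HBC proliferation shuts back down.  An
activation delay ``tau`` holds all compartments at their pre-injury
(basal) values for ``t < tau``.

``H2`` — the S-phase fraction — is the model counterpart of the
experimentally measured p63+/EdU+ fraction, and the free parameters are
estimated by least squares against such a time course via
:class:`RegenerationModel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "CellCycleParams",
    "OEState",
    "OETrajectory",
    "hill_rate",
    "rhs",
    "basal_state",
    "simulate",
    "RegenerationModel",
    "RegenerationResults",
    "FitWarning",
]

#: default fitted constants for the post-injury EdU time course
DEFAULT_K2 = 1.33  # S -> G2/M rate, 1/day (S phase ~ 18 h)
DEFAULT_K3 = 6.0   # G2/M division rate, 1/day (G2/M ~ 4 h)

FREE_PARAMETERS = ("kmax", "tau", "h", "K", "gamma")

# bounds used by the least-squares fit, per free parameter
_FIT_BOUNDS = {
    "kmax": (1e-6, 50.0),
    "tau": (0.0, 10.0),
    "K": (1e-4, 50.0),
    "gamma": (0.0, 10.0),
    "h": (1.0, 8.0),
}


class FitWarning(UserWarning):
    """Raised when a fit configuration is likely non-identifiable."""


@dataclass(frozen=True)
class CellCycleParams:
    """Rate constants of the regeneration model.

    Parameters
    ----------
    kmax : float
        Maximal G1->S transition rate (1/day), attained when D = 0.
    k2 : float
        S -> G2/M rate (1/day).  Default 1.33/day (S phase ~ 18 h).
    k3 : float
        G2/M division rate (1/day).  Default 6/day (G2/M ~ 4 h).
    gamma : float
        Turnover rate of differentiated cells (1/day).
    K : float
        Half-saturation of the feedback (same arbitrary units as D).
    h : float
        Hill coefficient of the feedback, >= 1.
    tau : float
        Activation delay after injury (days); all compartments are held
        at their basal values for t < tau.
    """

    kmax: float = 2.27
    k2: float = DEFAULT_K2
    k3: float = DEFAULT_K3
    gamma: float = 0.06
    K: float = 0.4
    h: float = 2.0
    tau: float = 0.8

    def __post_init__(self) -> None:
        for name in ("kmax", "k2", "k3", "K"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma!r}")
        if self.h < 1:
            raise ValueError(f"Hill coefficient h must be >= 1, got {self.h!r}")
        if self.tau < 0:
            raise ValueError(f"tau must be non-negative, got {self.tau!r}")

    def replace(self, **kwargs) -> "CellCycleParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CellCycleParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class OEState:
    """Compartment state at a single time point.

    H1, H2, H3 are fractions of the HBC pool in G1/S/G2-M; D is the
    differentiated-cell abundance in arbitrary units.
    """

    H1: float
    H2: float
    H3: float
    D: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("H1", "H2", "H3", "D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)!r}")

    @property
    def total_hbc(self) -> float:
        return self.H1 + self.H2 + self.H3

    def as_vector(self) -> np.ndarray:
        return np.array([self.H1, self.H2, self.H3, self.D], dtype=float)


class OETrajectory:
    """Time-indexed solution of the regeneration model."""

    def __init__(self, times: np.ndarray, values: np.ndarray):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or values.shape != (times.size, 4):
            raise ValueError("times must be 1-D and values (len(times), 4)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.times = times
        self.values = values

    @property
    def H1(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def H2(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def H3(self) -> np.ndarray:
        return self.values[:, 2]

    @property
    def D(self) -> np.ndarray:
        return self.values[:, 3]

    def state_at(self, i: int) -> OEState:
        return OEState(*self.values[i], t=self.times[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "H1": self.H1, "H2": self.H2, "H3": self.H3, "D": self.D}
        )

    def __len__(self) -> int:
        return self.times.size

    def plot(self, ax=None):
        """Plot all four compartments against time (days)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in ("H1", "H2", "H3", "D"):
            ax.plot(self.times, getattr(self, name), label=name)
        ax.set_xlabel("time post-injury (days)")
        ax.set_ylabel("fraction / abundance")
        ax.legend()
        return ax


def hill_rate(D, kmax: float, K: float, h: float):
    """Feedback-inhibited G1->S rate ``kmax / (1 + (D/K)**h)``.

    Strictly decreasing in the differentiated-cell abundance ``D`` and
    equal to ``kmax`` when ``D = 0`` (no feedback: injured tissue).
    """
    if not (kmax > 0 and K > 0):
        raise ValueError("kmax and K must be strictly positive")
    if h < 1:
        raise ValueError("Hill coefficient h must be >= 1")
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("D must be non-negative")
    out = kmax / (1.0 + (D / K) ** h)
    return float(out) if out.ndim == 0 else out


def rhs(state: OEState, params: CellCycleParams) -> tuple[float, float, float, float]:
    """Time derivatives (dH1, dH2, dH3, dD) at `state`, per day."""
    return tuple(_rhs_vec(state.as_vector(), params))


def _rhs_vec(y: np.ndarray, params: CellCycleParams) -> np.ndarray:
    h1, h2, h3, d = y
    k1 = params.kmax / (1.0 + (max(d, 0.0) / params.K) ** params.h)
    return np.array(
        [
            -k1 * h1 + params.k3 * h3,
            k1 * h1 - params.k2 * h2,
            params.k2 * h2 - params.k3 * h3,
            params.k3 * h3 - params.gamma * d,
        ]
    )


def basal_state(h2_basal: float, params: CellCycleParams) -> OEState:
    """Pre-injury state from the basal S-phase fraction.

    Only H2 (the measured p63+/EdU+ fraction, ~6.5% in uninjured
    controls) and D = 0 are pinned by data; H3 and H1 are completed by
    the basal flux balance ``k2*H2 = k3*H3`` with the HBC pool
    normalized to 1.
    """
    if not 0 < h2_basal < 1:
        raise ValueError(f"h2_basal must lie in (0, 1), got {h2_basal!r}")
    h3 = params.k2 * h2_basal / params.k3
    h1 = 1.0 - h2_basal - h3
    if h1 < 0:
        raise ValueError(
            f"h2_basal={h2_basal} leaves no G1 fraction (H1={h1:.3g} < 0)"
        )
    return OEState(H1=h1, H2=h2_basal, H3=h3, D=0.0, t=0.0)


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a solution."""


def simulate(
    params: CellCycleParams,
    init: OEState,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OETrajectory:
    """Integrate the delayed model over `t_grid` (days since injury).

    The state (all four components) is held at `init` for ``t < tau``;
    from ``tau`` onward the ODE system is integrated with an adaptive
    stiff-capable solver.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at or after the injury time 0")

    y0 = init.as_vector()
    out = np.tile(y0, (t_grid.size, 1))
    tau = params.tau
    after = t_grid > tau
    if np.any(after):
        t_eval = t_grid[after]
        sol = solve_ivp(
            lambda t, y: _rhs_vec(y, params),
            (tau, t_eval[-1]),
            y0,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"ODE integration failed: {sol.message}")
        y = sol.y.T
        # solver round-off can leave O(atol) negatives; clamp them
        y[(y < 0) & (y > -1e2 * max(atol, 1e-12))] = 0.0
        out[after] = y
    return OETrajectory(t_grid, out)


def _edu_fractions(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract (days, positive fractions) from an EdU time-course table.

    Accepts either ``day,n_cells,n_positive`` count columns or a direct
    ``day,fraction`` column.
    """
    if "day" not in data.columns:
        raise ValueError("EdU time course must have a 'day' column")
    days = data["day"].to_numpy(dtype=float)
    if "fraction" in data.columns:
        frac = data["fraction"].to_numpy(dtype=float)
    elif {"n_cells", "n_positive"} <= set(data.columns):
        n = data["n_cells"].to_numpy(dtype=float)
        k = data["n_positive"].to_numpy(dtype=float)
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= n_positive <= n_cells")
        frac = k / n
    else:
        raise ValueError(
            "EdU time course needs columns (day, fraction) or (day, n_cells, n_positive)"
        )
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    order = np.argsort(days)
    return days[order], frac[order]


class RegenerationModel:
    """Least-squares fit of the S-phase fraction H2(t) to an EdU time course.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``day,n_cells,n_positive`` (counts) or ``day,fraction``.
        The fitted observable is the positive fraction per day.
    params0 : CellCycleParams, optional
        Starting / fixed parameter values; defaults to the standard set.
    h2_basal : float, optional
        Basal S-phase fraction fixing the initial condition.  By default
        the fraction observed at the earliest day <= 0, else 0.065.

    The model holds k2 and k3 fixed (they are set by measured phase
    durations) and can free any subset of {kmax, tau, h, K, gamma}.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        params0: CellCycleParams | None = None,
        h2_basal: float | None = None,
    ):
        self.data = data
        self.days, self.fractions = _edu_fractions(data)
        self.params0 = params0 if params0 is not None else CellCycleParams()
        if h2_basal is None:
            at_zero = self.days <= 0
            h2_basal = float(self.fractions[at_zero][0]) if at_zero.any() else 0.065
        self.h2_basal = h2_basal

    # -- objective ---------------------------------------------------

    def predict_h2(self, params: CellCycleParams) -> np.ndarray:
        init = basal_state(self.h2_basal, params)
        # grid must be strictly increasing and cover day 0 for simulate()
        t_fit = np.unique(np.concatenate([[0.0], self.days]))
        traj = simulate(params, init, t_fit)
        return np.interp(self.days, traj.times, traj.H2)

    def _residuals(self, theta: np.ndarray, free: Sequence[str]) -> np.ndarray:
        params = self.params0.replace(**dict(zip(free, theta)))
        return self.predict_h2(params) - self.fractions

    # -- fitting -----------------------------------------------------

    def fit(
        self,
        free: Iterable[str] = ("kmax", "tau", "K", "gamma"),
        n_starts: int = 3,
    ) -> "RegenerationResults":
        """Fit the free parameters by (unweighted) least squares.

        ``h``, when freed, is searched on the integer grid {1, 2, 3, 4}
        with a continuous refit of the remaining free parameters at each
        grid value.
        """
        free = tuple(free)
        unknown = set(free) - set(FREE_PARAMETERS)
        if unknown:
            raise ValueError(f"cannot free parameter(s) {sorted(unknown)}; "
                             f"choose from {FREE_PARAMETERS}")
        if len(self.days) < max(len(free), 1):
            raise ValueError(
                f"{len(self.days)} data points cannot constrain {len(free)} free parameters"
            )
        if len(free) > 1 and len(self.days) == 1:
            warnings.warn("single data point with multiple free parameters is "
                          "non-identifiable", FitWarning)

        if not free:
            resid = self._residuals(np.empty(0), free)
            return RegenerationResults(self, self.params0, float(resid @ resid), free)

        cont = tuple(p for p in free if p != "h")
        h_grid = (1, 2, 3, 4) if "h" in free else (self.params0.h,)

        best: tuple[float, CellCycleParams] | None = None
        for h_val in h_grid:
            base = self.params0.replace(h=float(h_val))
            if not cont:
                r = RegenerationModel._sq(self, base, cont, ())
                cand = (r, base)
            else:
                cand = self._fit_continuous(base, cont, n_starts)
            if best is None or cand[0] < best[0]:
                best = cand
        ssr, params = best

        flat = self._flat_objective(params, free, ssr)
        if flat:
            warnings.warn(
                "objective is flat around the optimum; fit may be non-identifiable",
                FitWarning,
            )
        res = RegenerationResults(self, params, ssr, free, flat_objective=flat)
        return res

    @staticmethod
    def _sq(model: "RegenerationModel", params: CellCycleParams,
            cont: Sequence[str], theta: Sequence[float]) -> float:
        p = params.replace(**dict(zip(cont, theta)))
        r = model.predict_h2(p) - model.fractions
        return float(r @ r)

    def _fit_continuous(
        self, base: CellCycleParams, cont: Sequence[str], n_starts: int
    ) -> tuple[float, CellCycleParams]:
        lo = np.array([_FIT_BOUNDS[p][0] for p in cont])
        hi = np.array([_FIT_BOUNDS[p][1] for p in cont])
        x0 = np.array([getattr(base, p) for p in cont], dtype=float)
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        starts = [x0]
        for s in range(1, n_starts):
            scale = 0.5 * (s + 1)
            starts.append(np.clip(x0 * scale, lo + 1e-9, hi - 1e-9))

        def residuals(theta):
            p = base.replace(**dict(zip(cont, theta)))
            return self.predict_h2(p) - self.fractions

        best = None
        for start in starts:
            try:
                sol = least_squares(residuals, start, bounds=(lo, hi), xtol=1e-12,
                                    ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            ssr = float(sol.fun @ sol.fun)
            if best is None or ssr < best[0]:
                best = (ssr, base.replace(**dict(zip(cont, sol.x))))
        if best is None:
            raise IntegrationError("all least-squares starts failed")
        return best

    def _flat_objective(self, params: CellCycleParams, free: Sequence[str],
                        ssr: float, rel_step: float = 0.05) -> bool:
        """Crude identifiability probe: does perturbing any free parameter
        leave the objective essentially unchanged?"""
        scale = max(ssr, 1e-12)
        for p in free:
            v = getattr(params, p)
            step = rel_step * max(abs(v), 1e-3)
            try:
                pert = params.replace(**{p: v + step})
            except ValueError:
                continue
            r = self.predict_h2(pert) - self.fractions
            if abs(float(r @ r) - ssr) < 1e-10 * scale + 1e-14:
                return True
        return False


class RegenerationResults:
    """Fitted parameters, residual sum of squares and diagnostics."""

    def __init__(self, model: RegenerationModel, params: CellCycleParams,
                 ssr: float, free: Sequence[str], flat_objective: bool = False):
        self.model = model
        self.params = params
        self.ssr = ssr
        self.free = tuple(free)
        self.flat_objective = flat_objective

    @property
    def resid(self) -> np.ndarray:
        return self.model.predict_h2(self.params) - self.model.fractions

    def predict(self, t_grid: Sequence[float]) -> OETrajectory:
        init = basal_state(self.model.h2_basal, self.params)
        return simulate(self.params, init, np.asarray(t_grid, dtype=float))

    def summary(self) -> str:
        lines = [
            "Regeneration model fit (H2 vs EdU+ fraction)",
            "=" * 46,
            f"n observations: {len(self.model.days)}",
            f"free parameters: {', '.join(self.free) if self.free else '(none)'}",
            f"residual sum of squares: {self.ssr:.6g}",
        ]
        if self.flat_objective:
            lines.append("WARNING: flat objective; parameters may be non-identifiable")
        lines.append("-" * 46)
        for name in ("kmax", "k2", "k3", "gamma", "K", "h", "tau"):
            tag = "free " if name in self.free else "fixed"
            lines.append(f"  {name:<6} {getattr(self.params, name):>10.4g}   [{tag}]")
        return "\n".join(lines)

    def plot(self, t_max: float = 14.0, ax=None):
        """Overlay fitted H2(t) on the observed fractions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0.0, t_max, 400)
        grid = np.unique(np.concatenate([grid, self.model.days]))
        traj = self.predict(grid)
        ax.plot(traj.times, traj.H2, label="model H2(t)")
        ax.plot(self.model.days, self.model.fractions, "o", label="EdU+ fraction")
        ax.set_xlabel("days post-injury")
        ax.set_ylabel("S-phase fraction")
        ax.legend()
        return ax
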