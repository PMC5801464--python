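"""Saturation-kinetics model fitting: Michaelis-Menten, Hill, and activator
dose-response, with turnover and catalytic-efficiency derivations.

The central objects follow the Model/Results idiom: ``KineticModel`` wraps a
rate table and a model family, ``fit()`` returns a ``KineticFit`` carrying
estimates, standard errors (from the local curvature at the optimum), the
residual sum of squares and a ``summary()`` table.

Rate laws:
    MM:   v = Vmax * S / (S50 + S)
    Hill: v = Vmax * S^n / (S50^n + S^n),  n in [0.5, 12]

Fits are bounded nonlinear least squares with a deterministic multi-start
grid (Vmax at the maximal observed rate; S50 over observed-substrate
quantiles; n in {1, 2, 4, 8}); the best residual sum of squares wins, ties
broken by first-found.  Replicates are fitted pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synth import hill_rate

__all__ = [
    "RateTable",
    "KineticFit",
    "EnzymeSpec",
    "KineticModel",
    "fit_mm",
    "fit_hill",
    "select_model",
    "kcat",
    "efficiency",
    "activation_response",
    "fold_change",
]

HILL_N_BOUNDS = (0.5, 12.0)
MIN_SUBSTRATE_LEVELS = 4


class FitError(RuntimeError):
    """No start of the multi-start grid converged to a usable optimum."""


@dataclass
class RateTable:
    """Tidy rate measurements: substrate_mM, rate_U_per_mg, replicate."""

    data: pd.DataFrame
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"substrate_mM", "rate_U_per_mg"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"rate table needs columns {sorted(required)}")
        if (self.data["substrate_mM"] < 0).any():
            raise ValueError("substrate concentrations must be >= 0")
        if (self.data["rate_U_per_mg"] < 0).any():
            raise ValueError("rates must be >= 0")
        if self.data["substrate_mM"].nunique() < MIN_SUBSTRATE_LEVELS:
            raise ValueError(
                f"need >= {MIN_SUBSTRATE_LEVELS} distinct substrate levels for fitting"
            )

    @property
    def s(self) -> np.ndarray:
        return self.data["substrate_mM"].to_numpy(dtype=float)

    @property
    def v(self) -> np.ndarray:
        return self.data["rate_U_per_mg"].to_numpy(dtype=float)


@dataclass(frozen=True)
class EnzymeSpec:
    """Subunit mass and active-site count, needed to derive kcat from Vmax."""

    name: str
    subunit_mass_da: float  # g/mol
    sites_per_subunit: int = 1

    def __post_init__(self):
        if self.subunit_mass_da <= 0:
            raise ValueError("molar mass must be > 0")
        if self.sites_per_subunit < 1:
            raise ValueError("sites per subunit must be >= 1")


@dataclass
class KineticFit:
    """Fitted saturation-kinetics parameters with uncertainties."""

    model: str  # "MM" | "Hill"
    vmax: float
    s50: float
    hill_n: float
    se: dict[str, float]
    rss: float
    nobs: int
    converged: bool
    aicc: float
    low_confidence: bool = False

    @property
    def n_params(self) -> int:
        return 2 if self.model == "MM" else 3

    def predict(self, s) -> np.ndarray:
        return hill_rate(s, self.vmax, self.s50, self.hill_n)

    def summary(self) -> str:
        lines = [
            f"{self.model} kinetic fit ({self.nobs} observations, RSS={self.rss:.4g})",
            f"  Vmax = {self.vmax:.4g} U/mg (SE {self.se.get('vmax', float('nan')):.3g})",
            f"  S0.5 = {self.s50:.4g} mM (SE {self.se.get('s50', float('nan')):.3g})",
        ]
        if self.model == "Hill":
            lines.append(
                f"  Hill n = {self.hill_n:.4g} (SE {self.se.get('hill_n', float('nan')):.3g})"
            )
        lines.append(f"  AICc = {self.aicc:.4g}; converged = {self.converged}")
        if self.low_confidence:
            lines.append("  warning: sparse design, low-confidence fit")
        return "\n".join(lines)


def _aicc(rss: float, n: int, k: int) -> float:
    # least-squares AICc with Gaussian errors; guards the small-sample term
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = math.inf
    return aic


def _multi_start_fit(s, v, model: str) -> KineticFit:
    if np.all(v <= 0):
        raise FitError("all rates are zero; nothing to fit")
    order = np.lexsort((v, s))  # strict row-order invariance
    s, v = s[order], v[order]
    vmax0 = float(np.max(v))
    qs = np.quantile(np.unique(s[s > 0]), [0.1, 0.25, 0.5, 0.75, 0.9])
    s50_starts = sorted(set(float(q) for q in qs if q > 0))
    n_starts = [1.0] if model == "MM" else [1.0, 2.0, 4.0, 8.0]
    best = None
    for s50_0 in s50_starts:
        for n0 in n_starts:
            if model == "MM":
                x0 = [vmax0, s50_0]
                lower = [1e-12, 1e-12]
                upper = [np.inf, np.inf]

                def resid(x):
                    return hill_rate(s, x[0], x[1], 1.0) - v

            else:
                x0 = [vmax0, s50_0, n0]
                lower = [1e-12, 1e-12, HILL_N_BOUNDS[0]]
                upper = [np.inf, np.inf, HILL_N_BOUNDS[1]]

                def resid(x):
                    return hill_rate(s, x[0], x[1], x[2]) - v

            try:
                res = least_squares(
                    resid, x0, bounds=(lower, upper),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
                )
            except Exception:
                continue
            if not res.success and not np.isfinite(res.cost):
                continue
            rss = float(2 * res.cost)
            if best is None or rss < best[0] - 1e-15:
                best = (rss, res)
    if best is None:
        raise FitError(f"{model} fit failed from every start")
    rss, res = best
    n = len(s)
    k = len(res.x)
    # SEs from the Jacobian at the optimum
    se: dict[str, float] = {}
    names = ["vmax", "s50"] + (["hill_n"] if model == "Hill" else [])
    dof = n - k
    if dof > 0:
        J = res.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / dof)
            diag = np.clip(np.diag(cov), 0, None)
            se = {name: float(np.sqrt(d)) for name, d in zip(names, diag)}
        except np.linalg.LinAlgError:
            se = {name: float("nan") for name in names}
    params = dict(zip(names, (float(x) for x in res.x)))
    return KineticFit(
        model=model,
        vmax=params["vmax"],
        s50=params["s50"],
        hill_n=params.get("hill_n", 1.0),
        se=se,
        rss=rss,
        nobs=n,
        converged=bool(res.success),
        aicc=_aicc(rss, n, k),
        low_confidence=len(np.unique(s)) <= MIN_SUBSTRATE_LEVELS,
    )


class KineticModel:
    """Saturation-kinetics model bound to a rate table.

    kind: "mm", "hill", or "auto" (information-criterion selection with a
    configurable evidence margin favouring the simpler hyperbolic model).
    """

    def __init__(self, table: RateTable | pd.DataFrame, kind: str = "auto",
                 selection_margin: float = 2.0):
        if isinstance(table, pd.DataFrame):
            table = RateTable(table)
        if kind not in ("mm", "hill", "auto"):
            raise ValueError(f"kind must be mm|hill|auto, got {kind!r}")
        self.table = table
        self.kind = kind
        self.selection_margin = selection_margin

    def fit(self) -> KineticFit:
        if self.kind == "mm":
            return _multi_start_fit(self.table.s, self.table.v, "MM")
        if self.kind == "hill":
            return _multi_start_fit(self.table.s, self.table.v, "Hill")
        selected, mm, hill = self.select()
        return hill if selected == "Hill" else mm

    def select(self) -> tuple[str, KineticFit, KineticFit]:
        """Both fits plus the selected family name."""
        errors = []
        mm = hill = None
        try:
            mm = _multi_start_fit(self.table.s, self.table.v, "MM")
        except FitError as e:
            errors.append(str(e))
        try:
            hill = _multi_start_fit(self.table.s, self.table.v, "Hill")
        except FitError as e:
            errors.append(str(e))
        if mm is None and hill is None:
            raise FitError("; ".join(errors))
        if mm is None:
            return "Hill", mm, hill
        if hill is None:
            return "MM", mm, hill
        selected = "Hill" if mm.aicc - hill.aicc > self.selection_margin else "MM"
        return selected, mm, hill


def fit_mm(table: RateTable | pd.DataFrame) -> KineticFit:
    """Michaelis-Menten least-squares fit (multi-start, pooled replicates)."""
    return KineticModel(table, kind="mm").fit()


def fit_hill(table: RateTable | pd.DataFrame) -> KineticFit:
    """Hill-equation least-squares fit; n bounded in [0.5, 12]."""
    return KineticModel(table, kind="hill").fit()


def select_model(
    table: RateTable | pd.DataFrame, margin: float = 2.0
) -> tuple[str, KineticFit, KineticFit]:
    """Choose MM vs Hill by small-sample AICc with an evidence margin."""
    return KineticModel(table, kind="auto", selection_margin=margin).select()


def kcat(vmax_u_per_mg: float, enzyme: EnzymeSpec) -> float:
    """Turnover number (s^-1) from specific activity.

    1 U = 1 umol/min, so kcat = Vmax[umol/min/mg] x mass[g/mol] / 60000,
    divided by the number of catalytic sites per subunit.
    """
    if vmax_u_per_mg < 0:
        raise ValueError("Vmax must be >= 0")
    return vmax_u_per_mg * enzyme.subunit_mass_da / 60000.0 / enzyme.sites_per_subunit


def efficiency(kcat_per_s: float, s50_mm: float) -> float:
    """Catalytic efficiency kcat/S0.5 in mM^-1 s^-1."""
    if s50_mm <= 0:
        raise ValueError("S0.5 must be > 0")
    return kcat_per_s / s50_mm


def activation_response(
    table: RateTable | pd.DataFrame, subtract_baseline: bool = True
) -> KineticFit:
    """Hill-form fit of rate against activator concentration.

    The substrate column is read as the activator (mM).  If a zero-activator
    level is present its mean rate is subtracted as baseline before fitting,
    so the fit describes the activation above the unactivated rate.
    """
    if isinstance(table, pd.DataFrame):
        table = RateTable(table)
    data = table.data.copy()
    zero = data["substrate_mM"] == 0
    if subtract_baseline and zero.any():
        baseline = data.loc[zero, "rate_U_per_mg"].mean()
        data = data.loc[~zero].copy()
        data["rate_U_per_mg"] = (data["rate_U_per_mg"] - baseline).clip(lower=0.0)
    return _multi_start_fit(
        data["substrate_mM"].to_numpy(float),
        data["rate_U_per_mg"].to_numpy(float),
        "Hill",
    )


def fold_change(fit_a: KineticFit, fit_b: KineticFit, param: str) -> float:
    """Ratio of a named parameter between two fits, e.g. Vmax with/without AMP."""
    num = getattr(fit_a, param)
    den = getattr(fit_b, param)
    if den == 0:
        raise ZeroDivisionError(f"{param} of the reference fit is zero")
    return num / den
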