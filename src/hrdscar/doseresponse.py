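"""Dose-response curve fitting, IC50 computation, and PARPi sensitivity calls.

Clonogenic-assay absorbances are normalized to the mean of the control
(e.g. DMSO) wells, then fitted to a two-parameter curve of the response
fraction y (0 = no response, 1 = complete inhibition) against x = log10 of
the concentration in nmol/L:

    primary:   y = 1 - 1 / (1 + 10^(10^b * (x - a)))        IC50 = 10^a nmol/L
    fallback:  y = 1 / (1 + e^(-|b| * (x - a)))             IC50 = a

Both curves pass through y = 0.5 at x = a by construction. The fallback is
used only when the primary optimizer fails; its printed IC50 convention is
the parameter ``a`` itself (a log10 concentration), so the fit also records
10^a for audit.

A cell line is *sensitive* when at least 66% of replicate fits show
IC50 < 1 µmol/L and a maximal inhibitory response > 75%, *insensitive* when
at least 66% show IC50 >= 1 µmol/L and maximal response < 35%, and
*excluded* otherwise. Maximal response is the maximum observed normalized
inhibition, not the model asymptote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseFit",
    "DoseResponseCurve",
    "SensitivityCall",
    "normalize_plate",
    "fit_primary",
    "fit_fallback",
    "fit_dose_response",
    "classify_sensitivity",
]

MICROMOLAR_NMOL = 1000.0  # 1 µmol/L in nmol/L


@dataclass(frozen=True)
class DoseResponseFit:
    model: str  # "primary" or "fallback"
    a: float
    b: float
    ic50: float  # nmol/L for primary; the parameter a for fallback
    ic50_nmolL: float  # 10^a on both paths, for comparability
    max_response: float
    converged: bool
    residual_norm: float = float("nan")


@dataclass(frozen=True)
class SensitivityCall:
    cell_line: str
    drug: str
    call: str  # sensitive / insensitive / excluded
    fits: tuple[DoseResponseFit, ...] = ()
    reason: str = ""


def normalize_plate(raw: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Divide absorbances by the mean of the control wells."""
    control = np.asarray(control, dtype=float)
    if control.size == 0:
        raise ValueError("need at least one control well")
    mean = control.mean()
    if mean <= 0:
        raise ValueError(f"control mean {mean} is not positive")
    return np.asarray(raw, dtype=float) / mean


def _primary_curve(
    x: np.ndarray, a: float, b: float, slope_form: str = "power"
) -> np.ndarray:
    # the printed slope term reads as 10^b (positive slope, midpoint at a);
    # "linear" gives the alternative 10*b reading
    slope = 10.0 ** b if slope_form == "power" else 10.0 * b
    exponent = np.clip(slope * (x - a), -300.0, 300.0)
    return 1.0 - 1.0 / (1.0 + 10.0 ** exponent)


def _fallback_curve(x: np.ndarray, a: float, b: float) -> np.ndarray:
    exponent = np.clip(-np.abs(b) * (x - a), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(exponent))


def _check_points(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 4 or np.unique(x).size < 2:
        raise ValueError("need >= 4 points spanning >= 2 distinct doses")


def _multistart_fit(curve, x, y, b_starts) -> tuple[np.ndarray, float, bool]:
    """Bounded least squares over (a, b) with multistart over a and b."""
    best, best_cost = None, np.inf
    a_starts = np.linspace(x.min() - 1, x.max() + 1, 5)
    for a0 in a_starts:
        for b0 in b_starts:
            try:
                res = least_squares(
                    lambda p: curve(x, p[0], p[1]) - y,
                    x0=[a0, b0],
                    bounds=([x.min() - 10, -5], [x.max() + 10, 5]),
                    method="trf",
                )
            except Exception:
                continue
            if res.success and np.all(np.isfinite(res.x)) and res.cost < best_cost:
                best, best_cost = res, res.cost
    if best is None:
        return np.array([np.nan, np.nan]), np.inf, False
    return best.x, float(np.sqrt(2 * best.cost)), True


def fit_primary(x, y, slope_form: str = "power") -> DoseResponseFit:
    """Fit the primary model; IC50 = 10^a nmol/L.

    ``slope_form`` selects how the slope term is read: ``"power"`` (10^b,
    the default) or ``"linear"`` (10*b).
    """
    if slope_form not in {"power", "linear"}:
        raise ValueError(f"unknown slope_form {slope_form!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_points(x, y)
    (a, b), resid, ok = _multistart_fit(
        lambda xx, aa, bb: _primary_curve(xx, aa, bb, slope_form),
        x, y, b_starts=[-1.0, 0.0, 1.0],
    )
    return DoseResponseFit(
        model="primary",
        a=a,
        b=b,
        ic50=10.0 ** a if ok else float("nan"),
        ic50_nmolL=10.0 ** a if ok else float("nan"),
        max_response=float(np.max(y)),
        converged=ok,
        residual_norm=resid,
    )


def fit_fallback(x, y) -> DoseResponseFit:
    """Fit the fallback model; the reported IC50 is the parameter a."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_points(x, y)
    (a, b), resid, ok = _multistart_fit(_fallback_curve, x, y, b_starts=[0.5, 2.0, 4.0])
    return DoseResponseFit(
        model="fallback",
        a=a,
        b=abs(b),
        ic50=a if ok else float("nan"),
        ic50_nmolL=10.0 ** a if ok else float("nan"),
        max_response=float(np.max(y)),
        converged=ok,
        residual_norm=resid,
    )


def fit_dose_response(x, y) -> DoseResponseFit:
    """Primary fit, falling back to the alternative model on failure."""
    fit = fit_primary(x, y)
    if fit.converged:
        return fit
    return fit_fallback(x, y)


class DoseResponseCurve:
    """sklearn-style estimator wrapper around the two-model fit.

    Parameters
    ----------
    model : {"auto", "primary", "fallback"}
        "auto" tries the primary model and falls back on failure.

    Attributes (after :meth:`fit`)
    ------------------------------
    fit_ : DoseResponseFit
    a_, b_, ic50_ : floats from the winning model
    """

    def __init__(self, model: str = "auto"):
        self.model = model

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model}

    def set_params(self, **params) -> "DoseResponseCurve":
        for k, v in params.items():
            if k != "model":
                raise ValueError(f"unknown parameter {k!r}")
            self.model = v
        return self

    def fit(self, x, y) -> "DoseResponseCurve":
        fitter = {
            "auto": fit_dose_response,
            "primary": fit_primary,
            "fallback": fit_fallback,
        }.get(self.model)
        if fitter is None:
            raise ValueError(f"unknown model {self.model!r}")
        self.fit_ = fitter(x, y)
        self.a_, self.b_, self.ic50_ = self.fit_.a, self.fit_.b, self.fit_.ic50
        return self

    def predict(self, x) -> np.ndarray:
        if not hasattr(self, "fit_"):
            raise ValueError("DoseResponseCurve is not fitted")
        x = np.asarray(x, dtype=float)
        curve = _primary_curve if self.fit_.model == "primary" else _fallback_curve
        return curve(x, self.fit_.a, self.fit_.b)


def classify_sensitivity(
    fits: list[DoseResponseFit],
    cell_line: str = "",
    drug: str = "",
    vote_fraction: float = 0.66,
) -> SensitivityCall:
    """Replicate-vote PARPi sensitivity call.

    Sensitive: >= 66% of replicates with IC50 < 1 µmol/L and maximal
    response > 0.75. Insensitive: >= 66% with IC50 >= 1 µmol/L and maximal
    response < 0.35. Anything else (including no converged fit) is excluded.
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        return SensitivityCall(cell_line, drug, "excluded", tuple(fits),
                               reason="no successful replicate fit")
    n = len(ok)
    sens = sum(
        1 for f in ok if f.ic50_nmolL < MICROMOLAR_NMOL and f.max_response > 0.75
    )
    insens = sum(
        1 for f in ok if f.ic50_nmolL >= MICROMOLAR_NMOL and f.max_response < 0.35
    )
    if sens / n >= vote_fraction:
        call = "sensitive"
    elif insens / n >= vote_fraction:
        call = "insensitive"
    else:
        call = "excluded"
    return SensitivityCall(cell_line, drug, call, tuple(ok))
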