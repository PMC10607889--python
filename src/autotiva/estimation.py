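"""Online estimators driving the closed loop.

Two regressions are refit continuously during a case:

* a sigmoid Emax curve BIS(c) = E0 − Emax·cᵞ/(cᵞ + EC50ᵞ) through the
  (propofol effect-site concentration, BIS) pairs collected since infusion
  start. Inverting it at the sedation target (BIS = 45 by default) yields
  the patient's estimated target effect-site propofol concentration,
  esTEC-P45, which the propofol loop tracks.

* a rectangular hyperbola y = c/(x − a) + b through the
  (remifentanil effect-site concentration x, concurrent esTEC-P45 y) pairs —
  the patient's individual analgesia–sedation isobole. Its vertex
  (a + √c, b + √c) is where the curve's slope is exactly −1; beyond it,
  extra opioid buys almost no hypnotic sparing. The estimated maximal
  individual concentration esMIC_δ is the abscissa where the residual above
  the asymptote y = b has fallen to δ% of the vertex-to-asymptote gap √c:

      esMIC_δ = a + (100/δ)·√c            (δ = 20 by default)

Both estimators are written in the scikit-learn idiom (``fit`` /
``predict``, ``get_params``/``set_params``, trailing-underscore fitted
attributes) so they compose with sklearn tooling; the module-level
functions are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "NotReadyError",
    "PairedBISObservation",
    "IsoboleObservation",
    "SigmoidPDFit",
    "HyperbolaFit",
    "BisSigmoidRegressor",
    "IsoboleHyperbolaRegressor",
    "fit_bis_sigmoid",
    "invert_sigmoid",
    "fit_isodynamic_hyperbola",
    "esmic",
]


class NotReadyError(RuntimeError):
    """Raised when the data cannot identify the estimator yet.

    Controllers catch this and hold their last valid target.
    """


@dataclass(frozen=True)
class PairedBISObservation:
    """One (propofol Ce, BIS) pair with its signal quality."""

    ce_p: float
    bis: float
    sqi: float = 100.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bis <= 100.0:
            raise ValueError("bis must be in [0, 100]")
        if self.ce_p < 0:
            raise ValueError("ce_p must be >= 0")


@dataclass(frozen=True)
class IsoboleObservation:
    """One (remifentanil Ce, concurrent esTEC-P45) pair."""

    ce_r: float
    estec_p45: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.ce_r < 0 or self.estec_p45 < 0:
            raise ValueError("observations must be >= 0")


@dataclass(frozen=True)
class SigmoidPDFit:
    """Fitted sigmoid concentration–BIS curve plus diagnostics."""

    e0: float
    emax: float
    ec50: float
    gamma: float
    n_points: int
    rss: float

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        eff = np.zeros_like(c)
        pos = c > 0
        cg = np.power(c, self.gamma, where=pos, out=np.zeros_like(c))
        np.divide(cg, cg + self.ec50**self.gamma, where=pos, out=eff)
        return self.e0 - self.emax * eff

    def invert(self, bis_target: float = 45.0) -> float:
        """Unique concentration giving ``bis_target`` on the fitted curve."""
        drop = self.e0 - bis_target
        if not 0.0 < drop < self.emax:
            raise ValueError(
                f"BIS target {bis_target} outside the attainable range "
                f"({self.e0 - self.emax:.2f}, {self.e0:.2f})"
            )
        return self.ec50 * (drop / (self.emax - drop)) ** (1.0 / self.gamma)


@dataclass(frozen=True)
class HyperbolaFit:
    """Fitted rectangular hyperbola y = c/(x−a) + b plus diagnostics."""

    a: float
    b: float
    c: float
    n_points: int
    rss: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.c / (x - self.a) + self.b

    def slope(self, x):
        return -self.c / (np.asarray(x, dtype=float) - self.a) ** 2

    @property
    def vertex(self) -> tuple[float, float]:
        """(a + √c, b + √c): the point where the slope is exactly −1."""
        r = np.sqrt(self.c)
        return self.a + r, self.b + r

    def esmic(self, delta_pct: float = 20.0) -> float:
        if not 0.0 < delta_pct <= 100.0:
            raise ValueError("delta_pct must be in (0, 100]")
        return self.a + (100.0 / delta_pct) * np.sqrt(self.c)


class BisSigmoidRegressor:
    """Sigmoid Emax regression of BIS on propofol effect-site concentration.

    Parameters
    ----------
    bis_target : float
        Sedation target used by :meth:`invert` (default 45).
    sqi_min : float
        Pairs with signal quality below this are excluded (default 80).
    min_pairs, min_span : int, float
        Identifiability gate: at least ``min_pairs`` retained pairs spanning
        at least ``min_span`` µg·mL⁻¹ of concentration are required.
    warm_start : bool
        When refitting on a growing stream, start from the previous solution.

    Attributes (after ``fit``)
    --------------------------
    e0_, emax_, ec50_, gamma_ : fitted curve parameters
    n_points_, rss_ : diagnostics
    fit_result_ : the frozen :class:`SigmoidPDFit`
    """

    _BOUNDS = ([60.0, 1.0, 1e-3, 0.3], [100.0, 100.0, 30.0, 10.0])

    def __init__(self, bis_target: float = 45.0, sqi_min: float = 80.0,
                 min_pairs: int = 8, min_span: float = 0.5, warm_start: bool = False):
        self.bis_target = bis_target
        self.sqi_min = sqi_min
        self.min_pairs = min_pairs
        self.min_span = min_span
        self.warm_start = warm_start

    def get_params(self, deep: bool = True) -> dict:
        return {"bis_target": self.bis_target, "sqi_min": self.sqi_min,
                "min_pairs": self.min_pairs, "min_span": self.min_span,
                "warm_start": self.warm_start}

    def set_params(self, **params) -> "BisSigmoidRegressor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, ce, bis, sqi=None) -> "BisSigmoidRegressor":
        ce = np.asarray(ce, dtype=float).ravel()
        bis = np.asarray(bis, dtype=float).ravel()
        if ce.shape != bis.shape:
            raise ValueError("ce and bis must have the same length")
        if sqi is not None:
            keep = np.asarray(sqi, dtype=float).ravel() >= self.sqi_min
            ce, bis = ce[keep], bis[keep]
        if ce.size < self.min_pairs:
            raise NotReadyError(f"need >= {self.min_pairs} reliable pairs, have {ce.size}")
        if np.ptp(ce) < self.min_span:
            raise NotReadyError(
                f"concentration span {np.ptp(ce):.3g} < {self.min_span} µg/mL")

        if self.warm_start and hasattr(self, "fit_result_"):
            x0 = np.array([self.e0_, self.emax_, self.ec50_, self.gamma_])
            lo, hi = self._BOUNDS
            x0 = np.clip(x0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
        else:
            e0_0 = min(max(float(bis.max()), 60.0), 100.0)
            emax_0 = min(max(e0_0 - float(bis.min()), 1.0), 100.0)
            ec50_0 = min(max(float(np.median(ce)), 1e-2), 30.0)
            x0 = np.array([e0_0, emax_0, ec50_0, 2.0])

        ce_safe = np.maximum(ce, 1e-12)
        log_ce = np.log(ce_safe)

        def resid(p):
            e0, emax, ec50, gamma = p
            cg = np.power(ce_safe, gamma)
            return (e0 - emax * cg / (cg + ec50**gamma)) - bis

        def jac(p):
            e0, emax, ec50, gamma = p
            cg = np.power(ce_safe, gamma)
            eg = ec50**gamma
            u = cg / (cg + eg)
            du = u * (1.0 - u)
            J = np.empty((ce.size, 4))
            J[:, 0] = 1.0
            J[:, 1] = -u
            J[:, 2] = emax * du * gamma / ec50
            J[:, 3] = -emax * du * (log_ce - np.log(ec50))
            return J

        sol = least_squares(resid, x0, jac=jac, bounds=self._BOUNDS,
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if not sol.success:
            raise NotReadyError(f"sigmoid fit did not converge: {sol.message}")
        e0, emax, ec50, gamma = sol.x
        emax = min(emax, e0)  # maximal depression cannot exceed baseline
        self.e0_, self.emax_, self.ec50_, self.gamma_ = float(e0), float(emax), float(ec50), float(gamma)
        self.n_points_ = int(ce.size)
        self.rss_ = float(np.sum(resid([e0, emax, ec50, gamma]) ** 2))
        self.fit_result_ = SigmoidPDFit(self.e0_, self.emax_, self.ec50_,
                                        self.gamma_, self.n_points_, self.rss_)
        return self

    def predict(self, ce):
        self._check_fitted()
        return self.fit_result_.predict(ce)

    def invert(self, bis_target: float | None = None) -> float:
        self._check_fitted()
        return self.fit_result_.invert(self.bis_target if bis_target is None else bis_target)

    def _check_fitted(self) -> None:
        if not hasattr(self, "fit_result_"):
            raise NotReadyError("estimator has not been fitted")


class IsoboleHyperbolaRegressor:
    """Rectangular-hyperbola regression of the analgesia–sedation isobole.

    x is remifentanil Ce (ng·mL⁻¹), y the concurrent esTEC-P45 (µg·mL⁻¹).
    Fits y = c/(x − a) + b with c > 0 and a below every observed x.
    """

    def __init__(self, delta_pct: float = 20.0, min_pairs: int = 6,
                 min_span: float = 1.0, warm_start: bool = False):
        self.delta_pct = delta_pct
        self.min_pairs = min_pairs
        self.min_span = min_span
        self.warm_start = warm_start

    def get_params(self, deep: bool = True) -> dict:
        return {"delta_pct": self.delta_pct, "min_pairs": self.min_pairs,
                "min_span": self.min_span, "warm_start": self.warm_start}

    def set_params(self, **params) -> "IsoboleHyperbolaRegressor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, x, y) -> "IsoboleHyperbolaRegressor":
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if x.size < self.min_pairs:
            raise NotReadyError(f"need >= {self.min_pairs} pairs, have {x.size}")
        if np.ptp(x) < self.min_span:
            raise NotReadyError(f"x span {np.ptp(x):.3g} < {self.min_span} ng/mL")

        xmin = float(x.min())
        a0 = 0.9 * xmin if xmin > 0 else xmin - 1.0
        b0 = max(0.9 * float(y.min()), 0.0)
        # two-point solve for c through the extreme observations
        i, j = int(np.argmin(x)), int(np.argmax(x))
        c0 = max((y[i] - b0) * (x[i] - a0), 1e-3)
        a_hi = xmin - 1e-6

        def resid(p):
            a, b, c = p
            return c / (x - a) + b - y

        def jac(p):
            a, b, c = p
            inv = 1.0 / (x - a)
            J = np.empty((x.size, 3))
            J[:, 0] = c * inv**2
            J[:, 1] = 1.0
            J[:, 2] = inv
            return J

        x0 = np.array([min(a0, a_hi - 1e-6), b0, c0])
        if self.warm_start and hasattr(self, "fit_result_") and self.a_ < a_hi:
            x0 = np.array([self.a_, max(self.b_, 0.0), max(self.c_, 1e-9)])
        sol = least_squares(
            resid, x0, jac=jac,
            bounds=([-np.inf, 0.0, 1e-12], [a_hi, np.inf, np.inf]),
            xtol=1e-13, ftol=1e-13, gtol=1e-13,
        )
        if not sol.success:
            raise NotReadyError(f"hyperbola fit did not converge: {sol.message}")
        a, b, c = sol.x
        if c < 1e-6:
            raise NotReadyError("degenerate fit: curve is flat (c -> 0)")
        if np.any(x <= a):
            raise NotReadyError("observation at or below the fitted vertical asymptote")
        self.a_, self.b_, self.c_ = float(a), float(b), float(c)
        self.n_points_ = int(x.size)
        self.rss_ = float(np.sum(resid(sol.x) ** 2))
        self.fit_result_ = HyperbolaFit(self.a_, self.b_, self.c_, self.n_points_, self.rss_)
        return self

    def predict(self, x):
        self._check_fitted()
        return self.fit_result_.predict(x)

    def esmic(self, delta_pct: float | None = None) -> float:
        self._check_fitted()
        return self.fit_result_.esmic(self.delta_pct if delta_pct is None else delta_pct)

    def _check_fitted(self) -> None:
        if not hasattr(self, "fit_result_"):
            raise NotReadyError("estimator has not been fitted")


# ----------------------------------------------------------- function facade

def fit_bis_sigmoid(pairs: Sequence[PairedBISObservation], **kwargs) -> SigmoidPDFit:
    """Fit the sigmoid to observation objects; raises NotReadyError when unidentifiable."""
    ce = [p.ce_p for p in pairs]
    bis = [p.bis for p in pairs]
    sqi = [p.sqi for p in pairs]
    return BisSigmoidRegressor(**kwargs).fit(ce, bis, sqi).fit_result_


def invert_sigmoid(fit: SigmoidPDFit, bis_target: float = 45.0) -> float:
    return fit.invert(bis_target)


def fit_isodynamic_hyperbola(pairs: Sequence[IsoboleObservation], **kwargs) -> HyperbolaFit:
    x = [p.ce_r for p in pairs]
    y = [p.estec_p45 for p in pairs]
    return IsoboleHyperbolaRegressor(**kwargs).fit(x, y).fit_result_


def esmic(fit: HyperbolaFit, delta_pct: float = 20.0) -> float:
    return fit.esmic(delta_pct)
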