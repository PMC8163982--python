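"""Concentration-response and kinetic curve fitting.

Three model classes, each following the Model/Results pattern: construct
from data, call :meth:`fit`, get a results object with estimates,
standard errors and diagnostics.

* :class:`LogisticModel` -- 3-parameter (optionally 4-parameter) logistic
  concentration-response curve
  ``y = bottom + (top - bottom) / (1 + 10**(-pec50 - x))`` with
  ``x = log10(concentration in M)``.
* :class:`OnePhaseModel` -- one-phase exponential association
  ``y = SS * (1 - exp(-k t))``, the canonical G-protein recruitment and
  internalisation time course.
* :class:`RiseAndFallModel` -- bi-exponential
  ``y = D * (exp(-k1 t) - exp(-k2 t))`` with ``k2 > k1 >= 0``, the
  arrestin recruit-then-dissociate time course.

The kinetic efficacy kτ is defined as the fitted curve's initial rate at
t = 0: ``SS * k`` for one-phase and ``D * (k2 - k1)`` for rise-and-fall.
Initialisation is deterministic and data-driven (multi-start from a small
fixed grid around the data-derived guess), so repeated fits of the same
data are bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LogisticModel", "LogisticResults",
    "OnePhaseModel", "RiseAndFallModel", "KineticResults",
    "fit_logistic3", "fit_onephase", "fit_riseandfall",
    "normalise_emax", "rate_vs_concentration",
]

_LN10 = np.log(10.0)


def _covariance_bse(res, n_params: int) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    m = res.fun.size
    if m <= n_params:
        return np.full(n_params, np.nan)
    s2 = 2.0 * res.cost / (m - n_params)
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        return np.sqrt(np.clip(np.diag(jtj_inv) * s2, 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(n_params, np.nan)


# ---------------------------------------------------------------------------
# Logistic concentration-response
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray, bottom: float, top: float, pec50: float,
              hill: float = 1.0) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (-pec50 - x)))


@dataclass(frozen=True)
class LogisticResults:
    """Fitted logistic concentration-response curve.

    ``emax_pct`` is populated by :func:`normalise_emax`; ``top`` is the
    fitted maximum in the data's own response units.
    """

    bottom: float
    top: float
    pec50: float
    hill: float
    rss: float
    n_points: int
    converged: bool
    message: str
    bse: dict
    model: "LogisticModel | None" = None
    emax_pct: float | None = None

    @property
    def ec50(self) -> float:
        return 10.0 ** (-self.pec50)

    def predict(self, concentration) -> np.ndarray:
        x = np.log10(np.asarray(concentration, dtype=float))
        return _logistic(x, self.bottom, self.top, self.pec50, self.hill)

    def summary(self) -> str:
        lines = [
            "Logistic concentration-response fit",
            f"  n points   : {self.n_points}",
            f"  converged  : {self.converged} ({self.message})",
            f"  bottom     : {self.bottom:.4g} +/- {self.bse.get('bottom', float('nan')):.2g}",
            f"  top (Emax) : {self.top:.4g} +/- {self.bse.get('top', float('nan')):.2g}",
            f"  pEC50      : {self.pec50:.4g} +/- {self.bse.get('pec50', float('nan')):.2g}",
            f"  Hill       : {self.hill:.4g}",
            f"  RSS        : {self.rss:.4g}",
        ]
        if self.emax_pct is not None:
            lines.insert(5, f"  Emax (%)   : {self.emax_pct:.4g}")
        return "\n".join(lines)


class LogisticModel:
    """3-parameter (Hill = 1) or 4-parameter logistic fit of response vs
    concentration (molar).  Requires at least four distinct concentrations.
    """

    def __init__(self, concentration: Sequence[float],
                 response: Sequence[float]):
        conc = np.asarray(concentration, dtype=float)
        resp = np.asarray(response, dtype=float)
        if conc.shape != resp.shape:
            raise ValueError("concentration/response length mismatch")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive (molar)")
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        if np.unique(conc).size < 4:
            raise ValueError("need at least 4 distinct concentrations")
        order = np.argsort(conc)
        self.concentration = conc[order]
        self.response = resp[order]
        self.log_conc = np.log10(self.concentration)

    def _residuals(self, params, hill_free: bool):
        if hill_free:
            b, t, p, h = params
        else:
            (b, t, p), h = params, 1.0
        return _logistic(self.log_conc, b, t, p, h) - self.response

    def _jac(self, params, hill_free: bool):
        if hill_free:
            b, t, p, h = params
        else:
            (b, t, p), h = params, 1.0
        u = 10.0 ** (h * (-p - self.log_conc))
        f = 1.0 / (1.0 + u)
        d_b = 1.0 - f
        d_t = f
        d_p = (t - b) * _LN10 * h * u * f * f
        cols = [d_b, d_t, d_p]
        if hill_free:
            cols.append((t - b) * _LN10 * (-p - self.log_conc) * -u * f * f)
        return np.column_stack(cols)

    def fit(self, n_params: int = 3, bottom_floor: float | None = 0.0,
            pec50_bounds: tuple[float, float] = (3.0, 13.0)) -> LogisticResults:
        """Deterministic multi-start least-squares fit.

        ``bottom_floor=0`` constrains the bottom to be non-negative (the
        usual constraint for baseline-zeroed responses); pass ``None`` to
        float it freely.
        """
        y = self.response
        hill_free = n_params == 4
        if np.ptp(y) == 0:
            nan = float("nan")
            return LogisticResults(
                bottom=float(y[0]), top=float(y[0]), pec50=nan, hill=1.0,
                rss=0.0, n_points=y.size, converged=False,
                message="flat responses: EC50 not identifiable",
                bse={}, model=self)

        b0 = float(np.min(y))
        t0 = float(np.max(y))
        # pEC50 guess from the half-maximal crossing of the sorted data
        half = (b0 + t0) / 2.0
        above = np.nonzero(y >= half)[0]
        x_half = self.log_conc[above[0]] if above.size else self.log_conc[-1]
        p0 = float(np.clip(-x_half, *pec50_bounds))
        lo_b = -np.inf if bottom_floor is None else bottom_floor
        lower = [lo_b, -np.inf, pec50_bounds[0]]
        upper = [np.inf, np.inf, pec50_bounds[1]]
        x0_base = [max(b0, lo_b if np.isfinite(lo_b) else b0), t0]
        if hill_free:
            lower.append(0.2)
            upper.append(5.0)

        best = None
        for dp in (0.0, -1.0, 1.0):
            p_init = float(np.clip(p0 + dp, *pec50_bounds))
            x0 = x0_base + [p_init] + ([1.0] if hill_free else [])
            res = least_squares(self._residuals, x0=x0,
                                jac=self._jac, args=(hill_free,),
                                bounds=(lower, upper), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if best is None or res.cost < best.cost:
                best = res
        params = best.x
        hill = params[3] if hill_free else 1.0
        names = ["bottom", "top", "pec50"] + (["hill"] if hill_free else [])
        bse = dict(zip(names, _covariance_bse(best, len(params))))
        return LogisticResults(
            bottom=float(params[0]), top=float(params[1]),
            pec50=float(params[2]), hill=float(hill),
            rss=float(2.0 * best.cost), n_points=y.size,
            converged=bool(best.success), message=best.message,
            bse=bse, model=self)


def fit_logistic3(concentration, response, **kwargs) -> LogisticResults:
    """Convenience wrapper: 3-parameter logistic fit."""
    return LogisticModel(concentration, response).fit(n_params=3, **kwargs)


# ---------------------------------------------------------------------------
# Kinetic fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticResults:
    """Fitted kinetic time course and its derived initial-rate efficacy.

    ``ktau`` is the model's initial slope at t = 0: ``ss * k`` for the
    one-phase model, ``d * (k2 - k1)`` for rise-and-fall.  ``degenerate``
    flags rise-and-fall fits where the decline phase is absent (k1 -> 0)
    or the two rates coincide within tolerance.
    """

    kinetic_model: Literal["one_phase", "rise_and_fall"]
    params: dict
    rss: float
    n_points: int
    converged: bool
    degenerate: bool
    message: str
    bse: dict
    model: "OnePhaseModel | RiseAndFallModel | None" = None

    @property
    def ss(self) -> float | None:
        return self.params.get("ss")

    @property
    def k(self) -> float | None:
        return self.params.get("k")

    @property
    def d(self) -> float | None:
        return self.params.get("d")

    @property
    def k1(self) -> float | None:
        return self.params.get("k1")

    @property
    def k2(self) -> float | None:
        return self.params.get("k2")

    @property
    def ktau(self) -> float:
        if self.kinetic_model == "one_phase":
            return self.params["ss"] * self.params["k"]
        return self.params["d"] * (self.params["k2"] - self.params["k1"])

    @property
    def peak(self) -> float:
        """Maximum of the fitted curve (the plateau for one-phase)."""
        if self.kinetic_model == "one_phase":
            return self.params["ss"]
        d, k1, k2 = self.d, self.k1, self.k2
        if k1 == 0:
            return d
        t_peak = np.log(k2 / k1) / (k2 - k1)
        return d * (np.exp(-k1 * t_peak) - np.exp(-k2 * t_peak))

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        if self.kinetic_model == "one_phase":
            return self.params["ss"] * (1.0 - np.exp(-self.params["k"] * t))
        d, k1, k2 = self.d, self.k1, self.k2
        return d * (np.exp(-k1 * t) - np.exp(-k2 * t))

    def summary(self) -> str:
        lines = [f"Kinetic fit: {self.kinetic_model}",
                 f"  n points  : {self.n_points}",
                 f"  converged : {self.converged}"
                 + (" [degenerate]" if self.degenerate else "")]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"  {name:<9} : {value:.4g} +/- {se:.2g}")
        lines.append(f"  ktau      : {self.ktau:.4g} (initial rate, /min)")
        lines.append(f"  RSS       : {self.rss:.4g}")
        return "\n".join(lines)


class OnePhaseModel:
    """One-phase exponential association ``y = ss * (1 - exp(-k t))``."""

    min_points = 4

    def __init__(self, times: Sequence[float], response: Sequence[float]):
        t = np.asarray(times, dtype=float)
        y = np.asarray(response, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times/response length mismatch")
        if t.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} time points")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")
        self.times = t
        self.response = y

    def _residuals(self, params):
        ss, k = params
        return ss * (1.0 - np.exp(-k * self.times)) - self.response

    def _jac(self, params):
        ss, k = params
        e = np.exp(-k * self.times)
        return np.column_stack([1.0 - e, ss * self.times * e])

    def _k_guess(self) -> float:
        t, y = self.times, self.response
        ss0 = np.mean(y[t >= 0.75 * t[-1]]) or np.max(np.abs(y)) or 1.0
        half = 0.5 * ss0
        crossing = np.nonzero(y >= half)[0] if ss0 > 0 else np.array([])
        if crossing.size and t[crossing[0]] > 0:
            return float(np.log(2.0) / t[crossing[0]])
        return float(2.0 / max(t[-1], 1e-6))

    def fit(self, *, xtol: float = 1e-12, max_nfev: int | None = None
            ) -> KineticResults:
        t, y = self.times, self.response
        ss0 = float(np.mean(y[t >= 0.75 * t[-1]]))
        if ss0 == 0:
            ss0 = float(np.max(np.abs(y))) or 1.0
        k0 = self._k_guess()
        best = None
        for mult in (1.0, 0.3, 3.0):
            res = least_squares(
                self._residuals, x0=[ss0, k0 * mult], jac=self._jac,
                bounds=([-np.inf, 1e-9], [np.inf, np.inf]), method="trf",
                xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=max_nfev)
            if best is None or res.cost < best.cost:
                best = res
        ss, k = best.x
        bse = dict(zip(["ss", "k"], _covariance_bse(best, 2)))
        return KineticResults(
            kinetic_model="one_phase", params={"ss": float(ss), "k": float(k)},
            rss=float(2 * best.cost), n_points=t.size,
            converged=bool(best.success), degenerate=False,
            message=best.message, bse=bse, model=self)


class RiseAndFallModel:
    """Bi-exponential ``y = d * (exp(-k1 t) - exp(-k2 t))``, k2 > k1 >= 0.

    The label ambiguity (k1 <-> k2 swap with sign flip of d) is resolved
    by canonicalising to k2 > k1 with d > 0 for rising responses.
    """

    min_points = 6
    _degenerate_rel_gap = 1e-3

    def __init__(self, times: Sequence[float], response: Sequence[float]):
        t = np.asarray(times, dtype=float)
        y = np.asarray(response, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times/response length mismatch")
        if t.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} time points")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")
        self.times = t
        self.response = y

    def _residuals(self, params):
        d, k1, k2 = params
        return d * (np.exp(-k1 * self.times) - np.exp(-k2 * self.times)) \
            - self.response

    def _jac(self, params):
        d, k1, k2 = params
        e1 = np.exp(-k1 * self.times)
        e2 = np.exp(-k2 * self.times)
        return np.column_stack([e1 - e2, -d * self.times * e1,
                                d * self.times * e2])

    def _starts(self):
        t, y = self.times, self.response
        i_peak = int(np.argmax(y))
        y_peak = y[i_peak]
        t_peak = t[i_peak] if t[i_peak] > 0 else t[max(i_peak, 1)]
        k2_0 = 2.0 / max(t_peak, 1e-3)
        tail = y[-1]
        if y_peak > 0 and 0 < tail < 0.85 * y_peak and t[-1] > t_peak:
            k1_0 = float(np.log(y_peak / tail) / (t[-1] - t_peak))
        else:
            k1_0 = 0.01
        starts = []
        for m1 in (1.0, 0.3):
            for m2 in (1.0, 3.0):
                k1s, k2s = k1_0 * m1, k2_0 * m2
                if k2s <= k1s:
                    k2s = k1s * 10.0
                peak_unit = self._unit_peak(k1s, k2s)
                d0 = y_peak / peak_unit if peak_unit > 0 else max(y_peak, 1.0)
                starts.append([d0, k1s, k2s])
        return starts

    @staticmethod
    def _unit_peak(k1: float, k2: float) -> float:
        if k1 <= 0:
            return 1.0
        tp = np.log(k2 / k1) / (k2 - k1)
        return float(np.exp(-k1 * tp) - np.exp(-k2 * tp))

    def fit(self, *, xtol: float = 1e-12, max_nfev: int | None = None
            ) -> KineticResults:
        best = None
        for x0 in self._starts():
            res = least_squares(
                self._residuals, x0=x0, jac=self._jac,
                bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                method="trf", xtol=xtol, ftol=xtol, gtol=xtol,
                max_nfev=max_nfev)
            if best is None or res.cost < best.cost:
                best = res
        d, k1, k2 = best.x
        if k1 > k2:  # canonicalise the swap symmetry
            k1, k2, d = k2, k1, -d
        rel_gap = (k2 - k1) / k2 if k2 > 0 else 0.0
        degenerate = bool(k1 < 1e-6 or rel_gap < self._degenerate_rel_gap)
        bse = dict(zip(["d", "k1", "k2"], _covariance_bse(best, 3)))
        return KineticResults(
            kinetic_model="rise_and_fall",
            params={"d": float(d), "k1": float(k1), "k2": float(k2)},
            rss=float(2 * best.cost), n_points=self.times.size,
            converged=bool(best.success), degenerate=degenerate,
            message=best.message, bse=bse, model=self)


def fit_onephase(times, response) -> KineticResults:
    """Convenience wrapper: one-phase association fit."""
    return OnePhaseModel(times, response).fit()


def fit_riseandfall(times, response) -> KineticResults:
    """Convenience wrapper: bi-exponential rise-and-fall fit."""
    return RiseAndFallModel(times, response).fit()


# ---------------------------------------------------------------------------
# Emax normalisation and per-concentration kinetics
# ---------------------------------------------------------------------------

def _joint_shared_top(fits: Mapping[str, LogisticResults],
                      ligands: Sequence[str]) -> float:
    """Globally fitted shared maximum across several full agonists.

    Joint least squares with one common top and per-ligand bottom/pEC50,
    on the data stored in each fit's model.
    """
    datasets = []
    x0 = [float(np.mean([fits[l].top for l in ligands]))]
    for l in ligands:
        f = fits[l]
        if f.model is None:
            raise ValueError(f"fit for {l!r} carries no data for joint refit")
        datasets.append((f.model.log_conc, f.model.response))
        x0 += [f.bottom, f.pec50]

    def residuals(params):
        top = params[0]
        out = []
        for i, (x, y) in enumerate(datasets):
            b, p = params[1 + 2 * i], params[2 + 2 * i]
            out.append(_logistic(x, b, top, p) - y)
        return np.concatenate(out)

    res = least_squares(residuals, x0=x0, method="lm", xtol=1e-12, ftol=1e-12)
    return float(res.x[0])


def normalise_emax(fits: Mapping[str, LogisticResults],
                   full_agonists: Sequence[str] | None = None,
                   reference: str | None = None,
                   auto_threshold: float = 0.90) -> dict[str, LogisticResults]:
    """Express each fitted top as a percentage of the full-agonist maximum.

    The denominator is the single full agonist's fitted top when exactly
    one ligand is a full agonist, or a globally fitted shared maximum
    (joint refit with a common top) when there are several.  Full
    agonists are taken from ``full_agonists`` if given, else
    ``[reference]`` if given, else detected as every ligand whose top is
    within ``auto_threshold`` of the largest top.
    """
    if not fits:
        raise ValueError("empty fit set")
    if full_agonists is None:
        if reference is not None:
            if reference not in fits:
                raise ValueError(f"reference ligand {reference!r} not in fits")
            full_agonists = [reference]
        else:
            top_max = max(f.top for f in fits.values())
            full_agonists = [l for l, f in fits.items()
                             if f.top >= auto_threshold * top_max]
    if not full_agonists:
        raise ValueError("no full agonist designated or detected")
    if len(full_agonists) == 1:
        denom = fits[full_agonists[0]].top
    else:
        denom = _joint_shared_top(fits, full_agonists)
    if denom <= 0:
        raise ValueError("full-agonist maximum is non-positive")
    return {l: dataclasses.replace(f, emax_pct=100.0 * f.top / denom)
            for l, f in fits.items()}


def rate_vs_concentration(traces, min_conc: float = 1e-8):
    """Per-concentration one-phase rate constants above a threshold.

    ``traces`` is a sequence of :class:`~gpcrbias.traces.ProcessedTrace`;
    wells sharing a concentration are averaged pointwise before fitting.
    Concentrations at or below ``min_conc`` (default 10 nM) are excluded
    and reported with ``skipped=True``, since rate constants are poorly
    identified where the response barely rises.
    """
    import pandas as pd

    by_conc: dict[float, list] = {}
    for tr in traces:
        if tr.concentration is None:
            continue
        by_conc.setdefault(float(tr.concentration), []).append(tr)
    fitted = [c for c in by_conc if c > min_conc]
    if len(fitted) < 3:
        raise ValueError(
            f"need >= 3 concentrations above {min_conc:g} M, got {len(fitted)}")
    rows = []
    for conc in sorted(by_conc):
        group = by_conc[conc]
        if conc <= min_conc:
            rows.append(dict(concentration=conc, skipped=True, ss=np.nan,
                             k=np.nan, ktau=np.nan, converged=False))
            continue
        t = group[0].stim_times()
        y = np.mean([g.stim_response() for g in group], axis=0)
        fit = OnePhaseModel(t, y).fit()
        rows.append(dict(concentration=conc, skipped=False, ss=fit.ss,
                         k=fit.k, ktau=fit.ktau, converged=fit.converged))
    return pd.DataFrame(rows)
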