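"""Vehicle-normalised dose–response modelling with a five-parameter log-logistic.

Treated-well readouts are divided by the same-day mean of the vehicle
(solvent-only) wells, giving responses on a common scale where 1 means
"grew like control".  Responses are fitted against concentration with the
standard asymmetric five-parameter log-logistic (5PL)

    y(x) = c + (d − c) / (1 + exp(b·(ln x − ln e)))^f

with slope b, lower asymptote c, upper asymptote d, location e (nM) and
asymmetry f > 0 (f = 1 recovers the symmetric four-parameter model).
Two potency summaries are derived per fit:

* ED50 — the concentration giving the midpoint of the *fitted* span
  (c + d)/2; closed form e·(2^{1/f} − 1)^{1/b}.
* GI50 — the concentration where the curve crosses an absolute response
  of 0.5, i.e. 50% growth inhibition relative to control; undefined when
  the fitted curve never reaches 0.5.

The vehicle itself is never a fitted point (log 0 is undefined); it only
defines the normalisation denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .readouts import WellTimeSeries

logger = logging.getLogger(__name__)

_POINT_COLUMNS = ["sample_id", "day", "readout", "concentration_nM", "replicate", "response"]


class DegenerateFitError(ValueError):
    """All responses identical: the dose–response fit is undefined."""


def dose_ladder(cmin: float, cmax: float, fold: float) -> list[float]:
    """The geometric concentration series cmin, cmin·fold, …, cmax.

    The ladder must be exact: cmax has to equal cmin·fold^k for an integer
    k, otherwise the requested design is ambiguous and an error lists the
    nearest valid endpoints.
    """
    if cmin <= 0 or cmax < cmin or fold <= 1:
        raise ValueError("need 0 < min <= max and fold > 1")
    k = np.log(cmax / cmin) / np.log(fold)
    k_round = round(k)
    if not np.isclose(k, k_round, rtol=0, atol=1e-9):
        lo = cmin * fold ** np.floor(k)
        hi = cmin * fold ** np.ceil(k)
        raise ValueError(
            f"max {cmax} is not min·fold^k for integer k; nearest valid endpoints: {lo:g}, {hi:g}"
        )
    return [float(cmin * fold**i) for i in range(int(k_round) + 1)]


def normalize_to_control(
    treated: list[WellTimeSeries],
    vehicle: list[WellTimeSeries],
    readout: str,
    day: int,
) -> pd.DataFrame:
    """Divide each treated replicate's readout by the same-day vehicle mean.

    One row (dose–response point) per treated replicate well, so downstream
    fits see the replicate scatter rather than pre-averaged values.
    """
    veh_vals = []
    for w in vehicle:
        if day in w.data.index:
            v = w.value(readout, day)
            if np.isfinite(v):
                veh_vals.append(v)
    if not veh_vals:
        raise ValueError(f"no vehicle well has a defined {readout!r} value at day {day}")
    veh_mean = float(np.mean(veh_vals))
    if veh_mean == 0:
        raise ValueError(f"vehicle mean of {readout!r} at day {day} is zero")
    rows = []
    for w in treated:
        if w.is_vehicle:
            raise ValueError(f"well {w.well_id} is a vehicle well; vehicle wells are never points")
        if day not in w.data.index or not np.isfinite(w.value(readout, day)):
            logger.info("skipping %s day %s: missing %s", w.well_id, day, readout)
            continue
        rows.append(
            {
                "sample_id": w.sample_id,
                "day": day,
                "readout": readout,
                "concentration_nM": w.concentration_nM,
                "replicate": w.replicate,
                "response": w.value(readout, day) / veh_mean,
            }
        )
    return pd.DataFrame(rows, columns=_POINT_COLUMNS)


def ll5(x, b, c, d, e, f):
    """Evaluate the five-parameter log-logistic at concentration ``x`` (nM)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentration must be positive (vehicle is not a curve point)")
    if e <= 0 or f <= 0:
        raise ValueError("e and f must be positive")
    out = c + (d - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e)))) ** f
    return out if out.ndim else float(out)


@dataclass
class LL5Results:
    """Fitted 5PL parameters, uncertainties and potency summaries."""

    b: float
    c: float
    d: float
    e: float
    f: float
    converged: bool
    rss: float
    n_points: int
    bse: dict[str, float] = field(default_factory=dict)
    f_fixed: bool = False
    fallback_f1: bool = False  # fewer than 5 distinct doses: f pinned to 1
    ill_conditioned: bool = False
    sample_id: str = ""
    day: int | None = None
    readout: str = ""

    @property
    def params(self) -> dict[str, float]:
        return {"b": self.b, "c": self.c, "d": self.d, "e": self.e, "f": self.f}

    @property
    def span(self) -> float:
        """Fitted maximal inhibition span d − c."""
        return self.d - self.c

    @property
    def max_inhibition(self) -> float:
        """1 − c: the fitted maximal inhibition relative to control."""
        return 1.0 - self.c

    @property
    def ed50(self) -> float | None:
        return ed50(self)

    @property
    def gi50(self) -> float | None:
        return gi50(self)

    def predict(self, x) -> np.ndarray:
        return ll5(x, self.b, self.c, self.d, self.e, self.f)

    def plot(self, points: pd.DataFrame | None = None, ax=None):
        """Plot the fitted curve on a log-dose axis, optionally with the
        normalised replicate points it was fitted to."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo = self.e / 1000.0
        hi = self.e * 1000.0
        if points is not None and len(points):
            lo = min(lo, points["concentration_nM"].min() / 3.0)
            hi = max(hi, points["concentration_nM"].max() * 3.0)
            ax.plot(points["concentration_nM"], points["response"], "o",
                    color="0.3", ms=4, label="replicates")
        grid = np.geomspace(lo, hi, 200)
        ax.plot(grid, self.predict(grid), label="5PL fit")
        if self.ed50 is not None:
            ax.axvline(self.ed50, ls="--", lw=0.8, color="tab:orange", label="ED50")
        ax.set_xscale("log")
        ax.set_xlabel("concentration (nM)")
        ax.set_ylabel("response relative to vehicle")
        title = " ".join(
            str(v) for v in (self.sample_id, self.readout,
                             f"day {self.day}" if self.day is not None else "") if v
        )
        if title:
            ax.set_title(title)
        ax.legend(frameon=False, fontsize=8)
        return ax

    def summary(self) -> str:
        lines = [
            "Five-parameter log-logistic dose-response fit",
            f"  sample={self.sample_id or '-'}  day={self.day if self.day is not None else '-'}"
            f"  readout={self.readout or '-'}",
            f"  n_points={self.n_points}  converged={self.converged}  rss={self.rss:.6g}",
            f"  {'param':<6}{'estimate':>12}{'std err':>12}",
        ]
        for name in ("b", "c", "d", "e", "f"):
            se = self.bse.get(name)
            se_s = f"{se:>12.4g}" if se is not None and np.isfinite(se) else f"{'--':>12}"
            lines.append(f"  {name:<6}{getattr(self, name):>12.4g}{se_s}")
        ed, gi = self.ed50, self.gi50
        lines.append(f"  ED50 = {ed:.4g} nM" if ed is not None else "  ED50 undefined (flat fit)")
        lines.append(
            f"  GI50 = {gi:.4g} nM" if gi is not None else "  GI50 undefined (0.5 outside fitted range)"
        )
        if self.fallback_f1 or self.f_fixed:
            lines.append("  note: asymmetry f fixed at 1 (four-parameter fit)")
        if self.ill_conditioned:
            lines.append("  note: e-f direction ill-conditioned; refit with f = 1")
        return "\n".join(lines)


class LogLogistic5:
    """5PL dose–response model for one (sample, day, readout) point set.

    Parameters
    ----------
    dose : array-like of positive concentrations (nM), one per point.
    response : array-like of vehicle-normalised responses.

    ``fit()`` minimises squared residuals in log-dose space with a
    deterministic multi-start (no random initialisation): the base start
    takes c, d from the extreme mean responses, e from the dose nearest
    the midpoint response, slope sign from a log-dose linear regression
    and f = 1, and is expanded by a fixed 3×3 grid of (b, f) perturbations.
    """

    #: fixed multiplicative perturbation grid for (b, f) starts
    _B_GRID = (0.5, 1.0, 2.0)
    _F_GRID = (0.5, 1.0, 2.0)
    #: relative standard error of e above which the e-f direction is
    #: considered unidentifiable and the fit falls back to f = 1
    SE_LOG_E_LIMIT = 0.5

    def __init__(self, dose, response):
        dose = np.asarray(dose, dtype=float)
        response = np.asarray(response, dtype=float)
        keep = np.isfinite(dose) & np.isfinite(response)
        self.dose = dose[keep]
        self.response = response[keep]
        if len(self.dose) == 0:
            raise ValueError("no finite dose-response points")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive; vehicle wells are not fitted points")

    # -- internals -----------------------------------------------------
    def _residuals(self, theta, f_fixed):
        b, c, d, log_e = theta[:4]
        log_f = 0.0 if f_fixed else theta[4]
        # (1 + exp(z))^f computed as exp(f·log1p(exp(z))) via logaddexp for stability
        z = b * (np.log(self.dose) - log_e)
        pred = c + (d - c) * np.exp(-np.exp(log_f) * np.logaddexp(0.0, z))
        return pred - self.response

    def _bounds(self, f_fixed):
        y_lo, y_hi = float(self.response.min()), float(self.response.max())
        span = max(y_hi - y_lo, 1e-6)
        log_x = np.log(self.dose)
        lo = [-30.0, y_lo - 2 * span, y_lo - 2 * span, log_x.min() - np.log(100.0)]
        hi = [30.0, y_hi + 2 * span, y_hi + 2 * span, log_x.max() + np.log(100.0)]
        if not f_fixed:
            lo.append(np.log(0.2))
            hi.append(np.log(5.0))
        return np.array(lo), np.array(hi)

    def _base_start(self):
        means = pd.Series(self.response).groupby(pd.Series(self.dose)).mean()
        c0, d0 = float(means.min()), float(means.max())
        if d0 - c0 < 1e-12:
            d0 = c0 + max(1e-3, abs(c0) * 1e-3)
        slope = np.polyfit(np.log(self.dose), self.response, 1)[0]
        b0 = 1.0 if slope < 0 else -1.0
        mid = 0.5 * (c0 + d0)
        e0 = float(means.index[np.argmin(np.abs(means.to_numpy() - mid))])
        return b0, c0, d0, e0

    def _fit_once(self, start, f_fixed):
        n_par = 4 if f_fixed else 5
        lo, hi = self._bounds(f_fixed)
        x0 = np.clip(start[:n_par], lo + 1e-9, hi - 1e-9)
        return optimize.least_squares(
            self._residuals, x0, args=(f_fixed,), method="trf",
            bounds=(lo, hi), max_nfev=2000,
        )

    def fit(self, f_fixed: bool = False, **meta) -> LL5Results:
        if np.ptp(self.response) < 1e-12:
            raise DegenerateFitError("all responses identical; nothing to fit")
        b0, c0, d0, e0 = self._base_start()
        starts = []
        for bm in self._B_GRID:
            for f0 in self._F_GRID:
                starts.append(np.array([b0 * bm, c0, d0, np.log(e0), np.log(f0)]))
        best, best_cost = None, np.inf
        for s in starts:
            try:
                res = self._fit_once(s, f_fixed)
            except Exception:
                continue
            if np.all(np.isfinite(res.x)) and res.cost < best_cost:
                best, best_cost = res, res.cost
        if best is None:
            return LL5Results(
                b=np.nan, c=np.nan, d=np.nan, e=np.nan, f=np.nan,
                converged=False, rss=np.inf, n_points=len(self.dose),
                f_fixed=f_fixed, **meta,
            )
        result = self._results(best, f_fixed, False, meta)
        if not f_fixed and self._e_ill_determined(result):
            refit = self.fit(f_fixed=True, **meta)
            refit.ill_conditioned = True
            return refit
        return result

    def _e_ill_determined(self, result: LL5Results) -> bool:
        """True when the free fit leaves the location e statistically
        undetermined (the e-f identifiability ridge).

        Uses the estimated standard error of ln e: when e is not pinned
        down within a factor exp(SE_LIMIT), the asymmetric fit is reported
        through the stable symmetric (f = 1) model instead.  A perfect
        (near-zero-residual) fit always has tiny standard errors, so exact
        data keeps the free fit.
        """
        se_e = result.bse.get("e")
        if se_e is None or not np.isfinite(se_e):
            return True
        return se_e / result.e > self.SE_LOG_E_LIMIT

    def _results(self, res, f_fixed, ill, meta) -> LL5Results:
        b, c, d, log_e = res.x[:4]
        f = 1.0 if f_fixed else float(np.exp(res.x[4]))
        rss = float(2 * res.cost)
        names = ["b", "c", "d", "e"] + ([] if f_fixed else ["f"])
        bse: dict[str, float] = {}
        dof = len(self.dose) - len(res.x)
        if dof > 0:
            try:
                cov = np.linalg.inv(res.jac.T @ res.jac) * rss / dof
                diag = np.diag(cov)
                se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
                # log_e and log_f standard errors propagate to e and f scales
                scale = np.ones(len(res.x))
                scale[3] = np.exp(log_e)
                if not f_fixed:
                    scale[4] = f
                for name, s in zip(names, se * scale):
                    bse[name] = float(s)
            except np.linalg.LinAlgError:
                pass
        return LL5Results(
            b=float(b), c=float(c), d=float(d), e=float(np.exp(log_e)), f=f,
            converged=bool(res.success), rss=rss, n_points=len(self.dose),
            bse=bse, f_fixed=f_fixed, ill_conditioned=ill, **meta,
        )


def fit_ll5(points: pd.DataFrame) -> LL5Results:
    """Fit the 5PL to a table of dose–response points.

    ``points`` must have columns concentration_nM and response (plus
    optional sample_id/day/readout metadata carried into the results).
    With fewer than 5 distinct concentrations the asymmetry f is not
    identifiable; the fit falls back to the symmetric four-parameter model
    (f = 1) and is flagged.
    """
    meta = {}
    for col, key in (("sample_id", "sample_id"), ("day", "day"), ("readout", "readout")):
        if col in points.columns and len(points):
            meta[key] = points[col].iloc[0]
    model = LogLogistic5(points["concentration_nM"], points["response"])
    fallback = len(np.unique(model.dose)) < 5
    result = model.fit(f_fixed=fallback, **meta)
    result.fallback_f1 = fallback
    return result


def ed50(fit: LL5Results, span_tol: float = 1e-8) -> float | None:
    """Concentration at the midpoint of the fitted span: e·(2^{1/f} − 1)^{1/b}.

    Undefined (None) when the fitted span |d − c| is below tolerance —
    a flat curve has no midpoint dose.
    """
    if not np.isfinite(fit.b) or abs(fit.d - fit.c) < span_tol or fit.b == 0:
        return None
    return float(fit.e * (2.0 ** (1.0 / fit.f) - 1.0) ** (1.0 / fit.b))


def gi50(fit: LL5Results, target: float = 0.5) -> float | None:
    """Concentration where the fitted curve crosses an absolute response of 0.5.

    Inverts the 5PL; undefined (None, not an error) when the target lies
    outside the open interval between the fitted asymptotes.
    """
    if not np.isfinite(fit.b) or fit.b == 0:
        return None
    lo, hi = min(fit.c, fit.d), max(fit.c, fit.d)
    if not (lo < target < hi):
        return None
    q = (fit.d - fit.c) / (target - fit.c)
    inner = q ** (1.0 / fit.f) - 1.0
    if inner <= 0:
        return None
    return float(fit.e * inner ** (1.0 / fit.b))


_CRITERIA = ("max_inhibition", "ed50", "gi50")


def sensitivity_report(fits: dict[str, LL5Results]) -> pd.DataFrame:
    """Side-by-side sensitivity criteria and ranks for a set of samples.

    Rank 1 is most sensitive.  max_inhibition (1 − c) ranks descending;
    ed50 and gi50 rank ascending; samples with an undefined criterion rank
    last under that criterion.
    """
    rows = []
    for sample, fit in fits.items():
        rows.append(
            {
                "sample_id": sample,
                "max_inhibition": fit.max_inhibition,
                "ed50": fit.ed50,
                "gi50": fit.gi50,
            }
        )
    report = pd.DataFrame(rows).set_index("sample_id")
    for crit in _CRITERIA:
        col = report[crit].astype(float)
        asc = crit != "max_inhibition"
        report[f"rank_{crit}"] = col.rank(ascending=asc, na_option="bottom").astype(int)
    return report


def rank_sensitivity(fits: dict[str, LL5Results], criterion: str = "ed50") -> list[str]:
    """Samples ordered most-sensitive first under one criterion."""
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}")
    if len(fits) < 2:
        raise ValueError("need at least two samples to rank")
    report = sensitivity_report(fits)
    return list(report.sort_values(f"rank_{criterion}").index)
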