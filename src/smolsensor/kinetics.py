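"""Two-phase cooperative recruitment kinetics.

Membrane recruitment of a lipid biosensor after stimulation rises and falls
as the signalling lipid is first synthesised and then degraded.  Both phases
are sigmoidal ("s"-shaped), so each is modelled as a Hill term and the trace
as their difference:

    F(t) = F0                                              for t < 0
    F(t) = F_max * [ t^n_syn / (t^n_syn + tau_syn^n_syn)
                   - t^n_deg / (t^n_deg + tau_deg^n_deg) ]  for t >= 0

with the stimulus at t = 0.  ``tau_syn`` and ``tau_deg`` are the half-rise
times of the two phases (minutes); the rate constants are their reciprocals,
k_syn = 1/tau_syn and k_deg = 1/tau_deg.  F_max scales the difference of the
two Hill terms, so F(t) -> 0 as t -> infinity, matching decaying recruitment
traces.  ``n_syn`` and ``n_deg`` are Hill coefficients capturing the
cooperativity of the pathway.

The model is fitted by bounded trust-region nonlinear least squares with
jittered multistarts; uncertainties come from a residual-resampling
bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TimeCourse",
    "KineticParams",
    "RateConstants",
    "TwoPhaseHillModel",
    "TwoPhaseHillResults",
    "model_eval",
    "fit_timecourse",
    "rate_constants",
    "normalize_to_max",
    "fold_change_over_baseline",
]

# Fit bounds: tau in minutes, n dimensionless, F_max in normalized units.
TAU_BOUNDS = (0.05, 100.0)
N_BOUNDS = (0.5, 8.0)
FMAX_BOUNDS = (0.0, 10.0)


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the two-phase Hill model."""

    F_max: float
    n_syn: float
    tau_syn: float
    n_deg: float
    tau_deg: float
    F0: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_syn <= 0 or self.tau_deg <= 0:
            raise ValueError("tau_syn and tau_deg must be positive")
        if self.n_syn <= 0 or self.n_deg <= 0:
            raise ValueError("Hill coefficients must be positive")
        if self.F_max < 0:
            raise ValueError("F_max must be non-negative")


@dataclass(frozen=True)
class RateConstants:
    """Rate constants k = 1/tau, in min^-1, with optional 95% CIs."""

    k_syn: float
    k_deg: float
    k_syn_ci: tuple[float, float] | None = None
    k_deg_ci: tuple[float, float] | None = None


@dataclass
class TimeCourse:
    """A stimulus-aligned fluorescence (or molecule-density) trace.

    ``t`` is in minutes with the stimulus at t = 0; negative times are
    pre-stimulus baseline.  ``f`` is fluorescence or density in whatever
    normalization the caller uses.
    """

    t: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.f.shape:
            raise ValueError("t and f must be 1-D arrays of equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time_min", f_col: str = "F") -> "TimeCourse":
        return cls(df[time_col].to_numpy(), df[f_col].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "TimeCourse":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.t, "F": self.f})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.t < 0


def _hill(t: np.ndarray, n: float, tau: float) -> np.ndarray:
    tn = np.power(t, n)
    return tn / (tn + tau**n)


def _hill_grads(t: np.ndarray, n: float, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """(dh/dn, dh/dtau) of the Hill term, elementwise; 0 at t = 0."""
    pos = t > 0
    dn = np.zeros_like(t)
    dtau = np.zeros_like(t)
    tp = t[pos]
    tn = np.power(tp, n)
    taun = tau**n
    denom = (tn + taun) ** 2
    dn[pos] = tn * taun * (np.log(tp) - np.log(tau)) / denom
    dtau[pos] = -n * tau ** (n - 1) * tn / denom
    return dn, dtau


def model_eval(params: KineticParams, t) -> np.ndarray:
    """Evaluate the two-phase model at times ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.full(t.shape, params.F0, dtype=float)
    post = t >= 0
    tp = t[post]
    out[post] = params.F_max * (
        _hill(tp, params.n_syn, params.tau_syn) - _hill(tp, params.n_deg, params.tau_deg)
    )
    return out[0] if scalar else out


def rate_constants(params: KineticParams) -> RateConstants:
    """Derive k_syn = 1/tau_syn and k_deg = 1/tau_deg (exact reciprocals)."""
    if params.tau_syn <= 0 or params.tau_deg <= 0:
        raise ValueError("tau must be positive")
    return RateConstants(k_syn=1.0 / params.tau_syn, k_deg=1.0 / params.tau_deg)


def normalize_to_max(tc: TimeCourse) -> TimeCourse:
    """Rescale a trace to dF_t / dF_max: baseline mean 0, peak exactly 1.

    The baseline is the pre-stimulus (t < 0) mean, or the first sample if no
    pre-stimulus points exist.  Idempotent.
    """
    base = float(np.mean(tc.f[tc.baseline_mask])) if tc.baseline_mask.any() else float(tc.f[0])
    df = tc.f - base
    post = tc.t >= 0
    peak = float(np.max(df[post])) if post.any() else float(np.max(df))
    if peak <= 0:
        raise ValueError("trace has no response above baseline; cannot normalize to max")
    return TimeCourse(tc.t, df / peak)


def fold_change_over_baseline(tc: TimeCourse) -> float:
    """100 * (peak - baseline) / baseline, in percent."""
    if not tc.baseline_mask.any():
        raise ValueError("no pre-stimulus baseline points")
    base = float(np.mean(tc.f[tc.baseline_mask]))
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (float(np.max(tc.f)) - base) / base


@dataclass
class TwoPhaseHillResults:
    """Fit results: point estimates, diagnostics and bootstrap machinery."""

    model: "TwoPhaseHillModel"
    params: KineticParams
    rss: float
    n_obs: int
    converged: bool
    n_restarts: int

    @property
    def rates(self) -> RateConstants:
        return rate_constants(self.params)

    def predict(self, t=None) -> np.ndarray:
        t = self.model.tc.t if t is None else t
        return model_eval(self.params, t)

    @property
    def residuals(self) -> np.ndarray:
        return self.model.tc.f - self.predict()

    def bootstrap_ci(self, n_boot: int = 1000, seed: int | None = None, alpha: float = 0.05):
        """Residual-resampling bootstrap percentile CIs for every parameter.

        Returns a DataFrame indexed by parameter (including k_syn, k_deg)
        with columns ``estimate``, ``lo``, ``hi``.
        """
        if n_boot < 100:
            raise ValueError("n_boot must be >= 100 for meaningful percentile CIs")
        rng = np.random.default_rng(seed)
        tc = self.model.tc
        fitted = self.predict()
        resid = self.residuals
        names = ["F_max", "n_syn", "tau_syn", "n_deg", "tau_deg", "k_syn", "k_deg"]
        draws = np.empty((n_boot, len(names)))
        for b in range(n_boot):
            f_star = fitted + rng.choice(resid, size=resid.size, replace=True)
            res_b = TwoPhaseHillModel(TimeCourse(tc.t, f_star)).fit(
                init=self.params, restarts=1, jitter=0.0, tol=1e-8
            )
            p = res_b.params
            k = res_b.rates
            draws[b] = [p.F_max, p.n_syn, p.tau_syn, p.n_deg, p.tau_deg, k.k_syn, k.k_deg]
        lo = np.percentile(draws, 100 * alpha / 2, axis=0)
        hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
        p, k = self.params, self.rates
        est = [p.F_max, p.n_syn, p.tau_syn, p.n_deg, p.tau_deg, k.k_syn, k.k_deg]
        # percentile interval widened to include the point estimate, which
        # can sit at an interval edge for near-noiseless data
        lo = np.minimum(lo, est)
        hi = np.maximum(hi, est)
        return pd.DataFrame({"estimate": est, "lo": lo, "hi": hi}, index=names)

    def summary(self) -> str:
        p, k = self.params, self.rates
        lines = [
            "Two-phase Hill recruitment kinetics",
            "===================================",
            f"observations: {self.n_obs}   RSS: {self.rss:.6g}   converged: {self.converged}",
            f"F_max   = {p.F_max:.4g}",
            f"n_syn   = {p.n_syn:.4g}    tau_syn = {p.tau_syn:.4g} min    k_syn = {k.k_syn:.4g} 1/min",
            f"n_deg   = {p.n_deg:.4g}    tau_deg = {p.tau_deg:.4g} min    k_deg = {k.k_deg:.4g} 1/min",
            f"F0 (pre-stimulus, fixed) = {p.F0:.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p, k = self.params, self.rates
        return {
            "F_max": p.F_max, "n_syn": p.n_syn, "tau_syn": p.tau_syn,
            "n_deg": p.n_deg, "tau_deg": p.tau_deg, "F0": p.F0,
            "k_syn": k.k_syn, "k_deg": k.k_deg,
            "rss": self.rss, "n_obs": self.n_obs, "converged": self.converged,
        }

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tc = self.model.tc
        ax.plot(tc.t, tc.f, "o", ms=3, alpha=0.6, label="data")
        tg = np.linspace(tc.t.min(), tc.t.max(), 400)
        ax.plot(tg, model_eval(self.params, tg), "-", label="two-phase Hill fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("F")
        ax.legend()
        return ax


class TwoPhaseHillModel:
    """Two-phase Hill recruitment model bound to one time course.

    F0 is fixed to the pre-stimulus mean (0 if there are no t < 0 samples);
    the five free parameters (F_max, n_syn, tau_syn, n_deg, tau_deg) are
    estimated on the post-stimulus points by bounded least squares with
    jittered restarts.
    """

    def __init__(self, tc: TimeCourse):
        self.tc = tc
        if int(np.sum(tc.t >= 0)) < 8:
            raise ValueError("need at least 8 post-stimulus points to fit")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "TwoPhaseHillModel":
        return cls(TimeCourse.from_dataframe(df, **kw))

    def _default_init(self) -> KineticParams:
        t, f = self.tc.t, self.tc.f
        post = t >= 0
        tp, fp = t[post], f[post]
        t_peak = float(tp[np.argmax(fp)])
        t_peak = max(t_peak, 2 * TAU_BOUNDS[0])
        return KineticParams(
            F_max=max(2.0 * float(np.max(fp)), 1e-3),
            n_syn=2.0, tau_syn=np.clip(t_peak / 2, *TAU_BOUNDS),
            n_deg=2.0, tau_deg=np.clip(3 * t_peak, *TAU_BOUNDS),
            F0=0.0,
        )

    def fit(self, init: KineticParams | None = None, restarts: int = 5,
            jitter: float = 0.2, seed: int = 0, tol: float = 1e-12) -> TwoPhaseHillResults:
        """Fit by bounded trust-region least squares.

        ``restarts`` initial points are the supplied/derived init with
        multiplicative lognormal jitter of scale ``jitter`` (the first start
        is unjittered); the lowest-RSS solution wins.  Deterministic given
        data, init and seed.
        """
        tc = self.tc
        f0 = float(np.mean(tc.f[tc.baseline_mask])) if tc.baseline_mask.any() else 0.0
        post = tc.t >= 0
        tp, fp = tc.t[post], tc.f[post]
        p0 = init if init is not None else self._default_init()

        lb = np.array([FMAX_BOUNDS[0], N_BOUNDS[0], TAU_BOUNDS[0], N_BOUNDS[0], TAU_BOUNDS[0]])
        ub = np.array([FMAX_BOUNDS[1], N_BOUNDS[1], TAU_BOUNDS[1], N_BOUNDS[1], TAU_BOUNDS[1]])
        x0 = np.clip([p0.F_max, p0.n_syn, p0.tau_syn, p0.n_deg, p0.tau_deg], lb, ub)

        def resid(x):
            fmax, nsyn, tausyn, ndeg, taudeg = x
            return fmax * (_hill(tp, nsyn, tausyn) - _hill(tp, ndeg, taudeg)) - fp

        def jac(x):
            fmax, nsyn, tausyn, ndeg, taudeg = x
            hs = _hill(tp, nsyn, tausyn)
            hd = _hill(tp, ndeg, taudeg)
            dns, dts = _hill_grads(tp, nsyn, tausyn)
            dnd, dtd = _hill_grads(tp, ndeg, taudeg)
            return np.column_stack([hs - hd, fmax * dns, fmax * dts, -fmax * dnd, -fmax * dtd])

        rng = np.random.default_rng(seed)
        best = None
        converged = False
        for r in range(max(1, restarts)):
            xr = x0 if r == 0 else np.clip(x0 * rng.lognormal(0.0, jitter, size=5), lb, ub)
            try:
                sol = least_squares(resid, xr, jac=jac, bounds=(lb, ub),
                                    xtol=tol, ftol=tol, gtol=tol)
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
                converged = converged or bool(sol.success)
        if best is None:
            raise RuntimeError("all least-squares restarts failed")
        rss, x = best
        params = KineticParams(F_max=x[0], n_syn=x[1], tau_syn=x[2], n_deg=x[3], tau_deg=x[4], F0=f0)
        return TwoPhaseHillResults(
            model=self, params=params, rss=rss, n_obs=int(tp.size),
            converged=converged, n_restarts=max(1, restarts),
        )


def fit_timecourse(tc: TimeCourse, init: KineticParams | None = None, **kw) -> TwoPhaseHillResults:
    """Convenience wrapper: fit the two-phase Hill model to one trace."""
    return TwoPhaseHillModel(tc).fit(init=init, **kw)
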