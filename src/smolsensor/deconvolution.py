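"""Deconvolution of spot-intensity histograms into multimer fractions.

The intensity distribution of N fluorescent puncta of unknown polydispersity
is a mixture

    rho(x) = (1/N) * sum_{c=1}^{M} A_c * rho_c(x)

where A_c is the number of puncta containing c fluorophores, rho_c is the
intensity distribution of a pure c-mer population, and M is the highest
order considered (default 3: monomer/dimer/trimer).  The c = 1 basis comes
from a monomer calibration construct; higher-order bases are derived from it
either by axis scaling (rho_c(x) = rho_1(x/c)/c, a pure change of variables)
or by c-fold self-convolution (independent emitters summing their
intensities).  Both transforms are first-class via ``mode``; they coincide
at c = 1 and differ in variance for c >= 2.

The mixture weights are estimated by minimising the reduced chi-squared
between the experimental histogram and a Monte-Carlo-smoothed model
histogram, by projected Nelder-Mead on the simplex with random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "IntensityHistogram",
    "BasisSet",
    "MultimerMixtureModel",
    "MultimerMixtureResults",
    "build_histogram",
    "derive_basis",
    "simulate_model_histogram",
    "fit_mixture",
    "reduced_chi2",
]


@dataclass
class IntensityHistogram:
    """A binned intensity distribution.

    ``counts`` may be real-valued (normalized or expected counts);
    ``n_total`` is the total weight and equals counts.sum() for raw
    histograms.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("bin_edges and counts must be 1-D")
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def pmf(self) -> np.ndarray:
        s = self.counts.sum()
        return self.counts / s if s > 0 else self.counts

    def mean(self) -> float:
        return float(np.sum(self.pmf * self.centers))

    def var(self) -> float:
        m = self.mean()
        return float(np.sum(self.pmf * (self.centers - m) ** 2))

    def normalized(self) -> "IntensityHistogram":
        return IntensityHistogram(self.bin_edges, self.pmf, 1.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF draws: pick a bin by mass, then uniform within it."""
        if n == 0:
            return np.empty(0)
        p = self.pmf
        idx = rng.choice(p.size, size=int(n), p=p)
        lo = self.bin_edges[idx]
        hi = self.bin_edges[idx + 1]
        return lo + rng.random(int(n)) * (hi - lo)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "count": self.counts,
        })


def build_histogram(samples, n_bins: int = 50, range_policy="max") -> IntensityHistogram:
    """Histogram positive intensity samples on an equal-width grid from 0.

    ``range_policy``: "max" (default) spans [0, max(samples)] so every
    sample is counted; a float q in (0, 1) spans [0, q-th quantile] with
    samples above the range clipped into the top bin (counts still sum to
    the sample count).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    if np.any(x <= 0):
        raise ValueError("intensities must be positive")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if range_policy == "max":
        top = float(x.max())
    else:
        q = float(range_policy)
        if not 0 < q < 1:
            raise ValueError("range_policy must be 'max' or a quantile in (0, 1)")
        top = float(np.quantile(x, q))
    edges = np.linspace(0.0, top, n_bins + 1)
    counts, _ = np.histogram(np.minimum(x, top), bins=edges)
    return IntensityHistogram(edges, counts.astype(float), float(x.size))


def _redistribute(src_edges: np.ndarray, src_mass: np.ndarray, dst_edges: np.ndarray) -> np.ndarray:
    """Move interval masses onto a destination grid by proportional overlap."""
    out = np.zeros(dst_edges.size - 1)
    for (a, b), m in zip(zip(src_edges[:-1], src_edges[1:]), src_mass):
        if m == 0:
            continue
        i0 = np.searchsorted(dst_edges, a, side="right") - 1
        i1 = np.searchsorted(dst_edges, b, side="left")
        for i in range(max(i0, 0), min(i1, out.size)):
            lo = max(a, dst_edges[i])
            hi = min(b, dst_edges[i + 1])
            if hi > lo:
                out[i] += m * (hi - lo) / (b - a)
    return out


@dataclass
class BasisSet:
    """Normalized c-mer basis histograms rho_1..rho_M on a common grid."""

    bin_edges: np.ndarray
    rho: np.ndarray  # shape (M, B); each row sums to 1
    mode: str

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.ndim != 2 or self.rho.shape[1] != self.bin_edges.size - 1:
            raise ValueError("rho must be (M, B) on the shared grid")
        if not np.allclose(self.rho.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each basis row must sum to 1")

    @property
    def M(self) -> int:
        return self.rho.shape[0]

    def component(self, c: int) -> IntensityHistogram:
        return IntensityHistogram(self.bin_edges, self.rho[c - 1], 1.0)


def derive_basis(rho1: IntensityHistogram, M: int = 3, mode: str = "scale") -> BasisSet:
    """Derive order-1..M basis histograms from the monomer calibration.

    The common grid keeps rho1's bin width and extends to M times its upper
    edge so every derived component is fully supported.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if mode not in ("scale", "convolve"):
        raise ValueError("mode must be 'scale' or 'convolve'")
    w = float(rho1.widths[0])
    if not np.allclose(rho1.widths, w):
        raise ValueError("rho1 must have equal-width bins")
    e0 = float(rho1.bin_edges[0])
    top = float(rho1.bin_edges[-1])
    n_ext = int(np.ceil((M * top - e0) / w))
    edges = e0 + w * np.arange(n_ext + 1)
    p1 = rho1.pmf
    rows = []
    for c in range(1, M + 1):
        if mode == "scale":
            # rho_c(x) = rho_1(x/c)/c: bin [a,b] of mass m maps to [ca,cb]
            rows.append(_redistribute(c * rho1.bin_edges, p1, edges))
        else:
            # c-fold self-convolution on the bin-centre lattice
            pmf = p1.copy()
            for _ in range(c - 1):
                pmf = np.convolve(pmf, p1)
            # support centres: c*first_centre + k*w
            first = c * (e0 + w / 2)
            src_edges = first - w / 2 + w * np.arange(pmf.size + 1)
            rows.append(_redistribute(src_edges, pmf, edges))
    rho = np.array(rows)
    rho = rho / rho.sum(axis=1, keepdims=True)
    return BasisSet(edges, rho, mode)


def simulate_model_histogram(basis: BasisSet, fractions, n: int, seed=None) -> IntensityHistogram:
    """Draw n spots from the mixture over the basis and histogram them on
    the basis grid.  n = 0 yields an all-zero histogram."""
    fr = np.asarray(fractions, dtype=float)
    if fr.size != basis.M or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be a length-M simplex vector")
    counts = np.zeros(basis.bin_edges.size - 1)
    if n == 0:
        return IntensityHistogram(basis.bin_edges, counts, 0.0)
    rng = np.random.default_rng(seed)
    orders = rng.choice(basis.M, size=int(n), p=fr)
    for c in np.unique(orders):
        k = int(np.sum(orders == c))
        x = basis.component(int(c) + 1).sample(k, rng)
        counts += np.histogram(x, bins=basis.bin_edges)[0]
    return IntensityHistogram(basis.bin_edges, counts, float(n))


def _pool_bins(obs: np.ndarray, exp: np.ndarray, min_expected: float = 5.0):
    """Pool adjacent bins until each pooled bin has expected >= min_expected.

    Bins with zero expectation and zero observation are dropped; a trailing
    under-filled pool is merged backwards.
    """
    po, pe = [], []
    co = ce = 0.0
    for o, e in zip(obs, exp):
        co += o
        ce += e
        if ce >= min_expected:
            po.append(co)
            pe.append(ce)
            co = ce = 0.0
    if ce > 0 or co > 0:
        if pe:
            po[-1] += co
            pe[-1] += ce
        elif ce > 0:
            po.append(co)
            pe.append(ce)
    return np.asarray(po), np.asarray(pe)


def reduced_chi2(obs, expected, n_free_params: int, min_expected: float = 5.0) -> float:
    """Pearson chi-squared per degree of freedom between two histograms.

    ``obs`` and ``expected`` may be IntensityHistograms on a common grid or
    plain count arrays.  Bins with expected count below ``min_expected`` are
    pooled with neighbours; dof = pooled_bins - n_free_params - 1.
    """
    if isinstance(obs, IntensityHistogram):
        if isinstance(expected, IntensityHistogram) and not np.allclose(
            obs.bin_edges, expected.bin_edges
        ):
            raise ValueError("histograms must share a common grid")
        obs = obs.counts
    if isinstance(expected, IntensityHistogram):
        expected = expected.counts
    obs = np.asarray(obs, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if obs.shape != expected.shape:
        raise ValueError("obs and expected must have the same number of bins")
    po, pe = _pool_bins(obs, expected, min_expected)
    dof = po.size - int(n_free_params) - 1
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({dof})")
    return float(np.sum((po - pe) ** 2 / pe) / dof)


@dataclass
class MultimerMixtureResults:
    """Fitted multimer fractions with reduced-chi-squared fit quality."""

    model: "MultimerMixtureModel"
    fractions: np.ndarray
    chi2_red: float
    dof: int
    n_draws: int
    seed: int
    n_restarts: int

    @property
    def monomer_fraction(self) -> float:
        return float(self.fractions[0])

    def summary(self) -> str:
        lines = [
            "Multimer mixture deconvolution",
            "==============================",
            f"basis: M = {self.model.basis.M} ({self.model.basis.mode} mode), "
            f"n_total = {self.model.expt.n_total:.0f}",
            f"reduced chi2 = {self.chi2_red:.3f}  (dof = {self.dof})",
        ]
        for c, f in enumerate(self.fractions, start=1):
            lines.append(f"  {c}-mer fraction = {f:.4f}  ({100 * f:.1f}%)")
        lines.append(f"Monte-Carlo draws = {self.n_draws}, seed = {self.seed}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "fractions": [float(f) for f in self.fractions],
            "monomer_fraction": self.monomer_fraction,
            "chi2_red": self.chi2_red,
            "dof": self.dof,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "mode": self.model.basis.mode,
        }

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        expt = self.model.expt
        ax.stairs(expt.counts, expt.bin_edges, fill=True, alpha=0.4, label="experimental")
        obs_grid, exp_counts = self.model._expected_counts(self.fractions)
        ax.stairs(exp_counts[:-1], expt.bin_edges, color="k", label="mixture fit")
        ax.set_xlabel("spot intensity (ADU)")
        ax.set_ylabel("count")
        ax.legend()
        return ax


class MultimerMixtureModel:
    """Reduced-chi-squared mixture fit of an intensity histogram.

    The model histogram for weights f is n_total * sum_c f_c * rho~_c where
    rho~_c is a Monte-Carlo-smoothed version of basis component c rebinned
    onto the experimental grid (plus one overflow bin so no model mass is
    lost above the experimental range).  The smoothing draw is made once per
    fit from the stored seed, so the objective is deterministic.
    """

    def __init__(self, expt: IntensityHistogram, basis: BasisSet):
        if expt.n_total < 100:
            raise ValueError("need n_total >= 100 spots for a powered mixture fit")
        if expt.counts.sum() <= 0:
            raise ValueError("experimental histogram is all zero")
        self.expt = expt
        self.basis = basis
        self._smoothed = None

    @classmethod
    def from_samples(cls, expt_samples, calib_samples, M: int = 3, mode: str = "scale",
                     n_bins: int = 50) -> "MultimerMixtureModel":
        """Build histograms and basis directly from raw intensity samples."""
        rho1 = build_histogram(calib_samples, n_bins=n_bins).normalized()
        basis = derive_basis(rho1, M=M, mode=mode)
        expt = build_histogram(expt_samples, n_bins=n_bins)
        return cls(expt, basis)

    def _smooth_basis(self, n_draws: int, seed: int) -> np.ndarray:
        """(M, B+1) smoothed component pmfs on the expt grid + overflow bin."""
        rng = np.random.default_rng(seed)
        edges = self.expt.bin_edges
        out = np.empty((self.basis.M, edges.size))  # last column = overflow
        for c in range(1, self.basis.M + 1):
            x = self.basis.component(c).sample(n_draws, rng)
            h, _ = np.histogram(x, bins=edges)
            out[c - 1, :-1] = h
            out[c - 1, -1] = np.sum(x >= edges[-1])
        return out / n_draws

    def _expected_counts(self, fractions: np.ndarray):
        obs = np.append(self.expt.counts, 0.0)  # overflow bin observes 0
        exp = self.expt.n_total * (fractions @ self._smoothed)
        return obs, exp

    def fit(self, n_draws: int | None = None, seed: int = 0, restarts: int = 10) -> MultimerMixtureResults:
        """Minimise reduced chi2 over the simplex (Nelder-Mead, restarts)."""
        if n_draws is None:
            n_draws = int(20 * self.expt.n_total)
        self._smoothed = self._smooth_basis(n_draws, seed)
        M = self.basis.M
        obs0 = np.append(self.expt.counts, 0.0)

        def to_simplex(v: np.ndarray) -> np.ndarray:
            a = np.abs(v)
            s = a.sum()
            return a / s if s > 0 else np.full(M, 1.0 / M)

        def objective(v: np.ndarray) -> float:
            f = to_simplex(v)
            _, exp = self._expected_counts(f)
            try:
                return reduced_chi2(obs0, exp, n_free_params=M - 1)
            except ValueError:
                return np.inf

        rng = np.random.default_rng(seed)
        starts = [np.full(M, 1.0 / M)]
        if M > 1:
            starts.append(np.array([0.9] + [0.1 / (M - 1)] * (M - 1)))
        while len(starts) < restarts:
            starts.append(rng.dirichlet(np.ones(M)))
        best_v, best_val = None, np.inf
        for s in starts[:restarts]:
            res = minimize(objective, s, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
            if res.fun < best_val:
                best_val, best_v = res.fun, res.x
        fractions = to_simplex(best_v)
        _, exp = self._expected_counts(fractions)
        po, _ = _pool_bins(obs0, exp)
        dof = po.size - (M - 1) - 1
        return MultimerMixtureResults(
            model=self, fractions=fractions, chi2_red=float(best_val), dof=int(dof),
            n_draws=int(n_draws), seed=int(seed), n_restarts=int(restarts),
        )


def fit_mixture(expt: IntensityHistogram, basis: BasisSet, n_draws: int | None = None,
                seed: int = 0, restarts: int = 10) -> MultimerMixtureResults:
    """Convenience wrapper around :class:`MultimerMixtureModel`."""
    return MultimerMixtureModel(expt, basis).fit(n_draws=n_draws, seed=seed, restarts=restarts)
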