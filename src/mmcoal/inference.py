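r"""Minimum-l2 model fitting, likelihood-ratio G tests and approximate
multinomial log-likelihoods for observed site-frequency spectra.

The l2 distance between an observed spectrum xi (S segregating sites) and a
model's expected normalized spectrum phi is

    l2 = sum_{i=1}^{n-1} (xi_i / S - phi_i)^2,

and l_2 = sqrt(l2) is the companion root distance.  A coalescent family is
fitted by evaluating l2 on a parameter grid (expected spectra share one
seed stream per grid point, so the curve is smooth in the parameter) and
taking the argmin; the Kingman null l2(0) is always reported alongside.

The G goodness-of-fit statistic is 2 sum O_i ln(O_i / E_i) with E_i = S phi_i,
after pooling adjacent classes from the right tail until every pooled
expectation reaches ``pool_min`` (default 5, Cochran's rule for the validity
of the chi-square reference; configurable).  The multinomial models are
nested within Kingman, so differences of G between models are compared at
one degree of freedom.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .coalescent import (
    CoalescentModel,
    ExpectedSFS,
    expected_normalized_sfs,
    kingman_phi,
)
from .spectrum import SiteFrequencySpectrum, normalize, sfs_from_counts

__all__ = [
    "FitResult",
    "GTestResult",
    "l2_distance",
    "l2_root",
    "g_test",
    "approx_loglik",
    "fit_model",
    "SpectrumModelFit",
    "default_grid",
]

# every printed grid estimate in the source tables is a multiple of 0.005
DEFAULT_GRIDS = {
    "beta": (1.0, 2.0, 0.005),
    "dirac": (0.005, 1.0, 0.005),
    "exp_growth": (0.0, 50.0, 0.25),
    "alg_growth": (0.0, 50.0, 0.25),
}


def default_grid(family: str) -> np.ndarray:
    lo, hi, step = DEFAULT_GRIDS[family]
    m = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(m + 1), 10)


@dataclasses.dataclass(frozen=True)
class GTestResult:
    g_stat: float
    df: int
    p: Optional[float]  # None when df <= 0 after pooling
    n_pooled: int
    pool_min: float


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Result of a minimum-l2 grid fit of one coalescent family."""

    family: str
    grid: np.ndarray
    l2_curve: np.ndarray
    best_param: float
    l2_min: float
    l2_kingman: float
    g_stat: float
    g_df: int
    g_p: Optional[float]
    loglik: float
    reps: int
    seed: int
    tie: bool = False

    @property
    def l2_root(self) -> float:
        """The l_2 distance (square root of the minimized l2)."""
        return float(np.sqrt(self.l2_min))

    @property
    def l2_root_curve(self) -> np.ndarray:
        return np.sqrt(self.l2_curve)


# ---------------------------------------------------------------------------
# distances and test statistics


def _check_compatible(observed: SiteFrequencySpectrum, expected: ExpectedSFS) -> None:
    if observed.folded:
        raise ValueError("expected an unfolded observed spectrum")
    if observed.n != expected.n or len(observed.counts) != len(expected.phi):
        raise ValueError(
            f"class-count mismatch: observed n={observed.n} "
            f"({len(observed.counts)} classes) vs expected n={expected.n} "
            f"({len(expected.phi)} classes)"
        )
    if observed.S == 0:
        raise ValueError("observed spectrum has S = 0")


def l2_distance(observed: SiteFrequencySpectrum, expected: ExpectedSFS) -> float:
    """Sum of squared differences between xi/S and phi over all classes."""
    _check_compatible(observed, expected)
    return float(np.sum((normalize(observed) - expected.phi) ** 2))


def l2_root(observed: SiteFrequencySpectrum, expected: ExpectedSFS) -> float:
    """The l_2 distance, sqrt of :func:`l2_distance`."""
    return float(np.sqrt(l2_distance(observed, expected)))


def _pool_right(
    obs: np.ndarray, exp: np.ndarray, pool_min: float, from_right: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Pool adjacent classes until every pooled expectation >= pool_min.

    Pooling starts from the right tail by default (where expectations are
    smallest for decreasing spectra); a final under-threshold pool is merged
    into its neighbour.  Totals are preserved exactly.
    """
    order = range(len(exp) - 1, -1, -1) if from_right else range(len(exp))
    pooled_o: list[float] = []
    pooled_e: list[float] = []
    acc_o = acc_e = 0.0
    for i in order:
        acc_o += obs[i]
        acc_e += exp[i]
        if acc_e >= pool_min:
            pooled_o.append(acc_o)
            pooled_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if pooled_e:
            pooled_o[-1] += acc_o
            pooled_e[-1] += acc_e
        else:
            pooled_o.append(acc_o)
            pooled_e.append(acc_e)
    if from_right:
        pooled_o.reverse()
        pooled_e.reverse()
    return np.asarray(pooled_o), np.asarray(pooled_e)


def g_test(
    observed: SiteFrequencySpectrum,
    expected: ExpectedSFS,
    fitted_params: int = 0,
    pool_min: float = 5.0,
    pool_from_right: bool = True,
) -> GTestResult:
    """Likelihood-ratio G goodness-of-fit test of a model spectrum.

    G = 2 sum O ln(O/E) over pooled classes with O > 0, E = S * phi;
    df = pooled classes - 1 - fitted_params; the tail probability uses the
    chi-square reference.  When df <= 0 the statistic is still reported with
    p = None.
    """
    _check_compatible(observed, expected)
    S = observed.S
    exp_counts = S * expected.phi
    obs_p, exp_p = _pool_right(observed.counts.astype(float), exp_counts,
                               pool_min, pool_from_right)
    mask = obs_p > 0
    g = float(2.0 * np.sum(obs_p[mask] * np.log(obs_p[mask] / exp_p[mask])))
    df = len(exp_p) - 1 - fitted_params
    p = float(chi2.sf(g, df)) if df > 0 else None
    return GTestResult(g_stat=g, df=df, p=p, n_pooled=len(exp_p),
                       pool_min=pool_min)


def approx_loglik(
    observed: SiteFrequencySpectrum, expected: ExpectedSFS
) -> float:
    """Multinomial log-likelihood sum_i xi_i ln(phi_i), up to a constant.

    Zero expected cells that carry observations get a floor of half the
    smallest positive phi (the standard zero-cell guard for Monte-Carlo
    spectra).
    """
    _check_compatible(observed, expected)
    phi = expected.phi.copy()
    if (phi[observed.counts > 0] <= 0).any():
        floor = phi[phi > 0].min() / 2.0
        phi = np.where(phi > 0, phi, floor)
        phi = phi / phi.sum()
    mask = observed.counts > 0
    return float(np.sum(observed.counts[mask] * np.log(phi[mask])))


# ---------------------------------------------------------------------------
# grid fitting


class SpectrumModelFit(BaseEstimator):
    """Minimum-l2 grid fit of a coalescent family to an observed SFS.

    scikit-learn style estimator: construct with hyperparameters, call
    :meth:`fit` with an observed unfolded spectrum, read fitted attributes.

    Parameters
    ----------
    family : str
        One of ``beta``, ``dirac``, ``exp_growth``, ``alg_growth`` or
        ``kingman`` (the latter has an empty grid and only evaluates the
        null).
    grid_min, grid_max, grid_step : float, optional
        Parameter grid; defaults to the family's canonical grid
        (alpha in [1, 2] and psi in [0.005, 1] at step 0.005).
    reps : int
        Monte-Carlo genealogies per grid point for the expected spectra.
    random_state : int
        Seed shared by every grid point (variance reduction: the l2 curve is
        smooth in the parameter instead of re-randomized per evaluation).
    pool_min : float
        Pooling threshold for the G test (Cochran's rule by default).

    Attributes
    ----------
    grid_ : ndarray
        Evaluated parameter values.
    l2_curve_ : ndarray
        l2 at each grid point.
    best_param_ : float
        Arg-min of the curve (ties broken toward the smaller value).
    l2_min_, l2_kingman_ : float
        Minimum l2 and the Kingman-null l2(0).
    g_stat_, g_df_, g_p_, loglik_ : float
        Goodness-of-fit summaries at the best parameter.
    result_ : FitResult
        The complete result object.
    """

    def __init__(
        self,
        family: str = "beta",
        grid_min: Optional[float] = None,
        grid_max: Optional[float] = None,
        grid_step: Optional[float] = None,
        reps: int = 100_000,
        random_state: int = 0,
        pool_min: float = 5.0,
    ) -> None:
        self.family = family
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.grid_step = grid_step
        self.reps = reps
        self.random_state = random_state
        self.pool_min = pool_min

    # -- internals -------------------------------------------------------
    def _grid(self) -> np.ndarray:
        if self.family == "kingman":
            return np.array([])
        lo, hi, step = DEFAULT_GRIDS[self.family]
        lo = lo if self.grid_min is None else self.grid_min
        hi = hi if self.grid_max is None else self.grid_max
        step = step if self.grid_step is None else self.grid_step
        if hi < lo or step <= 0:
            raise ValueError(f"invalid grid [{lo}, {hi}] step {step}")
        m = int(round((hi - lo) / step))
        grid = np.round(lo + step * np.arange(m + 1), 10)
        grid = grid[grid <= hi + 1e-12]
        if len(grid) == 0:
            raise ValueError("empty parameter grid")
        # validate endpoints against the family's legal range
        CoalescentModel(self.family, float(grid[0]))
        CoalescentModel(self.family, float(grid[-1]))
        return grid

    def _as_sfs(self, X) -> SiteFrequencySpectrum:
        if isinstance(X, SiteFrequencySpectrum):
            return X
        return sfs_from_counts(np.asarray(X, dtype=int).ravel())

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y=None) -> "SpectrumModelFit":
        """Fit the family to an observed spectrum.

        ``X`` is a :class:`SiteFrequencySpectrum` or a 1-D count vector
        xi_1..xi_{n-1}; ``y`` is ignored (sklearn signature compatibility).
        """
        observed = self._as_sfs(X)
        if observed.folded:
            raise ValueError("fit requires an unfolded spectrum")
        if observed.S == 0:
            raise ValueError("cannot fit a spectrum with S = 0")
        n = observed.n
        grid = self._grid()
        obs_norm = normalize(observed)
        kingman_exp = ExpectedSFS(
            n=n, phi=kingman_phi(n), se=np.zeros(n - 1), method="closed_form",
            reps=0, seed=self.random_state)
        l2_null = float(np.sum((obs_norm - kingman_exp.phi) ** 2))

        if self.family == "kingman":
            best_exp = kingman_exp
            curve = np.array([])
            best_param = float("nan")
            l2_min = l2_null
            tie = False
            fitted_params = 0
        else:
            curve = np.empty(len(grid))
            expecteds = []
            for i, p in enumerate(grid):
                exp_sfs = expected_normalized_sfs(
                    n, CoalescentModel(self.family, float(p)),
                    reps=self.reps, seed=self.random_state)
                expecteds.append(exp_sfs)
                curve[i] = np.sum((obs_norm - exp_sfs.phi) ** 2)
            best_idx = int(np.argmin(curve))  # argmin takes the first = smaller param
            tie = bool(np.sum(curve == curve[best_idx]) > 1)
            best_param = float(grid[best_idx])
            l2_min = float(curve[best_idx])
            best_exp = expecteds[best_idx]
            fitted_params = 1

        gres = g_test(observed, best_exp, fitted_params=fitted_params,
                      pool_min=self.pool_min)
        self.grid_ = grid
        self.l2_curve_ = curve
        self.best_param_ = best_param
        self.l2_min_ = l2_min
        self.l2_kingman_ = l2_null
        self.expected_ = best_exp
        self.g_stat_ = gres.g_stat
        self.g_df_ = gres.df
        self.g_p_ = gres.p
        self.loglik_ = approx_loglik(observed, best_exp)
        self.tie_ = tie
        self.result_ = FitResult(
            family=self.family, grid=grid, l2_curve=curve,
            best_param=best_param, l2_min=l2_min, l2_kingman=l2_null,
            g_stat=gres.g_stat, g_df=gres.df, g_p=gres.p,
            loglik=self.loglik_, reps=self.reps, seed=self.random_state,
            tie=tie)
        return self

    def score(self, X, y=None) -> float:
        """Negative l2 of the fitted model against a spectrum (higher = better)."""
        observed = self._as_sfs(X)
        return -l2_distance(observed, self.expected_)


def fit_model(
    observed: SiteFrequencySpectrum,
    family: str,
    grid_min: Optional[float] = None,
    grid_max: Optional[float] = None,
    grid_step: Optional[float] = None,
    reps: int = 100_000,
    seed: int = 0,
    pool_min: float = 5.0,
) -> FitResult:
    """Functional wrapper around :class:`SpectrumModelFit`."""
    est = SpectrumModelFit(family=family, grid_min=grid_min, grid_max=grid_max,
                           grid_step=grid_step, reps=reps, random_state=seed,
                           pool_min=pool_min)
    est.fit(observed)
    return est.result_


def delta_g(
    observed: SiteFrequencySpectrum,
    expected_null: ExpectedSFS,
    expected_alt: ExpectedSFS,
    pool_min: float = 5.0,
) -> tuple[float, float]:
    """Nested likelihood-ratio comparison of two model spectra at df = 1.

    Returns (delta G, p).  Delta G is the difference of the unpooled-class
    G statistics (equivalently twice the log-likelihood-ratio), compared to
    chi-square with one degree of freedom.
    """
    g0 = g_test(observed, expected_null, pool_min=pool_min)
    g1 = g_test(observed, expected_alt, pool_min=pool_min)
    dg = g0.g_stat - g1.g_stat
    return dg, float(chi2.sf(max(dg, 0.0), 1))
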