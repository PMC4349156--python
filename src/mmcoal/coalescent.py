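r"""Coalescent models: Kingman, Beta(2-alpha, alpha), point-mass (Dirac psi)
multiple-merger coalescents and growth-time-changed Kingman models.

A Lambda coalescent with b active ancestral lineages merges any fixed set of
k of them at rate

    lambda_{b,k} = \int_0^1 x^{k-2} (1-x)^{b-k} Lambda(dx) / normalisation,

so the total rate of k-mergers is C(b,k) * lambda_{b,k}.  The families here:

* ``kingman``    -- lambda_{b,2} = 1, no multiple mergers (the binary null).
* ``beta``       -- Lambda = Beta(2-alpha, alpha), 1 <= alpha <= 2; smaller
  alpha means heavier-tailed offspring numbers and larger mergers; alpha = 2
  is exactly Kingman (the Beta(0, 2) measure degenerates to a point at 0).
* ``dirac``      -- Lambda = delta_psi, 0 < psi <= 1, giving
  lambda_{b,k} = psi^{k-2} (1-psi)^{b-k}; psi is the fraction of the
  population replaced by a single family per sweepstakes event; psi -> 0
  recovers Kingman.
* ``exp_growth`` / ``alg_growth`` -- Kingman pair mergers under a
  deterministic backwards relative population size nu(t) = exp(-beta t) or
  nu(t) = (1+t)^(-gamma); the pair-coalescence intensity scales as 1/nu(t).

Times are in coalescent units throughout; no conversion to generations.

Expected normalized spectra phi_i = E[L_i] / E[sum_i L_i] (L_i = total length
of branches subtending i of the n leaves) come from the Kingman closed form
phi_i proportional to 1/i, or from Monte Carlo over simulated genealogies for
every other family, with delta-method standard errors and caching keyed by
(n, family, param, reps, seed).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from scipy.special import betaln, gammaln

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

__all__ = [
    "CoalescentModel",
    "Genealogy",
    "ExpectedSFS",
    "merger_rate",
    "simulate_genealogy",
    "expected_normalized_sfs",
    "kingman_phi",
    "clear_cache",
]

FAMILIES = ("kingman", "beta", "dirac", "exp_growth", "alg_growth")
GROWTH_FAMILIES = ("exp_growth", "alg_growth")


@dataclasses.dataclass(frozen=True)
class CoalescentModel:
    """A coalescent family tag plus its single parameter.

    ``param`` is alpha for ``beta``, psi for ``dirac``, the growth rate
    beta/gamma for the growth families, and None for ``kingman``.
    """

    family: str
    param: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family == "kingman":
            if self.param is not None:
                raise ValueError("kingman takes no parameter")
        elif self.param is None:
            raise ValueError(f"family {self.family!r} requires a parameter")
        elif self.family == "beta" and not 1.0 <= self.param <= 2.0:
            raise ValueError(f"beta coalescent needs 1 <= alpha <= 2, got {self.param}")
        elif self.family == "dirac" and not 0.0 < self.param <= 1.0:
            raise ValueError(f"dirac coalescent needs 0 < psi <= 1, got {self.param}")
        elif self.family in GROWTH_FAMILIES and self.param < 0.0:
            raise ValueError(f"growth rate must be >= 0, got {self.param}")

    # -- constructors ----------------------------------------------------
    @classmethod
    def kingman(cls) -> "CoalescentModel":
        return cls("kingman")

    @classmethod
    def beta(cls, alpha: float) -> "CoalescentModel":
        return cls("beta", alpha)

    @classmethod
    def dirac(cls, psi: float) -> "CoalescentModel":
        return cls("dirac", psi)

    @classmethod
    def exp_growth(cls, beta: float) -> "CoalescentModel":
        return cls("exp_growth", beta)

    @classmethod
    def alg_growth(cls, gamma: float) -> "CoalescentModel":
        return cls("alg_growth", gamma)

    @property
    def is_kingman_equivalent(self) -> bool:
        """True when the model's rates coincide exactly with Kingman."""
        return (
            self.family == "kingman"
            or (self.family == "beta" and self.param == 2.0)
            or (self.family in GROWTH_FAMILIES and self.param == 0.0)
        )


@dataclasses.dataclass(frozen=True)
class Genealogy:
    """One simulated genealogy of ``n`` leaves.

    ``branches`` lists (leaf index tuple, branch length) for every branch;
    ``branch_lengths_by_class[i-1]`` is L_i, the total length subtending i
    leaves; ``event_log`` records (waiting time, merger size) per event.
    """

    n: int
    branches: list[tuple[tuple[int, ...], float]]
    branch_lengths_by_class: np.ndarray
    tmrca: float
    event_log: list[tuple[float, int]]

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths_by_class.sum())

    def newick(self) -> str:
        """Newick string (multifurcations allowed) of this genealogy."""
        return _to_newick(self)


@dataclasses.dataclass(frozen=True)
class ExpectedSFS:
    """Normalized expected spectrum phi_1..phi_{n-1} with provenance."""

    n: int
    phi: np.ndarray
    se: np.ndarray
    method: str  # closed_form | monte_carlo
    reps: int
    seed: int
    family: str = "kingman"
    param: Optional[float] = None


# ---------------------------------------------------------------------------
# merger rates


def merger_rate(b: int, k: int, model: CoalescentModel) -> float:
    """Rate lambda_{b,k} of any fixed k of b lineages merging.

    The total rate of k-mergers is C(b,k) * lambda_{b,k}.  Growth families
    are time-inhomogeneous Kingman models: their instantaneous pair rate at
    backwards time 0 is returned.
    """
    if k < 2 or k > b:
        raise ValueError(f"merger size k={k} outside [2, b={b}]")
    fam = model.family
    if fam == "kingman" or fam in GROWTH_FAMILIES or (
        fam == "beta" and model.param == 2.0
    ):
        return 1.0 if k == 2 else 0.0
    if fam == "beta":
        a = model.param
        return float(math.exp(betaln(k - a, b - k + a) - betaln(2.0 - a, a)))
    if fam == "dirac":
        psi = model.param
        return float(psi ** (k - 2) * (1.0 - psi) ** (b - k))
    raise AssertionError(fam)


def _rate_tables(n: int, model: CoalescentModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-state total rates and cumulative k-choice probabilities.

    Returns ``total_rate`` of shape (n+1,) with the total merger rate at b
    active lineages, and ``cum_k`` of shape (n+1, n-1) where ``cum_k[b, j]``
    is the cumulative probability that the merger size is <= j+2.
    """
    total = np.zeros(n + 1)
    cum = np.zeros((n + 1, max(n - 1, 1)))
    for b in range(2, n + 1):
        ks = np.arange(2, b + 1)
        logc = gammaln(b + 1) - gammaln(ks + 1) - gammaln(b - ks + 1)
        lam = np.array([merger_rate(b, int(k), model) for k in ks])
        with np.errstate(divide="ignore"):
            rates = np.where(lam > 0, np.exp(logc + np.log(np.where(lam > 0, lam, 1.0))), 0.0)
        tot = rates.sum()
        total[b] = tot
        cum[b, : b - 1] = np.cumsum(rates) / tot
        cum[b, b - 1:] = 1.0
    return total, cum


# ---------------------------------------------------------------------------
# single-genealogy simulation (pure Python; tracks leaf sets for mutations)


def _growth_waiting_time(
    family: str, rate_param: float, pair_rate: float, s: float, e: float
) -> float:
    """Invert the cumulative pair-coalescence intensity from time s.

    Solves int_s^{s+T} pair_rate / nu(t) dt = e for T, with
    nu(t) = exp(-beta t) (exponential) or (1+t)^(-gamma) (algebraic).
    Closed forms; rate_param = 0 reduces to homogeneous Kingman exactly.
    """
    if rate_param == 0.0:
        return e / pair_rate
    if family == "exp_growth":
        b = rate_param
        return math.log(math.exp(b * s) + b * e / pair_rate) / b - s
    g = rate_param
    return ((1.0 + s) ** (g + 1.0) + (g + 1.0) * e / pair_rate) ** (1.0 / (g + 1.0)) - 1.0 - s


def simulate_genealogy(
    n: int, model: CoalescentModel, seed: int = 0
) -> Genealogy:
    """Simulate one genealogy by the block-counting process.

    At b lineages an exponential waiting time with the total merger rate is
    drawn, the merger size k is chosen proportional to C(b,k) lambda_{b,k},
    and k uniformly chosen blocks merge.  Growth families use Kingman pair
    rates time-changed by the inverse relative population size.
    """
    if n < 2:
        raise ValueError("need n >= 2 leaves")
    rng = np.random.default_rng(seed)
    growth = model.family in GROWTH_FAMILIES and model.param > 0.0
    if not growth:
        total, cum = _rate_tables(n, model)
    blocks: list[list[int]] = [[i] for i in range(n)]
    birth: list[float] = [0.0] * n
    t = 0.0
    L = np.zeros(n - 1)
    branches: list[tuple[tuple[int, ...], float]] = []
    events: list[tuple[float, int]] = []
    while len(blocks) > 1:
        b = len(blocks)
        if growth:
            e = rng.exponential()
            dt = _growth_waiting_time(model.family, model.param,
                                      b * (b - 1) / 2.0, t, e)
            k = 2
        else:
            dt = rng.exponential(1.0 / total[b])
            u = rng.random()
            k = 2 + int(np.searchsorted(cum[b, : b - 1], u, side="left"))
        t += dt
        events.append((dt, k))
        chosen = sorted(rng.choice(b, size=k, replace=False), reverse=True)
        merged: list[int] = []
        for idx in chosen:
            blk = blocks.pop(idx)
            length = t - birth.pop(idx)
            L[len(blk) - 1] += length
            branches.append((tuple(blk), length))
            merged.extend(blk)
        blocks.append(sorted(merged))
        birth.append(t)
    return Genealogy(n=n, branches=branches,
                     branch_lengths_by_class=L, tmrca=t, event_log=events)


def _to_newick(g: Genealogy) -> str:
    """Reconstruct a newick string from the branch list."""
    # sort branches by subtree size so children are available before parents
    frag: dict[tuple[int, ...], str] = {}
    for leaves, length in sorted(g.branches, key=lambda x: len(x[0])):
        if len(leaves) == 1:
            frag[leaves] = f"{leaves[0]}:{length:.6g}"
        else:
            # children: maximal recorded subsets; greedy partition by size
            remaining = set(leaves)
            kids = []
            for sub in sorted(frag, key=len, reverse=True):
                if set(sub) <= remaining:
                    kids.append(frag[sub])
                    remaining -= set(sub)
                if not remaining:
                    break
            frag[leaves] = f"({','.join(kids)}):{length:.6g}"
    root_leaves = tuple(range(g.n))
    if root_leaves in frag:
        return frag[root_leaves].rsplit(":", 1)[0] + ";"
    # root (all leaves) has no branch above it; assemble from top-level frags
    remaining = set(range(g.n))
    kids = []
    for sub in sorted(frag, key=len, reverse=True):
        if set(sub) <= remaining:
            kids.append(frag[sub])
            remaining -= set(sub)
        if not remaining:
            break
    return f"({','.join(kids)});"


# ---------------------------------------------------------------------------
# batch Monte-Carlo engine for expected spectra


@njit(cache=False)
def _batch_lambda(n, total_rate, cum_k, reps, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    m = n - 1
    sum_l = np.zeros(m)
    sum_l2 = np.zeros(m)
    sum_lt = np.zeros(m)
    sum_t = 0.0
    sum_t2 = 0.0
    counts = np.empty(n, dtype=np.int64)
    for _ in range(reps):
        for i in range(n):
            counts[i] = 1
        b = n
        L = np.zeros(m)
        while b > 1:
            dt = np.random.exponential(1.0 / total_rate[b])
            for i in range(b):
                L[counts[i] - 1] += dt
            u = np.random.random()
            k = b  # default: largest merger
            for j in range(b - 1):
                if u <= cum_k[b, j]:
                    k = j + 2
                    break
            newc = 0
            for j in range(k):
                r = int(np.random.random() * (b - j))
                tmp = counts[r]
                counts[r] = counts[b - 1 - j]
                counts[b - 1 - j] = tmp
                newc += counts[b - 1 - j]
            b = b - k + 1
            counts[b - 1] = newc
        tot = 0.0
        for i in range(m):
            tot += L[i]
        for i in range(m):
            sum_l[i] += L[i]
            sum_l2[i] += L[i] * L[i]
            sum_lt[i] += L[i] * tot
        sum_t += tot
        sum_t2 += tot * tot
    return sum_l, sum_l2, sum_lt, sum_t, sum_t2


@njit(cache=False)
def _batch_growth(n, rate_param, is_exp, reps, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    m = n - 1
    sum_l = np.zeros(m)
    sum_l2 = np.zeros(m)
    sum_lt = np.zeros(m)
    sum_t = 0.0
    sum_t2 = 0.0
    counts = np.empty(n, dtype=np.int64)
    for _ in range(reps):
        for i in range(n):
            counts[i] = 1
        b = n
        t = 0.0
        L = np.zeros(m)
        while b > 1:
            pair_rate = b * (b - 1) / 2.0
            e = np.random.exponential(1.0)
            if rate_param == 0.0:
                dt = e / pair_rate
            elif is_exp:
                dt = np.log(np.exp(rate_param * t)
                            + rate_param * e / pair_rate) / rate_param - t
            else:
                g1 = rate_param + 1.0
                dt = ((1.0 + t) ** g1 + g1 * e / pair_rate) ** (1.0 / g1) - 1.0 - t
            for i in range(b):
                L[counts[i] - 1] += dt
            t += dt
            newc = 0
            for j in range(2):
                r = int(np.random.random() * (b - j))
                tmp = counts[r]
                counts[r] = counts[b - 1 - j]
                counts[b - 1 - j] = tmp
                newc += counts[b - 1 - j]
            b = b - 1
            counts[b - 1] = newc
        tot = 0.0
        for i in range(m):
            tot += L[i]
        for i in range(m):
            sum_l[i] += L[i]
            sum_l2[i] += L[i] * L[i]
            sum_lt[i] += L[i] * tot
        sum_t += tot
        sum_t2 += tot * tot
    return sum_l, sum_l2, sum_lt, sum_t, sum_t2


def kingman_phi(n: int) -> np.ndarray:
    """Closed-form Kingman normalized expected SFS: phi_i = (1/i)/H_{n-1}."""
    i = np.arange(1, n)
    w = 1.0 / i
    return w / w.sum()


_CACHE: dict[tuple, ExpectedSFS] = {}


def clear_cache() -> None:
    _CACHE.clear()


def expected_normalized_sfs(
    n: int,
    model: CoalescentModel,
    reps: int = 100_000,
    seed: int = 0,
    se_tol: Optional[float] = None,
    method: str = "auto",
) -> ExpectedSFS:
    """Expected normalized SFS phi_i = E[L_i]/E[total length].

    Kingman (and exact Kingman-equivalent models) use the closed form
    phi_i = (1/i) / sum_j (1/j); all other families use Monte-Carlo means of
    L_i over ``reps`` simulated genealogies with delta-method per-class
    standard errors.  ``method="monte_carlo"`` forces the simulation path
    even for Kingman-equivalent models (a consistency cross-check).
    Results are cached by (n, family, param, reps, seed).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if method not in ("auto", "closed_form", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    if model.is_kingman_equivalent and method != "monte_carlo":
        phi = kingman_phi(n)
        return ExpectedSFS(n=n, phi=phi, se=np.zeros(n - 1), method="closed_form",
                           reps=0, seed=seed, family=model.family, param=model.param)
    if method == "closed_form":
        raise ValueError(f"no closed form for family {model.family!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1 for monte_carlo")
    key = (n, model.family, model.param, reps, seed)
    if key in _CACHE:
        return _CACHE[key]
    if model.family in GROWTH_FAMILIES:
        sums = _batch_growth(n, float(model.param),
                             model.family == "exp_growth", reps, seed)
    else:
        total, cum = _rate_tables(n, model)
        sums = _batch_lambda(n, total, cum, reps, seed)
    sum_l, sum_l2, sum_lt, sum_t, sum_t2 = sums
    m = float(reps)
    mu_l = sum_l / m
    mu_t = sum_t / m
    phi = mu_l / mu_t
    if reps > 1:
        var_l = (sum_l2 - m * mu_l**2) / (m - 1)
        var_t = (sum_t2 - m * mu_t**2) / (m - 1)
        cov = (sum_lt - m * mu_l * mu_t) / (m - 1)
        var_phi = (var_l - 2.0 * phi * cov + phi**2 * var_t) / (mu_t**2 * m)
        se = np.sqrt(np.maximum(var_phi, 0.0))
    else:
        se = np.full(n - 1, np.nan)
    phi = phi / phi.sum()  # renormalize away ratio-estimator round-off
    result = ExpectedSFS(n=n, phi=phi, se=se, method="monte_carlo",
                         reps=reps, seed=seed, family=model.family,
                         param=model.param)
    if se_tol is not None and np.nanmax(se) > se_tol:
        import warnings

        warnings.warn(
            f"Monte-Carlo se up to {np.nanmax(se):.2e} exceeds requested "
            f"tolerance {se_tol:.2e}; increase reps", stacklevel=2)
    _CACHE[key] = result
    return result


def write_expected_sfs(exp_sfs: ExpectedSFS, path) -> None:
    """TSV (class, phi, se) with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# n={exp_sfs.n} family={exp_sfs.family} param={exp_sfs.param} "
                 f"method={exp_sfs.method} reps={exp_sfs.reps} seed={exp_sfs.seed}\n")
        fh.write("class\tphi\tse\n")
        for i, (p, s) in enumerate(zip(exp_sfs.phi, exp_sfs.se), start=1):
            fh.write(f"{i}\t{p:.10g}\t{s:.4g}\n")
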