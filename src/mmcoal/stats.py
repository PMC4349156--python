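"""Classical polymorphism, divergence, differentiation and LD statistics.

Implements the per-group summary layer (segregating sites, haplotype
diversity, Watterson's theta, nucleotide diversity, Tajima's D), Jukes-Cantor
corrected gross/net divergence between groups, Hudson's F_ST with a
permutation test, and pairwise D' linkage disequilibrium with singleton and
minor-allele-frequency filters.

Missing-data conventions (recorded in every result):

* S, theta_S, haplotypes and the SFS use complete-case columns - columns with
  a gap or N in any retained ingroup sequence are excluded entirely.
* Pairwise sequence differences (K, pi, F_ST, divergence) use pairwise
  deletion - a column is ignored only for pairs where either member has a
  gap/N there.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import BASES, LabeledAlignment

__all__ = [
    "SummaryStats",
    "DivergenceResult",
    "FstResult",
    "LdMatrix",
    "summary_stats",
    "jc_correct",
    "divergence",
    "hudson_fst",
    "ld_dprime",
    "haplogroup_frequencies",
    "tajima_constants",
    "tajima_d_pvalue",
]


@dataclasses.dataclass(frozen=True)
class SummaryStats:
    """Per-group polymorphism summary (one Table-1-style row)."""

    n: int
    S: int
    H: int
    h: float
    K: float
    theta_S: float
    pi: float
    tajima_d: float | None
    effective_length: int
    # missing-data conventions, for reconciling with published tables
    pairwise_deletion: bool = True
    complete_case_S: bool = True


@dataclasses.dataclass(frozen=True)
class DivergenceResult:
    """Jukes-Cantor corrected gross (dxy) and net (da) divergence per site."""

    dxy: float
    da: float
    sd: float


@dataclasses.dataclass(frozen=True)
class FstResult:
    """Hudson's F_ST = 1 - Hw/Hb with a permutation P-value."""

    estimate: float
    p_perm: float
    n_perm: int
    seed: int


@dataclasses.dataclass(frozen=True)
class LdMatrix:
    """Pairwise |D'| over retained biallelic sites (upper triangle)."""

    dprime: np.ndarray          # (m, m), NaN on/below the diagonal
    retained_sites: np.ndarray  # 1-based column indices, length m
    exclude_singletons: bool
    maf_min: float


# ---------------------------------------------------------------------------
# helpers


def _pairwise_differences(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise difference counts and compared-site counts (pairwise deletion)."""
    n = matrix.shape[0]
    valid = (matrix != "-") & (matrix != "N")
    diffs = np.zeros((n, n))
    sites = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            d = float(np.sum((matrix[i] != matrix[j]) & both))
            diffs[i, j] = diffs[j, i] = d
            sites[i, j] = sites[j, i] = float(both.sum())
    return diffs, sites


def tajima_constants(n: int) -> dict[str, float]:
    """Variance constants a1, a2, b1, b2, c1, c2, e1, e2 for Tajima's D."""
    if n < 2:
        raise ValueError("n must be >= 2")
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_pvalue(d: float, n: int) -> float:
    """Two-tailed P for Tajima's D under the beta approximation.

    D is assumed to follow a generalized beta on [Dmin, Dmax] with mean 0 and
    variance 1 in the large-S limit, the conventional approximation used to
    flag significance when no coalescent simulation is run.
    """
    c = tajima_constants(n)
    dmin = (2.0 / n - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    dmax = ((n + 1) / (2.0 * n) - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    x = (d - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    cdf = sps.beta.cdf(x, beta, alpha)
    return float(2.0 * min(cdf, 1.0 - cdf))


# ---------------------------------------------------------------------------
# operations


def summary_stats(
    aln: LabeledAlignment, subset: Sequence[str] | None = None
) -> SummaryStats:
    """Polymorphism summary for a set of ingroup samples.

    ``subset`` is a list of sample ids; by default all ingroup samples.
    """
    sub = aln.ingroup() if subset is None else aln.subset(subset).ingroup()
    n = sub.n
    if n < 2:
        raise ValueError("need at least 2 ingroup samples")
    mask = sub.retained_mask()
    eff = int(mask.sum())
    retained = sub.matrix[:, mask]

    # segregating sites over complete-case columns
    seg = 0
    for j in range(retained.shape[1]):
        if len(np.unique(retained[:, j])) > 1:
            seg += 1

    # haplotypes over retained columns
    haplos = ["".join(row) for row in retained]
    _, counts = np.unique(haplos, return_counts=True)
    H = len(counts)
    p = counts / n
    h = float(n / (n - 1) * (1.0 - np.sum(p**2)))

    diffs, _ = _pairwise_differences(sub.matrix)
    iu = np.triu_indices(n, k=1)
    K = float(diffs[iu].mean())

    c = tajima_constants(n)
    theta_s = seg / (c["a1"] * eff) if eff > 0 else 0.0
    pi = K / eff if eff > 0 else 0.0

    if seg == 0:
        d = None
    else:
        var = c["e1"] * seg + c["e2"] * seg * (seg - 1)
        d = float((K - seg / c["a1"]) / math.sqrt(var))

    return SummaryStats(n=n, S=seg, H=H, h=h, K=K, theta_S=theta_s, pi=pi,
                        tajima_d=d, effective_length=eff)


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3) for raw difference p."""
    if not 0.0 <= p < 0.75:
        raise ValueError(f"p = {p} outside [0, 3/4): Jukes-Cantor saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _mean_within_p(matrix: np.ndarray) -> float:
    """Mean pairwise raw per-site difference within a group (0 if n < 2)."""
    if matrix.shape[0] < 2:
        return 0.0
    diffs, sites = _pairwise_differences(matrix)
    iu = np.triu_indices(matrix.shape[0], k=1)
    with np.errstate(invalid="ignore"):
        props = np.where(sites[iu] > 0, diffs[iu] / np.maximum(sites[iu], 1), 0.0)
    return float(props.mean())


def divergence(
    aln: LabeledAlignment, group_x: Sequence[str], group_y: Sequence[str]
) -> DivergenceResult:
    """Gross D_XY and net D_a nucleotide divergence per site between groups.

    Both are Jukes-Cantor corrected; D_a subtracts the mean of the (also
    corrected) within-group diversities.  The standard deviation is the
    delta-method variance of the Jukes-Cantor estimator,
    Var = 9 p (1 - p) / ((3 - 4p)^2 L).
    """
    if set(group_x) & set(group_y):
        raise ValueError("groups must be disjoint")
    if not group_x or not group_y:
        raise ValueError("groups must be non-empty")
    mx = aln.subset(group_x).matrix
    my = aln.subset(group_y).matrix
    valid_x = (mx != "-") & (mx != "N")
    valid_y = (my != "-") & (my != "N")
    props = []
    lens = []
    for i in range(mx.shape[0]):
        for j in range(my.shape[0]):
            both = valid_x[i] & valid_y[j]
            ncmp = int(both.sum())
            if ncmp == 0:
                continue
            props.append(float(np.sum((mx[i] != my[j]) & both)) / ncmp)
            lens.append(ncmp)
    p_between = float(np.mean(props))
    L = float(np.mean(lens))
    dxy = jc_correct(p_between)
    pi_x = jc_correct(_mean_within_p(mx))
    pi_y = jc_correct(_mean_within_p(my))
    da = dxy - (pi_x + pi_y) / 2.0
    if p_between == 0.0:
        sd = 0.0
    else:
        sd = math.sqrt(9.0 * p_between * (1.0 - p_between)
                       / ((3.0 - 4.0 * p_between) ** 2 * L))
    return DivergenceResult(dxy=dxy, da=da, sd=sd)


def _fst_from_diffs(diffs: np.ndarray, groups: np.ndarray) -> float:
    """Hudson's 1 - Hw/Hb from a pairwise difference matrix and group labels."""
    labels = np.unique(groups)
    within_means = []
    sizes = []
    between = []
    for gi, g in enumerate(labels):
        idx = np.nonzero(groups == g)[0]
        if len(idx) >= 2:
            iu = np.triu_indices(len(idx), k=1)
            within_means.append(float(diffs[np.ix_(idx, idx)][iu].mean()))
            sizes.append(len(idx))
        for g2 in labels[gi + 1:]:
            idx2 = np.nonzero(groups == g2)[0]
            between.append(diffs[np.ix_(idx, idx2)].ravel())
    hw = float(np.average(within_means, weights=sizes))
    hb = float(np.concatenate(between).mean())
    if hb == 0.0:
        return 0.0
    return 1.0 - hw / hb


def hudson_fst(
    aln: LabeledAlignment,
    partition: Mapping[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> FstResult:
    """Hudson's F_ST between >= 2 groups with a label-permutation test.

    ``partition`` maps sample id to group name; samples not in the mapping are
    excluded.  Hw is the group-size-weighted mean of per-group mean pairwise
    differences; Hb the mean between-group pairwise difference.  The P-value
    is (#{permuted >= observed} + 1) / (n_perm + 1) under random reassignment
    preserving group sizes.
    """
    ids = [s for s in aln.ids if s in partition]
    sub = aln.subset(ids)
    groups = np.array([partition[s] for s in ids])
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with < 2 samples: {small}")
    diffs, _ = _pairwise_differences(sub.matrix)
    obs = _fst_from_diffs(diffs, groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _fst_from_diffs(diffs, perm) >= obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return FstResult(estimate=obs, p_perm=p, n_perm=n_perm, seed=seed)


def ld_dprime(
    aln: LabeledAlignment,
    exclude_singletons: bool = False,
    maf_min: float = 0.0,
) -> LdMatrix:
    """Pairwise |D'| among retained biallelic sites of a haploid alignment.

    Gametic phase is known (haploid sequences).  Sites are filtered to
    biallelic complete-case columns; singletons are dropped when
    ``exclude_singletons`` and sites with minor allele frequency <= ``maf_min``
    are dropped when ``maf_min`` > 0 (strict inequality retained, matching the
    "greater than 0.1" convention).
    """
    sub = aln.ingroup()
    mask = sub.retained_mask()
    positions = []
    cols = []
    for j in np.nonzero(mask)[0]:
        col = sub.matrix[:, j]
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) != 2:
            continue
        minor = counts.min()
        if exclude_singletons and minor == 1:
            continue
        if maf_min > 0.0 and minor / sub.n <= maf_min:
            continue
        positions.append(j + 1)
        cols.append(col == alleles[0])  # presence of (arbitrary) first allele
    m = len(positions)
    dmat = np.full((m, m), np.nan)
    if m >= 2:
        X = np.array(cols)
        p = X.mean(axis=1)
        for a in range(m):
            for b in range(a + 1, m):
                pab = float(np.mean(X[a] & X[b]))
                D = pab - p[a] * p[b]
                if D > 0:
                    dmax = min(p[a] * (1 - p[b]), (1 - p[a]) * p[b])
                elif D < 0:
                    dmax = min(p[a] * p[b], (1 - p[a]) * (1 - p[b]))
                else:
                    dmax = 1.0
                dmat[a, b] = abs(D) / dmax if dmax > 0 else 0.0
    return LdMatrix(
        dprime=dmat,
        retained_sites=np.array(positions, dtype=int),
        exclude_singletons=exclude_singletons,
        maf_min=maf_min,
    )


def haplogroup_frequencies(
    labels: Sequence[str],
    localities: Sequence[str],
    regions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-locality haplogroup counts and relative frequencies.

    ``labels`` and ``localities`` are aligned per sample.  When ``regions``
    maps locality codes to region names, regional aggregate rows are appended.
    Localities with no samples are omitted.
    """
    if len(labels) != len(localities):
        raise ValueError("labels and localities must align per sample")
    df = pd.DataFrame({"label": list(labels), "locality": list(localities)})
    out = []
    label_values = sorted(df["label"].unique())

    def _rows(frame: pd.DataFrame, name: str, kind: str) -> dict[str, object]:
        row: dict[str, object] = {"group": name, "kind": kind, "n": len(frame)}
        for lab in label_values:
            cnt = int((frame["label"] == lab).sum())
            row[f"count_{lab}"] = cnt
            row[f"freq_{lab}"] = cnt / len(frame)
        return row

    for loc, frame in df.groupby("locality", sort=True):
        out.append(_rows(frame, str(loc), "locality"))
    if regions is not None:
        df["region"] = [regions.get(l, "none") for l in df["locality"]]
        for reg, frame in df.groupby("region", sort=True):
            out.append(_rows(frame, str(reg), "region"))
    return pd.DataFrame(out)
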