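"""Site-frequency spectra: construction, folding, normalization, modes.

The unfolded spectrum xi_1..xi_{n-1} counts segregating sites by the number
of ingroup sequences carrying the derived allele, polarized against a single
designated outgroup sequence: a site enters the spectrum only when it is
biallelic among ingroup samples and the outgroup carries one of the two
ingroup alleles (that allele is taken as ancestral).  Sites that cannot be
polarized are dropped and tallied in ``polarization_log``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .io import LabeledAlignment

__all__ = [
    "SiteFrequencySpectrum",
    "unfolded_sfs",
    "fold",
    "normalize",
    "find_modes",
    "sfs_from_counts",
    "write_sfs",
    "read_sfs",
]


@dataclasses.dataclass(frozen=True)
class SiteFrequencySpectrum:
    """Counts xi_i (unfolded, i = 1..n-1) or eta_i (folded, i = 1..floor(n/2))."""

    n: int
    counts: np.ndarray
    folded: bool = False
    polarization_log: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        expected = self.n // 2 if self.folded else self.n - 1
        if len(counts) != expected:
            raise ValueError(
                f"{'folded' if self.folded else 'unfolded'} SFS for n={self.n} "
                f"needs {expected} classes, got {len(counts)}"
            )
        if (counts < 0).any():
            raise ValueError("negative class counts")
        object.__setattr__(self, "counts", counts)

    @property
    def S(self) -> int:
        return int(self.counts.sum())

    @property
    def classes(self) -> np.ndarray:
        return np.arange(1, len(self.counts) + 1)


def sfs_from_counts(
    counts: np.ndarray | list[int], n: int | None = None, folded: bool = False
) -> SiteFrequencySpectrum:
    """Wrap a raw count vector; n defaults to len(counts)+1 (unfolded)."""
    counts = np.asarray(counts, dtype=int)
    if n is None:
        if folded:
            raise ValueError("n is required for a folded spectrum")
        n = len(counts) + 1
    return SiteFrequencySpectrum(n=n, counts=counts, folded=folded)


def unfolded_sfs(
    aln: LabeledAlignment, outgroup_id: str
) -> SiteFrequencySpectrum:
    """Outgroup-polarized unfolded SFS of the ingroup samples.

    Columns are the complete-case ingroup columns (no gap/N in any ingroup
    sequence).  A column contributes when it is ingroup-biallelic and the
    outgroup base matches one of the two ingroup alleles; the other allele is
    derived.  Dropped columns are tallied by reason: ``outgroup_missing``
    (gap/N in the outgroup), ``outgroup_third_allele``, ``multiallelic``
    (3+ ingroup alleles).
    """
    out_idx = aln.index_of(outgroup_id)
    if aln.samples[out_idx].role != "outgroup":
        raise ValueError(f"sample {outgroup_id!r} does not have role=outgroup")
    ing_idx = aln.ingroup_indices()
    n = len(ing_idx)
    if n < 2:
        raise ValueError("need at least 2 ingroup samples")
    ing = aln.matrix[ing_idx]
    out = aln.matrix[out_idx]
    counts = np.zeros(n - 1, dtype=int)
    log = {"used": 0, "outgroup_missing": 0,
           "outgroup_third_allele": 0, "multiallelic": 0}
    for j in np.nonzero(aln.retained_mask())[0]:
        col = ing[:, j]
        alleles, acounts = np.unique(col, return_counts=True)
        if len(alleles) == 1:
            continue
        if len(alleles) > 2:
            log["multiallelic"] += 1
            continue
        ob = out[j]
        if ob in ("-", "N"):
            log["outgroup_missing"] += 1
            continue
        if ob not in alleles:
            log["outgroup_third_allele"] += 1
            continue
        derived = int(acounts[alleles != ob][0])
        counts[derived - 1] += 1
        log["used"] += 1
    return SiteFrequencySpectrum(n=n, counts=counts, folded=False,
                                 polarization_log=log)


def fold(sfs: SiteFrequencySpectrum) -> SiteFrequencySpectrum:
    """Fold an unfolded spectrum: eta_i = xi_i + xi_{n-i}, eta_{n/2} = xi_{n/2}."""
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    n = sfs.n
    xi = sfs.counts
    eta = np.zeros(n // 2, dtype=int)
    for i in range(1, n // 2 + 1):
        if i < n - i:
            eta[i - 1] = xi[i - 1] + xi[n - i - 1]
        else:  # i == n - i, even n middle class
            eta[i - 1] = xi[i - 1]
    return SiteFrequencySpectrum(n=n, counts=eta, folded=True,
                                 polarization_log=dict(sfs.polarization_log))


def normalize(sfs: SiteFrequencySpectrum) -> np.ndarray:
    """Relative spectrum xi_i / S; sums to 1.  Requires S > 0."""
    if sfs.S == 0:
        raise ValueError("cannot normalize an empty spectrum (S = 0)")
    return sfs.counts / sfs.S


def find_modes(
    sfs: SiteFrequencySpectrum, min_separation: int = 2
) -> list[tuple[int, int]]:
    """Local maxima of the count vector, ranked by height.

    Plateaus (runs of tied counts) are merged and reported at their leftmost
    class.  Modes closer than ``min_separation`` classes keep only the higher
    one (ties resolved toward the leftmost).  Returns (class index, count)
    pairs; an all-zero spectrum yields an empty list.
    """
    y = sfs.counts
    if y.sum() == 0:
        return []
    # collapse plateaus to (start_class, value)
    plateaus: list[tuple[int, int]] = []
    start = 0
    for j in range(1, len(y) + 1):
        if j == len(y) or y[j] != y[start]:
            plateaus.append((start + 1, int(y[start])))
            start = j
    modes = []
    for k, (cls, val) in enumerate(plateaus):
        left = plateaus[k - 1][1] if k > 0 else -1
        right = plateaus[k + 1][1] if k + 1 < len(plateaus) else -1
        if val > left and val > right:
            modes.append((cls, val))
    # enforce minimum separation, keeping higher (then leftmost) mode
    modes.sort(key=lambda m: (-m[1], m[0]))
    kept: list[tuple[int, int]] = []
    for cls, val in modes:
        if all(abs(cls - c) >= min_separation for c, _ in kept):
            kept.append((cls, val))
    kept.sort(key=lambda m: (-m[1], m[0]))
    return kept


def write_sfs(sfs: SiteFrequencySpectrum, path: str | Path) -> None:
    """Two-column TSV (class, count) with a provenance header comment."""
    log = ";".join(f"{k}={v}" for k, v in sorted(sfs.polarization_log.items()))
    with open(path, "w") as fh:
        fh.write(f"# n={sfs.n} folded={int(sfs.folded)} S={sfs.S} "
                 f"polarization={log}\n")
        fh.write("class\tcount\n")
        for i, c in zip(sfs.classes, sfs.counts):
            fh.write(f"{i}\t{c}\n")


def read_sfs(path: str | Path) -> SiteFrequencySpectrum:
    """Read a spectrum written by :func:`write_sfs`."""
    n = None
    folded = False
    log: dict[str, int] = {}
    counts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("n="):
                        n = int(tok[2:])
                    elif tok.startswith("folded="):
                        folded = bool(int(tok[7:]))
                    elif tok.startswith("polarization="):
                        for kv in tok[len("polarization="):].split(";"):
                            if "=" in kv:
                                k, v = kv.split("=")
                                log[k] = int(v)
                continue
            if line.startswith("class"):
                continue
            _, c = line.split("\t")
            counts.append(int(c))
    if n is None:
        raise ValueError(f"no 'n=' header in SFS file {path}")
    return SiteFrequencySpectrum(n=n, counts=np.array(counts, dtype=int),
                                 folded=folded, polarization_log=log)
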