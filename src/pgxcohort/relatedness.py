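"""Pairwise IBD estimation and greedy pruning to an unrelated subset.

The genome-wide IBD proportion pi between two diploid samples is
estimated with the classic method-of-moments IBS->IBD decomposition
(as popularized by PLINK's --genome): observed identity-by-state counts
per pair are compared with their allele-frequency expectations under
IBD = 0, 1 and 2 sharing, giving probabilities Z0, Z1, Z2 and

    pi-hat = Z1 / 2 + Z2,   clipped to [0, 1].

Pruning follows a deterministic greedy rule: among pairs with pi above
the threshold, trio offspring are removed first; afterwards the sample
with the largest summed pi over remaining flagged pairs is removed
repeatedly (ties broken by sample identifier) until no flagged pair
remains, so the retained set has max pairwise pi <= threshold by
construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import MISSING, CohortGenotypes

__all__ = [
    "PiMatrix",
    "PedigreeInfo",
    "RelatednessError",
    "estimate_pairwise_pi",
    "prune_related",
    "write_pi_matrix",
    "read_pedigree",
    "write_pedigree",
]

MIN_MARKERS = 50


class RelatednessError(ValueError):
    pass


@dataclass
class PiMatrix:
    samples: list[str]
    pi: np.ndarray  # symmetric, diagonal 1, values in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.pi.shape != (n, n):
            raise RelatednessError("pi matrix shape mismatch")
        if not np.allclose(self.pi, self.pi.T):
            raise RelatednessError("pi matrix must be symmetric")
        if not np.allclose(np.diag(self.pi), 1.0):
            raise RelatednessError("pi diagonal must be 1")
        if self.pi.min() < -1e-9 or self.pi.max() > 1 + 1e-9:
            raise RelatednessError("pi values must lie in [0, 1]")

    def value(self, a: str, b: str) -> float:
        i, j = self.samples.index(a), self.samples.index(b)
        return float(self.pi[i, j])


@dataclass
class PedigreeInfo:
    trios: list[tuple[str, str, str]]  # (father, mother, child)

    def __post_init__(self) -> None:
        for f, m, c in self.trios:
            if c in (f, m):
                raise RelatednessError(f"child {c} equals a parent")

    @property
    def children(self) -> set[str]:
        return {c for _, _, c in self.trios}


def estimate_pairwise_pi(
    cohort: CohortGenotypes, marker_subset: Sequence[int] | None = None
) -> PiMatrix:
    """Method-of-moments pi-hat for every sample pair.

    ``marker_subset`` selects marker indices (default: all).  Monomorphic
    markers are uninformative and dropped; fewer than 50 usable markers is
    an error.  Allele frequencies are taken from the cohort itself.
    """
    idx = np.arange(cohort.n_markers) if marker_subset is None else np.asarray(marker_subset)
    hap = cohort.haplotypes[:, idx, :]
    dos = hap.astype(float).sum(axis=2)  # (n, m); negative where missing
    miss = (hap == MISSING).any(axis=2)
    dos[miss] = np.nan

    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0  # ALT frequency per marker
    informative = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    dos = dos[:, informative]
    p = p[informative]
    m = p.size
    if m < MIN_MARKERS:
        raise RelatednessError(
            f"insufficient markers for IBD estimation ({m} < {MIN_MARKERS})"
        )
    q = 1.0 - p

    n = cohort.n_samples
    valid = ~np.isnan(dos)
    d = np.nan_to_num(dos)

    # one-hot genotype indicator matrices (n, m)
    g0 = ((d == 0) & valid).astype(float)
    g1 = ((d == 1) & valid).astype(float)
    g2 = ((d == 2) & valid).astype(float)

    # pairwise IBS counts over jointly observed markers
    i0 = g0 @ g2.T + g2 @ g0.T
    i2 = g0 @ g0.T + g1 @ g1.T + g2 @ g2.T
    vf = valid.astype(float)
    m_pair = vf @ vf.T
    i1 = m_pair - i0 - i2

    # per-marker IBS-class expectations under IBD = 0 and 1
    e0_z0 = 2.0 * p**2 * q**2
    e1_z0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e2_z0 = 1.0 - e0_z0 - e1_z0
    e1_z1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e2_z1 = 1.0 - e1_z1

    # pair-specific expectation sums restricted to jointly observed markers
    s0_z0 = (vf * e0_z0) @ vf.T
    s1_z0 = (vf * e1_z0) @ vf.T
    s2_z0 = (vf * e2_z0) @ vf.T
    s1_z1 = (vf * e1_z1) @ vf.T
    s2_z1 = (vf * e2_z1) @ vf.T

    with np.errstate(divide="ignore", invalid="ignore"):
        z0 = np.where(s0_z0 > 0, i0 / s0_z0, 0.0)
        z1 = np.where(s1_z1 > 0, (i1 - z0 * s1_z0) / s1_z1, 0.0)
    z2 = np.where(m_pair > 0, (i2 - z0 * s2_z0 - z1 * s2_z1) / np.maximum(m_pair, 1), 0.0)

    pi = np.clip(z1 / 2.0 + z2, 0.0, 1.0)
    np.fill_diagonal(pi, 1.0)
    pi = (pi + pi.T) / 2.0
    return PiMatrix(samples=list(cohort.samples), pi=pi)


def prune_related(
    pi: PiMatrix, pedigree: PedigreeInfo | None = None, threshold: float = 0.05
) -> list[str]:
    """Greedy pruning to a subset with no pairwise pi above the threshold.

    Trio offspring involved in any flagged pair are removed first; then the
    sample with the largest summed pi over remaining flagged pairs is
    removed iteratively (summed pi recomputed after each removal, ties by
    identifier order).
    """
    if not 0.0 < threshold < 1.0:
        raise RelatednessError("threshold must lie in (0, 1)")
    samples = list(pi.samples)
    mat = pi.pi
    n = len(samples)
    flagged = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if mat[i, j] > threshold
    }
    removed: set[int] = set()

    def active_pairs() -> set[tuple[int, int]]:
        return {(i, j) for i, j in flagged if i not in removed and j not in removed}

    children = pedigree.children if pedigree is not None else set()
    child_idx = {i for i, s in enumerate(samples) if s in children}
    # offspring first, in identifier order for determinism
    for i in sorted(child_idx, key=lambda k: samples[k]):
        if any(i in pair for pair in active_pairs()):
            removed.add(i)

    while True:
        pairs = active_pairs()
        if not pairs:
            break
        summed = np.zeros(n)
        for i, j in pairs:
            summed[i] += mat[i, j]
            summed[j] += mat[i, j]
        candidates = sorted(
            (i for i in range(n) if summed[i] > 0),
            key=lambda i: (-summed[i], samples[i]),
        )
        removed.add(candidates[0])

    return [s for i, s in enumerate(samples) if i not in removed]


# ---------------------------------------------------------------------------
# plain-text persistence
# ---------------------------------------------------------------------------


def write_pi_matrix(pi: PiMatrix, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_i", "sample_j", "pi"])
        for i in range(len(pi.samples)):
            for j in range(i + 1, len(pi.samples)):
                w.writerow([pi.samples[i], pi.samples[j], f"{pi.pi[i, j]:.6f}"])


def read_pedigree(path: str | Path) -> PedigreeInfo:
    trios = []
    with Path(path).open(newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "father":
                continue
            if len(row) != 3:
                raise RelatednessError(f"pedigree rows need 3 columns, got {row}")
            trios.append((row[0], row[1], row[2]))
    return PedigreeInfo(trios=trios)


def write_pedigree(ped: PedigreeInfo, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["father", "mother", "child"])
        for trio in ped.trios:
            w.writerow(trio)
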