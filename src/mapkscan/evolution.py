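"""Tajima's neutrality test and relative-rate test on amino-acid alignments.

Tajima's D contrasts two estimators of the population mutation parameter:
the mean pairwise diversity k_hat (via pi = k_hat / n) and the
segregating-site estimator S / a1, standardized by the variance terms of the
original method:

    D = (k_hat - S/a1) / sqrt(e1*S + e2*S*(S-1))

with a1 = sum_{i<m} 1/i, a2 = sum_{i<m} 1/i^2, b1 = (m+1)/(3(m-1)),
b2 = 2(m^2+m+3)/(9m(m-1)), c1 = b1 - 1/a1,
c2 = b2 - (m+2)/(a1*m) + a2/a1^2, e1 = c1/a1, e2 = c2/(a1^2+a2).

The relative-rate test compares lineage-specific substitution counts of two
ingroup sequences A and B against an outgroup C over complete-deletion
sites: chi2 = (uA - uB)^2 / (uA + uB) on 1 degree of freedom.

Gap handling follows the two standard modes: pairwise deletion (drop missing
data per sequence pair) and complete deletion (drop any column with missing
data). The ambiguity codes X, B and Z count as missing, like gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .seqio import Alignment

#: Characters treated as missing data in both deletion modes.
MISSING = frozenset("-XBZ")

PAIRWISE = "pairwise_deletion"
COMPLETE = "complete_deletion"


class DegenerateStatisticError(ValueError):
    """The requested statistic is undefined for this input (e.g. S = 0)."""


def _encode(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Alignment as (m, n) byte matrix plus a boolean missing-data mask."""
    mat = np.frombuffer(
        "".join(aln.sequences).encode("ascii"), dtype="S1"
    ).reshape(len(aln), aln.n_sites)
    missing = np.isin(mat, np.array([c.encode() for c in MISSING]))
    return mat, missing


def _check_gap_mode(gap_mode: str) -> None:
    if gap_mode not in (PAIRWISE, COMPLETE):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")


def pairwise_differences(
    aln: Alignment, gap_mode: str = PAIRWISE
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (differences, sites compared) matrices.

    Under pairwise deletion a pair is compared over sites where both
    residues are present; under complete deletion only over sites where
    every sequence in the alignment is present. Pairs with zero comparable
    sites show sites == 0; callers must treat them as missing estimates.
    """
    _check_gap_mode(gap_mode)
    mat, missing = _encode(aln)
    m = len(aln)
    if gap_mode == COMPLETE:
        usable = ~missing.any(axis=0)
        mat = mat[:, usable]
        missing = missing[:, usable]
    diffs = np.zeros((m, m), dtype=int)
    sites = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            both = ~missing[i] & ~missing[j]
            nc = int(both.sum())
            nd = int((mat[i, both] != mat[j, both]).sum())
            diffs[i, j] = diffs[j, i] = nd
            sites[i, j] = sites[j, i] = nc
    return diffs, sites


def segregating_sites(aln: Alignment, gap_mode: str = PAIRWISE) -> tuple[int, int]:
    """(S, n_used): segregating-site count and the site denominator.

    Complete deletion drops any column containing missing data before
    counting, and n_used is the number of retained columns. Pairwise
    deletion keeps all columns (n_used = n_sites); a column segregates when
    its present residues show >= 2 states.
    """
    _check_gap_mode(gap_mode)
    mat, missing = _encode(aln)
    if gap_mode == COMPLETE:
        usable = ~missing.any(axis=0)
        mat = mat[:, usable]
        n_used = int(usable.sum())
        cols = range(n_used)
        s = sum(1 for j in cols if len(set(mat[:, j].tobytes())) >= 2)
        return s, n_used
    n_used = aln.n_sites
    s = 0
    for j in range(n_used):
        present = mat[~missing[:, j], j]
        if len(set(present.tobytes())) >= 2:
            s += 1
    return s, n_used


def filter_site_coverage(aln: Alignment, max_missing_frac: float = 0.05) -> Alignment:
    """Drop columns whose missing-data fraction exceeds ``max_missing_frac``
    (default: 95% site coverage)."""
    _, missing = _encode(aln)
    frac = missing.mean(axis=0)
    keep = [j for j in range(aln.n_sites) if frac[j] <= max_missing_frac]
    if not keep:
        raise DegenerateStatisticError("no columns pass the coverage filter")
    return aln.take(keep)


@dataclass(frozen=True)
class TajimaCoefficients:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_coefficients(m: int) -> TajimaCoefficients:
    """Variance coefficients of Tajima's D for ``m`` sequences (m >= 4)."""
    if m < 4:
        raise ValueError("Tajima's D variance requires m >= 4")
    a1 = sum(1.0 / i for i in range(1, m))
    a2 = sum(1.0 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m**2 + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaCoefficients(a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass(frozen=True)
class TajimaDResult:
    """Tajima neutrality-test summary.

    m sequences over n sites; S segregating sites; p_s = S/n;
    theta = p_s/a1 (per site); pi = k_hat/n; k_hat mean pairwise
    differences; D the standardized statistic.
    """

    m: int
    n: int
    S: int
    p_s: float
    theta: float
    pi: float
    k_hat: float
    D: float
    coefficients: TajimaCoefficients

    def summary(self) -> str:
        c = self.coefficients
        lines = [
            "Tajima's test of neutrality (amino acids, pairwise deletion)",
            f"  m (sequences)         {self.m}",
            f"  n (sites)             {self.n}",
            f"  S (segregating sites) {self.S}",
            f"  p_s = S/n             {self.p_s:.6f}",
            f"  Theta = p_s/a1        {self.theta:.6f}",
            f"  pi (diversity)        {self.pi:.6f}",
            f"  k_hat (mean diffs)    {self.k_hat:.6f}",
            f"  D                     {self.D:.6f}",
            f"  a1={c.a1:.6f} a2={c.a2:.6f} e1={c.e1:.6f} e2={c.e2:.6f}",
        ]
        return "\n".join(lines)


def _tajima_d_core(m: int, S: int, n: int, k_hat: float) -> TajimaDResult:
    coeff = tajima_coefficients(m)
    if S < 1:
        raise DegenerateStatisticError("Tajima's D undefined for S = 0")
    var = coeff.e1 * S + coeff.e2 * S * (S - 1)
    d = (k_hat - S / coeff.a1) / math.sqrt(var)
    p_s = S / n
    return TajimaDResult(
        m=m,
        n=n,
        S=S,
        p_s=p_s,
        theta=p_s / coeff.a1,
        pi=k_hat / n,
        k_hat=k_hat,
        D=d,
        coefficients=coeff,
    )


def tajima_d(aln: Alignment) -> TajimaDResult:
    """Tajima's D on an amino-acid alignment, pairwise deletion.

    k_hat is the mean over sequence pairs of raw pairwise differences
    (pairs with no comparable sites are excluded from the mean); S counts
    columns whose present residues show >= 2 states. Raises for m < 4 or
    S = 0.
    """
    m = len(aln)
    if m < 4:
        raise ValueError("Tajima's D requires at least 4 sequences")
    S, n_used = segregating_sites(aln, PAIRWISE)
    diffs, sites = pairwise_differences(aln, PAIRWISE)
    iu = np.triu_indices(m, k=1)
    comparable = sites[iu] > 0
    if not comparable.any():
        raise DegenerateStatisticError("no sequence pair has comparable sites")
    k_hat = float(diffs[iu][comparable].mean())
    return _tajima_d_core(m, S, n_used, k_hat)


def tajima_d_from_summary(m: int, S: int, n: int, pi: float) -> TajimaDResult:
    """Tajima's D from published summary statistics.

    ``pi`` is per-site diversity; k_hat is reconstructed as pi * n. Useful
    for verifying printed tables where only (m, S, p_s, pi) are reported —
    n itself is recovered as round(S / p_s) when unprinted.
    """
    if not 0 <= pi <= 1:
        raise ValueError("pi must be a per-site value in [0, 1]")
    if n < S:
        raise ValueError("n must be >= S")
    return _tajima_d_core(m, S, n, pi * n)


@dataclass(frozen=True)
class RelRateResult:
    """Tajima relative-rate site partition and test for (A, B | outgroup C).

    Counts are over complete-deletion sites: identical_all (all three
    equal), unique_a (B=C != A), unique_b (A=C != B), unique_c (A=B != C),
    divergent_all (all pairwise distinct). For three gap-free sequences
    these five categories are exhaustive, so shared_pair_remainder is 0 by
    construction and kept only to make the conservation identity explicit.
    chi2/p are filled by :func:`relative_rate_test`.
    """

    id_a: str
    id_b: str
    id_c: str
    n_used: int
    identical_all: int
    divergent_all: int
    unique_a: int
    unique_b: int
    unique_c: int
    shared_pair_remainder: int = 0
    chi2: float | None = None
    df: int = 1
    p: float | None = None
    no_information: bool = False

    def summary(self) -> str:
        lines = [
            "Tajima's relative rate test (amino acids, complete deletion)",
            f"  A = {self.id_a}, B = {self.id_b}, outgroup C = {self.id_c}",
            f"  Sites used                      {self.n_used}",
            f"  Identical sites in all three    {self.identical_all}",
            f"  Divergent sites in all three    {self.divergent_all}",
            f"  Unique differences in A         {self.unique_a}",
            f"  Unique differences in B         {self.unique_b}",
            f"  Unique differences in C         {self.unique_c}",
        ]
        if self.chi2 is not None:
            lines += [
                f"  X^2 (df {self.df})                      {self.chi2:.2f}",
                f"  P-value                         {self.p:.5f}",
            ]
        return "\n".join(lines)


def relative_rate_counts(
    aln3: Alignment, outgroup_id: str | None = None
) -> RelRateResult:
    """Site partition for the relative-rate test on exactly 3 sequences.

    ``outgroup_id`` names sequence C (default: the third record); the other
    two keep their input order as A and B. Complete deletion is applied
    first; an empty usable region raises.
    """
    if len(aln3) != 3:
        raise ValueError("relative-rate test requires exactly 3 sequences")
    ids = list(aln3.ids)
    if outgroup_id is None:
        outgroup_id = ids[2]
    if outgroup_id not in ids:
        raise ValueError(f"outgroup id {outgroup_id!r} not in alignment")
    ingroup = [i for i in ids if i != outgroup_id]
    order = [ingroup[0], ingroup[1], outgroup_id]
    seqs = {rid: seq for rid, seq in aln3.records}
    a, b, c = (seqs[r] for r in order)
    identical = divergent = ua = ub = uc = 0
    n_used = 0
    for x, y, z in zip(a, b, c):
        if x in MISSING or y in MISSING or z in MISSING:
            continue
        n_used += 1
        if x == y == z:
            identical += 1
        elif y == z:
            ua += 1
        elif x == z:
            ub += 1
        elif x == y:
            uc += 1
        else:
            divergent += 1
    if n_used == 0:
        raise DegenerateStatisticError("no sites remain after complete deletion")
    return RelRateResult(
        id_a=order[0],
        id_b=order[1],
        id_c=order[2],
        n_used=n_used,
        identical_all=identical,
        divergent_all=divergent,
        unique_a=ua,
        unique_b=ub,
        unique_c=uc,
        shared_pair_remainder=n_used - (identical + divergent + ua + ub + uc),
    )


def chi2_upper_tail(x: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-square distribution with df = 1,
    via the closed form erfc(sqrt(x/2))."""
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df != 1:
        raise ValueError("only df = 1 is supported")
    return math.erfc(math.sqrt(x / 2.0))


def relative_rate_test(counts: RelRateResult) -> RelRateResult:
    """Fill in chi2 = (uA - uB)^2/(uA + uB), df = 1 and the upper-tail p.

    When uA + uB = 0 there is no rate information: chi2 = 0, p = 1 and the
    result is flagged ``no_information``.
    """
    ua, ub = counts.unique_a, counts.unique_b
    if ua + ub == 0:
        return replace(counts, chi2=0.0, p=1.0, no_information=True)
    chi2 = (ua - ub) ** 2 / (ua + ub)
    return replace(counts, chi2=chi2, p=chi2_upper_tail(chi2), no_information=False)


def rel_rate_chi2(unique_a: int, unique_b: int) -> tuple[float, float]:
    """(chi2, p) from the two ingroup unique-difference counts alone."""
    res = relative_rate_test(
        RelRateResult(
            id_a="A",
            id_b="B",
            id_c="C",
            n_used=unique_a + unique_b,
            identical_all=0,
            divergent_all=0,
            unique_a=unique_a,
            unique_b=unique_b,
            unique_c=0,
        )
    )
    return res.chi2, res.p
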