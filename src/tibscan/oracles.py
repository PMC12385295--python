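"""Brute-force reference implementations used to validate the fast paths.

Each function here recomputes a statistic by the most direct route
available — exhaustive pair counting, exact rational enumeration, or
re-scanning — deliberately sharing no code with the production
implementations in :mod:`hapstats`, :mod:`qc`, :mod:`freqstats` and
:mod:`regions`.  They are quadratic-or-worse and meant for small inputs.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from .io import MISSING, GenotypeMatrix


def ehh_pair_counting(alleles: np.ndarray, core: int, carriers: np.ndarray,
                      target: int, include_core: bool) -> float:
    """EHH by checking identity of every carrier pair over [core..target].

    *include_core* mirrors the pooled-core convention (the core site's own
    allele is part of the extended haplotype when carriers are pooled).
    """
    lo, hi = min(core, target), max(core, target)
    if not include_core:
        if target >= core:
            lo = core + 1
        else:
            hi = core - 1
    n = len(carriers)
    if n < 2:
        raise ValueError("need >= 2 carriers")
    ident = 0
    for a in range(n):
        for b in range(a + 1, n):
            if lo > hi or np.array_equal(
                alleles[carriers[a], lo:hi + 1], alleles[carriers[b], lo:hi + 1]
            ):
                ident += 1
    return ident / (n * (n - 1) / 2)


def trapezoid_ihh(offsets, values, cutoff: float) -> float:
    """One-sided iHH by explicit trapezoid summation with cutoff truncation."""
    area = 0.0
    for k in range(1, len(offsets)):
        area += (offsets[k] - offsets[k - 1]) * (values[k] + values[k - 1]) / 2
        if values[k] < cutoff:
            break
    return area


def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """HWE exact p by enumerating every genotype configuration with the
    observed allele counts, in exact rational arithmetic.

    P(a, h, b) ∝ multinomial(n; a, h, b) · 2^h; the two-sided p sums the
    probabilities of all heterozygote counts no more probable than the
    observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    if min(n_a, 2 * n - n_a) == 0:
        return 1.0
    weights = {}
    for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        b = (n_a - h) // 2
        a = n - h - b
        if a < 0 or b < 0:
            continue
        weights[h] = Fraction(comb(n, a) * comb(n - a, h) * 2**h)
    total = sum(weights.values())
    p_obs = weights[n_Aa] / total
    p = sum(w for w in weights.values() if w / total <= p_obs)
    return float(p / total)


def hudson_fst_textbook(p1: float, n1: int, p2: float, n2: int) -> float:
    """Hudson FST re-derived step by step from the published formula."""
    within1 = p1 * (1 - p1) * n1 / (n1 - 1)   # unbiased within-pop diversity
    within2 = p2 * (1 - p2) * n2 / (n2 - 1)
    between = p1 * (1 - p2) + p2 * (1 - p1)
    num = between - within1 - within2
    # algebraically identical to (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    if between == 0:
        return float("nan")
    return min(max(num / between, 0.0), 1.0)


def clump_rescan(selected, r2_fn, r2_max: float, window_bp: int):
    """Greedy clumping that re-scans every remaining SNV each iteration.

    *selected* is a list of dicts with keys chrom, pos, id, cms, site_idx;
    *r2_fn(i, j)* returns dosage r² between two site indices.  Returns a
    list of (peak_id, sorted member ids) tuples.
    """
    remaining = list(selected)
    out = []
    while remaining:
        peak = max(remaining, key=lambda s: (s["cms"], *_neg_key(s)))
        members = [peak]
        rest = []
        for s in remaining:
            if s is peak:
                continue
            r2 = r2_fn(peak["site_idx"], s["site_idx"])
            if (
                s["chrom"] == peak["chrom"]
                and abs(s["pos"] - peak["pos"]) <= window_bp
                and not np.isnan(r2)
                and r2 > r2_max
            ):
                members.append(s)
            else:
                rest.append(s)
        out.append((peak["id"], sorted(m["id"] for m in members)))
        remaining = rest
    return out


def _neg_key(s):
    # CMS ties break by ascending (chrom, pos): invert for use with max()
    return (_NegStr(s["chrom"]), -s["pos"])


class _NegStr(str):
    def __lt__(self, other):  # reversed ordering
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def dosage_r2_direct(gm: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation computed from first principles."""
    x = gm.calls[:, i]
    y = gm.calls[:, j]
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok].astype(float), y[ok].astype(float)
    if len(x) < 2:
        return float("nan")
    vx = ((x - x.mean()) ** 2).sum()
    vy = ((y - y.mean()) ** 2).sum()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).sum()
    return float(cov * cov / (vx * vy))
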