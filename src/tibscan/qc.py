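"""Sample- and variant-level quality control with per-rule accounting.

Filters mirror a standard WGS cohort workflow: samples are dropped for
excess missingness (inclusive threshold, default ≥3%) and for
heterozygosity outside mean ± 3 SD; variants are dropped, in order, as
singletons, for >5% missingness (strict), and for Hardy–Weinberg exact
p < 1e-6.  Each rule is counted on the survivors of the previous rule, so
the accounting identity ``n_in − Σ removed = n_out`` holds exactly.

A simplified method-of-moments IBD stage (PLINK-style PI_HAT from IBS
counts) flags close relatives; for each flagged pair the member with the
higher missing rate is removed greedily.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np

from .io import MISSING, GenotypeMatrix

SAMPLE_RULES = ("sample_missing", "het_outlier", "ibd")
VARIANT_RULES = ("singleton", "variant_missing", "hwe")


@dataclass
class QcReport:
    """Sequential per-rule QC accounting."""

    n_samples_in: int = 0
    n_samples_out: int = 0
    n_variants_in: int = 0
    n_variants_out: int = 0
    removed: dict = field(default_factory=dict)  # rule -> count
    thresholds: dict = field(default_factory=dict)

    def check(self) -> None:
        """Raise unless in − Σremoved = out for both samples and variants."""
        s_removed = sum(self.removed.get(r, 0) for r in SAMPLE_RULES)
        v_removed = sum(self.removed.get(r, 0) for r in VARIANT_RULES)
        if self.n_samples_in - s_removed != self.n_samples_out:
            raise ValueError("sample accounting identity violated")
        if self.n_variants_in - v_removed != self.n_variants_out:
            raise ValueError("variant accounting identity violated")

    def to_dict(self) -> dict:
        return {
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_variants_in": self.n_variants_in,
            "n_variants_out": self.n_variants_out,
            "removed": dict(self.removed),
            "thresholds": dict(self.thresholds),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def sequential_accounting(n_in: int, removals) -> int:
    """Apply sequential per-rule removals to a starting count.

    Each rule removes a count from the survivors of the previous rule;
    returns the final retained count and validates non-negativity.
    """
    n = int(n_in)
    for r in removals:
        r = int(r)
        if r < 0 or r > n:
            raise ValueError(f"removal count {r} out of range for {n} remaining")
        n -= r
    return n


def filter_samples(gm: GenotypeMatrix, miss_thresh: float = 0.03,
                   het_sd: float = 3.0, exclude: set | None = None):
    """Drop samples by missingness (≥ miss_thresh, inclusive) then by
    heterozygosity-rate outliers (outside mean ± het_sd·SD on the samples
    remaining after the missingness rule).  *exclude* accepts an external
    ID list (e.g. PCA outliers) applied first under rule ``exclude``.

    Returns ``(filtered_gm, fragment)`` where the fragment maps rule name
    to removal count.
    """
    frag = {}
    keep = np.arange(gm.n_samples)
    if exclude:
        mask = np.array([s not in exclude for s in gm.sample_ids])
        frag["exclude"] = int((~mask).sum())
        keep = keep[mask]

    miss = gm.missing_fraction_per_sample()[keep]
    ok = miss < miss_thresh
    frag["sample_missing"] = int((~ok).sum())
    keep = keep[ok]

    calls = gm.calls[keep]
    nonmiss = (calls != MISSING).sum(axis=1)
    het = (calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)
    mu = float(np.nanmean(het_rate))
    sd = float(np.nanstd(het_rate, ddof=0))
    if sd > 0:
        ok = np.abs(het_rate - mu) <= het_sd * sd
    else:
        ok = np.ones(len(keep), dtype=bool)  # degenerate SD: nobody is an outlier
    frag["het_outlier"] = int((~ok).sum())
    keep = keep[ok]

    if len(keep) == 0:
        raise ValueError("sample QC removed every sample")
    return gm.take_samples(keep), frag


@lru_cache(maxsize=100_000)
def _hwe_het_distribution(n: int, n_minor: int) -> tuple:
    """Exact conditional distribution of heterozygote count given allele counts.

    For n diploids with n_minor copies of the rarer allele, the number of
    heterozygotes h (same parity as n_minor) has probability proportional to
    2^h · n! / (n_AA! · h! · n_aa!); computed in exact rational arithmetic.
    Returns (h_values, probabilities as floats).
    """
    n_major = 2 * n - n_minor
    hs = list(range(n_minor % 2, n_minor + 1, 2))
    weights = []
    for h in hs:
        n_rr = (n_minor - h) // 2  # minor-allele homozygotes
        n_cc = (n_major - h) // 2
        if n_cc < 0:
            weights.append(0)
            continue
        w = Fraction(2) ** h * Fraction(
            comb(n, h) * comb(n - h, n_rr)
        )
        weights.append(w)
    total = sum(weights)
    probs = tuple(float(w / total) for w in weights)
    return tuple(hs), probs


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy–Weinberg exact test p-value.

    Sums the conditional probabilities (given the allele counts) of every
    heterozygote count whose probability does not exceed that of the
    observed count.  Monomorphic sites return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    n_minor = min(n_a, n_A)
    if n_minor == 0:
        return 1.0
    hs, probs = _hwe_het_distribution(n, n_minor)
    p_obs = probs[hs.index(n_Aa)]
    # tolerance guards against float round-off in ties
    p = sum(pr for pr in probs if pr <= p_obs * (1 + 1e-12))
    return min(1.0, p)


def filter_variants(gm: GenotypeMatrix, singleton: bool = True,
                    miss_thresh: float = 0.05, hwe_thresh: float = 1e-6):
    """Sequential variant filters: ① singletons, ② missingness > miss_thresh
    (strict), ③ HWE exact p < hwe_thresh on the pooled sample.  Each rule is
    counted on the survivors of the previous one."""
    frag = {}
    calls = gm.calls
    nonmiss = calls != MISSING

    keep = np.ones(gm.n_sites, dtype=bool)
    if singleton:
        alt = np.where(nonmiss, calls, 0).sum(axis=0)
        tot = 2 * nonmiss.sum(axis=0)
        minor = np.minimum(alt, tot - alt)
        is_singleton = minor == 1
        frag["singleton"] = int(is_singleton.sum())
        keep &= ~is_singleton
    else:
        frag["singleton"] = 0

    miss_frac = (~nonmiss).mean(axis=0)
    too_missing = keep & (miss_frac > miss_thresh)
    frag["variant_missing"] = int(too_missing.sum())
    keep &= ~too_missing

    hwe_bad = np.zeros(gm.n_sites, dtype=bool)
    idx = np.flatnonzero(keep)
    for j in idx:
        col = calls[:, j]
        n_aa = int((col == 2).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        if n_AA + n_Aa + n_aa == 0:
            continue
        if hwe_exact_p(n_AA, n_Aa, n_aa) < hwe_thresh:
            hwe_bad[j] = True
    frag["hwe"] = int(hwe_bad.sum())
    keep &= ~hwe_bad

    return gm.take_sites(keep), frag


def hwe_filter_per_population(gm: GenotypeMatrix, popmap, hwe_thresh: float = 1e-6):
    """Alternative HWE rule: a site fails if it violates HWE in any population."""
    pops = {}
    for i, s in enumerate(gm.sample_ids):
        pops.setdefault(popmap[s], []).append(i)
    bad = np.zeros(gm.n_sites, dtype=bool)
    for rows in pops.values():
        sub = gm.calls[rows]
        for j in range(gm.n_sites):
            col = sub[:, j]
            counts = [(col == g).sum() for g in (0, 1, 2)]
            if sum(counts) and hwe_exact_p(counts[0], counts[1], counts[2]) < hwe_thresh:
                bad[j] = True
    return gm.take_sites(~bad), {"hwe": int(bad.sum())}


def _pi_hat_matrix(calls: np.ndarray) -> np.ndarray:
    """PLINK-style method-of-moments PI_HAT for every sample pair.

    IBS0/1/2 counts over jointly non-missing sites are compared with their
    expectations under IBD state Z=0/1/2 given sample allele frequencies;
    PI_HAT = P(Z=1)/2 + P(Z=2), with the probabilities clipped to [0, 1].
    """
    n, m = calls.shape
    nonmiss = calls != MISSING
    alt = np.where(nonmiss, calls, 0).sum(axis=0)
    tot = 2 * nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    q = 1.0 - p
    informative = (tot > 0) & (p > 0) & (p < 1)

    # per-site expectations under each IBD state (no finite-sample correction)
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibs1 = 2 * p**2 * q + 2 * p * q**2
    e1_ibs2 = 1.0 - e1_ibs1
    pi = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = nonmiss[i] & nonmiss[j] & informative
        if both.sum() < 2:
            continue
        d = np.abs(calls[i, both].astype(int) - calls[j, both].astype(int))
        ibs0 = float((d == 2).sum())
        ibs1 = float((d == 1).sum())
        E0_0 = e0_ibs0[both].sum()
        E0_1 = e0_ibs1[both].sum()
        E0_2 = e0_ibs2[both].sum()
        E1_1 = e1_ibs1[both].sum()
        E1_2 = e1_ibs2[both].sum()
        M = float(both.sum())
        ibs2 = M - ibs0 - ibs1
        z0 = ibs0 / E0_0 if E0_0 > 0 else 0.0
        z0 = min(max(z0, 0.0), 1.0)
        z1 = (ibs1 - z0 * E0_1) / E1_1 if E1_1 > 0 else 0.0
        z1 = min(max(z1, 0.0), 1.0 - z0)
        z2 = (ibs2 - z0 * E0_2 - z1 * E1_2) / M
        z2 = min(max(z2, 0.0), 1.0 - z0 - z1)
        val = z1 / 2.0 + z2
        pi[i, j] = pi[j, i] = min(max(val, 0.0), 1.0)
    return pi


def ibd_prune(gm: GenotypeMatrix, pi_hat_thresh: float = 0.25, popmap=None):
    """Greedy relatedness pruning.

    Computes pairwise PI_HAT; while any pair exceeds the threshold, removes
    the member of the worst pair with the higher missing rate (ties: the
    later sample).  When *popmap* is given, relatedness is estimated within
    populations only (same-population pairs, population allele
    frequencies); allele-frequency divergence between populations otherwise
    inflates PI_HAT for every cross-population pair (a Wahlund-type
    artifact).  Returns ``(kept_sample_ids, flagged_pairs)`` where
    flagged_pairs lists ``(id_i, id_j, pi_hat)`` for every pair over the
    threshold in the original matrix.
    """
    if gm.n_samples < 2:
        raise ValueError("ibd_prune needs at least two samples")
    if popmap is None:
        pi = _pi_hat_matrix(gm.calls)
    else:
        pi = np.zeros((gm.n_samples, gm.n_samples))
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(gm.sample_ids):
            groups.setdefault(popmap[s], []).append(i)
        for rows in groups.values():
            if len(rows) < 2:
                continue
            rows = np.array(rows)
            sub = _pi_hat_matrix(gm.calls[rows])
            pi[np.ix_(rows, rows)] = sub
    miss = gm.missing_fraction_per_sample()
    flagged = [
        (gm.sample_ids[i], gm.sample_ids[j], float(pi[i, j]))
        for i, j in itertools.combinations(range(gm.n_samples), 2)
        if pi[i, j] > pi_hat_thresh
    ]
    active = np.ones(gm.n_samples, dtype=bool)
    while True:
        sub = np.where(np.outer(active, active), pi, 0.0)
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= pi_hat_thresh:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        drop = j if (miss[j], j) >= (miss[i], i) else i
        active[drop] = False
    kept = [s for s, a in zip(gm.sample_ids, active) if a]
    return kept, flagged


def run_qc(gm: GenotypeMatrix, popmap=None, *, sample_miss: float = 0.03,
           het_sd: float = 3.0, ibd_pi_hat: float | None = 0.25,
           singleton: bool = True, var_miss: float = 0.05,
           hwe_p: float = 1e-6, exclude: set | None = None):
    """Full QC: sample filters first (missingness, het outliers, IBD), then
    variant filters (singletons, missingness, HWE).  Returns the filtered
    matrix and a validated :class:`QcReport`."""
    report = QcReport(
        n_samples_in=gm.n_samples,
        n_variants_in=gm.n_sites,
        thresholds={
            "sample_miss": sample_miss,
            "het_sd": het_sd,
            "ibd_pi_hat": ibd_pi_hat,
            "var_miss": var_miss,
            "hwe_p": hwe_p,
        },
    )
    gm, frag = filter_samples(gm, sample_miss, het_sd, exclude=exclude)
    report.removed.update({k: v for k, v in frag.items() if k != "exclude"})
    if frag.get("exclude"):
        report.n_samples_in -= frag["exclude"]  # external exclusions precede QC
    if ibd_pi_hat is not None and gm.n_samples >= 2:
        kept, _ = ibd_prune(gm, ibd_pi_hat, popmap=popmap)
        report.removed["ibd"] = gm.n_samples - len(kept)
        idx = [i for i, s in enumerate(gm.sample_ids) if s in set(kept)]
        gm = gm.take_samples(np.array(idx))
    else:
        report.removed["ibd"] = 0
    report.n_samples_out = gm.n_samples

    gm, frag = filter_variants(gm, singleton, var_miss, hwe_p)
    report.removed.update(frag)
    report.n_variants_out = gm.n_sites
    report.check()
    return gm, report
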