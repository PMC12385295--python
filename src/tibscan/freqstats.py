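"""Per-SNV allele-frequency selection statistics: DAF, ΔDAF, FST, PBS.

The ancestral allele is taken to be the REF allele, so the derived allele
frequency (DAF) is simply the ALT frequency.  ΔDAF contrasts the focal
population T against the two outgroups S and H:

    ΔDAF = ((DAF_T − DAF_S) + (DAF_T − DAF_H)) / 2

The population branch statistic combines the three pairwise FST values to
isolate differentiation on the focal branch:

    PBS = (FST_TH + FST_TS − FST_SH) / 2            (linear mode)

with an optional canonical mode applying the same combination to the
branch-length transform T = −ln(1 − FST).  Per-SNV FST uses Hudson's
estimator by default (low bias under unequal sample sizes); a per-site
Weir–Cockerham estimator is available as an option.  Negative per-SNV FST
estimates are clipped to 0 before entering PBS.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

POPS = ("T", "S", "H")


def alt_freq(calls: np.ndarray):
    """ALT-allele frequency and non-missing allele count per site.

    Returns ``(freq, n_alleles)``; freq is NaN where every call is missing.
    """
    calls = np.atleast_2d(calls)
    nonmiss = calls != MISSING
    n_alleles = 2 * nonmiss.sum(axis=0)
    alt = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return freq, n_alleles


def split_by_population(gm: GenotypeMatrix, popmap) -> dict[str, np.ndarray]:
    """Row-index lookup per population label."""
    pops: dict[str, list[int]] = {}
    for i, s in enumerate(gm.sample_ids):
        pops.setdefault(popmap[s], []).append(i)
    return {k: np.array(v) for k, v in pops.items()}


def daf_table(gm: GenotypeMatrix, popmap) -> pd.DataFrame:
    """Per-SNV derived-allele frequencies and allele counts for T, S, H."""
    idx = split_by_population(gm, popmap)
    missing = [p for p in POPS if p not in idx]
    if missing:
        raise ValueError(f"population map lacks populations: {missing}")
    out = {}
    for p in POPS:
        freq, n = alt_freq(gm.calls[idx[p]])
        out[f"daf_{p}"] = freq
        out[f"n_{p}"] = n
    return pd.DataFrame(out)


def delta_daf(daf_t, daf_s, daf_h):
    """Mean focal-population DAF excess over the two outgroups; NaN propagates."""
    daf_t = np.asarray(daf_t, dtype=float)
    daf_s = np.asarray(daf_s, dtype=float)
    daf_h = np.asarray(daf_h, dtype=float)
    return ((daf_t - daf_s) + (daf_t - daf_h)) / 2.0


def hudson_fst(p1, n1, p2, n2):
    """Hudson's per-SNV FST estimator from allele frequencies and counts.

    numerator = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    denominator = p1(1−p2) + p2(1−p1)

    n1/n2 are allele (chromosome) counts; undefined (NaN) when either count
    is < 2 or the denominator is 0 (both populations monomorphic for the
    same allele).  Clipped to [0, 1].
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num / den
    fst = np.where((n1 < 2) | (n2 < 2) | (den == 0), np.nan, fst)
    return np.clip(fst, 0.0, 1.0)


def weir_cockerham_fst(calls1: np.ndarray, calls2: np.ndarray):
    """Per-SNV two-population Weir–Cockerham θ from genotype calls.

    Uses the standard variance-components estimator with observed
    heterozygosity; NaN where undefined.  Clipped to [0, 1].
    """
    r = 2.0
    stats = []
    for calls in (calls1, calls2):
        nonmiss = calls != MISSING
        n_i = nonmiss.sum(axis=0).astype(float)  # diploid counts
        alt = np.where(nonmiss, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * np.maximum(n_i, 1)), np.nan)
            h_i = np.where(n_i > 0, (calls == 1).sum(axis=0) / np.maximum(n_i, 1), np.nan)
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        theta = a / (a + b + c)
    theta = np.where((n1 < 1) | (n2 < 1) | ((a + b + c) == 0), np.nan, theta)
    return np.clip(theta, 0.0, 1.0)


def pbs(fst_th, fst_ts, fst_sh, mode: str = "linear"):
    """Population branch statistic for the focal population T.

    ``linear`` combines the raw FST values; ``log`` first applies the
    branch-length transform −ln(1−FST) (FST pre-clipped to ≤ 1−1e-9).
    NaN in any component propagates.
    """
    fst_th = np.asarray(fst_th, dtype=float)
    fst_ts = np.asarray(fst_ts, dtype=float)
    fst_sh = np.asarray(fst_sh, dtype=float)
    if mode == "linear":
        return (fst_th + fst_ts - fst_sh) / 2.0
    if mode == "log":
        def t(f):
            return -np.log(1.0 - np.minimum(f, 1.0 - 1e-9))
        return (t(fst_th) + t(fst_ts) - t(fst_sh)) / 2.0
    raise ValueError(f"unknown PBS mode: {mode!r}")


def score_freq_stats(gm: GenotypeMatrix, popmap, *, pbs_mode: str = "linear",
                     fst_estimator: str = "hudson") -> pd.DataFrame:
    """Per-SNV table of DAF triple, ΔDAF, pairwise FST and PBS."""
    dt = daf_table(gm, popmap)
    idx = split_by_population(gm, popmap)
    out = dt.copy()
    out["delta_daf"] = delta_daf(dt["daf_T"], dt["daf_S"], dt["daf_H"])
    pairs = {"fst_TH": ("T", "H"), "fst_TS": ("T", "S"), "fst_SH": ("S", "H")}
    for col, (a, b) in pairs.items():
        if fst_estimator == "hudson":
            fst = np.asarray(hudson_fst(
                dt[f"daf_{a}"], dt[f"n_{a}"], dt[f"daf_{b}"], dt[f"n_{b}"]
            ))
        elif fst_estimator == "wc":
            fst = np.asarray(weir_cockerham_fst(gm.calls[idx[a]], gm.calls[idx[b]]))
        else:
            raise ValueError(f"unknown FST estimator: {fst_estimator!r}")
        # continuous limit: two populations monomorphic for the same allele
        # are undifferentiated (FST -> 0), so PBS stays defined at sites
        # where the derived allele is private to the third population
        pa = dt[f"daf_{a}"].to_numpy()
        pb = dt[f"daf_{b}"].to_numpy()
        same_mono = (pa == pb) & ((pa == 0.0) | (pa == 1.0))
        fst = np.where(same_mono, 0.0, fst)
        out[col] = fst
    out["pbs"] = pbs(out["fst_TH"], out["fst_TS"], out["fst_SH"], mode=pbs_mode)
    return pd.concat([gm.variants.reset_index(drop=True), out], axis=1)
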