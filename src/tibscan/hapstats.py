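"""Haplotype-based selection statistics: EHH, iHH, iHS and XP-EHH.

Extended haplotype homozygosity (EHH) at distance x from a core SNV is the
probability that two random carrier haplotypes are identical over the
interval from the core out to x:

    EHH(x) = Σ_h C(c_h, 2) / C(n, 2)

summed over distinct extended haplotypes h with carrier counts c_h among
the n carriers.  iHH integrates EHH over physical distance (trapezoid
rule) on both sides of the core, truncating where EHH first drops below a
decay cutoff (default 0.05).  Sites whose EHH never decays below the
cutoff before the chromosome edge (or a large inter-SNV gap) are flagged
and excluded from standardization and downstream scoring.

iHS is ln(iHH_ancestral / iHH_derived), standardized within
derived-allele-frequency bins (equal-count bins).  XP-EHH is
ln(iHH_focal / iHH_reference) from pooled-core EHH computed separately
within each population, z-standardized genome-wide; positive values mean
longer haplotypes in the focal population.

Distances are physical (bp); no genetic map is assumed.  Inter-SNV gaps
larger than ``max_gap`` (default 200 kb) truncate integration so that
assembly gaps cannot inflate iHH.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HaplotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000
DEFAULT_MAX_EXTEND = 1_000_000


@dataclass
class EhhCurve:
    """One-sided EHH curve from a core site outward."""

    core: int
    direction: str  # "left" | "right"
    offsets_bp: np.ndarray  # increasing, starts at 0
    ehh_values: np.ndarray  # starts at 1.0, non-increasing
    gap_truncated: bool = False


def _refine(ids: np.ndarray, n_groups: int, alleles_col: np.ndarray):
    """Split haplotype groups by the next site's alleles; O(n + groups)."""
    new = ids * 2 + alleles_col
    counts = np.bincount(new, minlength=2 * n_groups)
    nonzero = counts > 0
    relabel = np.cumsum(nonzero) - 1
    return relabel[new], int(nonzero.sum()), counts[nonzero]


def _build_walk_kernel():
    """Compile the hot EHH walk loop with numba when available."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is a soft dependency
        return None

    @njit(cache=False)
    def kernel(sub, positions, core, step, include_core, stop_below,
               max_gap, max_extend, use_poly, poly):  # pragma: no cover
        n, n_sites = sub.shape
        denom = n * (n - 1) / 2.0
        ids = np.zeros(n, np.int64)
        n_groups = 1
        if include_core:
            for i in range(n):
                ids[i] = sub[i, core]
            n_groups = 2
        counts0 = np.zeros(n_groups, np.int64)
        for i in range(n):
            counts0[ids[i]] += 1
        pairs = 0.0
        for g in range(n_groups):
            c = counts0[g]
            pairs += c * (c - 1) / 2.0
        ehh_val = pairs / denom if include_core else 1.0

        offsets = np.empty(n_sites + 1, np.float64)
        values = np.empty(n_sites + 1, np.float64)
        offsets[0] = 0.0
        values[0] = 1.0
        m = 1
        gap_trunc = False
        core_pos = positions[core]
        prev_pos = core_pos
        label = np.empty(2 * n + 2, np.int64)
        cnts = np.zeros(2 * n + 2, np.int64)
        keys = np.empty(n, np.int64)
        j = core + step
        while 0 <= j < n_sites:
            gap = positions[j] - prev_pos
            if gap < 0:
                gap = -gap
            off = positions[j] - core_pos
            if off < 0:
                off = -off
            if max_gap > 0 and gap > max_gap:
                gap_trunc = True
                break
            if max_extend > 0 and off > max_extend:
                gap_trunc = True
                break
            if (not use_poly) or poly[j]:
                for i in range(n):
                    key = ids[i] * 2 + sub[i, j]
                    keys[i] = key
                    label[key] = -1
                    cnts[key] = 0
                ng = 0
                for i in range(n):
                    key = keys[i]
                    if label[key] < 0:
                        label[key] = ng
                        ng += 1
                    ids[i] = label[key]
                    cnts[key] += 1
                pairs = 0.0
                for i in range(n):
                    key = keys[i]
                    c = cnts[key]
                    if c > 1:
                        pairs += c * (c - 1) / 2.0
                        cnts[key] = 0  # count each group once
                n_groups = ng
                ehh_val = pairs / denom
            offsets[m] = off
            values[m] = ehh_val
            m += 1
            prev_pos = positions[j]
            if stop_below > 0 and ehh_val < stop_below:
                break
            if ehh_val == 0.0:
                break
            j += step
        return offsets[:m], values[:m], gap_trunc

    return kernel


_WALK_KERNEL = _build_walk_kernel()


def _walk(sub: np.ndarray, positions: np.ndarray, core: int,
          direction: str, *, include_core: bool,
          stop_below: float | None, max_gap: float | None,
          max_extend: float | None = None,
          poly: np.ndarray | None = None) -> EhhCurve:
    if _WALK_KERNEL is not None:
        pos64 = positions.astype(np.int64, copy=False)
        use_poly = poly is not None
        poly_arr = poly if use_poly else np.zeros(1, dtype=np.bool_)
        off, val, trunc = _WALK_KERNEL(
            np.ascontiguousarray(sub), pos64, core,
            1 if direction == "right" else -1, include_core,
            -1.0 if stop_below is None else float(stop_below),
            -1.0 if max_gap is None else float(max_gap),
            -1.0 if max_extend is None else float(max_extend),
            use_poly, np.asarray(poly_arr, dtype=np.bool_),
        )
        return EhhCurve(core, direction, off, val, bool(trunc))
    return _walk_py(sub, positions, core, direction,
                    include_core=include_core, stop_below=stop_below,
                    max_gap=max_gap, max_extend=max_extend, poly=poly)


def _walk_py(sub: np.ndarray, positions: np.ndarray, core: int,
             direction: str, *, include_core: bool,
             stop_below: float | None, max_gap: float | None,
             max_extend: float | None = None,
             poly: np.ndarray | None = None) -> EhhCurve:
    n = sub.shape[0]
    denom = n * (n - 1) / 2.0
    if direction == "right":
        cols = range(core + 1, sub.shape[1])
    else:
        cols = range(core - 1, -1, -1)
    if include_core:
        ids = sub[:, core].astype(np.int64)
        n_groups = 2
        counts = np.bincount(ids, minlength=1)
    else:
        ids = np.zeros(n, dtype=np.int64)
        n_groups = 1
        counts = np.array([n])
    offsets = [0]
    values = [1.0]
    ehh = float((counts * (counts - 1) // 2).sum() / denom) if include_core else 1.0
    gap_truncated = False
    prev_pos = positions[core]
    core_pos = positions[core]
    for j in cols:
        gap = abs(int(positions[j]) - int(prev_pos))
        if max_gap is not None and gap > max_gap:
            gap_truncated = True
            break
        if max_extend is not None and abs(int(positions[j]) - int(core_pos)) > max_extend:
            gap_truncated = True
            break
        # monomorphic columns cannot split groups: EHH carries over unchanged
        if poly is None or poly[j]:
            ids, n_groups, counts = _refine(ids, n_groups, sub[:, j])
            ehh = float((counts * (counts - 1) // 2).sum() / denom)
        offsets.append(abs(int(positions[j]) - int(core_pos)))
        values.append(ehh)
        prev_pos = positions[j]
        if stop_below is not None and ehh < stop_below:
            break
        if ehh == 0.0:
            break
    return EhhCurve(core, direction, np.asarray(offsets, dtype=float),
                    np.asarray(values), gap_truncated)


def ehh(hm: HaplotypeMatrix, core: int, allele: int | None = None, *,
        stop_below: float | None = None, max_gap: float | None = None,
        max_extend: float | None = None,
        _poly: np.ndarray | None = None) -> tuple[EhhCurve, EhhCurve]:
    """EHH curves (left, right) for a core site.

    *allele* selects carrier haplotypes (0 ancestral / 1 derived); ``None``
    pools all haplotypes, in which case the extended haplotype includes the
    core allele itself.  Undefined (raises ValueError) with < 2 carriers.
    """
    alleles = hm.alleles
    if allele is None:
        sub = alleles  # pooled: every haplotype is a carrier
        include_core = True
    else:
        carriers = np.flatnonzero(alleles[:, core] == allele)
        if len(carriers) < 2:
            raise ValueError("EHH undefined with fewer than 2 carrier haplotypes")
        sub = alleles[carriers]
        include_core = False
    if sub.shape[0] < 2:
        raise ValueError("EHH undefined with fewer than 2 carrier haplotypes")
    pos = hm.positions
    left = _walk(sub, pos, core, "left", include_core=include_core,
                 stop_below=stop_below, max_gap=max_gap,
                 max_extend=max_extend, poly=_poly)
    right = _walk(sub, pos, core, "right", include_core=include_core,
                  stop_below=stop_below, max_gap=max_gap,
                  max_extend=max_extend, poly=_poly)
    return left, right


def integrate_side(curve: EhhCurve, cutoff: float = DEFAULT_CUTOFF):
    """Trapezoidal iHH contribution of one curve side.

    Integration runs outward and stops at the first point where EHH drops
    below *cutoff* (that trapezoid is included).  Returns ``(area,
    decayed)`` with decayed False when the curve reaches its end (edge or
    gap truncation) still at or above the cutoff.
    """
    off, val = curve.offsets_bp, curve.ehh_values
    area = 0.0
    decayed = False
    for k in range(1, len(off)):
        area += (off[k] - off[k - 1]) * (val[k] + val[k - 1]) / 2.0
        if val[k] < cutoff:
            decayed = True
            break
    return float(area), decayed


def ihh(curves: tuple[EhhCurve, EhhCurve], cutoff: float = DEFAULT_CUTOFF):
    """Two-sided integrated EHH.  Returns ``(ihh, decay_flag)``; decay_flag
    is True only when EHH decays below the cutoff on both sides."""
    left, right = curves
    a_l, d_l = integrate_side(left, cutoff)
    a_r, d_r = integrate_side(right, cutoff)
    return a_l + a_r, d_l and d_r


def ihs_scan(hm: HaplotypeMatrix, *, cutoff: float = DEFAULT_CUTOFF,
             max_gap: float | None = DEFAULT_MAX_GAP,
             max_extend: float | None = DEFAULT_MAX_EXTEND,
             min_maf: float = 0.05) -> pd.DataFrame:
    """Unstandardized iHS over every eligible site of a haplotype matrix.

    Sites below the minor-allele-frequency floor, with < 2 carriers of
    either allele, or failing the decay rule get NaN scores.
    """
    n_hap, n_sites = hm.alleles.shape
    daf = hm.alleles.mean(axis=0)
    col_sum = hm.alleles.sum(axis=0)
    poly = (col_sum > 0) & (col_sum < n_hap)
    ihh_a = np.full(n_sites, np.nan)
    ihh_d = np.full(n_sites, np.nan)
    decay_ok = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        maf = min(daf[j], 1 - daf[j])
        if maf < min_maf:
            continue
        n_der = int(col_sum[j])
        if n_der < 2 or n_hap - n_der < 2:
            continue
        ia, ok_a = ihh(ehh(hm, j, allele=0, stop_below=cutoff, max_gap=max_gap,
                           max_extend=max_extend, _poly=poly), cutoff)
        id_, ok_d = ihh(ehh(hm, j, allele=1, stop_below=cutoff, max_gap=max_gap,
                            max_extend=max_extend, _poly=poly), cutoff)
        ihh_a[j] = ia
        ihh_d[j] = id_
        decay_ok[j] = ok_a and ok_d
    with np.errstate(invalid="ignore", divide="ignore"):
        ihs_unstd = np.where(
            (ihh_a > 0) & (ihh_d > 0), np.log(ihh_a / ihh_d), np.nan
        )
    ihs_unstd = np.where(decay_ok, ihs_unstd, np.nan)
    return pd.DataFrame(
        {
            "pos": hm.positions,
            "daf": daf,
            "ihh_A": ihh_a,
            "ihh_D": ihh_d,
            "ihs_unstd": ihs_unstd,
            "decay_ok": decay_ok,
        }
    )


def ihs_standardize(df: pd.DataFrame, n_bins: int = 20,
                    min_per_bin: int = 10) -> pd.DataFrame:
    """Standardize unstandardized iHS within equal-count DAF bins.

    Bins with fewer than *min_per_bin* valid scores are merged by using
    fewer quantile bins; bins with zero variance yield NaN (logged).
    Adds an ``ihs`` column.
    """
    out = df.copy()
    out["ihs"] = np.nan
    valid = out["ihs_unstd"].notna()
    n_valid = int(valid.sum())
    if n_valid == 0:
        return out
    bins = max(1, min(n_bins, n_valid // max(min_per_bin, 1)))
    ranks = out.loc[valid, "daf"].rank(method="first")
    bin_id = pd.qcut(ranks, q=bins, labels=False, duplicates="drop")
    vals = out.loc[valid, "ihs_unstd"]
    for b in np.unique(bin_id):
        sel = bin_id == b
        x = vals[sel]
        sd = x.std(ddof=0)
        if sd == 0 or np.isnan(sd):
            logger.warning("iHS bin %s has zero variance; scores undefined", b)
            continue
        out.loc[x.index, "ihs"] = (x - x.mean()) / sd
    return out


def xpehh_scan(hm: HaplotypeMatrix, rows_focal: np.ndarray,
               rows_ref: np.ndarray, *, cutoff: float = DEFAULT_CUTOFF,
               max_gap: float | None = DEFAULT_MAX_GAP,
               max_extend: float | None = DEFAULT_MAX_EXTEND) -> pd.DataFrame:
    """XP-EHH between a focal and a reference haplotype set.

    Pooled-core EHH is computed separately within each population;
    ``xpehh_unstd = ln(iHH_focal / iHH_ref)``, then z-standardized over
    valid sites (``xpehh`` column).  Positive = longer haplotype
    homozygosity in the focal population.  The decay rule applies within
    both populations.
    """
    hm_f = hm.take_haplotypes(rows_focal)
    hm_r = hm.take_haplotypes(rows_ref)
    poly_f = (hm_f.alleles.sum(axis=0) > 0) & (
        hm_f.alleles.sum(axis=0) < hm_f.n_haplotypes)
    poly_r = (hm_r.alleles.sum(axis=0) > 0) & (
        hm_r.alleles.sum(axis=0) < hm_r.n_haplotypes)
    n_sites = hm.n_sites
    x_unstd = np.full(n_sites, np.nan)
    decay_ok = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        i_f, ok_f = ihh(ehh(hm_f, j, allele=None, stop_below=cutoff,
                            max_gap=max_gap, max_extend=max_extend,
                            _poly=poly_f), cutoff)
        i_r, ok_r = ihh(ehh(hm_r, j, allele=None, stop_below=cutoff,
                            max_gap=max_gap, max_extend=max_extend,
                            _poly=poly_r), cutoff)
        decay_ok[j] = ok_f and ok_r
        if i_f > 0 and i_r > 0 and decay_ok[j]:
            x_unstd[j] = np.log(i_f / i_r)
    valid = ~np.isnan(x_unstd)
    x_std = np.full(n_sites, np.nan)
    if valid.sum() >= 2:
        mu = x_unstd[valid].mean()
        sd = x_unstd[valid].std(ddof=0)
        if sd > 0:
            x_std[valid] = (x_unstd[valid] - mu) / sd
        else:  # degenerate spread (e.g. identical populations): centre only
            x_std[valid] = x_unstd[valid] - mu
    return pd.DataFrame(
        {
            "pos": hm.positions,
            "xpehh_unstd": x_unstd,
            "xpehh": x_std,
            "xpehh_decay_ok": decay_ok,
        }
    )
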