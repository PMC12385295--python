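"""Composite-of-multiple-signals (CMS) scoring and top-quantile selection.

Each component statistic (PBS, ΔDAF, |iHS|, XP-EHH) is converted to a
one-sided empirical rank p-value

    p = (r + 1) / (N + 1)

where r counts SNVs with a strictly more extreme value in the selection
direction (tied values share a p).  The composite score is

    CMS = Σ −log10(p_i)

over the four components, defined only where all four are defined.  Being
rank-based, CMS is invariant to strictly monotone transforms of any
component.  Candidate SNVs are those with CMS strictly above the empirical
(1 − q) quantile (order statistic), q = 0.005 by default.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

MIN_SNVS = 100

CMS_COMPONENTS = ("pbs", "delta_daf", "ihs_abs", "xpehh")


def empirical_p(values, direction: str = "greater") -> np.ndarray:
    """One-sided empirical rank p-values; NaN inputs get NaN p-values.

    With direction "greater", larger values are more extreme.  For each
    SNV, r = number of valid SNVs with a strictly more extreme value, and
    p = (r + 1)/(N + 1) with N the number of valid SNVs.
    """
    values = np.asarray(values, dtype=float)
    valid = ~np.isnan(values)
    n = int(valid.sum())
    if n < MIN_SNVS:
        raise ValueError(f"empirical_p needs ≥{MIN_SNVS} valid SNVs, got {n}")
    v = values[valid]
    if direction == "less":
        v = -v
    elif direction != "greater":
        raise ValueError(f"unknown direction: {direction!r}")
    order = np.sort(v)
    # r = N - (number of values <= v) = strictly-greater count
    r = n - np.searchsorted(order, v, side="right")
    p = np.full(values.shape, np.nan)
    p[valid] = (r + 1) / (n + 1)
    return p


def cms_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Add component empirical p-values and the CMS column.

    Expects columns ``pbs``, ``delta_daf``, ``ihs`` (signed, standardized)
    and ``xpehh``.  iHS enters two-sided (|iHS|); the other components are
    one-sided toward focal-population selection (larger = more selected).
    """
    out = scores.copy()
    out["ihs_abs"] = out["ihs"].abs()
    for comp in CMS_COMPONENTS:
        out[f"p_{comp}"] = empirical_p(out[comp].to_numpy(), "greater")
    pcols = [f"p_{c}" for c in CMS_COMPONENTS]
    logs = -np.log10(out[pcols].to_numpy())
    cms = logs.sum(axis=1)  # NaN if any component undefined
    out["cms"] = cms
    return out


def top_quantile(cms: np.ndarray, q: float = 0.005):
    """Empirical top-q selection by strict threshold.

    The threshold is the ⌈(1−q)·N⌉-th smallest valid CMS value (an order
    statistic); selected SNVs are those strictly above it, so with all
    scores equal nothing is selected.  Returns ``(threshold, mask)``.
    """
    cms = np.asarray(cms, dtype=float)
    valid = ~np.isnan(cms)
    n = int(valid.sum())
    if n < 1 / q:
        raise ValueError(f"top_quantile needs ≥{int(np.ceil(1 / q))} valid SNVs")
    order = np.sort(cms[valid])
    k = int(np.ceil((1 - q) * n))
    threshold = float(order[k - 1])
    mask = np.zeros(cms.shape, dtype=bool)
    mask[valid] = cms[valid] > threshold
    return threshold, mask
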