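"""LD clumping of selected SNVs, gene assignment, and gene-set accounting.

Selected SNVs are collapsed into independent selection regions with the
PLINK-style greedy clump rule: repeatedly take the highest-CMS unassigned
SNV as the index (peak), and assign to its clump every unassigned selected
SNV on the same chromosome within the window (default 500 kb) whose r²
with the index exceeds the threshold (default 0.2).  Two surviving peaks
are therefore "independent": never both within the window at r² above the
threshold.  Genes are assigned to a region when their span intersects the
closed interval peak ± 5 kb.

r² is the squared Pearson correlation of ALT-dosage vectors over samples
non-missing at both sites (composite-LD convention, valid for unphased
data); a phased haplotype-based r² is available as an option.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GeneInterval, GenotypeMatrix, HaplotypeMatrix


@dataclass
class SelectionRegion:
    """A clumped run of selected SNVs with its peak and assigned genes."""

    chrom: str
    span_start: int
    span_end: int
    peak_snv: str
    peak_pos: int
    peak_cms: float
    members: list[str]
    gene_ids: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)


def ld_r2(gm: GenotypeMatrix, site_i: int, site_j: int) -> float:
    """Composite (dosage) r² between two sites; NaN when undefined."""
    x = gm.calls[:, site_i].astype(float)
    y = gm.calls[:, site_j].astype(float)
    ok = (gm.calls[:, site_i] != MISSING) & (gm.calls[:, site_j] != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def haplotype_r2(hm: HaplotypeMatrix, site_i: int, site_j: int) -> float:
    """Phase-aware r² from 0/1 haplotype alleles."""
    x = hm.alleles[:, site_i].astype(float)
    y = hm.alleles[:, site_j].astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_to_index(gm: GenotypeMatrix, index: int, others: np.ndarray) -> np.ndarray:
    """Vectorized composite r² between one index site and many others."""
    calls = gm.calls
    xi = calls[:, index]
    out = np.full(len(others), np.nan)
    for k, j in enumerate(others):
        out[k] = ld_r2(gm, index, int(j))
    return out


def clump(selected: pd.DataFrame, gm: GenotypeMatrix, r2_max: float = 0.2,
          window_bp: int = 500_000) -> list[SelectionRegion]:
    """Greedy LD clumping of a selected-SNV table.

    *selected* needs columns ``chrom``, ``pos``, ``id``, ``cms`` and
    ``site_idx`` (column index into *gm*).  CMS ties break by (chrom, pos)
    ascending.  Undefined r² (e.g. monomorphic after missingness) never
    joins a clump.
    """
    if len(selected) == 0:
        raise ValueError("clump: selected set is empty")
    df = selected.reset_index(drop=True)
    # peak order: descending CMS, ties by (chrom, pos) ascending
    order = df.sort_values(
        ["cms", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    ).index.to_numpy()
    assigned = np.zeros(len(df), dtype=bool)
    regions: list[SelectionRegion] = []
    chroms = df["chrom"].to_numpy()
    poss = df["pos"].to_numpy()
    for peak_row in order:
        if assigned[peak_row]:
            continue
        assigned[peak_row] = True
        cand = np.flatnonzero(
            ~assigned
            & (chroms == chroms[peak_row])
            & (np.abs(poss - poss[peak_row]) <= window_bp)
        )
        members = [peak_row]
        if len(cand):
            r2 = _r2_to_index(
                gm, int(df.loc[peak_row, "site_idx"]),
                df.loc[cand, "site_idx"].to_numpy(),
            )
            join = cand[np.nan_to_num(r2, nan=0.0) > r2_max]
            assigned[join] = True
            members.extend(join.tolist())
        mem = df.loc[members]
        regions.append(
            SelectionRegion(
                chrom=str(chroms[peak_row]),
                span_start=int(mem["pos"].min()),
                span_end=int(mem["pos"].max()),
                peak_snv=str(df.loc[peak_row, "id"]),
                peak_pos=int(poss[peak_row]),
                peak_cms=float(df.loc[peak_row, "cms"]),
                members=mem["id"].astype(str).tolist(),
            )
        )
    return regions


def assign_genes(regions: Sequence[SelectionRegion],
                 genes: Sequence[GeneInterval],
                 flank_bp: int = 5_000) -> list[SelectionRegion]:
    """Assign genes whose closed interval intersects peak ± flank (inclusive
    boundary: a gene ending exactly flank_bp away is assigned)."""
    for region in regions:
        lo = region.peak_pos - flank_bp
        hi = region.peak_pos + flank_bp
        region.gene_ids = sorted(
            g.gene_id
            for g in genes
            if g.chrom == region.chrom and g.start_bp <= hi and g.end_bp >= lo
        )
    return list(regions)


def region_accounting(regions: Sequence[SelectionRegion]) -> dict:
    """Split regions into gene-overlapping vs unannotated; totals must add."""
    n_with = sum(1 for r in regions if r.gene_ids)
    n_without = len(regions) - n_with
    return {
        "n_regions": len(regions),
        "n_gene_overlapping": n_with,
        "n_unannotated": n_without,
    }


@dataclass
class GeneSetAccounting:
    """Set intersections of selected genes with curated reproduction lists."""

    category_counts: dict[str, int]
    union_size: int
    n_duplicates_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "category_counts": dict(self.category_counts),
            "union_size": self.union_size,
            "n_duplicates_dropped": self.n_duplicates_dropped,
        }


def accounting(selected_genes, category_lists: dict[str, Sequence[str]]
               ) -> GeneSetAccounting:
    """Intersect the selected-gene set with each category gene list.

    Duplicate IDs within a list are deduplicated (counted); the union size
    is the number of distinct selected genes in any category.
    """
    n_dupes = 0
    selected = set(selected_genes)
    hits: dict[str, set] = {}
    for name, ids in category_lists.items():
        ids = list(ids)
        uniq = set(ids)
        n_dupes += len(ids) - len(uniq)
        hits[name] = uniq & selected
    union = set().union(*hits.values()) if hits else set()
    return GeneSetAccounting(
        category_counts={k: len(v) for k, v in hits.items()},
        union_size=len(union),
        n_duplicates_dropped=n_dupes,
    )


def read_gene_list(path) -> list[str]:
    """One gene ID per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def regions_to_frame(regions: Sequence[SelectionRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "span_start": [r.span_start for r in regions],
            "span_end": [r.span_end for r in regions],
            "peak_snv": [r.peak_snv for r in regions],
            "peak_cms": [r.peak_cms for r in regions],
            "n_members": [r.n_members for r in regions],
            "genes": [",".join(r.gene_ids) for r in regions],
        }
    )
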