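"""Model-style front end for the selection scan.

:class:`SelectionScan` is built from data (genotypes, phased haplotypes
and a sample→population map) the way a statsmodels model is built from
endog/exog; ``fit()`` runs the four per-SNV statistics (PBS, ΔDAF, iHS,
XP-EHH), composes them into CMS, applies the empirical top-quantile
threshold, clumps the selected SNVs into independent regions and assigns
nearby genes.  The returned :class:`SelectionScanResults` carries the
per-SNV score table, the threshold, the regions and a ``summary()``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import composite, freqstats, hapstats, regions as regions_mod
from .io import GeneInterval, GenotypeMatrix, HaplotypeMatrix, read_genes, read_vcf


@dataclass
class ScanConfig:
    """Tunable thresholds of the scan (defaults follow the pipeline's
    standard settings)."""

    pbs_mode: str = "linear"
    fst_estimator: str = "hudson"
    ehh_cutoff: float = 0.05
    max_gap_bp: float = 200_000
    min_maf: float = 0.05
    ihs_bins: int = 20
    cms_quantile: float = 0.005
    r2_max: float = 0.2
    window_bp: int = 500_000
    flank_bp: int = 5_000
    xpehh_reference: str = "pooled"  # "pooled" | "S" | "H"


class SelectionScan:
    """Three-population selection scan over a QC'd cohort.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Diploid calls for all samples (used for allele-frequency statistics
        and LD clumping; may contain missing genotypes).
    haplotypes : HaplotypeMatrix
        Phased complete-case haplotypes over the same cohort, rows ordered
        two per sample in genotype-sample order.
    popmap : mapping sample_id -> population
        Labels must include the focal population ``T`` and outgroups
        ``S`` and ``H``.
    genes : sequence of GeneInterval, optional
    config : ScanConfig, optional
    """

    def __init__(self, genotypes: GenotypeMatrix, haplotypes: HaplotypeMatrix,
                 popmap: Mapping[str, str],
                 genes: Sequence[GeneInterval] | None = None,
                 config: ScanConfig | None = None):
        self.genotypes = genotypes
        self.haplotypes = haplotypes
        self.popmap = dict(popmap)
        self.genes = list(genes) if genes is not None else []
        self.config = config or ScanConfig()
        missing = [s for s in genotypes.sample_ids if s not in self.popmap]
        if missing:
            raise ValueError(f"samples missing from popmap: {missing[:5]}")

    @classmethod
    def from_files(cls, vcf_path, popmap_path, genes_path=None,
                   config: ScanConfig | None = None) -> "SelectionScan":
        from .io import read_population_map

        popmap = read_population_map(popmap_path)
        gm, hm, _ = read_vcf(vcf_path, popmap)
        genes = read_genes(genes_path) if genes_path else None
        return cls(gm, hm, popmap, genes, config)

    def _haplotype_rows(self) -> dict[str, np.ndarray]:
        """Haplotype row indices per population (two rows per sample)."""
        rows: dict[str, list[int]] = {}
        sample_of_hap = [
            hid.rsplit("_", 1)[0] for hid in self.haplotypes.haplotype_ids
        ]
        for r, sid in enumerate(sample_of_hap):
            rows.setdefault(self.popmap[sid], []).append(r)
        return {k: np.array(v) for k, v in rows.items()}

    def fit(self) -> "SelectionScanResults":
        cfg = self.config
        gm, hm = self.genotypes, self.haplotypes

        scores = freqstats.score_freq_stats(
            gm, self.popmap, pbs_mode=cfg.pbs_mode,
            fst_estimator=cfg.fst_estimator,
        )

        hap_rows = self._haplotype_rows()
        hm_t = hm.take_haplotypes(hap_rows["T"])
        ihs_df = hapstats.ihs_scan(
            hm_t, cutoff=cfg.ehh_cutoff, max_gap=cfg.max_gap_bp,
            min_maf=cfg.min_maf,
        )
        ihs_df = hapstats.ihs_standardize(ihs_df, n_bins=cfg.ihs_bins)

        if cfg.xpehh_reference == "pooled":
            ref_rows = np.concatenate([hap_rows["S"], hap_rows["H"]])
        else:
            ref_rows = hap_rows[cfg.xpehh_reference]
        xp_df = hapstats.xpehh_scan(
            hm, hap_rows["T"], ref_rows, cutoff=cfg.ehh_cutoff,
            max_gap=cfg.max_gap_bp,
        )

        # align haplotype-site scores onto the genotype variant table
        # ihs_df and xp_df are row-aligned with hm's sites
        hap_scores = pd.concat(
            [
                pd.DataFrame({"chrom": hm.variants["chrom"].to_numpy(),
                              "pos": hm.positions}),
                ihs_df[["daf", "ihh_A", "ihh_D", "ihs_unstd", "ihs",
                        "decay_ok"]].reset_index(drop=True),
                xp_df[["xpehh_unstd", "xpehh",
                       "xpehh_decay_ok"]].reset_index(drop=True),
            ],
            axis=1,
        )
        scores = scores.merge(hap_scores, on=["chrom", "pos"], how="left",
                              suffixes=("", "_hap"))
        scores["site_idx"] = np.arange(len(scores))

        scores = composite.cms_scores(scores)
        threshold, mask = composite.top_quantile(
            scores["cms"].to_numpy(), cfg.cms_quantile
        )
        scores["selected"] = mask

        selected = scores.loc[mask, ["chrom", "pos", "id", "cms", "site_idx"]]
        if len(selected):
            regs = regions_mod.clump(selected, gm, cfg.r2_max, cfg.window_bp)
            regs = regions_mod.assign_genes(regs, self.genes, cfg.flank_bp)
        else:
            regs = []
        return SelectionScanResults(self, scores, float(threshold), regs)


@dataclass
class SelectionScanResults:
    """Fitted selection scan: per-SNV scores, threshold, clumped regions."""

    model: SelectionScan
    scores: pd.DataFrame
    cms_threshold: float
    regions: list = field(default_factory=list)

    @property
    def selected(self) -> pd.DataFrame:
        return self.scores.loc[self.scores["selected"]]

    @property
    def selected_genes(self) -> list[str]:
        return sorted({g for r in self.regions for g in r.gene_ids})

    def region_table(self) -> pd.DataFrame:
        return regions_mod.regions_to_frame(self.regions)

    def region_accounting(self) -> dict:
        return regions_mod.region_accounting(self.regions)

    def top_region(self):
        if not self.regions:
            return None
        return max(self.regions, key=lambda r: r.peak_cms)

    def summary(self) -> str:
        acc = self.region_accounting()
        n_scored = int(self.scores["cms"].notna().sum())
        lines = [
            "Selection scan results",
            "=" * 54,
            f"{'SNVs in':<38}{len(self.scores):>16,}",
            f"{'SNVs with CMS defined':<38}{n_scored:>16,}",
            "{:<38}{:>16.4f}".format(
                f"CMS threshold (top {self.model.config.cms_quantile:.3%})",
                self.cms_threshold,
            ),
            f"{'selected SNVs':<38}{int(self.scores['selected'].sum()):>16,}",
            f"{'independent regions':<38}{acc['n_regions']:>16,}",
            f"{'  gene-overlapping':<38}{acc['n_gene_overlapping']:>16,}",
            f"{'  unannotated':<38}{acc['n_unannotated']:>16,}",
            f"{'distinct genes assigned':<38}{len(self.selected_genes):>16,}",
            "=" * 54,
        ]
        top = self.top_region()
        if top is not None:
            lines.append(
                f"top region: {top.chrom}:{top.span_start}-{top.span_end} "
                f"peak {top.peak_snv} CMS={top.peak_cms:.2f} "
                f"genes={','.join(top.gene_ids) or '-'}"
            )
        return "\n".join(lines)

    def plot_manhattan(self, ax=None):
        """CMS Manhattan plot with the top-quantile threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        df = self.scores
        ax.scatter(df["pos"], df["cms"], s=4, c="steelblue", rasterized=True)
        ax.axhline(self.cms_threshold, color="red", lw=1,
                   label=f"CMS = {self.cms_threshold:.2f}")
        sel = self.selected
        ax.scatter(sel["pos"], sel["cms"], s=8, c="crimson")
        ax.set_xlabel("position (bp)")
        ax.set_ylabel("CMS")
        ax.legend(loc="upper right", frameon=False)
        return ax
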