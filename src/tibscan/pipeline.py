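"""End-to-end pipeline: QC → frequency scan → haplotype scan → CMS →
clumping → gene assignment, with atomic TSV/JSON outputs and a
machine-readable run summary.

All floats in outputs are printed to 6 significant digits so that
identical config + seed gives byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from .io import read_genes, read_population_map, read_vcf
from .model import ScanConfig, SelectionScan

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    vcf: str = ""
    popmap: str = ""
    genes: str | None = None
    outdir: str = "tibscan_out"
    sample_miss: float = 0.03
    het_sd: float = 3.0
    ibd_pi_hat: float | None = 0.25  # None disables the IBD stage
    var_miss: float = 0.05
    hwe_p: float = 1e-6
    ehh_cutoff: float = 0.05
    cms_quantile: float = 0.005
    r2_max: float = 0.2
    window_bp: int = 500_000
    flank_bp: int = 5_000
    pbs_mode: str = "linear"
    xpehh_reference: str = "pooled"
    seed: int = 0
    skip_qc: bool = False

    def validate(self) -> None:
        for name, lo, hi in [
            ("sample_miss", 0, 1), ("var_miss", 0, 1), ("hwe_p", 0, 1),
            ("ehh_cutoff", 0, 1), ("cms_quantile", 0, 0.5), ("r2_max", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.window_bp <= 0 or self.flank_bp < 0:
            raise ValueError("window_bp must be positive, flank_bp non-negative")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _frame_to_tsv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    header = "".join(f"# {k}: {v}\n" for k, v in sorted(meta.items()))
    body = df.to_csv(sep="\t", index=False, float_format="%.6g")
    _atomic_write(path, header + body)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts into ``config.outdir``.

    Returns the summary dict (also written as ``summary.json``).  Any
    stage failure raises with the stage named.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {k: v for k, v in config.to_dict().items() if v is not None}
    _atomic_write(outdir / "config.yaml",
                  yaml.safe_dump(config.to_dict(), sort_keys=True))

    stage = "read-input"
    try:
        if not Path(config.popmap).exists():
            raise FileNotFoundError(f"population map not found: {config.popmap}")
        if not Path(config.vcf).exists():
            raise FileNotFoundError(f"VCF not found: {config.vcf}")
        popmap = read_population_map(config.popmap)
        gm_raw, hm_raw, read_stats = read_vcf(config.vcf, popmap)
        gm = gm_raw
        genes = read_genes(config.genes) if config.genes else []

        stage = "qc"
        if config.skip_qc:
            report = qc_mod.QcReport(
                n_samples_in=gm.n_samples, n_samples_out=gm.n_samples,
                n_variants_in=gm.n_sites, n_variants_out=gm.n_sites,
            )
        else:
            gm, report = qc_mod.run_qc(
                gm, popmap, sample_miss=config.sample_miss,
                het_sd=config.het_sd, ibd_pi_hat=config.ibd_pi_hat,
                var_miss=config.var_miss, hwe_p=config.hwe_p,
            )
        report.to_json(outdir / "qc_report.json")

        stage = "rebuild-haplotypes"
        # restrict the haplotype matrix to QC-surviving samples and sites
        keep_samples = set(gm.sample_ids)
        popmap_qc = {s: p for s, p in popmap.items() if s in keep_samples}
        sample_idx = [i for i, s in enumerate(gm_raw.sample_ids)
                      if s in keep_samples]
        hap_rows = np.array([r for i in sample_idx for r in (2 * i, 2 * i + 1)])
        kept_pos = set(zip(gm.variants["chrom"], gm.variants["pos"]))
        site_mask = np.array(
            [(c, p) in kept_pos
             for c, p in zip(hm_raw.variants["chrom"], hm_raw.variants["pos"])]
        )
        hm = hm_raw.take_haplotypes(hap_rows).take_sites(site_mask)

        stage = "scan"
        scan_cfg = ScanConfig(
            pbs_mode=config.pbs_mode, ehh_cutoff=config.ehh_cutoff,
            cms_quantile=config.cms_quantile, r2_max=config.r2_max,
            window_bp=config.window_bp, flank_bp=config.flank_bp,
            xpehh_reference=config.xpehh_reference,
        )
        model = SelectionScan(gm, hm, popmap_qc, genes, scan_cfg)
        results = model.fit()

        stage = "write-output"
        _frame_to_tsv(results.scores, outdir / "scores.tsv", meta)
        _frame_to_tsv(results.region_table(), outdir / "regions.tsv", meta)
        acc = results.region_accounting()
        summary = {
            "stages": ["qc", "scan-freq", "scan-haplo", "compose", "clump",
                       "annotate"],
            "read": read_stats,
            "qc": report.to_dict(),
            "cms_threshold": round(float(results.cms_threshold), 6),
            "n_selected_snvs": int(results.scores["selected"].sum()),
            "regions": acc,
            "n_genes_assigned": len(results.selected_genes),
            "genes_assigned": results.selected_genes,
            "config": config.to_dict(),
        }
        _atomic_write(outdir / "summary.json",
                      json.dumps(summary, indent=2, sort_keys=True) + "\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
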