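"""Forward Wright–Fisher simulation of a three-population sweep cohort.

The generator emulates the study design the pipeline targets: a focal
high-altitude population T and two lowland outgroups S and H.  One
ancestral deme evolves for a burn-in, splits into T and the (S,H)
ancestor ``n_generations_split1`` generations before sampling, and the
(S,H) ancestor splits into S and H at ``n_generations_split2``.  Each deme
is a constant-size diploid Wright–Fisher population with discrete
generations, random mating (selfing allowed) and at most one crossover
per meiosis.  Variation enters as standing variants drawn from the
neutral site-frequency spectrum (P(count = i) ∝ 1/i) plus new mutations
at rate ``mut_rate`` per bp per generation.

A hard sweep is imposed in T only: from ``sweep_start_gen`` generations
before sampling, genotypes at ``sweep_pos_bp`` have fitness 1, 1+s/2,
1+s for 0/1/2 copies of the derived allele.  The swept variant starts as
a standing variant at frequency ``sweep_init_freq``; if it is lost before
sampling the post-checkpoint generations are re-run with a fresh
substream, up to ``max_sweep_retries`` times.

The ancestral allele is the REF allele at every site, so DAF = ALT
frequency.  Missingness is applied i.i.d. per genotype after phasing and
affects genotype-level data only; the returned haplotype matrices are
complete-case.  Identical config + seed gives byte-identical output.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (GeneInterval, GenotypeMatrix, HaplotypeMatrix, MISSING,
                 make_variant_table, write_population_map, write_vcf)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the three-population sweep simulation."""

    n_focal: int = 50
    n_out1: int = 50          # outgroup S sample size (diploids)
    n_out2: int = 50          # outgroup H sample size
    chrom_length_bp: int = 5_000_000
    n_sites: int = 6_000      # standing variants at burn-in start
    mut_rate: float = 1e-9    # per bp per generation
    recomb_rate: float = 2e-7  # rescaled for desk-scale N (see methods note)
    n_generations_split1: int = 110
    n_generations_split2: int = 55
    pop_size: int = 400       # diploids per deme
    sel_coeff: float = 0.1
    sweep_pos_bp: int = 2_500_000
    sweep_start_gen: int = 110
    missing_rate: float = 0.0
    seed: int = 0
    n_generations_burnin: int = 40
    sweep_init_freq: float = 0.005
    max_sweep_retries: int = 50
    # sampling is conditioned on a partial (established, incomplete) sweep:
    # focal-deme frequency of the swept allele must land in this band
    sweep_final_freq_range: tuple = (0.7, 0.9)
    chrom: str = "1"

    def validate(self) -> None:
        if min(self.n_focal, self.n_out1, self.n_out2, self.pop_size,
               self.chrom_length_bp, self.n_sites) <= 0:
            raise ValueError("counts and lengths must be positive")
        if not 0 <= self.sel_coeff <= 1:
            raise ValueError("sel_coeff must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 1 <= self.sweep_pos_bp <= self.chrom_length_bp:
            raise ValueError("sweep_pos_bp outside chromosome")
        if self.n_generations_split2 > self.n_generations_split1:
            raise ValueError("split2 must not predate split1")
        if self.sweep_start_gen > self.n_generations_split1:
            raise ValueError("sweep must start after the focal population exists")
        if max(self.n_focal, self.n_out1, self.n_out2) > self.pop_size:
            raise ValueError("sample sizes cannot exceed pop_size")


@dataclass
class TruthSet:
    """Simulator ground truth for downstream power checks."""

    sweep_pos_bp: int
    sel_coeff: float
    final_daf_focal: float
    population_labels: dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sweep_pos_bp": self.sweep_pos_bp,
                    "sel_coeff": self.sel_coeff,
                    "final_daf_focal": self.final_daf_focal,
                    "population_labels": self.population_labels,
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


@dataclass
class SimResult:
    """Sampled cohort: per-population haplotypes, pooled genotypes, truth."""

    haplotypes: dict[str, HaplotypeMatrix]
    genotypes: GenotypeMatrix
    phased_alleles: np.ndarray  # (n_samples, 2, n_sites) int8, -1 = missing
    popmap: dict[str, str]
    truth: TruthSet
    sweep_site_index: int | None  # column in genotype matrix, None if lost

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": str(outdir / "cohort.vcf"),
            "popmap": str(outdir / "popmap.tsv"),
            "truth": str(outdir / "truth.json"),
        }
        write_vcf(paths["vcf"], self.genotypes.variants,
                  self.genotypes.sample_ids, self.phased_alleles)
        write_population_map(paths["popmap"], self.popmap)
        self.truth.to_json(paths["truth"])
        return paths


def _reproduce(hap: np.ndarray, rng: np.random.Generator, positions: np.ndarray,
               r_total: float, fitness: np.ndarray | None) -> np.ndarray:
    """One WF generation: fitness-weighted parent choice, one gamete per
    parent per child haplotype, single crossover with probability r_total."""
    two_n = hap.shape[0]
    n = two_n // 2
    if fitness is None:
        parent = rng.integers(0, n, size=two_n)
    else:
        parent = rng.choice(n, size=two_n, p=fitness / fitness.sum())
    start = rng.integers(0, 2, size=two_n)
    child = hap[2 * parent + start].copy()
    rec = np.flatnonzero(rng.random(two_n) < r_total)
    if len(rec):
        cuts = rng.integers(1, int(positions[-1]) + 1, size=len(rec))
        cols = np.searchsorted(positions, cuts)
        for k, col in zip(rec, cols):
            other = hap[2 * parent[k] + 1 - start[k]]
            child[k, col:] = other[col:]
    return child


def _sweep_fitness(hap: np.ndarray, sweep_col: int, s: float) -> np.ndarray:
    g = hap[0::2, sweep_col].astype(np.float64) + hap[1::2, sweep_col]
    return 1.0 + (s / 2.0) * g  # 1, 1+s/2, 1+s for g = 0, 1, 2


def _mutate(hap: np.ndarray, rng: np.random.Generator, lam: float,
            pool: np.ndarray, ptr: int) -> int:
    n_new = rng.poisson(lam)
    for _ in range(n_new):
        if ptr >= len(pool):
            break  # mutation capacity exhausted; remaining events dropped
        row = rng.integers(0, hap.shape[0])
        hap[row, pool[ptr]] = 1
        ptr += 1
    return ptr


def simulate_trio(config: SimConfig) -> SimResult:
    """Run the three-population sweep simulation and sample a cohort.

    Raises ``RuntimeError("sweep lost")`` when the swept allele is lost in
    every retry.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    key_a, key_fin, key_base, *keys_b = ss.spawn(3 + max(config.max_sweep_retries, 1))

    L = config.chrom_length_bp
    two_n = 2 * config.pop_size
    deme_gens = (
        config.n_generations_burnin
        + (config.n_generations_split1 - config.n_generations_split2) * 2
        + config.n_generations_split2 * 3
    )
    lam = two_n * L * config.mut_rate
    cap = config.n_sites + int(4 * lam * deme_gens) + 64

    rng_a = np.random.default_rng(key_a)

    # -- site registry: all candidate positions fixed and sorted up front --
    positions = rng_a.choice(L, size=min(cap, L), replace=False) + 1
    if config.sweep_pos_bp not in positions:
        positions[rng_a.integers(0, len(positions))] = config.sweep_pos_bp
    positions = np.unique(positions)
    cap = len(positions)
    sweep_col = int(np.searchsorted(positions, config.sweep_pos_bp))

    cols = np.arange(cap)
    non_sweep = cols[cols != sweep_col]
    initial = rng_a.choice(non_sweep, size=config.n_sites - 1, replace=False)
    initial = np.concatenate([initial, [sweep_col]])
    pool = np.setdiff1d(cols, initial)
    rng_a.shuffle(pool)

    # -- standing variation from the neutral SFS --
    anc = np.zeros((two_n, cap), dtype=np.uint8)
    counts = np.arange(1, two_n)
    sfs_p = (1.0 / counts) / (1.0 / counts).sum()
    for col in initial:
        if col == sweep_col:
            k = max(1, int(round(config.sweep_init_freq * two_n)))
        else:
            k = int(rng_a.choice(counts, p=sfs_p))
        rows = rng_a.choice(two_n, size=k, replace=False)
        anc[rows, col] = 1

    r_total = config.recomb_rate * L
    split1 = config.n_generations_split1
    split2 = config.n_generations_split2
    t_total = config.n_generations_burnin + split1

    def evolve(state: dict[str, np.ndarray], g_from: int, g_to: int,
               rng: np.random.Generator, ptr: int, sweep_on: bool) -> int | None:
        """Advance all demes from g_from down to g_to (gens before present).

        Returns None (abort signal) when the swept allele is lost while
        selection is active — the attempt cannot recover, so the caller
        retries immediately instead of finishing the generations.
        """
        for g in range(g_from, g_to, -1):
            if g == split1 and "A" in state:
                a = state.pop("A")
                state["T"] = a.copy()
                state["SH"] = a
            if g == split2 and "SH" in state:
                sh = state.pop("SH")
                state["S"] = sh.copy()
                state["H"] = sh
            for name in list(state):
                fit = None
                if sweep_on and name == "T" and config.sel_coeff > 0:
                    fit = _sweep_fitness(state[name], sweep_col, config.sel_coeff)
                state[name] = _reproduce(state[name], rng, positions, r_total, fit)
                ptr = _mutate(state[name], rng, lam, pool, ptr)
            if sweep_on and config.sel_coeff > 0:
                focal = state.get("T", state.get("A"))
                if focal[:, sweep_col].sum() == 0:
                    return None
        return ptr

    # Phase A: burn-in and divergence up to the sweep checkpoint
    state: dict[str, np.ndarray] = {"A": anc}
    ptr = evolve(state, t_total, config.sweep_start_gen, rng_a, 0, sweep_on=False)
    assert ptr is not None
    checkpoint = {k: v.copy() for k, v in state.items()}
    ptr_ck = ptr

    # Phase B: selection in T; retried with a fresh substream if the sweep dies
    n_attempts = max(config.max_sweep_retries, 1) if config.sel_coeff > 0 else 1
    final_state = None
    for attempt in range(n_attempts):
        rng_b = np.random.default_rng(keys_b[attempt])
        state = {k: v.copy() for k, v in checkpoint.items()}
        if config.sel_coeff > 0:
            # (re)seed the beneficial allele in the focal deme if drift lost it
            focal = state["T"] if "T" in state else state["A"]
            if focal[:, sweep_col].sum() == 0:
                k = max(1, int(round(config.sweep_init_freq * two_n)))
                rows = rng_b.choice(two_n, size=k, replace=False)
                focal[rows, sweep_col] = 1
        out = evolve(state, config.sweep_start_gen, 0, rng_b, ptr_ck, sweep_on=True)
        if config.sel_coeff == 0:
            final_state = state
            break
        if out is None:  # allele lost mid-attempt
            continue
        focal = state["T"] if "T" in state else state["A"]
        freq = focal[:, sweep_col].mean()
        lo, hi = config.sweep_final_freq_range
        if lo <= freq <= hi:
            final_state = state
            break
    if final_state is None:
        raise RuntimeError("sweep lost")
    state = final_state
    if "SH" in state:  # split2 == 0: outgroups sampled from their common deme
        sh = state.pop("SH")
        state["S"] = sh.copy()
        state["H"] = sh

    # -- sample diploids per deme --
    rng_fin = np.random.default_rng(key_fin)
    sample_sizes = {"T": config.n_focal, "S": config.n_out1, "H": config.n_out2}
    hap_rows: dict[str, np.ndarray] = {}
    for pop in ("T", "S", "H"):
        picked = rng_fin.choice(config.pop_size, size=sample_sizes[pop],
                                replace=False)
        rows = np.sort(np.concatenate([2 * picked, 2 * picked + 1]))
        hap_rows[pop] = state[pop][rows]

    pooled = np.concatenate([hap_rows[p] for p in ("T", "S", "H")], axis=0)
    alt_count = pooled.sum(axis=0)
    seg = alt_count > 0
    seg_cols = np.flatnonzero(seg)
    sweep_site_index = (
        int(np.searchsorted(seg_cols, sweep_col)) if seg[sweep_col] else None
    )

    rng_base = np.random.default_rng(key_base)
    ref_idx = rng_base.integers(0, 4, size=cap)
    alt_idx = (ref_idx + rng_base.integers(1, 4, size=cap)) % 4
    variants = make_variant_table(
        np.full(seg.sum(), config.chrom, dtype=object),
        positions[seg],
        BASES[ref_idx[seg]],
        BASES[alt_idx[seg]],
    )

    sample_ids, popmap = [], {}
    for pop in ("T", "S", "H"):
        for i in range(sample_sizes[pop]):
            sid = f"{pop}{i + 1:03d}"
            sample_ids.append(sid)
            popmap[sid] = pop

    haplotypes = {}
    offset = 0
    for pop in ("T", "S", "H"):
        n2 = 2 * sample_sizes[pop]
        ids = [f"{sample_ids[offset // 2 + i // 2]}_{i % 2 + 1}" for i in range(n2)]
        haplotypes[pop] = HaplotypeMatrix(
            ids, variants.copy(), pooled[offset:offset + n2][:, seg]
        )
        offset += n2

    n_samples = len(sample_ids)
    phased = pooled[:, seg].reshape(n_samples, 2, -1).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng_fin.random((n_samples, phased.shape[2])) < config.missing_rate
        phased = phased.copy()
        phased[np.broadcast_to(miss[:, None, :], phased.shape)] = MISSING
    calls = np.where(
        (phased < 0).any(axis=1), MISSING, phased.clip(min=0).sum(axis=1)
    ).astype(np.int8)
    gm = GenotypeMatrix(sample_ids, variants.copy(), calls)

    focal_daf = float(hap_rows["T"][:, sweep_col].mean())
    truth = TruthSet(
        sweep_pos_bp=config.sweep_pos_bp,
        sel_coeff=config.sel_coeff,
        final_daf_focal=focal_daf,
        population_labels=popmap,
    )
    return SimResult(haplotypes, gm, phased, popmap, truth, sweep_site_index)


def pooled_haplotypes(result: SimResult) -> tuple[HaplotypeMatrix, dict[str, np.ndarray]]:
    """Stack the per-population haplotype matrices and return row indices
    per population (rows ordered T, S, H)."""
    mats = [result.haplotypes[p] for p in ("T", "S", "H")]
    alleles = np.concatenate([m.alleles for m in mats], axis=0)
    ids = [h for m in mats for h in m.haplotype_ids]
    hm = HaplotypeMatrix(ids, mats[0].variants.copy(), alleles)
    rows, offset = {}, 0
    for p, m in zip(("T", "S", "H"), mats):
        rows[p] = np.arange(offset, offset + m.n_haplotypes)
        offset += m.n_haplotypes
    return hm, rows


# ---------------------------------------------------------------------------
# deterministic toy fixture
# ---------------------------------------------------------------------------

@dataclass
class ToyFixture:
    """Hand-constructed 26-sample, 50-SNV dataset with documented QC cases.

    Constructed properties (all on chrom "1", positions 10 kb apart):

    * exactly one singleton (pos 50,000; the single minor allele is a het
      in sample ``s02``),
    * exactly one site with >5% missing genotypes (pos 100,000; missing in
      ``s03`` and ``s04``, 2/26 ≈ 7.7%),
    * exactly one HWE-violating site (pos 150,000; all 26 samples
      heterozygous — exact p ≈ 1.6e-7, and ≈ 2.7e-7 after the outlier
      sample is dropped),
    * exactly one heterozygosity outlier sample (``s26``, het at ~96% of
      sites vs ~33% baseline),
    * genes ``g1`` (146–149 kb, within 5 kb of the 150 kb anchor SNV) and
      ``g2`` (200–210 kb, 50 kb away from the anchor).
    """

    gm: GenotypeMatrix
    hm: HaplotypeMatrix
    genes: list[GeneInterval]
    popmap: dict[str, str]
    singleton_pos: int = 50_000
    miss_pos: int = 100_000
    hwe_pos: int = 150_000
    outlier_sample: str = "s26"
    anchor_pos: int = 150_000


def make_toy_fixture() -> ToyFixture:
    n_samples, n_sites = 26, 50
    sample_ids = [f"s{i + 1:02d}" for i in range(n_samples)]
    positions = np.arange(1, n_sites + 1) * 10_000
    j_singleton, j_miss, j_hwe = 4, 9, 14  # pos 50k, 100k, 150k

    calls = np.zeros((n_samples, n_sites), dtype=np.int8)
    for j in range(n_sites):
        if j in (j_singleton, j_miss, j_hwe):
            continue
        for i in range(n_samples):
            calls[i, j] = (i + j) % 3  # cycling background: freq ≈ 0.5
    calls[:, j_singleton] = 0
    calls[1, j_singleton] = 1  # s02 carries the singleton
    for i in range(n_samples):
        calls[i, j_miss] = (i + j_miss) % 3
    calls[2, j_miss] = MISSING  # s03
    calls[3, j_miss] = MISSING  # s04
    calls[:, j_hwe] = 1  # all heterozygous

    outlier = n_samples - 1  # s26
    for j in range(n_sites):
        if j == j_singleton:
            calls[outlier, j] = 0
        elif j != j_hwe:
            calls[outlier, j] = 1

    variants = make_variant_table(
        ["1"] * n_sites, positions,
        ["A"] * n_sites, ["G"] * n_sites,
    )
    gm = GenotypeMatrix(sample_ids, variants, calls)

    # phased haplotypes on complete sites; het phase alternates by sample
    complete = (calls != MISSING).all(axis=0)
    hap = np.zeros((2 * n_samples, int(complete.sum())), dtype=np.uint8)
    for i in range(n_samples):
        row = calls[i, complete]
        a0 = np.where(row == 2, 1, np.where(row == 1, i % 2, 0))
        a1 = np.where(row == 2, 1, np.where(row == 1, 1 - i % 2, 0))
        hap[2 * i] = a0
        hap[2 * i + 1] = a1
    hm = HaplotypeMatrix(
        [f"{s}_{k}" for s in sample_ids for k in (1, 2)],
        variants.loc[complete].reset_index(drop=True),
        hap,
    )

    genes = [
        GeneInterval("g1", "1", 146_000, 149_000, "+"),
        GeneInterval("g2", "1", 200_000, 210_000, "-"),
    ]
    popmap = {}
    for i, s in enumerate(sample_ids):
        popmap[s] = "T" if i < 10 else ("S" if i < 18 else "H")
    return ToyFixture(gm, hm, genes, popmap)
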