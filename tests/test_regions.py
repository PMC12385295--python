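"""LD r², greedy clumping, gene assignment and set accounting."""
import numpy as np
import pandas as pd
import pytest

from tibscan.io import GeneInterval, GenotypeMatrix, MISSING, make_variant_table
from tibscan.oracles import clump_rescan, dosage_r2_direct
from tibscan.regions import (SelectionRegion, accounting, assign_genes, clump,
                             haplotype_r2, ld_r2, region_accounting,
                             regions_to_frame)


def _gm(calls, positions=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, s = calls.shape
    if positions is None:
        positions = np.arange(1, s + 1) * 1000
    vt = make_variant_table(["1"] * s, positions, ["A"] * s, ["G"] * s)
    return GenotypeMatrix([f"s{i}" for i in range(n)], vt, calls)


class TestLdR2:
    def test_site_with_itself_is_one(self):
        gm = _gm([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]])
        assert ld_r2(gm, 0, 0) == pytest.approx(1.0)

    def test_hand_computed_six_sample_pair(self):
        x = [0, 1, 2, 2, 1, 0]
        y = [0, 1, 1, 2, 0, 0]
        gm = _gm(np.array([x, y]).T)
        r = np.corrcoef(x, y)[0, 1]
        assert ld_r2(gm, 0, 1) == pytest.approx(r * r)
        assert ld_r2(gm, 0, 1) == pytest.approx(dosage_r2_direct(gm, 0, 1))

    def test_missing_pairs_are_dropped(self):
        x = [0, 1, 2, 2, MISSING, 0]
        y = [0, 1, 1, 2, 0, MISSING]
        gm = _gm(np.array([x, y]).T)
        assert ld_r2(gm, 0, 1) == pytest.approx(dosage_r2_direct(gm, 0, 1))

    def test_zero_variance_is_undefined(self):
        gm = _gm([[1, 0], [1, 1], [1, 2]])
        assert np.isnan(ld_r2(gm, 0, 1))

    def test_independent_sites_have_low_r2(self):
        rng = np.random.default_rng(0)
        n = 500
        calls = rng.binomial(2, 0.5, size=(n, 40)).astype(np.int8)
        gm = _gm(calls)
        vals = [ld_r2(gm, i, j) for i in range(10) for j in range(10, 20)]
        assert np.nanmean(vals) < 3 / n

    def test_haplotype_r2_perfect_ld(self, tiny_rep):
        res, hm, rows = tiny_rep
        assert haplotype_r2(hm, 3, 3) == pytest.approx(1.0)


class TestClump:
    def _selected(self, gm, idx, cms):
        v = gm.variants
        return pd.DataFrame({
            "chrom": v.loc[idx, "chrom"].to_numpy(),
            "pos": v.loc[idx, "pos"].to_numpy(),
            "id": v.loc[idx, "id"].to_numpy(),
            "cms": cms,
            "site_idx": idx,
        })

    def test_sites_outside_window_never_merge(self):
        calls = np.tile([[0], [1], [2], [1], [0], [2]], (1, 2))
        gm = _gm(calls, positions=[1000, 700_000])  # r² = 1 but 699 kb apart
        sel = self._selected(gm, [0, 1], [5.0, 4.0])
        regions = clump(sel, gm)
        assert len(regions) == 2

    def test_linked_nearby_sites_merge_under_higher_peak(self):
        calls = np.tile([[0], [1], [2], [1], [0], [2]], (1, 2))
        gm = _gm(calls, positions=[1000, 11_000])  # r² = 1, 10 kb apart
        sel = self._selected(gm, [0, 1], [4.0, 9.0])
        regions = clump(sel, gm)
        assert len(regions) == 1
        assert regions[0].peak_snv == gm.variants.loc[1, "id"]
        assert regions[0].peak_cms == 9.0
        assert regions[0].span_start == 1000 and regions[0].span_end == 11_000

    def test_independence_postcondition(self, default_rep):
        """No two surviving peaks on one chromosome are both within the
        window and correlated above the threshold."""
        res, hm, rows, fit = default_rep
        peaks = [(r.chrom, r.peak_pos, r.peak_snv) for r in fit.regions]
        gmap = {v: i for i, v in enumerate(fit.scores["id"])}
        gm = res.genotypes
        for a in range(len(peaks)):
            for b in range(a + 1, len(peaks)):
                if peaks[a][0] != peaks[b][0]:
                    continue
                if abs(peaks[a][1] - peaks[b][1]) > 500_000:
                    continue
                r2 = ld_r2(gm, gmap[peaks[a][2]], gmap[peaks[b][2]])
                assert not (r2 > 0.2)

    def test_every_selected_snv_in_exactly_one_region(self, default_rep):
        res, hm, rows, fit = default_rep
        members = [m for r in fit.regions for m in r.members]
        assert sorted(members) == sorted(fit.selected["id"])
        assert len(members) == len(set(members))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_rescan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, s = 60, 50
        # blocky LD: adjacent sites correlated via shared latent dosage
        latent = rng.binomial(2, 0.5, size=(n, 10)).astype(np.int8)
        calls = np.empty((n, s), dtype=np.int8)
        for j in range(s):
            base = latent[:, j // 5]
            noise = rng.random(n) < 0.2
            calls[:, j] = np.where(noise, rng.integers(0, 3, n), base)
        gm = _gm(calls, positions=np.sort(rng.choice(2_000_000, s, False)) + 1)
        idx = np.sort(rng.choice(s, 20, replace=False))
        cms = rng.uniform(3, 10, 20).round(3)
        sel = self._selected(gm, idx, cms)
        got = [(r.peak_snv, sorted(r.members)) for r in clump(sel, gm)]
        expected = clump_rescan(
            sel.to_dict("records"), lambda i, j: ld_r2(gm, i, j), 0.2, 500_000)
        assert sorted(got) == sorted(expected)

    def test_empty_selection_is_error(self, toy):
        with pytest.raises(ValueError):
            clump(pd.DataFrame(columns=["chrom", "pos", "id", "cms",
                                        "site_idx"]), toy.gm)


class TestAssignGenes:
    def _region(self, peak_pos):
        return SelectionRegion("1", peak_pos, peak_pos, f"1:{peak_pos}",
                               peak_pos, 5.0, [f"1:{peak_pos}"])

    def test_boundary_exactly_5kb_is_assigned(self):
        genes = [GeneInterval("g", "1", 90_000, 95_000)]
        (r,) = assign_genes([self._region(100_000)], genes, flank_bp=5000)
        assert r.gene_ids == ["g"]

    def test_5001_bp_away_is_not_assigned(self):
        genes = [GeneInterval("g", "1", 90_000, 94_999)]
        (r,) = assign_genes([self._region(100_000)], genes, flank_bp=5000)
        assert r.gene_ids == []

    def test_toy_genes_g1_in_g2_out(self, toy):
        (r,) = assign_genes([self._region(toy.anchor_pos)], toy.genes)
        assert r.gene_ids == ["g1"]

    def test_invariant_to_gene_order_and_strand(self, toy):
        fwd = assign_genes([self._region(toy.anchor_pos)], toy.genes)
        rev_genes = [GeneInterval(g.gene_id, g.chrom, g.start_bp, g.end_bp,
                                  "-" if g.strand == "+" else "+")
                     for g in reversed(toy.genes)]
        rev = assign_genes([self._region(toy.anchor_pos)], rev_genes)
        assert fwd[0].gene_ids == rev[0].gene_ids

    def test_region_accounting_splits_annotated(self):
        regions = [self._region(100_000), self._region(400_000)]
        assign_genes(regions, [GeneInterval("g", "1", 99_000, 99_500)])
        acc = region_accounting(regions)
        assert acc == {"n_regions": 2, "n_gene_overlapping": 1,
                       "n_unannotated": 1}


class TestAccounting:
    def test_disjoint_categories_union(self):
        cats = {
            "testis_specific": [f"ts{i}" for i in range(4)],
            "testis_enriched": [f"te{i}" for i in range(15)],
            "ovary_enriched": [f"oe{i}" for i in range(73)],
            "pathway": [f"pw{i}" for i in range(73)],
        }
        selected = set().union(*[set(v) for v in cats.values()])
        acc = accounting(selected, cats)
        assert acc.category_counts == {"testis_specific": 4,
                                       "testis_enriched": 15,
                                       "ovary_enriched": 73, "pathway": 73}
        assert acc.union_size == 165

    def test_empty_deg_lists_reduce_to_pathway(self):
        acc = accounting({"a", "b", "c"},
                         {"deg": [], "pathway": ["a", "b", "x"]})
        assert acc.union_size == 2

    def test_duplicates_deduplicated_and_counted(self):
        acc = accounting({"a"}, {"l": ["a", "a", "b"]})
        assert acc.category_counts["l"] == 1
        assert acc.n_duplicates_dropped == 1

    def test_union_equals_bruteforce_set_union(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        selected = set(rng.choice(universe, 80, replace=False))
        cats = {k: list(rng.choice(universe, rng.integers(5, 50)))
                for k in "abcd"}
        acc = accounting(selected, cats)
        brute = set()
        for ids in cats.values():
            for g in ids:
                if g in selected:
                    brute.add(g)
        assert acc.union_size == len(brute)


def test_regions_frame_columns():
    r = SelectionRegion("1", 10, 20, "1:15", 15, 3.2, ["1:15"], ["g1"])
    df = regions_to_frame([r])
    assert df.loc[0, "genes"] == "g1"
    assert df.loc[0, "n_members"] == 1
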