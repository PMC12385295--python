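"""EHH curves, iHH integration, iHS and XP-EHH."""
import numpy as np
import pandas as pd
import pytest

from conftest import random_haplotypes
from tibscan import hapstats
from tibscan.hapstats import (EhhCurve, ehh, ihh, ihs_scan, ihs_standardize,
                              integrate_side, xpehh_scan)
from tibscan.io import HaplotypeMatrix, make_variant_table
from tibscan.oracles import ehh_pair_counting, trapezoid_ihh


def _hm(alleles, positions):
    alleles = np.asarray(alleles, dtype=np.uint8)
    vt = make_variant_table(["1"] * len(positions), positions,
                            ["A"] * len(positions), ["G"] * len(positions))
    return HaplotypeMatrix([f"h{i}" for i in range(len(alleles))], vt, alleles)


class TestEhh:
    def test_value_at_core_is_one(self):
        hm = _hm(np.array([[1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 1, 1]]),
                 [100, 200, 300])
        left, right = ehh(hm, 1, allele=1)
        assert left.ehh_values[0] == 1.0
        assert right.ehh_values[0] == 1.0

    def test_two_two_split_gives_one_third(self):
        # 4 derived carriers split 2/2 at the next site: (1+1)/C(4,2) = 1/3
        alleles = np.array([
            [1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1],
        ])
        hm = _hm(alleles, [100, 200])
        _, right = ehh(hm, 0, allele=1)
        assert right.ehh_values[1] == pytest.approx(1 / 3)

    def test_fewer_than_two_carriers_is_undefined(self):
        hm = _hm(np.array([[1, 0], [0, 0], [0, 1]]), [100, 200])
        with pytest.raises(ValueError, match="carrier"):
            ehh(hm, 0, allele=1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pair_counting_oracle(self, seed):
        """Random 10-haplotype panels: the incremental walk equals O(n²)
        all-pairs identity counting at every offset, for carrier-restricted
        and pooled cores."""
        hm = random_haplotypes(10, 25, seed)
        alleles = hm.alleles
        for core in (0, 8, 24):
            for allele in (0, 1, None):
                include = allele is None
                carriers = (np.arange(10) if include
                            else np.flatnonzero(alleles[:, core] == allele))
                if len(carriers) < 2:
                    continue
                left, right = ehh(hm, core, allele=allele)
                for curve, step in ((right, 1), (left, -1)):
                    for k in range(1, len(curve.offsets_bp)):
                        target = core + step * k
                        expected = ehh_pair_counting(
                            alleles, core, carriers, target, include)
                        assert curve.ehh_values[k] == pytest.approx(expected)

    def test_curves_non_increasing_and_bounded(self, tiny_rep):
        res, hm, rows = tiny_rep
        hm_t = hm.take_haplotypes(rows["T"])
        n = hm_t.n_sites
        for core in (5, n // 2, n - 6):
            for curve in ehh(hm_t, core, allele=None):
                v = curve.ehh_values
                assert (np.diff(v) <= 1e-12).all()
                assert (v >= 0).all() and (v <= 1).all()


class TestIhh:
    def test_hand_trapezoid(self):
        # constant 1 over 1000 bp then drop to 0: area 500 + full segment 1000
        curve = EhhCurve(0, "right", np.array([0., 1000., 2000.]),
                         np.array([1.0, 1.0, 0.0]))
        area, decayed = integrate_side(curve, cutoff=0.05)
        assert area == pytest.approx(1000 + 500)
        assert decayed

    def test_never_decaying_side_flags_false(self):
        curve = EhhCurve(0, "right", np.array([0., 1000.]),
                         np.array([1.0, 0.5]))
        _, decayed = integrate_side(curve, cutoff=0.05)
        assert not decayed

    def test_distance_doubling_doubles_area(self):
        off = np.array([0., 500., 900., 1400.])
        val = np.array([1.0, 0.6, 0.2, 0.01])
        a1, _ = integrate_side(EhhCurve(0, "right", off, val), 0.05)
        a2, _ = integrate_side(EhhCurve(0, "right", 2 * off, val), 0.05)
        assert a2 == pytest.approx(2 * a1)

    def test_matches_oracle_trapezoid(self):
        rng = np.random.default_rng(3)
        off = np.concatenate([[0.0], np.sort(rng.choice(5000, 20, False))])
        val = np.concatenate([[1.0], np.sort(rng.uniform(0, 1, 20))[::-1]])
        area, _ = integrate_side(EhhCurve(0, "right", off, val), 0.05)
        assert area == pytest.approx(trapezoid_ihh(off, val, 0.05))

    def test_two_sided_sum(self):
        left = EhhCurve(0, "left", np.array([0., 100.]), np.array([1.0, 0.0]))
        right = EhhCurve(0, "right", np.array([0., 300.]), np.array([1.0, 0.0]))
        total, decayed = ihh((left, right), 0.05)
        assert total == pytest.approx(50 + 150)
        assert decayed


class TestIhs:
    def test_antisymmetry_under_allele_swap(self):
        """Flipping the core site's labels exactly flips ihs_unstd."""
        hm = random_haplotypes(20, 40, 7)
        df = ihs_scan(hm, max_gap=None, max_extend=None)
        flipped = hm.alleles.copy()
        core_candidates = df.index[df["ihs_unstd"].notna()]
        assert len(core_candidates) > 0
        j = int(core_candidates[0])
        flipped[:, j] = 1 - flipped[:, j]
        hm2 = HaplotypeMatrix(hm.haplotype_ids, hm.variants.copy(), flipped)
        df2 = ihs_scan(hm2, max_gap=None, max_extend=None)
        assert df2.loc[j, "ihs_unstd"] == pytest.approx(
            -df.loc[j, "ihs_unstd"])

    def test_standardized_bins_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "daf": rng.uniform(0.05, 0.95, 4000),
            "ihs_unstd": rng.normal(0, 2, 4000),
        })
        out = ihs_standardize(df, n_bins=20)
        ranks = out["daf"].rank(method="first")
        bins = pd.qcut(ranks, 20, labels=False)
        for b in range(20):
            x = out.loc[bins == b, "ihs"]
            assert abs(x.mean()) < 1e-9
            assert abs(x.std(ddof=0) - 1) < 1e-9

    def test_single_bin_equals_global_zscore(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"daf": rng.uniform(0.05, 0.95, 500),
                           "ihs_unstd": rng.normal(size=500)})
        out = ihs_standardize(df, n_bins=1)
        x = df["ihs_unstd"]
        expected = (x - x.mean()) / x.std(ddof=0)
        assert np.allclose(out["ihs"], expected)

    def test_zero_variance_bin_is_undefined(self):
        df = pd.DataFrame({"daf": np.linspace(0.1, 0.9, 50),
                           "ihs_unstd": np.ones(50)})
        out = ihs_standardize(df, n_bins=1)
        assert out["ihs"].isna().all()

    def test_neutral_tail_fraction_near_normal(self, tiny_rep):
        """|iHS| > 2 should occur for roughly 5% of scored SNVs after
        within-bin standardization (normal tail), with generous slack for
        a short chromosome."""
        res, hm, rows = tiny_rep
        hm_t = hm.take_haplotypes(rows["T"])
        df = ihs_standardize(ihs_scan(hm_t), n_bins=10)
        frac = (df["ihs"].abs() > 2).mean()
        assert 0.0 <= frac < 0.15


class TestXpehh:
    def test_identical_populations_score_zero(self):
        hm = random_haplotypes(16, 30, 5)
        both = HaplotypeMatrix(
            hm.haplotype_ids + [h + "b" for h in hm.haplotype_ids],
            hm.variants.copy(),
            np.vstack([hm.alleles, hm.alleles]),
        )
        df = xpehh_scan(both, np.arange(16), np.arange(16, 32),
                        max_gap=None, max_extend=None)
        valid = df["xpehh_unstd"].dropna()
        assert len(valid) > 0
        assert np.allclose(valid, 0.0)
        assert np.allclose(df["xpehh"].dropna(), 0.0)

    def test_monomorphic_focal_span_scores_positive(self):
        """A focal population monomorphic around the core has longer
        haplotype homozygosity: unstandardized XP-EHH > 0."""
        rng = np.random.default_rng(11)
        ref = rng.integers(0, 2, size=(20, 41)).astype(np.uint8)
        focal = rng.integers(0, 2, size=(20, 41)).astype(np.uint8)
        focal[:, 10:31] = 0  # long homozygous span around core 20
        pos = np.arange(1, 42) * 1000
        hm = _hm(np.vstack([focal, ref]), pos)
        df = xpehh_scan(hm, np.arange(20), np.arange(20, 40),
                        max_gap=None, max_extend=None)
        assert df.loc[20, "xpehh_unstd"] > 0

    def test_matches_pair_counting_plus_trapezoid_oracle(self):
        """8-haplotype toy: XP-EHH equals the log-ratio of brute-force
        EHH integrals."""
        hm = random_haplotypes(16, 18, 9, span=40_000)
        rows_f, rows_r = np.arange(8), np.arange(8, 16)
        core = 9
        df = xpehh_scan(hm, rows_f, rows_r, max_gap=None, max_extend=None)
        ihh_parts = {}
        for name, rows in (("f", rows_f), ("r", rows_r)):
            total = 0.0
            sub = hm.alleles[rows]
            for step in (1, -1):
                offs, vals = [0.0], [1.0]
                j = core + step
                while 0 <= j < hm.n_sites:
                    offs.append(abs(float(hm.positions[j] - hm.positions[core])))
                    vals.append(ehh_pair_counting(hm.alleles, core, rows, j, True))
                    if vals[-1] < 0.05:
                        break
                    j += step
                total += trapezoid_ihh(offs, vals, 0.05)
            ihh_parts[name] = total
        expected = np.log(ihh_parts["f"] / ihh_parts["r"])
        assert df.loc[core, "xpehh_unstd"] == pytest.approx(expected)
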