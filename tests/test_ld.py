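import math

import numpy as np
import pytest
from scipy import stats

from hzscan.association import SiteAssociation
from hzscan.ld import (
    composite_delta,
    composite_r2,
    filter_pairs,
    ld_decay,
    ld_matrix,
    partition_sites_by_association,
    square_r2_matrix,
)
from hzscan.pipeline import Dataset, run_association, run_ld
from hzscan.synth import default_config, simulate_two_pop_dataset
from hzscan.variants import GenotypeMatrix, VariantSite


def _gm(dosage, positions=None, locus="l"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    sites = []
    for j in range(m):
        col = dosage[:, j]
        maf = float(np.nanmean(col))
        pos = positions[j] if positions else j + 1
        sites.append(VariantSite(locus, pos - 1, pos, ["A", "C"],
                                 np.zeros(2 * n, dtype=np.int8), maf))
    return GenotypeMatrix([f"i{k}" for k in range(n)], sites, dosage)


class TestCompositeStatistics:
    def test_coupled_homozygote_fixture(self):
        # 5 AABB + 5 aabb: Burrows count formula n_AB/n - 2 pA pB = 1 - 0.5
        x = np.repeat([1.0, 0.0], 5)
        assert composite_delta(x, x.copy()) == pytest.approx(0.5)
        assert composite_r2(x, x.copy()) == pytest.approx(1.0)

    def test_hand_derived_dosage_fixture(self):
        x = np.array([2, 2, 1, 1, 0]) / 2
        y = np.array([2, 1, 1, 2, 0]) / 2
        assert composite_delta(x, y) == pytest.approx(0.18)
        assert composite_r2(x, y) == pytest.approx(0.413265, abs=1e-6)

    def test_delta_matches_burrows_count_formula(self, rng):
        # oracle: n_AB/n - 2 pA pB with n_AB the expected joint-count form
        for _ in range(50):
            X = rng.integers(0, 3, 30).astype(float)
            Y = rng.integers(0, 3, 30).astype(float)
            if np.ptp(X) == 0 or np.ptp(Y) == 0:
                continue
            n = len(X)
            n_ab = np.mean(X * Y) / 2  # (1/2n) sum X_i Y_i
            pa, pb = X.mean() / 2, Y.mean() / 2
            assert composite_delta(X / 2, Y / 2) == pytest.approx(
                n_ab - 2 * pa * pb, abs=1e-12)

    def test_r2_equals_squared_dosage_pearson(self, rng):
        # module master oracle, >=100 random fixtures
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 40))
            x = rng.choice([0.0, 0.5, 1.0], n)
            y = rng.choice([0.0, 0.5, 1.0], n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, _ = stats.pearsonr(x, y)
            assert composite_r2(x, y) == pytest.approx(r * r, abs=1e-12)
            assert composite_r2(y, x) == pytest.approx(r * r, abs=1e-12)
            assert composite_r2(1 - x, y) == pytest.approx(r * r, abs=1e-12)
            checked += 1

    def test_independence_limit(self, rng):
        x = rng.choice([0.0, 0.5, 1.0], 20000)
        y = rng.choice([0.0, 0.5, 1.0], 20000)
        assert abs(composite_delta(x, y)) < 0.01

    def test_delta_bound(self, rng):
        # |Delta| <= 2 * min over loci of p*q (numerical bound check)
        for _ in range(50):
            x = rng.choice([0.0, 0.5, 1.0], 25)
            y = rng.choice([0.0, 0.5, 1.0], 25)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            d = composite_delta(x, y)
            pa, pb = x.mean(), y.mean()
            bound = 2 * min(pa * (1 - pa), pb * (1 - pb))
            assert abs(d) <= bound + 1e-9

    def test_monomorphic_is_nan(self):
        assert math.isnan(composite_delta(np.zeros(10), np.arange(10) % 2 / 2))


class TestLdMatrix:
    def test_pair_count(self):
        gm = _gm(np.random.default_rng(0).choice([0, 0.5, 1], (25, 3)))
        assert len(ld_matrix(gm, min_n=20)) == 3

    def test_insufficient_n_reported_as_na(self):
        gm = _gm(np.random.default_rng(0).choice([0, 0.5, 1], (19, 2)))
        (rec,) = ld_matrix(gm, min_n=20)
        assert rec.reason == "insufficient n"
        assert math.isnan(rec.r2)

    def test_pooled_run_matches_direct_concatenation(self):
        cfg = default_config(9)
        ds = simulate_two_pop_dataset(cfg)
        pds = Dataset(ds.alignments, ds.samples)
        pooled = run_ld(pds, ["aglaope", "amaryllis"], pool=True)
        (records,) = pooled.values()
        # direct recomputation on the concatenated dosage matrix
        from hzscan.config import Thresholds
        from hzscan.pipeline import genotype_matrix_for_samples
        samples = [s for s in pds.samples
                   if s.population in ("aglaope", "amaryllis")]
        gm = genotype_matrix_for_samples(pds.alignments, samples, Thresholds(),
                                         informative_only=True)
        direct = {((r.locus_i, r.pos_i), (r.locus_j, r.pos_j)): r.r2
                  for r in ld_matrix(gm, 20)}
        for r in records[:200]:
            expect = direct[((r.locus_i, r.pos_i), (r.locus_j, r.pos_j))]
            if math.isnan(r.r2):
                assert math.isnan(expect)
            else:
                assert r.r2 == pytest.approx(expect, abs=1e-12)

    def test_square_matrix_is_symmetric(self):
        gm = _gm(np.random.default_rng(1).choice([0, 0.5, 1], (30, 4)))
        recs = ld_matrix(gm, min_n=20)
        mat = square_r2_matrix(gm, recs).to_numpy()
        assert np.allclose(mat, mat.T, equal_nan=True)
        assert np.all(np.diag(mat) == 1.0)


class TestDecayAndPartition:
    def test_single_record_single_bin(self):
        gm = _gm(np.random.default_rng(2).choice([0, 0.5, 1], (30, 2)),
                 positions=[10, 110])
        (rec,) = ld_matrix(gm, min_n=20)
        table = ld_decay([rec], [0, 200])
        assert table.loc[0, "mean_r2"] == pytest.approx(rec.r2)
        assert table.loc[0, "n_pairs"] == 1

    def test_empty_bins_reported(self):
        gm = _gm(np.random.default_rng(2).choice([0, 0.5, 1], (30, 2)),
                 positions=[10, 110])
        recs = ld_matrix(gm, min_n=20)
        table = ld_decay(recs, [0, 50, 150, 250])
        assert list(table["n_pairs"]) == [0, 1, 0]

    def test_no_distances_errors(self):
        gm = _gm(np.random.default_rng(2).choice([0, 0.5, 1], (30, 2)))
        recs = ld_matrix(gm, min_n=20)
        for r in recs:
            r.distance = math.nan
        with pytest.raises(ValueError):
            ld_decay(recs, [0, 100])

    def test_block_ld_exceeds_background_and_decays(self):
        cfg = default_config(5)
        ds = simulate_two_pop_dataset(cfg)
        pds = Dataset(ds.alignments, ds.samples)
        (records,) = run_ld(pds, ["aglaope", "amaryllis"], pool=True).values()
        sel = set(ds.selected_positions)
        in_block = [r.r2 for r in records
                    if (r.locus_i, r.pos_i) in sel and (r.locus_j, r.pos_j) in sel]
        background = [r.r2 for r in records if not math.isnan(r.r2)
                      and not ((r.locus_i, r.pos_i) in sel
                               and (r.locus_j, r.pos_j) in sel)]
        assert np.mean(in_block) > 0.5
        assert np.mean(background) < 0.3

    def test_removing_associated_sites_collapses_long_range_ld(self):
        cfg = default_config(8)
        ds = simulate_two_pop_dataset(cfg)
        pds = Dataset(ds.alignments, ds.samples)
        assoc = run_association(pds)
        (records,) = run_ld(pds, ["aglaope", "amaryllis"], pool=True).values()
        records = partition_sites_by_association(records, assoc)
        far = [r for r in records if not math.isnan(r.distance) and r.distance > 2000]
        all_far = [r.r2 for r in far if not math.isnan(r.r2)]
        removed_far = [r.r2 for r in filter_pairs(far, "associated_removed", assoc)
                       if not math.isnan(r.r2)]
        assert np.mean(removed_far) < np.mean(all_far)
        assert np.mean(removed_far) < 0.1  # long-distance LD virtually disappears

    def test_partition_classes(self):
        assoc = [
            SiteAssociation("l", 1, 10, 5.0, 1e-6, 6.0, True),
            SiteAssociation("l", 2, 10, 5.0, 1e-6, 6.0, True),
            SiteAssociation("l", 3, 10, 0.1, 0.7, 0.15, False),
        ]
        gm = _gm(np.random.default_rng(3).choice([0, 0.5, 1], (30, 3)),
                 positions=[1, 2, 3])
        recs = partition_sites_by_association(ld_matrix(gm, 20), assoc)
        classes = {((r.pos_i, r.pos_j)): r.pair_class for r in recs}
        assert classes[(1, 2)] == "both_associated"
        assert classes[(1, 3)] == "other"
        removed = filter_pairs(recs, "associated_removed", assoc)
        assert removed == []  # every pair touches a significant site except (3,)
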