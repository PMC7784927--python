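"""Population generator: allele frequencies, LD decay, the tetrasomic gamete
law, trait architecture, and the read-count model."""

import numpy as np
import pytest
from scipy import stats

import tetragp as tg
from tetragp.data import truncated_poisson_mean
from tetragp.simpop import make_gamete, random_cross_plan

from conftest import make_parent


class TestFounders:
    def test_allele_frequency_matches_target(self, one_chrom_map):
        # 2500 founders = 10,000 haplotypes; binomial sampling oracle:
        # sd of the empirical frequency is sqrt(.3*.7/1e4) ~ 0.0046
        founders = tg.simulate_founders(
            2500, one_chrom_map, maf_range=(0.3, 0.3), ld_rho=0.0, seed=1
        )
        freq = founders.haplotypes.reshape(-1, one_chrom_map.n_markers).mean(axis=0)
        assert np.all(np.abs(freq - 0.30) < 0.02)

    def test_independent_markers_uncorrelated(self, one_chrom_map):
        founders = tg.simulate_founders(
            1000, one_chrom_map, maf_range=(0.4, 0.4), ld_rho=0.0, seed=2
        )
        haps = founders.haplotypes.reshape(-1, one_chrom_map.n_markers).astype(float)
        r = np.corrcoef(haps[:, 0], haps[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_ld_decays_with_distance(self):
        mm = tg.simulate_marker_map(n_chrom=1, markers_per_chrom=40, seed=3)
        founders = tg.simulate_founders(
            1500, mm, maf_range=(0.5, 0.5), ld_rho=0.9, seed=3
        )
        haps = founders.haplotypes.reshape(-1, mm.n_markers).astype(float)
        adj = np.mean([np.corrcoef(haps[:, k], haps[:, k + 1])[0, 1] for k in range(20)])
        far = np.mean([np.corrcoef(haps[:, k], haps[:, k + 10])[0, 1] for k in range(20)])
        assert adj > far
        # Markov-chain oracle: corr at lag k decays as rho^k
        assert adj == pytest.approx(0.9, abs=0.05)
        assert far == pytest.approx(0.9**10, abs=0.1)

    def test_invalid_arguments(self, one_chrom_map):
        with pytest.raises(ValueError):
            tg.simulate_founders(10, one_chrom_map, ld_rho=1.0)
        with pytest.raises(ValueError):
            tg.simulate_founders(10, one_chrom_map, maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            tg.MarkerMap([], [], [], [])


class TestGameteLaw:
    @pytest.mark.parametrize("dosage", [0, 1, 2, 3, 4])
    def test_hypergeometric_gamete_counts(self, dosage, one_chrom_map):
        """Bivalent pairing transmits 2 of the parent's 4 homologs, so the
        single-locus gamete allele count is hypergeometric(4, d, 2)."""
        parent = make_parent(dosage, one_chrom_map.n_markers)
        rng = np.random.default_rng(10 + dosage)
        counts = np.zeros(3, dtype=int)
        n_draws = 10_000
        for _ in range(n_draws):
            g = make_gamete(parent, one_chrom_map, rng)
            counts[int(g[:, 0].sum())] += 1
        expected = stats.hypergeom(4, dosage, 2).pmf([0, 1, 2]) * n_draws
        keep = expected > 0
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1) if keep.sum() > 1 else 1.0
        assert p > 1e-3
        assert counts[~keep].sum() == 0

    def test_duplex_probabilities(self, one_chrom_map):
        # duplex parent: P(0)=1/6, P(1)=4/6, P(2)=1/6
        parent = make_parent(2, one_chrom_map.n_markers)
        rng = np.random.default_rng(5)
        draws = np.array(
            [make_gamete(parent, one_chrom_map, rng)[:, 3].sum() for _ in range(6000)]
        )
        assert np.mean(draws == 1) == pytest.approx(4 / 6, abs=0.03)
        assert np.mean(draws == 0) == pytest.approx(1 / 6, abs=0.03)

    def test_bad_parent_shape(self, one_chrom_map):
        with pytest.raises(ValueError):
            make_gamete(np.zeros((3, one_chrom_map.n_markers)), one_chrom_map)


class TestCrosses:
    def test_fixed_dosage_crosses(self, one_chrom_map):
        m = one_chrom_map.n_markers
        haps = np.stack([make_parent(0, m), make_parent(4, m)])
        founders = tg.FounderHaplotypes(["null", "quad"], haps)
        ped, dos, _ = tg.simulate_crosses(
            founders, [("null", "null", 20), ("quad", "null", 20)], one_chrom_map, seed=1
        )
        assert np.all(dos[np.asarray(ped.family_id) == "F001"] == 0)
        assert np.all(dos[np.asarray(ped.family_id) == "F002"] == 2)

    def test_duplex_cross_moments(self, one_chrom_map):
        """Offspring dosage of duplex x duplex is the convolution of two
        hypergeometric gamete draws: mean 2, variance 2/3 (enumerated)."""
        m = one_chrom_map.n_markers
        founders = tg.FounderHaplotypes(["d1", "d2"], np.stack([make_parent(2, m)] * 2))
        _, dos, _ = tg.simulate_crosses(founders, [("d1", "d2", 600)], one_chrom_map, seed=2)
        gam = stats.hypergeom(4, 2, 2).pmf([0, 1, 2])
        conv = np.convolve(gam, gam)  # offspring dosage pmf over 0..4
        exp_mean = (np.arange(5) * conv).sum()
        exp_var = (np.arange(5) ** 2 * conv).sum() - exp_mean**2
        vals = dos[:, 0]
        assert vals.mean() == pytest.approx(exp_mean, abs=0.1)
        assert vals.var() == pytest.approx(exp_var, abs=0.15)

    def test_unknown_parent_errors(self, one_chrom_map):
        founders = tg.simulate_founders(3, one_chrom_map, seed=1)
        with pytest.raises(KeyError):
            tg.simulate_crosses(founders, [("P001", "nope", 5)], one_chrom_map)

    def test_random_plan_unequal_sizes(self):
        plan = random_cross_plan([f"P{i}" for i in range(20)], 15, 12, size_cv=0.4, seed=3)
        sizes = [n for _, _, n in plan]
        assert len(set(sizes)) > 1 and min(sizes) >= 2
        assert np.mean(sizes) == pytest.approx(12, abs=3)


class TestPhenotypes:
    def _dosages(self, n=1000, m=200, seed=0):
        rng = np.random.default_rng(seed)
        return rng.integers(0, 5, size=(n, m))

    def test_realized_h2(self):
        d = self._dosages()
        arch = tg.TraitArchitecture(n_qtl=50, h2=0.5, year_effects=(0.0,))
        rec, truth = tg.simulate_phenotypes(
            d, [f"i{k}" for k in range(1000)], [f"m{j}" for j in range(200)],
            arch, years=(2014,), seed=1,
        )
        vg = np.var(truth.g_true)
        vp = np.var(rec["value"].to_numpy())
        assert vg / vp == pytest.approx(0.5, abs=0.05)
        # law of total variance: regression of phenotype on g_true has slope 1
        slope = np.polyfit(truth.g_true, rec["value"].to_numpy(), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_h2_one_is_noise_free(self):
        d = self._dosages(n=50)
        arch = tg.TraitArchitecture(n_qtl=20, h2=1.0, year_effects=(0.0, 3.0))
        rec, _ = tg.simulate_phenotypes(
            d, [f"i{k}" for k in range(50)], [f"m{j}" for j in range(200)],
            arch, years=(2014, 2015), seed=2,
        )
        wide = rec.pivot(index="individual", columns="year", values="value")
        diff = wide[2015] - wide[2014]
        assert np.allclose(diff, 3.0)

    def test_zero_genetic_variance_errors(self):
        d = np.full((50, 10), 2)  # constant dosages -> zero genetic variance
        arch = tg.TraitArchitecture(n_qtl=5, h2=0.5, year_effects=(0.0,))
        with pytest.raises(ValueError, match="variance"):
            tg.simulate_phenotypes(
                d, [f"i{k}" for k in range(50)], [f"m{j}" for j in range(10)],
                arch, years=(2014,), seed=3,
            )

    def test_architecture_validation(self):
        with pytest.raises(ValueError):
            tg.TraitArchitecture(n_qtl=10, h2=0.0)
        with pytest.raises(ValueError):
            tg.TraitArchitecture(n_qtl=0, h2=0.5)


class TestReadCounts:
    def test_homozygous_boundaries(self):
        d0 = np.zeros((20, 30), dtype=int)
        rc = tg.simulate_read_counts(
            d0, [f"i{k}" for k in range(20)], [f"m{j}" for j in range(30)],
            mean_depth=30, error_rate=0.0, seed=1,
        )
        assert rc.ao.sum() == 0
        rc4 = tg.simulate_read_counts(
            d0 + 4, [f"i{k}" for k in range(20)], [f"m{j}" for j in range(30)],
            mean_depth=30, error_rate=0.0, seed=2,
        )
        assert rc4.ro.sum() == 0

    def test_duplex_ratio_unbiased(self):
        d = np.full((100, 200), 2)
        rc = tg.simulate_read_counts(
            d, [f"i{k}" for k in range(100)], [f"m{j}" for j in range(200)],
            mean_depth=60, error_rate=0.0, seed=3,
        )
        assert rc.ratios().mean() == pytest.approx(0.5, abs=0.01)

    def test_min_depth_and_truncated_mean(self):
        d = np.full((200, 200), 1)
        rc = tg.simulate_read_counts(
            d, [f"i{k}" for k in range(200)], [f"m{j}" for j in range(200)],
            mean_depth=2.0, min_depth=2, seed=4,
        )
        depth = rc.depth
        assert depth.min() >= 2
        # brute-force enumeration of the truncated pmf as the oracle
        lam, t, kmax = 2.0, 2, 200
        pmf = np.array([stats.poisson.pmf(k, lam) for k in range(kmax)])
        pmf[:t] = 0.0
        oracle_mean = (np.arange(kmax) * pmf).sum() / pmf.sum()
        assert depth.mean() == pytest.approx(oracle_mean, abs=0.02)
        assert truncated_poisson_mean(lam, t) == pytest.approx(oracle_mean, abs=1e-9)

    def test_error_rate_validation(self):
        d = np.zeros((2, 2), dtype=int)
        with pytest.raises(ValueError):
            tg.simulate_read_counts(d, ["a", "b"], ["x", "y"], 10, error_rate=0.5)

    def test_error_rate_shifts_homozygote_ratio(self):
        d = np.zeros((50, 100), dtype=int)
        rc = tg.simulate_read_counts(
            d, [f"i{k}" for k in range(50)], [f"m{j}" for j in range(100)],
            mean_depth=100, error_rate=0.01, seed=5,
        )
        assert rc.ratios().mean() == pytest.approx(0.01, abs=0.003)
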