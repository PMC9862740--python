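import hashlib

import numpy as np
import pytest

from conftest import make_hap_panel
from dogsel.fst import wc_fst_components
from dogsel.synthetic import (
    AutozygositySpec,
    SimulationParams,
    SweepSpec,
    draw_breed_freqs,
    inject_autozygosity,
    inject_sweep,
    round_half_up,
    sample_mosaic_haplotypes,
    simulate_dataset,
)


class TestBreedFreqs:
    def test_no_drift_limit(self):
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(draw_breed_freqs(0.5, 0.0, rng), [0.5])

    def test_beta_moments(self):
        """Beta(p(1-F)/F, (1-p)(1-F)/F) has mean p and variance F p (1-p)."""
        rng = np.random.default_rng(1)
        draws = draw_breed_freqs(np.full(100_000, 0.5), 0.2, rng)
        assert abs(draws.mean() - 0.5) < 0.01
        assert abs(draws.var() - 0.2 * 0.25) < 0.005

    def test_support_and_degenerate_F(self):
        rng = np.random.default_rng(2)
        draws = draw_breed_freqs(np.full(1000, 0.01), 0.3, rng)
        assert (draws >= 0).all() and (draws <= 1).all()
        assert np.median(draws) < 0.01  # mass near 0
        with pytest.raises(ValueError):
            draw_breed_freqs(0.5, 1.0, rng)


class TestMosaic:
    def test_single_founder_and_zero_recomb(self):
        rng = np.random.default_rng(3)
        pool1 = rng.integers(0, 2, size=(1, 50))
        pos = np.arange(1, 51) * 1000
        out = sample_mosaic_haplotypes(pool1, 5, 1e-6, pos, np.random.default_rng(0))
        assert (out == pool1[0]).all()
        pool = rng.integers(0, 2, size=(4, 50))
        out = sample_mosaic_haplotypes(pool, 20, 0.0, pos, np.random.default_rng(0))
        for row in out:
            assert any((row == f).all() for f in pool)

    def test_switch_rate_poisson_mean(self):
        """1e-8 switches/bp over 10 Mb -> ~0.1 switches per haplotype."""
        rng = np.random.default_rng(4)
        # founders chosen maximally distinguishable: all-0 vs all-1
        pool = np.vstack([np.zeros(100, np.int8), np.ones(100, np.int8)])
        pos = np.linspace(1, 10_000_000, 100).astype(np.int64)
        out = sample_mosaic_haplotypes(pool, 10_000, 1e-8, pos, rng)
        switches = (np.abs(np.diff(out, axis=1)).sum(axis=1)).mean()
        assert 0.05 < switches < 0.15  # Poisson mean 0.1, but switches can be silent

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_mosaic_haplotypes(np.empty((0, 5)), 1, 0.0, np.arange(5), np.random.default_rng(0))


class TestInjection:
    def _panel(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        pos = np.arange(1, 201) * 10_000  # 2 Mb, 200 snps
        return make_hap_panel(
            rng.integers(0, 2, size=(2 * n, 200)), positions=pos,
            groups=["LGD"] * (n // 2) + ["HSD"] * (n - n // 2),
        )

    def test_full_sweep_makes_target_identical(self):
        panel = self._panel()
        spec = SweepSpec(chrom="1", center_bp=1_000_000, span_bp=400_000,
                         target_group="LGD", carrier_freq=1.0, background_freq=0.0)
        out = inject_sweep(panel, spec, seed=1)
        bp = out.bp()
        cols = np.flatnonzero((bp >= spec.start_bp) & (bp <= spec.end_bp))
        rows = out.group_rows("LGD")
        span = out.alleles[np.ix_(rows, cols)]
        assert (span == span[0]).all()

    def test_sweep_freq_difference(self):
        panel = self._panel(seed=5)
        spec = SweepSpec(chrom="1", center_bp=1_000_000, span_bp=400_000,
                         target_group="LGD", carrier_freq=0.8, background_freq=0.1)
        bp = panel.bp()
        cols = np.flatnonzero((bp >= spec.start_bp) & (bp <= spec.end_bp))
        # start from a span monomorphic for ref, donor haplotype all-alt, so
        # the post-injection frequency difference is countable directly
        panel.alleles[:, cols] = 0
        panel.alleles[panel.group_rows("LGD")[0], cols] = 1
        out = inject_sweep(panel, spec, seed=2)
        rows_t = out.group_rows("LGD")
        rows_o = out.group_rows("HSD")
        f_t = out.alleles[np.ix_(rows_t, cols)].mean(axis=0)
        f_o = out.alleles[np.ix_(rows_o, cols)].mean(axis=0)
        # carriers: round(0.8*30)=24 target, round(0.1*30)=3 other haplotypes
        assert (f_t == 24 / 30).all() and (f_o == 3 / 30).all()
        assert (f_t - f_o >= 0.5).all()

    def test_sweep_invariant_violation(self):
        with pytest.raises(ValueError):
            SweepSpec(chrom="1", center_bp=1, span_bp=2, target_group="LGD",
                      carrier_freq=0.5, background_freq=0.5)

    def test_autozygosity_carrier_count_and_untouched_rows(self):
        panel = self._panel(seed=6, n=30)  # 15 LGD + 15 HSD
        spec = AutozygositySpec(chrom="1", start_bp=200_000, end_bp=1_200_000,
                                target_group="HSD", carrier_fraction=0.6)
        out, carriers = inject_autozygosity(panel, spec, seed=3)
        assert len(carriers) == round_half_up(0.6 * 15) == 9
        bp = np.array([m.bp for m in out.markers])
        cols = (bp >= spec.start_bp) & (bp <= spec.end_bp)
        for i, s in enumerate(out.samples):
            row0, row1 = out.alleles[2 * i], out.alleles[2 * i + 1]
            if s.id in carriers:
                assert (row0[cols] == row1[cols]).all()
            else:
                np.testing.assert_array_equal(row1, panel.alleles[2 * i + 1])
            # outside the interval nothing changes for anyone
            np.testing.assert_array_equal(row1[~cols], panel.alleles[2 * i + 1][~cols])

    def test_full_carrier_fraction(self):
        panel = self._panel(seed=7)
        spec = AutozygositySpec(chrom="1", start_bp=200_000, end_bp=1_200_000,
                                target_group="LGD", carrier_fraction=1.0)
        out, carriers = inject_autozygosity(panel, spec, seed=4)
        geno = out.collapse()
        bp = geno.bp()
        cols = (bp >= spec.start_bp) & (bp <= spec.end_bp)
        rows = [i for i, s in enumerate(out.samples) if s.group == "LGD"]
        assert np.isin(geno.dosage[np.ix_(rows, np.flatnonzero(cols))], (0, 2)).all()

    def test_interval_without_markers_rejected(self):
        panel = self._panel()
        with pytest.raises(ValueError, match="0 markers"):
            inject_autozygosity(
                panel,
                AutozygositySpec(chrom="2", start_bp=1, end_bp=2, target_group="LGD",
                                 carrier_fraction=0.5),
                seed=0,
            )


def _hash_dir(d):
    h = hashlib.sha256()
    for f in sorted(p for p in d.iterdir() if p.is_file()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


class TestSimulateDataset:
    PARAMS = SimulationParams(
        breeds=(("A", "LGD", 5), ("B", "HSD", 5)), n_chrom=1,
        chrom_length_bp=5_000_000, n_snp_per_chrom=500, fst_drift=0.1, seed=11,
    )

    def test_shape(self):
        hap, geno, _ = simulate_dataset(self.PARAMS)
        assert hap.alleles.shape == (20, 500)
        assert geno.dosage.shape == (10, 500)

    def test_determinism_hash_equal(self, tmp_path):
        simulate_dataset(self.PARAMS, out_dir=tmp_path / "a")
        simulate_dataset(self.PARAMS, out_dir=tmp_path / "b")
        assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")

    def test_neutral_flanks_unaffected_by_injection(self):
        sweep = SweepSpec(chrom="1", center_bp=2_500_000, span_bp=400_000,
                          target_group="LGD", carrier_freq=0.9, background_freq=0.0)
        hap0, _, _ = simulate_dataset(self.PARAMS)
        hap1, _, _ = simulate_dataset(self.PARAMS, sweeps=[sweep])
        bp = np.array([m.bp for m in hap0.markers])
        flank = (bp < sweep.start_bp) | (bp > sweep.end_bp)
        np.testing.assert_array_equal(hap0.alleles[:, flank], hap1.alleles[:, flank])

    def test_overlapping_specs_flagged(self):
        sweep = SweepSpec(chrom="1", center_bp=2_500_000, span_bp=400_000,
                          target_group="LGD", carrier_freq=0.9, background_freq=0.0)
        auto = AutozygositySpec(chrom="1", start_bp=2_400_000, end_bp=2_600_000,
                                target_group="LGD", carrier_fraction=0.5)
        _, _, truth = simulate_dataset(self.PARAMS, [sweep], [auto])
        assert truth["overlap_flags"]

    def test_two_deme_fst_matches_monte_carlo_oracle(self):
        """Generator differentiation agrees with the Balding-Nichols oracle.

        Oracle: BN beta frequencies + binomial genotypes, WC theta averaged
        over SNPs, computed by an independent code path.
        """
        rng = np.random.default_rng(99)
        M, n, F = 50_000, 30, 0.2
        anc = rng.uniform(0.05, 0.95, M)
        p1 = draw_breed_freqs(anc, F, rng)
        p2 = draw_breed_freqs(anc, F, rng)
        g1 = rng.binomial(2, p1, size=(n, M))
        g2 = rng.binomial(2, p2, size=(n, M))

        def stats(g):
            return np.full(M, float(n)), g.mean(0) / 2, (g == 1).mean(0)

        a, b, c = wc_fst_components(*stats(g1), *stats(g2))
        with np.errstate(invalid="ignore"):
            oracle = np.nanmean(a / (a + b + c))

        from dogsel.fst import fst_scan

        params = SimulationParams(
            breeds=(("A", "LGD", 30), ("B", "HSD", 30)), n_chrom=1,
            chrom_length_bp=50_000_000, n_snp_per_chrom=5000, fst_drift=F,
            founder_pool_size=200, seed=7,
        )
        _, geno, _ = simulate_dataset(params)
        fd = fst_scan(geno, "LGD", "HSD")
        assert abs(np.nanmean(fd.theta) - oracle) < 0.03
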