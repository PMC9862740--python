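import numpy as np
import pytest

from conftest import make_markers, make_panel
from dogsel.core_data import MISSING
from dogsel.roh import (
    ROHParams,
    detect_roh,
    detect_roh_sample,
    h_scores,
    nearest_rank_threshold,
    top_hscore_islands,
)
from dogsel.synthetic import AutozygositySpec, SimulationParams, simulate_dataset


def hom_run_positions(n_snps, span_bp, start=1_000_000):
    """n_snps positions whose closed span is exactly span_bp, gaps < 100 kb."""
    step = span_bp // n_snps
    pos = [start + i * step for i in range(n_snps - 1)]
    pos.append(start + span_bp - 1)
    assert pos[-1] - pos[0] + 1 == span_bp
    return np.array(pos)


def run_single(positions, dosage_row, params=None):
    markers = make_markers(positions)
    return detect_roh_sample(np.asarray(dosage_row, dtype=np.int8), markers,
                             params or ROHParams(), sample_id="s0")


class TestRohCriteria:
    def test_clean_run_detected(self):
        pos = hom_run_positions(60, 1_200_000)
        segs = run_single(pos, [2] * 60)
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start_bp, seg.end_bp, seg.n_snps) == (pos[0], pos[-1], 60)

    @pytest.mark.parametrize("n_snps,detected", [(49, False), (50, True)])
    def test_min_snp_count_boundary(self, n_snps, detected):
        pos = hom_run_positions(n_snps, 1_200_000)
        segs = run_single(pos, [0] * n_snps)
        assert bool(segs) is detected

    @pytest.mark.parametrize("span,detected", [(900_000, False), (1_000_000, True)])
    def test_min_length_boundary(self, span, detected):
        pos = hom_run_positions(60, span)
        segs = run_single(pos, [2] * 60)
        assert bool(segs) is detected

    @pytest.mark.parametrize("span,detected", [(3_600_000, False), (3_000_000, True)])
    def test_density_boundary(self, span, detected):
        # 60 SNPs over 3.6 Mb = 60 kb/SNP > 50 kb fails; 3.0 Mb = 50 kb passes
        pos = hom_run_positions(60, span)
        segs = run_single(pos, [2] * 60)
        assert bool(segs) is detected

    @pytest.mark.parametrize("gap,detected", [(101_000, False), (100_000, True)])
    def test_gap_boundary(self, gap, detected):
        # two 30-SNP halves, 20 kb spacing inside, variable central gap
        left = 1_000_000 + 20_000 * np.arange(30)
        right = left[-1] + gap + 20_000 * np.arange(30)
        pos = np.concatenate([left, right])
        segs = run_single(pos, [2] * 60)
        assert bool(segs) is detected
        if not detected:  # each half alone fails the 50-SNP criterion
            assert segs == []

    def test_het_breaks_run(self):
        pos = hom_run_positions(60, 1_200_000)
        row = [2] * 60
        row[30] = 1
        assert run_single(pos, row) == []

    def test_missing_tolerated_up_to_limit(self):
        pos = hom_run_positions(60, 1_200_000)
        row = np.full(60, 2, dtype=np.int8)
        row[10:15] = MISSING  # 5 missing allowed
        segs = run_single(pos, row)
        assert len(segs) == 1 and segs[0].n_missing == 5
        row[20] = MISSING  # 6th missing splits the run
        assert all(s.n_snps < 60 for s in run_single(pos, row))

    def test_unsorted_markers_rejected(self):
        markers = make_markers([100, 50])
        markers = [markers[0], markers[1]]
        with pytest.raises(ValueError):
            detect_roh_sample(np.array([0, 0], dtype=np.int8),
                              [make_markers([100])[0], make_markers([50])[0]])

    def test_property_reported_segments_satisfy_invariants(self):
        rng = np.random.default_rng(0)
        params = ROHParams(min_snps=10, min_length_bp=50_000, max_gap_bp=20_000,
                           max_bp_per_snp=10_000)
        for _ in range(20):
            m = 300
            pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=m, replace=False))
            row = rng.choice([0, 1, 2, 2, 0, 0], size=m).astype(np.int8)
            for seg in run_single(pos, row, params):
                assert seg.n_snps >= params.min_snps
                assert seg.end_bp - seg.start_bp + 1 >= params.min_length_bp
                assert (seg.end_bp - seg.start_bp + 1) / seg.n_snps <= params.max_bp_per_snp
                inside = (pos >= seg.start_bp) & (pos <= seg.end_bp)
                assert np.all(np.diff(pos[inside]) <= params.max_gap_bp)
                assert not np.any(row[inside] == 1)  # max_het=0


class TestHScores:
    def _panel_with_block(self, n_carriers, n_samples=10):
        pos = hom_run_positions(100, 1_500_000)
        rows = []
        rng = np.random.default_rng(1)
        for i in range(n_samples):
            if i < n_carriers:
                rows.append(np.full(100, 2, dtype=np.int8))
            else:
                rows.append(rng.choice([0, 1, 2], size=100).astype(np.int8))
        return make_panel(rows, positions=pos, groups=["G"] * n_samples)

    def test_fraction_of_group(self):
        panel = self._panel_with_block(6)
        segs = detect_roh(panel)
        track = h_scores(segs, panel, "G")
        assert track.max() == pytest.approx(0.6)
        assert track.min() >= 0.0

    def test_marker_outside_all_segments_is_zero(self):
        panel = self._panel_with_block(0)
        track = h_scores(detect_roh(panel), panel, "G")
        assert (track == 0).all()

    def test_group_size_scaling_keeps_interior_score(self):
        small = self._panel_with_block(5, n_samples=10)
        big = self._panel_with_block(10, n_samples=20)
        t_small = h_scores(detect_roh(small), small, "G")
        t_big = h_scores(detect_roh(big), big, "G")
        assert t_small.max() == t_big.max() == 0.5


class TestIslands:
    def test_single_block(self):
        pos = 1_000_000 + 10_000 * np.arange(500)
        track = np.zeros(500)
        track[200:260] = 0.7
        markers = make_markers(pos)
        islands = top_hscore_islands(track, markers, group="G")
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.start_bp, isl.end_bp) == (pos[200], pos[259])
        assert isl.n_top_snps == 60 and isl.peak_h_score == 0.7

    def test_two_distant_blocks_not_merged(self):
        pos = 1_000_000 + 10_000 * np.arange(1000)
        track = np.zeros(1000)
        track[100:110] = 0.5
        track[400:410] = 0.5  # 3 Mb away > merge_gap 500 kb
        islands = top_hscore_islands(track, make_markers(pos), group="G")
        assert len(islands) == 2

    def test_all_zero_track_warns_empty(self):
        with pytest.warns(UserWarning, match="zero"):
            assert top_hscore_islands(np.zeros(100), make_markers(1000 * np.arange(1, 101))) == []

    def test_min_island_snps_filter(self):
        pos = 1_000_000 + 10_000 * np.arange(500)
        track = np.zeros(500)
        track[10:12] = 0.9  # only two members
        islands = top_hscore_islands(track, make_markers(pos), min_island_snps=3)
        assert islands == []


def test_nearest_rank_top_set():
    vals = np.arange(1, 1001, dtype=float)
    assert nearest_rank_threshold(vals, 0.01) == 991.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_injected_autozygosity_recovered(seed):
    """Carrier-fraction truth is recovered exactly in interior H-scores."""
    params = SimulationParams(
        breeds=(("A", "LGD", 20), ("B", "HSD", 20)), n_chrom=1,
        chrom_length_bp=20_000_000, n_snp_per_chrom=2000, fst_drift=0.1, seed=seed,
    )
    spec = AutozygositySpec(chrom="1", start_bp=5_000_000, end_bp=6_500_000,
                            target_group="LGD", carrier_fraction=0.6)
    _, geno, truth = simulate_dataset(params, autozygosity_specs=[spec])
    segs = detect_roh(geno)
    track = h_scores(segs, geno, "LGD")
    bp = geno.bp()
    interior = (bp >= spec.start_bp + 200_000) & (bp <= spec.end_bp - 200_000)
    assert set(np.unique(track[interior])) == {0.6}
    islands = top_hscore_islands(track, geno.markers, group="LGD")
    assert len(islands) == 1
    assert abs(islands[0].start_bp - spec.start_bp) <= 100_000
    assert abs(islands[0].end_bp - spec.end_bp) <= 100_000
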