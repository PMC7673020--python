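"""Simulator contracts: map function, Mendelian expectations, linkage,
trait variance decomposition, masking, and the diversity panel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rilsweep.core import MISSING
from rilsweep.simulate import (
    PanelSimConfig,
    RILSimConfig,
    TraitSimConfig,
    default_marker_map,
    haldane_r,
    mask_genotypes,
    simulate_diversity_panel,
    simulate_ril_population,
    simulate_trait,
)
from rilsweep.sweep import WindowSpec, windowed_pi

from conftest import make_map


class TestHaldane:
    def test_closed_form_values(self):
        assert haldane_r(0.0) == 0.0
        # (1 - exp(-1)) / 2, evaluated independently
        assert haldane_r(50.0) == pytest.approx(0.31606027941427883, abs=1e-12)
        assert haldane_r(10_000.0) > 0.4999

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_r(-1.0)

    @given(st.floats(min_value=0.0, max_value=1e4),
           st.floats(min_value=0.0, max_value=1e4))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_bounded(self, d1, d2):
        r1, r2 = haldane_r(d1), haldane_r(d2)
        assert 0.0 <= r1 <= 0.5
        if d1 <= 500:  # strictly below 1/2 wherever that is representable
            assert r1 < 0.5
        if d1 < d2:
            assert r1 <= r2


class TestRILPopulation:
    def test_heterozygosity_halves_per_selfing_generation(self):
        mp = make_map(n_markers=20, spacing_cM=5.0)
        for g in (1, 3, 6):
            cfg = RILSimConfig(n_lines=2000, n_chrom=1, markers_per_chrom=20,
                               selfing_generations=g, seed=11 + g)
            G = simulate_ril_population(mp, cfg)
            expected = 0.5**g
            se = np.sqrt(expected * (1 - expected) / cfg.n_lines)
            # single-marker binomial check at a mid-chromosome marker
            het = (G.calls[:, 10] == 1).mean()
            assert abs(het - expected) < 3 * se

    def test_parent_b_allele_frequency_half(self):
        mp = make_map(n_markers=10, spacing_cM=10.0)
        cfg = RILSimConfig(n_lines=2000, n_chrom=1, markers_per_chrom=10, seed=7)
        G = simulate_ril_population(mp, cfg)
        freq = G.calls[:, 4].mean() / 2.0  # dosage mean / 2
        se = np.sqrt(0.25 / (2 * cfg.n_lines))
        assert abs(freq - 0.5) < 3 * se

    def test_zero_distance_markers_identical(self):
        import pandas as pd
        from rilsweep.core import MarkerMap
        rows = [("m1", "chr01", 100, 1.0), ("m2", "chr01", 200, 1.0),
                ("m3", "chr01", 300, 21.0)]
        mp = MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))
        cfg = RILSimConfig(n_lines=300, n_chrom=1, markers_per_chrom=3, seed=3)
        G = simulate_ril_population(mp, cfg)
        assert np.array_equal(G.calls[:, 0], G.calls[:, 1])

    def test_linkage_decays_with_distance(self):
        mp = make_map(n_markers=80, spacing_cM=1.0)
        cfg = RILSimConfig(n_lines=600, n_chrom=1, markers_per_chrom=80, seed=5)
        G = simulate_ril_population(mp, cfg).calls.astype(float)
        anchor = G[:, 0]
        r2 = np.array([np.corrcoef(anchor, G[:, j])[0, 1] ** 2 for j in range(1, 80)])
        # mean r^2 over distance bins must decrease monotonically
        bins = [r2[i * 16:(i + 1) * 16].mean() for i in range(4)]
        assert all(a > b for a, b in zip(bins, bins[1:]))

    def test_deterministic_given_seed(self):
        mp = make_map(n_markers=15)
        cfg = RILSimConfig(n_lines=50, n_chrom=1, markers_per_chrom=15, seed=42)
        assert simulate_ril_population(mp, cfg) == simulate_ril_population(mp, cfg)

    def test_empty_map_rejected(self):
        import pandas as pd
        from rilsweep.core import MarkerMap
        empty = MarkerMap(pd.DataFrame(columns=list(MarkerMap.COLUMNS)))
        with pytest.raises(ValueError):
            simulate_ril_population(empty, RILSimConfig(seed=1))


class TestTrait:
    @pytest.mark.parametrize("pve", [0.0, 0.1, 0.19, 0.5])
    def test_variance_explained_recovered(self, pve):
        """Mean causal-marker R^2 over 200 replicates matches the simulated
        QTL variance fraction (null expectation ~1/(n-1) when pve = 0)."""
        mp = make_map(n_markers=60, spacing_cM=1.5)
        r2 = []
        for rep in range(200):
            cfg = RILSimConfig(n_lines=219, n_chrom=1, markers_per_chrom=60,
                               seed=1000 + rep)
            G = simulate_ril_population(mp, cfg)
            tcfg = TraitSimConfig(qtl_marker=mp.marker_ids[30], pve_qtl=pve,
                                  seed=2000 + rep)
            y = simulate_trait(G, tcfg)["value"].to_numpy()
            g = G.calls[:, 30].astype(float)
            r2.append(np.corrcoef(y, g)[0, 1] ** 2)
        assert abs(np.mean(r2) - pve) < 0.02

    def test_null_qtl_uncorrelated(self):
        mp = make_map(n_markers=20)
        cfg = RILSimConfig(n_lines=219, n_chrom=1, markers_per_chrom=20, seed=9)
        G = simulate_ril_population(mp, cfg)
        y = simulate_trait(G, TraitSimConfig(qtl_marker=mp.marker_ids[10],
                                             pve_qtl=0.0, seed=10))
        r2 = np.corrcoef(y["value"], G.calls[:, 10].astype(float))[0, 1] ** 2
        assert r2 < 0.05

    def test_deterministic_given_seed(self):
        mp = make_map(n_markers=20)
        cfg = RILSimConfig(n_lines=60, n_chrom=1, markers_per_chrom=20, seed=2)
        G = simulate_ril_population(mp, cfg)
        tcfg = TraitSimConfig(qtl_marker=mp.marker_ids[5], pve_qtl=0.3, seed=4)
        assert simulate_trait(G, tcfg).equals(simulate_trait(G, tcfg))

    def test_constant_qtl_column_rejected(self):
        from conftest import make_matrix
        G = make_matrix(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            simulate_trait(G, TraitSimConfig(qtl_marker=G.marker_ids[0],
                                             pve_qtl=0.1, seed=1))

    def test_invalid_pve_split_rejected(self):
        with pytest.raises(ValueError):
            TraitSimConfig(qtl_marker="m", pve_qtl=0.6, pve_polygenic=0.5)


class TestMasking:
    def test_rate_zero_is_identity(self):
        mp = make_map(n_markers=10)
        cfg = RILSimConfig(n_lines=30, n_chrom=1, markers_per_chrom=10, seed=1)
        G = simulate_ril_population(mp, cfg)
        masked, idx = mask_genotypes(G, 0.0, seed=1)
        assert masked == G and len(idx) == 0

    def test_masked_fraction_binomial(self):
        mp = make_map(n_markers=100)
        cfg = RILSimConfig(n_lines=219, n_chrom=1, markers_per_chrom=100, seed=8)
        G = simulate_ril_population(mp, cfg)
        masked, idx = mask_genotypes(G, 0.1, seed=13)
        n_cells = G.n_lines * G.n_markers
        se = np.sqrt(0.1 * 0.9 / n_cells)
        assert abs(len(idx) / n_cells - 0.1) < 3 * se

    def test_mask_partitions_cells(self):
        mp = make_map(n_markers=50)
        cfg = RILSimConfig(n_lines=40, n_chrom=1, markers_per_chrom=50, seed=3)
        G = simulate_ril_population(mp, cfg)
        masked, idx = mask_genotypes(G, 0.2, seed=5)
        hidden = masked.calls == MISSING
        assert hidden.sum() == len(idx)
        # unchanged everywhere else, and truth recorded correctly
        assert np.array_equal(masked.calls[~hidden], G.calls[~hidden])
        li, mj = idx["line_idx"].to_numpy(), idx["marker_idx"].to_numpy()
        assert np.array_equal(G.calls[li, mj], idx["true_call"].to_numpy())

    def test_invalid_rate_rejected(self):
        mp = make_map(n_markers=5)
        cfg = RILSimConfig(n_lines=10, n_chrom=1, markers_per_chrom=5, seed=1)
        G = simulate_ril_population(mp, cfg)
        with pytest.raises(ValueError):
            mask_genotypes(G, 1.0, seed=1)


class TestDiversityPanel:
    def test_deterministic_given_seed(self):
        cfg = PanelSimConfig(seq_length_bp=200_000, sweep_start_bp=50_001,
                             sweep_end_bp=100_000, seed=6)
        a = simulate_diversity_panel(cfg)
        b = simulate_diversity_panel(cfg)
        assert a[0] == b[0] and a[1] == b[1] and a[2].equals(b[2])

    def test_no_sweep_cohorts_indistinguishable(self):
        cfg = PanelSimConfig(seq_length_bp=2_000_000, sweep_start_bp=500_001,
                             sweep_end_bp=1_000_000, sweep_reduction=1.0, seed=21)
        wild, big, smap = simulate_diversity_panel(cfg)
        spec = WindowSpec()
        pw = windowed_pi(wild, smap, spec, cfg.seq_length_bp)["pi"].mean()
        pb = windowed_pi(big, smap, spec, cfg.seq_length_bp)["pi"].mean()
        assert abs(pw / pb - 1.0) < 0.10

    def test_sweep_scales_cultivar_diversity_linearly(self):
        cfg = PanelSimConfig(seed=22)  # 5 Mb, reduction 0.1, sweep 0.5-1.0 Mb
        wild, big, smap = simulate_diversity_panel(cfg)
        track = windowed_pi(big, smap, WindowSpec(), cfg.seq_length_bp)
        inside = (track["start"] >= cfg.sweep_start_bp) & \
                 (track["end"] <= cfg.sweep_end_bp + 1)
        outside = (track["end"] <= cfg.sweep_start_bp) | \
                  (track["start"] > cfg.sweep_end_bp)
        ratio = track["pi"][inside].mean() / track["pi"][outside].mean()
        assert abs(ratio - cfg.sweep_reduction) < 0.2 * cfg.sweep_reduction

    def test_invalid_sweep_interval_rejected(self):
        with pytest.raises(ValueError):
            PanelSimConfig(seq_length_bp=1000, sweep_start_bp=500, sweep_end_bp=2000)
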