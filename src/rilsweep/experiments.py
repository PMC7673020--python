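"""Replicated simulation experiments over the pipeline's stages.

Each experiment wires generator -> method -> measurement at the study's
design points (219-line RILs, a 19%-PVE firmness-like QTL, the fixed 1e-6
genome-wide threshold, the 53-vs-166 accession diversity panel) and returns
per-replicate measurements, so calibration and recovery claims are
recomputed rather than quoted.  Replicate seeds are derived from one base
seed per experiment label.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .assoc import kinship_vanraden, marker_pve, mlm_scan
from .core import MISSING
from .impute import ImputeConfig, impute_matrix
from .simulate import (
    PanelSimConfig,
    RILSimConfig,
    TraitSimConfig,
    default_marker_map,
    mask_genotypes,
    simulate_diversity_panel,
    simulate_ril_population,
    simulate_trait,
)
from .sweep import WindowSpec, call_sweeps, pi_ratio, sweep_cutoff, windowed_pi

__all__ = [
    "rep_seeds",
    "qtl_replicates",
    "null_scan_replicates",
    "imputation_masking_experiment",
    "panel_pi_calibration",
    "sweep_recovery_replicates",
]


def rep_seeds(seed: int, label: str, n: int) -> list[int]:
    """n deterministic per-replicate seeds (< 2^31) from a base seed."""
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF]
    )
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) >> 1]


def qtl_replicates(n_reps: int = 200, seed: int = 1, pve_qtl: float = 0.19,
                   n_lines: int = 219, n_chrom: int = 12,
                   markers_per_chrom: int = 125,
                   qtl_chrom_index: int = 9, scan: bool = True,
                   p_threshold: float = 1e-6) -> pd.DataFrame:
    """Simulate RIL populations with one additive QTL; per replicate report
    the causal-marker OLS R^2 and (optionally) the mixed-model scan's
    smallest p at or adjacent to the causal marker.

    The QTL sits at the middle marker of chromosome ``qtl_chrom_index``
    (0-based; default the tenth chromosome, mirroring a firmness locus on
    the short arm of chromosome 10).
    """
    base = RILSimConfig(n_lines=n_lines, n_chrom=n_chrom,
                        markers_per_chrom=markers_per_chrom, seed=0)
    marker_map = default_marker_map(base)
    chrom = marker_map.chroms[qtl_chrom_index]
    chrom_ids = marker_map.chrom_slice(chrom)["marker_id"].tolist()
    qtl = chrom_ids[len(chrom_ids) // 2]
    jq = marker_map.index_of(qtl)
    neighborhood = marker_map.marker_ids[max(0, jq - 1):jq + 2]

    geno_seeds = rep_seeds(seed, "qtl-geno", n_reps)
    trait_seeds = rep_seeds(seed, "qtl-trait", n_reps)
    rows = []
    for rep in range(n_reps):
        cfg = RILSimConfig(n_lines=n_lines, n_chrom=n_chrom,
                           markers_per_chrom=markers_per_chrom,
                           seed=geno_seeds[rep])
        G = simulate_ril_population(marker_map, cfg)
        y = simulate_trait(G, TraitSimConfig(qtl_marker=qtl, pve_qtl=pve_qtl,
                                             seed=trait_seeds[rep]))
        row = {"rep": rep,
               "r2": marker_pve(y, G.calls[:, jq].astype(float))}
        if scan:
            K = kinship_vanraden(G)
            res = mlm_scan(G, y, K).set_index("marker_id")
            p_near = float(res.loc[res.index.intersection(neighborhood),
                                   "p_value"].min())
            row["p_at_qtl"] = p_near
            row["hit"] = p_near < p_threshold
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["qtl_marker"] = qtl
    return out


def null_scan_replicates(n_reps: int = 100, seed: int = 1,
                         pve_polygenic: float = 0.3, n_lines: int = 219,
                         n_chrom: int = 10, markers_per_chrom: int = 100,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Polygenic-only (no QTL) traits scanned with the mixed model; per
    replicate report the marker-wise rejection fraction at ``alpha``."""
    base = RILSimConfig(n_lines=n_lines, n_chrom=n_chrom,
                        markers_per_chrom=markers_per_chrom, seed=0)
    marker_map = default_marker_map(base)
    geno_seeds = rep_seeds(seed, "null-geno", n_reps)
    trait_seeds = rep_seeds(seed, "null-trait", n_reps)
    rows = []
    for rep in range(n_reps):
        cfg = RILSimConfig(n_lines=n_lines, n_chrom=n_chrom,
                           markers_per_chrom=markers_per_chrom,
                           seed=geno_seeds[rep])
        G = simulate_ril_population(marker_map, cfg)
        y = simulate_trait(G, TraitSimConfig(
            qtl_marker=marker_map.marker_ids[0], pve_qtl=0.0,
            pve_polygenic=pve_polygenic, seed=trait_seeds[rep]))
        res = mlm_scan(G, y, kinship_vanraden(G))
        rows.append({"rep": rep,
                     "rejection_fraction": float((res["p_value"] < alpha).mean()),
                     "n_markers": len(res)})
    return pd.DataFrame(rows)


def imputation_masking_experiment(seed: int = 1, n_lines: int = 219,
                                  n_chrom: int = 10, markers_per_chrom: int = 100,
                                  missing_rate: float = 0.1,
                                  flank_total: int = 20) -> dict:
    """Mask a fully observed simulated RIL matrix, impute, and score the
    imputed calls against the hidden truth."""
    g_seed, m_seed = rep_seeds(seed, "impute-mask", 2)
    cfg = RILSimConfig(n_lines=n_lines, n_chrom=n_chrom,
                       markers_per_chrom=markers_per_chrom, seed=g_seed)
    marker_map = default_marker_map(cfg)
    G = simulate_ril_population(marker_map, cfg)
    masked, mask_index = mask_genotypes(G, missing_rate, m_seed)
    imputed, report = impute_matrix(masked, ImputeConfig(flank_total=flank_total),
                                    marker_map)
    li = mask_index["line_idx"].to_numpy()
    mj = mask_index["marker_idx"].to_numpy()
    got = imputed.calls[li, mj]
    done = got != MISSING
    truth = mask_index["true_call"].to_numpy()
    return {
        "n_masked": int(len(mask_index)),
        "n_imputed": int(done.sum()),
        "imputed_fraction": float(done.mean()),
        "accuracy": float((got[done] == truth[done]).mean()),
        "report": report,
    }


def panel_pi_calibration(seed: int = 1, cfg: PanelSimConfig | None = None) -> dict:
    """Mean windowed diversity outside the engineered sweep, against the
    simulated per-bp theta."""
    if cfg is None:
        cfg = PanelSimConfig(seed=rep_seeds(seed, "panel-cal", 1)[0])
    wild, big, smap = simulate_diversity_panel(cfg)
    spec = WindowSpec()
    track = windowed_pi(wild, smap, spec, cfg.seq_length_bp)
    outside = (track["end"] <= cfg.sweep_start_bp) | \
              (track["start"] > cfg.sweep_end_bp)
    mean_pi = float(track.loc[outside, "pi"].mean())
    return {"mean_nonsweep_pi": mean_pi, "theta": cfg.theta_per_bp,
            "relative_error": mean_pi / cfg.theta_per_bp - 1.0,
            "n_windows": int(outside.sum())}


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    """Overlap fraction of the longer interval (half-open coordinates);
    >= 0.5 for both intervals iff >= 0.5 of the longer one."""
    ov = max(0, min(a_end, b_end) - max(a_start, b_start))
    return ov / max(a_end - a_start, b_end - b_start)


def sweep_recovery_replicates(n_reps: int = 50, seed: int = 1,
                              cfg: PanelSimConfig | None = None,
                              quantile: float = 0.95,
                              merge_gap_bp: int = 0) -> pd.DataFrame:
    """Simulate panels with an engineered sweep, run the pi-ratio scan with
    the top-5% cutoff, and score each replicate's best call by reciprocal
    overlap with the true swept interval."""
    seeds = rep_seeds(seed, "sweep-recovery", n_reps)
    spec = WindowSpec()
    rows = []
    for rep in range(n_reps):
        pc = cfg or PanelSimConfig()
        pc = PanelSimConfig(**{**pc.__dict__, "seed": seeds[rep]})
        wild, big, smap = simulate_diversity_panel(pc)
        tw = windowed_pi(wild, smap, spec, pc.seq_length_bp)
        tb = windowed_pi(big, smap, spec, pc.seq_length_bp)
        ratio = pi_ratio(tw, tb)
        cutoff = sweep_cutoff(ratio["ratio"], quantile=quantile)
        calls = call_sweeps(ratio, cutoff, merge_gap_bp=merge_gap_bp)
        true_start, true_end = pc.sweep_start_bp, pc.sweep_end_bp + 1
        best = 0.0
        for _, c in calls.iterrows():
            best = max(best, _reciprocal_overlap(c["start"], c["end"],
                                                 true_start, true_end))
        rows.append({"rep": rep, "n_calls": len(calls), "cutoff": cutoff,
                     "best_reciprocal_overlap": best,
                     "recovered": best >= 0.5})
    return pd.DataFrame(rows)
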