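"""Synthetic populations with known ground truth.

Two generators feed the pipeline:

* a biparental RIL population — single-seed descent from a fully heterozygous
  F1 through ``selfing_generations`` rounds of selfing, with recombination
  between adjacent markers given by the Haldane map function — plus an
  additive quantitative trait with a configurable variance decomposition and
  a masking step that hides calls while recording the truth;
* a two-population diversity panel (wild accessions vs. big-fruit cultivars)
  of near-inbred haplotypes, with an engineered low-diversity interval in the
  cultivated group that a sweep scan should recover.

All generators are pure functions of (config, seed): identical inputs give
identical outputs.  Per-component random streams are derived from the config
seed so stages do not perturb each other.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, MarkerMap, trait_table

__all__ = [
    "RILSimConfig",
    "TraitSimConfig",
    "PanelSimConfig",
    "haldane_r",
    "default_marker_map",
    "simulate_ril_population",
    "simulate_trait",
    "mask_genotypes",
    "simulate_diversity_panel",
]


@dataclass
class RILSimConfig:
    """Biparental RIL population design.

    Defaults emulate a tomato RIL panel: 219 lines over 12 chromosomes,
    six generations of selfing after the F1 (residual heterozygosity
    (1/2)^6 ~ 1.6% per marker).
    """

    n_lines: int = 219
    n_chrom: int = 12
    markers_per_chrom: int = 125
    chrom_length_bp: int = 60_000_000
    chrom_length_cM: float = 100.0
    selfing_generations: int = 6
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")
        if min(self.n_chrom, self.markers_per_chrom, self.chrom_length_bp) <= 0:
            raise ValueError("chromosome counts and lengths must be positive")
        if self.chrom_length_cM <= 0:
            raise ValueError("chrom_length_cM must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TraitSimConfig:
    """Additive trait: one QTL plus an optional marker-built polygenic term."""

    qtl_marker: str = ""
    pve_qtl: float = 0.19
    pve_polygenic: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pve_qtl < 1.0:
            raise ValueError("pve_qtl must be in [0, 1)")
        if not 0.0 <= self.pve_polygenic < 1.0:
            raise ValueError("pve_polygenic must be in [0, 1)")
        if self.pve_qtl + self.pve_polygenic >= 1.0:
            raise ValueError("pve_qtl + pve_polygenic must be < 1")


@dataclass
class PanelSimConfig:
    """Two-population diversity panel with an engineered sweep.

    Cohort sizes default to a tomato-style accession panel: 53 wild
    accessions against 166 big-fruit cultivars.  ``theta_per_bp`` is the
    expected per-bp nucleotide diversity outside the sweep; inside
    [sweep_start_bp, sweep_end_bp] (1-based, inclusive) the cultivars'
    diversity is scaled by ``sweep_reduction``.
    """

    n_wild: int = 53
    n_big: int = 166
    seq_length_bp: int = 5_000_000
    theta_per_bp: float = 0.005
    sweep_start_bp: int = 500_001
    sweep_end_bp: int = 1_000_000
    sweep_reduction: float = 0.1
    seed: int = 0
    chrom: str = "chr01"
    freq_low: float = 0.05   # site allele frequencies drawn U(freq_low, freq_high)
    freq_high: float = 0.95

    def __post_init__(self):
        if self.theta_per_bp <= 0:
            raise ValueError("theta_per_bp must be > 0")
        if not (1 <= self.sweep_start_bp < self.sweep_end_bp <= self.seq_length_bp):
            raise ValueError("sweep interval must satisfy 1 <= start < end <= seq_length")
        if not 0.0 < self.sweep_reduction <= 1.0:
            raise ValueError("sweep_reduction must be in (0, 1]")
        if min(self.n_wild, self.n_big) < 2:
            raise ValueError("each cohort needs >= 2 accessions")


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-component stream derived from a config seed."""
    # crc32 is a stable label hash (str.__hash__ is salted per process)
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF])
    return np.random.default_rng(ss)


def haldane_r(d_cM):
    """Haldane map function: genetic distance (cM) -> recombination fraction.

    r = (1 - exp(-2 d / 100)) / 2, assuming no crossover interference.
    Monotone increasing, r(0) = 0, r -> 0.5 as d -> infinity.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("genetic distance must be finite and non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


def default_marker_map(cfg: RILSimConfig) -> MarkerMap:
    """Evenly spaced markers with a linear cM <-> bp relation per chromosome."""
    rows = []
    for c in range(1, cfg.n_chrom + 1):
        chrom = f"chr{c:02d}"
        pos_bp = np.linspace(
            cfg.chrom_length_bp / cfg.markers_per_chrom,
            cfg.chrom_length_bp,
            cfg.markers_per_chrom,
        ).round().astype(int)
        pos_cM = pos_bp / cfg.chrom_length_bp * cfg.chrom_length_cM
        for i, (bp, cm) in enumerate(zip(pos_bp, pos_cM), start=1):
            rows.append((f"{chrom}_m{i:04d}", chrom, int(bp), float(cm)))
    return MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per line: Markov walk along markers switching parental
    haplotype with probability r[k] between adjacent markers."""
    n, m = hap_a.shape
    start = rng.random(n) < 0.5
    if m > 1:
        switches = rng.random((n, m - 1)) < r[None, :]
        state = np.empty((n, m), dtype=bool)
        state[:, 0] = start
        # cumulative XOR of switch events gives the active haplotype per marker
        state[:, 1:] = start[:, None] ^ np.logical_xor.accumulate(switches, axis=1)
    else:
        state = start[:, None]
    return np.where(state, hap_b, hap_a)


def simulate_ril_population(marker_map: MarkerMap, cfg: RILSimConfig) -> GenotypeMatrix:
    """Single-seed-descent RILs from a fully heterozygous F1.

    Each line selfs for ``cfg.selfing_generations`` generations; gametes are
    drawn as Markov chains along each chromosome with inter-marker
    recombination fraction ``haldane_r(delta cM)``.  Calls count the parent-B
    allele (0/1/2); masking is a separate step.
    """
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    rng = _substream(cfg.seed, "ril")
    n = cfg.n_lines
    columns = []
    for chrom in marker_map.chroms:
        sub = marker_map.chrom_slice(chrom)
        m = len(sub)
        r = haldane_r(np.diff(sub["pos_cM"].to_numpy())) if m > 1 else np.empty(0)
        hap_a = np.zeros((n, m), dtype=np.int8)  # F1: one chromosome from each parent
        hap_b = np.ones((n, m), dtype=np.int8)
        for _ in range(cfg.selfing_generations):
            g1 = _meiosis(hap_a, hap_b, r, rng)
            g2 = _meiosis(hap_a, hap_b, r, rng)
            hap_a, hap_b = g1, g2
        columns.append((hap_a + hap_b).astype(np.int8))
    calls = np.concatenate(columns, axis=1)
    line_ids = [f"RIL{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(line_ids, marker_map.marker_ids, calls)


def simulate_trait(G: GenotypeMatrix, cfg: TraitSimConfig) -> pd.DataFrame:
    """Quantitative trait y = a*g_qtl + u + e.

    The QTL effect a is scaled against the empirical variance of the causal
    dosage so Var(a*g)/Var(y) equals ``pve_qtl``; the polygenic term u is a
    random weighting of all (centered) marker columns scaled to
    ``pve_polygenic``; e is iid Gaussian for the remainder.  Total variance
    is 1 in the component scaling; a baseline of 50 shifts values into a
    plausible force range.
    """
    rng = _substream(cfg.seed, "trait")
    j = G.marker_index(cfg.qtl_marker)
    dos = G.dosage()
    col_means = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_means[None, :], dos)
    g = dos[:, j]
    if np.std(g) == 0:
        raise ValueError(f"QTL marker {cfg.qtl_marker!r} is monomorphic")

    n = G.n_lines
    genetic = np.zeros(n)
    if cfg.pve_qtl > 0:
        gc = g - g.mean()
        genetic = np.sqrt(cfg.pve_qtl) * gc / gc.std()

    poly = np.zeros(n)
    if cfg.pve_polygenic > 0:
        W = dos - dos.mean(axis=0)
        u = W @ rng.standard_normal(G.n_markers)
        sd = u.std()
        if sd > 0:
            poly = np.sqrt(cfg.pve_polygenic) * (u - u.mean()) / sd

    pve_env = 1.0 - cfg.pve_qtl - cfg.pve_polygenic
    e = rng.standard_normal(n)
    env = np.sqrt(pve_env) * (e - e.mean()) / e.std()

    y = 50.0 + genetic + poly + env
    return trait_table(G.line_ids, y)


def mask_genotypes(G: GenotypeMatrix, missing_rate: float, seed: int):
    """Hide observed calls at random, returning the masked matrix and a mask
    index recording (line_id, marker_id, true_call) for every hidden cell."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = _substream(seed, "mask")
    observed = G.calls != MISSING
    hide = observed & (rng.random(G.calls.shape) < missing_rate)
    masked = G.copy()
    masked.calls[hide] = MISSING
    li, mj = np.nonzero(hide)
    mask_index = pd.DataFrame(
        {
            "line_id": [G.line_ids[i] for i in li],
            "marker_id": [G.marker_ids[j] for j in mj],
            "line_idx": li,
            "marker_idx": mj,
            "true_call": G.calls[li, mj].astype(int),
        }
    )
    return masked, mask_index


def simulate_diversity_panel(cfg: PanelSimConfig):
    """Wild and cultivated cohorts of near-inbred accessions.

    Segregating sites are a Poisson process whose rate is calibrated so the
    expected windowed per-bp diversity outside the sweep equals
    ``theta_per_bp``: with site frequencies p ~ U(freq_low, freq_high) the
    expected per-site heterozygosity is E[2p(1-p)] (closed form below), and
    the site density is theta / E[2p(1-p)].  Inside the sweep interval each
    site is fixed in the cultivated group with probability
    1 - sweep_reduction, scaling its expected diversity linearly.

    Accessions are haplotype-coded (0/2, inbred consensus).  Returns
    (wild, big, site_map) where site_map has columns marker_id/chrom/pos_bp.
    """
    rng = _substream(cfg.seed, "panel")
    a, b = cfg.freq_low, cfg.freq_high
    # E[p] and E[p^2] for U(a,b) -> expected heterozygosity of a random site
    ep = (a + b) / 2.0
    ep2 = (b - a) ** 2 / 12.0 + ep**2
    mean_het = 2.0 * (ep - ep2)
    rate = cfg.theta_per_bp / mean_het
    n_sites = rng.poisson(rate * cfg.seq_length_bp)
    pos = np.sort(rng.choice(cfg.seq_length_bp, size=n_sites, replace=False)) + 1
    p = rng.uniform(a, b, size=len(pos))

    wild = (rng.random((cfg.n_wild, len(pos))) < p[None, :]).astype(np.int8) * 2
    big = (rng.random((cfg.n_big, len(pos))) < p[None, :]).astype(np.int8) * 2

    in_sweep = (pos >= cfg.sweep_start_bp) & (pos <= cfg.sweep_end_bp)
    if cfg.sweep_reduction < 1.0:
        fixed = in_sweep & (rng.random(len(pos)) >= cfg.sweep_reduction)
        fixed_allele = (rng.random(len(pos)) < p).astype(np.int8) * 2
        big[:, fixed] = fixed_allele[fixed][None, :]

    site_map = pd.DataFrame(
        {
            "marker_id": [f"{cfg.chrom}_s{q}" for q in pos],
            "chrom": cfg.chrom,
            "pos_bp": pos.astype(int),
        }
    )
    wild_ids = [f"WILD{i + 1:03d}" for i in range(cfg.n_wild)]
    big_ids = [f"BIG{i + 1:03d}" for i in range(cfg.n_big)]
    return (
        GenotypeMatrix(wild_ids, site_map["marker_id"].tolist(), wild),
        GenotypeMatrix(big_ids, site_map["marker_id"].tolist(), big),
        site_map,
    )
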