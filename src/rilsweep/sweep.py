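"""Sliding-window nucleotide diversity and pi-ratio sweep scan.

Nucleotide diversity per site is the unbiased mean pairwise difference
pi_site = n/(n-1) * (1 - sum_a p_a^2) over the n allele copies sampled at
the site; window diversity divides the summed site values by the full
window length in bp (100 kb windows, 10 kb step by default).  Diversity
loss under domestication is scanned as the ratio pi_wild / pi_cultivar per
window; windows strictly above the empirical top-5% cutoff (nearest-rank
order statistic over the finite ratios) are candidate sweeps, merged into
intervals.

Window coordinates are half-open [start, start + window_bp) on 1-based
starts anchored at position 1; trailing partial windows are dropped so all
windows are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = [
    "WindowSpec",
    "site_pi",
    "sites_pi",
    "windowed_pi",
    "pi_ratio",
    "sweep_cutoff",
    "call_sweeps",
]


@dataclass
class WindowSpec:
    window_bp: int = 100_000
    step_bp: int = 10_000

    def __post_init__(self):
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window_bp and step_bp must be positive")
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")


def site_pi(counts) -> float:
    """Unbiased per-site diversity from allele counts.

    pi = n/(n-1) * (1 - sum p_a^2): the mean pairwise difference over all
    n*(n-1)/2 pairs of allele copies at the site.
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("site_pi needs at least 2 allele copies")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p * p)))


def sites_pi(G: GenotypeMatrix, ploidy: str | int = "auto") -> np.ndarray:
    """Vectorized per-site pi over the columns of a dosage-coded cohort.

    With ploidy 2, allele counts come from dosages (0/1/2 copies of the
    alternate allele per accession; heterozygotes contribute one copy of
    each).  With ploidy 1 each accession is an inbred consensus haplotype
    (calls 0/2 only) contributing a single allele copy.  The default
    "auto" uses 1 when the cohort carries no heterozygous call, else 2.
    Missing calls are excluded from the counts.
    """
    calls = G.calls
    obs = calls != MISSING
    het_present = bool((calls == 1).any())
    if ploidy == "auto":
        ploidy = 2 if het_present else 1
    if ploidy == 1:
        if het_present:
            raise ValueError("haploid pi on a cohort with heterozygous calls")
        n = obs.sum(axis=0).astype(float)
        alt = (calls == 2).sum(axis=0)
    elif ploidy == 2:
        n = 2.0 * obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
    else:
        raise ValueError("ploidy must be 1, 2 or 'auto'")
    if (n < 2).any():
        raise ValueError("every site needs at least 2 allele copies")
    p = alt / n
    return n / (n - 1.0) * (1.0 - p**2 - (1.0 - p) ** 2)


def window_starts(seq_length_bp: int, spec: WindowSpec) -> np.ndarray:
    """1-based window start positions; trailing partial windows dropped."""
    last = seq_length_bp - spec.window_bp + 1
    if last < 1:
        return np.empty(0, dtype=int)
    return np.arange(1, last + 1, spec.step_bp)


def windowed_pi(G: GenotypeMatrix, site_map: pd.DataFrame, spec: WindowSpec,
                seq_length_bp: int | dict | None = None,
                ploidy: str | int = "auto") -> pd.DataFrame:
    """Sliding-window diversity track: per window chrom/start/end/pi/n_sites.

    Window pi = (sum of site_pi over sites in [start, start+window)) divided
    by the full window length in bp.  ``seq_length_bp`` (scalar or per-chrom
    dict) declares sequence length; default is the last site position.
    """
    if G.n_lines == 0:
        raise ValueError("empty cohort")
    if list(site_map["marker_id"]) != G.marker_ids:
        raise ValueError("site map must match matrix columns in order")
    site_map = site_map.reset_index(drop=True)
    pis = sites_pi(G, ploidy=ploidy)
    tracks = []
    for chrom, sub in site_map.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if isinstance(seq_length_bp, dict):
            L = seq_length_bp[chrom]
        elif seq_length_bp is not None:
            L = int(seq_length_bp)
        else:
            L = int(pos.max())
        if (pos > L).any():
            raise ValueError(f"{chrom}: site position beyond declared length {L}")
        starts = window_starts(L, spec)
        vals = pis[sub.index.to_numpy()]
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + spec.window_bp, side="left")
        tracks.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + spec.window_bp,
            "pi": (csum[hi] - csum[lo]) / spec.window_bp,
            "n_sites": hi - lo,
        }))
    return pd.concat(tracks, ignore_index=True)


def pi_ratio(wild: pd.DataFrame, big: pd.DataFrame) -> pd.DataFrame:
    """Per-window pi_wild / pi_big; NaN (undefined) where pi_big = 0."""
    same = (
        len(wild) == len(big)
        and (wild["chrom"].to_numpy() == big["chrom"].to_numpy()).all()
        and (wild["start"].to_numpy() == big["start"].to_numpy()).all()
        and (wild["end"].to_numpy() == big["end"].to_numpy()).all()
    )
    if not same:
        raise ValueError("wild and big tracks are on different window grids")
    out = wild[["chrom", "start", "end"]].copy()
    out["pi_wild"] = wild["pi"].to_numpy()
    out["pi_big"] = big["pi"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["pi_wild"] / out["pi_big"]
    out["ratio"] = np.where(out["pi_big"] > 0, ratio, np.nan)
    return out


def sweep_cutoff(ratios, quantile: float = 0.95, min_windows: int = 20) -> float:
    """Empirical top-quantile cutoff by the nearest-rank-lower convention:
    the ceil(q*m)-th order statistic of the m finite ratios.  Windows
    strictly above the cutoff are sweep candidates."""
    r = np.asarray(ratios, dtype=float)
    r = np.sort(r[np.isfinite(r)])
    m = r.size
    if m < min_windows:
        raise ValueError(f"need >= {min_windows} finite ratios, got {m}")
    k = math.ceil(quantile * m)
    return float(r[k - 1])


def call_sweeps(ratio_track: pd.DataFrame, cutoff: float,
                merge_gap_bp: int = 0) -> pd.DataFrame:
    """Merge candidate windows (finite ratio strictly above cutoff) into
    intervals when they overlap, touch, or fall within ``merge_gap_bp``;
    each call reports its peak-ratio window."""
    cand = ratio_track[np.isfinite(ratio_track["ratio"]) &
                       (ratio_track["ratio"] > cutoff)]
    cols = ["chrom", "start", "end", "peak_ratio", "peak_window_start", "n_windows"]
    if cand.empty:
        return pd.DataFrame(columns=cols)
    calls = []
    for chrom, sub in cand.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for _, row in sub.iterrows():
            if cur is not None and row["start"] <= cur["end"] + merge_gap_bp:
                cur["end"] = max(cur["end"], int(row["end"]))
                cur["n_windows"] += 1
                if row["ratio"] > cur["peak_ratio"]:
                    cur["peak_ratio"] = float(row["ratio"])
                    cur["peak_window_start"] = int(row["start"])
            else:
                if cur is not None:
                    calls.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "peak_ratio": float(row["ratio"]),
                    "peak_window_start": int(row["start"]),
                    "n_windows": 1,
                }
        calls.append(cur)
    return pd.DataFrame(calls, columns=cols)


def calls_to_bed(calls: pd.DataFrame, path) -> None:
    """Write sweep calls as BED (0-based half-open, converted here)."""
    with open(path, "w") as fh:
        for _, row in calls.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end']) - 1}"
                     f"\t.\t{row['peak_ratio']:.4f}\n")
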