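"""Consensus flanking-SNP genotype imputation for biparental populations.

A missing call at a target SNP in one line is inferred from the other lines
that share its local haplotype: the lines whose genotypes agree with the
focal line at the SNPs flanking the target (default 20, ten per side by map
order).  If every matching line that has a call at the target carries the
same genotype, that unanimous genotype is imputed; a conflict or an empty
match set leaves the cell missing, with the reason recorded.

Comparisons skip positions where either line is missing; a candidate must
contribute at least ``min_overlap`` informative comparisons (default half
the flank count).  One pass works on a snapshot of the observed calls, so
the result is independent of cell visiting order and imputed values never
serve as evidence within the same pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, MarkerMap

__all__ = ["ImputeConfig", "ImputeReport", "flanking_markers", "impute_site", "impute_matrix"]


@dataclass
class ImputeConfig:
    flank_total: int = 20
    require_unanimity: bool = True  # fixed by the method; kept for visibility
    max_passes: int = 1
    min_overlap: int | None = None  # default flank_total // 2

    def __post_init__(self):
        if self.flank_total < 2 or self.flank_total % 2 != 0:
            raise ValueError("flank_total must be even and >= 2")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")
        if not self.require_unanimity:
            raise ValueError("unanimity is fixed: require_unanimity must be True")

    @property
    def flank_each_side(self) -> int:
        return self.flank_total // 2

    @property
    def overlap_required(self) -> int:
        return self.flank_total // 2 if self.min_overlap is None else self.min_overlap


@dataclass
class ImputeReport:
    n_missing_before: int = 0
    n_imputed: int = 0
    n_left_missing: int = 0
    reasons: dict = field(default_factory=lambda: {
        "no_match": 0, "conflict": 0, "insufficient_flank": 0,
    })

    def check(self) -> None:
        assert self.n_imputed + self.n_left_missing == self.n_missing_before


def flanking_markers(marker_map: MarkerMap, target_marker: str,
                     flank_each_side: int) -> list[str]:
    """Up to ``flank_each_side`` nearest markers on each side of the target,
    same chromosome, in map order; truncated near chromosome ends."""
    row = marker_map.row(target_marker)  # KeyError if absent
    chrom_ids = marker_map.chrom_slice(row["chrom"])["marker_id"].tolist()
    k = chrom_ids.index(target_marker)
    left = chrom_ids[max(0, k - flank_each_side):k]
    right = chrom_ids[k + 1:k + 1 + flank_each_side]
    return left + right


def _match_candidates(flank_calls: np.ndarray, focal_flanks: np.ndarray,
                      min_overlap: int) -> np.ndarray:
    """Boolean mask over lines: agrees with the focal flanking profile at
    every position where both are observed, with enough informative overlap."""
    informative = (flank_calls != MISSING) & (focal_flanks != MISSING)[None, :]
    agree = (flank_calls == focal_flanks[None, :]) | ~informative
    return agree.all(axis=1) & (informative.sum(axis=1) >= min_overlap)


def impute_site(G: GenotypeMatrix, line: str, target_marker: str,
                cfg: ImputeConfig, marker_map: MarkerMap):
    """Infer one missing call; returns (call, reason).

    reason is "imputed" on success, else one of "insufficient_flank"
    (the focal line itself has too few observed flanking calls ever to
    reach the overlap requirement), "no_match", or "conflict".
    """
    i = G.line_index(line)
    j = G.marker_index(target_marker)
    if G.calls[i, j] != MISSING:
        raise ValueError(f"call at ({line}, {target_marker}) is not missing")
    flanks = flanking_markers(marker_map, target_marker, cfg.flank_each_side)
    fidx = np.array([G.marker_index(m) for m in flanks], dtype=int)
    return _impute_cell(G.calls, i, j, fidx, cfg)


def _impute_cell(calls: np.ndarray, i: int, j: int, fidx: np.ndarray,
                 cfg: ImputeConfig):
    focal = calls[i, fidx]
    if (focal != MISSING).sum() < cfg.overlap_required:
        return MISSING, "insufficient_flank"
    cand = _match_candidates(calls[:, fidx], focal, cfg.overlap_required)
    cand[i] = False  # evidence comes from the other lines
    targets = calls[cand, j]
    targets = targets[targets != MISSING]
    if targets.size == 0:
        return MISSING, "no_match"
    first = targets[0]
    if (targets == first).all():
        return int(first), "imputed"
    return MISSING, "conflict"


def impute_matrix(G: GenotypeMatrix, cfg: ImputeConfig, marker_map: MarkerMap):
    """Attempt every missing cell; returns (imputed matrix, ImputeReport).

    Each pass reads evidence from a snapshot taken at the start of the pass
    (newly imputed calls only become evidence in later passes, if
    ``max_passes`` > 1).  Observed calls are never altered.
    """
    if G.marker_ids != marker_map.marker_ids:
        raise ValueError("genotype matrix markers must match the marker map")
    report = ImputeReport(n_missing_before=int((G.calls == MISSING).sum()))
    flank_idx = [
        np.array([G.marker_index(m)
                  for m in flanking_markers(marker_map, mid, cfg.flank_each_side)],
                 dtype=int)
        for mid in G.marker_ids
    ]
    current = G.calls.copy()
    last_reason: dict[tuple[int, int], str] = {}
    for _ in range(cfg.max_passes):
        snapshot = current.copy()
        changed = False
        for j in range(G.n_markers):
            lines = np.nonzero(snapshot[:, j] == MISSING)[0]
            if lines.size == 0:
                continue
            fidx = flank_idx[j]
            for i in lines:
                call, reason = _impute_cell(snapshot, i, j, fidx, cfg)
                if call != MISSING:
                    current[i, j] = call
                    changed = True
                    last_reason.pop((i, j), None)
                else:
                    last_reason[(i, j)] = reason
        if not changed:
            break
    for reason in last_reason.values():
        report.reasons[reason] += 1
    report.n_left_missing = len(last_reason)
    report.n_imputed = report.n_missing_before - report.n_left_missing
    report.check()
    return GenotypeMatrix(list(G.line_ids), list(G.marker_ids), current), report
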