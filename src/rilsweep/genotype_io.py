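"""Genotype I/O, hard site filtering, and the parental marker index.

Reads VCF (via cyvcf2) and tab-separated genotype matrices into the shared
containers; applies GATK-VariantFiltration-style hard filters on site INFO
annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum, DP); and builds the
index of markers at which the two inbred parents carry different homozygous
alleles, orienting the 0/2 dosage coding so 0 counts the parent-A allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, MarkerMap

__all__ = [
    "SiteFilterCriteria",
    "SiteRecord",
    "ParseError",
    "read_vcf",
    "write_vcf",
    "hard_filter_sites",
    "parental_marker_index",
    "orient_genotypes",
    "missingness_summary",
    "genotypes_to_tsv",
    "genotypes_from_tsv",
    "read_trait_tsv",
    "write_trait_tsv",
]


class ParseError(ValueError):
    """Raised for malformed input files."""


@dataclass
class SiteFilterCriteria:
    """Hard-filter thresholds applied to site INFO annotations.

    A site is removed iff QD < qd_min, FS > fs_max, MQ < mq_min,
    MQRankSum < mqranksum_min, ReadPosRankSum < readposranksum_min, or
    DP < dp_min — each test firing only when its annotation is present.
    ``base_quality_min`` records the upstream calling threshold; it is
    metadata only (base qualities are not visible at the VCF site level).
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    dp_min: int = 10
    base_quality_min: int = 20


@dataclass
class SiteRecord:
    """One VCF site: coordinates, alleles, INFO annotations, per-sample dosages."""

    chrom: str
    pos_bp: int
    marker_id: str
    ref: str
    alt: list[str]
    info: dict = field(default_factory=dict)
    calls: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))

    @property
    def biallelic(self) -> bool:
        return len(self.alt) == 1


_INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP")


def read_vcf(path, cm_per_mb: float = 1.0):
    """Read a VCF into (MarkerMap, GenotypeMatrix, list[SiteRecord]).

    Diploid GT is mapped to the dosage of the (first) alternate allele:
    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> MISSING.  Multiallelic sites
    are kept in the record list and flagged (``biallelic`` False) but excluded
    from the analysis matrix.  VCF carries no genetic positions, so map cM is
    a nominal linear ``cm_per_mb`` conversion of bp.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports no text line number
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: VCF has no samples (GT is required)")
    records: list[SiteRecord] = []
    for i, v in enumerate(vcf, start=1):
        if v.gt_types is None or len(v.gt_types) != len(samples):
            raise ParseError(f"{path}: record {i}: missing GT field")
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        calls = np.array([0, 1, MISSING, 2], dtype=np.int8)[v.gt_types]
        info = {k: v.INFO.get(k) for k in _INFO_KEYS if v.INFO.get(k) is not None}
        marker_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        records.append(
            SiteRecord(v.CHROM, int(v.POS), marker_id, v.REF, list(v.ALT), info, calls)
        )
    vcf.close()
    bi = [r for r in records if r.biallelic]
    rows = pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in bi],
            "chrom": [r.chrom for r in bi],
            "pos_bp": [r.pos_bp for r in bi],
            "pos_cM": [r.pos_bp / 1e6 * cm_per_mb for r in bi],
        }
    )
    marker_map = MarkerMap(rows)
    calls = (
        np.stack([r.calls for r in bi], axis=1)
        if bi
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    # matrix columns follow map (sorted) order
    pos_by_id = {r.marker_id: k for k, r in enumerate(bi)}
    order = [pos_by_id[m] for m in marker_map.marker_ids]
    G = GenotypeMatrix(samples, marker_map.marker_ids, calls[:, order])
    return marker_map, G, records


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, marker_map: MarkerMap, path,
              records: list[SiteRecord] | None = None) -> None:
    """Write a minimal VCF v4.2 (GT only, one sample per line).

    REF/ALT and INFO come from ``records`` when given (matched by marker_id),
    else placeholder A/G alleles are used.
    """
    by_id = {r.marker_id: r for r in records} if records else {}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, sub in marker_map.table.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos_bp'].max())}>\n")
        for key, typ in (("QD", "Float"), ("FS", "Float"), ("MQ", "Float"),
                         ("MQRankSum", "Float"), ("ReadPosRankSum", "Float"),
                         ("DP", "Integer")):
            fh.write(f'##INFO=<ID={key},Number=1,Type={typ},Description="{key}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.line_ids) + "\n")
        for j, mid in enumerate(marker_map.marker_ids):
            row = marker_map.row(mid)
            rec = by_id.get(mid)
            ref = rec.ref if rec else "A"
            alt = ",".join(rec.alt) if rec else "G"
            if rec and rec.info:
                info = ";".join(
                    f"{k}={int(v) if k == 'DP' else round(float(v), 6)}"
                    for k, v in rec.info.items()
                )
            else:
                info = "."
            gts = "\t".join(_GT_STR[int(c)] for c in G.calls[:, G.marker_index(mid)])
            fh.write(
                f"{row['chrom']}\t{row['pos_bp']}\t{mid}\t{ref}\t{alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def hard_filter_sites(records: list[SiteRecord],
                      criteria: SiteFilterCriteria | None = None):
    """Apply the hard site filters; returns (kept records, rejection report).

    A site is removed iff at least one criterion fires on a *present*
    annotation (absent annotations never fire; they are tallied under
    ``annotation_absent``).  The report counts, per criterion, how many
    removed sites fired it (a site can fire several), plus totals.
    """
    criteria = criteria or SiteFilterCriteria()
    tests = {
        "QD": lambda info: info.get("QD") is not None and info["QD"] < criteria.qd_min,
        "FS": lambda info: info.get("FS") is not None and info["FS"] > criteria.fs_max,
        "MQ": lambda info: info.get("MQ") is not None and info["MQ"] < criteria.mq_min,
        "MQRankSum": lambda info: info.get("MQRankSum") is not None
        and info["MQRankSum"] < criteria.mqranksum_min,
        "ReadPosRankSum": lambda info: info.get("ReadPosRankSum") is not None
        and info["ReadPosRankSum"] < criteria.readposranksum_min,
        "DP": lambda info: info.get("DP") is not None and info["DP"] < criteria.dp_min,
    }
    report = {name: 0 for name in tests}
    report["annotation_absent"] = 0
    kept: list[SiteRecord] = []
    for rec in records:
        fired = [name for name, test in tests.items() if test(rec.info)]
        report["annotation_absent"] += sum(1 for k in tests if rec.info.get(k) is None)
        if fired:
            for name in fired:
                report[name] += 1
        else:
            kept.append(rec)
    report["n_input"] = len(records)
    report["n_kept"] = len(kept)
    report["n_removed"] = len(records) - len(kept)
    return kept, report


def parental_marker_index(parent_a: GenotypeMatrix, parent_b: GenotypeMatrix):
    """Markers at which the two parents are homozygous for different alleles.

    Rows of each matrix are replicate genotypings of one parent; a parent's
    consensus call must be a clean homozygote (no missing, no heterozygous,
    no within-parent conflict).  Returns (kept marker_ids, flip mask over the
    kept markers, report).  ``flip`` marks markers where parent A carried the
    allele coded 2, i.e. the coding must be reversed so that 0 = parent-A
    allele and 2 = parent-B allele.
    """
    if parent_a.marker_ids != parent_b.marker_ids:
        raise ValueError("parents must be genotyped on the same markers")

    def consensus(G: GenotypeMatrix) -> np.ndarray:
        out = np.full(G.n_markers, MISSING, dtype=np.int8)
        for j in range(G.n_markers):
            col = G.calls[:, j]
            vals = set(int(c) for c in col)
            if MISSING in vals or 1 in vals or len(vals) != 1:
                continue
            out[j] = col[0]
        return out

    ca, cb = consensus(parent_a), consensus(parent_b)
    report = {"parent_heterozygous_or_missing": 0, "parents_identical": 0}
    kept, flip = [], []
    for j, mid in enumerate(parent_a.marker_ids):
        if ca[j] == MISSING or cb[j] == MISSING:
            report["parent_heterozygous_or_missing"] += 1
            continue
        if ca[j] == cb[j]:
            report["parents_identical"] += 1
            continue
        kept.append(mid)
        flip.append(ca[j] == 2)
    if not kept:
        raise ValueError("no informative markers between the parents")
    report["n_kept"] = len(kept)
    return kept, np.array(flip, dtype=bool), report


def orient_genotypes(G: GenotypeMatrix, kept: list[str], flip: np.ndarray) -> GenotypeMatrix:
    """Subset to the parental index and flip coding (0 <-> 2) where needed."""
    sub = G.subset_markers(kept)
    calls = sub.calls.copy()
    obs = calls != MISSING
    cols = np.asarray(flip, dtype=bool)
    swap = obs & cols[None, :]
    calls[swap] = 2 - calls[swap]
    return GenotypeMatrix(sub.line_ids, sub.marker_ids, calls)


def missingness_summary(G: GenotypeMatrix):
    """Per-line and per-marker missing-call fractions."""
    miss = G.is_missing()
    per_line = pd.Series(miss.mean(axis=1), index=G.line_ids, name="missing_fraction")
    per_marker = pd.Series(miss.mean(axis=0), index=G.marker_ids, name="missing_fraction")
    return per_line, per_marker


# --- TSV dialects -----------------------------------------------------------

def genotypes_to_tsv(G: GenotypeMatrix, path) -> None:
    """Lines as rows, markers as columns, NA for missing."""
    df = pd.DataFrame(G.calls.astype(object), index=G.line_ids, columns=G.marker_ids)
    df[G.calls == MISSING] = "NA"
    df.index.name = "line_id"
    df.to_csv(path, sep="\t")


def genotypes_from_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line_id", na_values=["NA"])
    calls = df.to_numpy(dtype=float)
    out = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix([str(i) for i in df.index], [str(c) for c in df.columns], out)


def write_trait_tsv(trait: pd.DataFrame, path) -> None:
    trait.to_csv(path, sep="\t", index=False)


def read_trait_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    if not {"line_id", "value"} <= set(df.columns):
        raise ParseError(f"{path}: trait TSV needs columns line_id, value")
    return df[["line_id", "value"]]
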