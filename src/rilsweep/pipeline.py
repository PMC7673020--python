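"""Configured, reproducible pipeline runs: simulate -> filter -> impute ->
associate -> sweep.

A run is described by a plain YAML config (every key optional; documented
defaults fill the gaps; unknown keys are rejected with their path).  Each
randomized stage consumes a seed derived deterministically from the global
seed and the stage name, and every run writes a JSON manifest with the
config snapshot, package version, per-output SHA-256 checksums and
timestamps, sufficient to replay any stage.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assoc import AssocConfig, kinship_vanraden, marker_pve, mlm_scan, significant_hits
from .core import MISSING
from .genotype_io import (
    SiteFilterCriteria,
    genotypes_from_tsv,
    genotypes_to_tsv,
    hard_filter_sites,
    read_trait_tsv,
    read_vcf,
    write_trait_tsv,
    write_vcf,
)
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
from .sweep import WindowSpec, call_sweeps, calls_to_bed, pi_ratio, sweep_cutoff, windowed_pi

log = logging.getLogger("rilsweep")

__all__ = ["ConfigError", "StageError", "DEFAULT_CONFIG", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Configuration does not validate against the schema."""


class StageError(RuntimeError):
    """A pipeline stage failed."""


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "results/run",
    "stages": ["simulate", "impute", "assoc", "sweep"],
    "log_level": "INFO",
    "inputs": {"genotypes": None, "trait": None, "map": None, "vcf": None},
    "simulate": {
        "n_lines": 219,
        "n_chrom": 12,
        "markers_per_chrom": 125,
        "chrom_length_bp": 60_000_000,
        "chrom_length_cM": 100.0,
        "selfing_generations": 6,
        "missing_rate": 0.05,
        "qtl_marker": "",  # empty = middle marker of the last chromosome
        "pve_qtl": 0.19,
        "pve_polygenic": 0.0,
    },
    "filter": {
        "qd_min": 2.0,
        "fs_max": 60.0,
        "mq_min": 40.0,
        "mqranksum_min": -12.5,
        "readposranksum_min": -8.0,
        "dp_min": 10,
    },
    "impute": {"flank_total": 20, "max_passes": 1},
    "assoc": {
        "p_threshold": 1e-6,
        "p3d": True,
        "n_groups": "n",
        "locus_merge_gap_bp": 1_000_000,
    },
    "sweep": {
        "window_bp": 100_000,
        "step_bp": 10_000,
        "quantile": 0.95,
        "merge_gap_bp": 0,
        "n_wild": 53,
        "n_big": 166,
        "seq_length_bp": 5_000_000,
        "theta_per_bp": 0.005,
        "sweep_start_bp": 500_001,
        "sweep_end_bp": 1_000_000,
        "sweep_reduction": 0.1,
    },
}


def _coerce(value, default, path: str):
    """Coerce a config value to the type of its default ("1e-6" -> 1e-6)."""
    if default is None or value is None:
        return value
    if isinstance(default, bool):
        if isinstance(value, bool):
            return value
        if isinstance(value, str) and value.lower() in {"true", "false"}:
            return value.lower() == "true"
        raise ConfigError(f"{path}: expected boolean, got {value!r}")
    if isinstance(default, int) and not isinstance(default, bool):
        try:
            f = float(value)
        except (TypeError, ValueError):
            raise ConfigError(f"{path}: expected integer, got {value!r}") from None
        if f != int(f):
            raise ConfigError(f"{path}: expected integer, got {value!r}")
        return int(f)
    if isinstance(default, float):
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ConfigError(f"{path}: expected number, got {value!r}") from None
    if isinstance(default, str):
        return str(value)
    if isinstance(default, list):
        if not isinstance(value, list):
            raise ConfigError(f"{path}: expected list, got {value!r}")
        return value
    return value


def _merge(user: dict, defaults: dict, path: str = "") -> dict:
    out = {}
    unknown = set(user) - set(defaults)
    if unknown:
        key = sorted(unknown)[0]
        where = f"{path}{key}"
        raise ConfigError(f"unknown config key: {where!r}")
    for key, default in defaults.items():
        here = f"{path}{key}"
        if key not in user:
            out[key] = copy.deepcopy(default)
        elif isinstance(default, dict):
            if not isinstance(user[key], dict):
                raise ConfigError(f"{here}: expected mapping")
            out[key] = _merge(user[key], default, here + ".")
        else:
            out[key] = _coerce(user[key], default, here)
    return out


# "n_groups" may be the string "n" or an integer; handled after generic merge
def _normalize(cfg: dict) -> dict:
    ng = cfg["assoc"]["n_groups"]
    if ng != "n":
        try:
            cfg["assoc"]["n_groups"] = int(ng)
        except (TypeError, ValueError):
            raise ConfigError(f"assoc.n_groups: expected integer or 'n', got {ng!r}") from None
    known = {"simulate", "filter", "impute", "assoc", "sweep"}
    bad = set(cfg["stages"]) - known
    if bad:
        raise ConfigError(f"stages: unknown stage {sorted(bad)[0]!r}")
    return cfg


def validate_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate a YAML run config; defaults fill absent keys."""
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        user = loaded
    if overrides:
        user = _deep_update(copy.deepcopy(user), overrides)
    return _normalize(_merge(user, DEFAULT_CONFIG))


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: dict) -> dict:
    """Execute the selected stages in dependency order; returns the manifest.

    Each stage writes flat TSV/VCF/BED outputs under ``out_dir`` plus one
    JSON manifest.  A stage failure raises :class:`StageError` naming the
    stage; earlier outputs remain on disk and are flagged in the manifest.
    """
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg["log_level"].upper(), logging.INFO))
    manifest: dict = {
        "config": cfg,
        "version": __version__,
        "seed": cfg["seed"],
        "stages": {},
    }
    state: dict = {}
    order = ["simulate", "filter", "impute", "assoc", "sweep"]
    runners = {
        "simulate": _stage_simulate,
        "filter": _stage_filter,
        "impute": _stage_impute,
        "assoc": _stage_assoc,
        "sweep": _stage_sweep,
    }
    for stage in order:
        if stage not in cfg["stages"]:
            continue
        t0 = time.time()
        seed = stage_seed(cfg["seed"], stage)
        log.info("stage %s: seed=%d", stage, seed)
        try:
            outputs = runners[stage](cfg, state, out_dir, seed)
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out_dir)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        entry = {
            "status": "ok",
            "seed": seed,
            "wall_seconds": round(time.time() - t0, 3),
            "outputs": {str(p.name): _sha256(p) for p in outputs},
        }
        manifest["stages"][stage] = entry
        log.info("stage %s: done in %.2fs", stage, entry["wall_seconds"])
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _stage_simulate(cfg, state, out_dir, seed):
    sc = cfg["simulate"]
    ril_cfg = RILSimConfig(
        n_lines=sc["n_lines"], n_chrom=sc["n_chrom"],
        markers_per_chrom=sc["markers_per_chrom"],
        chrom_length_bp=sc["chrom_length_bp"], chrom_length_cM=sc["chrom_length_cM"],
        selfing_generations=sc["selfing_generations"],
        missing_rate=sc["missing_rate"], seed=seed,
    )
    marker_map = default_marker_map(ril_cfg)
    G = simulate_ril_population(marker_map, ril_cfg)
    qtl = sc["qtl_marker"]
    if not qtl:
        last = marker_map.chroms[-1]
        ids = marker_map.chrom_slice(last)["marker_id"].tolist()
        qtl = ids[len(ids) // 2]
    trait = simulate_trait(
        G, TraitSimConfig(qtl_marker=qtl, pve_qtl=sc["pve_qtl"],
                          pve_polygenic=sc["pve_polygenic"], seed=seed),
    )
    masked, mask_index = mask_genotypes(G, sc["missing_rate"], seed)
    marker_map.to_tsv(out_dir / "map.tsv")
    genotypes_to_tsv(G, out_dir / "genotypes_true.tsv")
    genotypes_to_tsv(masked, out_dir / "genotypes_masked.tsv")
    write_trait_tsv(trait, out_dir / "trait.tsv")
    mask_index.to_csv(out_dir / "mask_index.tsv", sep="\t", index=False)
    state.update(marker_map=marker_map, genotypes=masked, genotypes_true=G,
                 trait=trait, mask_index=mask_index, qtl_marker=qtl)
    return [out_dir / n for n in
            ("map.tsv", "genotypes_true.tsv", "genotypes_masked.tsv",
             "trait.tsv", "mask_index.tsv")]


def _stage_filter(cfg, state, out_dir, seed):
    vcf_path = cfg["inputs"]["vcf"]
    if vcf_path is None:
        raise StageError("filter stage requires inputs.vcf")
    fc = cfg["filter"]
    criteria = SiteFilterCriteria(
        qd_min=fc["qd_min"], fs_max=fc["fs_max"], mq_min=fc["mq_min"],
        mqranksum_min=fc["mqranksum_min"],
        readposranksum_min=fc["readposranksum_min"], dp_min=fc["dp_min"],
    )
    marker_map, G, records = read_vcf(vcf_path)
    kept, report = hard_filter_sites(records, criteria)
    kept_ids = [r.marker_id for r in kept if r.biallelic]
    sub_map_rows = marker_map.table[marker_map.table["marker_id"].isin(kept_ids)]
    from .core import MarkerMap
    sub_map = MarkerMap(sub_map_rows)
    sub = G.subset_markers(sub_map.marker_ids)
    write_vcf(sub, sub_map, out_dir / "filtered.vcf", records=kept)
    with open(out_dir / "filter_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    state.update(marker_map=sub_map, genotypes=sub)
    return [out_dir / "filtered.vcf", out_dir / "filter_report.json"]


def _load_inputs(cfg, state):
    from .core import MarkerMap
    ins = cfg["inputs"]
    if "genotypes" not in state and ins["genotypes"]:
        state["genotypes"] = genotypes_from_tsv(ins["genotypes"])
    if "marker_map" not in state and ins["map"]:
        state["marker_map"] = MarkerMap.from_tsv(ins["map"])
    if "trait" not in state and ins["trait"]:
        state["trait"] = read_trait_tsv(ins["trait"])


def _stage_impute(cfg, state, out_dir, seed):
    _load_inputs(cfg, state)
    if "genotypes" not in state or "marker_map" not in state:
        raise StageError("impute stage needs genotypes and a marker map "
                         "(run simulate or provide inputs)")
    icfg = ImputeConfig(flank_total=cfg["impute"]["flank_total"],
                        max_passes=cfg["impute"]["max_passes"])
    imputed, report = impute_matrix(state["genotypes"], icfg, state["marker_map"])
    genotypes_to_tsv(imputed, out_dir / "genotypes_imputed.tsv")
    rep = {
        "n_missing_before": report.n_missing_before,
        "n_imputed": report.n_imputed,
        "n_left_missing": report.n_left_missing,
        "reasons": report.reasons,
    }
    mask_index = state.get("mask_index")
    if mask_index is not None and len(mask_index):
        li = mask_index["line_idx"].to_numpy()
        mj = mask_index["marker_idx"].to_numpy()
        got = imputed.calls[li, mj]
        done = got != MISSING
        rep["masked_cells"] = int(len(mask_index))
        rep["imputed_of_masked"] = int(done.sum())
        rep["imputation_accuracy"] = (
            float((got[done] == mask_index["true_call"].to_numpy()[done]).mean())
            if done.any() else None
        )
    with open(out_dir / "impute_report.json", "w") as fh:
        json.dump(rep, fh, indent=2)
    state["genotypes"] = imputed
    return [out_dir / "genotypes_imputed.tsv", out_dir / "impute_report.json"]


def _stage_assoc(cfg, state, out_dir, seed):
    _load_inputs(cfg, state)
    for need in ("genotypes", "trait", "marker_map"):
        if need not in state:
            raise StageError(f"assoc stage needs {need}")
    ac = cfg["assoc"]
    acfg = AssocConfig(p_threshold=ac["p_threshold"], p3d=ac["p3d"],
                       n_groups=ac["n_groups"],
                       locus_merge_gap_bp=ac["locus_merge_gap_bp"])
    G, trait, marker_map = state["genotypes"], state["trait"], state["marker_map"]
    K = kinship_vanraden(G)
    result = mlm_scan(G, trait, K, acfg)
    coords = marker_map.table.set_index("marker_id")
    result.insert(1, "chrom", coords.loc[result["marker_id"], "chrom"].to_numpy())
    result.insert(2, "pos_bp", coords.loc[result["marker_id"], "pos_bp"].to_numpy())
    loci = significant_hits(result, marker_map, acfg)
    if len(loci):
        yv = trait.set_index("line_id").loc[G.line_ids, "value"].reset_index()
        yv.columns = ["line_id", "value"]
        pves = [
            marker_pve(yv, G.dosage()[:, G.marker_index(m)])
            for m in loci["peak_marker"]
        ]
        loci = loci.assign(peak_pve=pves)
    result.to_csv(out_dir / "assoc.tsv", sep="\t", index=False)
    loci.to_csv(out_dir / "loci.tsv", sep="\t", index=False)
    state.update(assoc_result=result, loci=loci)
    return [out_dir / "assoc.tsv", out_dir / "loci.tsv"]


def _stage_sweep(cfg, state, out_dir, seed):
    sw = cfg["sweep"]
    pcfg = PanelSimConfig(
        n_wild=sw["n_wild"], n_big=sw["n_big"], seq_length_bp=sw["seq_length_bp"],
        theta_per_bp=sw["theta_per_bp"], sweep_start_bp=sw["sweep_start_bp"],
        sweep_end_bp=sw["sweep_end_bp"], sweep_reduction=sw["sweep_reduction"],
        seed=seed,
    )
    wild, big, site_map = simulate_diversity_panel(pcfg)
    spec = WindowSpec(window_bp=sw["window_bp"], step_bp=sw["step_bp"])
    track_w = windowed_pi(wild, site_map, spec, pcfg.seq_length_bp)
    track_b = windowed_pi(big, site_map, spec, pcfg.seq_length_bp)
    ratio = pi_ratio(track_w, track_b)
    cutoff = sweep_cutoff(ratio["ratio"], quantile=sw["quantile"])
    calls = call_sweeps(ratio, cutoff, merge_gap_bp=sw["merge_gap_bp"])
    ratio.to_csv(out_dir / "pi_ratio_track.tsv", sep="\t", index=False)
    calls.to_csv(out_dir / "sweep_calls.tsv", sep="\t", index=False)
    calls_to_bed(calls, out_dir / "sweep_calls.bed")
    with open(out_dir / "sweep_summary.json", "w") as fh:
        json.dump({"cutoff": cutoff, "n_windows": int(len(ratio)),
                   "n_calls": int(len(calls))}, fh, indent=2)
    state.update(sweep_calls=calls, sweep_cutoff=cutoff)
    return [out_dir / n for n in
            ("pi_ratio_track.tsv", "sweep_calls.tsv", "sweep_calls.bed",
             "sweep_summary.json")]

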