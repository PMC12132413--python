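"""End-to-end orchestration: design -> simulate -> map -> count -> footprint
-> discover -> cluster, with a run manifest and structured logging.

A run is driven by a single flat config document (YAML or JSON) with one
section per stage; seeds are mandatory, never defaulted silently.  Every
stage writes plain-text artifacts into the run directory and the manifest
records input hashes, parameters and the package version, so a rerun with
the same config reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .barcode_pipeline import aggregate_variant_counts, map_barcodes
from .condition_clustering import (build_condition_matrix, cluster_global,
                                   cluster_promoter_conditions,
                                   replicate_correlation)
from .coords import index_to_label
from .footprint_stats import (expression_shift_matrix, information_footprint)
from .io import (footprint_to_frame, library_to_frame, load_promoters,
                 read_promoter_table, read_reference, shifts_to_frame,
                 write_barcode_map, write_counts, write_pool_fasta,
                 write_reads_fastq)
from .library_design import (DesignConfig, PromoterRegion, assign_barcodes,
                             design_pool, draw_barcode_counts, ints_to_seq)
from .site_discovery import (ClassifierConfig, call_sites, classify_footprint,
                             fit_two_state_hmm, ACTIVE)
from .synthetic_data import (architecture_from_json, barcode_map_frame,
                             default_architecture, ground_truth_sites,
                             null_architecture, repressor_architecture,
                             simulate_counts, simulate_reads)

logger = logging.getLogger(__name__)

_KNOWN_SECTIONS = {"seed", "design", "simulate", "map", "footprint",
                   "discover", "cluster"}


class ConfigError(ValueError):
    """Raised before any compute when the run config is invalid."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config, base=Path(path).parent)
    return config


def validate_config(config: dict, base: Path | None = None) -> None:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    if "seed" not in config:
        raise ConfigError("config must set an explicit seed")
    unknown = set(config) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    design = config.get("design", {})
    for key in ("promoters", "reference", "architecture"):
        path = design.get(key) if key != "architecture" else \
            config.get("simulate", {}).get(key)
        if isinstance(path, str) and "/" in path or \
                isinstance(path, str) and path.endswith((".tsv", ".fa", ".fasta", ".json")):
            p = Path(path)
            if base is not None and not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ConfigError(f"input path does not exist: {path}")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _synthetic_promoters(n: int, rng: np.random.Generator
                         ) -> list[PromoterRegion]:
    return [PromoterRegion(promoter_id=f"synp{i + 1:03d}", gene=f"gene{i + 1}",
                           tss=115, strand="+",
                           sequence=ints_to_seq(rng.integers(0, 4, 160)))
            for i in range(n)]


def run_pipeline(config: dict, out_dir: str | Path,
                 config_paths: list[Path] | None = None) -> dict:
    """Execute every stage of the pipeline into ``out_dir``.

    Returns the manifest dict (also written as manifest.json).
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    manifest: dict = {"version": __version__, "seed": seed,
                      "parameters": config, "inputs": {}, "outputs": []}
    for p in (config_paths or []):
        manifest["inputs"][str(p)] = _hash_file(Path(p))

    # ---- design -----------------------------------------------------------
    d = config.get("design", {})
    dconf = DesignConfig(
        mutation_rate=float(d.get("mutation_rate", 0.1)),
        n_variants=int(d.get("n_variants", 1500)),
        barcode_length=int(d.get("barcode_length", 20)),
        rng_seed=seed,
    )
    if "promoters" in d and "reference" in d:
        table = read_promoter_table(d["promoters"])
        reference = read_reference(d["reference"])
        promoters = load_promoters(table, reference)
    else:
        promoters = _synthetic_promoters(int(d.get("n_synthetic_promoters", 1)),
                                         rng)
    libraries, pool = design_pool(promoters, dconf)
    median_bcs = int(d.get("barcodes_per_variant", 3))
    taken: set[str] = set()
    assignments = []
    for pid, lib in libraries.items():
        counts = draw_barcode_counts(len(lib), median_bcs, rng)
        assignments.extend(assign_barcodes(lib, counts, dconf, rng=rng,
                                           taken=taken))
    barcode_map = barcode_map_frame(assignments)
    write_pool_fasta(pool, out / "pool.fasta")
    write_barcode_map(barcode_map, out / "barcode_map.tsv")
    pd.concat([library_to_frame(lib) for lib in libraries.values()]
              ).to_csv(out / "library.tsv", sep="\t", index=False)
    manifest["outputs"] += ["pool.fasta", "barcode_map.tsv", "library.tsv"]
    logger.info("designed %d promoters, %d pool entries, %d barcodes",
                len(promoters), len(pool), len(barcode_map))

    # ---- simulate ---------------------------------------------------------
    s = config.get("simulate", {})
    conditions = list(s.get("conditions", ["condA", "condB"]))
    active = list(s.get("active_conditions", conditions[:1]))
    inactive = [c for c in conditions if c not in active]
    arch_kind = s.get("architecture", "default")
    architectures = {}
    truth_rows = []
    for pid, lib in libraries.items():
        arch_rng = np.random.default_rng(rng.integers(2 ** 31))
        if isinstance(arch_kind, str) and arch_kind.endswith(".json"):
            arch = architecture_from_json(Path(arch_kind).read_text())
        elif arch_kind == "repressor":
            arch = repressor_architecture(lib, arch_rng, active, inactive)
        elif arch_kind == "null":
            arch = null_architecture(lib)
        else:
            arch = default_architecture(lib, arch_rng, active, inactive)
        architectures[pid] = arch
        truth_rows.append(ground_truth_sites(arch))
    pd.concat(truth_rows).to_csv(out / "true_sites.tsv", sep="\t", index=False)

    depth_dna = int(s.get("depth_dna", 100_000))
    depth_rna = int(s.get("depth_rna", 100_000))
    n_reps = int(s.get("n_replicates", 2))
    count_tables = []
    for pid, lib in libraries.items():
        count_tables.append(simulate_counts(
            lib, barcode_map, architectures[pid], conditions,
            depth_dna=depth_dna, depth_rna=depth_rna,
            seed=int(rng.integers(2 ** 31)), n_replicates=n_reps))
    counts = pd.concat(count_tables, ignore_index=True)
    write_counts(counts, out / "counts.tsv")
    manifest["outputs"] += ["true_sites.tsv", "counts.tsv"]

    if "reads" in s:
        r = s["reads"]
        for pid, lib in libraries.items():
            reads = simulate_reads(lib, barcode_map, int(r["n_reads"]),
                                   float(r.get("error_rate", 0.0)),
                                   seed=int(rng.integers(2 ** 31)))
            write_reads_fastq(reads, out / f"{pid}_variant_reads.fastq",
                              out / f"{pid}_barcode_reads.fastq")

    # ---- map & aggregate --------------------------------------------------
    m = config.get("map", {})
    if "reads" in s:
        all_reads = []
        from .io import read_paired_fastq
        for pid in libraries:
            all_reads.append(read_paired_fastq(
                out / f"{pid}_variant_reads.fastq",
                out / f"{pid}_barcode_reads.fastq"))
        mapping = map_barcodes(pd.concat(all_reads, ignore_index=True), pool,
                               min_support=int(m.get("min_support", 3)),
                               max_edit_distance=int(m.get("max_edit_distance", 20)))
    else:
        mapping = barcode_map.copy()
        mapping["read_support"] = np.nan
        mapping["edit_distance"] = 0
    mapping.to_csv(out / "mapping.tsv", sep="\t", index=False)
    variant_counts = aggregate_variant_counts(counts, mapping)
    write_counts(variant_counts, out / "variant_counts.tsv")
    manifest["outputs"] += ["mapping.tsv", "variant_counts.tsv"]

    # ---- footprints -------------------------------------------------------
    f = config.get("footprint", {})
    psi = float(f.get("pseudocount", 0.5))
    footprints: dict[tuple[str, int], dict] = {}
    fp_frames, shift_frames = [], []
    shift_store: dict[tuple[str, str, int], object] = {}
    for (pid, cond, rep), grp in variant_counts.groupby(
            ["promoter_id", "condition", "replicate"]):
        lib = libraries[pid]
        fp = information_footprint(grp, lib, pseudocount=psi)
        shifts = expression_shift_matrix(grp, lib, pseudocount=psi)
        footprints.setdefault((cond, rep), {})[pid] = fp
        shift_store[(pid, cond, rep)] = shifts
        fp_frames.append(footprint_to_frame(fp))
        shift_frames.append(shifts_to_frame(shifts))
    pd.concat(fp_frames).to_csv(out / "footprints.tsv", sep="\t", index=False)
    pd.concat(shift_frames).to_csv(out / "shifts.tsv", sep="\t", index=False)
    manifest["outputs"] += ["footprints.tsv", "shifts.tsv"]

    # ---- discover ---------------------------------------------------------
    disc = config.get("discover", {})
    cfg = ClassifierConfig(
        kernel_sigma=float(disc.get("kernel_sigma", 3.0)),
        cv_ratio_threshold=float(disc.get("cv_ratio_threshold", 0.5)),
        activity_threshold=float(disc.get("activity_threshold", 2e-3)))
    class_rows, call_rows = [], []
    for (cond, rep), by_pid in sorted(footprints.items()):
        for pid, fp in sorted(by_pid.items()):
            label = classify_footprint(fp, cfg)
            class_rows.append((pid, cond, rep, label))
            if label != ACTIVE:
                continue
            hmm = fit_two_state_hmm(fp)
            for call in call_sites(fp, hmm, shift_store[(pid, cond, rep)]):
                call_rows.append((pid, cond, rep, call.start, call.end,
                                  index_to_label(call.start),
                                  index_to_label(call.end - 1),
                                  call.mean_mi, call.sign, call.posterior))
    pd.DataFrame(class_rows, columns=["promoter_id", "condition", "replicate",
                                      "class"]
                 ).to_csv(out / "classification.tsv", sep="\t", index=False)
    pd.DataFrame(call_rows, columns=["promoter_id", "condition", "replicate",
                                     "start", "end", "start_label", "end_label",
                                     "mean_mi", "sign", "posterior"]
                 ).to_csv(out / "site_calls.tsv", sep="\t", index=False)
    manifest["outputs"] += ["classification.tsv", "site_calls.tsv"]

    # ---- cluster ----------------------------------------------------------
    cl = config.get("cluster", {})
    flat = {key: fps for key, fps in footprints.items()}
    all_fps = {key: next(iter(v.values())) for key, v in flat.items()}
    corr, flags = replicate_correlation(all_fps,
                                        floor=float(cl.get("replicate_floor", 0.3)))
    flags.to_csv(out / "replicate_flags.tsv", sep="\t", index=False)
    matrix = build_condition_matrix(footprints)
    result = cluster_global(matrix, cut=float(cl.get("cut", 0.5)))
    pd.DataFrame({"row": [f"{c}|{r}" for c, r in result.row_labels],
                  "cluster": result.labels}
                 ).to_csv(out / "global_clusters.tsv", sep="\t", index=False)
    manifest["outputs"] += ["replicate_flags.tsv", "global_clusters.tsv"]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
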