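"""Configuration-driven orchestration of the full synthetic study.

``run_pipeline`` executes, in order: data simulation, bulk RNA
differential expression and ChIP differential acetylation per region,
cross-region sharing and k-means modules, set enrichment, promoter
integration, composite region ranking, an RRHO comparison and the
single-cell stage. Every stage reads only files written by earlier
stages, so subsets of stages can be re-run against an existing output
directory. Outputs are plain TSV with stable column order; a JSON run
manifest records the config hash, seeds, stage status and an inventory
of output files with content hashes.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import math
import os
import time
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from regionomics import diffcount, enrich, integrate, io, modulemap, scpipe, simdata
from regionomics.containers import STATUS_DOWN, STATUS_UP

logger = logging.getLogger("regionomics")

STAGES = (
    "simulate",
    "bulk-de",
    "chip-da",
    "modules",
    "enrich",
    "integrate",
    "rank",
    "rrho",
    "sc",
)


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every offence."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class StageError(RuntimeError):
    pass


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "thresholds": {
        "fc": math.log2(1.25),
        "q_bulk": 0.1,
        "q_pseudobulk": 0.2,
        "q_regulon": 0.1,
        "alpha_proportion": 0.05,
    },
    "modules_k": 8,
    "rrho_regions": ["R01", "R02"],
    "bulk": {
        "n_regions": 8,
        "n_genes": 1000,
        "n_replicates": 4,
        "genes_per_module": 40,
        "effect": 1.0,
    },
    "chip": {"rho": 0.8, "n_replicates": 2},
    "sc": {
        "regions": ["dorDG", "venDG"],
        "n_genes": 800,
        "n_types": 6,
        "n_replicates": 5,
        "cells_per_replicate": 120,
        "proportion_shift_type": "type03",
        "proportion_shift_fold": 2.0,
        "module_shift_type": "type01",
        "module_shift_log2fc": 1.0,
        "regulon_shift_type": "type01",
        "regulon_shift_log2fc": 1.0,
        "lr_sender": "type02",
        "lr_receiver": "type01",
        "lr_shift_log2fc": 1.0,
        "min_genes": 200,
        "max_mito": 0.2,
    },
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError([f"config root must be a mapping ({path})"])
    return _merge(DEFAULT_CONFIG, raw)


def validate_config(config: Mapping | str) -> tuple[dict, list[str], list[str]]:
    """Structural and range checks. Returns (config, errors, warnings)."""
    warnings: list[str] = []
    if isinstance(config, str):
        config = load_config(config)
    else:
        if "seed" not in config:
            warnings.append("seed missing; defaulting to 1")
        config = _merge(DEFAULT_CONFIG, config)
    errors: list[str] = []
    thr = config["thresholds"]
    for key in ("q_bulk", "q_pseudobulk", "q_regulon", "alpha_proportion"):
        if not (0 < thr[key] < 1):
            errors.append(f"thresholds.{key} must lie in (0, 1), got {thr[key]}")
    if thr["fc"] < 0:
        errors.append("thresholds.fc must be non-negative")
    if config["modules_k"] < 1:
        errors.append("modules_k must be >= 1")
    for section, key in (("bulk", "n_replicates"), ("sc", "n_replicates")):
        if config[section][key] < 2:
            errors.append(f"{section}.{key} must be >= 2")
    if not -1 <= config["chip"]["rho"] <= 1:
        errors.append("chip.rho must lie in [-1, 1]")
    if len(config["rrho_regions"]) != 2:
        errors.append("rrho_regions must name exactly two regions")
    for key in ("gene_sets", "regulons", "lr_catalogue"):
        path = config.get("paths", {}).get(key)
        if path and not os.path.exists(path):
            errors.append(f"paths.{key}: file not found: {path}")
    return config, errors, warnings


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# stage implementations (each reads prior outputs from the output directory)
# ---------------------------------------------------------------------------


def _stage_simulate(config: dict, outdir: str) -> None:
    seed = int(config["seed"])
    bulk_cfg = config["bulk"]
    modules = simdata.default_bulk_modules(
        bulk_cfg["n_regions"],
        bulk_cfg["n_genes"],
        genes_per_module=bulk_cfg["genes_per_module"],
        effect=bulk_cfg["effect"],
    )
    bulk = simdata.simulate_bulk(
        simdata.BulkSimConfig(
            n_regions=bulk_cfg["n_regions"],
            n_genes=bulk_cfg["n_genes"],
            n_replicates=bulk_cfg["n_replicates"],
            modules=modules,
            seed=seed,
        )
    )
    from regionomics.containers import CountMatrix

    merged = CountMatrix.concat(bulk.sham, bulk.treated)
    io.write_counts_tsv(
        merged,
        os.path.join(outdir, "bulk_rna_counts.tsv"),
        os.path.join(outdir, "bulk_rna_samples.tsv"),
    )
    io.write_table(bulk.truth.effects, os.path.join(outdir, "truth_bulk.tsv"), "feature_id")

    chip = simdata.simulate_chip(
        bulk.truth,
        rho=config["chip"]["rho"],
        n_replicates=config["chip"]["n_replicates"],
        seed=seed + 1,
    )
    merged_chip = CountMatrix.concat(chip.sham, chip.treated)
    io.write_counts_tsv(
        merged_chip,
        os.path.join(outdir, "chip_counts.tsv"),
        os.path.join(outdir, "chip_samples.tsv"),
    )
    io.write_bed(chip.peaks, os.path.join(outdir, "peaks.bed"))
    io.write_tss(chip.tss, os.path.join(outdir, "tss.bed"))
    io.write_table(chip.truth.effects, os.path.join(outdir, "truth_chip.tsv"), "feature_id")
    with open(os.path.join(outdir, "genome_size.txt"), "w") as fh:
        fh.write(f"{simdata.PeakGeometry().gene_spacing * (bulk_cfg['n_genes'] + 1)}\n")

    # gene sets: the planted modules plus deterministic decoy sets
    sets = {m.label: list(m.gene_ids) for m in modules}
    rng = np.random.default_rng(seed + 2)
    universe = bulk.truth.effects.index.to_numpy()
    for i in range(4):
        sets[f"decoy{i + 1}"] = sorted(rng.choice(universe, size=40, replace=False))
    io.write_gmt(sets, os.path.join(outdir, "gene_sets.gmt"))

    # single-cell simulation per region; shifts planted only in the first
    sc_cfg = config["sc"]
    template = simdata.ScSimConfig(
        n_genes=sc_cfg["n_genes"],
        n_types=sc_cfg["n_types"],
        n_replicates=sc_cfg["n_replicates"],
        cells_per_replicate=sc_cfg["cells_per_replicate"],
    )
    gene_ids = template.gene_ids
    markers = template.markers()
    marker_genes = {g for ms in markers.values() for g in ms}
    free = [g for g in gene_ids[template.n_mito:] if g not in marker_genes]
    module_genes = tuple(free[:30])
    tf = free[30]
    targets = tuple(free[31:61])
    lig = markers[sc_cfg["lr_sender"]][0]
    rec = markers[sc_cfg["lr_receiver"]][0]

    sc_truths = []
    for i, region in enumerate(sc_cfg["regions"]):
        planted = i == 0
        cfg = simdata.ScSimConfig(
            n_genes=sc_cfg["n_genes"],
            n_types=sc_cfg["n_types"],
            n_replicates=sc_cfg["n_replicates"],
            cells_per_replicate=sc_cfg["cells_per_replicate"],
            region=region,
            seed=seed + 10 + i,
            proportion_shift=(
                {sc_cfg["proportion_shift_type"]: sc_cfg["proportion_shift_fold"]}
                if planted
                else {}
            ),
            module_shift=(
                simdata.ModuleShift(
                    gene_ids=module_genes,
                    cell_type=sc_cfg["module_shift_type"],
                    log2fc=sc_cfg["module_shift_log2fc"],
                    label="sc_module",
                )
                if planted
                else None
            ),
            regulon_shift=(
                simdata.RegulonShift(
                    tf=tf,
                    targets=targets,
                    cell_type=sc_cfg["regulon_shift_type"],
                    log2fc=sc_cfg["regulon_shift_log2fc"],
                )
                if planted
                else None
            ),
            lr_shift=(
                simdata.LREdgeShift(
                    ligand=lig,
                    receptor=rec,
                    sender=sc_cfg["lr_sender"],
                    receiver=sc_cfg["lr_receiver"],
                    log2fc=sc_cfg["lr_shift_log2fc"],
                )
                if planted
                else None
            ),
        )
        sim = simdata.simulate_scrna(cfg)
        for condition, adata in (("sham", sim.sham), ("treated", sim.treated)):
            io.write_mtx_dir(adata, os.path.join(outdir, f"sc_{region}_{condition}"))
        if len(sim.truth.sc_effects):
            sc_truths.append(sim.truth.sc_effects.assign(region=region))
    sc_truth = (
        pd.concat(sc_truths, ignore_index=True)
        if sc_truths
        else pd.DataFrame(columns=["kind", "cell_type", "target", "magnitude", "region"])
    )
    sc_truth.to_csv(os.path.join(outdir, "truth_sc.tsv"), sep="\t", index=False)
    io.write_gmt(markers, os.path.join(outdir, "markers.gmt"))
    io.write_gmt(
        {"sc_module": list(module_genes)}, os.path.join(outdir, "sc_gene_sets.gmt")
    )
    # planted regulon plus decoy regulons over unused genes
    regulons = {tf: list(targets)}
    pool = free[61:]
    for i in range(3):
        block = pool[i * 31 : (i + 1) * 31]
        if len(block) == 31:
            regulons[block[0]] = block[1:]
    io.write_gmt(regulons, os.path.join(outdir, "regulons.gmt"))
    lr_rows = [(lig, rec)]
    for t in list(markers)[2:4]:
        lr_rows.append((markers[t][1], markers[t][2]))
    io.write_lr_catalogue(
        pd.DataFrame(lr_rows, columns=["ligand", "receptor"]),
        os.path.join(outdir, "lr_pairs.tsv"),
    )


def _run_de(config: dict, outdir: str, counts_file: str, meta_file: str, subdir: str) -> None:
    cm = io.read_counts_tsv(
        os.path.join(outdir, counts_file), os.path.join(outdir, meta_file)
    )
    thr = config["thresholds"]
    de_dir = os.path.join(outdir, subdir)
    os.makedirs(de_dir, exist_ok=True)
    for region in cm.regions:
        sub = cm.subset_region(region)
        table = diffcount.test_differential(
            sub, fc_threshold=thr["fc"], q_threshold=thr["q_bulk"]
        )
        io.write_table(table, os.path.join(de_dir, f"{region}.tsv"), "feature_id")


def _read_de_dir(outdir: str, subdir: str) -> dict[str, pd.DataFrame]:
    de_dir = os.path.join(outdir, subdir)
    if not os.path.isdir(de_dir):
        raise StageError(f"missing stage output: {subdir}/ (run earlier stages first)")
    out = {}
    for name in sorted(os.listdir(de_dir)):
        if name.endswith(".tsv"):
            out[name[:-4]] = io.read_table(os.path.join(de_dir, name), "feature_id")
    if not out:
        raise StageError(f"no differential tables under {subdir}/")
    return out


def _stage_modules(config: dict, outdir: str) -> None:
    seed = int(config["seed"])
    for subdir, prefix in (("de_rna", "gene"), ("de_chip", "peak")):
        per_region = _read_de_dir(outdir, subdir)
        fcm = modulemap.build_foldchange_matrix(per_region)
        k = min(config["modules_k"], fcm.values.shape[0])
        part = modulemap.cluster_modules(fcm, k=k, seed=seed)
        io.write_table(
            part.assignments.to_frame(),
            os.path.join(outdir, f"{prefix}_modules.tsv"),
            "feature_id",
        )
        io.write_table(
            part.centroids, os.path.join(outdir, f"{prefix}_module_centroids.tsv"), "module"
        )
        summary = modulemap.sharing_summary(per_region)
        io.write_table(
            summary.per_feature, os.path.join(outdir, f"{prefix}_sharing.tsv"), "feature_id"
        )
        io.write_table(
            summary.histogram, os.path.join(outdir, f"{prefix}_sharing_histogram.tsv"), "degree"
        )


def _stage_enrich(config: dict, outdir: str) -> None:
    seed = int(config["seed"])
    per_region = _read_de_dir(outdir, "de_rna")
    sets = io.read_gmt(os.path.join(outdir, "gene_sets.gmt"))
    rows = []
    for region, table in per_region.items():
        universe = table.index[table["p_value"].notna()]
        collection = enrich.GeneSetCollection.from_dict(sets, universe)
        hits = table.index[table["status"].isin([STATUS_UP, STATUS_DOWN])]
        if len(hits) == 0 or not collection.sets:
            continue
        res = enrich.ora(hits, collection).assign(region=region)
        rows.append(res)
    if rows:
        io.write_table(pd.concat(rows, ignore_index=True), os.path.join(outdir, "ora.tsv"))

    # GSEA on the first region's signed ranking
    region = sorted(per_region)[0]
    table = per_region[region]
    tested = table[table["p_value"].notna()]
    scores = integrate.signed_ranking_score(tested)
    gsea_rows = []
    for name, members in sets.items():
        inter = set(members) & set(scores.index)
        if not inter:
            continue
        res = enrich.gsea(scores, inter, set_name=name, n_perm=200, seed=seed)
        gsea_rows.append(
            (name, res.es, res.nes, res.p_value, len(res.leading_edge))
        )
    io.write_table(
        pd.DataFrame(
            gsea_rows, columns=["set_name", "es", "nes", "p_value", "n_leading_edge"]
        ),
        os.path.join(outdir, f"gsea_{region}.tsv"),
    )

    # GREAT-style binomial enrichment of the first region's DA peaks
    per_chip = _read_de_dir(outdir, "de_chip")
    chip_region = sorted(per_chip)[0]
    da = per_chip[chip_region]
    da_peaks = da.index[da["status"].isin([STATUS_UP, STATUS_DOWN])]
    peaks = io.read_bed(os.path.join(outdir, "peaks.bed"))
    tss = io.read_tss(os.path.join(outdir, "tss.bed"))
    with open(os.path.join(outdir, "genome_size.txt")) as fh:
        genome_size = int(fh.read().strip())
    domains = enrich.build_regulatory_domains(tss, genome_size)
    da_bed = peaks[peaks["name"].isin(set(da_peaks))]
    rows = []
    if len(da_bed):
        for name, members in sets.items():
            rows.append(enrich.region_enrichment_binomial(da_bed, domains, members, name))
    great = pd.DataFrame(rows)
    if len(great):
        great["q_value"] = diffcount.bh_adjust(great["p_value"].to_numpy())
    io.write_table(great, os.path.join(outdir, f"great_{chip_region}.tsv"))


def _stage_integrate(config: dict, outdir: str) -> None:
    peaks = io.read_bed(os.path.join(outdir, "peaks.bed"))
    tss = io.read_tss(os.path.join(outdir, "tss.bed"))
    assignment = integrate.assign_peaks_to_promoters(peaks, tss)
    io.write_table(
        assignment.rename("gene_id").to_frame(),
        os.path.join(outdir, "promoter_assignment.tsv"),
        "peak_id",
    )
    per_rna = _read_de_dir(outdir, "de_rna")
    per_chip = _read_de_dir(outdir, "de_chip")
    rows = []
    for region in sorted(set(per_rna) & set(per_chip)):
        try:
            res = integrate.promoter_concordance(
                per_rna[region], per_chip[region], assignment, region=region
            )
            rows.append((region, res.n_pairs, res.spearman_rho, res.p_value))
        except ValueError:
            rows.append((region, 0, np.nan, np.nan))
    io.write_table(
        pd.DataFrame(rows, columns=["region", "n_pairs", "spearman_rho", "p_value"]),
        os.path.join(outdir, "concordance.tsv"),
    )


def _stage_rank(config: dict, outdir: str) -> None:
    per_rna = _read_de_dir(outdir, "de_rna")
    per_chip = _read_de_dir(outdir, "de_chip")
    n_deg = {
        r: int(t["status"].isin([STATUS_UP, STATUS_DOWN]).sum()) for r, t in per_rna.items()
    }
    n_da = {
        r: int(t["status"].isin([STATUS_UP, STATUS_DOWN]).sum()) for r, t in per_chip.items()
    }
    ranking = integrate.composite_region_ranking(n_deg, n_da)
    io.write_table(ranking, os.path.join(outdir, "region_ranking.tsv"), "region")


def _stage_rrho(config: dict, outdir: str) -> None:
    per_rna = _read_de_dir(outdir, "de_rna")
    r1, r2 = config["rrho_regions"]
    for r in (r1, r2):
        if r not in per_rna:
            raise StageError(f"rrho region {r!r} has no differential table")
    t1 = per_rna[r1][per_rna[r1]["p_value"].notna()]
    t2 = per_rna[r2][per_rna[r2]["p_value"].notna()]
    common = t1.index.intersection(t2.index)
    s1 = integrate.signed_ranking_score(t1.loc[common])
    s2 = integrate.signed_ranking_score(t2.loc[common])
    rmap = integrate.rrho_map(s1, s2)
    io.write_table(
        rmap.signed(), os.path.join(outdir, f"rrho_{r1}_vs_{r2}.tsv"), "top_list1"
    )


def _stage_sc(config: dict, outdir: str) -> None:
    sc_cfg = config["sc"]
    thr = config["thresholds"]
    markers = io.read_gmt(os.path.join(outdir, "markers.gmt"))
    ref = scpipe.ReferenceCentroids.from_marker_lists(markers)
    sets = io.read_gmt(os.path.join(outdir, "sc_gene_sets.gmt"))
    regulon_defs = io.read_gmt(os.path.join(outdir, "regulons.gmt"))
    regulons = [
        scpipe.Regulon(tf=tf, targets=tuple(targets))
        for tf, targets in regulon_defs.items()
    ]
    catalogue = io.read_lr_catalogue(os.path.join(outdir, "lr_pairs.tsv"))
    for region in sc_cfg["regions"]:
        sc_dir = os.path.join(outdir, f"sc_{region}")
        os.makedirs(sc_dir, exist_ok=True)
        import anndata as ad

        parts = [
            io.read_mtx_dir(os.path.join(outdir, f"sc_{region}_{cond}"))
            for cond in ("sham", "treated")
        ]
        adata = ad.concat(parts, join="outer", merge="same")
        adata.obs_names_make_unique()
        adata = scpipe.qc_and_normalize(
            adata, min_genes=sc_cfg["min_genes"], max_mito=sc_cfg["max_mito"]
        )
        typing = scpipe.assign_cell_types(adata, ref, seed=int(config["seed"]))
        io.write_table(typing, os.path.join(sc_dir, "cell_types.tsv"), "cell_id")
        labels = typing["label"]

        props = scpipe.test_proportions(labels, adata.obs)
        props["significant"] = props["p_value"] <= thr["alpha_proportion"]
        io.write_table(props, os.path.join(sc_dir, "proportions.tsv"), "cell_type")

        de = scpipe.pseudobulk_de(
            adata, labels, fc_threshold=thr["fc"], q_threshold=thr["q_pseudobulk"]
        )
        de_dir = os.path.join(sc_dir, "pseudobulk_de")
        os.makedirs(de_dir, exist_ok=True)
        for ctype, table in de.items():
            io.write_table(table, os.path.join(de_dir, f"{ctype}.tsv"), "feature_id")

        for name, members in sets.items():
            try:
                _, table = scpipe.score_gene_module(
                    adata, members, labels, seed=int(config["seed"])
                )
            except ValueError:
                continue
            io.write_table(
                table, os.path.join(sc_dir, f"module_score_{name}.tsv"), "cell_type"
            )

        usable = [
            r
            for r in regulons
            if sum(g in set(adata.var_names) for g in r.genes) >= 5
        ]
        if usable:
            diff = scpipe.differential_regulons(
                adata, usable, labels, q_threshold=thr["q_regulon"]
            )
            reg_dir = os.path.join(sc_dir, "regulons")
            os.makedirs(reg_dir, exist_ok=True)
            for ctype, table in diff.items():
                io.write_table(table, os.path.join(reg_dir, f"{ctype}.tsv"), "tf")

        try:
            edges = scpipe.lr_edges_and_diff(adata, labels, catalogue)
            io.write_table(edges, os.path.join(sc_dir, "lr_edges.tsv"))
        except ValueError:
            pass


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "bulk-de": lambda cfg, out: _run_de(
        cfg, out, "bulk_rna_counts.tsv", "bulk_rna_samples.tsv", "de_rna"
    ),
    "chip-da": lambda cfg, out: _run_de(
        cfg, out, "chip_counts.tsv", "chip_samples.tsv", "de_chip"
    ),
    "modules": _stage_modules,
    "enrich": _stage_enrich,
    "integrate": _stage_integrate,
    "rank": _stage_rank,
    "rrho": _stage_rrho,
    "sc": _stage_sc,
}


def run_pipeline(
    config: Mapping | str,
    outdir: str,
    stages: list[str] | None = None,
) -> dict:
    """Run the selected stages and write a manifest. Returns the manifest."""
    config, errors, warnings = validate_config(config)
    for w in warnings:
        logger.warning(w)
    if errors:
        raise ConfigError(errors)
    stages = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError([f"unknown stage(s): {unknown}"])
    stages = [s for s in STAGES if s in stages]  # canonical order
    os.makedirs(outdir, exist_ok=True)

    stage_status = []
    for stage in stages:
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:  # halt with a resumable state
            stage_status.append({"stage": stage, "status": "failed", "error": str(exc)})
            _write_manifest(config, outdir, stage_status)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        logger.info("stage %s: done in %.2fs", stage, dt)
        stage_status.append({"stage": stage, "status": "ok", "seconds": round(dt, 3)})
    return _write_manifest(config, outdir, stage_status)


def _write_manifest(config: Mapping, outdir: str, stage_status: list[dict]) -> dict:
    from regionomics import __version__

    inventory = {}
    for root, _, files in os.walk(outdir):
        for name in sorted(files):
            if name == "manifest.json":
                continue
            path = os.path.join(root, name)
            inventory[os.path.relpath(path, outdir)] = _hash_file(path)
    manifest = {
        "tool_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config["seed"],
        "stages": stage_status,
        "outputs": dict(sorted(inventory.items())),
    }
    tmp = os.path.join(outdir, "manifest.json.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    os.replace(tmp, os.path.join(outdir, "manifest.json"))
    return manifest
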