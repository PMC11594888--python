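"""End-to-end orchestration: sim -> filter -> annotate -> structure -> sweep
-> gwas -> markers -> enrich from one YAML config, with a JSON manifest.

All stage randomness derives from the single global seed; reruns with the
same config produce identical output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import enrich as enrich_mod
from . import gwas as gwas_mod
from . import markers as markers_mod
from . import structure as structure_mod
from . import sweep as sweep_mod
from . import variants as variants_mod
from .simdata import (
    CausalSnp,
    SimConfig,
    SweepRegion,
    read_phenotypes,
    simulate_genotypes_and_phenotypes,
    write_outputs,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a mapping")
    cfg.setdefault("seed", 0)
    cfg.setdefault("out_dir", "popsweep_run")
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config_from_block(block: dict, seed: int) -> SimConfig:
    block = dict(block or {})
    if "sweep_regions" in block:
        block["sweep_regions"] = [SweepRegion(**r) for r in block["sweep_regions"]]
    if "causal_snp" in block:
        block["causal_snp"] = CausalSnp(**block["causal_snp"])
    block.setdefault("seed", seed)
    return SimConfig(**block)


def run_pipeline(config: dict | str) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    if isinstance(config, str):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    out_dir = config["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": {}, "files": {}}

    def record(stage: str, params: dict, files: dict[str, str]) -> None:
        manifest["stages"][stage] = params
        for name, path in files.items():
            manifest["files"][f"{stage}:{name}"] = dict(
                path=path, sha256=_sha256(path)
            )

    # --- stage 1: simulated or supplied inputs -----------------------------
    if "inputs" in config:
        paths = dict(config["inputs"])
        record("inputs", {}, {})
    else:
        sim_cfg = _sim_config_from_block(config.get("sim", {}), seed)
        sim = simulate_genotypes_and_phenotypes(sim_cfg)
        sim_dir = os.path.join(out_dir, "sim")
        paths = write_outputs(sim, sim_dir)
        record(
            "sim",
            {k: v for k, v in asdict(sim_cfg).items() if k != "chrom_lengths"}
            | {"chrom_lengths": dict(sim_cfg.chrom_lengths)},
            paths,
        )

    for key in ("vcf", "phenotypes", "gff3", "reference"):
        if key not in paths or not os.path.exists(paths[key]):
            raise PipelineError(f"missing upstream output for stage using {key!r}")

    # --- stage 2: filter ---------------------------------------------------
    g = variants_mod.read_vcf(paths["vcf"])
    fblock = config.get("filter", {})
    g, report = variants_mod.filter_variants(
        g,
        min_quality=fblock.get("min_quality", 20),
        min_support=fblock.get("min_support", 4),
        min_maf=fblock.get("min_maf", 0.05),
        max_missing=fblock.get("max_missing", 0.1),
    )
    filtered_vcf = os.path.join(out_dir, "filtered.vcf")
    variants_mod.write_vcf(g, filtered_vcf)
    report_path = os.path.join(out_dir, "filter_report.tsv")
    report.to_frame().to_csv(report_path, sep="\t", index=False)
    record("filter", dict(fblock), {"vcf": filtered_vcf, "report": report_path})
    if g.n_variants == 0:
        raise PipelineError("stage filter removed every variant")

    pheno = read_phenotypes(paths["phenotypes"])
    pheno = pheno.set_index("sample").loc[g.samples].reset_index()
    models = annotate_mod.read_gff3(paths["gff3"])
    reference = annotate_mod.read_fasta(paths["reference"])

    # --- stage 3: annotate -------------------------------------------------
    annos = annotate_mod.annotate_matrix(g, models, reference)
    anno_path = os.path.join(out_dir, "annotations.tsv")
    pd.DataFrame(
        dict(
            chrom=[a.key[0] for a in annos],
            pos=[a.key[1] for a in annos],
            category=[a.category for a in annos],
            subcategory=[a.exonic_subcategory or "" for a in annos],
            genes=[",".join(a.genes) for a in annos],
        )
    ).to_csv(anno_path, sep="\t", index=False)
    summary = annotate_mod.summarize_annotations(annos, total=len(annos))
    summary_path = os.path.join(out_dir, "annotation_summary.tsv")
    summary.to_csv(summary_path, sep="\t", index=False)
    record("annotate", {}, {"annotations": anno_path, "summary": summary_path})

    # --- stage 4: structure ------------------------------------------------
    sblock = config.get("structure", {})
    n_boot = sblock.get("n_boot", 100)
    dm = structure_mod.p_distance_matrix(g)
    full = structure_mod.nj_tree(dm)
    support = structure_mod.bootstrap_support(g, n_boot=n_boot, seed=seed + 1)
    for part, node in full.bipartitions().items():
        node.support = support.get(part)
    tree_path = os.path.join(out_dir, "nj_tree.nwk")
    with open(tree_path, "w") as fh:
        fh.write(full.newick(with_support=True) + "\n")
    M = structure_mod.standardize_genotypes(g)
    pca_res = structure_mod.pca(M)
    pca_path = os.path.join(out_dir, "pca.tsv")
    pca_df = pd.DataFrame(
        pca_res.coordinates,
        columns=[f"PC{i + 1}" for i in range(pca_res.coordinates.shape[1])],
    )
    pca_df.insert(0, "sample", g.samples)
    pca_df.to_csv(pca_path, sep="\t", index=False)
    record("structure", {"n_boot": n_boot}, {"tree": tree_path, "pca": pca_path})

    # --- stage 5: sweep ----------------------------------------------------
    swblock = config.get("sweep", {})
    chrom_lengths = {
        chrom: int(sub["pos"].max()) for chrom, sub in g.variants.groupby("chrom")
    }
    if "sim" in manifest["stages"]:
        chrom_lengths = manifest["stages"]["sim"]["chrom_lengths"]
    windows = sweep_mod.make_windows(
        chrom_lengths,
        size=swblock.get("size", 100_000),
        step=swblock.get("step", 50_000),
    )
    tl = [s for s, grp in zip(pheno["sample"], pheno["group"]) if grp == "TL"]
    sl = [s for s, grp in zip(pheno["sample"], pheno["group"]) if grp == "SL"]
    sweep_mod.window_fst(g, tl, sl, windows)
    sweep_mod.window_pi(g, tl, windows, label="TL")
    sweep_mod.window_pi(g, sl, windows, label="SL")
    quantile = swblock.get("quantile", 0.95)
    pi_mode = swblock.get("pi_mode", "ratio")
    selected_genes: dict[str, list[str]] = {}
    bed_path = os.path.join(out_dir, "selected_regions.bed")
    with open(bed_path, "w") as bed:
        for focal in ("TL", "SL"):
            result = sweep_mod.joint_select(
                windows,
                focal,
                quantile=quantile,
                pi_mode=pi_mode,
                min_snps=swblock.get("min_snps", 5),
            )
            _per_window, union = sweep_mod.windows_to_genes(result.selected, models)
            selected_genes[focal] = union
            for w in result.selected:
                bed.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\t{focal}\n")
    win_path = os.path.join(out_dir, "windows.tsv")
    sweep_mod.windows_frame(windows).to_csv(win_path, sep="\t", index=False)
    shared = sorted(set(selected_genes["TL"]) & set(selected_genes["SL"]))
    genes_path = os.path.join(out_dir, "selected_genes.tsv")
    pd.DataFrame(
        [(f, gid) for f in ("TL", "SL") for gid in selected_genes[f]]
        + [("shared", gid) for gid in shared],
        columns=["group", "gene"],
    ).to_csv(genes_path, sep="\t", index=False)
    record(
        "sweep",
        dict(quantile=quantile, pi_mode=pi_mode),
        {"windows": win_path, "bed": bed_path, "genes": genes_path},
    )

    # --- stage 6: gwas -----------------------------------------------------
    gblock = config.get("gwas", {})
    y = pheno["leg_length_cm"].to_numpy()
    K = gwas_mod.kinship_centered(g)
    gres = gwas_mod.mlm_associate(y, g, K, alpha=gblock.get("alpha", 0.05))
    assoc_path = os.path.join(out_dir, "gwas.tsv")
    gres.table.to_csv(assoc_path, sep="\t", index=False)
    record(
        "gwas",
        dict(
            alpha=gblock.get("alpha", 0.05),
            threshold=gres.threshold,
            lambda_gc=gres.lambda_gc,
        ),
        {"assoc": assoc_path},
    )

    # --- stage 7: markers on the top GWAS SNP ------------------------------
    top = int(gres.table["p"].idxmin())
    v = g.variants.iloc[top]
    calls = g.calls[:, top]
    geno_names = {
        0: v.ref + v.ref,
        1: v.ref + v.alt,
        2: v.alt + v.alt,
    }
    called = calls != variants_mod.MISSING
    counts = (
        int(np.sum(calls == 2)),  # alt-hom first so p = alt frequency
        int(np.sum(calls == 1)),
        int(np.sum(calls == 0)),
    )
    mstats = markers_mod.marker_stats(counts, locus=f"{v.chrom}:{v.pos}")
    stats_path = os.path.join(out_dir, "marker_stats.tsv")
    markers_mod.stats_frame([mstats]).to_csv(stats_path, sep="\t", index=False)
    assoc = markers_mod.glm_association(
        y[called], np.array([geno_names[int(c)] for c in calls[called]])
    )
    marker_assoc_path = os.path.join(out_dir, "marker_association.tsv")
    assoc.groups.to_csv(marker_assoc_path, sep="\t", index=False)
    record(
        "markers",
        dict(locus=f"{v.chrom}:{v.pos}"),
        {"stats": stats_path, "association": marker_assoc_path},
    )

    # --- stage 8: enrichment -----------------------------------------------
    universe = sorted({m.gene_id for m in models})
    if "gmt" in paths and paths.get("gmt"):
        terms = enrich_mod.read_gmt(paths["gmt"])
    else:
        # synthetic term sets from the annotation, seeded from the global seed
        rng = np.random.default_rng(seed + 7)
        max_size = max(2, min(30, len(universe)))
        terms = [
            enrich_mod.TermSet(
                f"T{i:03d}",
                f"synthetic term {i}",
                set(
                    rng.choice(
                        universe,
                        size=rng.integers(1, max_size),
                        replace=False,
                    )
                ),
            )
            for i in range(50)
        ]
        logger.info("no GMT supplied; generated 50 synthetic term sets")
    sel_union = sorted(set(selected_genes["TL"]) | set(selected_genes["SL"]))
    etable = enrich_mod.enrich_table(sel_union, terms, universe)
    enrich_path = os.path.join(out_dir, "enrichment.tsv")
    etable.to_csv(enrich_path, sep="\t", index=False)
    record("enrich", dict(n_terms=len(terms)), {"table": enrich_path})

    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = manifest_path
    return manifest
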