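"""Readers/writers for the pipeline's table dialects, config handling, and the
end-to-end pipeline runner.

All result tables are TSVs with a one-line provenance header comment carrying
the tool version, the config hash and the master seed, so two runs with equal
configs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import chromnest
from chromnest import simulate as sim
from chromnest.chromatin import (
    MarkLibrary,
    active_gene_partition,
    annotate_windows_with_chromatin,
    classify_adjacent_pairs,
    classify_gene,
    ds_summary,
    gene_chromatin_table,
    read_island_set,
)
from chromnest.distance import binned_distance_correlation, cross_chromosome_baseline
from chromnest.expression import (
    ExpressionMatrix,
    expressed_in_tissue,
    filter_min_present,
    read_expression,
    write_expression,
)
from chromnest.genome import (
    GenomeAnnotation,
    order_genes,
    read_annotation,
    resolve_overlaps,
    write_annotation,
)
from chromnest.neighborhoods import SyntenyMap, best_tns_per_gene, score_windows
from chromnest.stats import tns_by_regulation_class

DEFAULT_CONFIG = {
    "alpha": 0.05,
    "min_genes": 2,
    "max_genes": 10,
    "bin_width": 10_000,
    "max_dist": 60_000_000,
    "ds_band": 2.0,
    "log_thresh": 8.0,
    "tns_hi": 0.4,
    "tns_lo": 0.01,
    "hub_min": 10,
    "window_size": 200,
    "n_perm": 1000,
    "seed": 0,
    "eps": 1.0,
    "method": "spearman",
    "min_present": 5,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if not (0 < cfg["alpha"] < 1):
        raise ValueError("alpha must be in (0, 1)")
    if cfg["min_genes"] < 2 or cfg["max_genes"] < cfg["min_genes"]:
        raise ValueError("need 2 <= min_genes <= max_genes")
    if cfg["bin_width"] <= 0 or cfg["max_dist"] <= 0:
        raise ValueError("bin_width and max_dist must be positive")
    for key in ("tns_lo", "tns_hi"):
        if not (0 <= cfg[key] <= 1):
            raise ValueError(f"{key} must be in [0, 1]")
    inputs = cfg.get("inputs", {})
    for name, p in inputs.items():
        if name == "islands":
            for entry in p:
                if not Path(entry["path"]).exists():
                    raise FileNotFoundError(f"missing input file: {entry['path']}")
        elif isinstance(p, str) and not Path(p).exists():
            raise FileNotFoundError(f"missing input file: {p}")


def config_hash(cfg: dict) -> str:
    return hashlib.md5(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance(cfg: dict) -> str:
    return (
        f"# chromnest {chromnest.__version__} "
        f"config_hash={config_hash(cfg)} seed={cfg.get('seed', 0)}\n"
    )


def write_table(df: pd.DataFrame, path, cfg: dict, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


# ---------------------------------------------------------------------------
# Synteny table dialect: (genome, gene_id, block_id, order_index)


def read_synteny(path, reference: str = "reference") -> SyntenyMap:
    df = pd.read_csv(path, sep="\t", dtype={"genome": str, "gene_id": str})
    genomes: dict[str, dict[str, tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        genomes.setdefault(row.genome, {})[row.gene_id] = (
            int(row.block_id),
            int(row.order_index),
        )
    return SyntenyMap(genomes=genomes, reference=reference)


def write_synteny(smap: SyntenyMap, path) -> None:
    rows = [
        {"genome": genome, "gene_id": gid, "block_id": b, "order_index": o}
        for genome, mapping in smap.genomes.items()
        for gid, (b, o) in mapping.items()
    ]
    pd.DataFrame(rows, columns=["genome", "gene_id", "block_id", "order_index"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Neighborhood result dialects


def write_neighborhood_tsv(scored: pd.DataFrame, path, cfg: dict) -> None:
    """All putative neighborhoods: chrom, start, end, n_genes, gene_ids, scores."""
    df = scored.copy()
    df["gene_ids"] = [",".join(g) for g in df["gene_ids"]]
    write_table(df, path, cfg)


def read_neighborhood_tsv(path) -> pd.DataFrame:
    df = read_table(path, dtype={"chrom": str})
    df["gene_ids"] = [tuple(g.split(",")) for g in df["gene_ids"]]
    return df


def write_best_tns(best: pd.Series, path, cfg: dict) -> None:
    df = best.rename_axis("gene_id").reset_index()
    write_table(df, path, cfg)


def _tns_color(t: float) -> str:
    if t >= 0.6:
        return "255,0,0"  # red
    if t >= 0.4:
        return "255,165,0"  # orange
    if t >= 0.1:
        return "255,255,0"  # bright yellow
    return "255,255,153"  # light yellow


def write_ucsc_track(scored: pd.DataFrame, path, cfg: dict, name: str = "TNS") -> None:
    """BED9 custom track, one feature per window, score = round(TNS x 1000)."""
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        fh.write(f'track name="{name}" itemRgb="On"\n')
        for row in scored.itertuples(index=False):
            t = 0.0 if np.isnan(row.TNS) else float(row.TNS)
            score = int(round(t * 1000))
            label = f"w{row.n_genes}_{row.start}"
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{label}\t{score}\t.\t"
                f"{row.start}\t{row.end}\t{_tns_color(t)}\n"
            )


def read_ucsc_track(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("track"):
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "name": parts[3],
                    "score": int(parts[4]),
                    "rgb": parts[8],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic bundle on disk


def write_bundle(outdir, seed: int = 0, **kw) -> None:
    """Emit a full synthetic input bundle (annotation, expression, synteny,
    islands, truth JSON) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, truth, expr, smap, marks = sim.simulate_bundle(seed=seed, **kw)
    write_annotation(ann, outdir / "annotation.tsv")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in ann.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    write_expression(
        expr, outdir / "values.tsv", outdir / "calls.tsv", outdir / "samples.tsv"
    )
    write_synteny(smap, outdir / "synteny.tsv")
    isl_dir = outdir / "islands"
    isl_dir.mkdir(exist_ok=True)
    manifest = []
    for attr, mark, tissue in [
        ("mam_k4", "H3K4me2", "mammary"), ("mam_k36", "H3K36me3", "mammary"),
        ("mam_k27", "H3K27me3", "mammary"), ("liv_k4", "H3K4me2", "liver"),
        ("liv_k36", "H3K36me3", "liver"), ("liv_k27", "H3K27me3", "liver"),
    ]:
        fname = f"{mark}_{tissue}.bed"
        getattr(marks, attr).to_frame().to_csv(
            isl_dir / fname, sep="\t", header=False, index=False, float_format="%.6g"
        )
        manifest.append({"path": str(isl_dir / fname), "mark": mark, "tissue": tissue})
    with open(outdir / "islands_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    truth.to_json(outdir / "truth.json")


def load_marks(manifest) -> MarkLibrary:
    """Build a MarkLibrary from a manifest: list of {path, mark, tissue}."""
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    by_key = {}
    for entry in manifest:
        by_key[(entry["mark"], entry["tissue"])] = read_island_set(
            entry["path"], entry["mark"], entry["tissue"]
        )
    return MarkLibrary(
        mam_k4=by_key[("H3K4me2", "mammary")],
        mam_k36=by_key[("H3K36me3", "mammary")],
        mam_k27=by_key[("H3K27me3", "mammary")],
        liv_k4=by_key[("H3K4me2", "liver")],
        liv_k36=by_key[("H3K36me3", "liver")],
        liv_k27=by_key[("H3K27me3", "liver")],
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline


def _check_gene_universe(ann: GenomeAnnotation, m: ExpressionMatrix) -> None:
    ann_ids = {g.gene_id for g in ann}
    matrix_only = sorted(set(m.gene_ids) - ann_ids)
    if matrix_only:
        raise ValueError(
            "expression matrix contains genes missing from the annotation: "
            + ", ".join(matrix_only[:10])
            + ("..." if len(matrix_only) > 10 else "")
        )


def run_pipeline(cfg: dict, outdir) -> dict:
    """Execute the full analysis and write results under ``outdir``.

    Stages: load/simulate inputs -> filter expression -> resolve overlaps ->
    distance profile -> window scoring (TNS) -> chromatin scores (gene and
    neighborhood) -> classifications -> group statistics -> writers.  Returns
    a dict of the in-memory results.
    """
    cfg = {**DEFAULT_CONFIG, **cfg}
    _validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    inputs = cfg.get("inputs")
    if inputs:
        ann = order_genes(read_annotation(inputs["annotation"]))
        expr = read_expression(inputs["values"], inputs["calls"], inputs["samples"])
        smap = read_synteny(inputs["synteny"])
        marks = load_marks(inputs["islands"])
    else:
        ann, _truth, expr, smap, marks = sim.simulate_bundle(
            seed=seed, **cfg.get("simulate", {})
        )
    _check_gene_universe(ann, expr)

    expr = filter_min_present(expr, k=int(cfg["min_present"]))
    ann = resolve_overlaps(order_genes(ann), expr)
    probed = ann.probed_only()
    probed = GenomeAnnotation(
        [g for g in probed if g.gene_id in expr.values.index], dict(ann.chrom_sizes)
    )

    profile = binned_distance_correlation(
        expr, probed, bin_width=int(cfg["bin_width"]), max_dist=int(cfg["max_dist"]),
        method=cfg["method"],
    )
    baseline = cross_chromosome_baseline(expr, probed, method=cfg["method"], seed=seed)
    write_table(profile, outdir / "distance_profile.tsv", cfg)

    scored = score_windows(
        probed, expr, smap,
        min_k=int(cfg["min_genes"]), max_k=int(cfg["max_genes"]),
        n_perm=int(cfg["n_perm"]), seed=seed, method=cfg["method"],
        alpha=float(cfg["alpha"]),
    )
    scored = annotate_windows_with_chromatin(scored, marks, eps=float(cfg["eps"]))
    write_neighborhood_tsv(scored, outdir / "neighborhoods.tsv", cfg)
    write_ucsc_track(scored, outdir / "tns_track.bed", cfg)

    best = best_tns_per_gene(scored, probed)
    write_best_tns(best, outdir / "best_tns.tsv", cfg)

    genes_tbl = gene_chromatin_table(probed, marks, eps=float(cfg["eps"]))
    log2 = lambda x: np.log2(np.asarray(x, dtype=float))
    genes_tbl["log2CADR"] = log2(genes_tbl["CADR"])
    genes_tbl["log2CSDR"] = log2(genes_tbl["CSDR"])
    genes_tbl["chromatin_class"] = [
        classify_gene(a, s, float(cfg["log_thresh"]), float(cfg["log_thresh"]))
        for a, s in zip(genes_tbl["log2CADR"], genes_tbl["log2CSDR"])
    ]
    write_table(genes_tbl.reset_index(), outdir / "gene_chromatin.tsv", cfg)

    pairs = classify_adjacent_pairs(genes_tbl, probed, t=float(cfg["ds_band"]))
    write_table(pairs, outdir / "pair_classes.tsv", cfg)

    summary = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "n_genes": len(probed),
        "n_windows": int(len(scored)),
        "cross_chrom_baseline": baseline["mean"],
        "ds": ds_summary(genes_tbl["DS"]),
        "active_partition": active_gene_partition(
            best, genes_tbl["DS"], ds_min=float(cfg["ds_band"]),
            tns_hi=float(cfg["tns_hi"]), tns_lo=float(cfg["tns_lo"]),
        ),
        "pair_class_percent": {
            k: round(100.0 * v / max(len(pairs), 1), 4)
            for k, v in pairs["pair_class"].value_counts().items()
        },
    }

    labels_path = (inputs or {}).get("regulation_classes")
    results = {
        "annotation": probed, "expression": expr, "scored": scored, "best_tns": best,
        "gene_chromatin": genes_tbl, "pairs": pairs, "profile": profile,
        "baseline": baseline, "summary": summary,
    }
    if labels_path:
        classes = pd.read_csv(labels_path, sep="\t", index_col="gene_id")["class"]
        cmp_tbl = tns_by_regulation_class(best, classes)
        write_table(cmp_tbl, outdir / "tns_by_class.tsv", cfg)
        results["tns_by_class"] = cmp_tbl

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    return results
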