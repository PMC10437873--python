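"""End-to-end orchestration: simulate/ingest -> filter -> matrices ->
necromass scores -> ordination -> Markdown report.

Every number printed in the report is recomputable from the TSVs the run
emits alongside it; the report itself does no private arithmetic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from thermenz import abundance as ab
from thermenz import io as tio
from thermenz import scoring, stats
from thermenz.scoring import threshold_counts
from thermenz.simulate import SimulationConfig, StudySet, generate_study, file_sha256

log = logging.getLogger("thermenz")

SCHEMES = ("CAZY", "MEROPS", "EC")


def _read_study(study: StudySet):
    """Read a study file set back through the public readers."""
    metadata = tio.read_site_metadata(study.metadata)
    stats_ = {s.sample_id: s.total_length for s in tio.read_assembly_stats(study.assembly_stats)}
    annots: dict[str, list] = {}
    coverages: dict[str, dict[str, float]] = {}
    for sample in study.samples:
        cazy = tio.read_cazyme_overview(study.sample_file(sample, "cazy"))
        dram = tio.read_dram_annotations(study.sample_file(sample, "dram"))
        secreted = tio.read_secretion_flags(study.sample_file(sample, "signalp"))
        gene_map = tio.read_gene_map(study.sample_file(sample, "gff"))
        recs = tio.attach_contigs(tio.attach_secretion(cazy + dram, secreted), gene_map)
        annots[sample] = recs
        coverages[sample] = {
            c.contig_id: c.mean_depth
            for c in tio.read_coverage(study.sample_file(sample, "coverage"))
        }
    return metadata, stats_, annots, coverages


def _score_only(score_df: pd.DataFrame, outdir: Path, report_cfg: dict) -> dict:
    """Recompute fractions, totals and threshold counts from a prepared
    cell/photosynthate score table (e.g. the packaged survey table)."""
    df = score_df.copy()
    df["necromass_fraction"] = scoring.necromass_fraction(df["cell"], df["photosynthate"])
    totals = {"cell": float(df["cell"].sum()),
              "photosynthate": float(df["photosynthate"].sum())}
    counts = threshold_counts(df, report_cfg["fraction_threshold"],
                              report_cfg["photo_share_threshold"])
    df.to_csv(outdir / "score_table.tsv", sep="\t", index=False)
    return {"scores": df, "totals": totals, "tcounts": counts}


def run_pipeline(
    outdir,
    sim_config: SimulationConfig | None = None,
    score_table: pd.DataFrame | str | Path | None = None,
    seed: int | None = None,
    prevalence: float = 0.75,
    dedup: str = "within-supergroup",
    fraction_threshold: float = 0.50,
    photo_share_threshold: float = 0.30,
    hightemp_threshold: float = 80.0,
    make_figures: bool = False,
) -> dict:
    """Run the pipeline and write all outputs under ``outdir``.

    Two modes:

    - synthetic (default): generate a study from ``sim_config`` (seed
      overridable via ``seed``), ingest it through the readers, and run
      every stage.
    - score-only: ``score_table`` is a prepared per-sample
      cell/photosynthate table; only scoring, summaries and the report
      run.

    Returns a dict of in-memory results; side effects are the TSVs, the
    Markdown report and a JSON run manifest in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report_cfg = {
        "fraction_threshold": fraction_threshold,
        "photo_share_threshold": photo_share_threshold,
        "hightemp_threshold": hightemp_threshold,
    }
    gmap = scoring.default_substrate_map()

    if score_table is not None:
        t0 = time.perf_counter()
        df = (score_table if isinstance(score_table, pd.DataFrame)
              else pd.read_csv(score_table, sep="\t"))
        result = _score_only(df, outdir, report_cfg)
        timings["score"] = time.perf_counter() - t0
        result["manifest"] = _write_manifest(outdir, None, seed, timings, [])
        _write_report(outdir / "report.md", result, report_cfg, mode="score-only")
        return result

    cfg = sim_config if sim_config is not None else SimulationConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)

    t0 = time.perf_counter()
    study, truth = generate_study(cfg, outdir / "study")
    timings["simulate"] = time.perf_counter() - t0
    log.info("simulate: %d samples in %.2fs", len(study.samples), timings["simulate"])

    t0 = time.perf_counter()
    metadata, lengths, annots, coverages = _read_study(study)
    timings["ingest"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    filtered = {s: ab.filter_annotations(a) for s, a in annots.items()}
    matrices = {}
    filtered_matrices = {}
    counts = {}
    for scheme in SCHEMES:
        m = ab.build_matrix(filtered, coverages, lengths, scheme)
        matrices[scheme] = m
        m.to_tsv(outdir / f"abundance_{scheme}.tsv")
        sidecar = {
            "scheme": scheme,
            "filters": {"secreted_only": True, "min_two_tools": scheme == "CAZY",
                        "ec_hydrolases_only": scheme == "EC"},
            "normalization": "depth x 1e9 / assembly bp",
        }
        (outdir / f"abundance_{scheme}.json").write_text(json.dumps(sidecar, indent=1))
        fm = ab.prevalence_filter(m, prevalence)
        filtered_matrices[scheme] = fm
        fm.to_tsv(outdir / f"abundance_{scheme}_prevalent.tsv")
        counts[scheme] = {
            "annotations": sum(sum(1 for a in recs if a.scheme == scheme)
                               for recs in filtered.values()),
            "families": len(m.families),
            "families_prevalent": len(fm.families),
        }
    timings["profile"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    scores, totals = scoring.score_table(matrices, gmap, metadata, dedup=dedup)
    scores.to_csv(outdir / "score_table.tsv", sep="\t", index=False)
    summary, global_cmp = scoring.fluid_sediment_summary(scores)
    summary.to_csv(outdir / "fluid_sediment_summary.tsv", sep="\t", index=False)
    tcounts = threshold_counts(scores, fraction_threshold, photo_share_threshold)
    timings["score"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    ordinations = {}
    cazy_prev = filtered_matrices["CAZY"]
    if len(cazy_prev.samples) >= 3 and len(cazy_prev.families) >= 2:
        corr = stats.spearman_matrix(cazy_prev, axis="samples")
        corr.to_frame().to_csv(outdir / "spearman_samples_CAZY.tsv", sep="\t")
        tree = stats.cluster(corr)
        (outdir / "dendrogram_samples_CAZY.nwk").write_text(tree.to_newick() + "\n")
        ordinations["sample_cluster"] = tree
    for side in ("cell", "photosynthate"):
        fams = gmap.supergroup_families(side, ("CAZY",), dedup=dedup)
        sub = matrices["CAZY"].data.loc[[f for f in matrices["CAZY"].families if f in fams]]
        if sub.shape[0] >= 2 and sub.shape[1] >= 2:
            res = stats.pca(sub)
            res.scores.to_csv(outdir / f"pca_scores_{side}.tsv", sep="\t")
            res.loadings.to_csv(outdir / f"pca_loadings_{side}.tsv", sep="\t")
            ordinations[f"pca_{side}"] = res
    timings["ordinate"] = time.perf_counter() - t0

    if make_figures:
        t0 = time.perf_counter()
        _write_figures(outdir, filtered_matrices, ordinations,
                       {m.sample_name: m.province for m in metadata})
        timings["figures"] = time.perf_counter() - t0

    result = {
        "study": study, "truth": truth, "matrices": matrices,
        "filtered_matrices": filtered_matrices, "scores": scores,
        "totals": totals, "counts": counts, "tcounts": tcounts,
        "fluid_sediment": summary, "global_comparison": global_cmp,
        "ordinations": ordinations, "metadata": metadata,
    }
    _write_report(outdir / "report.md", result, report_cfg, mode="synthetic")
    inputs = [study.metadata, study.assembly_stats] + [
        study.sample_file(s, k) for s in study.samples
        for k in ("cazy", "dram", "signalp", "gff", "coverage")
    ]
    result["manifest"] = _write_manifest(outdir, cfg, cfg.seed, timings, inputs)
    return result


def _write_manifest(outdir: Path, cfg, seed, timings, inputs) -> dict:
    from importlib.metadata import version as _pkg_version

    if cfg:
        cfg_dict = dataclasses.asdict(cfg)
        cfg_dict["volcanic_provinces"] = sorted(cfg_dict["volcanic_provinces"])
        cfg_dump = yaml.safe_dump(cfg_dict, sort_keys=True)
    else:
        cfg_dump = ""
    try:
        ver = _pkg_version("thermenz")
    except Exception:
        ver = "unknown"
    manifest = {
        "version": ver,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_dump.encode()).hexdigest() if cfg_dump else None,
        "inputs": {str(Path(p).relative_to(outdir)) if str(p).startswith(str(outdir))
                   else str(p): file_sha256(p) for p in inputs},
        "stage_timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _write_report(path: Path, result: dict, cfg: dict, mode: str) -> None:
    lines = [f"# thermenz run report ({mode} mode)", ""]
    scores = result["scores"]
    totals = result.get("totals") or {
        "cell": float(scores["cell"].sum()),
        "photosynthate": float(scores["photosynthate"].sum()),
    }
    if "counts" in result and "tcounts" in result:
        lines.append("## Annotation counts (post-filter)")
        lines.append("")
        lines.append("scheme | annotations | families | families at >=75% prevalence")
        lines.append("--- | --- | --- | ---")
        for scheme, c in result["counts"].items():
            lines.append(f"{scheme} | {c['annotations']} | {c['families']} | "
                         f"{c['families_prevalent']}")
        lines.append("")
    lines.append("## Substrate-group scores")
    lines.append("")
    lines.append(f"- Grand total cell (chitin + peptidoglycan) abundance: "
                 f"{_fmt(totals['cell'])}")
    lines.append(f"- Grand total photosynthate (xylan + cellulose) abundance: "
                 f"{_fmt(totals['photosynthate'])}")
    tc = result.get("tcounts") or result["counts"]
    lines.append(f"- Samples with necromass fraction < {cfg['fraction_threshold']:.2f}: "
                 f"{tc['n_fraction_below']}")
    lines.append(f"- Samples with photosynthate share > {cfg['photo_share_threshold']:.2f}: "
                 f"{tc['n_photosynthate_share_above']} "
                 f"(of which sediments: {tc['n_photosynthate_share_above_sediment']})")
    lines.append("")
    if "global_comparison" in result:
        g = result["global_comparison"]
        lines.append("## Fluid vs sediment")
        lines.append("")
        lines.append(f"- Photosynthate abundance, sediments vs fluids: "
                     f"{_fmt(g['photosynthate_sediment'])} vs {_fmt(g['photosynthate_fluid'])}")
        lines.append(f"- Cell abundance, fluids vs sediments: "
                     f"{_fmt(g['cell_fluid'])} vs {_fmt(g['cell_sediment'])}")
        lines.append("")
    if "ordinations" in result and result["ordinations"]:
        lines.append("## Ordination")
        lines.append("")
        for name, res in result["ordinations"].items():
            if hasattr(res, "explained_variance_fraction"):
                ev = res.explained_variance_fraction[:2]
                lines.append(f"- {name}: PC1 {ev[0]:.3f}, "
                             f"PC2 {ev[1]:.3f} of variance" if len(ev) > 1
                             else f"- {name}: PC1 {ev[0]:.3f} of variance")
            else:
                lines.append(f"- {name}: leaf order {', '.join(res.leaf_order[:8])} ...")
        lines.append("")
    path.write_text("\n".join(lines))


def _write_figures(outdir: Path, matrices, ordinations, provinces: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = matrices.get("CAZY")
    if m is not None and m.data.size:
        fig, ax = plt.subplots(figsize=(8, 6))
        ax.imshow(np.log10(m.data.to_numpy() + 0.5), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(m.samples)), m.samples, rotation=90, fontsize=6)
        ax.set_yticks(range(len(m.families)), m.families, fontsize=6)
        ax.set_title("CAZy family abundance, log10(x + 0.5)")
        fig.tight_layout()
        fig.savefig(outdir / "heatmap_CAZY.png", dpi=150)
        plt.close(fig)
    for name, res in ordinations.items():
        if not hasattr(res, "scores"):
            continue
        fig, ax = plt.subplots(figsize=(6, 5))
        provs = [provinces.get(s, "?") for s in res.scores.index]
        for prov in sorted(set(provs)):
            sel = [i for i, p in enumerate(provs) if p == prov]
            ax.scatter(res.scores.iloc[sel, 0], res.scores.iloc[sel, 1], label=prov, s=18)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=6)
        ax.set_title(name)
        fig.tight_layout()
        fig.savefig(outdir / f"{name}.png", dpi=150)
        plt.close(fig)
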