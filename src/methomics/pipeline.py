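"""End-to-end driver: chain the stages and write a consolidated JSON report.

Stage order: methylation calling -> gene scoring -> methylation-expression
correlation -> cohort analysis (optional) -> variant/CNV/fusion rules
(optional). Identical config + inputs produce byte-identical reports (the
report carries no timestamps and all collections are emitted sorted).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import auxgenomics, cohort, genescore, methcall, methexpr
from .config import PipelineConfig
from .errors import MethomicsError, PipelineError

logger = logging.getLogger(__name__)


def _sample_name(path: str) -> str:
    name = Path(path).name
    for suffix in (".cytosine_report.tsv", ".tsv", ".txt"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MethomicsError as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("methcall")
def _run_methcall(config: PipelineConfig, outdir: Path):
    records, groups = {}, {}
    for group, paths in (("tumor", config.tumor_reports), ("normal", config.normal_reports)):
        for p in paths:
            s = _sample_name(p)
            records[s] = methcall.read_cytosine_report(p, min_coverage=config.min_coverage)
            groups[s] = group
    table = methcall.compute_ratios(records, groups)
    table = methcall.intersect_cpgs(table)
    calls = methcall.call_dmrs(
        table,
        diff_threshold=config.dmr_diff_threshold,
        hypo_threshold=config.dmr_hypo_threshold,
        hyper_threshold=config.dmr_hyper_threshold,
        mode=config.dmr_mode,
    )
    meta = f"methomics v{__version__} config={config.config_hash()}"
    methcall.write_dmr_table(calls, outdir / "dmr_calls.tsv", header_comment=meta)
    methcall.write_dmr_summary(calls, outdir / "dmr_summary.json")
    return table, calls


@_stage("genescore")
def _run_genescore(config: PipelineConfig, calls: pd.DataFrame, outdir: Path):
    de = pd.read_csv(config.de_table, sep="\t", comment="#")
    gene_map = pd.read_csv(config.gene_map, sep="\t", comment="#")
    degs = genescore.filter_degs(
        de,
        min_abs_lfc=config.deg_min_abs_lfc,
        max_padj=config.deg_max_padj,
        min_basemean=config.deg_min_basemean,
    )
    statuses = (
        genescore.DMR_STATUSES_DEFAULT
        if config.count_indeterminate_as_dmr
        else (methcall.STATUS_HYPO, methcall.STATUS_HYPER)
    )
    tallies = genescore.map_cpgs_to_genes(calls, gene_map, dmr_statuses=statuses)
    scores = genescore.score_genes(
        tallies,
        degs["gene_id"],
        min_cpgs=config.gene_min_cpgs,
        min_fraction=config.gene_min_fraction,
    )
    ranked = genescore.rank_genes(scores, top_n=config.top_n)
    if ranked.empty:
        logger.warning("no eligible genes to rank")
    meta = f"methomics v{__version__} config={config.config_hash()}"
    genescore.write_gene_scores(scores, outdir / "gene_scores.tsv", header_comment=meta)
    genescore.write_top_genes(ranked, outdir / "top_genes.json")
    return gene_map, degs, scores, ranked


@_stage("methexpr")
def _run_methexpr(config: PipelineConfig, table, ranked, gene_map, outdir: Path):
    fpkm = pd.read_csv(config.fpkm, sep="\t", index_col=0, comment="#")
    if config.expr_scale == "normalized":
        expr = methexpr.normalize_fpkm(fpkm, mode=config.fpkm_center_mode)
    elif config.expr_scale == "log":
        import numpy as np

        expr = np.log10(fpkm + 1.0)
    else:
        expr = fpkm
    probe_ratios = table.ratios.copy()
    probe_ratios.index = table.cpg_ids()
    if config.links:
        links = pd.read_csv(config.links, sep="\t", comment="#")
    else:
        # derive links: every intersected CpG inside a top-ranked gene's interval
        rows = []
        gm = gene_map.set_index("gene_id")
        pos = table.ratios.index.get_level_values("pos")
        chrom = table.ratios.index.get_level_values("chrom")
        ids = probe_ratios.index
        for gene in ranked["gene_id"]:
            if gene not in gm.index:
                continue
            g = gm.loc[gene]
            inside = (chrom == g["chrom"]) & (pos >= g["start"]) & (pos <= g["end"])
            rows.extend((pid, gene) for pid in ids[inside])
        links = pd.DataFrame(rows, columns=["probe_id", "gene_id"])
    fits = methexpr.batch_correlate(links, probe_ratios, expr)
    fits.to_csv(outdir / "meth_expr_fits.tsv", sep="\t", index=False)
    return fits


@_stage("cohort")
def _run_cohort(config: PipelineConfig, outdir: Path):
    beta = cohort.read_beta_matrix(config.beta_matrix)
    labels = cohort.read_labels(config.beta_labels)
    target = config.target_class or str(labels.iloc[0])
    k = min(config.tsne_k, len(beta))
    top = cohort.top_variable_probes(beta, k)
    spec = cohort.specific_probes(
        beta, labels, target,
        threshold=config.specificity_threshold, mode=config.specificity_mode,
    )
    spec.to_csv(outdir / "specific_probes.tsv", sep="\t", index=False)
    extremes = None
    if config.reference_class:
        extremes = cohort.extreme_probes(
            beta, labels, target, config.reference_class, delta=config.extreme_delta
        )
        extremes.to_csv(outdir / "extreme_probes.tsv", sep="\t", index=False)
    embedding = None
    if config.run_tsne:
        embedding = cohort.embed_tsne(
            beta.loc[top], labels, seed=config.seed, perplexity=config.tsne_perplexity
        )
        embedding.to_csv(outdir / "tsne_embedding.tsv", sep="\t", index=False)
    return spec, extremes, embedding


@_stage("auxgenomics")
def _run_aux(config: PipelineConfig, outdir: Path):
    out = {}
    if config.variants:
        variants = pd.read_csv(config.variants, sep="\t", comment="#")
        kept = auxgenomics.filter_variants(
            variants,
            min_depth=config.variant_min_depth,
            max_af=config.variant_max_af,
            regions=config.variant_regions,
            missing_af_passes=config.missing_af_passes,
        )
        kept.to_csv(outdir / "variants_filtered.tsv", sep="\t", index=False)
        n_coding = int((kept["region_class"] == "exonic").sum())
        out["variants"] = auxgenomics.variant_filter_report(
            variants, kept, min_depth=config.variant_min_depth,
            regions=config.variant_regions,
        )
        out["tmb"] = auxgenomics.compute_tmb(n_coding, config.coding_length_mb)
    if config.fusions and config.coding_genes:
        fusions = pd.read_csv(config.fusions, sep="\t", comment="#")
        coding = {
            line.strip()
            for line in Path(config.coding_genes).read_text().splitlines()
            if line.strip()
        }
        kept_f = auxgenomics.filter_fusions(fusions, coding)
        kept_f.to_csv(outdir / "fusions_filtered.tsv", sep="\t", index=False)
        out["fusions"] = {"n_input": int(len(fusions)), "n_kept": int(len(kept_f))}
    if config.log2_table:
        log2 = pd.read_csv(config.log2_table, sep="\t", comment="#")
        cnv = auxgenomics.call_cnv(
            log2,
            del_threshold=config.cnv_del_threshold,
            amp_threshold=config.cnv_amp_threshold,
        )
        cnv.to_csv(outdir / "cnv_calls.tsv", sep="\t", index=False)
        out["cnv_state_counts"] = {
            k: int(v) for k, v in sorted(cnv["state"].value_counts().items())
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; write stage outputs and ``report.json``.

    Returns the report dict. Deterministic for identical config and inputs.
    """
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    report = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    table, calls = _run_methcall(config, outdir)
    report["dmr"] = methcall.dmr_summary(calls)

    ranked = None
    gene_map = None
    if config.de_table and config.gene_map:
        gene_map, degs, scores, ranked = _run_genescore(config, calls, outdir)
        report["genescore"] = {
            "n_degs": int(len(degs)),
            "n_eligible": int(scores["eligible"].sum()),
            "top_genes": [
                {
                    "gene_id": r.gene_id,
                    "rank": int(r.rank),
                    "dmr_fraction": float(r.dmr_fraction),
                    "n_cpgs": int(r.n_cpgs),
                }
                for r in ranked.itertuples(index=False)
            ],
        }

    if config.fpkm and ranked is not None:
        fits = _run_methexpr(config, table, ranked, gene_map, outdir)
        report["methexpr"] = {
            "n_fits": int(len(fits)),
            "n_negative_slope": int((fits["slope"] < 0).sum()),
            "top_fits": [
                {
                    "probe_id": r.probe_id,
                    "gene_id": r.gene_id,
                    "slope": float(r.slope),
                    "pearson_r": float(r.pearson_r),
                    "p_value": float(r.p_value),
                }
                for r in fits.head(5).itertuples(index=False)
            ],
        }

    if config.beta_matrix and config.beta_labels:
        spec, extremes, embedding = _run_cohort(config, outdir)
        report["cohort"] = {
            "n_specific": int(spec["specific"].sum()),
            "n_probes": int(len(spec)),
        }
        if extremes is not None:
            report["cohort"]["n_extreme"] = int(len(extremes))
        if embedding is not None:
            report["cohort"]["tsne_samples"] = int(len(embedding))

    aux = _run_aux(config, outdir)
    if aux:
        report["aux"] = aux

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def validate_inputs(config: PipelineConfig) -> list:
    """Check formats and cross-table consistency; returns a list of problems."""
    problems = []
    for group, paths in (("tumor", config.tumor_reports), ("normal", config.normal_reports)):
        for p in paths:
            if not Path(p).exists():
                problems.append(f"{group} report missing: {p}")
    for name in ("gene_map", "fpkm", "de_table", "beta_matrix", "beta_labels",
                 "variants", "fusions", "log2_table", "coding_genes", "links"):
        p = getattr(config, name)
        if p and not Path(p).exists():
            problems.append(f"{name} file missing: {p}")

    if config.gene_map and Path(config.gene_map).exists():
        gm = pd.read_csv(config.gene_map, sep="\t", comment="#")
        bad = gm[gm["start"] > gm["end"]]
        for g in bad["gene_id"]:
            problems.append(f"gene_map: interval start > end for {g}")
    if config.de_table and Path(config.de_table).exists():
        de = pd.read_csv(config.de_table, sep="\t", comment="#")
        out_of_range = de["padj"].dropna()
        out_of_range = out_of_range[(out_of_range < 0) | (out_of_range > 1)]
        if len(out_of_range):
            problems.append(f"de_table: {len(out_of_range)} padj values outside [0, 1]")
    if (
        config.beta_matrix
        and config.beta_labels
        and Path(config.beta_matrix).exists()
        and Path(config.beta_labels).exists()
    ):
        beta = pd.read_csv(config.beta_matrix, sep="\t", index_col=0, comment="#")
        labels = cohort.read_labels(config.beta_labels)
        for s in beta.columns:
            if s not in labels.index:
                problems.append(f"beta_matrix: sample {s} absent from labels")
        arr = beta.to_numpy()
        bad_mask = (arr < 0) | (arr > 1)
        if bad_mask.any():
            import numpy as np

            pi, si = map(int, next(zip(*np.nonzero(bad_mask))))
            problems.append(
                f"beta_matrix: value {arr[pi, si]} outside [0, 1] at probe "
                f"{beta.index[pi]} sample {beta.columns[si]}"
            )
    return problems
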