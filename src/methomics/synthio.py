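"""Synthetic multiomics inputs with planted, recorded ground truth.

Every downstream stage of the pipeline (DMR calling, gene scoring, cohort
specificity, methylation-expression correlation, variant/CNV/fusion filters)
can be exercised end to end on data produced here, with a :class:`TruthManifest`
recording what was planted so recovery can be measured exactly.

All randomness flows from a single root seed through ``numpy.random.SeedSequence``
substreams (one child stream per generator), so modules can be regenerated
independently and byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

CYTOSINE_REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]

# substream indices under the root SeedSequence
_STREAM_METHYLOME = 0
_STREAM_EXPRESSION = 1
_STREAM_COHORT = 2
_STREAM_AUX = 3


@dataclass(frozen=True)
class MethylSimConfig:
    """Parameters of the bisulfite count simulator.

    CpG methylation ratios are Beta-distributed in the background (human CpG
    methylation is strongly bimodal, which a U-shaped Beta emulates) and fixed
    group means at planted differential sites. Read coverage is Poisson per
    sample per CpG; methylated counts are Binomial given coverage.
    """

    n_cpgs: int = 10_000
    n_tumor: int = 6
    n_normal: int = 6
    mean_coverage: float = 30.0
    baseline_alpha: float = 0.6
    baseline_beta: float = 0.4
    frac_hypo: float = 0.05
    frac_hyper: float = 0.05
    hypo_normal_mean: float = 0.85
    hypo_tumor_mean: float = 0.10
    hyper_normal_mean: float = 0.15
    hyper_tumor_mean: float = 0.90
    block_size: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cpgs", "n_tumor", "n_normal", "block_size"):
            if int(getattr(self, name)) < 0 or (name != "n_cpgs" and getattr(self, name) < 1):
                raise ConfigError(f"{name} must be positive (got {getattr(self, name)})")
        if self.mean_coverage <= 0:
            raise ConfigError(f"mean_coverage must be positive (got {self.mean_coverage})")
        for name in ("baseline_alpha", "baseline_beta"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive (got {getattr(self, name)})")
        for name in ("frac_hypo", "frac_hyper"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1] (got {v})")
        if self.frac_hypo + self.frac_hyper > 1.0:
            raise ConfigError(
                f"frac_hypo + frac_hyper must be <= 1 (got {self.frac_hypo + self.frac_hyper})"
            )
        for name in (
            "hypo_normal_mean",
            "hypo_tumor_mean",
            "hyper_normal_mean",
            "hyper_tumor_mean",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a ratio in [0, 1] (got {v})")
        if not self.hypo_tumor_mean < self.hypo_normal_mean:
            raise ConfigError("hypo_tumor_mean must be < hypo_normal_mean")
        if not self.hyper_tumor_mean > self.hyper_normal_mean:
            raise ConfigError("hyper_tumor_mean must be > hyper_normal_mean")


@dataclass
class TruthManifest:
    """Record of everything the generators planted.

    Serializes losslessly to JSON (floats round-trip via ``repr``); every row of
    every emitted table has exactly one entry here.
    """

    params: dict = field(default_factory=dict)
    samples: dict = field(default_factory=dict)  # sample -> "tumor" | "normal"
    cpg_class: dict = field(default_factory=dict)  # cpg_id -> background|hypo|hyper
    cpg_group_ratio: dict = field(default_factory=dict)  # cpg_id -> {normal, tumor}
    genes: dict = field(default_factory=dict)  # gene_id -> {driver, slope, chrom, start, end}
    probe_class: dict = field(default_factory=dict)  # probe_id -> class name or "background"
    variants: dict = field(default_factory=dict)  # per_row + survivors
    fusions: dict = field(default_factory=dict)  # survivor_keys
    cnv: dict = field(default_factory=dict)  # feature_id -> state

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sample_names(n_tumor: int, n_normal: int) -> dict:
    names = {f"tumor_{i + 1:02d}": "tumor" for i in range(n_tumor)}
    names.update({f"normal_{i + 1:02d}": "normal" for i in range(n_normal)})
    return names


def simulate_methylome(config: MethylSimConfig):
    """Simulate per-sample Bismark-style cytosine reports.

    Planted differential CpGs are laid down in contiguous blocks of
    ``config.block_size`` sites (the planting granularity), which lets
    :func:`simulate_expression` tile gene intervals over the same grid so that
    driver genes cover planted CpGs only. Even-indexed CpGs have their coverage
    split across the two strands (plus-strand C at ``pos``, minus-strand C at
    ``pos + 1``) to exercise the strand-collapse path of the reader; odd-indexed
    CpGs are reported on the plus strand only.

    Returns ``(tables, truth)`` where ``tables`` maps sample name to a
    DataFrame in cytosine-report column order and ``truth`` is a fresh
    :class:`TruthManifest`.
    """
    config.validate()
    n = int(config.n_cpgs)
    truth = TruthManifest(params={"methylome": asdict(config)})
    truth.samples = _sample_names(config.n_tumor, config.n_normal)
    if n == 0:
        return {s: _empty_report() for s in truth.samples}, truth

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(4)
    rng_place = np.random.default_rng(streams[0])
    rng_ratio = np.random.default_rng(streams[1])
    rng_counts = np.random.default_rng(streams[2])

    positions = 100 + 50 * np.arange(n)  # plus-strand C coordinates, 1-based
    block = int(config.block_size)
    n_blocks = n // block if block <= n else 0

    # whole blocks planted; counts rounded to block granularity
    n_hypo_blocks = int(round(config.frac_hypo * n / block)) if n_blocks else 0
    n_hyper_blocks = int(round(config.frac_hyper * n / block)) if n_blocks else 0
    n_hypo_blocks = min(n_hypo_blocks, n_blocks)
    n_hyper_blocks = min(n_hyper_blocks, n_blocks - n_hypo_blocks)

    block_order = rng_place.permutation(n_blocks) if n_blocks else np.array([], dtype=int)
    hypo_blocks = np.sort(block_order[:n_hypo_blocks])
    hyper_blocks = np.sort(block_order[n_hypo_blocks : n_hypo_blocks + n_hyper_blocks])

    cls = np.zeros(n, dtype=int)  # 0 background, 1 hypo, 2 hyper
    for b in hypo_blocks:
        cls[b * block : (b + 1) * block] = 1
    for b in hyper_blocks:
        cls[b * block : (b + 1) * block] = 2

    background = rng_ratio.beta(config.baseline_alpha, config.baseline_beta, size=n)
    p_normal = np.where(
        cls == 1,
        config.hypo_normal_mean,
        np.where(cls == 2, config.hyper_normal_mean, background),
    )
    p_tumor = np.where(
        cls == 1,
        config.hypo_tumor_mean,
        np.where(cls == 2, config.hyper_tumor_mean, background),
    )

    class_names = np.array(["background", "hypo", "hyper"])
    for i in range(n):
        cid = f"chr1:{positions[i]}"
        truth.cpg_class[cid] = str(class_names[cls[i]])
        truth.cpg_group_ratio[cid] = {
            "normal": float(p_normal[i]),
            "tumor": float(p_tumor[i]),
        }
    truth.params["methylome_blocks"] = {
        "block_size": block,
        "hypo_blocks": [int(b) for b in hypo_blocks],
        "hyper_blocks": [int(b) for b in hyper_blocks],
        "n_blocks": int(n_blocks),
    }

    split = np.arange(n) % 2 == 0
    tables = {}
    for sample, group in truth.samples.items():
        p = p_tumor if group == "tumor" else p_normal
        cov = rng_counts.poisson(config.mean_coverage, size=n)
        meth = rng_counts.binomial(cov, p)
        plus_cov = cov.copy()
        plus_meth = meth.copy()
        minus_cov = np.zeros(n, dtype=np.int64)
        minus_meth = np.zeros(n, dtype=np.int64)
        idx = np.flatnonzero(split & (cov > 0))
        if idx.size:
            pc = rng_counts.binomial(cov[idx], 0.5)
            # split the methylated reads between strands without replacement
            pm = rng_counts.hypergeometric(meth[idx], cov[idx] - meth[idx], pc)
            plus_cov[idx] = pc
            plus_meth[idx] = pm
            minus_cov[idx] = cov[idx] - pc
            minus_meth[idx] = meth[idx] - pm
        rows = []
        keep_plus = plus_cov > 0
        rows.append(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": positions[keep_plus],
                    "strand": "+",
                    "count_methylated": plus_meth[keep_plus],
                    "count_unmethylated": (plus_cov - plus_meth)[keep_plus],
                    "context": "CpG",
                    "trinucleotide": "CGG",
                }
            )
        )
        keep_minus = minus_cov > 0
        rows.append(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": positions[keep_minus] + 1,
                    "strand": "-",
                    "count_methylated": minus_meth[keep_minus],
                    "count_unmethylated": (minus_cov - minus_meth)[keep_minus],
                    "context": "CpG",
                    "trinucleotide": "CGG",
                }
            )
        )
        table = pd.concat(rows, ignore_index=True)
        table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        tables[sample] = table
    return tables, truth


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in CYTOSINE_REPORT_COLUMNS})


def simulate_expression(
    truth: TruthManifest,
    n_genes: int,
    n_driver: int,
    slope: float = -1.2,
    noise_sd: float = 0.1,
    intercept: float = 2.5,
    bg_log_mean: float = 1.0,
    bg_log_sd: float = 0.4,
    seed: int = 0,
):
    """Simulate an FPKM matrix linearly coupled to planted methylation.

    Gene intervals tile the CpG blocks laid down by :func:`simulate_methylome`
    (gene *i* covers block *i* in genomic order); the first ``n_driver``
    hypomethylated blocks become driver genes whose per-sample log10 expression
    is ``intercept + slope * (true group mean ratio of the gene's CpGs)`` plus
    Gaussian noise, so hypomethylation in tumors drives overexpression.
    Non-driver genes draw a log-normal background independent of group.
    FPKM is ``10**v - 1`` (clipped at 0) so the downstream ``log10(FPKM + 1)``
    transform recovers ``v`` exactly.

    A two-group DE table (Welch t-test on log10(FPKM+1), Benjamini-Hochberg
    adjustment; method declared in the manifest) is emitted alongside.

    Returns ``(fpkm, de_table, gene_map, truth)``.
    """
    if n_driver > n_genes:
        raise ConfigError(f"n_driver ({n_driver}) must be <= n_genes ({n_genes})")
    blocks = truth.params.get("methylome_blocks")
    if blocks is None:
        raise ConfigError("truth manifest lacks a simulated methylome")
    hypo_blocks = [b for b in blocks["hypo_blocks"] if b < n_genes]
    if n_driver > len(hypo_blocks):
        raise ConfigError(
            f"n_driver ({n_driver}) exceeds the {len(hypo_blocks)} planted hypo blocks"
            " covered by gene intervals"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])

    block = int(blocks["block_size"])
    n_blocks = int(blocks["n_blocks"])
    cpg_ids = list(truth.cpg_class)
    positions = np.array([int(c.split(":")[1]) for c in cpg_ids])
    driver_blocks = set(hypo_blocks[:n_driver])

    samples = list(truth.samples)
    groups = np.array([truth.samples[s] for s in samples])
    n_samples = len(samples)

    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    rows_map = []
    log_expr = np.empty((n_genes, n_samples))
    for gi, gene in enumerate(gene_ids):
        if gi < n_blocks:
            start = int(positions[gi * block])
            end = int(positions[min((gi + 1) * block, len(positions)) - 1]) + 1
        else:  # more genes than blocks: park beyond the CpG grid (zero CpGs)
            start = int(positions[-1]) + 1000 + 100 * (gi - n_blocks)
            end = start + 50
        is_driver = gi in driver_blocks
        if is_driver:
            block_slice = slice(gi * block, (gi + 1) * block)
            mean_ratio_normal = float(
                np.mean([truth.cpg_group_ratio[cpg_ids[j]]["normal"]
                         for j in range(block_slice.start, block_slice.stop)])
            )
            mean_ratio_tumor = float(
                np.mean([truth.cpg_group_ratio[cpg_ids[j]]["tumor"]
                         for j in range(block_slice.start, block_slice.stop)])
            )
            mu = np.where(groups == "tumor", intercept + slope * mean_ratio_tumor,
                          intercept + slope * mean_ratio_normal)
        else:
            base = rng.normal(bg_log_mean, bg_log_sd)
            mu = np.full(n_samples, base)
        noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
        log_expr[gi] = mu + noise
        rows_map.append((gene, "chr1", start, end))
        truth.genes[gene] = {
            "driver": bool(is_driver),
            "slope": float(slope) if is_driver else 0.0,
            "chrom": "chr1",
            "start": start,
            "end": end,
        }

    fpkm = pd.DataFrame(
        np.clip(10.0 ** log_expr - 1.0, 0.0, None), index=gene_ids, columns=samples
    )
    fpkm.index.name = "gene_id"
    gene_map = pd.DataFrame(rows_map, columns=["gene_id", "chrom", "start", "end"])

    # declared DE method: Welch t on log10(FPKM+1), BH adjustment
    v = np.log10(fpkm.to_numpy() + 1.0)
    t_mask = groups == "tumor"
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(v[:, t_mask], v[:, ~t_mask], axis=1, equal_var=False)
    padj = np.full(n_genes, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        padj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    mean_t = fpkm.to_numpy()[:, t_mask].mean(axis=1)
    mean_n = fpkm.to_numpy()[:, ~t_mask].mean(axis=1)
    log2fc = np.log2((mean_t + 1.0) / (mean_n + 1.0))
    de_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": log2fc,
            "padj": padj,
            "basemean": fpkm.to_numpy().mean(axis=1),
        }
    )
    truth.params["expression"] = {
        "n_genes": int(n_genes),
        "n_driver": int(n_driver),
        "slope": float(slope),
        "noise_sd": float(noise_sd),
        "intercept": float(intercept),
        "seed": int(seed),
        "de_method": "welch-t on log10(FPKM+1), Benjamini-Hochberg",
    }
    return fpkm, de_table, gene_map, truth


def simulate_cohort(
    n_probes: int,
    classes: Mapping[str, int],
    n_specific: int,
    specific_delta: float,
    seed: int = 0,
    target_class: str | None = None,
    value_sd: float = 0.05,
    truth: TruthManifest | None = None,
):
    """Simulate an array-style beta matrix with class-specific probe blocks.

    Background probes share one Beta(2, 2)-distributed true mean across all
    classes; every class receives ``n_specific`` planted probes whose true mean
    is shifted by exactly ``specific_delta`` relative to all other classes
    (direction chosen at random, base mean drawn so no clipping is needed).
    Per-sample values are Gaussian around the class mean, clipped to [0, 1].
    Planting a signature for every class keeps all classes mutually separable,
    while the truth records which probes are specific to the designated target.

    Returns ``(beta, labels, truth)`` with ``beta`` probes x samples.
    """
    if not classes:
        raise ConfigError("classes must be non-empty")
    class_names = list(classes)
    if target_class is None:
        target_class = class_names[0]
    if target_class not in classes:
        raise ConfigError(f"unknown target class {target_class!r}")
    if not 0.0 <= specific_delta <= 1.0:
        raise ConfigError(f"specific_delta must be in [0, 1] (got {specific_delta})")
    if n_specific * len(class_names) > n_probes:
        raise ConfigError(
            f"n_specific * n_classes ({n_specific * len(class_names)}) exceeds n_probes"
        )
    for c, k in classes.items():
        if k < 1:
            raise ConfigError(f"class {c!r} has zero samples")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    probe_ids = [f"cg{i + 1:07d}" for i in range(n_probes)]
    order = rng.permutation(n_probes)

    # true mean per probe per class
    means = np.tile(
        np.clip(rng.beta(2.0, 2.0, size=n_probes), 0.02, 0.98)[:, None], (1, len(class_names))
    )
    if truth is None:
        truth = TruthManifest()
    probe_class = ["background"] * n_probes
    cursor = 0
    for ci, cname in enumerate(class_names):
        planted = order[cursor : cursor + n_specific]
        cursor += n_specific
        for p in planted:
            base = rng.uniform(0.0, 1.0 - specific_delta)
            if rng.random() < 0.5:
                own, other = base + specific_delta, base
            else:
                own, other = base, base + specific_delta
            means[p, :] = other
            means[p, ci] = own
            probe_class[p] = cname

    sample_names, label_vals, cols = [], [], []
    for ci, cname in enumerate(class_names):
        for si in range(classes[cname]):
            sample_names.append(f"{cname}_{si + 1:02d}")
            label_vals.append(cname)
            cols.append(np.clip(rng.normal(means[:, ci], value_sd), 0.0, 1.0))
    beta = pd.DataFrame(np.column_stack(cols) if cols else np.empty((n_probes, 0)),
                        index=probe_ids, columns=sample_names)
    beta.index.name = "probe_id"
    labels = pd.Series(label_vals, index=sample_names, name="class")
    for pid, pc in zip(probe_ids, probe_class):
        truth.probe_class[pid] = pc
    truth.params["cohort"] = {
        "n_probes": int(n_probes),
        "classes": {c: int(k) for c, k in classes.items()},
        "target_class": target_class,
        "n_specific": int(n_specific),
        "specific_delta": float(specific_delta),
        "value_sd": float(value_sd),
        "seed": int(seed),
    }
    return beta, labels, truth


@dataclass(frozen=True)
class AuxSizes:
    """Total row counts for the auxiliary tables (boundary templates first)."""

    n_variants: int = 40
    n_fusions: int = 25
    n_cnv: int = 40

    def validate(self) -> None:
        for name in ("n_variants", "n_fusions", "n_cnv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


# hand-written boundary templates: (depth, region, exac, gnomad, korean, survives, reason)
_VARIANT_TEMPLATES = [
    (9, "exonic", None, None, None, False, "depth"),
    (10, "exonic", None, None, None, True, ""),
    (50, "exonic", None, None, 0.01, False, "af"),
    (50, "exonic", None, None, 0.0099, True, ""),
    (50, "splicing", 0.0099, 0.005, None, True, ""),
    (50, "other", None, None, None, False, "region"),
    (0, "exonic", None, None, None, False, "depth"),
    (100, "exonic", 0.5, None, None, False, "af"),
    (10, "splicing", 0.009, 0.009, 0.009, True, ""),
    (9, "other", 0.5, None, None, False, "depth,region,af"),
]

# (gene_a, gene_b, pos_a, pos_b, junction, spanning, n_copies, survives_once)
_FUSION_TEMPLATES = [
    ("CODA", "CODB", 1000, 5000, 5, 3, 1, True),
    ("NCX1", "NCX2", 1100, 5100, 5, 3, 1, False),
    ("CODA", "NCX1", 1200, 5200, 0, 3, 1, False),
    ("CODA", "NCX1", 1300, 5300, 4, 0, 1, False),
    ("CODB", "NCX2", 1400, 5400, 7, 2, 2, True),  # exact duplicate pair
    ("CODC", "CODD", 1500, 5500, 6, 6, 1, True),
    ("CODD", "CODC", 5500, 1500, 6, 6, 1, True),  # orientation swap kept separately
]

_CNV_TEMPLATES = [
    (-0.4, "deletion"),
    (-0.41, "deletion"),
    (-0.39, "neutral"),
    (0.3, "neutral"),
    (0.31, "amplification"),
    (0.0, "neutral"),
    (1.5, "amplification"),
    (-2.0, "deletion"),
]

_CODING_GENES = frozenset({"CODA", "CODB", "CODC", "CODD", "CODE", "CODF"})


def simulate_aux_tables(seed: int = 0, sizes: AuxSizes = AuxSizes(),
                        truth: TruthManifest | None = None):
    """Simulate variant / fusion / CNV log2-ratio tables with recorded truth.

    The first rows of each table come from hand-written boundary templates that
    straddle every filter cutoff (depth 9/10, AF 0.0099/0.01, region classes,
    zero read counts, exact duplicates, log2 at -0.4 and 0.3); the remainder
    are random rows whose expected fate is computed by the generator's own copy
    of the rules and recorded in the truth manifest.

    Returns ``(variants, fusions, cnv, coding_genes, truth)``.
    """
    sizes.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    if truth is None:
        truth = TruthManifest()

    # --- variants -----------------------------------------------------------
    v_rows, per_row = [], {}
    for i in range(sizes.n_variants):
        rid = f"var_{i + 1:04d}"
        if i < len(_VARIANT_TEMPLATES):
            depth, region, exac, gnomad, korean, survives, reason = _VARIANT_TEMPLATES[i]
        else:
            depth = int(rng.poisson(40))
            region = str(rng.choice(["exonic", "splicing", "other"], p=[0.6, 0.2, 0.2]))
            exac = float(rng.uniform(0, 0.02)) if rng.random() < 0.5 else None
            gnomad = float(rng.uniform(0, 0.02)) if rng.random() < 0.5 else None
            korean = float(rng.uniform(0, 0.02)) if rng.random() < 0.5 else None
            reasons = []
            if depth < 10:
                reasons.append("depth")
            if region not in ("exonic", "splicing"):
                reasons.append("region")
            if any(f is not None and f >= 0.01 for f in (exac, gnomad, korean)):
                reasons.append("af")
            survives, reason = not reasons, ",".join(reasons)
        v_rows.append(
            {
                "row_id": rid,
                "chrom": "chr1",
                "pos": 10_000 + 10 * i,
                "ref": "A",
                "alt": "T",
                "total_depth": depth,
                "region_class": region,
                "af_exac_eas": exac,
                "af_gnomad_eas": gnomad,
                "af_korean": korean,
            }
        )
        per_row[rid] = {"survives": bool(survives), "reason": reason}
    variants = pd.DataFrame(
        v_rows,
        columns=[
            "row_id", "chrom", "pos", "ref", "alt", "total_depth", "region_class",
            "af_exac_eas", "af_gnomad_eas", "af_korean",
        ],
    )
    truth.variants = {
        "per_row": per_row,
        "survivors": sorted(r for r, t in per_row.items() if t["survives"]),
    }

    # --- fusions ------------------------------------------------------------
    f_rows, survivor_keys = [], set()
    emitted = 0
    for ga, gb, pa, pb, j, s, copies, survives in _FUSION_TEMPLATES:
        emitted_copies = 0
        for _ in range(copies):
            if emitted >= sizes.n_fusions:
                break
            f_rows.append(
                {
                    "gene_a": ga, "gene_b": gb,
                    "chrom_a": "chr2", "pos_a": pa, "chrom_b": "chr3", "pos_b": pb,
                    "junction_reads": j, "spanning_reads": s,
                }
            )
            emitted += 1
            emitted_copies += 1
        if survives and emitted_copies > 0:
            survivor_keys.add(fusion_key(ga, gb, "chr2", pa, "chr3", pb, j, s))
    while emitted < sizes.n_fusions:
        coding = rng.random() < 0.7
        ga = str(rng.choice(sorted(_CODING_GENES))) if coding else f"NCR{emitted}"
        gb = f"NCP{emitted}"
        pa, pb = int(rng.integers(1, 10**6)), int(rng.integers(1, 10**6))
        j, s = int(rng.poisson(4)), int(rng.poisson(4))
        f_rows.append(
            {
                "gene_a": ga, "gene_b": gb,
                "chrom_a": "chr2", "pos_a": pa, "chrom_b": "chr3", "pos_b": pb,
                "junction_reads": j, "spanning_reads": s,
            }
        )
        if (ga in _CODING_GENES or gb in _CODING_GENES) and j > 0 and s > 0:
            survivor_keys.add(fusion_key(ga, gb, "chr2", pa, "chr3", pb, j, s))
        emitted += 1
    fusions = pd.DataFrame(
        f_rows,
        columns=["gene_a", "gene_b", "chrom_a", "pos_a", "chrom_b", "pos_b",
                 "junction_reads", "spanning_reads"],
    )
    truth.fusions = {"survivor_keys": sorted(survivor_keys)}

    # --- CNV log2 ratios ----------------------------------------------------
    c_rows = []
    for i in range(sizes.n_cnv):
        fid = f"feat_{i + 1:04d}"
        if i < len(_CNV_TEMPLATES):
            val, state = _CNV_TEMPLATES[i]
        else:
            val = float(rng.uniform(-1.0, 1.0))
            state = "deletion" if val <= -0.4 else ("amplification" if val > 0.3 else "neutral")
        c_rows.append({"feature_id": fid, "log2_ratio": val})
        truth.cnv[fid] = state
    cnv = pd.DataFrame(c_rows, columns=["feature_id", "log2_ratio"])

    truth.params["aux"] = {"sizes": asdict(sizes), "seed": int(seed),
                           "coding_genes": sorted(_CODING_GENES)}
    return variants, fusions, cnv, set(_CODING_GENES), truth


def fusion_key(ga, gb, ca, pa, cb, pb, j, s) -> str:
    """Canonical identity of a fusion record: partners, breakpoints, counts."""
    return f"{ga}|{gb}|{ca}:{pa}|{cb}:{pb}|{j}|{s}"


# ---------------------------------------------------------------------------
# file writers (the generator's external interface)
# ---------------------------------------------------------------------------

def write_cytosine_reports(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> dict:
    """Write one headerless Bismark-dialect cytosine report TSV per sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample in sorted(tables):
        p = outdir / f"{sample}.cytosine_report.tsv"
        tables[sample].to_csv(p, sep="\t", header=False, index=False)
        paths[sample] = p
    return paths


def write_fixture(
    outdir: str | Path,
    seed: int = 0,
    methyl_config: MethylSimConfig | None = None,
    n_genes: int | None = None,
    n_driver: int = 5,
    cohort_classes: Mapping[str, int] | None = None,
    cohort_probes: int = 600,
    cohort_specific: int = 40,
    cohort_delta: float = 0.6,
    aux_sizes: AuxSizes = AuxSizes(),
) -> dict:
    """Generate and write a complete, coupled pipeline fixture.

    Returns a dict of file paths (strings) suitable for building a
    :class:`~methomics.config.PipelineConfig`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if methyl_config is None:
        methyl_config = MethylSimConfig(n_cpgs=4000, seed=seed)
    tables, truth = simulate_methylome(methyl_config)
    report_paths = write_cytosine_reports(tables, outdir / "reports")
    if n_genes is None:
        n_genes = methyl_config.n_cpgs // methyl_config.block_size
    fpkm, de, gene_map, truth = simulate_expression(
        truth, n_genes=n_genes, n_driver=n_driver, seed=seed
    )
    if cohort_classes is None:
        cohort_classes = {"CN": 20, "GBM": 20, "LGG": 20, "EPN": 20, "MED": 20}
    beta, labels, truth = simulate_cohort(
        cohort_probes, cohort_classes, cohort_specific, cohort_delta,
        seed=seed, truth=truth,
    )
    variants, fusions, cnv, coding, truth = simulate_aux_tables(
        seed=seed, sizes=aux_sizes, truth=truth
    )

    paths = {
        "gene_map": outdir / "gene_map.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "de_table": outdir / "de_table.tsv",
        "beta_matrix": outdir / "beta_matrix.tsv",
        "beta_labels": outdir / "beta_labels.tsv",
        "variants": outdir / "variants.tsv",
        "fusions": outdir / "fusions.tsv",
        "log2_table": outdir / "log2_table.tsv",
        "coding_genes": outdir / "coding_genes.txt",
        "truth": outdir / "truth.json",
    }
    gene_map.to_csv(paths["gene_map"], sep="\t", index=False)
    fpkm.to_csv(paths["fpkm"], sep="\t")
    de.to_csv(paths["de_table"], sep="\t", index=False)
    beta.to_csv(paths["beta_matrix"], sep="\t")
    labels.rename_axis("sample").reset_index().to_csv(paths["beta_labels"], sep="\t", index=False)
    variants.to_csv(paths["variants"], sep="\t", index=False)
    fusions.to_csv(paths["fusions"], sep="\t", index=False)
    cnv.to_csv(paths["log2_table"], sep="\t", index=False)
    paths["coding_genes"].write_text("\n".join(sorted(coding)) + "\n")
    truth.to_json(paths["truth"])

    out = {k: str(v) for k, v in paths.items()}
    out["tumor_reports"] = sorted(
        str(p) for s, p in report_paths.items() if truth.samples[s] == "tumor"
    )
    out["normal_reports"] = sorted(
        str(p) for s, p in report_paths.items() if truth.samples[s] == "normal"
    )
    out["target_class"] = truth.params["cohort"]["target_class"]
    return out
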