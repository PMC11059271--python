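"""Per-CpG methylation ratios and threshold-based DMR calling.

The methylation ratio at a CpG is the number of methylated reads on both
strands divided by the total read count. CpG sets are intersected across all
samples (the only site filter applied), and a site is a differentially
methylated region (DMR) when the tumor-normal mean ratio difference exceeds a
threshold (default 0.4, strict); DMRs are sub-classified hypomethylated when
the tumor mean is below 0.3 and hypermethylated when above 0.7. A DMR whose
tumor mean falls between the two is kept as ``indeterminate`` rather than
dropped, so gene-level tallies stay complete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ParseError
from .synthio import CYTOSINE_REPORT_COLUMNS

logger = logging.getLogger(__name__)

STATUS_NOT_DMR = "not_dmr"
STATUS_HYPO = "hypo"
STATUS_HYPER = "hyper"
STATUS_INDETERMINATE = "indeterminate"


@dataclass
class RatioTable:
    """Per-CpG methylation ratios across samples.

    ``ratios`` and ``totals`` share a (chrom, pos) MultiIndex; NaN marks a CpG
    absent from (or under-covered in) a sample. ``groups`` maps every sample
    column to ``"tumor"`` or ``"normal"``.
    """

    ratios: pd.DataFrame
    totals: pd.DataFrame
    groups: dict

    @property
    def samples(self) -> list:
        return list(self.ratios.columns)

    @property
    def tumor_samples(self) -> list:
        return [s for s in self.samples if self.groups[s] == "tumor"]

    @property
    def normal_samples(self) -> list:
        return [s for s in self.samples if self.groups[s] == "normal"]

    def cpg_ids(self) -> list:
        return [f"{c}:{p}" for c, p in self.ratios.index]


def read_cytosine_report(path: str | Path, min_coverage: int = 1) -> pd.DataFrame:
    """Read a Bismark-dialect cytosine report and collapse strands.

    Minus-strand cytosines (reported at their own coordinate) are collapsed
    onto the paired plus-strand C at ``pos - 1`` with counts summed, so each
    CpG contributes reads from both strands. Collapsed records with
    ``total_count < min_coverage`` are dropped. Returns a DataFrame with
    columns ``chrom, pos, meth_count, total_count`` sorted by (chrom, pos).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, names=CYTOSINE_REPORT_COLUMNS,
                          dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=CYTOSINE_REPORT_COLUMNS)
    if raw.empty:
        return pd.DataFrame(columns=["chrom", "pos", "meth_count", "total_count"])

    for col in ("pos", "count_methylated", "count_unmethylated"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted != converted.astype("Int64").astype(float))
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}: line {line}: non-integer {col} field")
        raw[col] = converted.astype(np.int64)
    bad_strand = ~raw["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ParseError(f"{path}: line {int(bad_strand.idxmax()) + 1}: bad strand")
    if (raw["pos"] < 1).any():
        line = int((raw["pos"] < 1).idxmax()) + 1
        raise ParseError(f"{path}: line {line}: position must be >= 1")
    if (raw[["count_methylated", "count_unmethylated"]] < 0).any().any():
        raise ParseError(f"{path}: negative read count")

    cpg_pos = raw["pos"] - (raw["strand"] == "-").astype(np.int64)
    merged = (
        raw.assign(pos=cpg_pos, total=raw["count_methylated"] + raw["count_unmethylated"])
        .groupby(["chrom", "pos"], as_index=False)
        .agg(meth_count=("count_methylated", "sum"), total_count=("total", "sum"))
    )
    if (merged["meth_count"] > merged["total_count"]).any():
        raise DataError(f"{path}: methylated count exceeds total after strand merge")
    merged = merged[merged["total_count"] >= int(min_coverage)]
    return merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def compute_ratios(records: Mapping[str, pd.DataFrame], group_labels: Mapping[str, str]) -> RatioTable:
    """Build a :class:`RatioTable` (ratio = meth / total per CpG per sample)."""
    for sample in records:
        if sample not in group_labels:
            raise ConfigError(f"sample {sample!r} has no group label")
        if group_labels[sample] not in ("tumor", "normal"):
            raise ConfigError(
                f"sample {sample!r}: group must be 'tumor' or 'normal',"
                f" got {group_labels[sample]!r}"
            )
    ratio_cols, total_cols = {}, {}
    for sample, rec in records.items():
        if len(rec) and (rec["total_count"] == 0).any():
            raise DataError(f"sample {sample!r}: zero total_count present")
        idx = pd.MultiIndex.from_arrays(
            [rec["chrom"], rec["pos"]], names=["chrom", "pos"]
        )
        ratio_cols[sample] = pd.Series(
            rec["meth_count"].to_numpy() / np.maximum(rec["total_count"].to_numpy(), 1),
            index=idx,
        )
        total_cols[sample] = pd.Series(rec["total_count"].to_numpy(), index=idx, dtype=float)
    ratios = pd.DataFrame(ratio_cols)
    totals = pd.DataFrame(total_cols)
    if len(ratios):
        ratios = ratios.sort_index()
        totals = totals.sort_index()
    groups = {s: group_labels[s] for s in records}
    return RatioTable(ratios=ratios, totals=totals, groups=groups)


def intersect_cpgs(table: RatioTable, policy: str = "all-samples") -> RatioTable:
    """Restrict the table to CpGs present in every sample (default policy)."""
    if policy != "all-samples":
        raise ConfigError(f"unknown intersection policy {policy!r}")
    if not table.normal_samples:
        raise ConfigError("intersection requires at least one normal sample")
    keep = table.ratios.notna().all(axis=1)
    if len(table.ratios) and not keep.any():
        logger.warning("CpG intersection across samples is empty")
    return RatioTable(
        ratios=table.ratios.loc[keep],
        totals=table.totals.loc[keep],
        groups=dict(table.groups),
    )


def call_dmrs(
    table: RatioTable,
    diff_threshold: float = 0.4,
    hypo_threshold: float = 0.3,
    hyper_threshold: float = 0.7,
    mode: str = "absolute",
) -> pd.DataFrame:
    """Call per-CpG DMRs by the three-threshold rule.

    A CpG is a DMR when the tumor-normal mean ratio difference exceeds
    ``diff_threshold`` (strict). Under the default ``mode="absolute"`` the
    absolute difference is tested (both hypo- and hypermethylated shifts count);
    ``mode="normal_minus_tumor"`` tests the signed loss of methylation only.
    DMRs are then classified by the tumor mean: ``hypo`` below
    ``hypo_threshold``, ``hyper`` above ``hyper_threshold`` (both strict),
    ``indeterminate`` in between. Returns one row per input CpG with columns
    ``chrom, pos, normal_mean, tumor_mean, diff, status``.
    """
    tumor, normal = table.tumor_samples, table.normal_samples
    if not tumor or not normal:
        raise ConfigError("call_dmrs requires at least one tumor and one normal sample")
    if mode not in ("absolute", "normal_minus_tumor"):
        raise ConfigError(f"unknown DMR difference mode {mode!r}")
    if table.ratios[tumor + normal].isna().any().any():
        raise DataError("missing ratios present; run intersect_cpgs first")

    tumor_mean = table.ratios[tumor].mean(axis=1).to_numpy()
    normal_mean = table.ratios[normal].mean(axis=1).to_numpy()
    diff = tumor_mean - normal_mean
    magnitude = np.abs(diff) if mode == "absolute" else (normal_mean - tumor_mean)
    is_dmr = magnitude > diff_threshold
    status = np.where(
        ~is_dmr,
        STATUS_NOT_DMR,
        np.where(
            tumor_mean < hypo_threshold,
            STATUS_HYPO,
            np.where(tumor_mean > hyper_threshold, STATUS_HYPER, STATUS_INDETERMINATE),
        ),
    )
    idx = table.ratios.index
    return pd.DataFrame(
        {
            "chrom": idx.get_level_values("chrom"),
            "pos": idx.get_level_values("pos"),
            "normal_mean": normal_mean,
            "tumor_mean": tumor_mean,
            "diff": diff,
            "status": status,
        }
    ).reset_index(drop=True)


def write_dmr_table(calls: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write DMR calls as BED-like TSV (0-based half-open interval)."""
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["pos"] - 1,
            "end": calls["pos"],
            "normal_mean": calls["normal_mean"],
            "tumor_mean": calls["tumor_mean"],
            "diff": calls["diff"],
            "status": calls["status"],
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_dmr_table(path: str | Path) -> pd.DataFrame:
    """Read a BED-like DMR TSV back to the 1-based call representation."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df["pos"] = df["end"].astype(int)
    return df[["chrom", "pos", "normal_mean", "tumor_mean", "diff", "status"]]


def dmr_summary(calls: pd.DataFrame) -> dict:
    """Counts per status plus total intersected CpGs, for the JSON report."""
    counts = calls["status"].value_counts().to_dict()
    return {
        "n_cpgs": int(len(calls)),
        "counts": {
            k: int(counts.get(k, 0))
            for k in (STATUS_NOT_DMR, STATUS_HYPO, STATUS_HYPER, STATUS_INDETERMINATE)
        },
    }


def write_dmr_summary(calls: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dmr_summary(calls), indent=2, sort_keys=True))
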