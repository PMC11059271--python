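"""Bespoke WES/RNA companion rules: variant filters, TMB, CNV thresholds, fusions.

These are the fixed filtering rules applied downstream of external callers:
a minimum-depth cutoff of 10 (inclusive), exonic/splicing region selection,
three population-frequency filters at < 0.01 (strict; a frequency missing from
the databases passes by default), tumor mutation burden as coding mutations
per megabase (~30 Mb of RefSeq coding sequence), copy-number states from
tumor/normal log2 ratios (deletion <= -0.4, amplification > 0.3), and the
three-rule gene-fusion filter (a protein-coding partner, no zero read counts,
exact duplicates collapsed).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .synthio import fusion_key

AF_COLUMNS = ("af_exac_eas", "af_gnomad_eas", "af_korean")
DEFAULT_REGIONS = frozenset({"exonic", "splicing"})


def filter_variants(
    records: pd.DataFrame,
    min_depth: int = 10,
    max_af: float = 0.01,
    regions: Iterable[str] = DEFAULT_REGIONS,
    missing_af_passes: bool = True,
) -> pd.DataFrame:
    """Apply the depth / region / population-frequency variant filters.

    Kept iff depth >= ``min_depth`` (inclusive), region in ``regions``, and
    every present frequency < ``max_af`` (strict). A missing frequency passes
    by default (absence from the population databases); set
    ``missing_af_passes=False`` to fail closed.
    """
    regions = set(regions)
    for col in AF_COLUMNS:
        vals = pd.to_numeric(records[col], errors="coerce")
        bad = records[col].notna() & vals.isna()
        if bad.any():
            raise DataError(f"malformed frequency in column {col}")
        present = vals.notna()
        if ((vals[present] < 0) | (vals[present] > 1)).any():
            raise DataError(f"frequency outside [0, 1] in column {col}")
    keep = (records["total_depth"] >= min_depth) & records["region_class"].isin(regions)
    for col in AF_COLUMNS:
        vals = pd.to_numeric(records[col], errors="coerce")
        if missing_af_passes:
            keep &= vals.isna() | (vals < max_af)
        else:
            keep &= vals.notna() & (vals < max_af)
    return records[keep].reset_index(drop=True)


def compute_tmb(n_coding_mutations: int, coding_length_mb: float = 30.0) -> float:
    """Tumor mutation burden: coding mutations per megabase of coding sequence."""
    if n_coding_mutations < 0:
        raise ConfigError("mutation count must be nonnegative")
    if coding_length_mb <= 0:
        raise ConfigError("coding_length_mb must be positive")
    return n_coding_mutations / coding_length_mb


def zrpkm(rpkm: pd.DataFrame, reference_samples: Iterable[str], center: str = "median"):
    """Z-score each feature's RPKM against a reference-sample distribution.

    ``z = (rpkm - median(reference)) / sd(reference)`` per feature (sample
    standard deviation, ddof=1); ``center="mean"`` swaps the median for the
    mean. Features whose reference SD is zero are excluded and returned in the
    second element of the ``(z, excluded)`` result.
    """
    reference_samples = list(reference_samples)
    if len(reference_samples) < 2:
        raise ConfigError("zrpkm requires at least 2 reference samples")
    missing = [s for s in reference_samples if s not in rpkm.columns]
    if missing:
        raise ConfigError(f"reference samples absent from matrix: {missing}")
    if center not in ("median", "mean"):
        raise ConfigError(f"unknown centering {center!r}")
    ref = rpkm[reference_samples]
    loc = ref.median(axis=1) if center == "median" else ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    excluded = rpkm.index[sd == 0].tolist()
    keep = sd > 0
    z = rpkm.loc[keep].sub(loc[keep], axis=0).div(sd[keep], axis=0)
    return z, excluded


def call_cnv(
    log2_values: pd.DataFrame,
    del_threshold: float = -0.4,
    amp_threshold: float = 0.3,
) -> pd.DataFrame:
    """Classify per-feature log2 ratios into deletion / neutral / amplification.

    Deletion at ``log2 <= del_threshold`` (inclusive), amplification at
    ``log2 > amp_threshold`` (strict), neutral otherwise.
    """
    vals = log2_values["log2_ratio"].to_numpy(dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        feat = log2_values["feature_id"].to_numpy()[bad][0]
        raise DataError(f"non-finite log2 ratio for feature {feat}")
    state = np.where(
        vals <= del_threshold,
        "deletion",
        np.where(vals > amp_threshold, "amplification", "neutral"),
    )
    return pd.DataFrame(
        {
            "feature_id": log2_values["feature_id"],
            "log2_ratio": vals,
            "state": state,
        }
    ).reset_index(drop=True)


def filter_fusions(records: pd.DataFrame, coding_genes: Iterable[str]) -> pd.DataFrame:
    """Apply the three fusion rules and collapse exact duplicates.

    Kept iff at least one partner is protein-coding and both junction and
    spanning read counts are nonzero; then records identical in partners,
    breakpoints and both read counts are collapsed to a single survivor.
    Orientation-swapped pairs (B-A vs A-B) are distinct records.
    """
    coding = set(coding_genes)
    if not coding:
        raise ConfigError("coding gene set must be non-empty")
    keep = (
        (records["gene_a"].isin(coding) | records["gene_b"].isin(coding))
        & (records["junction_reads"] > 0)
        & (records["spanning_reads"] > 0)
    )
    kept = records[keep]
    dedup_cols = [
        "gene_a", "gene_b", "chrom_a", "pos_a", "chrom_b", "pos_b",
        "junction_reads", "spanning_reads",
    ]
    return kept.drop_duplicates(subset=dedup_cols).reset_index(drop=True)


def fusion_keys(records: pd.DataFrame) -> list:
    """Canonical identity strings for fusion records (sorted)."""
    return sorted(
        fusion_key(r.gene_a, r.gene_b, r.chrom_a, r.pos_a, r.chrom_b, r.pos_b,
                   r.junction_reads, r.spanning_reads)
        for r in records.itertuples(index=False)
    )


def variant_filter_report(records: pd.DataFrame, kept: pd.DataFrame,
                          min_depth: int = 10,
                          regions: Iterable[str] = DEFAULT_REGIONS) -> dict:
    """JSON-ready tallies of the variant filter outcome."""
    return {
        "n_input": int(len(records)),
        "n_kept": int(len(kept)),
        "n_dropped": int(len(records) - len(kept)),
        "n_fail_depth": int((records["total_depth"] < min_depth).sum()),
        "n_fail_region": int((~records["region_class"].isin(set(regions))).sum()),
    }
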