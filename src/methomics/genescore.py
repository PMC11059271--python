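"""Gene-level DMR-fraction scoring and ranking of differentially expressed genes.

DEGs are defined by fold-change, adjusted-p and baseMean cutoffs applied to an
externally produced DE table. Intersected CpGs are assigned to every gene whose
annotated interval contains them; a gene is eligible for ranking when it has
more than ``min_cpgs`` CpGs and more than ``min_fraction`` of them are DMRs
(both strict), and eligible genes are ranked by DMR fraction.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import AnnotationError, DataError
from .methcall import STATUS_HYPER, STATUS_HYPO, STATUS_INDETERMINATE

DMR_STATUSES_DEFAULT = (STATUS_HYPO, STATUS_HYPER, STATUS_INDETERMINATE)


def filter_degs(
    de_table: pd.DataFrame,
    min_abs_lfc: float = 2.0,
    max_padj: float = 0.05,
    min_basemean: float = 100.0,
) -> pd.DataFrame:
    """Select DEGs: |log2fc| >= min_abs_lfc, padj < max_padj, basemean >= min_basemean.

    Fold-change and baseMean cutoffs are inclusive, the adjusted-p cutoff is
    strict; rows with missing padj are excluded. Raises on duplicate gene ids.
    """
    dupes = de_table["gene_id"][de_table["gene_id"].duplicated()].unique()
    if len(dupes):
        raise DataError(f"duplicate gene_id in DE table: {sorted(map(str, dupes))}")
    lfc = de_table["log2fc"].abs() >= min_abs_lfc
    padj = de_table["padj"].notna() & (de_table["padj"] < max_padj)
    base = de_table["basemean"] >= min_basemean
    return de_table[lfc & padj & base].reset_index(drop=True)


def map_cpgs_to_genes(
    dmr_calls: pd.DataFrame,
    gene_map: pd.DataFrame,
    dmr_statuses: Iterable[str] = DMR_STATUSES_DEFAULT,
) -> pd.DataFrame:
    """Tally intersected CpGs and DMRs per gene.

    Gene intervals are 1-based inclusive and may overlap; a CpG is counted in
    every gene whose interval contains it. ``dmr_statuses`` selects which call
    statuses count as DMRs (by default hypo, hyper and indeterminate, i.e.
    every call that passed the difference threshold). Returns a DataFrame with
    one row per gene: ``gene_id, n_cpgs, n_dmr, median_abs_diff, mean_abs_diff``.
    """
    if len(gene_map) and (gene_map["start"] > gene_map["end"]).any():
        bad = gene_map[gene_map["start"] > gene_map["end"]]["gene_id"].tolist()
        raise AnnotationError(f"gene interval with start > end: {bad}")
    statuses = set(dmr_statuses)
    rows = []
    by_chrom = {}
    for chrom, sub in dmr_calls.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        by_chrom[chrom] = (
            sub["pos"].to_numpy(),
            sub["status"].isin(statuses).to_numpy(),
            sub["diff"].abs().to_numpy(),
        )
    for gene, chrom, start, end in gene_map[["gene_id", "chrom", "start", "end"]].itertuples(
        index=False
    ):
        if chrom in by_chrom:
            pos, is_dmr, absdiff = by_chrom[chrom]
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
        else:
            lo = hi = 0
        n = int(hi - lo)
        if n:
            rows.append(
                (
                    gene,
                    n,
                    int(is_dmr[lo:hi].sum()),
                    float(np.median(absdiff[lo:hi])),
                    float(np.mean(absdiff[lo:hi])),
                )
            )
        else:
            rows.append((gene, 0, 0, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_cpgs", "n_dmr", "median_abs_diff", "mean_abs_diff"]
    )


def score_genes(
    tallies: pd.DataFrame,
    deg_ids: Iterable[str],
    min_cpgs: int = 10,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Score every DEG by its DMR fraction and flag eligibility.

    Eligibility requires strictly more than ``min_cpgs`` intersected CpGs and a
    DMR fraction strictly above ``min_fraction``. DEGs with no mapped CpGs are
    scored with ``n_cpgs = 0`` and are ineligible. Rank is left unset here
    (see :func:`rank_genes`).
    """
    deg_ids = list(dict.fromkeys(deg_ids))
    scores = (
        pd.DataFrame({"gene_id": deg_ids})
        .merge(tallies, on="gene_id", how="left")
        .fillna({"n_cpgs": 0, "n_dmr": 0})
    )
    scores["n_cpgs"] = scores["n_cpgs"].astype(int)
    scores["n_dmr"] = scores["n_dmr"].astype(int)
    with np.errstate(invalid="ignore"):
        scores["dmr_fraction"] = np.where(
            scores["n_cpgs"] > 0, scores["n_dmr"] / scores["n_cpgs"].clip(lower=1), 0.0
        )
    scores["eligible"] = (scores["n_cpgs"] > min_cpgs) & (scores["dmr_fraction"] > min_fraction)
    scores["rank"] = pd.array([pd.NA] * len(scores), dtype="Int64")
    return scores[
        [
            "gene_id", "n_cpgs", "n_dmr", "dmr_fraction",
            "median_abs_diff", "mean_abs_diff", "eligible", "rank",
        ]
    ]


def rank_genes(scores: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Rank eligible genes by DMR fraction (desc) and return the top ``top_n``.

    Ties break by mean absolute tumor-normal difference (desc), then by
    gene id (lexicographic), so the order is deterministic.
    """
    eligible = scores[scores["eligible"]].copy()
    eligible = eligible.sort_values(
        ["dmr_fraction", "mean_abs_diff", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).head(top_n)
    eligible["rank"] = pd.array(range(1, len(eligible) + 1), dtype="Int64")
    return eligible.reset_index(drop=True)


def write_gene_scores(scores: pd.DataFrame, path: str | Path,
                      header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        scores.to_csv(fh, sep="\t", index=False)


def write_top_genes(ranked: pd.DataFrame, path: str | Path) -> None:
    records = []
    for row in ranked.itertuples(index=False):
        records.append(
            {
                "gene_id": row.gene_id,
                "rank": int(row.rank),
                "n_cpgs": int(row.n_cpgs),
                "n_dmr": int(row.n_dmr),
                "dmr_fraction": float(row.dmr_fraction),
                "median_abs_diff": None if pd.isna(row.median_abs_diff) else float(row.median_abs_diff),
                "mean_abs_diff": None if pd.isna(row.mean_abs_diff) else float(row.mean_abs_diff),
            }
        )
    Path(path).write_text(json.dumps({"top_genes": records}, indent=2, sort_keys=True))
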