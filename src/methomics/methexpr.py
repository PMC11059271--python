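"""Expression normalization and per-probe methylation-expression regression.

Expression is normalized as centered log10(FPKM + 1) per gene across samples;
the methylation-expression relationship is quantified per (probe, gene) link by
an ordinary least-squares fit ``expression = intercept + slope * ratio`` with
Pearson r and a two-sided p-value from the t distribution on n - 2 degrees of
freedom. Promoter hypomethylation driving overexpression shows up as a
negative slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


def normalize_fpkm(fpkm: pd.DataFrame, mode: str = "center") -> pd.DataFrame:
    """Normalize FPKM as log10(FPKM + 1) centered per gene across samples.

    ``mode="center"`` returns ``v - mean(v)`` (per-gene values sum to zero);
    ``mode="mean_minus_value"`` is the sign-flipped literal alternative.
    """
    if mode not in ("center", "mean_minus_value"):
        raise ConfigError(f"unknown normalization mode {mode!r}")
    if (fpkm.to_numpy() < 0).any():
        raise DataError("negative FPKM value")
    v = np.log10(fpkm + 1.0)
    centered = v.sub(v.mean(axis=1), axis=0)
    return centered if mode == "center" else -centered


@dataclass(frozen=True)
class MethExprFit:
    """One OLS fit of expression on methylation ratio."""

    probe_id: str
    gene_id: str
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    n: int


def fit_meth_expr(ratios, expression, probe_id: str = "", gene_id: str = "") -> MethExprFit:
    """OLS fit of paired expression on methylation ratio.

    Pairs with a missing value on either side are dropped. Requires at least
    three complete pairs and non-constant methylation.
    """
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(expression, dtype=float)
    if x.shape != y.shape:
        raise ConfigError("ratios and expression must be paired 1-D arrays")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DataError(f"insufficient data for fit ({x.size} complete pairs, need >= 3)")
    if np.ptp(x) == 0:
        raise DataError("degenerate fit: methylation values are all identical")
    res = stats.linregress(x, y)
    return MethExprFit(
        probe_id=probe_id,
        gene_id=gene_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def batch_correlate(
    links: pd.DataFrame,
    probe_ratios: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Fit every unique (probe, gene) link with complete paired data.

    ``probe_ratios`` and ``expression`` are probes x samples and genes x
    samples; pairing is by the shared sample columns. Links to unknown probes
    or genes, or with degenerate/insufficient data, are skipped with a logged
    warning. Output is sorted by p-value ascending, ties by probe id.
    """
    shared = [s for s in probe_ratios.columns if s in expression.columns]
    rows = []
    seen = set()
    for probe, gene in links[["probe_id", "gene_id"]].itertuples(index=False):
        if (probe, gene) in seen:
            continue
        seen.add((probe, gene))
        if probe not in probe_ratios.index:
            logger.warning("link skipped: unknown probe %s", probe)
            continue
        if gene not in expression.index:
            logger.warning("link skipped: unknown gene %s", gene)
            continue
        try:
            fit = fit_meth_expr(
                probe_ratios.loc[probe, shared].to_numpy(dtype=float),
                expression.loc[gene, shared].to_numpy(dtype=float),
                probe_id=probe,
                gene_id=gene,
            )
        except DataError as exc:
            logger.warning("link (%s, %s) skipped: %s", probe, gene, exc)
            continue
        rows.append(fit)
    out = pd.DataFrame([f.__dict__ for f in rows],
                       columns=["probe_id", "gene_id", "slope", "intercept",
                                "pearson_r", "r_squared", "p_value", "n"])
    return out.sort_values(["p_value", "probe_id"], kind="mergesort").reset_index(drop=True)
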