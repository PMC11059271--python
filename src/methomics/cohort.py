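"""Reference-cohort probe analysis: specificity, extremes and t-SNE embedding.

Works on an array-style beta matrix (probes x samples, values in [0, 1]) with
one class label per sample. A probe is specific to the target tumor class when
its target-class mean differs from the mean of every other class by more than a
threshold (default 0.4, strict); "extreme" probes differ from a designated
reference class by more than a larger delta (default 0.8). Samples are embedded
in 2-D with t-SNE on the most variable probes.
"""

from __future__ import annotations

import pandas as pd
import numpy as np
from sklearn.manifold import TSNE

from .errors import ConfigError, DataError


def _class_means(beta: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-probe mean beta per class (missing values excluded)."""
    missing = [s for s in beta.columns if s not in labels.index]
    if missing:
        raise ConfigError(f"samples without class label: {missing}")
    out = {}
    for cls in pd.unique(labels.loc[beta.columns]):
        cols = [s for s in beta.columns if labels[s] == cls]
        if not cols:
            raise ConfigError(f"class {cls!r} has zero samples")
        out[cls] = beta[cols].mean(axis=1)
    return pd.DataFrame(out)


def top_variable_probes(beta: pd.DataFrame, k: int) -> list:
    """The ``k`` probes with the largest across-sample variance.

    Population variance (ddof=0) on available values; descending, with
    deterministic ties broken by probe id.
    """
    if k <= 0:
        raise ConfigError(f"k must be positive (got {k})")
    if k > len(beta):
        raise ConfigError(f"k ({k}) exceeds the number of probes ({len(beta)})")
    var = beta.var(axis=1, ddof=0)
    order = var.to_frame("var").sort_index().sort_values("var", ascending=False,
                                                         kind="mergesort")
    return order.index[:k].tolist()


def specific_probes(
    beta: pd.DataFrame,
    labels: pd.Series,
    target_class: str,
    threshold: float = 0.4,
    mode: str = "per_class",
) -> pd.DataFrame:
    """Probes whose target-class mean differs from other classes by > threshold.

    Under the default ``mode="per_class"`` the strict difference must hold
    against every other class's mean; ``mode="pooled"`` tests the single mean
    over all non-target samples. Returns one row per probe with the per-class
    means, the minimal absolute difference actually tested, and a ``specific``
    flag.
    """
    if mode not in ("per_class", "pooled"):
        raise ConfigError(f"unknown specificity mode {mode!r}")
    means = _class_means(beta, labels)
    if target_class not in means.columns:
        raise ConfigError(f"unknown target class {target_class!r}")
    if means.shape[1] < 2:
        raise ConfigError("specificity requires at least 2 classes")
    others = [c for c in means.columns if c != target_class]
    if mode == "per_class":
        diffs = (means[others].sub(means[target_class], axis=0)).abs()
        min_diff = diffs.min(axis=1)
    else:
        other_cols = [s for s in beta.columns if labels[s] != target_class]
        pooled = beta[other_cols].mean(axis=1)
        min_diff = (means[target_class] - pooled).abs()
    out = means.copy()
    out.columns = [f"mean_{c}" for c in means.columns]
    out["min_abs_diff"] = min_diff
    out["specific"] = min_diff > threshold
    out.index.name = "probe_id"
    return out.reset_index()


def extreme_probes(
    beta: pd.DataFrame,
    labels: pd.Series,
    target_class: str,
    reference_class: str,
    delta: float = 0.8,
) -> pd.DataFrame:
    """Probes with |target mean - reference mean| > delta, sorted descending."""
    means = _class_means(beta, labels)
    for cls in (target_class, reference_class):
        if cls not in means.columns:
            raise ConfigError(f"class {cls!r} absent from labels")
    diff = (means[target_class] - means[reference_class]).abs()
    out = pd.DataFrame(
        {
            "probe_id": means.index,
            "mean_target": means[target_class].to_numpy(),
            "mean_reference": means[reference_class].to_numpy(),
            "abs_diff": diff.to_numpy(),
        }
    )
    out = out[out["abs_diff"] > delta]
    return out.sort_values(["abs_diff", "probe_id"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def embed_tsne(
    beta: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """2-D t-SNE embedding of the samples (columns) of a beta matrix.

    Deterministic for a fixed seed and library version (random initialization,
    no PCA init). Requires at least ``3 * perplexity + 1`` samples.
    """
    n_samples = beta.shape[1]
    if n_samples < 3 * perplexity + 1:
        raise ConfigError(
            f"t-SNE needs >= 3*perplexity+1 = {int(3 * perplexity + 1)} samples, got "
            f"{n_samples}; lower the perplexity"
        )
    x = beta.T.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DataError("beta matrix contains missing values; impute or drop first")
    emb = TSNE(
        n_components=2, perplexity=perplexity, init="random", random_state=seed
    ).fit_transform(x)
    return pd.DataFrame(
        {
            "sample": beta.columns,
            "x": emb[:, 0],
            "y": emb[:, 1],
            "class": [labels[s] for s in beta.columns],
        }
    )


def read_beta_matrix(path) -> pd.DataFrame:
    beta = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if len(beta) and ((beta.to_numpy() < 0) | (beta.to_numpy() > 1)).any():
        raise DataError(f"{path}: beta values outside [0, 1]")
    return beta


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#")
    return pd.Series(df["class"].to_numpy(), index=df["sample"], name="class")
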