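"""Global methylation summaries: per-sample medians, PCA, clinical correlations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import _group_label

__all__ = ["GlobalSummary", "global_median", "pca_profiles", "correlate_globals"]


@dataclass
class GlobalSummary:
    sample_median: pd.Series   # one median beta per sample
    group_median: pd.Series    # median of the sample medians, per comparison group


def global_median(betas: pd.DataFrame, sheet: pd.DataFrame) -> GlobalSummary:
    """Median global methylation, per sample first, then per group.

    The per-sample median runs over all probes (missing excluded); the group
    summary is the median of its samples' medians.  Study samples group by
    timepoint, controls by group label.
    """
    if betas.size == 0:
        raise ValueError("empty beta matrix")
    values = betas.to_numpy(dtype=float)
    if np.isnan(values).all(axis=0).any():
        bad = betas.columns[np.isnan(values).all(axis=0)]
        raise ValueError(f"sample(s) with no observed values: {list(bad[:5])}")
    sample_median = betas.median(axis=0, skipna=True)
    sample_median.name = "median_beta"
    labels = _group_label(sheet)
    med = {}
    for group in labels.unique():
        cols = [c for c in labels.index[labels == group] if c in sample_median.index]
        if cols:
            med[group] = float(sample_median[cols].median())
    return GlobalSummary(sample_median=sample_median, group_median=pd.Series(med))


def pca_profiles(betas: pd.DataFrame, n_components: int = 2):
    """PCA of sample methylation profiles.

    Probes with any missing value are dropped listwise, samples are centred
    per probe, and the decomposition is a plain SVD.  Component signs are
    fixed by making each component's largest-magnitude probe loading
    positive, so results are identical across linear-algebra backends.

    Returns
    -------
    scores : DataFrame (samples × components)
    variance_explained : ndarray, fraction of total variance per component
        (all zeros when the samples are identical).
    """
    n_samples = betas.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > n_samples:
        raise ValueError(f"cannot extract {n_components} components from {n_samples} samples")
    complete = betas.dropna(axis=0, how="any")
    x = complete.to_numpy(dtype=float).T            # samples × probes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s ** 2).sum())
    k = n_components
    scores = u[:, :k] * s[:k]
    loadings = vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    for comp in range(k):
        pivot = np.argmax(np.abs(loadings[comp]))
        if loadings[comp, pivot] < 0:
            loadings[comp] *= -1.0
            scores[:, comp] *= -1.0
    variance_explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    scores = pd.DataFrame(
        scores, index=betas.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return scores, variance_explained


def correlate_globals(
    sample_median: pd.Series, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of the per-sample median methylation with clinical parameters.

    One test per clinical column (paired on the shared sample index, missing
    pairs dropped), Bonferroni-adjusted across the parameters.  Zero-variance
    parameters are reported as NA with a warning.
    """
    rows = []
    m = clinical.shape[1]
    for param in clinical.columns:
        paired = pd.concat([sample_median, clinical[param]], axis=1, join="inner").dropna()
        if len(paired) < 3:
            raise ValueError(f"parameter {param!r}: fewer than 3 paired observations")
        x, y = paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"parameter {param!r} (or the medians) has zero variance; r undefined")
            rows.append(dict(parameter=param, n=len(paired), r=np.nan, p=np.nan, p_adj=np.nan))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            dict(parameter=param, n=len(paired), r=r, p=p, p_adj=min(1.0, m * p))
        )
    return pd.DataFrame(rows).set_index("parameter")
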