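"""Fold-change enrichment of a called CpG subset across manifest feature categories.

For a feature category F on one annotation axis, the fold change is the
frequency of F in the called subset over its frequency in the array
background:

    FC(F) = (observed / subset_size) / (background_count / background_size)

FC > 1 means the called sites over-represent F, FC < 1 depletion, and FC = 1
is the frequency expected by chance.  Significance is assessed against a
size-matched uniform resampling null.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import CGI_RELATIONS, GENE_REGIONS, REGULATORY_FEATURES

__all__ = ["FEATURE_AXES", "feature_fold_change", "enrichment_resample_p"]

FEATURE_AXES = {
    "gene_region": GENE_REGIONS,
    "cgi_relation": CGI_RELATIONS,
    "regulatory_feature": REGULATORY_FEATURES,
}


def _axis_labels(manifest: pd.DataFrame, feature_axis: str) -> pd.Series:
    if feature_axis not in FEATURE_AXES:
        raise ValueError(
            f"unknown feature_axis {feature_axis!r}; expected one of {sorted(FEATURE_AXES)}"
        )
    return manifest[feature_axis].astype(str)


def feature_fold_change(
    subset, manifest: pd.DataFrame, feature_axis: str
) -> pd.DataFrame:
    """Observed/background counts and fold change per category of one axis.

    Categories present in the background but absent from the subset get
    FC = 0; vocabulary categories absent from the background are omitted
    with a warning (their FC is undefined).
    """
    subset = pd.Index(subset)
    if len(subset) == 0:
        raise ValueError("probe subset is empty")
    missing = subset.difference(manifest.index)
    if len(missing):
        raise KeyError(f"subset probes absent from manifest: {list(missing[:5])}")
    labels = _axis_labels(manifest, feature_axis)
    background_size = len(manifest)
    subset_size = len(subset)
    bg_counts = labels.value_counts()
    sub_counts = labels.loc[subset].value_counts()

    absent = [c for c in FEATURE_AXES[feature_axis] if c not in bg_counts.index]
    if absent:
        warnings.warn(
            f"{feature_axis} categor(ies) absent from background, omitted: {absent}"
        )

    rows = []
    for category in [c for c in FEATURE_AXES[feature_axis] if c in bg_counts.index]:
        observed = int(sub_counts.get(category, 0))
        bg = int(bg_counts[category])
        fc = (observed / subset_size) / (bg / background_size)
        rows.append(
            dict(
                category=category,
                observed_count=observed,
                subset_size=subset_size,
                background_count=bg,
                background_size=background_size,
                fold_change=fc,
            )
        )
    return pd.DataFrame(rows).set_index("category")


def _extremity(counts: np.ndarray, subset_size: int, bg_freq: np.ndarray) -> np.ndarray:
    """Two-sided enrichment extremity |log FC| on the count scale.

    Zero counts take a half-count continuity value before the ratio, so a
    category's fold change of 0 is scored by how depleted the count actually
    is relative to expectation rather than by log of zero.
    """
    cont = np.maximum(np.asarray(counts, dtype=float), 0.5)
    fc = (cont / subset_size) / bg_freq
    return np.abs(np.log(fc))


def enrichment_resample_p(
    subset,
    manifest: pd.DataFrame,
    feature_axis: str,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Empirical two-sided p per category from size-matched uniform resampling.

    p = (1 + #{draws with |log FC| ≥ observed}) / (n_draws + 1); the +1
    pseudo-count keeps p off zero.  Zero counts (observed or drawn) enter
    the log fold change through a half-count continuity value, so extremity
    is always finite and comparable on the count scale.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    subset = pd.Index(subset)
    if len(subset) > len(manifest):
        raise ValueError("subset larger than the probe background")
    obs = feature_fold_change(subset, manifest, feature_axis)
    labels = _axis_labels(manifest, feature_axis)
    categories = list(obs.index)
    codes = pd.Categorical(labels, categories=categories).codes
    n, s = len(manifest), len(subset)
    bg_freq = obs["background_count"].to_numpy() / n

    rng = np.random.default_rng(seed)
    counts = np.empty((n_draws, len(categories)), dtype=np.int64)
    for i in range(n_draws):
        draw = rng.choice(n, size=s, replace=False)
        counts[i] = np.bincount(codes[draw], minlength=len(categories))
    e_obs = _extremity(obs["observed_count"].to_numpy(), s, bg_freq)
    e_rand = _extremity(counts, s, bg_freq)
    hits = (e_rand >= e_obs[None, :] - 1e-12).sum(axis=0)
    p = (1 + hits) / (n_draws + 1)
    return pd.Series(p, index=obs.index, name="empirical_p")
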