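"""Per-patient Δβ computation and consensus-threshold calling of diet-responsive CpGs.

The differential-methylation procedure is deliberately not inferential: for
each patient the methylation change at every CpG is

    Δβ(probe, patient) = mean(β_T2, β_T3) − β_T1

(positive Δβ = gain of methylation after the intervention), and a CpG is
*called* when at least a consensus fraction of patients individually show
|Δβ| at or above an absolute beta-scale threshold, in the same direction.
Defaults — 10 % methylation difference in at least 77 % of participants —
give a consensus bar of 14 of 18 patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DeltaCallParams:
    """Tuning knobs of the consensus caller.

    delta_threshold
        absolute beta-scale difference a patient must show (default 0.10,
        i.e. "10 % methylation difference").
    consensus_fraction
        minimum fraction of evaluable patients that must individually pass
        the threshold (default 0.77).
    require_direction_consistency
        if True (default) hyper and hypo exceedances are counted separately
        and consensus must be reached within one direction; if False a
        patient qualifies on |Δβ| ≥ threshold and the call direction is the
        majority sign among qualifying patients (ties → no call).
    """

    delta_threshold: float = 0.10
    consensus_fraction: float = 0.77
    require_direction_consistency: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_threshold < 1.0:
            raise ValueError("delta_threshold must be in (0, 1)")
        if not 0.0 < self.consensus_fraction <= 1.0:
            raise ValueError("consensus_fraction must be in (0, 1]")


@dataclass
class DeltaCallResult:
    """Per-probe Δβ summaries and consensus calls."""

    delta: pd.DataFrame               # probes × patients
    hyper_count: pd.Series            # patients with Δβ ≥ threshold
    hypo_count: pd.Series             # patients with Δβ ≤ −threshold
    n_eval: pd.Series                 # patients with a non-missing Δβ
    call: pd.Series                   # 'hyper' | 'hypo' | 'none'
    params: DeltaCallParams = field(default_factory=DeltaCallParams)

    @property
    def called_subset(self) -> pd.Index:
        return self.call.index[self.call != "none"]

    def to_frame(self) -> pd.DataFrame:
        """Flat per-probe table (the on-disk `calls.tsv` layout)."""
        return pd.DataFrame(
            {
                "mean_delta": self.delta.mean(axis=1),
                "hyper_count": self.hyper_count,
                "hypo_count": self.hypo_count,
                "n_eval": self.n_eval,
                "call": self.call,
            }
        )


def min_patients(n_patients: int, consensus_fraction: float) -> int:
    """Smallest patient count satisfying the consensus fraction: ceil(f·n).

    For the study design (18 patients at 0.77) this is 14 — the same bar as
    the "more than 3/4" reading.  The inner round guards against binary
    floating-point artifacts (0.1 × 30 is not exactly 3).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    return int(math.ceil(round(consensus_fraction * n_patients, 9)))


def compute_delta(betas: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-patient methylation change, probes × patients.

    Δβ = mean over available post-diet timepoints (T2, T3) − T1.  A patient
    missing one of T2/T3 falls back to the single available post-diet value;
    a patient with no T1 sample or no post-diet sample at all is an error,
    since Δβ is anchored at baseline.
    """
    study = sheet[(sheet["group"] == "study") & (sheet["tissue"] == "blood")]
    if study.empty:
        raise ValueError("sample sheet contains no study blood samples")
    deltas: dict[str, pd.Series] = {}
    for patient, rows in study.groupby("patient_id", sort=False):
        by_tp = rows.set_index("timepoint")["sample_id"]
        if "T1" not in by_tp.index:
            raise ValueError(f"patient {patient!r} has no T1 (baseline) sample")
        post_ids = [by_tp[tp] for tp in ("T2", "T3") if tp in by_tp.index]
        if not post_ids:
            raise ValueError(f"patient {patient!r} has neither a T2 nor a T3 sample")
        post = betas[post_ids].mean(axis=1)  # skips NA timepoints per probe
        deltas[str(patient)] = post - betas[by_tp["T1"]]
    out = pd.DataFrame(deltas)
    out.index.name = "probe_id"
    out.columns.name = "patient_id"
    return out


def call_sites(delta: pd.DataFrame, params: DeltaCallParams | None = None) -> DeltaCallResult:
    """Consensus-threshold calling over a probes × patients Δβ matrix.

    A patient with a missing Δβ at a probe is excluded from both the
    numerator and the denominator for that probe: the consensus bar is
    recomputed per probe on the evaluable patient count.
    """
    params = params or DeltaCallParams()
    if delta.shape[1] < 1:
        raise ValueError("delta matrix must cover at least one patient")
    d = delta.to_numpy(dtype=float)
    valid = ~np.isnan(d)
    n_eval = valid.sum(axis=1)
    thr = params.delta_threshold

    hyper = ((d >= thr) & valid).sum(axis=1)
    hypo = ((d <= -thr) & valid).sum(axis=1)
    # per-probe consensus bar on evaluable n; probes with n_eval==0 are never called
    bar = np.array([min_patients(n, params.consensus_fraction) if n else np.iinfo(np.int64).max
                    for n in n_eval])

    call = np.full(delta.shape[0], "none", dtype=object)
    if params.require_direction_consistency:
        is_hyper = hyper >= bar
        is_hypo = hypo >= bar
        both = is_hyper & is_hypo
        if both.any():
            if params.consensus_fraction > 0.5:
                raise RuntimeError(
                    "internal error: probe reached consensus in both directions "
                    "with consensus_fraction > 0.5"
                )
            # ambiguous at lax fractions: no call
            is_hyper &= ~both
            is_hypo &= ~both
        call[is_hyper] = "hyper"
        call[is_hypo] = "hypo"
    else:
        qual = (np.abs(d) >= thr) & valid
        q_pos = (qual & (d > 0)).sum(axis=1)
        q_neg = (qual & (d < 0)).sum(axis=1)
        passed = qual.sum(axis=1) >= bar
        call[passed & (q_pos > q_neg)] = "hyper"
        call[passed & (q_neg > q_pos)] = "hypo"

    idx = delta.index
    return DeltaCallResult(
        delta=delta,
        hyper_count=pd.Series(hyper, index=idx, name="hyper_count"),
        hypo_count=pd.Series(hypo, index=idx, name="hypo_count"),
        n_eval=pd.Series(n_eval, index=idx, name="n_eval"),
        call=pd.Series(call, index=idx, name="call"),
        params=params,
    )


def _group_label(sheet: pd.DataFrame) -> pd.Series:
    """Comparison group per sample: study samples split by timepoint, others by group."""
    lab = sheet["group"].astype(str).copy()
    is_study = sheet["group"] == "study"
    lab[is_study] = sheet.loc[is_study, "timepoint"].astype(str)
    lab.index = sheet["sample_id"].to_numpy()
    return lab


def subset_median_profile(
    betas: pd.DataFrame, subset, sheet: pd.DataFrame
) -> pd.Series:
    """Median methylation at a probe subset, per comparison group.

    Study samples are grouped by timepoint (T1/T2/T3); control samples by
    their group label.  The median pools all beta values of the group's
    samples at the subset probes.
    """
    subset = pd.Index(subset)
    if len(subset) == 0:
        raise ValueError("probe subset is empty")
    missing = subset.difference(betas.index)
    if len(missing):
        raise KeyError(f"subset probes absent from matrix: {list(missing[:5])}")
    labels = _group_label(sheet)
    sub = betas.loc[subset]
    out = {}
    for group in labels.unique():
        cols = labels.index[labels == group]
        cols = [c for c in cols if c in sub.columns]
        if not cols:
            continue
        out[group] = float(np.nanmedian(sub[cols].to_numpy()))
    return pd.Series(out, name="median_beta")


def subset_variance_test(
    betas: pd.DataFrame,
    subset,
    sheet: pd.DataFrame,
    reference: str = "T1",
    pooled: bool = False,
) -> pd.DataFrame:
    """Group variances at a probe subset plus a dispersion test of each group vs T1.

    By default the variance is taken over per-sample mean subset methylation
    (one value per participant/control), the convention behind comparisons of
    baseline heterogeneity; ``pooled=True`` instead pools all probe-level
    values.  Pairwise dispersion against the reference group uses the
    Brown–Forsythe test (Levene with median centring).
    """
    subset = pd.Index(subset)
    if len(subset) == 0:
        raise ValueError("probe subset is empty")
    labels = _group_label(sheet)
    sub = betas.loc[subset]
    groups: dict[str, np.ndarray] = {}
    for group in labels.unique():
        cols = [c for c in labels.index[labels == group] if c in sub.columns]
        if not cols:
            continue
        if pooled:
            vals = sub[cols].to_numpy().ravel()
        else:
            vals = np.nanmean(sub[cols].to_numpy(), axis=0)  # per-sample means
        groups[group] = vals[~np.isnan(vals)]
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    ref = groups[reference]
    rows = []
    for group, vals in groups.items():
        if group == reference:
            p = np.nan
        else:
            _, p = stats.levene(ref, vals, center="median")
        rows.append(
            {
                "group": group,
                "n": len(vals),
                "variance": float(np.var(vals, ddof=1)),
                "p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows).set_index("group")
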