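"""Synthetic EPIC-like methylation cohorts with a planted ground truth.

The generator emulates the study design this package analyses: a blood
longitudinal cohort (18 patients × 3 timepoints) plus a healthy-blood control
group, and liver panels labelled with fibrosis grades 0–3.  A configurable
subset of CpGs is *planted* as diet-responsive: carrier patients' baseline
(T1) betas are shifted away from a common post-diet mean that T2, T3 and
healthy blood share, so the per-patient Δβ = mean(T2, T3) − T1 recovers the
planted effect.  Hyper-planted sites are baseline-hypomethylated (the
dominant direction in blood after an unhealthy diet) and gain methylation
after the intervention; hypo-planted sites are symmetric.

Per-probe baseline means follow the bimodal distribution characteristic of
methylation arrays (components concentrated near 0.1 and 0.9 plus an
intermediate component).  Per-observation noise is Beta-distributed,
reparameterised by (mean, sd), so draws respect the [0, 1] support; all
betas are clamped to [0.01, 0.99].

Everything is driven by one master seed through a single ordered stream:
identical config → byte-identical emitted files.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CGI_RELATIONS,
    GENE_REGIONS,
    REGULATORY_FEATURES,
    write_beta_matrix,
    write_manifest,
    write_sample_sheet,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "simulate_liver_panel", "write_cohort"]

# default single-label category frequencies, loosely EPIC-like
DEFAULT_FEATURE_PROBS: dict[str, dict[str, float]] = {
    "gene_region": {
        "TSS1500": 0.13,
        "TSS200": 0.07,
        "5'UTR": 0.10,
        "1stExon": 0.06,
        "ExonBoundary": 0.05,
        "GeneBody": 0.30,
        "3'UTR": 0.07,
        "intergenic": 0.22,
    },
    "cgi_relation": {
        "Island": 0.30,
        "NorthShore": 0.12,
        "SouthShore": 0.10,
        "NorthShelf": 0.05,
        "SouthShelf": 0.05,
        "OpenSea": 0.38,
    },
    "regulatory_feature": {
        "Promoter": 0.15,
        "PromoterFlanking": 0.08,
        "Enhancer": 0.12,
        "CTCF": 0.05,
        "OpenChromatin": 0.05,
        "TFBS": 0.05,
        "none": 0.50,
    },
}

_AXIS_VOCAB = {
    "gene_region": GENE_REGIONS,
    "cgi_relation": CGI_RELATIONS,
    "regulatory_feature": REGULATORY_FEATURES,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants of the emulated cohort.

    The defaults mirror the design under analysis: 18 patients sampled at
    three timepoints, 60 healthy-blood controls, a planted effect of
    Δβ = 0.20 carried by 90 % of patients, and liver panels of 40 profiles
    per fibrosis grade drifting 0.15 beta per grade toward the diseased mean.
    """

    n_patients: int = 18
    n_probes: int = 5000
    n_planted_hyper: int = 100
    n_planted_hypo: int = 10
    delta_effect: float = 0.20
    consensus_carrier_fraction: float = 0.9
    noise_sd: float = 0.03
    n_healthy_blood: int = 60
    n_liver_per_grade: dict[int, int] = field(
        default_factory=lambda: {0: 40, 1: 40, 2: 40, 3: 40}
    )
    n_healthy_liver: int = 23
    grade_drift: float = 0.15
    seed: int = 0
    feature_probs: dict[str, dict[str, float]] | None = None
    planted_feature_bias: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_planted_hyper + self.n_planted_hypo > self.n_probes:
            raise ValueError("planted probes exceed n_probes")
        if not 0.0 <= self.delta_effect < 1.0:
            raise ValueError("delta_effect must be in [0, 1)")
        if not 0.0 < self.consensus_carrier_fraction <= 1.0:
            raise ValueError("consensus_carrier_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if min(self.n_patients, self.n_probes) < 1:
            raise ValueError("n_patients and n_probes must be >= 1")
        for axis, probs in (self.feature_probs or {}).items():
            _check_probs(axis, probs)
        for axis, probs in (self.planted_feature_bias or {}).items():
            _check_probs(axis, probs)

    @classmethod
    def from_toml(cls, path) -> "SimulationConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "n_liver_per_grade" in raw:
            raw["n_liver_per_grade"] = {int(k): int(v) for k, v in raw["n_liver_per_grade"].items()}
        return cls(**raw)


def _check_probs(axis: str, probs: dict[str, float]) -> None:
    if axis not in _AXIS_VOCAB:
        raise ValueError(f"unknown feature axis {axis!r}")
    bad = set(probs) - set(_AXIS_VOCAB[axis])
    if bad:
        raise ValueError(f"unknown {axis} categories: {sorted(bad)}")
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError(f"{axis} probabilities must sum to 1")


@dataclass
class GroundTruth:
    """Ledger of planted diet-responsive CpGs.

    Beyond the planted sets and carrier flags, the per-probe post-diet and
    diseased (baseline-like) mean vectors are recorded so liver panels can
    be placed on the same probe means.
    """

    planted_hyper: pd.Index
    planted_hypo: pd.Index
    carriers: pd.DataFrame          # planted probes × patients, bool
    post_means: pd.Series           # per-probe post-diet / healthy mean
    diseased_means: pd.Series       # per-probe baseline-like (T1 carrier) mean

    @property
    def planted(self) -> pd.Index:
        return self.planted_hyper.append(self.planted_hypo)


def _beta_around(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Beta-distributed draws with the given mean and (approximate) sd.

    The Beta(a, b) pair is solved from mean m and variance s² via the
    concentration ν = m(1−m)/s² − 1; means are clipped away from the bounds
    so ν stays positive, and draws are clamped to [0.01, 0.99].
    """
    m = np.clip(np.asarray(mean, dtype=float), 0.02, 0.98)
    nu = np.maximum(m * (1.0 - m) / (sd * sd) - 1.0, 0.5)
    draw = rng.beta(m * nu, (1.0 - m) * nu)
    return np.clip(draw, 0.01, 0.99)


def _baseline_means(rng: np.random.Generator, n_probes: int) -> np.ndarray:
    """Bimodal array-like per-probe means: low, intermediate and high components."""
    comp = rng.choice(3, size=n_probes, p=[0.40, 0.25, 0.35])
    low = rng.beta(1.5, 12.0, size=n_probes)      # mode near 0.05–0.15
    mid = rng.beta(2.0, 2.0, size=n_probes)       # broad intermediate
    high = rng.beta(12.0, 1.5, size=n_probes)     # mode near 0.85–0.95
    return np.select([comp == 0, comp == 1], [low, mid], default=high)


def _draw_categories(
    rng: np.random.Generator,
    axis: str,
    n: int,
    probs: dict[str, float],
) -> np.ndarray:
    cats = [c for c in _AXIS_VOCAB[axis] if probs.get(c, 0.0) > 0.0]
    p = np.array([probs[c] for c in cats])
    return rng.choice(np.array(cats, dtype=object), size=n, p=p / p.sum())


def simulate_cohort(config: SimulationConfig):
    """Generate the blood cohort: (betas, sample sheet, probe manifest, ground truth).

    Draw order from the master seed: probe baseline means → planted probe
    choice → planted means → carrier choice → blood betas (T1, T2, T3,
    healthy) → manifest categories.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, config.n_probes
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(p)], name="probe_id")
    patient_ids = [f"P{i + 1:02d}" for i in range(n)]

    base = _baseline_means(rng, p)
    nh, nl = config.n_planted_hyper, config.n_planted_hypo
    planted_idx = rng.choice(p, size=nh + nl, replace=False)
    hyper_idx, hypo_idx = planted_idx[:nh], planted_idx[nh:]

    post = base.copy()
    diseased = base.copy()
    d = config.delta_effect
    # hyper sites: baseline-low, gain methylation after the diet change
    post[hyper_idx] = rng.uniform(d + 0.10, 0.95, size=nh)
    diseased[hyper_idx] = post[hyper_idx] - d
    # hypo sites: baseline-high, lose methylation
    post[hypo_idx] = rng.uniform(0.05, 0.90 - d, size=nl)
    diseased[hypo_idx] = post[hypo_idx] + d

    n_carriers = int(round(config.consensus_carrier_fraction * n))
    carriers = np.zeros((nh + nl, n), dtype=bool)
    for row in range(nh + nl):
        carriers[row, rng.choice(n, size=n_carriers, replace=False)] = True

    # per-patient T1 means: diseased at planted sites for carriers, else post
    t1_means = np.tile(post[:, None], (1, n))
    for row, probe in enumerate(planted_idx):
        t1_means[probe, carriers[row]] = diseased[probe]

    t1 = _beta_around(rng, t1_means, config.noise_sd)
    t2 = _beta_around(rng, np.tile(post[:, None], (1, n)), config.noise_sd)
    t3 = _beta_around(rng, np.tile(post[:, None], (1, n)), config.noise_sd)
    hb = _beta_around(
        rng, np.tile(post[:, None], (1, config.n_healthy_blood)), config.noise_sd
    )

    columns: list[str] = []
    rows_sheet: list[dict] = []
    blocks: list[np.ndarray] = []
    for tp, block in (("T1", t1), ("T2", t2), ("T3", t3)):
        for j, pid in enumerate(patient_ids):
            columns.append(f"{pid}_{tp}")
            rows_sheet.append(
                dict(sample_id=f"{pid}_{tp}", patient_id=pid, timepoint=tp,
                     group="study", tissue="blood", fibrosis_grade=np.nan)
            )
        blocks.append(block)
    for j in range(config.n_healthy_blood):
        columns.append(f"HB{j + 1:02d}")
        rows_sheet.append(
            dict(sample_id=f"HB{j + 1:02d}", patient_id=f"HB{j + 1:02d}",
                 timepoint=np.nan, group="healthy_blood", tissue="blood",
                 fibrosis_grade=np.nan)
        )
    blocks.append(hb)

    betas = pd.DataFrame(np.hstack(blocks), index=probe_ids, columns=columns)
    sheet = pd.DataFrame(rows_sheet)

    manifest = _simulate_manifest(rng, config, probe_ids, planted_idx)

    truth = GroundTruth(
        planted_hyper=probe_ids[hyper_idx],
        planted_hypo=probe_ids[hypo_idx],
        carriers=pd.DataFrame(
            carriers, index=probe_ids[planted_idx], columns=patient_ids
        ),
        post_means=pd.Series(post, index=probe_ids),
        diseased_means=pd.Series(diseased, index=probe_ids),
    )
    return betas, sheet, manifest, truth


def _simulate_manifest(
    rng: np.random.Generator,
    config: SimulationConfig,
    probe_ids: pd.Index,
    planted_idx: np.ndarray,
) -> pd.DataFrame:
    p = len(probe_ids)
    probs = {**DEFAULT_FEATURE_PROBS, **(config.feature_probs or {})}
    cols = {}
    for axis in ("gene_region", "cgi_relation", "regulatory_feature"):
        cats = _draw_categories(rng, axis, p, probs[axis])
        bias = (config.planted_feature_bias or {}).get(axis)
        if bias is not None and len(planted_idx):
            cats[planted_idx] = _draw_categories(rng, axis, len(planted_idx), bias)
        cols[axis] = cats
    chromosome = rng.choice([f"chr{i}" for i in range(1, 23)], size=p)
    # ~3 probes per gene on average; intergenic probes carry no gene
    gene_pool = np.array([f"G{i:05d}" for i in range(max(p // 3, 1))], dtype=object)
    gene_id = rng.choice(gene_pool, size=p)
    gene_id = np.where(cols["gene_region"] == "intergenic", np.nan, gene_id)
    manifest = pd.DataFrame(
        {
            "chromosome": chromosome,
            "gene_id": gene_id,
            "gene_region": cols["gene_region"],
            "cgi_relation": cols["cgi_relation"],
            "regulatory_feature": cols["regulatory_feature"],
        },
        index=probe_ids,
    )
    return manifest


def simulate_liver_panel(config: SimulationConfig, truth: GroundTruth):
    """Generate fibrosis-graded liver profiles on the cohort's probe means.

    Grade-0 (and healthy-liver) profiles sit at the healthy post-diet mean;
    grade-g profiles are shifted g × grade_drift toward the diseased
    (baseline-like) mean at planted sites, capped at that mean.  Non-planted
    probes are identically distributed across grades.
    """
    if truth is None:
        raise ValueError("ground truth from simulate_cohort is required")
    rng = np.random.default_rng([config.seed, 1])
    post = truth.post_means.to_numpy()
    diseased = truth.diseased_means.to_numpy()
    probe_ids = truth.post_means.index

    columns: list[str] = []
    rows_sheet: list[dict] = []
    blocks: list[np.ndarray] = []
    for grade in sorted(config.n_liver_per_grade):
        n_g = config.n_liver_per_grade[grade]
        if n_g == 0:
            continue
        if config.delta_effect > 0:
            frac = min(grade * config.grade_drift, config.delta_effect) / config.delta_effect
        else:
            frac = 0.0
        means = post + frac * (diseased - post)
        blocks.append(_beta_around(rng, np.tile(means[:, None], (1, n_g)), config.noise_sd))
        for j in range(n_g):
            sid = f"LV{grade}_{j + 1:02d}"
            columns.append(sid)
            rows_sheet.append(
                dict(sample_id=sid, patient_id=sid, timepoint=np.nan,
                     group="nafld_liver", tissue="liver", fibrosis_grade=grade)
            )
    if config.n_healthy_liver:
        blocks.append(
            _beta_around(
                rng, np.tile(post[:, None], (1, config.n_healthy_liver)), config.noise_sd
            )
        )
        for j in range(config.n_healthy_liver):
            sid = f"HL{j + 1:02d}"
            columns.append(sid)
            rows_sheet.append(
                dict(sample_id=sid, patient_id=sid, timepoint=np.nan,
                     group="healthy_liver", tissue="liver", fibrosis_grade=np.nan)
            )
    betas = pd.DataFrame(np.hstack(blocks), index=probe_ids, columns=columns)
    return betas, pd.DataFrame(rows_sheet)


def write_cohort(config: SimulationConfig, outdir) -> None:
    """Emit the full synthetic study as TSVs: blood + liver matrices, sheets, manifest, truth ledger."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    betas, sheet, manifest, truth = simulate_cohort(config)
    liver_betas, liver_sheet = simulate_liver_panel(config, truth)
    write_beta_matrix(betas, outdir / "blood_betas.tsv")
    write_sample_sheet(sheet, outdir / "blood_samples.tsv")
    write_beta_matrix(liver_betas, outdir / "liver_betas.tsv")
    write_sample_sheet(liver_sheet, outdir / "liver_samples.tsv")
    write_manifest(manifest, outdir / "manifest.tsv")
    truth_rows = []
    for probe in truth.planted:
        direction = "hyper" if probe in set(truth.planted_hyper) else "hypo"
        flags = truth.carriers.loc[probe]
        truth_rows.append(
            {
                "probe_id": probe,
                "direction": direction,
                "carrier_patients": ";".join(flags.index[flags]),
            }
        )
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
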