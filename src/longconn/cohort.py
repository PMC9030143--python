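"""Synthetic longitudinal cohorts with group- and time-dependent connectivity.

The generator emulates the study design the pipeline targets: four diagnostic
groups (NC, sMCI, pMCI, AD), each subject scanned at baseline, 12 months and
24 months. Group structure enters through the covariance of a zero-mean
multivariate normal: a base random correlation matrix is shared by everyone,
and for affected groups a fixed subset of edges has its correlation shrunk
toward 0 — a static disease effect plus, for the progressive groups (pMCI,
AD), an extra shrinkage growing linearly with timepoint index, emulating the
degeneration of inter-regional coupling as disease advances. A Gaussian
generative model is used because Pearson correlation fully characterises
dependence there, so the functional-connectivity matrix is a sufficient
description of what differs between groups.

Each subject additionally carries a stable "connectome fingerprint" with two
components, both drawn once per subject and applied identically at all three
visits: an elementwise symmetric perturbation (``subject_noise_sd``) and a
global connectivity scale (``subject_scale_sd``) that multiplies every edge,
emulating between-subject differences in global signal amplitude. The global
scale is a classic confound: at a single visit a globally low-connectivity
healthy subject looks like a progressed patient. Cross-sectional classifiers
are limited by it; longitudinal models can cancel it against the subject's
own baseline, which is precisely the advantage the pipeline is designed to
measure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import TIMEPOINTS, FCMatrix, ROITimeSeries, write_series_tsv

GROUPS = ("NC", "sMCI", "pMCI", "AD")
PROGRESSIVE_GROUPS = ("pMCI", "AD")
AFFECTED_GROUPS = ("sMCI", "pMCI", "AD")

__all__ = [
    "GROUPS",
    "PROGRESSIVE_GROUPS",
    "CohortSpec",
    "GroundTruthTemplate",
    "Cohort",
    "build_templates",
    "simulate_cohort",
    "write_cohort",
    "project_to_correlation",
]


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort.

    Defaults are desk-scale: 20 regions, 130 frames (a 140-frame scan minus
    ten dropped leading frames), 50 subjects per group.
    """

    roi_count: int = 20
    frames_per_scan: int = 130
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NC": 50, "sMCI": 50, "pMCI": 50, "AD": 50})
    edge_effect: float = 0.25
    progression_rate: float = 0.1
    affected_edge_fraction: float = 0.3
    subject_noise_sd: float = 0.1
    subject_scale_sd: float = 0.0
    trajectory_only: bool = False
    frame_period: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.roi_count < 2:
            raise ValueError("roi_count must be >= 2")
        if self.frames_per_scan < 3:
            raise ValueError("frames_per_scan must be >= 3")
        if not self.group_sizes:
            raise ValueError("at least one group required")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n < 1:
                raise ValueError(f"group {g} must have >= 1 subject")
        for name in ("edge_effect", "progression_rate", "subject_noise_sd",
                     "subject_scale_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not (0 < self.affected_edge_fraction <= 1):
            raise ValueError("affected_edge_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruthTemplate:
    """Per (group, timepoint) generating correlation matrices plus the affected-edge set."""

    matrices: dict[tuple[str, str], np.ndarray]
    affected_edges: np.ndarray  # (k, 2) array of (i, j) index pairs, i < j

    def matrix(self, group: str, timepoint: str) -> np.ndarray:
        return self.matrices[(group, timepoint)]


@dataclass
class Cohort:
    spec: CohortSpec
    templates: GroundTruthTemplate
    manifest: pd.DataFrame  # subject_id, group, timepoint, (series_path after writing)
    series: dict[tuple[str, str], ROITimeSeries]  # (subject_id, timepoint) -> series

    def subjects(self) -> pd.DataFrame:
        """One row per subject: subject_id, group."""
        return (self.manifest[["subject_id", "group"]]
                .drop_duplicates().reset_index(drop=True))


def project_to_correlation(m: np.ndarray, min_eig: float = 1e-10) -> np.ndarray:
    """Nearest-ish valid correlation matrix: symmetrize, clip eigenvalues,
    renormalise to unit diagonal, clamp to [-1, 1]."""
    m = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(m)
    vals = np.clip(vals, min_eig, None)
    m = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    m = (m + m.T) / 2.0
    np.clip(m, -1.0, 1.0, out=m)
    np.fill_diagonal(m, 1.0)
    return m


def _base_correlation(r: int, rng: np.random.Generator, n_factors: int = 4,
                      shared_variance: float = 0.65) -> np.ndarray:
    """Random correlation matrix from a low-rank factor model.

    Resting-state FC is dominated by a handful of large-scale networks, so the
    base covariance is Lambda Lambda^T (a few random factors) plus independent
    noise, normalised to unit diagonal. With the defaults this yields mean
    absolute off-diagonal correlations around 0.2-0.25, the magnitude typical
    of ROI-level connectomes, leaving room for disease effects to shrink.
    """
    lam = rng.standard_normal((r, n_factors))
    cov = lam @ lam.T * (shared_variance / n_factors) + (1 - shared_variance) * np.eye(r)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    return project_to_correlation(corr)


def _shrink_amount(spec: CohortSpec, group: str, t_index: int) -> float:
    """Total shrinkage toward 0 applied to affected edges for (group, timepoint)."""
    if group == "NC":
        return 0.0
    static = 0.0 if spec.trajectory_only else spec.edge_effect
    if group in PROGRESSIVE_GROUPS:
        return static + t_index * spec.progression_rate
    return static


def build_templates(spec: CohortSpec) -> GroundTruthTemplate:
    """Generating correlation matrices for every (group, timepoint).

    Affected edges are one fixed random subset shared by all affected groups,
    so the static disease effect is common and group separation within the
    MCI pair is purely longitudinal.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.roi_count
    base = _base_correlation(r, rng)
    iu = np.column_stack(np.triu_indices(r, k=1))
    n_edges = iu.shape[0]
    k = max(1, int(round(spec.affected_edge_fraction * n_edges)))
    chosen = iu[rng.choice(n_edges, size=k, replace=False)]
    matrices: dict[tuple[str, str], np.ndarray] = {}
    for group in spec.group_sizes:
        for t_index, tp in enumerate(TIMEPOINTS):
            s = min(1.0, _shrink_amount(spec, group, t_index))
            m = base.copy()
            if s > 0:
                ii, jj = chosen[:, 0], chosen[:, 1]
                m[ii, jj] *= (1.0 - s)
                m[jj, ii] = m[ii, jj]
            matrices[(group, tp)] = project_to_correlation(m)
    return GroundTruthTemplate(matrices=matrices, affected_edges=chosen)


def _subject_perturbation(r: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric zero-diagonal jitter added to a subject's templates."""
    noise = rng.standard_normal((r, r)) * sd
    noise = (noise + noise.T) / 2.0
    np.fill_diagonal(noise, 0.0)
    return noise


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Draw every subject-timepoint ROI series from its generating template.

    Deterministic given ``spec.seed``: per-subject RNG streams are spawned
    from the spec seed so outputs are byte-identical across runs.
    """
    templates = build_templates(spec)
    # per-subject streams spawned from the spec seed; build_templates consumed
    # its own generator from the same seed independently
    ss = np.random.SeedSequence(spec.seed)
    rows = []
    series: dict[tuple[str, str], ROITimeSeries] = {}
    subject_streams = ss.spawn(sum(spec.group_sizes.values()))
    idx = 0
    for group in spec.group_sizes:
        for i in range(spec.group_sizes[group]):
            sid = f"{group}_{i:03d}"
            rng = np.random.default_rng(subject_streams[idx])
            idx += 1
            fingerprint = _subject_perturbation(spec.roi_count,
                                                spec.subject_noise_sd, rng)
            # stable per-subject global connectivity level (vigilance / global
            # signal amplitude): scales every edge, identically at all visits
            gscale = float(np.clip(rng.normal(0.0, spec.subject_scale_sd), -0.6, 0.6)) \
                if spec.subject_scale_sd > 0 else 0.0
            for tp in TIMEPOINTS:
                tpl = templates.matrix(group, tp)
                m = (1.0 - gscale) * tpl + fingerprint
                np.fill_diagonal(m, 1.0)
                sigma = project_to_correlation(m)
                chol = np.linalg.cholesky(
                    sigma + 1e-9 * np.eye(spec.roi_count))
                z = rng.standard_normal((spec.frames_per_scan, spec.roi_count))
                x = z @ chol.T
                series[(sid, tp)] = ROITimeSeries(
                    x, frame_period=spec.frame_period, subject_id=sid, timepoint=tp)
                rows.append({"subject_id": sid, "group": group, "timepoint": tp})
    manifest = pd.DataFrame(rows)
    return Cohort(spec=spec, templates=templates, manifest=manifest, series=series)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write series TSVs, a manifest TSV and a JSON sidecar of the spec."""
    out_dir = Path(out_dir)
    series_dir = out_dir / "series"
    series_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for _, row in cohort.manifest.iterrows():
        key = (row["subject_id"], row["timepoint"])
        rel = f"series/{row['subject_id']}_{row['timepoint']}.tsv"
        write_series_tsv(cohort.series[key], out_dir / rel)
        paths.append(rel)
    manifest = cohort.manifest.copy()
    manifest["series_path"] = paths
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    with open(out_dir / "cohort_spec.json", "w") as fh:
        json.dump(cohort.spec.to_dict(), fh, indent=2, sort_keys=True)
    return out_dir / "manifest.tsv"


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Rebuild an in-memory cohort from a written manifest."""
    from .connectome import read_series_tsv

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    spec_path = root / "cohort_spec.json"
    if spec_path.exists():
        with open(spec_path) as fh:
            spec = CohortSpec(**json.load(fh))
    else:
        warnings.warn("cohort_spec.json missing; using default CohortSpec fields")
        spec = CohortSpec()
    series = {}
    for _, row in manifest.iterrows():
        series[(row["subject_id"], row["timepoint"])] = read_series_tsv(
            root / row["series_path"], subject_id=row["subject_id"],
            timepoint=row["timepoint"])
    templates = build_templates(spec)
    return Cohort(spec=spec, templates=templates,
                  manifest=manifest[["subject_id", "group", "timepoint"]],
                  series=series)
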