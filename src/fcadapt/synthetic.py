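"""Synthetic multi-site, multi-class FC cohort generator with ground truth.

Emulates the structure of pooled multi-site autism cohorts: several
acquisition sites per domain, three diagnostic classes (control, autism,
and Asperger's with a mean intermediate between the other two), per-site
additive and multiplicative feature effects (the location/scale shift a
ComBat-style harmonizer models), and connectivity values strictly inside
(-1, 1).

All effects — class mean shifts, site offsets/scalings, subject noise —
are composed in Fisher-z space and then mapped through tanh.  This keeps
features in (-1, 1) and makes the additive/multiplicative site-effect
model exactly correct in z-space, so a harmonizer has a recoverable
ground truth.  Time-series mode instead draws each subject's regional
series from a zero-mean multivariate normal whose correlation matrix is
the subject's ground-truth FC matrix, so the full extraction pipeline
can be exercised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import CohortManifest, SubjectRecord
from .features import devectorize, inverse_fisher_z, n_features_for_rois

__all__ = [
    "SiteSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "inject_site_effects",
    "simulate_timeseries",
    "hide_diagnosis",
    "default_sites",
]

CLASS_ORDER = ("control", "autism", "asperger")


@dataclass(frozen=True)
class SiteSpec:
    """One acquisition site: id, domain membership, per-class counts."""

    site_id: str
    domain: str
    n_per_class: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_class.values())


def default_sites(
    n_sites_per_domain: int = 3, n_per_class: int = 20,
    domains: tuple[str, ...] = ("source", "target"),
) -> list[SiteSpec]:
    """Balanced default: 3 sites per domain, 20 subjects/class/site."""
    sites = []
    for dom in domains:
        for s in range(n_sites_per_domain):
            sites.append(
                SiteSpec(
                    site_id=f"{dom}_site{s}",
                    domain=dom,
                    n_per_class={c: n_per_class for c in CLASS_ORDER},
                )
            )
    return sites


@dataclass
class SimulationConfig:
    """Knobs of the cohort simulator (all effect sizes in Fisher-z units).

    class_effect is the autism-vs-control mean shift on the affected
    features; Asperger's sits halfway (a mapping per class may be given
    instead).  site_additive_sd scales per-site per-feature offsets
    (gamma), site_scale_range bounds per-site multiplicative factors
    (delta); both default to magnitudes comparable to the class effect,
    reflecting the regime where site variance rivals group differences.
    """

    n_rois: int = 30
    sites: list[SiteSpec] = field(default_factory=default_sites)
    class_effect: float | dict = 0.3
    n_affected: int = 40
    site_additive_sd: float = 0.3
    site_scale_range: tuple[float, float] = (0.7, 1.4)
    subject_noise_sd: float = 0.25
    baseline_sd: float = 0.3
    mode: str = "fc"
    t_points: int = 200
    seed: int = 0

    def __post_init__(self):
        nf = n_features_for_rois(self.n_rois)
        if self.n_affected > nf:
            raise ValueError(f"n_affected={self.n_affected} exceeds {nf} features")
        lo, hi = self.site_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("site_scale_range must be a positive interval")
        if self.mode not in ("fc", "timeseries"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if sum(s.n_subjects for s in self.sites) == 0:
            raise ValueError("zero total subjects")
        for s in self.sites:
            if any(v < 0 for v in s.n_per_class.values()):
                raise ValueError("negative subject count")

    @property
    def n_features(self) -> int:
        return n_features_for_rois(self.n_rois)

    def class_shifts(self) -> dict:
        if isinstance(self.class_effect, dict):
            return dict(self.class_effect)
        e = float(self.class_effect)
        # Asperger intermediate between control (0) and autism (e)
        return {"control": 0.0, "asperger": e / 2.0, "autism": e}


@dataclass
class GroundTruth:
    """The simulated truth: class means, affected set, site effects (z-space)."""

    class_means: dict            # class -> (n_features,) Fisher-z mean vector
    affected_features: np.ndarray
    site_params: dict            # site -> {"gamma": vec, "delta": vec}


def _draw_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    nf = config.n_features
    baseline = rng.normal(0.0, config.baseline_sd, size=nf)
    affected = np.sort(rng.choice(nf, size=config.n_affected, replace=False))
    shifts = config.class_shifts()
    class_means = {}
    for c in CLASS_ORDER:
        mu = baseline.copy()
        mu[affected] += shifts.get(c, 0.0)
        class_means[c] = mu
    lo, hi = config.site_scale_range
    site_params = {}
    for site in config.sites:
        gamma = rng.normal(0.0, config.site_additive_sd, size=nf)
        delta = rng.uniform(lo, hi, size=nf)
        site_params[site.site_id] = {"gamma": gamma, "delta": delta}
    return GroundTruth(class_means, affected, site_params)


def _subject_rows(config: SimulationConfig):
    for site in config.sites:
        for c in CLASS_ORDER:
            for i in range(site.n_per_class.get(c, 0)):
                yield site, c, i


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[np.ndarray, CohortManifest, GroundTruth]:
    """Simulate per-subject FC feature vectors for a multi-site cohort.

    Returns (features, manifest, truth) where features is
    subjects x n_features with entries strictly in (-1, 1), row order
    matching the manifest.  Byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    rows, records = [], []
    assignment = []
    for site, c, i in _subject_rows(config):
        z = truth.class_means[c] + rng.normal(0.0, config.subject_noise_sd, config.n_features)
        rows.append(z)
        assignment.append(site.site_id)
        records.append(
            SubjectRecord(
                subject_id=f"{site.site_id}_{c}_{i:03d}",
                site=site.site_id,
                domain=site.domain,
                diagnosis=c,
            )
        )
    z_matrix = np.asarray(rows)
    z_matrix = inject_site_effects(z_matrix, truth.site_params, assignment)
    features = inverse_fisher_z(z_matrix)
    manifest = CohortManifest(records, provenance=f"simulated seed={config.seed}")
    return features, manifest, truth


def inject_site_effects(
    features_z: np.ndarray, site_params: dict, site_assignment
) -> np.ndarray:
    """Apply the per-site affine map out = delta*in + gamma in z-space."""
    features_z = np.asarray(features_z, dtype=np.float64)
    out = np.empty_like(features_z)
    for s, site_id in enumerate(site_assignment):
        if site_id not in site_params:
            raise KeyError(f"unknown site id {site_id!r}")
        p = site_params[site_id]
        out[s] = p["delta"] * features_z[s] + p["gamma"]
    return out


def _nearest_correlation(c: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Repair a non-PD target correlation by eigenvalue clipping."""
    w, v = np.linalg.eigh(c)
    if w.min() > eig_floor:
        return c
    warnings.warn(
        f"target correlation not positive definite (min eig {w.min():.2e}); "
        "applying eigenvalue-clipping repair",
        RuntimeWarning,
        stacklevel=3,
    )
    w = np.clip(w, eig_floor, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def simulate_timeseries(
    config: SimulationConfig,
) -> tuple[list[np.ndarray], CohortManifest, GroundTruth]:
    """Simulate per-subject T x R regional time series.

    Each subject's series is multivariate normal with zero mean and
    correlation equal to the subject's ground-truth FC matrix (after a
    positive-definiteness repair where needed), so recomputing Pearson
    correlations recovers the truth up to sampling error ~1/sqrt(T).
    """
    if config.mode != "timeseries":
        raise ValueError("config.mode must be 'timeseries'")
    if config.t_points < 2:
        raise ValueError("t_points must be >= 2")
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    series, records = [], []
    for site, c, i in _subject_rows(config):
        z = truth.class_means[c] + rng.normal(0.0, config.subject_noise_sd, config.n_features)
        p = truth.site_params[site.site_id]
        z = p["delta"] * z + p["gamma"]
        corr = devectorize(inverse_fisher_z(z), config.n_rois)
        corr = _nearest_correlation(corr)
        chol = np.linalg.cholesky(corr)
        ts = rng.standard_normal((config.t_points, config.n_rois)) @ chol.T
        series.append(ts)
        records.append(
            SubjectRecord(
                subject_id=f"{site.site_id}_{c}_{i:03d}",
                site=site.site_id,
                domain=site.domain,
                diagnosis=c,
            )
        )
    manifest = CohortManifest(records, provenance=f"simulated-ts seed={config.seed}")
    return series, manifest, truth


def hide_diagnosis(manifest: CohortManifest) -> CohortManifest:
    """Return a copy with every diagnosis replaced by "unknown".

    Used to strip target-domain labels before semi-supervised training;
    the original manifest is retained separately for evaluation only.
    """
    return CohortManifest(
        [
            SubjectRecord(r.subject_id, r.site, r.domain, "unknown", r.age, r.sex)
            for r in manifest.records
        ],
        provenance=manifest.provenance + ":unlabeled",
    )


def write_simulation(outdir, features, manifest, truth) -> None:
    """Write features (TSV), manifest (TSV) and ground truth (JSON)."""
    import json
    from pathlib import Path

    import pandas as pd

    from .datasets import write_manifest

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(features)
    df.insert(0, "subject_id", manifest.subject_ids)
    df.to_csv(outdir / "features.tsv", sep="\t", index=False)
    write_manifest(manifest, outdir / "manifest.tsv")
    payload = {
        "class_means": {c: m.tolist() for c, m in truth.class_means.items()},
        "affected_features": truth.affected_features.tolist(),
        "site_params": {
            s: {"gamma": p["gamma"].tolist(), "delta": p["delta"].tolist()}
            for s, p in truth.site_params.items()
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(payload))
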