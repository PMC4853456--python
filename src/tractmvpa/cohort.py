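"""Synthetic DTI cohort generation on a tract skeleton.

Generates per-subject voxelwise diffusion-tensor metrics (FA, MD, AD, RD)
on a :class:`~tractmvpa.skeletons.TractSkeleton`, with a group-effect
field that is positive at the frontal end of the tract and negative at
the temporal end of mean diffusivity, spatially smooth within-subject
noise, SART behavioural outcomes and questionnaire scores.  All
quantities derive from the tensor eigenvalues, so the identities

    AD = lambda1,  RD = (lambda2 + lambda3) / 2,  MD = (AD + 2 RD) / 3

hold to machine precision for every generated voxel, and FA is computed
from the eigenvalue triple by the standard tensor formula

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||.

Group coding follows the two-group convention used throughout the
package: +1 for the "athlete" (exposed) group, -1 for controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .sart import ResponseModel, SARTSchedule, make_sart_schedule, simulate_sart
from .skeletons import TractSkeleton, make_skeleton

__all__ = [
    "SubjectRecord", "EffectSpec", "NoiseSpec", "CohortDataset",
    "fa_from_eigenvalues", "simulate_dti_cohort", "simulate_behaviour_scores",
    "simulate_roi_timecourses", "make_default_cohort",
]

METRICS = ("FA", "MD", "AD", "RD")

# conventional healthy white-matter skeleton magnitudes (mm^2/s); these
# are standard textbook values, used as generator baselines
DEFAULT_AD = 1.2e-3
DEFAULT_RD = 0.55e-3


@dataclass
class SubjectRecord:
    id: str
    group: int                  # +1 athlete, -1 control
    age: float                  # years
    rt_mean: float = np.nan     # ms
    errors: int = 0             # commission errors, 0..n_no_go
    aggression: float = np.nan
    mania: float = np.nan

    def __post_init__(self):
        if self.group not in (-1, 1):
            raise ValueError("group must be +1 (athlete) or -1 (control)")


@dataclass(frozen=True)
class EffectSpec:
    """Implanted group-difference field.

    The expected athlete-minus-control difference in ``metric`` at arc
    position t is ``amplitude * w(t)`` with
    ``w(t) = exp(-(t/taper)^2) - exp(-((1-t)/taper)^2)``:
    +amplitude at the frontal-end centre (t=0), -amplitude at the
    temporal-end centre (t=1), tapering to zero mid-tract.
    """
    metric: str = "MD"
    amplitude: float = 0.0      # mm^2/s
    taper: float = 0.2

    def weights(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-(t / self.taper) ** 2) - np.exp(-((1.0 - t) / self.taper) ** 2)


@dataclass(frozen=True)
class NoiseSpec:
    """Between-subject variability of the diffusivity fields (mm^2/s).

    subject_sd: global per-subject offset shared by all voxels;
    voxel_sd: spatially smooth per-voxel field (exponential-kernel
    Gaussian random field with the given decay length in voxels);
    iid_sd: unsmoothed per-voxel noise.
    """
    subject_sd: float = 2.5e-5
    voxel_sd: float = 2.5e-5
    iid_sd: float = 5e-6
    decay_length: float = 5.0

    @property
    def total_voxel_sd(self) -> float:
        """Per-voxel between-subject SD implied by the model."""
        return float(np.sqrt(self.subject_sd ** 2 + self.voxel_sd ** 2
                             + self.iid_sd ** 2))


@dataclass
class CohortDataset:
    """Subjects, their voxel feature matrices and generation metadata."""
    skeleton: TractSkeleton
    subjects: list
    features: dict              # metric -> (n_subjects, V) array
    effect: EffectSpec
    noise: NoiseSpec
    seed: int
    schedule: SARTSchedule | None = None

    def __post_init__(self):
        n, v = len(self.subjects), self.skeleton.n_voxels
        for m, mat in self.features.items():
            if mat.shape != (n, v):
                raise ValueError(f"feature matrix {m} has shape {mat.shape}, "
                                 f"expected {(n, v)}")

    @property
    def y(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects], dtype=float)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def metric(self, name: str) -> np.ndarray:
        if name not in self.features:
            raise KeyError(f"unknown metric {name!r}; have {sorted(self.features)}")
        return self.features[name]

    def subject_summary(self, metric: str) -> np.ndarray:
        """Per-subject tract mean of a metric."""
        return self.metric(metric).mean(axis=1)

    def table(self):
        import pandas as pd
        return pd.DataFrame(
            [{"id": s.id, "group": s.group, "age": s.age, "rt_mean": s.rt_mean,
              "errors": s.errors, "aggression": s.aggression, "mania": s.mania}
             for s in self.subjects])


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy from the tensor eigenvalue triple."""
    l1, l2, l3 = np.broadcast_arrays(l1, l2, l3)
    mean = (l1 + l2 + l3) / 3.0
    num = (l1 - mean) ** 2 + (l2 - mean) ** 2 + (l3 - mean) ** 2
    den = l1 ** 2 + l2 ** 2 + l3 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(num / np.where(den > 0, den, 1.0))
    return np.where(den > 0, fa, 0.0)


def _subject_rng(seed: int, subject_index: int, stream: int = 0):
    """Counter-based per-subject stream: independent of cohort size."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream, subject_index)))


def _smooth_field_factory(skeleton: TractSkeleton, decay_length: float):
    """Cholesky factor of the exponential-kernel field covariance."""
    d = cdist(skeleton.voxel_coords, skeleton.voxel_coords)
    cov = np.exp(-d / max(decay_length, 1e-9))
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov)


def simulate_dti_cohort(skeleton: TractSkeleton, n_pos: int = 19, n_neg: int = 17,
                        effect: EffectSpec | None = None,
                        noise: NoiseSpec | None = None,
                        behaviour: bool = True,
                        seed: int = 0) -> CohortDataset:
    """Simulate a two-group cohort of voxelwise DTI metrics.

    Athletes (+1, first ``n_pos`` subjects) and controls (-1) share
    baseline diffusivities; the athlete group additionally receives the
    ``effect`` field on the named metric.  When ``behaviour`` is true,
    SART outcomes and questionnaire scores with group differences in the
    study's direction (athletes faster, more errors, higher
    aggression/mania) are attached.
    """
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 subjects per group")
    effect = effect or EffectSpec()
    noise = noise or NoiseSpec()
    if not np.isfinite(effect.amplitude):
        raise ValueError("effect amplitude must be finite")
    if min(noise.subject_sd, noise.voxel_sd, noise.iid_sd) < 0 or \
            noise.total_voxel_sd <= 0:
        raise ValueError("noise SDs must be non-negative and not all zero")
    if effect.metric not in METRICS:
        raise ValueError(f"effect metric must be one of {METRICS}")
    # guard against negative diffusivities at the stated noise level
    margin = abs(effect.amplitude) + 6.0 * noise.total_voxel_sd
    if DEFAULT_RD - margin <= 0 or DEFAULT_AD - margin <= 0:
        raise ValueError("effect amplitude/noise would produce negative "
                         "diffusivities at the configured baselines")

    V = skeleton.n_voxels
    n = n_pos + n_neg
    chol = _smooth_field_factory(skeleton, noise.decay_length)
    w = effect.weights(skeleton.arc_position)

    # per-eigenvalue shift implementing the effect on the named metric:
    # MD -> equal shift of all eigenvalues; AD -> lambda1 only;
    # RD -> lambda2/lambda3 only; FA effects are implemented by moving
    # lambda1 up and lambda2/3 down in a trace-preserving way
    def eig_shift(delta):
        if effect.metric == "MD":
            return delta, delta
        if effect.metric == "AD":
            return delta, np.zeros_like(delta)
        if effect.metric == "RD":
            return np.zeros_like(delta), delta
        return delta, -delta / 2.0  # FA-like, trace-preserving

    l1 = np.empty((n, V))
    l23 = np.empty((n, V))
    groups = np.r_[np.ones(n_pos, int), -np.ones(n_neg, int)]
    for i in range(n):
        rng = _subject_rng(seed, i)
        off_ad, off_rd = rng.normal(0.0, noise.subject_sd, size=2)
        f_ad = chol @ rng.normal(size=V) * noise.voxel_sd
        f_rd = chol @ rng.normal(size=V) * noise.voxel_sd
        e_ad = rng.normal(0.0, noise.iid_sd, size=V)
        e_rd = rng.normal(0.0, noise.iid_sd, size=V)
        ad = DEFAULT_AD + off_ad + f_ad + e_ad
        rd = DEFAULT_RD + off_rd + f_rd + e_rd
        if groups[i] > 0:
            d1, d23 = eig_shift(effect.amplitude * w)
            ad = ad + d1
            rd = rd + d23
        # enforce eigenvalue admissibility exactly
        rd = np.maximum(rd, 0.0)
        ad = np.maximum(ad, rd)
        l1[i] = ad
        l23[i] = rd

    features = {
        "AD": l1,
        "RD": l23.copy(),
        "MD": (l1 + 2.0 * l23) / 3.0,
        "FA": fa_from_eigenvalues(l1, l23, l23),
    }

    ages = {1: (50.0, 12.0), -1: (46.0, 10.0)}
    subjects = []
    schedule = make_sart_schedule(seed=seed) if behaviour else None
    for i in range(n):
        g = int(groups[i])
        rng = _subject_rng(seed, i, stream=1)
        mu, sd = ages[g]
        age = float(np.clip(rng.normal(mu, sd), 25.0, 80.0))
        rec = SubjectRecord(id=f"sub-{i + 1:03d}", group=g, age=age)
        if behaviour:
            rt_mu = rng.normal(340.0 if g > 0 else 400.0, 35.0)
            logit = np.log(0.55 / 0.45) if g > 0 else np.log(0.30 / 0.70)
            p_err = 1.0 / (1.0 + np.exp(-(rng.normal(logit, 0.5))))
            model = ResponseModel(rt_mean_ms=rt_mu, rt_sd_ms=60.0,
                                  commission_p=float(p_err), omission_p=0.02)
            out = simulate_sart(schedule, model,
                                seed=int(rng.integers(0, 2 ** 31 - 1)))
            rec.rt_mean = out.rt_mean
            rec.errors = out.errors
            rec.aggression = float(rng.normal(58.0 if g > 0 else 48.0, 7.0))
            rec.mania = float(rng.normal(56.0 if g > 0 else 47.0, 7.0))
        subjects.append(rec)

    return CohortDataset(skeleton=skeleton, subjects=subjects, features=features,
                         effect=effect, noise=noise, seed=seed, schedule=schedule)


def simulate_behaviour_scores(cohort: CohortDataset, summary_metric: str = "AD",
                              targets: dict | None = None,
                              within_group: int | None = 1,
                              score_params: dict | None = None,
                              seed: int = 0) -> CohortDataset:
    """Regenerate questionnaire scores correlated with a tract summary.

    Each named score is redrawn from a linear-Gaussian model whose
    population correlation with the per-subject tract mean of
    ``summary_metric`` equals the requested target, within the group
    selected by ``within_group`` (+1/-1) or across the whole cohort
    (``None``).  Subjects outside the selected group keep an independent
    draw around their group mean.
    """
    targets = targets if targets is not None else {"aggression": -0.543, "mania": -0.50}
    defaults = {"aggression": {1: (58.0, 7.0), -1: (48.0, 7.0)},
                "mania": {1: (56.0, 7.0), -1: (47.0, 7.0)}}
    score_params = score_params or defaults
    for name, r in targets.items():
        if not abs(r) < 1:
            raise ValueError(f"|target_corr| must be < 1, got {r} for {name!r}")
    summary = cohort.subject_summary(summary_metric)
    groups = cohort.y
    sel = np.ones(len(groups), bool) if within_group is None else groups == within_group
    if summary[sel].std() == 0:
        raise ValueError("tract summary is constant across subjects; "
                         "cannot implant a correlation")
    z = np.zeros(len(groups))
    z[sel] = (summary[sel] - summary[sel].mean()) / summary[sel].std()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    subjects = [replace_subject(s) for s in cohort.subjects]
    for name, r in targets.items():
        eps = rng.normal(size=len(groups))
        latent = np.where(sel, r * z + np.sqrt(1 - r ** 2) * eps, eps)
        for i, s in enumerate(subjects):
            mu, sd = score_params[name][int(groups[i])]
            setattr(s, name, float(mu + sd * latent[i]))
    return CohortDataset(skeleton=cohort.skeleton, subjects=subjects,
                         features=cohort.features, effect=cohort.effect,
                         noise=cohort.noise, seed=cohort.seed,
                         schedule=cohort.schedule)


def replace_subject(s: SubjectRecord) -> SubjectRecord:
    return SubjectRecord(id=s.id, group=s.group, age=s.age, rt_mean=s.rt_mean,
                         errors=s.errors, aggression=s.aggression, mania=s.mania)


def simulate_roi_timecourses(n_timepoints: int = 150, tr: float = 2.0,
                             target_r: float = 0.7, seed: int = 0):
    """Bivariate Gaussian ROI time-course pair with population correlation
    ``target_r``.  150 default time points correspond to a ~5-minute scan
    at TR = 2 s with the first volumes discarded."""
    if n_timepoints < 3:
        raise ValueError("need at least 3 time points")
    if not abs(target_r) <= 1:
        raise ValueError("|target_r| must be <= 1")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n_timepoints)
    if abs(target_r) == 1.0:
        y = np.sign(target_r) * x
    else:
        y = target_r * x + np.sqrt(1 - target_r ** 2) * rng.normal(size=n_timepoints)
    return x, y


def make_default_cohort(seed: int = 0, n_voxels: int = 940,
                        amplitude_sd_ratio: float = 3.0,
                        hemisphere: str = "right") -> CohortDataset:
    """The package's default synthetic study: 19 athletes vs 17 controls
    on a ~940-voxel tract, MD effect amplitude ``amplitude_sd_ratio``
    times the per-voxel noise SD, behaviour attached, and questionnaire
    scores correlated with mean AD within the athlete group."""
    skeleton = make_skeleton(n_voxels=n_voxels, hemisphere=hemisphere, seed=seed)
    noise = NoiseSpec()
    effect = EffectSpec(metric="MD",
                        amplitude=amplitude_sd_ratio * noise.total_voxel_sd)
    cohort = simulate_dti_cohort(skeleton, n_pos=19, n_neg=17, effect=effect,
                                 noise=noise, behaviour=True, seed=seed)
    return simulate_behaviour_scores(cohort, summary_metric="AD",
                                     targets={"aggression": -0.543, "mania": -0.50},
                                     within_group=1, seed=seed)
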