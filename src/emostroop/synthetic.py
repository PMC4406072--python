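"""Synthetic multi-subject datasets with known ground truth.

No public data accompany the study design this package analyses, so every
downstream stage is exercised on simulated data whose statistical structure
matches the study conditions: two groups of 11 (FH+) and 7 (FH-) subjects,
148-trial counterbalanced congruent/incongruent sequences at TR = 2 s, ROI
time courses combining a vector-autoregressive (VAR) coupling process,
HRF-convolved condition effects, and AR(1) measurement noise, miniature 4D
volumes with blob-shaped group effects, and per-subject reaction-time
tables.

Directed coupling is calibrated from target Granger causality indices: for
a channel with target GCI g, the lag-1 coefficient is chosen by inverting
the large-sample relation GCI = ln(1 + c^2 var(source)/var(innovation)).
Per-subject GCIs are drawn from the configured group mean +/- sd, so the
simulated group summaries approximate the configured table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .task_design import (
    PAIR_TYPES,
    HrfSpec,
    TrialSequence,
    build_design_matrix,
    generate_trial_sequence,
)

__all__ = [
    "GROUP_POS",
    "GROUP_NEG",
    "ChannelTarget",
    "GroundTruth",
    "Subject",
    "RoiDataset",
    "BlobSpec",
    "simulate_roi_dataset",
    "simulate_volume_dataset",
    "simulate_reaction_times",
    "simulate_motion",
    "default_ground_truth",
    "default_rt_means",
    "default_rt_ses",
]

GROUP_POS = "FH+"
GROUP_NEG = "FH-"

DEFAULT_ROI_NAMES = (
    "ACC",
    "MFG",
    "SFG",
    "SMG",
    "IFG",
    "Insula",
    "Hippocampus",
    "Putamen",
    "Thalamus",
    "VTA",
)


@dataclass(frozen=True)
class ChannelTarget:
    """Target per-subject GCI distribution for one directed channel."""

    source: str
    target: str
    mediator: str | None  # joint-mode partner routed through this region
    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float


def _default_channel_targets() -> tuple[ChannelTarget, ...]:
    # group mean +/- sd of the per-subject GCI for each channel
    return (
        ChannelTarget("MFG", "SMG", None, 0.06, 0.04, 0.17, 0.05),
        ChannelTarget("IFG", "SMG", None, 0.07, 0.06, 0.19, 0.09),
        ChannelTarget("Insula", "ACC", None, 0.12, 0.11, 0.27, 0.11),
        ChannelTarget("IFG", "ACC", None, 0.0503, 0.0657, 0.2333, 0.1325),
        ChannelTarget("IFG", "Hippocampus", None, 0.04, 0.03, 0.05, 0.03),
        ChannelTarget("IFG", "Putamen", None, 0.06, 0.04, 0.08, 0.07),
        ChannelTarget("IFG", "VTA", None, 0.08, 0.04, 0.10, 0.06),
        ChannelTarget("Putamen", "IFG", "Thalamus", 0.38, 0.21, 0.44, 0.22),
        ChannelTarget("VTA", "IFG", "Thalamus", 0.59, 0.18, 0.62, 0.19),
    )


def _default_condition_betas() -> dict[str, dict[str, dict[str, float]]]:
    """Condition effect sizes (signal units) per group x ROI x condition.

    FH+ shows larger conflict-related responses (cI, iI elevated), FH- a
    flat profile, so cI-cC and I-C contrasts are positive for FH+ > FH-.
    """
    pos_profile = {"cC": 0.30, "iC": 0.35, "cI": 0.90, "iI": 0.70}
    neg_profile = {"cC": 0.30, "iC": 0.35, "cI": 0.45, "iI": 0.40}
    return {
        GROUP_POS: {roi: dict(pos_profile) for roi in DEFAULT_ROI_NAMES},
        GROUP_NEG: {roi: dict(neg_profile) for roi in DEFAULT_ROI_NAMES},
    }


@dataclass(frozen=True)
class GroundTruth:
    """Everything the ROI generator needs, and what tests assert against."""

    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES
    condition_betas: dict = field(default_factory=_default_condition_betas)
    channel_targets: tuple[ChannelTarget, ...] = field(
        default_factory=_default_channel_targets
    )
    self_lag: float = 0.3  # own lag-1 coefficient of every ROI
    innovation_sd: float = 1.0
    noise_sd: float = 0.3  # AR(1) measurement noise on top of the VAR
    ar1_rho: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.innovation_sd <= 0:
            raise ValueError("noise/innovation sd must be positive")
        if not -1 < self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in (-1, 1)")

    def coupling_matrix(self, group: str) -> np.ndarray:
        """Group-mean lag-1 coupling matrix implied by the channel targets."""
        mean_attr = "mean_pos" if group == GROUP_POS else "mean_neg"
        gcis = {
            i: getattr(ch, mean_attr) for i, ch in enumerate(self.channel_targets)
        }
        return _couplings_from_gcis(self, gcis)


def default_ground_truth(**overrides) -> GroundTruth:
    return replace(GroundTruth(), **overrides) if overrides else GroundTruth()


def _target_contributions(
    channels: list[tuple[ChannelTarget, float]], sigma_eff2: float
) -> dict[str, float]:
    """Per-source explained-variance contributions X_s for one target.

    For a target whose incoming channels have GCI targets g_i, the measured
    bivariate GCI of channel i is approximately
    ln((sigma^2 + S) / (sigma^2 + S - X_i)) with S the total incoming
    contribution, so X_i = (sigma^2 + S) * (1 - exp(-g_i)) and
    S = sigma^2 * Q / (1 - Q), Q = sum_i (1 - exp(-g_i)).

    Joint mediated channels that share a mediator give the mediator the
    dominant share (90%) of the smaller shared target, so the mediator
    carries the common signal and each co-source only its increment.
    """
    direct = [(ch, g) for ch, g in channels if ch.mediator is None]
    mediated = [(ch, g) for ch, g in channels if ch.mediator is not None]
    if direct and mediated:
        raise NotImplementedError(
            "mixing direct and mediated channels into one target is not "
            "supported by the coupling inversion"
        )
    qs = [-np.expm1(-max(g, 0.0)) for _, g in channels]
    if mediated:
        mediators = {ch.mediator for ch, _ in mediated}
        if len(mediators) != 1:
            raise NotImplementedError("multiple mediators into one target")
        q_med = 0.9 * min(qs)
        q_eff = sum(qs) - q_med * (len(qs) - 1) if len(qs) > 1 else qs[0]
    else:
        q_med = 0.0
        q_eff = sum(qs)
    if q_eff > 0.9:  # keep the implied coupling stationary and solvable
        scale = 0.9 / q_eff
        qs = [q * scale for q in qs]
        q_med *= scale
        q_eff = 0.9
    D = sigma_eff2 / (1.0 - q_eff)
    out: dict[str, float] = {}
    if mediated:
        mediator = mediated[0][0].mediator
        out[mediator] = D * q_med
        for (ch, _), q in zip(mediated, qs):
            out[ch.source] = out.get(ch.source, 0.0) + max(D * (q - q_med), 0.0)
    else:
        for (ch, _), q in zip(direct, qs):
            out[ch.source] = out.get(ch.source, 0.0) + D * q
    return out


def _couplings_from_gcis(
    truth: GroundTruth, gci_by_channel: dict[int, float]
) -> np.ndarray:
    """Invert GCI targets to a lag-1 coupling matrix A (target row, source col).

    Per target the multi-source system X_i = (sigma^2 + S)(1 - exp(-g_i)) is
    solved for each source's explained-variance contribution; coefficients
    follow from c = sqrt(X / var(source)), where source variances are the
    stationary VAR variances (discrete Lyapunov equation), found by
    fixed-point iteration since A depends on them.  Measurement noise is
    compensated to first order through an inflated effective innovation
    variance and an errors-in-variables factor on each source.
    """
    from scipy.linalg import solve_discrete_lyapunov

    names = list(truth.roi_names)
    R = len(names)
    sigma_e2 = truth.innovation_sd**2
    noise2 = truth.noise_sd**2
    sigma_eff2 = sigma_e2 + noise2 * (1.0 - truth.ar1_rho**2)

    by_target: dict[str, list[tuple[ChannelTarget, float]]] = {}
    for i, ch in enumerate(truth.channel_targets):
        by_target.setdefault(ch.target, []).append((ch, gci_by_channel[i]))
    contributions = {
        t: _target_contributions(chans, sigma_eff2)
        for t, chans in by_target.items()
    }

    def assemble(variances: np.ndarray) -> np.ndarray:
        A = np.eye(R) * truth.self_lag
        for target, contrib in contributions.items():
            ti = names.index(target)
            for source, X in contrib.items():
                si = names.index(source)
                v = variances[si]
                # errors-in-variables compensation for source noise
                A[ti, si] = np.sqrt(X / v) * (1.0 + noise2 / v)
        return A

    # damped fixed point: A depends on the stationary variances it induces;
    # early iterates may be transiently unstable, so clamp the radius for
    # the Lyapunov solve and verify stability of the converged matrix only
    variances = np.full(R, sigma_e2 / (1.0 - truth.self_lag**2))
    A = assemble(variances)
    for _ in range(60):
        A = assemble(variances)
        radius = float(np.max(np.abs(np.linalg.eigvals(A))))
        A_solve = A * (0.95 / radius) if radius >= 0.97 else A
        cov = solve_discrete_lyapunov(A_solve, sigma_e2 * np.eye(R))
        new_var = np.real(np.diag(cov))
        if np.max(np.abs(new_var - variances) / variances) < 1e-6:
            variances = new_var
            break
        variances = 0.5 * variances + 0.5 * new_var
    check_stable(A)
    return A


def check_stable(A: np.ndarray) -> None:
    eig = np.linalg.eigvals(A)
    radius = float(np.max(np.abs(eig)))
    if radius >= 1.0:
        worst = eig[np.argmax(np.abs(eig))]
        raise ValueError(
            f"unstable coupling: spectral radius {radius:.3f} >= 1 "
            f"(eigenvalue {worst:.3f})"
        )


def simulate_var(
    A: np.ndarray,
    n_time: int,
    rng: np.random.Generator,
    innovation_sd: float = 1.0,
    burn_in: int = 100,
) -> np.ndarray:
    """Simulate a stationary VAR process; returns (n_roi, n_time).

    ``A`` may be (R, R) for lag 1 or (p, R, R) for order p.  The first
    ``burn_in`` samples are discarded.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, R, _ = A.shape
    if p == 1:
        check_stable(A[0])
    else:
        # companion-form stability
        comp = np.zeros((p * R, p * R))
        comp[:R] = np.concatenate(list(A), axis=1)
        comp[R:, :-R] = np.eye((p - 1) * R)
        check_stable(comp)
    total = n_time + burn_in
    e = rng.normal(0.0, innovation_sd, size=(total, R))
    x = np.zeros((total, R))
    for t in range(total):
        acc = e[t].copy()
        for lag in range(1, p + 1):
            if t - lag >= 0:
                acc += A[lag - 1] @ x[t - lag]
        x[t] = acc
    return x[burn_in:].T


def ar1_noise(
    n: int, rho: float, sd: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """(size, n) AR(1) noise with stationary standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((size, n))
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    e = rng.normal(0.0, innov_sd, size=(size, n))
    x = np.empty((size, n))
    x[:, 0] = rng.normal(0.0, sd, size=size)
    for t in range(1, n):
        x[:, t] = rho * x[:, t - 1] + e[:, t]
    return x


def simulate_motion(
    n_scans: int, rng: np.random.Generator, amplitude: float = 0.05
) -> np.ndarray:
    """Six motion parameters as smoothed random walks of small amplitude."""
    walk = np.cumsum(rng.normal(0.0, amplitude, size=(n_scans, 6)), axis=0)
    return ndimage.gaussian_filter1d(walk, sigma=3.0, axis=0)


@dataclass
class Subject:
    subject_id: str
    group: str
    roi_series: np.ndarray  # (n_roi, n_time)
    trial_sequence: TrialSequence
    motion: np.ndarray  # (n_time, 6)


@dataclass
class RoiDataset:
    """Per-subject ROI time series with group labels."""

    subjects: list[Subject]
    roi_names: tuple[str, ...]
    tr_s: float

    def __post_init__(self):
        counts = {s.roi_series.shape for s in self.subjects}
        if len(counts) > 1:
            raise ValueError("subjects disagree on ROI/scan counts")
        if len({s.group for s in self.subjects}) != 2:
            raise ValueError("need exactly two group labels")

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for s in self.subjects:
            df = pd.DataFrame(s.roi_series.T, columns=list(self.roi_names))
            df.insert(0, "scan", np.arange(df.shape[0]))
            df.insert(0, "group", s.group)
            df.insert(0, "subject_id", s.subject_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _task_signal(
    seq: TrialSequence, n_scans: int, tr_s: float, hrf: HrfSpec | None
) -> dict[str, np.ndarray]:
    dm = build_design_matrix(seq, n_scans=n_scans, tr_s=tr_s, hrf=hrf)
    return {p: dm.column(p) for p in PAIR_TYPES}


def _simulate_subject_series(
    truth: GroundTruth,
    group: str,
    gcis: dict[int, float],
    rng: np.random.Generator,
    n_scans: int,
    tr_s: float,
    n_trials: int,
    burn_in: int,
) -> tuple[np.ndarray, TrialSequence]:
    """One subject's ROI series for given per-channel GCIs."""
    seq = generate_trial_sequence(n_trials=n_trials, seed=rng, stimulus_duration_s=1.0)
    signals = _task_signal(seq, n_scans, tr_s, None)
    A = _couplings_from_gcis(truth, gcis)
    series = simulate_var(
        A, n_scans, rng, innovation_sd=truth.innovation_sd, burn_in=burn_in
    )
    betas = truth.condition_betas[group]
    for i, roi in enumerate(truth.roi_names):
        for cond in PAIR_TYPES:
            series[i] += betas.get(roi, {}).get(cond, 0.0) * signals[cond]
    series += ar1_noise(
        n_scans, truth.ar1_rho, truth.noise_sd, rng, size=len(truth.roi_names)
    )
    return series, seq


def _measure_channel_gcis(
    truth: GroundTruth, series: np.ndarray
) -> dict[int, float]:
    from .granger import gci as gci_fn
    from .granger import mediated_gci

    names = list(truth.roi_names)
    out = {}
    for i, ch in enumerate(truth.channel_targets):
        tgt = series[names.index(ch.target)]
        src = series[names.index(ch.source)]
        if ch.mediator is None:
            out[i] = gci_fn(src, tgt).gci
        else:
            med = series[names.index(ch.mediator)]
            out[i] = mediated_gci(src, med, tgt, mode="joint").gci
    return out


_GAIN_CACHE: dict[str, dict[tuple[int, str], float]] = {}
_MAX_GAIN = 4.0


def _truth_cache_key(truth: GroundTruth, n_scans: int, tr_s: float, n_trials: int) -> str:
    return repr((truth, n_scans, tr_s, n_trials))


def calibrate_channel_gains(
    truth: GroundTruth,
    n_scans: int = 390,
    tr_s: float = 2.0,
    n_trials: int = 148,
    n_subjects: int = 12,
    n_iterations: int = 4,
    burn_in: int = 100,
) -> dict[tuple[int, str], float]:
    """Per-channel, per-group gain factors for the coupling inversion.

    The analytic inversion ignores attenuation by the target's own-lag
    absorption, the shared task signal and measurement noise, so measured
    GCIs fall short of their targets.  This routine simulates small cohorts
    at the group-mean GCIs, measures the shortfall per channel, and fits a
    multiplicative gain (capped to keep the coupling stationary) applied to
    the drawn GCIs.  Deterministic given the ground truth's own seed, and
    cached per configuration.
    """
    key = _truth_cache_key(truth, n_scans, tr_s, n_trials)
    if key in _GAIN_CACHE:
        return _GAIN_CACHE[key]
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, 0x5EED)))
    gains = {
        (i, grp): 1.0
        for i in range(len(truth.channel_targets))
        for grp in (GROUP_POS, GROUP_NEG)
    }
    for _ in range(n_iterations):
        for group in (GROUP_POS, GROUP_NEG):
            mean_attr = "mean_pos" if group == GROUP_POS else "mean_neg"
            targets = {
                i: getattr(ch, mean_attr)
                for i, ch in enumerate(truth.channel_targets)
            }
            gcis = {
                k: targets[k] * gains[(k, group)] for k in targets
            }
            measured = {k: [] for k in targets}
            for _ in range(n_subjects):
                series, _ = _simulate_subject_series(
                    truth, group, gcis, rng, n_scans, tr_s, n_trials, burn_in
                )
                for k, v in _measure_channel_gcis(truth, series).items():
                    measured[k].append(v)
            for k in targets:
                if targets[k] <= 0:
                    continue
                m = float(np.mean(measured[k]))
                if m <= 1e-4:
                    gains[(k, group)] = min(gains[(k, group)] * 2.0, _MAX_GAIN)
                else:
                    gains[(k, group)] = float(
                        np.clip(gains[(k, group)] * targets[k] / m, 0.2, _MAX_GAIN)
                    )
    _GAIN_CACHE[key] = gains
    return gains


def simulate_roi_dataset(
    truth: GroundTruth | None = None,
    n_per_group: tuple[int, int] = (11, 7),
    n_scans: int = 390,
    tr_s: float = 2.0,
    n_trials: int = 148,
    seed: int = 0,
    burn_in: int = 100,
    calibrate: bool = True,
) -> RoiDataset:
    """Simulate the full two-group ROI dataset.

    Each subject's ROI series is a VAR(1) coupling process (per-subject
    coupling inverted from GCIs drawn from the group's target distribution,
    with self-calibrated gains compensating measurement attenuation) plus
    HRF-convolved condition effects plus AR(1) measurement noise.
    Deterministic given ``seed``.
    """
    truth = truth or GroundTruth()
    if n_per_group[0] < 2 or n_per_group[1] < 2:
        raise ValueError("need >= 2 subjects per group")
    # validate group-mean coupling up front so bad configs fail loudly
    for g in (GROUP_POS, GROUP_NEG):
        check_stable(truth.coupling_matrix(g))
    if calibrate:
        gains = calibrate_channel_gains(truth, n_scans, tr_s, n_trials, burn_in=burn_in)
    else:
        gains = {
            (i, grp): 1.0
            for i in range(len(truth.channel_targets))
            for grp in (GROUP_POS, GROUP_NEG)
        }
    rng = np.random.default_rng(seed)
    subjects = []
    sid = 0
    for group, n_subj in ((GROUP_POS, n_per_group[0]), (GROUP_NEG, n_per_group[1])):
        for _ in range(n_subj):
            sid += 1
            gcis = {}
            for i, ch in enumerate(truth.channel_targets):
                mu, sd = (
                    (ch.mean_pos, ch.sd_pos)
                    if group == GROUP_POS
                    else (ch.mean_neg, ch.sd_neg)
                )
                g = max(rng.normal(mu, sd), 0.0)
                gcis[i] = g * gains[(i, group)]
            series, seq = _simulate_subject_series(
                truth, group, gcis, rng, n_scans, tr_s, n_trials, burn_in
            )
            motion = simulate_motion(n_scans, rng)
            subjects.append(
                Subject(
                    subject_id=f"sub-{sid:02d}",
                    group=group,
                    roi_series=series,
                    trial_sequence=seq,
                    motion=motion,
                )
            )
    return RoiDataset(subjects=subjects, roi_names=truth.roi_names, tr_s=tr_s)


@dataclass(frozen=True)
class BlobSpec:
    """A spherical activation blob with a group effect on one condition.

    Subject amplitude = group mean (amp_pos or amp_neg) + N(0, between_sd).
    """

    center: tuple[int, int, int]
    radius: float
    condition: str = "cI"
    amp_pos: float = 1.0
    amp_neg: float = 0.0
    between_sd: float = 0.25


@dataclass
class VolumeSubject:
    subject_id: str
    group: str
    data: np.ndarray  # (x, y, z, t)
    trial_sequence: TrialSequence


@dataclass
class VolumeDataset:
    subjects: list[VolumeSubject]
    shape: tuple[int, int, int]
    tr_s: float
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    blob_specs: tuple[BlobSpec, ...] = ()

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff

    def to_nifti(self, subject: VolumeSubject):
        import nibabel as nib

        return nib.Nifti1Image(subject.data.astype(np.float32), self.affine)

    def blob_mask(self, blob: BlobSpec) -> np.ndarray:
        grid = np.indices(self.shape).astype(float)
        d2 = sum((grid[i] - blob.center[i]) ** 2 for i in range(3))
        return d2 <= blob.radius**2


def simulate_volume_dataset(
    blob_specs: list[BlobSpec],
    shape: tuple[int, int, int] = (20, 20, 20),
    n_per_group: tuple[int, int] = (11, 7),
    n_scans: int = 120,
    tr_s: float = 2.0,
    n_trials: int = 48,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> VolumeDataset:
    """Miniature 4D volumes: background Gaussian noise + blob task signal.

    Each blob adds (subject amplitude) x (HRF-convolved regressor of its
    condition) inside a spherical mask; amplitudes differ by group, so
    second-level contrasts recover the blobs.  3 mm isotropic voxels.
    """
    ds = VolumeDataset(subjects=[], shape=tuple(shape), tr_s=tr_s,
                       blob_specs=tuple(blob_specs))
    for blob in blob_specs:
        c = blob.center
        if any(not 0 <= c[i] < shape[i] for i in range(3)):
            raise ValueError(f"blob center {c} outside grid {shape}")
        if any(
            c[i] - blob.radius < -0.5 or c[i] + blob.radius > shape[i] - 0.5
            for i in range(3)
        ):
            raise ValueError(f"blob at {c} radius {blob.radius} exceeds grid {shape}")
    rng = np.random.default_rng(seed)
    sid = 0
    masks = [ds.blob_mask(b) for b in blob_specs]
    for group, n_subj in ((GROUP_POS, n_per_group[0]), (GROUP_NEG, n_per_group[1])):
        for _ in range(n_subj):
            sid += 1
            seq = generate_trial_sequence(n_trials=n_trials, seed=rng)
            signals = _task_signal(seq, n_scans, tr_s, None)
            data = rng.normal(0.0, noise_sd, size=(*shape, n_scans))
            for blob, mask in zip(blob_specs, masks):
                amp_mean = blob.amp_pos if group == GROUP_POS else blob.amp_neg
                amp = amp_mean + rng.normal(0.0, blob.between_sd)
                data[mask] += amp * signals[blob.condition]
            ds.subjects.append(
                VolumeSubject(
                    subject_id=f"sub-{sid:02d}",
                    group=group,
                    data=data,
                    trial_sequence=seq,
                )
            )
    return ds


def default_rt_means() -> dict[str, dict[str, float]]:
    """Default per-condition mean RTs (ms) per group."""
    return {
        GROUP_POS: {"cC": 858.30, "iC": 900.18, "cI": 943.12, "iI": 963.91},
        GROUP_NEG: {"cC": 776.01, "iC": 781.04, "cI": 834.80, "iI": 822.33},
    }


def default_rt_ses() -> dict[str, dict[str, float]]:
    """Between-subject standard errors (ms) matching the default means."""
    return {
        GROUP_POS: {"cC": 67.05, "iC": 67.44, "cI": 68.67, "iI": 78.11},
        GROUP_NEG: {"cC": 10.96, "iC": 16.10, "cI": 15.59, "iI": 23.73},
    }


def simulate_reaction_times(
    group_means: dict[str, dict[str, float]] | None = None,
    group_ses: dict[str, dict[str, float]] | None = None,
    n_per_group: tuple[int, int] = (11, 7),
    n_trials_per_type: int = 37,
    adaptation_noise_ms: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject mean reaction times per pair type.

    Each subject has one general-speed offset shared by all four pair
    types, drawn with SD equal to the group's mean condition SE times
    sqrt(n_group) — so the between-subject SE of every condition mean
    reproduces the configured scale — plus independent condition-specific
    noise of SD ``min(adaptation_noise_ms, smallest condition SD)``.
    Keeping the condition-specific part small makes each group's conflict
    -adaptation pattern (the iI - cI sign) a stable characteristic of the
    group while leaving between-group condition comparisons dominated by
    the large general-speed variance.  Draws are truncated at zero.

    Columns: subject_id, group, pair_type, mean_rt_ms, n_trials.
    """
    means = group_means or default_rt_means()
    ses = group_ses or default_rt_ses()
    for g, table in means.items():
        missing = set(PAIR_TYPES) - set(table)
        if missing:
            raise ValueError(f"group {g} missing pair types {sorted(missing)}")
        if any(v <= 0 for v in table.values()):
            raise ValueError("mean RTs must be positive")
        if any(ses[g][p] < 0 for p in table):
            raise ValueError("SEs must be non-negative")
    rng = np.random.default_rng(seed)
    n_by_group = {GROUP_POS: n_per_group[0], GROUP_NEG: n_per_group[1]}
    rows = []
    sid = 0
    for group in (GROUP_POS, GROUP_NEG):
        n = n_by_group[group]
        subject_sd = float(np.mean([ses[group][p] for p in PAIR_TYPES])) * np.sqrt(n)
        cond_sds = {p: ses[group][p] * np.sqrt(n) for p in PAIR_TYPES}
        eps_sd = min(adaptation_noise_ms, min(cond_sds.values()))
        for _ in range(n):
            sid += 1
            offset = rng.normal(0.0, subject_sd)
            for p in PAIR_TYPES:
                rt = means[group][p] + offset + rng.normal(0.0, eps_sd)
                while rt <= 0:  # truncation at zero
                    offset_r = rng.normal(0.0, subject_sd)
                    rt = means[group][p] + offset_r + rng.normal(0.0, eps_sd)
                rows.append(
                    {
                        "subject_id": f"sub-{sid:02d}",
                        "group": group,
                        "pair_type": p,
                        "mean_rt_ms": float(rt),
                        "n_trials": n_trials_per_type,
                    }
                )
    return pd.DataFrame(rows)
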