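"""Group-level inference: two-sample t maps, Monte-Carlo cluster-extent
thresholds, cluster extraction and ROI summaries.

Family-wise error over voxels is controlled by cluster-extent correction:
an uncorrected voxelwise threshold (here p = 0.01 two-sided) is combined
with a minimum cluster extent k estimated by Monte-Carlo simulation of
smoothed Gaussian null volumes, following the approach of simulating the
null distribution of the maximum suprathreshold cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import StatResult

__all__ = [
    "ClusterThresholdSpec",
    "Cluster",
    "GroupSummary",
    "two_sample_t_map",
    "two_sample_t_from_summary",
    "two_sample_t_from_samples",
    "monte_carlo_cluster_threshold",
    "extract_clusters",
    "extract_roi_summary",
]


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")


@dataclass(frozen=True)
class ClusterThresholdSpec:
    """Monte-Carlo cluster-extent simulation parameters.

    Defaults mirror common practice for this design: voxelwise p = 0.01,
    family-wise alpha = 0.05, 8 mm FWHM smoothing on 3 mm voxels.
    """

    voxel_p: float = 0.01
    alpha_fw: float = 0.05
    fwhm_mm: float = 8.0
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_iterations: int = 1000
    connectivity: int = 18
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must be in (0, 1)")
        if not 0 < self.alpha_fw < 1:
            raise ValueError("alpha_fw must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        _connectivity_structure(self.connectivity)


@dataclass
class Cluster:
    """A suprathreshold connected component of a statistic map."""

    voxel_list: list[tuple[int, int, int]]
    peak_location: tuple[int, int, int]
    peak_t: float
    sign: int = 1
    peak_location_mm: tuple[float, float, float] | None = None

    @property
    def extent(self) -> int:
        return len(self.voxel_list)

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        idx = tuple(np.array(self.voxel_list).T)
        m[idx] = True
        return m


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and n of a quantity in two groups."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self):
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("sds must be >= 0")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")


def two_sample_t_from_summary(s: GroupSummary, welch: bool = False) -> StatResult:
    """Two-sample t-test from group means, SDs and sizes.

    Pooled-variance (Student) form by default:
    t = (m1 - m2) / sqrt(s_p^2 (1/n1 + 1/n2)),
    s_p^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2), df = n1 + n2 - 2.
    """
    if welch:
        t, p = stats.ttest_ind_from_stats(
            s.mean1, s.sd1, s.n1, s.mean2, s.sd2, s.n2, equal_var=False
        )
        v1, v2 = s.sd1**2 / s.n1, s.sd2**2 / s.n2
        df = (v1 + v2) ** 2 / (v1**2 / (s.n1 - 1) + v2**2 / (s.n2 - 1))
    else:
        t, p = stats.ttest_ind_from_stats(
            s.mean1, s.sd1, s.n1, s.mean2, s.sd2, s.n2, equal_var=True
        )
        df = s.n1 + s.n2 - 2
    return StatResult(
        estimate=s.mean1 - s.mean2,
        t_value=float(t),
        dof=float(df),
        p_two_sided=float(p),
    )


def two_sample_t_from_samples(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> StatResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return two_sample_t_from_summary(
        GroupSummary(
            float(a.mean()), float(a.std(ddof=1)), a.size,
            float(b.mean()), float(b.std(ddof=1)), b.size,
        ),
        welch=welch,
    )


def two_sample_t_map(maps_a: np.ndarray, maps_b: np.ndarray):
    """Voxelwise pooled-variance two-sample t between groups of maps.

    Parameters
    ----------
    maps_a, maps_b : arrays of shape (n_subjects, ...voxels...), identical
        voxel grids.

    Returns
    -------
    (t_map, dof) with dof = nA + nB - 2.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape[1:] != maps_b.shape[1:]:
        raise ValueError(
            f"voxel grids differ: {maps_a.shape[1:]} vs {maps_b.shape[1:]}"
        )
    na, nb = maps_a.shape[0], maps_b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 subjects per group")
    m1, m2 = maps_a.mean(axis=0), maps_b.mean(axis=0)
    v1 = maps_a.var(axis=0, ddof=1)
    v2 = maps_b.var(axis=0, ddof=1)
    dof = na + nb - 2
    sp2 = ((na - 1) * v1 + (nb - 1) * v2) / dof
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t, dof


def _fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm) -> tuple[float, ...]:
    factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    return tuple(fwhm_mm / factor / v for v in voxel_size_mm)


def simulate_max_extents(
    mask: np.ndarray, spec: ClusterThresholdSpec
) -> np.ndarray:
    """Null distribution of the maximum suprathreshold cluster extent.

    Each iteration fills the grid with unit Gaussian noise, smooths it with
    the spec's FWHM, re-standardises within the mask, thresholds |z| at the
    two-sided voxel_p critical value, and records the largest connected
    cluster inside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    import warnings

    sigmas = _fwhm_to_sigma_voxels(spec.fwhm_mm, spec.voxel_size_mm)
    if spec.fwhm_mm > 0 and spec.fwhm_mm < min(spec.voxel_size_mm):
        warnings.warn("FWHM below voxel size: essentially no smoothing")
    zcrit = stats.norm.isf(spec.voxel_p / 2.0)
    structure = _connectivity_structure(spec.connectivity)
    rng = np.random.default_rng(spec.seed)
    max_extents = np.zeros(spec.n_iterations, dtype=int)
    for i in range(spec.n_iterations):
        noise = rng.standard_normal(mask.shape)
        if spec.fwhm_mm > 0:
            noise = ndimage.gaussian_filter(noise, sigmas)
        vals = noise[mask]
        z = np.zeros_like(noise)
        z[mask] = (vals - vals.mean()) / vals.std()
        supra = (np.abs(z) > zcrit) & mask
        if supra.any():
            labels, n = ndimage.label(supra, structure=structure)
            if n:
                sizes = np.bincount(labels.ravel())[1:]
                max_extents[i] = int(sizes.max())
    return max_extents


def monte_carlo_cluster_threshold(
    mask: np.ndarray, spec: ClusterThresholdSpec
) -> int:
    """Cluster-extent threshold k controlling family-wise error.

    k is the smallest extent whose exceedance frequency across the simulated
    null volumes is <= alpha_fw.  Deterministic given ``spec.seed``.
    """
    max_extents = simulate_max_extents(mask, spec)
    # smallest k with P(max extent >= k) <= alpha
    for k in range(1, int(max_extents.max()) + 2):
        if np.mean(max_extents >= k) <= spec.alpha_fw:
            return k
    return int(max_extents.max()) + 1


def extract_clusters(
    stat_map: np.ndarray,
    voxel_p: float,
    dof: float,
    k: int = 1,
    connectivity: int = 18,
    affine: np.ndarray | None = None,
) -> list[Cluster]:
    """Suprathreshold clusters of a t map, both signs handled separately.

    Voxels with |t| above the two-sided critical value at ``voxel_p`` are
    grouped into connected components; components of extent >= k are
    returned, each with its peak voxel (max |t|).
    """
    stat_map = np.asarray(stat_map, dtype=float)
    tcrit = stats.t.isf(voxel_p / 2.0, dof)
    structure = _connectivity_structure(connectivity)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        supra = (sign * stat_map) > tcrit
        if not supra.any():
            continue
        labels, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            if len(vox) < k:
                continue
            ts = stat_map[tuple(vox.T)]
            peak_i = int(np.argmax(sign * ts))
            peak = tuple(int(c) for c in vox[peak_i])
            mm = None
            if affine is not None:
                mm = tuple(float(x) for x in (affine @ np.array([*peak, 1.0]))[:3])
            clusters.append(
                Cluster(
                    voxel_list=[tuple(int(c) for c in v) for v in vox],
                    peak_location=peak,
                    peak_t=float(ts[peak_i]),
                    sign=sign,
                    peak_location_mm=mm,
                )
            )
    clusters.sort(key=lambda c: -abs(c.peak_t))
    return clusters


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        mm = c.peak_location_mm or (np.nan, np.nan, np.nan)
        rows.append(
            {
                "peak_x": c.peak_location[0],
                "peak_y": c.peak_location[1],
                "peak_z": c.peak_location[2],
                "peak_x_mm": mm[0],
                "peak_y_mm": mm[1],
                "peak_z_mm": mm[2],
                "peak_t": c.peak_t,
                "extent": c.extent,
                "sign": c.sign,
            }
        )
    return pd.DataFrame(rows)


def extract_roi_summary(
    data: np.ndarray,
    cluster: Cluster,
    method: str = "mean",
) -> np.ndarray:
    """Summarise a cluster across its voxels for each subject (or time point).

    Parameters
    ----------
    data : (n_subjects, ...voxels...) contrast maps, or (n_time, ...voxels...)
        time series.
    method : "mean" averages over cluster voxels; "eigenvariate" projects
        onto the first principal direction of the rows x voxel matrix,
        sign-aligned to correlate positively with the cluster mean.

    Returns a vector of one scalar per row of ``data``.
    """
    if cluster.extent == 0:
        raise ValueError("empty cluster")
    data = np.asarray(data, dtype=float)
    idx = tuple(np.array(cluster.voxel_list).T)
    mat = data[(slice(None),) + idx]  # rows x voxels
    roi_mean = mat.mean(axis=1)
    if method == "mean":
        return roi_mean
    if method == "eigenvariate":
        centered = mat - mat.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        # scale so a spatially constant ROI reproduces its per-row value
        pc = u[:, 0] * s[0] / np.sqrt(mat.shape[1])
        if roi_mean.std() > 0 and np.dot(pc, roi_mean - roi_mean.mean()) < 0:
            pc = -pc
        return pc + roi_mean.mean()
    raise ValueError(f"method must be 'mean' or 'eigenvariate', got {method!r}")
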