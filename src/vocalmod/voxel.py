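"""Voxelwise covariate GLM with Monte-Carlo cluster-extent inference.

Per-speaker 3D contrast volumes are regressed voxel-by-voxel on a
covariate of interest plus nuisance covariates; the covariate t-map is
thresholded at an uncorrected voxel p, and cluster extents are compared
against a minimum size derived by Monte-Carlo simulation of smoothed
Gaussian noise.  Cluster peaks are reported in mm coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.measure import label as sk_label

logger = logging.getLogger(__name__)

#: Neighbourhood conventions: faces (6), faces+edges (18), faces+edges+corners (26).
CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


class VolumeConfigError(ValueError):
    pass


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian sigma in voxel units for a given FWHM in mm."""
    if fwhm_mm < 0:
        raise VolumeConfigError("fwhm must be non-negative")
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm


def smooth_volume(vol: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing; fwhm=0 returns the input unchanged."""
    sigma = fwhm_to_sigma(fwhm_mm, voxel_size_mm)
    if sigma == 0:
        return np.asarray(vol, dtype=float)
    return ndimage.gaussian_filter(np.asarray(vol, dtype=float), sigma=sigma)


@dataclass
class VolumeSet:
    """Stack of per-speaker 3D contrast volumes sharing one geometry."""

    data: np.ndarray  # (n_speakers, nx, ny, nz)
    voxel_size_mm: float = 2.0
    origin: np.ndarray = None  # mm coordinate of voxel (0, 0, 0)
    mask: np.ndarray = None  # 3D boolean

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise VolumeConfigError("data must be (speakers, x, y, z)")
        if min(self.data.shape[1:]) < 1:
            raise VolumeConfigError("grid dimensions must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[1:]:
            raise VolumeConfigError("mask shape must match volume shape")
        if not self.mask.any():
            raise VolumeConfigError("mask is empty")

    @property
    def n_speakers(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.eye(3) * self.voxel_size_mm
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path) -> None:
        """Write the stack as one 4D NIfTI-1 file."""
        img = nib.Nifti1Image(np.moveaxis(self.data, 0, -1), self.affine())
        nib.save(img, str(path))

    def to_nifti_dir(self, directory, prefix: str = "speaker") -> list[Path]:
        """Write one 3D NIfTI-1 file per speaker; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i in range(self.n_speakers):
            p = directory / f"{prefix}_{i:03d}.nii"
            nib.save(nib.Nifti1Image(self.data[i], self.affine()), str(p))
            paths.append(p)
        return paths

    @classmethod
    def from_nifti(cls, path, mask: np.ndarray | None = None) -> "VolumeSet":
        """Load a 4D stack (or a directory of 3D files) written by this class."""
        path = Path(path)
        if path.is_dir():
            files = sorted(path.glob("*.nii")) + sorted(path.glob("*.nii.gz"))
            if not files:
                raise VolumeConfigError(f"no NIfTI files in {path}")
            imgs = [nib.load(str(f)) for f in files]
            data = np.stack([np.asarray(im.dataobj, dtype=float) for im in imgs])
            aff = imgs[0].affine
        else:
            img = nib.load(str(path))
            arr = np.asarray(img.dataobj, dtype=float)
            if arr.ndim != 4:
                raise VolumeConfigError("expected a 4D NIfTI stack")
            data = np.moveaxis(arr, -1, 0)
            aff = img.affine
        voxel_size = float(np.abs(aff[0, 0]))
        origin = aff[:3, 3].copy()
        return cls(data=data, voxel_size_mm=voxel_size, origin=origin, mask=mask)


@dataclass
class StatMap:
    t_map: np.ndarray
    z_map: np.ndarray
    df: int
    voxel_size_mm: float = 2.0
    origin: np.ndarray = None
    mask: np.ndarray = None
    n_degenerate: int = 0
    direction: str | None = None

    def __post_init__(self):
        if self.origin is None:
            self.origin = np.zeros(3)
        if self.mask is None:
            self.mask = np.isfinite(self.t_map)


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Sign-preserving p-matched conversion of t values to z values."""
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        z = np.sign(t) * stats.norm.isf(stats.t.sf(np.abs(t), df))
    z = np.where(np.isinf(t), t, z)
    return z


def voxelwise_regression(
    volumes: VolumeSet,
    covariate,
    nuisance: pd.DataFrame | np.ndarray | None = None,
) -> StatMap:
    """Per-voxel OLS of contrast values on [intercept, covariate, nuisance].

    Returns the t-map for the covariate term and its p-matched z-map;
    df = n - number of regressors.  Constant voxels yield t = 0
    (nothing explained); voxels with a perfect noiseless fit and a
    non-zero covariate effect yield signed infinities and are counted in
    ``n_degenerate``.
    """
    cov = np.asarray(covariate, dtype=float)
    n = volumes.n_speakers
    if cov.shape != (n,):
        raise VolumeConfigError(f"covariate must have one value per speaker ({n})")
    cols = [np.ones(n), cov]
    if nuisance is not None:
        N = np.asarray(nuisance, dtype=float)
        if N.ndim == 1:
            N = N[:, None]
        cols.extend(N.T)
    X = np.column_stack(cols)
    p = X.shape[1]
    if n <= p:
        raise VolumeConfigError(f"need more speakers ({n}) than regressors ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise VolumeConfigError("rank-deficient design matrix")

    flat_mask = volumes.mask.reshape(-1)
    Y = volumes.data.reshape(n, -1)[:, flat_mask]
    const_voxel = np.ptp(Y, axis=0) == 0  # nothing to explain: t := 0
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    s2 = np.sum(resid**2, axis=0) / df
    c = xtx_inv[1, 1]
    se = np.sqrt(s2 * c)
    b = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / se
    # conventions at degenerate voxels
    t = np.where((se == 0) & (b == 0), 0.0, t)
    t = np.where((se == 0) & (b > 0), np.inf, t)
    t = np.where((se == 0) & (b < 0), -np.inf, t)
    t = np.where(const_voxel, 0.0, t)
    n_degen = int(np.sum((se == 0) | const_voxel))
    if n_degen:
        logger.info("voxelwise_regression: %d zero-residual-variance voxel(s)", n_degen)

    t_map = np.full(volumes.grid_shape, np.nan)
    t_map.reshape(-1)[flat_mask] = t
    z_map = np.full(volumes.grid_shape, np.nan)
    z_map.reshape(-1)[flat_mask] = t_to_z(t, df)
    return StatMap(
        t_map=t_map,
        z_map=z_map,
        df=df,
        voxel_size_mm=volumes.voxel_size_mm,
        origin=volumes.origin,
        mask=volumes.mask,
        n_degenerate=n_degen,
    )


def label_clusters(binary: np.ndarray, connectivity: int = 18) -> np.ndarray:
    """Connected-component labels of a 3D boolean array.

    ``connectivity`` is the neighbour count: 6 (faces), 18 (faces+edges)
    or 26 (faces+edges+corners).
    """
    if connectivity not in CONNECTIVITY_RANK:
        raise VolumeConfigError(f"connectivity must be one of {sorted(CONNECTIVITY_RANK)}")
    return sk_label(
        np.asarray(binary, dtype=bool), connectivity=CONNECTIVITY_RANK[connectivity]
    )


def mc_cluster_threshold(
    grid_shape,
    mask: np.ndarray | None,
    fwhm_mm: float,
    voxel_size_mm: float,
    voxel_p: float = 0.001,
    n_iter: int = 1000,
    alpha: float = 0.05,
    connectivity: int = 18,
    seed: int = 0,
) -> int:
    """Monte-Carlo cluster-extent threshold for smoothed Gaussian noise.

    Each iteration draws a standard-normal volume, smooths it to the
    nominal FWHM, re-standardizes to unit variance within the mask,
    thresholds at the one-tailed ``voxel_p`` quantile and records the
    maximum cluster size.  Returns the smallest k such that the
    empirical probability of a max cluster >= k is <= ``alpha``.
    """
    if not 0.0 < voxel_p < 1.0:
        raise VolumeConfigError("voxel_p must be in (0, 1)")
    if n_iter < 100:
        raise VolumeConfigError("n_iter must be >= 100")
    if fwhm_mm < 0:
        raise VolumeConfigError("fwhm must be non-negative")
    grid_shape = tuple(int(s) for s in grid_shape)
    if min(grid_shape) < 1:
        raise VolumeConfigError("grid dimensions must be positive")
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise VolumeConfigError("mask is empty")
    rng = np.random.default_rng(seed)
    zcrit = stats.norm.isf(voxel_p)
    maxima = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        noise = rng.standard_normal(grid_shape)
        noise = smooth_volume(noise, fwhm_mm, voxel_size_mm)
        vals = noise[mask]
        noise = (noise - vals.mean()) / vals.std()
        supra = (noise > zcrit) & mask
        if not supra.any():
            maxima[i] = 0
            continue
        labels = label_clusters(supra, connectivity)
        maxima[i] = int(np.bincount(labels.reshape(-1))[1:].max())
    for k in range(1, int(maxima.max()) + 2):
        if np.mean(maxima >= k) <= alpha:
            return k
    return int(maxima.max()) + 1


def extract_clusters(
    stat_map: StatMap,
    voxel_p: float = 0.001,
    k_min: int = 1,
    direction: str = "positive",
    connectivity: int = 18,
    peak_sep_mm: float = 8.0,
    max_peaks: int = 3,
) -> pd.DataFrame:
    """Suprathreshold clusters and their peaks from a covariate t-map.

    The map is thresholded one-tailed at the ``voxel_p`` critical t
    value in the requested direction; connected components smaller than
    ``k_min`` are discarded.  Within each surviving cluster up to
    ``max_peaks`` local maxima separated by at least ``peak_sep_mm`` are
    reported with mm coordinates.  T and Z columns carry the
    direction-signed (positive) statistic magnitudes.

    An empty DataFrame (with the full column set) is a valid result.
    """
    if direction not in ("positive", "negative"):
        raise VolumeConfigError("direction must be 'positive' or 'negative'")
    sign = 1.0 if direction == "positive" else -1.0
    signed = sign * np.where(np.isnan(stat_map.t_map), -np.inf, stat_map.t_map)
    tcrit = stats.t.isf(voxel_p, stat_map.df)
    supra = (signed > tcrit) & stat_map.mask
    columns = ["cluster_id", "k", "peak_rank", "x", "y", "z", "T", "Z", "direction"]
    if not supra.any():
        return pd.DataFrame(columns=columns)
    labels = label_clusters(supra, connectivity)
    sizes = np.bincount(labels.reshape(-1))
    footprint = ndimage.generate_binary_structure(3, CONNECTIVITY_RANK[connectivity])
    rows = []
    origin = np.asarray(stat_map.origin, dtype=float)
    vsize = float(stat_map.voxel_size_mm)
    out_id = 0
    order = np.argsort(sizes[1:])[::-1] + 1  # largest clusters first
    for lab in order:
        k = int(sizes[lab])
        if k < k_min:
            continue
        out_id += 1
        in_cluster = labels == lab
        masked = np.where(in_cluster, signed, -np.inf)
        local_max = (ndimage.maximum_filter(masked, footprint=footprint) == masked) & in_cluster
        cand = np.argwhere(local_max)
        cand_vals = masked[local_max]
        cand = cand[np.argsort(cand_vals)[::-1]]
        peaks: list[np.ndarray] = []
        for idx in cand:
            if len(peaks) >= max_peaks:
                break
            mm = origin + idx * vsize
            if all(np.linalg.norm(mm - p) >= peak_sep_mm for p in peaks):
                peaks.append(mm)
                i, j, l = idx
                rows.append(
                    {
                        "cluster_id": out_id,
                        "k": k,
                        "peak_rank": len(peaks),
                        "x": mm[0],
                        "y": mm[1],
                        "z": mm[2],
                        "T": float(signed[i, j, l]),
                        "Z": float(sign * stat_map.z_map[i, j, l]),
                        "direction": direction,
                    }
                )
    return pd.DataFrame(rows, columns=columns)


@dataclass
class VoxelGLMResult:
    stat_map: StatMap
    k_min: int
    clusters: pd.DataFrame
    params: dict = field(default_factory=dict)


def run_voxel_glm(
    volumes: VolumeSet,
    covariate,
    nuisance=None,
    fwhm_mm: float = 8.0,
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_iter: int = 1000,
    connectivity: int = 18,
    seed: int = 0,
    directions: tuple[str, ...] = ("positive", "negative"),
) -> VoxelGLMResult:
    """Full chain: voxelwise regression, MC extent threshold, cluster tables."""
    stat_map = voxelwise_regression(volumes, covariate, nuisance)
    k_min = mc_cluster_threshold(
        volumes.grid_shape,
        volumes.mask,
        fwhm_mm,
        volumes.voxel_size_mm,
        voxel_p=voxel_p,
        n_iter=n_iter,
        alpha=alpha,
        connectivity=connectivity,
        seed=seed,
    )
    tables = [
        extract_clusters(
            stat_map, voxel_p=voxel_p, k_min=k_min, direction=d, connectivity=connectivity
        )
        for d in directions
    ]
    non_empty = [t for t in tables if not t.empty]
    clusters = (
        pd.concat(non_empty, ignore_index=True) if non_empty else tables[0].iloc[0:0]
    )
    return VoxelGLMResult(
        stat_map=stat_map,
        k_min=k_min,
        clusters=clusters,
        params={
            "voxel_p": voxel_p,
            "alpha": alpha,
            "n_iter": n_iter,
            "fwhm_mm": fwhm_mm,
            "connectivity": connectivity,
            "seed": seed,
        },
    )
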