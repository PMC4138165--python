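"""Environmental PCA space and gridded niche occupancy densities.

The climatic niche of a species in a region is summarised as a smoothed
density of its occurrences over the first two principal components of the
climate available in the *pooled* backgrounds of both study regions
(PCA-env). Occurrence density is corrected by background availability so the
resulting occupancy ``z`` reflects environmental preference rather than the
abundance of a climate on the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.decomposition import PCA

from .geo import BackgroundRegion, OccurrenceSet
from .raster import ClimateStack

__all__ = ["PcaSpace", "NicheGrid", "fit_pca", "project_points", "build_niche_grid"]


@dataclass
class PcaSpace:
    """Standardize-then-rotate transform fitted on pooled backgrounds.

    ``loadings`` has one column per component (variables x components,
    orthonormal columns); the first two components define the niche plane.
    ``axis1_range``/``axis2_range`` record the pooled background extent on
    those components, the fixed frame every niche grid shares.
    """

    variable_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    axis1_range: tuple[float, float]
    axis2_range: tuple[float, float]
    n_components_kept: int = 2

    def transform(self, env: np.ndarray) -> np.ndarray:
        """Scores on the first two components for rows of raw environment."""
        env = np.asarray(env, dtype=float)
        std = (env - self.means) / self.scales
        return std @ self.loadings[:, : self.n_components_kept]


def fit_pca(
    stack_native: ClimateStack,
    stack_invaded: ClimateStack,
    bg_native: BackgroundRegion,
    bg_invaded: BackgroundRegion,
) -> PcaSpace:
    """Fit the common climate space on both regions' pooled background points.

    Variables are standardized to zero mean and unit variance over the pooled
    sample before rotation, so each climate variable contributes equally.
    """
    if stack_native.layer_names != stack_invaded.layer_names:
        raise ValueError("stacks must share an identical, ordered variable set")
    env_n = stack_native.env_at_points(bg_native.lon, bg_native.lat)
    env_i = stack_invaded.env_at_points(bg_invaded.lon, bg_invaded.lat)
    env = np.vstack([env_n, env_i])
    if len(env) < 3:
        raise ValueError("need at least 3 background points to fit a PCA")
    means = env.mean(axis=0)
    scales = env.std(axis=0)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        bad = [stack_native.layer_names[i] for i in zero]
        raise ValueError(f"zero-variance variables {bad}; prune before fitting")
    std = (env - means) / scales
    pca = PCA()
    scores = pca.fit_transform(std)
    loadings = pca.components_.T  # variables x components, orthonormal columns
    space = PcaSpace(
        variable_names=list(stack_native.layer_names),
        means=means,
        scales=scales,
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_,
        axis1_range=(float(scores[:, 0].min()), float(scores[:, 0].max())),
        axis2_range=(float(scores[:, 1].min()), float(scores[:, 1].max())),
    )
    return space


def project_points(
    pca: PcaSpace, stack: ClimateStack, lon, lat
) -> np.ndarray:
    """Project geographic points into the niche plane (n x 2 scores).

    Raises with the offending indices if any point sits on a nodata cell.
    """
    env = stack.env_at_points(lon, lat)
    return pca.transform(env)


@dataclass
class NicheGrid:
    """R x R occupancy grid over the first two PCA axes for one region.

    ``o``: occurrence kernel density, ``e``: background kernel density,
    ``z``: occupancy corrected for availability, ``envelope_100``/``_75``:
    cells inside the full / densest-75% climate envelope of the region's
    background. Index [i, j] is (axis1 bin i, axis2 bin j).
    """

    R: int
    axis1_range: tuple[float, float]
    axis2_range: tuple[float, float]
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    envelope_100: np.ndarray
    envelope_75: np.ndarray
    region_id: str = ""

    def same_frame(self, other: "NicheGrid") -> bool:
        return (
            self.R == other.R
            and np.allclose(self.axis1_range, other.axis1_range)
            and np.allclose(self.axis2_range, other.axis2_range)
        )

    @property
    def p(self) -> np.ndarray:
        """Occupancy normalized to a probability mass over cells."""
        total = self.z.sum()
        if total <= 0:
            raise ValueError("occupancy grid has zero total density")
        return self.z / total


def _silverman_bandwidth(x: np.ndarray) -> float:
    # per-axis Silverman rule for a 2-D KDE: h = sigma * n^(-1/6)
    n = len(x)
    return float(np.std(x, ddof=1)) * n ** (-1.0 / 6.0)


def _binned_kde(
    scores: np.ndarray,
    axis1_range: tuple[float, float],
    axis2_range: tuple[float, float],
    R: int,
    bandwidth: tuple[float, float],
) -> np.ndarray:
    """Gaussian KDE evaluated on the grid via binning + separable smoothing.

    The kernel is truncated at 4 bandwidths, so cells far from any data point
    are exactly zero — this defines the finite support used by the overlap
    decomposition. Points outside the frame are clipped onto the edge bins.
    """
    edges1 = np.linspace(*axis1_range, R + 1)
    edges2 = np.linspace(*axis2_range, R + 1)
    x = np.clip(scores[:, 0], axis1_range[0], axis1_range[1])
    y = np.clip(scores[:, 1], axis2_range[0], axis2_range[1])
    hist, _, _ = np.histogram2d(x, y, bins=[edges1, edges2])
    cell1 = (axis1_range[1] - axis1_range[0]) / R
    cell2 = (axis2_range[1] - axis2_range[0]) / R
    sigma = (max(bandwidth[0], 1e-12) / cell1, max(bandwidth[1], 1e-12) / cell2)
    dens = gaussian_filter(hist, sigma=sigma, mode="constant", truncate=4.0)
    dens[dens < 0] = 0.0
    return dens


def build_niche_grid(
    pca: PcaSpace,
    stack: ClimateStack,
    bg: BackgroundRegion,
    occ: OccurrenceSet,
    R: int = 100,
    bandwidth_rule: str = "silverman",
    bandwidth: tuple[float, float] | None = None,
    correct_by_background: bool = True,
) -> NicheGrid:
    """Grid one region's occurrence density in the shared niche plane.

    ``z`` is the availability-corrected occupancy ``(o/e) / max(o/e)`` over
    cells with background density ``e > 0`` (zero elsewhere); with
    ``correct_by_background=False`` the uncorrected ``o / max(o)`` is used.
    The 75% envelope keeps cells whose background density exceeds the 25th
    percentile of positive values — the densest three quarters of the
    region's available climate.

    One bandwidth — Silverman's rule per axis on the region's background
    scores — smooths both densities. Separate bandwidths would make the
    ratio o/e blow up wherever the narrower kernel's density decays first,
    concentrating spurious occupancy at the envelope edge; with a shared
    bandwidth the two tails decay at the same rate and the ratio stays
    bounded by the local data counts.
    """
    if R < 25:
        raise ValueError("grid resolution R must be >= 25")
    if len(occ) < 5:
        raise ValueError("need at least 5 occurrences for a stable kernel density")
    occ_scores = project_points(pca, stack, occ.lon, occ.lat)
    bg_scores = project_points(pca, stack, bg.lon, bg.lat)

    if bandwidth is None:
        if bandwidth_rule != "silverman":
            raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
        bw = (_silverman_bandwidth(bg_scores[:, 0]), _silverman_bandwidth(bg_scores[:, 1]))
    else:
        bw = bandwidth

    o = _binned_kde(occ_scores, pca.axis1_range, pca.axis2_range, R, bw)
    e = _binned_kde(bg_scores, pca.axis1_range, pca.axis2_range, R, bw)

    envelope_100 = e > 0
    if not envelope_100.any():
        raise ValueError("background density is zero everywhere")
    pos = e[envelope_100]
    envelope_75 = e > np.percentile(pos, 25)

    if correct_by_background:
        ratio = np.zeros_like(o)
        np.divide(o, e, out=ratio, where=envelope_100)
        top = ratio.max()
        z = ratio / top if top > 0 else ratio
    else:
        top = o.max()
        z = o / top if top > 0 else o.copy()
        z = np.where(envelope_100, z, 0.0)
    return NicheGrid(
        R=R,
        axis1_range=pca.axis1_range,
        axis2_range=pca.axis2_range,
        o=o,
        e=e,
        z=z,
        envelope_100=envelope_100,
        envelope_75=envelope_75,
        region_id=occ.region_id,
    )
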