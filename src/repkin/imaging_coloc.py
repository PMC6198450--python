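"""3D colocalization analysis of replication/repair signals.

Workflow for one multichannel 3D acquisition (DNA counterstain, FISH probe,
EdU and/or gammaH2AX channels): a nuclear mask is derived from the DNA
channel (Gaussian blur, automatic Otsu threshold, hole filling, dilation),
background is removed from the channels to be compared with a per-plane local
mean filter, and two colocalization scores are computed per z-plane inside
the mask:

* Pearson's correlation coefficient ``r`` in [-1, 1];
* the H coefficient, the normalized intensity cross-product
  ``H = <I1 * I2> / (<I1> * <I2>)``: ~1 for independent signals, > 1 for
  co-enriched signals, < 1 (down to 0) for mutually exclusive ones.

A mid-nuclear plane (the plane with the strongest in-mask DNA signal) is
selected to report a single value per cell. Cells are additionally staged
within S phase from their EdU pattern (early: interior foci; mid:
peri-nuclear/peri-nucleolar rim; late: few large spots) and, for EdU-negative
cells, into G1/G2 by clustering nuclear volume and integrated DNA content.

Reference acquisition geometry: 86.6 nm pixels, 125 nm z-spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

__all__ = [
    "ImageStack",
    "NucleusMask",
    "ColocResult",
    "SPhaseCall",
    "SPhaseConfig",
    "nuclear_mask",
    "local_mean_subtract",
    "pearson_coloc",
    "h_coefficient",
    "select_midplane",
    "coloc_profile",
    "classify_sphase",
    "dna_content_stage",
    "PlaneValue",
]

#: Voxel size (dz, dy, dx) in µm of the reference confocal acquisition.
REFERENCE_VOXEL_SIZE = (0.125, 0.0866, 0.0866)


@dataclass
class ImageStack:
    """Multichannel 3D image with physical voxel sizes.

    ``channels`` maps a channel name (e.g., DNA, FISH, EdU, gH2AX) to a
    ``(z, y, x)`` intensity array; all channels share one shape.
    ``voxel_size`` is (dz, dy, dx) in µm.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = REFERENCE_VOXEL_SIZE

    def __post_init__(self):
        if not self.channels:
            raise ValueError("empty image stack")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        for name, ch in self.channels.items():
            if np.any(np.asarray(ch) < 0):
                raise ValueError(f"negative intensities in channel {name!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class NucleusMask:
    """Labeled nuclear regions with per-region volume and DNA content."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    volumes: dict[int, float] = field(default_factory=dict)       # µm³
    dna_content: dict[int, float] = field(default_factory=dict)   # integrated intensity

    @property
    def n_regions(self) -> int:
        return len(self.volumes)

    def region(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def any_mask(self) -> np.ndarray:
        return self.labels > 0


class PlaneValue(NamedTuple):
    """A per-plane statistic that may be missing, with the reason why."""

    value: float
    reason: str | None = None


@dataclass
class ColocResult:
    """Per-plane Pearson r and H coefficient plus the selected mid-plane."""

    pearson: list[PlaneValue]
    h: list[PlaneValue]
    midplane: int

    @property
    def mid_pearson(self) -> float:
        return self.pearson[self.midplane].value

    @property
    def mid_h(self) -> float:
        return self.h[self.midplane].value


@dataclass
class SPhaseCall:
    """S-phase substage call with the features that produced it."""

    label: str  # early | mid | late | non-S
    features: dict[str, float]


@dataclass
class SPhaseConfig:
    """Thresholds for the rule-based S-phase substage classifier.

    ``edu_min_mean`` separates EdU-negative (non-S) nuclei from replicating
    ones; it is on the intensity scale of the (background-subtracted) EdU
    channel and should be calibrated once per imaging condition. The late
    pattern is few large replication factories; the mid pattern concentrates
    EdU in a peripheral shell of ``shell_um`` microns.
    """

    edu_min_mean: float = 1.5
    late_max_foci: int = 20
    late_min_volume: float = 0.4     # µm³ mean focus volume
    mid_min_peripheral: float = 0.4
    shell_um: float = 1.0
    focus_k_sd: float = 2.0


def _as_volume_um3(mask: np.ndarray, voxel_size) -> float:
    return float(mask.sum()) * float(np.prod(voxel_size))


def nuclear_mask(
    dna_channel: np.ndarray,
    voxel_size: tuple[float, float, float],
    min_volume: float = 400.0,
    sigma: float = 1.0,
    dilate_iterations: int = 2,
) -> NucleusMask:
    """Segment nuclei from the DNA counterstain.

    Pipeline: Gaussian smoothing (sigma in pixels), automatic (Otsu) global
    threshold, fill holes, binary dilation (``dilate_iterations``), fill
    holes again, then remove components smaller than ``min_volume`` µm³
    (default 400, a lower bound for an intact cultured-cell nucleus).
    Labels are assigned in deterministic raster order.
    """
    dna = np.asarray(dna_channel, dtype=float)
    if dna.size == 0:
        raise ValueError("empty image")
    smoothed = ndimage.gaussian_filter(dna, sigma=sigma)
    if np.all(smoothed == smoothed.flat[0]):
        binary = np.zeros(dna.shape, dtype=bool)
    else:
        binary = smoothed > threshold_otsu(smoothed)
    if binary.any():
        binary = ndimage.binary_fill_holes(binary)
        if dilate_iterations > 0:
            binary = ndimage.binary_dilation(binary, iterations=dilate_iterations)
        binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    voxvol = float(np.prod(voxel_size))
    volumes: dict[int, float] = {}
    dna_content: dict[int, float] = {}
    out = np.zeros_like(labels)
    next_label = 0
    for lab in range(1, n + 1):
        region = labels == lab
        vol = region.sum() * voxvol
        if vol < min_volume:
            continue
        next_label += 1
        out[region] = next_label
        volumes[next_label] = vol
        dna_content[next_label] = float(dna[region].sum())
    if next_label == 0:
        warnings.warn("no nuclear region survived filtering", stacklevel=2)
    return NucleusMask(out, tuple(voxel_size), volumes, dna_content)


def local_mean_subtract(channel: np.ndarray, radius_px: int = 10) -> np.ndarray:
    """Remove background by subtracting a per-plane local mean.

    Each z-plane is filtered with a square (2*radius+1)² mean window and the
    result subtracted from the input, clipped at zero. Diffuse background
    varies slowly and is removed; focal signal narrower than the window
    survives as a positive residual.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    ch = np.asarray(channel, dtype=float)
    size = 2 * radius_px + 1
    background = ndimage.uniform_filter(ch, size=(1, size, size), mode="nearest")
    return np.maximum(ch - background, 0.0)


def _plane_pair(ch1, ch2, mask, plane):
    m = mask[plane]
    return np.asarray(ch1[plane], float)[m], np.asarray(ch2[plane], float)[m]


def pearson_coloc(ch1, ch2, mask, plane: int) -> PlaneValue:
    """Pearson correlation of two channels over in-mask voxels of one plane."""
    a, b = _plane_pair(ch1, ch2, mask, plane)
    if a.size < 3:
        return PlaneValue(np.nan, "too_few_voxels")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return PlaneValue(np.nan, "constant_channel")
    return PlaneValue(float(np.corrcoef(a, b)[0, 1]), None)


def h_coefficient(ch1, ch2, mask, plane: int) -> PlaneValue:
    """Normalized intensity cross-product over in-mask voxels of one plane.

    ``H = mean(I1 * I2) / (mean(I1) * mean(I2))``. Statistically independent
    signals give H ~ 1, co-enrichment gives H > 1, spatial exclusion gives
    H < 1 (0 for disjoint supports). Requires both plane means > 0.
    """
    a, b = _plane_pair(ch1, ch2, mask, plane)
    if a.size == 0:
        return PlaneValue(np.nan, "too_few_voxels")
    ma, mb = a.mean(), b.mean()
    if ma <= 0 or mb <= 0:
        return PlaneValue(np.nan, "zero_mean")
    return PlaneValue(float((a * b).mean() / (ma * mb)), None)


def select_midplane(dna_channel: np.ndarray, mask: np.ndarray) -> int:
    """Plane with the strongest in-mask DNA signal (ties -> lower index).

    Serves as the mid-nuclear section with the best signal quality.
    """
    dna = np.asarray(dna_channel, dtype=float)
    totals = np.array([dna[z][mask[z]].sum() if mask[z].any() else -np.inf
                       for z in range(dna.shape[0])])
    return int(np.argmax(totals))


def coloc_profile(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray,
    dna_channel: np.ndarray | None = None,
) -> ColocResult:
    """Per-plane Pearson and H profiles plus the mid-plane summary.

    The mid-plane is chosen on ``dna_channel`` when given, else on ``ch1``.
    """
    nz = ch1.shape[0]
    pearson = [pearson_coloc(ch1, ch2, mask, z) for z in range(nz)]
    h = [h_coefficient(ch1, ch2, mask, z) for z in range(nz)]
    ref = dna_channel if dna_channel is not None else ch1
    mid = select_midplane(ref, mask)
    return ColocResult(pearson, h, mid)


def _boundary_distance(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Physical distance (µm) of each in-mask voxel to the mask boundary."""
    return ndimage.distance_transform_edt(mask, sampling=voxel_size)


def classify_sphase(
    edu_channel: np.ndarray,
    nucleus: np.ndarray,
    voxel_size: tuple[float, float, float],
    config: SPhaseConfig | None = None,
) -> SPhaseCall:
    """Call the S-phase substage of one nucleus from its EdU pattern.

    Decision rules, applied in order on features of the in-mask EdU signal:

    1. mean EdU below ``edu_min_mean`` -> non-S (EdU negative);
    2. few foci (<= ``late_max_foci``) that are large
       (mean volume >= ``late_min_volume`` µm³) -> late;
    3. EdU concentrated in the peripheral shell
       (fraction within ``shell_um`` of the nuclear border
       >= ``mid_min_peripheral``) -> mid;
    4. otherwise -> early (many foci throughout the interior).

    Always returns a call together with the computed features.
    """
    from repkin.foci_kinetics import segment_foci

    cfg = config or SPhaseConfig()
    nucleus = np.asarray(nucleus, dtype=bool)
    if not nucleus.any():
        raise ValueError("empty nucleus mask")
    edu = np.asarray(edu_channel, dtype=float)
    inside = edu[nucleus]
    mean_edu = float(inside.mean())

    dist = _boundary_distance(nucleus, voxel_size)
    shell = nucleus & (dist <= cfg.shell_um)
    total = float(inside.sum())
    peripheral_fraction = float(edu[shell].sum() / total) if total > 0 else 0.0
    # intensity-weighted mean normalized depth: 0 at the rim, 1 at the center
    dmax = float(dist.max())
    if total > 0 and dmax > 0:
        interior_dispersion = float((edu[nucleus] * dist[nucleus]).sum() / total / dmax)
    else:
        interior_dispersion = 0.0

    foci = segment_foci(
        edu, nucleus, voxel_size, k_sd=cfg.focus_k_sd, min_volume=0.1,
        dilate_nucleus_iterations=0,
    )
    n_foci = foci.n_foci
    mean_focus_volume = float(np.mean(list(foci.volumes.values()))) if n_foci else 0.0

    features = {
        "mean_edu": mean_edu,
        "n_foci": float(n_foci),
        "mean_focus_volume": mean_focus_volume,
        "peripheral_fraction": peripheral_fraction,
        "interior_dispersion": interior_dispersion,
    }
    if mean_edu < cfg.edu_min_mean:
        label = "non-S"
    elif n_foci <= cfg.late_max_foci and mean_focus_volume >= cfg.late_min_volume:
        label = "late"
    elif peripheral_fraction >= cfg.mid_min_peripheral:
        label = "mid"
    else:
        label = "early"
    return SPhaseCall(label, features)


def dna_content_stage(
    dapi_content,
    volumes,
    edu_flags,
    random_state: int = 0,
) -> np.ndarray:
    """Stage cells into G1/S/G2 from DNA content, volume and EdU status.

    EdU-positive cells are in S phase. EdU-negative cells are split by
    2-means clustering on standardized (nuclear volume, integrated DAPI);
    the cluster with the lower mean DAPI content is G1 (2C), the other G2
    (4C). A single EdU-negative cell cannot be clustered and is assigned G1
    with a warning.
    """
    dapi = np.asarray(dapi_content, dtype=float)
    vol = np.asarray(volumes, dtype=float)
    edu = np.asarray(edu_flags, dtype=bool)
    if not (dapi.shape == vol.shape == edu.shape):
        raise ValueError("inputs must share length")
    stages = np.full(dapi.shape, "S", dtype=object)
    neg = ~edu
    n_neg = int(neg.sum())
    if n_neg == 0:
        return stages
    if n_neg == 1:
        warnings.warn("single EdU-negative cell; assigned G1", stacklevel=2)
        stages[neg] = "G1"
        return stages
    X = np.column_stack([vol[neg], dapi[neg]])
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(X)
    mean_dapi = [dapi[neg][km.labels_ == k].mean() for k in (0, 1)]
    g1_cluster = int(np.argmin(mean_dapi))
    calls = np.where(km.labels_ == g1_cluster, "G1", "G2")
    stages[neg] = calls
    return stages
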