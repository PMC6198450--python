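"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, each reproducible from a single seed:

* :func:`simulate_tracks` — per-interval tracks with a planted Spearman
  correlation structure via a Gaussian copula;
* :func:`simulate_reads` — a 1-Mb toy genome of interleaved repeat-class
  blocks with uniquely and multi-mapped reads whose true class (or DISCARD
  status) is known by construction;
* :func:`simulate_image` / :func:`simulate_repair_timecourse` — 3D
  multichannel nuclei with planted EdU replication patterns (early / mid /
  late), FISH channels at a controlled colocalization level, and damage foci
  whose repeat-signal overlap decays over post-irradiation timepoints.

Every generator returns machine-readable ground truth next to the data, so
pipeline tests consume only (data, truth) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from repkin.genome_binning import FeatureTrack, IntervalGrid, bin_genome
from repkin.imaging_coloc import REFERENCE_VOXEL_SIZE, ImageStack
from repkin.metarepeat import DISCARD, NONREPEAT, AlignedRead

__all__ = [
    "TrackSimSpec",
    "ReadSimSpec",
    "ImageSimSpec",
    "simulate_tracks",
    "simulate_reads",
    "simulate_image",
    "simulate_repair_timecourse",
    "latent_pearson_for_spearman",
]

#: Default metarepeat class proportions: the early-response composition of
#: single-signature damage-mark reads over the four reported repeat classes.
DEFAULT_CLASS_PROPORTIONS = {"Alu": 0.47, "LINE": 0.24, "SAT": 0.15, "LTR": 0.14}


def latent_pearson_for_spearman(rho_s: np.ndarray) -> np.ndarray:
    """Latent Gaussian Pearson correlation giving a target Spearman rho.

    For a Gaussian copula the Spearman correlation of the observed margins is
    ``rho_S = (6/pi) * arcsin(rho_latent / 2)``; this inverts that map.
    """
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


# ------------------------------------------------------------------- tracks

@dataclass
class TrackSimSpec:
    """Planted-correlation track simulation.

    ``target_spearman`` is the desired Spearman matrix between tracks
    (symmetric, unit diagonal). ``marginals`` maps each label to its marginal
    distribution: ``("normal",)``, ``("lognormal", sigma)`` for RPKM-like
    continuous coverage, or ``("poisson", lam)`` for copy-count tracks.
    """

    n_intervals: int = 10_000
    labels: tuple[str, ...] = ("trackA", "trackB")
    target_spearman: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.6], [0.6, 1.0]])
    )
    marginals: dict[str, tuple] = field(default_factory=dict)
    width: int = 10_000
    seed: int = 0


def _nearest_psd(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 1e-10, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    return out / np.outer(d, d)


def simulate_tracks(spec: TrackSimSpec) -> tuple[list[FeatureTrack], pd.DataFrame]:
    """Draw correlated tracks through a Gaussian copula.

    Latent multivariate normal with Pearson correlation mapped from the
    target Spearman matrix; each margin is then transformed monotonically
    (rank-preserving), so the planted Spearman structure is the ground truth
    up to sampling error (exactly, for target +/-1).

    Returns the tracks on a single-chromosome toy grid and the target matrix
    as a labeled DataFrame.
    """
    t = np.asarray(spec.target_spearman, dtype=float)
    k = len(spec.labels)
    if t.shape != (k, k):
        raise ValueError("target matrix shape does not match labels")
    if not np.allclose(t, t.T) or not np.allclose(np.diag(t), 1.0):
        raise ValueError("target matrix must be symmetric with unit diagonal")
    rng = np.random.default_rng(spec.seed)
    latent_corr = latent_pearson_for_spearman(t)
    np.fill_diagonal(latent_corr, 1.0)
    try:
        chol = np.linalg.cholesky(latent_corr)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(_nearest_psd(latent_corr))
    z = rng.standard_normal((spec.n_intervals, k)) @ chol.T
    grid = bin_genome({"chrSim": spec.n_intervals * spec.width}, spec.width)
    tracks = []
    for j, label in enumerate(spec.labels):
        marg = spec.marginals.get(label, ("normal",))
        col = z[:, j]
        if marg[0] == "normal":
            vals = col
        elif marg[0] == "lognormal":
            vals = np.exp(marg[1] * col)
        elif marg[0] == "poisson":
            u = stats.norm.cdf(col)
            vals = stats.poisson.ppf(u, marg[1])
        else:
            raise ValueError(f"unknown marginal {marg[0]!r}")
        tracks.append(FeatureTrack(grid, label, np.asarray(vals, dtype=float)))
    truth = pd.DataFrame(t, index=spec.labels, columns=spec.labels)
    return tracks, truth


# -------------------------------------------------------------------- reads

@dataclass
class ReadSimSpec:
    """Toy genome + read simulation with known per-read class truth.

    The genome interleaves fixed-size annotation blocks of each class,
    separated by unannotated gaps wider than a read, so a read placed inside
    a block overlaps exactly that class and a read placed inside a gap
    overlaps nothing. Multi-mapped reads are either within-class (all
    placements in distinct copies of one class; still classifiable) or
    cross-class (true outcome DISCARD).
    """

    genome_length: int = 1_000_000
    block: int = 1_000
    gap: int = 500
    read_length: int = 50
    classes: tuple[str, ...] = ("Alu", "LINE", "SAT", "LTR")
    proportions: tuple[float, ...] = (0.47, 0.24, 0.15, 0.14)
    nonrepeat_rate: float = 0.10
    multimap_rate: float = 0.20
    cross_class_rate: float = 0.25  # of multi-mapped reads
    n_placements: int = 3
    n_reads: int = 20_000
    chrom: str = "chrToy"
    seed: int = 0


def _toy_annotation(spec: ReadSimSpec) -> pd.DataFrame:
    rows = []
    period = spec.block + spec.gap
    i = 0
    while (start := i * period) + spec.block <= spec.genome_length:
        rows.append(
            {
                "chrom": spec.chrom,
                "start": start,
                "end": start + spec.block,
                "strand": "+",
                "repeat_class": spec.classes[i % len(spec.classes)],
                "repeat_name": f"{spec.classes[i % len(spec.classes)]}_{i}",
            }
        )
        i += 1
    return pd.DataFrame(rows)


def simulate_reads(
    spec: ReadSimSpec,
) -> tuple[list[AlignedRead], pd.DataFrame, pd.DataFrame]:
    """Simulate reads with ground-truth class labels.

    Returns (reads, annotation table, truth table); the truth table has one
    row per read with its true outcome: a class name, ``NONREPEAT`` or
    ``DISCARD``.
    """
    if abs(sum(spec.proportions) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if spec.gap <= spec.read_length + 2:
        raise ValueError("gap must exceed the read length for clean truth")
    rng = np.random.default_rng(spec.seed)
    ann = _toy_annotation(spec)
    by_class = {
        c: ann[ann["repeat_class"] == c][["start", "end"]].to_numpy()
        for c in spec.classes
    }
    period = spec.block + spec.gap
    n_gaps = spec.genome_length // period

    def place_in_block(cls: str) -> tuple[str, int, int]:
        blocks = by_class[cls]
        b = blocks[rng.integers(len(blocks))]
        start = int(rng.integers(b[0], b[1] - spec.read_length + 1))
        return (spec.chrom, start, start + spec.read_length)

    def place_in_gap() -> tuple[str, int, int]:
        g = int(rng.integers(n_gaps))
        lo = g * period + spec.block + 1
        hi = (g + 1) * period - spec.read_length - 1
        start = int(rng.integers(lo, hi))
        return (spec.chrom, start, start + spec.read_length)

    reads, truth_rows = [], []
    for i in range(spec.n_reads):
        rid = f"read{i:06d}"
        if rng.random() < spec.nonrepeat_rate:
            reads.append(AlignedRead(rid, (place_in_gap(),)))
            truth_rows.append((rid, NONREPEAT))
            continue
        cls = spec.classes[rng.choice(len(spec.classes), p=spec.proportions)]
        if rng.random() < spec.multimap_rate:
            if rng.random() < spec.cross_class_rate:
                other = spec.classes[
                    (list(spec.classes).index(cls) + 1 + rng.integers(len(spec.classes) - 1))
                    % len(spec.classes)
                ]
                pl = (place_in_block(cls), place_in_block(other))
                reads.append(AlignedRead(rid, pl))
                truth_rows.append((rid, DISCARD))
            else:
                k = int(rng.integers(2, spec.n_placements + 1))
                pl = tuple(place_in_block(cls) for _ in range(k))
                reads.append(AlignedRead(rid, pl))
                truth_rows.append((rid, cls))
        else:
            reads.append(AlignedRead(rid, (place_in_block(cls),)))
            truth_rows.append((rid, cls))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "truth"])
    return reads, ann, truth


# ------------------------------------------------------------------- images

@dataclass
class ImageSimSpec:
    """One synthetic nucleus acquisition.

    The nucleus is an ellipsoid with ``semi_axes`` (z, y, x) in µm; the
    default (4, 5, 6) gives ~503 µm³, comfortably above the 400 µm³ nuclear
    minimum. ``pattern`` selects the planted EdU replication pattern;
    ``coloc_alpha`` mixes the FISH channel between the EdU reference and an
    independent pattern; ``overlap_fraction``, when set, instead plants a
    known fraction of FISH intensity inside the damage foci (repair mode).
    Noise is Poisson on the expected counts plus a constant offset.
    """

    semi_axes: tuple[float, float, float] = (4.0, 5.0, 6.0)
    voxel_size: tuple[float, float, float] = REFERENCE_VOXEL_SIZE
    pad_um: float = 1.0
    pattern: str | None = "early"      # early | mid | late | None (non-S)
    coloc_alpha: float | None = None
    overlap_fraction: float | None = None
    foci_count: int = 20
    focus_sigma_um: float = 0.5
    focus_snr: float = 10.0
    foci_min_sep_um: float = 1.5
    dna_level: float = 100.0
    edu_amp: float = 300.0
    fish_level: float = 50.0
    background: float = 2.0
    noise: bool = True
    seed: int = 0


def _ellipsoid_mask(spec: ImageSimSpec) -> tuple[np.ndarray, tuple[int, int, int]]:
    shape = tuple(
        int(np.ceil(2 * (a + spec.pad_um) / v))
        for a, v in zip(spec.semi_axes, spec.voxel_size)
    )
    center = tuple((s - 1) / 2.0 for s in shape)
    axes = [
        (np.arange(s) - c) * v
        for s, c, v in zip(shape, center, spec.voxel_size)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    a_z, a_y, a_x = spec.semi_axes
    mask = (zz / a_z) ** 2 + (yy / a_y) ** 2 + (xx / a_x) ** 2 <= 1.0
    return mask, shape


def _render_blobs(shape, centers, sigma_um, voxel_size, amplitude) -> np.ndarray:
    """Sum of Gaussian blobs, each with the given peak amplitude."""
    img = np.zeros(shape)
    if len(centers) == 0:
        return img
    for c in centers:
        img[tuple(c)] += 1.0
    sig_vox = [sigma_um / v for v in voxel_size]
    img = ndimage.gaussian_filter(img, sigma=sig_vox)
    peak0 = float(np.prod([1.0 / (np.sqrt(2 * np.pi) * s) for s in sig_vox]))
    return img * (amplitude / peak0)


def _sample_centers(rng, candidates, n, min_sep_um, voxel_size):
    """Rejection-sample voxel centers at pairwise physical separation."""
    chosen: list[np.ndarray] = []
    scale = np.asarray(voxel_size)
    tries = 0
    while len(chosen) < n and tries < 20000:
        tries += 1
        c = candidates[rng.integers(len(candidates))]
        if all(np.linalg.norm((c - p) * scale) >= min_sep_um for p in chosen):
            chosen.append(c)
    return chosen


def simulate_image(spec: ImageSimSpec) -> tuple[ImageStack, dict]:
    """Render one synthetic nucleus and return (stack, ground truth).

    Channels: ``DNA`` (ellipsoid body with smooth texture), ``EdU`` (planted
    replication pattern), ``FISH`` (colocalization- or overlap-controlled),
    ``gH2AX`` (planted damage foci). Truth carries the nucleus and foci
    masks, the pattern label and the planted parameters.
    """
    rng = np.random.default_rng(spec.seed)
    mask, shape = _ellipsoid_mask(spec)
    voxvol = float(np.prod(spec.voxel_size))
    dist = ndimage.distance_transform_edt(mask, sampling=spec.voxel_size)

    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    texture = 1.0 + 0.2 * texture / max(texture.std(), 1e-9)
    dna = spec.dna_level * mask * np.clip(texture, 0.2, None)

    interior = np.argwhere(mask & (dist > 1.2))
    shell = np.argwhere(mask & (dist <= 0.8) & (dist > 0))

    if spec.pattern is None:
        edu = np.zeros(shape)
    elif spec.pattern == "early":
        centers = [interior[i] for i in rng.choice(len(interior), 40, replace=False)]
        edu = _render_blobs(shape, centers, 0.25, spec.voxel_size, spec.edu_amp)
    elif spec.pattern == "mid":
        centers = [shell[i] for i in rng.choice(len(shell), 40, replace=False)]
        edu = _render_blobs(shape, centers, 0.25, spec.voxel_size, spec.edu_amp)
    elif spec.pattern == "late":
        centers = _sample_centers(rng, interior, 6, 2.0, spec.voxel_size)
        edu = _render_blobs(shape, centers, 0.55, spec.voxel_size, spec.edu_amp)
    else:
        raise ValueError(f"unknown pattern {spec.pattern!r}")
    edu = edu * mask

    # damage foci (gH2AX): peak amplitude A set so the Poisson shot-noise
    # detection SNR at the peak, A / sqrt(A + background), equals focus_snr
    s, b = spec.focus_snr, spec.background
    foci_amp = (s**2 + s * np.sqrt(s**2 + 4 * b)) / 2.0
    foci_centers = _sample_centers(
        rng, interior, spec.foci_count, spec.foci_min_sep_um, spec.voxel_size
    )
    gh2ax = _render_blobs(
        shape, foci_centers, spec.focus_sigma_um, spec.voxel_size, foci_amp
    ) * mask
    foci_mask = gh2ax > 0.25 * foci_amp

    if spec.overlap_fraction is not None:
        f = float(spec.overlap_fraction)
        inside = foci_mask & mask
        outside = mask & ~foci_mask
        fish = np.zeros(shape)
        total = spec.fish_level * mask.sum()
        if inside.any():
            fish[inside] = f * total / inside.sum()
        if outside.any():
            fish[outside] = (1 - f) * total / outside.sum()
    elif spec.coloc_alpha is not None:
        a = float(spec.coloc_alpha)
        # the independent pattern is uniform over the whole nucleus so that
        # it is a true colocalization null (E[H] = 1) against any reference
        anywhere = np.argwhere(mask)
        indep_centers = [
            anywhere[i] for i in rng.choice(len(anywhere), 40, replace=False)
        ]
        indep = _render_blobs(shape, indep_centers, 0.25, spec.voxel_size, spec.edu_amp)
        if spec.pattern is not None:
            reference = edu
        else:
            ref_centers = [
                interior[i] for i in rng.choice(len(interior), 40, replace=False)
            ]
            reference = _render_blobs(
                shape, ref_centers, 0.25, spec.voxel_size, spec.edu_amp
            )
        fish = (a * reference + (1 - a) * indep) * mask
    else:
        fish = spec.fish_level * mask.astype(float)

    def finish(img):
        expected = img + spec.background
        if spec.noise:
            return rng.poisson(expected).astype(float)
        return expected

    stack = ImageStack(
        {"DNA": finish(dna), "EdU": finish(edu), "FISH": finish(fish),
         "gH2AX": finish(gh2ax)},
        spec.voxel_size,
    )
    truth = {
        "nucleus_mask": mask,
        "nucleus_volume_um3": float(mask.sum() * voxvol),
        "pattern": spec.pattern if spec.pattern is not None else "non-S",
        "foci_centers": foci_centers,
        "foci_mask": foci_mask,
        "coloc_alpha": spec.coloc_alpha,
        "overlap_fraction": spec.overlap_fraction,
    }
    return stack, truth


def simulate_repair_timecourse(
    timepoints=(0.5, 3.0, 24.0),
    decay=(1.0, 0.5, 0.2),
    n_cells: int = 30,
    base_overlap: float = 0.4,
    seed: int = 0,
    out_dir=None,
    **image_kwargs,
) -> tuple[pd.DataFrame, list[tuple[ImageStack, dict]]]:
    """Cohorts of nuclei whose foci-overlap fraction decays over time.

    At timepoint ``i`` every cell is rendered with planted
    ``overlap_fraction = base_overlap * decay[i]``, so the fold-change
    medians of the recovered kinetics equal ``decay`` up to measurement
    error. Per-cell seeds are spawned deterministically from ``seed``.
    Returns a manifest (cell_id, timepoint, planted overlap) and the list of
    (stack, truth) pairs in manifest order; with ``out_dir`` the stacks are
    also written as TIFFs and the manifest gains their paths.
    """
    if len(timepoints) != len(decay):
        raise ValueError("timepoints and decay must align")
    if len(timepoints) < 2:
        raise ValueError("a kinetics experiment needs at least two timepoints")
    children = np.random.SeedSequence(seed).spawn(len(timepoints) * n_cells)
    rows, cells = [], []
    k = 0
    for tp, d in zip(timepoints, decay):
        for i in range(n_cells):
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            spec = ImageSimSpec(
                pattern=None,
                overlap_fraction=base_overlap * d,
                seed=sub_seed,
                **image_kwargs,
            )
            stack, truth = simulate_image(spec)
            cell_id = f"t{tp}_cell{i:03d}"
            row = {
                "cell_id": cell_id,
                "timepoint": tp,
                "planted_overlap": base_overlap * d,
            }
            if out_dir is not None:
                from repkin.io import write_stack_tiff

                paths = write_stack_tiff(out_dir, stack, prefix=cell_id)
                row.update({f"path_{c}": str(p) for c, p in paths.items()})
            rows.append(row)
            cells.append((stack, truth))
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(f"{out_dir}/manifest.tsv", sep="\t", index=False)
    return manifest, cells
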