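import numpy as np
import pandas as pd
import pytest

from repkin.genome_binning import bin_genome

# Coarse isotropic voxel used for cohort-scale imaging tests; single-image
# examples use the reference acquisition geometry instead.
COARSE_VOXEL = (0.25, 0.25, 0.25)


@pytest.fixture
def grid25k():
    """Three-interval toy grid: one 25-kb chromosome at 10-kb width."""
    return bin_genome({"chrA": 25_000}, 10_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rank_average(v):
    """Average fractional ranks with ties sharing their mean rank (oracle)."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Independent Spearman oracle: explicit average ranks, then Pearson."""
    rx, ry = rank_average(x), rank_average(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def classify_oracle(read, annotations, mixed_policy="discard"):
    """Brute-force read classification: explicit per-placement class sets."""
    classes = set()
    any_nonrepeat = False
    for chrom, start, end in read.placements:
        hit = set(
            annotations.loc[
                (annotations["chrom"] == chrom)
                & (annotations["start"] < end)
                & (annotations["end"] > start),
                "repeat_class",
            ]
        )
        if hit:
            classes |= hit
        else:
            any_nonrepeat = True
    if not classes:
        return "NONREPEAT"
    if len(classes) > 1:
        return "DISCARD"
    if any_nonrepeat and mixed_policy == "discard":
        return "DISCARD"
    return next(iter(classes))


def quantile_oracle(values, q):
    """Linear-interpolation quantile, computed from first principles."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return float(v[lo] + (pos - lo) * (v[hi] - v[lo]))


def kinetics_records(cells, manifest):
    """Run the fraction-in-foci pipeline over simulated timecourse cells."""
    from repkin.foci_kinetics import fraction_in_regions, segment_foci
    from repkin.imaging_coloc import nuclear_mask

    rows = []
    for (stack, _truth), rec in zip(cells, manifest.to_dict("records")):
        nm = nuclear_mask(stack.channels["DNA"], stack.voxel_size)
        foci = segment_foci(stack.channels["gH2AX"], nm, stack.voxel_size)
        rows.append(
            {
                "cell_id": rec["cell_id"],
                "timepoint": rec["timepoint"],
                "raw_fraction": fraction_in_regions(stack.channels["FISH"], foci, nm),
            }
        )
    return pd.DataFrame(rows)
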