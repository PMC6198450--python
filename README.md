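# repkin

Replication timing and DNA-repair kinetics of repetitive DNA elements.

Roughly half of a mammalian genome is repetitive — Alu and MIR SINEs, L1/L2
LINEs, LTR/DNA transposons, satellites, low-complexity runs. Where these
elements sit relative to chromatin state determines when they replicate in
S phase and how the DNA damage response (γH2AX) engages them after ionizing
radiation. `repkin` is a tested, reusable implementation of the three kinds
of quantification this question needs, plus a synthetic-data generator that
produces every input format with known ground truth.

## What it computes

**Genome-wide interval tracks and rank correlation.** The genome is tiled
into non-overlapping 10-kb intervals (half-open, BED coordinates). Repeat
copy counts (midpoint-assigned), GC fraction, and RPKM coverage

    RPKM_i = count_i / (length_i[kb] · total_mapped / 10⁶)

are projected onto the grid and compared by Spearman's ρ (average fractional
ranks, pairwise missing-removal, asymptotic p-values). Intervals can be
stratified, e.g. L1-rich (> 10 copies per interval) vs L1-poor (none), and
each stratum correlated separately.

**Metarepetitive-element read accounting.** Reads from repeats rarely map
uniquely. Each read — including multi-mapped ones — is assigned by a strict
signature rule: all placements overlapping one single repeat class → counted
into that class; placements overlapping ≥ 2 classes → discarded; no repeat
overlap → non-repetitive. Per-class counts normalized to all
single-signature repeat reads give class fractions ("metarepetitive
elements"); fraction ratios across post-irradiation timepoints give relative
enrichment.

**3D image quantification.** From multichannel confocal stacks (DNA, FISH
probe, EdU, γH2AX; reference voxel 0.0866 × 0.0866 × 0.125 µm): nuclear
masking (Gaussian blur, Otsu, hole-filling, dilation, ≥ 400 µm³); per-plane
local-mean background subtraction; colocalization per z-plane by Pearson's r
and the H coefficient

    H = ⟨I₁·I₂⟩ / (⟨I₁⟩·⟨I₂⟩)   (≈ 1 independent, > 1 co-enriched, < 1 exclusive)

with a mid-nuclear reporting plane; S-phase substaging from the EdU pattern
(early: interior foci; mid: peripheral shell; late: few large spots) and
G1/S/G2 staging from DNA content; γH2AX focus segmentation (mean + k·SD
threshold, 3³ median fine filter, 1-µm watershed separation, ≥ 0.3 µm³) and
repair kinetics as the fraction of probe signal inside foci, normalized to
the 0.5-h median.

## Worked example

```python
import numpy as np
from repkin.synthetic import TrackSimSpec, simulate_tracks
from repkin.correlation import correlation_matrix

spec = TrackSimSpec(
    n_intervals=10_000,
    labels=("GC", "L1_count"),
    target_spearman=np.array([[1.0, -0.4], [-0.4, 1.0]]),
    marginals={"L1_count": ("poisson", 3.0)},
    seed=1,
)
tracks, truth = simulate_tracks(spec)
m = correlation_matrix(tracks)
print(m.rho.round(3))
```

prints

```
              GC  L1_count
GC         1.000    -0.403
L1_count  -0.403     1.000
```

a 10,000-interval track pair with a planted Spearman correlation of −0.4
(GC vs L1 copy number anti-correlate), recovered as −0.407 — within sampling
error, with unit diagonal. The same machinery runs on real chrom.sizes /
BED / RepeatMasker `.out` / SAM / bedGraph / FASTA inputs via the CLI:

```bash
repkin simulate reads --seed 5 --out sim/
repkin metarepeat --sam 0.5h=sim/reads.sam --repeats sim/repeats.bed --out meta.tsv
```

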