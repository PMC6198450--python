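"""Readers and writers for the formats the pipeline consumes and emits.

Genomic text formats (chrom.sizes, BED, RepeatMasker ``.out``, bedGraph,
SAM via pysam, FASTA via pyfaidx) and image stacks (TIFF via tifffile).
Internally every interval is 0-based half-open; 1-based inclusive sources
are converted on read.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import tifffile
from pyfaidx import Fasta

from repkin.genome_binning import FeatureTrack, IntervalGrid
from repkin.metarepeat import AlignedRead

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_repeatmasker_out",
    "open_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "bedgraph_track",
    "read_sam_reads",
    "read_sam_placements",
    "write_sam",
    "write_tracks_tsv",
    "read_tracks_tsv",
    "write_correlation_tsvs",
    "read_stack_tiff",
    "write_stack_tiff",
    "read_grouping",
]


# ---------------------------------------------------------------- genomic text

def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(path, chrom_sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path, class_from_name: bool = True) -> pd.DataFrame:
    """BED3/BED6 -> DataFrame with chrom/start/end/strand/repeat_class.

    For annotation BEDs the name column (4th) carries the repeat class.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols
    if "strand" not in df:
        df["strand"] = "."
    df["repeat_class"] = df["name"] if ("name" in df and class_from_name) else "."
    if "name" not in df:
        df["name"] = "."
    return df[["chrom", "start", "end", "name", "strand", "repeat_class"]]


def write_bed(path, annotations: pd.DataFrame) -> None:
    df = annotations.copy()
    if "name" not in df:
        df["name"] = df.get("repeat_class", ".")
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_repeatmasker_out(path) -> pd.DataFrame:
    """RepeatMasker ``.out`` annotation table.

    Skips the three header lines; converts the 1-based inclusive query
    coordinates to 0-based half-open. ``repeat_class`` is the class/family
    column (e.g., ``SINE/Alu``), ``repeat_name`` the matching repeat.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            parts = line.split()
            if lineno < 3 or not parts:
                continue
            if not parts[0].lstrip("-").isdigit():
                continue
            strand = "-" if parts[8] == "C" else "+"
            rows.append(
                {
                    "chrom": parts[4],
                    "start": int(parts[5]) - 1,
                    "end": int(parts[6]),
                    "strand": strand,
                    "repeat_name": parts[9],
                    "repeat_class": parts[10],
                }
            )
    return pd.DataFrame(rows)


def open_fasta(path) -> Fasta:
    """Indexed FASTA access (builds the .fai on first use)."""
    return Fasta(str(path))


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df[~df["chrom"].astype(str).str.startswith("track")].reset_index(drop=True)


def bedgraph_track(grid: IntervalGrid, bedgraph: pd.DataFrame, label: str) -> FeatureTrack:
    """Project a bedGraph onto the grid as a coverage-weighted mean.

    Grid intervals not covered by any bedGraph record are missing.
    """
    num = np.zeros(len(grid))
    den = np.zeros(len(grid))
    offsets = grid._offsets()
    for row in bedgraph.itertuples(index=False):
        size = grid.chrom_sizes.get(row.chrom)
        if size is None:
            continue
        start, end = max(0, int(row.start)), min(size, int(row.end))
        while start < end:
            idx = offsets[row.chrom] + start // grid.width
            seg_end = min(end, (start // grid.width + 1) * grid.width)
            w = seg_end - start
            num[idx] += row.value * w
            den[idx] += w
            start = seg_end
    values = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    return FeatureTrack(grid, label, values)


def write_bedgraph(path, track: FeatureTrack) -> None:
    grid = track.grid
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            if np.isfinite(v):
                fh.write(f"{grid.chroms[i]}\t{grid.starts[i]}\t{grid.ends[i]}\t{v:g}\n")


# ------------------------------------------------------------------------- SAM

def _placement_from_aln(aln) -> tuple[str, int, int]:
    return (aln.reference_name, aln.reference_start, aln.reference_end)


def _xa_placements(aln) -> list[tuple[str, int, int]]:
    """Parse BWA-style XA:Z:chr,±pos,CIGAR,NM;... auxiliary placements."""
    out = []
    if not aln.has_tag("XA"):
        return out
    length = aln.query_length or (aln.reference_end - aln.reference_start)
    for entry in aln.get_tag("XA").rstrip(";").split(";"):
        chrom, pos, _cigar, _nm = entry.split(",")
        start = abs(int(pos)) - 1  # XA positions are 1-based, sign = strand
        out.append((chrom, start, start + length))
    return out


def read_sam_reads(path) -> list[AlignedRead]:
    """Read a (minimal) SAM into multi-placement reads.

    Multi-mapping is accepted in both dialects: repeated records per QNAME
    (secondary alignments) and XA auxiliary tags; placements are pooled and
    de-duplicated per read.
    """
    placements: dict[str, list[tuple[str, int, int]]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            name = aln.query_name
            if name not in placements:
                placements[name] = []
                order.append(name)
            placements[name].append(_placement_from_aln(aln))
            placements[name].extend(_xa_placements(aln))
    reads = []
    for name in order:
        uniq = tuple(dict.fromkeys(placements[name]))
        reads.append(AlignedRead(name, uniq))
    return reads


def read_sam_placements(path) -> pd.DataFrame:
    """Per-placement 5' positions for coverage counting.

    Every placement of a multi-mapped read contributes one point; the 5'
    position of a reverse-strand placement is its rightmost aligned base.
    """
    rows = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            pos = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            rows.append((aln.reference_name, pos))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def write_sam(path, reads, chrom_sizes: dict[str, int]) -> None:
    """Write multi-placement reads as SAM, extra placements as secondary."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_sizes.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        refid = {c: i for i, c in enumerate(chrom_sizes)}
        for read in reads:
            for k, (chrom, start, end) in enumerate(read.placements):
                a = pysam.AlignedSegment(sam.header)
                a.query_name = read.read_id
                a.reference_id = refid[chrom]
                a.reference_start = start
                a.cigarstring = f"{end - start}M"
                a.mapping_quality = 0 if len(read.placements) > 1 else 60
                a.flag = 0 if k == 0 else 256  # secondary
                a.query_sequence = "N" * (end - start) if k == 0 else None
                sam.write(a)


# ---------------------------------------------------------------- track tables

def write_tracks_tsv(path, tracks) -> None:
    """Wide TSV: chrom/start/end plus one column per track."""
    grid = tracks[0].grid
    df = grid.to_frame()
    for t in tracks:
        df[t.label] = t.values
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tracks_tsv(path, width: int | None = None):
    """Read a wide track TSV back into (grid, tracks)."""
    df = pd.read_csv(path, sep="\t", na_values="NA")
    chrom_sizes = df.groupby("chrom", sort=False)["end"].max().to_dict()
    if width is None:
        width = int((df["end"] - df["start"]).max())
    from repkin.genome_binning import bin_genome

    grid = bin_genome(chrom_sizes, width)
    tracks = [
        FeatureTrack(grid, col, df[col].to_numpy(dtype=float))
        for col in df.columns[3:]
    ]
    return grid, tracks


def write_correlation_tsvs(prefix, matrix) -> None:
    """Write rho/p-value/n TSVs with a shared path prefix."""
    prefix = str(prefix)
    matrix.rho.to_csv(prefix + ".rho.tsv", sep="\t", na_rep="NA")
    matrix.pvalue.to_csv(prefix + ".pvalue.tsv", sep="\t", na_rep="NA")
    matrix.n_used.to_csv(prefix + ".n.tsv", sep="\t")


# ------------------------------------------------------------------------ TIFF

def read_stack_tiff(channel_paths: dict[str, os.PathLike], voxel_size):
    """Read one multi-page TIFF per channel into an ImageStack."""
    from repkin.imaging_coloc import ImageStack

    channels = {
        name: np.asarray(tifffile.imread(str(p)), dtype=float)
        for name, p in channel_paths.items()
    }
    return ImageStack(channels, tuple(voxel_size))


def write_stack_tiff(out_dir, stack, prefix: str = "cell") -> dict[str, Path]:
    """Write each channel as <prefix>_<channel>.tif; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, ch in stack.channels.items():
        p = out_dir / f"{prefix}_{name}.tif"
        tifffile.imwrite(str(p), np.asarray(ch, dtype=np.float32))
        paths[name] = p
    return paths


def read_grouping(path) -> dict[str, str]:
    """Two-column TSV (or YAML) mapping annotation families to classes."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            return dict(yaml.safe_load(fh))
    df = pd.read_csv(path, sep="\t", header=None, names=["family", "cls"])
    return dict(zip(df["family"], df["cls"]))
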