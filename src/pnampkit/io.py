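"""Readers and writers for the plain-text formats the pipeline touches.

Count tables are CSV with columns ``chrom,bin_index,watson,crick`` (one file
per strain, 100-bp bins by default).  Tracks go out as 4-column bedgraph
(0-based half-open) or fixedStep wig (1-based starts, step = span = bin size);
masked bins are simply omitted, which in wig means starting a fresh fixedStep
block after each gap.  Intervals come in as BED3 plus an optional label
column.  Alignment records may be ingested from a simple TSV export rather
than BAM.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tracks import AlignmentRecord, BinnedTrack, GenomicInterval

PathLike = Union[str, Path]

COUNT_COLUMNS = ("chrom", "bin_index", "watson", "crick")


def load_count_table(
    path: PathLike, bin_size: int = 100
) -> Dict[str, Tuple[BinnedTrack, BinnedTrack]]:
    """Load a per-strain bin-count CSV into (Watson, Crick) track pairs.

    Returns a mapping ``chrom -> (watson_track, crick_track)`` with raw counts
    as values and an all-false mask.  Bin indices must be contiguous from 0
    per chromosome and counts non-negative.
    """
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing}")
    if len(df) == 0:
        raise ValueError("no bins")
    if (df["watson"] < 0).any() or (df["crick"] < 0).any():
        raise ValueError("negative count in table")
    out: Dict[str, Tuple[BinnedTrack, BinnedTrack]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = sub["bin_index"].to_numpy()
        expected = np.arange(len(sub))
        if not np.array_equal(np.sort(idx), expected):
            raise ValueError(
                f"ragged bin indices for {chrom}: expected contiguous 0..{len(sub) - 1}"
            )
        sub = sub.sort_values("bin_index")
        out[str(chrom)] = (
            BinnedTrack(str(chrom), bin_size, sub["watson"].to_numpy(float), "watson"),
            BinnedTrack(str(chrom), bin_size, sub["crick"].to_numpy(float), "crick"),
        )
    return out


def write_count_table(
    path: PathLike, watson: BinnedTrack, crick: BinnedTrack
) -> None:
    """Write a (Watson, Crick) track pair as a bin-count CSV."""
    if not watson.same_grid(crick):
        raise ValueError("watson and crick tracks on different grids")
    pd.DataFrame(
        {
            "chrom": watson.chrom,
            "bin_index": np.arange(watson.n_bins),
            "watson": watson.values,
            "crick": crick.values,
        }
    ).to_csv(path, index=False)


def write_track(track: BinnedTrack, path: PathLike, format: str = "bedgraph") -> None:
    """Write a track as bedgraph or fixedStep wig; masked bins are omitted."""
    if format not in ("bedgraph", "wig"):
        raise ValueError(f"unknown track format {format!r}")
    path = Path(path)
    chrom_end = (
        track.chrom_length
        if track.chrom_length is not None
        else track.n_bins * track.bin_size
    )
    with open(path, "w") as fh:
        if format == "bedgraph":
            for i in range(track.n_bins):
                if track.mask[i]:
                    continue
                start = i * track.bin_size
                end = min(start + track.bin_size, chrom_end)
                fh.write(f"{track.chrom}\t{start}\t{end}\t{track.values[i]:g}\n")
        else:  # wig: 1-based fixedStep; new block after every masked gap
            in_block = False
            for i in range(track.n_bins):
                if track.mask[i]:
                    in_block = False
                    continue
                if not in_block:
                    start1 = i * track.bin_size + 1
                    fh.write(
                        f"fixedStep chrom={track.chrom} start={start1} "
                        f"step={track.bin_size} span={track.bin_size}\n"
                    )
                    in_block = True
                fh.write(f"{track.values[i]:g}\n")


def load_bedgraph_track(
    path: PathLike, bin_size: int = 100, strand: str = "unstranded"
) -> BinnedTrack:
    """Read a single-chromosome bedgraph written by :func:`write_track`.

    Bins absent from the file are restored as masked (value 0).
    """
    rows: List[Tuple[str, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    if not rows:
        raise ValueError("empty bedgraph")
    chroms = {r[0] for r in rows}
    if len(chroms) != 1:
        raise ValueError(f"expected one chromosome, found {sorted(chroms)}")
    chrom = rows[0][0]
    n_bins = max(r[1] for r in rows) // bin_size + 1
    values = np.zeros(n_bins)
    mask = np.ones(n_bins, dtype=bool)
    for _, start, _end, value in rows:
        if start % bin_size != 0:
            raise ValueError(f"bedgraph start {start} not on a {bin_size}-bp grid")
        values[start // bin_size] = value
        mask[start // bin_size] = False
    return BinnedTrack(chrom, bin_size, values, strand, mask)


def load_intervals(path: PathLike) -> List[GenomicInterval]:
    """Read BED3(+label) intervals (0-based half-open)."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else ""
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), label))
    return out


def write_intervals(path: PathLike, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


ALIGNMENT_COLUMNS = ("read_id", "chrom", "five_prime_pos", "strand")


def read_alignment_tsv(path: PathLike) -> List[AlignmentRecord]:
    """Read alignment records from TSV.

    Required columns: read_id, chrom, five_prime_pos, strand; optional:
    primary_score, secondary_score (blank = absent).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment TSV missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        primary = getattr(row, "primary_score", None)
        secondary = getattr(row, "secondary_score", None)
        records.append(
            AlignmentRecord(
                read_id=str(row.read_id),
                chrom=str(row.chrom),
                five_prime_pos=int(row.five_prime_pos),
                strand=str(row.strand),
                primary_score=None if pd.isna(primary) else float(primary),
                secondary_score=None if pd.isna(secondary) else float(secondary),
            )
        )
    return records


def read_fasta(path: PathLike) -> List[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(path: PathLike, records: Sequence[SeqRecord]) -> None:
    SeqIO.write(records, str(path), "fasta")


def make_seq_record(seq: str, name: str, description: str = "") -> SeqRecord:
    return SeqRecord(Seq(seq), id=name, description=description)
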