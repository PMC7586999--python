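"""Readers and writers for the plain-text genomics formats the pipeline touches.

Formats: chrom.sizes TSV, MACS2 narrowPeak (and a headered TSV fallback),
bedGraph, wiggle (fixedStep / variableStep, 1-based start converted at this
boundary), BED fragment lists, FASTA, 4-row PFM TSV / JASPAR matrices and
sample sheets. All readers accept gzip-compressed files transparently;
bigWig is supported behind the same track contract when pyBigWig is present.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak
from .tracks import CoverageTrack, GenomeSequence


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# peaks

_NARROWPEAK_COLS = 10


def read_peaks(path: str | Path) -> list[Peak]:
    """Read peaks from a narrowPeak file (or a headered TSV with the same
    content: chrom, start, end, name, score, strand, fold_enrichment, ...,
    summit offset in the last column).

    The narrowPeak summit column is an offset from ``start``; it is
    converted here to an absolute 0-based coordinate.
    """
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < _NARROWPEAK_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_NARROWPEAK_COLS} narrowPeak "
                    f"columns, got {len(fields)}"
                )
            # skip a header row of a TSV export
            if lineno == 1 and fields[1].lower() in ("start", "chromstart"):
                continue
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[4])
                strand = fields[5] if fields[5] in ("+", "-", ".") else "."
                fold = float(fields[6])
                offset = int(fields[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            if offset < 0 or offset >= end - start:
                raise ValueError(
                    f"{path}:{lineno}: summit offset {offset} outside peak of "
                    f"length {end - start}"
                )
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    summit=start + offset,
                    fold_enrichment=fold,
                    score=score,
                    id=name or f"peak_{lineno}",
                )
            )
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        iv.chrom,
                        iv.start,
                        iv.end,
                        p.id,
                        p.score,
                        iv.strand,
                        p.fold_enrichment,
                        -1,
                        -1,
                        p.summit - iv.start,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# coverage tracks


def read_track(path: str | Path, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """Read a bedGraph, wiggle or bigWig file into per-base coverage.

    Uncovered bases are 0; overlapping records sum (midpoint-smoothed
    tracks are additive by construction). Wiggle coordinates are 1-based
    in the format and converted to the package's 0-based convention here.
    """
    spath = str(path)
    if spath.endswith((".bw", ".bigwig", ".bigWig")):
        return _read_bigwig(spath, chrom_sizes)
    track = CoverageTrack(chrom_sizes)
    with _open_text(path) as fh:
        first = fh.read(4096)
        fh2 = _io.StringIO(first + fh.read())
    if _looks_like_wig(first):
        _read_wig_into(fh2, track, spath)
    else:
        _read_bedgraph_into(fh2, track, spath)
    return track


def _looks_like_wig(head: str) -> bool:
    for line in head.splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        return line.startswith(("fixedStep", "variableStep"))
    return False


def _read_bedgraph_into(fh: TextIO, track: CoverageTrack, name: str) -> None:
    for lineno, line in enumerate(fh, 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"{name}:{lineno}: expected 4 bedGraph columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if chrom not in track:
            raise ValueError(f"{name}:{lineno}: unknown chromosome {chrom!r}")
        if end > len(track[chrom]):
            raise ValueError(
                f"{name}:{lineno}: record end {end} beyond chromosome "
                f"{chrom} length {len(track[chrom])}"
            )
        track.add(chrom, start, end, value)


def _read_wig_into(fh: TextIO, track: CoverageTrack, name: str) -> None:
    chrom, pos, step, span, mode = None, 0, 1, 1, None
    for lineno, line in enumerate(fh, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith(("fixedStep", "variableStep")):
            params = dict(kv.split("=") for kv in line.split()[1:])
            chrom = params["chrom"]
            span = int(params.get("span", 1))
            if line.startswith("fixedStep"):
                mode = "fixed"
                pos = int(params["start"]) - 1  # wig is 1-based
                step = int(params.get("step", 1))
            else:
                mode = "variable"
            if chrom not in track:
                raise ValueError(f"{name}:{lineno}: unknown chromosome {chrom!r}")
            continue
        if mode is None or chrom is None:
            raise ValueError(f"{name}:{lineno}: data before a wig declaration line")
        if mode == "fixed":
            value = float(line)
            start = pos
            pos += step
        else:
            p, v = line.split()[:2]
            start = int(p) - 1
            value = float(v)
        if start + span > len(track[chrom]):
            raise ValueError(
                f"{name}:{lineno}: record beyond chromosome {chrom} end"
            )
        track.add(chrom, start, start + span, value)


def _read_bigwig(path: str, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    import pyBigWig  # optional, behind the same contract

    track = CoverageTrack(chrom_sizes)
    with pyBigWig.open(path) as bw:
        for chrom, size in chrom_sizes.items():
            if chrom not in bw.chroms():
                continue
            vals = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, min(size, bw.chroms()[chrom])))
            )
            track[chrom][: len(vals)] += vals
    return track


def write_track(track: CoverageTrack, path: str | Path) -> None:
    """Write as bedGraph, run-length encoding constant stretches and
    omitting zero runs; read_track(write_track(t)) reproduces t exactly."""
    with _open_text(path, "wt") as fh:
        for chrom, arr in track.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# fragments (BED), FASTA, PFM, sample sheet


def read_fragments(path: str | Path) -> list[GenomicInterval]:
    """Paired-end fragment spans from a BED3+ file."""
    frags: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            frags.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return frags


def write_fragments(frags: Iterable[GenomicInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in frags:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_fasta(path: str | Path) -> GenomeSequence:
    from Bio import SeqIO

    with _open_text(path) as fh:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for chrom in genome.chroms:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pfm(path: str | Path) -> np.ndarray:
    """Position frequency matrix as a 4 x L array (rows A, C, G, T).

    Accepts a 4-row TSV whose first column is the base label, or a
    JASPAR-style file (``>name`` then ``A [ n n n ]`` rows).
    """
    rows: dict[str, list[float]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ">")):
                continue
            cleaned = line.replace("[", " ").replace("]", " ")
            fields = cleaned.split()
            base = fields[0].upper()
            if base not in "ACGT":
                raise ValueError(f"{path}: unexpected PFM row label {fields[0]!r}")
            rows[base] = [float(x) for x in fields[1:]]
    if set(rows) != set("ACGT"):
        raise ValueError(f"{path}: PFM needs rows A, C, G and T; got {sorted(rows)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: PFM rows have unequal lengths {sorted(lengths)}")
    return np.array([rows[b] for b in "ACGT"], dtype=float)


def write_pfm(pfm: np.ndarray, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for base, row in zip("ACGT", np.asarray(pfm)):
            fh.write(base + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


SAMPLE_SHEET_COLUMNS = ["path", "time_min", "replicate", "role", "total_fragments"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """TSV describing one sequencing sample per row.

    Columns: path, time_min, replicate, role (IP/input), total_fragments.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    df["time_min"] = df["time_min"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    df["total_fragments"] = df["total_fragments"].astype(int)
    return df
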