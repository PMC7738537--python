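"""Strand-specific read-end count tracks.

dRNA-Seq marks transcript 5' boundaries and Term-Seq marks 3' boundaries by
piling sequenced read ends at single-nucleotide positions.  This module turns
alignments (SAM/BAM or BED6) into per-replicon, per-strand integer tracks of
read-end counts: the raw material for the enrichment statistic in
:mod:`txends.calling`.

Conventions
-----------
* Internal coordinates are 1-based inclusive; ``counts[i]`` is the count at
  genomic position ``i + 1``.
* BED and bedGraph files are 0-based half-open, GFF3 is 1-based inclusive,
  matching each format's standard.
* For a ``+`` strand alignment the 5' end is its leftmost position and the
  3' end its rightmost; for a ``-`` strand alignment the reverse.
* Term-Seq reads sequence the transcript 3' end antisense, so their strands
  must be flipped (:func:`invert_termseq_read`) *before* counting 3' ends.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
STRANDS = ("+", "-")

# SAM flags for records that carry no usable primary position
_FLAG_UNMAPPED = 0x4
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class Replicon:
    """A reference sequence (chromosome or plasmid).

    Streptomyces chromosomes are linear, so ``topology`` defaults to
    ``"linear"``; circular replicons wrap the background window of the
    enrichment statistic around the origin.
    """

    id: str
    length: int
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("replicon id must be non-empty")
        if self.length < 1:
            raise ValueError(f"replicon length must be >= 1, got {self.length}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")


class AlignedRead(NamedTuple):
    """A mapped read interval, 1-based inclusive reference coordinates."""

    replicon_id: str
    start: int
    end: int
    strand: str


@dataclass
class EndCountTrack:
    """Per-position counts of read ends on one replicon strand.

    ``counts[i]`` is the number of read 5' (or 3') ends at position ``i+1``.
    ``library_size`` is the total number of primary mapped alignments in the
    originating library (both strands, all replicons) and is the denominator
    for CPM normalization.
    """

    replicon_id: str
    strand: str
    end_type: str
    counts: np.ndarray
    library_label: str = ""
    library_size: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end_type not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"unknown end_type {self.end_type!r}")
        if (self.counts < 0).any():
            raise ValueError("end counts must be non-negative")

    @property
    def length(self) -> int:
        return int(self.counts.size)


@dataclass
class NormalizedTrack:
    """Counts-per-million view of an :class:`EndCountTrack`."""

    replicon_id: str
    strand: str
    end_type: str
    values: np.ndarray
    library_label: str = ""


def invert_termseq_read(read: AlignedRead) -> AlignedRead:
    """Flip the strand of a Term-Seq alignment, keeping its interval.

    Term-Seq sequencing output runs antisense to the transcript, so the
    mapped orientation must be inverted before 3'-end counting.  The
    operation is an involution.
    """
    return read._replace(strand="-" if read.strand == "+" else "+")


def _replicon_map(replicons: Sequence[Replicon]) -> dict[str, Replicon]:
    return {r.id: r for r in replicons}


def _read_bed(path: Path, by_id: Mapping[str, Replicon]) -> Iterator[AlignedRead]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 record needs 6 columns, got {len(fields)}"
                )
            chrom, start0, end0, _name, _score, strand = fields[:6]
            if chrom not in by_id:
                raise ValueError(f"{path}:{lineno}: unknown replicon id {chrom!r}")
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                s0, e0 = int(start0), int(end0)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= s0 < e0):
                raise ValueError(f"{path}:{lineno}: bad interval {s0}..{e0}")
            if e0 > by_id[chrom].length:
                raise ValueError(
                    f"{path}:{lineno}: interval end {e0} beyond replicon "
                    f"{chrom!r} length {by_id[chrom].length}"
                )
            # BED is 0-based half-open; internal is 1-based closed.
            yield AlignedRead(chrom, s0 + 1, e0, strand)


def _read_sam(path: Path, by_id: Mapping[str, Replicon]) -> Iterator[AlignedRead]:
    import pysam

    save = pysam.set_verbosity(0)  # silence missing-index warning for BAM
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for i, rec in enumerate(fh, start=1):
                if rec.flag & (_FLAG_UNMAPPED | _FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
                    continue
                if rec.reference_name is None or rec.reference_end is None:
                    continue
                rid = rec.reference_name
                if rid not in by_id:
                    raise ValueError(f"{path}: record {i}: unknown replicon id {rid!r}")
                # reference_start is 0-based, reference_end is exclusive:
                # clipped bases have no reference coordinate and are excluded.
                yield AlignedRead(
                    rid,
                    rec.reference_start + 1,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
    finally:
        pysam.set_verbosity(save)


def read_alignments(
    path: str | os.PathLike, replicons: Sequence[Replicon]
) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM or BED6 file.

    Unmapped, secondary and supplementary records are skipped.  Records
    naming a replicon absent from ``replicons`` raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    by_id = _replicon_map(replicons)
    suffix = path.suffix.lower()
    if suffix in (".bed",):
        yield from _read_bed(path, by_id)
    elif suffix in (".sam", ".bam", ".cram"):
        yield from _read_sam(path, by_id)
    else:
        raise ValueError(f"cannot infer alignment format from suffix {suffix!r}")


def count_ends(
    reads: Iterable[AlignedRead],
    end_type: str,
    replicons: Sequence[Replicon],
    library_label: str = "",
) -> dict[tuple[str, str], EndCountTrack]:
    """Count read 5' or 3' ends per position, strand and replicon.

    Each read increments exactly one position on the track matching its
    strand: for ``+`` reads the 5' end is ``start`` and the 3' end is
    ``end``; for ``-`` reads the converse.  Replicons with no reads get
    all-zero tracks so downstream shapes are predictable.  The total number
    of counted reads is stored as ``library_size`` on every track.
    """
    if end_type not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"unknown end_type {end_type!r}")
    arrays = {
        (rep.id, strand): np.zeros(rep.length, dtype=np.int64)
        for rep in replicons
        for strand in STRANDS
    }
    n_reads = 0
    for read in reads:
        if (read.replicon_id, read.strand) not in arrays:
            raise ValueError(f"unknown replicon id {read.replicon_id!r}")
        if read.strand == "+":
            pos = read.start if end_type == FIVE_PRIME else read.end
        else:
            pos = read.end if end_type == FIVE_PRIME else read.start
        arrays[(read.replicon_id, read.strand)][pos - 1] += 1
        n_reads += 1
    return {
        key: EndCountTrack(
            replicon_id=key[0],
            strand=key[1],
            end_type=end_type,
            counts=arr,
            library_label=library_label,
            library_size=n_reads,
        )
        for key, arr in arrays.items()
    }


def normalize_cpm(track: EndCountTrack) -> NormalizedTrack:
    """Scale counts to counts per million mapped library reads."""
    if track.library_size <= 0:
        raise ValueError(
            f"cannot normalize track {track.library_label!r} "
            f"({track.replicon_id}{track.strand}): library_size is 0"
        )
    return NormalizedTrack(
        replicon_id=track.replicon_id,
        strand=track.strand,
        end_type=track.end_type,
        values=track.counts.astype(np.float64) * 1e6 / track.library_size,
        library_label=track.library_label,
    )


# ---------------------------------------------------------------------------
# bedGraph track I/O


def _runs(values: np.ndarray) -> Iterator[tuple[int, int, float]]:
    """Yield (start0, end0, value) runs of equal non-zero values."""
    n = values.size
    if n == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        v = values[s]
        if v != 0:
            yield int(s), int(e), v


def write_bedgraph(track_values: np.ndarray, replicon_id: str, path: str | os.PathLike) -> None:
    """Write one per-position array as 0-based half-open bedGraph."""
    values = np.asarray(track_values)
    with open(path, "w") as fh:
        for s, e, v in _runs(values):
            if float(v).is_integer():
                fh.write(f"{replicon_id}\t{s}\t{e}\t{int(v)}\n")
            else:
                fh.write(f"{replicon_id}\t{s}\t{e}\t{v:.6g}\n")


def write_track(track: EndCountTrack, path: str | os.PathLike) -> None:
    """Write a count track as bedGraph (runs of equal counts merged)."""
    write_bedgraph(track.counts, track.replicon_id, path)


def read_bedgraph_values(
    path: str | os.PathLike,
    replicons: Sequence[Replicon],
    dtype=np.float64,
) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-replicon arrays; uncovered positions are 0.

    Overlapping intervals are a fatal error: a bedGraph is a function of
    position, not a pile-up.
    """
    by_id = _replicon_map(replicons)
    arrays = {r.id: np.zeros(r.length, dtype=dtype) for r in replicons}
    seen: dict[str, list[tuple[int, int]]] = {r.id: [] for r in replicons}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, s0, e0, val = fields[:4]
            if chrom not in by_id:
                raise ValueError(f"{path}:{lineno}: unknown replicon id {chrom!r}")
            s, e = int(s0), int(e0)
            if not (0 <= s < e <= by_id[chrom].length):
                raise ValueError(f"{path}:{lineno}: bad interval {s}..{e}")
            arrays[chrom][s:e] += np.asarray(val, dtype=dtype)
            seen[chrom].append((s, e))
    for rid, ivs in seen.items():
        ivs.sort()
        for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping bedGraph intervals on {rid!r} "
                    f"({s1}..{e1} and {s2}..)"
                )
    return arrays


def read_track(
    path: str | os.PathLike,
    replicon: Replicon,
    strand: str,
    end_type: str,
    library_label: str = "",
    library_size: int | None = None,
) -> EndCountTrack:
    """Read one strand's bedGraph back into an :class:`EndCountTrack`."""
    arrays = read_bedgraph_values(path, [replicon], dtype=np.int64)
    counts = arrays[replicon.id]
    if library_size is None:
        library_size = int(counts.sum())
    return EndCountTrack(
        replicon_id=replicon.id,
        strand=strand,
        end_type=end_type,
        counts=counts,
        library_label=library_label,
        library_size=library_size,
    )


# ---------------------------------------------------------------------------
# Track manifests: one TSV row per bedGraph file of a library

MANIFEST_COLUMNS = ("label", "end_type", "strand", "library_size", "path")


def write_track_manifest(rows: Sequence[Mapping[str, object]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in MANIFEST_COLUMNS) + "\n")


def read_track_manifest(path: str | os.PathLike) -> list[dict[str, object]]:
    rows: list[dict[str, object]] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != list(MANIFEST_COLUMNS):
            raise ValueError(f"{path}: unexpected manifest header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            values = line.split("\t")
            row = dict(zip(MANIFEST_COLUMNS, values))
            row["library_size"] = int(row["library_size"])  # type: ignore[index]
            rows.append(row)
    return rows


def write_library(
    tracks: Mapping[tuple[str, str], EndCountTrack],
    out_dir: str | os.PathLike,
    label: str,
) -> list[dict[str, object]]:
    """Write all tracks of one library as bedGraph files plus manifest rows.

    One file per (replicon, strand) with ``.plus.bedgraph`` /
    ``.minus.bedgraph`` suffixes; returns the manifest rows written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict[str, object]] = []
    for (rid, strand), track in sorted(tracks.items()):
        suffix = "plus" if strand == "+" else "minus"
        fname = f"{label}.{rid}.{suffix}.bedgraph"
        write_track(track, out_dir / fname)
        rows.append(
            {
                "label": label,
                "end_type": track.end_type,
                "strand": strand,
                "library_size": track.library_size,
                "path": fname,
            }
        )
    return rows
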