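"""RNA-Seq density validation of called boundaries.

If called TSSs are genuine transcript 5' boundaries, average RNA-Seq read
depth should step up across them in transcript orientation; across genuine
TTSs it should step down.  This module computes metagene (metaplot)
profiles of strand-specific coverage in fixed windows centred on site sets
and a scalar downstream/upstream density ratio quantifying the step.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calling import SITE_TSS, SITE_TTS, BoundarySite
from .tracks import Replicon, read_bedgraph_values

DEFAULT_FLANK = 100
DEFAULT_EPS = 1e-6


@dataclass
class CoverageTrack:
    """Per-position RNA-Seq read depth on one replicon strand."""

    replicon_id: str
    strand: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("coverage must be non-negative")


@dataclass
class MetaProfile:
    """Mean coverage per offset around a site set, transcript-oriented.

    Offsets run -flank..+flank; positive offsets point downstream in
    transcript orientation regardless of genomic strand.
    """

    offsets: np.ndarray
    mean_density: np.ndarray
    n_sites: int
    n_dropped: int = 0


def read_bedgraph_coverage(
    path_plus: str | os.PathLike,
    path_minus: str | os.PathLike,
    replicons: Sequence[Replicon],
) -> dict[tuple[str, str], CoverageTrack]:
    """Load a strand-specific bedGraph pair into coverage tracks."""
    out: dict[tuple[str, str], CoverageTrack] = {}
    for strand, path in (("+", path_plus), ("-", path_minus)):
        arrays = read_bedgraph_values(path, replicons)
        for rid, values in arrays.items():
            out[(rid, strand)] = CoverageTrack(rid, strand, values)
    return out


def metaprofile(
    coverage: Mapping[tuple[str, str], CoverageTrack],
    sites: Sequence[BoundarySite],
    flank: int = DEFAULT_FLANK,
) -> MetaProfile:
    """Average coverage in +-flank windows centred on each site.

    Coverage is taken from the track matching each site's strand; for minus
    strand sites the offset axis is reversed so positive offsets always
    point downstream along the transcript.  Sites whose window runs off the
    replicon are dropped and counted in ``n_dropped``.
    """
    if not sites:
        raise ValueError("metaprofile needs at least one site")
    width = 2 * flank + 1
    total = np.zeros(width)
    used = 0
    dropped = 0
    for site in sites:
        key = (site.replicon_id, site.strand)
        if key not in coverage:
            raise ValueError(f"no coverage track for {key}")
        values = coverage[key].values
        lo = site.position - flank - 1  # 0-based window start
        hi = site.position + flank
        if lo < 0 or hi > values.size:
            dropped += 1
            continue
        window = values[lo:hi]
        if site.strand == "-":
            window = window[::-1]
        total += window
        used += 1
    if used == 0:
        raise ValueError("no usable sites: all windows exceed the replicon")
    return MetaProfile(
        offsets=np.arange(-flank, flank + 1),
        mean_density=total / used,
        n_sites=used,
        n_dropped=dropped,
    )


def step_statistic(profile: MetaProfile, eps: float = DEFAULT_EPS) -> float:
    """Downstream/upstream mean-density ratio of a metaprofile.

    Ratio of the mean density over offsets 1..flank to the mean over
    -flank..-1, with the denominator floored at ``eps``.  A step increase
    (TSS) gives a ratio > 1, a step decrease (TTS) a ratio < 1; flat
    coverage gives exactly 1.
    """
    flank = (profile.offsets.size - 1) // 2
    upstream = float(np.mean(profile.mean_density[:flank]))
    downstream = float(np.mean(profile.mean_density[flank + 1 :]))
    return downstream / max(upstream, eps)


def write_metaprofile_tsv(
    profiles: Mapping[str, MetaProfile], path: str | os.PathLike
) -> None:
    """TSV with one offset column and one mean-density column per profile."""
    labels = sorted(profiles)
    if not labels:
        raise ValueError("no profiles to write")
    offsets = profiles[labels[0]].offsets
    for label in labels:
        if not np.array_equal(profiles[label].offsets, offsets):
            raise ValueError("profiles have mismatched offset axes")
    with open(path, "w") as fh:
        fh.write("offset\t" + "\t".join(labels) + "\n")
        for i, off in enumerate(offsets):
            row = "\t".join(f"{profiles[l].mean_density[i]:.6g}" for l in labels)
            fh.write(f"{off}\t{row}\n")
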