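"""Read-count enrichment statistic and boundary-site calling.

The caller scores every genomic position x by a local modified z-score

    Z(x) = (r(x) - m(C(x))) / sigma(C(x))

where r(x) is the read-end count at x and m, sigma are the mean and standard
deviation of counts over the ring window C(x) = {y : e < |x - y| <= w}
(defaults e = 2, w = 50).  Excluding the focal position and its immediate
neighbourhood keeps the boundary's own signal out of the background
estimate.  Z is computed per biological replicate and then averaged.

Filters, in pipeline order:

* positions where the local background mean m(C(x)) <= 0.25 in *any*
  replicate are masked (too little signal to estimate a background);
* for dRNA-Seq only, a position is eligible only where the TAP(+) CPM is
  more than two-fold the TAP(-) CPM (strict) — processed 5' ends ligate in
  both libraries and fail this test, primary (triphosphate) 5' ends pass;
* positions with averaged z-score strictly greater than 12 are retained;
* among retained positions within 3 nt of each other, only the highest
  z-score survives (greedy, descending z, ties to the smaller coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .tracks import EndCountTrack, NormalizedTrack, normalize_cpm

SITE_TSS = "TSS"
SITE_TTS = "TTS"


@dataclass(frozen=True)
class CallingParams:
    """All numeric knobs of the boundary-calling procedure.

    Attributes
    ----------
    exclusion_radius:
        Positions within this distance of the focal position (including the
        position itself) are excluded from the background window (nt).
    window_radius:
        Outer radius of the background window (nt).
    min_local_mean:
        Mask positions whose window mean is <= this value in any replicate.
    tap_fold:
        dRNA-Seq eligibility requires TAP(+) CPM strictly greater than
        ``tap_fold`` times TAP(-) CPM.
    z_threshold:
        Retain positions with averaged z strictly greater than this.
    collapse_distance:
        Retained positions within this distance (|delta| <= d) of a stronger
        one are discarded (nt).
    sd_mode:
        ``"population"`` (divide by n) or ``"sample"`` (n - 1) for sigma.
    sd_floor:
        If > 0, sigma is replaced by max(sigma, sd_floor); with the default
        0, zero-variance windows leave z undefined and the position masked.
    tap_mode:
        ``"per_replicate"``: the fold test must hold in every replicate
        pair; ``"pooled"``: it is applied to replicate-averaged CPM.
    """

    exclusion_radius: int = 2
    window_radius: int = 50
    min_local_mean: float = 0.25
    tap_fold: float = 2.0
    z_threshold: float = 12.0
    collapse_distance: int = 3
    sd_mode: str = "population"
    sd_floor: float = 0.0
    tap_mode: str = "per_replicate"

    def __post_init__(self) -> None:
        if not (0 <= self.exclusion_radius < self.window_radius):
            raise ValueError("need 0 <= exclusion_radius < window_radius")
        if self.min_local_mean < 0:
            raise ValueError("min_local_mean must be >= 0")
        if self.tap_fold <= 0:
            raise ValueError("tap_fold must be > 0")
        if self.collapse_distance < 0:
            raise ValueError("collapse_distance must be >= 0")
        if self.sd_mode not in ("population", "sample"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")
        if self.sd_floor < 0:
            raise ValueError("sd_floor must be >= 0")
        if self.tap_mode not in ("per_replicate", "pooled"):
            raise ValueError(f"unknown tap_mode {self.tap_mode!r}")


@dataclass
class LocalStats:
    """Per-position window statistics for one replicate track.

    ``z_raw`` is NaN where undefined: empty window, or zero window SD with
    ``sd_floor == 0``.  ``local_mean``/``local_sd`` are NaN only for empty
    windows.
    """

    z_raw: np.ndarray
    local_mean: np.ndarray
    local_sd: np.ndarray


@dataclass
class ZScoreProfile:
    """Replicate-averaged z-scores with a validity mask for one strand."""

    replicon_id: str
    strand: str
    z: np.ndarray
    masked: np.ndarray


@dataclass(frozen=True)
class BoundarySite:
    """One called transcript boundary (TSS or TTS), 1-based position."""

    replicon_id: str
    position: int
    strand: str
    z: float
    site_type: str


def ring_window(
    x: int, length: int, params: CallingParams, topology: str = "linear"
) -> np.ndarray:
    """Positions forming the background window C(x), 1-based, sorted.

    Linear replicons truncate the window at the ends; circular replicons
    measure distance around the origin (min of the two arc lengths).
    """
    if not (1 <= x <= length):
        raise ValueError(f"position {x} outside 1..{length}")
    e, w = params.exclusion_radius, params.window_radius
    if topology == "linear":
        lo = max(1, x - w)
        hi = min(length, x + w)
        ys = np.arange(lo, hi + 1)
        d = np.abs(ys - x)
    elif topology == "circular":
        ys = np.arange(1, length + 1)
        raw = np.abs(ys - x)
        d = np.minimum(raw, length - raw)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return ys[(d > e) & (d <= w)]


def _linear_window_sums(values: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum and size of {y : |x-y| <= radius} for every x, truncated at ends."""
    n = values.size
    prefix = np.concatenate(([0.0], np.cumsum(values, dtype=np.float64)))
    x = np.arange(1, n + 1)
    hi = np.minimum(x + radius, n)
    lo = np.maximum(x - radius - 1, 0)
    return prefix[hi] - prefix[lo], (hi - lo).astype(np.float64)


def _ring_stats_linear(
    counts: np.ndarray, params: CallingParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = counts.astype(np.float64)
    s_out, n_out = _linear_window_sums(c, params.window_radius)
    s_in, n_in = _linear_window_sums(c, params.exclusion_radius)
    q_out, _ = _linear_window_sums(c * c, params.window_radius)
    q_in, _ = _linear_window_sums(c * c, params.exclusion_radius)
    return s_out - s_in, q_out - q_in, n_out - n_in


def _ring_stats_circular(
    counts: np.ndarray, params: CallingParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = counts.size
    w = params.window_radius
    if n <= 2 * w:
        # Window arms overlap themselves; fall back to explicit windows.
        sums = np.empty(n)
        sqs = np.empty(n)
        sizes = np.empty(n)
        for x in range(1, n + 1):
            ys = ring_window(x, n, params, "circular")
            vals = counts[ys - 1].astype(np.float64)
            sums[x - 1] = vals.sum()
            sqs[x - 1] = (vals * vals).sum()
            sizes[x - 1] = vals.size
        return sums, sqs, sizes
    padded = np.concatenate((counts[-w:], counts, counts[:w])).astype(np.float64)
    s_out, _ = _linear_window_sums(padded, w)
    s_in, _ = _linear_window_sums(padded, params.exclusion_radius)
    q_out, _ = _linear_window_sums(padded * padded, w)
    q_in, _ = _linear_window_sums(padded * padded, params.exclusion_radius)
    size = float(2 * (w - params.exclusion_radius))
    sl = slice(w, w + n)
    return (s_out - s_in)[sl], (q_out - q_in)[sl], np.full(n, size)


def local_zscore(
    track: EndCountTrack | np.ndarray,
    params: CallingParams | None = None,
    topology: str = "linear",
) -> LocalStats:
    """Compute per-position ring-window mean, SD and modified z-score.

    Accepts a full :class:`EndCountTrack` or a bare count array.  Runs in
    O(length) via prefix sums; a brute-force per-position loop over
    :func:`ring_window` gives identical values and is used as the oracle in
    the test suite.
    """
    params = params or CallingParams()
    counts = track.counts if isinstance(track, EndCountTrack) else np.asarray(track)
    if topology == "linear":
        ring_sum, ring_sq, ring_n = _ring_stats_linear(counts, params)
    else:
        ring_sum, ring_sq, ring_n = _ring_stats_circular(counts, params)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ring_n > 0, ring_sum / np.maximum(ring_n, 1), np.nan)
        var = ring_sq / np.maximum(ring_n, 1) - mean * mean
        var = np.maximum(var, 0.0)  # guard tiny negative from rounding
        if params.sd_mode == "sample":
            var = np.where(ring_n > 1, var * ring_n / (ring_n - 1), np.nan)
        sd = np.sqrt(var)
        mean = np.where(ring_n > 0, mean, np.nan)
        sd = np.where(ring_n > 0, sd, np.nan)
        denom = np.maximum(sd, params.sd_floor)
        z = (counts.astype(np.float64) - mean) / denom
        z = np.where(np.isfinite(z), z, np.nan)
        z[~(denom > 0)] = np.nan
    return LocalStats(z_raw=z, local_mean=mean, local_sd=sd)


def mask_low_background(
    replicate_stats: Sequence[LocalStats], params: CallingParams
) -> np.ndarray:
    """Positions invalid in ANY replicate: low window mean or undefined z."""
    if not replicate_stats:
        raise ValueError("need at least one replicate")
    masked = np.zeros(replicate_stats[0].z_raw.size, dtype=bool)
    for stats in replicate_stats:
        masked |= ~np.isfinite(stats.z_raw)
        masked |= ~(stats.local_mean > params.min_local_mean)  # NaN mean masks too
    return masked


def average_replicates(z_raws: Sequence[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of per-replicate z-scores at each position."""
    if not z_raws:
        raise ValueError("need at least one replicate")
    return np.mean(np.vstack(z_raws), axis=0)


def tap_precondition(
    tap_plus: Sequence[NormalizedTrack],
    tap_minus: Sequence[NormalizedTrack],
    params: CallingParams,
) -> np.ndarray:
    """Eligibility mask from the TAP(+)/TAP(-) fold comparison.

    Per-replicate mode requires ``plus > tap_fold * minus`` (strict, no
    pseudocount) in every replicate pair; pooled mode compares the
    replicate-averaged CPM once.  A zero TAP(-) value with positive TAP(+)
    passes; 0 vs 0 fails.
    """
    if len(tap_plus) != len(tap_minus):
        raise ValueError(
            f"TAP(+) and TAP(-) replicate counts differ: "
            f"{len(tap_plus)} vs {len(tap_minus)}"
        )
    if not tap_plus:
        raise ValueError("need at least one TAP replicate pair")
    if params.tap_mode == "pooled":
        plus = np.mean([t.values for t in tap_plus], axis=0)
        minus = np.mean([t.values for t in tap_minus], axis=0)
        return plus > params.tap_fold * minus
    eligible = np.ones(tap_plus[0].values.size, dtype=bool)
    for plus, minus in zip(tap_plus, tap_minus):
        eligible &= plus.values > params.tap_fold * minus.values
    return eligible


def call_sites(
    profile: ZScoreProfile, params: CallingParams, site_type: str
) -> list[BoundarySite]:
    """Threshold and collapse a z-score profile into boundary sites.

    Candidates are unmasked positions with z strictly above the threshold.
    They are accepted greedily in descending z (ties broken toward the
    smaller coordinate); a candidate within ``collapse_distance`` nt of an
    already accepted site is discarded.  Output is sorted by position.
    """
    if site_type not in (SITE_TSS, SITE_TTS):
        raise ValueError(f"unknown site_type {site_type!r}")
    with np.errstate(invalid="ignore"):
        keep = ~profile.masked & np.isfinite(profile.z) & (profile.z > params.z_threshold)
    candidates = np.flatnonzero(keep) + 1  # 1-based
    order = sorted(candidates, key=lambda p: (-profile.z[p - 1], p))
    accepted: list[int] = []
    for pos in order:
        if all(abs(pos - q) > params.collapse_distance for q in accepted):
            accepted.append(int(pos))
    return [
        BoundarySite(
            replicon_id=profile.replicon_id,
            position=pos,
            strand=profile.strand,
            z=float(profile.z[pos - 1]),
            site_type=site_type,
        )
        for pos in sorted(accepted)
    ]


Library = Mapping[tuple[str, str], EndCountTrack]


def _as_libraries(tracks: Sequence) -> list[Library]:
    """Allow bare EndCountTrack replicates as single-track libraries."""
    out: list[Library] = []
    for item in tracks:
        if isinstance(item, EndCountTrack):
            out.append({(item.replicon_id, item.strand): item})
        else:
            out.append(item)
    return out


def _topology_of(rid: str, topologies) -> str:
    if isinstance(topologies, str):
        return topologies
    return topologies.get(rid, "linear")


def build_profile(
    replicate_tracks: Sequence[EndCountTrack],
    params: CallingParams,
    topology: str = "linear",
    eligible: np.ndarray | None = None,
) -> tuple[ZScoreProfile, list[LocalStats]]:
    """Per-replicate z on raw counts -> mask -> (optional eligibility) -> average."""
    stats = [local_zscore(t, params, topology) for t in replicate_tracks]
    masked = mask_low_background(stats, params)
    if eligible is not None:
        masked |= ~eligible
    z_avg = average_replicates([s.z_raw for s in stats])
    first = replicate_tracks[0]
    return ZScoreProfile(first.replicon_id, first.strand, z_avg, masked), stats


def run_drnaseq_calling(
    tap_plus: Sequence[Library | EndCountTrack],
    tap_minus: Sequence[Library | EndCountTrack],
    params: CallingParams | None = None,
    topologies: str | Mapping[str, str] = "linear",
) -> list[BoundarySite]:
    """TSS calling from paired TAP(+)/TAP(-) dRNA-Seq 5'-end tracks.

    ``tap_plus``/``tap_minus`` are per-replicate mappings from
    ``(replicon_id, strand)`` to :class:`EndCountTrack` (as produced by
    :func:`txends.tracks.count_ends`), paired by replicate index.  The
    z-score is computed on raw TAP(+) counts; CPM normalization enters only
    the TAP fold comparison.
    """
    params = params or CallingParams()
    plus_libs = _as_libraries(tap_plus)
    minus_libs = _as_libraries(tap_minus)
    if len(plus_libs) != len(minus_libs):
        raise ValueError(
            f"TAP(+) and TAP(-) replicate counts differ: "
            f"{len(plus_libs)} vs {len(minus_libs)}"
        )
    sites: list[BoundarySite] = []
    for key in sorted(plus_libs[0]):
        rid, _strand = key
        plus_tracks = [lib[key] for lib in plus_libs]
        minus_tracks = [lib[key] for lib in minus_libs]
        eligible = tap_precondition(
            [normalize_cpm(t) for t in plus_tracks],
            [normalize_cpm(t) for t in minus_tracks],
            params,
        )
        profile, _ = build_profile(
            plus_tracks, params, _topology_of(rid, topologies), eligible
        )
        sites.extend(call_sites(profile, params, SITE_TSS))
    return sites


def run_termseq_calling(
    term_tracks: Sequence[Library | EndCountTrack],
    params: CallingParams | None = None,
    topologies: str | Mapping[str, str] = "linear",
) -> list[BoundarySite]:
    """TTS calling from replicated Term-Seq 3'-end tracks (no TAP filter)."""
    params = params or CallingParams()
    libs = _as_libraries(term_tracks)
    if not libs:
        raise ValueError("need at least one Term-Seq replicate")
    sites: list[BoundarySite] = []
    for key in sorted(libs[0]):
        rid, _strand = key
        tracks = [lib[key] for lib in libs]
        profile, _ = build_profile(tracks, params, _topology_of(rid, topologies))
        sites.extend(call_sites(profile, params, SITE_TTS))
    return sites


# ---------------------------------------------------------------------------
# Site table I/O


def write_sites_bed(sites: Sequence[BoundarySite], path) -> None:
    """BED6: score = min(1000, round(10 z)), names TSS_n / TTS_n."""
    counters = {SITE_TSS: 0, SITE_TTS: 0}
    with open(path, "w") as fh:
        for site in sorted(sites, key=lambda s: (s.replicon_id, s.position, s.strand)):
            counters[site.site_type] += 1
            name = f"{site.site_type}_{counters[site.site_type]}"
            score = min(1000, round(site.z * 10))
            fh.write(
                f"{site.replicon_id}\t{site.position - 1}\t{site.position}\t"
                f"{name}\t{score}\t{site.strand}\n"
            )


def write_sites_tsv(sites: Sequence[BoundarySite], path) -> None:
    with open(path, "w") as fh:
        fh.write("replicon\tposition\tstrand\tz\tsite_type\n")
        for site in sorted(sites, key=lambda s: (s.replicon_id, s.position, s.strand)):
            fh.write(
                f"{site.replicon_id}\t{site.position}\t{site.strand}\t"
                f"{site.z:.6g}\t{site.site_type}\n"
            )


def read_sites_tsv(path) -> list[BoundarySite]:
    sites: list[BoundarySite] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:5] != ["replicon", "position", "strand", "z", "site_type"]:
            raise ValueError(f"{path}: unexpected site table header")
        for line in fh:
            if not line.strip():
                continue
            rid, pos, strand, z, stype = line.rstrip("\n").split("\t")[:5]
            sites.append(BoundarySite(rid, int(pos), strand, float(z), stype))
    return sites
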