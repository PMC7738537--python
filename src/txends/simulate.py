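"""Ground-truthed synthetic datasets for end-to-end recovery testing.

The generator emulates the statistical structure the boundary caller
assumes, with every injected feature recorded as ground truth:

* per-position read-end counts as Poisson background (rate ``lambda_bg``)
  with high Poisson spikes at true boundary positions;
* TAP(+) dRNA-Seq tracks with full-strength 5'-end spikes at true TSSs and
  paired TAP(-) tracks where only a small leak fraction of that signal
  remains (imperfect depletion of primary triphosphate ends);
* processed 5' ends, spiked at equal strength in TAP(+) and TAP(-), which a
  correct caller must reject; processed 3' ends spiked in Term-Seq, which
  Term-Seq cannot distinguish from termination;
* independent Poisson draws per biological replicate;
* step-function RNA-Seq coverage: ``rnaseq_depth`` plus Gaussian noise
  between each gene's TSS and TTS, background-level noise elsewhere;
* two region intervals covering 10% of the genome standing in for
  secondary-metabolite biosynthetic gene clusters.

It does not emulate mappability variation, positional biases of library
chemistry, rRNA contamination or overlapping transcription units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import GeneModel, Region
from .calling import Library
from .tracks import (
    FIVE_PRIME,
    THREE_PRIME,
    EndCountTrack,
    Replicon,
    read_track,
    read_track_manifest,
    write_bedgraph,
    write_library,
    write_track_manifest,
)
from .validate import CoverageTrack

# Minimum same-strand distance between injected spikes, chosen so no spike
# sits inside another spike's background ring window (outer radius 50 nt).
MIN_SPIKE_SEPARATION = 120

GENE_LENGTH_RANGE = (300, 1500)
UTR_OFFSET_RANGE = (20, 200)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic dataset.

    Rates are per position per library; strengths are the added Poisson
    mean at a spiked position.
    """

    genome_length: int = 100_000
    n_genes: int = 40
    seed: int = 0
    lambda_bg: float = 1.0
    tss_strength: float = 50.0
    tap_minus_leak: float = 0.05
    n_processed_sites: int = 20
    processed_strength: float = 50.0
    tts_strength: float = 50.0
    n_replicates: int = 2
    rnaseq_depth: float = 20.0
    rnaseq_noise_sd: float = 2.0
    replicon_id: str = "synthetic"

    def __post_init__(self) -> None:
        for name in (
            "lambda_bg",
            "tss_strength",
            "tap_minus_leak",
            "processed_strength",
            "tts_strength",
            "rnaseq_depth",
            "rnaseq_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.genome_length < 1 or self.n_genes < 0:
            raise ValueError("genome_length >= 1 and n_genes >= 0 required")


@dataclass
class SyntheticTruth:
    """Injected ground-truth positions, all 1-based, with strands."""

    tss: list[tuple[int, str]]
    tts: list[tuple[int, str]]
    processed_five: list[tuple[int, str]]
    processed_three: list[tuple[int, str]]


@dataclass
class SimulatedDataset:
    params: SimulationParams
    replicon: Replicon
    genes: list[GeneModel]
    truth: SyntheticTruth
    tap_plus: list[Library]
    tap_minus: list[Library]
    term: list[Library]
    coverage: dict[tuple[str, str], CoverageTrack]
    regions: list[Region]


def _place_genes(params: SimulationParams, rng: np.random.Generator):
    """Place non-overlapping gene cassettes (TSS..gene..TTS spans).

    Cassettes are kept disjoint across both strands so every injected spike
    has a clean local background (this also guarantees the per-strand
    non-overlap the gene models require).
    """
    L = params.genome_length
    occupied: list[tuple[int, int]] = []
    genes: list[GeneModel] = []
    tss: list[tuple[int, str]] = []
    tts: list[tuple[int, str]] = []
    for i in range(params.n_genes):
        for _attempt in range(1000):
            gene_len = int(rng.integers(GENE_LENGTH_RANGE[0], GENE_LENGTH_RANGE[1] + 1))
            utr5 = int(rng.integers(UTR_OFFSET_RANGE[0], UTR_OFFSET_RANGE[1] + 1))
            utr3 = int(rng.integers(UTR_OFFSET_RANGE[0], UTR_OFFSET_RANGE[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            span = utr5 + gene_len + utr3
            if span + 2 * MIN_SPIKE_SEPARATION >= L:
                continue
            start = int(rng.integers(1, L - span + 1))
            stop = start + span - 1
            pad = MIN_SPIKE_SEPARATION
            if any(start - pad <= e and s <= stop + pad for s, e in occupied):
                continue
            occupied.append((start, stop))
            if strand == "+":
                gene = GeneModel(f"g{i + 1:03d}", params.replicon_id, start + utr5, start + utr5 + gene_len - 1, "+")
                tss.append((start, "+"))
                tts.append((stop, "+"))
            else:
                gene = GeneModel(f"g{i + 1:03d}", params.replicon_id, start + utr3, start + utr3 + gene_len - 1, "-")
                tss.append((stop, "-"))
                tts.append((start, "-"))
            genes.append(gene)
            break
        else:
            raise ValueError(
                f"could not place gene {i + 1} without overlap after 1000 attempts; "
                "lower n_genes or increase genome_length"
            )
    return genes, tss, tts, occupied


def _place_processed(
    n: int,
    L: int,
    rng: np.random.Generator,
    taken: dict[str, list[int]],
) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    for j in range(n):
        for _attempt in range(1000):
            pos = int(rng.integers(1 + MIN_SPIKE_SEPARATION, L - MIN_SPIKE_SEPARATION + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if all(abs(pos - p) >= MIN_SPIKE_SEPARATION for p in taken[strand]):
                taken[strand].append(pos)
                out.append((pos, strand))
                break
        else:
            raise ValueError(
                f"could not place processed site {j + 1} after 1000 attempts; "
                "lower n_processed_sites or increase genome_length"
            )
    return out


def _spike_rates(
    L: int,
    base: float,
    spikes: Sequence[tuple[float, Sequence[tuple[int, str]]]],
) -> dict[str, np.ndarray]:
    rates = {s: np.full(L, base, dtype=np.float64) for s in ("+", "-")}
    for strength, positions in spikes:
        for pos, strand in positions:
            rates[strand][pos - 1] += strength
    return rates


def _draw_library(
    rates: dict[str, np.ndarray],
    end_type: str,
    label: str,
    replicon_id: str,
    rng: np.random.Generator,
) -> Library:
    counts = {s: rng.poisson(rates[s]) for s in ("+", "-")}
    library_size = int(sum(c.sum() for c in counts.values()))
    return {
        (replicon_id, s): EndCountTrack(
            replicon_id=replicon_id,
            strand=s,
            end_type=end_type,
            counts=counts[s],
            library_label=label,
            library_size=library_size,
        )
        for s in ("+", "-")
    }


def simulate(params: SimulationParams | None = None, seed: int | None = None) -> SimulatedDataset:
    """Generate one complete dataset; identical params + seed -> identical output."""
    params = params or SimulationParams()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    L = params.genome_length
    replicon = Replicon(params.replicon_id, L, "linear")

    genes, tss, tts, _occupied = _place_genes(params, rng)
    taken = {
        "+": [p for p, s in tss + tts if s == "+"],
        "-": [p for p, s in tss + tts if s == "-"],
    }
    processed_five = _place_processed(params.n_processed_sites, L, rng, taken)
    processed_three = _place_processed(params.n_processed_sites, L, rng, taken)
    truth = SyntheticTruth(tss, tts, processed_five, processed_three)

    plus_rates = _spike_rates(
        L,
        params.lambda_bg,
        [(params.tss_strength, tss), (params.processed_strength, processed_five)],
    )
    minus_rates = _spike_rates(
        L,
        params.lambda_bg,
        [
            (params.tap_minus_leak * params.tss_strength, tss),
            (params.processed_strength, processed_five),
        ],
    )
    term_rates = _spike_rates(
        L,
        params.lambda_bg,
        [(params.tts_strength, tts), (params.processed_strength, processed_three)],
    )

    tap_plus, tap_minus, term = [], [], []
    for r in range(1, params.n_replicates + 1):
        tap_plus.append(_draw_library(plus_rates, FIVE_PRIME, f"tap_plus_rep{r}", replicon.id, rng))
        tap_minus.append(_draw_library(minus_rates, FIVE_PRIME, f"tap_minus_rep{r}", replicon.id, rng))
        term.append(_draw_library(term_rates, THREE_PRIME, f"term_rep{r}", replicon.id, rng))

    coverage: dict[tuple[str, str], CoverageTrack] = {}
    transcripts = {
        "+": [(p, q) for (p, s1), (q, s2) in zip(tss, tts) if s1 == "+"],
        "-": [(q, p) for (p, s1), (q, s2) in zip(tss, tts) if s1 == "-"],
    }
    for strand in ("+", "-"):
        values = rng.poisson(params.lambda_bg, L).astype(np.float64)
        for left, right in transcripts[strand]:
            n = right - left + 1
            depth = params.rnaseq_depth + rng.normal(0.0, params.rnaseq_noise_sd, n)
            values[left - 1 : right] = np.maximum(depth, 0.0)
        coverage[(replicon.id, strand)] = CoverageTrack(replicon.id, strand, values)

    regions = [
        Region(replicon.id, int(0.20 * L) + 1, int(0.25 * L), "smBGC_1"),
        Region(replicon.id, int(0.60 * L) + 1, int(0.65 * L), "smBGC_2"),
    ]
    return SimulatedDataset(
        params, replicon, genes, truth, tap_plus, tap_minus, term, coverage, regions
    )


# ---------------------------------------------------------------------------
# On-disk dataset layout


def write_dataset(bundle: SimulatedDataset, out_dir: str | os.PathLike) -> None:
    """Write the full dataset so the pipeline can run from the directory.

    Layout: ``replicons.tsv``, ``genes.gff3``, ``regions.bed``,
    ``truth.tsv``, per-library bedGraph tracks with a ``tracks.tsv``
    manifest, and strand-specific RNA-Seq ``coverage.*.bedgraph``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rep = bundle.replicon
    with open(out_dir / "replicons.tsv", "w") as fh:
        fh.write("id\tlength\ttopology\n")
        fh.write(f"{rep.id}\t{rep.length}\t{rep.topology}\n")

    with open(out_dir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in bundle.genes:
            fh.write(
                f"{g.replicon_id}\ttxends_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )

    with open(out_dir / "regions.bed", "w") as fh:
        for r in bundle.regions:
            fh.write(f"{r.replicon_id}\t{r.start - 1}\t{r.end}\t{r.label}\n")

    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("site_type\treplicon\tposition\tstrand\n")
        for label, entries in (
            ("TSS", bundle.truth.tss),
            ("TTS", bundle.truth.tts),
            ("processed_5p", bundle.truth.processed_five),
            ("processed_3p", bundle.truth.processed_three),
        ):
            for pos, strand in entries:
                fh.write(f"{label}\t{rep.id}\t{pos}\t{strand}\n")

    manifest_rows = []
    for group, libs in (
        ("tap_plus", bundle.tap_plus),
        ("tap_minus", bundle.tap_minus),
        ("term", bundle.term),
    ):
        for i, lib in enumerate(libs, start=1):
            manifest_rows.extend(write_library(lib, out_dir, f"{group}_rep{i}"))
    write_track_manifest(manifest_rows, out_dir / "tracks.tsv")

    for strand, suffix in (("+", "plus"), ("-", "minus")):
        track = bundle.coverage[(rep.id, strand)]
        write_bedgraph(track.values, rep.id, out_dir / f"coverage.{suffix}.bedgraph")


def read_replicons_tsv(path: str | os.PathLike) -> list[Replicon]:
    replicons: list[Replicon] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["id", "length", "topology"]:
            raise ValueError(f"{path}: unexpected replicon table header {header}")
        for line in fh:
            if not line.strip():
                continue
            rid, length, topology = line.strip().split("\t")
            replicons.append(Replicon(rid, int(length), topology))
    return replicons


def read_truth_tsv(path: str | os.PathLike) -> dict[str, list[tuple[str, int, str]]]:
    """Truth sites keyed by type as (replicon, position, strand) tuples."""
    out: dict[str, list[tuple[str, int, str]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            stype, rid, pos, strand = line.strip().split("\t")
            out.setdefault(stype, []).append((rid, int(pos), strand))
    return out


def load_libraries(
    dataset_dir: str | os.PathLike, replicons: Sequence[Replicon]
) -> dict[str, Library]:
    """Reload all end-count libraries of a written dataset, keyed by label."""
    dataset_dir = Path(dataset_dir)
    rows = read_track_manifest(dataset_dir / "tracks.tsv")
    by_id = {r.id: r for r in replicons}
    libraries: dict[str, Library] = {}
    for row in rows:
        label = str(row["label"])
        path = dataset_dir / str(row["path"])
        rid = Path(str(row["path"])).name.split(".")[-3]
        track = read_track(
            path,
            by_id[rid],
            str(row["strand"]),
            str(row["end_type"]),
            library_label=label,
            library_size=int(row["library_size"]),
        )
        libraries.setdefault(label, {})[(rid, str(row["strand"]))] = track
    return libraries
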