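"""Relating called boundaries to gene models.

A TSS upstream of a gene start defines that gene's 5'-UTR; a TTS downstream
of a gene end defines its 3'-UTR.  Assignment is to the nearest same-strand
gene within a configurable distance (default 500 nt); a site with no such
gene is reported as an orphan, including TSSs falling inside gene bodies —
no internal/antisense taxonomy is imposed here.  Overlap with region sets
(e.g. secondary-metabolite biosynthetic gene clusters) is strand-agnostic,
inclusive containment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from .calling import SITE_TSS, SITE_TTS, BoundarySite

DEFAULT_FEATURE_TYPES = ("gene", "CDS")
DEFAULT_MAX_DIST = 500


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the gene's 5' boundary (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class Region:
    replicon_id: str
    start: int  # 1-based inclusive
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.label!r}: start > end")


@dataclass(frozen=True)
class AnnotatedSite:
    site: BoundarySite
    assigned_gene: str | None
    utr_length: int | None
    category: str  # "assigned" | "orphan"


def _parse_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for piece in attr_field.strip().split(";"):
        piece = piece.strip()
        if not piece or "=" not in piece:
            continue
        key, value = piece.split("=", 1)
        out[key] = value
    return out


def load_gff(
    path: str | os.PathLike,
    feature_types: Sequence[str] = DEFAULT_FEATURE_TYPES,
) -> list[GeneModel]:
    """Load gene models from GFF3, keeping the configured feature types.

    Gene ids come from the ID, locus_tag or gene attribute, in that order.
    Missing strand or malformed coordinates are fatal, with the line number.
    """
    wanted = set(feature_types)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(fields)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in wanted:
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if s < 1 or s > e:
                raise ValueError(f"{path}:{lineno}: malformed interval {s}..{e}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing or bad strand {strand!r}")
            parsed = _parse_attributes(attrs)
            gid = parsed.get("ID") or parsed.get("locus_tag") or parsed.get("gene")
            if gid is None:
                gid = f"feature_{lineno}"
            genes.append(GeneModel(gid, seqid, s, e, strand))
    return genes


def _assignment_distance(site: BoundarySite, gene: GeneModel) -> int | None:
    """Distance from site to the gene boundary it could explain, or None.

    TSS: distance to the gene 5' boundary, requiring the gene downstream of
    the site.  TTS: distance to the gene 3' boundary, requiring the gene
    upstream.  Zero distance (site exactly at the boundary) is allowed.
    """
    if gene.strand != site.strand or gene.replicon_id != site.replicon_id:
        return None
    if site.site_type == SITE_TSS:
        d = gene.five_prime - site.position if site.strand == "+" else site.position - gene.five_prime
    else:
        d = site.position - gene.three_prime if site.strand == "+" else gene.three_prime - site.position
    return d if d >= 0 else None


def assign_sites(
    sites: Iterable[BoundarySite],
    genes: Sequence[GeneModel],
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[AnnotatedSite]:
    """Assign each site to its nearest compatible gene within ``max_dist``.

    The UTR length equals the assignment distance (5'-UTR for TSSs, 3'-UTR
    for TTSs).  Ties between equidistant genes resolve to the
    lexicographically smaller gene id.
    """
    annotated: list[AnnotatedSite] = []
    for site in sites:
        best: tuple[int, str] | None = None
        for gene in genes:
            d = _assignment_distance(site, gene)
            if d is None or d > max_dist:
                continue
            key = (d, gene.gene_id)
            if best is None or key < best:
                best = key
        if best is None:
            annotated.append(AnnotatedSite(site, None, None, "orphan"))
        else:
            annotated.append(AnnotatedSite(site, best[1], best[0], "assigned"))
    return annotated


def region_overlap_fraction(
    sites: Sequence[BoundarySite], regions: Sequence[Region]
) -> tuple[int, int, float | None]:
    """(count inside, total, fraction) of sites inside any region.

    Containment is strand-agnostic with inclusive bounds.  With zero sites
    the fraction is None (undefined), not 0.
    """
    total = len(sites)
    count_in = 0
    for site in sites:
        for region in regions:
            if (
                region.replicon_id == site.replicon_id
                and region.start <= site.position <= region.end
            ):
                count_in += 1
                break
    fraction = count_in / total if total > 0 else None
    return count_in, total, fraction


def load_regions_bed(path: str | os.PathLike, label_prefix: str = "region") -> list[Region]:
    """Read regions from BED (0-based half-open -> 1-based inclusive)."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, s0, e0 = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else f"{label_prefix}_{lineno}"
            regions.append(Region(chrom, s0 + 1, e0, label))
    return regions


def write_sites_gff(
    annotated: Sequence[AnnotatedSite], path: str | os.PathLike
) -> None:
    """GFF3 of annotated sites; deterministic (replicon, position, strand)."""
    ordered = sorted(
        annotated, key=lambda a: (a.site.replicon_id, a.site.position, a.site.strand)
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in ordered:
            s = ann.site
            attrs = [f"ID={s.site_type}_{s.replicon_id}_{s.position}_{s.strand}"]
            attrs.append(f"z_score={s.z:.6g}")
            if ann.assigned_gene is not None:
                attrs.append(f"gene={ann.assigned_gene}")
                attrs.append(f"utr_length={ann.utr_length}")
            fh.write(
                f"{s.replicon_id}\ttxends\t{s.site_type}\t{s.position}\t{s.position}\t"
                f"{s.z:.6g}\t{s.strand}\t.\t{';'.join(attrs)}\n"
            )


def write_annotation_tsv(
    annotated: Sequence[AnnotatedSite], path: str | os.PathLike
) -> None:
    ordered = sorted(
        annotated, key=lambda a: (a.site.replicon_id, a.site.position, a.site.strand)
    )
    with open(path, "w") as fh:
        fh.write("replicon\tposition\tstrand\tz\tsite_type\tgene\tutr_length\tcategory\n")
        for ann in ordered:
            s = ann.site
            fh.write(
                f"{s.replicon_id}\t{s.position}\t{s.strand}\t{s.z:.6g}\t{s.site_type}\t"
                f"{ann.assigned_gene or '.'}\t"
                f"{ann.utr_length if ann.utr_length is not None else '.'}\t"
                f"{ann.category}\n"
            )
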