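"""Raw per-sample measurements from one indexed BAM/CRAM.

Three kinds of quantity feed the batch statistics:

* allele-support counts ``D1``/``D2`` at the three paralog-discriminating
  sites — reads mapped to *either* the SMN1 or the SMN2 coordinate are pooled,
  because mismapping between the near-identical paralogs makes the mapped
  locus uninformative; only the base a read carries discriminates;
* mean depth over each of the 22 registry gene intervals (``c_i1``, ``c_i2``,
  ``H_ki``), zero-depth positions included;
* read support for the two duplication-haplotype polymorphisms used to tag
  silent (2+0) carriers.

Reads flagged duplicate, secondary, supplementary, QC-fail or unmapped are
excluded everywhere. Mapping quality is deliberately *not* filtered by
default: near-identical paralogs legitimately produce MAPQ-0 multi-mappers
and discarding them would destroy the allele signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator

import pysam

from .registry import (
    DiscriminatingSite,
    DuplicationVariant,
    GeneInterval,
    LocusRegistry,
    resolve_contig,
)

__all__ = [
    "ReadFilters",
    "SampleCounts",
    "PileupError",
    "MissingContigError",
    "MissingIndexError",
    "ReferenceRequiredError",
    "open_alignment",
    "count_discriminating_site",
    "mean_gene_depth",
    "screen_duplication_variant",
    "collect_sample_counts",
]


class PileupError(RuntimeError):
    pass


class MissingContigError(PileupError):
    pass


class MissingIndexError(PileupError):
    pass


class ReferenceRequiredError(PileupError):
    pass


@dataclass(frozen=True)
class ReadFilters:
    """Read- and base-level filter settings.

    ``min_base_quality`` applies only at discriminating/variant positions,
    never to depth-of-coverage, which counts every aligned base.
    """

    min_base_quality: int = 13
    min_mapping_quality: int = 0
    exclude_duplicates: bool = True
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_qcfail: bool = True

    def passes(self, read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        if self.exclude_qcfail and read.is_qcfail:
            return False
        if read.mapping_quality < self.min_mapping_quality:
            return False
        return True


@dataclass
class SampleCounts:
    """All raw measurements for one sample."""

    sample_id: str
    d1: dict[str, int] = field(default_factory=dict)
    d2: dict[str, int] = field(default_factory=dict)
    smn1_mean_depth: float = 0.0
    smn2_mean_depth: float = 0.0
    control_mean_depth: dict[str, float] = field(default_factory=dict)
    dup_variant_support: dict[str, tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        if sorted(self.d1) != ["a", "b", "c"] or sorted(self.d2) != ["a", "b", "c"]:
            raise ValueError("d1/d2 must have entries for exactly sites a, b, c")
        for m in (self.d1, self.d2):
            if any(v < 0 for v in m.values()):
                raise ValueError("negative allele count")
        if self.smn1_mean_depth < 0 or self.smn2_mean_depth < 0:
            raise ValueError("negative mean depth")
        if any(v < 0 for v in self.control_mean_depth.values()):
            raise ValueError("negative control depth")
        for label, (sup, cov) in self.dup_variant_support.items():
            if not 0 <= sup <= cov:
                raise ValueError(f"{label}: supporting_reads must be in [0, covering]")


def open_alignment(path: str | os.PathLike, reference: str | None = None) -> pysam.AlignmentFile:
    """Open an indexed BAM/CRAM for random access.

    CRAM decoding needs the reference FASTA; opening a CRAM without one is an
    explicit error rather than a deferred decode failure.
    """
    path = os.fspath(path)
    if path.endswith(".cram") and reference is None:
        raise ReferenceRequiredError(
            f"{path}: CRAM input requires the reference FASTA (--reference)"
        )
    af = pysam.AlignmentFile(
        path, reference_filename=reference, require_index=False
    )
    if not af.has_index():
        raise MissingIndexError(f"{path}: no BAI/CSI/CRAI index found")
    return af


def _resolve(af: pysam.AlignmentFile, chromosome: str) -> str:
    try:
        return resolve_contig(chromosome, af.references)
    except KeyError as exc:
        raise MissingContigError(str(exc)) from None


def _base_at(read: pysam.AlignedSegment, rpos0: int) -> tuple[str, int] | None:
    """Base and quality the read carries at 0-based reference position ``rpos0``.

    Returns ``None`` when the read's alignment has a deletion or reference
    skip there (no base to compare).
    """
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X: consumes both
            if rpos <= rpos0 < rpos + length:
                i = qpos + (rpos0 - rpos)
                seq = read.query_sequence
                qual = read.query_qualities
                return seq[i], (qual[i] if qual is not None else 0)
            qpos += length
            rpos += length
        elif op in (1, 4):  # I, S: consumes query
            qpos += length
        elif op in (2, 3):  # D, N: consumes reference
            if rpos <= rpos0 < rpos + length:
                return None
            rpos += length
        # H, P consume neither
    return None


def _deletion_spans(read: pysam.AlignedSegment, start0: int, end0: int) -> bool:
    """True when a single aligned deletion (CIGAR D) covers [start0, end0]."""
    rpos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8, 3):
            rpos += length
        elif op == 2:
            if rpos <= start0 and end0 < rpos + length:
                return True
            rpos += length
    return False


def _fragment_bases(
    af: pysam.AlignmentFile,
    contig: str,
    pos0: int,
    filters: ReadFilters,
    best: dict[str, tuple[str, int]],
) -> None:
    """Accumulate per-fragment best-quality base calls at ``pos0`` into ``best``.

    Keyed by query name so an overlapping mate pair contributes one molecule,
    the higher-base-quality mate winning.
    """
    for read in af.fetch(contig, pos0, pos0 + 1):
        if not filters.passes(read):
            continue
        hit = _base_at(read, pos0)
        if hit is None:
            continue
        base, qual = hit
        if qual < filters.min_base_quality:
            continue
        prev = best.get(read.query_name)
        if prev is None or qual > prev[1]:
            best[read.query_name] = (base, qual)


def count_discriminating_site(
    af: pysam.AlignmentFile,
    site: DiscriminatingSite,
    filters: ReadFilters = ReadFilters(),
) -> tuple[int, int]:
    """Pooled allele-support counts (D1, D2) at one discriminating site.

    D1 counts fragments carrying the SMN1 base at the SMN1 *or* the SMN2
    coordinate; D2 analogously for the SMN2 base. Fragments carrying neither
    base (sequencing error, N, or a deletion) count in neither.
    """
    contig = _resolve(af, site.chromosome)
    best: dict[str, tuple[str, int]] = {}
    for pos in (site.smn1_position, site.smn2_position):
        _fragment_bases(af, contig, pos - 1, filters, best)
    d1 = sum(1 for base, _ in best.values() if base == site.smn1_allele)
    d2 = sum(1 for base, _ in best.values() if base == site.smn2_allele)
    return d1, d2


def mean_gene_depth(
    af: pysam.AlignmentFile,
    interval: GeneInterval,
    filters: ReadFilters = ReadFilters(),
) -> float:
    """Arithmetic mean per-base depth over the closed interval.

    Zero-depth positions contribute zero; base quality is not filtered here.
    """
    contig = _resolve(af, interval.chromosome)
    b0, e0 = interval.start - 1, interval.end - 1
    total = 0
    for read in af.fetch(contig, b0, e0 + 1):
        if not filters.passes(read):
            continue
        for blk_start, blk_end in read.get_blocks():  # aligned segments, D/N excluded
            ov = min(blk_end - 1, e0) - max(blk_start, b0) + 1
            if ov > 0:
                total += ov
    return total / len(interval)


def screen_duplication_variant(
    af: pysam.AlignmentFile,
    variant: DuplicationVariant,
    filters: ReadFilters = ReadFilters(),
) -> tuple[int, int]:
    """(supporting_reads, covering_reads) for one duplication-tag polymorphism.

    Covering reads span every affected base. An SNV is supported by reads
    carrying the alternate base; the 2-bp deletion only by reads whose
    alignment deletes both bases (a partial overlap is not the HGVS event).
    """
    contig = _resolve(af, variant.chromosome)
    start0, end0 = variant.start - 1, variant.end - 1
    supporting = covering = 0
    for read in af.fetch(contig, start0, end0 + 1):
        if not filters.passes(read):
            continue
        if read.reference_start > start0 or read.reference_end <= end0:
            continue
        covering += 1
        if variant.variant_class == "SNV":
            hit = _base_at(read, start0)
            if (
                hit is not None
                and hit[0] == variant.alt_allele
                and hit[1] >= filters.min_base_quality
            ):
                supporting += 1
        else:
            if _deletion_spans(read, start0, end0):
                supporting += 1
    return supporting, covering


def collect_sample_counts(
    path: str | os.PathLike,
    registry: LocusRegistry,
    filters: ReadFilters = ReadFilters(),
    reference: str | None = None,
    sample_id: str | None = None,
) -> SampleCounts:
    """Extract every raw quantity the batch statistics need from one file."""
    if sample_id is None:
        sample_id = os.path.basename(os.fspath(path)).rsplit(".", 1)[0]
    try:
        with open_alignment(path, reference=reference) as af:
            counts = SampleCounts(sample_id=sample_id)
            for site in registry.sites:
                d1, d2 = count_discriminating_site(af, site, filters)
                counts.d1[site.label] = d1
                counts.d2[site.label] = d2
            counts.smn1_mean_depth = mean_gene_depth(af, registry.smn1, filters)
            counts.smn2_mean_depth = mean_gene_depth(af, registry.smn2, filters)
            for gene in registry.control_genes:
                counts.control_mean_depth[gene.gene_symbol] = mean_gene_depth(
                    af, gene, filters
                )
            for variant in registry.variants:
                counts.dup_variant_support[variant.hgvs_label] = (
                    screen_duplication_variant(af, variant, filters)
                )
    except PileupError as exc:
        raise type(exc)(f"sample {sample_id}: {exc}") from None
    counts.validate()
    return counts
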