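"""Synthetic aligned-read fixtures for the SMN locus and control genes.

Emits coordinate-sorted, indexed BAMs that emulate the coverage model the
copy-number statistics assume, for arbitrary SMN1:SMN2 genotypes, together
with an exact ground-truth record computed from the emitted read set.

Model
-----
* Each gene copy contributes ``mean_depth_per_copy`` of evenly tiled
  single-end reads over the SMN window, so total SMN depth is proportional
  to total copy number; control genes are tiled at ``control_depth``.
* Reads from SMN1 copies carry the SMN1 base at the three discriminating
  sites (plus both duplication-tag variant alleles when the spec asks for a
  silent-carrier haplotype); SMN2-copy reads carry the SMN2 bases.
* Each SMN read is placed at the SMN1 or the SMN2 locus with probability
  ``mismap_fraction`` for the homologous locus (default 0.5), emulating the
  mapping ambiguity between near-identical paralogs; the constant homologous
  offset between the paralogs keeps site coordinates consistent. SMN reads
  get MAPQ 0, as real multi-mappers do.
* Per-base errors are applied at ``base_error_rate`` after allele painting,
  and the truth record tallies the bases actually written.

Reads are written pre-aligned (simple-match CIGARs, except reads carrying
the 2-bp deletion), restricted to the registry intervals; contig lengths in
the header are full GRCh37 lengths so coordinates remain authentic. Depth is
quasi-deterministic (tiling, not Poisson sampling) — see the methods note
for what that does and does not exercise.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pysam

from .pileup import SampleCounts
from .registry import (
    GRCH37_CONTIG_LENGTHS,
    GeneInterval,
    LocusRegistry,
    load_registry,
)

__all__ = [
    "SyntheticSampleSpec",
    "TruthRecord",
    "fixture_registry",
    "generate_sample",
    "generate_batch",
]

#: Homologous coordinate offset SMN1 -> SMN2 shared by all three
#: discriminating sites (e.g. 70247724 - 69372304).
PARALOG_OFFSET = 875420

_ACGT = b"ACGT"


@dataclass(frozen=True)
class SyntheticSampleSpec:
    """Genotype and sequencing parameters for one synthetic sample."""

    sample_id: str
    smn1_copies: int = 2
    smn2_copies: int = 2
    silent_carrier_haplotype: bool = False
    mean_depth_per_copy: float = 15.0
    control_depth: float = 30.0
    read_length: int = 150
    base_error_rate: float = 0.0
    mismap_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smn1_copies < 0 or self.smn2_copies < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.mean_depth_per_copy <= 0 or self.control_depth <= 0:
            raise ValueError("depths must be positive")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must be in [0, 1)")

    @property
    def genotype(self) -> str:
        return f"{self.smn1_copies}:{self.smn2_copies}"


@dataclass
class TruthRecord:
    """Exact expected extraction results, bookkept from the emitted reads."""

    sample_id: str
    spec: SyntheticSampleSpec
    counts: SampleCounts


def fixture_registry(control_window: int = 1000, smn_pad: int = 300) -> LocusRegistry:
    """A desk-scale registry with shrunken gene windows, for fast fixtures.

    The statistics are interval-agnostic — mean depth over any window of a
    gene carries the same normalization signal — so fixtures shrink each
    control gene to a ``control_window``-bp window inside its real span and
    the SMN intervals to a window around the discriminating sites and
    duplication variants. Chromosomes, sites and variants are the real ones.
    """
    real = load_registry("GRCh37")
    lo = min(s.smn1_position for s in real.sites) - smn_pad
    hi = max(v.end for v in real.variants) + smn_pad
    genes: list[GeneInterval] = []
    for g in real.genes:
        if g.gene_symbol == "SMN1":
            genes.append(dataclasses.replace(g, start=lo, end=hi))
        elif g.gene_symbol == "SMN2":
            genes.append(
                dataclasses.replace(g, start=lo - PARALOG_OFFSET, end=hi - PARALOG_OFFSET)
            )
        else:
            mid = (g.start + g.end) // 2
            genes.append(
                dataclasses.replace(
                    g,
                    start=mid - control_window // 2,
                    end=mid - control_window // 2 + control_window - 1,
                )
            )
    reg = dataclasses.replace(real, genes=tuple(genes))
    reg.validate()
    return reg


def _tile_starts(rng, b0: int, e0: int, depth: float, read_len: int) -> np.ndarray:
    """Evenly spaced 0-based read starts so [b0, e0] sees ~``depth`` coverage."""
    lo = b0 - read_len + 1
    width = e0 - lo + 1
    n = max(1, round(depth * width / read_len))
    phase = rng.random()
    return lo + ((np.arange(n) + phase) * width / n).astype(int)


def _overlap(s: int, e: int, b: int, d: int) -> int:
    ov = min(e, d) - max(s, b) + 1
    return ov if ov > 0 else 0


def generate_sample(
    spec: SyntheticSampleSpec,
    registry: LocusRegistry,
    out_dir: str | os.PathLike,
) -> tuple[str, TruthRecord]:
    """Write ``<out_dir>/<sample_id>.bam`` (+ .bai, + truth JSON sidecar)."""
    rng = np.random.default_rng(spec.seed)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    L = spec.read_length

    chroms = sorted(GRCH37_CONTIG_LENGTHS, key=int)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": GRCH37_CONTIG_LENGTHS[c]} for c in chroms],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}
    # position-keyed background fill, one variant per start phase
    fills = [bytes(_ACGT[(p + i) % 4] for i in range(L)) for p in range(4)]
    qual_array = pysam.qualitystring_to_array("I" * L)  # Q40 everywhere

    smn1, smn2 = registry.smn1, registry.smn2
    sites = registry.sites
    snv = next(v for v in registry.variants if v.variant_class == "SNV")
    deletion = next(v for v in registry.variants if v.variant_class == "deletion")
    snv0 = snv.start - 1
    del_b0, del_e0 = deletion.start - 1, deletion.end - 1

    d1 = {s.label: 0 for s in sites}
    d2 = {s.label: 0 for s in sites}
    depth_sum = {g.gene_symbol: 0 for g in registry.genes}
    var_sup = {v.hgvs_label: 0 for v in registry.variants}
    var_cov = {v.hgvs_label: 0 for v in registry.variants}

    reads: list[tuple[int, int, str, bytes, tuple]] = []
    serial = 0

    # --- SMN locus: per-copy tiling in SMN1 coordinates, then random placement
    smn_b0, smn_e0 = smn1.start - 1, smn1.end - 1
    smn1_span = (smn_b0, smn_e0)
    smn2_span = (smn2.start - 1, smn2.end - 1)
    for is_smn1 in [True] * spec.smn1_copies + [False] * spec.smn2_copies:
        starts = _tile_starts(rng, smn_b0, smn_e0, spec.mean_depth_per_copy, L)
        at_smn2 = rng.random(len(starts)) < spec.mismap_fraction
        for s0, mis in zip(starts.tolist(), at_smn2.tolist()):
            seq = bytearray(fills[s0 % 4])
            carries_del = False
            for site in sites:
                off = site.smn1_position - 1 - s0
                if 0 <= off < L:
                    seq[off] = ord(site.smn1_allele if is_smn1 else site.smn2_allele)
            if is_smn1 and spec.silent_carrier_haplotype:
                off = snv0 - s0
                if 0 <= off < L:
                    seq[off] = ord(snv.alt_allele)
                # the deletion shows only in reads with >=1 aligned base each side
                carries_del = 1 <= del_b0 - s0 <= L - 1
            if spec.base_error_rate > 0:
                n_err = rng.binomial(L, spec.base_error_rate)
                for i in rng.choice(L, size=n_err, replace=False).tolist():
                    seq[i] = _ACGT[(_ACGT.index(seq[i]) + rng.integers(1, 4)) % 4]

            place0 = s0 - PARALOG_OFFSET if mis else s0
            if carries_del:
                a = del_b0 - s0
                cigar = ((0, a), (2, 2), (0, L - a))
                segments = ((place0, place0 + a - 1), (place0 + a + 2, place0 + L + 1))
                ref_end_excl = place0 + L + 2
            else:
                cigar = ((0, L),)
                segments = ((place0, place0 + L - 1),)
                ref_end_excl = place0 + L

            name = f"{spec.sample_id}.r{serial}"
            serial += 1
            reads.append((tid["5"], place0, name, bytes(seq), cigar))

            gene, span = (smn2, smn2_span) if mis else (smn1, smn1_span)
            for seg_s, seg_e in segments:
                depth_sum[gene.gene_symbol] += _overlap(seg_s, seg_e, *span)

            # pooled allele tallies: same query offset at either locus
            for site in sites:
                off = site.smn1_position - 1 - s0
                if 0 <= off < L:
                    if seq[off] == ord(site.smn1_allele):
                        d1[site.label] += 1
                    elif seq[off] == ord(site.smn2_allele):
                        d2[site.label] += 1
            if not mis:  # variant screening reads only SMN1 coordinates
                if place0 <= snv0 < ref_end_excl:
                    var_cov[snv.hgvs_label] += 1
                    if seq[snv0 - s0] == ord(snv.alt_allele):
                        var_sup[snv.hgvs_label] += 1
                if place0 <= del_b0 and ref_end_excl > del_e0:
                    # spans both deleted bases
                    var_cov[deletion.hgvs_label] += 1
                    if carries_del:
                        var_sup[deletion.hgvs_label] += 1

    # --- control genes: plain tiling at control_depth
    for g in registry.control_genes:
        gb0, ge0 = g.start - 1, g.end - 1
        for s0 in _tile_starts(rng, gb0, ge0, spec.control_depth, L).tolist():
            seq = fills[s0 % 4]
            if spec.base_error_rate > 0:
                mutable = bytearray(seq)
                n_err = rng.binomial(L, spec.base_error_rate)
                for i in rng.choice(L, size=n_err, replace=False).tolist():
                    mutable[i] = _ACGT[(_ACGT.index(mutable[i]) + rng.integers(1, 4)) % 4]
                seq = bytes(mutable)
            name = f"{spec.sample_id}.r{serial}"
            serial += 1
            reads.append((tid[g.chromosome], s0, name, seq, ((0, L),)))
            depth_sum[g.gene_symbol] += _overlap(s0, s0 + L - 1, gb0, ge0)

    reads.sort(key=lambda r: (r[0], r[1]))
    bam_path = os.path.join(out_dir, f"{spec.sample_id}.bam")
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for rtid, pos, name, seq, cigar in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.query_sequence = seq.decode("ascii")
            a.flag = 0
            a.reference_id = rtid
            a.reference_start = pos
            a.mapping_quality = 0 if rtid == tid["5"] else 60
            a.cigartuples = cigar
            a.query_qualities = qual_array
            bam.write(a)
    pysam.index(bam_path)

    counts = SampleCounts(sample_id=spec.sample_id)
    counts.d1, counts.d2 = d1, d2
    for g in registry.genes:
        mean = depth_sum[g.gene_symbol] / len(g)
        if g.gene_symbol == "SMN1":
            counts.smn1_mean_depth = mean
        elif g.gene_symbol == "SMN2":
            counts.smn2_mean_depth = mean
        else:
            counts.control_mean_depth[g.gene_symbol] = mean
    for v in registry.variants:
        counts.dup_variant_support[v.hgvs_label] = (
            var_sup[v.hgvs_label],
            var_cov[v.hgvs_label],
        )
    counts.validate()

    truth = TruthRecord(sample_id=spec.sample_id, spec=spec, counts=counts)
    with open(os.path.join(out_dir, f"{spec.sample_id}.truth.json"), "w") as fh:
        json.dump(
            {
                "sample_id": spec.sample_id,
                "genotype": spec.genotype,
                "silent_carrier_haplotype": spec.silent_carrier_haplotype,
                "counts": dataclasses.asdict(counts),
            },
            fh,
            indent=1,
        )
    return bam_path, truth


def generate_batch(
    specs: list[SyntheticSampleSpec],
    out_dir: str | os.PathLike,
    base_seed: int = 0,
    registry: LocusRegistry | None = None,
) -> tuple[list[str], list[TruthRecord]]:
    """Generate a batch with per-sample seeds derived from ``base_seed``.

    Per-sample seeds come from a seed sequence spawned off ``base_seed`` so a
    whole batch is reproducible from one integer; the specs' own ``seed``
    fields are overridden. A truth-table TSV accompanies the BAMs. Uses the
    desk-scale :func:`fixture_registry` unless another registry is given.
    """
    if not specs:
        raise ValueError("empty batch specification")
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in batch specification")
    if registry is None:
        registry = fixture_registry()
    child_seeds = np.random.SeedSequence(base_seed).generate_state(len(specs)) % (2**31)
    paths: list[str] = []
    truths: list[TruthRecord] = []
    for spec, seed in zip(specs, child_seeds):
        spec = dataclasses.replace(spec, seed=int(seed))
        path, truth = generate_sample(spec, registry=registry, out_dir=out_dir)
        paths.append(path)
        truths.append(truth)
    _write_truth_table(truths, os.path.join(os.fspath(out_dir), "truth.tsv"))
    return paths, truths


def _write_truth_table(truths: list[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tsmn1_copies\tsmn2_copies\tsilent_carrier_haplotype\t"
            "d1_a\td1_b\td1_c\td2_a\td2_b\td2_c\tsmn1_mean_depth\tsmn2_mean_depth\n"
        )
        for t in truths:
            c = t.counts
            fh.write(
                f"{t.sample_id}\t{t.spec.smn1_copies}\t{t.spec.smn2_copies}\t"
                f"{t.spec.silent_carrier_haplotype}\t"
                f"{c.d1['a']}\t{c.d1['b']}\t{c.d1['c']}\t"
                f"{c.d2['a']}\t{c.d2['b']}\t{c.d2['c']}\t"
                f"{c.smn1_mean_depth:.4f}\t{c.smn2_mean_depth:.4f}\n"
            )
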