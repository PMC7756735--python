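"""Packaged genomic coordinates for the SMN locus and the depth-control genes.

The SMN1/SMN2 paralogs on chr5q13.2 differ at a handful of fixed nucleotides.
Three of those paralog-discriminating positions (labelled ``a``, ``b``, ``c``;
``b`` is the exon-7 c.840 position that defines a functional SMN1 copy) drive
the allele counting, twenty unlinked genes with historically stable coverage
relative to the SMN locus anchor the depth normalization, and two intronic
polymorphisms tag the duplication haplotype behind silent (2+0) carriers.

All coordinates are GRCh37, 1-based inclusive; conversion to the 0-based
half-open convention happens only at the alignment-access boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "DiscriminatingSite",
    "GeneInterval",
    "DuplicationVariant",
    "LocusRegistry",
    "UnsupportedBuildError",
    "RegistryValidationError",
    "load_registry",
    "resolve_contig",
    "GRCH37_CONTIG_LENGTHS",
]

SITE_LABELS = ("a", "b", "c")

#: Full GRCh37 primary-contig lengths for every chromosome the registry touches,
#: used by alignment writers so that headers carry authentic coordinates.
GRCH37_CONTIG_LENGTHS: Mapping[str, int] = {
    "1": 249250621,
    "2": 243199373,
    "3": 198022430,
    "5": 180915260,
    "8": 146364022,
    "10": 135534747,
    "11": 135006516,
    "13": 115169878,
    "15": 102531392,
    "17": 81195210,
}


class UnsupportedBuildError(ValueError):
    """Raised when a genome build other than the bundled one is requested."""


class RegistryValidationError(ValueError):
    """Raised when the packaged coordinate table violates its invariants."""


@dataclass(frozen=True)
class DiscriminatingSite:
    """A position where SMN1 and SMN2 carry different fixed bases.

    ``smn1_position``/``smn2_position`` are the paired homologous coordinates;
    reads mapped to either locus are informative only through the allele they
    carry, because mismapping between the near-identical paralogs is frequent.
    """

    label: str
    chromosome: str
    smn1_position: int
    smn2_position: int
    smn1_allele: str
    smn2_allele: str


@dataclass(frozen=True)
class GeneInterval:
    """A gene span used for average-depth computation."""

    gene_symbol: str
    chromosome: str
    start: int
    end: int
    role: str  # "target" (SMN1/SMN2) or "control"

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DuplicationVariant:
    """A polymorphism associated with SMN1 duplication events (silent-carrier tag)."""

    hgvs_label: str
    chromosome: str
    start: int
    end: int
    variant_class: str  # "SNV" or "deletion"
    alt_allele: str  # empty for a pure deletion


@dataclass(frozen=True)
class LocusRegistry:
    build: str
    sites: tuple[DiscriminatingSite, ...]
    genes: tuple[GeneInterval, ...]
    variants: tuple[DuplicationVariant, ...]

    @property
    def smn1(self) -> GeneInterval:
        return next(g for g in self.genes if g.gene_symbol == "SMN1")

    @property
    def smn2(self) -> GeneInterval:
        return next(g for g in self.genes if g.gene_symbol == "SMN2")

    @property
    def control_genes(self) -> tuple[GeneInterval, ...]:
        return tuple(g for g in self.genes if g.role == "control")

    @property
    def control_order(self) -> tuple[str, ...]:
        """Control gene symbols in their fixed registry order (index k)."""
        return tuple(g.gene_symbol for g in self.control_genes)

    def site(self, label: str) -> DiscriminatingSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)

    def validate(self) -> None:
        if tuple(s.label for s in self.sites) != SITE_LABELS:
            raise RegistryValidationError("expected exactly sites a, b, c in order")
        for s in self.sites:
            if s.smn1_allele == s.smn2_allele:
                raise RegistryValidationError(f"site {s.label}: identical alleles")
        targets = [g for g in self.genes if g.role == "target"]
        if sorted(g.gene_symbol for g in targets) != ["SMN1", "SMN2"]:
            raise RegistryValidationError("expected exactly SMN1 and SMN2 targets")
        if len(self.control_genes) != 20:
            raise RegistryValidationError(
                f"expected 20 control genes, found {len(self.control_genes)}"
            )
        for g in self.genes:
            if not g.start < g.end:
                raise RegistryValidationError(f"{g.gene_symbol}: start must be < end")
        smn1, smn2 = self.smn1, self.smn2
        if smn1.chromosome != "5" or smn2.chromosome != "5":
            raise RegistryValidationError("SMN1/SMN2 must be on chr5")
        for s in self.sites:
            if not smn1.start <= s.smn1_position <= smn1.end:
                raise RegistryValidationError(f"site {s.label} outside SMN1 interval")
            if not smn2.start <= s.smn2_position <= smn2.end:
                raise RegistryValidationError(f"site {s.label} outside SMN2 interval")
        if len(self.variants) != 2:
            raise RegistryValidationError("expected exactly two duplication variants")


def _parse_rows(lines: Iterable[str]) -> tuple[list, list, list]:
    sites, genes, variants = [], [], []
    header: list[str] | None = None
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = line.split("\t")
            continue
        row = dict(zip(header, line.split("\t")))
        kind = row["record_type"]
        if kind == "site":
            sites.append(
                DiscriminatingSite(
                    label=row["name"],
                    chromosome=row["chromosome"],
                    smn1_position=int(row["start"]),
                    smn2_position=int(row["end"]),
                    smn1_allele=row["allele_smn1"],
                    smn2_allele=row["allele_smn2"],
                )
            )
        elif kind == "gene":
            genes.append(
                GeneInterval(
                    gene_symbol=row["name"],
                    chromosome=row["chromosome"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    role=row["info"],
                )
            )
        elif kind == "variant":
            alt = row["alt_allele"]
            variants.append(
                DuplicationVariant(
                    hgvs_label=row["name"],
                    chromosome=row["chromosome"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    variant_class=row["info"],
                    alt_allele="" if alt in (".", "-") else alt,
                )
            )
        else:
            raise RegistryValidationError(f"unknown record_type {kind!r}")
    return sites, genes, variants


def load_registry(build: str = "GRCh37") -> LocusRegistry:
    """Load the packaged, validated coordinate registry for ``build``.

    Only GRCh37 is bundled; any other build tag raises
    :class:`UnsupportedBuildError`. Loading is pure and deterministic.
    """
    if build != "GRCh37":
        raise UnsupportedBuildError(
            f"genome build {build!r} is not bundled; only GRCh37 is supported"
        )
    text = (
        resources.files("smncopy").joinpath("data/grch37_registry.tsv").read_text()
    )
    sites, genes, variants = _parse_rows(text.splitlines())
    reg = LocusRegistry(
        build=build, sites=tuple(sites), genes=tuple(genes), variants=tuple(variants)
    )
    reg.validate()
    return reg


def resolve_contig(chromosome: str, header_contigs: Iterable[str]) -> str:
    """Map a registry chromosome name onto whichever alias the alignment header declares.

    Registries store bare names ("5"); alignment files may declare either
    "5" or "chr5". Raises ``KeyError`` when neither alias is present.
    """
    declared = set(header_contigs)
    for candidate in (chromosome, f"chr{chromosome}", chromosome.removeprefix("chr")):
        if candidate in declared:
            return candidate
    raise KeyError(
        f"contig {chromosome!r} (or 'chr{chromosome}') absent from alignment header"
    )
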