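"""Coordinate maps, intron splicing phases and domain intron patterns.

Splicing phases follow the standard convention: phase 0 (P0) introns fall
between codons, phase 1 (P1) after the first nucleotide of a codon, phase 2
(P2) after the second.  A P0 intron between codon ``p`` and codon ``p + 1``
is labeled with the N-terminal residue ``p``; P1/P2 introns carry the residue
whose codon they interrupt.

Within the bZIP domain window (positions -25..-1, basic + hinge) the observed
intron configurations fall into four recurring patterns:

``a``  one P0 intron at hinge position -5
``b``  two P0 introns, one in the basic region and one in the hinge
``c``  one P2 intron at basic position -20
``d``  no intron in the basic or hinge region

Configurations matching none of these are reported as ``other`` rather than
forced into the nearest class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from bzipkit.domain_scanner import DomainAnnotation


class Region(str, Enum):
    basic = "basic"
    hinge = "hinge"
    outside = "outside"


class IntronPattern(str, Enum):
    a = "a"
    b = "b"
    c = "c"
    d = "d"
    other = "other"


@dataclass
class GeneModel:
    """A protein-coding gene model as an ordered list of CDS exon intervals.

    Exons are genomic ``(start, end)`` intervals, 1-based and inclusive,
    listed in transcription order: ascending starts on the plus strand,
    descending on the minus strand.  Only CDS-carrying exons belong here.
    """

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    protein_id: str | None = None
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon {s}..{e} inverted")
        genomic_sorted = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if self.exons != expected:
            raise ValueError(
                f"{self.gene_id}: exons not in transcription order for "
                f"strand {self.strand}"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class IntronRecord:
    """One intron with its CDS offset, splicing phase and protein position.

    ``cds_offset`` counts CDS nucleotides upstream of the junction;
    ``phase = cds_offset mod 3``.  ``protein_pos`` is 1-based: the residue
    preceding a P0 junction, or the residue whose codon a P1/P2 junction
    interrupts.  ``domain_pos``/``region`` are filled in by
    :func:`annotate_domain_positions`.
    """

    index: int
    cds_offset: int
    phase: int
    protein_pos: int
    domain_pos: int | None = None
    region: Region = field(default=Region.outside)

    def __post_init__(self) -> None:
        if self.phase != self.cds_offset % 3:
            raise ValueError("phase must equal cds_offset mod 3")


class CdsMap:
    """Bijective map between genomic coordinates and CDS positions.

    CDS positions are 1-based and counted in transcription order; minus-strand
    exons are traversed end-to-start.  Protein residue ``p`` corresponds to
    CDS nucleotides ``3p - 2 .. 3p``.
    """

    def __init__(self, model: GeneModel):
        if model.cds_length % 3 != 0:
            raise ValueError(
                f"{model.gene_id}: CDS length {model.cds_length} not a "
                "multiple of 3"
            )
        self.model = model
        self._cds_to_gen: list[int] = []
        for s, e in model.exons:
            if model.strand == "+":
                self._cds_to_gen.extend(range(s, e + 1))
            else:
                self._cds_to_gen.extend(range(e, s - 1, -1))
        self._gen_to_cds = {
            g: c + 1 for c, g in enumerate(self._cds_to_gen)
        }

    @property
    def cds_length(self) -> int:
        return len(self._cds_to_gen)

    @property
    def n_codons(self) -> int:
        return len(self._cds_to_gen) // 3

    def cds_to_genomic(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= self.cds_length:
            raise IndexError(f"CDS position {cds_pos} out of range")
        return self._cds_to_gen[cds_pos - 1]

    def genomic_to_cds(self, genomic_pos: int) -> int:
        try:
            return self._gen_to_cds[genomic_pos]
        except KeyError:
            raise IndexError(
                f"genomic position {genomic_pos} not in any CDS exon"
            ) from None

    def residue_to_cds(self, residue: int) -> tuple[int, int]:
        """CDS interval (3p-2, 3p) of protein residue ``p``."""
        if not 1 <= residue <= self.n_codons:
            raise IndexError(f"residue {residue} out of range")
        return 3 * residue - 2, 3 * residue

    def residue_to_genomic(self, residue: int) -> list[int]:
        lo, hi = self.residue_to_cds(residue)
        return [self.cds_to_genomic(c) for c in range(lo, hi + 1)]


def build_cds_map(model: GeneModel) -> CdsMap:
    """Build the genomic <-> CDS coordinate map for a gene model."""
    return CdsMap(model)


def locate_introns(model: GeneModel) -> list[IntronRecord]:
    """Compute one :class:`IntronRecord` per inter-exon gap.

    Records come back in transcription order with
    ``phase = cds_offset mod 3`` and the protein position derived from the
    cumulative exon CDS length.
    """
    build_cds_map(model)  # validates divisibility and exon geometry
    records: list[IntronRecord] = []
    cum = 0
    for idx, (s, e) in enumerate(model.exons[:-1], start=1):
        cum += e - s + 1
        phase = cum % 3
        protein_pos = cum // 3 if phase == 0 else (cum + 2) // 3
        records.append(
            IntronRecord(
                index=idx, cds_offset=cum, phase=phase, protein_pos=protein_pos
            )
        )
    return records


def annotate_domain_positions(
    introns: list[IntronRecord],
    ann: DomainAnnotation,
    protein_id: str | None = None,
) -> list[IntronRecord]:
    """Fill ``domain_pos`` and ``region`` of introns falling in -25..-1.

    The residue at ``ann.anchor_n`` (0-based) is domain position -18; there
    is no position 0.  Introns whose labeled residue lies outside the
    basic+hinge window keep ``region=outside`` and ``domain_pos=None``.
    """
    if protein_id is not None and ann.protein_id != protein_id:
        raise ValueError(
            f"annotation is for {ann.protein_id!r}, introns for {protein_id!r}"
        )
    anchor_residue = ann.anchor_n + 1  # 1-based residue at position -18
    for rec in introns:
        dpos = rec.protein_pos - anchor_residue - 18
        if -25 <= dpos <= -1:
            rec.domain_pos = dpos
            rec.region = Region.basic if dpos <= -10 else Region.hinge
        else:
            rec.domain_pos = None
            rec.region = Region.outside
    return introns


def classify_pattern(introns: list[IntronRecord]) -> IntronPattern:
    """Classify the basic+hinge intron configuration into patterns a-d.

    Only introns with ``region`` basic or hinge participate; introns outside
    the domain window are ignored, so the full record list of a gene can be
    passed directly.
    """
    inside = [r for r in introns if r.region in (Region.basic, Region.hinge)]
    if not inside:
        return IntronPattern.d
    if len(inside) == 1:
        (r,) = inside
        if r.region is Region.hinge and r.domain_pos == -5 and r.phase == 0:
            return IntronPattern.a
        if r.region is Region.basic and r.domain_pos == -20 and r.phase == 2:
            return IntronPattern.c
        return IntronPattern.other
    if len(inside) == 2:
        regions = {r.region for r in inside}
        if all(r.phase == 0 for r in inside) and regions == {
            Region.basic,
            Region.hinge,
        }:
            return IntronPattern.b
    return IntronPattern.other
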