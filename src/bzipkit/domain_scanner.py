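"""Detection and annotation of bZIP domains in protein sequences.

The bZIP DNA-binding module is located by its invariant sequence signature:
an asparagine (position -18), an arginine or lysine eight residues downstream
(position -10), and the first leucine of the zipper coiled coil exactly nine
residues after that (position +1).  Domain positions are numbered with no
position 0: the basic region spans -25..-10, the hinge -9..-1, and the zipper
starts at +1.

Variant DNA-binding sites are called from the residue at -10: lysine instead
of arginine (seen in whole phylogenetic groups) or the rare hydrophobic
isoleucine replacement that abolishes G-box recognition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_X = AA_ALPHABET | {"X"}

#: Offsets from the anchor asparagine (position -18) to landmarks.
OFFSET_MINUS10 = 8
OFFSET_ZIPPER = 18
BASIC_LEN = 16
HINGE_LEN = 9


class BindingVariant(str, Enum):
    """DNA-binding-site class from the residues at positions -18 and -10."""

    canonical_R = "canonical_R"
    variant_K = "variant_K"
    variant_I = "variant_I"
    noncanonical = "noncanonical"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier.

    Letters must come from the 20-residue alphabet plus ``X`` (unknown).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET_X
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residue letters {sorted(bad)}"
            )


@dataclass
class DomainAnnotation:
    """Coordinates and key residues of one detected bZIP domain.

    All indices are 0-based into the protein sequence.  ``anchor_n`` is the
    invariant asparagine candidate (domain position -18); ``zipper_start`` is
    domain position +1.  Spans are half-open ``(start, stop)`` tuples.
    """

    protein_id: str
    anchor_n: int
    pos_minus18_residue: str
    pos_minus10_residue: str
    zipper_start: int
    basic_span: tuple[int, int]
    hinge_span: tuple[int, int]
    zipper_span: tuple[int, int]
    n_heptads: int
    variant_class: BindingVariant = field(default=BindingVariant.noncanonical)
    basic_truncated: bool = False

    def __post_init__(self) -> None:
        if self.anchor_n + OFFSET_ZIPPER != self.zipper_start:
            raise ValueError("zipper_start must be anchor_n + 18")
        if self.hinge_span[1] - self.hinge_span[0] != HINGE_LEN:
            raise ValueError("hinge span must cover 9 residues (-9..-1)")
        if self.basic_span[1] - self.basic_span[0] > BASIC_LEN:
            raise ValueError("basic span cannot exceed 16 residues (-25..-10)")


def classify_binding_variant(
    minus18: str, minus10: str
) -> BindingVariant:
    """Classify a DNA-binding site from the -18 and -10 residues.

    ``canonical_R`` for N/R, ``variant_K`` for N/K, ``variant_I`` whenever the
    -10 residue is isoleucine, otherwise ``noncanonical``.  Total over every
    residue pair.
    """
    if minus10 == "I":
        return BindingVariant.variant_I
    if minus18 == "N" and minus10 == "R":
        return BindingVariant.canonical_R
    if minus18 == "N" and minus10 == "K":
        return BindingVariant.variant_K
    return BindingVariant.noncanonical


def scan_domain(
    protein: ProteinRecord,
    relaxed: bool = False,
    min_heptads: int = 2,
    max_heptads: int = 8,
) -> list[DomainAnnotation]:
    """Scan a protein for bZIP domains by the invariant motif.

    A hit at index ``i`` requires ``sequence[i] == 'N'``, ``sequence[i+8]`` in
    ``{R, K}`` (also ``I`` when ``relaxed`` is set, to admit the isoleucine
    binding-site variant), ``sequence[i+18] == 'L'`` (first zipper leucine),
    and at least ``min_heptads - 1`` further leucines spaced seven residues
    apart from it.  ``X`` never matches a motif position.

    Parameters
    ----------
    protein:
        Validated protein record.
    relaxed:
        Accept isoleucine at the -10 position.
    min_heptads:
        Minimum number of heptad-spaced leucines (including the first).
    max_heptads:
        Cap on the zipper extent; the zipper span runs from +1 to
        ``min(sequence end, zipper_start + 7 * max_heptads)``.

    Returns
    -------
    list of :class:`DomainAnnotation`, ordered by anchor position; empty when
    the motif is absent.
    """
    seq = protein.sequence
    allowed_minus10 = {"R", "K", "I"} if relaxed else {"R", "K"}
    hits: list[DomainAnnotation] = []
    for i in range(len(seq) - OFFSET_ZIPPER):
        if seq[i] != "N":
            continue
        if seq[i + OFFSET_MINUS10] not in allowed_minus10:
            continue
        z = i + OFFSET_ZIPPER
        if seq[z] != "L":
            continue
        n_leu = 1
        for k in range(1, max_heptads):
            pos = z + 7 * k
            if pos >= len(seq):
                break
            if seq[pos] == "L":
                n_leu += 1
        if n_leu < min_heptads:
            continue
        hits.append(_annotate(protein, i, max_heptads))
    return hits


def _annotate(
    protein: ProteinRecord, anchor: int, max_heptads: int
) -> DomainAnnotation:
    seq = protein.sequence
    basic_start = anchor - 7
    truncated = basic_start < 0
    basic_span = (max(basic_start, 0), anchor + OFFSET_MINUS10 + 1)
    zipper_start = anchor + OFFSET_ZIPPER
    zipper_end = min(len(seq), zipper_start + 7 * max_heptads)
    n_heptads = math.ceil((zipper_end - zipper_start) / 7)
    minus18 = seq[anchor]
    minus10 = seq[anchor + OFFSET_MINUS10]
    return DomainAnnotation(
        protein_id=protein.id,
        anchor_n=anchor,
        pos_minus18_residue=minus18,
        pos_minus10_residue=minus10,
        zipper_start=zipper_start,
        basic_span=basic_span,
        hinge_span=(anchor + OFFSET_MINUS10 + 1, zipper_start),
        zipper_span=(zipper_start, zipper_end),
        n_heptads=n_heptads,
        variant_class=classify_binding_variant(minus18, minus10),
        basic_truncated=truncated,
    )


def extract_regions(
    ann: DomainAnnotation, protein: ProteinRecord
) -> tuple[str, str, str]:
    """Return the (basic, hinge, zipper) substrings of an annotated domain.

    The basic region covers positions -25..-10 and may be shorter than 16
    residues when the sequence starts inside it (``ann.basic_truncated``).
    """
    if ann.protein_id != protein.id:
        raise ValueError(
            f"annotation for {ann.protein_id!r} does not belong to "
            f"protein {protein.id!r}"
        )
    seq = protein.sequence
    if ann.zipper_span[1] > len(seq) or ann.anchor_n < 0:
        raise ValueError("annotation out of sequence bounds")
    basic = seq[ann.basic_span[0] : ann.basic_span[1]]
    hinge = seq[ann.hinge_span[0] : ann.hinge_span[1]]
    zipper = seq[ann.zipper_span[0] : ann.zipper_span[1]]
    return basic, hinge, zipper
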