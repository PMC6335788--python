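"""Heptad registers and dimerization-property statistics of leucine zippers.

Coiled-coil heptads are labeled a-g; the d positions carry the zipper
leucines and, together with a, form the hydrophobic dimer interface, while
the flanking e and g positions govern electrostatic dimer specificity.  The
register is anchored at the first zipper leucine (domain position +1), which
is assigned the d slot of heptad 1; labels then continue cyclically
(e, f, g, a, b, c, d, ...) toward the C terminus, so heptad 1 has no a-c
slots and the final heptad may be partial.

g<->e' pairs couple the g residue of heptad n with the e residue of heptad
n + 1 (the residue facing it on the partner helix of a parallel homodimer).
Pairs are classified by charge: basic = {R, K}, acidic = {D, E}; histidine
counts as uncharged.  Oppositely charged pairs are attractive (+/- when g is
basic, -/+ when g is acidic), like-charged pairs are basic- or
acidic-repulsive, and anything else is uncharged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from bzipkit.domain_scanner import DomainAnnotation, ProteinRecord

HEPTAD_LABELS = "abcdefg"
BASIC_RESIDUES = frozenset("RK")
ACIDIC_RESIDUES = frozenset("DE")

#: Register slot of the first zipper residue (index into a-g): 3 = 'd'.
DEFAULT_REGISTER_OFFSET = 3


class GECategory(str, Enum):
    attractive_plus_minus = "attractive_plus_minus"
    attractive_minus_plus = "attractive_minus_plus"
    basic_repulsive = "basic_repulsive"
    acidic_repulsive = "acidic_repulsive"
    uncharged = "uncharged"


@dataclass
class HeptadRegister:
    """A zipper partitioned into heptads with a-g slot labels.

    ``heptads`` maps slot labels to residues per heptad; slots absent from a
    partial first or last heptad are simply missing from the mapping.
    """

    protein_id: str
    heptads: list[dict[str, str]]

    def __post_init__(self) -> None:
        for h in self.heptads:
            bad = set(h) - set(HEPTAD_LABELS)
            if bad:
                raise ValueError(f"unknown heptad slots {sorted(bad)}")

    @property
    def n_heptads(self) -> int:
        return len(self.heptads)

    def residue(self, heptad: int, slot: str) -> str | None:
        """Residue at 1-based heptad number and slot label, or None."""
        if not 1 <= heptad <= len(self.heptads):
            return None
        return self.heptads[heptad - 1].get(slot)


@dataclass(frozen=True)
class GEPair:
    """A g<->e' residue pair between consecutive heptads."""

    heptad_index: int
    g_residue: str
    e_prime_residue: str
    category: GECategory


def assign_register(
    ann: DomainAnnotation,
    protein: ProteinRecord,
    register_offset: int = DEFAULT_REGISTER_OFFSET,
) -> HeptadRegister:
    """Assign a-g labels to the zipper residues of an annotated domain.

    The first zipper residue takes the slot ``HEPTAD_LABELS[register_offset]``
    of heptad 1 (default d, the leucine anchor); labels continue cyclically.
    Idempotent: depends only on the zipper span and the offset.
    """
    if ann.protein_id != protein.id:
        raise ValueError("annotation does not belong to this protein")
    start, stop = ann.zipper_span
    zipper = protein.sequence[start:stop]
    if not zipper:
        raise ValueError(f"{protein.id}: empty zipper span")
    if not 0 <= register_offset < 7:
        raise ValueError("register_offset must be in 0..6")
    n_heptads = (register_offset + len(zipper) - 1) // 7 + 1
    heptads: list[dict[str, str]] = [{} for _ in range(n_heptads)]
    for j, res in enumerate(zipper):
        slot_index = (register_offset + j) % 7
        heptads[(register_offset + j) // 7][HEPTAD_LABELS[slot_index]] = res
    return HeptadRegister(protein_id=ann.protein_id, heptads=heptads)


def composition_by_position(
    registers: list[HeptadRegister],
    positions: str = "adeg",
) -> dict[str, tuple[dict[str, float], int]]:
    """Residue composition at the interface positions, pooled over heptads.

    For each requested slot, residues from every heptad of every register are
    pooled; ``X`` residues are excluded from the denominator.  Returns
    ``{slot: (frequencies, denominator)}`` with frequencies summing to 1 over
    observed residues (empty mapping when nothing observed).
    """
    if not registers:
        raise ValueError("at least one register required")
    out: dict[str, tuple[dict[str, float], int]] = {}
    for slot in positions:
        counts: Counter[str] = Counter()
        for reg in registers:
            for heptad in reg.heptads:
                res = heptad.get(slot)
                if res is not None and res != "X":
                    counts[res] += 1
        denom = sum(counts.values())
        freqs = {res: c / denom for res, c in sorted(counts.items())} if denom else {}
        out[slot] = (freqs, denom)
    return out


def asn_a_by_heptad(registers: list[HeptadRegister]) -> pd.DataFrame:
    """Percentage of asparagine at the a slot, per heptad index.

    For heptad ``h``, the percentage is 100 times the number of registers
    carrying N at a of heptad ``h`` over the number of registers with any
    non-X residue there.  Returns a frame indexed by heptad number with
    columns ``pct_asn``, ``n_asn`` and ``n_observed``.
    """
    if not registers:
        raise ValueError("at least one register required")
    max_h = max(reg.n_heptads for reg in registers)
    rows = []
    for h in range(1, max_h + 1):
        observed = 0
        asn = 0
        for reg in registers:
            res = reg.residue(h, "a")
            if res is None or res == "X":
                continue
            observed += 1
            if res == "N":
                asn += 1
        pct = 100.0 * asn / observed if observed else 0.0
        rows.append({"heptad": h, "pct_asn": pct, "n_asn": asn, "n_observed": observed})
    return pd.DataFrame(rows).set_index("heptad")


def classify_ge_pair(g_residue: str, e_prime_residue: str) -> GECategory:
    """Charge category of one g<->e' residue pair."""
    g_basic = g_residue in BASIC_RESIDUES
    g_acid = g_residue in ACIDIC_RESIDUES
    e_basic = e_prime_residue in BASIC_RESIDUES
    e_acid = e_prime_residue in ACIDIC_RESIDUES
    if g_basic and e_acid:
        return GECategory.attractive_plus_minus
    if g_acid and e_basic:
        return GECategory.attractive_minus_plus
    if g_basic and e_basic:
        return GECategory.basic_repulsive
    if g_acid and e_acid:
        return GECategory.acidic_repulsive
    return GECategory.uncharged


def classify_ge_pairs(register: HeptadRegister) -> list[GEPair]:
    """All g<->e' pairs of one register (g of heptad n, e of heptad n+1).

    A pair exists only where both residues are present and neither is X;
    fewer than two heptads yields an empty list.
    """
    pairs: list[GEPair] = []
    for n in range(1, register.n_heptads):
        g = register.residue(n, "g")
        e = register.residue(n + 1, "e")
        if g is None or e is None or "X" in (g, e):
            continue
        pairs.append(
            GEPair(
                heptad_index=n,
                g_residue=g,
                e_prime_residue=e,
                category=classify_ge_pair(g, e),
            )
        )
    return pairs


def aggregate_ge(
    registers: list[HeptadRegister], per_heptad: bool = True
) -> pd.DataFrame:
    """Frequency of each g<->e' category, per heptad index.

    With ``per_heptad`` (default) frequencies are normalized by the number of
    pairs observed at that heptad index; otherwise by the total pair count,
    matching the alternative reading of family-wide percentages.  Columns are
    the five categories plus ``n_pairs``; frequencies are on 0..1.
    """
    all_pairs = [p for reg in registers for p in classify_ge_pairs(reg)]
    if not all_pairs:
        return pd.DataFrame(
            columns=[c.value for c in GECategory] + ["n_pairs"]
        )
    total = len(all_pairs)
    max_h = max(p.heptad_index for p in all_pairs)
    rows = []
    for h in range(1, max_h + 1):
        at_h = [p for p in all_pairs if p.heptad_index == h]
        denom = len(at_h) if per_heptad else total
        row = {"heptad": h, "n_pairs": len(at_h)}
        for cat in GECategory:
            count = sum(1 for p in at_h if p.category is cat)
            row[cat.value] = count / denom if denom else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("heptad")


def read_register_table(path) -> list[HeptadRegister]:
    """Ingest a pre-annotated heptad alignment table (TSV).

    The first column holds protein ids; remaining columns are register slots
    named ``<heptad><slot>`` (e.g. ``1d``, ``2a``).  Empty cells and ``-``
    denote absent slots.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = df.columns[0]
    slot_cols: list[tuple[int, str, str]] = []
    for col in df.columns[1:]:
        name = col.strip()
        heptad, slot = name[:-1], name[-1]
        if not heptad.isdigit() or slot not in HEPTAD_LABELS:
            raise ValueError(f"column {col!r} is not a <heptad><slot> label")
        slot_cols.append((int(heptad), slot, col))
    registers = []
    for _, row in df.iterrows():
        n_heptads = max(h for h, _, _ in slot_cols)
        heptads: list[dict[str, str]] = [{} for _ in range(n_heptads)]
        for h, slot, col in slot_cols:
            val = row[col]
            if pd.isna(val) or val in ("", "-"):
                continue
            heptads[h - 1][slot] = str(val).strip().upper()
        while heptads and not heptads[-1]:
            heptads.pop()
        registers.append(HeptadRegister(protein_id=row[id_col], heptads=heptads))
    return registers
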