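"""Seeded generators producing bZIP-like data with known ground truth.

Every pipeline stage in this package can be exercised without external
genome downloads: this module builds proteins carrying the invariant
N-x7-R/K basic-region motif and a leucine-heptad zipper, gene models with
introns planted at chosen domain positions and phases, codon-sequence pairs
with controlled synonymous/nonsynonymous divergence, gene-order tables with
planted tandem clusters, and FPKM/Ct expression tables realizing the four
seed-development profile groups and treatment/control contrasts.

All generators are deterministic given their seed (byte-identical outputs).
Flanking and filler sequence is drawn from the amino-acid alphabet without
asparagine, so a generated protein contains exactly the planted domain
anchor and scanning it back recovers the ground truth.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from Bio.Data.CodonTable import standard_dna_table

from bzipkit.domain_scanner import (
    BASIC_LEN,
    HINGE_LEN,
    AA_ALPHABET,
    BindingVariant,
    DomainAnnotation,
    classify_binding_variant,
)
from bzipkit.intron_phase_mapper import GeneModel, IntronRecord, Region

# Flank/filler alphabet excludes N so no spurious motif anchor can arise.
_FLANK_ALPHABET = "".join(sorted(AA_ALPHABET - {"N"}))

# Default basic region: invariant N at index 7 (position -18) and R at
# index 15 (position -10); no other asparagine.
DEFAULT_BASIC = "EKALDRSNRESARRSR"
# Default hinge (-9..-1) with Gln at -5 followed by Ala at -4, the junction
# where hinge introns of pattern a fall.
DEFAULT_HINGE = "RRSQQAYEA"
# Default zipper heptads in sequence order d,e,f,g,a,b,c (zipper starts at d).
DEFAULT_HEPTADS = ("LEQKVAE", "LSRKVAE", "LERKVAE", "LTGEVAR")

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_CODON_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


@dataclass
class DomainSpec:
    """Recipe for one synthetic bZIP-domain protein.

    ``basic_residues`` (16 letters, positions -25..-10) must embed
    ``residue_at_minus18`` at index 7 and ``residue_at_minus10`` at index 15;
    ``hinge_residues`` covers -9..-1 and each zipper heptad is 7 letters.
    """

    residue_at_minus18: str = "N"
    residue_at_minus10: str = "R"
    basic_residues: str | None = None
    hinge_residues: str = DEFAULT_HINGE
    zipper_heptads: tuple[str, ...] = DEFAULT_HEPTADS
    n_flank_left: int = 0
    n_flank_right: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.basic_residues is None:
            b = list(DEFAULT_BASIC)
            b[7] = self.residue_at_minus18
            b[15] = self.residue_at_minus10
            self.basic_residues = "".join(b)
        if len(self.basic_residues) != BASIC_LEN:
            raise ValueError("basic_residues must be 16 letters (-25..-10)")
        if len(self.hinge_residues) != HINGE_LEN:
            raise ValueError("hinge_residues must be 9 letters (-9..-1)")
        if self.basic_residues[7] != self.residue_at_minus18:
            raise ValueError("basic_residues[7] must be the -18 residue")
        if self.basic_residues[15] != self.residue_at_minus10:
            raise ValueError("basic_residues[15] must be the -10 residue")
        for h in self.zipper_heptads:
            if len(h) != 7:
                raise ValueError("each zipper heptad must be 7 letters")
        letters = (
            self.basic_residues
            + self.hinge_residues
            + "".join(self.zipper_heptads)
        )
        bad = set(letters) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid amino-acid letters {sorted(bad)}")
        if self.n_flank_left < 0 or self.n_flank_right < 0:
            raise ValueError("flank lengths must be non-negative")


def make_domain_protein(
    spec: DomainSpec, protein_id: str = "synth1"
) -> tuple[str, DomainAnnotation]:
    """Assemble a protein around a planted bZIP domain.

    Returns the sequence ``flank_left + basic(16) + hinge(9) + zipper +
    flank_right`` and the ground-truth annotation (anchor at flank + 7,
    zipper start at flank + 25).
    """
    rng = random.Random(spec.seed)
    left = "".join(rng.choice(_FLANK_ALPHABET) for _ in range(spec.n_flank_left))
    right = "".join(rng.choice(_FLANK_ALPHABET) for _ in range(spec.n_flank_right))
    zipper = "".join(spec.zipper_heptads)
    sequence = left + spec.basic_residues + spec.hinge_residues + zipper + right
    anchor = spec.n_flank_left + 7
    zipper_start = anchor + 18
    ann = DomainAnnotation(
        protein_id=protein_id,
        anchor_n=anchor,
        pos_minus18_residue=spec.residue_at_minus18,
        pos_minus10_residue=spec.residue_at_minus10,
        zipper_start=zipper_start,
        basic_span=(spec.n_flank_left, anchor + 9),
        hinge_span=(anchor + 9, zipper_start),
        zipper_span=(zipper_start, zipper_start + len(zipper)),
        n_heptads=len(spec.zipper_heptads),
        variant_class=classify_binding_variant(
            spec.residue_at_minus18, spec.residue_at_minus10
        ),
        basic_truncated=False,
    )
    return sequence, ann


def random_domain_spec(rng: random.Random, max_flank: int = 100) -> DomainSpec:
    """Draw a random valid :class:`DomainSpec` (for property tests).

    The -10 residue is R, K or I; non-landmark residues avoid asparagine so
    the planted anchor is unique; zipper d slots are leucines.
    """
    minus10 = rng.choice("RKI")
    basic = [rng.choice(_FLANK_ALPHABET) for _ in range(BASIC_LEN)]
    basic[7] = "N"
    basic[15] = minus10
    hinge = [rng.choice(_FLANK_ALPHABET) for _ in range(HINGE_LEN)]
    n_heptads = rng.randint(2, 6)
    heptads = []
    for _ in range(n_heptads):
        h = [rng.choice(_FLANK_ALPHABET) for _ in range(7)]
        h[0] = "L"
        heptads.append("".join(h))
    return DomainSpec(
        residue_at_minus18="N",
        residue_at_minus10=minus10,
        basic_residues="".join(basic),
        hinge_residues="".join(hinge),
        zipper_heptads=tuple(heptads),
        n_flank_left=rng.randint(0, max_flank),
        n_flank_right=rng.randint(0, max_flank),
        seed=rng.randrange(2**31),
    )


@dataclass
class IntronPlan:
    """Where to plant introns when building a synthetic gene model.

    ``entries`` holds ``(position, phase)`` pairs in N-to-C order: negative
    positions are domain positions (-25..-1, resolved against the domain
    annotation), positive ones are 1-based protein residues.  ``intron_lengths``
    optionally fixes intron lengths; otherwise lengths are drawn from
    ``length_range`` (default 60-200 nt).
    """

    entries: list[tuple[int, int]] = field(default_factory=list)
    intron_lengths: list[int] | None = None
    length_range: tuple[int, int] = (60, 200)

    def __post_init__(self) -> None:
        for pos, phase in self.entries:
            if phase not in (0, 1, 2):
                raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
            if pos == 0:
                raise ValueError("there is no position 0")
            if pos < -25:
                raise ValueError("domain positions lie in -25..-1")
        if self.intron_lengths is not None:
            if len(self.intron_lengths) != len(self.entries):
                raise ValueError("one intron length per entry required")
            if any(l < 4 for l in self.intron_lengths):
                raise ValueError("introns need >= 4 nt for GT..AG ends")


@dataclass
class SyntheticGene:
    """A generated gene: CDS, model, GFF3 text and ground-truth introns."""

    cds: str
    model: GeneModel
    gff3: str
    introns: list[IntronRecord]
    genomic_seq: str


def reverse_translate(protein: str, rng: random.Random) -> str:
    """Back-translate with a seeded uniform codon choice per residue."""
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS.get(aa)
        if options is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(rng.choice(options))
    return "".join(codons)


def _resolve_cds_offsets(
    protein: str,
    plan: IntronPlan,
    annotation: DomainAnnotation | None,
) -> list[int]:
    offsets = []
    for pos, phase in plan.entries:
        if pos < 0:
            if annotation is None:
                raise ValueError(
                    "domain-relative intron positions need a DomainAnnotation"
                )
            residue = annotation.anchor_n + 1 + (pos + 18)
        else:
            residue = pos
        if not 1 <= residue <= len(protein):
            raise ValueError(f"intron position {pos} beyond protein end")
        if phase == 0:
            off = 3 * residue
        else:
            off = 3 * (residue - 1) + phase
        offsets.append(off)
    if offsets != sorted(set(offsets)):
        raise ValueError("intron positions must be strictly increasing")
    if offsets and offsets[-1] >= 3 * len(protein):
        raise ValueError("intron planted at or beyond the CDS end")
    return offsets


def make_gene_model(
    protein: str,
    plan: IntronPlan,
    seed: int = 0,
    annotation: DomainAnnotation | None = None,
    gene_id: str = "synthgene1",
    chrom: str = "chr1",
    strand: str = "+",
    gene_start: int = 1001,
) -> SyntheticGene:
    """Build a gene model realizing a protein with planted introns.

    The protein is reverse-translated with a seeded codon choice, the CDS is
    split at the planted positions/phases, and random introns with canonical
    GT..AG ends are inserted.  The exon-concatenated CDS retranslates to the
    input protein by construction; the returned ground-truth records carry
    the planted offsets and phases.
    """
    rng = random.Random(seed)
    cds = reverse_translate(protein, rng)
    offsets = _resolve_cds_offsets(protein, plan, annotation)
    if plan.intron_lengths is not None:
        lengths = list(plan.intron_lengths)
    else:
        lengths = [
            rng.randint(*plan.length_range) for _ in offsets
        ]
    intron_seqs = [
        "GT" + "".join(rng.choice("ACGT") for _ in range(n - 4)) + "AG"
        for n in lengths
    ]
    # Plus-strand layout first; minus strand is its reverse complement.
    pieces = []
    exon_bounds = []  # (start, end) 1-based inclusive in layout coordinates
    cursor = gene_start
    prev = 0
    for off, iseq in zip(offsets + [len(cds)], intron_seqs + [None]):
        exon_seq = cds[prev:off]
        pieces.append(exon_seq)
        exon_bounds.append((cursor, cursor + len(exon_seq) - 1))
        cursor += len(exon_seq)
        if iseq is not None:
            pieces.append(iseq)
            cursor += len(iseq)
        prev = off
    layout = "".join(pieces)
    if strand == "+":
        genomic = layout
        exons = exon_bounds
    else:
        genomic = _revcomp(layout)
        span = gene_start + len(layout) - 1  # flip within the layout span
        exons = [
            (gene_start + (span - e), gene_start + (span - s))
            for s, e in exon_bounds
        ]
    model = GeneModel(
        gene_id=gene_id,
        strand=strand,
        exons=exons,
        protein_id=gene_id,
        chrom=chrom,
    )
    truth = []
    for idx, off in enumerate(offsets, start=1):
        phase = off % 3
        protein_pos = off // 3 if phase == 0 else (off + 2) // 3
        truth.append(
            IntronRecord(
                index=idx, cds_offset=off, phase=phase, protein_pos=protein_pos
            )
        )
    return SyntheticGene(
        cds=cds,
        model=model,
        gff3=write_gff3(model),
        introns=truth,
        genomic_seq=genomic,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def write_gff3(model: GeneModel) -> str:
    """Serialize a gene model as GFF3 (gene, mRNA and CDS features)."""
    genomic_sorted = sorted(model.exons)
    gene_lo = genomic_sorted[0][0]
    gene_hi = genomic_sorted[-1][1]
    lines = ["##gff-version 3"]
    gid = model.gene_id
    lines.append(
        "\t".join(
            [model.chrom, "bzipkit", "gene", str(gene_lo), str(gene_hi), ".",
             model.strand, ".", f"ID={gid}"]
        )
    )
    mrna = f"{gid}.t1"
    lines.append(
        "\t".join(
            [model.chrom, "bzipkit", "mRNA", str(gene_lo), str(gene_hi), ".",
             model.strand, ".", f"ID={mrna};Parent={gid}"]
        )
    )
    cum = 0
    for i, (s, e) in enumerate(model.exons, start=1):
        gff_phase = (3 - cum % 3) % 3
        lines.append(
            "\t".join(
                [model.chrom, "bzipkit", "CDS", str(s), str(e), ".",
                 model.strand, str(gff_phase),
                 f"ID={mrna}.cds{i};Parent={mrna}"]
            )
        )
        cum += e - s + 1
    return "\n".join(lines) + "\n"


@dataclass
class CodonEvolParams:
    """Target divergence for a simulated codon-sequence pair.

    ``target_dS``/``target_dN`` are expected substitutions per synonymous /
    nonsynonymous site between the two output sequences.
    """

    target_dS: float
    target_dN: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_dS < 0 or self.target_dN < 0:
            raise ValueError("target divergences must be non-negative")


def evolve_pair(cds: str, params: CodonEvolParams) -> tuple[str, str]:
    """Derive a diverged copy of a CDS with controlled dS and dN.

    Substitution events are proposed at Poisson-distributed random positions
    (uniform among the three alternative bases, matching the Jukes-Cantor
    assumption of the downstream estimator) and accepted with probabilities
    proportional to the synonymous and nonsynonymous targets.  Events that
    would create a stop codon are discarded.  The first returned sequence is
    the input; the second is the mutated copy.  With both targets zero the
    copies are identical.
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for c in codons:
        if c in _STOPS:
            raise ValueError("input contains a stop codon")
        if c not in _CODON_AA:
            raise ValueError(f"invalid codon {c!r}")
    mu = max(params.target_dS, params.target_dN)
    if mu == 0:
        return seq, seq
    p_syn = params.target_dS / mu
    p_non = params.target_dN / mu
    rng = np.random.default_rng(params.seed)
    n_events = rng.poisson(mu * len(seq))
    positions = rng.integers(0, len(seq), size=n_events)
    base_choice = rng.integers(0, 3, size=n_events)
    accept_draw = rng.random(size=n_events)
    mutable = list(seq)
    for pos, bc, u in zip(positions, base_choice, accept_draw):
        old = mutable[pos]
        alts = [b for b in "ACGT" if b != old]
        new = alts[bc]
        ci = pos // 3
        codon = "".join(mutable[3 * ci : 3 * ci + 3])
        k = pos % 3
        alt_codon = codon[:k] + new + codon[k + 1 :]
        if alt_codon in _STOPS:
            continue
        synonymous = _CODON_AA[alt_codon] == _CODON_AA[codon]
        if u < (p_syn if synonymous else p_non):
            mutable[pos] = new
    return seq, "".join(mutable)


def random_cds(n_codons: int, seed: int = 0) -> str:
    """A random stop-free CDS of the given codon count."""
    rng = random.Random(seed)
    sense = sorted(_CODON_AA)
    return "".join(rng.choice(sense) for _ in range(n_codons))


def make_gene_order_table(
    n_genes: int,
    planted_clusters: list[list[int]],
    seed: int = 0,
    chrom: str = "chr1",
    n_background_edges: int | None = None,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """A chromosome gene order with similarity edges and planted clusters.

    ``planted_clusters`` are disjoint lists of 0-based order positions; every
    within-cluster pair receives an e-value below 1e-20, while background
    edges between other genes stay at or above 1e-20.  Returns the
    ``{chrom: [gene ids]}`` order mapping and an edge table with columns
    ``gene_a, gene_b, evalue``.
    """
    seen: set[int] = set()
    for cl in planted_clusters:
        if any(p in seen for p in cl):
            raise ValueError("planted clusters must be disjoint")
        if any(not 0 <= p < n_genes for p in cl):
            raise ValueError("cluster position out of range")
        seen.update(cl)
    rng = random.Random(seed)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    rows = []
    for cl in planted_clusters:
        ids = [genes[p] for p in sorted(cl)]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append(
                    {
                        "gene_a": ids[i],
                        "gene_b": ids[j],
                        "evalue": 10 ** -rng.uniform(21, 60),
                    }
                )
    if n_background_edges is None:
        n_background_edges = n_genes // 2
    cluster_pairs = {
        frozenset((r["gene_a"], r["gene_b"])) for r in rows
    }
    attempts = 0
    while n_background_edges > 0 and attempts < 50 * (n_background_edges + 1):
        attempts += 1
        a, b = rng.sample(genes, 2)
        if frozenset((a, b)) in cluster_pairs:
            continue
        rows.append(
            {"gene_a": a, "gene_b": b, "evalue": 10 ** -rng.uniform(0, 19)}
        )
        n_background_edges -= 1
    return {chrom: genes}, pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "evalue"]
    )


@dataclass
class ExpressionSimConfig:
    """Recipe for FPKM and qPCR Ct tables with planted profile groups.

    ``group_sizes`` gives gene counts per profile class; ``base_fpkm`` is the
    baseline abundance, ``fold`` (> 1) the planted peak/trough fold change
    and ``noise_cv`` the coefficient of variation of the multiplicative
    log-normal noise.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "not_expressed": 24, "I": 37, "II": 15, "III": 17, "IV": 22
        }
    )
    base_fpkm: float = 10.0
    fold: float = 5.0
    noise_cv: float = 0.1
    floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        known = {"not_expressed", "I", "II", "III", "IV"}
        bad = set(self.group_sizes) - known
        if bad:
            raise ValueError(f"unknown profile groups {sorted(bad)}")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")
        if self.base_fpkm <= 0:
            raise ValueError("base_fpkm must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    # mean-one multiplicative noise
    return rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=size)


def make_expression_data(
    cfg: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """FPKM matrix over DAF20/40/60 with planted groups, plus a Ct table.

    Planted patterns: group I peaks at DAF20, II at DAF40, III dips at
    DAF40, IV is high and flat, and ``not_expressed`` sits far below the
    floor.  Returns (fpkm, truth labels, qPCR Ct table); the Ct table covers
    treatment/control at 0/1/5/10 h with three replicates and the internal
    control gene, with no planted treatment effect (ddCt = 0 up to noise).
    """
    rng = np.random.default_rng(cfg.seed)
    b, f = cfg.base_fpkm, cfg.fold
    patterns = {
        "not_expressed": (0.1 * cfg.floor,) * 3,
        "I": (b * f, b, b),
        "II": (b, b * f, b),
        "III": (b * f, b, b * f),
        "IV": (b * f, b * f, b * f),
    }
    genes, labels, values = [], [], []
    counter = 0
    for group in ("not_expressed", "I", "II", "III", "IV"):
        for _ in range(cfg.group_sizes.get(group, 0)):
            counter += 1
            genes.append(f"bzip{counter}")
            labels.append(group)
            values.append(patterns[group])
    fpkm = pd.DataFrame(values, index=genes, columns=["DAF20", "DAF40", "DAF60"])
    fpkm *= _lognormal_noise(rng, cfg.noise_cv, fpkm.shape)
    truth = pd.Series(labels, index=genes, name="profile_group")
    ddct = {g: {} for g in genes}
    ct = make_qpcr_table(
        genes,
        planted_ddct=ddct,
        time_points=(0, 1, 5, 10),
        seed=int(rng.integers(0, 2**31)),
    )
    return fpkm, truth, ct


def make_qpcr_table(
    genes: list[str],
    planted_ddct: dict[str, dict] | None = None,
    time_points: tuple = (0, 1, 5, 10),
    n_replicates: int = 3,
    base_dct: float = 4.0,
    control_gene_ct: float = 20.0,
    noise_sd: float = 0.15,
    seed: int = 0,
    control_gene: str = "Actin",
) -> pd.DataFrame:
    """Long-format qPCR Ct table with planted ddCt effects.

    ``planted_ddct[gene][time]`` is the true ddCt of the treatment against
    the control condition at that time point (absent entries mean 0, i.e. no
    effect).  Per-replicate Ct values are the internal-control Ct plus the
    condition dCt plus Gaussian technical noise.  Columns: gene, condition,
    time, replicate, ct, control_ct; rows for the internal control gene
    itself are included with ct equal to control_ct.
    """
    rng = np.random.default_rng(seed)
    planted_ddct = planted_ddct or {}
    rows = []
    for gene in genes:
        for time in time_points:
            effect = float(planted_ddct.get(gene, {}).get(time, 0.0))
            for condition, dct in (
                ("control", base_dct),
                ("treatment", base_dct + effect),
            ):
                for rep in range(1, n_replicates + 1):
                    ref_ct = control_gene_ct + rng.normal(0, noise_sd)
                    ct_val = ref_ct + dct + rng.normal(0, noise_sd)
                    rows.append(
                        {
                            "gene": gene,
                            "condition": condition,
                            "time": time,
                            "replicate": rep,
                            "ct": ct_val,
                            "control_ct": ref_ct,
                        }
                    )
    for time in time_points:
        for condition in ("control", "treatment"):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": control_gene,
                        "condition": condition,
                        "time": time,
                        "replicate": rep,
                        "ct": control_gene_ct,
                        "control_ct": control_gene_ct,
                    }
                )
    return pd.DataFrame(rows)
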