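"""Coordinate maps, splicing phases and domain intron patterns a-d."""

import random

import pytest

from bzipkit.domain_scanner import ProteinRecord, scan_domain
from bzipkit.intron_phase_mapper import (
    GeneModel,
    IntronPattern,
    IntronRecord,
    Region,
    annotate_domain_positions,
    build_cds_map,
    classify_pattern,
    locate_introns,
)
from bzipkit.synthetic_data import (
    DomainSpec,
    IntronPlan,
    make_domain_protein,
    make_gene_model,
    random_domain_spec,
)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def test_single_exon_map_is_direct_arithmetic():
    model = GeneModel("g", "+", [(101, 400)])
    cmap = build_cds_map(model)
    assert cmap.cds_length == 300 and cmap.n_codons == 100
    assert cmap.residue_to_genomic(1) == [101, 102, 103]
    assert cmap.cds_to_genomic(1) == 101
    assert cmap.genomic_to_cds(400) == 300


def test_residue_maps_to_codon_interval():
    model = GeneModel("g", "+", [(1, 30)])
    cmap = build_cds_map(model)
    for p in range(1, 11):
        assert cmap.residue_to_cds(p) == (3 * p - 2, 3 * p)


def test_minus_strand_round_trip_is_identity():
    model = GeneModel("g", "-", [(500, 640), (100, 300)])
    cmap = build_cds_map(model)
    assert cmap.cds_to_genomic(1) == 640  # transcription starts at the high end
    for c in range(1, cmap.cds_length + 1):
        assert cmap.genomic_to_cds(cmap.cds_to_genomic(c)) == c


def test_invalid_models_rejected():
    with pytest.raises(ValueError, match="multiple of 3"):
        build_cds_map(GeneModel("g", "+", [(1, 10)]))
    with pytest.raises(ValueError, match="overlapping"):
        GeneModel("g", "+", [(1, 10), (5, 20)])
    with pytest.raises(ValueError, match="transcription order"):
        GeneModel("g", "+", [(50, 60), (1, 9)])


def test_single_exon_gene_has_no_introns():
    assert locate_introns(GeneModel("g", "+", [(1, 30)])) == []


@pytest.mark.parametrize(
    "first_exon_len, phase, protein_pos",
    [(9, 0, 3), (10, 1, 4), (11, 2, 4)],
)
def test_first_intron_phase_follows_mod3(first_exon_len, phase, protein_pos):
    """P0 after a whole codon; P1/P2 label the interrupted residue."""
    model = GeneModel(
        "g", "+", [(1, first_exon_len), (200, 200 + 30 - first_exon_len - 1)]
    )
    (rec,) = locate_introns(model)
    assert rec.cds_offset == first_exon_len
    assert rec.phase == phase
    assert rec.protein_pos == protein_pos


def test_phase_equals_offset_mod_three_invariant():
    with pytest.raises(ValueError):
        IntronRecord(index=1, cds_offset=10, phase=0, protein_pos=4)


def test_intron_far_downstream_is_outside_domain():
    seq, ann = make_domain_protein(DomainSpec(seed=1), "g")
    plan = IntronPlan(entries=[(len(seq) - 1, 0)])
    gene = make_gene_model(seq, plan, seed=1, annotation=ann)
    recs = annotate_domain_positions(locate_introns(gene.model), ann)
    assert recs[0].region is Region.outside
    assert recs[0].domain_pos is None


@pytest.mark.parametrize(
    "entry, region, dpos",
    [
        ((-5, 0), Region.hinge, -5),
        ((-20, 2), Region.basic, -20),
        ((-10, 0), Region.basic, -10),
        ((-9, 1), Region.hinge, -9),
    ],
)
def test_domain_positions_assigned_from_anchor(entry, region, dpos):
    seq, ann = make_domain_protein(DomainSpec(n_flank_left=20, seed=2), "g")
    gene = make_gene_model(seq, IntronPlan(entries=[entry]), seed=2, annotation=ann)
    recs = annotate_domain_positions(locate_introns(gene.model), ann)
    assert recs[0].region is region
    assert recs[0].domain_pos == dpos
    assert recs[0].phase == entry[1]


def test_hinge_intron_falls_between_gln_and_ala():
    """With the default hinge, the pattern-a junction splits Gln|Ala at -5."""
    seq, ann = make_domain_protein(DomainSpec(seed=3), "g")
    gene = make_gene_model(seq, IntronPlan(entries=[(-5, 0)]), seed=3,
                           annotation=ann)
    (rec,) = gene.introns
    assert seq[rec.protein_pos - 1] == "Q"
    assert seq[rec.protein_pos] == "A"


def _rec(region, dpos, phase):
    offset = 30 + phase  # any offset consistent with the phase
    r = IntronRecord(index=1, cds_offset=offset, phase=phase,
                     protein_pos=10 if phase else 10)
    r.region = region
    r.domain_pos = dpos
    return r


@pytest.mark.parametrize(
    "introns, expected",
    [
        ([], IntronPattern.d),
        ([(Region.hinge, -5, 0)], IntronPattern.a),
        ([(Region.basic, -14, 0), (Region.hinge, -3, 0)], IntronPattern.b),
        ([(Region.basic, -20, 2)], IntronPattern.c),
        ([(Region.basic, -20, 1)], IntronPattern.other),
        ([(Region.hinge, -4, 0)], IntronPattern.other),
        ([(Region.basic, -14, 0), (Region.basic, -12, 0)], IntronPattern.other),
        ([(Region.basic, -14, 2), (Region.hinge, -3, 0)], IntronPattern.other),
        (
            [(Region.basic, -20, 0), (Region.hinge, -5, 0), (Region.hinge, -2, 0)],
            IntronPattern.other,
        ),
    ],
)
def test_pattern_classification(introns, expected):
    recs = [_rec(*args) for args in introns]
    assert classify_pattern(recs) is expected


def test_outside_introns_do_not_affect_pattern():
    recs = [_rec(Region.hinge, -5, 0), _rec(Region.outside, None, 1)]
    assert classify_pattern(recs) is IntronPattern.a


PATTERN_PLANS = {
    IntronPattern.a: [(-5, 0)],
    IntronPattern.b: [(-14, 0), (-3, 0)],
    IntronPattern.c: [(-20, 2)],
    IntronPattern.d: [],
}


def test_planted_patterns_recovered_from_gene_models():
    """500 synthetic gene models: phases, truth records and labels recover."""
    rng = random.Random(99)
    patterns = list(PATTERN_PLANS)
    for trial in range(500):
        spec = random_domain_spec(rng, max_flank=40)
        seq, _ = make_domain_protein(spec, f"g{trial}")
        (ann,) = scan_domain(ProteinRecord(f"g{trial}", seq), relaxed=True)
        label = patterns[trial % 4]
        entries = list(PATTERN_PLANS[label])
        if rng.random() < 0.5:  # extra intron outside the domain window
            entries.append((len(seq) - 2, rng.choice([0, 1, 2])))
        strand = rng.choice("+-")
        gene = make_gene_model(
            seq, IntronPlan(entries=entries), seed=trial, annotation=ann,
            strand=strand, gene_id=f"g{trial}",
        )
        recs = locate_introns(gene.model)
        assert [(r.cds_offset, r.phase, r.protein_pos) for r in recs] == [
            (r.cds_offset, r.phase, r.protein_pos) for r in gene.introns
        ]
        annotate_domain_positions(recs, ann)
        assert classify_pattern(recs) is label


def test_coordinate_round_trips_on_generated_models_both_strands():
    rng = random.Random(5)
    for trial in range(40):
        spec = random_domain_spec(rng, max_flank=30)
        seq, ann = make_domain_protein(spec, f"g{trial}")
        strand = "+" if trial % 2 else "-"
        gene = make_gene_model(
            seq, IntronPlan(entries=[(-5, 0), (len(seq) - 2, 2)]), seed=trial,
            annotation=ann, strand=strand,
        )
        cmap = build_cds_map(gene.model)
        start = 1001
        rebuilt = []
        for c in range(1, cmap.cds_length + 1):
            g = cmap.cds_to_genomic(c)
            assert cmap.genomic_to_cds(g) == c
            base = gene.genomic_seq[g - start]
            rebuilt.append(base if strand == "+" else base.translate(COMPLEMENT))
        assert "".join(rebuilt) == gene.cds
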