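"""Ka/Ks estimation, tandem clusters and Ks histograms.

The NG86 checks compare the implementation against an independent
brute-force oracle written here from first principles: synonymous site
fractions obtained by translating every single-base mutant with Biopython,
and difference counts from a recursive enumeration of substitution
pathways.
"""

import math
from itertools import permutations, product

import numpy as np
import pytest
from Bio.Seq import Seq

from bzipkit.duplication_evolution import (
    SENSE_CODONS,
    KaKsResult,
    TandemCluster,
    codon_align_ungapped,
    find_tandem_clusters,
    kaks_ng86,
    ks_histogram,
    purifying_summary,
)
from bzipkit.synthetic_data import (
    CodonEvolParams,
    evolve_pair,
    make_gene_order_table,
    random_cds,
)

# --- independent oracle -----------------------------------------------------


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(codon: str) -> float:
    """Fraction-of-synonymous-changes site count via Biopython translation."""
    total = 0.0
    for pos, b in product(range(3), "ACGT"):
        if b == codon[pos]:
            continue
        mutant = codon[:pos] + b + codon[pos + 1 :]
        if _translate(mutant) != "*" and _translate(mutant) == _translate(codon):
            total += 1 / 3
    return total


def oracle_pair_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Average (Sd, Nd) over stop-free substitution orderings."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    outcomes = []
    for order in permutations(diff):
        cur, sd, nd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _translate(nxt) == "*":
                ok = False
                break
            sd, nd = (sd + 1, nd) if _translate(nxt) == _translate(cur) else (
                sd, nd + 1
            )
            cur = nxt
        if ok:
            outcomes.append((sd, nd))
    if not outcomes:
        return math.nan, math.nan
    return (
        sum(o[0] for o in outcomes) / len(outcomes),
        sum(o[1] for o in outcomes) / len(outcomes),
    )


def oracle_kaks(cds_a: str, cds_b: str) -> tuple[float, float]:
    """(Ka, Ks) from the oracle counts with Jukes-Cantor correction."""
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    s = (
        sum(map(oracle_syn_sites, codons_a))
        + sum(map(oracle_syn_sites, codons_b))
    ) / 2
    n = 3 * len(codons_a) - s
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d_s, d_n = oracle_pair_diffs(ca, cb)
        sd += d_s
        nd += d_n
    jc = lambda p: math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(nd / n), jc(sd / s) if s > 0 else 0.0


# --- NG86 -------------------------------------------------------------------


def test_identical_sequences_have_zero_divergence():
    r = kaks_ng86("ATGGCTAAA", "ATGGCTAAA")
    assert r.ka == 0.0 and r.ks == 0.0
    assert r.ratio is None
    assert r.s_sites + r.n_sites == pytest.approx(9.0)


def test_worked_single_difference_pair():
    """One synonymous difference in TTT/GAT/GCC vs TTC/GAT/GCC.

    Hand count: synonymous sites 1/3 + 1/3 + 1 = 5/3 per sequence, one
    synonymous difference, so pS = 3/5 and
    Ks = -(3/4) ln(1 - (4/3)(3/5)).
    """
    r = kaks_ng86("TTTGATGCC", "TTCGATGCC")
    assert r.s_sites == pytest.approx(5 / 3)
    assert r.sd == pytest.approx(1.0)
    assert r.nd == pytest.approx(0.0)
    assert r.ka == 0.0
    assert r.ks == pytest.approx(-0.75 * math.log(1 - 0.8), abs=1e-12)
    assert r.ks == pytest.approx(1.2069, abs=2e-4)


def test_site_counts_total_three_per_codon_on_random_pairs():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = random_cds(30, seed=int(rng.integers(2**31)))
        b = random_cds(30, seed=int(rng.integers(2**31)))
        r = kaks_ng86(a, b)
        assert r.s_sites + r.n_sites == pytest.approx(90.0, abs=1e-9)


def test_ng86_matches_pathway_enumeration_oracle_on_all_codon_pairs():
    """Exhaustive 61 x 61 single-codon check against the oracle (< 1e-12)."""
    for ca in SENSE_CODONS:
        for cb in SENSE_CODONS:
            r = kaks_ng86(ca, cb)
            ka_o, ks_o = oracle_kaks(ca, cb)
            for mine, theirs in ((r.ka, ka_o), (r.ks, ks_o)):
                if math.isnan(theirs):
                    assert math.isnan(mine)
                else:
                    assert mine == pytest.approx(theirs, abs=1e-12)


def test_simulation_recovery_of_planted_divergence():
    """Planted dS = 0.3, dN = 0.05 on 10,000 codons, 10 seeds."""
    cds = random_cds(10_000, seed=11)
    ks_vals, ka_vals = [], []
    for seed in range(10):
        a, b = evolve_pair(cds, CodonEvolParams(0.3, 0.05, seed=seed))
        r = kaks_ng86(a, b)
        ks_vals.append(r.ks)
        ka_vals.append(r.ka)
    assert np.mean(ks_vals) == pytest.approx(0.3, rel=0.10)
    assert np.mean(ka_vals) == pytest.approx(0.05, rel=0.15)


def test_ks_monotone_in_planted_divergence():
    cds = random_cds(3000, seed=5)
    means = []
    for target in (0.1, 0.4, 0.8):
        vals = []
        for seed in range(5):
            a, b = evolve_pair(cds, CodonEvolParams(target, 0.02, seed=seed))
            vals.append(kaks_ng86(a, b).ks)
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


@pytest.mark.parametrize(
    "a, b, err",
    [
        ("ATGGCT", "ATG", "mismatch"),
        ("ATGG", "ATGG", "multiple of 3"),
        ("ATGTAAGCT", "ATGTAAGCT", "internal stop"),
    ],
)
def test_invalid_pairs_rejected(a, b, err):
    with pytest.raises(ValueError, match=err):
        kaks_ng86(a, b)


# --- purifying selection summary -------------------------------------------


def _result(ratio):
    return KaKsResult("a", "b", 10, 20, 1, 1, 0.1, 0.2, ratio)


def test_purifying_summary_strict_cutoff():
    res = [_result(0.2), _result(0.5), _result(0.7), _result(None)]
    summary = purifying_summary(res, cutoff=0.5)
    assert summary == {"below": 1, "at_or_above": 2, "undefined": 1}


def test_purifying_summary_recovers_planted_omega_split():
    """90% of pairs evolved at omega 0.2, 10% at omega 0.8."""
    cds = random_cds(2000, seed=21)
    results = []
    for i in range(30):
        omega = 0.8 if i < 3 else 0.2
        a, b = evolve_pair(cds, CodonEvolParams(0.5, 0.5 * omega, seed=100 + i))
        results.append(kaks_ng86(a, b))
    summary = purifying_summary(results, cutoff=0.5)
    assert summary["below"] == 27
    assert summary["at_or_above"] == 3


# --- Ks histogram -----------------------------------------------------------


def test_histogram_single_bin():
    h = ks_histogram([0.03, 0.03, 0.03])
    assert h.counts.sum() == 3
    assert h.counts[0] == 3
    assert h.peak_midpoint == pytest.approx(0.025)


def test_histogram_bins_are_half_open():
    h = ks_histogram([0.05], bin_width=0.05)
    assert h.counts[1] == 1 and h.counts[0] == 0


def test_histogram_finds_two_planted_modes():
    """A mixture around 0.035 and 0.90 shows local maxima in those bins."""
    rng = np.random.default_rng(3)
    vals = np.concatenate(
        [
            rng.normal(0.035, 0.01, 400).clip(0),
            rng.normal(0.90, 0.05, 300).clip(0),
        ]
    )
    h = ks_histogram(vals.tolist())
    peaks = h.local_peaks()
    assert any(p == 0 for p in peaks)  # [0.00, 0.05) holds the ortholog-like mode
    assert any(abs((p + 0.5) * 0.05 - 0.90) <= 0.05 for p in peaks)
    assert h.counts.sum() == len(vals)


def test_histogram_rejects_negative():
    with pytest.raises(ValueError):
        ks_histogram([-0.1])


# --- tandem clusters --------------------------------------------------------


def _order(n):
    return {"chr1": [f"g{i + 1}" for i in range(n)]}


def test_no_edges_below_threshold_yields_no_clusters():
    edges = [("g1", "g2", 1e-10)]
    assert find_tandem_clusters(_order(5), edges) == []


def test_threshold_is_strict():
    assert find_tandem_clusters(_order(5), [("g1", "g2", 1e-20)]) == []
    got = find_tandem_clusters(_order(5), [("g1", "g2", 1e-30)])
    assert len(got) == 1 and got[0].members == ("g1", "g2")


def test_one_intervening_gene_tolerated_per_gap():
    """Members at order positions 3,4,6 join; a two-gene gap (3,4,7) breaks."""
    edges = [("g3", "g4", 1e-30), ("g4", "g6", 1e-30)]
    got = find_tandem_clusters(_order(8), edges)
    assert len(got) == 1 and got[0].members == ("g3", "g4", "g6")

    edges = [("g3", "g4", 1e-30), ("g4", "g7", 1e-30)]
    got = find_tandem_clusters(_order(8), edges)
    assert len(got) == 1 and got[0].members == ("g3", "g4")


def test_per_cluster_tolerance_budget():
    edges = [("g1", "g2", 1e-30), ("g2", "g4", 1e-30), ("g4", "g6", 1e-30)]
    per_gap = find_tandem_clusters(_order(6), edges)
    assert per_gap[0].members == ("g1", "g2", "g4", "g6")
    budgeted = find_tandem_clusters(_order(6), edges, per_cluster_tolerance=True)
    assert budgeted[0].members == ("g1", "g2", "g4")


def test_clusters_do_not_span_chromosomes():
    order = {"chr1": ["g1", "g2"], "chr2": ["g3", "g4"]}
    edges = [("g2", "g3", 1e-30)]
    assert find_tandem_clusters(order, edges) == []


def test_unknown_gene_in_edge_raises():
    with pytest.raises(ValueError, match="unknown gene"):
        find_tandem_clusters(_order(3), [("g1", "zzz", 1e-30)])


def test_cluster_invariants_on_random_tables():
    """Definitional invariants over many random planted gene-order tables."""
    rng = np.random.default_rng(17)
    for trial in range(200):
        n = int(rng.integers(6, 40))
        start = int(rng.integers(0, n - 3))
        cluster = sorted(
            {start, start + 1, start + int(rng.integers(2, 4))} & set(range(n))
        )
        order, edges_df = make_gene_order_table(
            n, [cluster] if len(cluster) >= 2 else [], seed=trial
        )
        edge_list = list(edges_df.itertuples(index=False, name=None))
        clusters = find_tandem_clusters(order, edge_list)
        shuffled = edge_list[::-1]
        assert find_tandem_clusters(order, shuffled) == clusters
        for c in clusters:
            assert len(c.members) >= 2
            for p, q in zip(c.positions, c.positions[1:]):
                assert 1 <= q - p <= 2


def test_codon_align_ungapped_validates():
    assert codon_align_ungapped("atggct", "ATGGCA") == ("ATGGCT", "ATGGCA")
    with pytest.raises(ValueError):
        codon_align_ungapped("ATG", "ATGGCT")
    with pytest.raises(ValueError):
        codon_align_ungapped("AT-GCT", "ATGGCT")
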