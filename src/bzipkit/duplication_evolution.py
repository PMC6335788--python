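"""Tandem-duplication clusters, Nei-Gojobori Ka/Ks and Ks distributions.

Tandem clusters follow the consecutive-gene rule: at least two genes with
pairwise similarity below an e-value threshold (strict ``<``), adjacent in
chromosome order, with at most one unrelated intervening gene tolerated
between order-adjacent members (per gap by default; a per-cluster budget is
available).

Ka/Ks uses the Nei-Gojobori (1986) unweighted-pathway method: synonymous and
nonsynonymous site fractions are counted per codon (mutations to stop codons
count as nonsynonymous, so S + N is exactly three per codon), averaged over
the two sequences; codons differing at several positions average the
synonymous/nonsynonymous difference counts over all substitution orderings,
skipping orderings that pass through a stop codon.  Proportions are corrected
for multiple hits with the Jukes-Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``; proportions at or beyond 3/4 are saturated
and reported as NaN with a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

_BASES = "ACGT"
_CODON_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_CODON_AA))


def _syn_site_fractions() -> dict[str, float]:
    """Synonymous site count per sense codon (0..3).

    Each codon position contributes the fraction of its three single-base
    changes that preserve the amino acid; changes to stop codons count as
    nonsynonymous so the synonymous + nonsynonymous sites always total 3.
    """
    table = {}
    for codon in SENSE_CODONS:
        aa = _CODON_AA[codon]
        s = 0.0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt not in _STOPS and _CODON_AA[alt] == aa:
                    s += 1 / 3
        table[codon] = s
    return table


_SYN_SITES = _syn_site_fractions()


def _codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts for one codon pair.

    Averages over all orderings of the differing positions with equal
    weights; orderings passing through a stop codon are skipped, falling back
    to all orderings if every one is blocked.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            if _CODON_AA[current] == _CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        pathways.append((sd, nd, blocked))
    valid = [(s, n) for s, n, b in pathways if not b]
    if not valid:
        # every ordering crosses a stop; average over all of them, counting
        # the steps actually taken plus the remaining steps as nonsynonymous
        valid = []
        for order in permutations(diff):
            current = codon_a
            sd = nd = 0
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if _CODON_AA.get(current, "*") == _CODON_AA.get(nxt, "*"):
                    sd += 1
                else:
                    nd += 1
                current = nxt
            valid.append((sd, nd))
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance for a proportion of differing sites.

    Returns NaN at or beyond the saturation point p = 3/4.
    """
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsResult:
    """Site counts, difference counts and corrected rates for one pair."""

    gene_a: str
    gene_b: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ka: float
    ks: float
    ratio: float | None
    saturated_s: bool = False
    saturated_n: bool = False

    @property
    def n_codons(self) -> int:
        return round((self.s_sites + self.n_sites) / 3)


def _codons(cds: str, name: str) -> list[str]:
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in _STOPS:
            raise ValueError(f"{name}: internal stop codon {c} at codon {i + 1}")
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    for c in codons:
        if c not in _CODON_AA:
            raise ValueError(f"{name}: invalid codon {c!r}")
    return codons


def kaks_ng86(
    cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b"
) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction for a codon-aligned pair.

    The two sequences must be equal length, codon-aligned and gap-free, with
    no internal stops; a shared terminal stop codon is dropped.  The Ka/Ks
    ratio is None when Ks is zero or saturated.
    """
    codons_a = _codons(cds_a, gene_a)
    codons_b = _codons(cds_b, gene_b)
    if len(codons_a) != len(codons_b):
        raise ValueError(
            f"length mismatch: {len(codons_a)} vs {len(codons_b)} codons"
        )
    if not codons_a:
        raise ValueError("empty alignment")
    s_a = sum(_SYN_SITES[c] for c in codons_a)
    s_b = sum(_SYN_SITES[c] for c in codons_b)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(codons_a) - s_sites
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d_s, d_n = _codon_pair_differences(ca, cb)
        sd += d_s
        nd += d_n
    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(p_s)
    ka = jukes_cantor(p_n)
    saturated_s = math.isnan(ks)
    saturated_n = math.isnan(ka)
    if saturated_s or ks == 0.0 or math.isnan(ka):
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(
        gene_a=gene_a,
        gene_b=gene_b,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ka=ka,
        ks=ks,
        ratio=ratio,
        saturated_s=saturated_s,
        saturated_n=saturated_n,
    )


def purifying_summary(
    results: list[KaKsResult], cutoff: float = 0.5
) -> dict[str, int]:
    """Partition pairs by Ka/Ks below (strict) vs at-or-above a cutoff.

    Pairs without a defined ratio (Ks zero or saturated) are reported under
    ``undefined`` and excluded from the partition.
    """
    below = at_or_above = undefined = 0
    for r in results:
        if r.ratio is None:
            undefined += 1
        elif r.ratio < cutoff:
            below += 1
        else:
            at_or_above += 1
    return {"below": below, "at_or_above": at_or_above, "undefined": undefined}


@dataclass
class KsHistogram:
    """Binned Ks distribution with the global peak bin."""

    bin_width: float
    edges: np.ndarray
    counts: np.ndarray
    peak_bin: int
    peak_midpoint: float

    def local_peaks(self) -> list[int]:
        """Indices of bins strictly exceeding both neighbours (plateau-free)."""
        c = self.counts
        peaks = []
        for i in range(len(c)):
            left = c[i - 1] if i > 0 else -1
            right = c[i + 1] if i < len(c) - 1 else -1
            if c[i] > left and c[i] > right and c[i] > 0:
                peaks.append(i)
        return peaks


def ks_histogram(ks_values, bin_width: float = 0.05) -> KsHistogram:
    """Histogram Ks values into half-open bins [k*w, (k+1)*w).

    NaN (saturated) values are dropped; negative values raise.  The peak is
    the bin with the maximal count, ties broken toward the lower bin.
    """
    vals = np.asarray([v for v in ks_values if not math.isnan(v)], dtype=float)
    if vals.size and vals.min() < 0:
        raise ValueError("negative Ks value")
    n_bins = max(1, int(np.floor(vals.max() / bin_width)) + 1) if vals.size else 1
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins, dtype=int)
    if vals.size:
        idx = np.floor(vals / bin_width).astype(int)
        idx = np.minimum(idx, n_bins - 1)
        np.add.at(counts, idx, 1)
    peak_bin = int(np.argmax(counts))  # argmax takes the first (lower) maximum
    return KsHistogram(
        bin_width=bin_width,
        edges=edges,
        counts=counts,
        peak_bin=peak_bin,
        peak_midpoint=(peak_bin + 0.5) * bin_width,
    )


@dataclass
class TandemCluster:
    """Consecutive similar genes on one chromosome (order positions kept)."""

    chrom: str
    members: tuple[str, ...]
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a tandem cluster needs at least two members")
        for p, q in zip(self.positions, self.positions[1:]):
            if q - p > 2:
                raise ValueError("more than one intervening gene between members")


def find_tandem_clusters(
    gene_order: dict[str, list[str]],
    edges,
    threshold: float = 1e-20,
    per_cluster_tolerance: bool = False,
) -> list[TandemCluster]:
    """Find tandem-duplication clusters from gene order and similarity edges.

    Parameters
    ----------
    gene_order:
        Mapping chromosome -> genes in chromosomal order.
    edges:
        Iterable of ``(gene_a, gene_b, evalue)`` triples (order-free pairs).
    threshold:
        Similarity e-value cutoff; membership requires ``evalue < threshold``.
    per_cluster_tolerance:
        If set, at most one unrelated gene is tolerated in the whole cluster;
        by default each gap between order-adjacent members may skip one.

    Greedy left-to-right: a cluster seeded at a gene grows while the next
    similar gene (below-threshold edge to at least one current member) lies
    at most one position beyond the last member.  Clusters never span
    chromosomes and only maximal clusters are returned.  The result does not
    depend on the order of the edge list.
    """
    known = {g for genes in gene_order.values() for g in genes}
    similar: set[frozenset[str]] = set()
    for a, b, ev in edges:
        if a not in known or b not in known:
            raise ValueError(f"edge references unknown gene: {a!r}/{b!r}")
        if float(ev) < threshold and a != b:
            similar.add(frozenset((a, b)))

    def linked(gene: str, members: list[str]) -> bool:
        return any(frozenset((gene, m)) in similar for m in members)

    clusters: list[TandemCluster] = []
    for chrom, genes in gene_order.items():
        i = 0
        n = len(genes)
        while i < n:
            members = [genes[i]]
            positions = [i]
            skips_used = 0
            j = i + 1
            while j < n:
                gap = j - positions[-1] - 1
                if gap > 1:
                    break
                budget_ok = (
                    gap == 0 or not per_cluster_tolerance or skips_used + gap <= 1
                )
                if budget_ok and linked(genes[j], members):
                    skips_used += gap
                    members.append(genes[j])
                    positions.append(j)
                j += 1
            if len(members) >= 2:
                clusters.append(
                    TandemCluster(
                        chrom=chrom,
                        members=tuple(members),
                        positions=tuple(positions),
                    )
                )
                i = positions[-1] + 1
            else:
                i += 1
    return clusters


def codon_align_ungapped(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Validate a gap-free codon alignment of two equal-length CDSs.

    This helper serves synthetic, indel-free pairs; alignments of real
    sequences with indels are expected from an external aligner.
    """
    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences differ in length; align them externally")
    if len(a) % 3 != 0:
        raise ValueError("length not a multiple of 3")
    if "-" in a or "-" in b:
        raise ValueError("gapped input; this helper only checks gap-free pairs")
    return a, b
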