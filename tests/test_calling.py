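"""Caller behaviour: thresholds, strand rule, filter cascade, consequences."""

from __future__ import annotations

import numpy as np
import pytest

from edscan.calling import (CallThresholds, annotate_consequence,
                            apply_filter_cascade, call_editing, call_snvs,
                            editing_level, high_confidence,
                            select_strand_consistent)
from edscan.counts import BASES, SiteCountTable
from edscan.genome import GeneModel, GenomeContext


def make_counts(cells, samples=None, near_indel=None, alt_read_pos=None):
    """cells: {(sample, contig, pos, ref): (nA, nC, nG, nT)}."""
    samples = samples or sorted({k[0] for k in cells})
    sites = sorted({(c, p, r) for _s, c, p, r in cells})
    counts = np.zeros((len(samples), len(sites), 4), dtype=int)
    arp = np.full((len(samples), len(sites)), np.nan)
    for (s, c, p, r), vals in cells.items():
        i, j = samples.index(s), sites.index((c, p, r))
        counts[i, j] = vals
        ref_i = BASES.index(r)
        if sum(vals) - vals[ref_i] > 0:
            arp[i, j] = 0.5
    if alt_read_pos:
        for (s, c, p), v in alt_read_pos.items():
            i = samples.index(s)
            j = next(k for k, (cc, pp, _r) in enumerate(sites)
                     if (cc, pp) == (c, p))
            arp[i, j] = v
    ni = np.zeros(len(sites), bool)
    if near_indel:
        for c, p in near_indel:
            j = next(k for k, (cc, pp, _r) in enumerate(sites)
                     if (cc, pp) == (c, p))
            ni[j] = True
    return SiteCountTable(samples, sites, counts, arp, ni)


def plus_gene(contig="chr1", lo=1, hi=1000):
    return GeneModel("GP", contig, "+", [(lo, hi)])


def simple_genome(seq="AGCT" * 250, genes=None, **kw):
    ctx = GenomeContext(contigs={"chr1": seq}, genes=genes or [plus_gene()],
                        **kw)
    return ctx


# --------------------------------------------------------------------------
# editing level and calling thresholds
# --------------------------------------------------------------------------

@pytest.mark.parametrize("ref,ed,expect", [
    (90, 10, 0.10),
    (0, 50, 1.0),
    (97, 2, 2 / 99),        # the C reads are excluded from the denominator
])
def test_editing_level_formula(ref, ed, expect):
    assert editing_level(ref, ed) == pytest.approx(expect)


def test_editing_level_zero_evidence_is_missing_not_zero():
    assert np.isnan(editing_level(0, 0))


@pytest.mark.parametrize("depth_counts,called", [
    ((6, 0, 3, 0), False),         # depth 9 < 10 despite alt 3
    ((99, 0, 1, 0), False),        # alt depth 1 < 2
    ((198, 0, 2, 0), True),        # depth 200, alt 2, AAF exactly 1% (>=)
])
def test_snv_calling_thresholds(depth_counts, called):
    counts = make_counts({("s1", "chr1", 100, "A"): depth_counts})
    out = call_snvs(counts)
    assert bool(out) is called
    if called:
        assert out[0].aaf[0] == pytest.approx(0.01)


def test_threshold_monotonicity():
    rng = np.random.default_rng(0)
    cells = {}
    for p in range(10, 200, 7):
        for s in ("s1", "s2"):
            nA = int(rng.integers(0, 40))
            nG = int(rng.integers(0, 6))
            cells[(s, "chr1", p, "A")] = (nA, 0, nG, 0)
    counts = make_counts(cells)
    base = {c.key for c in call_snvs(counts)}
    for th in (CallThresholds(min_depth=15),
               CallThresholds(min_alt_depth=3),
               CallThresholds(min_aaf=0.05)):
        assert {c.key for c in call_snvs(counts, th)} <= base


# --------------------------------------------------------------------------
# strand rule
# --------------------------------------------------------------------------

def test_strand_rule_cases():
    genes = [GeneModel("GP", "chr1", "+", [(1, 300)]),
             GeneModel("GM", "chr1", "-", [(401, 700)]),
             GeneModel("GX", "chr1", "+", [(650, 900)])]
    cells = {
        ("s1", "chr1", 100, "A"): (40, 0, 10, 0),    # A→G in + gene: keep
        ("s1", "chr1", 500, "A"): (40, 0, 10, 0),    # A→G in − gene: drop
        ("s1", "chr1", 510, "T"): (0, 10, 0, 40),    # T→C in − gene: keep
        ("s1", "chr1", 120, "C"): (0, 40, 0, 10),    # C→T anywhere: drop
        ("s1", "chr1", 950, "A"): (40, 0, 10, 0),    # intergenic
        ("s1", "chr1", 660, "T"): (0, 10, 0, 40),    # genes on both strands
    }
    snvs = call_snvs(make_counts(cells))
    kept, log = select_strand_consistent(snvs, genes)
    kept_pos = {c.pos for c in kept}
    assert kept_pos == {100, 510}
    reasons = {(e["pos"], e["reason"]) for e in log}
    assert (500, "non_AG") in reasons
    assert (120, "non_AG") in reasons
    assert (950, "intergenic") in reasons
    assert (660, "ambiguous_strand") in reasons
    assert next(c for c in kept if c.pos == 510).strand == "-"


def test_strand_symmetry_under_reverse_complement():
    """Reverse-complementing the genome and swapping strands re-keys the
    same event set."""
    seq = "".join(np.random.default_rng(5).choice(list("ACGT"), 200))
    seq = seq[:99] + "A" + seq[100:]
    gene = GeneModel("G", "chr1", "+", [(51, 150)])
    genome = GenomeContext(contigs={"chr1": seq}, genes=[gene])
    counts = make_counts({("s1", "chr1", 100, "A"): (40, 0, 10, 0),
                          ("s2", "chr1", 100, "A"): (38, 0, 12, 0)})
    m_fwd = call_editing(counts, genome)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    L = len(seq)
    gene_rc = GeneModel("G", "chr1", "-",
                        [(L - 150 + 1, L - 51 + 1)])
    genome_rc = GenomeContext(contigs={"chr1": rc}, genes=[gene_rc])
    pos_rc = L - 100 + 1
    counts_rc = make_counts({("s1", "chr1", pos_rc, "T"): (0, 10, 0, 40),
                             ("s2", "chr1", pos_rc, "T"): (0, 12, 0, 38)})
    m_rev = call_editing(counts_rc, genome_rc)
    assert len(m_fwd.levels) == len(m_rev.levels) == 1
    np.testing.assert_allclose(m_fwd.levels.to_numpy(),
                               m_rev.levels.to_numpy())
    assert m_rev.events.iloc[0]["pos"] == pos_rc


# --------------------------------------------------------------------------
# filter cascade
# --------------------------------------------------------------------------

def cascade_one(counts, genome, **kw):
    snvs = call_snvs(counts)
    kept, _ = select_strand_consistent(snvs, genome.genes)
    return apply_filter_cascade(kept, genome, **kw)


def test_homopolymer_rule_and_whitelist_rescue():
    seq = ("C" * 99 + "AAAAA" + "C" * 896)
    genome = simple_genome(seq)
    counts = make_counts({("s1", "chr1", 101, "A"): (40, 0, 10, 0),
                          ("s2", "chr1", 101, "A"): (40, 0, 10, 0)})
    kept, log = cascade_one(counts, genome)
    assert not kept and log[0]["reason"] == "homopolymer"
    genome.editing_whitelist.add(("chr1", 101))
    kept, log = cascade_one(counts, genome)
    assert len(kept) == 1 and kept[0].whitelisted and not log


def test_germline_pattern_rule():
    cells = {}
    for i in range(10):                      # AAF 0.5 in 10/10 samples
        cells[(f"s{i}", "chr1", 49, "A")] = (25, 0, 25, 0)
    genome = simple_genome()
    kept, log = cascade_one(make_counts(cells), genome)
    assert log[0]["reason"] == "germline_pattern"
    # same pattern in only 8/10 samples: rule does not fire
    for i in range(8, 10):
        cells[(f"s{i}", "chr1", 49, "A")] = (45, 0, 5, 0)
    kept, log = cascade_one(make_counts(cells), genome)
    assert len(kept) == 1


def test_homozygous_aaf_pattern_rule():
    cells = {f"s{i}": (0, 0, 30, 0) for i in range(5)}
    counts = make_counts({(s, "chr1", 61, "A"): v for s, v in cells.items()})
    kept, log = cascade_one(counts, simple_genome())
    assert not kept and log[0]["reason"] == "germline_pattern"


def test_read_end_junction_indel_mito_blacklist_rules():
    base = {("s1", "chr1", 201, "A"): (40, 0, 10, 0),
            ("s2", "chr1", 201, "A"): (40, 0, 10, 0)}
    # read end: median alt position 0.03
    counts = make_counts(dict(base), alt_read_pos={("s1", "chr1", 201): 0.03,
                                                   ("s2", "chr1", 201): 0.03})
    kept, log = cascade_one(counts, simple_genome())
    assert log[0]["reason"] == "read_end"
    # splice junction within 6 nt
    genome = simple_genome(junctions={("chr1", 206)})
    kept, log = cascade_one(make_counts(dict(base)), genome)
    assert log[0]["reason"] == "splice_junction"
    genome = simple_genome(junctions={("chr1", 209)})       # distance 8: keep
    kept, _ = cascade_one(make_counts(dict(base)), genome)
    assert len(kept) == 1
    # indel proximity
    counts = make_counts(dict(base), near_indel=[("chr1", 201)])
    kept, log = cascade_one(counts, simple_genome())
    assert log[0]["reason"] == "near_indel"
    # mitochondrial contig
    genome = simple_genome(mito_name="chr1")
    kept, log = cascade_one(make_counts(dict(base)), genome)
    assert log[0]["reason"] == "mitochondria"
    # simple repeat interval
    genome = simple_genome(repeats={"chr1": [(190, 210, "simple_repeat")]})
    kept, log = cascade_one(make_counts(dict(base)), genome)
    assert log[0]["reason"] == "simple_repeat"
    # alu intervals are annotation only, not a removal rule
    genome = simple_genome(repeats={"chr1": [(190, 210, "alu")]})
    kept, _ = cascade_one(make_counts(dict(base)), genome)
    assert len(kept) == 1
    # snp blacklist
    genome = simple_genome(snp_blacklist={("chr1", 201)})
    kept, log = cascade_one(make_counts(dict(base)), genome)
    assert log[0]["reason"] == "snp_blacklist"


def test_whitelist_monotonicity(default_bundle):
    counts, genome = default_bundle.counts, default_bundle.genome
    base = set(call_editing(counts, genome).levels.index)
    bigger = GenomeContext(
        contigs=genome.contigs, mito_name=genome.mito_name,
        repeats=genome.repeats, junctions=genome.junctions,
        genes=genome.genes,
        editing_whitelist=genome.editing_whitelist
        | {(c, p) for c, p, _r in counts.sites},
        snp_blacklist=genome.snp_blacklist)
    enlarged = set(call_editing(counts, bigger).levels.index)
    assert base <= enlarged


# --------------------------------------------------------------------------
# high confidence
# --------------------------------------------------------------------------

def test_high_confidence_rule():
    genome = simple_genome()

    def events_for(cells):
        snvs = call_snvs(make_counts(cells))
        kept, _ = select_strand_consistent(snvs, genome.genes)
        kept, _ = apply_filter_cascade(kept, genome)
        return high_confidence(kept, genome)

    two = {("s1", "chr1", 9, "A"): (98, 0, 2, 0),      # level 0.02
           ("s2", "chr1", 9, "A"): (197, 0, 3, 0),     # level 0.015
           ("s3", "chr1", 9, "A"): (50, 0, 0, 0)}
    kept, _ = events_for(two)
    assert len(kept) == 1
    one = {("s1", "chr1", 9, "A"): (98, 0, 2, 0),
           ("s2", "chr1", 9, "A"): (200, 0, 0, 0),
           ("s3", "chr1", 9, "A"): (50, 0, 0, 0)}
    kept, log = events_for(one)
    assert not kept and log[0]["reason"] == "low_confidence"
    genome.editing_whitelist.add(("chr1", 9))
    kept, _ = events_for(one)
    assert len(kept) == 1                     # whitelisted: retained anyway
    genome.editing_whitelist.discard(("chr1", 9))


def test_levels_missing_below_depth_floor():
    genome = simple_genome()
    cells = {("s1", "chr1", 9, "A"): (45, 0, 5, 0),
             ("s2", "chr1", 9, "A"): (40, 0, 10, 0),
             ("s3", "chr1", 9, "A"): (5, 0, 4, 0)}    # depth 9 < 10
    m = call_editing(make_counts(cells), genome)
    lev = m.levels.iloc[0]
    assert lev["s1"] == pytest.approx(0.1)
    assert np.isnan(lev["s3"])


# --------------------------------------------------------------------------
# filter log conservation on the full simulation
# --------------------------------------------------------------------------

def test_filter_log_accounts_for_every_candidate_once(default_bundle,
                                                      default_matrix):
    from edscan.calling import call_snvs as _call
    n_candidates = len(_call(default_bundle.counts))
    log = default_matrix.filter_log
    assert len(log) == n_candidates
    assert not log.duplicated(["contig", "pos", "ref", "alt"]).any()
    n_retained = (log["stage"] == "retained").sum()
    assert n_retained == len(default_matrix.levels)
    assert (log["stage"] != "retained").sum() == n_candidates - n_retained


# --------------------------------------------------------------------------
# consequence annotation
# --------------------------------------------------------------------------

def snv_at(genome, gene, pos):
    ref = genome.base(gene.contig, pos)
    alt = "G" if ref == "A" else "C"
    c = call_snvs(make_counts({("s1", gene.contig, pos, ref):
                               tuple(40 if b == ref else (10 if b == alt else 0)
                                     for b in BASES)}))[0]
    c.gene_id, c.strand = gene.gene_id, gene.strand
    return c


def test_consequence_missense_on_plus_strand():
    # ATG codon at CDS start: A→G gives GTG, M→V
    seq = "C" * 10 + "ATGAAATTTTAA" + "C" * 78
    gene = GeneModel("G", "chr1", "+", [(5, 30)], cds=(11, 22))
    genome = GenomeContext(contigs={"chr1": seq}, genes=[gene])
    c = snv_at(genome, gene, 11)
    assert annotate_consequence(c, [gene], genome) == "missense"


def test_consequence_synonymous_on_minus_strand():
    # coding codon CTA (Leu); third base A is genomic T on the − strand;
    # genomic T→C is coding A→G: CTA→CTG, still Leu.
    #   coding 5'→3' CTA GGG  => genomic (reverse complement) CCC TAG
    seq = "G" * 10 + "CCCTAG" + "G" * 84
    gene = GeneModel("G", "chr1", "-", [(5, 30)], cds=(11, 16))
    genome = GenomeContext(contigs={"chr1": seq}, genes=[gene])
    pos = 14          # genomic T, third base of the coding CTA codon
    assert genome.base("chr1", pos) == "T"
    c = snv_at(genome, gene, pos)
    assert annotate_consequence(c, [gene], genome) == "synonymous"


def test_consequence_utr_intron_noncoding():
    seq = "A" * 200
    gene = GeneModel("G", "chr1", "+", [(11, 50), (81, 120)], cds=(21, 100))
    genome = GenomeContext(contigs={"chr1": seq}, genes=[gene])
    assert annotate_consequence(snv_at(genome, gene, 110), [gene],
                                genome) == "3_prime_UTR"
    assert annotate_consequence(snv_at(genome, gene, 12), [gene],
                                genome) == "5_prime_UTR"
    assert annotate_consequence(snv_at(genome, gene, 60), [gene],
                                genome) == "intron"
    nc = GeneModel("N", "chr1", "+", [(131, 180)])
    assert annotate_consequence(snv_at(genome, nc, 150), [nc],
                                genome) == "non_coding"
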