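"""Synthetic mini-genomes, planted editing/SNP truth, pileup counts and clinics.

The generator emulates the statistical structure the analysis assumes:

* a small reference genome with genes on both strands, homopolymer runs,
  simple-repeat tracts, Alu-like intervals, splice junctions and an optional
  mitochondrial contig;
* planted A-to-I editing sites whose per-sample editing levels follow a
  beta distribution around group means (beta-binomial read counts), with an
  optional differential effect between case and control groups;
* a block of "hub" editing sites tied together by a shared latent factor so
  that their levels are correlated across samples and with clinical hormones;
* germline heterozygous/homozygous SNPs, sequencing errors, and context
  decoys (sites with genuine-looking signal placed in homopolymers, repeats,
  the mitochondrion, near junctions, near indels, at blacklisted positions or
  with read-end alignment artifacts) that the filter cascade must remove.

Every operation is fully deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .counts import SampleMetadata, SiteCountTable
from .genome import GeneModel, GenomeContext

DECOY_CLASSES = ["homopolymer", "simple_repeat", "mito", "junction",
                 "read_end", "near_indel", "blacklist"]

__all__ = [
    "SimulationConfig", "TruthTable", "SimulationBundle",
    "simulate_genome", "plant_truth", "simulate_counts", "simulate_clinical",
    "simulate_expression", "simulate_all", "simulate_dre_counts",
    "write_truth",
]


class PlacementError(ValueError):
    """Requested planted features do not fit in the configured genome."""


class ConfigError(ValueError):
    pass


def _default_hormone_model() -> dict[str, tuple[float, float, float, float]]:
    # feature -> (intercept, loading on hub latent factor, group effect, noise SD)
    # Units: LH/FSH IU/L, T ng/mL, DHEAS ug/dL, E2 pg/mL.
    return {
        "LH":    (7.0, 3.0, 2.0, 1.0),
        "FSH":   (6.0, 0.0, 0.0, 0.8),
        "T":     (0.5, 0.08, 0.15, 0.08),
        "DHEAS": (200.0, 25.0, 40.0, 30.0),
        "E2":    (40.0, 4.0, 6.0, 8.0),
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the package's study conditions.

    The default cohort is 12 cases vs 10 controls at mean depth 50 with
    negative-binomial depth dispersion 5 (so ~7% of cells fall below the
    depth-10 callability floor), per-base sequencing error 0.1%, 200 planted
    editing sites of which 100 are differential at effect size delta = 0.15,
    100 het and 50 hom SNPs, 200 context decoys and 100 unedited null sites.
    """

    # cohort
    n_case: int = 12
    n_control: int = 10
    # genome geometry
    contig_length: int = 30_000
    mito: bool = True
    mito_length: int = 2_000
    exon_length: int = 3_000
    intron_length: int = 1_000
    # planted genomic context features
    n_homopolymers: int = 30
    homopolymer_length: int = 6
    n_simple_repeats: int = 8
    simple_repeat_length: int = 48
    n_alu: int = 6
    alu_length: int = 300
    # planted sites
    n_edit: int = 200
    n_differential: int = 100
    delta: float = 0.15
    n_het_snp: int = 100
    n_hom_snp: int = 50
    n_decoy: int = 200
    n_null: int = 100
    # editing-level model
    mu_low: float = 0.02
    mu_high: float = 0.35
    kappa: float = 50.0
    het_kappa: float = 200.0
    # hub block (shared latent factor)
    n_hub: int = 20
    hub_loading: float = 0.9
    hub_sigma: float = 0.08
    hub_mu_low: float = 0.15
    hub_mu_high: float = 0.30
    # catalogue coverage
    whitelist_fraction: float = 0.5
    snp_blacklist_fraction: float = 0.95
    # sequencing
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.001
    # clinical hormone model: feature -> (alpha, beta_factor, gamma_group, sd)
    hormone_model: dict = field(default_factory=_default_hormone_model)
    # expression matrix
    expr_mean: float = 500.0
    expr_dispersion: float = 10.0
    cis_strength: float = 2.0

    def validate(self) -> None:
        for name in ("n_case", "n_control", "n_edit", "n_differential",
                     "n_het_snp", "n_hom_snp", "n_decoy", "n_null", "n_hub"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ConfigError("error_rate must lie in [0, 0.05]")
        if self.n_differential > self.n_edit:
            raise ConfigError("n_differential exceeds n_edit")
        if self.n_hub > self.n_differential:
            raise ConfigError("n_hub exceeds n_differential")
        if not (0.0 <= self.hub_loading <= 1.0):
            raise ConfigError("hub_loading must lie in [0, 1]")
        if self.mito and self.mito_length < 500:
            raise ConfigError("mito contig too short")

    def sample_names(self) -> list[str]:
        return ([f"case_{i+1:02d}" for i in range(self.n_case)]
                + [f"ctrl_{i+1:02d}" for i in range(self.n_control)])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Planted ground truth: one row per site plus per-sample true levels.

    ``table`` columns include the site key (contig, pos, ref, alt), the host
    gene and strand, the planted ``kind`` (edit / het_snp / hom_snp / null),
    the decoy class when the site is a context decoy, group mean levels, and
    all context flags the filter cascade targets.  ``levels`` is the
    (n_samples, n_sites) matrix of true per-sample allele fractions;
    ``latent`` is the per-sample hub factor.
    """

    samples: list[str]
    groups: dict[str, str]
    table: pd.DataFrame
    levels: np.ndarray
    latent: np.ndarray

    def site_keys(self) -> list[tuple[str, int]]:
        return [(r.contig, int(r.pos)) for r in self.table.itertuples()]

    def group_vector(self) -> np.ndarray:
        return np.array([1.0 if self.groups[s] == "case" else 0.0
                         for s in self.samples])

    def callable_edit_mask(self) -> pd.Series:
        """Planted edit sites in clean context: the caller's target set."""
        t = self.table
        return (t["kind"] == "edit") & (t["decoy_class"] == "")


class SimulationBundle(NamedTuple):
    genome: GenomeContext
    truth: TruthTable
    counts: SiteCountTable
    metadata: list[SampleMetadata]
    expression: pd.DataFrame


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Genome
# --------------------------------------------------------------------------

def _make_gene(gene_id: str, contig: str, strand: str, start: int, end: int,
               exon_len: int, intron_len: int, with_cds: bool) -> GeneModel:
    exons = []
    s = start
    while s + exon_len - 1 <= end:
        exons.append((s, s + exon_len - 1))
        s += exon_len + intron_len
    if len(exons) < 2:
        raise PlacementError(f"{gene_id}: gene span too short for two exons")
    cds = None
    if with_cds and len(exons) >= 4:
        cs, ce = exons[1][0], exons[-2][1]
        n_coding = sum(min(e, ce) - max(s_, cs) + 1
                       for s_, e in exons if max(s_, cs) <= min(e, ce))
        ce -= n_coding % 3           # keep the reading frame whole
        cds = (cs, ce)
    return GeneModel(gene_id, contig, strand, exons, cds)


def _place_intervals(rng, occupied: list[tuple[int, int]], lo: int, hi: int,
                     n: int, length: int, margin: int = 10,
                     max_tries: int = 20_000) -> list[tuple[int, int]]:
    """Place n non-overlapping [start, start+length-1] intervals in [lo, hi]."""
    placed = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} intervals of length {length} in "
                f"[{lo},{hi}]")
        start = int(rng.integers(lo, hi - length + 1))
        iv = (start, start + length - 1)
        if all(iv[1] + margin < s or e + margin < iv[0] for s, e in occupied):
            occupied.append(iv)
            placed.append(iv)
    return sorted(placed)


def simulate_genome(config: SimulationConfig, seed) -> GenomeContext:
    """Build the toy reference: two gene-bearing contigs plus optional chrM.

    chr1 carries a +-strand coding gene (editing appears as A→G there);
    chr2 carries a −-strand coding gene (editing appears as genomic T→C).
    Poly-A / poly-T homopolymer runs, simple-repeat tracts and Alu-like
    intervals are planted inside the gene bodies at recorded positions, and
    the splice-junction-adjacent bases of every gene are annotated.
    """
    config.validate()
    rng = _rng(seed)
    L = config.contig_length
    contigs = {
        "chr1": list(rng.choice(list("ACGT"), size=L)),
        "chr2": list(rng.choice(list("ACGT"), size=L)),
    }
    genes = [
        _make_gene("GENE_P1", "chr1", "+", 1001, L - 1000,
                   config.exon_length, config.intron_length, True),
        _make_gene("GENE_M1", "chr2", "-", 1001, L - 1000,
                   config.exon_length, config.intron_length, True),
    ]
    mito_name = None
    if config.mito:
        mito_name = "chrM"
        contigs["chrM"] = list(rng.choice(list("ACGT"),
                                          size=config.mito_length))
        genes.append(GeneModel("GENE_MT1", "chrM", "+",
                               [(101, config.mito_length - 100)], None))

    repeats: dict[str, list[tuple[int, int, str]]] = {}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    half = config.n_homopolymers // 2
    plans = [("chr1", "A", "AC", half), ("chr2", "T", "GT",
                                         config.n_homopolymers - half)]
    for contig, homo_base, rep_unit, n_homo in plans:
        gene = next(g for g in genes if g.contig == contig)
        lo, hi = gene.span
        # keep planted features clear of splice boundaries
        for j in gene.junction_adjacent_bases():
            occupied[contig].append((j - 8, j + 8))
        for s, e in _place_intervals(rng, occupied[contig], lo, hi, n_homo,
                                     config.homopolymer_length):
            contigs[contig][s - 1:e] = homo_base * (e - s + 1)
            repeats.setdefault(contig, []).append((s, e, "homopolymer"))
        n_rep = config.n_simple_repeats // 2
        for s, e in _place_intervals(rng, occupied[contig], lo, hi, n_rep,
                                     config.simple_repeat_length):
            tract = (rep_unit * ((e - s + 1) // 2 + 1))[: e - s + 1]
            contigs[contig][s - 1:e] = tract
            repeats.setdefault(contig, []).append((s, e, "simple_repeat"))
        n_alu = config.n_alu // 2
        for s, e in _place_intervals(rng, occupied[contig], lo, hi, n_alu,
                                     config.alu_length):
            repeats.setdefault(contig, []).append((s, e, "alu"))
    for contig in repeats:
        repeats[contig].sort()

    junctions = {(g.contig, p) for g in genes
                 for p in g.junction_adjacent_bases()}
    ctx = GenomeContext(contigs={c: "".join(s) for c, s in contigs.items()},
                        mito_name=mito_name, repeats=repeats,
                        junctions=junctions, genes=genes)
    ctx.validate()
    return ctx


# --------------------------------------------------------------------------
# Truth planting
# --------------------------------------------------------------------------

def _contig_context(genome: GenomeContext, contig: str) -> dict:
    """Vectorized per-position context masks for one contig (0-based)."""
    seq = np.frombuffer(genome.contigs[contig].encode("ascii"), dtype="S1")
    n = seq.size
    change = np.r_[True, seq[1:] != seq[:-1]]
    run_id = np.cumsum(change) - 1
    runlen = np.bincount(run_id)[run_id]
    simple = np.zeros(n, dtype=bool)
    homo_bed = np.zeros(n, dtype=bool)
    for s, e, kind in genome.repeats.get(contig, []):
        if kind == "simple_repeat":
            simple[s - 1:e] = True
        elif kind == "homopolymer":
            homo_bed[s - 1:e] = True
    near_j = np.zeros(n, dtype=bool)
    for c, j in genome.junctions:
        if c == contig:
            near_j[max(j - 7, 0):j + 6] = True
    return {"seq": seq, "runlen": runlen, "simple": simple,
            "homo_bed": homo_bed, "near_j": near_j}


def _gene_base_mask(ctx: dict, gene: GeneModel) -> np.ndarray:
    """Positions (0-based mask) inside the gene with the strand's edit base."""
    need = b"A" if gene.strand == "+" else b"T"
    m = np.zeros(ctx["seq"].size, dtype=bool)
    lo, hi = gene.span
    m[lo - 1:hi] = True
    return m & (ctx["seq"] == need)


def _clean_pool(genome: GenomeContext, gene: GeneModel,
                ctx: dict | None = None) -> list[int]:
    """Positions in a gene usable for clean planted sites.

    Clean means: correct reference base for the gene's strand (A on +, T on −),
    homopolymer run < 5, outside simple-repeat tracts, > 6 nt from any splice
    junction, and not on the mitochondrial contig.
    """
    if gene.contig == genome.mito_name:
        return []
    if ctx is None:
        ctx = _contig_context(genome, gene.contig)
    mask = (_gene_base_mask(ctx, gene) & (ctx["runlen"] < 5)
            & ~ctx["simple"] & ~ctx["near_j"])
    return [int(p) + 1 for p in np.flatnonzero(mask)]


def _split_counts(total: int, n_bins: int) -> list[int]:
    base, rem = divmod(total, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


def plant_truth(genome: GenomeContext, config: SimulationConfig,
                seed) -> TruthTable:
    """Plant editing sites, SNPs, nulls and context decoys; draw true levels.

    Updates ``genome.editing_whitelist`` and ``genome.snp_blacklist`` in
    place so that the catalogue annotations cover the planted truth
    (``whitelist_fraction`` of clean editing sites; ``snp_blacklist_fraction``
    of germline SNPs plus every blacklist-class decoy).
    """
    config.validate()
    rng = _rng(seed)
    samples = config.sample_names()
    groups = {s: ("case" if s.startswith("case") else "control")
              for s in samples}
    n_s = len(samples)
    is_case = np.array([groups[s] == "case" for s in samples])

    host_genes = [g for g in genome.genes if g.contig != genome.mito_name]
    if not host_genes:
        raise PlacementError("no non-mitochondrial genes available")
    ctx_of = {c: _contig_context(genome, c) for c in genome.contigs}
    clean: list[tuple[GeneModel, int]] = []
    for g in host_genes:
        clean.extend((g, p) for p in _clean_pool(genome, g, ctx_of[g.contig]))
    rng.shuffle(clean)

    per_class = dict(zip(DECOY_CLASSES,
                         _split_counts(config.n_decoy, len(DECOY_CLASSES))))
    n_clean_needed = (config.n_edit + config.n_het_snp + config.n_hom_snp
                      + config.n_null + per_class["read_end"]
                      + per_class["near_indel"] + per_class["blacklist"])
    if len(clean) < n_clean_needed:
        raise PlacementError(
            f"need {n_clean_needed} clean positions, only {len(clean)} eligible")

    rows: list[dict] = []
    used: set[tuple[str, int]] = set()

    def add_site(gene: GeneModel, pos: int, kind: str, decoy_class: str = "",
                 **flags) -> dict:
        key = (gene.contig, pos)
        used.add(key)
        ref = genome.base(gene.contig, pos)
        row = {"contig": gene.contig, "pos": pos, "ref": ref,
               "alt": "G" if ref == "A" else "C",
               "gene_id": gene.gene_id, "strand": gene.strand,
               "kind": kind, "decoy_class": decoy_class,
               "is_differential": False, "is_hub": False,
               "mu_case": 0.0, "mu_control": 0.0,
               "in_homopolymer": False, "in_simple_repeat": False,
               "on_mito": False, "near_junction": False,
               "read_end_artifact": False, "near_indel": False,
               "whitelisted": False, "blacklisted": False}
        row.update(flags)
        rows.append(row)
        return row

    it = iter(clean)

    def take_clean(n: int) -> list[tuple[GeneModel, int]]:
        out = []
        while len(out) < n:
            g, p = next(it)
            if (g.contig, p) not in used:
                out.append((g, p))
                used.add((g.contig, p))
        return out

    # clean editing sites -------------------------------------------------
    edit_rows = []
    for i, (g, p) in enumerate(take_clean(config.n_edit)):
        hub = i < config.n_hub
        diff = i < config.n_differential
        if hub:
            mu_c = float(rng.uniform(config.hub_mu_low, config.hub_mu_high))
        else:
            mu_c = float(rng.uniform(config.mu_low, config.mu_high))
        mu_case = float(np.clip(mu_c + (config.delta if diff else 0.0),
                                0.01, 0.99))
        edit_rows.append(add_site(g, p, "edit", is_differential=diff,
                                  is_hub=hub, mu_case=mu_case, mu_control=mu_c))
    n_white = int(round(config.whitelist_fraction * len(edit_rows)))
    for row in [edit_rows[k] for k in
                rng.choice(len(edit_rows), size=n_white, replace=False)] \
            if edit_rows else []:
        row["whitelisted"] = True
        genome.editing_whitelist.add((row["contig"], row["pos"]))

    # germline SNPs --------------------------------------------------------
    snp_rows = []
    for g, p in take_clean(config.n_het_snp):
        snp_rows.append(add_site(g, p, "het_snp", mu_case=0.5, mu_control=0.5))
    for g, p in take_clean(config.n_hom_snp):
        snp_rows.append(add_site(g, p, "hom_snp", mu_case=1.0, mu_control=1.0))
    n_black = int(round(config.snp_blacklist_fraction * len(snp_rows)))
    for row in [snp_rows[k] for k in
                rng.choice(len(snp_rows), size=n_black, replace=False)] \
            if snp_rows else []:
        row["blacklisted"] = True
        genome.snp_blacklist.add((row["contig"], row["pos"]))

    # null (unedited) sites ------------------------------------------------
    for g, p in take_clean(config.n_null):
        add_site(g, p, "null")

    # context decoys -------------------------------------------------------
    def decoy_mu() -> tuple[float, float]:
        mu = float(rng.uniform(0.10, 0.40))
        return mu, mu

    def context_positions(cls: str) -> list[tuple[GeneModel, int]]:
        """Eligible positions for one decoy context class (vectorized).

        Each class flags exactly one removal rule: positions carry the
        class's context and are otherwise clean, so the first firing
        cascade rule matches the planted class.
        """
        out = []
        for g in genome.genes:
            on_mito = g.contig == genome.mito_name
            if (cls == "mito") != on_mito:
                continue
            ctx = ctx_of[g.contig]
            mask = _gene_base_mask(ctx, g)
            if cls == "homopolymer":
                mask &= ctx["homo_bed"] & (ctx["runlen"] >= 5) & ~ctx["near_j"]
            elif cls == "simple_repeat":
                mask &= ctx["simple"] & (ctx["runlen"] < 5) & ~ctx["near_j"]
            elif cls == "mito":
                mask &= (ctx["runlen"] < 5) & ~ctx["simple"] & ~ctx["near_j"]
            elif cls == "junction":
                mask &= ctx["near_j"] & (ctx["runlen"] < 5) & ~ctx["simple"]
            else:
                raise ValueError(cls)
            out.extend((g, int(p) + 1) for p in np.flatnonzero(mask)
                       if (g.contig, int(p) + 1) not in used)
        return out

    def place_decoys(cls: str, pool: list[tuple[GeneModel, int]],
                     **flags) -> None:
        n = per_class[cls]
        if len(pool) < n:
            raise PlacementError(
                f"decoy class {cls}: need {n} positions, found {len(pool)}")
        idx = rng.choice(len(pool), size=n, replace=False)
        for k in idx:
            g, p = pool[k]
            mc, mu = decoy_mu()
            row = add_site(g, p, "edit", decoy_class=cls,
                           mu_case=mc, mu_control=mu, **flags)
            if cls == "blacklist":
                row["blacklisted"] = True
                genome.snp_blacklist.add((g.contig, p))

    place_decoys("homopolymer", context_positions("homopolymer"),
                 in_homopolymer=True)
    place_decoys("simple_repeat", context_positions("simple_repeat"),
                 in_simple_repeat=True)
    if config.mito:
        place_decoys("mito", context_positions("mito"), on_mito=True)
    elif per_class["mito"]:
        raise PlacementError("mito decoys requested without a mito contig")
    place_decoys("junction", context_positions("junction"),
                 near_junction=True)
    for g, p in take_clean(per_class["read_end"]):
        mc, mu = decoy_mu()
        add_site(g, p, "edit", decoy_class="read_end", mu_case=mc,
                 mu_control=mu, read_end_artifact=True)
    for g, p in take_clean(per_class["near_indel"]):
        mc, mu = decoy_mu()
        add_site(g, p, "edit", decoy_class="near_indel", mu_case=mc,
                 mu_control=mu, near_indel=True)
    for g, p in take_clean(per_class["blacklist"]):
        mc, mu = decoy_mu()
        row = add_site(g, p, "edit", decoy_class="blacklist", mu_case=mc,
                       mu_control=mu, blacklisted=True)
        genome.snp_blacklist.add((g.contig, p))

    table = pd.DataFrame(rows).sort_values(["contig", "pos"],
                                           ignore_index=True)

    # per-sample true levels ----------------------------------------------
    latent = rng.standard_normal(n_s)
    levels = np.zeros((n_s, len(table)))
    lam, sig = config.hub_loading, config.hub_sigma
    for j, row in enumerate(table.itertuples()):
        mu = np.where(is_case, row.mu_case, row.mu_control)
        if row.kind == "null":
            continue
        if row.kind == "hom_snp":
            levels[:, j] = 1.0
        elif row.kind == "het_snp":
            a = config.het_kappa / 2.0
            levels[:, j] = rng.beta(a, a, size=n_s)
        elif row.is_hub:
            eps = rng.standard_normal(n_s)
            levels[:, j] = np.clip(
                mu + lam * sig * latent + np.sqrt(1 - lam ** 2) * sig * eps,
                0.005, 0.995)
        else:
            levels[:, j] = rng.beta(mu * config.kappa,
                                    (1 - mu) * config.kappa, size=n_s)
    return TruthTable(samples=samples, groups=groups, table=table,
                      levels=levels, latent=latent)


# --------------------------------------------------------------------------
# Read counts
# --------------------------------------------------------------------------

def simulate_counts(truth: TruthTable, genome: GenomeContext,
                    config: SimulationConfig, seed) -> SiteCountTable:
    """Draw pileup counts: NB depth, binomial edited reads, error scatter.

    Edited/alt reads appear as G at A-reference sites (+-strand genes) and as
    C at T-reference sites (−-strand genes).  Sequencing errors move each
    read to one of the other three bases with probability ``error_rate``.
    ``alt_read_pos`` (the median relative position of alt reads within their
    reads) is uniform(0.05, 0.95) for genuine cells and ≤ 0.04 for
    read-end-artifact decoys.
    """
    from .counts import BASE_INDEX

    rng = _rng(seed)
    n_s = len(truth.samples)
    table = truth.table
    n_p = len(table)
    disp, mean = config.depth_dispersion, config.depth_mean
    lam = rng.gamma(shape=disp, scale=mean / disp, size=(n_s, n_p))
    depth = rng.poisson(lam)
    alt_true = rng.binomial(depth, np.clip(truth.levels, 0.0, 1.0))
    ref_true = depth - alt_true

    counts = np.zeros((n_s, n_p, 4), dtype=np.int64)
    e = config.error_rate
    others_of = {i: [k for k in range(4) if k != i] for i in range(4)}
    for j, row in enumerate(table.itertuples()):
        ri, ai = BASE_INDEX[row.ref], BASE_INDEX[row.alt]
        for origin, n_origin in ((ri, ref_true[:, j]), (ai, alt_true[:, j])):
            if e > 0:
                kept = rng.binomial(n_origin, 1.0 - e)
                err = n_origin - kept
                counts[:, j, origin] += kept
                if err.sum():
                    scattered = rng.multinomial(err, [1 / 3] * 3)
                    for col, dest in enumerate(others_of[origin]):
                        counts[:, j, dest] += scattered[:, col]
            else:
                counts[:, j, origin] += n_origin

    ref_idx = np.array([BASE_INDEX[r] for r in table["ref"]])
    nonref = depth - counts[np.arange(n_s)[:, None], np.arange(n_p)[None, :],
                            ref_idx[None, :]]
    arp = np.full((n_s, n_p), np.nan)
    is_end = (table["decoy_class"] == "read_end").to_numpy()
    genuine = rng.uniform(0.05, 0.95, size=(n_s, n_p))
    endpos = rng.uniform(0.005, 0.04, size=(n_s, n_p))
    arp = np.where(nonref > 0, np.where(is_end[None, :], endpos, genuine),
                   np.nan)
    sites = [(r.contig, int(r.pos), r.ref) for r in table.itertuples()]
    return SiteCountTable(samples=list(truth.samples), sites=sites,
                          counts=counts, alt_read_pos=arp,
                          near_indel=table["near_indel"].to_numpy(bool))


# --------------------------------------------------------------------------
# Clinical covariates and expression
# --------------------------------------------------------------------------

def simulate_clinical(truth: TruthTable, config: SimulationConfig,
                      seed) -> list[SampleMetadata]:
    """Hormone features driven by the hub latent factor and group membership.

    hormone = alpha + beta * latent + gamma * group + Normal(0, sd), clipped
    to be positive; the LH/FSH ratio is recomputed from the simulated values.
    """
    rng = _rng(seed)
    g = truth.group_vector()
    out = []
    for i, sample in enumerate(truth.samples):
        hormones: dict[str, float] = {}
        for feat, (alpha, beta, gamma, sd) in config.hormone_model.items():
            val = alpha + beta * truth.latent[i] + gamma * g[i] \
                + rng.normal(0.0, sd)
            hormones[feat] = float(max(val, 0.01))
        if "LH" in hormones and "FSH" in hormones:
            hormones["LH_FSH_ratio"] = hormones["LH"] / hormones["FSH"]
        out.append(SampleMetadata(sample, truth.groups[sample], hormones))
    return out


def simulate_expression(truth: TruthTable, genome: GenomeContext,
                        config: SimulationConfig, seed) -> pd.DataFrame:
    """Per-gene negative-binomial expression counts (genes x samples).

    Genes hosting hub editing sites get a cis-coupling: their expected
    expression is scaled by (1 + cis_strength * mean hub editing level), so
    editing level and host-gene expression correlate positively.
    """
    rng = _rng(seed)
    n_s = len(truth.samples)
    hub_by_gene: dict[str, list[int]] = {}
    for j, row in enumerate(truth.table.itertuples()):
        if row.is_hub:
            hub_by_gene.setdefault(row.gene_id, []).append(j)
    rows = {}
    for gene in sorted(g.gene_id for g in genome.genes):
        mean = np.full(n_s, config.expr_mean)
        if gene in hub_by_gene:
            lev = truth.levels[:, hub_by_gene[gene]].mean(axis=1)
            mean = mean * (1.0 + config.cis_strength * lev)
        lam = rng.gamma(shape=config.expr_dispersion,
                        scale=mean / config.expr_dispersion)
        rows[gene] = rng.poisson(lam)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(truth.samples))


# --------------------------------------------------------------------------
# Convenience and calibration harnesses
# --------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, seed: int) -> SimulationBundle:
    """Run all generator stages with independent child seeds of ``seed``."""
    ss = np.random.SeedSequence(seed)
    r_genome, r_truth, r_counts, r_clin, r_expr = \
        [np.random.default_rng(s) for s in ss.spawn(5)]
    genome = simulate_genome(config, r_genome)
    truth = plant_truth(genome, config, r_truth)
    counts = simulate_counts(truth, genome, config, r_counts)
    metadata = simulate_clinical(truth, config, r_clin)
    expression = simulate_expression(truth, genome, config, r_expr)
    return SimulationBundle(genome, truth, counts, metadata, expression)


def simulate_dre_counts(n_events: int, n_case: int, n_control: int,
                        delta: float, depth_mean: float = 50.0,
                        depth_dispersion: float = 5.0,
                        mu_range: tuple[float, float] = (0.05, 0.30),
                        seed=0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binomial (edited, unedited) count pairs for test-calibration studies.

    Per event the control mean level is uniform over ``mu_range`` and the case
    mean is shifted by ``delta``; per-sample levels equal the group mean (the
    binomial sampling model under which the likelihood-ratio test is
    calibrated).  Returns (edited, unedited) arrays of shape
    (n_events, n_case + n_control) and the 0/1 group vector.
    """
    rng = _rng(seed)
    n_s = n_case + n_control
    groups = np.array([1.0] * n_case + [0.0] * n_control)
    mu_ctrl = rng.uniform(*mu_range, size=n_events)
    mu_case = np.clip(mu_ctrl + delta, 0.01, 0.95)
    level = np.where(groups[None, :] == 1.0, mu_case[:, None],
                     mu_ctrl[:, None])
    lam = rng.gamma(shape=depth_dispersion,
                    scale=depth_mean / depth_dispersion,
                    size=(n_events, n_s))
    depth = rng.poisson(lam)
    edited = rng.binomial(depth, level)
    return edited, depth - edited, groups


def write_truth(truth: TruthTable, tsv_path: str | Path,
                header_comment: str | None = None) -> None:
    df = truth.table.copy()
    for i, s in enumerate(truth.samples):
        df[f"level_{s}"] = np.round(truth.levels[i, :], 6)
    with open(tsv_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
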