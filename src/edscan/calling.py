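"""A-to-I editing-event calling: SNV thresholds, strand rule, filter cascade.

The caller starts from base-quality-filtered pileup counts and reproduces a
conservative RNA-editing detection recipe:

1. per-sample SNV calling at minimum sequencing depth 10, minimum alternative
   allele depth 2 and alternative allele frequency (AAF) >= 1%;
2. the strand rule: only A→G candidates inside +-strand genes and T→C
   candidates inside −-strand genes survive (inosine reads as G on the coding
   strand);
3. a four-rule removal cascade — (1) homopolymer runs >= 5 nt, simple
   repeats, or the mitochondrial contig; (2) within 6 nt of a splice
   junction, within 1 nt of an indel, or with alt reads within 4% of the
   read ends; (3) known-SNP blacklist membership; (4) a germline-like AAF
   pattern (AAF exactly 100% or between 40 and 60% in more than 90% of the
   callable samples).  Candidates in the known-editing whitelist bypass all
   four rules;
4. the high-confidence rule: editing level >= 1% in at least two samples, or
   whitelisted.

Editing level is edited/(reference + edited) on the strand-appropriate bases:
nG/(nA+nG) at +-strand sites, nC/(nT+nC) at −-strand sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .counts import BASE_INDEX, SiteCountTable
from .genome import GeneModel, GenomeContext

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONSEQUENCES = ["3_prime_UTR", "5_prime_UTR", "intron", "missense",
                "synonymous", "stop_gained", "non_coding"]

FILTER_REASONS = ["non_AG", "intergenic", "ambiguous_strand",
                  "homopolymer", "simple_repeat", "mitochondria",
                  "splice_junction", "near_indel", "read_end",
                  "snp_blacklist", "germline_pattern", "low_confidence"]

__all__ = [
    "CallThresholds", "SNVCall", "EditingMatrix",
    "editing_level", "call_snvs", "select_strand_consistent",
    "apply_filter_cascade", "high_confidence", "annotate_consequence",
    "call_editing", "strand_counts",
]


@dataclass(frozen=True)
class CallThresholds:
    """Per-sample SNV calling thresholds (base quality is upstream)."""

    min_depth: int = 10
    min_alt_depth: int = 2
    min_aaf: float = 0.01


@dataclass
class SNVCall:
    """One candidate substitution with its per-sample evidence.

    ``aaf`` is alt/(ref+alt) per sample (0 where both are 0); ``called``
    marks the samples that individually pass the thresholds.  ``gene`` and
    ``strand`` are attached by the strand-consistency step.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    depth: np.ndarray          # total sequencing depth per sample
    ref_count: np.ndarray
    alt_count: np.ndarray
    aaf: np.ndarray
    called: np.ndarray
    alt_read_pos: np.ndarray
    near_indel: bool
    gene_id: str | None = None
    strand: str | None = None
    whitelisted: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class EditingMatrix:
    """Retained events x samples editing levels, with event metadata and log.

    ``levels`` is indexed by event_id ("GENE:contig:pos"); cells are NaN
    where the sample's depth at the site is below the callability floor.
    ``filter_log`` accounts for every candidate exactly once (retained or
    dropped with the first firing rule).
    """

    levels: pd.DataFrame
    events: pd.DataFrame
    filter_log: pd.DataFrame

    @property
    def event_ids(self) -> list[str]:
        return list(self.levels.index)


def editing_level(n_ref_strand: int, n_edited_strand: int) -> float:
    """Editing level = edited/(ref + edited); NaN when both are zero.

    Only the reference and edited base count — other bases (errors) are
    excluded from the denominator.
    """
    if n_ref_strand < 0 or n_edited_strand < 0:
        raise ValueError("counts must be non-negative")
    total = n_ref_strand + n_edited_strand
    if total == 0:
        return float("nan")
    return n_edited_strand / total


def call_snvs(counts: SiteCountTable,
              thresholds: CallThresholds = CallThresholds()) -> list[SNVCall]:
    """Per-sample SNV calling; a site/alt pair is a candidate when called
    in at least one sample."""
    depth = counts.depth()
    out: list[SNVCall] = []
    for j, (contig, pos, ref) in enumerate(counts.sites):
        if ref not in BASE_INDEX:
            continue
        ref_c = counts.counts[:, j, BASE_INDEX[ref]]
        for alt in "ACGT":
            if alt == ref:
                continue
            alt_c = counts.counts[:, j, BASE_INDEX[alt]]
            if not alt_c.any():
                continue
            denom = ref_c + alt_c
            with np.errstate(invalid="ignore", divide="ignore"):
                aaf = np.where(denom > 0, alt_c / np.maximum(denom, 1), 0.0)
            called = ((depth[:, j] >= thresholds.min_depth)
                      & (alt_c >= thresholds.min_alt_depth)
                      & (aaf >= thresholds.min_aaf))
            if called.any():
                out.append(SNVCall(
                    contig=contig, pos=pos, ref=ref, alt=alt,
                    depth=depth[:, j].copy(), ref_count=ref_c.copy(),
                    alt_count=alt_c.copy(), aaf=aaf, called=called,
                    alt_read_pos=counts.alt_read_pos[:, j].copy(),
                    near_indel=bool(counts.near_indel[j])))
    return out


def _log_entry(c: SNVCall, stage: str, reason: str) -> dict:
    return {"contig": c.contig, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "stage": stage, "reason": reason}


def select_strand_consistent(snvs: list[SNVCall], genes: list[GeneModel],
                             ) -> tuple[list[SNVCall], list[dict]]:
    """Keep A→G candidates in +-strand genes and T→C in −-strand genes.

    Candidates outside every gene are dropped as ``intergenic``; candidates
    overlapping genes on both strands are dropped as ``ambiguous_strand``
    (conservative — the transcribed strand cannot be resolved); everything
    that is not the strand-appropriate substitution is dropped as ``non_AG``.
    """
    kept: list[SNVCall] = []
    log: list[dict] = []
    for c in snvs:
        overlapping = [g for g in genes
                       if g.contig == c.contig and g.contains(c.pos)]
        if not overlapping:
            log.append(_log_entry(c, "strand", "intergenic"))
            continue
        strands = {g.strand for g in overlapping}
        if len(strands) > 1:
            log.append(_log_entry(c, "strand", "ambiguous_strand"))
            continue
        strand = strands.pop()
        expected = ("A", "G") if strand == "+" else ("T", "C")
        if (c.ref, c.alt) != expected:
            log.append(_log_entry(c, "strand", "non_AG"))
            continue
        gene = sorted(overlapping, key=lambda g: g.gene_id)[0]
        c.gene_id, c.strand = gene.gene_id, strand
        kept.append(c)
    return kept, log


def _cascade_reason(c: SNVCall, genome: GenomeContext,
                    min_depth: int) -> str | None:
    """First firing removal rule for a candidate, or None."""
    # rule 1: homopolymer / simple repeat / mitochondria
    if genome.homopolymer_run_length(c.contig, c.pos) >= 5:
        return "homopolymer"
    if genome.in_repeat(c.contig, c.pos, ("simple_repeat",)):
        return "simple_repeat"
    if genome.mito_name is not None and c.contig == genome.mito_name:
        return "mitochondria"
    # rule 2: splice junctions, indels, read ends
    if genome.near_junction(c.contig, c.pos, 6):
        return "splice_junction"
    if c.near_indel:
        return "near_indel"
    with_alt = c.alt_count > 0
    if with_alt.any():
        med = float(np.median(c.alt_read_pos[with_alt]))
        if med <= 0.04 or med >= 0.96:
            return "read_end"
    # rule 3: known-SNP blacklist
    if (c.contig, c.pos) in genome.snp_blacklist:
        return "snp_blacklist"
    # rule 4: germline-like AAF pattern over the callable samples
    callable_ = c.depth >= min_depth
    if callable_.any():
        hom_like = (c.ref_count == 0) & (c.alt_count > 0)
        het_like = (c.aaf >= 0.40) & (c.aaf <= 0.60)
        frac = float((hom_like | het_like)[callable_].mean())
        if frac > 0.90:
            return "germline_pattern"
    return None


def apply_filter_cascade(candidates: list[SNVCall], genome: GenomeContext,
                         thresholds: CallThresholds = CallThresholds(),
                         whitelist_rescue: bool = True,
                         ) -> tuple[list[SNVCall], list[dict]]:
    """Apply the four removal rules; whitelisted candidates bypass them all."""
    kept: list[SNVCall] = []
    log: list[dict] = []
    for c in candidates:
        c.whitelisted = (c.contig, c.pos) in genome.editing_whitelist
        if whitelist_rescue and c.whitelisted:
            kept.append(c)
            continue
        reason = _cascade_reason(c, genome, thresholds.min_depth)
        if reason is None:
            kept.append(c)
        else:
            log.append(_log_entry(c, "cascade", reason))
    return kept, log


def high_confidence(filtered: list[SNVCall], genome: GenomeContext,
                    thresholds: CallThresholds = CallThresholds(),
                    ) -> tuple[list[SNVCall], list[dict]]:
    """Retain events with level >= 1% in >= 2 samples, or whitelisted."""
    kept: list[SNVCall] = []
    log: list[dict] = []
    for c in filtered:
        levels = _sample_levels(c, thresholds.min_depth)
        n_pass = int(np.sum(levels >= 0.01))
        if n_pass >= 2 or c.whitelisted:
            kept.append(c)
        else:
            log.append(_log_entry(c, "confidence", "low_confidence"))
    return kept, log


def _sample_levels(c: SNVCall, min_depth: int) -> np.ndarray:
    """Per-sample editing levels; NaN where total depth < min_depth."""
    denom = c.ref_count + c.alt_count
    with np.errstate(invalid="ignore", divide="ignore"):
        lev = np.where(denom > 0, c.alt_count / np.maximum(denom, 1), np.nan)
    return np.where(c.depth >= min_depth, lev, np.nan)


def annotate_consequence(c: SNVCall, genes: list[GeneModel],
                         genome: GenomeContext) -> str:
    """Variant consequence from a single-transcript gene model.

    CDS events are translated through the standard codon table on the coding
    strand; exonic non-CDS events become 5'/3'-UTR by strand-aware position;
    intra-gene non-exonic events are intronic; genes without a CDS yield
    ``non_coding``.
    """
    gene = next((g for g in genes if g.gene_id == c.gene_id), None)
    if gene is None or not gene.contains(c.pos):
        raise ValueError(f"event {c.contig}:{c.pos} outside gene model")
    cls = gene.classify(c.pos)
    if cls == "intron":
        return "intron"
    if cls == "non_coding":
        return "non_coding"
    if cls == "utr5":
        return "5_prime_UTR"
    if cls == "utr3":
        return "3_prime_UTR"
    # CDS: build the affected codon on the coding strand
    coding = gene.coding_positions()
    idx = coding.index(c.pos)
    codon_start = (idx // 3) * 3
    codon_pos = [coding[codon_start + k] for k in range(3)]
    ref_codon = "".join(
        genome.base(gene.contig, p) if gene.strand == "+"
        else COMPLEMENT[genome.base(gene.contig, p)]
        for p in codon_pos)
    ref_base = c.ref if gene.strand == "+" else COMPLEMENT[c.ref]
    alt_base = c.alt if gene.strand == "+" else COMPLEMENT[c.alt]
    offset = idx - codon_start
    assert ref_codon[offset] == ref_base
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gained"
    if alt_aa == ref_aa:
        return "synonymous"
    return "missense"


def _event_id(c: SNVCall) -> str:
    return f"{c.gene_id}:{c.contig}:{c.pos}"


def call_editing(counts: SiteCountTable, genome: GenomeContext,
                 thresholds: CallThresholds = CallThresholds(),
                 whitelist_rescue: bool = True) -> EditingMatrix:
    """Full caller: thresholds → strand rule → cascade → high confidence.

    Returns the editing matrix over retained events plus a filter log in
    which every candidate appears exactly once.
    """
    candidates = call_snvs(counts, thresholds)
    log: list[dict] = []
    stranded, drops = select_strand_consistent(candidates, genome.genes)
    log.extend(drops)
    filtered, drops = apply_filter_cascade(stranded, genome, thresholds,
                                           whitelist_rescue)
    log.extend(drops)
    final, drops = high_confidence(filtered, genome, thresholds)
    log.extend(drops)
    log.extend(_log_entry(c, "retained", "retained") for c in final)

    rows = {}
    meta = []
    for c in final:
        eid = _event_id(c)
        rows[eid] = _sample_levels(c, thresholds.min_depth)
        meta.append({"event_id": eid, "contig": c.contig, "pos": c.pos,
                     "ref": c.ref, "alt": c.alt, "gene_id": c.gene_id,
                     "strand": c.strand,
                     "consequence": annotate_consequence(c, genome.genes,
                                                         genome),
                     "whitelisted": c.whitelisted})
    levels = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=counts.samples)
    events = (pd.DataFrame(meta, columns=["event_id", "contig", "pos", "ref",
                                          "alt", "gene_id", "strand",
                                          "consequence", "whitelisted"])
              .set_index("event_id"))
    filter_log = pd.DataFrame(
        log, columns=["contig", "pos", "ref", "alt", "stage", "reason"])
    filter_log = filter_log.sort_values(["contig", "pos", "alt"],
                                        kind="mergesort", ignore_index=True)
    return EditingMatrix(levels=levels, events=events, filter_log=filter_log)


def strand_counts(counts: SiteCountTable, events: pd.DataFrame,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(edited, unedited) strand-appropriate counts for a set of events.

    Returns two (n_events, n_samples) arrays aligned with ``events`` rows:
    edited = nG / unedited = nA at +-strand sites, edited = nC / unedited =
    nT at −-strand sites.
    """
    idx = counts.site_index()
    n_e, n_s = len(events), counts.n_samples
    edited = np.zeros((n_e, n_s), dtype=np.int64)
    unedited = np.zeros((n_e, n_s), dtype=np.int64)
    for i, row in enumerate(events.itertuples()):
        j = idx[(row.contig, int(row.pos))]
        edited[i] = counts.counts[:, j, BASE_INDEX[row.alt]]
        unedited[i] = counts.counts[:, j, BASE_INDEX[row.ref]]
    return edited, unedited
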