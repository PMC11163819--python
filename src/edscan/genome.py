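"""Toy-genome data model: contigs, repeat/junction annotations and gene models.

The pipeline works on small reference genomes ("mini-genomes") described by a
FASTA file plus plain-text interval annotations:

* repeats          — BED4, the name column is the repeat class
                     (``alu``, ``simple_repeat``, ``homopolymer``)
* junctions        — BED3 of the exonic bases adjacent to splice boundaries
* whitelist        — BED3 of known editing sites (a REDIportal-style catalogue)
* blacklist        — BED3 of known germline SNPs (a dbSNP-style catalogue)
* genes            — GTF-lite with ``exon`` and ``CDS`` features

Internally every coordinate is 1-based closed; BED input/output converts at the
boundary (0-based half-open on disk).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

__all__ = [
    "GeneModel",
    "GenomeContext",
    "read_genome",
    "write_genome",
    "bed_to_internal",
    "internal_to_bed",
]


class GenomeValidationError(ValueError):
    """An annotation is inconsistent with the genome it annotates."""


class ParseError(ValueError):
    """A malformed line in an input file; names the file and line number."""


def bed_to_internal(start: int, end: int) -> tuple[int, int]:
    """Convert a BED 0-based half-open interval to 1-based closed."""
    return start + 1, end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based closed interval to BED 0-based half-open."""
    return start - 1, end


@dataclass
class GeneModel:
    """A single-transcript gene: ordered exons and an optional CDS span.

    ``exons`` are 1-based closed intervals, sorted and non-overlapping.
    ``cds``, when present, is a genomic span contained in the exons; the
    coding sequence is the exonic bases inside that span, read 5'→3' on the
    gene's strand.  UTRs are derived: exonic bases outside the CDS span are
    5'-UTR on the transcription-start side and 3'-UTR on the other.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GenomeValidationError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise GenomeValidationError(f"{self.gene_id}: overlapping exons")
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.span[0] <= cs <= ce <= self.span[1]):
                raise GenomeValidationError(f"{self.gene_id}: CDS outside exon span")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return self.span[0] <= pos <= self.span[1]

    def is_exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def classify(self, pos: int) -> str | None:
        """Classify a position as cds / utr5 / utr3 / intron / non_coding.

        Returns ``None`` outside the gene span.  Genes without a CDS yield
        ``non_coding`` for every exonic base.
        """
        if not self.contains(pos):
            return None
        if not self.is_exonic(pos):
            return "intron"
        if self.cds is None:
            return "non_coding"
        cs, ce = self.cds
        if cs <= pos <= ce:
            return "cds"
        upstream = pos < cs
        if self.strand == "+":
            return "utr5" if upstream else "utr3"
        return "utr3" if upstream else "utr5"

    def utr_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Derived 5'/3'-UTR intervals (empty when there is no CDS)."""
        out: dict[str, list[tuple[int, int]]] = {"utr5": [], "utr3": []}
        if self.cds is None:
            return out
        current: tuple[str, int, int] | None = None
        for s, e in self.exons:
            for pos in range(s, e + 1):
                cls = self.classify(pos)
                if cls not in ("utr5", "utr3"):
                    if current is not None:
                        out[current[0]].append((current[1], current[2]))
                        current = None
                    continue
                if current is not None and current[0] == cls and current[2] == pos - 1:
                    current = (cls, current[1], pos)
                else:
                    if current is not None:
                        out[current[0]].append((current[1], current[2]))
                    current = (cls, pos, pos)
        if current is not None:
            out[current[0]].append((current[1], current[2]))
        return out

    def coding_positions(self) -> list[int]:
        """Genomic positions of CDS bases in translation (5'→3') order."""
        if self.cds is None:
            return []
        cs, ce = self.cds
        pos = [p for s, e in self.exons for p in range(max(s, cs), min(e, ce) + 1)
               if s <= p <= e and cs <= p <= ce]
        return pos[::-1] if self.strand == "-" else pos

    def junction_adjacent_bases(self) -> list[int]:
        """Exonic bases flanking each internal splice boundary."""
        out: list[int] = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.extend([e1, s2])
        return out


@dataclass
class GenomeContext:
    """A reference mini-genome plus the annotations the filter cascade needs."""

    contigs: dict[str, str]
    mito_name: str | None = None
    repeats: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    junctions: set[tuple[str, int]] = field(default_factory=set)
    genes: list[GeneModel] = field(default_factory=list)
    editing_whitelist: set[tuple[str, int]] = field(default_factory=set)
    snp_blacklist: set[tuple[str, int]] = field(default_factory=set)

    def validate(self) -> None:
        for name, seq in self.contigs.items():
            if set(seq) - VALID_BASES:
                raise GenomeValidationError(f"contig {name}: non-ACGTN characters")
        for name, ivs in self.repeats.items():
            self._check_contig(name)
            for s, e, _kind in ivs:
                self._check_interval(name, s, e)
        for contig, pos in self.junctions:
            self._check_interval(contig, pos, pos)
        for g in self.genes:
            self._check_interval(g.contig, *g.span)
        for coll in (self.editing_whitelist, self.snp_blacklist):
            for contig, pos in coll:
                self._check_interval(contig, pos, pos)

    def _check_contig(self, name: str) -> None:
        if name not in self.contigs:
            raise GenomeValidationError(f"unknown contig {name!r}")

    def _check_interval(self, contig: str, start: int, end: int) -> None:
        self._check_contig(contig)
        if not (1 <= start <= end <= len(self.contigs[contig])):
            raise GenomeValidationError(
                f"interval {contig}:{start}-{end} outside contig bounds")

    # --- queries used by the filter cascade ------------------------------

    def base(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos - 1]

    def homopolymer_run_length(self, contig: str, pos: int) -> int:
        """Length of the maximal single-nucleotide run containing ``pos``."""
        seq = self.contigs[contig]
        b = seq[pos - 1]
        i = pos - 1
        while i > 0 and seq[i - 1] == b:
            i -= 1
        j = pos - 1
        while j < len(seq) - 1 and seq[j + 1] == b:
            j += 1
        return j - i + 1

    def in_repeat(self, contig: str, pos: int, kinds: Iterable[str]) -> bool:
        kinds = set(kinds)
        for s, e, kind in self.repeats.get(contig, []):
            if kind in kinds and s <= pos <= e:
                return True
        return False

    def near_junction(self, contig: str, pos: int, max_dist: int = 6) -> bool:
        return any(c == contig and abs(pos - j) <= max_dist
                   for c, j in self.junctions)

    def genes_overlapping(self, contig: str, pos: int) -> list[GeneModel]:
        return [g for g in self.genes if g.contig == contig and g.contains(pos)]


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _read_bed(path: str | Path, n_cols: int) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < n_cols:
                raise ParseError(f"{path}:{lineno}: expected >= {n_cols} columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{lineno}: invalid BED interval")
            rows.append((fields[0], start, end) + tuple(fields[3:n_cols]))
    return rows


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def _read_gtf(path: str | Path) -> list[GeneModel]:
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            contig, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            m = _GTF_GENE_ID.search(attrs)
            if m is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            gid = m.group(1)
            rec = exons.setdefault(gid, {"contig": contig, "strand": strand,
                                         "exons": [], "cds": []})
            if feature == "exon":
                rec["exons"].append((s, e))
            else:
                rec["cds"].append((s, e))
    genes = []
    for gid, rec in exons.items():
        cds = None
        if rec["cds"]:
            cds = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        genes.append(GeneModel(gid, rec["contig"], rec["strand"],
                               rec["exons"], cds))
    genes.sort(key=lambda g: (g.contig, g.span[0], g.gene_id))
    return genes


def read_genome(fasta_path: str | Path,
                annotation_paths: Mapping[str, str | Path] | None = None,
                mito_name: str | None = None) -> GenomeContext:
    """Load a FASTA mini-genome plus optional annotation files.

    ``annotation_paths`` maps any of ``repeats`` (BED4), ``junctions``,
    ``whitelist``, ``blacklist`` (BED3) and ``genes`` (GTF-lite) to paths.
    BED intervals are converted to the internal 1-based closed convention;
    junction/whitelist/blacklist BEDs are expanded to per-base position sets.
    """
    contigs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ParseError(f"{fasta_path}: no FASTA records")
    ctx = GenomeContext(contigs=contigs, mito_name=mito_name)
    paths = dict(annotation_paths or {})
    if "repeats" in paths:
        for contig, start, end, kind in _read_bed(paths["repeats"], 4):
            s, e = bed_to_internal(start, end)
            ctx.repeats.setdefault(contig, []).append((s, e, kind))
    for key, target in (("junctions", ctx.junctions),
                        ("whitelist", ctx.editing_whitelist),
                        ("blacklist", ctx.snp_blacklist)):
        if key in paths:
            for contig, start, end in _read_bed(paths[key], 3):
                s, e = bed_to_internal(start, end)
                target.update((contig, p) for p in range(s, e + 1))
    if "genes" in paths:
        ctx.genes = _read_gtf(paths["genes"])
    ctx.validate()
    return ctx


def write_genome(ctx: GenomeContext, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + annotation files with deterministic ordering.

    Returns a mapping of annotation keys to the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out / "genome.fa"
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(ctx.contigs.items())]
    SeqIO.write(records, str(fasta), "fasta")
    paths["fasta"] = fasta

    rep = out / "repeats.bed"
    with open(rep, "w") as fh:
        for contig in sorted(ctx.repeats):
            for s, e, kind in sorted(ctx.repeats[contig]):
                bs, be = internal_to_bed(s, e)
                fh.write(f"{contig}\t{bs}\t{be}\t{kind}\n")
    paths["repeats"] = rep

    for key, coll in (("junctions", ctx.junctions),
                      ("whitelist", ctx.editing_whitelist),
                      ("blacklist", ctx.snp_blacklist)):
        p = out / f"{key}.bed"
        with open(p, "w") as fh:
            for contig, pos in sorted(coll):
                bs, be = internal_to_bed(pos, pos)
                fh.write(f"{contig}\t{bs}\t{be}\n")
        paths[key] = p

    gtf = out / "genes.gtf"
    with open(gtf, "w") as fh:
        for g in sorted(ctx.genes, key=lambda g: (g.contig, g.span[0], g.gene_id)):
            attrs = f'gene_id "{g.gene_id}";'
            for s, e in g.exons:
                fh.write(f"{g.contig}\tedscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            if g.cds is not None:
                cs, ce = g.cds
                for s, e in g.exons:
                    os_, oe = max(s, cs), min(e, ce)
                    if os_ <= oe:
                        fh.write(f"{g.contig}\tedscan\tCDS\t{os_}\t{oe}\t.\t{g.strand}\t.\t{attrs}\n")
    paths["genes"] = gtf
    return paths
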