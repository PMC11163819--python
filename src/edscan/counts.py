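"""Per-sample, per-site base counts and sample metadata.

A :class:`SiteCountTable` is the pipeline's universal currency: for every
sample and genomic site it stores the A/C/G/T read counts that passed the
upstream base-quality filter (BQ >= 25 by contract), a site-level summary of
where alt-supporting reads sit within their reads, and a per-site flag for
indel proximity.  On disk it is a long-format TSV with one row per populated
(sample, site) cell; absent cells are depth 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

COUNT_COLUMNS = ["sample", "contig", "pos", "ref", "nA", "nC", "nG", "nT",
                 "alt_read_pos", "near_indel"]

DEFAULT_GROUP_ALIASES = {
    "case": "case", "control": "control",
    "pcos": "case", "con": "control", "normal": "control", "healthy": "control",
}

HORMONE_FEATURES = ["LH", "FSH", "LH_FSH_ratio", "T", "DHEAS", "E2"]


class CountTableError(ValueError):
    pass


class MetadataError(ValueError):
    pass


@dataclass
class SiteCountTable:
    """samples x sites x {A,C,G,T} read counts with site-level artifact flags.

    ``counts`` has shape (n_samples, n_sites, 4) in ACGT order.
    ``alt_read_pos`` is the median relative read position (0..1) of the
    alt-supporting (non-reference) reads in that cell, NaN when the cell has
    no alt reads.  ``near_indel`` marks sites within 1 nt of an indel.
    """

    samples: list[str]
    sites: list[tuple[str, int, str]]   # (contig, pos 1-based, ref base)
    counts: np.ndarray
    alt_read_pos: np.ndarray
    near_indel: np.ndarray

    def __post_init__(self) -> None:
        n_s, n_p = len(self.samples), len(self.sites)
        if self.counts.shape != (n_s, n_p, 4):
            raise CountTableError("counts shape mismatch")
        if (self.counts < 0).any():
            raise CountTableError("negative counts")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def depth(self) -> np.ndarray:
        """Total sequencing depth per (sample, site)."""
        return self.counts.sum(axis=2)

    def site_index(self) -> dict[tuple[str, int], int]:
        return {(c, p): i for i, (c, p, _r) in enumerate(self.sites)}

    def base_counts(self, base: str) -> np.ndarray:
        return self.counts[:, :, BASE_INDEX[base]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame of the populated cells, sorted (contig,pos,sample)."""
        rows = []
        depth = self.depth()
        for j, (contig, pos, ref) in enumerate(self.sites):
            for i, sample in enumerate(self.samples):
                if depth[i, j] == 0:
                    continue
                arp = self.alt_read_pos[i, j]
                rows.append((sample, contig, pos, ref,
                             *(int(self.counts[i, j, k]) for k in range(4)),
                             "" if np.isnan(arp) else round(float(arp), 6),
                             int(self.near_indel[j])))
        df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
        return df.sort_values(["contig", "pos", "sample"], kind="mergesort",
                              ignore_index=True)


def read_counts(tsv_path: str | Path) -> SiteCountTable:
    """Read a long-format counts TSV into a pivoted :class:`SiteCountTable`."""
    df = pd.read_csv(tsv_path, sep="\t", comment="#",
                     dtype={"sample": str, "contig": str, "ref": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{tsv_path}: missing columns {missing}")
    if (df["pos"] < 1).any():
        raise CountTableError(f"{tsv_path}: pos < 1")
    for c in ("nA", "nC", "nG", "nT"):
        if (df[c] < 0).any():
            raise CountTableError(f"{tsv_path}: negative counts in {c}")
    if df.duplicated(["sample", "contig", "pos"]).any():
        dup = df[df.duplicated(["sample", "contig", "pos"])].iloc[0]
        raise CountTableError(
            f"{tsv_path}: duplicate record for {dup['sample']} "
            f"{dup['contig']}:{dup['pos']}")
    ref_check = df.groupby(["contig", "pos"])["ref"].nunique()
    if (ref_check > 1).any():
        raise CountTableError(f"{tsv_path}: conflicting ref base at a site")

    samples = sorted(df["sample"].unique())
    site_df = (df[["contig", "pos", "ref"]].drop_duplicates()
               .sort_values(["contig", "pos"], ignore_index=True))
    sites = [(r.contig, int(r.pos), r.ref) for r in site_df.itertuples()]
    s_idx = {s: i for i, s in enumerate(samples)}
    p_idx = {(c, p): i for i, (c, p, _r) in enumerate(sites)}

    counts = np.zeros((len(samples), len(sites), 4), dtype=np.int64)
    arp = np.full((len(samples), len(sites)), np.nan)
    near_indel = np.zeros(len(sites), dtype=bool)
    for row in df.itertuples():
        i, j = s_idx[row.sample], p_idx[(row.contig, int(row.pos))]
        counts[i, j] = (row.nA, row.nC, row.nG, row.nT)
        if not pd.isna(row.alt_read_pos) and row.alt_read_pos != "":
            arp[i, j] = float(row.alt_read_pos)
        if bool(int(row.near_indel)):
            near_indel[j] = True
    return SiteCountTable(samples, sites, counts, arp, near_indel)


def write_counts(table: SiteCountTable, tsv_path: str | Path,
                 header_comment: str | None = None) -> None:
    df = table.to_frame()
    with open(tsv_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


# --------------------------------------------------------------------------
# Sample metadata
# --------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    sample_id: str
    group: str          # "case" or "control"
    hormones: dict[str, float] = field(default_factory=dict)


def read_metadata(tsv_path: str | Path,
                  group_aliases: dict[str, str] | None = None,
                  ) -> list[SampleMetadata]:
    """Read sample metadata; recomputes LH/FSH ratio when it is blank.

    Group labels are matched case-insensitively against ``group_aliases``
    (default accepts case/control plus the common cohort labels PCOS/Con).
    """
    aliases = {k.lower(): v for k, v in
               (group_aliases or DEFAULT_GROUP_ALIASES).items()}
    df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise MetadataError(f"{tsv_path}: need sample_id and group columns")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise MetadataError(f"{tsv_path}: duplicate sample_id {dup!r}")
    out = []
    for row in df.to_dict("records"):
        label = str(row["group"]).strip().lower()
        if label not in aliases:
            raise MetadataError(
                f"{tsv_path}: unknown group label {row['group']!r} for "
                f"sample {row['sample_id']!r}")
        hormones: dict[str, float] = {}
        for feat in HORMONE_FEATURES:
            if feat in df.columns and not pd.isna(row[feat]):
                hormones[feat] = float(row[feat])
        if ("LH_FSH_ratio" not in hormones and "LH" in hormones
                and "FSH" in hormones and hormones["FSH"] != 0):
            hormones["LH_FSH_ratio"] = hormones["LH"] / hormones["FSH"]
        out.append(SampleMetadata(str(row["sample_id"]), aliases[label], hormones))
    return out


def write_metadata(metadata: list[SampleMetadata], tsv_path: str | Path,
                   header_comment: str | None = None) -> None:
    rows = []
    for m in sorted(metadata, key=lambda m: m.sample_id):
        row = {"sample_id": m.sample_id, "group": m.group}
        for feat in HORMONE_FEATURES:
            row[feat] = round(m.hormones[feat], 6) if feat in m.hormones else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=["sample_id", "group"] + HORMONE_FEATURES)
    with open(tsv_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def metadata_frame(metadata: list[SampleMetadata]) -> pd.DataFrame:
    """Samples x (group coding + hormones) frame; group coded control=0, case=1."""
    rows = {}
    for m in metadata:
        row = {"group": 1.0 if m.group == "case" else 0.0}
        row.update(m.hormones)
        rows[m.sample_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def groups_dict(metadata: list[SampleMetadata]) -> dict[str, str]:
    return {m.sample_id: m.group for m in metadata}


def check_samples_covered(table: SiteCountTable,
                          metadata: list[SampleMetadata]) -> None:
    """Every sample with counts must appear in the metadata."""
    known = {m.sample_id for m in metadata}
    missing = [s for s in table.samples if s not in known]
    if missing:
        raise MetadataError(f"samples missing from metadata: {missing}")
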