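"""Readers/writers for the standard genomic formats the pipeline touches,
plus the shared coordinate data model.

All internal coordinates are 0-based half-open; conversions from 1-based
conventions (GTF, pileup position columns) happen only at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("psidelta")

STRANDS = ("+", "-", ".")

PILEUP_COLUMNS = ["chrom", "pos", "ref_base", "depth", "del_count", "library_id"]


class ParseError(ValueError):
    """Malformed record in an input file; message names the line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to the coordinates the pipeline needs.

    ``tss``/``tes`` are 0-based coordinates of the first/last transcribed
    base, so on the minus strand ``tss >= tes``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: plus strand requires tss <= tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: minus strand requires tss >= tes")

    @property
    def span(self) -> GenomicInterval:
        lo, hi = sorted((self.tss, self.tes))
        return GenomicInterval(self.chrom, lo, hi + 1, self.strand)


class CoverageTrack:
    """Per-base coverage, stored densely per chromosome.

    Overlapping input intervals are summed, so replicate-merged tracks can
    be built by adding records. Positions never touched report 0.
    """

    def __init__(self) -> None:
        self._arrays: dict[str, np.ndarray] = {}

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        if value < 0:
            raise ValueError(f"negative coverage value {value} at {chrom}:{start}")
        if end <= start or start < 0:
            raise ValueError(f"bad interval [{start}, {end}) on {chrom}")
        arr = self._arrays.get(chrom)
        if arr is None or arr.size < end:
            new = np.zeros(max(end, 256, 0 if arr is None else 2 * arr.size))
            if arr is not None:
                new[: arr.size] = arr
            self._arrays[chrom] = arr = new
        arr[start:end] += value

    def per_base(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base values over the interval; uncovered bases are 0."""
        out = np.zeros(interval.width)
        arr = self._arrays.get(interval.chrom)
        if arr is None:
            return out
        lo = max(interval.start, 0)
        hi = min(interval.end, arr.size)
        if hi > lo:
            out[lo - interval.start : hi - interval.start] = arr[lo:hi]
        return out

    def coverage(self, interval: GenomicInterval) -> float:
        arr = self._arrays.get(interval.chrom)
        if arr is None:
            return 0.0
        lo = max(interval.start, 0)
        hi = min(interval.end, arr.size)
        return float(arr[lo:hi].sum()) if hi > lo else 0.0

    def value_at(self, chrom: str, pos: int) -> float:
        arr = self._arrays.get(chrom)
        if arr is None or not (0 <= pos < arr.size):
            return 0.0
        return float(arr[pos])

    def total_mass(self) -> float:
        return float(sum(a.sum() for a in self._arrays.values()))

    def chroms(self) -> list[str]:
        return sorted(self._arrays)

    def scaled(self, factor: float) -> "CoverageTrack":
        out = CoverageTrack()
        for chrom, arr in self._arrays.items():
            out._arrays[chrom] = arr * factor
        return out

    def to_bedgraph(self, path) -> None:
        """Write the track as run-length bedGraph records (zero runs omitted)."""
        with open(path, "w") as fh:
            for chrom in sorted(self._arrays):
                arr = self._arrays[chrom]
                # run-length encode
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


class SequenceStore:
    """Uppercase DNA sequences keyed by chromosome name."""

    _COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

    def __init__(self, sequences: dict[str, str] | None = None) -> None:
        self._seqs: dict[str, str] = {}
        for chrom, seq in (sequences or {}).items():
            self.add(chrom, seq)

    @classmethod
    def from_fasta(cls, path) -> "SequenceStore":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def add(self, chrom: str, seq: str) -> None:
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{chrom}: alphabet outside ACGTN: {sorted(bad)}")
        self._seqs[chrom] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def base_at(self, chrom: str, pos: int) -> str:
        seq = self._seqs.get(chrom)
        if seq is None or not (0 <= pos < len(seq)):
            return "N"
        return seq[pos]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand slice; out-of-bounds flanks padded with N."""
        seq = self._seqs.get(chrom, "")
        lo, hi = max(start, 0), min(end, len(seq))
        core = seq[lo:hi] if hi > lo else ""
        return "N" * (lo - start) + core + "N" * (end - hi)

    @classmethod
    def revcomp(cls, seq: str) -> str:
        return seq.translate(cls._COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _gtf_attributes(field8: str) -> dict[str, str]:
    out = {}
    for chunk in field8.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, raw = chunk.partition(" ")
            out[key] = raw.strip().strip('"')
    return out


def read_gene_models(path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from GTF (gene records) or the 6-column TSV dialect.

    GTF coordinates are 1-based inclusive and are converted to the 0-based
    internal convention; TSS is the strand-appropriate transcribed end.
    Records with unknown strand are rejected with a warning count.
    """
    path = str(path)
    if fmt is None:
        fmt = "gtf" if path.endswith((".gtf", ".gff")) else "tsv"
    if fmt == "gtf":
        return _read_gtf(path)
    if fmt == "tsv":
        return _read_gene_tsv(path)
    raise ValueError(f"unknown gene-model format {fmt!r}")


def _read_gtf(path: str) -> list[GeneModel]:
    models: list[GeneModel] = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields")
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            strand = fields[6]
            attrs = _gtf_attributes(fields[8])
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene record lacks gene_id")
            if strand not in ("+", "-"):
                rejected += 1
                continue
            biotype = attrs.get("gene_biotype") or attrs.get("gene_type") or "protein_coding"
            left, right = start1 - 1, end1 - 1  # 0-based first/last base
            tss, tes = (left, right) if strand == "+" else (right, left)
            models.append(GeneModel(gene_id, fields[0], strand, tss, tes, biotype))
    if rejected:
        logger.warning("%s: %d gene records with unknown strand rejected", path, rejected)
    if not models:
        logger.warning("%s: no gene models parsed", path)
    return models


def _read_gene_tsv(path: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"gene_id", "chrom", "strand", "tss", "tes", "biotype"}
    if df.empty and not required <= set(df.columns):
        logger.warning("%s: empty gene-model table", path)
        return []
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    models, rejected = [], 0
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            rejected += 1
            continue
        models.append(
            GeneModel(str(row.gene_id), str(row.chrom), row.strand,
                      int(row.tss), int(row.tes), str(row.biotype))
        )
    if rejected:
        logger.warning("%s: %d records with unknown strand rejected", path, rejected)
    return models


def read_bedgraph(path) -> CoverageTrack:
    """Load a 4-column bedGraph into a CoverageTrack (overlaps summed)."""
    track = CoverageTrack()
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative coverage value {value}")
            if end <= start:
                rejected += 1
                continue
            track.add(chrom, start, end, value)
    if rejected:
        logger.warning("%s: %d records with end <= start rejected", path, rejected)
    return track


def read_pileup_counts(path) -> pd.DataFrame:
    """Read a per-site pileup count TSV into a SiteCounts table.

    Input positions are 1-based; the returned frame carries a 0-based
    ``pos0`` column. Duplicate (chrom, pos, library) keys and counts that
    violate ``del_count <= depth`` are hard errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "library_id": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["depth"] < 0).any():
        raise ParseError(f"{path}: negative depth")
    if (df["del_count"] < 0).any():
        raise ParseError(f"{path}: negative del_count")
    bad = df["del_count"] > df["depth"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ParseError(
            f"{path}: del_count > depth at {row.chrom}:{row.pos} ({row.library_id})"
        )
    dup = df.duplicated(subset=["chrom", "pos", "library_id"], keep=False)
    if dup.any():
        keys = df[dup][["chrom", "pos", "library_id"]].drop_duplicates()
        raise ParseError(f"{path}: duplicate site keys: {keys.to_records(index=False).tolist()}")
    out = df.copy()
    out["pos0"] = out["pos"].astype(int) - 1
    return out[["chrom", "pos0", "ref_base", "depth", "del_count", "library_id"]]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_sites_bed(sites, path) -> None:
    """Write called sites as BED6 single-base intervals.

    Score = round(mean fraction * 1000); rows sorted by (chrom, start).
    """
    rows = sorted(sites, key=lambda s: (s.chrom, s.pos0))
    with open(path, "w") as fh:
        fh.write("# BED6: chrom start end name score(strand-mean-fraction*1000) strand\n")
        for s in rows:
            name = getattr(s, "site_id", None) or f"{s.chrom}:{s.pos0 + 1}"
            score = int(round(s.mean_fraction * 1000))
            fh.write(f"{s.chrom}\t{s.pos0}\t{s.pos0 + 1}\t{name}\t{score}\t{s.strand}\n")


def read_sites_bed(path) -> pd.DataFrame:
    """Read BED6 site records back (chrom, start, end, name, score, strand)."""
    return pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
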