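"""Readers and writers for the standard formats the pipeline touches.

All coordinates are normalized to a single internal convention: 0-based,
half-open intervals.  Conversions from the 1-based inclusive conventions of
GFF3, VCF, depth tables and BLAST tabular output happen only here, at the
I/O boundary.

Sequence alphabet is {A, C, G, T, N}, uppercase.  IUPAC ambiguity codes are
mapped to N on read (with a warning) and N positions are excluded from all
denominators downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_ALLOWED = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: chromosome or plasmid sequence.

    ``seq`` is uppercase over {A, C, G, T, N}.  ``topology`` records whether
    the molecule is circular (typical bacterial chromosome) or linear; the
    coordinate frame is linear either way, with position 0 at the arbitrary
    origin of the deposited sequence.
    """

    contig_id: str
    seq: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        bad = set(self.seq) - _ALLOWED
        if bad:
            raise ValueError(f"disallowed symbols in {self.contig_id}: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular or linear, got {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature in internal 0-based half-open coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    phase: int = 0
    locus_tag: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad CDS interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantRecord:
    """One called difference against the reference.

    ``pos`` is 0-based.  ``vtype`` follows the caller's vocabulary:
    snp (1 bp substitution), mnp (equal-length multi-base substitution),
    ins, del, and complex (mixed-length block substitution).
    """

    contig_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.ref_allele:
            raise ValueError("ref_allele must be nonempty")
        expected = variant_type(self.ref_allele, self.alt_allele)
        if self.vtype != expected:
            raise ValueError(
                f"vtype {self.vtype!r} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele} (expected {expected!r})"
            )

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference positions the variant occupies, half-open."""
        return self.pos, self.pos + len(self.ref_allele)


def variant_type(ref: str, alt: str) -> str:
    """Classify an allele pair into snp/mnp/ins/del/complex."""
    if len(ref) == 1 and len(alt) == 1:
        return "snp"
    if len(ref) == len(alt):
        return "mnp"
    if len(ref) < len(alt) and alt.startswith(ref):
        return "ins"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "del"
    return "complex"


@dataclass
class DepthTrack:
    """Per-position sequencing depth of one library on one contig."""

    sample_id: str
    contig_id: str
    depth: np.ndarray  # int, length == contig length

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be 1-D")
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise nucleotide (or protein) alignment hit, BLAST outfmt-6 style.

    Coordinates are kept as read (1-based inclusive); ``s_reverse`` flags
    hits where the subject interval was given end-before-start (minus
    orientation).  ``q_interval``/``s_interval`` expose normalized 0-based
    half-open intervals.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError("pct_identity must be in [0, 100]")

    @property
    def s_reverse(self) -> bool:
        return self.s_start > self.s_end

    @property
    def q_interval(self) -> tuple[int, int]:
        return self.q_start - 1, self.q_end

    @property
    def s_interval(self) -> tuple[int, int]:
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


@dataclass
class OrthogroupTable:
    """Orthogroup membership: orthogroup -> strain -> [(locus_tag, length_bp)].

    A strain may have zero members in an orthogroup; member lengths are CDS
    nucleotide lengths and must be positive.
    """

    groups: dict[str, dict[str, list[tuple[str, int]]]] = field(default_factory=dict)

    def add(self, orthogroup_id: str, strain: str, locus_tag: str, length_bp: int) -> None:
        if length_bp <= 0:
            raise ValueError(f"member length must be > 0 ({orthogroup_id}/{locus_tag})")
        self.groups.setdefault(orthogroup_id, {}).setdefault(strain, []).append(
            (locus_tag, length_bp)
        )

    def strains(self) -> list[str]:
        out: set[str] = set()
        for members in self.groups.values():
            out.update(members)
        return sorted(out)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _clean_sequence(raw: str, contig_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _ALLOWED
    if bad:
        logger.warning(
            "contig %s: %d symbol(s) outside {A,C,G,T,N} (%s) mapped to N",
            contig_id,
            sum(seq.count(b) for b in bad),
            "".join(sorted(bad)),
        )
        seq = "".join(c if c in _ALLOWED else "N" for c in seq)
    return seq


def read_fasta(path: str | Path, topology: str = "circular") -> list[GenomeSequence]:
    """Read FASTA into :class:`GenomeSequence` records.

    Sequences are uppercased, U mapped to T, and any other non-{A,C,G,T,N}
    symbol mapped to N with a warning.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate contig_id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, _clean_sequence(str(rec.seq), rec.id), topology))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path) -> None:
    recs = [SeqRecord(Seq(g.seq), id=g.contig_id, description="") for g in genomes]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (CDS features only)
# ---------------------------------------------------------------------------


def _parse_gff_attributes(col9: str) -> dict[str, str]:
    out = {}
    for piece in col9.strip().split(";"):
        if "=" in piece:
            k, v = piece.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_cds(path: str | Path) -> list[CdsFeature]:
    """Read CDS rows from a GFF3 file; other feature types are ignored.

    GFF 1-based inclusive coordinates become internal 0-based half-open.
    A missing locus_tag/ID is synthesized as ``contig:start-end`` and logged.
    """
    features: list[CdsFeature] = []
    seen_tags: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            contig, _src, ftype, start_s, end_s, _score, strand, phase_s, attrs_s = cols[:9]
            if ftype != "CDS":
                continue
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            phase = int(phase_s) if phase_s in ("0", "1", "2") else 0
            attrs = _parse_gff_attributes(attrs_s)
            tag = attrs.get("locus_tag") or attrs.get("ID")
            if not tag:
                tag = f"{contig}:{start1 - 1}-{end1}"
                logger.warning("%s:%d: CDS without locus_tag/ID, synthesized %s", path, lineno, tag)
            if tag in seen_tags:
                raise FormatError(f"{path}:{lineno}: duplicate locus_tag {tag!r}")
            seen_tags.add(tag)
            features.append(
                CdsFeature(contig, start1 - 1, end1, strand, phase, tag, attrs.get("product", ""))
            )
    return features


def write_gff3_cds(features: Iterable[CdsFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.contig_id}\tsymbiorate\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t{f.phase}\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, sample_id: str = "") -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` lists.

    1-based POS becomes 0-based; multi-allelic rows are split into one
    record per ALT; symbolic or missing ALT alleles are skipped with a
    warning.  The variant type is re-derived from the allele lengths.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None:
                logger.warning("%s: record at %s:%d has no ALT, skipped", path, rec.contig, rec.pos)
                continue
            for alt in rec.alts:
                if alt is None or alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
                    logger.warning(
                        "%s: symbolic ALT %r at %s:%d skipped", path, alt, rec.contig, rec.pos
                    )
                    continue
                ref = rec.ref.upper()
                alt = alt.upper()
                out.append(
                    VariantRecord(
                        rec.contig, rec.pos - 1, ref, alt, variant_type(ref, alt), sample_id
                    )
                )
    return out


def write_vcf(
    variants: Sequence[VariantRecord],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write variants as minimal VCF 4.2 with contig header lines."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for cid, length in contig_lengths.items():
            fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.contig_id, v.pos)):
            fh.write(
                f"{v.contig_id}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t"
                f"TYPE={v.vtype}\n"
            )


# ---------------------------------------------------------------------------
# Depth tables (samtools-depth-like TSV)
# ---------------------------------------------------------------------------


def read_depth(
    path: str | Path, contigs: Mapping[str, int], sample_id: str = ""
) -> list[DepthTrack]:
    """Read a three-column depth TSV (contig, 1-based pos, depth).

    Returns one dense track per contig in ``contigs`` (a contig -> length
    mapping); positions absent from the file are depth 0.
    """
    tracks = {cid: np.zeros(length, dtype=np.int64) for cid, length in contigs.items()}
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["contig", "pos", "depth"],
            dtype={"contig": str, "pos": np.int64, "depth": np.int64},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["contig", "pos", "depth"])
    for cid, sub in df.groupby("contig", sort=False):
        if cid not in tracks:
            raise FormatError(f"{path}: unknown contig {cid!r}")
        pos = sub["pos"].to_numpy() - 1
        if (pos < 0).any() or (pos >= len(tracks[cid])).any():
            raise FormatError(f"{path}: position outside contig {cid!r}")
        tracks[cid][pos] = sub["depth"].to_numpy()
    return [DepthTrack(sample_id, cid, arr) for cid, arr in tracks.items()]


def write_depth(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    """Write depth TSV, omitting zero-depth positions (sparse convention)."""
    frames = []
    for t in tracks:
        (nz,) = np.nonzero(t.depth)
        frames.append(
            pd.DataFrame({"contig": t.contig_id, "pos": nz + 1, "depth": t.depth[nz]})
        )
    df = pd.concat(frames) if frames else pd.DataFrame(columns=["contig", "pos", "depth"])
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

_OUTFMT6_COLS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]


def read_hits_table(path: str | Path) -> list[AlignmentHit]:
    """Read 12-column BLAST tabular (outfmt 6) hits."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=_OUTFMT6_COLS, comment="#",
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return []
    for col in ("pct_identity", "evalue", "bitscore"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: non-numeric values in column {col}")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            AlignmentHit(
                str(row.query_id),
                str(row.subject_id),
                float(row.pct_identity),
                int(row.aln_length),
                int(row.mismatches),
                int(row.gap_opens),
                int(row.q_start),
                int(row.q_end),
                int(row.s_start),
                int(row.s_end),
                float(row.evalue),
                float(row.bitscore),
            )
        )
    return hits


def write_hits_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:g}\t{h.aln_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# Orthogroup tables
# ---------------------------------------------------------------------------


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Read a long-format orthogroup TSV: orthogroup_id, strain, locus_tag, length_bp."""
    table = OrthogroupTable()
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return table
    required = {"orthogroup_id", "strain", "locus_tag", "length_bp"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    for row in df.itertuples(index=False):
        table.add(str(row.orthogroup_id), str(row.strain), str(row.locus_tag), int(row.length_bp))
    return table


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("orthogroup_id\tstrain\tlocus_tag\tlength_bp\n")
        for og in sorted(table.groups):
            for strain in sorted(table.groups[og]):
                for tag, length in table.groups[og][strain]:
                    fh.write(f"{og}\t{strain}\t{tag}\t{length}\n")
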