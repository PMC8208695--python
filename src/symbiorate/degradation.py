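"""Comparative genome-degradation metrics for a pair of related strains.

Covers the length-ratio truncation/pseudogene rule, coding density, the
viral-protein similarity rule for prophage-related genes, greedy best-first
synteny-block construction with per-kilobase CDS-density differentials, and
clock-based divergence-time arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import AlignmentHit, CdsFeature, GenomeSequence, OrthogroupTable
from .rate_pipeline import AnalysisConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Truncation / pseudogenization calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncationCall:
    """Length comparison of one strain's longest orthogroup member against
    the other strain's longest; flagged when the ratio is at most the
    truncation threshold (a CDS eroded to <= 60% of its counterpart is
    likely pseudogenized or truncated)."""

    orthogroup_id: str
    strain: str
    longest_own_bp: int
    counterpart_bp: int
    ratio: float
    flagged: bool


def call_truncations(
    table: OrthogroupTable, truncation_ratio: float = 0.60
) -> list[TruncationCall]:
    """Apply the length-ratio rule to every two-strain orthogroup.

    For each orthogroup where both strains have at least one member, each
    strain's longest CDS is compared with the other strain's longest; the
    strain is flagged when ratio <= truncation_ratio (boundary inclusive:
    exactly 60% is flagged).  Orthogroups missing a strain yield no call
    for it.
    """
    strains = table.strains()
    if len(strains) != 2:
        raise ValueError(f"truncation calls need exactly two strains, got {strains}")
    a, b = strains
    calls: list[TruncationCall] = []
    for og in sorted(table.groups):
        members = table.groups[og]
        if a not in members or b not in members:
            logger.info("orthogroup %s: strain missing, no call", og)
            continue
        longest = {s: max(length for _tag, length in members[s]) for s in (a, b)}
        for own, other in ((a, b), (b, a)):
            ratio = longest[own] / longest[other]
            calls.append(
                TruncationCall(og, own, longest[own], longest[other], ratio,
                               ratio <= truncation_ratio)
            )
    return calls


# ---------------------------------------------------------------------------
# Coding density
# ---------------------------------------------------------------------------


def coding_density(genome: Sequence[GenomeSequence], cds_list: Iterable[CdsFeature]) -> float:
    """Percent of the genome covered by the union of CDS intervals.

    Overlapping CDSs are counted once (interval union, not length sum).
    """
    lengths = {g.contig_id: g.length for g in genome}
    total = sum(lengths.values())
    covered = 0
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for cds in cds_list:
        if cds.contig_id not in lengths:
            raise ValueError(f"CDS {cds.locus_tag}: contig {cds.contig_id!r} absent from genome")
        if cds.end > lengths[cds.contig_id]:
            raise ValueError(f"CDS {cds.locus_tag}: exceeds contig bounds")
        by_contig.setdefault(cds.contig_id, []).append((cds.start, cds.end))
    for ivs in by_contig.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return 100.0 * covered / total


# ---------------------------------------------------------------------------
# Prophage-related gene classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProphageCall:
    """Similarity-rule classification of one gene against viral proteins.

    flagged iff some hit is at least ``prophage_min_identity`` percent
    identical over at least ``prophage_min_cov`` percent of the length of
    any viral protein; the best hit is the highest-bitscore passing hit.
    """

    locus_tag: str
    best_viral_hit: str | None
    pct_identity: float
    viral_coverage: float
    flagged: bool


def classify_prophage_loci(
    protein_hits: Iterable[AlignmentHit],
    viral_lengths: Mapping[str, int],
    config: AnalysisConfig | None = None,
) -> list[ProphageCall]:
    """Classify genes as prophage related by the identity/coverage rule.

    ``protein_hits`` are gene-product-vs-viral-protein alignments (query =
    locus_tag, subject = viral protein).  Coverage is the alignment length
    as a percent of the viral protein's length.
    """
    config = config or AnalysisConfig()
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in protein_hits:
        if h.subject_id not in viral_lengths:
            raise ValueError(f"viral protein {h.subject_id!r} missing from length table")
        by_query.setdefault(h.query_id, []).append(h)

    calls: list[ProphageCall] = []
    for tag in sorted(by_query):
        passing = []
        for h in by_query[tag]:
            cov = 100.0 * h.aln_length / viral_lengths[h.subject_id]
            if h.pct_identity >= config.prophage_min_identity and cov >= config.prophage_min_cov:
                passing.append((h, cov))
        if passing:
            best, best_cov = max(passing, key=lambda pc: pc[0].bitscore)
            calls.append(ProphageCall(tag, best.subject_id, best.pct_identity, best_cov, True))
        else:
            best = max(by_query[tag], key=lambda h: h.bitscore)
            cov = 100.0 * best.aln_length / viral_lengths[best.subject_id]
            calls.append(ProphageCall(tag, None, best.pct_identity, cov, False))
    return calls


# ---------------------------------------------------------------------------
# Synteny blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntenyBlock:
    """A pair of alignable intervals on genomes A and B with CDS densities.

    Intervals are 0-based half-open; density_diff = cds_per_kb_a −
    cds_per_kb_b, so a negative value means fewer CDSs in A.
    """

    a_contig: str
    a_start: int
    a_end: int
    b_contig: str
    b_start: int
    b_end: int
    pct_identity: float
    reverse: bool
    cds_count_a: int
    cds_count_b: int
    cds_per_kb_a: float
    cds_per_kb_b: float

    @property
    def density_diff(self) -> float:
        return self.cds_per_kb_a - self.cds_per_kb_b

    @property
    def a_length(self) -> int:
        return self.a_end - self.a_start


def _midpoint_count(cds_list: Sequence[CdsFeature], contig: str, start: int, end: int) -> int:
    """CDSs whose midpoint lies in [start, end) on ``contig``."""
    n = 0
    for cds in cds_list:
        if cds.contig_id != contig:
            continue
        mid = (cds.start + cds.end) // 2
        if start <= mid < end:
            n += 1
    return n


def build_synteny_blocks(
    hits: Iterable[AlignmentHit],
    cds_a: Sequence[CdsFeature],
    cds_b: Sequence[CdsFeature],
    config: AnalysisConfig | None = None,
) -> list[SyntenyBlock]:
    """Greedy best-first synteny blocks from whole-genome alignment hits.

    Hits shorter than ``synteny_min_len`` or below ``synteny_min_identity``
    are discarded (boundaries kept: exactly 1000 bp and exactly 95% pass).
    The rest are taken best-first by bitscore (ties: longer alignment, then
    subject coordinates) and a hit is retained only if its A(query)-interval
    overlaps no previously retained A-interval — one best match per A
    region.  Per block, CDS density per kb is counted by CDS midpoint.
    """
    config = config or AnalysisConfig()
    candidates = [
        h for h in hits
        if h.aln_length >= config.synteny_min_len
        and h.pct_identity >= config.synteny_min_identity
    ]
    candidates.sort(key=lambda h: (-h.bitscore, -h.aln_length, h.subject_id, h.s_start, h.s_end))

    retained: list[AlignmentHit] = []
    taken: dict[str, list[tuple[int, int]]] = {}
    for h in candidates:
        qs, qe = h.q_interval
        if any(qs < e and s < qe for s, e in taken.get(h.query_id, [])):
            continue
        retained.append(h)
        taken.setdefault(h.query_id, []).append((qs, qe))

    blocks: list[SyntenyBlock] = []
    for h in retained:
        qs, qe = h.q_interval
        ss, se = h.s_interval
        na = _midpoint_count(cds_a, h.query_id, qs, qe)
        nb = _midpoint_count(cds_b, h.subject_id, ss, se)
        blocks.append(
            SyntenyBlock(
                h.query_id, qs, qe, h.subject_id, ss, se, h.pct_identity, h.s_reverse,
                na, nb, 1000.0 * na / (qe - qs), 1000.0 * nb / (se - ss),
            )
        )
    blocks.sort(key=lambda b: (b.a_contig, b.a_start))
    return blocks


@dataclass(frozen=True)
class BlockSummary:
    """Partition of syntenic blocks by the sign of the A−B CDS-count
    difference, with base-pair spans taken on genome A."""

    n_blocks: int
    n_fewer_a: int
    n_more_a: int
    n_equal: int
    bp_fewer_a: int
    bp_more_a: int
    bp_equal: int
    mean_density_diff: float | None


def summarize_block_density(blocks: Sequence[SyntenyBlock]) -> BlockSummary:
    """Tally blocks with fewer/more/equal CDS counts in genome A."""
    n_f = n_m = n_e = bp_f = bp_m = bp_e = 0
    for b in blocks:
        d = b.cds_count_a - b.cds_count_b
        if d < 0:
            n_f += 1
            bp_f += b.a_length
        elif d > 0:
            n_m += 1
            bp_m += b.a_length
        else:
            n_e += 1
            bp_e += b.a_length
    mean_diff = float(np.mean([b.density_diff for b in blocks])) if blocks else None
    return BlockSummary(len(blocks), n_f, n_m, n_e, bp_f, bp_m, bp_e, mean_diff)


# ---------------------------------------------------------------------------
# Divergence time
# ---------------------------------------------------------------------------


def estimate_divergence_time(
    per_site_divergence: float, rate: float, formula: str = "d-over-2r"
) -> float:
    """Years since two lineages split, from per-site divergence and a clock.

    The default ``d-over-2r`` assumes both lineages accumulate changes
    independently at ``rate``, so divergence grows at 2r per year;
    ``d-over-r`` treats the divergence as accumulated along a single
    lineage (an upper bound).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if not 0 <= per_site_divergence < 1:
        raise ValueError("per-site divergence must be in [0, 1)")
    if formula == "d-over-2r":
        return per_site_divergence / (2.0 * rate)
    if formula == "d-over-r":
        return per_site_divergence / rate
    raise ValueError(f"unknown divergence formula {formula!r}")
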