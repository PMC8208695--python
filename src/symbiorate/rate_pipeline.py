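"""Tip-dated substitution-rate estimation from third codon positions.

The estimator compares a serially sampled isolate against a reference of
known temporal separation and computes

    rate = k / L / t

where ``k`` is the number of observed substitutions at third codon
positions, ``L`` the number of considered third-position sites, and ``t``
the elapsed time in years.  Third positions are used because most changes
there are synonymous, so the raw count approximates the neutral
substitution process without a codon model.

Sites enter the analysis only if every sequencing library covers them at a
minimum depth (default 5x), and a CDS contributes third-position sites only
if it is entirely covered in all libraries.  No multiple-hit correction is
applied: over the year-scale intervals this estimator targets, the expected
number of hits per site is << 1 and raw counts are unbiased to first order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import CdsFeature, DepthTrack, GenomeSequence, VariantRecord

logger = logging.getLogger(__name__)

SPECTRUM_CLASSES = ("GC>AT", "GC>TA", "GC>CG", "AT>GC", "AT>TA", "AT>CG")

# strand-collapsed class of a (ref, alt) single-base change
_CLASS_OF = {
    ("G", "A"): "GC>AT", ("C", "T"): "GC>AT",
    ("G", "T"): "GC>TA", ("C", "A"): "GC>TA",
    ("G", "C"): "GC>CG", ("C", "G"): "GC>CG",
    ("A", "G"): "AT>GC", ("T", "C"): "AT>GC",
    ("A", "T"): "AT>TA", ("T", "A"): "AT>TA",
    ("A", "C"): "AT>CG", ("T", "G"): "AT>CG",
}


@dataclass
class AnalysisConfig:
    """Thresholds and options for the rate and degradation analyses.

    Defaults are the study conditions: 5x minimum depth, the
    Mollicutes/Spiroplasma genetic code (translation table 4, TGA = Trp),
    a 60% length ratio for truncation calls, 1000 bp / 95% identity synteny
    filters, and 60% identity over 50% coverage for prophage-related genes.
    """

    min_depth: int = 5
    genetic_code: int = 4
    truncation_ratio: float = 0.60
    synteny_min_len: int = 1000
    synteny_min_identity: float = 95.0
    prophage_min_identity: float = 60.0
    prophage_min_cov: float = 50.0
    denominator: str = "intersection"  # or "all-third"
    divergence_formula: str = "d-over-2r"  # or "d-over-r"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.truncation_ratio <= 1:
            raise ValueError("truncation_ratio must be in (0, 1]")
        if self.denominator not in ("intersection", "all-third"):
            raise ValueError(f"unknown denominator mode {self.denominator!r}")
        if self.divergence_formula not in ("d-over-2r", "d-over-r"):
            raise ValueError(f"unknown divergence formula {self.divergence_formula!r}")


# ---------------------------------------------------------------------------
# Codon-position map
# ---------------------------------------------------------------------------


@dataclass
class CodonPositionMap:
    """Per-position codon-position labels (1, 2, 3 or 0 = none) and CDS owner.

    Positions covered by two or more CDSs are ambiguous and labelled 0 with
    owner -1; a site cannot have two codon positions.  ``cds_list`` holds
    the features that contributed labels (in-frame CDSs only) and ``owner``
    indexes into it.
    """

    codon_pos: dict[str, np.ndarray]  # int8 per contig: 0..3
    owner: dict[str, np.ndarray]  # int32 per contig: index into cds_list or -1
    cds_list: list[CdsFeature]
    excluded: list[CdsFeature] = field(default_factory=list)

    def owner_cds(self, contig_id: str, pos: int) -> CdsFeature | None:
        idx = int(self.owner[contig_id][pos])
        return self.cds_list[idx] if idx >= 0 else None


def build_codon_position_map(
    genome: Sequence[GenomeSequence], cds_list: Iterable[CdsFeature]
) -> CodonPositionMap:
    """Label every genome position with its codon position and owning CDS.

    On the plus strand the frame cycles 1,2,3 from ``start + phase``; on the
    minus strand it cycles 1,2,3 from ``end - phase`` downward.  CDSs whose
    length minus phase is not a multiple of 3 have no defined frame (typical
    of pseudogenes) and are excluded with a log message.  Positions claimed
    by two or more CDSs are set to 0/none.
    """
    lengths = {g.contig_id: g.length for g in genome}
    codon_pos = {cid: np.zeros(n, dtype=np.int8) for cid, n in lengths.items()}
    owner = {cid: np.full(n, -1, dtype=np.int32) for cid, n in lengths.items()}
    claims = {cid: np.zeros(n, dtype=np.int16) for cid, n in lengths.items()}
    kept: list[CdsFeature] = []
    excluded: list[CdsFeature] = []

    for cds in cds_list:
        if cds.contig_id not in lengths:
            raise ValueError(f"CDS {cds.locus_tag}: contig {cds.contig_id!r} absent from genome")
        if cds.end > lengths[cds.contig_id]:
            raise ValueError(f"CDS {cds.locus_tag}: exceeds contig {cds.contig_id!r} bounds")
        if (cds.length - cds.phase) % 3 != 0:
            logger.info(
                "CDS %s: length %d minus phase %d not divisible by 3, excluded from frame map",
                cds.locus_tag, cds.length, cds.phase,
            )
            excluded.append(cds)
            continue
        kept.append(cds)

    for idx, cds in enumerate(kept):
        cp = codon_pos[cds.contig_id]
        ow = owner[cds.contig_id]
        cl = claims[cds.contig_id]
        pos = np.arange(cds.start, cds.end)
        if cds.strand == "+":
            frame_from = cds.start + cds.phase
            labels = ((pos - frame_from) % 3) + 1
            if cds.phase:
                labels[: cds.phase] = 0  # bases before the first complete codon
        else:
            frame_from = cds.end - 1 - cds.phase
            labels = ((frame_from - pos) % 3) + 1
            if cds.phase:
                labels[-cds.phase:] = 0
        cp[pos] = labels.astype(np.int8)
        ow[pos] = idx
        cl[pos] += 1

    for cid in lengths:
        ambiguous = claims[cid] >= 2
        codon_pos[cid][ambiguous] = 0
        owner[cid][ambiguous] = -1

    return CodonPositionMap(codon_pos, owner, kept, excluded)


# ---------------------------------------------------------------------------
# Coverage masks
# ---------------------------------------------------------------------------


@dataclass
class CoverageMask:
    """Positions on one contig meeting a depth threshold, as merged intervals."""

    contig_id: str
    length: int
    intervals: list[tuple[int, int]]
    min_depth: int

    def to_bool(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=bool)
        for s, e in self.intervals:
            arr[s:e] = True
        return arr

    @property
    def n_positions(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @classmethod
    def from_bool(cls, contig_id: str, flags: np.ndarray, min_depth: int) -> "CoverageMask":
        flags = np.asarray(flags, dtype=bool)
        padded = np.concatenate(([False], flags, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.where(diff == 1)[0]
        ends = np.where(diff == -1)[0]
        return cls(contig_id, len(flags), list(zip(starts.tolist(), ends.tolist())), min_depth)


def build_coverage_mask(track: DepthTrack, min_depth: int) -> CoverageMask:
    """Mask of positions with depth >= min_depth, merged into maximal intervals."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return CoverageMask.from_bool(track.contig_id, track.depth >= min_depth, min_depth)


def intersect_masks(masks: Sequence[CoverageMask]) -> CoverageMask:
    """Positions present in every mask (same contig); the all-libraries filter."""
    if not masks:
        raise ValueError("need at least one mask")
    contigs = {m.contig_id for m in masks}
    if len(contigs) != 1:
        raise ValueError(f"masks span multiple contigs: {sorted(contigs)}")
    flags = masks[0].to_bool()
    for m in masks[1:]:
        if m.length != masks[0].length:
            raise ValueError("mask lengths differ")
        flags &= m.to_bool()
    return CoverageMask.from_bool(masks[0].contig_id, flags, max(m.min_depth for m in masks))


def select_fully_covered_cds(
    cds_list: Iterable[CdsFeature], mask: CoverageMask
) -> list[CdsFeature]:
    """Keep exactly the CDSs whose every position lies in the mask.

    One uncovered base disqualifies a CDS ("entirely covered" semantics).
    """
    flags = mask.to_bool()
    cum = np.concatenate(([0], np.cumsum(flags)))
    out = []
    for cds in cds_list:
        if cds.contig_id != mask.contig_id:
            continue
        if cum[cds.end] - cum[cds.start] == cds.length:
            out.append(cds)
    return out


def filter_variants_by_mask(
    variants: Iterable[VariantRecord], mask: CoverageMask
) -> list[VariantRecord]:
    """Retain variants whose full reference span lies inside the mask."""
    flags = mask.to_bool()
    cum = np.concatenate(([0], np.cumsum(flags)))
    out = []
    for v in variants:
        if v.contig_id != mask.contig_id:
            continue
        s, e = v.ref_span
        if e <= mask.length and cum[e] - cum[s] == e - s:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Counting and the rate estimate
# ---------------------------------------------------------------------------


def _decompose_equal_length(v: VariantRecord) -> list[tuple[int, str, str]]:
    """Per-base (pos, ref, alt) changes of an equal-length substitution record."""
    return [
        (v.pos + i, r, a)
        for i, (r, a) in enumerate(zip(v.ref_allele, v.alt_allele))
        if r != a
    ]


def count_third_position_changes(
    variants: Iterable[VariantRecord],
    cpmap: CodonPositionMap,
    retained_cds: Iterable[CdsFeature],
) -> int:
    """Number of substituted bases at third codon positions of retained CDSs.

    SNPs count 1 when they land on a position-3 site; equal-length MNP and
    complex records are decomposed base-by-base; indels and length-changing
    records contribute 0 (a per-site change count is only well defined for
    substitutions).
    """
    retained = {cds.locus_tag for cds in retained_cds}
    k = 0
    for v in variants:
        if len(v.ref_allele) != len(v.alt_allele):
            continue
        cp = cpmap.codon_pos[v.contig_id]
        ow = cpmap.owner[v.contig_id]
        for pos, _r, _a in _decompose_equal_length(v):
            if cp[pos] == 3:
                idx = int(ow[pos])
                if idx >= 0 and cpmap.cds_list[idx].locus_tag in retained:
                    k += 1
    return k


def count_third_position_sites(
    cpmap: CodonPositionMap,
    retained_cds: Iterable[CdsFeature],
    mask: CoverageMask | None = None,
) -> int:
    """Number of considered third-position sites (the rate denominator).

    With a mask, only masked positions count (the default "intersection"
    denominator); without one, all third positions of the retained CDSs.
    """
    retained_idx = {
        i for i, cds in enumerate(cpmap.cds_list)
        if cds.locus_tag in {c.locus_tag for c in retained_cds}
    }
    total = 0
    for cid, cp in cpmap.codon_pos.items():
        ow = cpmap.owner[cid]
        third = (cp == 3) & np.isin(ow, list(retained_idx) or [-2])
        if mask is not None:
            if mask.contig_id != cid:
                continue
            third &= mask.to_bool()
        total += int(third.sum())
    return total


@dataclass(frozen=True)
class RateEstimate:
    """k substitutions over L third-position sites in t years: rate = k/L/t."""

    comparison_id: str
    k_changes: int
    L_sites: int
    t_years: float
    rate: float

    def poisson_se(self) -> float:
        """Poisson standard error of the rate: sqrt(k)/(L*t)."""
        return float(np.sqrt(self.k_changes) / (self.L_sites * self.t_years))


def estimate_rate(
    k_changes: int, L_sites: int, t_years: float, comparison_id: str = ""
) -> RateEstimate:
    """Point estimate of the per-site per-year substitution rate."""
    if L_sites <= 0:
        raise ValueError("L_sites must be > 0")
    if t_years <= 0:
        raise ValueError("t_years must be > 0")
    return RateEstimate(comparison_id, k_changes, L_sites, t_years, k_changes / L_sites / t_years)


# ---------------------------------------------------------------------------
# Variant-effect classification (translation table 4)
# ---------------------------------------------------------------------------

EFFECTS = ("synonymous", "nonsynonymous", "frameshift", "inframe_indel", "intergenic", "complex")


@dataclass(frozen=True)
class EffectCall:
    variant: VariantRecord
    effect: str
    ref_codon: str | None = None
    alt_codon: str | None = None
    locus_tag: str | None = None


def _codon_bounds(cds: CdsFeature, pos: int) -> tuple[int, int] | None:
    """Genomic half-open interval of the codon containing ``pos``, or None
    if the position falls in a partial codon created by a nonzero phase."""
    if cds.strand == "+":
        off = pos - (cds.start + cds.phase)
        if off < 0:
            return None
        cstart = cds.start + cds.phase + 3 * (off // 3)
        return cstart, cstart + 3
    off = (cds.end - 1 - cds.phase) - pos
    if off < 0:
        return None
    cend = cds.end - cds.phase - 3 * (off // 3)
    return cend - 3, cend


def _translate(codon: str, table: CodonTable.CodonTable) -> str:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table.get(codon, "X")


def classify_variant_effect(
    variant: VariantRecord,
    cpmap: CodonPositionMap,
    genome: Sequence[GenomeSequence],
    genetic_code: int = 4,
) -> EffectCall:
    """Classify one variant's coding effect under the given genetic code.

    Substitutions confined to one codon of one CDS are translated on the
    whole-codon amino-acid change (table 4 reads TGA as Trp, so TGA->TGG is
    synonymous).  Indels inside a CDS are frameshift when the net length
    change is not a multiple of 3, else in-frame.  Variants entirely outside
    CDSs are intergenic; anything else (multi-codon MNPs, length-changing
    complex records, CDS-boundary straddlers) is reported as complex.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[genetic_code]
    except KeyError:
        raise ValueError(f"unsupported genetic code table id {genetic_code}")

    seqs = {g.contig_id: g.seq for g in genome}
    ow = cpmap.owner[variant.contig_id]
    s, e = variant.ref_span
    owners = {int(ow[p]) for p in range(s, e)}

    ref, alt = variant.ref_allele, variant.alt_allele
    if len(ref) != len(alt):
        # indel or length-changing complex record
        if owners == {-1}:
            return EffectCall(variant, "intergenic")
        net = len(alt) - len(ref)
        effect = "frameshift" if net % 3 != 0 else "inframe_indel"
        idx = next(i for i in owners if i >= 0)
        return EffectCall(variant, effect, locus_tag=cpmap.cds_list[idx].locus_tag)

    if owners == {-1}:
        return EffectCall(variant, "intergenic")
    if len(owners) != 1 or -1 in owners:
        return EffectCall(variant, "complex")

    cds = cpmap.cds_list[owners.pop()]
    bounds = _codon_bounds(cds, s)
    if bounds is None or _codon_bounds(cds, e - 1) != bounds:
        return EffectCall(variant, "complex", locus_tag=cds.locus_tag)

    cstart, cend = bounds
    ref_codon_fwd = seqs[variant.contig_id][cstart:cend]
    alt_list = list(ref_codon_fwd)
    for pos, r, a in zip(range(s, e), ref, alt):
        if alt_list[pos - cstart] != r:
            logger.warning(
                "variant at %s:%d: ref allele %r does not match reference base %r",
                variant.contig_id, pos, r, alt_list[pos - cstart],
            )
        alt_list[pos - cstart] = a
    alt_codon_fwd = "".join(alt_list)

    if cds.strand == "-":
        ref_codon = str(Seq(ref_codon_fwd).reverse_complement())
        alt_codon = str(Seq(alt_codon_fwd).reverse_complement())
    else:
        ref_codon, alt_codon = ref_codon_fwd, alt_codon_fwd

    if "N" in ref_codon or "N" in alt_codon:
        return EffectCall(variant, "complex", ref_codon, alt_codon, cds.locus_tag)
    effect = (
        "synonymous"
        if _translate(ref_codon, table) == _translate(alt_codon, table)
        else "nonsynonymous"
    )
    return EffectCall(variant, effect, ref_codon, alt_codon, cds.locus_tag)


def classify_all_effects(
    variants: Iterable[VariantRecord],
    cpmap: CodonPositionMap,
    genome: Sequence[GenomeSequence],
    genetic_code: int = 4,
) -> list[EffectCall]:
    return [classify_variant_effect(v, cpmap, genome, genetic_code) for v in variants]


# ---------------------------------------------------------------------------
# Substitution spectrum
# ---------------------------------------------------------------------------


@dataclass
class SpectrumTable:
    """Counts of the six strand-collapsed single-base substitution classes.

    G>A and C>T are one class (GC>AT), etc.  ``gc_to_at_fraction`` is None
    when no substitutions were classified.
    """

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def gc_to_at_fraction(self) -> float | None:
        return self.counts["GC>AT"] / self.total if self.total else None


def substitution_spectrum(
    variants: Iterable[VariantRecord], genome: Sequence[GenomeSequence] | None = None
) -> SpectrumTable:
    """Tally single-base substitutions (after MNP decomposition) by class.

    Equal-length records are decomposed base-by-base; indels and
    length-changing records are ignored, as are changes involving N.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for v in variants:
        if len(v.ref_allele) != len(v.alt_allele):
            continue
        for _pos, r, a in _decompose_equal_length(v):
            cls = _CLASS_OF.get((r, a))
            if cls is not None:
                counts[cls] += 1
    return SpectrumTable(counts)


# ---------------------------------------------------------------------------
# One full comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    estimate: RateEstimate
    effects: list[EffectCall]
    spectrum: SpectrumTable
    n_retained_cds: int
    n_variants_in: int
    n_variants_masked: int


def run_rate_comparison(
    genome: Sequence[GenomeSequence],
    cpmap: CodonPositionMap,
    variants: Sequence[VariantRecord],
    depth_tracks: Sequence[DepthTrack],
    t_years: float,
    comparison_id: str,
    config: AnalysisConfig | None = None,
) -> ComparisonResult:
    """Run the whole per-comparison pipeline on one contig set.

    Steps: per-library coverage masks at ``min_depth`` -> intersection
    across libraries -> selection of entirely covered CDSs -> variant
    filtering by the mask -> third-position change counting -> rate.
    Effect classification and the substitution spectrum are computed on the
    mask-filtered variants.
    """
    config = config or AnalysisConfig()
    contig_ids = [g.contig_id for g in genome]

    k_total = 0
    L_total = 0
    retained_all: list[CdsFeature] = []
    kept_variants: list[VariantRecord] = []

    for cid in contig_ids:
        tracks = [t for t in depth_tracks if t.contig_id == cid]
        if not tracks:
            logger.warning("contig %s: no depth tracks, skipped", cid)
            continue
        masks = [build_coverage_mask(t, config.min_depth) for t in tracks]
        mask = intersect_masks(masks)
        cds_here = [c for c in cpmap.cds_list if c.contig_id == cid]
        retained = select_fully_covered_cds(cds_here, mask)
        retained_all.extend(retained)
        vars_here = [v for v in variants if v.contig_id == cid]
        kept = filter_variants_by_mask(vars_here, mask)
        kept_variants.extend(kept)
        k_total += count_third_position_changes(kept, cpmap, retained)
        L_total += count_third_position_sites(
            cpmap, retained, mask if config.denominator == "intersection" else None
        )

    estimate = estimate_rate(k_total, L_total, t_years, comparison_id)
    effects = classify_all_effects(kept_variants, cpmap, genome, config.genetic_code)
    spectrum = substitution_spectrum(kept_variants, genome)
    return ComparisonResult(
        estimate, effects, spectrum, len(retained_all), len(variants), len(kept_variants)
    )
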