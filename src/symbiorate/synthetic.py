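"""Synthetic genome-evolution fixtures with ground truth.

Generates the statistical structure the analyses assume — an AT-rich
annotated bacterial genome, lineages diverging for a known number of years
at a known per-site per-year rate with a GC>AT-biased spectrum, per-library
Poisson depth tracks with contiguous dropout segments, orthogroup length
erosion, and rearranged genome pairs with exact syntenic-block ground truth
— so every pipeline stage can be verified without external downloads.

All stochastic operations draw from one :class:`numpy.random.Generator`
seeded from ``SimulationConfig.seed``; the draw order within
:func:`generate_fixture_set` is fixed (genome, evolution, depth,
rearrangement, orthogroups), so a config and seed determine every output
byte.

The mutation model is single-hit: each site changes at most once per
comparison, a valid approximation while rate x years per site is well
below 1 (it is <= 1e-4 in all regimes simulated here).  Indel evolution,
sequencing error and read-level simulation are out of scope.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import (
    AlignmentHit,
    CdsFeature,
    DepthTrack,
    GenomeSequence,
    OrthogroupTable,
    VariantRecord,
    write_depth,
    write_fasta,
    write_gff3_cds,
    write_hits_table,
    write_orthogroups,
    write_vcf,
)
from .rate_pipeline import SPECTRUM_CLASSES, CodonPositionMap, build_codon_position_map

logger = logging.getLogger(__name__)

# alt base produced by each strand-collapsed class, given the reference base
_ALT_OF = {
    "G": {"GC>AT": "A", "GC>TA": "T", "GC>CG": "C"},
    "C": {"GC>AT": "T", "GC>TA": "A", "GC>CG": "G"},
    "A": {"AT>GC": "G", "AT>TA": "T", "AT>CG": "C"},
    "T": {"AT>GC": "C", "AT>TA": "A", "AT>CG": "G"},
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults emulate a reduced AT-rich endosymbiont chromosome: ~1 Mbp,
    800 CDSs (~72% coding), 27% GC, a third-position substitution rate of
    1e-5 per site per year observed over 10 years, and a spectrum with 60%
    of changes in the GC>AT class.  ``first_second_rate_fraction`` scales
    the rate at codon positions 1 and 2 relative to third/noncoding
    positions (purifying selection on amino-acid-changing sites).
    """

    genome_length: int = 1_000_000
    n_cds: int = 800
    gc_content: float = 0.27
    cds_length_range: tuple[int, int] = (300, 1500)  # multiples of 3
    rate_per_site_per_year: float = 1.0e-5
    years: float = 10.0
    first_second_rate_fraction: float = 0.5
    spectrum_weights: tuple[float, ...] = (0.60, 0.10, 0.05, 0.10, 0.10, 0.05)
    n_libraries: int = 3
    mean_depth: float = 20.0
    dropout_fraction: float = 0.05
    dropout_segment_len: int = 2000
    n_inversions: int = 5
    n_translocations: int = 2
    rearranged_segment_range: tuple[int, int] = (10_000, 40_000)
    identity_jitter: float = 0.0
    erosion_fraction: float = 0.10
    missing_fraction: float = 0.02
    genetic_code: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        w = np.asarray(self.spectrum_weights, dtype=float)
        if len(w) != 6 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("spectrum_weights must be 6 non-negative values summing to 1")
        lo, hi = self.cds_length_range
        if lo % 3 or hi % 3 or lo < 3 or hi < lo:
            raise ValueError("cds_length_range must be increasing multiples of 3")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Exact record of what the generator did, for verification."""

    true_variants: list[VariantRecord] = field(default_factory=list)
    true_effects: list[str] = field(default_factory=list)  # aligned with true_variants
    true_rate: float = 0.0
    true_blocks: list[dict] = field(default_factory=list)
    true_truncations: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Annotated genome
# ---------------------------------------------------------------------------


def simulate_annotated_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, list[CdsFeature]]:
    """I.i.d. nucleotide sequence at the target GC with non-overlapping CDSs.

    CDS lengths are multiples of 3 drawn uniformly from the configured
    range; features are placed left to right with random intergenic gaps
    (every gap at least 1 bp, so no two CDSs touch) and random strands.
    """
    rng = rng if rng is not None else config.rng()
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = bases[rng.choice(4, size=config.genome_length, p=probs)].tobytes().decode()

    lo, hi = config.cds_length_range
    lengths = rng.integers(lo // 3, hi // 3 + 1, size=config.n_cds) * 3
    slack = config.genome_length - int(lengths.sum())
    if slack < config.n_cds + 1:
        raise ValueError("infeasible packing: CDSs do not fit in the genome")
    gaps = rng.multinomial(slack - (config.n_cds + 1), [1 / (config.n_cds + 1)] * (config.n_cds + 1)) + 1

    features = []
    pos = 0
    for i in range(config.n_cds):
        pos += int(gaps[i])
        start, end = pos, pos + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            CdsFeature("chr1", start, end, strand, 0, f"SYN_{i:04d}", "hypothetical protein")
        )
        pos = end
    return GenomeSequence("chr1", seq, "circular"), features


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _translate(codon: str, table: CodonTable.CodonTable) -> str:
    return "*" if codon in table.stop_codons else table.forward_table.get(codon, "X")


def _effect_of_change(
    seq: str, cds: CdsFeature, pos: int, alt: str, table: CodonTable.CodonTable
) -> str:
    """Simulator-side syn/nonsyn bookkeeping for one substitution in a CDS."""
    if cds.strand == "+":
        off = (pos - cds.start) % 3
        cstart = pos - off
        ref_codon = seq[cstart : cstart + 3]
        alt_codon = ref_codon[:off] + alt + ref_codon[off + 1 :]
    else:
        off = (cds.end - 1 - pos) % 3
        cend = pos + off + 1
        fwd_ref = seq[cend - 3 : cend]
        fwd_alt = fwd_ref[: 2 - off] + alt + fwd_ref[3 - off :]
        ref_codon = str(Seq(fwd_ref).reverse_complement())
        alt_codon = str(Seq(fwd_alt).reverse_complement())
    return (
        "synonymous" if _translate(ref_codon, table) == _translate(alt_codon, table)
        else "nonsynonymous"
    )


def evolve_sequence(
    genome: GenomeSequence,
    cpmap: CodonPositionMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "evolved",
) -> tuple[GenomeSequence, GroundTruth]:
    """Mutate each site independently, at most one hit per site.

    The mean mutation probability over third-codon and noncoding positions
    is rate x years; positions 1 and 2 are scaled by
    ``first_second_rate_fraction``.  The substitution class is drawn from
    ``spectrum_weights`` conditioned on the reference base (a G or C site
    can only realize a GC>* class).  Per-site probabilities are weighted by
    (compatible-class weight / base-group composition), which makes the
    marginal class distribution of the realized changes equal
    ``spectrum_weights`` exactly while keeping the aggregate per-site rate
    at the configured value; a base group with zero total weight (e.g. A/T
    under an all-GC>AT spectrum) never mutates.
    """
    rng = rng if rng is not None else config.rng()
    table = CodonTable.unambiguous_dna_by_id[config.genetic_code]
    L = genome.length
    cp = cpmap.codon_pos[genome.contig_id]
    base_p = config.rate_per_site_per_year * config.years
    p = np.full(L, base_p)
    p[(cp == 1) | (cp == 2)] = base_p * config.first_second_rate_fraction

    w = np.asarray(config.spectrum_weights, dtype=float)
    w_gc, w_at = w[:3], w[3:]
    seq = np.frombuffer(genome.seq.encode(), dtype="S1").copy()
    is_gc = (seq == b"G") | (seq == b"C")
    is_at = (seq == b"A") | (seq == b"T")
    n_real = int(is_gc.sum() + is_at.sum())
    f_gc = is_gc.sum() / n_real if n_real else 0.0
    f_at = 1.0 - f_gc if n_real else 0.0
    mult = np.zeros(L)
    if w_gc.sum() > 0 and f_gc > 0:
        mult[is_gc] = w_gc.sum() / f_gc
    if w_at.sum() > 0 and f_at > 0:
        mult[is_at] = w_at.sum() / f_at
    p = np.clip(p * mult, 0.0, 1.0)

    hit = rng.random(L) < p
    truth = GroundTruth(true_rate=config.rate_per_site_per_year)
    for pos in np.where(hit)[0]:
        ref = seq[pos].decode()
        if ref in "GC":
            cls = SPECTRUM_CLASSES[rng.choice(3, p=w_gc / w_gc.sum())]
        else:
            cls = SPECTRUM_CLASSES[3 + rng.choice(3, p=w_at / w_at.sum())]
        alt = _ALT_OF[ref][cls]
        pos = int(pos)
        variant = VariantRecord(genome.contig_id, pos, ref, alt, "snp", sample_id)
        owner = cpmap.owner_cds(genome.contig_id, pos)
        effect = (
            _effect_of_change(genome.seq, owner, pos, alt, table) if owner is not None
            else "intergenic"
        )
        seq[pos] = alt.encode()
        truth.true_variants.append(variant)
        truth.true_effects.append(effect)
    evolved = GenomeSequence(genome.contig_id, seq.tobytes().decode(), genome.topology)
    return evolved, truth


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------


def simulate_depth_tracks(
    genome: GenomeSequence,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[DepthTrack]:
    """Per library: Poisson(mean_depth) per position, then contiguous
    dropout segments forced to zero until ``dropout_fraction`` of the
    genome is dark (segments may overlap, so realized dropout can be
    slightly below the target)."""
    rng = rng if rng is not None else config.rng()
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    L = genome.length
    tracks = []
    for lib in range(config.n_libraries):
        depth = rng.poisson(config.mean_depth, size=L)
        if config.dropout_fraction >= 1.0:
            depth[:] = 0
        elif config.dropout_fraction > 0:
            target = int(round(config.dropout_fraction * L))
            seg = min(config.dropout_segment_len, L)
            n_seg = max(1, target // seg)
            starts = rng.integers(0, max(1, L - seg + 1), size=n_seg)
            for s in starts:
                depth[s : s + seg] = 0
        tracks.append(DepthTrack(f"lib{lib + 1}", genome.contig_id, depth))
    return tracks


# ---------------------------------------------------------------------------
# Rearranged genome pairs
# ---------------------------------------------------------------------------


def simulate_rearranged_pair(
    genome: GenomeSequence,
    cds_list: Sequence[CdsFeature],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    b_contig_id: str = "chr1_B",
) -> tuple[GenomeSequence, list[CdsFeature], list[AlignmentHit], GroundTruth]:
    """Genome B from genome A by random non-overlapping inversions and
    translocations, with lifted CDSs, one alignment hit per true block, and
    the exact block coordinates as ground truth.

    The chosen segments partition A into 2n+1 fragments (n segments plus
    n+1 interior gaps); inverted segments are reverse-complemented in
    place, translocated segments are reinserted at a random other junction.
    Every fragment boundary is a rearrangement breakpoint, so the true
    syntenic blocks are exactly the fragments in their B order.  CDSs
    straddling a breakpoint are dropped from B's annotation with a log
    message.
    """
    rng = rng if rng is not None else config.rng()
    L = genome.length
    n = config.n_inversions + config.n_translocations

    if n == 0:
        hits = [_block_hit(genome.contig_id, b_contig_id, 0, L, 0, L, False, config, rng)]
        truth = GroundTruth(true_blocks=[
            {"a_contig": genome.contig_id, "a_start": 0, "a_end": L,
             "b_contig": b_contig_id, "b_start": 0, "b_end": L, "reverse": False}
        ])
        cds_b = [CdsFeature(b_contig_id, c.start, c.end, c.strand, c.phase,
                            c.locus_tag + "_B", c.product) for c in cds_list]
        return GenomeSequence(b_contig_id, genome.seq, genome.topology), cds_b, hits, truth

    lo, hi = config.rearranged_segment_range
    if n * lo + n + 1 > L:
        raise ValueError(
            "segments exhaust genome: "
            f"{n} segments of >= {lo} bp do not fit in {L} bp with interior gaps"
        )
    hi = min(hi, (L - (n + 1)) // n)
    seg_lengths = rng.integers(lo, hi + 1, size=n)
    slack = L - int(seg_lengths.sum())
    gaps = rng.multinomial(slack - (n + 1), [1 / (n + 1)] * (n + 1)) + 1

    # fragments in A order: gap0, seg1, gap1, ..., segn, gapn
    frags: list[tuple[int, int]] = []
    seg_frag_idx: list[int] = []
    pos = 0
    for i in range(n):
        pos_end = pos + int(gaps[i])
        frags.append((pos, pos_end))
        s_end = pos_end + int(seg_lengths[i])
        seg_frag_idx.append(len(frags))
        frags.append((pos_end, s_end))
        pos = s_end
    frags.append((pos, L))

    ops = np.array(["inv"] * config.n_inversions + ["trans"] * config.n_translocations)
    rng.shuffle(ops)

    order: list[tuple[int, int]] = [(i, +1) for i in range(len(frags))]  # (frag idx, orientation)
    for seg_i, op in zip(seg_frag_idx, ops):
        j = next(k for k, (fi, _o) in enumerate(order) if fi == seg_i)
        if op == "inv":
            order[j] = (seg_i, -1)
        else:
            entry = order.pop(j)
            choices = [k for k in range(len(order) + 1) if k != j]
            order.insert(int(rng.choice(choices)), entry)

    seq_parts = []
    cds_b: list[CdsFeature] = []
    truth = GroundTruth()
    hits: list[AlignmentHit] = []
    b_pos = 0
    for fi, orient in order:
        a_s, a_e = frags[fi]
        part = genome.seq[a_s:a_e]
        if orient < 0:
            part = str(Seq(part).reverse_complement())
        b_s, b_e = b_pos, b_pos + (a_e - a_s)
        seq_parts.append(part)
        truth.true_blocks.append(
            {"a_contig": genome.contig_id, "a_start": a_s, "a_end": a_e,
             "b_contig": b_contig_id, "b_start": b_s, "b_end": b_e, "reverse": orient < 0}
        )
        hits.append(_block_hit(genome.contig_id, b_contig_id, a_s, a_e, b_s, b_e,
                               orient < 0, config, rng))
        for cds in cds_list:
            if cds.start >= a_s and cds.end <= a_e:
                if orient > 0:
                    ns, ne, strand = b_s + (cds.start - a_s), b_s + (cds.end - a_s), cds.strand
                else:
                    ns = b_s + (a_e - cds.end)
                    ne = b_s + (a_e - cds.start)
                    strand = "-" if cds.strand == "+" else "+"
                cds_b.append(CdsFeature(b_contig_id, ns, ne, strand, cds.phase,
                                        cds.locus_tag + "_B", cds.product))
        b_pos = b_e

    dropped = len(cds_list) - len(cds_b)
    if dropped:
        logger.info("%d CDS(s) straddle rearrangement breakpoints, dropped from genome B", dropped)
    cds_b.sort(key=lambda c: c.start)
    genome_b = GenomeSequence(b_contig_id, "".join(seq_parts), genome.topology)
    return genome_b, cds_b, hits, truth


def _block_hit(
    a_contig: str, b_contig: str, a_s: int, a_e: int, b_s: int, b_e: int,
    reverse: bool, config: SimulationConfig, rng: np.random.Generator,
) -> AlignmentHit:
    length = a_e - a_s
    identity = 100.0
    if config.identity_jitter > 0:
        identity = float(np.clip(100.0 - abs(rng.normal(0, config.identity_jitter)), 0, 100))
    mismatches = int(round(length * (1 - identity / 100)))
    s_start, s_end = (b_e, b_s + 1) if reverse else (b_s + 1, b_e)
    return AlignmentHit(
        a_contig, b_contig, round(identity, 3), length, mismatches, 0,
        a_s + 1, a_e, s_start, s_end, 0.0, float(2 * length),
    )


# ---------------------------------------------------------------------------
# Orthogroup length erosion
# ---------------------------------------------------------------------------


def simulate_eroded_orthogroups(
    cds_list: Sequence[CdsFeature],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    strain_a: str = "A",
    strain_b: str = "B",
) -> tuple[OrthogroupTable, list[tuple[str, str]]]:
    """One orthogroup per CDS; strain B's copy is eroded in a random subset.

    Eroded copies keep 20-55% of the original length (well under the 60%
    truncation threshold); intact copies keep 80-100%.  A small fraction of
    orthogroups lack the strain-B member entirely (gene loss).  Returns the
    table and the ground-truth list of (orthogroup, strain) truncations.
    """
    rng = rng if rng is not None else config.rng()
    table = OrthogroupTable()
    truncated: list[tuple[str, str]] = []
    for i, cds in enumerate(cds_list):
        og = f"OG{i:05d}"
        table.add(og, strain_a, cds.locus_tag, cds.length)
        u = rng.random()
        if u < config.missing_fraction:
            continue
        if u < config.missing_fraction + config.erosion_fraction:
            ratio = rng.uniform(0.20, 0.55)
            truncated.append((og, strain_b))
        else:
            ratio = rng.uniform(0.80, 1.00)
        table.add(og, strain_b, cds.locus_tag + "_B", max(3, int(cds.length * ratio)))
    return table, truncated


# ---------------------------------------------------------------------------
# Fixture sets on disk
# ---------------------------------------------------------------------------


@dataclass
class FixtureSet:
    config: SimulationConfig
    genome: GenomeSequence
    cds_list: list[CdsFeature]
    cpmap: CodonPositionMap
    evolved: GenomeSequence
    depth_tracks: list[DepthTrack]
    genome_b: GenomeSequence
    cds_b: list[CdsFeature]
    synteny_hits: list[AlignmentHit]
    orthogroups: OrthogroupTable
    truth: GroundTruth


def generate_fixture_set(config: SimulationConfig) -> FixtureSet:
    """Generate every fixture from one seeded generator in a fixed order."""
    rng = config.rng()
    genome, cds_list = simulate_annotated_genome(config, rng)
    cpmap = build_codon_position_map([genome], cds_list)
    evolved, truth = evolve_sequence(genome, cpmap, config, rng)
    tracks = simulate_depth_tracks(genome, config, rng)
    genome_b, cds_b, hits, block_truth = simulate_rearranged_pair(genome, cds_list, config, rng)
    orthogroups, truncations = simulate_eroded_orthogroups(cds_list, config, rng)
    truth.true_blocks = block_truth.true_blocks
    truth.true_truncations = truncations
    return FixtureSet(config, genome, cds_list, cpmap, evolved, tracks,
                      genome_b, cds_b, hits, orthogroups, truth)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_set(fixtures: FixtureSet, directory: str | Path) -> dict:
    """Write all fixtures as standard text formats plus a JSON manifest.

    The manifest lists every file with its sha256 checksum, echoes the
    config and seed, and records the ground truth (variants are in the VCF;
    blocks and truncations inline).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fx = fixtures
    contig_len = {fx.genome.contig_id: fx.genome.length}

    paths = {}
    paths["reference.fasta"] = directory / "reference.fasta"
    write_fasta([fx.genome], paths["reference.fasta"])
    paths["reference.gff3"] = directory / "reference.gff3"
    write_gff3_cds(fx.cds_list, paths["reference.gff3"])
    paths["evolved.vcf"] = directory / "evolved.vcf"
    write_vcf(fx.truth.true_variants, contig_len, paths["evolved.vcf"])
    for t in fx.depth_tracks:
        name = f"depth_{t.sample_id}.tsv"
        paths[name] = directory / name
        write_depth([t], paths[name])
    paths["genome_b.fasta"] = directory / "genome_b.fasta"
    write_fasta([fx.genome_b], paths["genome_b.fasta"])
    paths["genome_b.gff3"] = directory / "genome_b.gff3"
    write_gff3_cds(fx.cds_b, paths["genome_b.gff3"])
    paths["synteny_hits.tsv"] = directory / "synteny_hits.tsv"
    write_hits_table(fx.synteny_hits, paths["synteny_hits.tsv"])
    paths["orthogroups.tsv"] = directory / "orthogroups.tsv"
    write_orthogroups(fx.orthogroups, paths["orthogroups.tsv"])

    manifest = {
        "config": asdict(fx.config),
        "seed": fx.config.seed,
        "files": {name: _sha256(p) for name, p in sorted(paths.items())},
        "ground_truth": {
            "true_rate": fx.truth.true_rate,
            "n_true_variants": len(fx.truth.true_variants),
            "true_effects": fx.truth.true_effects,
            "true_blocks": fx.truth.true_blocks,
            "true_truncations": [list(t) for t in fx.truth.true_truncations],
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
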