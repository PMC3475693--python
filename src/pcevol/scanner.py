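"""Detect miR482-related polycistrons in EST/contig sequences.

A hit requires two homologous precursor-like regions clustered on the
same strand — within 2000 nt for genomic contigs — whose mutual p-distance
is at most 0.40 (the observed distance between the two precursors of the
polycistron sets this threshold), with both regions passing a hairpin
plausibility check in the spirit of the community criteria for annotating
plant miRNAs (single dominant stem, a well-paired ~21-nt duplex window
with limited consecutive mismatches, negative folding energy).

Candidate matches are found by infix (semi-global) edit-distance alignment
of the query precursor against both strands, iteratively masking each
match to find the next one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio import Align

from .core_io import SequenceRecord, revcomp
from .rna import EnergyModel, fold


@dataclass(frozen=True)
class ScannerConfig:
    max_pair_distance: float = 0.40  # p-distance between the two regions
    max_separation: int = 2000  # nt between the two regions (contigs)
    max_match_distance: float = 0.45  # cap for reporting a raw query match
    max_matches_per_strand: int = 8
    # hairpin criteria
    hairpin_min_len: int = 60
    hairpin_max_len: int = 400
    duplex_length: int = 21
    max_duplex_mismatches: int = 5
    max_consecutive_mismatches: int = 3
    max_duplex_asymmetry: int = 3  # extra unpaired nt on the partner arm
    min_stem_fraction: float = 0.8  # pairs in the dominant stem / all pairs
    # the stem must hold a mature duplex plus the ~15-bp lower stem that
    # precursor processing requires: (21 - 5) + 15
    min_stem_pairs: int = 31

    def __post_init__(self) -> None:
        if not (0 < self.max_pair_distance < 1):
            raise ValueError("max_pair_distance must be in (0, 1)")
        if self.max_separation <= 0:
            raise ValueError("max_separation must be positive")


@dataclass
class HairpinCheck:
    passed: bool
    energy: float = 0.0
    n_pairs: int = 0
    stem_fraction: float = 0.0
    best_window_mismatches: int | None = None
    reason: str = ""


@dataclass(frozen=True)
class PolycistronHit:
    sequence_id: str
    strand: str
    interval_a: tuple[int, int]  # forward-strand coordinates
    interval_b: tuple[int, int]
    p_distance: float
    separation: int
    hairpin_a: HairpinCheck = field(compare=False, default=None)
    hairpin_b: HairpinCheck = field(compare=False, default=None)


def _find_matches(
    sequence: str, query: str, config: ScannerConfig
) -> list[tuple[int, int, int]]:
    """Non-overlapping infix matches of *query*: (start, end, edit_distance)."""
    seq = sequence
    out = []
    max_ed = int(config.max_match_distance * len(query))
    for _ in range(config.max_matches_per_strand):
        res = edlib.align(query, seq, mode="HW", task="locations", k=max_ed)
        if res["editDistance"] < 0:
            break
        s, e = res["locations"][0]
        e += 1  # edlib end is inclusive
        out.append((s, e, res["editDistance"]))
        seq = seq[:s] + "X" * (e - s) + seq[e:]
    out.sort()
    return out


def region_p_distance(seq_a: str, seq_b: str) -> float:
    """p-distance between two regions from their affine-gap global
    alignment, gap columns excluded.

    Affine penalties matter here: unit-cost edit alignments hide divergence
    inside gaps, deflating the apparent p-distance of diverged regions.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    best = aligner.align(seq_a, seq_b)[0]
    matches = mismatches = 0
    for (ts, te), (qs, qe) in zip(*best.aligned):
        for x, y in zip(seq_a[ts:te], seq_b[qs:qe]):
            if x == y:
                matches += 1
            else:
                mismatches += 1
    total = matches + mismatches
    return mismatches / total if total else 1.0


def _query_column_map(query: str, region: str) -> dict[int, str]:
    """Map query positions to the region bases aligned to them (affine NW)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    best = aligner.align(query, region)[0]
    out: dict[int, str] = {}
    for (qs, qe), (rs, re) in zip(*best.aligned):
        for k in range(qe - qs):
            out[qs + k] = region[rs + k]
    return out


def projected_p_distance(query: str, region_a: str, region_b: str) -> float:
    """p-distance between two regions, site-wise through the query anchor.

    Both regions are aligned to the query they matched; bases facing the
    same query position are compared.  Anchoring the comparison prevents a
    direct region-vs-region alignment from hiding divergence in gaps when
    the regions are self-similar (hairpins nearly are their own reverse
    complement).
    """
    map_a = _query_column_map(query, region_a)
    map_b = _query_column_map(query, region_b)
    shared = set(map_a) & set(map_b)
    if not shared:
        return 1.0
    diffs = sum(1 for q in shared if map_a[q] != map_b[q])
    return diffs / len(shared)


def offset_p_distance(region_a: str, region_b: str, min_overlap_frac: float = 0.9) -> float:
    """p-distance at the identity-maximising ungapped offset of two regions.

    Gapped estimators systematically understate the divergence of
    self-similar hairpin regions (the aligner shifts one arm onto the
    other); since the regions compared here evolve essentially without
    indels, a sliding ungapped comparison with near-full overlap is the
    robust estimator.
    """
    from .evodistance import best_offset_identity

    min_overlap = int(min_overlap_frac * min(len(region_a), len(region_b)))
    cmp = best_offset_identity(region_a, region_b, min_overlap=max(min_overlap, 1))
    return (cmp.compared_sites - cmp.identities) / cmp.compared_sites


def hairpin_check(
    candidate: str,
    config: ScannerConfig = ScannerConfig(),
    model: EnergyModel | None = None,
) -> HairpinCheck:
    """Plausibility check that a region can fold into a miRNA-like hairpin.

    Pass criteria: negative folding energy; one stem holds at least
    ``min_stem_fraction`` of all pairs; and some ``duplex_length`` window
    pairs into a single opposite arm with at most ``max_duplex_mismatches``
    unpaired positions and no more than ``max_consecutive_mismatches`` in a
    row.
    """
    candidate = candidate.upper().replace("T", "U")
    n = len(candidate)
    if not (config.hairpin_min_len <= n <= config.hairpin_max_len):
        return HairpinCheck(False, reason=f"length {n} outside candidate range")
    result = fold(candidate, model)
    structure = result.structure
    if result.energy >= 0 or structure.n_pairs == 0:
        return HairpinCheck(
            False, energy=result.energy, n_pairs=structure.n_pairs,
            reason="no stable structure",
        )
    pt = structure.pair_table
    # single stem = the nested chain of pairs walked from a top-level pair
    # through interior loops only; a multibranch loop ends the stem.  A true
    # stem-loop precursor keeps ~all pairs in one such chain, while random
    # sequences scatter pairs over multiloops and separate branches.
    def chain_pairs(i: int, j: int) -> set[tuple[int, int]]:
        chain = set()
        while True:
            chain.add((i, j))
            kids = []
            k = i + 1
            while k < j:
                if pt[k] > k:
                    kids.append((k, pt[k]))
                    k = pt[k] + 1
                else:
                    k += 1
            if len(kids) != 1:
                return chain
            i, j = kids[0]

    top = []
    k = 0
    while k < n:
        if pt[k] > k:
            top.append((k, pt[k]))
            k = pt[k] + 1
        else:
            k += 1
    best_chain: set[tuple[int, int]] = max(
        (chain_pairs(i, j) for i, j in top), key=len
    )
    stem_fraction = len(best_chain) / structure.n_pairs
    stem_positions = {p for ij in best_chain for p in ij}
    if len(best_chain) < config.min_stem_pairs:
        return HairpinCheck(
            False, energy=result.energy, n_pairs=structure.n_pairs,
            stem_fraction=stem_fraction,
            reason=f"stem too short ({len(best_chain)} < {config.min_stem_pairs} pairs)",
        )
    if stem_fraction < config.min_stem_fraction:
        return HairpinCheck(
            False, energy=result.energy, n_pairs=structure.n_pairs,
            stem_fraction=stem_fraction, reason="no dominant stem",
        )
    # duplex window: well-paired within the stem, partners monotone on a
    # single opposite arm (positions paired outside the stem count as
    # mismatches)
    W = config.duplex_length
    best_mm: int | None = None
    for start in range(0, n - W + 1):
        mm = consec = max_consec = 0
        partners = []
        for i in range(start, start + W):
            if pt[i] == -1 or i not in stem_positions:
                mm += 1
                consec += 1
                max_consec = max(max_consec, consec)
            else:
                partners.append(pt[i])
                consec = 0
        if not partners:
            continue
        # all partners on one side of the window, antiparallel
        if not (max(partners) < start or min(partners) >= start + W):
            continue
        if any(b >= a for a, b in zip(partners, partners[1:])):
            continue
        asymmetry = (max(partners) - min(partners) + 1) - len(partners)
        if (
            mm <= config.max_duplex_mismatches
            and max_consec <= config.max_consecutive_mismatches
            and asymmetry <= config.max_duplex_asymmetry
        ):
            if best_mm is None or mm < best_mm:
                best_mm = mm
    passed = best_mm is not None
    return HairpinCheck(
        passed=passed,
        energy=result.energy,
        n_pairs=structure.n_pairs,
        stem_fraction=stem_fraction,
        best_window_mismatches=best_mm,
        reason="" if passed else "no well-paired duplex window",
    )


def scan(
    sequence: SequenceRecord | str,
    query_precursor: str,
    config: ScannerConfig = ScannerConfig(),
    model: EnergyModel | None = None,
) -> list[PolycistronHit]:
    """Find clustered precursor + homolog pairs in one sequence.

    Both strands are searched; hit coordinates always refer to the forward
    strand, sorted by position.
    """
    if isinstance(sequence, SequenceRecord):
        seq_id, seq = sequence.id, sequence.residues
    else:
        seq_id, seq = "query", sequence.upper().replace("T", "U")
    query = query_precursor.upper().replace("T", "U")
    if len(seq) < len(query):
        return []
    hits: list[PolycistronHit] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        matches = _find_matches(s, query, config)
        for ai in range(len(matches)):
            for bi in range(ai + 1, len(matches)):
                (s1, e1, _), (s2, e2, _) = matches[ai], matches[bi]
                separation = s2 - e1
                if separation > config.max_separation:
                    continue
                p = offset_p_distance(s[s1:e1], s[s2:e2])
                if p > config.max_pair_distance:
                    continue
                ha = hairpin_check(s[s1:e1], config, model)
                hb = hairpin_check(s[s2:e2], config, model)
                if not (ha.passed and hb.passed):
                    continue
                iv_a, iv_b = (s1, e1), (s2, e2)
                if strand == "-":
                    n = len(seq)
                    iv_a = (n - e1, n - s1)
                    iv_b = (n - e2, n - s2)
                    iv_a, iv_b = min(iv_a, iv_b), max(iv_a, iv_b)
                hits.append(
                    PolycistronHit(
                        sequence_id=seq_id,
                        strand=strand,
                        interval_a=iv_a,
                        interval_b=iv_b,
                        p_distance=p,
                        separation=separation,
                        hairpin_a=ha,
                        hairpin_b=hb,
                    )
                )
    # hairpins are near-palindromic, so the same locus is often matched on
    # both strands with slightly shifted boundaries: deduplicate by overlap
    def _overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
        inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
        return inter / max(a[1] - a[0], b[1] - b[0], 1)

    hits.sort(key=lambda h: (h.p_distance, 0 if h.strand == "+" else 1))
    kept: list[PolycistronHit] = []
    for h in hits:
        if any(
            _overlap(h.interval_a, k.interval_a) > 0.5
            and _overlap(h.interval_b, k.interval_b) > 0.5
            for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.interval_a, h.interval_b))
    return kept


def scan_library(
    records: list[SequenceRecord],
    query_precursor: str,
    config: ScannerConfig = ScannerConfig(),
    model: EnergyModel | None = None,
) -> list[PolycistronHit]:
    """Scan a whole EST/contig library."""
    out: list[PolycistronHit] = []
    for rec in records:
        out.extend(scan(rec, query_precursor, config, model))
    return out
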