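"""Five-region anatomy of a MIR482-MIR1448 polycistron.

A polycistron record is annotated by projecting reference precursor
sequences onto it with affine-gap local alignment: the two precursor
intervals, the internal region between them, and the 5'/3' flanks.
Packaged default references are synthetic hairpin constructs around the
published mature sequences (user-replaceable with real precursors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

from Bio import Align

from .core_io import SequenceRecord, read_fasta, revcomp

log = logging.getLogger(__name__)

REGION_ORDER = ("flank5", "pre482", "internal", "pre1448", "flank3")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class PrecursorMatch:
    found: bool
    interval: tuple[int, int] = (0, 0)  # on the forward strand of the query
    identity: float = 0.0
    p_distance: float = 1.0
    strand: str = "+"
    score: float = 0.0


@dataclass(frozen=True)
class RegionAnnotation:
    region: str  # one of REGION_ORDER
    interval: tuple[int, int]
    reference_identity: float  # 1.0 for regions without a reference

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class AnnotatedPolycistron:
    record: SequenceRecord
    regions: dict[str, RegionAnnotation]

    def __post_init__(self) -> None:
        pos = 0
        for name in REGION_ORDER:
            r = self.regions[name]
            if r.interval[0] != pos:
                raise AnnotationError(
                    f"region {name} starts at {r.interval[0]}, expected {pos}"
                )
            pos = r.interval[1]
        if pos != len(self.record):
            raise AnnotationError(
                f"regions cover {pos} nt of a {len(self.record)} nt record"
            )

    @property
    def region_lengths(self) -> tuple[int, ...]:
        return tuple(self.regions[n].length for n in REGION_ORDER)

    def to_bed_rows(self) -> list[tuple[str, int, int, str]]:
        return [
            (self.record.id, *self.regions[n].interval, n) for n in REGION_ORDER
        ]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -4.0
    a.extend_gap_score = -1.0
    return a


def _align_one_strand(sequence: str, reference: str) -> tuple[float, tuple[int, int], int, int]:
    """Best local alignment; returns (score, target_interval, matches, aligned_cols)."""
    aligner = _aligner()
    alignments = aligner.align(sequence, reference)
    if len(alignments) == 0:
        return -1.0, (0, 0), 0, 0
    best = alignments[0]
    matches = 0
    cols = 0
    for (ts, te), (qs, qe) in zip(*best.aligned):
        cols += te - ts
        matches += sum(
            1 for x, y in zip(sequence[ts:te], reference[qs:qe]) if x == y
        )
    t_blocks = best.aligned[0]
    interval = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    return float(best.score), interval, matches, cols


def locate_precursor(
    sequence: str | SequenceRecord,
    reference_precursor: str,
    max_distance: float = 0.40,
    search_reverse: bool = True,
    min_coverage: float = 0.6,
) -> PrecursorMatch:
    """Locate the best local match of a reference precursor in a sequence.

    The match must have a p-distance (mismatches over aligned, ungapped
    columns) of at most *max_distance* and span at least *min_coverage* of
    the reference (short spurious local matches are rejected); otherwise a
    not-found result is returned.  Both strands are searched unless
    *search_reverse* is off; the interval always refers to the forward
    strand.
    """
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else sequence
    seq = seq.upper().replace("T", "U")
    ref = reference_precursor.upper().replace("T", "U")
    if not ref:
        raise AnnotationError("reference precursor must be non-empty")
    candidates = [("+", seq)]
    if search_reverse:
        candidates.append(("-", revcomp(seq)))
    best: PrecursorMatch | None = None
    for strand, s in candidates:
        score, interval, matches, cols = _align_one_strand(s, ref)
        if cols < min_coverage * len(ref):
            continue
        if strand == "-":
            interval = (len(seq) - interval[1], len(seq) - interval[0])
        m = PrecursorMatch(
            found=True,
            interval=interval,
            identity=matches / cols,
            p_distance=1.0 - matches / cols,
            strand=strand,
            score=score,
        )
        if best is None or m.score > best.score:
            best = m
    if best is None or best.p_distance > max_distance:
        return PrecursorMatch(found=False)
    return best


def annotate_polycistron(
    record: SequenceRecord | str,
    ref_pre482: str | None = None,
    ref_pre1448: str | None = None,
    max_distance: float = 0.40,
) -> AnnotatedPolycistron:
    """Assign the five-region anatomy of a polycistron record.

    Both precursors must be locatable on the same strand with pre-miR482
    upstream of pre-miR1448; a record matching on the reverse strand is
    reverse-complemented before annotation (logged).
    """
    if isinstance(record, str):
        record = SequenceRecord.from_raw("query", record)
    if ref_pre482 is None or ref_pre1448 is None:
        d482, d1448 = default_references()
        ref_pre482 = ref_pre482 or d482.residues
        ref_pre1448 = ref_pre1448 or d1448.residues
    m482 = locate_precursor(record, ref_pre482, max_distance)
    m1448 = locate_precursor(record, ref_pre1448, max_distance)
    if not (m482.found and m1448.found):
        missing = [
            n for n, m in (("pre482", m482), ("pre1448", m1448)) if not m.found
        ]
        raise AnnotationError(
            f"precursor(s) {missing} not found within p-distance {max_distance}"
        )
    if m482.strand != m1448.strand:
        raise AnnotationError("precursors match on opposite strands")
    if m482.strand == "-":
        log.info("record %s matches on the reverse strand; reverse-complementing", record.id)
        return annotate_polycistron(
            record.reverse_complement(), ref_pre482, ref_pre1448, max_distance
        )
    (s4, e4), (s1, e1) = m482.interval, m1448.interval
    if max(s4, s1) < min(e4, e1):
        raise AnnotationError(
            f"precursor intervals {m482.interval} / {m1448.interval} overlap"
        )
    if s1 < s4:
        raise AnnotationError(
            f"wrong order: pre1448 at {m1448.interval} lies upstream of "
            f"pre482 at {m482.interval}"
        )
    n = len(record)
    regions = {
        "flank5": RegionAnnotation("flank5", (0, s4), 1.0),
        "pre482": RegionAnnotation("pre482", (s4, e4), m482.identity),
        "internal": RegionAnnotation("internal", (e4, s1), 1.0),
        "pre1448": RegionAnnotation("pre1448", (s1, e1), m1448.identity),
        "flank3": RegionAnnotation("flank3", (e1, n), 1.0),
    }
    return AnnotatedPolycistron(record=record, regions=regions)


def default_references() -> tuple[SequenceRecord, SequenceRecord]:
    """Packaged synthetic pre-miR482 / pre-miR1448 reference hairpins."""
    out = []
    for name in ("synthetic_pre_mir482.fa", "synthetic_pre_mir1448.fa"):
        with resources.as_file(resources.files("pcevol.data").joinpath(name)) as p:
            out.append(read_fasta(p)[0])
    return out[0], out[1]
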