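"""Synthetic data: polycistron alignments, EST libraries and CDS target sets.

Everything the analysis stages consume can be generated here with known
ground truth, so the whole pipeline is testable without downloads.  The
defaults emulate the study system: a five-region polycistron
(92/107/80/85/628 nt) whose regions evolve at the observed region-specific
rates (0.066/0.014/0.006/0.016/0.060 substitutions per site between
sequence pairs), precursor hairpins whose mature:star duplex is perfectly
paired, an internal region that folds back on itself, and a tunable
compensatory coupling ``c`` that re-pairs the partner of a mutated stem
site with probability ``c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import dendropy

from .core_io import Alignment, SequenceRecord, revcomp
from .rna import SecondaryStructure, can_pair

MIR482_2 = "UCUUGCCUACUCCUCCCAUU"  # published mature miR482.2
MIR1448 = "CUUUCCAACGCCUCCCAUAC"  # published mature miR1448

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_PAIR_CHOICES = {"A": ["U"], "U": ["A", "G"], "G": ["C", "U"], "C": ["G"]}
_TRANSITION = {"A": "G", "G": "A", "C": "U", "U": "C"}
_TRANSVERSIONS = {"A": "CU", "G": "CU", "C": "AG", "U": "AG"}
_BASES = "ACGU"


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# hairpin construction


@dataclass
class HairpinDesign:
    sequence: str
    structure: SecondaryStructure
    mature_interval: tuple[int, int]
    stem_pairs: list[tuple[int, int]]  # paired positions, local coordinates


def build_hairpin_precursor(
    mature: str,
    total_length: int,
    rng: np.random.Generator,
    loop_length: int = 7,
    lower_gc: float = 0.25,
) -> HairpinDesign:
    """Design a precursor hairpin around a mature sequence.

    Layout: 5' lower-stem arm | mature | loop | mature* | lower-stem arm 3'.
    The mature:star (upper stem) duplex is perfectly complementary; the
    lower stem is AU-biased (*lower_gc*), making it thermodynamically
    weaker than the upper stem, as in real pre-miR482/pre-miR1448 hairpins.
    """
    m = len(mature)
    stem = (total_length - 2 * m - loop_length) // 2
    loop = total_length - 2 * m - 2 * stem
    if stem < 4 or loop < 3:
        raise SimulationError(
            f"total_length {total_length} too short for a {m}-nt mature duplex"
        )
    probs = np.array(
        [(1 - lower_gc) / 2, lower_gc / 2, lower_gc / 2, (1 - lower_gc) / 2]
    )
    arm = "".join(rng.choice(list(_BASES), size=stem, p=probs))
    loop_seq = "".join(rng.choice(list(_BASES), size=loop))
    seq = arm + mature + loop_seq + revcomp(mature) + revcomp(arm)
    pairs = [(i, len(seq) - 1 - i) for i in range(stem + m)]
    structure = SecondaryStructure.from_pairs(len(seq), pairs)
    return HairpinDesign(
        sequence=seq,
        structure=structure,
        mature_interval=(stem, stem + m),
        stem_pairs=pairs,
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n)) if n else ""


# ---------------------------------------------------------------------------
# polycistron alignment simulation


@dataclass
class SynthConfig:
    """Study conditions for polycistron alignment simulation."""

    tree: str = "star:20"  # "star:n" or a newick string
    region_lengths: tuple[int, ...] = (92, 107, 80, 85, 628)
    region_rates: tuple[float, ...] = (0.066, 0.014, 0.006, 0.016, 0.060)
    coupling: float = 0.0  # compensatory coupling c in [0, 1]
    kappa: float = 2.0  # transition:transversion rate ratio
    seed: int = 0
    loop_length: int = 7
    internal_stem: int = 30  # arm length of the internal-region foldback

    def __post_init__(self) -> None:
        if not (0 <= self.coupling <= 1):
            raise SimulationError("coupling must be in [0, 1]")
        if any(r < 0 for r in self.region_rates):
            raise SimulationError("rates must be >= 0")
        if any(l < 0 for l in self.region_lengths):
            raise SimulationError("lengths must be >= 0")


@dataclass
class SimulatedPolycistron:
    alignment: Alignment
    root: str
    regions: dict[str, tuple[int, int]]  # true region intervals (columns)
    structures: dict[str, SecondaryStructure]  # true structure per region
    stem_pairs: list[tuple[int, int]]  # global coordinates, precursor stems
    mature_intervals: dict[str, tuple[int, int]]


def _k2p_substitute(
    base: str, d: float, kappa: float, rng: np.random.Generator
) -> str:
    """One K2P draw for a branch of expected *d* substitutions per site."""
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e1 = math.exp(-4.0 * bt)
    e2 = math.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    u = rng.random()
    if u < p_ts:
        return _TRANSITION[base]
    if u < p_ts + 2 * p_tv:
        return _TRANSVERSIONS[base][0 if u < p_ts + p_tv else 1]
    return base


def _parse_tree(spec: str, seed_names: bool = True):
    """Return list of (taxon, branch_path) where branch_path is a list of
    (branch_length,) segments from root to tip; star trees shortcut."""
    if spec.startswith("star:"):
        n = int(spec.split(":", 1)[1])
        return [(f"taxon{i:02d}", [0.5]) for i in range(n)]
    tree = dendropy.Tree.get(data=spec, schema="newick")
    out = []
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(node.edge.length or 0.0)
            node = node.parent_node
        out.append((leaf.taxon.label, list(reversed(path))))
    return out


def simulate_polycistron_alignment(config: SynthConfig) -> SimulatedPolycistron:
    """Evolve a five-region polycistron along a tree.

    Per-region rates are calibrated so that the expected pairwise distance
    between two tips equals the configured rate (each star branch carries
    half).  When a stem site mutates, its partner simultaneously receives a
    re-pairing substitution with probability ``c`` (sampled uniformly among
    canonical partners of the new base, G:U included).
    """
    rng = np.random.default_rng(config.seed)
    L = config.region_lengths
    names = ("flank5", "pre482", "internal", "pre1448", "flank3")
    matures = {"pre482": MIR482_2, "pre1448": MIR1448}

    blocks: dict[str, str] = {}
    structures: dict[str, SecondaryStructure] = {}
    mature_intervals: dict[str, tuple[int, int]] = {}
    local_stem_pairs: dict[str, list[tuple[int, int]]] = {}
    for name, n in zip(names, L):
        if name in matures and n > 0:
            design = build_hairpin_precursor(
                matures[name], n, rng, loop_length=config.loop_length
            )
            blocks[name] = design.sequence
            structures[name] = design.structure
            mature_intervals[name] = design.mature_interval
            local_stem_pairs[name] = design.stem_pairs
        elif name == "internal" and n >= 2 * 8 + 3:
            arm = min(config.internal_stem, (n - 3) // 2)
            core = _random_seq(rng, arm)
            mid = _random_seq(rng, n - 2 * arm)
            blocks[name] = core + mid + revcomp(core)
            structures[name] = SecondaryStructure.from_pairs(
                n, [(i, n - 1 - i) for i in range(arm)]
            )
        else:
            blocks[name] = _random_seq(rng, n)
            if n:
                structures[name] = SecondaryStructure.from_pairs(n, [])

    offsets: dict[str, int] = {}
    pos = 0
    regions: dict[str, tuple[int, int]] = {}
    for name, n in zip(names, L):
        offsets[name] = pos
        regions[name] = (pos, pos + n)
        pos += n
    root = "".join(blocks[name] for name in names)

    stem_pairs = [
        (offsets[name] + i, offsets[name] + j)
        for name in ("pre482", "pre1448")
        if name in local_stem_pairs
        for i, j in local_stem_pairs[name]
    ]
    partner = {}
    for i, j in stem_pairs:
        partner[i] = j
        partner[j] = i

    site_rate = np.empty(len(root))
    for name, rate in zip(names, config.region_rates):
        s, e = regions[name]
        site_rate[s:e] = rate

    tips = _parse_tree(config.tree)
    records = []
    for taxon, path in tips:
        seq = list(root)
        for blen in path:
            forced: set[int] = set()
            for i in range(len(seq)):
                if i in forced:
                    continue
                new = _k2p_substitute(seq[i], blen * site_rate[i], config.kappa, rng)
                if new == seq[i]:
                    continue
                seq[i] = new
                j = partner.get(i)
                if j is not None and rng.random() < config.coupling:
                    # simultaneous re-pairing substitution at the partner
                    seq[j] = str(rng.choice(_PAIR_CHOICES[new]))
                    if j > i:
                        forced.add(j)
        records.append(SequenceRecord(id=taxon, residues="".join(seq)))

    return SimulatedPolycistron(
        alignment=Alignment(records),
        root=root,
        regions=regions,
        structures=structures,
        stem_pairs=stem_pairs,
        mature_intervals=mature_intervals,
    )


# ---------------------------------------------------------------------------
# EST library simulation


def mutate_sequence(
    seq: str, divergence: float, rng: np.random.Generator
) -> str:
    """Substitute an exact count round(divergence * len) of distinct sites."""
    if not (0 <= divergence < 1):
        raise SimulationError("divergence must be in [0, 1)")
    k = round(divergence * len(seq))
    sites = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for i in sites:
        out[i] = str(rng.choice([b for b in _BASES if b != out[i]]))
    return "".join(out)


def mutate_preserving_pairs(
    seq: str,
    divergence: float,
    rng: np.random.Generator,
    pairs: list[tuple[int, int]] | None = None,
) -> str:
    """Diverge a hairpin sequence while keeping its stems paired.

    Exactly round(divergence * len) sites are changed, but substitutions at
    paired positions are compensatory: the partner simultaneously receives a
    re-pairing base (G:U allowed).  This emulates how real precursor
    homologs diverge — under selection for the hairpin — so a diverged
    homolog still satisfies miRNA hairpin criteria, unlike a randomly
    mutated copy.  *pairs* defaults to the pairs of the folded input.
    """
    if not (0 <= divergence < 1):
        raise SimulationError("divergence must be in [0, 1)")
    if pairs is None:
        from .rna import fold as _fold

        pairs = _fold(seq).structure.pairs
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    k = round(divergence * len(seq))
    out = list(seq)
    changed: set[int] = set()
    order = [int(x) for x in rng.permutation(len(seq))]
    for i in order:
        if len(changed) >= k:
            break
        if i in changed:
            continue
        j = partner.get(i)
        budget = k - len(changed)
        if j is None or j in changed:
            out[i] = str(rng.choice([b for b in _BASES if b != out[i]]))
            changed.add(i)
        elif budget >= 2:
            new = str(rng.choice([b for b in _BASES if b != out[i]]))
            out[i] = new
            re_pair = [b for b in _PAIR_CHOICES[new] if b != out[j]]
            if re_pair:
                out[j] = str(rng.choice(re_pair))
                changed.add(j)
            changed.add(i)
        else:
            # last change: prefer a single re-pairing substitution (wobble)
            single = [
                b for b in _BASES
                if b != out[i] and out[j] in _PAIR_CHOICES.get(b, [])
            ]
            if single:
                out[i] = str(rng.choice(single))
                changed.add(i)
    return "".join(out)


@dataclass
class SimulatedESTLibrary:
    records: list[SequenceRecord]
    truth: pd.DataFrame  # est_id, planted, intervals and divergence


def simulate_est_library(
    query_precursor: str,
    n: int = 40,
    length_range: tuple[int, int] = (800, 1500),
    planted_fraction: float = 0.5,
    divergence: float = 0.2,
    separation: int = 80,
    seed: int = 0,
    preserve_structure: bool = True,
) -> SimulatedESTLibrary:
    """EST-like sequences, a fraction carrying a planted polycistron.

    A planted EST embeds an exact copy of the query precursor, a spacer of
    *separation* random nt, and a homolog at the stated divergence.  By
    default the homolog diverges structure-aware (compensatory stem
    substitutions, :func:`mutate_preserving_pairs`), matching how real
    precursor paralogs keep their hairpins; set *preserve_structure* off
    for unconstrained substitutions.
    """
    rng = np.random.default_rng(seed)
    q = len(query_precursor)
    query_pairs = None
    if preserve_structure:
        from .rna import fold as _fold

        query_pairs = _fold(query_precursor).structure.pairs
    need = 2 * q + separation + 40
    if length_range[0] < need:
        raise SimulationError(
            f"minimum EST length {length_range[0]} too short to plant "
            f"(needs >= {need})"
        )
    records = []
    rows = []
    n_planted = round(planted_fraction * n)
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        est_id = f"est{i:03d}"
        if i < n_planted:
            left = int(rng.integers(10, length - need + 30))
            if preserve_structure:
                homolog = mutate_preserving_pairs(
                    query_precursor, divergence, rng, pairs=query_pairs
                )
            else:
                homolog = mutate_sequence(query_precursor, divergence, rng)
            seq = (
                _random_seq(rng, left)
                + query_precursor
                + _random_seq(rng, separation)
                + homolog
            )
            seq += _random_seq(rng, max(0, length - len(seq)))
            a = (left, left + q)
            b = (left + q + separation, left + q + separation + q)
            rows.append(
                {
                    "est_id": est_id, "planted": True,
                    "a_start": a[0], "a_end": a[1],
                    "b_start": b[0], "b_end": b[1],
                    "divergence": divergence,
                }
            )
        else:
            seq = _random_seq(rng, length)
            rows.append(
                {
                    "est_id": est_id, "planted": False,
                    "a_start": -1, "a_end": -1, "b_start": -1, "b_end": -1,
                    "divergence": float("nan"),
                }
            )
        records.append(SequenceRecord(id=est_id, residues=seq))
    return SimulatedESTLibrary(records=records, truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# CDS target simulation

_STOPS = {"UAA", "UAG", "UGA"}


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["AUG"]
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


@dataclass
class SimulatedTargets:
    records: list[SequenceRecord]
    cds: pd.DataFrame  # transcript_id, cds_start, cds_end (0-based half-open)
    truth: pd.DataFrame  # transcript_id, mirna_id, start, end, frame, mismatches


def simulate_cds_targets(
    mirnas: dict[str, str],
    plants: list[tuple[int, str, int, int]],
    n_transcripts: int = 12,
    cds_codons: int = 100,
    seed: int = 0,
) -> SimulatedTargets:
    """Transcripts with planted miRNA complement sites.

    *plants* lists (transcript_index, mirna_id, frame_offset, n_mismatches):
    the reverse complement of the mature sequence (degraded by
    *n_mismatches* substitutions) is written into the CDS so that its start
    sits at the requested codon frame offset.
    """
    rng = np.random.default_rng(seed)
    seqs = [_random_cds(rng, cds_codons) for _ in range(n_transcripts)]
    rows = []
    used: dict[int, list[tuple[int, int]]] = {}
    for t_idx, mid, frame, n_mm in plants:
        if t_idx >= n_transcripts:
            raise SimulationError(f"transcript index {t_idx} out of range")
        site = revcomp(mirnas[mid])
        if n_mm:
            site = mutate_sequence(site, n_mm / len(site), rng)
        cds = seqs[t_idx]
        lo, hi = 9, len(cds) - len(site) - 9
        for _ in range(200):
            start = int(rng.integers(lo // 3, hi // 3)) * 3 + frame
            span = (start, start + len(site))
            if all(
                span[1] <= s or span[0] >= e for s, e in used.get(t_idx, [])
            ):
                break
        else:
            raise SimulationError(f"no room for a site on transcript {t_idx}")
        used.setdefault(t_idx, []).append(span)
        seqs[t_idx] = cds[: span[0]] + site + cds[span[1]:]
        rows.append(
            {
                "transcript_id": f"tx{t_idx:03d}", "mirna_id": mid,
                "start": span[0], "end": span[1],
                "frame": frame, "mismatches": n_mm,
            }
        )
    records = [
        SequenceRecord(id=f"tx{i:03d}", residues=s) for i, s in enumerate(seqs)
    ]
    cds_rows = [
        {"transcript_id": r.id, "cds_start": 0, "cds_end": len(r)} for r in records
    ]
    return SimulatedTargets(
        records=records, cds=pd.DataFrame(cds_rows), truth=pd.DataFrame(rows)
    )
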