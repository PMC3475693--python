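"""Pairwise evolutionary distances and region-wise substitution summaries.

Implements the Kimura 2-parameter (K2P) distance
``K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]`` with transition proportion
*P* and transversion proportion *Q* counted under pairwise deletion, the
ungapped best-offset comparison used to compare two mature miRNAs, the
per-region substitution-ratio table for an annotated polycistron
alignment, the Welch t-test between region distance vectors, and the
per-column conservation (counts) matrix that underlies sequence LOGOs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Alignment

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CU")
_BASES = frozenset("ACGU")


def is_transition(x: str, y: str) -> bool:
    """A<->G or C<->U change (x != y assumed)."""
    return (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)


@dataclass(frozen=True)
class DistanceResult:
    """P/Q/p-distance/K2P for one aligned sequence pair (pairwise deletion)."""

    P: float
    Q: float
    p_dist: float
    k2p: float  # nan when the log argument is non-positive (saturation)
    sites_compared: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.k2p)


class DistanceError(ValueError):
    pass


def k2p_from_pq(P: float, Q: float) -> float:
    """Closed-form K2P distance; nan if outside the domain of the log."""
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return float("nan")
    return -0.5 * math.log(a * math.sqrt(b))


def pairwise_distance(seq_a: str, seq_b: str) -> DistanceResult:
    """P, Q, p-distance and K2P for two equal-length aligned sequences.

    Sites where either symbol is not one of A/C/G/U (gaps, N) are dropped
    (pairwise deletion).
    """
    if len(seq_a) != len(seq_b):
        raise DistanceError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    n = ts = tv = 0
    for x, y in zip(seq_a, seq_b):
        if x in _BASES and y in _BASES:
            n += 1
            if x != y:
                if is_transition(x, y):
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        raise DistanceError("no comparable sites after pairwise deletion")
    P, Q = ts / n, tv / n
    return DistanceResult(P=P, Q=Q, p_dist=P + Q, k2p=k2p_from_pq(P, Q), sites_compared=n)


@dataclass(frozen=True)
class OffsetComparison:
    """Best ungapped sliding comparison of two sequences.

    ``offset`` is the shift of sequence B relative to A: position ``i`` of A
    aligns with position ``i - offset`` of B.
    """

    offset: int
    identities: int
    compared_sites: int
    transitions: int
    transversions: int
    diff_positions: tuple[tuple[int, str, str], ...]  # (pos in A, base A, base B)


def best_offset_identity(seq_a: str, seq_b: str, min_overlap: int | None = None) -> OffsetComparison:
    """Slide two ungapped sequences over all offsets and keep the identity
    maximum.

    Overlap must be at least half the shorter length (rounded up) unless
    *min_overlap* overrides it.  Ties are broken by smallest ``|offset|``,
    then negative offset first.
    """
    if not seq_a or not seq_b:
        raise DistanceError("sequences must be non-empty")
    if "-" in seq_a or "-" in seq_b:
        raise DistanceError("sequences must be ungapped")
    if min_overlap is None:
        min_overlap = -(-min(len(seq_a), len(seq_b)) // 2)
    best: tuple | None = None
    for off in range(-(len(seq_b) - min_overlap), len(seq_a) - min_overlap + 1):
        lo = max(0, off)
        hi = min(len(seq_a), len(seq_b) + off)
        if hi - lo < min_overlap:
            continue
        ident = ts = tv = 0
        diffs: list[tuple[int, str, str]] = []
        for i in range(lo, hi):
            x, y = seq_a[i], seq_b[i - off]
            if x == y:
                ident += 1
            else:
                diffs.append((i, x, y))
                if is_transition(x, y):
                    ts += 1
                else:
                    tv += 1
        key = (ident, -abs(off), 1 if off < 0 else 0)
        if best is None or key > best[0]:
            best = (key, OffsetComparison(off, ident, hi - lo, ts, tv, tuple(diffs)))
    assert best is not None
    return best[1]


@dataclass
class RegionRow:
    region: str
    length: int
    mean: float
    sd: float
    n_pairs: int
    n_undefined: int  # pairs with undefined K2P, excluded from the mean
    flagged: bool  # zero comparable columns or single pair


@dataclass
class RegionSubstitutionTable:
    """Per-region mean +/- SD of pairwise distances (Table-2 style)."""

    rows: list[RegionRow]
    distances: dict[str, np.ndarray]  # region -> vector of defined pairwise distances

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region": r.region,
                    "length": r.length,
                    "mean": r.mean,
                    "sd": r.sd,
                    "n_pairs": r.n_pairs,
                    "n_undefined": r.n_undefined,
                    "flagged": r.flagged,
                }
                for r in self.rows
            ]
        )


def _pair_vector(aln: Alignment, interval: tuple[int, int], kind: str) -> tuple[np.ndarray, int]:
    sub = aln.columns(interval)
    vals: list[float] = []
    undefined = 0
    for a, b in combinations(sub.records, 2):
        try:
            d = pairwise_distance(a.residues, b.residues)
        except DistanceError:
            undefined += 1
            continue
        v = d.k2p if kind == "k2p" else d.p_dist
        if math.isnan(v):
            undefined += 1
        else:
            vals.append(v)
    return np.asarray(vals, dtype=float), undefined


def region_substitution_table(
    aln: Alignment,
    regions: dict[str, tuple[int, int]],
    kind: str = "k2p",
) -> RegionSubstitutionTable:
    """Mean and sample SD of pairwise distances per region of an alignment.

    *regions* maps region name to a [start, end) column interval (already in
    alignment coordinates).  *kind* is ``"k2p"`` or ``"p"``.
    """
    if kind not in ("k2p", "p"):
        raise ValueError("kind must be 'k2p' or 'p'")
    rows: list[RegionRow] = []
    dists: dict[str, np.ndarray] = {}
    for name, interval in regions.items():
        vec, undefined = _pair_vector(aln, interval, kind)
        dists[name] = vec
        n = len(vec)
        flagged = n == 0 or n == 1
        mean = float(vec.mean()) if n else float("nan")
        sd = float(vec.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            RegionRow(
                region=name,
                length=interval[1] - interval[0],
                mean=mean,
                sd=sd,
                n_pairs=n,
                n_undefined=undefined,
                flagged=flagged,
            )
        )
    return RegionSubstitutionTable(rows=rows, distances=dists)


def region_ratio_test(values_a, values_b) -> tuple[float, float]:
    """Welch two-sample two-tailed t-test between two pairwise-distance vectors.

    Returns ``(t, p)``.  Identical constant groups give ``(0, 1)`` by
    convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DistanceError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class ConservationMatrix:
    """Per-column A/C/G/U/gap counts with consensus (the LOGO substrate)."""

    counts: pd.DataFrame  # columns A,C,G,U,gap; one row per alignment column
    consensus: str
    identity: np.ndarray  # fraction of the modal base per column
    ties: np.ndarray  # bool per column: consensus was a tie, broken alphabetically


def conservation_matrix(aln: Alignment) -> ConservationMatrix:
    """Column base counts, consensus (ties broken alphabetically and flagged)
    and identity fraction.  ``N`` is tallied with gaps as uninformative."""
    symbols = ["A", "C", "G", "U", "gap"]
    n_col = aln.n_columns
    counts = np.zeros((n_col, 5), dtype=int)
    idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    for rec in aln.records:
        for j, ch in enumerate(rec.residues):
            counts[j, idx.get(ch, 4)] += 1
    consensus = []
    identity = np.zeros(n_col)
    ties = np.zeros(n_col, dtype=bool)
    for j in range(n_col):
        base_counts = counts[j, :4]
        top = base_counts.max()
        winners = [b for b, c in zip("ACGU", base_counts) if c == top]
        ties[j] = len(winners) > 1 and top > 0
        consensus.append(winners[0] if top > 0 else "-")
        identity[j] = top / len(aln)
    frame = pd.DataFrame(counts, columns=symbols)
    return ConservationMatrix(
        counts=frame, consensus="".join(consensus), identity=identity, ties=ties
    )


def distance_matrix(aln: Alignment, kind: str = "k2p") -> pd.DataFrame:
    """Square symmetric distance matrix over all records of an alignment."""
    n = len(aln)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = pairwise_distance(aln.records[i].residues, aln.records[j].residues)
        v = d.k2p if kind == "k2p" else d.p_dist
        mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=aln.ids, columns=aln.ids)
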