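"""Compensatory substitutions in stem regions of pre-miRNA hairpins.

Substitutions at structurally paired sites are counted against a designated
reference sequence and its secondary structure, classified as single vs
double and pairing-preserving vs pairing-breaking, and compared with the
Dixon-Hillis theoretical expectations (single: 4 of 32 random substitutions
preserve pairing; double: 11 of 43).  An excess of pairing-preserving
changes over expectation is evidence of selection on the stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .core_io import Alignment
from .rna import SecondaryStructure, can_pair


@dataclass(frozen=True)
class CompSubModel:
    """Dixon-Hillis theoretical substitution weights."""

    single_pp: int = 4  # pairing -> pairing
    single_pn: int = 28  # pairing -> non-pairing
    double_pp: int = 11
    double_pn: int = 32

    @property
    def single_total(self) -> int:
        return self.single_pp + self.single_pn

    @property
    def double_total(self) -> int:
        return self.double_pp + self.double_pn


@dataclass(frozen=True)
class SubstitutionEvent:
    site_pair: tuple[int, int]  # positions in ungapped reference coordinates
    kind: str  # "single" | "double"
    pairing: bool  # derived state still pairs (GU counts as pairing)
    derived: tuple[str, str]
    taxa: tuple[str, ...]  # taxa sharing this exact event


class CompensatoryError(ValueError):
    pass


def _reference_column_map(reference_residues: str) -> list[int]:
    """Map ungapped reference position -> alignment column."""
    return [col for col, ch in enumerate(reference_residues) if ch != "-"]


def count_substitutions(
    aln: Alignment,
    reference_id: str,
    reference_structure: SecondaryStructure,
    deduplicate: bool = True,
) -> list[SubstitutionEvent]:
    """List substitution events at reference-paired sites.

    For every pair (i, j) of the reference structure and every non-reference
    taxon, a state differing from the reference at exactly one of the two
    positions is a single substitution; at both, a double substitution.
    Identical changes shared by several taxa are merged into one event when
    *deduplicate* is set (the default).  Sites where a taxon has a gap or N
    are skipped for that taxon.
    """
    try:
        ref = aln[reference_id]
    except KeyError:
        raise CompensatoryError(f"reference {reference_id!r} not in alignment")
    colmap = _reference_column_map(ref.residues)
    if len(reference_structure) != len(colmap):
        raise CompensatoryError(
            f"structure length {len(reference_structure)} != ungapped reference "
            f"length {len(colmap)}"
        )
    events: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    for i, j in reference_structure.pairs:
        ci, cj = colmap[i], colmap[j]
        rx, ry = ref.residues[ci], ref.residues[cj]
        for rec in aln.records:
            if rec.id == reference_id:
                continue
            x, y = rec.residues[ci], rec.residues[cj]
            if x not in "ACGU" or y not in "ACGU":
                continue
            d1, d2 = x != rx, y != ry
            if not (d1 or d2):
                continue
            kind = "double" if (d1 and d2) else "single"
            key = ((i, j), kind, (x, y))
            if key not in events:
                events[key] = []
                order.append(key)
            events[key].append(rec.id)
    out: list[SubstitutionEvent] = []
    for key in order:
        (site, kind, derived), taxa = key, events[key]
        n_copies = 1 if deduplicate else len(taxa)
        for _ in range(n_copies):
            out.append(
                SubstitutionEvent(
                    site_pair=site,
                    kind=kind,
                    pairing=can_pair(*derived),
                    derived=derived,
                    taxa=tuple(taxa),
                )
            )
    return out


def expected_counts(
    total_singles: int, total_doubles: int, model: CompSubModel | None = None
) -> dict[str, float]:
    """Dixon-Hillis expected counts per (kind x class) cell."""
    m = model or CompSubModel()
    if total_singles < 0 or total_doubles < 0:
        raise CompensatoryError("totals must be non-negative")
    return {
        "single_pp": total_singles * m.single_pp / m.single_total,
        "single_pn": total_singles * m.single_pn / m.single_total,
        "double_pp": total_doubles * m.double_pp / m.double_total,
        "double_pn": total_doubles * m.double_pn / m.double_total,
    }


def printed_expected(total: int, weight_pp: int, weight_total: int) -> tuple[float, float]:
    """Expected cells as a printed summary table shows them: the
    pairing-preserving cell rounded half-up to one decimal, the other cell
    as the complement so the pair still sums to the observed total."""
    from decimal import ROUND_HALF_UP, Decimal

    exact_pp = total * weight_pp / weight_total
    pp = float(Decimal(str(exact_pp)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return pp, round(total - pp, 10)


def compensatory_test(
    observed_pp: int,
    observed_pn: int,
    expected_pp: float,
    expected_pn: float,
) -> dict[str, float]:
    """Two-tailed tests of pairing-preserving excess.

    Returns both the Fisher exact p on the 2x2 of observed vs rounded
    expected counts and an exact binomial p (observed_pp successes out of
    the observed total at the theoretical success probability), which
    avoids rounding the expectations.
    """
    if observed_pp < 0 or observed_pn < 0:
        raise CompensatoryError("observed counts must be non-negative")
    total = observed_pp + observed_pn
    if total == 0 and expected_pp == 0 and expected_pn == 0:
        return {"fisher_p": 1.0, "binomial_p": 1.0}
    table = [[observed_pp, observed_pn], [round(expected_pp), round(expected_pn)]]
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if total > 0 and expected_pp + expected_pn > 0:
        # success probability implied by the expectations (4/32 or 11/43
        # when they come straight from the Dixon-Hillis model)
        prob = expected_pp / (expected_pp + expected_pn)
        binom_p = float(stats.binomtest(observed_pp, total, prob).pvalue)
    else:
        binom_p = 1.0
    return {"fisher_p": fisher_p, "binomial_p": binom_p}


@dataclass
class CompSubTable:
    """Observed vs expected substitution counts in stems (one gene)."""

    observed: dict[str, int]
    expected: dict[str, float]
    p_single: dict[str, float] = field(default_factory=dict)
    p_double: dict[str, float] = field(default_factory=dict)
    events: list[SubstitutionEvent] = field(default_factory=list)

    @property
    def total_singles(self) -> int:
        return self.observed["single_pp"] + self.observed["single_pn"]

    @property
    def total_doubles(self) -> int:
        return self.observed["double_pp"] + self.observed["double_pn"]

    def to_frame(self) -> pd.DataFrame:
        m = CompSubModel()
        rows = [
            ("single", "pairing->pairing", m.single_pp,
             self.expected["single_pp"], self.observed["single_pp"]),
            ("single", "pairing->non-pairing", m.single_pn,
             self.expected["single_pn"], self.observed["single_pn"]),
            ("double", "pairing->pairing", m.double_pp,
             self.expected["double_pp"], self.observed["double_pp"]),
            ("double", "pairing->non-pairing", m.double_pn,
             self.expected["double_pn"], self.observed["double_pn"]),
        ]
        return pd.DataFrame(
            rows, columns=["kind", "class", "weight", "expected", "observed"]
        )


def compsub_report(
    aln: Alignment,
    reference_id: str,
    structure: SecondaryStructure,
    model: CompSubModel | None = None,
    deduplicate: bool = True,
) -> CompSubTable:
    """End-to-end counting, expectation and significance testing."""
    m = model or CompSubModel()
    events = count_substitutions(aln, reference_id, structure, deduplicate=deduplicate)
    obs = {"single_pp": 0, "single_pn": 0, "double_pp": 0, "double_pn": 0}
    for ev in events:
        obs[f"{ev.kind}_{'pp' if ev.pairing else 'pn'}"] += 1
    exp = expected_counts(
        obs["single_pp"] + obs["single_pn"], obs["double_pp"] + obs["double_pn"], m
    )
    p_single = compensatory_test(
        obs["single_pp"], obs["single_pn"], exp["single_pp"], exp["single_pn"]
    )
    p_double = compensatory_test(
        obs["double_pp"], obs["double_pn"], exp["double_pp"], exp["double_pn"]
    )
    return CompSubTable(
        observed=obs, expected=exp, p_single=p_single, p_double=p_double, events=events
    )
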