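"""Dot-bracket secondary structures and loop-decomposed energy evaluation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PAIR_TYPES, EnergyModel, default_model


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free pairing, as dot-bracket string and pair table.

    ``pair_table[i]`` is the partner index of position *i*, or -1.
    """

    dot_bracket: str
    pair_table: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != len(self.pair_table):
            raise StructureError("dot-bracket and pair table lengths differ")
        for i, j in enumerate(self.pair_table):
            if j >= 0:
                if self.pair_table[j] != i:
                    raise StructureError(f"pair table not symmetric at {i}")
                if i < j and j - i - 1 < 3:
                    raise StructureError(f"hairpin loop < 3 nt at pair ({i},{j})")

    def __len__(self) -> int:
        return len(self.dot_bracket)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Ordered (i, j) pairs with i < j."""
        return [(i, j) for i, j in enumerate(self.pair_table) if j > i]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_dot_bracket(cls, db: str) -> "SecondaryStructure":
        table = [-1] * len(db)
        stack: list[int] = []
        for i, ch in enumerate(db):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {i}")
                j = stack.pop()
                table[j], table[i] = i, j
            elif ch != ".":
                raise StructureError(f"invalid character {ch!r} at position {i}")
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1]}")
        return cls(dot_bracket=db, pair_table=tuple(table))

    @classmethod
    def from_pairs(cls, n: int, pairs) -> "SecondaryStructure":
        table = [-1] * n
        db = ["."] * n
        for i, j in pairs:
            if not (0 <= i < j < n):
                raise StructureError(f"pair ({i},{j}) out of range")
            if table[i] != -1 or table[j] != -1:
                raise StructureError(f"position reused in pair ({i},{j})")
            table[i], table[j] = j, i
            db[i], db[j] = "(", ")"
        s = cls(dot_bracket="".join(db), pair_table=tuple(table))
        # nesting check: dot-bracket reconstruction must reproduce the table
        if s.from_dot_bracket(s.dot_bracket).pair_table != s.pair_table:
            raise StructureError("pairs are pseudoknotted (non-nested)")
        return s


EMPTY = SecondaryStructure  # alias for doc purposes


def _children(pair_table, i: int, j: int) -> list[tuple[int, int]]:
    """Direct daughter pairs inside (i, j)."""
    out = []
    k = i + 1
    while k < j:
        p = pair_table[k]
        if p > k:
            out.append((k, p))
            k = p + 1
        else:
            k += 1
    return out


def _top_level(pair_table) -> list[tuple[int, int]]:
    out = []
    k = 0
    while k < len(pair_table):
        p = pair_table[k]
        if p > k:
            out.append((k, p))
            k = p + 1
        else:
            k += 1
    return out


def energy_decomposition(
    sequence: str,
    structure: SecondaryStructure,
    model: EnergyModel | None = None,
) -> tuple[float, np.ndarray]:
    """Total free energy and its per-position additive decomposition.

    Stack energies are split equally among the four stacked positions; each
    loop penalty is split equally among the positions that define the loop
    (closing pair, unpaired loop nucleotides and, for internal and
    multibranch loops, the inner pair positions); helix-end penalties go to
    the two positions of the pair concerned.  The decomposition sums to the
    total energy by construction.
    """
    model = model or default_model()
    n = len(sequence)
    if len(structure) != n:
        raise StructureError(f"structure length {len(structure)} != sequence length {n}")
    contrib = np.zeros(n)
    pt = structure.pair_table
    pidx = {p: k for k, p in enumerate(PAIR_TYPES)}

    def ptype(i: int, j: int) -> int:
        key = sequence[i] + sequence[j]
        if key not in pidx:
            raise StructureError(
                f"non-canonical pair {key} at positions ({i},{j})"
            )
        return pidx[key]

    def add(positions, amount: float) -> None:
        share = amount / len(positions)
        for p in positions:
            contrib[p] += share

    def add_terminal(i: int, j: int) -> None:
        add([i, j], float(model.terminal[ptype(i, j)]))

    for i, j in _top_level(pt):  # exterior branches
        add_terminal(i, j)
    for i, j in structure.pairs:
        kids = _children(pt, i, j)
        if not kids:  # hairpin loop
            size = j - i - 1
            add([i, j] + list(range(i + 1, j)), model.hairpin_penalty(size))
            add_terminal(i, j)
        elif len(kids) == 1:
            k, l = kids[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:  # stack
                add([i, j, k, l], float(model.stack[ptype(i, j), ptype(k, l)]))
            else:  # bulge or internal loop
                positions = (
                    [i, j, k, l]
                    + list(range(i + 1, k))
                    + list(range(l + 1, j))
                )
                add(positions, model.interior_penalty(left, right))
                add_terminal(i, j)
                add_terminal(k, l)
        else:  # multibranch loop
            penalty = model.ml_init + model.ml_branch * (len(kids) + 1)
            unpaired = [
                p
                for p in range(i + 1, j)
                if pt[p] == -1 and not any(k < p < l for k, l in kids)
            ]
            positions = [i, j] + [x for kl in kids for x in kl] + unpaired
            add(positions, penalty)
            add_terminal(i, j)
            for k, l in kids:
                add_terminal(k, l)
    return float(contrib.sum()), contrib


def energy_of_structure(
    sequence: str,
    structure: SecondaryStructure,
    model: EnergyModel | None = None,
) -> float:
    """Free energy (kcal/mol) of *structure* on *sequence* under *model*."""
    total, _ = energy_decomposition(sequence, structure, model)
    return total
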