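"""Nearest-neighbor free-energy model for RNA secondary structure.

The model is deliberately minimal and fully transparent: a stacking table
over the six canonical pairs (Watson-Crick plus G:U wobble), size-indexed
hairpin/bulge/internal-loop penalties with Jacobson-Stockmayer logarithmic
extrapolation, a two-constant multibranch penalty, and an AU/GU helix-end
penalty.  No dangles, no coaxial stacking, no special loop sequences.  All
parameters live in an editable TSV shipped with the package and can be
swapped at run time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

#: order of canonical pair types used everywhere in this subpackage
PAIR_TYPES = ("AU", "UA", "GC", "CG", "GU", "UG")

#: base encoding used by the folding kernels
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

#: 1.75 * R * T at 37 C, kcal/mol — loop-size extrapolation coefficient
_LOOP_EXTRAPOLATION = 1.75 * 0.001987 * 310.15


def pair_type_table() -> np.ndarray:
    """5x5 table mapping (base_i, base_j) to a pair-type index or -1."""
    pt = -np.ones((5, 5), dtype=np.int64)
    for k, name in enumerate(PAIR_TYPES):
        pt[BASE_INDEX[name[0]], BASE_INDEX[name[1]]] = k
    return pt


PAIR_TABLE = pair_type_table()


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-RNA symbol {exc} in sequence") from exc


def can_pair(x: str, y: str) -> bool:
    return x + y in PAIR_TYPES


@dataclass
class EnergyModel:
    """Parameter container; all energies in kcal/mol.

    ``stack[p, q]`` is the free energy of pair type *q* stacked directly
    inside pair type *p*; loop arrays are indexed by loop size and
    extrapolated logarithmically beyond the tabulated range.
    """

    stack: np.ndarray  # (6, 6)
    hairpin: dict[int, float]
    bulge: dict[int, float]
    internal: dict[int, float]
    ml_init: float
    ml_branch: float
    terminal: np.ndarray  # (6,) helix-end penalty per pair type
    min_hairpin: int = 3
    max_interior: int = 30  # cap on total unpaired nt in a bulge/internal loop

    def __post_init__(self) -> None:
        if np.any(self.stack > 0):
            raise ValueError("canonical stacking energies must be <= 0")
        if any(v < 0 for v in self.hairpin.values()) or self.ml_init < 0:
            raise ValueError("loop penalties must be >= 0")

    def _loop_array(self, table: dict[int, float], n: int) -> np.ndarray:
        """Dense size-indexed penalty array up to *n*, log-extrapolated."""
        arr = np.full(n + 1, np.inf)
        if not table:
            return arr
        kmax = max(table)
        for k, v in table.items():
            if k <= n:
                arr[k] = v
        for k in range(kmax + 1, n + 1):
            arr[k] = table[kmax] + _LOOP_EXTRAPOLATION * math.log(k / kmax)
        return arr

    def arrays_for(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(hairpin, bulge, internal) penalty arrays dense up to size *n*."""
        return (
            self._loop_array(self.hairpin, n),
            self._loop_array(self.bulge, n),
            self._loop_array(self.internal, n),
        )

    def hairpin_penalty(self, size: int) -> float:
        return float(self._loop_array(self.hairpin, max(size, 3))[size])

    def interior_penalty(self, left: int, right: int) -> float:
        """Bulge (one side 0) or internal loop penalty by total size."""
        size = left + right
        table = self.bulge if (left == 0 or right == 0) else self.internal
        return float(self._loop_array(table, size)[size])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnergyModel":
        stack = np.zeros((6, 6))
        hairpin: dict[int, float] = {}
        bulge: dict[int, float] = {}
        internal: dict[int, float] = {}
        terminal = np.zeros(6)
        ml_init = ml_branch = 0.0
        pidx = {p: k for k, p in enumerate(PAIR_TYPES)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                kind, k1, k2, val = line.split("\t")
                v = float(val)
                if kind == "stack":
                    stack[pidx[k1], pidx[k2]] = v
                elif kind == "hairpin":
                    hairpin[int(k1)] = v
                elif kind == "bulge":
                    bulge[int(k1)] = v
                elif kind == "internal":
                    internal[int(k1)] = v
                elif kind == "multiloop":
                    if k1 == "init":
                        ml_init = v
                    else:
                        ml_branch = v
                elif kind == "terminal":
                    terminal[pidx[k1]] = v
                else:
                    raise ValueError(f"unknown parameter kind {kind!r}")
        return cls(
            stack=stack,
            hairpin=hairpin,
            bulge=bulge,
            internal=internal,
            ml_init=ml_init,
            ml_branch=ml_branch,
            terminal=terminal,
        )

    @classmethod
    def default(cls) -> "EnergyModel":
        with resources.as_file(
            resources.files("pcevol.data").joinpath("energy_params.tsv")
        ) as p:
            return cls.from_tsv(p)


_DEFAULT: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = EnergyModel.default()
    return _DEFAULT
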