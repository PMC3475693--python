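"""Per-position thermodynamic profiles averaged across species.

Each species' structure energy is decomposed additively over positions
(:func:`pcevol.rna.structure.energy_decomposition`); positions are mapped
through the species' alignment row onto columns, and each column is
summarised by its mean contribution and a variability band of twice the
standard error across species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core_io import Alignment
from .model import EnergyModel, default_model
from .structure import SecondaryStructure, energy_decomposition


@dataclass
class PositionProfile:
    mean: np.ndarray  # per alignment column; nan where masked
    variability: np.ndarray  # 2 x SE across species; 0 where n < 2
    n_species: np.ndarray  # contributing species per column
    per_species: np.ndarray  # (n_species, n_columns) contributions, nan at gaps

    def __len__(self) -> int:
        return len(self.mean)


def position_profile(
    aln: Alignment,
    structures: dict[str, SecondaryStructure],
    model: EnergyModel | None = None,
) -> PositionProfile:
    """Profile energy contributions across the species of an alignment.

    *structures* maps record id to the structure of that record's ungapped
    sequence.  Entirely-gapped columns are masked (nan mean).
    """
    model = model or default_model()
    n_col = aln.n_columns
    mat = np.full((len(aln), n_col), np.nan)
    for row, rec in enumerate(aln.records):
        ungapped = rec.ungapped
        structure = structures[rec.id]
        if len(structure) != len(ungapped):
            raise ValueError(
                f"{rec.id}: structure length {len(structure)} != "
                f"ungapped length {len(ungapped)}"
            )
        _, contrib = energy_decomposition(ungapped, structure, model)
        k = 0
        for col, ch in enumerate(rec.residues):
            if ch != "-":
                mat[row, col] = contrib[k]
                k += 1
    n_sp = np.sum(~np.isnan(mat), axis=0)
    mean = np.full(n_col, np.nan)
    covered = n_sp > 0
    mean[covered] = np.nansum(np.nan_to_num(mat), axis=0)[covered] / n_sp[covered]
    var = np.zeros(n_col)
    for col in range(n_col):
        vals = mat[~np.isnan(mat[:, col]), col]
        if len(vals) > 1:
            var[col] = 2.0 * vals.std(ddof=1) / np.sqrt(len(vals))
    return PositionProfile(mean=mean, variability=var, n_species=n_sp, per_species=mat)
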