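"""Reverse-docking energy reduction and per-chemical protein ranking.

A docking screen scores each chemical against many predicted binding
pockets per protein, by both sequence- and structure-based pocket
predictions.  For each (chemical, protein) pair the single most
favourable (lowest) energy is kept; within each chemical the proteins
are then ranked ascending by that energy (rank 1 = strongest predicted
binder, competition ranking for ties).  Ranks, not raw energies, are
compared across chemicals because mean binding energy varies by
chemical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["reduce_min_energy", "rank_proteins", "top_k_membership"]

ENERGY_COL = "energy_kcal_mol"


def reduce_min_energy(table: pd.DataFrame) -> pd.DataFrame:
    """Per (chemical, protein) minimum energy over pockets and methods."""
    if table.empty:
        raise ValueError("empty docking table")
    out = (table.groupby(["chemical", "protein"], sort=True)[ENERGY_COL]
           .min().reset_index())
    return out


def rank_proteins(min_energies: pd.DataFrame) -> pd.DataFrame:
    """Chemicals x proteins rank matrix (1 = lowest energy).

    Ties share the minimum (competition) rank; proteins missing for a
    chemical stay NaN and do not consume a rank.
    """
    wide = min_energies.pivot(index="chemical", columns="protein",
                              values=ENERGY_COL)
    ranks = wide.rank(axis=1, method="min", ascending=True)
    return ranks


def top_k_membership(ranks: pd.DataFrame, k: int = 10):
    """Proteins ranked in the top ``k`` for at least one chemical.

    Returns (sorted protein list, boolean chemicals x member-proteins
    membership frame).
    """
    member = ranks <= k
    proteins = sorted(member.columns[member.any(axis=0)])
    return proteins, member[proteins]
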