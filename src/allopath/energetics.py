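"""MM-PBSA energy bookkeeping.

End-state binding free energies are assembled from per-frame molecular-
mechanics and solvation components (all kcal/mol):

    E_gas = E_int + E_ele + E_vdw
    G_sol = G_psolv + G_npsolv
    G     = E_gas + G_sol            (conformational entropy omitted)
    ΔG_binding = G_complex − (G_receptor + G_ligand)

The nonpolar solvation term is γ·SASA with γ = 0.0072 kcal/(mol·Å²) by
default.  The Poisson–Boltzmann polar term is never solved here: ``G_psolv``
is always an input column.  Hot-spot residues are those whose mean
per-residue contribution falls strictly below a threshold (−1 kcal/mol by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import ENERGY_COLUMNS, TableSchemaError

__all__ = ["EnergySummary", "combine_components", "binding_energy",
           "nonpolar_solvation", "hot_residues", "GAMMA_NONPOLAR",
           "DERIVED_COLUMNS"]

#: Surface-tension coefficient for γ·SASA nonpolar solvation, kcal/(mol·Å²).
GAMMA_NONPOLAR = 0.0072

DERIVED_COLUMNS = ("E_gas", "G_sol", "G")


@dataclass(frozen=True)
class EnergySummary:
    """Per-component mean ± sd over frames, plus the binding energy."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_frames: int

    @property
    def binding_mean(self) -> float:
        return self.mean["G"]

    @property
    def binding_sd(self) -> float:
        return self.sd["G"]

    def as_dict(self) -> dict:
        return {"n_frames": self.n_frames,
                "mean": dict(self.mean), "sd": dict(self.sd)}


def combine_components(table: pd.DataFrame) -> pd.DataFrame:
    """Add the derived columns ``E_gas``, ``G_sol``, ``G`` row-wise.

    The identities hold exactly (plain floating-point sums in a fixed
    order); the input frame is not modified.
    """
    missing = [c for c in ENERGY_COLUMNS if c not in table.columns]
    if missing:
        raise TableSchemaError(f"energy table missing column(s) {missing}")
    out = table.copy()
    out["E_gas"] = out["E_int"] + out["E_ele"] + out["E_vdw"]
    out["G_sol"] = out["G_psolv"] + out["G_npsolv"]
    out["G"] = out["E_gas"] + out["G_sol"]
    return out


def _summarize(g: np.ndarray, components: pd.DataFrame) -> EnergySummary:
    if len(g) == 0:
        raise ValueError("cannot summarize an empty energy table")
    cols = list(ENERGY_COLUMNS) + list(DERIVED_COLUMNS)
    mean = {c: float(components[c].mean()) for c in cols}
    # sample sd (n−1); a single frame reports sd 0 rather than NaN
    ddof = 1 if len(g) > 1 else 0
    sd = {c: float(components[c].std(ddof=ddof)) for c in cols}
    return EnergySummary(mean=mean, sd=sd, n_frames=len(g))


def binding_energy(complex_table: pd.DataFrame,
                   receptor_table: pd.DataFrame | None = None,
                   ligand_table: pd.DataFrame | None = None,
                   allow_unequal_frames: bool = False) -> EnergySummary:
    """ΔG_binding = G_complex − (G_receptor + G_ligand), summarized.

    With only ``complex_table`` given, it is treated as a pre-differenced
    "delta" table and summarized directly.  Otherwise the three tables are
    differenced frame-wise under the single-trajectory convention, which
    requires equal frame counts unless ``allow_unequal_frames`` (then each
    table is reduced to its own per-frame values and the means are
    differenced, the multi-trajectory convention).
    """
    cplx = combine_components(complex_table)
    if receptor_table is None and ligand_table is None:
        return _summarize(cplx["G"].to_numpy(), cplx)
    if receptor_table is None or ligand_table is None:
        raise ValueError("supply both receptor and ligand tables, or neither")
    rec = combine_components(receptor_table)
    lig = combine_components(ligand_table)
    cols = list(ENERGY_COLUMNS) + list(DERIVED_COLUMNS)
    if len(cplx) == len(rec) == len(lig):
        delta = cplx[cols].to_numpy() - rec[cols].to_numpy() - lig[cols].to_numpy()
        frame = pd.DataFrame(delta, columns=cols)
        return _summarize(frame["G"].to_numpy(), frame)
    if not allow_unequal_frames:
        raise ValueError(
            f"frame counts differ (complex {len(cplx)}, receptor {len(rec)}, "
            f"ligand {len(lig)}); pass allow_unequal_frames=True for the "
            "multi-trajectory convention")
    mean = {c: float(cplx[c].mean() - rec[c].mean() - lig[c].mean()) for c in cols}
    sd = {c: float(np.sqrt(cplx[c].var(ddof=1) / len(cplx)
                           + rec[c].var(ddof=1) / len(rec)
                           + lig[c].var(ddof=1) / len(lig))) for c in cols}
    return EnergySummary(mean=mean, sd=sd,
                         n_frames=min(len(cplx), len(rec), len(lig)))


def nonpolar_solvation(sasa_value: float, gamma: float = GAMMA_NONPOLAR) -> float:
    """Nonpolar solvation free energy γ·SASA (kcal/mol)."""
    if sasa_value < 0:
        raise ValueError(f"SASA must be ≥ 0, got {sasa_value}")
    return float(gamma * sasa_value)


def hot_residues(table: pd.DataFrame | dict, threshold: float = -1.0,
                 ) -> list[tuple[str, float]]:
    """Residues whose mean contribution is strictly below the threshold.

    ``table`` maps residue identifiers to per-frame contributions (a dict of
    scalars or arrays, or a DataFrame with residues as columns).  Returns
    ``(residue, mean)`` pairs sorted most favorable (lowest) first; a value
    exactly at the threshold is excluded.
    """
    if isinstance(table, pd.DataFrame):
        items = {str(c): float(table[c].mean()) for c in table.columns}
    else:
        items = {str(k): float(np.mean(v)) for k, v in table.items()}
    if not items:
        raise ValueError("per-residue table is empty")
    hot = [(r, m) for r, m in items.items() if m < threshold]
    return sorted(hot, key=lambda rm: (rm[1], rm[0]))
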