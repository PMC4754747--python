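"""Binding-free-energy tables: windowed statistics, system comparison, and
key-residue selection by per-residue binding-energy differences.

The endpoint free-energy calculation itself (MM/PBSA) is not performed
here; the module consumes its outputs as delimited-text tables — per-frame
binding free energies for a system, and per-residue decompositions — and
implements the downstream statistics: windowed mean +/- SD summaries, a
Welch two-sample t-test between systems, and selection of residues whose
binding contribution changes by more than a threshold between a wild-type
and a mutant system (per-residue dG difference, mutant minus wild type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ResidueSelection, ValidationError

#: double-precision reporting floor for p-values, as printed in R.
P_FLOOR = 2.2e-16


@dataclass
class EnergySeries:
    """Per-frame binding free energy (kcal/mol) of one system."""

    system_id: str
    per_frame_dG: np.ndarray
    frame_times: np.ndarray  # ns, strictly increasing

    def __post_init__(self) -> None:
        self.per_frame_dG = np.asarray(self.per_frame_dG, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.per_frame_dG.shape != self.frame_times.shape:
            raise ValidationError("energies and times must have equal length")
        if not np.all(np.isfinite(self.per_frame_dG)):
            raise ValidationError("energies must be finite")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame times must be strictly increasing")


@dataclass
class EnergyTable:
    """Per-residue contribution (kcal/mol) to the binding free energy."""

    system_id: str
    per_residue_dG: dict  # (chain_id, residue_index) -> kcal/mol

    def residues(self) -> list:
        return list(self.per_residue_dG.keys())


# ---------------------------------------------------------------------------
# Delimited-text I/O contract
# ---------------------------------------------------------------------------


def read_energy_series(path: str, system_id: str | None = None) -> EnergySeries:
    """Read a per-frame series CSV/TSV with columns
    (system, time_ns, dG_kcal_mol)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"system", "time_ns", "dG_kcal_mol"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: needs columns {sorted(required)}")
    if system_id is not None:
        df = df[df["system"] == system_id]
    else:
        system_id = str(df["system"].iloc[0])
        df = df[df["system"] == system_id]
    return EnergySeries(
        system_id=system_id,
        per_frame_dG=df["dG_kcal_mol"].to_numpy(),
        frame_times=df["time_ns"].to_numpy(),
    )


def write_energy_series(series: EnergySeries, path: str) -> None:
    pd.DataFrame(
        {
            "system": series.system_id,
            "time_ns": series.frame_times,
            "dG_kcal_mol": series.per_frame_dG,
        }
    ).to_csv(path, index=False)


def read_energy_table(path: str, system_id: str | None = None) -> EnergyTable:
    """Read a per-residue decomposition CSV/TSV with columns
    (system, chain, residue, dG_kcal_mol)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"system", "chain", "residue", "dG_kcal_mol"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: needs columns {sorted(required)}")
    if system_id is not None:
        df = df[df["system"] == system_id]
    else:
        system_id = str(df["system"].iloc[0])
        df = df[df["system"] == system_id]
    table: dict = {}
    for _, row in df.iterrows():
        key = (str(row["chain"]), int(row["residue"]))
        if key in table:
            raise ValidationError(f"{path}: duplicate residue {key}")
        table[key] = float(row["dG_kcal_mol"])
    return EnergyTable(system_id=system_id, per_residue_dG=table)


def write_energy_table(table: EnergyTable, path: str) -> None:
    rows = [
        {"system": table.system_id, "chain": c, "residue": r, "dG_kcal_mol": v}
        for (c, r), v in table.per_residue_dG.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------


def windowed_stats(
    series: EnergySeries, windows: list[float]
) -> pd.DataFrame:
    """Mean +/- SD of the energy over frames with time <= each window end
    (ns).  The rounded columns report integer kcal/mol for table parity."""
    rows = []
    for end in windows:
        mask = series.frame_times <= end
        if not np.any(mask):
            raise ValidationError(f"window {end} ns contains no frames")
        vals = series.per_frame_dG[mask]
        rows.append(
            {
                "window_ns": end,
                "n_frames": int(mask.sum()),
                "mean_kcal_mol": float(vals.mean()),
                "sd_kcal_mol": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "mean_rounded": int(np.rint(vals.mean())),
                "sd_rounded": int(np.rint(vals.std(ddof=1))) if len(vals) > 1 else 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    system_a: str
    system_b: str
    mean_difference: float  # mean(a) - mean(b), kcal/mol
    t_statistic: float
    p_value: float
    p_label: str  # "< 2.2e-16" below the double-precision reporting floor


def compare_systems(a: EnergySeries, b: EnergySeries) -> ComparisonResult:
    """Welch two-sample t-test on the per-frame binding energies."""
    if len(a.per_frame_dG) < 2 or len(b.per_frame_dG) < 2:
        raise ValidationError("both series need at least 2 frames")
    t, p = stats.ttest_ind(a.per_frame_dG, b.per_frame_dG, equal_var=False)
    label = f"< {P_FLOOR}" if p < P_FLOOR else f"{p:.3g}"
    return ComparisonResult(
        system_a=a.system_id,
        system_b=b.system_id,
        mean_difference=float(a.per_frame_dG.mean() - b.per_frame_dG.mean()),
        t_statistic=float(t),
        p_value=float(p),
        p_label=label,
    )


# ---------------------------------------------------------------------------
# Key-residue selection
# ---------------------------------------------------------------------------


@dataclass
class KeyResidues:
    selection: ResidueSelection  # ordered, strongest effect first
    ddG: dict  # residue -> mutant-minus-wildtype difference, kcal/mol
    direction: str


def select_key_residues(
    wt: EnergyTable,
    mut: EnergyTable,
    threshold: float = 1.0,
    direction: str = "stabilizing",
) -> KeyResidues:
    """Residues whose per-residue binding contribution changes by more than
    ``threshold`` kcal/mol between mutant and wild type.

    ddG(res) = dG_mut(res) - dG_wt(res).  ``stabilizing`` selects
    ddG < -threshold (mutation strengthens binding), sorted most negative
    first; ``destabilizing`` selects ddG > +threshold, sorted most positive
    first.  Inequalities are strict.
    """
    wt_res = set(wt.per_residue_dG)
    mut_res = set(mut.per_residue_dG)
    if wt_res != mut_res:
        offenders = sorted(wt_res.symmetric_difference(mut_res))
        raise ValidationError(f"residue universes differ: {offenders}")
    ddg = {
        res: mut.per_residue_dG[res] - wt.per_residue_dG[res] for res in wt_res
    }
    if direction == "stabilizing":
        chosen = [r for r, v in ddg.items() if v < -threshold]
        chosen.sort(key=lambda r: ddg[r])
    elif direction == "destabilizing":
        chosen = [r for r, v in ddg.items() if v > threshold]
        chosen.sort(key=lambda r: -ddg[r])
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    return KeyResidues(
        selection=ResidueSelection(chosen),
        ddG={r: ddg[r] for r in chosen},
        direction=direction,
    )


def common_key_residues(
    set_a: KeyResidues | ResidueSelection, set_b: KeyResidues | ResidueSelection
) -> ResidueSelection:
    """Intersection of two key-residue selections, ordered by the first."""
    sel_a = set_a.selection if isinstance(set_a, KeyResidues) else set_a
    sel_b = set_b.selection if isinstance(set_b, KeyResidues) else set_b
    members_b = set(sel_b.entries)
    return ResidueSelection([r for r in sel_a if r in members_b])
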