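"""Docking-energy accounting: binding enthalpy of protein-DNA complexes.

The binding-enthalpy proxy is ΔH = E_complex - (E_protein + E_DNA); more
negative values indicate more favourable binding.  Wild-type and mutant
variants of a protein are compared per DNA box through
ΔΔH = ΔH(mutant) - ΔH(WT): negative ΔΔH beyond a tolerance means the
mutant binds more strongly, positive means weaker.  The module is
unit-agnostic: it reports whatever energy unit the input tables carry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class DockingEnergies:
    """Component energies of one (protein variant, DNA box) docking."""

    variant: str
    box: str
    e_complex: float
    e_protein: float
    e_dna: float

    def __post_init__(self) -> None:
        for name in ("e_complex", "e_protein", "e_dna"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite for ({self.variant}, {self.box})")


def delta_h(e: DockingEnergies) -> float:
    """Binding enthalpy: E_complex - (E_protein + E_DNA). Exact arithmetic."""
    return e.e_complex - (e.e_protein + e.e_dna)


@dataclass
class DeltaHComparison:
    """Per-variant ΔH, per-box ΔΔH (mutant minus WT), and qualitative calls."""

    delta_h: dict[tuple[str, str], float]  # (variant, box) -> ΔH
    delta_delta_h: dict[str, float]  # box -> ΔΔH
    calls: dict[str, str]  # box -> stronger | weaker | unchanged
    wt_label: str = "WT"
    mutant_label: str = "mutant"
    tolerance: float = 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "wt": self.wt_label,
            "mutant": self.mutant_label,
            "tolerance": self.tolerance,
            "delta_h": {f"{v}/{b}": dh for (v, b), dh in self.delta_h.items()},
            "delta_delta_h": self.delta_delta_h,
            "calls": self.calls,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def compare_variants(
    records: Sequence[DockingEnergies],
    tolerance: float = 0.0,
    wt_label: str = "WT",
    mutant_label: str | None = None,
) -> DeltaHComparison:
    """Compare mutant vs wild-type binding enthalpies per DNA box.

    ``records`` must contain exactly one WT and one mutant record per box
    compared.  With |ΔΔH| <= tolerance the call is "unchanged"; otherwise
    a more negative mutant ΔH calls "stronger" binding.  Swapping which
    label is treated as WT flips every call (antisymmetry of ΔΔH).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    variants = sorted({r.variant for r in records})
    if wt_label not in variants:
        raise ValueError(f"no records labelled {wt_label!r}; have {variants}")
    if mutant_label is None:
        others = [v for v in variants if v != wt_label]
        if len(others) != 1:
            raise ValueError(f"cannot infer mutant label among {others}")
        mutant_label = others[0]
    dh: dict[tuple[str, str], float] = {}
    for r in records:
        key = (r.variant, r.box)
        if key in dh:
            raise ValueError(f"duplicate record for {key}")
        dh[key] = delta_h(r)
    boxes = sorted({b for (_, b) in dh})
    ddh: dict[str, float] = {}
    calls: dict[str, str] = {}
    for box in boxes:
        if (wt_label, box) not in dh:
            raise ValueError(f"missing WT counterpart for box {box!r}")
        if (mutant_label, box) not in dh:
            raise ValueError(f"missing mutant record for box {box!r}")
        d = dh[(mutant_label, box)] - dh[(wt_label, box)]
        ddh[box] = d
        if abs(d) <= tolerance:
            calls[box] = "unchanged"
        elif d < 0:
            calls[box] = "stronger"
        else:
            calls[box] = "weaker"
    return DeltaHComparison(
        delta_h=dh,
        delta_delta_h=ddh,
        calls=calls,
        wt_label=wt_label,
        mutant_label=mutant_label,
        tolerance=tolerance,
    )


def read_energies_csv(path: str | Path) -> list[DockingEnergies]:
    """Read a (variant, box, e_complex, e_protein, e_dna) CSV."""
    df = pd.read_csv(path)
    required = {"variant", "box", "e_complex", "e_protein", "e_dna"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"energies CSV is missing columns: {sorted(missing)}")
    return [
        DockingEnergies(
            variant=str(row.variant),
            box=str(row.box),
            e_complex=float(row.e_complex),
            e_protein=float(row.e_protein),
            e_dna=float(row.e_dna),
        )
        for row in df.itertuples()
    ]
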