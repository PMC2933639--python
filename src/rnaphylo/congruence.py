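"""Incongruence length difference (ILD), cost-regime selection, and the
across-regime ("Navajo rug") sensitivity grid.

ILD follows the Mickevich–Farris normalised form,

    ILD = (L_combined - sum_k L_k) / L_combined,

where ``L_combined`` is the best tree length on all partitions together
and ``L_k`` the best length on partition ``k`` alone, all under the same
cost regime and analysis mode.  The regime minimising ILD is selected;
exact ties go to the lexicographically first label (and are flagged).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import trees


def ild(combined_length: float, partition_lengths: Sequence[float]) -> float:
    """Normalised incongruence length difference."""
    if combined_length == 0:
        raise ValueError("combined length is zero")
    total = sum(partition_lengths)
    value = (combined_length - total) / combined_length
    if value < -1e-9:
        warnings.warn(
            "sum of partition lengths exceeds the combined length; "
            "partitions are probably not subsets of the combined data")
    return value


@dataclass
class IldTable:
    """Per-regime combined and per-partition best lengths plus ILD."""

    rows: dict[str, dict] = field(default_factory=dict)

    def add(self, regime_label: str, combined_length: float,
            partition_lengths: Mapping[str, float]) -> None:
        self.rows[regime_label] = {
            "combined": combined_length,
            "partitions": dict(partition_lengths),
            "ild": ild(combined_length, list(partition_lengths.values())),
            "raw": combined_length - sum(partition_lengths.values()),
        }

    def _tied_with_min(self) -> list[str]:
        """Labels indistinguishable from the ILD minimum: equal normalised
        value, or equal raw incongruence steps (the normalised values then
        differ only through the combined-length denominator)."""
        def raw(row):
            return row.get("raw", row["ild"] * row["combined"])

        items = sorted(self.rows.items())
        best_label = min(items, key=lambda kv: (kv[1]["ild"], kv[0]))[0]
        best = self.rows[best_label]
        return [label for label, row in items
                if abs(row["ild"] - best["ild"]) <= 1e-12
                or abs(raw(row) - raw(best)) <= 1e-9]

    @property
    def tie_flagged(self) -> bool:
        return len(self._tied_with_min()) > 1

    def chosen_regime(self) -> str:
        return select_regime(self)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for label, row in sorted(self.rows.items()):
            rec = {"regime": label, "combined": row["combined"],
                   "ild": row["ild"]}
            for k, v in row["partitions"].items():
                rec[f"L_{k}"] = v
            recs.append(rec)
        return pd.DataFrame(recs)


def select_regime(table: IldTable) -> str:
    """Regime with minimum ILD; ties — equal normalised values, or equal
    raw incongruence steps — break to the first label in sorted order
    (flagged via ``table.tie_flagged``)."""
    if not table.rows:
        raise ValueError("no regimes evaluated")
    tied = table._tied_with_min()
    if len(tied) > 1:
        warnings.warn("ILD tie between regimes; lexicographically first "
                      "label chosen")
    return min(tied)


@dataclass
class SensitivityGrid:
    """Monitored clades x cost regimes boolean recovery matrix.

    A clade is recovered under a regime iff it appears in the strict
    consensus of that regime's optimal trees.
    """

    clades: dict[str, frozenset]
    regimes: list[str]
    recovered: dict[tuple[str, str], bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {reg: {name: self.recovered[(name, reg)] for name in self.clades}
             for reg in self.regimes})

    def recovery_counts(self) -> dict[str, int]:
        return {name: sum(self.recovered[(name, reg)]
                          for reg in self.regimes)
                for name in self.clades}

    def plot(self, path) -> None:
        """Render the grid in the familiar black/white rug style."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        frame = self.to_frame()
        fig, ax = plt.subplots(figsize=(1 + 0.5 * len(self.regimes),
                                        1 + 0.4 * len(self.clades)))
        ax.imshow(frame.to_numpy().astype(float), cmap="Greys_r",
                  aspect="auto", vmin=0, vmax=1)
        ax.set_xticks(range(len(frame.columns)), frame.columns, rotation=90)
        ax.set_yticks(range(len(frame.index)), frame.index)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def sensitivity_grid(per_regime_trees: Mapping[str, Sequence[trees.Node]],
                     clade_definitions: Mapping[str, Iterable[str]]
                     ) -> SensitivityGrid:
    """Boolean recovery of each monitored clade under each regime."""
    regimes = sorted(per_regime_trees)
    clades = {name: frozenset(leaves)
              for name, leaves in clade_definitions.items()}
    recovered = {}
    for reg in regimes:
        cons = trees.strict_consensus(list(per_regime_trees[reg]))
        for name, leafset in clades.items():
            recovered[(name, reg)] = trees.has_clade(cons, leafset)
    return SensitivityGrid(clades, regimes, recovered)
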