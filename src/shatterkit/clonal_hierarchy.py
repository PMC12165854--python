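"""Single-cell clonal-state tabulation and lesion-order inference.

Cells carry per-lesion calls (mutant / wt / missing) plus an amplification
state for chr21 (amp / normal / missing).  Ordering uses approximate set
containment: lesion A precedes lesion B when (up to a small allele-dropout
tolerance) every B-mutant cell is also A-mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TRACKED_LESIONS = ("JAK2", "TP53", "chr21amp")

#: column -> value meaning "lesion present"
_MUTANT_VALUES = {"JAK2": "mutant", "TP53": "mutant", "chr21amp": "amp"}
_COLUMN_OF = {"JAK2": "JAK2", "TP53": "TP53", "chr21amp": "chr21"}


class InsufficientDataError(ValueError):
    """No usable cells (or no mutant cells) to tabulate or order."""


@dataclass
class StateCounts:
    """Counts over the 2x2x2 lesion space, usable cells only."""

    counts: dict[str, int]
    n_usable: int
    n_unusable: int

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class HierarchyResult:
    state_counts: StateCounts
    order: list[str] | None
    precedence: list[tuple[str, str]]
    flagged_pairs: list[tuple[str, str]]
    n_contradictory_cells: int
    note: str = ""


def _lesion_flags(cells: pd.DataFrame, lesions: Sequence[str]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(mutant, missing) boolean arrays of shape (n_cells, n_lesions)."""
    mut = np.zeros((len(cells), len(lesions)), dtype=bool)
    mis = np.zeros_like(mut)
    for k, lesion in enumerate(lesions):
        col = cells[_COLUMN_OF[lesion]].astype(str)
        mut[:, k] = (col == _MUTANT_VALUES[lesion]).to_numpy()
        mis[:, k] = (col == "missing").to_numpy()
    return mut, mis


def _state_label(flags: Sequence[bool], lesions: Sequence[str]) -> str:
    present = [l for l, f in zip(lesions, flags) if f]
    return "+".join(present) if present else "WT"


def tabulate_states(cells: pd.DataFrame,
                    lesions: Sequence[str] = TRACKED_LESIONS) -> StateCounts:
    """Exact contingency over the lesion space.

    Cells with any missing tracked call are counted separately as unusable
    and excluded from the contingency.
    """
    mut, mis = _lesion_flags(cells, lesions)
    usable = ~mis.any(axis=1)
    if not usable.any():
        raise InsufficientDataError("no cells with complete tracked calls")
    counts: dict[str, int] = {}
    for flags in mut[usable]:
        label = _state_label(flags, lesions)
        counts[label] = counts.get(label, 0) + 1
    return StateCounts(counts=counts,
                       n_usable=int(usable.sum()),
                       n_unusable=int((~usable).sum()))


def infer_event_order(cells: pd.DataFrame,
                      contradiction_tolerance: float = 0.01,
                      lesions: Sequence[str] = TRACKED_LESIONS
                      ) -> HierarchyResult:
    """Infer lesion acquisition order from nested mutant-cell sets.

    For each ordered pair (A, B), A precedes B iff the fraction of B-mutant
    cells lacking A — among cells non-missing for both — is at most the
    tolerance.  A strict chain over all lesions yields a total order;
    otherwise a partial order is returned with the unresolvable pairs
    flagged.  Tolerance 0 reduces to exact set containment.
    """
    if not 0.0 <= contradiction_tolerance <= 1.0:
        raise ValueError("tolerance must lie in [0, 1]")
    state_counts = tabulate_states(cells, lesions)
    mut, mis = _lesion_flags(cells, lesions)

    active = [k for k in range(len(lesions)) if (mut[:, k] & ~mis[:, k]).any()]
    if len(active) < 2:
        raise InsufficientDataError(
            "need >= 2 lesions with mutant cells to infer an order")

    precedes: dict[tuple[int, int], bool] = {}
    contradictions: dict[tuple[int, int], int] = {}
    for a in active:
        for b in active:
            if a == b:
                continue
            both = ~mis[:, a] & ~mis[:, b]
            n_b = int((mut[:, b] & both).sum())
            viol = int((mut[:, b] & ~mut[:, a] & both).sum())
            contradictions[(a, b)] = viol
            precedes[(a, b)] = n_b > 0 and viol / n_b <= contradiction_tolerance

    flagged: list[tuple[str, str]] = []
    edges: list[tuple[str, str]] = []
    for a in active:
        for b in active:
            if a >= b:
                continue
            ab, ba = precedes[(a, b)], precedes[(b, a)]
            if ab and not ba:
                edges.append((lesions[a], lesions[b]))
            elif ba and not ab:
                edges.append((lesions[b], lesions[a]))
            elif not ab and not ba:
                flagged.append((lesions[a], lesions[b]))
            # ab and ba: indistinguishable (coincident) — flag as well
            else:
                flagged.append((lesions[a], lesions[b]))

    order: list[str] | None = None
    note = ""
    if not flagged:
        # chain check: sort by number of successors; a strict total order has
        # out-degrees n-1, n-2, ..., 0
        succ = {lesions[k]: 0 for k in active}
        for u, _v in edges:
            succ[u] += 1
        ranked = sorted(succ, key=lambda u: -succ[u])
        if sorted(succ.values(), reverse=True) == list(
                range(len(active) - 1, -1, -1)):
            order = ranked
        else:
            note = "precedence relation is not a chain"
    else:
        note = (f"ambiguous order: {len(flagged)} lesion pair(s) without "
                f"clear precedence")
    n_contra = sum(contradictions[(a, b)] for a, b in precedes if precedes[(a, b)])
    return HierarchyResult(state_counts=state_counts, order=order,
                           precedence=edges, flagged_pairs=flagged,
                           n_contradictory_cells=n_contra, note=note)


def hierarchy_to_dot(result: HierarchyResult) -> str:
    """DOT graph of the inferred precedence relation."""
    lines = ["digraph clonal_hierarchy {"]
    if result.order:
        for u, v in zip(result.order, result.order[1:]):
            lines.append(f'  "{u}" -> "{v}";')
    else:
        for u, v in result.precedence:
            lines.append(f'  "{u}" -> "{v}";')
        for u, v in result.flagged_pairs:
            lines.append(f'  "{u}" -> "{v}" [dir=none, style=dashed];')
    lines.append("}")
    return "\n".join(lines)


def states_to_frame(state_counts: StateCounts) -> pd.DataFrame:
    rows = [{"state": k, "n_cells": v}
            for k, v in sorted(state_counts.counts.items(),
                               key=lambda kv: (-kv[1], kv[0]))]
    rows.append({"state": "unusable", "n_cells": state_counts.n_unusable})
    return pd.DataFrame(rows)
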