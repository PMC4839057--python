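"""Doehlert uniform-shell experimental designs.

A Doehlert design for ``k`` factors places ``k**2 + k + 1`` distinct points in
coded units: the center of the region plus a uniform shell of ``k**2 + k``
points at unit distance from the center, with nearest-neighbour spacing also
equal to one.  The shell is obtained by the simplex-difference construction:
take the ``k + 1`` vertices of a regular unit-edge simplex (first vertex at the
origin) and form all pairwise vertex differences.

The design is deliberately anisotropic in its level structure: the first coded
column takes five distinct values, the middle columns seven, and the last
column three.  This lets an experimenter resolve some factors more finely than
others by choosing which physical factor is mapped onto which column.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoehlertDesign",
    "FactorRange",
    "generate_doehlert",
    "count_levels",
    "assign_factors",
    "scale_to_process",
]

_TOL = 1e-9


@dataclass(frozen=True)
class FactorRange:
    """Process-unit range of one factor: ``value = center + coded * half_range``."""

    name: str
    center: float
    half_range: float

    def __post_init__(self) -> None:
        if not self.half_range > 0:
            raise ValueError(f"half_range for {self.name!r} must be > 0")


@dataclass(frozen=True)
class DoehlertDesign:
    """Coded Doehlert design matrix with factor-to-column bookkeeping.

    Rows are ordered as ``center_replicates`` center points followed by the
    ``k**2 + k`` shell points.  ``factor_assignment`` maps factor names to
    design-matrix columns (0-based).
    """

    k: int
    coded_matrix: np.ndarray
    center_replicates: int
    factor_assignment: dict[str, int]
    level_counts: dict[str, int]

    @property
    def n_runs(self) -> int:
        return self.coded_matrix.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return [n for n, _ in sorted(self.factor_assignment.items(), key=lambda kv: kv[1])]


def _simplex_vertices(k: int) -> np.ndarray:
    """Vertices of a regular k-simplex with unit edges, first vertex at origin."""
    v = np.zeros((k + 1, k))
    for j in range(1, k + 1):
        for i in range(1, j):
            v[j, i - 1] = 1.0 / np.sqrt(2.0 * i * (i + 1))
        v[j, j - 1] = np.sqrt((j + 1) / (2.0 * j))
    return v


def generate_doehlert(k: int, center_replicates: int = 1) -> DoehlertDesign:
    """Generate a coded k-factor Doehlert design.

    Parameters
    ----------
    k
        Number of factors (>= 1).
    center_replicates
        Number of replicated center points (>= 1).  A four-factor design with
        three center replicates has 23 runs.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError("k must be an integer >= 1")
    if not (isinstance(center_replicates, (int, np.integer)) and center_replicates >= 1):
        raise ValueError("center_replicates must be an integer >= 1")

    v = _simplex_vertices(k)
    shell = [v[i] - v[j] for i in range(k + 1) for j in range(k + 1) if i != j]
    matrix = np.vstack([np.zeros((center_replicates, k)), np.asarray(shell)])
    # snap values that are numerically identical across rows to a common
    # representative so that level counting is stable
    names = [f"x{i + 1}" for i in range(k)]
    design = DoehlertDesign(
        k=int(k),
        coded_matrix=matrix,
        center_replicates=int(center_replicates),
        factor_assignment={n: i for i, n in enumerate(names)},
        level_counts={},
    )
    return replace(design, level_counts=count_levels(design))


def _distinct_values(column: np.ndarray, tol: float = _TOL) -> int:
    s = np.sort(np.asarray(column, dtype=float))
    if s.size == 0:
        return 0
    return 1 + int(np.count_nonzero(np.diff(s) > tol))


def count_levels(design: DoehlertDesign) -> dict[str, int]:
    """Distinct coded values per factor (tolerance 1e-9 on coordinates)."""
    return {
        name: _distinct_values(design.coded_matrix[:, col])
        for name, col in design.factor_assignment.items()
    }


def assign_factors(design: DoehlertDesign, assignment: Mapping[str, int]) -> DoehlertDesign:
    """Map physical factor names onto design columns.

    ``assignment`` must be a permutation of the columns ``0..k-1``.  The level
    structure is a property of the columns, so assigning a factor to a middle
    column resolves it at seven levels, to the first at five, to the last at
    three.
    """
    cols = sorted(assignment.values())
    if cols != list(range(design.k)):
        raise ValueError(
            f"assignment must be a permutation of columns 0..{design.k - 1}, got {cols}"
        )
    out = replace(design, factor_assignment=dict(assignment), level_counts={})
    return replace(out, level_counts=count_levels(out))


def scale_to_process(
    design: DoehlertDesign, ranges: Sequence[FactorRange] | Mapping[str, FactorRange]
) -> pd.DataFrame:
    """Scale the coded design to process units.

    Returns a table with one row per run: ``run_id``, the coded settings
    (``<factor>_coded``) and the process-unit settings (``<factor>``), where
    ``value = center + coded * half_range``.
    """
    if not isinstance(ranges, Mapping):
        ranges = {r.name: r for r in ranges}
    missing = [n for n in design.factor_assignment if n not in ranges]
    if missing:
        raise ValueError(f"missing factor range(s): {missing}")

    data: dict[str, np.ndarray] = {"run_id": np.arange(1, design.n_runs + 1)}
    for name in design.factor_names:
        col = design.factor_assignment[name]
        coded = design.coded_matrix[:, col]
        data[f"{name}_coded"] = coded
        r = ranges[name]
        data[name] = r.center + coded * r.half_range
    return pd.DataFrame(data)


def unscale_from_process(
    values: pd.DataFrame, ranges: Sequence[FactorRange] | Mapping[str, FactorRange]
) -> pd.DataFrame:
    """Inverse of :func:`scale_to_process` on the process-unit columns."""
    if not isinstance(ranges, Mapping):
        ranges = {r.name: r for r in ranges}
    out = {}
    for name, r in ranges.items():
        out[name] = (values[name].to_numpy() - r.center) / r.half_range
    return pd.DataFrame(out)
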