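"""Contrast families over the strain x salinity cell means.

Two families are used throughout:

* the **salinity set** — for every strain and every unordered pair of
  salinity levels, the within-strain difference (lower minus higher
  salinity), plus an "average" contrast per salinity pair with all strains
  weighted equally.  For S strains and L levels that is (S+1) * C(L, 2)
  contrasts: 27 in the default 8 x 3 design.
* the **interaction set** — for every pair of strains and every pair of
  salinity levels, the difference of the two strains' salinity responses.
  C(S, 2) * C(L, 2) contrasts: 84 in the default design.

Sign convention: positive logFC means higher expression at the *lower*
salinity ("upregulated in low salinities").
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .containers import ContrastSet, cell_label

__all__ = ["build_salinity_contrasts", "build_interaction_contrasts"]

SALINITY_FAMILY = "salinity-set"
INTERACTION_FAMILY = "interaction-set"
AVERAGE_LABEL = "average"


def _check_layout(strains, salinities, min_strains: int) -> None:
    if len(set(strains)) != len(strains):
        raise ValueError("duplicate strain labels")
    if len(strains) < min_strains:
        raise ValueError(f"need at least {min_strains} strain(s)")
    if len(set(salinities)) != len(salinities):
        raise ValueError("duplicate salinity levels")
    if len(salinities) < 2:
        raise ValueError("need at least 2 salinity levels")


def _cells(strains, salinities) -> list[str]:
    return [cell_label(st, sal) for st in strains for sal in salinities]


def build_salinity_contrasts(strains, salinities) -> ContrastSet:
    """Per-strain and strain-averaged salinity comparisons.

    Ordering: one block of C(L,2) contrasts per strain (salinity pairs in
    combination order, e.g. 8-16, 8-24, 16-24), then the average block.
    """
    _check_layout(strains, salinities, min_strains=1)
    cells = _cells(strains, salinities)
    S = len(strains)
    rows, names = [], []
    pairs = list(combinations(salinities, 2))

    for strain in strains:
        for lo, hi in pairs:
            w = pd.Series(0.0, index=cells)
            w[cell_label(strain, lo)] = 1.0
            w[cell_label(strain, hi)] = -1.0
            rows.append(w)
            names.append(f"{strain}:{lo}-{hi}")
    for lo, hi in pairs:
        w = pd.Series(0.0, index=cells)
        for strain in strains:
            w[cell_label(strain, lo)] = 1.0 / S
            w[cell_label(strain, hi)] = -1.0 / S
        rows.append(w)
        names.append(f"{AVERAGE_LABEL}:{lo}-{hi}")

    weights = pd.DataFrame(rows, index=names)
    return ContrastSet(family=SALINITY_FAMILY, weights=weights)


def build_interaction_contrasts(strains, salinities) -> ContrastSet:
    """Differences of salinity responses between strain pairs.

    For strains (a, b) and salinities (lo, hi) the weights realise
    (cell(a, lo) - cell(a, hi)) - (cell(b, lo) - cell(b, hi)); positive
    values mean strain a responds more strongly (or more positively) to
    low salinity than strain b.
    """
    _check_layout(strains, salinities, min_strains=2)
    cells = _cells(strains, salinities)
    rows, names = [], []

    for a, b in combinations(strains, 2):
        for lo, hi in combinations(salinities, 2):
            w = pd.Series(0.0, index=cells)
            w[cell_label(a, lo)] += 1.0
            w[cell_label(a, hi)] -= 1.0
            w[cell_label(b, lo)] -= 1.0
            w[cell_label(b, hi)] += 1.0
            rows.append(w)
            names.append(f"{a}-vs-{b}:{lo}-{hi}")

    weights = pd.DataFrame(rows, index=names)
    return ContrastSet(family=INTERACTION_FAMILY, weights=weights)


def strain_of_contrast(name: str) -> str:
    """The strain block a salinity-set contrast belongs to ("average" for
    the strain-averaged block)."""
    return name.split(":", 1)[0]


def salinity_pair_of_contrast(name: str) -> str:
    """The salinity-pair tag of a contrast name, e.g. "8-24"."""
    return name.split(":", 1)[1]
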