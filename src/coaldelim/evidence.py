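"""Integrative-evidence stage: comparing partitions and trait support.

Species hypotheses coming from different loci and methods (per-gene GMYC
partitions, MSC delimitations under each prior setting) are compared with
the adjusted Rand index, tested for association with independent
categorical traits (e.g. photobiont morphotype) by a permutation
chi-square, and finally filtered by the conservative rule that a split
counts as well supported only when its posterior probability clears the
threshold under *every* prior combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import TraitTable

__all__ = [
    "Partition",
    "SupportTable",
    "adjusted_rand_index",
    "trait_association_test",
    "aggregate_supported_species",
    "TraitAssociation",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of individuals to delimited units, with a source tag."""

    assignments: Mapping[str, str]
    source: str = ""

    @property
    def individuals(self) -> frozenset[str]:
        return frozenset(self.assignments)

    @property
    def n_units(self) -> int:
        return len(set(self.assignments.values()))

    def labels_for(self, order: Sequence[str]) -> list[str]:
        return [self.assignments[i] for i in order]


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Adjusted Rand index between two partitions of the same individuals.

    1 for identical partitions, 0 in expectation under the permutation
    null; can be negative for partitions that agree less than chance.
    """
    if p1.individuals != p2.individuals:
        only1 = sorted(p1.individuals - p2.individuals)
        only2 = sorted(p2.individuals - p1.individuals)
        raise ValueError(
            f"partitions cover different individuals (e.g. {only1[:3]} vs {only2[:3]})"
        )
    order = sorted(p1.individuals)
    return float(adjusted_rand_score(p1.labels_for(order), p2.labels_for(order)))


@dataclass
class TraitAssociation:
    """Result of the permutation chi-square trait association test."""

    contingency: pd.DataFrame
    statistic: float
    p_value: float
    n_perm: int
    n_used: int
    n_missing: int


def _chi2_stat(table: np.ndarray) -> float:
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = rows @ cols / total
    mask = expected > 0
    return float(((table - expected)[mask] ** 2 / expected[mask]).sum())


def trait_association_test(
    partition: Partition,
    traits: TraitTable,
    trait_name: str,
    n_perm: int = 999,
    seed: int = 0,
) -> TraitAssociation:
    """Permutation chi-square test of partition-trait association.

    The statistic is the chi-square of the units-by-levels contingency
    table; its null distribution comes from randomly permuting trait values
    across individuals, so no asymptotic assumptions enter.  The p-value
    uses the add-one convention ``(1 + #{permuted >= observed}) / (n_perm + 1)``.
    Individuals missing the trait are dropped (counted in ``n_missing``).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    values = traits.trait(trait_name)  # raises for unknown traits
    used = [i for i in sorted(partition.individuals) if values.get(i) is not None]
    n_missing = len(partition.individuals) - len(used)
    units = np.asarray([partition.assignments[i] for i in used])
    levels = np.asarray([values[i] for i in used])
    unit_names = sorted(set(units))
    level_names = sorted(set(levels))
    unit_idx = np.searchsorted(unit_names, units)
    level_idx = np.searchsorted(level_names, levels)

    def tabulate(lv: np.ndarray) -> np.ndarray:
        table = np.zeros((len(unit_names), len(level_names)))
        np.add.at(table, (unit_idx, lv), 1.0)
        return table

    observed_table = tabulate(level_idx)
    observed = _chi2_stat(observed_table)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(level_idx)
        if _chi2_stat(tabulate(perm)) >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return TraitAssociation(
        contingency=pd.DataFrame(
            observed_table, index=unit_names, columns=level_names
        ),
        statistic=observed,
        p_value=float(p),
        n_perm=n_perm,
        n_used=len(used),
        n_missing=n_missing,
    )


@dataclass
class SupportTable:
    """Posterior split support per prior combination.

    ``values`` maps each split (or candidate species) identifier to its
    posterior probability under each prior-combination label; every row
    must cover the same combinations.
    """

    values: dict[str, dict[str, float]]
    combos: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.combos:
            first = next(iter(self.values.values()), {})
            self.combos = list(first)
        for split, row in self.values.items():
            missing = [c for c in self.combos if c not in row]
            if missing:
                raise ValueError(
                    f"split {split!r} lacks prior combinations {missing}"
                )
            for c, pp in row.items():
                if not 0.0 <= pp <= 1.0:
                    raise ValueError(f"PP out of range for {split!r}/{c!r}: {pp}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SupportTable":
        return cls(
            values={str(i): {str(c): float(frame.loc[i, c]) for c in frame.columns}
                    for i in frame.index},
            combos=[str(c) for c in frame.columns],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: [self.values[s][c] for s in self.values] for c in self.combos},
            index=list(self.values),
        )


@dataclass
class SupportDecision:
    split: str
    supported: bool
    prior_sensitive: bool
    min_pp: float
    max_pp: float


def aggregate_supported_species(
    table: SupportTable, threshold: float = 0.95
) -> dict[str, SupportDecision]:
    """Apply the conservative all-priors support rule.

    A split is *well supported* iff its PP strictly exceeds ``threshold``
    under every prior combination.  Splits that clear the threshold under
    some but not all combinations are flagged prior-sensitive.
    """
    out: dict[str, SupportDecision] = {}
    for split, row in table.values.items():
        pps = [row[c] for c in table.combos]
        above = [pp > threshold for pp in pps]
        out[split] = SupportDecision(
            split=split,
            supported=all(above),
            prior_sensitive=any(above) and not all(above),
            min_pp=min(pps),
            max_pp=max(pps),
        )
    return out
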