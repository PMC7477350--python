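"""Spectral-count quantification: count matrices, Rsc fold change, Venn partitions.

The spectral count (SpC) of a mutant proteoform in a sample is the
number of MS/MS spectra assigned to it — a semiquantitative abundance
proxy. Two trait groups are compared with the log2-scale spectral-count
ratio

    Rsc = log2((n2 + f) / (n1 + f)) + log2((t1 - n1 + f) / (t2 - n2 + f))

where n1, n2 are a protein's summed counts in the two groups, t1, t2
the groups' total assigned spectra and f a pseudocount (default 0.5)
that keeps the ratio finite for proteins absent from one group.
|Rsc| > 1 corresponds to more than a two-fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from saavkit.core_io import SampleMetadata, SaavkitError
from saavkit.psm_filter import MutantEvidence


@dataclass
class SpectralCountMatrix:
    """Integer count matrix, rows = entry groups, columns = samples."""

    counts: pd.DataFrame
    column_traits: dict[str, str]

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class DifferentialResult:
    entry_group: str
    n1: int
    n2: int
    t1: int
    t2: int
    rsc: float
    upregulated_flag: bool


@dataclass(frozen=True)
class PartitionSummary:
    """Counts and percentages over the 7 disjoint regions of a 3-set Venn diagram."""

    set_names: tuple[str, str, str]
    region_counts: Mapping[tuple[bool, bool, bool], int]
    total: int
    region_percentages: Mapping[tuple[bool, bool, bool], float]

    def unique_to(self, name: str) -> int:
        i = self.set_names.index(name)
        key = tuple(j == i for j in range(3))
        return self.region_counts[key]

    def common_to_all(self) -> int:
        return self.region_counts[(True, True, True)]


def build_count_matrix(
    evidence: Sequence[MutantEvidence], metadata: Sequence[SampleMetadata]
) -> SpectralCountMatrix:
    """Assemble the complete entry-group x sample matrix, zeros for absent pairs.

    Row and column order is lexicographic, so the matrix is
    deterministic regardless of evidence order.
    """
    traits = {m.sample_id: m.trait for m in metadata}
    for ev in evidence:
        if ev.sample_id not in traits:
            raise SaavkitError(f"sample {ev.sample_id!r} missing from metadata")
    samples = sorted(traits)
    groups = sorted({ev.entry_group for ev in evidence})
    df = pd.DataFrame(0, index=groups, columns=samples, dtype=int)
    for ev in evidence:
        df.loc[ev.entry_group, ev.sample_id] += ev.spectral_count
    return SpectralCountMatrix(df, {s: traits[s] for s in samples})


def rsc(n1: int, n2: int, t1: int, t2: int, f: float = 0.5) -> float:
    """Log2 spectral-count ratio with pseudocount ``f``.

    Antisymmetric under swapping the two groups: rsc(a, b, ta, tb) ==
    -rsc(b, a, tb, ta).
    """
    if f <= 0:
        raise ValueError("pseudocount f must be positive")
    if t1 < n1 or t2 < n2:
        raise SaavkitError("total less than protein count")
    return math.log2((n2 + f) / (n1 + f)) + math.log2((t1 - n1 + f) / (t2 - n2 + f))


def group_compare(
    matrix: SpectralCountMatrix,
    trait_a: str,
    trait_b: str,
    threshold: float = 1.0,
    f: float = 0.5,
) -> tuple[list[DifferentialResult], dict[str, set[str]]]:
    """Rsc comparison between two trait groups plus per-trait unique-presence sets.

    Per protein: n = summed counts over the trait's samples; t = the
    grand total of counts over those samples (all proteins). Proteins
    with zero counts in both groups are dropped. The second return value
    maps each trait to the set of proteins detected only in its samples.
    """
    cols_a = [s for s, t in matrix.column_traits.items() if t == trait_a]
    cols_b = [s for s, t in matrix.column_traits.items() if t == trait_b]
    if not cols_a or not cols_b:
        missing = trait_a if not cols_a else trait_b
        raise SaavkitError(f"trait {missing!r} has no samples in the matrix")
    na = matrix.counts[cols_a].sum(axis=1)
    nb = matrix.counts[cols_b].sum(axis=1)
    t1, t2 = int(na.sum()), int(nb.sum())
    results = []
    for protein in matrix.counts.index:
        n1, n2 = int(na[protein]), int(nb[protein])
        if n1 == 0 and n2 == 0:
            continue
        value = rsc(n1, n2, t1, t2, f)
        results.append(
            DifferentialResult(protein, n1, n2, t1, t2, value, abs(value) > threshold)
        )
    uniques = {
        trait_a: set(na.index[(na > 0) & (nb == 0)]),
        trait_b: set(nb.index[(nb > 0) & (na == 0)]),
    }
    return results, uniques


def percent_of(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total, rounded half-up (matching printed-table convention)."""
    if total == 0:
        raise SaavkitError("percentage of zero total")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    q = Decimal(100) * Decimal(count) / Decimal(total)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def partition_summary(presence_sets: Mapping[str, set[str]]) -> PartitionSummary:
    """Partition the union of three presence sets into the 7 exclusive Venn regions."""
    if len(presence_sets) != 3:
        raise ValueError("exactly three presence sets required")
    names = tuple(presence_sets)
    sets = [presence_sets[n] for n in names]
    union = set().union(*sets)
    counts: dict[tuple[bool, bool, bool], int] = {}
    for key in (
        (a, b, c) for a in (False, True) for b in (False, True) for c in (False, True)
    ):
        if not any(key):
            continue
        counts[key] = 0
    for element in union:
        key = tuple(element in s for s in sets)
        counts[key] += 1
    total = len(union)
    percentages = {
        key: (percent_of(count, total) if total else 0.0) for key, count in counts.items()
    }
    return PartitionSummary(names, counts, total, percentages)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-wise sorted means.

    Ties within a column receive the mean of the quantile values they
    span (average-rank convention). Idempotent up to numerical noise.
    """
    if matrix.shape[1] < 1:
        raise ValueError("need at least one column")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = np.empty(len(reference))
        col[np.argsort(values[:, j], kind="stable")] = reference
        # tied input values share the mean of the quantile values they span
        out[:, j] = pd.Series(col).groupby(values[:, j]).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
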