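"""Bioactivity curation and fingerprint feature selection.

Turns raw per-assay IC50 records into one pIC50 value per compound, splits
the modelling table, and selects fingerprint bits by correlation-based
feature selection (CFS) with a best-first subset search.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FingerprintDataset

__all__ = [
    "ActivityRecord",
    "SplitIndices",
    "FeatureSelection",
    "curate_activities",
    "to_pic50",
    "split_dataset",
    "cfs_select",
    "cfs_merit",
    "make_folds",
]

logger = logging.getLogger(__name__)

#: IC50 class boundary (nM) separating "active" (< 1000) from "inactive"
CLASS_BOUNDARY_NM = 1000.0

_UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6, "µM": 1e-6, "M": 1.0}


@dataclass
class ActivityRecord:
    """One assay measurement: IC50 in nM with its relational qualifier."""

    compound_id: str
    ic50_value: float  # nM
    qualifier: str = "eq"  # eq | gt | lt
    source: str = ""

    def __post_init__(self) -> None:
        if self.qualifier not in ("eq", "gt", "lt"):
            raise ValueError("qualifier must be eq, gt or lt")


@dataclass
class SplitIndices:
    train: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test overlap")


@dataclass
class FeatureSelection:
    selected_bits: list[int]
    merit: float
    search_trace: list[tuple[tuple[int, ...], float]] = field(default_factory=list)


def to_pic50(ic50: float, unit: str = "nM") -> float:
    """pIC50 = −log10(IC50 in mol/L); for nM this is 9 − log10(value)."""
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown unit {unit!r}")
    if not (ic50 > 0 and math.isfinite(ic50)):
        raise ValueError("IC50 must be positive and finite")
    return -math.log10(ic50 * _UNIT_TO_MOLAR[unit])


def curate_activities(records: list[ActivityRecord]) -> pd.DataFrame:
    """Collapse raw assay records into one IC50/pIC50 row per compound.

    Rules:

    - records with non-positive IC50 are rejected (logged);
    - a compound's exact (``eq``) measurements are collapsed to their median
      (mean of the central pair for even counts);
    - qualified records (``gt``/``lt``) survive only when the inequality pins
      the compound's 1000 nM activity class — ``gt`` with a bound ≥ 1000 nM
      or ``lt`` with a bound ≤ 1000 nM — and then contribute their bound as
      the working IC50; class-ambiguous qualified records are dropped;
    - when a compound has both exact and surviving qualified records, the
      exact median wins; ``class_consistent`` flags whether every surviving
      record agrees on the activity class.

    Returns a DataFrame with columns ``compound_id, ic50_nM, pIC50,
    qualifier, n_records, is_active, class_consistent``.
    """
    if not records:
        raise ValueError("no records to curate")
    by_compound: dict[str, list[ActivityRecord]] = {}
    for rec in records:
        if not (rec.ic50_value > 0 and math.isfinite(rec.ic50_value)):
            logger.warning(
                "rejecting record for %s: non-positive IC50 %r", rec.compound_id, rec.ic50_value
            )
            continue
        by_compound.setdefault(rec.compound_id, []).append(rec)

    rows = []
    for cid in sorted(by_compound):
        recs = by_compound[cid]
        exact = [r.ic50_value for r in recs if r.qualifier == "eq"]
        qualified = [
            r
            for r in recs
            if r.qualifier == "gt"
            and r.ic50_value >= CLASS_BOUNDARY_NM
            or r.qualifier == "lt"
            and r.ic50_value <= CLASS_BOUNDARY_NM
        ]
        for r in recs:
            if r.qualifier != "eq" and r not in qualified:
                logger.info(
                    "dropping class-ambiguous qualified record for %s (%s %g nM)",
                    cid,
                    r.qualifier,
                    r.ic50_value,
                )
        classes = set()
        if exact:
            value = float(np.median(exact))
            qualifier = "eq"
            classes.add(value < CLASS_BOUNDARY_NM)
            classes.update(q.qualifier == "lt" for q in qualified)
        elif qualified:
            # a gt bound places the compound in the inactive class, lt in the
            # active class; use the tightest bound as the working value
            value = float(np.median([q.ic50_value for q in qualified]))
            qualifier = qualified[0].qualifier
            classes.update(q.qualifier == "lt" for q in qualified)
        else:
            continue
        rows.append(
            {
                "compound_id": cid,
                "ic50_nM": value,
                "pIC50": to_pic50(value, "nM"),
                "qualifier": qualifier,
                "n_records": len(recs),
                "is_active": bool(value < CLASS_BOUNDARY_NM),
                "class_consistent": len(classes) <= 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "ic50_nM",
            "pIC50",
            "qualifier",
            "n_records",
            "is_active",
            "class_consistent",
        ],
    )


def split_dataset(ds: FingerprintDataset, test_fraction: float = 0.10, seed: int = 0) -> SplitIndices:
    """Uniform random train/test split; test size = ``ceil(n·fraction)``
    (minimum 1), so 103 compounds at 10% give a 92/11 split."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = ds.n_compounds
    if n < 2:
        raise ValueError("need at least two rows to split")
    n_test = max(1, math.ceil(n * test_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitIndices(train=np.sort(perm[n_test:]), test=np.sort(perm[:n_test]), seed=seed)


def make_folds(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Seeded k-fold assignment vector; fold sizes differ by at most one."""
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    base, extra = divmod(n, k)
    start = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        folds[perm[start : start + size]] = f
        start += size
    return folds


def cfs_merit(cf: np.ndarray, ff: np.ndarray, subset: tuple[int, ...]) -> float:
    """CFS merit M(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff) for a feature subset,
    given |feature–activity| correlations ``cf`` and the |feature–feature|
    correlation matrix ``ff``."""
    k = len(subset)
    if k == 0:
        return 0.0
    idx = np.asarray(subset)
    r_cf = cf[idx].mean()
    if k == 1:
        return float(r_cf)
    sub = ff[np.ix_(idx, idx)]
    r_ff = (sub.sum() - k) / (k * (k - 1))
    return float(k * r_cf / math.sqrt(k + k * (k - 1) * r_ff))


def _correlations(bits: np.ndarray, activity: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Absolute Pearson correlations (feature↔activity, feature↔feature) on
    the non-constant columns; returns (usable column indices, cf, ff)."""
    x = bits.astype(float)
    std = x.std(axis=0)
    usable = np.flatnonzero(std > 0)
    x = x[:, usable]
    xc = x - x.mean(axis=0)
    yc = activity - activity.mean()
    y_norm = math.sqrt(float(yc @ yc))
    col_norm = np.sqrt((xc**2).sum(axis=0))
    cf = np.abs(xc.T @ yc) / (col_norm * y_norm)
    ff = np.abs((xc.T @ xc) / np.outer(col_norm, col_norm))
    np.fill_diagonal(ff, 1.0)
    return usable, cf, ff


def cfs_select(
    ds: FingerprintDataset,
    max_stale: int = 5,
    max_expansions: int | None = None,
) -> FeatureSelection:
    """Correlation-based feature selection with a best-first subset search.

    Starting from the empty set, the search repeatedly expands the
    highest-merit open subset by adding each unused bit; it terminates after
    ``max_stale`` consecutive expansions that fail to improve the incumbent
    best merit.  Zero-variance columns are excluded before the search.

    Returns the best subset found (indices refer to the dataset's original
    columns), its merit, and a trace of ``(subset, merit)`` incumbents.
    """
    if ds.n_bits < 2:
        raise ValueError("need at least 2 fingerprint columns")
    if ds.activity.std() == 0:
        raise ValueError("activity has zero variance")
    usable, cf, ff = _correlations(ds.bits, ds.activity)
    if usable.size == 0:
        logger.warning("all fingerprint columns are constant; empty selection")
        return FeatureSelection(selected_bits=[], merit=0.0)
    m = usable.size

    best_subset: tuple[int, ...] = ()
    best_merit = 0.0
    trace: list[tuple[tuple[int, ...], float]] = []
    # open list keyed by -merit; entries carry the subset as a sorted tuple
    counter = itertools.count()
    open_heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, next(counter), ())]
    seen: set[tuple[int, ...]] = {()}
    stale = 0
    expansions = 0

    while open_heap and stale < max_stale:
        if max_expansions is not None and expansions >= max_expansions:
            break
        _, _, subset = heapq.heappop(open_heap)
        expansions += 1
        improved = False
        in_subset = set(subset)
        for j in range(m):
            if j in in_subset:
                continue
            child = tuple(sorted(subset + (j,)))
            if child in seen:
                continue
            seen.add(child)
            merit = cfs_merit(cf, ff, child)
            heapq.heappush(open_heap, (-merit, next(counter), child))
            if merit > best_merit + 1e-12:
                best_subset, best_merit = child, merit
                trace.append((tuple(int(usable[i]) for i in child), merit))
                improved = True
        stale = 0 if improved else stale + 1

    selected = sorted(int(usable[i]) for i in best_subset)
    return FeatureSelection(selected_bits=selected, merit=best_merit, search_trace=trace)
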