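"""Virtual-screening funnel analytics.

ROC/enrichment validation of scoring protocols, Z-normalised consensus
scoring, benchmark-threshold and top-N selection, hit-list intersection, and
cognate-pose RMSD — the decision logic that turns raw score tables into a
shortlist.
"""

from __future__ import annotations

import math

import numpy as np

from ._stats import mann_whitney_auc
from .datatypes import PosePair, RankedList, ScoreTable

__all__ = [
    "roc_auc",
    "enrichment_factor",
    "znorm_consensus",
    "rank_protocol",
    "apply_score_threshold",
    "intersect_hits",
    "pose_rmsd",
    "merge_score_tables",
]


def roc_auc(table: ScoreTable, protocol: str) -> float:
    """ROC AUC of one protocol's scores against the table's active labels,
    with the protocol's score direction applied (midrank ties)."""
    if table.labels is None:
        raise ValueError("score table has no activity labels")
    return mann_whitney_auc(table.oriented(protocol), table.labels)


def _ranked_order(table: ScoreTable, oriented: np.ndarray) -> np.ndarray:
    """Indices sorted best-first; ties broken lexicographically by id."""
    ids = np.asarray(table.compound_ids)
    return np.lexsort((ids, -oriented))


def enrichment_factor(table: ScoreTable, protocol: str, fraction: float = 0.05) -> float:
    """Enrichment factor EF(fraction) of a protocol's ranking.

    ``EF = (actives among the top ⌈fraction·N⌉) / ⌈fraction·N⌉ ÷ (A/N)``
    where A is the number of actives among the N scored compounds.  EF(1) is
    identically 1; an uninformative ranking has expectation 1.
    """
    if table.labels is None:
        raise ValueError("score table has no activity labels")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = table.n_compounds
    n_active = int(table.labels.sum())
    if n_active == 0:
        raise ValueError("EF undefined: no active compounds")
    top = math.ceil(fraction * n)
    order = _ranked_order(table, table.oriented(protocol))
    hits = int(table.labels[order[:top]].sum())
    return (hits / top) / (n_active / n)


def rank_protocol(table: ScoreTable, protocol: str) -> RankedList:
    """Best-first ranking of one protocol (direction-aware, id tie-break)."""
    oriented = table.oriented(protocol)
    order = _ranked_order(table, oriented)
    return RankedList(
        compound_ids=[table.compound_ids[i] for i in order],
        ranking_score=oriented[order],
        provenance=protocol,
    )


def znorm_consensus(table: ScoreTable, protocols: list[str] | None = None) -> RankedList:
    """Z-normalised consensus ranking over a subset of protocols.

    Each protocol's scores are standardised over the table, oriented so that
    larger means better (lower-better protocols are negated), and summed; the
    consensus list is ranked by descending summed z-score.  Positive affine
    transforms of any single protocol's raw scores leave the result
    unchanged.
    """
    if protocols is None:
        protocols = list(table.protocol_names)
    if len(protocols) < 2:
        raise ValueError("consensus needs at least two protocols")
    z_sum = np.zeros(table.n_compounds)
    for protocol in protocols:
        oriented = table.oriented(protocol)
        sd = oriented.std()
        if sd == 0:
            raise ValueError(f"protocol {protocol!r} has zero score variance")
        z_sum += (oriented - oriented.mean()) / sd
    order = _ranked_order(table, z_sum)
    return RankedList(
        compound_ids=[table.compound_ids[i] for i in order],
        ranking_score=z_sum[order],
        provenance="consensus:" + "+".join(protocols),
    )


def apply_score_threshold(table: ScoreTable, protocol: str, benchmark: float) -> set[str]:
    """Compounds scoring equal-or-better than a benchmark under the
    protocol's direction (for docking energies: score ≤ benchmark)."""
    col = table.column(protocol)
    if table.directions[protocol] == "lower_better":
        keep = col <= benchmark
    else:
        keep = col >= benchmark
    return {cid for cid, k in zip(table.compound_ids, keep) if k}


def intersect_hits(lists: list[RankedList | set[str]]) -> tuple[set[str], dict[str, int]]:
    """Intersection of hit lists, plus pairwise and total overlap sizes.

    Returns ``(shared ids, sizes)`` where ``sizes`` contains each list's own
    size, every pairwise intersection and the total intersection, keyed for
    Venn-style reporting.
    """
    if len(lists) < 2:
        raise ValueError("need at least two hit lists")
    sets = [lst.id_set() if isinstance(lst, RankedList) else set(lst) for lst in lists]
    names = [
        lst.provenance if isinstance(lst, RankedList) and lst.provenance else f"list{i}"
        for i, lst in enumerate(lists)
    ]
    sizes: dict[str, int] = {name: len(s) for name, s in zip(names, sets)}
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            sizes[f"{names[i]} & {names[j]}"] = len(sets[i] & sets[j])
    shared = set.intersection(*sets)
    sizes["all"] = len(shared)
    return shared, sizes


def pose_rmsd(pair: PosePair, threshold: float = 2.0) -> tuple[float, bool]:
    """Cognate-docking RMSD between two poses sharing the receptor frame.

    No superposition is applied — both poses live in the same coordinate
    system, so rigid displacement of a pose counts in full.  Returns the
    RMSD in Å and a pass flag at ``threshold`` (default 2.0 Å).
    """
    a = pair.coords_a[pair.correspondence[:, 0]]
    b = pair.coords_b[pair.correspondence[:, 1]]
    rmsd = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    return rmsd, rmsd < threshold


def merge_score_tables(tables: list[ScoreTable]) -> ScoreTable:
    """Column-join single-protocol tables that share the same compounds."""
    if not tables:
        raise ValueError("nothing to merge")
    base = tables[0]
    ids = list(base.compound_ids)
    for t in tables[1:]:
        if list(t.compound_ids) != ids:
            raise ValueError("tables must share identical compound ordering")
    names: list[str] = []
    directions: dict[str, str] = {}
    cols = []
    for t in tables:
        for p in t.protocol_names:
            if p in names:
                raise ValueError(f"duplicate protocol name {p!r}")
            names.append(p)
            directions[p] = t.directions[p]
            cols.append(t.column(p))
    labels = base.labels
    return ScoreTable(ids, names, np.column_stack(cols), directions, labels=labels)
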