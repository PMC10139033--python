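"""Core in-memory containers shared across the screening-funnel stages.

Each container is a light dataclass around numpy arrays / pandas frames with
validation at construction; the analysis modules operate on these rather than
on raw files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FingerprintDataset",
    "PredictionSet",
    "ScoreTable",
    "RankedList",
    "PosePair",
    "Trajectory",
    "AtomSelection",
]


@dataclass
class FingerprintDataset:
    """Binary fingerprint matrix plus a pIC50 activity vector.

    Parameters
    ----------
    ids : list of str
        One compound identifier per row.
    bits : (n, m) ndarray of {0, 1}
        Fingerprint matrix; each column is one structural-fragment bit.
    activity : (n,) ndarray
        pIC50 values (−log10 of IC50 in mol/L).
    fingerprint_name : str
        Label for the fingerprint family (e.g. ``"cdk-extended"``).
    metadata : dict
        Free-form provenance (planted bits, generator seed, ...).
    """

    ids: list[str]
    bits: np.ndarray
    activity: np.ndarray
    fingerprint_name: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-D matrix")
        n = self.bits.shape[0]
        if len(self.ids) != n or self.activity.shape != (n,):
            raise ValueError("ids, bits and activity must agree on row count")
        uniq = np.unique(self.bits)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("fingerprint entries must be 0/1")

    @property
    def n_compounds(self) -> int:
        return self.bits.shape[0]

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def subset_rows(self, index: Sequence[int]) -> "FingerprintDataset":
        index = np.asarray(index, dtype=int)
        return FingerprintDataset(
            ids=[self.ids[i] for i in index],
            bits=self.bits[index],
            activity=self.activity[index],
            fingerprint_name=self.fingerprint_name,
            metadata=dict(self.metadata),
        )

    def subset_bits(self, columns: Sequence[int]) -> "FingerprintDataset":
        columns = np.asarray(columns, dtype=int)
        return FingerprintDataset(
            ids=list(self.ids),
            bits=self.bits[:, columns],
            activity=self.activity.copy(),
            fingerprint_name=self.fingerprint_name,
            metadata={**self.metadata, "selected_columns": columns.tolist()},
        )

    def to_frame(self) -> pd.DataFrame:
        width = len(str(self.n_bits))
        cols = [f"bit_{i + 1:0{width}d}" for i in range(self.n_bits)]
        frame = pd.DataFrame(self.bits, columns=cols)
        frame.insert(0, "compound_id", self.ids)
        frame["pIC50"] = self.activity
        return frame


@dataclass
class PredictionSet:
    """Paired observed/predicted activities, the input to validation metrics.

    ``kind`` records provenance: ``"cv"`` / ``"loo"`` for cross-validated
    predictions, ``"external"`` for an independent test set, ``"train"`` for
    resubstitution.  ``train_mean``, ``n_train`` and ``train_ss`` (training
    sum of squared deviations about ``train_mean``) carry the training-set
    moments needed by the external Q²F functions.
    """

    observed: np.ndarray
    predicted: np.ndarray
    kind: str = "external"
    train_mean: float | None = None
    n_train: int | None = None
    train_ss: float | None = None
    ids: Optional[list[str]] = None

    _KINDS = ("cv", "loo", "external", "train")

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float).ravel()
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        if self.observed.shape != self.predicted.shape:
            raise ValueError("observed and predicted must have equal length")
        if self.observed.size < 2:
            raise ValueError("need at least two observations")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if not (np.all(np.isfinite(self.observed)) and np.all(np.isfinite(self.predicted))):
            raise ValueError("observed/predicted must be finite")

    @property
    def n(self) -> int:
        return self.observed.size


@dataclass
class ScoreTable:
    """Per-compound scores across named scoring protocols.

    ``directions`` maps each protocol to ``"lower_better"`` (docking energies)
    or ``"higher_better"``; ranked operations honour it.  ``labels`` is an
    optional active/inactive flag per compound for enrichment work.
    """

    compound_ids: list[str]
    protocol_names: list[str]
    scores: np.ndarray
    directions: dict[str, str]
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim == 1:
            self.scores = self.scores[:, None]
        n, p = self.scores.shape
        if len(self.compound_ids) != n:
            raise ValueError("compound_ids length must match score rows")
        if len(self.protocol_names) != p:
            raise ValueError("protocol_names length must match score columns")
        missing = set(self.protocol_names) - set(self.directions)
        if missing:
            raise ValueError(f"directions missing for protocols: {sorted(missing)}")
        for d in self.directions.values():
            if d not in ("lower_better", "higher_better"):
                raise ValueError("direction must be lower_better or higher_better")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool).ravel()
            if self.labels.shape != (n,):
                raise ValueError("labels length must match compounds")

    @property
    def n_compounds(self) -> int:
        return self.scores.shape[0]

    def column(self, protocol: str) -> np.ndarray:
        try:
            j = self.protocol_names.index(protocol)
        except ValueError as exc:
            raise KeyError(f"unknown protocol {protocol!r}") from exc
        return self.scores[:, j]

    def oriented(self, protocol: str) -> np.ndarray:
        """Scores flipped so that larger is always better."""
        col = self.column(protocol)
        if self.directions[protocol] == "lower_better":
            return -col
        return col


@dataclass
class RankedList:
    """An ordered hit list with its ranking scores (non-improving order)."""

    compound_ids: list[str]
    ranking_score: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.ranking_score = np.asarray(self.ranking_score, dtype=float).ravel()
        if len(self.compound_ids) != self.ranking_score.size:
            raise ValueError("ids and scores must align")
        if np.any(np.diff(self.ranking_score) > 1e-12):
            raise ValueError("ranking_score must be non-increasing")

    def top(self, n: int) -> "RankedList":
        return RankedList(
            self.compound_ids[:n], self.ranking_score[:n], provenance=self.provenance
        )

    def id_set(self) -> set[str]:
        return set(self.compound_ids)


@dataclass
class PosePair:
    """Two poses of the same molecule in a shared receptor frame."""

    coords_a: np.ndarray
    coords_b: np.ndarray
    correspondence: Optional[np.ndarray] = None  # (k, 2) index pairs

    def __post_init__(self) -> None:
        self.coords_a = np.asarray(self.coords_a, dtype=float)
        self.coords_b = np.asarray(self.coords_b, dtype=float)
        for c in (self.coords_a, self.coords_b):
            if c.ndim != 2 or c.shape[1] != 3:
                raise ValueError("coordinates must be (N, 3)")
        if self.correspondence is None:
            if self.coords_a.shape != self.coords_b.shape:
                raise ValueError("implicit correspondence needs equal atom counts")
            n = self.coords_a.shape[0]
            self.correspondence = np.column_stack([np.arange(n), np.arange(n)])
        self.correspondence = np.asarray(self.correspondence, dtype=int)
        if self.correspondence.size == 0:
            raise ValueError("empty atom correspondence")
        a_idx, b_idx = self.correspondence[:, 0], self.correspondence[:, 1]
        if len(np.unique(a_idx)) != len(a_idx) or len(np.unique(b_idx)) != len(b_idx):
            raise ValueError("correspondence must be a bijection")


#: columns required in the per-atom metadata table of a Trajectory
ATOM_COLUMNS = (
    "residue_index",
    "residue_name",
    "atom_name",
    "element",
    "mass",
    "chain",
    "backbone",
)

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


def make_atom_table(records: Sequence[tuple]) -> pd.DataFrame:
    """Build an atom metadata table from ``(residue_index, residue_name,
    atom_name, element, backbone_flag, mass)`` tuples, inferring the chain
    tag from the residue name (LIG/UNL → ligand, HOH/WAT/SOL → solvent)."""
    rows = []
    for residue_index, residue_name, atom_name, element, backbone, mass in records:
        if residue_name in ("LIG", "UNL", "UNK"):
            chain = "ligand"
        elif residue_name in ("HOH", "WAT", "SOL"):
            chain = "solvent"
        else:
            chain = "protein"
        rows.append(
            {
                "residue_index": int(residue_index),
                "residue_name": residue_name,
                "atom_name": atom_name,
                "element": element,
                "mass": float(mass),
                "chain": chain,
                "backbone": bool(backbone),
            }
        )
    return pd.DataFrame(rows, columns=list(ATOM_COLUMNS))


@dataclass
class Trajectory:
    """Cartesian trajectory: ``coords`` is (frames, atoms, 3) in Å.

    ``atoms`` is a DataFrame with one row per atom and the columns in
    :data:`ATOM_COLUMNS`; ``time_per_frame`` is the sampling interval in ps.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    time_per_frame: float = 2.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (F, N, 3)")
        if self.coords.shape[0] < 1 or self.coords.shape[1] < 1:
            raise ValueError("need at least one frame and one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table must match coordinate atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class AtomSelection:
    """A set of atom indices into a trajectory plus its defining string."""

    indices: np.ndarray
    definition: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int).ravel()
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("selection indices must be unique")

    def __len__(self) -> int:
        return self.indices.size
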