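"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Three generators stand in for the real screening inputs: a fingerprint
activity dataset with a planted linear bit–activity signal, active/inactive
score distributions for enrichment validation, and trajectories built from
per-atom Gaussian fluctuation, rigid-body motion and a scheduled
hydrogen-bond geometry.  Everything is bitwise reproducible under a fixed
seed.  No attempt is made at realistic chemistry: fingerprints are abstract
bit vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import FingerprintDataset, ScoreTable, Trajectory, make_atom_table

__all__ = [
    "SyntheticSpec",
    "ScoreSimSpec",
    "RigidMotion",
    "TrajSimSpec",
    "gen_qsar_dataset",
    "gen_score_set",
    "gen_trajectory",
]

#: pIC50 window of the curated kinase-inhibition set the generator emulates
DEFAULT_ACTIVITY_RANGE = (4.398, 7.721)


@dataclass
class SyntheticSpec:
    """Parameters of the planted-signal fingerprint dataset.

    Defaults emulate the curated modelling table: 103 compounds, a 1024-bit
    fingerprint, pIC50 spanning [4.398, 7.721].  ``effect_weights`` are in
    pIC50 units per set bit (before the affine rescale that maps the
    noiseless signal onto ``activity_range``); ``noise_sd`` is additive
    Gaussian noise in pIC50 units, applied after the rescale.
    """

    n_compounds: int = 103
    n_bits: int = 1024
    n_informative: int = 10
    effect_weights: Optional[np.ndarray] = None  # defaults to ones
    noise_sd: float = 0.3
    activity_range: tuple[float, float] = DEFAULT_ACTIVITY_RANGE
    bit_prob_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_bits:
            raise ValueError("n_informative must not exceed n_bits")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.activity_range
        if not lo < hi:
            raise ValueError("activity_range must satisfy low < high")
        if self.effect_weights is None:
            self.effect_weights = np.ones(self.n_informative)
        self.effect_weights = np.asarray(self.effect_weights, dtype=float)
        if self.effect_weights.shape != (self.n_informative,):
            raise ValueError("effect_weights must have length n_informative")


def gen_qsar_dataset(spec: SyntheticSpec) -> FingerprintDataset:
    """Generate a fingerprint dataset with a planted linear activity signal.

    Uninformative bits are Bernoulli(p) with p drawn once per bit from
    U(bit_prob_range); the noiseless signal ``Σ wⱼ·bitⱼ`` over the planted
    informative bits is affinely rescaled to span ``activity_range`` exactly,
    and Gaussian noise of sd ``noise_sd`` is then added.  The planted bit
    indices, rescale coefficients and effective (post-rescale) weights are
    recorded in the metadata.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_compounds, spec.n_bits
    p = rng.uniform(*spec.bit_prob_range, size=m)
    bits = (rng.random((n, m)) < p).astype(np.int8)
    informative = np.sort(rng.choice(m, size=spec.n_informative, replace=False))

    signal = bits[:, informative].astype(float) @ spec.effect_weights
    lo, hi = spec.activity_range
    span = signal.max() - signal.min()
    if span > 0:
        slope = (hi - lo) / span
        intercept = lo - slope * signal.min()
    else:  # degenerate signal (e.g. no informative bits): park at midpoint
        slope = 0.0
        intercept = (lo + hi) / 2.0
    activity = intercept + slope * signal + rng.normal(0.0, spec.noise_sd, size=n)

    width = len(str(n))
    ids = [f"SYN{i + 1:0{width}d}" for i in range(n)]
    return FingerprintDataset(
        ids=ids,
        bits=bits,
        activity=activity,
        fingerprint_name="synthetic-bits",
        metadata={
            "planted_bits": informative.tolist(),
            "effect_weights": spec.effect_weights.tolist(),
            "effective_weights": (slope * spec.effect_weights).tolist(),
            "rescale_slope": slope,
            "rescale_intercept": intercept,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    )


@dataclass
class ScoreSimSpec:
    """Two-Gaussian score model for enrichment/AUC validation fixtures."""

    n_active: int = 100
    n_inactive: int = 1900
    mean_active: float = -9.5
    mean_inactive: float = -7.5
    sd_active: float = 1.0
    sd_inactive: float = 1.0
    direction: str = "lower_better"
    protocol_name: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active <= 0 or self.n_inactive <= 0:
            raise ValueError("class counts must be positive")
        if self.sd_active <= 0 or self.sd_inactive <= 0:
            raise ValueError("score sds must be positive")
        if self.direction not in ("lower_better", "higher_better"):
            raise ValueError("bad direction")

    def analytic_auc(self) -> float:
        """Closed-form AUC of the two-Gaussian model,
        Φ(Δ/√(σₐ² + σᵢ²)) with Δ the separation in the favourable
        direction."""
        from scipy.stats import norm

        delta = self.mean_active - self.mean_inactive
        if self.direction == "lower_better":
            delta = -delta
        return float(norm.cdf(delta / np.hypot(self.sd_active, self.sd_inactive)))


def gen_score_set(spec: ScoreSimSpec) -> ScoreTable:
    """Draw Gaussian scores per class into a labelled single-protocol table."""
    rng = np.random.default_rng(spec.seed)
    active = rng.normal(spec.mean_active, spec.sd_active, size=spec.n_active)
    inactive = rng.normal(spec.mean_inactive, spec.sd_inactive, size=spec.n_inactive)
    scores = np.concatenate([active, inactive])
    labels = np.concatenate(
        [np.ones(spec.n_active, dtype=bool), np.zeros(spec.n_inactive, dtype=bool)]
    )
    width = len(str(scores.size))
    ids = [f"CPD{i + 1:0{width}d}" for i in range(scores.size)]
    return ScoreTable(
        compound_ids=ids,
        protocol_names=[spec.protocol_name],
        scores=scores[:, None],
        directions={spec.protocol_name: spec.direction},
        labels=labels,
    )


@dataclass
class RigidMotion:
    """Per-frame rigid-body motion: a translation schedule plus a rotation
    angle schedule about ``axis`` through the template centroid."""

    translations: Optional[np.ndarray] = None  # (F, 3), Å
    rotation_angles: Optional[np.ndarray] = None  # (F,), radians
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def apply(self, coords: np.ndarray, frame: int, centroid: np.ndarray) -> np.ndarray:
        out = coords
        if self.rotation_angles is not None:
            theta = float(self.rotation_angles[frame])
            axis = np.asarray(self.axis, dtype=float)
            axis = axis / np.linalg.norm(axis)
            K = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
            out = (out - centroid) @ R.T + centroid
        if self.translations is not None:
            out = out + np.asarray(self.translations[frame], dtype=float)
        return out


@dataclass
class TrajSimSpec:
    """Parameters of the synthetic trajectory.

    ``atom_template`` rows are ``(residue_index, residue_name, atom_name,
    element, backbone_flag, mass)``; ``reference_coords`` gives the reference
    structure (N × 3, Å).  Each frame is the reference plus isotropic
    Gaussian displacement of sd ``fluct_sd`` per coordinate, then the frame's
    rigid motion.  ``hbond_schedule`` lists ``(donor, hydrogen, acceptor,
    fraction)`` atom-index triples to be placed at conforming hydrogen-bond
    geometry in exactly the scheduled fraction of frames.
    """

    n_frames: int
    atom_template: Sequence[tuple]
    reference_coords: np.ndarray
    fluct_sd: float = 0.3
    rigid_motion: RigidMotion = field(default_factory=RigidMotion)
    hbond_schedule: Sequence[tuple[int, int, int, float]] = ()
    time_per_frame: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if self.fluct_sd < 0:
            raise ValueError("fluct_sd must be non-negative")
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.reference_coords.shape != (len(self.atom_template), 3):
            raise ValueError("reference_coords must be (n_atoms, 3)")
        n = len(self.atom_template)
        for donor, hydrogen, acceptor, fraction in self.hbond_schedule:
            for i in (donor, hydrogen, acceptor):
                if not 0 <= i < n:
                    raise ValueError(f"hbond schedule references unknown atom {i}")
            if not 0.0 <= fraction <= 1.0:
                raise ValueError("scheduled fraction must be in [0, 1]")


#: conforming/non-conforming donor···acceptor distances used by the generator
_HB_ON_DIST = 2.8
_HB_OFF_DIST = 5.0


def gen_trajectory(spec: TrajSimSpec) -> tuple[Trajectory, np.ndarray]:
    """Generate a synthetic trajectory plus its reference structure.

    Frame ``t`` = rigid_motion_t ∘ (reference + N(0, fluct_sd) per
    coordinate).  For every scheduled hydrogen bond, the acceptor is placed
    on the donor→hydrogen ray at 2.8 Å from the donor (D–H···A = 180°,
    conforming) in exactly ``round(fraction · n_frames)`` seeded-random
    frames and at 5.0 Å (non-conforming) otherwise; rigid motion preserves
    the geometry.
    """
    rng = np.random.default_rng(spec.seed)
    atoms = make_atom_table(spec.atom_template)
    n_atoms = len(atoms)
    ref = spec.reference_coords
    centroid = ref.mean(axis=0)

    on_frames: list[np.ndarray] = []
    for *_, fraction in spec.hbond_schedule:
        n_on = int(round(fraction * spec.n_frames))
        chosen = rng.choice(spec.n_frames, size=n_on, replace=False)
        on_frames.append(np.sort(chosen))

    coords = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        frame = ref + rng.normal(0.0, spec.fluct_sd, size=(n_atoms, 3))
        for (donor, hydrogen, acceptor, _), on in zip(spec.hbond_schedule, on_frames):
            u = frame[hydrogen] - frame[donor]
            norm = np.linalg.norm(u)
            if norm == 0:  # degenerate noise draw: fall back to +x
                u = np.array([1.0, 0.0, 0.0])
                norm = 1.0
            u = u / norm
            dist = _HB_ON_DIST if f in on else _HB_OFF_DIST
            frame[acceptor] = frame[donor] + dist * u
        coords[f] = spec.rigid_motion.apply(frame, f, centroid)

    traj = Trajectory(coords=coords, atoms=atoms, time_per_frame=spec.time_per_frame)
    return traj, ref.copy()
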