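"""Synthetic resting-state cohort generator.

Emulates the study design the downstream analysis assumes: two groups of
~23 subjects, 110 parcellated regions, 200 retained volumes at TR = 2 s.
Each subject's regional signal is a stationary multivariate Gaussian process
coloured into the 0.01–0.1 Hz band, drawn from a common block-structured
population correlation matrix.  Group A additionally carries planted
"hub" regions whose correlations with every other region are elevated by a
fixed increment, and every subject's behavioural score is coupled (with a
configurable target correlation) to the realised Fisher-z weight of one
designated edge — the two effects the pipeline is meant to recover.

Motion traces are small-amplitude random walks; ventricle- and white-matter-
like nuisance signals are band-limited noise mixed into the emitted series
with small random loadings so that nuisance regression has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .conditioning import bandpass_sos
from .labels import noi_indices, region_labels

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "build_base_correlation",
    "inject_hub_effect",
    "nearest_correlation",
    "simulate_cohort",
    "plant_motion_outlier",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-group resting-state cohort.

    Defaults reproduce the study conditions: 23 subjects per group, 110
    regions, 200 volumes at TR 2 s, a 0.25 correlation increment on the six
    bilateral body-representation regions (PostC, SPL, IC) in group A, and a
    −0.6 coupling between one insula–postcentral edge weight and the
    behavioural (selfness-like) score.

    Attributes
    ----------
    n_subjects_per_group : int
    n_regions : int
    n_volumes : int
        Retained volumes (205 acquired minus 5 saturation scans).
    tr_seconds : float
    block_size : int
        Width of the equicorrelated blocks of the base correlation matrix.
    within_block_r, between_block_r : float
        Population correlation inside / across blocks.
    hub_regions : tuple of int or None
        Regions given elevated connectivity in group A; ``None`` selects the
        six NOIs for 110 regions, else six evenly spaced regions.
    hub_effect : float
        Additive correlation increment, in [0, 1).
    behavior_edge : (int, int) or None
        Edge whose subject-level weight drives the behavioural score;
        ``None`` selects (IC_R, PostC_R) for 110 regions, else (0, 1).
    behavior_coupling : float
        Target correlation between edge weight and score, in [−1, 1].
    noise_sd : float
        Observation-noise standard deviation, folded into the covariance
        diagonal before band-pass colouring (keeps the signal band-limited).
    nuisance_strength : float
        Scale of the ventricle/white-matter/motion contamination mixed into
        the emitted series (0 disables it).
    motion_step_sd : float
        Random-walk step SD of the motion trace, mm or degrees per volume.
    seed : int
    """

    n_subjects_per_group: int = 23
    n_regions: int = 110
    n_volumes: int = 200
    tr_seconds: float = 2.0
    block_size: int = 11
    within_block_r: float = 0.30
    between_block_r: float = 0.05
    hub_regions: tuple[int, ...] | None = None
    hub_effect: float = 0.25
    behavior_edge: tuple[int, int] | None = None
    behavior_coupling: float = -0.6
    behavior_edge_r: float = 0.35
    noise_sd: float = 0.25
    nuisance_strength: float = 0.2
    motion_step_sd: float = 0.03
    color_filter_order: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_regions < 2 or self.n_volumes < 8:
            raise ValueError("cohort dimensions too small")
        if not 0 <= self.hub_effect < 1:
            raise ValueError(f"hub_effect must be in [0, 1), got {self.hub_effect}")
        if not -1 <= self.behavior_coupling <= 1:
            raise ValueError("behavior_coupling must be in [-1, 1]")
        if self.noise_sd < 0 or self.tr_seconds <= 0:
            raise ValueError("noise_sd and tr_seconds must be positive")
        hubs = self.resolved_hub_regions()
        if len(set(hubs)) != len(hubs) or any(
            not 0 <= h < self.n_regions for h in hubs
        ):
            raise ValueError(f"hub_regions invalid for {self.n_regions} regions: {hubs}")
        a, b = self.resolved_behavior_edge()
        if a == b or not (0 <= a < self.n_regions and 0 <= b < self.n_regions):
            raise ValueError(f"behavior_edge invalid: {(a, b)}")

    def resolved_hub_regions(self) -> tuple[int, ...]:
        if self.hub_regions is not None:
            return tuple(self.hub_regions)
        if self.n_regions == 110:
            return tuple(noi_indices())
        step = max(self.n_regions // 6, 1)
        return tuple(range(0, step * 6, step))[:6]

    def resolved_behavior_edge(self) -> tuple[int, int]:
        if self.behavior_edge is not None:
            a, b = self.behavior_edge
        elif self.n_regions == 110:
            labs = region_labels()
            a, b = labs.index("IC_R"), labs.index("PostC_R")
        else:
            a, b = 0, 1
        return (min(a, b), max(a, b))

    def labels(self) -> list[str]:
        return region_labels(self.n_regions)


@dataclass
class SyntheticSubject:
    """One simulated participant."""

    subject_id: str
    group: str  # "A" or "B"
    timeseries: np.ndarray  # time × region
    motion: np.ndarray  # time × 6 (mm, mm, mm, deg, deg, deg)
    nuisance: np.ndarray  # time × 2 (ventricle-like, white-matter-like)
    behavior_score: float
    region_labels: list[str] = field(default_factory=list)
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")
        if not np.all(np.isfinite(self.timeseries)):
            raise ValueError("timeseries contains non-finite values")
        if np.any(self.timeseries.std(axis=0) == 0):
            raise ValueError("every region must have nonzero variance")
        if not 0 <= self.behavior_score <= 10:
            raise ValueError("behavior_score must lie in [0, 10]")


def build_base_correlation(spec: CohortSpec) -> np.ndarray:
    """Block-structured population correlation matrix shared by both groups.

    Contiguous blocks of ``block_size`` regions are equicorrelated at
    ``within_block_r``; regions in different blocks correlate at
    ``between_block_r``.  The designated behaviour edge is floored at
    ``behavior_edge_r`` so its weight is a monotone function of the signed
    correlation.  The construction is positive definite by design
    (between·J + blockdiag + residual identity).
    """
    n = spec.n_regions
    c = np.full((n, n), spec.between_block_r)
    for start in range(0, n, spec.block_size):
        stop = min(start + spec.block_size, n)
        c[start:stop, start:stop] = spec.within_block_r
    np.fill_diagonal(c, 1.0)
    a, b = spec.resolved_behavior_edge()
    if c[a, b] < spec.behavior_edge_r:
        c[a, b] = c[b, a] = spec.behavior_edge_r
        c = nearest_correlation(c)
    return c


def nearest_correlation(c: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a nearby positive-definite correlation.

    Eigenvalues are floored and the result renormalised to unit diagonal;
    two passes suffice for the mild adjustments made here.
    """
    m = (c + c.T) / 2.0
    for _ in range(2):
        w, v = np.linalg.eigh(m)
        if w.min() >= floor:
            break
        m = (v * np.maximum(w, floor)) @ v.T
        d = 1.0 / np.sqrt(np.diag(m))
        m = m * np.outer(d, d)
        m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return m


def inject_hub_effect(
    base: np.ndarray, hub_regions: Sequence[int], effect: float
) -> np.ndarray:
    """Elevate every correlation touching a hub region by ``effect``.

    Hub–hub pairs are incremented once.  Off-diagonals are capped at 0.95 and
    the matrix projected back to a positive-definite correlation.  Raises if
    the implied matrix cannot be made positive definite.
    """
    if not 0 <= effect < 1:
        raise ValueError(f"hub effect {effect} outside [0, 1)")
    c = base.copy()
    hubs = np.asarray(sorted(set(hub_regions)), dtype=int)
    mask = np.zeros(c.shape, dtype=bool)
    mask[hubs, :] = True
    mask[:, hubs] = True
    np.fill_diagonal(mask, False)
    c[mask] = np.minimum(c[mask] + effect, 0.95)
    c = nearest_correlation(c)
    w = np.linalg.eigvalsh(c)
    if w.min() <= 0:
        raise ValueError(
            f"hub_effect={effect} yields a non-positive-definite population "
            f"correlation (min eigenvalue {w.min():.3g})"
        )
    return c


def _colored_noise(
    rng: np.random.Generator, sos: np.ndarray, shape: tuple[int, ...]
) -> np.ndarray:
    """White Gaussian noise coloured into the analysis band (zero-phase)."""
    return sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=0).copy()


def _band_weight(x: np.ndarray, a: int, b: int) -> float:
    """Signed Fisher z of the Pearson correlation between two columns."""
    r = float(np.corrcoef(x[:, a], x[:, b])[0, 1])
    return float(np.arctanh(np.clip(r, -1 + 1e-6, 1 - 1e-6)))


def simulate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Draw a full two-group cohort; deterministic given ``spec.seed``.

    Group B subjects are drawn from the base correlation structure, group A
    from the hub-augmented one.  After the signals are realised, each
    subject's behavioural score is generated as a linear function of the
    realised behaviour-edge Fisher z (standardised within group) plus
    independent noise, calibrated so the within-group sample correlation
    targets ``behavior_coupling``; scores are mapped to the 0–10 visual-
    analogue scale.
    """
    rng = np.random.default_rng(spec.seed)
    base = build_base_correlation(spec)
    hub = inject_hub_effect(base, spec.resolved_hub_regions(), spec.hub_effect)
    # observation noise on the diagonal, before colouring: keeps the emitted
    # signal band-limited while attenuating correlations uniformly
    cov = {"A": hub + spec.noise_sd**2 * np.eye(spec.n_regions),
           "B": base + spec.noise_sd**2 * np.eye(spec.n_regions)}
    chol = {g: np.linalg.cholesky(c) for g, c in cov.items()}
    sos = bandpass_sos(spec.tr_seconds, order=spec.color_filter_order)
    labels = spec.labels()
    a_idx, b_idx = spec.resolved_behavior_edge()

    subjects: list[SyntheticSubject] = []
    weights: dict[str, list[float]] = {"A": [], "B": []}
    for group in ("A", "B"):
        for k in range(spec.n_subjects_per_group):
            innov = rng.standard_normal((spec.n_volumes, spec.n_regions))
            clean = sps.sosfiltfilt(sos, innov @ chol[group].T, axis=0).copy()
            weights[group].append(_band_weight(clean, a_idx, b_idx))

            motion = np.cumsum(
                rng.normal(0.0, spec.motion_step_sd, size=(spec.n_volumes, 6)), axis=0
            )
            nuis = _colored_noise(rng, sos, (spec.n_volumes, 2))
            ts = clean
            if spec.nuisance_strength > 0:
                load = rng.normal(0.0, 1.0, size=(2, spec.n_regions))
                mload = rng.normal(0.0, 0.2, size=(6, spec.n_regions))
                ts = ts + spec.nuisance_strength * (nuis @ load + motion @ mload)
            subjects.append(
                SyntheticSubject(
                    subject_id=f"{group}{k + 1:02d}",
                    group=group,
                    timeseries=ts,
                    motion=motion,
                    nuisance=nuis,
                    behavior_score=5.0,  # filled below
                    region_labels=labels,
                    tr_seconds=spec.tr_seconds,
                )
            )

    # behaviour scores: score = 5 + s·(rho·z_w + sqrt(1-rho^2)·eps) on 0-10 VAS
    rho = spec.behavior_coupling
    scale = 1.2
    for group in ("A", "B"):
        w = np.asarray(weights[group])
        sd = w.std()
        z = (w - w.mean()) / sd if sd > 0 else np.zeros_like(w)
        eps = rng.standard_normal(len(w))
        raw = 5.0 + scale * (rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * eps)
        members = [s for s in subjects if s.group == group]
        for subj, score in zip(members, np.clip(raw, 0.0, 10.0)):
            subj.behavior_score = float(score)
    return subjects


def plant_motion_outlier(
    subject: SyntheticSubject, volume_index: int, magnitude: float
) -> SyntheticSubject:
    """Return a copy whose first translation parameter equals ``magnitude``
    (mm) at ``volume_index``; everything else is unchanged.

    The downstream screen uses a strict inequality, so magnitude 2.0 still
    passes while 2.5 fails.
    """
    if not 0 <= volume_index < subject.motion.shape[0]:
        raise IndexError(f"volume_index {volume_index} out of range")
    motion = subject.motion.copy()
    motion[volume_index, 0] = magnitude
    return replace(subject, motion=motion)
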