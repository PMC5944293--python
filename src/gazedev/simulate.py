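"""Synthetic nine-point acquisition: subject models and cohort generation.

The simulator emulates the screen-based acquisition protocol so the whole
pipeline is testable without clinical recordings: for each of the nine
targets in display order, binocular samples are drawn at the protocol's
sampling rate, each eye's gaze being the target plus isotropic Gaussian
fixation noise; the deviating eye of a strabismic subject additionally
carries a constant deviation vector whenever the deviation is *expressed*.
Pairs are screened with the effectiveness rule and retained until the
per-target quota is met or the display time runs out.

Subject kinds
-------------
``normal``
    No deviation; fixation noise only (plus optional attention lapses).
``recessive``
    A small deviation (phoria-scale, default magnitude 0.02-0.06) expressed
    throughout; hard to separate from a sloppy normal fixator.
``intermittent``
    A tropia-scale deviation expressed only during a random fraction of
    0.5-second dwell segments; fixation alternates between fused and
    deviated states on the timescale of fixations, not samples.
``manifest``
    A tropia-scale deviation (default magnitude 0.1-0.3) expressed
    throughout, on the deviating eye only.
``incomitant``
    A manifest-style deviation expressed only at a subset of the nine
    targets (gaze-direction-dependent misalignment).

Attention lapses model momentary inattention in *any* subject: with a small
per-sample probability both eyes jump by a common isotropic offset of
magnitude 0.1-0.3, producing the occasional far-from-target sample that
gives even normal subjects a deviation tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import GazePair, GazeSession, ProtocolConfig

__all__ = [
    "SubjectModel",
    "CohortSpec",
    "STRABISMUS_KINDS",
    "simulate_session",
    "simulate_cohort",
]

STRABISMUS_KINDS = ("recessive", "intermittent", "manifest", "incomitant")
KINDS = ("normal",) + STRABISMUS_KINDS

#: Dwell-segment length (seconds) of the two-state intermittency process.
SEGMENT_SECONDS = 0.5

_LAPSE_MAGNITUDE = (0.1, 0.3)


@dataclass(frozen=True)
class SubjectModel:
    """Generative model of one subject's fixation behaviour."""

    kind: str = "normal"
    fixation_noise_sd: float = 0.01
    deviation_vector: tuple[float, float] = (0.0, 0.0)
    deviating_eye: str = "left"
    intermittency_prob: float = 0.5
    affected_targets: frozenset[int] = frozenset(range(1, 10))
    attention_lapse_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.fixation_noise_sd < 0:
            raise ValueError("fixation_noise_sd must be >= 0")
        if not 0.0 <= self.intermittency_prob <= 1.0:
            raise ValueError("intermittency_prob must be in [0, 1]")
        if not 0.0 <= self.attention_lapse_prob <= 1.0:
            raise ValueError("attention_lapse_prob must be in [0, 1]")
        if self.deviating_eye not in ("left", "right"):
            raise ValueError("deviating_eye must be 'left' or 'right'")
        if self.kind == "normal" and any(v != 0.0 for v in self.deviation_vector):
            raise ValueError("normal subjects must have a zero deviation_vector")
        if not self.affected_targets <= set(range(1, 10)):
            raise ValueError("affected_targets must be a subset of 1..9")

    @property
    def label(self) -> str:
        return "normal" if self.kind == "normal" else "strabismic"


def _expressed(model: SubjectModel, target_index: int, rng: np.random.Generator) -> bool:
    """Whether the deviation is expressed during the upcoming dwell segment."""
    if model.kind == "normal":
        return False
    if model.kind == "incomitant" and target_index not in model.affected_targets:
        return False
    if model.kind == "intermittent":
        return bool(rng.random() < model.intermittency_prob)
    return True


def simulate_session(
    model: SubjectModel,
    protocol: ProtocolConfig | None = None,
    subject_id: str = "sim",
    rng: np.random.Generator | None = None,
    keep_ineffective: bool = False,
) -> GazeSession:
    """Simulate one subject's full nine-target acquisition.

    Deterministic given ``model.seed`` (or an explicit ``rng``).  Timestamps
    are ``sample_index / sampling_rate`` counted from each target's onset,
    with ``sample_index`` counting every drawn sample, so the last retained
    pair's timestamp is the simulated per-target collection time.

    With ``keep_ineffective=True`` the raw sample stream is returned without
    the effectiveness screen (the retention quota still applies per target);
    the default mirrors the acquisition device, which stores retained pairs
    only.
    """
    protocol = protocol or ProtocolConfig()
    if rng is None:
        rng = np.random.default_rng(model.seed)
    seg_len = max(1, round(SEGMENT_SECONDS * protocol.sampling_rate))
    max_samples = int(round(protocol.max_display_time * protocol.sampling_rate))
    dev = np.asarray(model.deviation_vector, dtype=float)
    pairs: list[GazePair] = []
    for target in protocol.targets:
        t = np.asarray(target.position, dtype=float)
        retained = 0
        expressed = False
        for i in range(1, max_samples + 1):
            if (i - 1) % seg_len == 0:
                expressed = _expressed(model, target.index, rng)
            left = t + rng.normal(0.0, model.fixation_noise_sd, size=2)
            right = t + rng.normal(0.0, model.fixation_noise_sd, size=2)
            if expressed:
                if model.deviating_eye == "left":
                    left = left + dev
                else:
                    right = right + dev
            if model.attention_lapse_prob and rng.random() < model.attention_lapse_prob:
                mag = rng.uniform(*_LAPSE_MAGNITUDE)
                ang = rng.uniform(0.0, 2.0 * math.pi)
                lapse = mag * np.array([math.cos(ang), math.sin(ang)])
                left = left + lapse
                right = right + lapse
            pair = GazePair(
                target_index=target.index,
                sample_index=i,
                left=(float(left[0]), float(left[1])),
                right=(float(right[0]), float(right[1])),
                timestamp=i / protocol.sampling_rate,
            )
            d_left = math.hypot(t[0] - left[0], t[1] - left[1])
            d_right = math.hypot(t[0] - right[0], t[1] - right[1])
            effective = min(d_left, d_right) < protocol.effectiveness_threshold
            if effective or keep_ineffective:
                pairs.append(pair)
                retained += 1
                if retained >= protocol.pairs_per_target:
                    break
    return GazeSession(
        subject_id=subject_id, label=model.label, pairs=pairs, protocol=protocol
    )


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic study cohort.

    Defaults mirror the study design the package targets: 25 normal and 17
    strabismic adults, the strabismic group mixing recessive, intermittent,
    manifest, and incomitant presentations in various severities.
    ``severity_ranges`` give the uniform sampling interval of the deviation
    magnitude per kind (normalized screen units); ``noise_sd_range`` is the
    per-subject fixation-noise interval shared by both classes.
    """

    n_normal: int = 25
    n_strabismic: int = 17
    kind_weights: dict[str, float] = field(
        default_factory=lambda: {
            "recessive": 0.25,
            "intermittent": 0.25,
            "manifest": 0.35,
            "incomitant": 0.15,
        }
    )
    severity_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "recessive": (0.02, 0.06),
            "intermittent": (0.1, 0.3),
            "manifest": (0.1, 0.3),
            "incomitant": (0.1, 0.3),
        }
    )
    noise_sd_range: tuple[float, float] = (0.005, 0.02)
    attention_lapse_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_strabismic < 0:
            raise ValueError("cohort counts must be >= 0")
        if set(self.kind_weights) - set(STRABISMUS_KINDS):
            raise ValueError(f"kind_weights keys must be among {STRABISMUS_KINDS}")
        total = sum(self.kind_weights.values())
        if self.n_strabismic and not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"kind_weights must sum to 1, got {total}")

    @classmethod
    def separable(cls, seed: int = 0, n_normal: int = 25, n_strabismic: int = 17) -> "CohortSpec":
        """A clearly separable cohort: manifest/intermittent tropias only.

        Deviation magnitudes start at 0.15 normalized units against fixation
        noise of at most 0.02, i.e. deviations at least 7.5 noise SDs —
        conditions under which both the image pipeline and the Gaussian
        baseline should classify nearly perfectly.
        """
        return cls(
            n_normal=n_normal,
            n_strabismic=n_strabismic,
            kind_weights={"manifest": 0.6, "intermittent": 0.4},
            severity_ranges={"manifest": (0.15, 0.3), "intermittent": (0.15, 0.3)},
            noise_sd_range=(0.01, 0.02),
            seed=seed,
        )


def _draw_model(
    spec: CohortSpec, kind: str, rng: np.random.Generator, seed: int
) -> SubjectModel:
    noise_sd = rng.uniform(*spec.noise_sd_range)
    if kind == "normal":
        return SubjectModel(
            kind="normal",
            fixation_noise_sd=noise_sd,
            attention_lapse_prob=spec.attention_lapse_prob,
            seed=seed,
        )
    mag = rng.uniform(*spec.severity_ranges[kind])
    # Strabismic deviations are predominantly horizontal (eso-/exotropia);
    # jitter the axis by up to 30 degrees and pick the side at random.
    ang = rng.uniform(-math.pi / 6, math.pi / 6)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    deviation = (sign * mag * math.cos(ang), mag * math.sin(ang))
    affected = frozenset(range(1, 10))
    if kind == "incomitant":
        n_affected = int(rng.integers(2, 5))
        affected = frozenset(int(j) for j in rng.choice(9, size=n_affected, replace=False) + 1)
    return SubjectModel(
        kind=kind,
        fixation_noise_sd=noise_sd,
        deviation_vector=deviation,
        deviating_eye="left" if rng.random() < 0.5 else "right",
        intermittency_prob=float(rng.uniform(0.3, 0.7)),
        affected_targets=affected,
        attention_lapse_prob=spec.attention_lapse_prob,
        seed=seed,
    )


def simulate_cohort(
    spec: CohortSpec, protocol: ProtocolConfig | None = None
) -> list[GazeSession]:
    """Simulate a labeled cohort; reproducible from ``spec.seed`` alone.

    Per-subject seeds are spawned from the master seed, so adding subjects
    or reordering the returned list cannot perturb other subjects' data.
    """
    protocol = protocol or ProtocolConfig()
    n_total = spec.n_normal + spec.n_strabismic
    if n_total == 0:
        return []
    master = np.random.SeedSequence(spec.seed)
    draw_rng = np.random.default_rng(master.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(n_total + 1)[1:]]
    kinds = ["normal"] * spec.n_normal
    if spec.n_strabismic:
        names = list(spec.kind_weights)
        weights = np.array([spec.kind_weights[k] for k in names], dtype=float)
        kinds += [
            names[i]
            for i in draw_rng.choice(len(names), size=spec.n_strabismic, p=weights / weights.sum())
        ]
    sessions = []
    for idx, (kind, seed) in enumerate(zip(kinds, child_seeds), start=1):
        model = _draw_model(spec, kind, draw_rng, seed)
        sessions.append(
            simulate_session(model, protocol=protocol, subject_id=f"subj-{idx:03d}")
        )
    return sessions
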