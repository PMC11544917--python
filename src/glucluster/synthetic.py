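"""Seeded synthetic nocturnal CGM cohorts with known cluster structure.

Real nocturnal CGM panels from clinical databases are not publicly
redistributable, so this module generates surrogate cohorts whose ground-truth
structure is known. Each simulated night is built from an archetype curve —
one of a small taxonomy of nocturnal glucose patterns (stable in-target,
stable elevated, downward/upward trends, hypoglycemic dips below 3.9 mmol/L)
— plus a per-night level offset, AR(1) sensor-like noise, and injected
missingness (isolated single points and occasional long 3-6 point outages).

All values are interstitial glucose in mmol/L, clipped to the common CGM
detectable range [2.2, 22.2] (40-400 mg/dL), sampled every 5 minutes over
00:00-05:55 (72 readings).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError
from .preprocessing import NH_THRESHOLD, NocturnalSegment, SEGMENT_LENGTH

SENSOR_MIN = 2.2
SENSOR_MAX = 22.2

SHAPES = (
    "stable_target",
    "stable_elevated",
    "downward_trend",
    "upward_trend",
    "hypo_dip",
    "hypo_low_stable",
)
HYPO_SHAPES = ("hypo_dip", "hypo_low_stable")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parametric description of one nocturnal glucose pattern.

    ``start_level``/``end_level`` anchor the noiseless mean curve;
    ``dip_time_index``/``dip_depth`` apply only to the hypo_dip shape
    (nadir position and glucose at the nadir).
    """

    id: int
    shape: str
    start_level: float
    end_level: float
    dip_time_index: int | None = None
    dip_depth: float | None = None

    def validate(self, length: int = SEGMENT_LENGTH) -> None:
        if self.shape not in SHAPES:
            raise ConfigurationError(f"unknown archetype shape {self.shape!r}")
        for lvl in (self.start_level, self.end_level):
            if not SENSOR_MIN <= lvl <= SENSOR_MAX:
                raise ConfigurationError(
                    f"archetype {self.id}: level {lvl} outside sensor range"
                )
        if self.shape == "hypo_dip":
            if self.dip_time_index is None or self.dip_depth is None:
                raise ConfigurationError(
                    "hypo_dip requires dip_time_index and dip_depth"
                )
            if not 1 <= self.dip_time_index <= length - 2:
                raise ConfigurationError("dip_time_index must be interior")
        curve = archetype_curve(self, length)
        if self.shape in HYPO_SHAPES:
            if not _has_run_below(curve, NH_THRESHOLD, 3):
                raise ConfigurationError(
                    f"archetype {self.id}: hypo shape never sustains <{NH_THRESHOLD} mmol/L"
                )
        elif curve.min() < 4.4:
            raise ConfigurationError(
                f"archetype {self.id}: non-hypo shape dips below 4.4 mmol/L"
            )


def _has_run_below(values: np.ndarray, threshold: float, min_run: int) -> bool:
    run = 0
    for v in values:
        run = run + 1 if v < threshold else 0
        if run >= min_run:
            return True
    return False


def archetype_curve(spec: ArchetypeSpec, length: int = SEGMENT_LENGTH) -> np.ndarray:
    """Noiseless mean glucose curve for an archetype.

    Stable and trend shapes (and the low-stable hypo shape) interpolate
    linearly from start_level to end_level. The hypo_dip shape follows a
    smooth cosine descent from start_level to dip_depth at dip_time_index,
    then a cosine partial recovery towards end_level.
    """
    if length < 4:
        raise ConfigurationError("length must be >= 4")
    if spec.shape not in SHAPES:
        raise ConfigurationError(f"unknown archetype shape {spec.shape!r}")
    if spec.shape == "hypo_dip":
        t_dip = spec.dip_time_index
        if t_dip is None or spec.dip_depth is None:
            raise ConfigurationError("hypo_dip requires dip_time_index and dip_depth")
        curve = np.empty(length)
        down = np.arange(t_dip + 1) / t_dip
        curve[: t_dip + 1] = spec.start_level + (spec.dip_depth - spec.start_level) * (
            1 - np.cos(np.pi * down)
        ) / 2
        up = np.arange(length - t_dip) / (length - 1 - t_dip)
        curve[t_dip:] = spec.dip_depth + (spec.end_level - spec.dip_depth) * (
            1 - np.cos(np.pi * up)
        ) / 2
    else:
        curve = np.linspace(spec.start_level, spec.end_level, length)
    return np.clip(curve, SENSOR_MIN, SENSOR_MAX)


def default_archetypes() -> list[ArchetypeSpec]:
    """The shipped six-pattern palette spanning the nocturnal taxonomy."""
    return [
        ArchetypeSpec(1, "stable_target", 6.5, 6.5),
        ArchetypeSpec(2, "stable_elevated", 10.5, 10.5),
        ArchetypeSpec(3, "downward_trend", 10.0, 5.5),
        ArchetypeSpec(4, "upward_trend", 6.0, 11.0),
        ArchetypeSpec(5, "hypo_dip", 7.0, 5.5, dip_time_index=36, dip_depth=3.2),
        ArchetypeSpec(6, "hypo_low_stable", 4.4, 3.3),
    ]


@dataclass
class CohortConfig:
    """Cohort-level generation settings.

    Noise is AR(1) with coefficient ``noise_phi`` and innovation sd
    ``noise_sigma`` (mmol/L), mimicking the smooth autocorrelated error of CGM
    traces; ``offset_sigma`` is the sd of a per-night constant level shift.
    ``gap_rate_single`` is the per-index probability of an isolated missing
    reading, ``gap_rate_long`` the per-segment probability of one 3-6 point
    outage.
    """

    n_patients: int
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    archetype_mix: Sequence[float] | None = None  # default: uniform
    noise_phi: float = 0.8
    noise_sigma: float = 0.3
    offset_sigma: float = 0.5
    gap_rate_single: float = 0.01
    gap_rate_long: float = 0.05
    seed: int = 0

    def mix(self) -> np.ndarray:
        if self.archetype_mix is None:
            return np.full(len(self.archetypes), 1.0 / len(self.archetypes))
        return np.asarray(self.archetype_mix, dtype=float)

    def validate(self, length: int = SEGMENT_LENGTH) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not self.archetypes:
            raise ConfigurationError("at least one archetype required")
        mix = self.mix()
        if len(mix) != len(self.archetypes):
            raise ConfigurationError("archetype_mix length mismatch")
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError("archetype_mix must be nonnegative and sum to 1")
        if not 0 <= self.noise_phi < 1:
            raise ConfigurationError("noise_phi must be in [0, 1)")
        for spec in self.archetypes:
            spec.validate(length)


@dataclass
class SyntheticCohort:
    """Generated segments plus their ground-truth archetype assignment."""

    segments: list[NocturnalSegment]
    archetype_ids: np.ndarray  # true archetype id per segment
    config: CohortConfig
    length: int = SEGMENT_LENGTH


def generate_cohort(config: CohortConfig, length: int = SEGMENT_LENGTH) -> SyntheticCohort:
    """Draw a seeded cohort of one nocturnal segment per simulated patient.

    Each segment is archetype curve + N(0, offset_sigma) level shift +
    stationary AR(1) noise, clipped to the sensor range; gaps are then
    injected as masked zero entries. Identical (config, length) gives
    bit-identical output.
    """
    config.validate(length)
    rng = np.random.default_rng(config.seed)
    curves = [archetype_curve(a, length) for a in config.archetypes]
    mix = config.mix()

    segments: list[NocturnalSegment] = []
    ids = np.empty(config.n_patients, dtype=int)
    for i in range(config.n_patients):
        a_idx = int(rng.choice(len(config.archetypes), p=mix))
        ids[i] = config.archetypes[a_idx].id
        offset = rng.normal(0.0, config.offset_sigma)
        noise = np.empty(length)
        stat_sd = (
            config.noise_sigma / np.sqrt(1.0 - config.noise_phi**2)
            if config.noise_sigma > 0
            else 0.0
        )
        noise[0] = rng.normal(0.0, stat_sd)
        innov = rng.normal(0.0, config.noise_sigma, size=length - 1)
        for t in range(1, length):
            noise[t] = config.noise_phi * noise[t - 1] + innov[t - 1]
        values = np.clip(curves[a_idx] + offset + noise, SENSOR_MIN, SENSOR_MAX)

        mask = rng.random(length) < config.gap_rate_single
        if rng.random() < config.gap_rate_long:
            gap_len = int(rng.integers(3, 7))
            start = int(rng.integers(0, length - gap_len + 1))
            mask[start : start + gap_len] = True
        values = values.copy()
        values[mask] = 0.0
        segments.append(
            NocturnalSegment(
                patient_id=f"P{i + 1:04d}",
                night_index=0,
                values=values,
                missing_mask=mask,
            )
        )
    return SyntheticCohort(segments, ids, config, length)


# ---------------------------------------------------------------------------
# CSV writers (long-format trace + ground-truth label sidecar)
# ---------------------------------------------------------------------------

def write_cohort_csv(
    cohort: SyntheticCohort,
    trace_path,
    labels_path=None,
    base_date: str = "2024-01-01",
) -> None:
    """Write the long-format trace CSV and, optionally, the archetype sidecar.

    Trace columns: patient_id, night_index, timestamp_iso8601, glucose_mmol_l
    (missing readings leave the glucose field empty). Sidecar columns:
    patient_id, night_index, archetype_id.
    """
    base = np.datetime64(base_date)
    with open(trace_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "night_index", "timestamp_iso8601", "glucose_mmol_l"])
        for seg in cohort.segments:
            night = base + np.timedelta64(seg.night_index, "D")
            for idx in range(seg.length):
                ts = (
                    np.datetime64(night, "m") + np.timedelta64(5 * idx, "m")
                ).astype("datetime64[s]")
                glu = "" if seg.missing_mask[idx] else format(seg.values[idx], ".6f")
                writer.writerow([seg.patient_id, seg.night_index, str(ts), glu])
    if labels_path is not None:
        with open(labels_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["patient_id", "night_index", "archetype_id"])
            for seg, aid in zip(cohort.segments, cohort.archetype_ids):
                writer.writerow([seg.patient_id, seg.night_index, int(aid)])
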