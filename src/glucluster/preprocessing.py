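"""Preprocessing of raw CGM records into fixed-length nocturnal segments.

Raw continuous glucose monitoring (CGM) traces are sliced into per-night
windows of 72 five-minute readings (00:00-05:59), quality-filtered, gap-imputed,
labeled for nocturnal hypoglycemia (NH), and split into train/validation/test
pools stratified by NH status.

Missing readings are represented internally as masked entries (the stored value
is 0.0 wherever ``missing_mask`` is True); externally, as empty CSV fields.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import time as dtime
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import BoundaryGapError, ConfigurationError, DataError, PreconditionError

#: Nominal segment length: 6 h of 5-min samples.
SEGMENT_LENGTH = 72
#: Sampling interval in minutes.
SAMPLING_INTERVAL_MIN = 5
#: Hypoglycemia threshold, mmol/L (70 mg/dL).
NH_THRESHOLD = 3.9
#: Consecutive sub-threshold readings required for an NH episode (3 x 5 min = 15 min).
NH_MIN_RUN = 3

ROLES = ("train", "validation", "test")

REASON_LONG_GAP = "LONG_GAP"
REASON_TOO_SPARSE = "TOO_SPARSE"
REASON_BOUNDARY_GAP = "BOUNDARY_GAP"


@dataclass
class CGMRecord:
    """One patient's raw CGM trace.

    ``glucose`` uses NaN for missing readings; timestamps must be strictly
    increasing.
    """

    patient_id: str
    times: np.ndarray  # datetime64[ns]
    glucose: np.ndarray  # float, mmol/L, NaN = missing

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.shape != self.glucose.shape:
            raise DataError("times and glucose must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > np.timedelta64(0, "ns")):
            raise DataError(f"timestamps not strictly increasing for patient {self.patient_id}")
        finite = self.glucose[~np.isnan(self.glucose)]
        if np.any(finite <= 0):
            raise DataError("non-missing glucose values must be positive")


@dataclass
class NocturnalSegment:
    """One night's glucose vector (mmol/L) with missingness mask and NH label."""

    patient_id: str
    night_index: int
    values: np.ndarray
    missing_mask: np.ndarray
    nh_label: bool | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape or self.values.ndim != 1:
            raise DataError("values and missing_mask must be 1-D and of equal length")

    @property
    def length(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def missing_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of missing entries as (start, length) pairs."""
        runs: list[tuple[int, int]] = []
        i = 0
        m = self.missing_mask
        while i < len(m):
            if m[i]:
                j = i
                while j < len(m) and m[j]:
                    j += 1
                runs.append((i, j - i))
                i = j
            else:
                i += 1
        return runs


@dataclass
class SegmentSet:
    """A panel of equal-length segments partitioned into train/validation/test."""

    segments: list[NocturnalSegment]
    roles: list[str]
    series_length: int = SEGMENT_LENGTH

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.roles):
            raise DataError("one role per segment required")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise DataError(f"unknown roles: {sorted(bad)}")
        for seg in self.segments:
            if seg.length != self.series_length:
                raise DataError("all segments must share series_length")

    def subset(self, role: str) -> list[NocturnalSegment]:
        return [s for s, r in zip(self.segments, self.roles) if r == role]

    def matrix(self, role: str | None = None) -> np.ndarray:
        """Segments stacked as an (n, L) array, optionally restricted to one role."""
        segs = self.segments if role is None else self.subset(role)
        if not segs:
            return np.empty((0, self.series_length))
        return np.vstack([s.values for s in segs])

    def by_nh_group(self) -> dict[str, "SegmentSet"]:
        """Split into 'no_NH' / 'NH' sub-panels, preserving roles."""
        out: dict[str, SegmentSet] = {}
        for name, flag in (("no_NH", False), ("NH", True)):
            pairs = [
                (s, r)
                for s, r in zip(self.segments, self.roles)
                if bool(s.nh_label) is flag
            ]
            if pairs:
                segs, roles = zip(*pairs)
                out[name] = SegmentSet(list(segs), list(roles), self.series_length)
        return out

    def counts(self) -> dict[str, int]:
        return {role: self.roles.count(role) for role in ROLES}


class FilterDecision(NamedTuple):
    keep: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------

def extract_nocturnal_segments(
    record: CGMRecord,
    window_start: dtime = dtime(0, 0),
    window_end: dtime = dtime(5, 59),
    interval_min: int = SAMPLING_INTERVAL_MIN,
) -> list[NocturnalSegment]:
    """Slice a raw record into per-night candidate segments.

    Each calendar night contributes one candidate aligned to the expected
    5-min slots (slot index = minutes-since-midnight / 5); slots without a
    sample are marked missing. Nights with no in-window sample are skipped.
    A segment is attributed to the calendar date of its 00:00 start.
    """
    if interval_min != SAMPLING_INTERVAL_MIN:
        raise ConfigurationError("only 5-min sampling is supported")
    start_min = window_start.hour * 60 + window_start.minute
    end_min = window_end.hour * 60 + window_end.minute
    n_slots = (end_min - start_min) // interval_min + 1

    ts = pd.DatetimeIndex(record.times)
    minutes = ts.hour * 60 + ts.minute
    in_window = (minutes >= start_min) & (minutes <= end_min)
    if not in_window.any():
        return []

    dates = ts.normalize()
    segments: list[NocturnalSegment] = []
    night_index = 0
    for date in pd.unique(dates[in_window]):
        sel = in_window & (dates == date)
        values = np.zeros(n_slots)
        mask = np.ones(n_slots, dtype=bool)
        slot = ((minutes[sel] - start_min) // interval_min).to_numpy()
        glu = record.glucose[np.asarray(sel)]
        for s, g in zip(slot, glu):
            if not np.isnan(g):
                values[s] = g
                mask[s] = False
        segments.append(
            NocturnalSegment(record.patient_id, night_index, values, mask)
        )
        night_index += 1
    return segments


# ---------------------------------------------------------------------------
# Gap filtering and imputation
# ---------------------------------------------------------------------------

def filter_segment(
    segment: NocturnalSegment,
    max_missing_frac: float = 0.10,
    long_gap_len: int = 3,
) -> FilterDecision:
    """Keep/reject decision with reason code, applied before imputation.

    Rejects segments with any run of >= ``long_gap_len`` consecutive missing
    values (LONG_GAP), with strictly more than ``max_missing_frac`` of entries
    missing (TOO_SPARSE; for 72 points and 10% that means >= 8 missing), or
    with a short gap touching the boundary so that no two-sided mean exists
    (BOUNDARY_GAP).
    """
    runs = segment.missing_runs()
    if any(length >= long_gap_len for _, length in runs):
        return FilterDecision(False, REASON_LONG_GAP)
    if segment.n_missing > max_missing_frac * segment.length:
        return FilterDecision(False, REASON_TOO_SPARSE)
    for start, length in runs:
        if start == 0 or start + length == segment.length:
            return FilterDecision(False, REASON_BOUNDARY_GAP)
    return FilterDecision(True, None)


def impute_short_gaps(segment: NocturnalSegment) -> NocturnalSegment:
    """Fill 1-2 point gaps with the mean of the nearest non-missing neighbors.

    Both entries of a double gap receive the same left/right mean. Gaps of
    three or more points violate the precondition (such segments must be
    rejected by :func:`filter_segment` first); gaps at the boundary raise
    :class:`BoundaryGapError`.
    """
    values = segment.values.copy()
    mask = segment.missing_mask.copy()
    for start, length in segment.missing_runs():
        if length >= 3:
            raise PreconditionError(
                f"gap of length {length} at index {start}: reject before imputing"
            )
        left, right = start - 1, start + length
        if left < 0 or right >= segment.length:
            raise BoundaryGapError(
                f"gap at index {start} touches the segment boundary"
            )
        fill = 0.5 * (values[left] + values[right])
        values[start:right] = fill
        mask[start:right] = False
    return replace(segment, values=values, missing_mask=mask)


# ---------------------------------------------------------------------------
# Nocturnal hypoglycemia labeling
# ---------------------------------------------------------------------------

def label_nocturnal_hypoglycemia(
    segment: NocturnalSegment | np.ndarray,
    threshold: float = NH_THRESHOLD,
    min_run: int = NH_MIN_RUN,
) -> bool:
    """True iff glucose stays strictly below ``threshold`` for >= ``min_run``
    consecutive readings (default 3 x 5 min = 15 min persistence)."""
    if isinstance(segment, NocturnalSegment):
        if segment.missing_mask.any():
            raise PreconditionError("segment must be imputed before NH labeling")
        values = segment.values
    else:
        values = np.asarray(segment, dtype=float)
    below = values < threshold
    run = 0
    for b in below:
        run = run + 1 if b else 0
        if run >= min_run:
            return True
    return False


def label_segments(
    segments: Iterable[NocturnalSegment],
    threshold: float = NH_THRESHOLD,
    min_run: int = NH_MIN_RUN,
) -> list[NocturnalSegment]:
    """Return copies of ``segments`` with ``nh_label`` set."""
    return [
        replace(s, nh_label=label_nocturnal_hypoglycemia(s, threshold, min_run))
        for s in segments
    ]


# ---------------------------------------------------------------------------
# Train/validation/test split
# ---------------------------------------------------------------------------

def _largest_remainder_counts(n: int, ratios: Sequence[float]) -> list[int]:
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_dataset(
    segments: Sequence[NocturnalSegment],
    ratios: Sequence[float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    stratify_by_nh: bool = True,
) -> SegmentSet:
    """Shuffle-and-allocate split into train/validation/test.

    Counts per role follow the largest-remainder rule so they sum exactly to
    n. When ``stratify_by_nh`` (the default) the NH-positive and NH-negative
    pools are split independently, so each role contains both glucose-pattern
    groups in proportion.
    """
    ratios = list(ratios)
    if any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError("ratios must be nonnegative and sum to 1")
    n_nonzero = sum(r > 0 for r in ratios)
    if len(segments) < n_nonzero:
        raise DataError(
            f"{len(segments)} segments cannot fill {n_nonzero} nonempty roles"
        )

    if stratify_by_nh and any(s.nh_label is not None for s in segments):
        pools = [
            [s for s in segments if bool(s.nh_label)],
            [s for s in segments if not bool(s.nh_label)],
        ]
    else:
        pools = [list(segments)]

    rng = np.random.default_rng(seed)
    out_segments: list[NocturnalSegment] = []
    out_roles: list[str] = []
    for pool in pools:
        if not pool:
            continue
        perm = rng.permutation(len(pool))
        counts = _largest_remainder_counts(len(pool), ratios)
        cursor = 0
        for role, count in zip(ROLES, counts):
            for idx in perm[cursor : cursor + count]:
                out_segments.append(pool[idx])
                out_roles.append(role)
            cursor += count
    length = out_segments[0].length if out_segments else SEGMENT_LENGTH
    return SegmentSet(out_segments, out_roles, series_length=length)


# ---------------------------------------------------------------------------
# Full raw-to-split pipeline step
# ---------------------------------------------------------------------------

@dataclass
class PreprocessSummary:
    """Kept/rejected tallies for one preprocessing run."""

    n_candidates: int = 0
    n_kept: int = 0
    rejected: dict[str, int] = field(default_factory=dict)


def preprocess_records(
    records: Iterable[CGMRecord],
    nh_threshold: float = NH_THRESHOLD,
    nh_min_run: int = NH_MIN_RUN,
    ratios: Sequence[float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[SegmentSet, PreprocessSummary]:
    """Extract, filter, impute, NH-label and split all nights of a cohort."""
    summary = PreprocessSummary()
    kept: list[NocturnalSegment] = []
    for record in records:
        for segment in extract_nocturnal_segments(record):
            summary.n_candidates += 1
            decision = filter_segment(segment)
            if not decision.keep:
                summary.rejected[decision.reason] = (
                    summary.rejected.get(decision.reason, 0) + 1
                )
                continue
            kept.append(impute_short_gaps(segment))
    summary.n_kept = len(kept)
    labeled = label_segments(kept, nh_threshold, nh_min_run)
    return split_dataset(labeled, ratios, seed), summary


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_long_csv(path) -> list[CGMRecord]:
    """Read the long-format cohort CSV (patient_id, night_index,
    timestamp_iso8601, glucose_mmol_l; empty glucose = missing)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "timestamp_iso8601", "glucose_mmol_l"}
    if not required.issubset(df.columns):
        raise DataError(f"long CSV must contain columns {sorted(required)}")
    df["timestamp_iso8601"] = pd.to_datetime(df["timestamp_iso8601"])
    records = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("timestamp_iso8601")
        records.append(
            CGMRecord(
                patient_id=str(pid),
                times=grp["timestamp_iso8601"].to_numpy(),
                glucose=grp["glucose_mmol_l"].to_numpy(dtype=float),
            )
        )
    return records


def write_segments_csv(segset: SegmentSet, path) -> None:
    """Write the wide-format segment matrix CSV
    (patient_id, night_index, nh_label, role, g00..g71)."""
    cols = [f"g{i:02d}" for i in range(segset.series_length)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "night_index", "nh_label", "role", *cols])
        for seg, role in zip(segset.segments, segset.roles):
            label = "" if seg.nh_label is None else int(seg.nh_label)
            writer.writerow(
                [seg.patient_id, seg.night_index, label, role]
                + [format(v, ".6f") for v in seg.values]
            )


def read_segments_csv(path) -> SegmentSet:
    """Read the wide-format segment matrix CSV written by write_segments_csv."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    gcols = [c for c in df.columns if c.startswith("g") and c[1:].isdigit()]
    gcols.sort(key=lambda c: int(c[1:]))
    segments, roles = [], []
    for _, row in df.iterrows():
        values = row[gcols].to_numpy(dtype=float)
        nh = row.get("nh_label")
        segments.append(
            NocturnalSegment(
                patient_id=str(row["patient_id"]),
                night_index=int(row["night_index"]),
                values=values,
                missing_mask=np.zeros(len(values), dtype=bool),
                nh_label=None if pd.isna(nh) else bool(int(nh)),
            )
        )
        roles.append(str(row["role"]) if "role" in df.columns else "train")
    return SegmentSet(segments, roles, series_length=len(gcols))
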