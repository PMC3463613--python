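"""Plate-assay reduction: background subtraction, technical replicates,
percent-of-control normalization.

Raw 96-well luminescence/fluorescence readings are background-subtracted,
averaged in groups of >= 5 wells into technical replicates, and expressed
as a percentage of the solvent-control mean at each timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import defaultdict

import numpy as np

from .simulate import WellRecord

logger = logging.getLogger(__name__)

__all__ = [
    "WellRecord",
    "TechnicalReplicate",
    "NormalizedMeasurement",
    "subtract_background",
    "group_wells_to_replicates",
    "percent_of_control",
]

MIN_WELLS_PER_REPLICATE = 5


@dataclass(frozen=True)
class TechnicalReplicate:
    """Mean of >= 5 wells sharing a treatment and timepoint."""

    member_wells: tuple[WellRecord, ...]
    mean_luminescence: float
    sem_luminescence: float
    treatment: str
    timepoint_h: float

    def __post_init__(self):
        if len(self.member_wells) < MIN_WELLS_PER_REPLICATE:
            raise ValueError("a technical replicate needs at least 5 wells")
        for w in self.member_wells:
            if w.treatment != self.treatment or w.timepoint_h != self.timepoint_h:
                raise ValueError(
                    "all member wells must share treatment and timepoint"
                )


@dataclass(frozen=True)
class NormalizedMeasurement:
    """Percent-of-control bioluminescence for one treatment and timepoint."""

    treatment: str
    timepoint_h: float
    percent_of_control: float
    n_replicates: int
    sem: float


def subtract_background(
    records: list[WellRecord],
    background: float,
    channel: str = "luminescence",
) -> list[WellRecord]:
    """Subtract a constant background from one reader channel.

    Values are floored at zero; the number of clamped wells is logged.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    if channel not in ("luminescence", "fluorescence"):
        raise ValueError("channel must be 'luminescence' or 'fluorescence'")
    out: list[WellRecord] = []
    n_clamped = 0
    for rec in records:
        value = getattr(rec, channel)
        corrected = value - background
        if corrected < 0:
            corrected = 0.0
            n_clamped += 1
        out.append(
            WellRecord(
                plate_id=rec.plate_id,
                row=rec.row,
                col=rec.col,
                treatment=rec.treatment,
                timepoint_h=rec.timepoint_h,
                luminescence=corrected if channel == "luminescence" else rec.luminescence,
                fluorescence=corrected if channel == "fluorescence" else rec.fluorescence,
                worm_count=rec.worm_count,
            )
        )
    if n_clamped:
        logger.info(
            "background subtraction clamped %d well(s) to zero", n_clamped
        )
    return out


def group_wells_to_replicates(
    records: list[WellRecord], group_size: int = 8
) -> list[TechnicalReplicate]:
    """Partition wells into technical replicates of ``group_size`` wells.

    Wells are grouped per (treatment, timepoint) in column order (plate,
    then column, then row), matching replicate-per-plate-column practice.
    Each replicate carries the arithmetic mean and SEM of member
    luminescence.  Leftover wells that do not fill a group are an error.
    """
    if group_size < MIN_WELLS_PER_REPLICATE:
        raise ValueError(
            f"group_size must be >= {MIN_WELLS_PER_REPLICATE} "
            "(minimum of 5 wells per technical replicate)"
        )
    by_arm: dict[tuple[str, float], list[WellRecord]] = defaultdict(list)
    for rec in records:
        by_arm[(rec.treatment, rec.timepoint_h)].append(rec)

    replicates: list[TechnicalReplicate] = []
    for (treatment, timepoint_h), wells in sorted(by_arm.items()):
        wells = sorted(wells, key=lambda w: (w.plate_id, w.col, w.row))
        leftover = len(wells) % group_size
        if leftover:
            stragglers = ", ".join(
                f"{w.plate_id}:{w.well}" for w in wells[-leftover:]
            )
            raise ValueError(
                f"{leftover} leftover well(s) for ({treatment!r}, "
                f"{timepoint_h:g} h) do not fill a group of {group_size}: "
                f"{stragglers}"
            )
        for start in range(0, len(wells), group_size):
            members = tuple(wells[start : start + group_size])
            lum = np.array([w.luminescence for w in members])
            replicates.append(
                TechnicalReplicate(
                    member_wells=members,
                    mean_luminescence=float(lum.mean()),
                    sem_luminescence=float(lum.std(ddof=1) / np.sqrt(lum.size)),
                    treatment=treatment,
                    timepoint_h=timepoint_h,
                )
            )
    return replicates


def percent_of_control(
    replicates: list[TechnicalReplicate], control_label: str
) -> list[NormalizedMeasurement]:
    """Express replicate means as a percentage of the control-arm mean.

    Per (treatment, timepoint): 100 x mean of treatment replicate means /
    mean of control replicate means (control pooled across replicates at
    that timepoint).  The SEM is propagated from the spread of treatment
    replicate means only; the control mean is treated as the scale.
    """
    by_arm: dict[tuple[str, float], list[float]] = defaultdict(list)
    timepoints = set()
    for rep in replicates:
        by_arm[(rep.treatment, rep.timepoint_h)].append(rep.mean_luminescence)
        timepoints.add(rep.timepoint_h)

    control_means: dict[float, float] = {}
    for tp in sorted(timepoints):
        values = by_arm.get((control_label, tp))
        if not values:
            raise ValueError(
                f"no {control_label!r} control replicates at timepoint {tp:g} h"
            )
        mean = float(np.mean(values))
        if mean <= 0:
            raise ValueError(
                f"control mean is not positive at timepoint {tp:g} h"
            )
        control_means[tp] = mean

    out: list[NormalizedMeasurement] = []
    for (treatment, tp), values in sorted(by_arm.items()):
        arr = np.asarray(values)
        scale = 100.0 / control_means[tp]
        if arr.size > 1:
            sem = float(arr.std(ddof=1) / np.sqrt(arr.size) * scale)
        else:
            sem = 0.0
        out.append(
            NormalizedMeasurement(
                treatment=treatment,
                timepoint_h=tp,
                percent_of_control=float(arr.mean() * scale),
                n_replicates=arr.size,
                sem=sem,
            )
        )
    return out
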