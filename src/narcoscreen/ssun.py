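"""SSUN exceedance filtering: the extraction step of the screening pipeline.

Flags every prescription record that exceeds one of the per-drug safe-use
limits, on four axes:

``DOSE``
    the record's daily dose exceeds the drug's cap (per prescription);
``EPISODE``
    the record belongs to a treatment episode whose total days supplied
    exceeds the episode cap — an episode chains prescriptions of one
    patient-drug pair whose coverage gaps are at most
    ``episode_gap_days`` (default 7);
``CUMULATIVE``
    the record lies in some rolling 90-day window ``[t, t+90)`` in which
    the pair's summed days supplied exceeds the cumulative cap;
``FREQUENCY``
    the record is the (k+1)-th or later dispensing event of the pair
    within some rolling 30-day window ``[t, t+30)``.

Exceeding a limit is a screening signal, not a clinical judgment: doctors
may legitimately exceed the standards at their discretion, which is why
the downstream analysis looks at network structure rather than flag
counts alone.

The analysis subset (``flagged_subset``) keeps the *whole* prescription
history of every flagged patient-drug pair by default, so that the
two-mode network reflects each flagged patient's full visiting pattern
across hospitals, not only the violating visits.
"""

from __future__ import annotations

import enum
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .records import (
    ConfigError,
    Drug,
    PrescriptionRecord,
    SSUNRule,
)

#: Persistence window: a new prescription starting no more than this many
#: days after the previous prescription's coverage end continues the same
#: treatment episode.
EPISODE_GAP_DAYS: int = 7

CUMULATIVE_WINDOW_DAYS: int = 90
FREQUENCY_WINDOW_DAYS: int = 30


class Reason(enum.Enum):
    """Which rule axis a flag refers to."""

    DOSE = "DOSE"
    EPISODE = "EPISODE"
    CUMULATIVE = "CUMULATIVE"
    FREQUENCY = "FREQUENCY"


@dataclass(frozen=True)
class ExceedanceFlag:
    """One violation signal attached to one record (by index)."""

    record_index: int
    patient_id: str
    hospital_id: str
    drug: Drug
    reason: Reason


@dataclass(frozen=True)
class ExceedanceSummary:
    """Per-drug distribution of prescription counts over flagged patients.

    ``mean`` and ``sd`` are ``None`` when no patient was flagged; ``sd``
    is the population standard deviation by default.
    """

    drug: Drug
    n_patients: int
    mean: float | None
    sd: float | None


def flag_exceedances(
    records: Sequence[PrescriptionRecord],
    rules: Mapping[Drug, SSUNRule],
    episode_gap_days: int = EPISODE_GAP_DAYS,
) -> list[ExceedanceFlag]:
    """Flag every record exceeding its drug's SSUN limits.

    A record may carry several flags (one per violated axis).  Flags are
    returned sorted by ``(record_index, reason)``.

    Raises
    ------
    ConfigError
        If some record's drug has no rule in ``rules``.
    """
    for rec in records:
        if rec.drug not in rules:
            raise ConfigError(f"no SSUN rule configured for drug {rec.drug.value}")

    flagged: set[tuple[int, Reason]] = set()

    # DOSE: purely per record.
    for idx, rec in enumerate(records):
        cap = rules[rec.drug].max_daily_dose_mg
        if cap is not None and rec.daily_dose_mg > cap:
            flagged.add((idx, Reason.DOSE))

    # Group record indices by patient-drug pair, sorted by (date, index).
    groups: dict[tuple[str, Drug], list[int]] = defaultdict(list)
    for idx, rec in enumerate(records):
        groups[(rec.patient_id, rec.drug)].append(idx)

    for (_, drug), idxs in groups.items():
        rule = rules[drug]
        idxs = sorted(idxs, key=lambda i: (records[i].date, i))
        dates = [records[i].date.toordinal() for i in idxs]
        days = [records[i].days_supplied for i in idxs]
        n = len(idxs)

        if rule.max_episode_days is not None:
            # Chain into episodes by the persistence-window convention.
            ep_start = 0
            cover_end = dates[0] + days[0]
            for j in range(1, n + 1):
                new_episode = j == n or dates[j] > cover_end + episode_gap_days
                if new_episode:
                    total = sum(days[ep_start:j])
                    if total > rule.max_episode_days:
                        for i in idxs[ep_start:j]:
                            flagged.add((i, Reason.EPISODE))
                    if j < n:
                        ep_start = j
                        cover_end = dates[j] + days[j]
                else:
                    cover_end = max(cover_end, dates[j] + days[j])

        if rule.max_cumulative_days is not None:
            # Sliding window [d_i, d_i + 90) anchored at each record.
            right = 0
            win_sum = 0
            for left in range(n):
                if right < left:
                    right = left
                    win_sum = 0
                while right < n and dates[right] < dates[left] + CUMULATIVE_WINDOW_DAYS:
                    win_sum += days[right]
                    right += 1
                if win_sum > rule.max_cumulative_days:
                    for i in idxs[left:right]:
                        flagged.add((i, Reason.CUMULATIVE))
                win_sum -= days[left]

        if rule.max_events_per_30_days is not None:
            # Record j violates if it is event number > k within the
            # 30-day window starting at some earlier event.
            left = 0
            for j in range(n):
                while dates[j] - dates[left] >= FREQUENCY_WINDOW_DAYS:
                    left += 1
                if j - left + 1 > rule.max_events_per_30_days:
                    flagged.add((idxs[j], Reason.FREQUENCY))

    order = {r: k for k, r in enumerate(Reason)}
    out = []
    for idx, reason in sorted(flagged, key=lambda t: (t[0], order[t[1]])):
        rec = records[idx]
        out.append(
            ExceedanceFlag(
                record_index=idx,
                patient_id=rec.patient_id,
                hospital_id=rec.hospital_id,
                drug=rec.drug,
                reason=reason,
            )
        )
    return out


def flagged_subset(
    records: Sequence[PrescriptionRecord],
    flags: Iterable[ExceedanceFlag],
    whole_history: bool = True,
) -> list[PrescriptionRecord]:
    """The analysis subset induced by the flags, in original record order.

    With ``whole_history`` (default), returns every record of any
    patient-drug pair that carries at least one flag.  With
    ``whole_history=False``, returns only the violating records
    themselves.
    """
    flags = list(flags)
    if whole_history:
        pairs = {(f.patient_id, f.drug) for f in flags}
        return [r for r in records if (r.patient_id, r.drug) in pairs]
    keep = sorted({f.record_index for f in flags})
    return [records[i] for i in keep]


def summarize_exceedance(
    flagged_records: Sequence[PrescriptionRecord],
    population_sd: bool = True,
) -> dict[Drug, ExceedanceSummary]:
    """Mean/SD of per-patient prescription counts in the flagged subset.

    Computed per drug over the patients present in ``flagged_records``
    (i.e. after :func:`flagged_subset`).  Drugs with no flagged patient
    get ``n_patients=0`` and undefined (``None``) mean/SD.
    """
    counts: dict[Drug, dict[str, int]] = {d: defaultdict(int) for d in Drug}
    for rec in flagged_records:
        counts[rec.drug][rec.patient_id] += 1

    out: dict[Drug, ExceedanceSummary] = {}
    for drug in Drug:
        per_patient = list(counts[drug].values())
        if not per_patient:
            out[drug] = ExceedanceSummary(drug, 0, None, None)
            continue
        n = len(per_patient)
        mean = sum(per_patient) / n
        ddof = 0 if population_sd else 1
        if n - ddof <= 0:
            sd = 0.0
        else:
            var = sum((c - mean) ** 2 for c in per_patient) / (n - ddof)
            sd = math.sqrt(var)
        out[drug] = ExceedanceSummary(drug, n, mean, sd)
    return out


def write_flags(
    flags: Iterable[ExceedanceFlag],
    path,
    delimiter: str = ",",
    header_comment: str | None = None,
) -> None:
    """Export flags as delimited text."""
    import csv
    from pathlib import Path

    with open(Path(path), "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(
            ["patient_id", "hospital_id", "drug", "record_index", "reason"]
        )
        for f in flags:
            writer.writerow(
                [f.patient_id, f.hospital_id, f.drug.value, f.record_index,
                 f.reason.value]
            )
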