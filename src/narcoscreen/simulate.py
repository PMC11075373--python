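"""Seeded generator of synthetic prescription datasets.

The real national dispensing data is legally restricted, so this module
generates datasets with the *statistical structure* the screening
analysis assumes, per drug class:

* an overdispersed per-patient prescription-count distribution (single-
  prescription patients plus a shifted negative-binomial multi-visit
  group, calibrated per preset to the flagged-patient count summaries the
  surveillance literature reports);
* hub hospitals that attract a tunable share of all visits (centralized
  vs fragmented network archetypes);
* overprescriber hospitals with few patients but inflated per-visit
  prescription counts (the pattern that decouples weighted degree from
  degree);
* "shopper" patients who draw a fresh hospital for every prescription,
  vs ordinary patients who reuse a personal set of 1-2 hospitals;
* regional locality of visits (community structure along regions);
* dose / duration / inter-event-gap draws that realize configurable
  violation rates against the SSUN limits.

Everything is driven by one :class:`numpy.random.Generator` seeded from
the profile, so identical profiles produce identical datasets across
runs and platforms.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .records import (
    ConfigError,
    DEFAULT_STUDY_WINDOW,
    Drug,
    HospitalAttributes,
    PrescriptionRecord,
    REGIONS,
    SIZE_CATEGORIES,
    default_ssun_rules,
)

#: Default hospital size mix: clinics (CL) are the modal institution type.
DEFAULT_SIZE_WEIGHTS: dict[str, float] = {
    "CL": 0.55, "HO": 0.12, "DC": 0.08, "CH": 0.04, "GH": 0.03,
    "PH": 0.03, "OMH": 0.03, "PHCE": 0.04, "PHCL": 0.04, "PHU": 0.04,
}

#: Appetite-suppressant daily doses (phentermine-like products), mg.
_APPETITE_DOSES = (18.75, 30.0, 37.5)


@dataclass(frozen=True)
class GeneratorProfile:
    """Parameters of one synthetic dataset.

    Parameters
    ----------
    drug
        Drug class to emit.
    n_hospitals, n_patients
        Population sizes (both must be positive).
    hub_concentration
        Probability that a visit is routed to the fixed hub set.
    n_hubs
        Size of the hub set (the first ``n_hubs`` hospitals).
    frac_overprescriber_hospitals
        Fraction of hospitals (taken from the end of the id range,
        disjoint from hubs) that inflate per-visit prescription counts.
    overprescriber_boost
        Mean number of *extra* prescriptions an overprescriber issues per
        visit (Poisson).
    frac_shopper_patients
        Fraction of patients who draw a fresh hospital per prescription.
    region_locality
        Probability that a non-hub visit stays in the patient's home
        region.
    single_rx_frac
        Probability a patient receives exactly one prescription.
    rx_count_mean, rx_count_dispersion
        Mean and negative-binomial dispersion (size parameter ``r``) of
        the multi-visit group's count distribution
        ``2 + NB(mean - 2, r)``; requires ``rx_count_mean > 2``.
    dose_violation_rate, duration_violation_rate, frequency_violation_rate
        Per-record probabilities of drawing a dose above the cap, a
        duration above the episode cap, or a date clustered within 30
        days of the previous event (each applies only when the drug's
        rule has the corresponding limit).
    size_category_weights, region_weights
        Distributions over the 10 size codes and 16 region codes
        (defaults: clinic-modal mix; uniform regions).
    personal_hospitals_max
        Maximum size of a non-shopper's personal hospital set (1 or 2).
    max_rx_per_patient
        Cap on a patient's total emitted records, including
        overprescriber extras (tames the extreme tail).
    seed
        RNG seed; identical profiles are fully deterministic.
    """

    drug: Drug
    n_hospitals: int = 600
    n_patients: int = 2000
    hub_concentration: float = 0.2
    n_hubs: int = 8
    frac_overprescriber_hospitals: float = 0.01
    overprescriber_boost: float = 5.0
    frac_shopper_patients: float = 0.1
    region_locality: float = 0.7
    single_rx_frac: float = 0.35
    rx_count_mean: float = 5.0
    rx_count_dispersion: float = 0.3
    dose_violation_rate: float = 0.0
    duration_violation_rate: float = 0.0
    frequency_violation_rate: float = 0.0
    size_category_weights: Mapping[str, float] | None = None
    region_weights: Mapping[str, float] | None = None
    personal_hospitals_max: int = 2
    max_rx_per_patient: int = 2000
    study_window: tuple[dt.date, dt.date] = DEFAULT_STUDY_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hospitals <= 0 or self.n_patients <= 0:
            raise ConfigError("n_hospitals and n_patients must be positive")
        for name in ("hub_concentration", "frac_overprescriber_hospitals",
                     "frac_shopper_patients", "region_locality",
                     "single_rx_frac", "dose_violation_rate",
                     "duration_violation_rate", "frequency_violation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_hubs < 0 or self.n_hubs > self.n_hospitals:
            raise ConfigError("n_hubs must be in [0, n_hospitals]")
        if self.rx_count_mean <= 2.0:
            raise ConfigError("rx_count_mean must exceed 2")
        if self.rx_count_dispersion <= 0:
            raise ConfigError("rx_count_dispersion must be positive")
        if self.personal_hospitals_max not in (1, 2):
            raise ConfigError("personal_hospitals_max must be 1 or 2")
        for weights, vocab, name in (
            (self.size_category_weights, SIZE_CATEGORIES, "size_category_weights"),
            (self.region_weights, REGIONS, "region_weights"),
        ):
            if weights is None:
                continue
            if set(weights) - set(vocab):
                raise ConfigError(f"{name} has unknown codes: "
                                  f"{sorted(set(weights) - set(vocab))}")
            total = float(sum(weights.values()))
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ConfigError(f"{name} must sum to 1, got {total}")

    def resolved_size_weights(self) -> dict[str, float]:
        w = dict(self.size_category_weights or DEFAULT_SIZE_WEIGHTS)
        return {c: w.get(c, 0.0) for c in SIZE_CATEGORIES}

    def resolved_region_weights(self) -> dict[str, float]:
        if self.region_weights is None:
            return {r: 1.0 / len(REGIONS) for r in REGIONS}
        return {r: self.region_weights.get(r, 0.0) for r in REGIONS}


@dataclass
class Population:
    """Hospitals with attributes, patients with home regions, hub sets."""

    hospitals: list[HospitalAttributes]
    patient_regions: dict[str, str]
    hub_ids: tuple[str, ...]
    overprescriber_ids: tuple[str, ...]

    @property
    def hospital_ids(self) -> list[str]:
        return [h.hospital_id for h in self.hospitals]


def _rng_for(profile: GeneratorProfile, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([profile.seed, stream]))


def generate_population(profile: GeneratorProfile) -> Population:
    """Draw hospitals (size category, region) and patient home regions.

    Hub hospitals are the first ``n_hubs`` ids and overprescribers the
    last ``round(frac * n_hospitals)`` ids, so both sets are fixed and
    known to callers/tests; they are disjoint by construction (an error
    is raised if the two ranges would overlap).
    """
    rng = _rng_for(profile, 0)
    n_h = profile.n_hospitals
    n_over = int(round(profile.frac_overprescriber_hospitals * n_h))
    if profile.n_hubs + n_over > n_h:
        raise ConfigError("hub and overprescriber sets exceed n_hospitals")

    width = max(4, len(str(n_h)))
    ids = [f"H-{i + 1:0{width}d}" for i in range(n_h)]
    size_w = profile.resolved_size_weights()
    region_w = profile.resolved_region_weights()
    sizes = rng.choice(SIZE_CATEGORIES, size=n_h,
                       p=[size_w[c] for c in SIZE_CATEGORIES])
    regions = rng.choice(REGIONS, size=n_h, p=[region_w[r] for r in REGIONS])
    hospitals = [
        HospitalAttributes(hid, str(s), str(r))
        for hid, s, r in zip(ids, sizes, regions)
    ]

    pwidth = max(4, len(str(profile.n_patients)))
    patient_ids = [f"P-{i + 1:0{pwidth}d}" for i in range(profile.n_patients)]
    patient_regions = rng.choice(REGIONS, size=profile.n_patients,
                                 p=[region_w[r] for r in REGIONS])
    return Population(
        hospitals=hospitals,
        patient_regions={p: str(r) for p, r in zip(patient_ids, patient_regions)},
        hub_ids=tuple(ids[: profile.n_hubs]),
        overprescriber_ids=tuple(ids[n_h - n_over:]) if n_over else (),
    )


def _draw_counts(rng: np.random.Generator, profile: GeneratorProfile,
                 n: int) -> np.ndarray:
    """Per-patient prescription counts: 1 w.p. single_rx_frac, else
    2 + NB(mean-2, r), truncated at max_rx_per_patient."""
    single = rng.random(n) < profile.single_rx_frac
    mu = profile.rx_count_mean - 2.0
    r = profile.rx_count_dispersion
    nb = rng.negative_binomial(r, r / (r + mu), size=n)
    counts = np.where(single, 1, 2 + nb)
    return np.minimum(counts, profile.max_rx_per_patient)


def generate_prescriptions(
    population: Population, profile: GeneratorProfile
) -> list[PrescriptionRecord]:
    """Draw prescription records for the population.

    Each patient draws a count, a shopper/non-shopper role and (for
    non-shoppers) a personal hospital set via the hub/region mixture;
    dates are uniform over the study window with optional 30-day
    clustering; doses and durations realize the configured violation
    rates; visits to overprescriber hospitals spawn extra prescriptions.
    """
    rng = _rng_for(profile, 1)
    rule = default_ssun_rules()[profile.drug]
    start = profile.study_window[0].toordinal()
    end = profile.study_window[1].toordinal()

    hosp_ids = population.hospital_ids
    n_h = len(hosp_ids)
    hub_ids = list(population.hub_ids)
    over_set = set(population.overprescriber_ids)
    region_lists: dict[str, list[str]] = {r: [] for r in REGIONS}
    for h in population.hospitals:
        region_lists.setdefault(h.region, []).append(h.hospital_id)

    def choose_hospital(home_region: str) -> str:
        if hub_ids and rng.random() < profile.hub_concentration:
            return hub_ids[int(rng.integers(len(hub_ids)))]
        local = region_lists.get(home_region)
        if local and rng.random() < profile.region_locality:
            return local[int(rng.integers(len(local)))]
        return hosp_ids[int(rng.integers(n_h))]

    patient_ids = list(population.patient_regions)
    counts = _draw_counts(rng, profile, len(patient_ids))
    shopper = rng.random(len(patient_ids)) < profile.frac_shopper_patients

    dose_cap = rule.max_daily_dose_mg
    episode_cap = rule.max_episode_days
    freq_capped = rule.max_events_per_30_days is not None

    records: list[PrescriptionRecord] = []
    for p_idx, pid in enumerate(patient_ids):
        c = int(counts[p_idx])
        n_emitted = 0
        home = population.patient_regions[pid]
        if not shopper[p_idx]:
            k = 1
            if profile.personal_hospitals_max == 2 and rng.random() < 0.3:
                k = 2
            personal = [choose_hospital(home) for _ in range(k)]

        if freq_capped and c > 1:
            # Gap-chain date process: each inter-event gap is short
            # (1-14 d, a frequency violation) with the configured
            # probability, else at least 30 d; keeps the realized
            # violation rate on target, which sorting perturbed uniform
            # draws would distort.
            span = end - start
            long_hi = max(35, min(150, (2 * span) // c))
            t = start + int(rng.integers(0, max(1, span // 3)))
            chain = [t]
            for _ in range(c - 1):
                if rng.random() < profile.frequency_violation_rate:
                    gap = int(rng.integers(1, 15))
                else:
                    gap = int(rng.integers(30, long_hi))
                t = min(t + gap, end)
                chain.append(t)
            dates = np.array(chain, dtype=np.int64)
        else:
            dates = np.sort(rng.integers(start, end + 1, size=c))

        for j in range(c):
            hid = (choose_hospital(home) if shopper[p_idx]
                   else personal[int(rng.integers(len(personal)))])

            # dose
            if profile.drug is Drug.APPETITE_SUPPRESSANT:
                dose = float(_APPETITE_DOSES[int(rng.integers(3))])
            elif dose_cap is not None:
                if rng.random() < profile.dose_violation_rate:
                    dose = dose_cap * float(rng.uniform(1.05, 2.0))
                else:
                    dose = dose_cap * float(rng.uniform(0.25, 1.0))
            else:
                dose = float(rng.uniform(50.0, 200.0))

            # days supplied
            if profile.drug is Drug.PROPOFOL:
                days = 1
            elif (episode_cap is not None
                  and rng.random() < profile.duration_violation_rate):
                days = int(rng.integers(episode_cap + 1, 2 * episode_cap + 5))
            else:
                days = int(rng.integers(1, 15))

            base = PrescriptionRecord(
                patient_id=pid, hospital_id=hid, drug=profile.drug,
                date=dt.date.fromordinal(int(dates[j])),
                daily_dose_mg=round(dose, 2), days_supplied=days,
            )
            records.append(base)
            n_emitted += 1
            if hid in over_set:
                extra = int(rng.poisson(profile.overprescriber_boost))
                extra = min(extra, profile.max_rx_per_patient - n_emitted)
                for _ in range(extra):
                    shift = int(rng.integers(0, 4))
                    records.append(dataclasses.replace(
                        base,
                        date=dt.date.fromordinal(min(int(dates[j]) + shift, end)),
                    ))
                n_emitted += max(extra, 0)
    return records


def generate_dataset(
    profile: GeneratorProfile,
) -> tuple[list[PrescriptionRecord], Population]:
    """Convenience: population + prescriptions in one call."""
    population = generate_population(profile)
    return generate_prescriptions(population, profile), population


# --------------------------------------------------------------------------
# Presets: one archetype per drug class
# --------------------------------------------------------------------------
#
# Count marginals are calibrated so the flagged-patient summaries land on
# the reported per-drug means/SDs (appetite 5.6/6.3, zolpidem 3.8/8.3,
# propofol 7.9/27.2); structural dials are calibrated so the end-to-end
# pipeline reproduces the cross-drug orderings: two-mode modularity
# zolpidem > propofol > appetite, average weighted degree propofol >
# appetite > zolpidem, and top-1% degree/weighted-degree overlap far
# lower for propofol than for the other two.

_PRESETS: dict[str, dict] = {
    # Centralized, geographically dispersed network with doctor-shopping
    # patients; duration violations dominate (episode/cumulative caps).
    "appetite_like": dict(
        drug=Drug.APPETITE_SUPPRESSANT,
        hub_concentration=0.5, n_hubs=8,
        frac_overprescriber_hospitals=0.005, overprescriber_boost=4.0,
        frac_shopper_patients=0.35, region_locality=0.4,
        single_rx_frac=0.30, rx_count_mean=5.6, rx_count_dispersion=0.36,
        duration_violation_rate=0.45,
    ),
    # Fragmented, regionally local network of small communities with a
    # modest hub share (top hospitals dominate both degree and weighted
    # degree); dose and duration violations at moderate rates.
    "zolpidem_like": dict(
        drug=Drug.ZOLPIDEM,
        hub_concentration=0.25, n_hubs=8,
        frac_overprescriber_hospitals=0.002, overprescriber_boost=4.0,
        frac_shopper_patients=0.05, region_locality=0.9,
        single_rx_frac=0.45, rx_count_mean=3.8, rx_count_dispersion=0.048,
        dose_violation_rate=0.3, duration_violation_rate=0.2,
    ),
    # Heavy-tailed counts, moderate hubs, overprescriber hospitals that
    # issue many prescriptions to few patients (decoupling the weighted-
    # degree ranking from the degree ranking); only the once-per-month
    # frequency cap applies.
    "propofol_like": dict(
        drug=Drug.PROPOFOL,
        hub_concentration=0.2, n_hubs=8,
        frac_overprescriber_hospitals=0.02, overprescriber_boost=25.0,
        frac_shopper_patients=0.1, region_locality=0.85,
        single_rx_frac=0.50, rx_count_mean=5.2, rx_count_dispersion=0.10,
        frequency_violation_rate=0.8, max_rx_per_patient=500,
    ),
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)


def preset(name: str, **overrides) -> GeneratorProfile:
    """A calibrated per-drug profile; ``overrides`` replace any field."""
    if name not in _PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    params = dict(_PRESETS[name])
    params.update(overrides)
    return GeneratorProfile(**params)
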