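"""Study designs for longitudinal microbiome sampling.

A cohort is a set of subjects, each randomised to one of two treatment
arms and sampled repeatedly on a fixed nominal schedule around the start
of antibiotic treatment (day 0).  Actual stool-collection times deviate
from the nominal days by a small jitter, and non-baseline samples can be
missing at random — both features the downstream distance and AUC
machinery must tolerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Nominal sampling days relative to treatment start (day 0): three
#: pre-treatment visits, dense sampling during and just after the
#: 3-day antibiotic course, and late follow-up out to three months.
DEFAULT_SCHEDULE: tuple[int, ...] = (-15, -7, -1, 1, 2, 3, 4, 7, 10, 15, 30, 90)

#: Days eligible to serve as the per-subject baseline, in preference order.
BASELINE_CANDIDATE_DAYS: tuple[int, ...] = (-1, -7, -15)

DEFAULT_ARMS: tuple[str, str] = ("ceftriaxone", "cefotaxime")

#: Collection-time jitter half-width (days); small enough that nominal-day
#: labelling stays unambiguous for any schedule with unit spacing.
JITTER_HALF_WIDTH = 0.25


@dataclass(frozen=True)
class SampleMeta:
    """One stool sample: who, which arm, when (nominal and actual)."""

    subject_id: str
    arm: str
    nominal_day: int
    collection_time: float  # days relative to treatment start

    @property
    def sample_id(self) -> str:
        return f"{self.subject_id}_d{self.nominal_day}"


@dataclass
class StudyDesign:
    """A realised sampling design: subjects, arms and retained samples."""

    subjects: list[str]
    arms: dict[str, str]
    schedule: list[int]
    samples: list[SampleMeta]
    seed: int
    missingness_rate: float = 0.0
    _by_subject: dict[str, list[SampleMeta]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for s in self.samples:
            key = (s.subject_id, s.nominal_day)
            if key in seen:
                raise ValueError(f"duplicate sample for {key}")
            seen.add(key)
            if s.nominal_day not in self.schedule:
                raise ValueError(f"nominal day {s.nominal_day} not in schedule")
            if not np.isfinite(s.collection_time):
                raise ValueError("non-finite collection time")
            if abs(s.collection_time - s.nominal_day) > 0.5:
                raise ValueError("collection time > 0.5 day from nominal day")
            self._by_subject.setdefault(s.subject_id, []).append(s)

    def subject_samples(self, subject_id: str) -> list[SampleMeta]:
        return list(self._by_subject.get(subject_id, []))

    def to_frame(self) -> pd.DataFrame:
        """Long table of retained samples (the samples.tsv contract)."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "subject_id": [s.subject_id for s in self.samples],
                "arm": [s.arm for s in self.samples],
                "nominal_day": [s.nominal_day for s in self.samples],
                "collection_time": [s.collection_time for s in self.samples],
            }
        )


def generate_design(
    n_subjects: int,
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE,
    missingness_rate: float = 0.0,
    seed: int = 0,
    arms: tuple[str, str] = DEFAULT_ARMS,
) -> StudyDesign:
    """Generate a randomised two-arm longitudinal sampling design.

    Subjects are assigned 1:1 to the two arms.  Each sample's actual
    collection time is its nominal day plus uniform jitter on
    ±0.25 day.  Every sample is independently dropped with probability
    ``missingness_rate``, except that at least one pre-treatment sample
    (day −1, −7 or −15) is always retained per subject so a baseline is
    defined.

    Identical arguments (including ``seed``) yield an identical design.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not (0 <= missingness_rate < 1):
        raise ValueError("missingness_rate must be in [0, 1)")
    schedule = tuple(int(d) for d in schedule)
    if len(schedule) == 0:
        raise ValueError("schedule must be nonempty")
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly increasing")

    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    # 1:1 randomisation: permute, split in half (first arm gets the extra
    # subject when n is odd).
    order = rng.permutation(n_subjects)
    n_first = (n_subjects + 1) // 2
    arm_of = {
        subjects[j]: (arms[0] if rank < n_first else arms[1])
        for rank, j in enumerate(order)
    }

    baseline_days = [d for d in schedule if d in BASELINE_CANDIDATE_DAYS]
    samples: list[SampleMeta] = []
    for subj in subjects:
        jitter = rng.uniform(-JITTER_HALF_WIDTH, JITTER_HALF_WIDTH, len(schedule))
        dropped = rng.random(len(schedule)) < missingness_rate
        kept = {
            d: float(d + j)
            for d, j, drop in zip(schedule, jitter, dropped)
            if not drop
        }
        # Force at least one pre-treatment sample so baseline selection is
        # defined; resurrect the most-preferred candidate day.
        if baseline_days and not any(d in kept for d in baseline_days):
            d = -1 if -1 in baseline_days else baseline_days[0]
            idx = schedule.index(d)
            kept[d] = float(d + jitter[idx])
        for d in sorted(kept):
            samples.append(SampleMeta(subj, arm_of[subj], d, kept[d]))

    return StudyDesign(
        subjects=subjects,
        arms=arm_of,
        schedule=list(schedule),
        samples=samples,
        seed=seed,
        missingness_rate=missingness_rate,
    )
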