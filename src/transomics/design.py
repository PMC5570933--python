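"""Study design for the fasting→feeding circadian sampling timeline.

The experiment spans four consecutive days: two fasting days (NF1, NF2)
followed by two feeding days (F3, F4) on which fish are fed at ZT2 and
ZT10. Muscle is sampled every 4 h at ZT2, 6, 10, 14, 18 and 22, except
that the late-evening points (ZT18, ZT22) are missing on the first day
of each condition (NF1 and F3). The photoperiod is 11 h light : 13 h
dark, so lights go off at ZT11; ZT is hours since lights-on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DAYS = ("NF1", "NF2", "F3", "F4")
ZT_GRID = (2, 6, 10, 14, 18, 22)
#: ZT points absent on the first fasting day and the first feeding day.
MISSING_EVENINGS = {("NF1", 18), ("NF1", 22), ("F3", 18), ("F3", 22)}
FASTING_DAYS = ("NF1", "NF2")
FEEDING_DAYS = ("F3", "F4")
FEEDING_ZTS = (2, 10)
LIGHTS_ON_H = 11
LIGHTS_OFF_H = 13


@dataclass(frozen=True)
class SamplePoint:
    """One sampled (day, ZT) cell of the design."""

    day: str
    zt: int
    state: str  # "fasting" | "feeding"
    replicate_ids: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"{self.day}_ZT{self.zt:02d}"

    @property
    def hours(self) -> int:
        """Hours since the start of the experiment (NF1 ZT0)."""
        return DAYS.index(self.day) * 24 + self.zt

    @property
    def is_day(self) -> bool:
        """True if sampled while lights are on (ZT < 11)."""
        return self.zt < LIGHTS_ON_H


@dataclass(frozen=True)
class StudyDesign:
    """Ordered sampling timeline plus photoperiod and feeding events."""

    samples: tuple[SamplePoint, ...]
    zt_grid: tuple[int, ...] = ZT_GRID
    photoperiod: tuple[int, int] = (LIGHTS_ON_H, LIGHTS_OFF_H)
    feeding_events: tuple[tuple[str, int], ...] = field(
        default=tuple((d, zt) for d in FEEDING_DAYS for zt in FEEDING_ZTS)
    )

    @property
    def n_points(self) -> int:
        return len(self.samples)

    @property
    def n_replicates(self) -> int:
        return len(self.samples[0].replicate_ids)

    @property
    def sample_ids(self) -> list[str]:
        """Flat chronological replicate-level sample identifiers."""
        return [rid for p in self.samples for rid in p.replicate_ids]

    @property
    def point_labels(self) -> list[str]:
        return [p.label for p in self.samples]

    def point_of_sample(self) -> list[int]:
        """Index of the design point each flat sample belongs to."""
        return [i for i, p in enumerate(self.samples) for _ in p.replicate_ids]

    def to_frame(self):
        """Replicate-level metadata table (one row per sample)."""
        import pandas as pd

        rows = []
        for p in self.samples:
            for rid in p.replicate_ids:
                rows.append(
                    {
                        "sample_id": rid,
                        "day": p.day,
                        "zt": p.zt,
                        "state": p.state,
                        "hours": p.hours,
                        "point": p.label,
                    }
                )
        return pd.DataFrame(rows)


def build_design(replicates_per_point: int = 3) -> StudyDesign:
    """Build the 4-day fasting→feeding design.

    Parameters
    ----------
    replicates_per_point : int
        Number of fish sampled at each (day, ZT) point. The study sampled
        three to twelve fish per point; 3 is the conservative default.

    Returns
    -------
    StudyDesign
        20 sample points (4 days × 6 ZTs − 4 missing evening points), each
        carrying ``replicates_per_point`` replicate ids, in chronological
        order.
    """
    if not isinstance(replicates_per_point, (int,)) or replicates_per_point < 1:
        raise ValueError(
            f"replicates_per_point must be a positive integer, got {replicates_per_point!r}"
        )
    points = []
    for day in DAYS:
        state = "fasting" if day in FASTING_DAYS else "feeding"
        for zt in ZT_GRID:
            if (day, zt) in MISSING_EVENINGS:
                continue
            rids = tuple(
                f"{day}_ZT{zt:02d}_r{i + 1}" for i in range(replicates_per_point)
            )
            points.append(SamplePoint(day=day, zt=zt, state=state, replicate_ids=rids))
    return StudyDesign(samples=tuple(points))
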