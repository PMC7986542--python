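"""Gait parameters from raw footfall records of a single CatWalk run.

A *footfall record* is one paw placement on the glass walkway: which paw,
when it first touched down (initial contact), when it lifted off (release),
when its contact area was maximal, and where its center was (x along the
direction of travel, y across the walkway width; both in cm).

All per-paw parameters follow the conventional CatWalk definitions:

* stand time — duration of contact;
* swing time — duration of non-contact until the next placement of the
  same paw;
* step cycle — time between two consecutive initial contacts of the same
  paw (= stand + swing);
* duty cycle — stand time as a percentage of the step cycle;
* stride length — distance between the center points of two consecutive
  placements of the same paw;
* swing speed — stride length divided by swing time;
* body speed — stride length divided by step cycle, averaged over paws;
* max contact at (%) — time from initial contact to maximal contact, as a
  percentage of stand time (the braking-to-propulsion transition point);
* base of support (BOS) — mean width on the y axis between the two paws of
  a girdle;
* regularity index (RI) — 100 x 4 x NSSP / PP where NSSP counts normal
  step sequence patterns and PP counts paw placements;
* AB sequence (%) — share of the alternate LF-RH-RF-LH pattern among the
  classified patterns.

Parameters that are undefined for a run (e.g. stride length with a single
placement) are returned as NaN; genuinely invalid input (overlapping
placements of one paw, a max-contact time outside the stand phase) raises
``ValueError``.  Unit conversions never happen here: times are seconds,
positions cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping


class Paw(str, Enum):
    """The four paw labels, in the canonical tie-break order RF, LF, RH, LH."""

    RF = "RF"
    LF = "LF"
    RH = "RH"
    LH = "LH"

    @property
    def side(self) -> str:
        return "right" if self.value[0] == "R" else "left"

    @property
    def girdle(self) -> str:
        return "fore" if self.value[1] == "F" else "hind"


PAW_ORDER: tuple[Paw, ...] = (Paw.RF, Paw.LF, Paw.RH, Paw.LH)

#: The six normal step sequence patterns (NSSP): cruciate, alternate, rotary.
NSSP_PATTERNS: dict[str, tuple[Paw, Paw, Paw, Paw]] = {
    "CA": (Paw.RF, Paw.LF, Paw.RH, Paw.LH),
    "CB": (Paw.LF, Paw.RF, Paw.LH, Paw.RH),
    "AA": (Paw.RF, Paw.RH, Paw.LF, Paw.LH),
    "AB": (Paw.LF, Paw.RH, Paw.RF, Paw.LH),
    "RA": (Paw.RF, Paw.LF, Paw.LH, Paw.RH),
    "RB": (Paw.LF, Paw.RF, Paw.RH, Paw.LH),
}


@dataclass(frozen=True)
class Footfall:
    """One paw placement.

    Times in seconds; ``x`` is the travel axis and ``y`` the walkway-width
    axis, both in cm.
    """

    paw: Paw
    t_contact: float
    t_release: float
    t_max_contact: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not self.t_contact < self.t_release:
            raise ValueError(
                f"{self.paw.value}: t_contact ({self.t_contact}) must precede "
                f"t_release ({self.t_release})"
            )
        if not (self.t_contact <= self.t_max_contact <= self.t_release):
            raise ValueError(
                f"{self.paw.value}: t_max_contact ({self.t_max_contact}) must lie "
                f"within [t_contact, t_release] = [{self.t_contact}, {self.t_release}]"
            )

    @property
    def stand(self) -> float:
        return self.t_release - self.t_contact


@dataclass
class Run:
    """A single walkway crossing: ordered footfalls plus the camera rate.

    Records are kept sorted by initial-contact time; ties are broken by the
    fixed paw order RF, LF, RH, LH so that step-sequence scanning is
    deterministic.
    """

    run_id: str
    records: list[Footfall]
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.records = sorted(
            self.records, key=lambda r: (r.t_contact, PAW_ORDER.index(r.paw))
        )

    def placements(self, paw: Paw) -> list[Footfall]:
        return [r for r in self.records if r.paw is paw]


@dataclass(frozen=True)
class StepSequenceSummary:
    placements: tuple[Paw, ...]
    nssp_labels: tuple[str, ...]

    @property
    def pp(self) -> int:
        return len(self.placements)

    @property
    def nssp_count(self) -> int:
        return len(self.nssp_labels)


@dataclass(frozen=True)
class SupportProfile:
    """Percentages of sampled run time spent with 0..4 paws in contact.

    Two-paw ticks are split into diagonal (a forepaw plus the contralateral
    hindpaw), girdle (both forepaws or both hindpaws) and lateral
    (ipsilateral fore + hind).
    """

    pct_zero: float
    pct_one: float
    pct_diagonal: float
    pct_girdle: float
    pct_lateral: float
    pct_three: float
    pct_four: float

    def as_dict(self) -> dict[str, float]:
        return {
            "zero": self.pct_zero,
            "one": self.pct_one,
            "diagonal": self.pct_diagonal,
            "girdle": self.pct_girdle,
            "lateral": self.pct_lateral,
            "three": self.pct_three,
            "four": self.pct_four,
        }


MISSING = float("nan")


def _mean(xs: Iterable[float]) -> float:
    xs = list(xs)
    return sum(xs) / len(xs) if xs else MISSING


def _consecutive(placements: list[Footfall]):
    return zip(placements[:-1], placements[1:])


def stride_length(run: Run, paw: Paw) -> float:
    """Mean distance between consecutive placements of ``paw`` (cm).

    NaN if the paw was placed fewer than twice.
    """
    pts = run.placements(paw)
    if len(pts) < 2:
        return MISSING
    return _mean(math.hypot(b.x - a.x, b.y - a.y) for a, b in _consecutive(pts))


def stand_swing_cycle(run: Run, paw: Paw) -> tuple[float, float, float]:
    """Mean (stand, swing, step cycle) for ``paw`` in seconds.

    Only placements with a successor contribute, so the trailing incomplete
    cycle is excluded; per pair, stand + swing == step cycle exactly.
    Overlapping records of the same paw (negative swing) are invalid.
    """
    pts = run.placements(paw)
    if len(pts) < 2:
        return (MISSING, MISSING, MISSING)
    stands, swings, cycles = [], [], []
    for a, b in _consecutive(pts):
        swing = b.t_contact - a.t_release
        if swing < 0:
            raise ValueError(
                f"{paw.value}: overlapping placements at t={a.t_contact}..{a.t_release} "
                f"and t={b.t_contact} (negative swing)"
            )
        stands.append(a.stand)
        swings.append(swing)
        cycles.append(b.t_contact - a.t_contact)
    return (_mean(stands), _mean(swings), _mean(cycles))


def duty_cycle(run: Run, paw: Paw) -> float:
    """Mean per-pair 100 x stand / step-cycle for ``paw`` (%)."""
    pts = run.placements(paw)
    if len(pts) < 2:
        return MISSING
    ratios = []
    for a, b in _consecutive(pts):
        cycle = b.t_contact - a.t_contact
        if cycle <= 0:
            raise ValueError(f"{paw.value}: non-positive step cycle ({cycle})")
        ratios.append(100.0 * a.stand / cycle)
    return _mean(ratios)


def swing_speed(run: Run, paw: Paw) -> float:
    """Mean stride length / swing time for ``paw`` (cm/s)."""
    pts = run.placements(paw)
    if len(pts) < 2:
        return MISSING
    speeds = []
    for a, b in _consecutive(pts):
        swing = b.t_contact - a.t_release
        if swing < 0:
            raise ValueError(f"{paw.value}: negative swing time")
        if swing > 0:
            speeds.append(math.hypot(b.x - a.x, b.y - a.y) / swing)
    return _mean(speeds)


def max_contact_at_pct(run: Run, paw: Paw) -> float:
    """Mean of 100 x (t_max_contact - t_contact) / stand over placements (%).

    The numerator is clocked from the initial contact of the placement, the
    only reading under which the ratio to stand time lies in [0, 100].
    """
    pts = run.placements(paw)
    if not pts:
        return MISSING
    return _mean(100.0 * (p.t_max_contact - p.t_contact) / p.stand for p in pts)


def paw_speed(run: Run, paw: Paw) -> float:
    """Mean placement-to-placement distance over initial-contact interval (cm/s)."""
    pts = run.placements(paw)
    if len(pts) < 2:
        return MISSING
    return _mean(
        math.hypot(b.x - a.x, b.y - a.y) / (b.t_contact - a.t_contact)
        for a, b in _consecutive(pts)
    )


def body_speed(run: Run) -> float:
    """Body speed (cm/s): mean of the per-paw speeds over paws with >=2 placements."""
    speeds = [s for p in PAW_ORDER if not math.isnan(s := paw_speed(run, p))]
    return _mean(speeds)


def base_of_support(run: Run, girdle: str) -> float:
    """Mean |y_right - y_left| between the two paws of ``girdle`` ('fore'/'hind'), cm.

    Each right-paw placement is paired with the most recent left-paw
    placement (the first left placement if none precedes it); the absolute
    value makes the width sign-free.
    """
    if girdle not in ("fore", "hind"):
        raise ValueError("girdle must be 'fore' or 'hind'")
    right = run.placements(Paw.RF if girdle == "fore" else Paw.RH)
    left = run.placements(Paw.LF if girdle == "fore" else Paw.LH)
    if not right or not left:
        return MISSING
    widths = []
    for r in right:
        prior = [l for l in left if l.t_contact <= r.t_contact]
        mate = prior[-1] if prior else left[0]
        widths.append(abs(r.y - mate.y))
    return _mean(widths)


def step_sequence(run: Run) -> StepSequenceSummary:
    """Classify the placement order into NSSPs by a greedy left-to-right scan.

    If the next four placements match one of the six patterns, all four are
    consumed and the label recorded; otherwise the scan advances by one
    placement.  A perfectly patterned run is fully partitioned, giving
    RI = 100.
    """
    order = tuple(r.paw for r in run.records)
    labels: list[str] = []
    i = 0
    while i + 4 <= len(order):
        window = order[i : i + 4]
        for label, pattern in NSSP_PATTERNS.items():
            if window == pattern:
                labels.append(label)
                i += 4
                break
        else:
            i += 1
    return StepSequenceSummary(placements=order, nssp_labels=tuple(labels))


def regularity_index(summary: StepSequenceSummary) -> float:
    """RI (%) = 100 x NSSP x 4 / PP; NaN when fewer than 4 placements."""
    if summary.pp < 4:
        return MISSING
    return 100.0 * summary.nssp_count * 4 / summary.pp


def ab_sequence_pct(summary: StepSequenceSummary) -> float:
    """Share of AB (alternate LF-RH-RF-LH) among classified patterns (%)."""
    if summary.nssp_count == 0:
        return MISSING
    return 100.0 * summary.nssp_labels.count("AB") / summary.nssp_count


def support_profile(run: Run) -> SupportProfile:
    """Sample paw-contact counts on the camera tick grid.

    Time is sampled at 1/frame_rate steps from the first initial contact to
    the last release; a paw is down on a tick t iff t_contact <= t <
    t_release (half-open membership).  The seven category percentages sum
    to 100.
    """
    if not run.records:
        raise ValueError("support_profile of an empty run")
    t0 = min(r.t_contact for r in run.records)
    t1 = max(r.t_release for r in run.records)
    dt = 1.0 / run.frame_rate
    n_ticks = max(1, math.ceil((t1 - t0) / dt))
    counts = {k: 0 for k in ("zero", "one", "diagonal", "girdle", "lateral", "three", "four")}
    for k in range(n_ticks):
        t = t0 + k * dt
        down = [r.paw for r in run.records if r.t_contact <= t < r.t_release]
        n = len(set(down))
        if n == 0:
            counts["zero"] += 1
        elif n == 1:
            counts["one"] += 1
        elif n == 3:
            counts["three"] += 1
        elif n >= 4:
            counts["four"] += 1
        else:
            a, b = sorted(set(down), key=PAW_ORDER.index)
            if a.girdle == b.girdle:
                counts["girdle"] += 1
            elif a.side == b.side:
                counts["lateral"] += 1
            else:
                counts["diagonal"] += 1
    pct = {k: 100.0 * v / n_ticks for k, v in counts.items()}
    return SupportProfile(
        pct_zero=pct["zero"],
        pct_one=pct["one"],
        pct_diagonal=pct["diagonal"],
        pct_girdle=pct["girdle"],
        pct_lateral=pct["lateral"],
        pct_three=pct["three"],
        pct_four=pct["four"],
    )


#: per-paw parameter base names emitted by :func:`compute_run_features`
PER_PAW_PARAMS = (
    "stand_time",
    "swing_time",
    "step_cycle",
    "stride_length",
    "swing_speed",
    "duty_cycle",
    "max_contact_at",
    "body_speed",
)


def compute_run_features(run: Run) -> dict[str, float]:
    """All engine parameters of one run as a flat name -> value map.

    Per-paw parameters are suffixed with the lower-case paw label
    (``swing_time_rf`` ...); run-level parameters are ``regularity_index``,
    ``ab_sequence``, ``forepaw_bos``, ``hindpaw_bos`` and the
    ``support_pct_*`` categories.  Undefined parameters are NaN — they are
    propagated, never zero-filled.
    """
    values: dict[str, float] = {}
    for paw in PAW_ORDER:
        sfx = paw.value.lower()
        stand, swing, cycle = stand_swing_cycle(run, paw)
        values[f"stand_time_{sfx}"] = stand
        values[f"swing_time_{sfx}"] = swing
        values[f"step_cycle_{sfx}"] = cycle
        values[f"stride_length_{sfx}"] = stride_length(run, paw)
        values[f"swing_speed_{sfx}"] = swing_speed(run, paw)
        values[f"duty_cycle_{sfx}"] = duty_cycle(run, paw)
        values[f"max_contact_at_{sfx}"] = max_contact_at_pct(run, paw)
        values[f"body_speed_{sfx}"] = paw_speed(run, paw)
    summary = step_sequence(run)
    values["regularity_index"] = regularity_index(summary)
    values["ab_sequence"] = ab_sequence_pct(summary)
    values["forepaw_bos"] = base_of_support(run, "fore")
    values["hindpaw_bos"] = base_of_support(run, "hind")
    profile = support_profile(run)
    for cat, pct in profile.as_dict().items():
        values[f"support_pct_{cat}"] = pct
    return values
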