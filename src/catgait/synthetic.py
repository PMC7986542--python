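"""Synthetic gait data with known ground truth.

Two generators make every stage of the pipeline testable without any
recorded data:

* :func:`generate_run` emits footfall records realizing a gait template
  (step cycle, duty factor, stride, base of support, step-sequence
  pattern).  With zero noise and zero irregularity every engine parameter
  equals the template value exactly, so such runs are fixed points of the
  footfall engine.
* :func:`generate_feature_dataset` draws run-level feature vectors around
  per-group means/SDs through a hierarchical model (animal effect + run
  effect), with the regularity index and AB-sequence percentage clipped at
  their 100% ceiling so that well-coordinated groups pile up mass at 100,
  as real cohorts do.

The summary statistics of the ten published SCI cohorts the index was
derived and validated on ship with the package
(:data:`COHORT_STATISTICS`); :func:`group_spec` turns any of them into a
generator spec.  All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import GroupedFeatureData
from .footfalls import NSSP_PATTERNS, Footfall, Run

#: the nine index parameters, in the order of the published weight vector
SCORING_PARAMETERS: tuple[str, ...] = (
    "forepaw_swing_time",
    "forepaw_stride_length",
    "forepaw_duty_cycle",
    "hindpaw_bos",
    "regularity_index",
    "body_speed",
    "ab_sequence",
    "forepaw_max_contact_at",
    "hindpaw_stride_length",
)

#: animals and runs per published cohort (from the source studies)
COHORT_SIZES: dict[str, tuple[int, int]] = {
    "study1_veh_mod": (8, 31),
    "study1_veh_modsev": (7, 30),
    "study2_sci": (7, 32),
    "study2_sci_prog": (7, 27),
    "study3_young": (6, 28),
    "study3_old": (6, 33),
    "study2_30dpi": (7, 32),
    "study4_30dpi": (16, 42),
    "study5_uninjured": (6, 36),
    "study5_sci": (6, 36),
}


def _load_cohort_statistics() -> pd.DataFrame:
    with resources.files("catgait.data").joinpath("cohort_statistics.csv").open() as fh:
        return pd.read_csv(fh)


#: published per-cohort mean/SD of the index (row p_lda) and its nine parameters
COHORT_STATISTICS: pd.DataFrame = _load_cohort_statistics()


def cohort_parameter_means(cohort: str) -> pd.Series:
    """The nine published parameter means of one cohort, index-ordered."""
    sub = COHORT_STATISTICS[COHORT_STATISTICS["cohort"] == cohort]
    if sub.empty:
        raise KeyError(f"unknown cohort {cohort!r}; known: {sorted(COHORT_SIZES)}")
    s = sub.set_index("parameter")["mean"]
    return s.reindex(SCORING_PARAMETERS)


def cohort_index_mean(cohort: str) -> float:
    sub = COHORT_STATISTICS[COHORT_STATISTICS["cohort"] == cohort]
    return float(sub.set_index("parameter").loc["p_lda", "mean"])


# ---------------------------------------------------------------------------
# footfall-level generator


@dataclass(frozen=True)
class GaitTemplate:
    """Ground truth for one generated run.

    Defaults describe a well-coordinated adult rat crossing: 0.35 s step
    cycle at duty factor 0.6, 13 cm stride (body speed 37.1 cm/s), fore /
    hind base of support 2.5 / 3.0 cm, alternate AB stepping.
    """

    step_cycle: float = 0.35  # s
    duty: float = 0.6  # stand / step cycle
    stride: float = 13.0  # cm
    bos_fore: float = 2.5  # cm
    bos_hind: float = 3.0  # cm
    pattern: str = "AB"
    n_cycles: int = 10
    max_contact_frac: float = 0.45  # of stand time
    irregularity: float = 0.0  # rate of inserted out-of-pattern placements
    time_noise_sd: float = 0.0  # s, on contact times
    position_noise_sd: float = 0.0  # cm, on x/y
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.duty < 1:
            raise ValueError("duty must be in (0, 1)")
        if not 0 <= self.irregularity < 1:
            raise ValueError("irregularity must be in [0, 1)")
        if self.pattern not in NSSP_PATTERNS:
            raise ValueError(f"pattern must be one of {sorted(NSSP_PATTERNS)}")
        if self.step_cycle <= 0 or self.stride < 0 or self.n_cycles < 2:
            raise ValueError("invalid template geometry")

    @property
    def body_speed(self) -> float:
        return self.stride / self.step_cycle

    @property
    def stand(self) -> float:
        return self.duty * self.step_cycle

    @property
    def swing(self) -> float:
        return (1.0 - self.duty) * self.step_cycle


def generate_run(template: GaitTemplate, run_id: str = "sim", frame_rate: float = 100.0) -> Run:
    """Realize a template as footfall records.

    Each cycle places the four paws in the template's pattern order at
    quarter-cycle phase offsets; every paw advances one stride per cycle.
    Noise-free, regular templates reproduce every engine parameter exactly
    (stride, stand/swing/cycle, duty, body speed, BOS, max-contact-at,
    RI = 100).
    """
    rng = np.random.default_rng(template.seed)
    paws = NSSP_PATTERNS[template.pattern]
    cycle, stand = template.step_cycle, template.stand
    records: list[Footfall] = []
    for c in range(template.n_cycles):
        for k, paw in enumerate(paws):
            t0 = (c + k / 4.0) * cycle
            bos = template.bos_fore if paw.girdle == "fore" else template.bos_hind
            x = (c + k / 4.0) * template.stride + (5.0 if paw.girdle == "fore" else 0.0)
            y = bos / 2.0 if paw.side == "right" else -bos / 2.0
            if template.time_noise_sd > 0:
                t0 += rng.normal(0.0, template.time_noise_sd)
            if template.position_noise_sd > 0:
                x += rng.normal(0.0, template.position_noise_sd)
                y += rng.normal(0.0, template.position_noise_sd)
            records.append(
                Footfall(
                    paw=paw,
                    t_contact=t0,
                    t_release=t0 + stand,
                    t_max_contact=t0 + template.max_contact_frac * stand,
                    x=x,
                    y=y,
                )
            )
        # out-of-pattern extra placement, inserted in the lead paw's swing
        # phase so it never overlaps its regular placements
        if c > 0 and rng.random() < template.irregularity:
            lead = paws[0]
            prev_release = (c - 1) * cycle + stand
            t0 = prev_release + 0.3 * template.swing
            bos = template.bos_fore if lead.girdle == "fore" else template.bos_hind
            records.append(
                Footfall(
                    paw=lead,
                    t_contact=t0,
                    t_release=t0 + 0.2 * template.swing,
                    t_max_contact=t0 + 0.1 * template.swing,
                    x=(c - 0.5) * template.stride + (5.0 if lead.girdle == "fore" else 0.0),
                    y=bos / 2.0 if lead.side == "right" else -bos / 2.0,
                )
            )
    return Run(run_id=run_id, records=records, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# feature-level generator


@dataclass
class GroupSpec:
    """Per-group feature-generator specification.

    Run values are drawn hierarchically: an animal effect plus a run
    effect whose variances sum to sd^2, split by ``between_animal_frac``
    (default 50/50 — the source cohorts report pooled SDs only).
    Parameters named in ``ceiling`` are clipped at their bound after the
    draw, which piles probability mass at the ceiling.
    """

    label: str
    means: dict[str, float]
    sds: dict[str, float]
    n_animals: int = 6
    runs_per_animal: int = 4
    between_animal_frac: float = 0.5
    ceiling: dict[str, float] = field(
        default_factory=lambda: {"regularity_index": 100.0, "ab_sequence": 100.0}
    )
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.runs_per_animal < 1:
            raise ValueError("need at least one animal and one run per animal")
        if not 0 <= self.between_animal_frac <= 1:
            raise ValueError("between_animal_frac must be in [0, 1]")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must name the same parameters")
        for k, s in self.sds.items():
            if s < 0:
                raise ValueError(f"negative SD for {k!r}")
        for k, bound in self.ceiling.items():
            if k in self.means and self.means[k] > bound:
                raise ValueError(f"mean of {k!r} exceeds its ceiling {bound}")


def group_spec(cohort: str, **overrides) -> GroupSpec:
    """Generator spec seeded from one published cohort's statistics."""
    sub = COHORT_STATISTICS[COHORT_STATISTICS["cohort"] == cohort]
    if sub.empty:
        raise KeyError(f"unknown cohort {cohort!r}; known: {sorted(COHORT_SIZES)}")
    sub = sub.set_index("parameter")
    means = {p: float(sub.loc[p, "mean"]) for p in SCORING_PARAMETERS}
    sds = {p: float(sub.loc[p, "sd"]) for p in SCORING_PARAMETERS}
    n_animals, n_runs = COHORT_SIZES[cohort]
    kwargs = dict(
        label=cohort,
        means=means,
        sds=sds,
        n_animals=n_animals,
        runs_per_animal=max(1, round(n_runs / n_animals)),
    )
    kwargs.update(overrides)
    return GroupSpec(**kwargs)


def generate_feature_dataset(
    specs: Sequence[GroupSpec], seed: int = 0
) -> pd.DataFrame:
    """Run-statistics table (one row per run) drawn from group specs.

    Columns: run_id, animal_id, group, timepoint, then the spec
    parameters.  Deterministic under ``seed``.
    """
    if not specs:
        raise ValueError("need at least one group spec")
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        params = list(spec.means)
        between = {
            p: np.sqrt(spec.between_animal_frac) * spec.sds[p] for p in params
        }
        within = {
            p: np.sqrt(1.0 - spec.between_animal_frac) * spec.sds[p] for p in params
        }
        for a in range(spec.n_animals):
            animal_id = f"{spec.label}_a{a:02d}"
            effects = {p: rng.normal(0.0, between[p]) if between[p] > 0 else 0.0 for p in params}
            for r in range(spec.runs_per_animal):
                values = {}
                for p in params:
                    v = spec.means[p] + effects[p]
                    if within[p] > 0:
                        v += rng.normal(0.0, within[p])
                    if p in spec.ceiling:
                        v = min(v, spec.ceiling[p])
                    values[p] = v
                rows.append(
                    {
                        "run_id": f"{animal_id}_r{r:02d}",
                        "animal_id": animal_id,
                        "group": spec.label,
                        "timepoint": spec.timepoint,
                        **values,
                    }
                )
    return pd.DataFrame.from_records(rows)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a planted two-group study."""

    shifted_parameters: tuple[str, ...]
    direction: pd.Series  # optimal discriminant direction, unit norm


@dataclass
class TwoGroupStudy:
    frame: pd.DataFrame
    data: GroupedFeatureData
    planted: PlantedTruth


def generate_two_group_study(
    uninjured: GroupSpec,
    injured: GroupSpec,
    n_noise_parameters: int = 13,
    seed: int = 0,
) -> TwoGroupStudy:
    """Two-group run-level study with planted separation plus null columns.

    The noise parameters are standard-normal draws with an identical
    distribution in both groups.  The planted discriminant direction is
    the independence-model optimum delta_mu_k / sigma_k^2 (zero on noise
    columns), unit-normalized.
    """
    if set(uninjured.means) != set(injured.means):
        raise ValueError("group specs must share parameter names")
    frame = generate_feature_dataset([uninjured, injured], seed=seed)
    rng = np.random.default_rng(seed + 1)
    for k in range(n_noise_parameters):
        frame[f"noise_{k:02d}"] = rng.normal(0.0, 1.0, size=len(frame))
    params = [c for c in frame.columns if c not in ("run_id", "animal_id", "group", "timepoint")]
    direction = {}
    shifted = []
    for p in params:
        if p in uninjured.means:
            delta = uninjured.means[p] - injured.means[p]
            pooled_var = (uninjured.sds[p] ** 2 + injured.sds[p] ** 2) / 2.0
            direction[p] = delta / pooled_var if pooled_var > 0 else 0.0
            if delta != 0:
                shifted.append(p)
        else:
            direction[p] = 0.0
    d = pd.Series(direction)
    norm = np.linalg.norm(d.to_numpy())
    if norm > 0:
        d = d / norm
    data = GroupedFeatureData(
        features=frame[params],
        groups=frame["group"],
        animal_ids=frame["animal_id"],
    )
    return TwoGroupStudy(
        frame=frame, data=data, planted=PlantedTruth(tuple(shifted), d)
    )


def make_selection_fixture(
    seed: int = 0,
    n_animals: int = 12,
    runs_per_animal: int = 4,
    shift: float = 2.0,
    sd: float = 1.0,
    n_noise_parameters: int = 13,
    between_animal_frac: float = 0.5,
) -> TwoGroupStudy:
    """Planted ranking fixture: nine parameters shifted by ``shift`` pooled
    SDs between groups, plus group-identical noise parameters."""
    means_u = {p: 0.0 for p in SCORING_PARAMETERS}
    means_i = {p: -shift * sd for p in SCORING_PARAMETERS}
    sds = {p: sd for p in SCORING_PARAMETERS}
    mk = lambda label, means: GroupSpec(
        label=label,
        means=means,
        sds=dict(sds),
        n_animals=n_animals,
        runs_per_animal=runs_per_animal,
        between_animal_frac=between_animal_frac,
        ceiling={},
    )
    return generate_two_group_study(
        mk("uninjured", means_u), mk("injured", means_i), n_noise_parameters, seed=seed
    )
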