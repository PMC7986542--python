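"""Run-statistics tables -> the candidate feature set.

This module turns per-run parameter maps (computed by the footfall engine
or imported from a CatWalk export) into the candidate feature matrix used
for ranking and for the discriminant fit:

* a name registry translates the two CatWalk export header dialects into
  canonical names;
* green-pixel-intensity parameters are excluded;
* right/left paws are averaged into forepaw/hindpaw means (body speed is
  averaged over all four paws);
* the Support_* time percentages are combined into a single support number
  in [0, 4];
* runs are aggregated into unweighted per-animal means.

Missing values are propagated, never imputed.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .footfalls import PAW_ORDER, SupportProfile

#: metadata columns of a run-statistics table, in order
META_COLUMNS = ("run_id", "animal_id", "group", "timepoint")

#: girdle-averaged per-paw parameter bases, in registry order
_SUPPORT_WEIGHTS = {
    "zero": 0.0,
    "one": 1.0,
    "diagonal": 2.0,
    "girdle": 2.0,
    "lateral": 2.0,
    "three": 3.0,
    "four": 4.0,
}


class UnknownParameterError(KeyError):
    """A column name that no registry alias matches."""


@dataclass(frozen=True)
class ParameterDef:
    canonical: str
    unit: str
    scope: str  # per_paw | all_paw | run | support
    intensity: bool = False
    aliases: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class RunFeatures:
    """One run's named parameter -> value map plus its metadata."""

    run_id: str
    values: dict[str, float]
    animal_id: str = ""
    group: str = ""
    timepoint: str = ""


class ParameterRegistry:
    """Canonical-name registry over the CatWalk export dialects.

    Every alias (and every canonical key itself) maps to exactly one
    canonical key; unknown names raise :class:`UnknownParameterError` with
    closest-match suggestions.
    """

    def __init__(self, defs: Sequence[ParameterDef]):
        self.defs = list(defs)
        seen = set()
        for d in self.defs:
            if d.canonical in seen:
                raise ValueError(f"duplicate canonical name {d.canonical!r}")
            seen.add(d.canonical)
        self._alias_map: dict[str, str] = {}
        for d in self.defs:
            if d.scope in ("per_paw", "all_paw"):
                for paw in PAW_ORDER:
                    key = f"{d.canonical}_{paw.value.lower()}"
                    self._add_alias(key, key)
                    for alias in d.aliases.values():
                        self._add_alias(alias.replace("{PAW}", paw.value), key)
            else:
                self._add_alias(d.canonical, d.canonical)
                for alias in d.aliases.values():
                    self._add_alias(alias, d.canonical)
        # averaged / combined output names are valid identities too, so that
        # already-preprocessed tables round-trip through the same code path
        for name in self.candidate_names():
            self._add_alias(name, name)

    def _add_alias(self, alias: str, key: str) -> None:
        existing = self._alias_map.get(alias)
        if existing is not None and existing != key:
            raise ValueError(f"alias {alias!r} maps to both {existing!r} and {key!r}")
        self._alias_map[alias] = key

    @classmethod
    def default(cls) -> "ParameterRegistry":
        with resources.files("catgait.data").joinpath("registry.yaml").open() as fh:
            return cls.from_stream(fh)

    @classmethod
    def from_yaml(cls, path) -> "ParameterRegistry":
        with open(path) as fh:
            return cls.from_stream(fh)

    @classmethod
    def from_stream(cls, fh) -> "ParameterRegistry":
        raw = yaml.safe_load(fh)
        defs = [
            ParameterDef(
                canonical=e["canonical"],
                unit=str(e.get("unit", "")),
                scope=e["scope"],
                intensity=bool(e.get("intensity", False)),
                aliases=dict(e.get("aliases", {})),
            )
            for e in raw["parameters"]
        ]
        return cls(defs)

    def resolve(self, name: str) -> str:
        try:
            return self._alias_map[name]
        except KeyError:
            near = difflib.get_close_matches(name, self._alias_map, n=3)
            raise UnknownParameterError(
                f"unknown parameter {name!r}; nearest aliases: {near}"
            ) from None

    def per_paw_bases(self, include_intensity: bool = False) -> list[str]:
        return [
            d.canonical
            for d in self.defs
            if d.scope == "per_paw" and (include_intensity or not d.intensity)
        ]

    def intensity_keys(self) -> set[str]:
        keys = set()
        for d in self.defs:
            if not d.intensity:
                continue
            if d.scope in ("per_paw", "all_paw"):
                keys |= {f"{d.canonical}_{p.value.lower()}" for p in PAW_ORDER}
            else:
                keys.add(d.canonical)
        return keys

    def run_level_names(self) -> list[str]:
        return [d.canonical for d in self.defs if d.scope == "run" and not d.intensity]

    def candidate_names(self) -> list[str]:
        """Post-averaging candidate parameter names (default registry: 22)."""
        names = []
        for base in self.per_paw_bases():
            names.append(f"forepaw_{base}")
            names.append(f"hindpaw_{base}")
        names.append("body_speed")
        names.extend(self.run_level_names())
        names.append("support_number")
        return names


def default_registry() -> ParameterRegistry:
    return ParameterRegistry.default()


def support_number(profile) -> float:
    """Weighted number of supporting paws, in [0, 4].

    ``profile`` may be a :class:`SupportProfile` or any mapping holding the
    seven category time percentages (``support_pct_*`` keys or bare
    category names).  The combination is
    (one + 2 diagonal + 2 girdle + 2 lateral + 3 three + 4 four) / 100.
    """
    if isinstance(profile, SupportProfile):
        pcts = profile.as_dict()
    else:
        pcts = {}
        for cat in _SUPPORT_WEIGHTS:
            for key in (cat, f"support_pct_{cat}"):
                if key in profile:
                    pcts[cat] = float(profile[key])
                    break
            else:
                if cat != "zero":  # a zero-paw column is optional in exports
                    raise KeyError(f"support percentage for {cat!r} not found")
                pcts[cat] = 0.0
    for cat, v in pcts.items():
        if v < 0:
            raise ValueError(f"negative support percentage for {cat!r}: {v}")
    return sum(_SUPPORT_WEIGHTS[c] * v for c, v in pcts.items()) / 100.0


def _pair_mean(values: Mapping[str, float], a: str, b: str) -> float:
    va, vb = values.get(a, np.nan), values.get(b, np.nan)
    if np.isnan(va) or np.isnan(vb):
        return np.nan
    return (va + vb) / 2.0


def average_left_right(
    features: RunFeatures, registry: ParameterRegistry | None = None
) -> RunFeatures:
    """Collapse per-paw parameters to forepaw/hindpaw means of (right, left).

    Body speed collapses to the mean over all four paws (paws with a
    missing value excluded); run-level parameters and already-averaged
    names pass through.  Missing on either side makes the averaged value
    missing.  The operation is idempotent.
    """
    registry = registry or default_registry()
    values = dict(features.values)
    out: dict[str, float] = {}
    for base in registry.per_paw_bases(include_intensity=True):
        fore = _pair_mean(values, f"{base}_rf", f"{base}_lf")
        hind = _pair_mean(values, f"{base}_rh", f"{base}_lh")
        had_any = any(f"{base}_{s}" in values for s in ("rf", "lf", "rh", "lh"))
        if had_any:
            out[f"forepaw_{base}"] = fore
            out[f"hindpaw_{base}"] = hind
    speeds = [
        values[k]
        for p in PAW_ORDER
        if (k := f"body_speed_{p.value.lower()}") in values and not np.isnan(values[k])
    ]
    if speeds:
        out["body_speed"] = float(np.mean(speeds))
    per_paw_keys = {
        f"{base}_{p.value.lower()}"
        for base in registry.per_paw_bases(include_intensity=True) + ["body_speed"]
        for p in PAW_ORDER
    }
    for name, v in values.items():
        if name not in per_paw_keys and name not in out:
            out[name] = v
    return RunFeatures(
        run_id=features.run_id,
        values=out,
        animal_id=features.animal_id,
        group=features.group,
        timepoint=features.timepoint,
    )


def features_to_frame(rows: Iterable[RunFeatures]) -> pd.DataFrame:
    """Stack RunFeatures into a table with the four metadata columns first."""
    recs = []
    for r in rows:
        rec = {
            "run_id": r.run_id,
            "animal_id": r.animal_id,
            "group": r.group,
            "timepoint": r.timepoint,
        }
        rec.update(r.values)
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def frame_to_features(frame: pd.DataFrame) -> list[RunFeatures]:
    param_cols = [c for c in frame.columns if c not in META_COLUMNS]
    return [
        RunFeatures(
            run_id=str(row.get("run_id", "")),
            animal_id=str(row.get("animal_id", "")),
            group=str(row.get("group", "")),
            timepoint=str(row.get("timepoint", "")),
            values={c: float(row[c]) for c in param_cols},
        )
        for _, row in frame.iterrows()
    ]


@dataclass
class GroupedFeatureData:
    """Run-level candidate-feature matrix with group labels.

    ``features`` holds one row per run (candidate parameters only);
    ``groups`` is the parallel group-label series.
    """

    features: pd.DataFrame
    groups: pd.Series
    animal_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups).reset_index(drop=True)
        self.features = self.features.reset_index(drop=True)
        if len(self.features) != len(self.groups):
            raise ValueError("features and groups lengths differ")

    @property
    def classes(self) -> list:
        return list(pd.unique(self.groups))

    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts()

    def group_means(self) -> pd.DataFrame:
        return self.features.groupby(self.groups).mean()

    def overall_mean(self) -> pd.Series:
        return self.features.mean()


def preprocess_table(
    frame: pd.DataFrame,
    registry: ParameterRegistry | None = None,
    unknown: str = "error",
) -> pd.DataFrame:
    """Canonicalize, de-intensify, average L/R and combine support columns.

    Returns the table with metadata columns followed by the candidate
    parameters that the input could realize, in registry order.
    ``unknown='keep'`` passes unregistered columns through as extra
    run-level candidates (appended after the registry's own) instead of
    raising.
    """
    registry = registry or default_registry()
    if frame.empty:
        raise ValueError("empty run-statistics table")
    rename = {}
    extra = []
    for c in frame.columns:
        if c in META_COLUMNS:
            continue
        try:
            rename[c] = registry.resolve(c)
        except UnknownParameterError:
            if unknown != "keep":
                raise
            extra.append(c)
    frame = frame.rename(columns=rename)
    frame = frame.drop(
        columns=[c for c in registry.intensity_keys() if c in frame], errors="ignore"
    )
    rows = frame_to_features(frame)
    averaged = [average_left_right(r, registry) for r in rows]
    for r in averaged:
        if "support_number" not in r.values:
            try:
                r.values["support_number"] = support_number(r.values)
            except KeyError:
                pass  # no support columns in this export
    out = features_to_frame(averaged)
    candidates = [c for c in registry.candidate_names() if c in out.columns]
    candidates += [c for c in extra if c in out.columns]
    return out[list(META_COLUMNS) + candidates]


def build_candidate_set(
    table: Iterable[RunFeatures] | pd.DataFrame,
    registry: ParameterRegistry | None = None,
) -> GroupedFeatureData:
    """Preprocess a run-statistics table into the candidate feature matrix.

    Column names are canonicalized via the registry, intensity-flagged
    parameters dropped, right/left paws averaged, the support number
    computed, and runs with no candidate value at all excluded (with a
    warning).  Output missingness is a subset of input missingness: no
    value is ever invented.
    """
    registry = registry or default_registry()
    if isinstance(table, pd.DataFrame):
        frame = table.copy()
    else:
        frame = features_to_frame(table)
    out = preprocess_table(frame, registry)
    candidates = [c for c in out.columns if c not in META_COLUMNS]
    matrix = out[candidates].astype(float)
    keep = ~matrix.isna().all(axis=1)
    if not keep.all():
        dropped = list(out.loc[~keep, "run_id"])
        warnings.warn(f"excluding runs with all candidate parameters missing: {dropped}")
    return GroupedFeatureData(
        features=matrix[keep.values].reset_index(drop=True),
        groups=out.loc[keep, "group"].reset_index(drop=True),
        animal_ids=out.loc[keep, "animal_id"].reset_index(drop=True),
    )


def per_animal_means(table: Iterable[RunFeatures] | pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-animal (per timepoint, per group) means over runs.

    Missing entries are ignored per parameter; every run must carry an
    animal_id.
    """
    frame = table.copy() if isinstance(table, pd.DataFrame) else features_to_frame(table)
    if "animal_id" not in frame.columns or (frame["animal_id"] == "").any():
        raise ValueError("every run needs an animal_id for per-animal averaging")
    keys = [k for k in ("animal_id", "group", "timepoint") if k in frame.columns]
    param_cols = [c for c in frame.columns if c not in META_COLUMNS]
    grouped = frame.groupby(keys, sort=False, dropna=False)[param_cols].mean()
    return grouped.reset_index()
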