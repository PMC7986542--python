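"""CSV dialects, configuration and run manifests.

Two table formats are defined:

* footfall CSV — one row per paw placement, header
  ``run_id,paw,t_contact,t_release,t_max_contact,x_cm,y_cm``;
* run-statistics CSV — one row per run, metadata columns
  ``run_id,animal_id,group,timepoint`` followed by parameter columns in
  any registered alias dialect.

Both are comma-separated UTF-8 with '.' decimals by default; regional
CatWalk exports using ';' separators and ',' decimals are handled by the
explicit ``dialect='semicolon'`` option (never auto-sniffed).  Every CLI
invocation writes a manifest recording inputs, outputs (with checksums),
configuration and seeds, so results can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .footfalls import Footfall, Paw, Run

FOOTFALL_COLUMNS = (
    "run_id",
    "paw",
    "t_contact",
    "t_release",
    "t_max_contact",
    "x_cm",
    "y_cm",
)

_DIALECTS = {"standard": dict(sep=",", decimal="."), "semicolon": dict(sep=";", decimal=",")}


def _dialect(name: str) -> dict:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise ValueError(f"unknown dialect {name!r}; choose from {sorted(_DIALECTS)}") from None


def _write_opts(dialect: str) -> dict:
    """to_csv options: shortest round-trip float repr in the dialect's decimal."""
    opts = dict(_dialect(dialect))
    decimal = opts["decimal"]
    if decimal == ".":
        opts["float_format"] = lambda v: repr(float(v))
    else:
        opts["float_format"] = lambda v: repr(float(v)).replace(".", decimal)
    return opts


def _read_opts(dialect: str) -> dict:
    return dict(_dialect(dialect), float_precision="round_trip")


def read_footfalls(path, dialect: str = "standard", frame_rate: float = 100.0) -> list[Run]:
    """Parse a footfall CSV into runs.

    Malformed rows are rejected with their line numbers (as warnings); a
    run is dropped only when no valid record remains.
    """
    frame = pd.read_csv(path, **_read_opts(dialect))
    missing = [c for c in FOOTFALL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"footfall CSV {path} lacks columns {missing}")
    if frame.empty:
        raise ValueError(f"footfall CSV {path} contains no records")
    by_run: dict[str, list[Footfall]] = {}
    bad: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            rec = Footfall(
                paw=Paw(str(row["paw"]).strip().upper()),
                t_contact=float(row["t_contact"]),
                t_release=float(row["t_release"]),
                t_max_contact=float(row["t_max_contact"]),
                x=float(row["x_cm"]),
                y=float(row["y_cm"]),
            )
        except (ValueError, KeyError) as exc:
            bad.append(f"line {line}: {exc}")
            continue
        by_run.setdefault(str(row["run_id"]), []).append(rec)
    if bad:
        warnings.warn("rejected footfall rows: " + "; ".join(bad))
    return [
        Run(run_id=rid, records=recs, frame_rate=frame_rate)
        for rid, recs in by_run.items()
    ]


def write_footfalls(runs, path, dialect: str = "standard") -> None:
    rows = [
        {
            "run_id": run.run_id,
            "paw": rec.paw.value,
            "t_contact": rec.t_contact,
            "t_release": rec.t_release,
            "t_max_contact": rec.t_max_contact,
            "x_cm": rec.x,
            "y_cm": rec.y,
        }
        for run in runs
        for rec in run.records
    ]
    pd.DataFrame(rows, columns=list(FOOTFALL_COLUMNS)).to_csv(
        path, index=False, **_write_opts(dialect)
    )


def read_run_statistics(path, dialect: str = "standard") -> pd.DataFrame:
    frame = pd.read_csv(path, **_read_opts(dialect))
    if "run_id" not in frame.columns:
        raise ValueError(f"run-statistics CSV {path} lacks a run_id column")
    for col in ("animal_id", "group", "timepoint"):
        if col not in frame.columns:
            frame[col] = ""
        frame[col] = frame[col].fillna("").astype(str)
    frame["run_id"] = frame["run_id"].astype(str)
    return frame


def write_run_statistics(frame: pd.DataFrame, path, dialect: str = "standard") -> None:
    frame.to_csv(path, index=False, **_write_opts(dialect))


@dataclass
class PipelineConfig:
    """Shared pipeline settings; see the CLI ``--config`` option."""

    frame_rate: float = 100.0  # Hz; 50 for the older CatWalk generation
    registry: str | None = None  # path to a registry YAML; None = packaged
    weights: str = "published"  # 'published' or a weight-vector CSV path
    alpha: float = 0.05
    p_threshold: float = 0.01
    sb_weighting: str = "literal"
    seed: int = 0
    dialect: str = "standard"
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.p_threshold < 1:
            raise ValueError("alpha and p_threshold must lie in (0, 1)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.sb_weighting not in ("literal", "nj_weighted"):
            raise ValueError("sb_weighting must be 'literal' or 'nj_weighted'")
        _dialect(self.dialect)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    inputs,
    outputs,
    config: PipelineConfig,
    warnings_seen=(),
) -> Path:
    """Record one invocation: inputs, checksummed outputs, config, seed."""
    out_dir = Path(out_dir)
    cfg = config.as_dict()
    manifest = {
        "command": command,
        "package_version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "inputs": [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in inputs
        ],
        "outputs": [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in outputs
        ],
        "warnings": list(warnings_seen),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
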