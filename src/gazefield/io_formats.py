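"""Readers and writers for every external format the pipeline touches.

Three event-table dialects are supported:

``csv_events``
    One row per event.  Columns: ``participant, clip, event`` (``fix`` or
    ``sac``), ``t_on_ms, t_off_ms``, and either ``x, y`` (fixation) or
    ``x0, y0, x1, y1, amp_deg, dir_deg, pvel`` (saccade).  Positions are
    top-left-origin pixels and are converted to screen-centered degrees on
    read.

``eyelink_asc``
    The EyeLink ASCII event dialect: ``EFIX``/``ESACC`` lines as produced by
    ``edf2asc`` (``MSG`` lines are tolerated and ignored).  Raw-sample lines
    are out of scope — raw gaze comes in via ``raw_samples_csv``.

``raw_samples_csv``
    ``participant, clip, t_ms, x_px, y_px`` gaze samples for event detection
    (see :func:`gazefield.gaze.detect_events`).

Perimetry files (``location_id, x_deg, y_deg, sensitivity_db`` with one
header row) are validated against the canonical HFA 24-2 / 30-2 layouts.
Visual-field maps round-trip through a delimited matrix plus a JSON metadata
sidecar, losslessly at 1e-12.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventTrial, Fixation, Saccade
from .geometry import ScreenGeometry
from .perimetry import SensitivityField, hfa_locations

__all__ = [
    "EventTableDialect",
    "FormatError",
    "DataError",
    "load_io_config",
    "read_event_table",
    "write_event_table",
    "read_samples",
    "read_sensitivity_grid",
    "write_sensitivity_grid",
    "write_map",
    "read_map",
]

_CSV_EVENT_ROLES = ("participant", "clip", "event", "t_on_ms", "t_off_ms", "x", "y")
_MASK_SENTINEL = "nan"


class FormatError(ValueError):
    """A file does not conform to its declared dialect or layout."""


class DataError(ValueError):
    """A structurally valid file carries inconsistent data."""


@dataclass(frozen=True)
class EventTableDialect:
    """How to interpret an event table on disk.

    ``columns`` maps the file's column names onto the roles the reader
    needs; identity mapping by default.
    """

    kind: str = "csv_events"  # csv_events | eyelink_asc | raw_samples_csv
    columns: dict = dc_field(default_factory=dict)

    def resolve(self, role: str) -> str:
        return self.columns.get(role, role)


def load_io_config(path) -> tuple[ScreenGeometry, EventTableDialect]:
    """Read a YAML config describing screen geometry and table dialect.

    Schema::

        geometry: {width_px, height_px, width_cm, height_cm, distance_cm}
        dialect:  {kind: csv_events, columns: {role: column-name, ...}}

    The ``dialect`` block is optional (defaults to ``csv_events`` with
    identity column mapping).
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "geometry" not in cfg:
        raise FormatError("io config must contain a 'geometry' block")
    geometry = ScreenGeometry(**cfg["geometry"])
    dial = cfg.get("dialect", {})
    dialect = EventTableDialect(kind=dial.get("kind", "csv_events"),
                                columns=dial.get("columns", {}))
    return geometry, dialect


def _events_from_rows(df: pd.DataFrame, dialect: EventTableDialect,
                      geometry: ScreenGeometry) -> list[EventTrial]:
    col = dialect.resolve
    for role in _CSV_EVENT_ROLES:
        if col(role) not in df.columns:
            raise FormatError(f"csv_events file is missing mapped column {col(role)!r}")
    trials: list[EventTrial] = []
    for (pid, clip), grp in df.groupby([col("participant"), col("clip")], sort=True):
        grp = grp.reset_index(drop=True)
        onsets = grp[col("t_on_ms")].to_numpy(dtype=float)
        if np.any(np.diff(onsets) < 0):
            raise DataError(
                f"non-monotone event timestamps in trial participant={pid!r} clip={clip!r}"
            )
        trial = EventTrial(participant=str(pid), clip=str(clip))
        for _, row in grp.iterrows():
            kind = str(row[col("event")])
            t_on, t_off = float(row[col("t_on_ms")]), float(row[col("t_off_ms")])
            if kind == "fix":
                x, y = geometry.px_to_deg(row[col("x")], row[col("y")])
                trial.fixations.append(
                    Fixation(t_on, t_off, float(x), float(y), str(pid), str(clip))
                )
            elif kind == "sac":
                x0, y0 = geometry.px_to_deg(row[col("x0")], row[col("y0")])
                x1, y1 = geometry.px_to_deg(row[col("x1")], row[col("y1")])
                pvel = float(row.get(col("pvel"), np.nan))
                trial.saccades.append(
                    Saccade.from_endpoints(
                        t_on, t_off, float(x0), float(y0), float(x1), float(y1),
                        peak_velocity=pvel, participant=str(pid), clip=str(clip),
                    )
                )
            else:
                raise FormatError(f"unknown event kind {kind!r} (expected 'fix' or 'sac')")
        trials.append(trial)
    return trials


_ASC_EFIX = re.compile(
    r"^EFIX\s+[LR]\s+(?P<on>[\d.]+)\s+(?P<off>[\d.]+)\s+(?P<dur>[\d.]+)"
    r"\s+(?P<x>-?[\d.]+)\s+(?P<y>-?[\d.]+)"
)
_ASC_ESACC = re.compile(
    r"^ESACC\s+[LR]\s+(?P<on>[\d.]+)\s+(?P<off>[\d.]+)\s+(?P<dur>[\d.]+)"
    r"\s+(?P<x0>-?[\d.]+)\s+(?P<y0>-?[\d.]+)\s+(?P<x1>-?[\d.]+)\s+(?P<y1>-?[\d.]+)"
    r"\s+(?P<amp>[\d.]+)\s+(?P<pv>[\d.]+)"
)
_ASC_TRIAL = re.compile(r"^MSG\s+[\d.]+\s+TRIALID\s+(?P<pid>\S+)\s+(?P<clip>\S+)")


def _events_from_asc(path: Path, geometry: ScreenGeometry) -> list[EventTrial]:
    trials: list[EventTrial] = []
    current: EventTrial | None = None
    for line in path.read_text().splitlines():
        m = _ASC_TRIAL.match(line)
        if m:
            current = EventTrial(participant=m["pid"], clip=m["clip"])
            trials.append(current)
            continue
        if current is None:
            continue
        m = _ASC_EFIX.match(line)
        if m:
            x, y = geometry.px_to_deg(float(m["x"]), float(m["y"]))
            current.fixations.append(
                Fixation(float(m["on"]), float(m["off"]), float(x), float(y),
                         current.participant, current.clip)
            )
            continue
        m = _ASC_ESACC.match(line)
        if m:
            x0, y0 = geometry.px_to_deg(float(m["x0"]), float(m["y0"]))
            x1, y1 = geometry.px_to_deg(float(m["x1"]), float(m["y1"]))
            current.saccades.append(
                Saccade.from_endpoints(
                    float(m["on"]), float(m["off"]), float(x0), float(y0),
                    float(x1), float(y1), peak_velocity=float(m["pv"]),
                    participant=current.participant, clip=current.clip,
                )
            )
    for trial in trials:
        onsets = [e.onset for e in sorted(
            trial.fixations + trial.saccades, key=lambda e: e.onset)]
        if any(b < a for a, b in zip(onsets, onsets[1:])):  # pragma: no cover
            raise DataError(f"non-monotone timestamps in ASC trial {trial.participant}")
    return trials


def read_event_table(path, dialect: EventTableDialect,
                     geometry: ScreenGeometry) -> list[EventTrial]:
    """Read an event table and return trials in screen-centered degrees.

    Events are grouped by (participant, clip); pixel positions (top-left
    origin) are converted so the screen center maps to (0, 0) deg with
    right/up positive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect.kind == "csv_events":
        return _events_from_rows(pd.read_csv(path), dialect, geometry)
    if dialect.kind == "eyelink_asc":
        return _events_from_asc(path, geometry)
    raise FormatError(
        f"dialect kind {dialect.kind!r} is not an event-table dialect "
        "(raw samples go through read_samples)"
    )


def write_event_table(trials: list[EventTrial], path,
                      geometry: ScreenGeometry) -> None:
    """Write trials back to the ``csv_events`` dialect (pixels, top-left origin)."""
    rows = []
    for t in trials:
        for f in t.fixations:
            xp, yp = geometry.deg_to_px(f.x, f.y)
            rows.append(dict(participant=t.participant, clip=t.clip, event="fix",
                             t_on_ms=f.onset, t_off_ms=f.offset,
                             x=float(xp), y=float(yp), x0="", y0="", x1="", y1="",
                             amp_deg="", dir_deg="", pvel=""))
        for s in t.saccades:
            x0, y0 = geometry.deg_to_px(s.x0, s.y0)
            x1, y1 = geometry.deg_to_px(s.x1, s.y1)
            rows.append(dict(participant=t.participant, clip=t.clip, event="sac",
                             t_on_ms=s.onset, t_off_ms=s.offset, x="", y="",
                             x0=float(x0), y0=float(y0), x1=float(x1), y1=float(y1),
                             amp_deg=s.amplitude, dir_deg=s.direction,
                             pvel=s.peak_velocity))
    rows.sort(key=lambda r: (r["participant"], r["clip"], r["t_on_ms"]))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_samples(path, dialect: EventTableDialect | None = None,
                 geometry: ScreenGeometry | None = None) -> pd.DataFrame:
    """Read a ``raw_samples_csv`` file; returns t_ms, x_deg, y_deg per trial."""
    dialect = dialect or EventTableDialect(kind="raw_samples_csv")
    df = pd.read_csv(path)
    col = dialect.resolve
    for role in ("participant", "clip", "t_ms", "x_px", "y_px"):
        if col(role) not in df.columns:
            raise FormatError(f"raw_samples_csv is missing column {col(role)!r}")
    out = df.rename(columns={col(r): r for r in
                             ("participant", "clip", "t_ms", "x_px", "y_px")})
    if geometry is not None:
        x, y = geometry.px_to_deg(out["x_px"].to_numpy(), out["y_px"].to_numpy())
        out["x_deg"], out["y_deg"] = x, y
    return out


def read_sensitivity_grid(path, layout: str, eye: str = "right",
                          mirror_left: bool = True,
                          md: float = float("nan")) -> SensitivityField:
    """Read a SAP CSV (``location_id, x_deg, y_deg, sensitivity_db``).

    Left-eye files are mirrored into right-eye orientation when
    ``mirror_left`` is set (the default), so downstream binocular merges are
    positionwise.
    """
    df = pd.read_csv(path)
    expected = hfa_locations(layout)
    if len(df) != len(expected):
        raise FormatError(
            f"layout {layout} expects {len(expected)} locations, file has {len(df)}"
        )
    order = np.lexsort((df["x_deg"].to_numpy(), -df["y_deg"].to_numpy()))
    df = df.iloc[order]
    fld = SensitivityField(
        layout=layout,
        locations=df[["x_deg", "y_deg"]].to_numpy(dtype=float),
        sensitivity=df["sensitivity_db"].to_numpy(dtype=float),
        eye=eye,
        md=md,
    )
    if eye == "left" and mirror_left:
        fld = fld.mirrored()
        fld.eye = "left"
    if not np.allclose(fld.locations, expected):
        raise FormatError(f"file locations do not match the canonical {layout} grid")
    return fld


def write_sensitivity_grid(fld: SensitivityField, path) -> None:
    pd.DataFrame({
        "location_id": np.arange(len(fld.sensitivity)),
        "x_deg": fld.locations[:, 0],
        "y_deg": fld.locations[:, 1],
        "sensitivity_db": fld.sensitivity,
    }).to_csv(path, index=False)


def write_map(vfmap, path) -> None:
    """Write a :class:`~gazefield.maps.VFMap` as TSV matrix + JSON sidecar.

    Masked bins are serialized as NaN sentinels and restored as masked on
    read; values round-trip losslessly at 1e-12 (written at full precision).
    """
    path = Path(path)
    values = np.where(vfmap.mask, np.nan, vfmap.values)
    np.savetxt(path, values, delimiter="\t", fmt="%.17g")
    meta = {
        "kind": vfmap.kind,
        "half_x": vfmap.spec.half_x,
        "half_y": vfmap.spec.half_y,
        "bin_size": vfmap.spec.bin_size,
        "sigma": vfmap.spec.sigma,
        "central_exclusion": vfmap.spec.central_exclusion,
        "convention": vfmap.spec.convention,
        "provenance": vfmap.provenance,
        "mask": vfmap.mask.astype(int).tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_map(path):
    """Inverse of :func:`write_map`."""
    from .maps import MapSpec, VFMap

    path = Path(path)
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = MapSpec(half_x=meta["half_x"], half_y=meta["half_y"],
                   bin_size=meta["bin_size"], sigma=meta["sigma"],
                   central_exclusion=meta["central_exclusion"],
                   convention=meta["convention"])
    mask = np.array(meta["mask"], dtype=bool)
    values = np.where(mask, 0.0, np.nan_to_num(values))
    return VFMap(values=values, mask=mask, spec=spec, kind=meta["kind"],
                 provenance=meta["provenance"])
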