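"""File formats for the structome pipeline.

Delimited text (TSV by default, CSV on request) with ``#``-prefixed
metadata lines, plus JSON for profiles, summaries, comparison reports and
calibration models.  Units are fixed in the column names (``_um``,
``_um2``, ``_nm``, ``_fl``; fl is identical to um^3) so they cannot drift
silently.  Numeric values round-trip through the text dialect at 17
significant digits.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence, TextIO

import pandas as pd
import yaml

from . import stats as _stats
from .stereology import (
    DEFAULT_THICKNESS_UM,
    CellProfile,
    SectionMeasurement,
    SectionStack,
    round_half_away,
    round_nearest_10,
)

logger = logging.getLogger(__name__)

STACK_COLUMNS = [
    "cell_id", "section_index",
    "p_om_um", "p_pm_um", "a_om_um2", "a_pm_um2",
    "minor_om_um", "major_om_um", "minor_pm_um", "major_pm_um",
    "ribosomes", "om_thickness_nm", "pm_thickness_nm",
]

PROFILE_COLUMNS = [
    "cell_id", "n_sections",
    "length_um", "diam_om_um", "diam_pm_um", "aspect_ratio",
    "surf_om_um2", "surf_pm_um2",
    "vol_whole_fl", "vol_om_fl", "vol_periplasm_fl", "vol_pm_fl",
    "vol_cytoplasm_fl",
    "ribosomes_total", "ribosome_density",
]

#: profile column -> CellProfile attribute
_PROFILE_ATTR = {
    "cell_id": "cell_id", "n_sections": "n_sections",
    "length_um": "length", "diam_om_um": "diam_om", "diam_pm_um": "diam_pm",
    "aspect_ratio": "aspect_ratio",
    "surf_om_um2": "surf_om", "surf_pm_um2": "surf_pm",
    "vol_whole_fl": "vol_whole", "vol_om_fl": "vol_om",
    "vol_periplasm_fl": "vol_periplasm", "vol_pm_fl": "vol_pm",
    "vol_cytoplasm_fl": "vol_cytoplasm",
    "ribosomes_total": "ribosomes_total",
    "ribosome_density": "ribosome_density",
}

_FOOTER_LABELS = ("Average", "SD", "Min", "Max")


class ValidationError(ValueError):
    """Raised for malformed input files or inconsistent metadata."""


Format = Literal["tsv", "csv", "json"]


def _sep(fmt: str) -> str:
    if fmt == "tsv":
        return "\t"
    if fmt == "csv":
        return ","
    raise ValidationError(f"unknown delimited format {fmt!r}")


def _fmt_num(x: float | int) -> str:
    if isinstance(x, int):
        return str(x)
    if x != x:  # NaN
        return "nan"
    return format(float(x), ".17g")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Pipeline-wide options, loadable from a YAML or JSON config file."""

    section_thickness: float = DEFAULT_THICKNESS_UM
    diameter_estimator: str = "median_central"
    periplasm_mode: str = "table_consistent"
    length_mode: str = "section_count"
    t_test_variant: str = "welch"
    density_rounding: str = "nearest_10"
    seed: int = 0
    output_format: str = "tsv"

    _ENUMS = {
        "diameter_estimator": {"median_central", "mean_all", "max"},
        "periplasm_mode": {"table_consistent", "text_literal"},
        "length_mode": {"section_count", "supplied"},
        "t_test_variant": {"welch", "pooled"},
        "density_rounding": {"none", "nearest_10"},
        "output_format": {"tsv", "csv", "json"},
    }

    def __post_init__(self) -> None:
        if not self.section_thickness > 0:
            raise ValidationError("section_thickness must be > 0")
        for name, allowed in self._ENUMS.items():
            v = getattr(self, name)
            if v not in allowed:
                raise ValidationError(
                    f"{name} must be one of {sorted(allowed)}, got {v!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (or JSON, a YAML subset)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# metadata lines


def _read_lines(path: str | Path) -> tuple[dict[str, str], str]:
    """Split '#key=value' metadata lines from the table body."""
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped and not stripped.startswith(" "):
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if line.strip():
            body.append(line)
    return meta, "\n".join(body)


def _write_header(fh: TextIO, meta: Mapping[str, object], timestamp: bool) -> None:
    if timestamp:
        fh.write(f"# generated={datetime.datetime.now().isoformat(timespec='seconds')}\n")
    for k, v in meta.items():
        fh.write(f"# {k}={v}\n")


# ---------------------------------------------------------------------------
# section stacks


def write_section_stacks(stacks: Sequence[SectionStack], path: str | Path,
                         fmt: Literal["tsv", "csv"] = "tsv",
                         timestamp: bool = False) -> None:
    """Write stacks as delimited text with a ``#thickness_um=`` header."""
    if not stacks:
        raise ValidationError("no stacks to write")
    thickness = stacks[0].thickness
    for s in stacks:
        if s.thickness != thickness:
            raise ValidationError("all stacks in one file must share thickness")
    sep = _sep(fmt)
    with open(path, "w") as fh:
        meta: dict[str, object] = {"thickness_um": _fmt_num(thickness)}
        for s in stacks:
            if s.supplied_length is not None:
                meta[f"length_um:{s.cell_id}"] = _fmt_num(s.supplied_length)
        _write_header(fh, meta, timestamp)
        fh.write(sep.join(STACK_COLUMNS) + "\n")
        for s in stacks:
            for m in s.sections:
                row = [
                    s.cell_id, str(m.section_index),
                    _fmt_num(m.p_om), _fmt_num(m.p_pm),
                    _fmt_num(m.a_om), _fmt_num(m.a_pm),
                    _fmt_num(m.minor_om), _fmt_num(m.major_om),
                    _fmt_num(m.minor_pm), _fmt_num(m.major_pm),
                    str(m.ribosomes),
                    _fmt_num(m.om_thickness_nm) if m.om_thickness_nm is not None else "",
                    _fmt_num(m.pm_thickness_nm) if m.pm_thickness_nm is not None else "",
                ]
                fh.write(sep.join(row) + "\n")


def read_section_stacks(path: str | Path,
                        fmt: Literal["tsv", "csv"] | None = None,
                        thickness: float | None = None) -> list[SectionStack]:
    """Read section stacks from delimited text.

    The section thickness comes from a ``#thickness_um=`` metadata line or
    the ``thickness`` argument (the argument wins).  Rows are grouped by
    ``cell_id`` in order of first appearance and ordered by
    ``section_index``; duplicated (cell, index) pairs are a hard error.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    meta, body = _read_lines(path)
    if thickness is None:
        if "thickness_um" not in meta:
            raise ValidationError(
                f"{path}: no '#thickness_um=' metadata line and no thickness given")
        thickness = float(meta["thickness_um"])

    import io as _io
    df = pd.read_csv(_io.StringIO(body), sep=_sep(fmt), dtype={"cell_id": str},
                     float_precision="round_trip")
    missing = [c for c in STACK_COLUMNS if c not in df.columns
               and c not in ("om_thickness_nm", "pm_thickness_nm")]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    seen: set[tuple[str, int]] = set()
    stacks: dict[str, list[SectionMeasurement]] = {}
    for _, row in df.iterrows():
        cid = str(row["cell_id"])
        idx = int(row["section_index"])
        if (cid, idx) in seen:
            raise ValidationError(
                f"{path}: duplicate section row (cell {cid!r}, index {idx})")
        seen.add((cid, idx))

        def opt(col: str) -> float | None:
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        try:
            m = SectionMeasurement(
                section_index=idx,
                p_om=float(row["p_om_um"]), p_pm=float(row["p_pm_um"]),
                a_om=float(row["a_om_um2"]), a_pm=float(row["a_pm_um2"]),
                minor_om=float(row["minor_om_um"]), major_om=float(row["major_om_um"]),
                minor_pm=float(row["minor_pm_um"]), major_pm=float(row["major_pm_um"]),
                ribosomes=int(row["ribosomes"]),
                om_thickness_nm=opt("om_thickness_nm"),
                pm_thickness_nm=opt("pm_thickness_nm"),
            )
        except ValueError as exc:
            raise ValidationError(
                f"{path}: invalid measurement (cell {cid!r}, index {idx}): {exc}"
            ) from exc
        stacks.setdefault(cid, []).append(m)

    out = []
    for cid, sections in stacks.items():
        sections.sort(key=lambda m: m.section_index)
        supplied = meta.get(f"length_um:{cid}")
        try:
            out.append(SectionStack(
                cell_id=cid, thickness=thickness, sections=sections,
                supplied_length=float(supplied) if supplied is not None else None,
            ))
        except ValueError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# profile tables


def _profile_row(profile: CellProfile, rounded: bool) -> list[str]:
    values = []
    for col in PROFILE_COLUMNS:
        v = getattr(profile, _PROFILE_ATTR[col])
        if col in ("cell_id",):
            values.append(str(v))
        elif col == "n_sections":
            values.append(str(int(v)))
        elif col in ("ribosomes_total", "ribosome_density"):
            if rounded:
                values.append(str(int(round_nearest_10(v))))
            else:
                values.append(_fmt_num(float(v)))
        else:
            if rounded:
                values.append(f"{round_half_away(float(v), 2):.2f}")
            else:
                values.append(_fmt_num(float(v)))
    return values


def write_profile_table(profiles: Sequence[CellProfile], path: str | Path,
                        fmt: Format = "tsv", rounded: bool = True,
                        footer: bool = True, timestamp: bool = False) -> None:
    """Write per-cell profiles, with Average/SD/Min/Max footer rows.

    ``rounded`` applies the report conventions (2 dp; ribosome counts and
    densities to the nearest 10).  JSON output always carries full
    precision and parses back losslessly.  With a single profile the SD
    footer row is suppressed (noted in a comment line).
    """
    if not profiles:
        raise ValidationError("no profiles to write")
    if fmt == "json":
        payload = {
            "profiles": [dataclasses.asdict(p) for p in profiles],
        }
        if footer and len(profiles) >= 2:
            payload["summary"] = {
                m: dataclasses.asdict(
                    _stats.summarize([getattr(p, m) for p in profiles], metric=m))
                for m in CellProfile.METRICS
            }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
        return

    sep = _sep(fmt)
    numeric_cols = [c for c in PROFILE_COLUMNS if c not in ("cell_id", "n_sections")]
    with open(path, "w") as fh:
        _write_header(fh, {}, timestamp)
        if footer and len(profiles) < 2:
            fh.write("# single profile: SD footer suppressed\n")
        fh.write(sep.join(PROFILE_COLUMNS) + "\n")
        for p in profiles:
            fh.write(sep.join(_profile_row(p, rounded)) + "\n")
        if footer:
            summaries = {
                c: _stats.summarize([getattr(p, _PROFILE_ATTR[c]) for p in profiles])
                for c in numeric_cols
            }
            rows: list[tuple[str, str]] = [("Average", "mean")]
            if len(profiles) >= 2:
                rows.append(("SD", "sd"))
            rows += [("Min", "min"), ("Max", "max")]
            for label, attr in rows:
                cells = [label, ""]
                for c in numeric_cols:
                    v = getattr(summaries[c], attr)
                    if rounded:
                        if c in ("ribosomes_total", "ribosome_density"):
                            cells.append(str(int(round_nearest_10(v))))
                        else:
                            cells.append(f"{round_half_away(v, 2):.2f}")
                    else:
                        cells.append(_fmt_num(float(v)))
                fh.write(sep.join(cells) + "\n")


def read_profile_table(path: str | Path, fmt: Format | None = None,
                       ) -> list[CellProfile]:
    """Read a per-cell profile table (footer rows are skipped)."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "json" if suffix == ".json" else ("csv" if suffix == ".csv" else "tsv")
    if fmt == "json":
        payload = json.loads(path.read_text())
        return [CellProfile(**d) for d in payload["profiles"]]
    _, body = _read_lines(path)
    import io as _io
    df = pd.read_csv(_io.StringIO(body), sep=_sep(fmt), dtype={"cell_id": str},
                     float_precision="round_trip")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    profiles = []
    for _, row in df.iterrows():
        if str(row["cell_id"]) in _FOOTER_LABELS:
            continue
        kwargs = {}
        for col, attr in _PROFILE_ATTR.items():
            v = row[col]
            if attr == "cell_id":
                kwargs[attr] = str(v)
            elif attr == "n_sections":
                kwargs[attr] = int(v)
            else:
                kwargs[attr] = float(v)
        profiles.append(CellProfile(**kwargs))
    return profiles


# ---------------------------------------------------------------------------
# metric summaries and comparison reports


def read_summary_table(path: str | Path, fmt: Literal["tsv", "csv"] | None = None,
                       ) -> list[_stats.MetricSummary]:
    """Read a (group_label, metric, n, mean, sd[, min, max]) table."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    _, body = _read_lines(path)
    import io as _io
    df = pd.read_csv(_io.StringIO(body), sep=_sep(fmt),
                     float_precision="round_trip")
    required = ["group_label", "metric", "n", "mean", "sd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(_stats.MetricSummary(
            group_label=str(row["group_label"]), metric=str(row["metric"]),
            n=int(row["n"]), mean=float(row["mean"]), sd=float(row["sd"]),
            min=float(row["min"]) if "min" in df.columns and not pd.isna(row["min"]) else float("nan"),
            max=float(row["max"]) if "max" in df.columns and not pd.isna(row["max"]) else float("nan"),
        ))
    return out


def write_summary_table(summaries: Sequence[_stats.MetricSummary],
                        path: str | Path, fmt: Format = "tsv",
                        timestamp: bool = False) -> None:
    if fmt == "json":
        Path(path).write_text(json.dumps(
            [dataclasses.asdict(s) for s in summaries], indent=2) + "\n")
        return
    sep = _sep(fmt)
    with open(path, "w") as fh:
        _write_header(fh, {}, timestamp)
        fh.write(sep.join(["group_label", "metric", "n", "mean", "sd", "min", "max"]) + "\n")
        for s in summaries:
            fh.write(sep.join([
                s.group_label, s.metric, str(s.n),
                _fmt_num(float(s.mean)), _fmt_num(float(s.sd)),
                _fmt_num(float(s.min)), _fmt_num(float(s.max)),
            ]) + "\n")


def write_comparison_report(rows: Sequence[_stats.MetricComparison],
                            path: str | Path, fmt: Format = "tsv",
                            timestamp: bool = False) -> None:
    """Write a metric-by-metric comparison report.

    Text output formats tiny p-values as ``< 1e-15``; JSON keeps full
    precision.
    """
    if fmt == "json":
        Path(path).write_text(json.dumps(
            [dataclasses.asdict(r) for r in rows], indent=2) + "\n")
        return
    sep = _sep(fmt)
    header = ["metric",
              "n_a", "mean_a", "sd_a", "n_b", "mean_b", "sd_b",
              "test", "t", "df", "p", "significant"]
    with open(path, "w") as fh:
        _write_header(fh, {}, timestamp)
        fh.write(sep.join(header) + "\n")
        for r in rows:
            fh.write(sep.join([
                r.metric,
                str(r.summary_a.n), _fmt_num(float(r.summary_a.mean)),
                _fmt_num(float(r.summary_a.sd)),
                str(r.summary_b.n), _fmt_num(float(r.summary_b.mean)),
                _fmt_num(float(r.summary_b.sd)),
                r.test.test_name,
                f"{r.test.statistic:.4f}", f"{r.test.df:.3f}",
                _stats.format_p(r.test.p_value),
                str(r.significant),
            ]) + "\n")


# ---------------------------------------------------------------------------
# calibration pairs


def read_calibration_pairs(path: str | Path,
                           fmt: Literal["tsv", "csv"] | None = None,
                           ) -> list[tuple[float, float]]:
    """Read 2-column (density, doubling_time_min) pairs from delimited text."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    _, body = _read_lines(path)
    import io as _io
    df = pd.read_csv(_io.StringIO(body), sep=_sep(fmt),
                     float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected 2 columns (density, doubling time)")
    return [(float(a), float(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
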