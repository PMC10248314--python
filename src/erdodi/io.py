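"""Battery configuration and cohort-table I/O.

Battery configurations are YAML or JSON documents with one entry per
component (``name``, ``direction``, ``cuts``, optional ``units``,
``valid_range``, ``granularity``) and top-level classification bands
(``pass_max``, ``borderline_max``).  The standard EI-5 battery ships
with the package and is returned by :func:`default_battery`.

Cohort tables are plain CSV with one row per examinee; component score
columns are mapped by name, percent columns accept a trailing ``%``,
and unrecognized columns are preserved as covariates.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .cutoffs import BatteryConfig, ComponentSpec, CutoffSpecError

__all__ = [
    "default_battery",
    "read_battery_config",
    "write_battery_config",
    "battery_to_dict",
    "battery_from_dict",
    "read_cohort_csv",
]

_REQUIRED_COMPONENT_KEYS = ("name", "direction", "cuts")


def battery_from_dict(doc: Mapping) -> BatteryConfig:
    """Build a validated :class:`BatteryConfig` from a parsed document."""
    if "components" not in doc or not doc["components"]:
        raise CutoffSpecError("battery document has no components")
    specs = []
    for entry in doc["components"]:
        missing = [k for k in _REQUIRED_COMPONENT_KEYS if k not in entry]
        if missing:
            raise CutoffSpecError(
                f"component {entry.get('name', '<unnamed>')!r} missing "
                f"key(s): {missing}"
            )
        specs.append(
            ComponentSpec(
                name=str(entry["name"]),
                direction=entry["direction"],
                cuts=tuple(entry["cuts"]),
                units=str(entry.get("units", "")),
                valid_range=tuple(
                    entry.get("valid_range", (float("-inf"), float("inf")))
                ),
                granularity=entry.get("granularity"),
            )
        )
    return BatteryConfig(
        name=str(doc.get("name", "battery")),
        components=tuple(specs),
        pass_max=int(doc.get("pass_max", 1)),
        borderline_max=int(doc.get("borderline_max", 3)),
        missing_policy=str(doc.get("missing_policy", "error")),
    )


def battery_to_dict(battery: BatteryConfig) -> dict:
    """Serialize a battery to a plain document (YAML/JSON-ready)."""
    return {
        "name": battery.name,
        "pass_max": battery.pass_max,
        "borderline_max": battery.borderline_max,
        "missing_policy": battery.missing_policy,
        "components": [
            {
                "name": c.name,
                "direction": c.direction.value,
                "cuts": list(c.cuts),
                "units": c.units,
                "valid_range": list(c.valid_range),
                "granularity": c.granularity,
            }
            for c in battery.components
        ],
    }


def read_battery_config(path: str | Path) -> BatteryConfig:
    """Read and validate a battery config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise CutoffSpecError(f"{path}: expected a mapping at top level")
    return battery_from_dict(doc)


def write_battery_config(battery: BatteryConfig, path: str | Path) -> None:
    path = Path(path)
    doc = battery_to_dict(battery)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def default_battery() -> BatteryConfig:
    """The packaged standard five-component (EI-5) battery."""
    ref = resources.files("erdodi").joinpath("data/ei5_battery.yaml")
    doc = yaml.safe_load(ref.read_text())
    return battery_from_dict(doc)


def _strip_percent(series: pd.Series) -> pd.Series:
    if series.dtype == object:
        stripped = series.astype(str).str.rstrip("%")
        return pd.to_numeric(stripped, errors="raise")
    return series


def read_cohort_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    percent_columns: tuple[str, ...] = ("wmt_ir", "wmt_dr", "wmt_cns"),
) -> pd.DataFrame:
    """Read a cohort CSV, optionally renaming columns.

    ``column_map`` maps canonical names (component names, criterion
    flag columns) to the file's column headers.  Percent columns accept
    values with or without a trailing ``%``.  Unknown columns are kept
    untouched as covariates; missing numeric cells stay NaN and are
    handled at scoring time by the battery's missing policy.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise KeyError(f"{path}: mapped column(s) not found: {missing}")
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in percent_columns:
        if col in df.columns:
            df[col] = _strip_percent(df[col])
    return df
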