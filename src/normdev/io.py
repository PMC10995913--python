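"""Readers and writers for participant ROI tables and FreeSurfer stats files.

The canonical on-disk cohort format is a plain CSV with a header row and
columns ``participant_id, age, sex, site, group`` followed by optional
clinical-score columns and then the 169 region columns in canonical
index order.  :func:`read_roi_table` accepts any column order and
reorders; it validates that every region column is present and numeric
and that participant ids are unique.

:func:`read_freesurfer_stats` assembles one cohort row from a subject's
``lh.aparc.a2009s.stats`` / ``rh.aparc.a2009s.stats`` (ThickAvg column)
and ``aseg.stats`` (Volume_mm3 column) files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .regions import DESTRIEUX_LABELS, region_names
from .simulate import COVARIATE_COLUMNS

__all__ = ["read_roi_table", "write_roi_table", "read_freesurfer_stats"]


def read_roi_table(path, regions: list[str] | None = None) -> pd.DataFrame:
    """Read and validate a participant ROI table.

    Returns columns ordered: covariates, extra (clinical) columns in file
    order, then regions in canonical order.
    """
    regions = regions if regions is not None else region_names()
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cov = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing_cov:
        raise ValidationError(f"{path}: missing required columns {missing_cov}")
    missing_reg = [r for r in regions if r not in df.columns]
    if missing_reg:
        raise ValidationError(
            f"{path}: missing {len(missing_reg)} region column(s), e.g. {missing_reg[:5]}"
        )
    dup = df["participant_id"][df["participant_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate participant ids: {list(dup.unique())[:5]}")
    bad = [r for r in regions if not np.issubdtype(df[r].dtype, np.number)]
    if bad:
        raise ValidationError(f"{path}: non-numeric region column(s): {bad[:5]}")
    extra = [c for c in df.columns if c not in COVARIATE_COLUMNS and c not in regions]
    return df[COVARIATE_COLUMNS + extra + regions]


def write_roi_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _parse_stats_table(path) -> tuple[list[str], list[list[str]]]:
    """Split a FreeSurfer .stats file into column headers and data rows."""
    headers: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("# ColHeaders"):
                    headers = line.split()[2:]
                continue
            fields = line.split()
            if headers is not None and len(fields) != len(headers):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(headers)} fields, got {len(fields)}"
                )
            rows.append(fields)
    if headers is None:
        raise ParseError(f"{path}: no '# ColHeaders' line found")
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return headers, rows


def _read_aparc(path, hemi_prefix: str) -> dict[str, float]:
    headers, rows = _parse_stats_table(path)
    try:
        i_name = headers.index("StructName")
        i_thick = headers.index("ThickAvg")
    except ValueError as exc:
        raise ParseError(f"{path}: missing StructName/ThickAvg column") from exc
    known = set(DESTRIEUX_LABELS)
    out: dict[str, float] = {}
    for lineno, fields in enumerate(rows, start=1):
        label = fields[i_name]
        if label not in known:
            raise ParseError(f"{path}: unknown cortical label {label!r} (data row {lineno})")
        out[f"{hemi_prefix}_{label}"] = float(fields[i_thick])
    return out


def _read_aseg(path) -> dict[str, float]:
    headers, rows = _parse_stats_table(path)
    try:
        i_name = headers.index("StructName")
        i_vol = headers.index("Volume_mm3")
    except ValueError as exc:
        raise ParseError(f"{path}: missing StructName/Volume_mm3 column") from exc
    wanted = {r for r in region_names() if not r.startswith(("lh_", "rh_"))}
    out: dict[str, float] = {}
    for fields in rows:
        label = fields[i_name]
        if label in wanted:  # aseg files list many structures we do not use
            out[label] = float(fields[i_vol])
    return out


def read_freesurfer_stats(lh_aparc, rh_aparc, aseg) -> pd.Series:
    """One participant's 169 region values from FreeSurfer stats files.

    Returns a Series indexed by the canonical region names.  Raises
    :class:`ParseError` when a file is malformed or a required region is
    absent.
    """
    values: dict[str, float] = {}
    values.update(_read_aparc(lh_aparc, "lh"))
    values.update(_read_aparc(rh_aparc, "rh"))
    values.update(_read_aseg(aseg))
    missing = [r for r in region_names() if r not in values]
    if missing:
        raise ParseError(f"missing {len(missing)} region(s) in stats files, e.g. {missing[:5]}")
    return pd.Series({r: values[r] for r in region_names()})
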