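"""Readers and writers for the deposited Mg/Ca table layouts.

The deposited files (``MgCa_per_laser_spot.tab``, ``MgCa_avg.tab``) are
UTF-8, tab-separated, LF-terminated tables with one header row and optional
``#`` comment lines; missing values are the tokens ``n.a.`` (not available)
and ``n.app.`` (not applicable). This module parses and emits that dialect,
validates sample identifiers of the cruise/station/cast scheme
(``ESyyCnn_sss_cc`` with an optional ``_s`` subsample digit), and packages
the in-repo station/chamber-mean fixture.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "StationRecord",
    "ParseError",
    "SAMPLE_ID_PATTERN",
    "parse_sample_id",
    "parse_depth_interval",
    "MISSING_TOKENS",
    "CHAMBERS",
    "read_mgca_table",
    "write_mgca_table",
    "load_table2",
    "load_table2_records",
]

log = logging.getLogger(__name__)

MISSING_TOKENS = ("n.a.", "n.app.")
CHAMBERS = ("F0", "F-1", "F-2")

#: ES <2-digit year> C <2-digit cruise> _ <3-digit station> _ <2-digit cast>
#: with an optional single-digit subsample suffix.
SAMPLE_ID_PATTERN = re.compile(r"^ES\d{2}C\d{2}_\d{3}_\d{2}(_\d)?$")


class ParseError(ValueError):
    """Malformed table content, annotated with the offending line number."""


def parse_sample_id(sample_id: str) -> dict[str, str]:
    """Split a sample identifier into its cruise/station/cast components."""
    if not SAMPLE_ID_PATTERN.match(sample_id):
        raise ParseError(f"malformed sample id: {sample_id!r}")
    parts = sample_id.split("_")
    out = {"cruise": parts[0], "station": parts[1], "cast": parts[2]}
    if len(parts) == 4:
        out["subsample"] = parts[3]
    return out


def parse_depth_interval(text: str) -> tuple[float, float]:
    """Parse '20-100' / '20–100' style depth intervals (metres).

    A single number (a bongonet tow depth such as '50') is returned as a
    zero-width interval.
    """
    t = str(text).strip().replace("–", "-")
    if re.fullmatch(r"\d+(\.\d+)?", t):
        d = float(t)
        return (d, d)
    m = re.fullmatch(r"(\d+(?:\.\d+)?)-(\d+(?:\.\d+)?)", t)
    if not m:
        raise ParseError(f"malformed depth interval: {text!r}")
    top, bottom = float(m.group(1)), float(m.group(2))
    if top > bottom:
        raise ParseError(f"depth interval inverted: {text!r}")
    return (top, bottom)


@dataclass(frozen=True)
class StationRecord:
    """One station/cast row: chamber-mean Mg/Ca ± 1σ and temperatures."""

    sample_number: str
    device: Literal["MN", "BN"]
    water_depth_m: tuple[float, float]
    mgca_f0: Optional[float]
    sigma_f0: Optional[float]
    mgca_f1: Optional[float]
    sigma_f1: Optional[float]
    mgca_f2: Optional[float]
    sigma_f2: Optional[float]
    sst_c: Optional[float]
    t_mld_c: Optional[float]
    t_insitu_c: Optional[float]

    def __post_init__(self) -> None:
        parse_sample_id(self.sample_number)
        if self.device not in ("MN", "BN"):
            raise ValueError(f"unknown device {self.device!r}")
        top, bottom = self.water_depth_m
        if top < 0 or bottom < top:
            raise ValueError("water depths must be non-negative and ordered")
        for name in ("mgca_f0", "mgca_f1", "mgca_f2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when present")

    def mgca(self, chamber: str) -> Optional[float]:
        return getattr(self, f"mgca_{chamber.replace('-', '').lower()}")


_PER_SPOT_REQUIRED = ("sample_id", "specimen_id", "chamber", "mgca_mmolmol",
                      "error_1s")
_AVERAGED_REQUIRED = ("sample_id", "chamber", "mgca_mmolmol", "error_1s")


def _parse_float(token: str, column: str, lineno: int) -> float:
    token = token.strip()
    if token in MISSING_TOKENS or token == "":
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"line {lineno}: non-numeric value {token!r} in column "
            f"{column!r}") from None


def read_mgca_table(path: str | Path,
                    kind: Literal["per_spot", "averaged"]) -> pd.DataFrame:
    """Read a deposited-layout Mg/Ca table into a typed DataFrame.

    Missing-value tokens become NaN. Unknown chamber labels, non-numeric
    Mg/Ca entries and duplicated header lines raise :class:`ParseError` with
    the line number.
    """
    if kind not in ("per_spot", "averaged"):
        raise ValueError("kind must be 'per_spot' or 'averaged'")
    required = _PER_SPOT_REQUIRED if kind == "per_spot" else _AVERAGED_REQUIRED

    path = Path(path)
    header: Optional[list[str]] = None
    rows: list[dict] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in required if c not in header]
                if missing:
                    raise ParseError(
                        f"line {lineno}: header lacks required columns "
                        f"{missing}")
                continue
            if [f.strip() for f in fields] == header:
                raise ParseError(f"line {lineno}: duplicate header row")
            if len(fields) != len(header):
                raise ParseError(
                    f"line {lineno}: {len(fields)} fields, expected "
                    f"{len(header)}")
            rec: dict = {}
            for col, tok in zip(header, fields):
                tok = tok.strip()
                if col == "chamber":
                    if tok not in CHAMBERS:
                        raise ParseError(
                            f"line {lineno}: unknown chamber label {tok!r}")
                    rec[col] = tok
                elif col in ("sample_id", "specimen_id", "device",
                             "time_of_sampling", "species"):
                    rec[col] = tok
                elif col.startswith(("mgca", "error", "sigma")):
                    rec[col] = _parse_float(tok, col, lineno)
                else:
                    # metadata columns may be free text (depth intervals,
                    # timestamps); numbers are typed when they parse
                    if tok in MISSING_TOKENS or tok == "":
                        rec[col] = np.nan
                    else:
                        try:
                            rec[col] = float(tok)
                        except ValueError:
                            rec[col] = tok
            if "sample_id" in rec:
                parse_sample_id(rec["sample_id"])
            if np.isfinite(rec.get("mgca_mmolmol", np.nan)) and \
                    rec["mgca_mmolmol"] <= 0:
                raise ParseError(
                    f"line {lineno}: non-positive Mg/Ca "
                    f"{rec['mgca_mmolmol']!r}")
            rows.append(rec)
    if header is None:
        raise ParseError("file has no header row")
    df = pd.DataFrame(rows, columns=header)
    log.info("read %d rows, columns %s from %s", len(df), list(df.columns),
             path)
    return df


def write_mgca_table(df: pd.DataFrame, path: str | Path,
                     comment: Optional[str] = None) -> None:
    """Write a table in the deposited dialect (tab-separated, LF, UTF-8,
    missing values as 'n.a.')."""
    path = Path(path)
    buf = StringIO()
    if comment:
        for line in comment.splitlines():
            buf.write(f"# {line}\n")
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda v: "n.a." if not np.isfinite(v) else f"{v:.6g}")
    out.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def _table2_text() -> str:
    return (resources.files("mgcalab.data") / "table2.tab").read_text(
        encoding="utf-8")


def load_table2() -> pd.DataFrame:
    """The packaged station/chamber-mean table as a DataFrame.

    Columns: sample_number, device, water_depth_m (string interval),
    chamber means/sigmas in mmol/mol, and the three temperature measures in
    °C (NaN where missing).
    """
    df = pd.read_csv(StringIO(_table2_text()), sep="\t", comment="#",
                     na_values=list(MISSING_TOKENS))
    return df


def load_table2_records() -> list[StationRecord]:
    """The packaged station table as validated :class:`StationRecord`s."""
    df = load_table2()

    def opt(v) -> Optional[float]:
        return None if pd.isna(v) else float(v)

    records = []
    for _, row in df.iterrows():
        records.append(StationRecord(
            sample_number=row["sample_number"],
            device=row["device"],
            water_depth_m=parse_depth_interval(row["water_depth_m"]),
            mgca_f0=opt(row["mgca_f0"]), sigma_f0=opt(row["sigma_f0"]),
            mgca_f1=opt(row["mgca_f1"]), sigma_f1=opt(row["sigma_f1"]),
            mgca_f2=opt(row["mgca_f2"]), sigma_f2=opt(row["sigma_f2"]),
            sst_c=opt(row["sst_c"]), t_mld_c=opt(row["t_mld_c"]),
            t_insitu_c=opt(row["t_insitu_c"]),
        ))
    return records
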