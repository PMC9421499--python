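"""Readers and writers for the two text dialects.

panel-CSV
    Long format, one row per wave (a waveless individual contributes one
    row with empty wave fields).  Columns::

        id, birth_month, birth_year, death_month, death_year,
        education, obese, smoker, exercise, bmi,
        wave_date, pf_score, needs_help, state,
        wave_education, wave_obese, wave_smoker, wave_exercise, wave_bmi

    Dates are ISO (YYYY-MM-DD), missing values are empty cells, states are
    {0, 1, -1}.  Round trips are lossless; malformed rows are rejected with
    the offending line number.

IMaCH-style dialect
    Whitespace-delimited, one line per individual: id, weight, covariate
    values, birth month/year, death month/year, then per wave month/day/year
    and a 1-based state code {1, 2, 3} (-1 unknown).  Unknown dates are
    ``99/9999`` (``99/99/9999`` for waves); lines are padded to a common
    wave count with unknown markers.  PF scores, help flags and BMI are not
    part of this dialect.
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path
from typing import Sequence

from .panel import (COVARIATE_FIELDS, UNKNOWN, IndividualRecord, PanelDataset,
                    WaveObservation)

_CSV_COLUMNS = (
    "id", "birth_month", "birth_year", "death_month", "death_year",
    "education", "obese", "smoker", "exercise", "bmi",
    "wave_date", "pf_score", "needs_help", "state",
    "wave_education", "wave_obese", "wave_smoker", "wave_exercise", "wave_bmi",
)

_VALID_STATES = {"-1", "0", "1"}


class PanelFormatError(ValueError):
    """Malformed panel file; message carries the 1-based line number."""


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_int(text: str, line: int, col: str) -> int | None:
    if text == "":
        return None
    try:
        return int(text)
    except ValueError:
        raise PanelFormatError(f"line {line}: bad integer in {col}: {text!r}")


def _parse_float(text: str, line: int, col: str) -> float | None:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise PanelFormatError(f"line {line}: bad number in {col}: {text!r}")


def _parse_binary(text: str, line: int, col: str) -> int | None:
    v = _parse_int(text, line, col)
    if v is not None and v not in (0, 1):
        raise PanelFormatError(f"line {line}: {col} must be 0/1, got {text!r}")
    return v


def write_panel_csv(dataset: PanelDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for rec in dataset:
            base = [rec.id, rec.birth_month, rec.birth_year, rec.death_month,
                    rec.death_year, rec.education, rec.obese, rec.smoker,
                    rec.exercise, rec.bmi]
            if not rec.waves:
                writer.writerow([_fmt(v) for v in base] + [""] * 9)
            for w in rec.waves:
                row = base + [w.date.isoformat(), w.pf_score, w.needs_help,
                              w.state, w.education, w.obese, w.smoker,
                              w.exercise, w.bmi]
                writer.writerow([_fmt(v) for v in row])


def read_panel_csv(path: str | Path) -> PanelDataset:
    records: dict[str, IndividualRecord] = {}
    seen_waves: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PanelFormatError("line 1: empty file (header expected)")
        if tuple(header) != _CSV_COLUMNS:
            raise PanelFormatError(
                f"line 1: bad header, expected {','.join(_CSV_COLUMNS)}")
        for n, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_CSV_COLUMNS):
                raise PanelFormatError(
                    f"line {n}: expected {len(_CSV_COLUMNS)} fields, got {len(row)}")
            cells = dict(zip(_CSV_COLUMNS, row))
            iid = cells["id"]
            if iid == "":
                raise PanelFormatError(f"line {n}: empty id")
            if iid not in records:
                bm = _parse_int(cells["birth_month"], n, "birth_month")
                by = _parse_int(cells["birth_year"], n, "birth_year")
                if bm is None or by is None:
                    raise PanelFormatError(f"line {n}: missing birth month/year")
                records[iid] = IndividualRecord(
                    id=iid, birth_month=bm, birth_year=by,
                    death_month=_parse_int(cells["death_month"], n, "death_month"),
                    death_year=_parse_int(cells["death_year"], n, "death_year"),
                    education=_parse_binary(cells["education"], n, "education"),
                    obese=_parse_binary(cells["obese"], n, "obese"),
                    smoker=_parse_binary(cells["smoker"], n, "smoker"),
                    exercise=_parse_binary(cells["exercise"], n, "exercise"),
                    bmi=_parse_float(cells["bmi"], n, "bmi"),
                )
            if cells["wave_date"] == "":
                continue  # waveless individual
            if (iid, cells["wave_date"]) in seen_waves:
                raise PanelFormatError(
                    f"line {n}: duplicate wave {cells['wave_date']} for id {iid!r}")
            seen_waves.add((iid, cells["wave_date"]))
            try:
                date = dt.date.fromisoformat(cells["wave_date"])
            except ValueError:
                raise PanelFormatError(
                    f"line {n}: malformed date {cells['wave_date']!r}")
            if cells["state"] not in _VALID_STATES:
                raise PanelFormatError(
                    f"line {n}: unknown state code {cells['state']!r}")
            nh = _parse_binary(cells["needs_help"], n, "needs_help")
            records[iid].waves.append(WaveObservation(
                date=date,
                pf_score=_parse_float(cells["pf_score"], n, "pf_score"),
                needs_help=None if nh is None else bool(nh),
                state=int(cells["state"]),
                education=_parse_binary(cells["wave_education"], n, "wave_education"),
                obese=_parse_binary(cells["wave_obese"], n, "wave_obese"),
                smoker=_parse_binary(cells["wave_smoker"], n, "wave_smoker"),
                exercise=_parse_binary(cells["wave_exercise"], n, "wave_exercise"),
                bmi=_parse_float(cells["wave_bmi"], n, "wave_bmi"),
            ))
    dataset = PanelDataset(individuals=list(records.values()))
    dataset.validate()
    return dataset


# ---------------------------------------------------------------- IMaCH-style

_UNKNOWN_MY = "99/9999"
_UNKNOWN_MDY = "99/99/9999"


def _state_to_dialect(state: int) -> str:
    return "-1" if state == UNKNOWN else str(state + 1)


def _state_from_dialect(text: str, line: int = 0) -> int:
    if text == "-1":
        return UNKNOWN
    if text in ("1", "2", "3"):
        return int(text) - 1
    raise PanelFormatError(f"line {line}: bad state code {text!r}")


def write_imach_input(dataset: PanelDataset, path: str | Path,
                      covariates: Sequence[str] = COVARIATE_FIELDS) -> None:
    """Emit the whitespace dialect (one padded line per individual)."""
    for rec in dataset:
        if not rec.waves:
            raise ValueError(f"{rec.id}: cannot emit an individual with no waves")
    n_waves = max(len(rec.waves) for rec in dataset) if len(dataset) else 0
    with open(path, "w") as fh:
        for rec in dataset:
            parts = [rec.id, "1"]
            for c in covariates:
                v = rec.covariate(c)
                parts.append("." if v is None else str(v))
            parts.append(f"{rec.birth_month:02d}/{rec.birth_year:04d}")
            if rec.died:
                parts.append(f"{rec.death_month:02d}/{rec.death_year:04d}")
            else:
                parts.append(_UNKNOWN_MY)
            for w in rec.waves:
                parts.append(f"{w.date.month:02d}/{w.date.day:02d}/{w.date.year:04d}")
                parts.append(_state_to_dialect(w.state))
            for _ in range(n_waves - len(rec.waves)):
                parts.extend([_UNKNOWN_MDY, "-1"])
            fh.write(" ".join(parts) + "\n")


def read_imach_input(path: str | Path,
                     covariates: Sequence[str] = COVARIATE_FIELDS) -> PanelDataset:
    """Invert :func:`write_imach_input` (padding entries are dropped)."""
    individuals = []
    with open(path) as fh:
        for n, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            fixed = 2 + len(covariates) + 2
            if len(parts) < fixed or (len(parts) - fixed) % 2:
                raise PanelFormatError(f"line {n}: malformed record")
            iid = parts[0]
            covs = {}
            for c, cell in zip(covariates, parts[2:2 + len(covariates)]):
                if cell == ".":
                    covs[c] = None
                elif cell in ("0", "1"):
                    covs[c] = int(cell)
                else:
                    raise PanelFormatError(f"line {n}: bad covariate {cell!r}")
            try:
                bm, by = (int(v) for v in parts[fixed - 2].split("/"))
            except ValueError:
                raise PanelFormatError(f"line {n}: malformed birth date")
            death = parts[fixed - 1]
            dm = dy = None
            if death != _UNKNOWN_MY:
                try:
                    dm, dy = (int(v) for v in death.split("/"))
                except ValueError:
                    raise PanelFormatError(f"line {n}: malformed death date")
            waves = []
            tail = parts[fixed:]
            for k in range(0, len(tail), 2):
                if tail[k] == _UNKNOWN_MDY:
                    continue  # padding
                try:
                    m, d, y = (int(v) for v in tail[k].split("/"))
                    date = dt.date(y, m, d)
                except ValueError:
                    raise PanelFormatError(f"line {n}: malformed wave date {tail[k]!r}")
                waves.append(WaveObservation(
                    date=date, state=_state_from_dialect(tail[k + 1], n)))
            individuals.append(IndividualRecord(
                id=iid, birth_month=bm, birth_year=by,
                death_month=dm, death_year=dy, waves=waves, **covs))
    dataset = PanelDataset(individuals=individuals)
    dataset.validate()
    return dataset
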