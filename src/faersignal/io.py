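"""Reading and writing FAERS-style quarterly ASCII tables.

FAERS quarters are distributed as "$"-delimited text files, one file per
table (DEMO, DRUG, REAC, OUTC, THER), with a header row naming the
columns.  Column names drifted across database eras (``GNDR_COD`` became
``SEX``, ``DRUG_SEQ`` became ``DSG_DRUG_SEQ`` in THER, ...), so columns
are matched case-insensitively against the known aliases.

Rows that violate a table's basic contract (empty PRIMARYID, an
unparseable mandatory date, an unknown drug role code) are dropped but
*counted* in a :class:`ParseIssues` record — a spontaneous-report
pipeline must account for every row it discards.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .dates import PartialDate

DELIM = "$"

#: FAERS role codes: primary suspect, secondary suspect, concomitant, interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

#: FAERS age unit codes -> spec categories.
AGE_UNITS = {"DEC": "decade", "YR": "year", "MON": "month", "WK": "week",
             "DY": "day", "HR": "hour"}

WEIGHT_UNITS = {"KG": "kg", "KGS": "kg", "LBS": "lbs", "LB": "lbs", "IB": "lbs"}

SEX_CODES = {"F": "female", "M": "male"}

REPORTER_CODES = {"MD": "physician", "PH": "pharmacist", "CN": "consumer",
                  "OT": "other health-professional", "RN": "registered nurse",
                  "LW": "lawyer"}

#: FAERS outcome codes -> the seven-category outcome set.
OUTCOME_CODES = {
    "DE": "death",
    "LT": "life threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital anomaly",
    "RI": "required intervention",
    "OT": "other serious",
}
OUTCOME_NAMES = set(OUTCOME_CODES.values())


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class DemoRecord:
    """One report version from the DEMO table."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate
    event_dt: Optional[PartialDate] = None
    sex: str = "unknown"                  # female / male / unknown
    age_value: Optional[float] = None
    age_unit: str = "unknown"             # decade/year/month/week/day/hour/unknown
    weight_value: Optional[float] = None
    weight_unit: str = "unknown"          # kg / lbs / unknown
    reporter: str = "unknown"
    country: str = "unknown"


@dataclass(slots=True)
class DrugRecord:
    primaryid: str
    drug_seq: int
    drugname: str
    role: str                             # PS / SS / C / I
    dose_text: Optional[str] = None


@dataclass(slots=True)
class ReacRecord:
    primaryid: str
    pt: str


@dataclass(slots=True)
class OutcRecord:
    primaryid: str
    outcome: str                          # one of OUTCOME_NAMES


@dataclass(slots=True)
class TherRecord:
    primaryid: str
    drug_seq: int
    start_dt: Optional[PartialDate] = None


@dataclass
class ParseIssues:
    """Per-table tallies of rows dropped or degraded during parsing."""

    counts: dict[str, int] = field(default_factory=dict)

    def bump(self, reason: str, n: int = 1) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class QuarterData:
    """Typed record collections for one (or several concatenated) quarters."""

    demo: list[DemoRecord] = field(default_factory=list)
    drug: list[DrugRecord] = field(default_factory=list)
    reac: list[ReacRecord] = field(default_factory=list)
    outc: list[OutcRecord] = field(default_factory=list)
    ther: list[TherRecord] = field(default_factory=list)
    issues: dict[str, ParseIssues] = field(default_factory=dict)

    def extend(self, other: "QuarterData") -> None:
        self.demo.extend(other.demo)
        self.drug.extend(other.drug)
        self.reac.extend(other.reac)
        self.outc.extend(other.outc)
        self.ther.extend(other.ther)
        for table, issues in other.issues.items():
            mine = self.issues.setdefault(table, ParseIssues())
            for reason, n in issues.counts.items():
                mine.bump(reason, n)


class MissingColumnError(ValueError):
    """A mandatory column is absent from a table file."""


# ---------------------------------------------------------------------------
# Column resolution
# ---------------------------------------------------------------------------

_ALIASES: Mapping[str, Mapping[str, Sequence[str]]] = {
    "demo": {
        "primaryid": ("primaryid", "isr"),
        "caseid": ("caseid", "case"),
        "fda_dt": ("fda_dt",),
        "event_dt": ("event_dt",),
        "sex": ("sex", "gndr_cod"),
        "age": ("age",),
        "age_cod": ("age_cod",),
        "wt": ("wt",),
        "wt_cod": ("wt_cod",),
        "occp_cod": ("occp_cod",),
        "reporter_country": ("reporter_country",),
    },
    "drug": {
        "primaryid": ("primaryid", "isr"),
        "drug_seq": ("drug_seq", "dsg_drug_seq"),
        "drugname": ("drugname",),
        "role_cod": ("role_cod",),
        "dose_vbm": ("dose_vbm",),
    },
    "reac": {
        "primaryid": ("primaryid", "isr"),
        "pt": ("pt",),
    },
    "outc": {
        "primaryid": ("primaryid", "isr"),
        "outc_cod": ("outc_cod", "outc_code"),
    },
    "ther": {
        "primaryid": ("primaryid", "isr"),
        "drug_seq": ("dsg_drug_seq", "drug_seq"),
        "start_dt": ("start_dt",),
    },
}

_MANDATORY = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drug_seq", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "ther": ("primaryid", "drug_seq"),
}


def _resolve_columns(table: str, header: Sequence[str], path: str) -> dict[str, str]:
    lower = {h.lower().strip(): h for h in header}
    found: dict[str, str] = {}
    for logical, aliases in _ALIASES[table].items():
        for alias in aliases:
            if alias in lower:
                found[logical] = lower[alias]
                break
    missing = [c for c in _MANDATORY[table] if c not in found]
    if missing:
        wanted = ", ".join(_ALIASES[table][c][0] for c in missing)
        raise MissingColumnError(
            f"{path}: {table.upper()} table lacks mandatory column(s): {wanted}"
        )
    return found


def _read_frame(path: str | Path, table: str) -> tuple[pd.DataFrame, dict[str, str]]:
    path = Path(path)
    df = pd.read_csv(path, sep=DELIM, dtype=str, keep_default_na=False,
                     engine="python", quoting=csv.QUOTE_NONE)
    if df.empty and len(df.columns) == 0:
        raise MissingColumnError(f"{path}: empty file with no header for {table.upper()}")
    cols = _resolve_columns(table, list(df.columns), str(path))
    if len(df) == 0:
        warnings.warn(f"{path}: {table.upper()} file has a header but no rows")
    return df, cols


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return value or None


def _opt_float(value: str) -> Optional[float]:
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Per-table readers
# ---------------------------------------------------------------------------

def read_demo(path: str | Path) -> tuple[list[DemoRecord], ParseIssues]:
    df, cols = _read_frame(path, "demo")
    issues = ParseIssues()
    records: list[DemoRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        get = lambda k: str(row[cols[k]]) if k in cols else ""
        pid = get("primaryid").strip()
        if not pid:
            issues.bump("empty_primaryid")
            continue
        if pid in seen:
            issues.bump("duplicate_primaryid")
            continue
        caseid = get("caseid").strip()
        if not caseid:
            issues.bump("empty_caseid")
            continue
        fda_dt = PartialDate.parse(get("fda_dt"))
        if fda_dt is None:
            issues.bump("unparseable_fda_dt")
            continue
        age_raw = _opt(get("age"))
        age_value = _opt_float(age_raw) if age_raw is not None else None
        if age_raw is not None and age_value is None:
            issues.bump("non_numeric_age")
        wt_raw = _opt(get("wt"))
        weight_value = _opt_float(wt_raw) if wt_raw is not None else None
        if wt_raw is not None and weight_value is None:
            issues.bump("non_numeric_weight")
        seen.add(pid)
        records.append(DemoRecord(
            primaryid=pid,
            caseid=caseid,
            fda_dt=fda_dt,
            event_dt=PartialDate.parse(_opt(get("event_dt"))),
            sex=SEX_CODES.get(get("sex").strip().upper(), "unknown"),
            age_value=age_value,
            age_unit=AGE_UNITS.get(get("age_cod").strip().upper(), "unknown"),
            weight_value=weight_value,
            weight_unit=WEIGHT_UNITS.get(get("wt_cod").strip().upper(), "unknown"),
            reporter=REPORTER_CODES.get(get("occp_cod").strip().upper(), "unknown"),
            country=_opt(get("reporter_country")) or "unknown",
        ))
    return records, issues


def read_drug(path: str | Path) -> tuple[list[DrugRecord], ParseIssues]:
    df, cols = _read_frame(path, "drug")
    issues = ParseIssues()
    records: list[DrugRecord] = []
    seen: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        get = lambda k: str(row[cols[k]]) if k in cols else ""
        pid = get("primaryid").strip()
        if not pid:
            issues.bump("empty_primaryid")
            continue
        role = get("role_cod").strip().upper()
        if role not in ROLE_CODES:
            issues.bump("unknown_role_cod")
            continue
        try:
            seq = int(float(get("drug_seq")))
        except (TypeError, ValueError):
            issues.bump("non_numeric_drug_seq")
            continue
        if (pid, seq) in seen:
            issues.bump("duplicate_drug_seq")
            continue
        name = get("drugname").strip()
        if not name:
            issues.bump("empty_drugname")
            continue
        seen.add((pid, seq))
        records.append(DrugRecord(primaryid=pid, drug_seq=seq, drugname=name,
                                  role=role, dose_text=_opt(get("dose_vbm"))))
    return records, issues


def read_reac(path: str | Path) -> tuple[list[ReacRecord], ParseIssues]:
    df, cols = _read_frame(path, "reac")
    issues = ParseIssues()
    records: list[ReacRecord] = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        pid = str(row[cols["primaryid"]]).strip()
        pt = str(row[cols["pt"]]).strip()
        if not pid:
            issues.bump("empty_primaryid")
            continue
        if not pt:
            issues.bump("empty_pt")
            continue
        records.append(ReacRecord(primaryid=pid, pt=pt))
    return records, issues


def read_outc(path: str | Path) -> tuple[list[OutcRecord], ParseIssues]:
    df, cols = _read_frame(path, "outc")
    issues = ParseIssues()
    records: list[OutcRecord] = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        pid = str(row[cols["primaryid"]]).strip()
        code = str(row[cols["outc_cod"]]).strip().upper()
        if not pid:
            issues.bump("empty_primaryid")
            continue
        if code not in OUTCOME_CODES:
            issues.bump("unknown_outc_cod")
            continue
        records.append(OutcRecord(primaryid=pid, outcome=OUTCOME_CODES[code]))
    return records, issues


def read_ther(path: str | Path) -> tuple[list[TherRecord], ParseIssues]:
    df, cols = _read_frame(path, "ther")
    issues = ParseIssues()
    records: list[TherRecord] = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        get = lambda k: str(row[cols[k]]) if k in cols else ""
        pid = get("primaryid").strip()
        if not pid:
            issues.bump("empty_primaryid")
            continue
        try:
            seq = int(float(get("drug_seq")))
        except (TypeError, ValueError):
            issues.bump("non_numeric_drug_seq")
            continue
        records.append(TherRecord(primaryid=pid, drug_seq=seq,
                                  start_dt=PartialDate.parse(_opt(get("start_dt")))))
    return records, issues


def read_quarter(paths: Mapping[str, str | Path | Sequence[str | Path]]) -> QuarterData:
    """Read one quarter's tables into typed records.

    Parameters
    ----------
    paths
        Mapping with keys among ``demo, drug, reac, outc, ther``; each
        value is a file path or a sequence of file paths (several
        quarters of the same table may be concatenated).
    """
    readers = {"demo": read_demo, "drug": read_drug, "reac": read_reac,
               "outc": read_outc, "ther": read_ther}
    unknown = set(paths) - set(readers)
    if unknown:
        raise ValueError(f"unknown table keys: {sorted(unknown)}")
    out = QuarterData()
    for table, reader in readers.items():
        if table not in paths:
            continue
        value = paths[table]
        file_list = [value] if isinstance(value, (str, Path)) else list(value)
        issues = out.issues.setdefault(table, ParseIssues())
        for path in file_list:
            records, file_issues = reader(path)
            getattr(out, table).extend(records)
            for reason, n in file_issues.counts.items():
                issues.bump(reason, n)
    # enforce primaryid uniqueness across concatenated DEMO files too
    seen: set[str] = set()
    unique: list[DemoRecord] = []
    for rec in out.demo:
        if rec.primaryid in seen:
            out.issues["demo"].bump("duplicate_primaryid")
            continue
        seen.add(rec.primaryid)
        unique.append(rec)
    out.demo = unique
    return out


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts of the readers)
# ---------------------------------------------------------------------------

def _dt_str(d: Optional[PartialDate]) -> str:
    return d.faers_str() if d is not None else ""


_REV_SEX = {v: k for k, v in SEX_CODES.items()}
_REV_AGE = {v: k for k, v in AGE_UNITS.items()}
_REV_WT = {"kg": "KG", "lbs": "LBS"}
_REV_REPORTER = {v: k for k, v in REPORTER_CODES.items()}
_REV_OUTCOME = {v: k for k, v in OUTCOME_CODES.items()}


def _num_str(x: Optional[float]) -> str:
    if x is None:
        return ""
    return f"{x:g}"


def write_quarter(data: QuarterData, out_dir: str | Path,
                  prefix: str = "") -> dict[str, Path]:
    """Write records back to "$"-delimited files; inverse of read_quarter."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, header: list[str], rows: Iterable[list[str]]) -> None:
        path = out_dir / f"{prefix}{name}.txt"
        with open(path, "w", newline="") as fh:
            fh.write(DELIM.join(header) + "\n")
            for row in rows:
                fh.write(DELIM.join(row) + "\n")
        paths[name] = path

    _write("demo",
           ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
            "age_cod", "wt", "wt_cod", "occp_cod", "reporter_country"],
           ([r.primaryid, r.caseid, _dt_str(r.fda_dt), _dt_str(r.event_dt),
             _REV_SEX.get(r.sex, ""), _num_str(r.age_value),
             _REV_AGE.get(r.age_unit, ""), _num_str(r.weight_value),
             _REV_WT.get(r.weight_unit, ""), _REV_REPORTER.get(r.reporter, ""),
             "" if r.country == "unknown" else r.country]
            for r in data.demo))
    _write("drug",
           ["primaryid", "drug_seq", "drugname", "role_cod", "dose_vbm"],
           ([r.primaryid, str(r.drug_seq), r.drugname, r.role, r.dose_text or ""]
            for r in data.drug))
    _write("reac", ["primaryid", "pt"],
           ([r.primaryid, r.pt] for r in data.reac))
    _write("outc", ["primaryid", "outc_cod"],
           ([r.primaryid, _REV_OUTCOME[r.outcome]] for r in data.outc))
    _write("ther", ["primaryid", "dsg_drug_seq", "start_dt"],
           ([r.primaryid, str(r.drug_seq), _dt_str(r.start_dt)]
            for r in data.ther))
    return paths


# ---------------------------------------------------------------------------
# Dictionary / mapping files
# ---------------------------------------------------------------------------

def normalize_pt(pt: str) -> str:
    """Case-insensitive, whitespace-normalized preferred-term key."""
    return " ".join(pt.split()).lower()


class PtSocMap:
    """Preferred term -> system organ class dictionary.

    Stands in for the licensed MedDRA hierarchy: a plain two-column file
    supplies one organ class per preferred term.  Lookup is
    case-insensitive after whitespace normalization.
    """

    def __init__(self, entries: Mapping[str, str]):
        self._map = {normalize_pt(pt): " ".join(soc.split()).lower()
                     for pt, soc in entries.items()}

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self._map

    def get(self, pt: str, default: str = "unmapped") -> str:
        return self._map.get(normalize_pt(pt), default)

    def items(self):
        return self._map.items()


def read_pt_soc_map(path: str | Path, sep: str = ",") -> PtSocMap:
    """Read a two-column pt,soc file; conflicting duplicates are an error."""
    entries: dict[str, str] = {}
    conflicts: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header is None:
            warnings.warn(f"{path}: empty PT->SOC mapping file")
            return PtSocMap({})
        # accept files with or without a header row
        if [h.lower().strip() for h in header[:2]] != ["pt", "soc"]:
            rows = [header]
        else:
            rows = []
        rows.extend(reader)
    for row in rows:
        if len(row) < 2:
            continue
        pt, soc = normalize_pt(row[0]), " ".join(row[1].split()).lower()
        if not pt:
            continue
        if pt in entries and entries[pt] != soc:
            conflicts.append(pt)
        entries[pt] = soc
    if conflicts:
        raise ValueError(
            "conflicting SOC mapping for preferred term(s): "
            + ", ".join(sorted(set(conflicts))))
    return PtSocMap(entries)


def read_drug_dictionary(path: str | Path, sep: str = ","):
    """Read a raw_name,canonical_name synonym file into a DrugDictionary."""
    from .cleaning import DrugDictionary  # local import avoids a cycle
    synonyms: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        rows: list[list[str]] = []
        if header is not None:
            if [h.lower().strip() for h in header[:2]] != ["raw_name", "canonical_name"]:
                rows.append(header)
            rows.extend(reader)
    for row in rows:
        if len(row) >= 2 and row[0].strip():
            synonyms[row[0]] = row[1].strip().lower()
    return DrugDictionary(synonyms)


# ---------------------------------------------------------------------------
# Signal table output
# ---------------------------------------------------------------------------

def fmt2(x: float) -> str:
    """Render a number the way the published tables do: 2 decimals, no
    trailing zeros (4.87 -> "4.87", 5.20 -> "5.2", 2.00 -> "2")."""
    import math
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{round(float(x) + 0.0, 2):g}"


SIGNAL_COLUMNS = ["soc", "pt", "n", "ror", "ror_low", "ror_high",
                  "prr", "prr_low", "prr_high", "ic", "ic025",
                  "ebgm", "ebgm05", "flag_ror", "flag_prr", "flag_bcpnn",
                  "flag_ebgm", "flag_all4"]


def write_signal_table(rows, path: str | Path, human: bool = False) -> Path:
    """Write SignalStats rows as a delimited table.

    With ``human=True`` the point estimate and interval are merged into
    one column per statistic, matching the presentation style
    ``4.87 (4.56, 5.2)`` of published signal tables.
    """
    path = Path(path)
    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    if human:
        writer.writerow(["soc", "pt", "n", "ror_95ci", "prr_95ci",
                         "ic_ic025", "ebgm_ebgm05", "flag_all4"])
        for r in rows:
            writer.writerow([
                r.soc, r.event, r.n,
                f"{fmt2(r.ror)} ({fmt2(r.ror_ci_low)}, {fmt2(r.ror_ci_high)})",
                f"{fmt2(r.prr)} ({fmt2(r.prr_ci_low)}, {fmt2(r.prr_ci_high)})",
                f"{fmt2(r.ic)} ({fmt2(r.ic025_crude)})",
                f"{fmt2(r.ebgm)} ({fmt2(r.ebgm05)})",
                "yes" if r.flag_all4 else "no",
            ])
    else:
        writer.writerow(SIGNAL_COLUMNS)
        for r in rows:
            writer.writerow([
                r.soc, r.event, r.n,
                fmt2(r.ror), fmt2(r.ror_ci_low), fmt2(r.ror_ci_high),
                fmt2(r.prr), fmt2(r.prr_ci_low), fmt2(r.prr_ci_high),
                fmt2(r.ic), fmt2(r.ic025), fmt2(r.ebgm), fmt2(r.ebgm05),
                int(r.flag_ror), int(r.flag_prr), int(r.flag_bcpnn),
                int(r.flag_ebgm), int(r.flag_all4),
            ])
    path.write_text(buf.getvalue())
    return path
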