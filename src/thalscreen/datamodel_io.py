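"""Subject-level data model and delimited-text cohort I/O.

A cohort is an ordered collection of :class:`SubjectRecord`, one per
subject, carrying the routine red-cell indices (Hb, RBC, HCT, MCV, MCH,
MCHC, RDW) and the reticulocyte cell-population-data (CPD) channels
reported by a haematology analyzer (MN-LMALS-RET and friends), plus an
optional diagnosis label.

Parsing is lossless: rows that violate the physiologic sanity bounds are
retained but *flagged*; whether a flagged record participates in a given
computation is decided by that computation, never at parse time. Missing
values are encoded as empty cells or ``NA`` — never as 0, since zero is a
legal analyzer channel reading.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "LABELS",
    "NUMERIC_FIELDS",
    "CPD_FIELDS",
    "SanityBounds",
    "SubjectRecord",
    "Cohort",
    "ParseReport",
    "read_cohort",
    "write_results",
    "canonical_column",
]

#: Fixed diagnosis vocabulary: healthy controls, the two thalassaemia
#: carrier states, haemoglobin-E trait, iron-deficiency anaemia and iron
#: deficiency without anaemia.
LABELS = frozenset(
    {"healthy", "alpha_trait", "beta_trait", "hbe_trait", "ida", "id"}
)

#: Routine red-cell indices (units in :class:`SubjectRecord`).
INDEX_FIELDS = ("hb", "rbc", "hct", "mcv", "mch", "mchc", "rdw")

#: Reticulocyte CPD / research parameters (analyzer units; volumes in fL).
CPD_FIELDS = (
    "mn_lmals_ret",
    "mn_mals_ret",
    "mn_lmals_nret",
    "mn_v_ret",
    "mn_v_nret",
    "maf",
)

NUMERIC_FIELDS = INDEX_FIELDS + CPD_FIELDS

# Analyzer exports spell the CPD channels several ways ("MN-LMALS-RET",
# "@MNLMALSRET"); matching is done on a squashed lowercase form.
_SQUASH = re.compile(r"[^a-z0-9]")


def _squash(name: str) -> str:
    return _SQUASH.sub("", str(name).lower())


_CANONICAL_BY_SQUASH = {_squash(c): c for c in ("subject_id", "label") + NUMERIC_FIELDS}
_CANONICAL_BY_SQUASH.update(
    {
        "id": "subject_id",
        "sampleid": "subject_id",
        "group": "label",
        "diagnosis": "label",
        "hgb": "hb",
        "haemoglobin": "hb",
        "hemoglobin": "hb",
    }
)


def canonical_column(name: str) -> Optional[str]:
    """Map a header spelling to its canonical lower-snake name, or None."""
    return _CANONICAL_BY_SQUASH.get(_squash(name))


@dataclass(frozen=True)
class SanityBounds:
    """Configurable physiologic plausibility bounds used for flagging.

    Values outside these bounds are almost certainly transcription or
    analyzer errors rather than pathology; the record is kept but marked.
    """

    mcv: tuple[float, float] = (40.0, 140.0)  # fL
    mch: tuple[float, float] = (10.0, 50.0)  # pg
    rdw_min: float = 0.0  # %

    def violations(self, record: "SubjectRecord") -> tuple[str, ...]:
        bad: list[str] = []
        for name in NUMERIC_FIELDS:
            v = getattr(record, name)
            if v is None:
                continue
            if not math.isfinite(v) or v <= 0.0:
                # rdw may legitimately be 0 by its own bound below
                if not (name == "rdw" and v >= self.rdw_min and math.isfinite(v)):
                    bad.append(name)
                    continue
        if record.mcv is not None and math.isfinite(record.mcv):
            if not (self.mcv[0] <= record.mcv <= self.mcv[1]):
                if "mcv" not in bad:
                    bad.append("mcv")
        if record.mch is not None and math.isfinite(record.mch):
            if not (self.mch[0] <= record.mch <= self.mch[1]):
                if "mch" not in bad:
                    bad.append("mch")
        if record.rdw is not None and math.isfinite(record.rdw):
            if record.rdw < self.rdw_min and "rdw" not in bad:
                bad.append("rdw")
        return tuple(bad)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's red-cell indices and reticulocyte CPD values.

    Units: hb g/dL; rbc 10^6/µL; hct %; mcv fL; mch pg; mchc g/dL;
    rdw % (CV of red-cell volume). CPD channels are dimensionless
    analyzer units except the volume channels (mn_v_ret, mn_v_nret, fL).
    ``flags`` lists fields that violated the sanity bounds at parse time.
    """

    subject_id: str
    hb: Optional[float] = None
    rbc: Optional[float] = None
    hct: Optional[float] = None
    mcv: Optional[float] = None
    mch: Optional[float] = None
    mchc: Optional[float] = None
    rdw: Optional[float] = None
    mn_lmals_ret: Optional[float] = None
    mn_mals_ret: Optional[float] = None
    mn_lmals_nret: Optional[float] = None
    mn_v_ret: Optional[float] = None
    mn_v_nret: Optional[float] = None
    maf: Optional[float] = None
    label: Optional[str] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {sorted(LABELS)}"
            )

    def has(self, *fields: str) -> bool:
        """True if every named field is present, finite and unflagged."""
        for name in fields:
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or name in self.flags:
                return False
        return True


@dataclass
class ParseReport:
    """Bookkeeping from :func:`read_cohort`."""

    n_read: int = 0
    n_flagged: int = 0
    missing_per_column: dict[str, int] = field(default_factory=dict)
    unknown_columns: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class Cohort:
    """Ordered collection of :class:`SubjectRecord` with unique ids."""

    def __init__(
        self,
        records: Iterable[SubjectRecord],
        provenance: str = "",
        parse_report: Optional[ParseReport] = None,
    ) -> None:
        self.records: list[SubjectRecord] = list(records)
        self.provenance = provenance
        self.parse_report = parse_report
        seen: set[str] = set()
        for r in self.records:
            if r.subject_id in seen:
                raise ValueError(f"duplicate subject_id {r.subject_id!r}")
            seen.add(r.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_label(self, label: str) -> list[SubjectRecord]:
        return [r for r in self.records if r.label == label]

    def labelled(self) -> list[SubjectRecord]:
        return [r for r in self.records if r.label is not None]

    @property
    def labels_present(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.label is not None and r.label not in out:
                out.append(r.label)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; one row per subject, canonical column order."""
        cols = ("subject_id",) + NUMERIC_FIELDS + ("label",)
        data = {
            c: [getattr(r, c) for r in self.records] for c in cols
        }
        data["flags"] = [";".join(r.flags) for r in self.records]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        provenance: str = "",
        bounds: Optional[SanityBounds] = None,
    ) -> "Cohort":
        bounds = bounds or SanityBounds()
        records = []
        for _, row in frame.iterrows():
            kwargs: dict = {"subject_id": str(row["subject_id"])}
            for name in NUMERIC_FIELDS:
                if name in frame.columns and pd.notna(row[name]):
                    kwargs[name] = float(row[name])
            if "label" in frame.columns and pd.notna(row["label"]):
                kwargs["label"] = str(row["label"])
            rec = SubjectRecord(**kwargs)
            viol = bounds.violations(rec)
            if viol:
                rec = dataclasses.replace(rec, flags=viol)
            records.append(rec)
        return cls(records, provenance=provenance)


def read_cohort(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: Optional[str] = None,
    bounds: Optional[SanityBounds] = None,
    autogenerate_ids: bool = False,
) -> Cohort:
    """Read a delimited-text cohort (comma or tab, header row required).

    ``column_map`` maps raw header names to canonical field names and
    takes precedence over the built-in alias dictionary. Rows violating
    the sanity bounds are retained but flagged; the attached
    ``parse_report`` counts reads, flags and per-column missingness.

    Raises ``OSError`` for an unreadable file and ``ValueError`` when the
    header carries no subject identifier (unless ``autogenerate_ids``).
    """
    path = Path(path)
    bounds = bounds or SanityBounds()
    if delimiter is None:
        frame = pd.read_csv(
            path, sep=None, engine="python",
            na_values=["NA", ""], keep_default_na=False, dtype={"subject_id": str},
        )
    else:
        frame = pd.read_csv(
            path, sep=delimiter,
            na_values=["NA", ""], keep_default_na=False, dtype=str,
        )

    rename: dict[str, str] = {}
    unknown: list[str] = []
    for col in frame.columns:
        if column_map and col in column_map:
            rename[col] = column_map[col]
            continue
        canon = canonical_column(col)
        if canon is not None:
            rename[col] = canon
        else:
            unknown.append(col)
    frame = frame.rename(columns=rename)

    if "subject_id" not in frame.columns:
        if not autogenerate_ids:
            raise ValueError(
                f"{path}: header has no subject identifier column; "
                "pass autogenerate_ids=True to number rows sequentially"
            )
        frame = frame.copy()
        frame["subject_id"] = [f"S{i + 1:04d}" for i in range(len(frame))]

    # normalise types (needed for the explicit-delimiter dtype=str path)
    for name in NUMERIC_FIELDS:
        if name in frame.columns:
            frame[name] = pd.to_numeric(frame[name], errors="coerce")
    frame["subject_id"] = frame["subject_id"].astype(str)

    cohort = Cohort.from_frame(frame, provenance=str(path), bounds=bounds)

    report = ParseReport(n_read=len(cohort))
    report.n_flagged = sum(1 for r in cohort if r.flags)
    report.unknown_columns = tuple(unknown)
    for name in NUMERIC_FIELDS:
        if name in frame.columns:
            report.missing_per_column[name] = int(frame[name].isna().sum())
        else:
            report.missing_per_column[name] = len(frame)
    cohort.parse_report = report
    return cohort


def _config_digest(metadata: Mapping) -> str:
    blob = json.dumps(metadata, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    table: pd.DataFrame | "Cohort",
    path: str | Path,
    metadata: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> Path:
    """Write a result table as delimited text plus a JSON metadata sidecar.

    Floats are written with 17 significant digits so a read→write→read
    round-trip preserves every value bit-for-bit. The sidecar (same stem,
    ``.meta.json``) records package version, seed and a config digest.
    """
    from . import __version__

    path = Path(path)
    if isinstance(table, Cohort):
        frame = table.to_frame()
    else:
        frame = table
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")

    meta = dict(metadata or {})
    meta.setdefault("version", __version__)
    meta.setdefault("seed", seed)
    meta["config_digest"] = _config_digest(meta)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    return path
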