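"""Authentic-standard spectral library: data model, I/O and validation.

The library is the "database" of the database-aided identification
workflow: one record per authentic standard, carrying its retention time,
singly charged ion formula, cached theoretical m/z, diagnostic and
non-diagnostic MS/MS fragments, and the formula herbs the compound can
originate from.  A bundled fixture transcribes the 52-compound reference
table of a 19-herb granule formula; it is loaded with
:func:`load_default_library`.

Records flagged ``anomalous`` carry a short reason string: the bundled
fixture flags rows whose printed m/z values are internally inconsistent
(one row's observed m/z, and two rows whose printed theoretical values
follow the electron-corrected rather than the plain formula-mass
convention).  Validation tolerates flagged rows and reports them.
"""

from __future__ import annotations

import csv
import io
import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .masscalc import (
    IonSpecies,
    FormulaError,
    monoisotopic_mz,
    ppm_error,
    round_half_up,
)

__all__ = [
    "HERB_ALIASES",
    "HERB_VOCABULARY",
    "Library",
    "LibraryValidationReport",
    "StandardRecord",
    "load_default_library",
    "load_library",
    "query_precursor",
    "save_library",
    "validate_library",
]

#: The 19 constituent herbs of the granule formula, pinyin names.
HERB_VOCABULARY: Tuple[str, ...] = (
    "Cangzhu", "Shanzha", "Chaihu", "Zhishi", "Qianghuo", "Maiya",
    "Fangfeng", "Gancao", "Baizhi", "Jiegeng", "Chuanxiong", "Zisuye",
    "Guanghuoxiang", "Houpo", "Qianhu", "Liushenqu", "Lianqiao",
    "Chenpi", "Hongcha",
)

#: Alternative spellings found in source tables, mapped to the canonical
#: vocabulary.  "Zhisuzi" is the printed variant of Zisuye (Perillae folium).
HERB_ALIASES: Dict[str, str] = {"Zhisuzi": "Zisuye"}

#: Cached theoretical m/z must recompute from the ion formula within this
#: many Da, except on records flagged anomalous.
_RECOMPUTE_TOL_DA = 5e-5

_SCHEMA = (
    "id", "name", "rt_min", "ion_formula", "polarity", "theoretical_mz",
    "diagnostic_fragments", "other_fragments", "source_herbs", "is_marker",
    "anomalous",
)


def canonical_herb(name: str) -> str:
    """Map a herb name (or known alias, any capitalisation) to the vocabulary."""
    name = name.strip().capitalize()
    return HERB_ALIASES.get(name, name)


@dataclass
class StandardRecord:
    """One authentic standard of the library."""

    id: str
    name: str
    rt_min: float
    ion: IonSpecies
    theoretical_mz: float  # cached, 4 dp, as the reference table prints it
    diagnostic_fragments: List[float]
    other_fragments: List[float] = field(default_factory=list)
    source_herbs: frozenset = frozenset()
    is_marker: bool = False
    anomalous: str = ""  # empty, or the reason the printed row is inconsistent

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated record invariant."""
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.rt_min <= 0:
            raise ValueError(f"{self.id}: rt_min must be positive")
        if not self.diagnostic_fragments:
            raise ValueError(f"{self.id}: diagnostic fragment list is empty")
        for mz in list(self.diagnostic_fragments) + list(self.other_fragments):
            if mz >= self.theoretical_mz + 1.0:
                raise ValueError(
                    f"{self.id}: fragment m/z {mz} above precursor {self.theoretical_mz}"
                )
        unknown = {h for h in self.source_herbs if h not in HERB_VOCABULARY}
        if unknown:
            raise ValueError(f"{self.id}: source herbs outside vocabulary: {sorted(unknown)}")
        if not self.anomalous:
            recomputed = monoisotopic_mz(self.ion)
            if abs(recomputed - self.theoretical_mz) > _RECOMPUTE_TOL_DA:
                raise ValueError(
                    f"{self.id}: theoretical_mz {self.theoretical_mz} does not recompute "
                    f"from {self.ion.formula} (got {recomputed:.4f})"
                )

    @property
    def fragments(self) -> List[float]:
        return list(self.diagnostic_fragments) + list(self.other_fragments)


class Library:
    """Validated collection of standards with a precursor-m/z lookup index."""

    def __init__(self, records: Sequence[StandardRecord]):
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")
        self.records: List[StandardRecord] = list(records)
        self._by_id = {r.id: r for r in self.records}
        # per-polarity index sorted by theoretical m/z for window queries
        self._index: Dict[str, List[Tuple[float, StandardRecord]]] = {}
        for pol in ("negative", "positive"):
            entries = [(r.theoretical_mz, r) for r in self.records if r.ion.polarity == pol]
            entries.sort(key=lambda e: (e[0], e[1].id))
            self._index[pol] = entries

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> StandardRecord:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def markers(self) -> List[StandardRecord]:
        return [r for r in self.records if r.is_marker]


def query_precursor(lib: Library, mz: float, polarity: str, tol_ppm: float) -> List[StandardRecord]:
    """Records of the given polarity whose theoretical m/z is within ``tol_ppm``.

    Sorted by ascending ppm error (ties by id).  An empty list is a valid
    result.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    entries = lib._index.get(polarity, [])
    keys = [e[0] for e in entries]
    # tol is relative to each record's theoretical mass; bound the window
    # with the query mass and a small safety factor before the exact test.
    half = mz * tol_ppm / 1e6 * (1 + 2 * tol_ppm / 1e6) + 1e-9
    lo = bisect_left(keys, mz - half)
    hi = bisect_right(keys, mz + half)
    hits = [
        (ppm_error(mz, rec.theoretical_mz), rec)
        for _, rec in entries[lo:hi]
        if ppm_error(mz, rec.theoretical_mz) <= tol_ppm
    ]
    hits.sort(key=lambda h: (h[0], h[1].id))
    return [rec for _, rec in hits]


# ---------------------------------------------------------------------------
# I/O


def _parse_float_list(text: str) -> List[float]:
    return [float(tok) for tok in text.split(";") if tok.strip()]


def _record_from_row(row: Dict[str, str], where: str) -> StandardRecord:
    try:
        ion = IonSpecies.from_string(row["ion_formula"], row["polarity"].strip())
        rec = StandardRecord(
            id=row["id"].strip(),
            name=row["name"].strip(),
            rt_min=float(row["rt_min"]),
            ion=ion,
            theoretical_mz=float(row["theoretical_mz"]),
            diagnostic_fragments=_parse_float_list(row["diagnostic_fragments"]),
            other_fragments=_parse_float_list(row.get("other_fragments", "")),
            source_herbs=frozenset(
                canonical_herb(h) for h in row["source_herbs"].split(";") if h.strip()
            ),
            is_marker=row.get("is_marker", "false").strip().lower() in ("true", "1", "yes"),
            anomalous=row.get("anomalous", "").strip(),
        )
        rec.validate()
        return rec
    except (KeyError, ValueError, FormulaError) as exc:
        key = exc.args[0] if isinstance(exc, KeyError) else exc
        raise ValueError(f"{where}: {key}") from exc


def load_library(path) -> Library:
    """Load a library from CSV or JSON (chosen by file extension).

    Rows failing record invariants are rejected with row-numbered messages.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        rows = payload["records"] if isinstance(payload, dict) else payload
        records = [
            _record_from_row({k: str(v) if not isinstance(v, list) else ";".join(map(str, v))
                              for k, v in row.items()}, f"record {i + 1}")
            for i, row in enumerate(rows)
        ]
        return Library(records)
    return _library_from_csv_text(path.read_text(), str(path))


def _library_from_csv_text(text: str, origin: str) -> Library:
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise ValueError(f"{origin}: empty file")
    missing = [c for c in _SCHEMA if c not in reader.fieldnames and c not in ("other_fragments", "is_marker", "anomalous")]
    if missing:
        raise ValueError(f"{origin}: missing columns {missing}")
    records = [
        _record_from_row(row, f"{origin} row {i + 2}")  # +2: header is line 1
        for i, row in enumerate(reader)
    ]
    return Library(records)


def save_library(lib: Library, path) -> None:
    """Write a library as CSV or JSON; round-trips field for field."""
    path = Path(path)
    rows = []
    for r in lib:
        rows.append({
            "id": r.id,
            "name": r.name,
            "rt_min": f"{r.rt_min:.2f}",
            "ion_formula": _formula_str(r),
            "polarity": r.ion.polarity,
            "theoretical_mz": f"{r.theoretical_mz:.4f}",
            "diagnostic_fragments": ";".join(f"{x:.4f}" for x in r.diagnostic_fragments),
            "other_fragments": ";".join(f"{x:.4f}" for x in r.other_fragments),
            "source_herbs": ";".join(sorted(r.source_herbs)),
            "is_marker": str(r.is_marker).lower(),
            "anomalous": r.anomalous,
        })
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"records": rows}, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_SCHEMA)
        writer.writeheader()
        writer.writerows(rows)


def _formula_str(rec: StandardRecord) -> str:
    from .masscalc import formula_to_string

    return formula_to_string(rec.ion.formula)


def load_default_library() -> Library:
    """The bundled 52-compound authentic-standard fixture."""
    text = resources.files("qmarker.data").joinpath("table3_library.csv").read_text()
    return _library_from_csv_text(text, "table3_library.csv")


# ---------------------------------------------------------------------------
# Validation report


@dataclass
class RecordCheck:
    record_id: str
    recomputed_mz: float  # 4 dp
    cached_mz: float
    exact_match: bool
    anomalous: str


@dataclass
class LibraryValidationReport:
    checks: List[RecordCheck]

    @property
    def n_exact(self) -> int:
        return sum(c.exact_match for c in self.checks)

    @property
    def flagged(self) -> List[RecordCheck]:
        return [c for c in self.checks if c.anomalous]

    @property
    def unexplained_mismatches(self) -> List[RecordCheck]:
        """Cached/recomputed disagreements on rows not flagged anomalous."""
        return [c for c in self.checks if not c.exact_match and not c.anomalous]

    @property
    def clean(self) -> bool:
        return not self.unexplained_mismatches


def validate_library(lib: Library) -> LibraryValidationReport:
    """Recompute every record's theoretical m/z and compare at 4 dp.

    Flagged (anomalous) records are reported but do not make the report
    unclean; an unflagged 4-dp mismatch does.
    """
    checks = []
    for rec in lib:
        recomputed = round_half_up(monoisotopic_mz(rec.ion), 4)
        checks.append(RecordCheck(
            record_id=rec.id,
            recomputed_mz=recomputed,
            cached_mz=rec.theoretical_mz,
            exact_match=recomputed == round_half_up(rec.theoretical_mz, 4),
            anomalous=rec.anomalous,
        ))
    return LibraryValidationReport(checks)
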