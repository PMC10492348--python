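"""Q-marker panel logic: XIC extraction, presence calls, herb verdicts.

Counterfeit recognition works at the chromatogram level: for each quality
marker the exact ion m/z is derived from its neutral formula (deprotonated
in negative mode, protonated in positive mode), an extracted-ion
chromatogram (XIC) is pulled from the run within a narrow ppm window, and
the marker is called present iff the trace apex reaches a minimum
intensity.  A herb is suspect-absent iff every marker mapping to it is
absent; herbs no marker covers are simply not covered.  The panel's reach
over the formula is summarised by two coverage rates:

* TCR (total characterizing rate): herbs covered by any marker / total
  herbs, as a percentage.
* SCR (specifically characterizing rate): herbs having at least one marker
  whose source set is exactly that single herb / total herbs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .library import HERB_VOCABULARY, canonical_herb
from .masscalc import (
    FormulaError,
    IonSpecies,
    monoisotopic_mz,
    parse_formula,
    round_half_up,
)

__all__ = [
    "AuthenticationReport",
    "ChromatogramRun",
    "CoverageMetrics",
    "HerbVerdict",
    "MarkerEntry",
    "MarkerPanel",
    "MarkerPresence",
    "Scan",
    "XicTrace",
    "authenticate_run",
    "coverage_metrics",
    "extract_xic",
    "load_default_panel",
    "load_panel",
    "marker_ion_mz",
    "marker_present",
    "read_run_csv",
    "write_run_csv",
    "write_verdict_tsv",
]

#: Default XIC extraction window, ppm.  Wider than the identification
#: precursor tolerance: XIC authentication is a screening step.
DEFAULT_XIC_TOL_PPM = 10.0

#: Default presence threshold, counts.  Genuine marker apexes sit around
#: 1e5-1e6; counterfeit traces show no peak at all, so the gate only has
#: to sit well above baseline.
DEFAULT_MIN_INTENSITY = 1e4


@dataclass(frozen=True)
class MarkerEntry:
    """One quality marker: compound, neutral formula, polarity, source herbs."""

    id: str
    neutral_formula: str
    polarity: str
    herbs: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValueError(f"marker {self.id}: must map to at least one herb")
        unknown = {h for h in self.herbs if h not in HERB_VOCABULARY}
        if unknown:
            raise ValueError(f"marker {self.id}: unknown herbs {sorted(unknown)}")


@dataclass(frozen=True)
class MarkerPanel:
    """The marker-to-herb map driving authentication and coverage metrics."""

    entries: Tuple[MarkerEntry, ...]
    total_herbs: int = len(HERB_VOCABULARY)

    def __post_init__(self) -> None:
        if self.total_herbs <= 0:
            raise ValueError("total_herbs must be positive")

    @property
    def covered_herbs(self) -> FrozenSet[str]:
        out: set = set()
        for e in self.entries:
            out |= e.herbs
        return frozenset(out)

    @property
    def specific_herbs(self) -> FrozenSet[str]:
        """Herbs pinned down by at least one single-herb marker."""
        return frozenset(
            next(iter(e.herbs)) for e in self.entries if len(e.herbs) == 1
        )


def load_panel(path) -> MarkerPanel:
    """Load a marker panel from JSON."""
    payload = json.loads(Path(path).read_text())
    return _panel_from_payload(payload)


def _panel_from_payload(payload: dict) -> MarkerPanel:
    entries = tuple(
        MarkerEntry(
            id=m["id"],
            neutral_formula=m["neutral_formula"],
            polarity=m["polarity"],
            herbs=frozenset(canonical_herb(h) for h in m["herbs"]),
        )
        for m in payload["markers"]
    )
    return MarkerPanel(entries=entries, total_herbs=int(payload.get("total_herbs", len(HERB_VOCABULARY))))


def load_default_panel() -> MarkerPanel:
    """The packaged six-marker panel covering 7 of the 19 formula herbs."""
    text = resources.files("qmarker.data").joinpath("default_panel.json").read_text()
    return _panel_from_payload(json.loads(text))


def marker_ion_mz(entry: MarkerEntry) -> float:
    """Exact target m/z for a marker's XIC, derived from the neutral formula.

    Negative mode extracts [M-H]- (neutral minus one H), positive mode
    [M+H]+ (plus one H); the plain formula-mass convention is used, always
    from the exact formula rather than a nominal integer mass.
    """
    counts = dict(parse_formula(entry.neutral_formula))
    if entry.polarity == "negative":
        if counts.get("H", 0) < 1:
            raise FormulaError(
                f"marker {entry.id}: cannot deprotonate {entry.neutral_formula}"
            )
        counts["H"] -= 1
        if counts["H"] == 0:
            del counts["H"]
    else:
        counts["H"] = counts.get("H", 0) + 1
    return monoisotopic_mz(IonSpecies(counts, entry.polarity))


# ---------------------------------------------------------------------------
# Chromatograms and XIC


@dataclass
class Scan:
    rt_min: float
    polarity: str
    peaks: List[Tuple[float, float]]  # (m/z, intensity) centroids


@dataclass
class ChromatogramRun:
    """A centroided run: scans in strictly increasing RT order per polarity."""

    scans: List[Scan]

    def __post_init__(self) -> None:
        last: Dict[str, float] = {}
        for s in self.scans:
            if s.rt_min <= last.get(s.polarity, -np.inf):
                raise ValueError("scan RTs must be strictly increasing per polarity")
            last[s.polarity] = s.rt_min
            for _, inten in s.peaks:
                if inten < 0:
                    raise ValueError("scan intensities must be non-negative")

    def total_intensity(self) -> float:
        return float(sum(i for s in self.scans for _, i in s.peaks))


@dataclass
class XicTrace:
    """Extracted-ion chromatogram: per-scan summed intensity near a target."""

    target_mz: float
    tol_ppm: float
    points: List[Tuple[float, float]]  # (rt_min, summed intensity)

    @property
    def apex(self) -> Tuple[Optional[float], float]:
        """(apex RT, max intensity); (None, 0.0) for an empty/zero trace."""
        if not self.points:
            return None, 0.0
        rt, inten = max(self.points, key=lambda p: (p[1], -p[0]))
        return (rt if inten > 0 else None), inten


def extract_xic(
    run: ChromatogramRun,
    target_mz: float,
    tol_ppm: float = DEFAULT_XIC_TOL_PPM,
    polarity: Optional[str] = None,
) -> XicTrace:
    """Sum, per scan, the centroid intensities within +/-tol of the target.

    Scans of the other polarity are skipped when ``polarity`` is given.
    Scans with no centroid in the window contribute an explicit zero.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    half = target_mz * tol_ppm / 1e6
    points = []
    for scan in run.scans:
        if polarity is not None and scan.polarity != polarity:
            continue
        total = sum(i for mz, i in scan.peaks if abs(mz - target_mz) <= half)
        points.append((scan.rt_min, float(total)))
    return XicTrace(target_mz=target_mz, tol_ppm=tol_ppm, points=points)


@dataclass
class MarkerPresence:
    marker_id: str
    target_mz: float
    present: bool
    apex_intensity: float
    apex_rt_min: Optional[float]


def marker_present(trace: XicTrace, min_intensity: float = DEFAULT_MIN_INTENSITY):
    """Presence call on a trace: apex >= threshold (inclusive boundary).

    Returns ``(present, apex_intensity, apex_rt)``.
    """
    if min_intensity <= 0:
        raise ValueError("min_intensity must be positive")
    rt, inten = trace.apex
    return inten >= min_intensity, inten, rt


# ---------------------------------------------------------------------------
# Verdicts


@dataclass
class HerbVerdict:
    herb: str
    status: str  # "verified" | "suspect-absent" | "not-covered"
    supporting_markers: List[str]


@dataclass
class AuthenticationReport:
    markers: List[MarkerPresence]
    herbs: List[HerbVerdict]

    @property
    def suspect_herbs(self) -> FrozenSet[str]:
        return frozenset(h.herb for h in self.herbs if h.status == "suspect-absent")

    @property
    def verified_herbs(self) -> FrozenSet[str]:
        return frozenset(h.herb for h in self.herbs if h.status == "verified")


def authenticate_run(
    run: ChromatogramRun,
    panel: Optional[MarkerPanel] = None,
    tol_ppm: float = DEFAULT_XIC_TOL_PPM,
    min_intensity: float = DEFAULT_MIN_INTENSITY,
) -> AuthenticationReport:
    """Per-marker presence calls and per-herb verdicts for one run.

    A herb is ``suspect-absent`` iff every panel marker mapping to it is
    absent; it is ``verified`` if any such marker is present; herbs outside
    the panel's reach are ``not-covered``.
    """
    panel = panel or load_default_panel()
    presences = []
    present_by_marker: Dict[str, bool] = {}
    for entry in panel.entries:
        target = marker_ion_mz(entry)
        trace = extract_xic(run, target, tol_ppm, polarity=entry.polarity)
        ok, inten, rt = marker_present(trace, min_intensity)
        present_by_marker[entry.id] = ok
        presences.append(MarkerPresence(
            marker_id=entry.id, target_mz=target, present=ok,
            apex_intensity=inten, apex_rt_min=rt,
        ))
    herbs = []
    for herb in HERB_VOCABULARY:
        covering = [e.id for e in panel.entries if herb in e.herbs]
        if not covering:
            herbs.append(HerbVerdict(herb, "not-covered", []))
            continue
        supporting = [m for m in covering if present_by_marker[m]]
        status = "verified" if supporting else "suspect-absent"
        herbs.append(HerbVerdict(herb, status, supporting or covering))
    return AuthenticationReport(markers=presences, herbs=herbs)


# ---------------------------------------------------------------------------
# Coverage metrics


@dataclass
class CoverageMetrics:
    tcr: float  # percent, 1 dp
    scr: float  # percent, 1 dp
    covered_herbs: FrozenSet[str]
    specific_herbs: FrozenSet[str]


def coverage_metrics(panel: MarkerPanel) -> CoverageMetrics:
    """TCR and SCR of a panel, in percent rounded half-up to one decimal."""
    covered = panel.covered_herbs
    specific = panel.specific_herbs
    tcr = round_half_up(100.0 * len(covered) / panel.total_herbs, 1)
    scr = round_half_up(100.0 * len(specific) / panel.total_herbs, 1)
    return CoverageMetrics(tcr=tcr, scr=scr, covered_herbs=covered,
                           specific_herbs=specific)


# ---------------------------------------------------------------------------
# Run and report I/O


def write_run_csv(run: ChromatogramRun, path) -> None:
    """Write a run as (scan_rt_min, polarity, mz, intensity) triples."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scan_rt_min", "polarity", "mz", "intensity"])
        for s in run.scans:
            if not s.peaks:
                writer.writerow([f"{s.rt_min:.4f}", s.polarity, "", ""])
            for mz, inten in s.peaks:
                writer.writerow([f"{s.rt_min:.4f}", s.polarity, f"{mz:.5f}", f"{inten:.1f}"])


def read_run_csv(path) -> ChromatogramRun:
    """Read a run written by :func:`write_run_csv`."""
    scans: Dict[Tuple[str, float], Scan] = {}
    order: List[Tuple[str, float]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["polarity"], float(row["scan_rt_min"]))
            if key not in scans:
                scans[key] = Scan(rt_min=key[1], polarity=key[0], peaks=[])
                order.append(key)
            if row["mz"]:
                scans[key].peaks.append((float(row["mz"]), float(row["intensity"])))
    return ChromatogramRun(scans=[scans[k] for k in order])


def write_verdict_tsv(report: AuthenticationReport, path) -> None:
    presence = {m.marker_id: m for m in report.markers}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["herb", "status", "markers", "apex_intensity", "apex_rt_min"])
        for h in report.herbs:
            apexes = [presence[m] for m in h.supporting_markers if m in presence]
            best = max(apexes, key=lambda p: p.apex_intensity, default=None)
            writer.writerow([
                h.herb, h.status, ";".join(h.supporting_markers),
                f"{best.apex_intensity:.1f}" if best else "",
                f"{best.apex_rt_min:.2f}" if best and best.apex_rt_min is not None else "",
            ])
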