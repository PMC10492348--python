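"""Multi-criteria matching of sample features against the standard library.

A feature (RT, precursor m/z, centroided MS/MS peak list) is identified by
the combination of four comparisons against each library candidate drawn
from a precursor-m/z window: precursor ppm error, retention-time
difference, coverage of the candidate's diagnostic fragments, and the
cosine similarity of the full MS/MS profiles.  A candidate is accepted
only when all four criteria pass; candidates are ranked by a documented
total order so results are reproducible.  Retention time is the
discriminator between co-formulaic isomers whose spectra are similar;
where even the RTs coincide, the diagnostic-fragment coverage carries the
discrimination.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mgf as _mgf

from .library import Library, StandardRecord, query_precursor
from .masscalc import ppm_error

__all__ = [
    "DEFAULT_MATCH_PARAMS",
    "IdentificationResult",
    "MatchParams",
    "MatchResult",
    "SampleFeature",
    "cosine_similarity",
    "diagnostic_coverage",
    "identify_run",
    "match_feature",
    "read_features",
    "write_features",
    "write_identification_tsv",
]


@dataclass
class SampleFeature:
    """One observed feature: precursor plus its centroided MS/MS spectrum."""

    feature_id: str
    rt_min: float
    precursor_mz: float
    polarity: str
    peaks: List[Tuple[float, float]] = field(default_factory=list)  # (m/z, intensity)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.feature_id}: precursor m/z must be positive")
        for mz, inten in self.peaks:
            if not (np.isfinite(inten) and inten >= 0):
                raise ValueError(f"{self.feature_id}: bad peak intensity {inten}")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])


@dataclass(frozen=True)
class MatchParams:
    """Acceptance thresholds of the four-way comparison.

    Defaults: 5 ppm precursor tolerance (published accepted matches sit
    below 5 ppm), +/-0.005 Da fragment tolerance (orbitrap MS/MS mass
    accuracy), +/-0.20 min RT window (twice the spacing of the closest
    resolved isomer pair apart from the chalcone pair), >=60% diagnostic
    coverage and >=0.2 spectral cosine.  The cosine gate is deliberately
    permissive: against unit-intensity reference spectra the absolute
    square-root-intensity cosine is deflated, and true matches of sparse
    (3-6 fragment) spectra tail down toward ~0.25 while profile-level
    mismatches score near zero.  The gate therefore only rejects
    profile-level garbage; discrimination is carried by the coverage and
    RT gates and by the candidate ranking, where cosine enters at full
    resolution.
    """

    precursor_tol_ppm: float = 5.0
    fragment_tol_da: float = 0.005
    rt_tol_min: float = 0.20
    min_diagnostic_coverage: float = 0.6
    min_cosine: float = 0.2

    def __post_init__(self) -> None:
        for name in ("precursor_tol_ppm", "fragment_tol_da", "rt_tol_min",
                     "min_diagnostic_coverage", "min_cosine"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.min_diagnostic_coverage <= 1 and self.min_cosine <= 1):
            raise ValueError("coverage/cosine thresholds must be <= 1")


DEFAULT_MATCH_PARAMS = MatchParams()


@dataclass
class MatchResult:
    """One scored feature-candidate comparison."""

    feature_id: str
    candidate_id: str
    ppm_err: float
    rt_delta_min: float
    diagnostic_coverage: float
    cosine: float
    accepted: bool
    rank: int = 0


def _greedy_pairs(
    query_mz: Sequence[float], peaks: Sequence[Tuple[float, float]], tol: float
) -> List[Optional[int]]:
    """For each query m/z, the index of its matched peak (or None).

    Greedy nearest-m/z assignment; each peak is claimed at most once, ties
    broken toward the lower-m/z peak.  Queries are processed in order of
    their best available distance so a closer query wins a contested peak.
    """
    candidates = []  # (distance, query_index, peak_index)
    for qi, q in enumerate(query_mz):
        for pi, (mz, _) in enumerate(peaks):
            d = abs(mz - q)
            if d <= tol:
                candidates.append((d, peaks[pi][0], qi, pi))
    candidates.sort()
    assigned: List[Optional[int]] = [None] * len(query_mz)
    used_peaks = set()
    for _, _, qi, pi in candidates:
        if assigned[qi] is None and pi not in used_peaks:
            assigned[qi] = pi
            used_peaks.add(pi)
    return assigned


def diagnostic_coverage(feature: SampleFeature, std: StandardRecord, tol_da: float) -> float:
    """Fraction of the standard's diagnostic fragments found in the feature.

    Each library fragment may claim at most one feature peak within
    +/-``tol_da`` (greedy nearest, ties to lower m/z).
    """
    if not std.diagnostic_fragments:
        raise ValueError(f"{std.id}: no diagnostic fragments")
    if not feature.peaks:
        return 0.0
    assigned = _greedy_pairs(std.diagnostic_fragments, feature.peaks, tol_da)
    return sum(a is not None for a in assigned) / len(std.diagnostic_fragments)


def cosine_similarity(
    peaks_a: Sequence[Tuple[float, float]],
    peaks_b: Sequence[Tuple[float, float]],
    tol_da: float,
) -> float:
    """Greedy-paired normalized dot product of square-root intensities.

    Library spectra without measured intensities are represented with unit
    intensities.  The score is 0 when either list is empty, 1 for identical
    lists, and ignores nothing: unmatched peaks on either side count in the
    norms.
    """
    if tol_da <= 0:
        raise ValueError("tolerance must be positive")
    if not peaks_a or not peaks_b:
        return 0.0
    a_sqrt = np.sqrt([i for _, i in peaks_a])
    b_sqrt = np.sqrt([i for _, i in peaks_b])
    na, nb = np.linalg.norm(a_sqrt), np.linalg.norm(b_sqrt)
    if na == 0 or nb == 0:
        return 0.0
    assigned = _greedy_pairs([mz for mz, _ in peaks_a], peaks_b, tol_da)
    dot = sum(
        a_sqrt[qi] * b_sqrt[pi] for qi, pi in enumerate(assigned) if pi is not None
    )
    return float(min(1.0, dot / (na * nb)))


def _unit_spectrum(std: StandardRecord) -> List[Tuple[float, float]]:
    return [(mz, 1.0) for mz in std.fragments]


def match_feature(
    feature: SampleFeature, lib: Library, params: MatchParams = DEFAULT_MATCH_PARAMS
) -> List[MatchResult]:
    """Score a feature against all precursor-window candidates.

    Acceptance requires all four criteria; results are ranked by
    (coverage desc, cosine desc, |dRT| asc, ppm asc, candidate id) -- a
    total order, so identical inputs always give identical output.
    Cosine outranks |dRT| so that co-formulaic isomers whose RTs nearly
    coincide are discriminated by their MS/MS profiles: a feature's own
    record matches a superset of its peaks, giving it a strictly higher
    cosine than the rival isomer whenever a distinguishing fragment exists.
    """
    results = []
    for cand in query_precursor(lib, feature.precursor_mz, feature.polarity,
                                params.precursor_tol_ppm):
        ppm = ppm_error(feature.precursor_mz, cand.theoretical_mz)
        drt = abs(feature.rt_min - cand.rt_min)
        cov = diagnostic_coverage(feature, cand, params.fragment_tol_da)
        cos = cosine_similarity(_unit_spectrum(cand), feature.peaks, params.fragment_tol_da)
        accepted = (
            ppm <= params.precursor_tol_ppm
            and drt <= params.rt_tol_min
            and cov >= params.min_diagnostic_coverage
            and cos >= params.min_cosine
        )
        results.append(MatchResult(
            feature_id=feature.feature_id,
            candidate_id=cand.id,
            ppm_err=ppm,
            rt_delta_min=drt,
            diagnostic_coverage=cov,
            cosine=cos,
            accepted=accepted,
        ))
    results.sort(key=lambda r: (-r.diagnostic_coverage, -r.cosine, r.rt_delta_min,
                                r.ppm_err, r.candidate_id))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


@dataclass
class IdentificationResult:
    """Outcome of identifying a whole run."""

    assignments: List[MatchResult]  # accepted, one per (feature, record) pair
    unidentified: List[str]  # feature ids with no accepted assignment

    @property
    def identified_ids(self) -> List[str]:
        return [m.candidate_id for m in self.assignments]

    def __len__(self) -> int:
        return len(self.assignments)


def identify_run(
    features: Sequence[SampleFeature],
    lib: Library,
    params: MatchParams = DEFAULT_MATCH_PARAMS,
) -> IdentificationResult:
    """One-to-one assignment of library records to features.

    All accepted candidate matches across the run compete; assignment is
    greedy in the ranking order (coverage desc, cosine desc, |dRT| asc,
    ppm asc, ids), and each library record and each feature is claimed at
    most once.  Deterministic given identical inputs.
    """
    pool: List[MatchResult] = []
    for feat in features:
        pool.extend(m for m in match_feature(feat, lib, params) if m.accepted)
    pool.sort(key=lambda m: (-m.diagnostic_coverage, -m.cosine, m.rt_delta_min,
                             m.ppm_err, m.candidate_id, m.feature_id))
    taken_features, taken_records = set(), set()
    assignments = []
    for m in pool:
        if m.feature_id in taken_features or m.candidate_id in taken_records:
            continue
        taken_features.add(m.feature_id)
        taken_records.add(m.candidate_id)
        assignments.append(m)
    assignments.sort(key=lambda m: (lib[m.candidate_id].rt_min, m.candidate_id))
    unidentified = [f.feature_id for f in features if f.feature_id not in taken_features]
    return IdentificationResult(assignments=assignments, unidentified=unidentified)


# ---------------------------------------------------------------------------
# Feature-list I/O: CSV of precursors + MGF of MS/MS spectra


def write_features(features: Sequence[SampleFeature], csv_path, mgf_path) -> None:
    """Write a feature list as precursor CSV plus MGF spectra keyed by id."""
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["feature_id", "rt_min", "precursor_mz", "polarity"])
        for f in features:
            writer.writerow([f.feature_id, f"{f.rt_min:.4f}", f"{f.precursor_mz:.5f}",
                             f.polarity])
    spectra = []
    for f in features:
        mzs = np.array([mz for mz, _ in f.peaks])
        intens = np.array([i for _, i in f.peaks])
        spectra.append({
            "m/z array": mzs,
            "intensity array": intens,
            "params": {
                "title": f.feature_id,
                "pepmass": f.precursor_mz,
                "rtinseconds": f.rt_min * 60.0,
                "charge": "1-" if f.polarity == "negative" else "1+",
            },
        })
    _mgf.write(spectra, str(mgf_path), file_mode="w")


def read_features(csv_path, mgf_path) -> List[SampleFeature]:
    """Read a feature list written by :func:`write_features`."""
    spectra: Dict[str, List[Tuple[float, float]]] = {}
    with _mgf.MGF(str(mgf_path)) as reader:
        for spec in reader:
            title = spec["params"]["title"]
            spectra[title] = list(zip(spec["m/z array"].tolist(),
                                      spec["intensity array"].tolist()))
    features = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            fid = row["feature_id"]
            features.append(SampleFeature(
                feature_id=fid,
                rt_min=float(row["rt_min"]),
                precursor_mz=float(row["precursor_mz"]),
                polarity=row["polarity"],
                peaks=spectra.get(fid, []),
            ))
    return features


def write_identification_tsv(result: IdentificationResult, lib: Library, path) -> None:
    """Identification report mirroring the reference-table columns plus scores."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow([
            "candidate_id", "name", "rt_min", "ion_formula", "polarity",
            "theoretical_mz", "feature_id", "ppm_err", "rt_delta_min",
            "diagnostic_coverage", "cosine", "source_herbs",
        ])
        from .masscalc import formula_to_string

        for m in result.assignments:
            rec = lib[m.candidate_id]
            writer.writerow([
                rec.id, rec.name, f"{rec.rt_min:.2f}",
                formula_to_string(rec.ion.formula), rec.ion.polarity,
                f"{rec.theoretical_mz:.4f}", m.feature_id, f"{m.ppm_err:.4f}",
                f"{m.rt_delta_min:.3f}", f"{m.diagnostic_coverage:.3f}",
                f"{m.cosine:.3f}", ";".join(sorted(rec.source_herbs)),
            ])
        for fid in result.unidentified:
            writer.writerow(["-", "unidentified", "", "", "", "", fid, "", "", "", "", ""])
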