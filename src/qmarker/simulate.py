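"""Seeded generator of synthetic granule runs and herb-removal counterfeits.

The generator emulates what a centroided LC-MS/MS acquisition of the
19-herb granule looks like downstream of peak picking: one feature per
library compound with ppm-scale mass noise on precursor and fragments, RT
jitter, log-normal intensities, stochastic loss of non-diagnostic
fragments, spurious decoy peaks inside spectra, and whole decoy features
whose precursors sit far from every library record.  A chromatogram is
built by summing Gaussian elution peaks on a regular scan grid so the
XIC-based authentication stage can be exercised end to end.

Counterfeits are constructed by herb removal: a compound disappears from
the run iff *every* herb that can supply it was replaced.  The bundled
six counterfeit specifications (CWG 1-6) each replace one target herb
(or the Chenpi+Zhishi pair) with inert filler.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .authenticate import ChromatogramRun, Scan, write_run_csv
from .identify import SampleFeature, write_features
from .library import HERB_VOCABULARY, Library, StandardRecord, canonical_herb

__all__ = [
    "CWG_SPECS",
    "CounterfeitSpec",
    "SimParams",
    "SimulatedRun",
    "simulate_counterfeit",
    "simulate_feature",
    "simulate_run",
]


@dataclass(frozen=True)
class SimParams:
    """Noise model of the synthetic acquisition.

    Magnitudes are anchored to what the reference acquisition shows:
    accepted precursor errors all below 5 ppm (so ppm noise sd 1.5 keeps
    >99.9% of simulated errors inside that window), RT values printed to
    0.01 min with isomer pairs 0.2-0.3 min apart (jitter sd 0.03 min),
    and genuine marker apexes in the 1e5-1e6 range (log10 mean 5.5,
    sd 0.5).  Decoy spectrum peaks are an order of magnitude weaker than
    true fragments, as instrument noise peaks are.
    """

    seed: int = 0
    ppm_noise_sd: float = 1.5
    rt_jitter_sd_min: float = 0.03
    fragment_keep_prob: float = 0.8
    diagnostic_keep_prob: float = 1.0
    decoy_features_per_run: int = 10
    intensity_log10_mean: float = 5.5
    intensity_log10_sd: float = 0.5
    decoy_intensity_log10_mean: float = 4.5
    max_decoy_peaks: int = 5
    decoy_min_ppm: float = 50.0
    chrom_sigma_min: float = 0.05
    chrom_rt_start: float = 0.0
    chrom_rt_end: float = 17.0
    chrom_step_min: float = 0.01

    def __post_init__(self) -> None:
        for p in (self.fragment_keep_prob, self.diagnostic_keep_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("keep probabilities must lie in [0, 1]")
        for s in (self.ppm_noise_sd, self.rt_jitter_sd_min, self.intensity_log10_sd):
            if s < 0:
                raise ValueError("noise standard deviations must be >= 0")
        if self.decoy_features_per_run < 0 or self.max_decoy_peaks < 0:
            raise ValueError("decoy counts must be >= 0")


@dataclass(frozen=True)
class CounterfeitSpec:
    """A counterfeit recipe: which herbs were replaced by inert filler."""

    name: str
    removed_herbs: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.removed_herbs:
            raise ValueError(f"{self.name}: removed herb set must be non-empty")
        unknown = {h for h in self.removed_herbs if h not in HERB_VOCABULARY}
        if unknown:
            raise ValueError(f"{self.name}: unknown herbs {sorted(unknown)}")


def _cwg(name: str, *herbs: str) -> CounterfeitSpec:
    return CounterfeitSpec(name, frozenset(canonical_herb(h) for h in herbs))


#: The six bundled counterfeit recipes (herb replaced by wood powder).
CWG_SPECS: Tuple[CounterfeitSpec, ...] = (
    _cwg("CWG1", "Zhishi", "Chenpi"),
    _cwg("CWG2", "Chaihu"),
    _cwg("CWG3", "Hongcha"),
    _cwg("CWG4", "Chuanxiong"),
    _cwg("CWG5", "Houpo"),
    _cwg("CWG6", "Gancao"),
)


def _lognormal_intensity(rng: np.random.Generator, log10_mean: float, log10_sd: float) -> float:
    return float(10.0 ** rng.normal(log10_mean, log10_sd))


def simulate_feature(
    std: StandardRecord, params: SimParams, rng: np.random.Generator
) -> SampleFeature:
    """One noisy feature emulating a library compound.

    Precursor m/z is perturbed by Normal(0, ppm_noise_sd) ppm and RT by
    Normal(0, rt_jitter_sd); diagnostic fragments are kept with
    ``diagnostic_keep_prob`` and the rest with ``fragment_keep_prob``,
    each with its own ppm-scale mass noise and log-normal intensity; 0-5
    weak decoy peaks are added at random m/z.
    """
    eps = rng.normal(0.0, params.ppm_noise_sd)
    precursor = std.theoretical_mz * (1.0 + eps / 1e6)
    rt = std.rt_min + rng.normal(0.0, params.rt_jitter_sd_min)
    peaks: List[Tuple[float, float]] = []
    for frag_mz, keep_p in (
        [(mz, params.diagnostic_keep_prob) for mz in std.diagnostic_fragments]
        + [(mz, params.fragment_keep_prob) for mz in std.other_fragments]
    ):
        if rng.random() < keep_p:
            noisy = frag_mz * (1.0 + rng.normal(0.0, params.ppm_noise_sd) / 1e6)
            peaks.append((noisy, _lognormal_intensity(
                rng, params.intensity_log10_mean, params.intensity_log10_sd)))
    n_decoys = int(rng.integers(0, params.max_decoy_peaks + 1))
    for _ in range(n_decoys):
        mz = float(rng.uniform(50.0, max(60.0, precursor)))
        peaks.append((mz, _lognormal_intensity(
            rng, params.decoy_intensity_log10_mean, params.intensity_log10_sd)))
    return SampleFeature(
        feature_id=f"F_{std.id}",
        rt_min=float(rt),
        precursor_mz=float(precursor),
        polarity=std.ion.polarity,
        peaks=peaks,
    )


def _decoy_feature(
    idx: int, lib: Library, params: SimParams, rng: np.random.Generator
) -> SampleFeature:
    """A feature whose precursor is guaranteed >= decoy_min_ppm from every record."""
    ref = np.array([r.theoretical_mz for r in lib]) if len(lib) else np.array([300.0])
    while True:
        mz = float(rng.uniform(120.0, 900.0))
        if len(lib) == 0 or np.min(np.abs(ref - mz) / ref) * 1e6 >= params.decoy_min_ppm:
            break
    rt = float(rng.uniform(0.5, params.chrom_rt_end - 0.5))
    n_peaks = int(rng.integers(3, 9))
    peaks = [
        (float(rng.uniform(50.0, mz)), _lognormal_intensity(
            rng, params.decoy_intensity_log10_mean, params.intensity_log10_sd))
        for _ in range(n_peaks)
    ]
    return SampleFeature(
        feature_id=f"DECOY_{idx}",
        rt_min=rt,
        precursor_mz=mz,
        polarity="negative",
        peaks=peaks,
    )


@dataclass
class SimulatedRun:
    """Output bundle of one synthetic acquisition."""

    name: str
    features: List[SampleFeature]
    chromatogram: ChromatogramRun
    apex_intensity: Dict[str, float]  # feature_id -> elution apex
    params: SimParams

    def write(self, outdir) -> Dict[str, str]:
        """Write feature CSV + MGF + chromatogram CSV + manifest; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "features_csv": str(outdir / f"{self.name}_features.csv"),
            "spectra_mgf": str(outdir / f"{self.name}_spectra.mgf"),
            "chromatogram_csv": str(outdir / f"{self.name}_run.csv"),
            "manifest_json": str(outdir / f"{self.name}_manifest.json"),
        }
        write_features(self.features, paths["features_csv"], paths["spectra_mgf"])
        write_run_csv(self.chromatogram, paths["chromatogram_csv"])
        manifest = {
            "name": self.name,
            "n_features": len(self.features),
            "params": dataclasses.asdict(self.params),
            "files": {k: Path(v).name for k, v in paths.items() if k != "manifest_json"},
        }
        Path(paths["manifest_json"]).write_text(json.dumps(manifest, indent=1))
        return paths


def _build_chromatogram(
    features: Sequence[SampleFeature],
    apex: Dict[str, float],
    params: SimParams,
) -> ChromatogramRun:
    """Sum Gaussian elution peaks on a regular RT grid, per polarity.

    Each feature elutes as a Gaussian centred on its RT with width
    ``chrom_sigma_min``; the centroid m/z in every scan is the feature's
    (noisy) precursor m/z.  Contributions beyond 4 sigma are dropped.
    """
    grid = np.arange(params.chrom_rt_start, params.chrom_rt_end + 1e-9,
                     params.chrom_step_min)
    peaks_per_scan: Dict[str, List[List[Tuple[float, float]]]] = {
        "negative": [[] for _ in grid], "positive": [[] for _ in grid],
    }
    sigma = params.chrom_sigma_min
    for f in features:
        a = apex[f.feature_id]
        lo = np.searchsorted(grid, f.rt_min - 4 * sigma)
        hi = np.searchsorted(grid, f.rt_min + 4 * sigma, side="right")
        for i in range(lo, hi):
            inten = a * float(np.exp(-0.5 * ((grid[i] - f.rt_min) / sigma) ** 2))
            peaks_per_scan[f.polarity][i].append((f.precursor_mz, inten))
    scans = []
    for pol in ("negative", "positive"):
        for i, rt in enumerate(grid):
            scans.append(Scan(rt_min=float(rt), polarity=pol,
                              peaks=sorted(peaks_per_scan[pol][i])))
    scans.sort(key=lambda s: (s.rt_min, s.polarity))
    return ChromatogramRun(scans=scans)


def simulate_run(
    lib: Library,
    params: SimParams = SimParams(),
    name: str = "genuine",
    include: Optional[Sequence[str]] = None,
) -> SimulatedRun:
    """A full synthetic acquisition: one feature per library record + decoys.

    ``include`` restricts the simulated compounds to the given record ids
    (used by the counterfeit builder); decoy features are always added.
    Output is a deterministic function of (inputs, params.seed).
    """
    rng = np.random.default_rng(params.seed)
    wanted = set(include) if include is not None else None
    features: List[SampleFeature] = []
    apex: Dict[str, float] = {}
    for rec in lib:
        # burn the record's noise draws even when excluded so that genuine
        # and counterfeit runs at the same seed stay comparable
        feat = simulate_feature(rec, params, rng)
        a = _lognormal_intensity(rng, params.intensity_log10_mean,
                                 params.intensity_log10_sd)
        if wanted is None or rec.id in wanted:
            features.append(feat)
            apex[feat.feature_id] = a
    for i in range(params.decoy_features_per_run):
        feat = _decoy_feature(i, lib, params, rng)
        features.append(feat)
        apex[feat.feature_id] = _lognormal_intensity(
            rng, params.decoy_intensity_log10_mean, params.intensity_log10_sd)
    chromatogram = _build_chromatogram(features, apex, params)
    return SimulatedRun(name=name, features=features, chromatogram=chromatogram,
                        apex_intensity=apex, params=params)


def surviving_records(lib: Library, spec: CounterfeitSpec) -> List[str]:
    """Ids of compounds still present after herb removal.

    A compound vanishes only if *every* herb that can supply it was
    replaced (source_herbs a subset of the removed set); a compound with
    any surviving source herb is still extracted from the granule.
    """
    return [r.id for r in lib if not r.source_herbs <= spec.removed_herbs]


def simulate_counterfeit(
    lib: Library, spec: CounterfeitSpec, params: SimParams = SimParams()
) -> SimulatedRun:
    """Synthetic acquisition of a herb-removal counterfeit granule."""
    return simulate_run(lib, params, name=spec.name,
                        include=surviving_records(lib, spec))
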