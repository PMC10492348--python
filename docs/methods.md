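# Methods

## Exact-mass arithmetic

All ions are treated as singly charged, so m/z equals ion mass in Da.
The theoretical m/z of an ion formula is its *plain* monoisotopic mass,
Σ countₑ · massₑ, computed from a packaged IUPAC isotope table (C = 12
exactly; other elements to ≥ 7 decimals). The formula is taken as
already de/protonated (e.g. C₇H₁₁O₆⁻ for the [M−H]⁻ of quinic acid) and
no electron-mass term is applied by default. This is the convention that
reproduces 50 of the 52 theoretical values in the bundled reference
table at 4 decimal places; two rows (scoparone, oleic acid) were printed
under the physically rigorous electron-corrected convention
(m/z = mass ∓ mₑ for cations/anions), which is available via
`monoisotopic_mz(..., electron_correction=True)` and reproduces those
two rows exactly. Both rows are flagged `anomalous` in the fixture, as
is the ethyl stearate row, whose *printed observed* m/z sits 407 ppm
from its own formula mass and is treated as a typographical anomaly.

ppm error is |obs − theo| / theo × 10⁶ — the denominator is the
theoretical (reference) mass, which reproduces the printed δ column
exactly; a table-reproduction mode first rounds both inputs half-up to
4 decimals, then rounds the result to 4 decimals, because that is how
printed δ values arise from printed m/z pairs. Rounding is always
half-up (ties away from zero), not banker's rounding.

## The standard library

One record per authentic standard: id, name, RT (min), ion formula and
polarity, cached 4-dp theoretical m/z, diagnostic fragments (the
evidence-bearing MS/MS ions), other fragments, and the set of formula
herbs that can supply the compound. Record invariants (positive RT,
non-empty diagnostics, fragments below precursor + 1 Da, herbs within
the 19-herb vocabulary, cached m/z recomputable within 5 × 10⁻⁵ Da
unless flagged) are enforced at load time with row-numbered errors.
`validate_library` recomputes every cached m/z and reports 4-dp
mismatches; mismatches on flagged rows are tolerated and listed.

The bundled fixture transcribes the 52-compound reference table,
including which fragments are diagnostic (taken verbatim from the
table's bolding — no re-derivation is attempted, since no selection
rule is stated) and each compound's source herbs. The variant spelling
"Zhisuzi" that three rows use for Perillae folium is kept in the file
and normalised to the vocabulary entry "Zisuye" on load. Three rows in
the printed table carry garbled ion formulas that contradict their own
printed theoretical m/z and δ arithmetic; the fixture stores the
formula consistent with the printed m/z columns.

## The matching engine

Candidates for a feature are all same-polarity records whose
theoretical m/z lies within the precursor tolerance. Each candidate is
scored on four axes and accepted only if **all four** pass:

| criterion | default gate | rationale |
|---|---|---|
| precursor ppm error | ≤ 5 ppm | every accepted reference match is below 5 ppm |
| &#124;ΔRT&#124; | ≤ 0.20 min | twice the spacing of the closest RT-resolved isomer pair |
| diagnostic coverage | ≥ 0.6 | majority of the evidence fragments must appear |
| spectral cosine | ≥ 0.2 | profile sanity check; see below |

Diagnostic coverage is the fraction of the candidate's diagnostic
fragments with a feature peak within ±0.005 Da, each library fragment
claiming at most one peak (greedy nearest, ties to the lower-m/z peak).
The spectral cosine is the normalized dot product of square-root
intensities after the same greedy pairing; library spectra carry no
intensities and are represented as unit vectors. Against unit-intensity
references the absolute cosine is deflated: measured over 300 simulated
runs × 52 compounds, true-match scores for sparse (4–6 peak) spectra
tail down to ≈ 0.25, while profile-level mismatches score near zero.
The 0.2 gate was therefore set from that score distribution: it rejects
garbage without vetoing sparse true matches, and the cosine's
discriminative power is used at full resolution in the ranking instead.

Candidates are ranked by the total order (coverage desc, cosine desc,
|ΔRT| asc, ppm asc, candidate id); run-level identification assigns
features to records greedily in that order, one-to-one. Placing cosine
ahead of |ΔRT| is what discriminates the hardest isomer pair: naringenin
and naringenin chalcone share the formula, differ by 0.01 min in RT
(inside any realistic jitter), and the chalcone's spectrum contains
every naringenin diagnostic — but each feature matches a strict
superset of its own record's fragments, so its own-record cosine
dominates whenever a distinguishing fragment (the chalcone's m/z
187.04) exists. The other two shared-formula pairs
(vitexin/isovitexin, daidzein/7,4′-dihydroxyflavone) are separated by
RT (0.26 and 0.22 min). Positive-mode features are matched only against
positive-mode records.

## Marker-panel authentication

The default panel maps six markers to seven herbs: hesperidin →
{Chenpi, Zhishi}, saikosaponin A → {Chaihu}, caffeine → {Hongcha},
S-senkyunolide A → {Chuanxiong}, magnolol → {Houpo},
18β-glycyrrhetinic acid → {Gancao}. Target m/z is always derived from
the neutral formula ([M−H]⁻ or [M+H]⁺ under the plain convention),
never from a nominal integer mass. XICs are extracted at ±10 ppm —
wider than the identification gate because screening favours capture
over specificity — and a marker is present iff the trace apex reaches
10⁴ counts (inclusive). The cutoff is an artifact decision: genuine
marker apexes simulate (and are reported) at 10⁵–10⁶ while a removed
compound gives an exactly empty trace, so the gate only needs to clear
baseline. A herb is suspect-absent iff *every* marker mapping to it is
absent; platycodin D (low instrument response) can be added to a custom
panel to cover Jiegeng, with the caveat that a weak-response marker
makes absence calls less trustworthy.

TCR and SCR are reported in percent, rounded half-up to one decimal.
For the default panel: TCR = 7/19 = 36.8%, SCR = 5/19 = 26.3% (Chenpi
and Zhishi share hesperidin, so neither is *specifically* covered).

## The synthetic-data generator

The generator emulates a centroided acquisition downstream of peak
picking; its defaults are the study conditions the package is tested
under.

* Precursor and fragment m/z noise: multiplicative Normal(0, 1.5 ppm) —
  anchored to the reference table's sub-5-ppm accepted errors, it keeps
  ≈ 99.9% of precursor draws inside the 5 ppm gate.
* RT jitter: Normal(0, 0.03 min), consistent with the table's 0.01-min
  RT granularity and the 0.2-min matching window.
* Fragment dropout: diagnostics kept with probability 1.0,
  non-diagnostics 0.8.
* Intensities: log-normal, log₁₀ mean 5.5 and sd 0.5 for true signals
  (apexes land in the reported 10⁵–10⁶ range); decoy peaks and decoy
  features are drawn ten-fold weaker (log₁₀ mean 4.5), as instrument
  noise peaks are.
* Per-spectrum decoy peaks: 0–5 at uniform random m/z; whole decoy
  features: 10 per run, rejection-sampled so their precursors sit
  ≥ 50 ppm from every library record, making decoy-rejection claims
  well defined.
* Chromatogram: each feature elutes as a Gaussian (σ = 0.05 min,
  truncated at 4σ) on a 0–17 min grid at 0.01-min steps, both
  polarities; the centroid m/z in every scan is the feature's noisy
  precursor.

Counterfeits are built by herb removal: a compound is omitted iff its
source-herb set is a subset of the removed set — a compound survives as
long as any supplying herb remains (quinic acid survives the
black-tea-removal counterfeit because hawthorn also supplies it). The
six bundled recipes remove, respectively, {Zhishi, Chenpi}, {Chaihu},
{Hongcha}, {Chuanxiong}, {Houpo}, {Gancao}. Excluded records still
consume their random draws so that genuine and counterfeit runs at the
same seed are feature-for-feature comparable.

What the generator does **not** model: isotope envelopes, in-source
fragmentation, co-elution/matrix suppression, intensity correlation
between a compound's fragments, chromatographic tailing, and
between-batch RT drift. Passing tests on synthetic runs therefore
demonstrate the correctness and calibration of the matching and
authentication logic under the stated noise model, not instrument-level
performance on real extracts.

## Problem sizes and stochastic tails

The test suite exercises full-size runs (52 compounds + 10 decoys) over
20 fixed seeds for identification recovery and one fixed seed for the
six-counterfeit matrix; both complete in seconds. Two tail behaviours
of the noise model are worth knowing. First, a precursor noise draw
beyond 5 ppm (probability ≈ 0.09% per feature, so a few percent of
whole runs) leaves that one compound unidentified — the same mechanism
by which a real acquisition loses borderline features. Second, a marker
apex drawn 3σ below the intensity median (≈ 0.1% per marker) falls
under the presence cutoff and produces a false herb alarm in roughly
1% of seeds; this mirrors the behaviour of any fixed-intensity presence
gate. Neither tail is patched over: the defaults are the study
conditions, and the reported recovery numbers are what the method
produces under them.

## Numerical and degenerate-input choices

Round-half-up is used wherever printed tables are reproduced. Empty
peak lists give coverage 0 and cosine 0; an empty library or feature
list yields empty results rather than errors; an all-zero XIC has apex
intensity 0 and no apex RT; the presence boundary is inclusive;
`query_precursor` ties (identical ppm error) order by record id;
deprotonating a hydrogen-free formula in negative mode is an error.
All randomness flows through one seeded `numpy` generator per run, and
identical (inputs, seed) produce byte-identical output files.
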