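# Methods

## Coordinate and template model

Every analyzed locus is a restriction fragment with offsets in bp measured
from the probe-proximal restriction cut (0-based, half-open intervals),
increasing toward the telomere or distal end — the natural frame of
indirect end-labeling, where a probe-anchored fragment of size *s* marks a
cut at offset *s*. A template layers three things: sequence **features**
(restriction sites, probe, ACS, GRF motifs, TG tract, element boundaries),
ground-truth **occupants** (protein footprints with a protection value),
and the **planted cut sites** implied by the occupancy (accessible linker
centers). Coordinates printed in the source literature (TEL03L Abf1 at
783, site IV at 804 ± 21; X(TEL05R) ACS at 1325, Abf1 at 1545, X-III at
1594 ± 19; Y′-I at junction + 70; the 221 ± 1 bp ACS–Abf1 spacing of
X-only telomeres; the 300 ± 75 bp TG tract) anchor each layout; offsets
shown only graphically are reconstructed by chaining printed spacings from
those anchors and carry `source="reconstructed"` — they are template data,
not code constants, and tests never assert them against the literature.

Occupant footprints are disjoint; nucleosomes are exactly 146 bp; ORC
covers 41 bp (midpoint of the 38–44 bp range measured in vitro), centered
on the ACS. Protected spans whose occupant the evidence leaves open (the
short ACS-adjacent fragments may be ORC plus an unidentified factor) use a
generic `unknown` occupant; for the Y′ junction both ground-truth variants
(`orc_plus_unknown`, `orc_alone`) are available. Default protections are
0.997 (nucleosome), 0.98 (ORC/GRFs), 0.99 (unknown filler) and 0.995
(Rap1-covered TG repeats): the modeled blots show sharp bands with
virtually no background cutting inside protected chromatin, and weaker
protection manufactures broad first-cut humps that the band caller would
report as spurious sites. All protections are per-occupant configurable.
Partially accessible linkers encode construct- and genotype-dependent
sites: the subtelomere–telomere junction cut is shielded from free
nucleases (accessibility 0.2 on Y′/TEL03L, 0.5 on the more open TEL06R),
and the TEL03L site-II linker opens only in `sir`/`yku` genotypes.

The terminal TG tract length is drawn per molecule from Normal(300, 75²)
truncated to [150, 525] (± 2 SD), which produces the characteristic
full-length smear of terminal fragments.

## Digestion model

Cuts per molecule form an inhomogeneous Poisson process with per-bp mean
`k · a(x) · c(x) · f_T · t`:

* `k = 0.04` cuts · bp⁻¹ · min⁻¹ at 30 °C — chosen so ~5 min at 30 °C cuts
  ≥ 90 % of open 12-bp linkers (near-complete digestion), matching the
  qualitative kinetic anchor that complete histone-tethered digestion is
  reached by 5 min;
* `f_T` — temperature factor, 1.0 at 30 °C and 0.05 on ice (15 min at 4 °C
  ≈ 1 min at 30 °C, the stated equivalence rounded to a single factor);
* `a(x)` — 1 on naked DNA, `1 − protection` inside footprints;
* `c(x)` — 1 for free constructs (GBD-MN, NLS-MN); tethered constructs add
  a box kernel of amplitude λ and half-width *d* around their anchors:
  MN-Rap1 (λ = 10, d = 200 bp) at Rap1-site features and the TG-tract
  midpoint, H2A-MN (λ = 1, d = 80 bp) at nucleosome centers, Yku70-MN
  (λ = 10, d = 150 bp) at the physical end. λ for MN-Rap1 balances two
  qualitative constraints: the junction band must dominate early MN-Rap1
  lanes, yet first-cut competition must not erase the distal enhanced
  sites. H2A-MN gets only a small amplitude because, under probe-anchored
  detection, a large uniform enhancement over a nucleosome array is
  indistinguishable from digesting longer and simply deletes distal bands;
  the informative very-partial regime is instead reached through the
  on-ice lanes, as in the original experimental design.

Sequence preference of the nuclease is not modeled. Detection keeps, per
molecule, the fragment overlapping the probe (anchor → first cut, or full
length if uncut): the single-cut logic of indirect end-labeling. The full
pre-filter fragment list is available for conservation checks. Every lane
draws its RNG stream from a SHA-256 hash of (master seed, lane identity),
so any lane subset reproduces exactly.

Default schedule: 1, 2, 5 min at 30 °C plus 5 and 15 min at 4 °C, per
construct — partial points carry the distal sites, late points the
proximal mononucleosome-like end products.

## Virtual Southern blot and band calling

Migration follows `m(s) = a − b·log₁₀(s)`; each detected fragment adds a
unit-area Gaussian (band σ ≈ 1.23 profile units, making species ~6.5 %
apart in size — the finest spacing the modeled blots resolve, e.g. 85 bp
at 1.3 kb — sit 4σ apart). Signal is count-proportional (one probe
hybridization per fragment), not mass-proportional. Ladder calibration is
a least-squares fit of position on log₁₀(size); sizing inverts the fitted
law (exact round trip with a noiseless ladder, < 1 % error at 0.2-unit
ladder noise). Bands are profile maxima above a prominence threshold
(default 5 % of lane maximum; 3 % for H2A-MN on-ice lanes, whose very
partial cleavage is what reveals probe-distal sites), with centroid
refinement over ± 2σ; the full-length band (terminal: any size beyond the
TG-tract start + 10 bp; internal: > 97 % of fragment length) is excluded.
`percent_signal` integrates ± 2σ around the peak over total lane signal.

Offsets pooled over lanes, times and constructs are consolidated by
single-linkage clustering with 25-bp tolerance (in 1-D: split sorted
offsets at gaps > 25 bp); clusters need ≥ 2 observations, report
mean ± SD and supporting constructs, and receive Roman labels — numbered
from the telomere on terminal fragments (gel convention) and from the
probe on internal ones. A region between bands is flagged "diffuse" when
the inter-peak baseline exceeds half the smaller flanking peak — the
operational version of a qualitative judgement.

## Interpretation

Inter-site spacings propagate flanking SDs in quadrature. Spacing < 146 bp
(the minimal nucleosome footprint) ⇒ `sub_nucleosomal`; exactly 146
counts as nucleosome-compatible (146 is the stated minimum). Associations
need a feature center ≥ 10 bp inside the interval (the paper-style
association of site IV at 804 with Abf1 at 783 spans 21 bp), precedence
ORC_ACS > Abf1 > Tbf1/Reb1 array. Reconstruction maps
nucleosome-compatible intervals to nucleosomes, sub-nucleosomal ones to
their associated factor, and the junction-proximal interval of a terminal
fragment with a GRF array to a GRF-held NFR; `terminal_nfr` records that
no nucleosome abuts the TG repeats. Junction accessibility ratios divide
the junction band's percent signal by the ACS-region bands' (Y′: I/(II+III);
TEL03L: I/(V+VI); TEL06R: I/III), averaged over a construct's lanes, with
a detection-limit flag when the denominator is unmeasurable. Only the
ordering of these ratios is meaningful (tethered ≫ free; TEL06R ≫ TEL03L
for free nucleases): magnitudes depend on the unmeasured kinetic
constants.

## Fold-back discrimination

Both hypotheses for efficient MN-Rap1 cutting over internal X elements are
implemented as anchor rules: `direct_binding` enhances MN-Rap1 at
X-element Rap1 sites in every genotype and context; `foldback` grants that
enhancement only to the WT chromosomal locus (SIR/yKu-delivered terminal
Rap1), leaving TG-tract anchoring otherwise — and the analyzed X–Y′
fragments carry no TG tract. Discrimination lanes use one very partial
on-ice MN-Rap1 digestion (1 min, 4 °C) called at prominence 0.1: the only
regime in which tether-enhanced cutting of the (fully accessible) X-element
linkers is detectable while free-level cutting of the same linkers is not —
at stronger digestion an untethered nuclease also cuts open linkers and no
site-count difference can exist. Patterns are compared on X-start-relative
offsets via a matched-band L1 divergence (sites matched within 25 bp
contribute |Δ percent|, unmatched ones their full percent) against the
WT-chromosomal reference of the same mode.

## What the synthetic data do and do not show

The generator emulates partial-digestion time courses, construct
tethering, restriction anchoring, probe selection, heterogeneous TG
tracts, log-linear migration with band broadening, and finite-sample
(2000 molecules/lane) counting noise. It does not emulate sequence-biased
MNase cutting, cross-hybridizing bands, membrane/probe artifacts,
cell-cycle or population heterogeneity of occupancy, or 2-D gel imaging
(profiles are 1-D densitometry). Passing tests therefore demonstrate that
the inference chain recovers planted chromatin architecture under
realistic gel physics and sampling noise — not that it would be robust to
every artifact of real blots. Likewise the bundled count matrices are
synthetic consensus-derived stand-ins carrying curated-database IDs as
labels; scanner behaviour (exact p-values, strand symmetry, planted-motif
recovery, false-positive calibration) is fully tested, but genome-scale
hit counts are not comparable to scans with curated matrices.

## Numerical choices and degenerate inputs

Score-grid granularity for exact p-values is 0.01 bits; the quantization
error (≤ L·g/2) is absorbed into the tail threshold, and `-inf` log-odds
entries (zero counts with zero pseudocount) shed their probability mass
below every finite score. Pseudocount 0.8 split by background; uniform
background by default. Ties in count matrices resolve to the
alphabetically first base for consensus planting. Flat profiles and
time-0 lanes yield empty band lists; sub-60-bp band sizes are discarded
(off-gel); clustering tie-breaks do not arise under the sorted-gap
formulation. Problem sizes throughout (2000 molecules/lane, 4 constructs,
5 time/temperature points) are the package's defaults and match the scale
at which the acceptance measurements are quoted.

## Known limitations

Figure-only coordinates are reconstructions; absolute kinetic constants
(k, λ, d, protections) are free parameters fixed once from qualitative
anchors, so only orderings and geometry — not band-intensity magnitudes —
are claimed. The MN-Rap1-specific shielded site in early Y′(TEL05R)
(planted at junction + 180) is below the default schedule's detection
regime and is recovered only in very-partial lanes. Multi-cut fragments
released between two internal cuts are discarded by probe selection, so
the simulator cannot reproduce probe-internal rehybridization experiments.
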