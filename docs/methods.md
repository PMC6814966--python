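# Methods

## Scientific setting

Spinocerebellar ataxia type 1 is caused by expansion of the polyglutamine
(polyQ) tract of Ataxin-1 (ATXN1) beyond its physiological length.  The
package compares, *in silico*, how the wild-type protein (Q29, 816
residues, polyQ at 197–225, AXH domain at 562–693) and the disease-length
variant (Q82, 869 residues) bind their reported protein partners.  The
inputs are two-chain docked complexes (one ATXN1-like receptor chain, one
partner chain) plus per-model docking scores; the outputs are interface
characterizations, region-resolved interface tallies, per-interactor
binding-preference calls, agreement scores against experimental preference
labels, and the supporting nonparametric statistics.

## Interface model

**SASA.** Solvent-accessible surface area is computed with the
Shrake–Rupley point-sampling algorithm: each atom sphere is inflated by
the probe radius (default 1.4 Å, water) and covered with `n_points`
sample points (default 960) from a fixed golden-angle spiral, so the
computation involves no random numbers and is bit-reproducible.  A point
is accessible if it lies outside every other inflated atom sphere; the
atom's area is the accessible fraction times the inflated sphere area.
Van der Waals radii default to a Bondi-type protein set (C 1.70, N 1.55,
O 1.52, S/P 1.80 Å; unknown elements 1.80 Å with a warning); the table is
injectable for sensitivity analyses.  Hydrogens are excluded by default
because docking models normally lack them.  Quadrature error scales as
1/√`n_points`; at 960 points the isolated-sphere limit is reproduced to
well under 1%.

**Interface definition.** For a receptor/partner chain pair, each chain's
SASA is computed in isolation and in the complex with identical
parameters.  ΔASA = isolated − in-complex is non-negative by construction
(the same point set is used, and adding atoms can only occlude points).  A
residue is an interface residue when its ΔASA exceeds 0.01 Å² — small
enough to mean "any buried area", large enough to absorb floating-point
noise.  The interface area is half the total buried area,
(SASA_A + SASA_B − SASA_AB)/2; per-chain buried percentage uses the
isolated-chain SASA as the denominator; interface-residue percentages use
the number of residues present in the model (not the full-length
sequence), so truncated models stay self-consistent.

**Bonds.** Hydrogen bonds are inter-chain donor(N/O)–acceptor(O/N)
heavy-atom contacts within 3.5 Å, with donor/acceptor capability taken
from per-residue atom dictionaries for the 20 standard residues (backbone
N donates except in proline; backbone O/OXT accept).  No angle criterion
is applied, again because the models lack hydrogens.  Salt bridges are
basic-N (LYS NZ, ARG NE/NH1/NH2, HIS ND1/NE2) to acidic-O (ASP OD1/OD2,
GLU OE1/OE2) contacts within 4.0 Å.  A contact that qualifies as a salt
bridge is reported only in the salt-bridge list, so the two categories
are disjoint; the flag `exclude_salt_bridges=False` restores the raw
donor–acceptor list.  Both cutoffs are configurable, since published
interface servers do not document their exact criteria; paired
*statistics* over complexes, not absolute bond counts, are the intended
comparison level.

## Region schemes

Wild-type coordinates: before-polyQ 1–196, polyQ 197–225, after-polyQ
226–816, 20-residue flanks 177–196 and 226–245, AXH 562–693.  The Q82
tract inserts 53 glutamines inside the tract (a pure insertion), so every
downstream bound shifts by +53: polyQ 197–278, AXH 615–746, length 869.
The three "partition" regions tile the sequence, so their percentages sum
to 100; the flanks and the AXH domain are overlapping sub-regions of the
partition and are reported alongside.  Optional labels (SAR 494–604,
RNA-binding 540–766, NLS 794–797, C-terminal 690–816) are carried in the
scheme but drive no headline result.  Tallies pool residues over
complexes with multiplicity (a residue counts once per complex it appears
in); `unique_positions=True` switches to counting distinct positions.
Residues outside the scheme range are a hard error rather than a silent
drop, so mis-numbered models are caught immediately.

## Preference classification and agreement

One docking model per (interactor, variant) is selected either by lowest
cluster Z-score ("approach 1") or by highest interaction probability
("approach 2"); ties break to the lexicographically first model id, and
the tie is logged.  The classifier compares a single interface metric
between the two variants' complexes: larger for the Q82 dock → "expanded",
smaller → "wt", equal → "no_preference".  Six metrics are computed for
every complex (receptor interface-residue count and percentage, partner
count and percentage, buried area, buried-area percentage); the
classification metric is an explicit, logged parameter, defaulting to the
receptor interface-residue count.  Equality is exact for the count
metrics and uses a 0.05 tolerance for the floating-point area metrics.
Interactors missing a dock for either variant are skipped with a logged
warning.  Agreement against experimental labels is an exact
cross-tabulation with overall and per-experimental-class percentages
(one decimal).

The package ships two plain-text tables for the 71 ATXN1 partners of the
quantitative yeast two-hybrid screen of Suter et al. (2013):
per-interactor methodology categories (which approach called which
variant) and approach-2 predictions against the experimental labels.
Interactors are keyed by UniProt accession; gene symbols are kept as
printed in the sources (the same accession O43251 appears as
RBFOX2/RBM9).  From these tables the pipeline recomputes the headline
validation numbers: 60/71 interactors concordant between the two
approaches (7 wt + 53 expanded), approach-2 agreement 43/71 (60.6%),
approach-1 agreement 38/71, per-class agreement 3/16 (wt) and 40/48
(expanded).  Note 3/16 = 18.75%, which the package rounds to 18.8 rather
than truncating.

## Statistics

* **Sign test** — exact, paired; zero differences are dropped and the
  two-sided p doubles the smaller binomial tail at θ = ½, capped at 1.
  Equal to full 2ⁿ enumeration (verified for n ≤ 12).
* **Mann–Whitney U** — U from midrank sums.  For min(n, m) ≥ 8 the
  p-value is the tie-corrected normal approximation with continuity
  correction (scipy); below that, exact enumeration over all group
  labelings, two-sided by distance of U from its mean (well-defined under
  ties).  Enumeration is capped at 200 000 labelings, falling back to the
  approximation, because a small minimum group with a large complement
  can still make enumeration infeasible.
* **Fisher exact** — two-sided, summing hypergeometric probabilities of
  tables no more probable than the observed one (scipy); zero margins
  give p = 1 with a note.
* **OLS** — scipy `linregress`; r² defined as 0 when y is constant;
  constant x is an error.
* **Pooled-permutation regression comparison** — to ask whether two
  groups' fitted lines could come from one population, all points are
  pooled and, per draw, a subset of each group's size is sampled *without
  replacement* and refitted; the observed slope and intercept of each
  group are located within the resampled distributions (proportions ≥ and
  ≤).  One resample stream per group provides both the slope and
  intercept proportions of a draw.  Default 1000 draws; a single integer
  seed (default 20191026) drives all randomness.  The subset-resampling
  reading of "permutation" follows the procedure the comparison is meant
  to emulate (random samples of one group's size from the pooled data),
  rather than label shuffling.

## Synthetic data: what it emulates and what it does not

The generators produce inputs whose ground truth is provable, not
realistic:

* **Contact complexes** — chains are idealized extended strands (3.8 Å
  Cα spacing) of single-Cα residues.  A partner contact atom sits 5.5 Å
  above each planted receptor residue: two carbons interact below
  r₁ + r₂ + 2·probe = 6.2 Å, so the planted residue is buried while the
  neighbouring Cα, at √(5.5² + 3.8²) = 6.68 Å, is untouched.  Planted
  hydrogen bonds use ASN ND2 / GLN OE1 stubs at 2.9 Å and planted salt
  bridges LYS NZ / GLU OE1 stubs at 3.4 Å, with stub heights chosen so
  that every non-planted residue keeps ≥ 0.15 Å clearance from any
  occlusion radius; a ±0.15 Å z-jitter (seeded) individualizes complexes
  without eroding those margins.  Non-contact partner residues are parked
  30 Å away.  An optional self-check re-derives the truth with a 3840-point
  SASA pass before the complex is emitted.
* **Paired variant studies** — each synthetic interactor gets a base
  interface (1–3 residues before the polyQ, 5–9 in the AXH domain, 2–4
  elsewhere after the polyQ; the AXH-heavy profile mirrors the observed
  dominance of AXH contacts).  The expanded complex uses the same set
  shifted by +53 beyond residue 196, and the variant named by the planted
  preference gains extra residues per region (`region_gain`; default 2
  after the polyQ when unspecified).  Planted "no preference" means
  bit-identical interface counts.  The `noise` parameter adds
  Poisson-distributed extra after-polyQ residues to *both* variants, so
  between-interactor variability grows while paired differences stay
  exact.  Sampling windows (before: 1–156; after: 300–500; AXH: 562–693,
  wt coordinates) keep every planted residue inside a single reporting
  region.
* **Interactor-count tables** — x is discrete uniform (default 1–60),
  y = slope·x + intercept + Gaussian noise, truncated at 0 and rounded to
  integer counts.  Defaults (slope 4.89, intercept 18.9, noise SD 55)
  emulate the human-vs-mouse interactor-count regression for polyQ
  proteins, with the noise level set so the line explains roughly
  two-thirds of the variance over the default x-range.

Because the geometry is idealized, passing tests demonstrate the
correctness of the bookkeeping (SASA quadrature, ΔASA accounting, region
arithmetic, classification and statistics), not the realism of docking
models: real interfaces have packed side chains, partial burial,
correlated contacts and bond geometries the distance-only criteria can
miss or over-count.

## Numerical and design choices

* Sphere points from a deterministic spiral; no RNG anywhere in the SASA
  path.  Deterministic end-to-end reruns are asserted in the tests.
* Altloc resolution keeps the highest-occupancy conformer (ties: first
  listed); only MODEL 1 of multi-model files is read; HETATM waters are
  dropped.  Malformed fixed-width ATOM records fail with the line number.
* Model selection ties break on model id so reruns are reproducible.
* Problem sizes used in the shipped checks — 20-interactor studies,
  60–80-residue receptors for the random-complex checks, 1000 permutation
  draws, 200/100 calibration replicates — keep every check exact or
  tightly calibrated while running in seconds on one core.

## Known limitations

* Bond detection is distance-only; without hydrogens or angle terms the
  absolute counts are not comparable to geometry-aware tools, only paired
  differences across variants are meaningful.
* The expanded-variant coordinate scheme assumes a pure insertion within
  the polyQ tract; docking models renumbered any other way must be mapped
  before region analysis.
* Interface percentages are relative to residues present in the model;
  comparing models with very different truncations therefore needs care.
* The pipeline treats binary complexes only; multi-partner assemblies
  are out of scope.
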