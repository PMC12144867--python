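# Methods

## Mass model

All arithmetic is monoisotopic.  A species with chains `c₁…cₙ` and
modification counts `m` has neutral mass

    M = Σᵢ Σ_residues(cᵢ) + n·18.010565 + Σ_kind m_kind·Δ_kind

Residue masses are the conventional proteomics table fixed at the fifth
decimal (values padded to six decimals in `masses.RESIDUE_MASSES`); the
proton is 1.0072765 Da and reported m/z values are rounded half-up at
four decimals.  This combination reproduces published high-resolution
[M+nH]ⁿ⁺ values digit-for-digit; a full-precision atomic-mass table
differs in the fourth decimal for one published value (379.6682 vs
379.6681) because that value sits within 2·10⁻⁶ Da of the rounding
boundary.  The cost is that absolute neutral masses are accurate to
~5·10⁻⁶ Da rather than 10⁻⁶; tests assert masses at 10⁻⁴ Da.

Modification deltas (Da): dehydration and thioether ring −18.010565 each
(ring closure itself is mass-neutral — the ring "is" its dehydration),
disulfide −2.015650, methylation +14.015650, acetylation +42.010565,
hydroxylation +15.994915, chain scission +18.010565, DTT reduction
+2.015650 per disulfide, desulfurization −29.956421 per opened thioether
bridge and −31.972071 per free Cys thiol.  The derivatization deltas are
provisional defaults (the primary literature reports the treatments but
not the exact deltas used) and are exposed in the constants table so
audits can diff them.

Bookkeeping convention: in a `CandidateSpecies`, `thioether_ring` counts
rings (each carrying its own dehydration) and `dehydration` counts *free*
Dha/Dhb only, so the two are never double counted.  Backbone scission is
not a mods entry: splitting a chain adds one water through the per-chain
water term, which makes the two-chain (DADC) mass law an identity —
ring (−H₂O) plus ring-internal hydrolysis (+H₂O) equals the unmodified
linear chain.  This is verified over 1000 random candidates in the tests.

## Species enumeration

For a precursor, leader cleavage is hypothesized at every position in the
C-terminal half whose core retains ≥1 Cys and ≥1 Ser/Thr (explicit site
lists override the scan; a site list is taken as given).  Modification
multisets are bounded by the core inventory: free dehydrations + rings ≤
#Ser+#Thr, rings ≤ #Cys, disulfides ≤ ⌊(#Cys − rings)/2⌋, tailoring
(methylation/acetylation/hydroxylation) capped at one each by default.  A
core without any Ser/Thr/Cys is not a lanthipeptide substrate and yields
only the unmodified peptide.  Ring topologies pair donors (Ser→Lan,
Thr→MeLan) with Cys acceptors injectively; adjacent-residue rings and
crossing (intertwined) rings are allowed.  Positions are 1-based on the
core, ring spans inclusive.

Scissions model the DADC maturation: a backbone bond is cut (+H₂O, two
new termini) only where at least one crosslink spans the bond, so the
product remains one covalently connected species; the default cap is one
scission.  Trims remove up to `max_trim` terminal residues, never a
crosslinked one.  Trims are applied only to candidates carrying at least
one crosslink: for an unbridged linear peptide an N-terminal trim is
indistinguishable from another cleavage hypothesis and a C-terminal trim
duplicates masses without biological motivation (the observed phenomenon
is trimming of residues extending *outside* rings).  Trimmed residues are
accounted at their unmodified residue masses; free dehydrations are not
re-localized when termini are removed (they are unpositioned in the mass
model).

### Library construction

The MS1 library deduplicates on (sorted chain sequences, mass rounded to
10⁻⁶ Da): topologically distinct isomers of equal mass collapse for MS1
matching.  Because that key depends on the topology only through its
existence, the builder never materialises the topology cross-product.
It enumerates chain configurations (an optional cut bond plus
per-terminus trim depths) and modification counts, and admits a
configuration iff the retained residue inventory can realise the
requested ring/disulfide counts, with — for a cut — at least one
potential link spanning the cut bond.  For a single cut the spanning
condition is exactly the connectivity contract: a path reconnecting the
two halves must cross the cut coordinate, and only a spanning crosslink
can.  One deterministic witness topology (smallest-position pairing,
spanning link first) is constructed per unique key and validated by the
species invariant checks.  With `max_scissions > 1` the builder falls
back to explicit enumeration, where the spanning argument is no longer
exact.  Both paths are compared against an independent brute-force
generator (own pairing, own graph connectivity, own mass sums) on small
cores in the test suite.

For MS/MS the collapse is undone on demand: `pipeline._isomers` expands a
library representative into every ring/disulfide placement consistent
with its chains and counts, and fragment support is the maximum over
isomers.  This mirrors practice: MS1 can only see the mass; the ring
position is then inferred from the fragments.

## Fragment prediction

b/y ions are predicted per chain at charges 1–2.  A cleavage is emitted
only when it separates a clean chain prefix (b) or suffix (y) from the
rest of the possibly multi-chain species — equivalently, when no
crosslink has exactly one endpoint in the fragment span.  A fragment
enclosing complete crosslinks carries their deltas (−18.010565 per
thioether ring, −2.015650 per disulfide), yielding the diagnostic
"b5, −H₂O, −18 Da" pattern for a 1–5 ring.  A fully caged species
predicts no ions.  Free dehydrations and tailoring modifications are not
distributed onto fragments (their positions are not modelled); fragment
m/z values are therefore exact for ring-only species and for the
ring-localized part of the deficit otherwise.  c/z series are not
predicted by default but the `FragmentIon` framework is series-extensible.

MS2 support uses greedy nearest-peak assignment: all (fragment, peak)
pairs within tolerance ranked by |ppm|, each predicted fragment and each
observed peak used at most once.

Default tolerances are 10 ppm (MS1) and 20 ppm (MS2), ordinary practice
for Orbitrap-class instruments; both are parameters.

## Catalog statistics

Pairwise identity is global alignment (match +1, mismatch 0, linear gap
−1, via Biopython's PairwiseAligner) with identity = matches / alignment
length; X never matches.  This scoring was chosen for reproducibility
over substitution matrices and is configurable.  SSN families are
connected components of the graph with edges at identity ≥ threshold
(inclusive); the threshold defaults to 0.40 — a conventional coarse-family
cut, since the originating analysis states only the 100%-identity node
rule, not its edge metric — and exact duplicates are merged into single
nodes beforehand.  Family numbering is by decreasing size then
representative id; the representative is the longest member (ties:
lexicographically smallest id), making outputs byte-stable.

Length comparisons use the two-sided Mann–Whitney U test: the
tie-corrected normal approximation (scipy) when both samples have ≥ 20
members, otherwise an exhaustive permutation distribution computed on
midranks (capped at 200 000 splits, beyond which the normal approximation
is used).  Sets with fewer than two members report medians only.

Composition bias uses a one-sample binomial normal approximation per
residue, z = (k − np)/√(np(1−p)), with focal counts pooled across
sequences (not averaged per sequence) and the background providing p.
Classification is strict: Over iff z > 2.0, Under iff z < −2.0, boundary
values NS; no continuity correction and no multiple-testing adjustment,
matching the |Z| > 2 classification convention.  A residue with p ∈ {0,1}
has undefined variance and is flagged NS.  The focal set is the archaeal
catalog and the background the bacterial one, so positive z means
enrichment in the focal (archaeal) set.

## Synthetic data

The generator emulates the statistical structure of the real inputs:
Met-initiated leaders (15–30 aa) with a generic acidic-leaning
composition; short cores (6–15 aa) drawn from a Ser/Thr/Cys-enriched
distribution (~36% S/T/C combined, with C and S favoured over T); and a
"bacterial" background set, ~7 aa longer on average, shifted toward
K/I/L/N/Q and away from D/V/R/P — the mesophile-vs-halophile contrast the
bias statistics are meant to detect.  One true mature species per
precursor is drawn from the precursor's own rule space (80% ringed, 25%
of ringed species scissioned into two chains, 10% disulfides, 10%
methylation); planted MS1 peaks get Gaussian ppm error (σ = 2 ppm
default, the mass accuracy of a well-calibrated Orbitrap) at a random
charge 1–3 among uniform decoy peaks; MS2 spectra carry a random 70%
subset of predicted 1+ fragments with 5 ppm noise plus noise peaks.  All
randomness flows through one seeded generator; outputs are
byte-deterministic.

Enumeration bounds on synthetic runs form a closed world with the planted
inventory (≤2 rings, ≤1 disulfide, ≤1 methylation, ≤1 scission, ≤1 trim;
no acetylation/hydroxylation planted, hence none enumerated).  What the
synthetic data does *not* emulate: isotope envelopes, chromatography and
co-elution, intensity structure, deamidation-type artefacts, and
sequence homology between precursors.  Passing the recovery test
therefore demonstrates correctness of the enumeration/matching/ranking
machinery at realistic mass accuracy, not performance on real extracts.

## End-to-end recovery

A planted species counts as recovered when the top-ranked candidate on
its planted peak — fragment support first (maximised over isomers and
spectra with matching precursor), then |ppm| — has the same neutral mass.
Mass-degenerate modification multisets are counted as correct: MS1
cannot distinguish them by construction, and the isomer-level MS/MS
disambiguation is reported separately (chain-count and chain-sequence
agreement in `RecoveryResult`).  At the default study conditions (200
precursors, σ = 2 ppm, 10 ppm window, generator seed 0) the pipeline
recovers 97.5% of planted species; residual misses are dominated by
fully caged species that predict no fragments and so cannot be ranked
above an isobaric competitor by any MS/MS-based method.  The 200-precursor
problem size keeps the full run under a minute on one CPU.

## Known limitations

* Stereochemistry (LL vs DL rings) and leader-recognition motifs are out
  of scope; the enumerator proposes chemically possible topologies, not
  enzymatically preferred ones.
* The SSN threshold that would reproduce a specific published family
  count is not reverse-engineered; the threshold is a parameter.
* Fragment prediction ignores neutral losses other than the ring
  dehydrations, and internal (doubly cleaved) fragments.
* Average-mass mode, adducts other than protons, and isotope patterns
  are not implemented.
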