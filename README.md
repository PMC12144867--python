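# halolan

Rule-guided discovery of archaeal lanthipeptides from precursor sequences
and high-resolution mass-spectrometry data.

Lanthipeptides are ribosomally synthesized peptides (RiPPs) in which a
class II synthase (LanM) dehydrates Ser/Thr residues of a precursor
peptide (LanA) and cyclizes them onto Cys thiols, forming lanthionine
(Lan) and methyllanthionine (MeLan) thioether rings (net −H₂O per ring).
In haloarchaea this chemistry produces unusually short core peptides and a
two-chain subfamily — DADC lanthipeptides — in which a backbone bond
*inside* a ring is hydrolysed, leaving two antiparallel chains held
together only by the thioether bridges.

`halolan` implements the in-silico half of a heterologous-expression
discovery workflow for these molecules:

* **Mass algebra** — exact monoisotopic masses of multi-chain, multiply
  modified species: `M = Σ residues + n_chains·H₂O + Σ counts·Δ`, with
  Δ(dehydration) = −18.010565 Da, Δ(disulfide) = −2.015650 Da, and so on;
  `[M+zH]z⁺ = (M + z·1.0072765)/z`.
* **Species enumeration** — leader-cleavage hypotheses, modification
  multisets bounded by the core's Ser/Thr/Cys inventory, all ring
  topologies (crossing rings allowed), ring-internal scissions (the DADC
  maturation; mass-neutral relative to the unmodified linear chain, since
  the ring's −H₂O cancels the hydrolysis' +H₂O), and terminal trims that
  never remove a crosslinked residue.
* **Spectral matching** — ppm-tolerance MS1 matching of the candidate
  library against peak lists (|obs − calc|/calc × 10⁶), and
  topology-aware b/y fragment prediction: a backbone bond spanned by a
  crosslink releases no fragment pair, and a fragment enclosing a whole
  ring is lighter by that ring's dehydration (the diagnostic
  "b5, −H₂O, −18 Da" ion).
* **Comparative statistics** — sequence-similarity-network families over
  precursor catalogs (exact-duplicate nodes, identity-threshold edges,
  connected components), Mann–Whitney length comparisons (exact
  permutation for small samples), and per-residue binomial composition
  Z-scores, `z = (k − np)/√(np(1−p))`, classified Over/Under at |z| > 2.
* **Synthetic data** — generators for precursors, planted mature species,
  and noisy MS1/MS2 data with known ground truth, so the entire pipeline
  is testable offline.

## Worked example

The smallest natural lanthipeptide known is a six-residue core, CTRYSF,
carrying one dehydration consumed by a Cys1–Ser5 thioether ring.  Starting
from its precursor and one observed MS1 peak:

```python
from halolan import (PrecursorRecord, EnumerationRules,
                     build_candidate_library, match_ms1, annotate_report)
from halolan.matching import PeakList, Peak

precursor = PrecursorRecord("SalA", "MSDLNACTRYSF", cleavage_site=6)
library = build_candidate_library([precursor], EnumerationRules())
peaks = PeakList([Peak(mz=379.6688, charge=2, intensity=3.2e5)])
best = match_ms1(library, peaks, tol_ppm=10.0)[0]
print(annotate_report([best]).to_string(index=False))
```

prints (columns abridged):

```
charge  observed_mz  calculated_mz delta_ppm  neutral_mass
     2     379.6688       379.6682       1.7     757.32175
```

i.e. the library (328 mass-distinct candidates for this precursor)
contains a species at calculated [M+2H]²⁺ = 379.6682 — the dehydrated
CTRYSF — matching the observed peak within 1.7 ppm.  Its ring topology
then constrains the MS/MS prediction:

```python
from halolan.enumeration import CandidateSpecies, Crosslink, RingTopology
from halolan import predict_fragments

a2 = CandidateSpecies("SalA", "CTRYSF", [(1, 6)],
                      RingTopology((Crosslink(1, 5, "Lan"),)),
                      {"thioether_ring": 1})
for f in predict_fragments(a2, charges=(1,)):
    print(f"{f.annotation:<18s} m/z {f.mz:.4f}")
```

```
b5, -H2O, -18 Da   m/z 593.2501
y1                 m/z 166.0863
```

Only the bond outside the ring fragments: b5 appears 18 Da below its
linear value (the enclosed ring's dehydration), and b2–b4 are absent
because those bonds are bridged.  This is exactly the evidence pattern
used to assign the ring position in the real compound.

A full synthetic run (catalog → bias stats → enumeration → MS1 matching →
MS/MS-ranked recovery) is available from the command line:

```sh
halolan run --seed 0 --n-precursors 50 --out out/demo
```

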