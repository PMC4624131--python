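# Methods

## Model

`lbrscan` treats a candidate α-helical window of N residues as a rigid
helical wheel with angular periodicity δ = 100° per residue and scores it
by four quantities:

- **Mean hydrophobicity** ⟨H⟩ = (1/N) Σₙ Hₙ, the arithmetic mean of
  per-residue hydrophobicities. Order-independent; a pure composition
  statistic.
- **Hydrophobic moment** ⟨μH⟩ = (1/N) ‖Σₙ Hₙ (cos nδ, sin nδ)‖, n = 0…N−1
  (the Eisenberg moment, per-residue normalized). It measures how strongly
  hydrophobicity segregates to one face of the helix: zero for a uniform
  window whose length closes whole turns, maximal when all hydrophobic
  residues fall on one side of the wheel.
- **Net charge** z = (#K + #R) − (#D + #E). Histidine and the termini are
  neutral; there is no pH-dependent protonation model.
- **Discrimination factor** D = 0.944·⟨μH⟩ + 0.33·z, the HeliQuest linear
  score for lipid-binding propensity. The positive weight on z reflects
  that the prediction targets binding to *anionic* phospholipid membranes,
  where basic residues contribute electrostatically.

Classification on the hydrophobic moment plot (⟨μH⟩ vs ⟨H⟩) uses three
rules, all strict inequalities: lipid-binding when D > 0.68, transmembrane
when ⟨H⟩ > 0.75, surface-seeking when ⟨μH⟩ > 0.645 − 0.324·⟨H⟩ (suppressed
for TM windows, whose position above that line does not carry the
surface-binding meaning). Windows firing no rule are globular — defined as
the complement of the three rules, not as a positively delimited polygon.
Labels are a set because real windows carry compound calls (e.g. D and S
at once).

### Assumptions

The score is only meaningful if the window actually folds as an α-helix;
the package does not predict secondary structure. When a per-residue
H/E/C annotation is available (from a predictor or a known structure), the
helicity gate demotes windows whose helix fraction is below a threshold
(default 0.5; a boundary-equal fraction passes). The gate is off by
default. The ideal-wheel assumption (exact 100° periodicity, no kinks or
curvature) and the fixed formal-charge model are inherited from the
moment-plot methodology.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| hydrophobicity scale | Fauchère–Pliška | dimensionless (kcal/mol-derived) | the scale HeliQuest uses; replaceable via a scale file, but any replacement must re-validate against the bundled reference set |
| window size N | 18 | residues | ≈ 5 helical turns, the length at which the bundled reference values were derived |
| δ | 100 | degrees/residue | α-helix periodicity; 18 × 100° = 5 full turns, which is why 18-mer homopolymers have exactly zero moment |
| D cutoff | 0.68 | — | lipid-binding call |
| TM cutoff | 0.75 | ⟨H⟩ | transmembrane call |
| surface line | 0.645 − 0.324·⟨H⟩ | ⟨μH⟩ | surface-seeking boundary |
| near band | 0.05 | same as the gated value | operationalizes "close vicinity" to a boundary; chosen so that exactly the one borderline reference window (Pam16 5–22, ⟨H⟩ = 0.735) is flagged and no other |
| helicity gate | 0.5, off by default | helix fraction | only applied when an annotation is supplied |
| step | 1 | residues | exhaustive scan |

Classification always uses full-precision values; rounding (⟨H⟩/⟨μH⟩ to 3
decimals, D to 2) happens only in reports, matching the precision at which
such values are conventionally published.

## Numerical and design choices

- **Strict boundaries, no tolerance.** "Above 0.68/0.75/the line" is
  implemented as `>`; boundary-equal values do not fire but do raise a
  near flag. This is documented rather than smoothed because the published
  call semantics are threshold crossings.
- **Moment convention.** n starts at 0 and the sum is divided by N. The
  implementation is numpy-vectorized; the test suite checks it against an
  independent pure-Python loop to 1e−12 on 1,000 random peptides, plus
  reversal invariance, the zero-moment property of 18-mer homopolymers,
  and invariance of μH (but a pure shift of ⟨H⟩) under adding a constant
  to the scale.
- **Non-canonical residues** (B, J, O, U, X, Z) have no scale value;
  windows containing them are skipped with a logged warning. Imputing a
  value would silently corrupt D.
- **Merging.** Maximal runs of span-overlapping positive windows become
  one region; the representative window maximizes D with ties broken
  toward the smaller start, so output is deterministic. Merging is
  insensitive to input order and idempotent. Hand-picked-window workflows
  are recovered with per-window output.
- **Reference errata.** The bundled 18-window reference set carries two
  documented deviations between the curated expected values and the values
  as originally published: one ⟨H⟩ with a dropped minus sign
  (−0.066 printed as 0.066) and one last-digit slip (0.182778 printed as
  0.182). The sequences are authoritative: z, μH and all D values
  reproduce exactly, and the sign correction follows from the scale sums.
  `check_reference` compares against the corrected values; the errata and
  original values are kept in `lbrscan.reference.ERRATA`. Two reference
  windows are labelled by spans of 17 and 19 residues in their names but
  print 18-residue sequences; the sequences are treated as authoritative.
- **Charge neutralization.** `neutralized_discrimination_factor` recomputes
  D with z increased by the number of acidic side chains assumed
  neutralized upon binding a negatively charged membrane (each removes one
  −1 charge; μH unchanged, so D rises by exactly 0.33 per residue). This
  models how a region just below the D cutoff can become lipid-binding in
  an anionic-membrane context.
- **Wheel convention.** Residue 1 at 0°, angles increase counter-clockwise,
  residue n at (n−1)·100° mod 360°. Windows longer than 36 residues reuse
  wheel positions (drawn slightly further out in figures).

## Synthetic data

The generator plants one window of a known class inside neutral flanks
(default 50 residues each side) so scanner recovery can be measured with
exact ground truth:

- background: residues drawn from {G, S, T, N, Q, A, P} with ~3% isolated
  alternating K/E — low hydrophobicity, near-zero charge, low moment;
- D class: an amphipathic template (L/I/F/V on one 180° wheel arc, K/R on
  the other) with net charge drawn from {+2, +3, +4}, the charge range of
  typical D-positive windows;
- TM class: hydrophobic-heavy draws from {I, L, V, F, A};
- S class: the amphipathic template with zero net charge;
- globular: background only.

Class membership is *verified*, never assumed: each planted window must be
confirmed by the classifier, and every window lying fully in the flanks
must classify globular (for the globular class, the entire sequence),
with rejection sampling capped at 10,000 attempts — the templates hit
their classes within a few draws, so the cap only catches
misconfiguration. A fixed seed makes output byte-identical.

Shuffle nulls are composition-preserving permutations: ⟨H⟩ and z are
conserved exactly, μH is not, which isolates the *arrangement* signal. The
test suite uses this both ways: a genuinely amphipathic window beats the
95th percentile of its 999-shuffle null, while a window whose D is carried
by charge alone (z = +4 gives D ≥ 1.32 regardless of arrangement) stays
D-positive under every permutation — D-positivity of charged windows is
partly a composition property, a caveat for interpreting scan hits.

What the synthetic material does **not** emulate: real mitochondrial
protein composition, evolutionary conservation, genuine secondary
structure, or membrane context. Passing recovery tests (≥95/100 planted
D and TM windows recovered across frozen seeds) shows the scanning and
merging machinery is correct, not that the thresholds generalize to
arbitrary proteomes.

## Problem sizes

The default test suite scans sequences of 18–200 residues, uses 1,000
random peptides for the moment-oracle check, 100 seeds per class for
planted-window recovery, and 999 permutations for the null comparison —
sizes at which every property is exercised while the whole suite runs in
seconds on one CPU. The acceptance script's quantities are single-window
computations and are exact at any size.

## Limitations

- No secondary-structure or topology prediction; the helicity gate relies
  entirely on user-supplied annotations.
- The fixed charge model ignores histidine protonation, terminal charges
  and pH; D near the cutoff can flip for His-rich windows under other
  charge models.
- Thresholds (0.68, 0.75, the surface line) are taken as given by the
  moment-plot methodology and are not re-fit; the package makes no
  accuracy claim beyond reproducing the reference calls.
- Coordinates of windows in full proteins depend on the exact input
  sequence (isoform, species); the bundled reference peptides are
  validated as stand-alone windows.
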