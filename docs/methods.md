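# Methods

## Problem setting

Protein-linked N-glycans of *Chlorella*-clade microalgae carry features
unknown from land plants or animals: arabinose, O-methylated sugars, and
recurring MALDI-TOF peak patterns ("glyco groups") that track phylogeny
better than morphology does. The analytically awkward core fact is an exact
isobar: a deoxyhexose weighs exactly as much as a pentose plus a methyl
group (146.05791 = 132.04226 + 14.01565 Da). A dominating [M+Na]+ ion at
m/z 1049.36 is therefore compatible both with the classic plant glycan
Man2GlcNAc2XylFuc (MUXF3) and with a methylated two-pentose glycan
(composition code os2221) — and two microalgal groups ("Raa", arabinose-
bearing, and "Now", xylose-bearing) share that major ion while having
entirely different structures. glycomark implements the desk-scale
inference chain that resolves this: composition assignment from peaks,
glycosidic fragment explanation, predicted methylation (linkage) analysis,
and satellite-peak fingerprint classification.

## Mass model

Residue (dehydrated) monoisotopic masses in Da: Hex 162.05282,
HexNAc 203.07937, Pent 132.04226, dHex 146.05791, CH2 (O-methyl) 14.01565;
water 18.01056; alditol increment (borohydride reduction) 2.01565; adducts
Na+ +22.98922, H+ +1.00728, -H -1.00728. Neutral mass = residue sum + water
(+ alditol if reduced); ion m/z = (M + z·shift)/z. Average masses, isotope
envelopes and elemental compositions are out of scope.

All constants carry exactly five decimals, so sums are computed in integer
units of 1e-5 Da and divided once (`exact_mass_sum`). This makes mass
equality of isobaric residue multisets *bit-exact*, not merely close —
swapping dHex for Pent+CH2 anywhere yields the identical float. Custom mass
tables that are not 5-decimal-exact fall back to `math.fsum`. Identities
that combine two independently rounded sums (B+Y complementarity,
C−B = water) hold to float noise and are tested at 1e-9 Da.

## Composition decomposition

`decompose` walks the bounded integer lattice (hex, hexnac, pent, dhex,
methyl) exhaustively with an upper-mass prune and returns every composition
whose theoretical ion m/z is within tolerance, ordered by |error| then
lexicographically. Defaults encode the glycans this workflow targets:
hex ≤ 9 (O-methylated oligomannosides up to Man9 occur), hexnac fixed at 2
(the chitobiose core), pent ≤ 3, dhex ≤ 1, methyl ≤ 9; MALDI tolerance
±0.3 Da (printed satellite values deviate up to ~0.06 Da from theory;
0.3 Da keeps them while excluding cross-class confusions at this mass
range). Both halves of any dHex/Pent+CH2 ambiguity within bounds always
co-occur in the output by construction.

## Structure model and grammar

Structures are rooted ordered trees of residues (identity, ring p/f,
anomeric a/b, natural O-methyl positions, parent-linkage carbon), written
non-reducing → reducing, branches bracketed before their attachment
residue, the root's linkage slot recording the reducing-end state
(`r` free, `ol` alditol). Canonical formatting puts the deepest child
inline (ties: lowest linkage position) and bracketed branches in ascending
position, so parse∘format is the identity on canonical strings. Validity
checks: no two children on one carbon, O-methyls on carbons 2–6 and never
on a bonded carbon. D/L configuration and 3-D geometry are not modelled;
anomeric configuration never affects mass. The two elucidated six-residue
structures and MUXF3 are built-in fixtures; the "Raa" fixture defaults to
the alditol (its NMR preparation was reduced) and can be switched to the
free reducing end, which is the species all printed MALDI values refer to.

## Fragment enumeration

Only glycosidic cleavages are modelled (B/C/Y/Z and, with two cuts,
internal fragments and doubly truncated Y ions); cross-ring A/X ions are
excluded because none are needed to explain the observed spectra. For a
residue-subset sum S: B = S + adduct, C = B + water, Y = S + water + adduct
(+ alditol when the precursor is reduced), Z = Y − water, internal =
S + adduct; all at z = 1. Enumeration cuts every edge and edge pair of the
tree; an independent test oracle instead enumerates all connected residue
subsets with ≤ 2 boundary edges, and the two routes must agree exactly.
The intact molecule counts as precursor, not fragment, so a linear chain of
n residues yields exactly 4(n−1) single-cleavage fragments. Fragment
intensities (including the strong observed bias between b- and c-type
peaks) are deliberately not predicted. Proton-adduct assignments are
flagged low-confidence because protonated glycans rearrange in the gas
phase; sodium adducts are the trusted channel. Annotation tolerance
defaults to ±0.3 Da (reflector MALDI LID, values printed to one decimal)
and ±0.05 Da for theory-vs-theory comparisons.

## PMAA prediction

Each residue maps to one descriptor: substitution positions = carbons
bearing child linkages (the residue's own anomeric attachment does not
count), plus its natural O-methyl positions. Labels follow the fixed
grammar "Terminal X" / "k-substituted X" / "j,k-di-substituted X" with an
optional "n-O-methyl" prefix, compared case-insensitively against observed
tables given as (label, count) rows. Ring form is dropped (the alditol
acetates are open-chain) and a reduced root reports as the plain sugar.
Retention times in the shipped observed tables are data for display only.
Conservation laws (descriptors = residues, terminals = leaves, total
substitutions = residues − 1) are property-tested on random trees.

## Fingerprints and classification

Reference profiles: "Raa" = major 1049.37 plus satellites 771.26, 903.31,
917.33, 1079.39, 1093.39; "Now" = major 1049.41 plus 873.30, 887.34,
903.32, 1035.39, 1197.46, 1211.47, 1359.51, 1373.49, 1521.56 (all [M+Na]+,
all carrying their composition codes). The published table prints the
two-pentose/one-hexose satellite as 837.30; that is arithmetically
impossible for its stated composition H1N2P2 (= 873.296) and the
accompanying text reads 873.3, so the profile uses 873.30. No reference
intensities are published anywhere, so one free parameter covers them:
every minor peak defaults to 0.15 of the base peak (overridable).

Similarity is a matched-filter cosine: greedy nearest-neighbour matching of
observed to reference peaks within ±0.3 Da (ties toward the lower-m/z
reference), dot product of matched intensity pairs divided by the product
of full-vector norms; unmatched peaks dilute the score but contribute no
overlap. The score is 1 exactly for identical normalized patterns and is
invariant to uniform intensity rescaling. Classification is the argmax over
profiles with deterministic tie-breaks (matched-peak count, then name).
Because both groups share the isobaric major ion, a spectrum stripped to
its major peak scores nearly equally against both profiles: the mean
classification margin drops from ≈0.12 to ≈0.036, the small residue coming
from the different profile norms rather than from any discriminating
signal. This is the quantitative form of the founding observation that the
dominant mass alone cannot separate the groups.

## Synthetic data

`simulate_profile_spectrum` draws one peak per profile entry with additive
Gaussian m/z error (default σ = 0.05 Da, matching the few-hundredths-Da
scatter of the printed major-peak values), multiplicative mean-one
log-normal abundance noise (CV 0.3; log-normal keeps intensities positive),
plus 5 uniform-random noise peaks over m/z 700–1600 (the displayed spectral
window) with abundance ≤ 0.1 of base. `simulate_msms` Bernoulli-thins the
theoretical fragment list (detection probability default 0.8) and perturbs
masses the same way. All draws come from `numpy.random.default_rng` under
an integer seed; identical seeds give identical spectra on any platform.
The generators emulate peak positions and rough relative abundances only —
no isotope envelopes, detector saturation, baseline, matrix clusters or
mixture effects — so passing the end-to-end test demonstrates that the
pipeline recovers the generating group under the stated noise model, not
that real spectra of new samples will classify this reliably. At σ = 0.05,
5 noise peaks and 500 replicates per group the simulate→classify loop
assigns ≥ 95 % of spectra to their generating group (in practice ~100 %;
the satellite sets of the two groups barely overlap). These problem sizes
keep the whole suite in the low seconds.

## Numerical and degenerate-input choices

Zero tolerance, zero charge, empty peak lists for similarity, and malformed
codes/structures raise ValueError subclasses with the offending token or
line number. Empty decomposition lattices return empty results (not
errors). Peak lists sort canonically by m/z and reject exact duplicates and
negative intensities. All orderings (decomposition candidates, fragments,
assignments, classification ranking) have total, documented sort keys so
every output is reproducible byte for byte.

## Known limitations

- Reference profile intensities are a modelling convention (flat 0.15);
  classification margins, though not the ranking logic, depend on it.
- The "Now" reference derives from a commercial sample that DNA barcoding
  showed to be a mixture (predominantly Scenedesmaceae plus one *Chlorella
  lewinii* clone); whether it represents a pure-strain pattern is unknown.
- Consecutive gas-phase losses and rearrangements are outside the ≤2-cut
  fragment model; some published ESI sequence ions (e.g. a protonated
  methylpentose–hexose–HexNAc ion) are therefore not enumerated.
- Only Hex/HexNAc/Pent/dHex/CH2 chemistry is supported; sialic acids,
  uronic acids and sulfate/phosphate are absent from this glycan family
  and from the code.
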