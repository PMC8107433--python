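# glycomark

Mass-spectrometric characterization and chemotaxonomic fingerprinting of
small, O-methylated, pentose-bearing N-glycans — the glycan family found on
microalgae of the *Chlorella*/*Scenedesmus* clades.

## The problem

MALDI-TOF MS of microalgal N-glycan pools yields a composition per peak in
terms of hexoses (H), N-acetylhexosamines (N), pentoses (P) and methyl
groups (me) — the 4-digit code `os2221` means H2 N2 P2 me1. But a
deoxyhexose is *exactly* isobaric with a pentose plus a methyl group
(146.05791 = 132.04226 + 14.01565 Da), so the dominating microalgal
[M+Na]⁺ ion at m/z 1049.36 is mass-identical to the classic plant glycan
Man₂GlcNAc₂XylFuc (MUXF³) — and two different microalgal glyco groups
("Raa", arabinose-bearing, and "Now", xylose-bearing) share it while having
entirely different structures. Resolving such peaks takes the full chain:

1. **glycomath / decomposer** — monoisotopic arithmetic over compositions
   and exhaustive bounded decomposition of observed m/z values, surfacing
   every isobaric reading;
2. **topology** — a rooted-tree model and linear grammar for fully
   specified structures (the two elucidated six-residue structures and
   MUXF³ ship as fixtures);
3. **fragmenter** — Domon–Costello B/C/Y/Z (+2-cut internal) glycosidic
   fragment enumeration and MS/MS annotation;
4. **pmaa** — predicted methylation (linkage) analysis: one partially
   methylated alditol acetate descriptor per residue, compared as
   label-count multisets against observed GC-MS tables;
5. **fingerprint** — satellite-peak profiles of the "Raa" and "Now" glyco
   groups and a matched-cosine classifier;
6. **synthetic_data** — seeded generators of MALDI-style peak lists and
   MS/MS spectra so the whole pipeline is testable without instrument data.

For a topology *T* with residue-subset mass S, singly charged fragment
masses follow B = S + Na, C = B + H₂O, Y = S + H₂O + Na (+2H if reduced),
Z = Y − H₂O. Classification scores an observed peak list against each
reference profile by greedy nearest-neighbour peak matching within ±0.3 Da
followed by a cosine over matched intensities (unmatched peaks dilute the
score); the group call is the argmax.

## Worked example

```text
$ glycomark mass os2221
composition os2221
neutral mass 1026.3751 Da
[M+sodium]1: m/z 1049.3643
```

The sodiated major ion of the methylated two-pentose glycan computes to
1049.3643 Th. Decomposing that observed mass shows the isobaric ambiguity —
both the plant-type H2N2P1F1 (MUXF³) and os2221 match within 0.7 mDa:

```text
$ glycomark decompose 1049.365
1049.3650	H2N2P1F1	1049.3643	-0.7
1049.3650	os2221	1049.3643	-0.7
```

Only the satellite peaks separate the glyco groups. Simulate a noisy "Now"
spectrum (σ = 0.05 Da, 5 noise peaks) and classify it:

```text
$ glycomark simulate profile Now --seed 7 --out now7.tsv
wrote 15 peaks to now7.tsv
$ glycomark classify now7.tsv
best	Now	margin	0.1001
Now	0.9907	10 matched
Raa	0.8906	2 matched
```

All 10 "Now" reference peaks matched (similarity 0.9907); "Raa" only picks
up the shared major ion and the shared 903.3 satellite. Finally, predicted
linkage analysis of the arabinose-type structure reproduces its observed
PMAA table exactly — two terminal arabinoses, a 4-substituted 3-O-methyl
mannose, a 3-substituted mannose, and the 4- and 3,4-substituted core
GlcNAcs:

```text
$ glycomark pmaa Raa --observed Raa
3,4-di-substituted GlcNAc	1
3-substituted mannose	1
4-substituted 3-O-methyl mannose	1
4-substituted GlcNAc	1
Terminal arabinose	2
match vs Raa: yes
```

The same chain is available as a library (`glycomark.decompose`,
`glycomark.enumerate_fragments`, `glycomark.classify`, ...) and as a single
`glycomark report peaks.tsv --structure Raa` call producing a JSON +
human-readable report.

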