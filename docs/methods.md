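# Methods

This note records the models, parameters, and numerical choices behind
`glycotrace`, in the order the pipeline applies them.

## Deamidation-trace site calling

PNGase F releases N-glycans and converts the glycosylated asparagine to
aspartate. Search engines report this as deamidation (+0.984016 Da) on
Asn, written here as lowercase `n` in the peptide string. A site call
requires two things: a deamidated Asn, and a valid sequon N-X-S/T (X ≠ P)
at that position.

Sequon validity is resolved against protein context when a proteome
(FASTA) is supplied: a tryptic peptide ending at the Asn or at X still
gets its S/T checked in the protein. In peptide-only mode the same
situation is reported as `unresolved` rather than guessed. Deamidated
Asn outside any sequon (spontaneous chemical deamidation) is kept in a
separate `invalid_sequon` channel, never called as a glycosite. Peptides
matching more than one protein produce calls at every location, flagged
`ambiguous`. Evidence from multiple peptides covering the same protein
position is merged into one call; the call's ratio class comes from the
evidence peptide with the highest WT intensity.

## Comparative quantification

Each peptide carries WT and KO intensities (or a pre-computed ratio). A
value counts as detected when it is positive and at or above the
detection limit. Bins:

| class      | condition                |
|------------|--------------------------|
| `WT_ONLY`  | detected in WT only      |
| `HIGH`     | ratio > 4                |
| `MODERATE` | 1 < ratio ≤ 4            |
| `UNCHANGED`| ratio ≤ 1                |
| `KO_ONLY`  | detected in KO only      |

Boundaries are deliberate: exactly 4 is `MODERATE`, exactly 1 is
`UNCHANGED` (the enriched bins use strict lower inequalities). Thresholds
are configuration (`t_high`, `t_low`), not constants.

## Mass arithmetic

Monoisotopic residue masses ship as a data file with 8 decimal places,
generated from atomic masses; rounding a 30-residue peptide's residue
masses at fewer decimals can accumulate error above 1e-6 Da, which the
test suite's independent elemental-composition oracle would catch. The
deamidation delta is defined as mass(D) − mass(N) from the same table
(0.98401558 Da) so that annotating `n` and substituting D are exactly
equivalent. Water 18.010565, proton 1.007276; monosaccharides
HexNAc 203.07937, Hex 162.05282, Fuc 146.05791, NeuAc 291.09542.
Tolerance checks (`ppm` for precursors, `mmu` for fragments) treat the
boundary as inclusive.

## Glycopeptide verification

Theoretical precursors are [M+zH]z+ for the modified peptide plus glycan.
An extracted-ion chromatogram sums, per MS1 spectrum, all peaks within
the ppm tolerance of the target, recording an explicit zero when none
match, so the apex is taken over a dense retention-time grid. Spectrum
averaging over a retention window merges peaks within a ppm tolerance
(intensity-weighted m/z, intensity divided by the number of spectra).

Y ions are enumerated as every subcomposition of the glycan — counts per
charge are Π(countᵢ + 1) over the monosaccharide types — attached to the
intact modified peptide; oxonium ions come from a fixed list of small
glycan fragments restricted to the composition. MS2 annotation is greedy:
candidate (template, peak) pairs within the mmu tolerance are sorted by
absolute error (charge as tie-break) and assigned one peak per template,
each peak used at most once, which makes the result independent of input
peak order. A spectrum is flagged as bisecting-diagnostic when an
annotated Y ion retains at least 3 HexNAc with at most 1 Hex — a heavy
HexNAc remnant on a trimmed core that a non-bisected glycan cannot
produce.

## Motif analysis

Windows of ±k residues (default k = 5) around each called Asn are
stacked; positions outside the protein or peptide are padded and excluded
from the counts. Per-offset information content is log2(20) minus the
Shannon entropy of the residue frequencies, with the standard
small-sample correction 19 / (2·ln 2·n) subtracted (clipped at zero),
which puts offsets with unequal effective sample sizes on one scale.

The permutation null pools all residues at scored offsets, sorts the pool
(so the null depends only on composition, not window order), reshuffles,
and redeals into the same slots. The null statistic per permutation is
the **maximum** corrected IC across scored offsets; each observed offset's
p-value is the add-one fraction of permutations whose max reaches it,
then Bonferroni-adjusted across scored offsets. Offsets 0 (the Asn) and
+2 (the sequon's S/T) are conditioned on by selection and excluded from
scoring. The verdict is "motif" iff the minimum adjusted p ≤ α (default
0.05). This max-statistic null is conservative by construction; the test
suite checks both its calibration (false-positive rate ≤ 10% at α = 0.05
on uniform windows) and its power (a fully penetrant planted residue is
always detected).

## Synthetic data generator

The generator emulates the enrichment experiment, not the instrument in
full detail. Defaults are study conditions, fixed before any evaluation:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 30 | random proteomes, uniform residues, planted sequons (every protein gets ≥1 valid sequon) |
| intensity | LogNormal(μ=14, σ=1) | ln-scale, standard for label-free MS |
| `ko_suppression` (δ) | 0.02 | KO = δ·WT·exp(ε), ε ~ Normal(0, 0.3) |
| `ratio_noise_sigma` | 0.3 | biological/technical spread of the WT/KO ratio |
| `contaminant_survival` | 0.2 | fraction of non-glycosylated peptides passing enrichment |
| `spontaneous_deamidation` | 0.005 | per-Asn chemical deamidation rate |
| detection limit | 5th percentile of KO draws | intensities below it become absent |
| `ppm_jitter` | 2.0 | uniform ±ppm mass error on planted peaks |
| RT model | Gaussian, σ = 0.15 min, grid 0.1 min | precursor elution profile |

KO intensities are modeled as a correlated multiple of WT rather than an
independent draw: enrichment depletes the same molecules in both
conditions, and an independent-draw model cannot produce the observed
"nothing HIGH when δ = 1" behavior. Bisecting status is assigned per
glycopeptide (not per site) because the enrichment step selects peptides;
this keeps site-level ground truth coherent with peptide-level selection.
PNGase F conversion of glycosylated Asn is treated as certain. MS2
spectra contain the full Y-ion ladder (z = 1), oxonium ions, and
uniform-random noise peaks.

Recovery scoring treats a site as predicted when its call is classified
`WT_ONLY` or `HIGH`, and scores sensitivity/precision against the planted
bisected sites. With all noise processes off, recovery is exact up to
genuine peptide-sharing ambiguity (a short tryptic peptide occurring
verbatim in two proteins yields an ambiguous extra call).

## Numerical and format choices

- All randomness flows through `numpy.random.default_rng` seeded from
  configuration; derived seeds stay below 2^31.
- The permutation scan is vectorized (tiled pool, `rng.permuted`,
  bincount reshape), so hundreds of 1000-permutation scans run in
  seconds.
- Spectra travel as JSON-lines (one spectrum per line) with MGF export
  for MS2; mzML is deliberately out of scope and noted as an adapter
  point. Peptide tables are TSV; proteomes are FASTA via Biopython.
- Non-goals: search-engine scoring, FDR estimation, retention-time
  prediction, and glycan structure (as opposed to composition) modeling.
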