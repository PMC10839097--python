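# Methods

This note documents the models, parameter choices and numerical conventions
behind each pipeline stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Coordinates and I/O

All public coordinates are 1-based inclusive (the GFF3 convention); internal
half-open arithmetic never reaches reports. FASTA reading folds sequence to
upper case and rejects duplicate IDs and out-of-alphabet residues with the
record and position named. GFF3 parsing keeps one gene model per gene, using
the first-listed mRNA when several exist — real annotations rarely mark a
canonical isoform, and surveys of this kind treat one model per gene; this
is our convention, not a biological claim. The CDS anchor (`cds_start`) is
the minimum CDS coordinate on the plus strand and the maximum on the minus
strand, i.e. the first coding base in translation order.

## Finger detection and set classification

The detector is a deterministic pattern matcher, not a profile HMM. The
default pattern `C-x(2,4)-C-x(12)-H-x(3,5)-H` is the canonical C2H2 spacing;
a relaxed variant `C-x(1,5)-C-x(9,14)-H-x(2,6)-H` is selectable for
degenerate fingers. A pattern matcher is reproducible without external
profile files and has exactly specifiable semantics: scanning proceeds left
to right, at each cysteine anchor the shortest legal match is taken (first
gap minimised, then the last), and scanning resumes after the final
histidine, so overlapping candidates and shared histidines are resolved
deterministically. The cost is sensitivity: a real proteome's degenerate
fingers scored by an HMM may be missed, so family counts on real data are
not expected to match any particular published tally.

Linkers are measured between pattern-delimited finger ends (last H to next
C, exclusive). The tandem-array threshold is ≤ 10 residues, the consensus
definition for C2H2 arrays (five residues is the most frequent linker);
arrays need ≥ 2 fingers. Set labels: one array → A, several → B, none → C;
proteins with zero fingers are outside the family.

## Physicochemical profiling

Molecular weight uses average residue masses plus one water (18.015 Da),
with `X` rejected because its mass is undefined. The theoretical pI is found
by bisection (tolerance 0.001 pH) on the Henderson–Hasselbalch net charge
over C, D, E, H, K, R, Y and the termini; the net charge is strictly
decreasing in pH and brackets zero on [0, 14], so bisection always
converges. The default pKa set is EMBOSS's (N-term 8.6, C-term 3.6, C 8.5,
D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1); the Bjellqvist/ExPASy-style
set is selectable. Published pI values computed with other tables typically
differ by a few tenths of a pH unit — comparisons across tools should use
matching tables. The instability index is Guruprasad's dipeptide sum,
II = (10/L)·Σ DIWV(xᵢ, xᵢ₊₁), with II ≤ 40 called stable; the aliphatic
index is X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in mole percent; GRAVY is
the mean Kyte–Doolittle hydropathy with GRAVY < 0 called hydrophilic.

## Ka/Ks (NG86 with Jukes–Cantor correction)

Inputs are pre-aligned in-frame codon pairs (equal length, no internal
stops). Per codon, synonymous sites are (synonymous single-base mutants)/3,
mutants to stops counting as nonsynonymous, so s + n = 3 exactly. Observed
differences are split by averaging over all orderings of the differing
positions; orderings through a stop are excluded and the average
renormalised (if every ordering hits a stop, all are kept with stop steps
counted nonsynonymous, so the pair remains countable). Site counts are
averaged over the two sequences; pS and pN are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4 (saturation error). The
method name (`NG86+JC69`) is recorded in output because different Ka/Ks
tools use different models and their values are not interchangeable.

Report rounding is 4 decimals, half-up. When Ks = 0 the ratio is undefined
and reported as such; a compatibility flag prints 0.0000 instead, matching
the convention of some duplicated-pair tables. Selection calls: ratio < 1
purifying, = 1 (±1e-9) neutral, > 1 positive.

A subtlety worth recording: even when every accepted mutation in the
generating process is synonymous, NG86's pathway averaging can attribute a
small nonsynonymous fraction to codons hit at two positions, because some
orderings pass through nonsynonymous intermediates. Ka under a purely
synonymous history is therefore near zero, not identically zero.

## Duplication detection

Genes are ranked by start coordinate per chromosome. Tandem: same
chromosome, rank distance ≤ 2 (at most one intervening gene), the adjacency
convention of collinearity toolkits. Segmental: both genes of a pair anchor
the same collinear block. Blocks are found per chromosome pair by a
longest-chain dynamic programme over anchors, monotone in both rank axes
(increasing, or decreasing for inverted blocks), with consecutive gaps ≤ 25
ranks on both axes and ≥ 5 anchors; longer chains claim anchors first, ties
broken by leftmost start. This is chain extraction without per-gap
substitution scores — deterministic and sufficient to recover planted
blocks exactly; it is not a reimplementation of any particular toolkit's
scoring. Homologous pairs are an *input* (a TSV), so detection does not
depend on an external aligner. Tandem takes precedence over block
co-membership when both apply.

## Promoters and cis-elements

The promoter is the 2000 bp upstream of the CDS start (not the transcript
start): plus strand `[cds_start−2000, cds_start−1]`, minus strand
`[cds_start+1, cds_start+2000]` reverse-complemented, clipped and flagged
at chromosome ends. Elements are IUPAC motifs scanned on both strands; all
overlapping occurrences are reported; `N` in the sequence never matches; a
palindromic pattern matching the identical interval on both strands is
counted once. The bundled table is a package-authored set of 26
PlantCARE-style plant elements mapped to five functional categories
(transcription, hormone, stress, development, cell cycle); its patterns
were chosen free of substring/reverse-complement cross-matches so planted
counts are recoverable exactly. Users supply their own table for real
analyses. Category percentages count occurrences (not element types) and
are reported to 1 decimal, half-up.

## Gene structure, SSRs, primers

Introns per gene = exons − 1, binned {0, 1–2, 3–10, >10} with percentages
to 1 decimal. SSRs are maximal perfect repeats of a primitive 1–6 bp unit
with MISA-style minimum repeat numbers (10/6/5/5/5/5 for unit lengths
1–6); units are reported as the lexicographically smallest rotation, and
nested or overlapping runs are merged to the maximal one. Primer QC reports
length, GC% (printed without decimals when integral, as primer tables do)
and a SantaLucia-1998 nearest-neighbor Tm at 50 mM monovalent salt and
500 nM oligo; Tm is informational — published annealing temperatures come
from unstated formulas and carry no acceptance claim here.

## Expression and qPCR

Bias classification: a gene is not expressed when no sample reaches the
floor (default 1.0, TPM-like); otherwise replicate means per (phenotype,
stage) are averaged over the four stages per phenotype, a pseudocount of
floor/10 is added to both means, and fold = F/M decides F-biased (≥ 1.5),
M-biased (≤ 1/1.5) or unbiased. All three constants are config. The fold
rule itself is scale-free; the floor and pseudocount are on the data scale,
so strict invariance under global rescaling holds when the floor is
rescaled with the data. No p-values are computed — the stage classifies, it
does not test. qPCR: ΔCT = CT_target − CT_reference per sample, ΔΔCT
subtracts the calibrator group's mean ΔCT, RQ = 2^−ΔΔCT; per-group mean and
sd are reported, and the RQ at the calibrator group's mean is exactly 1.
Reference gene and calibrator group are required inputs.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed) and serialize their
ground truth as JSON sidecars. Defaults mirror the survey's shape: a
27/3/70 A/B/C proteome; 9 chromosomes × 50 genes with 2 planted tandem
pairs and 9 duplicated segments of 6 anchors; codon pairs at chosen ω with
synonymous divergence targeted at 0.3 (safely below Jukes–Cantor
saturation); promoter sets with exact planted element counts; a 100-gene
expression matrix with 23 F-biased, 15 M-biased and 13 silent genes at
fold 4 and lognormal noise CV 0.2 over 2 phenotypes × 4 stages × 3
replicates; qPCR CTs with 0.1-cycle noise. Where the survey fixes no value
(fold 4, noise CV 0.2, block size 6, baseline ≈ 20 TPM), the defaults are
ordinary magnitudes for plant RNA-seq and collinearity analyses, chosen
once.

Deliberate simplifications: proteome background excludes C and H so planted
fingers are unambiguous (a full-alphabet hard mode would define truth by
coordinates instead); the codon simulator is mutation–acceptance (uniform
proposals accepted with probability 1/ω/0 for synonymous/nonsynonymous/
stop), not a continuous-time Markov chain with branch lengths; genome
sequence is uniform random with regularly spaced genes; promoter
backgrounds are scrubbed of accidental motif matches; expression noise is
i.i.d. lognormal with no library-size or dispersion structure. Passing
recovery tests therefore demonstrates correctness of the implementations
under their stated definitions — not detector sensitivity on degenerate
real fingers, robustness to noisy homolog lists, or power under realistic
RNA-seq dispersion.

## Problem sizes

The test suite and the acceptance script run at the survey's own scale:
100-protein proteomes, 450-gene genomes, 3000-codon pairs × 20 replicates
per ω, 50-promoter element sets, 100 × 24 expression matrices. The full
synthetic end-to-end run (simulate + all stages) completes in seconds.

## Known limitations

- The pattern matcher is not an HMM; real-proteome family counts depend on
  scoring thresholds no pattern can express.
- NG86 is a counting method; for deep divergence or strong codon bias a
  maximum-likelihood codon model would differ (out of scope).
- Collinearity chaining has no substitution/gap scoring, so borderline
  blocks that a scored DP would split or merge may differ.
- Codon-alignment construction, homolog discovery and figure rendering are
  inputs or external concerns, not pipeline stages.
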