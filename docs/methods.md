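# Methods

`microintron` re-implements, as a tested pipeline, the analysis that
identifies, screens and validates evolutionarily conserved ultra-short
(≤65 nt) pre-mRNA introns: intron extraction under the GT–AG rule,
length-distribution thresholding, a dual local-alignment conservation
screen, splice-junction read evidence, intron-retention/NMD consequence
analysis, splice-signal scoring, G-rich/ISE sequence features, and
integration into a per-candidate evidence report.

## Intron extraction and the GT–AG rule

Transcript models are ordered exon intervals (0-based, half-open,
genomically ascending) with an optional CDS interval; GFF3's 1-based
inclusive coordinates are converted on read, BED12 is native. One intron
is extracted per gap between consecutive exons; on the minus strand the
sequence is reverse-complemented and intron numbers count from the
transcript's 5′ end, so numbering always follows transcription order. An
intron is *canonical* iff it begins `GT` and ends `AG`; an `N` at a
terminal position is conservatively noncanonical. Region assignment
(CDS / UTR5 / UTR3) is by CDS overlap, with a gap abutting a CDS boundary
assigned CDS whenever either junction-adjacent exonic base is coding —
retention there would interrupt codons. Transcripts whose CDS spans the
full exonic extent carry a `partial` flag (no annotated UTR), as do
transcripts explicitly marked partial by the source.

## Length distribution and threshold detection

Canonical and noncanonical introns are counted per length up to 949 nt
(the plotted domain of the human distribution), and the
noncanonical/canonical ratio curve is formed, left undefined (not
imputed) at lengths with zero canonical count. In human data this ratio
rises sharply below ~65 nt, the signature of *false introns* —
artifactual alignment gaps over-fitted to the GT–AG rule. The published
threshold was chosen by visual inspection; here it is operationalized as
a two-window mean-difference changepoint: the detected threshold is the
length T maximizing mean(ratio on [T−w, T]) − mean(ratio on (T, T+w])
over defined points, with window w = 10 nt and search range 40–120 nt,
ties broken toward smaller T. A candidate T requires at least w defined
points per side; if none qualifies, a `NoThresholdError` is raised.
Introns ≤65 nt are classed *ultra-short*, 66–85 nt *short*. The peak
estimator is simply the argmax of the canonical counts.

## Conservation screen

The screen mirrors a dual BLAST strategy at desk scale. Hits are tabular
records (an outfmt-6 dialect with an appended species column). A
mapping-error pre-filter discards any transcript whose best self-species
hit (lowest E-value) contains gap columns, the operational meaning of
"erroneously mapped with insertions/deletions" (no numeric rule exists
in the source). Hits are then filtered with the printed bound senses
honored exactly: alignment length **> 55**, bit score **> 99**, E-value
**≤ 1e-19**, identity **≥ 96 %** (all configurable); an intron is
*conserved* only when the same species survives in both the
transcriptome-targeted and genome-targeted searches for that intron.
Conserved introns ≤65 nt hosted by non-partial transcripts form the
candidate set — an apparent ultra-short intron in a partial transcript
cannot be distinguished from a truncation artifact.

`local_align` provides a self-contained stand-in for BLAST so the screen
is testable end-to-end: Smith–Waterman local alignment
(Bio.Align.PairwiseAligner) with match +1 / mismatch −2, affine gaps
(open −5, extend −2), wrapped in Karlin–Altschul statistics
bits = (λS − ln K)/ln 2 and E = m·n·2^(−bits) with ungapped DNA defaults
λ = 1.28, K = 0.46. These constants are an approximation — E-values here
gate a filter, not a publication claim — and are configurable. Identity
is computed over all aligned columns, gap columns included.

## Junction read evidence

For each intron a junction fragment is built from exon sequence only:
the last F nt of the upstream exon concatenated to the first F nt of the
downstream exon (default F = 42, i.e. read length 50 minus the minimum
anchor 8), truncations recorded. A read (or its reverse complement)
supports a junction when it aligns ungapped within the fragment with at
most 1 mismatch (default) and covers ≥8 nt on *both* sides of the
breakpoint; the double anchor makes support from unspliced pre-mRNA
impossible for exact reads, since the breakpoint-spanning sequence does
not exist in the genome. A junction is called spliced in a sample at ≥1
supporting read (configurable); across samples, junctions are labelled
*ubiquitous* (all samples), *tissue-specific* (some) or *none*. Matching
is ungapped by design — fragments are short and indels are out of scope
at this scale.

## Retention consequences and NMD

For each intron a retained-mRNA model is built: all other introns
spliced, the target retained; junction offsets downstream of the
retained intron shift by its length, as do the CDS start and the native
stop when they lie downstream of the insertion point. Frame effect is
classed by length mod 3 (UTR introns: not applicable). The retained CDS
is translated codon-by-codon from the annotated start; the first stop
codon that is not the annotated native stop is the premature termination
codon (PTC) — "premature" is defined relative to the pre-retention stop
because the source gives no operational definition. The mRNA is an NMD
target iff a PTC exists, at least one exon–exon junction lies downstream
of it, and the 3′-most junction is more than a boundary distance
downstream. The boundary defaults to 50 nt (the permissive end of the
50–55 nt rule) and is configurable up to 55; the call is monotone in the
boundary. A retention with no PTC returns a negative call rather than an
error.

The packaged `retention_facts.tsv` records, for each of the 22
candidates, the frame class implied by its length and region, the single
in-intron stop codon, and the PTC position category (beyond the boundary
upstream of the last junction, downstream of the last junction, or no
PTC). `nmd_targets_from_facts` realizes each category as representative
retained-mRNA offsets and applies the same `nmd_classify` rule; on this
table the rule yields 15 NMD targets.

## Splice-signal scoring

Donor (positions −3..+6, 9 nt) and acceptor (−14..+1, 16 nt) sites are
scored with a Shapiro–Senapathy-style percent score from a
position-weight matrix trained on a provided site collection (≥20 sites,
pseudocount 0.5): t = Σ freq[base], score = 100(t − t_min)/(t_max −
t_min) over the column minima/maxima sums, so the column-consensus site
scores 100 and the anti-consensus 0; `N` contributes the column minimum.
The exact windows used by published web scorers are not documented, so
the window coordinates are configuration, not claims.

Donor strength is additionally summarized as the free energy of the
duplex with the U1 snRNA 5′ end (template 3′-GUCCAUUCA-5′ opposite
positions −3..+6). The energy model is a nearest-neighbor stack table
derived from base-pair strengths (G-C 3.3, A-U 2.1, G·U wobble 1.0
kcal/mol): adjacent paired positions contribute −(s₁+s₂)/2 and
mismatches contribute nothing. The absolute scale is approximate by
construction; only orderings are asserted anywhere (the perfect
complement `CAGGTAAGT` is the verified unique minimum over all 4⁹
donors, and every single mutant is strictly weaker).

Branch sites are all matches (overlapping included) of the human
consensus (C/T)T(N)A(C/T); the per-intron scan uses the last 40 nt of
the intron excluding the final 3 nt (the acceptor itself), a convention
— the source shows branch points near the 3′ end but states no window.
The bare scanning operation applies no 3′ exclusion so that it equals a
plain regex oracle.

Raw scores are calibrated as mid-rank percentiles (fraction strictly
below plus half the ties) against reference score collections; ΔG
percentiles are computed on −ΔG so larger is always stronger. A signal
is flagged *inefficient* iff every percentile in its pair — (S&S, ΔG)
for donors, (S&S, branch) for acceptors — is below 0.1 or NA; one value
at or above 0.1 clears the flag. Maximum-entropy and comparative scoring
models published elsewhere are out of scope; the pair structure of the
decision rule is preserved with implementable components.

## Sequence features

Base composition reports exact counts with every tied most-frequent base
(`N` tallied separately and excluded from fractions); G-runs are maximal
runs of ≥3 G reported once at full extent. The 11-nt intronic splicing
enhancer CAGGGGCTGGG is searched by unit-cost edit distance: every
window within 2 edits (configurable) is a candidate, reduced to the best
non-overlapping windows (smallest distance, then leftmost). Two edits
preserve both G-triplets of the motif in most cases, which is the
operational meaning adopted for "highly homologous". Per-length-class
G-content is reported as the mean G fraction with n (mean, not median,
chosen where the source is silent).

## Synthetic data generator

The generator emulates the study conditions with known ground truth. Its
defaults:

| parameter | default | rationale |
|---|---|---|
| n_genes | 200 | desk-scale genome (~0.5 Mb) |
| introns_per_gene | 6–10 | human average ≈ 8 introns/gene; gives per-length counts dense enough for changepoint estimation |
| exon_length | 80–160 nt | typical internal exon sizes |
| p_ultra_short | 0.40 | planted ultra-short share; enriches the screened range the way the curated candidate set does |
| ultra_short_range | 38–65 nt | the observed candidate range |
| short mode | log-normal, median 85 nt, σ 0.25, truncated to (65, 300] | the narrow short-intron mode; truncation by rejection keeps the mode near 85 |
| long mode | log-normal, median 2000 nt, σ 0.6, p = 0.08 | the broad long-intron mode, down-weighted for desk scale |
| false_intron_rate_below_threshold | 0.5 | sub-threshold noncanonical/canonical ratio ≈ 1, the qualitative magnitude of the observed rise |
| g_fraction ultra-short / short | 0.40 / 0.25 | the G-content gradient |
| ise_insertion_rate | 0.25 | a minority of ultra-short introns carry the ISE |
| splice_frequency | 0.9 | typical per-intron splicing rate |
| p_partial | 0.05 | occasional UTR-less transcripts |
| ortholog identities | 98 % / 97 % (conserved), 90 % (non-conserved) | clear separation around the 96 % screen threshold |
| read_length / coverage / error_rate | 50 nt / 20× / 0.005 | short-read archive conditions |

Genes carry GT–AG termini on all true introns; false introns
(noncanonical termini) are injected only at lengths ≤ the planted
threshold. A start codon is planted at the CDS start and a stop at the
CDS end. Ortholog hit tables mutate the transcriptome query
(concatenated 60-nt flanking exons) and the genomic query (intron plus
flanks) to the planted identity with exact substitution counts, then
align them with `local_align`; introns are planted conserved only up to
120 nt, mirroring a screen that targets the short range. All generators
draw from one root seed through fixed per-stream spawn keys
(`SeedSequence([seed, stream_id])`), so outputs are byte-identical under
a fixed seed and each generator is reproducible in isolation.

What the generator does **not** emulate: real human sequence content or
codon structure beyond the planted start/stop, insertions/deletions in
orthologs (identities are substitution-only), splice-site or branch
motifs inside synthetic introns, expression-level variation between
samples, and RT-PCR chemistry (experimental outcomes enter only as
recorded evidence flags). Passing recovery tests therefore demonstrate
the correctness and power of the screening logic under controlled
conditions, not performance on real annotation databases.

## Numerical choices and degenerate inputs

Ties in threshold detection break toward smaller T; a flat ratio curve
returns the lower search bound. Undefined ratio points are skipped,
never imputed. Percentiles use the mid-rank convention. Species names
compare case-insensitively after trimming. Zero-length junction flanks
are skipped with a warning; a missing ATG at a CDS start warns but the
PTC scan proceeds; inconsistent CDS annotation during the retention
report is a per-record error that does not abort the run. Reported
identity percentages include gap columns in the denominator.

## Known limitations

The genome-scale discovery counts of the original study depend on
2006-era database versions and are not reproducible here; discovery-side
guarantees are property-based on synthetic data. Printed per-candidate
signal scores from the original web scorer are version-dependent and are
not asserted; the scoring surface is validated by construction
(consensus extremes, brute-force energy minimum, oracle-equal branch
scan) instead. The junction matcher handles single junctions only (no
multi-junction reads, no indels), and the alignment stand-in uses
ungapped Karlin–Altschul constants for an affine-gap alignment, which is
a documented approximation.
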