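# Methods

## The integration event being modelled

A PiggyBac-family transposase excises an ITR-flanked cargo and inserts
it at a TTAA tetranucleotide, duplicating the motif so one full TTAA
copy flanks each side of the cargo (target-site duplication, TSD). In
coordinates: if the pre-insertion chromosome has the motif at 0-based
positions `s..s+3`, the modified chromosome is
`prefix(..s+4) + cargo + TTAA + suffix(s+4..)` — the prefix already ends
with the original motif copy. The reported *junction interval* is the
1-based pair `(L, L+1)` with `L = s+4`: the two genome bases bracketing
the insertion point, immediately downstream of the TSD. Reverse
orientation inserts the reverse complement of the cargo; excising the
cargo plus exactly one TSD copy restores the original chromosome
byte-for-byte (a tested inverse).

The TSD motif is configurable; TTAA is the default because it is the
defining PiggyBac target. TSD detection in the caller is advisory: a
call without the motif is still reported (transposons occasionally
integrate atypically), it simply carries no TSD annotation.

## Read simulation

Fragments are drawn uniformly over positions and strands with length
~ Normal(350, 30) bp (clamped at the read length); mate 1 is read from
the fragment 5′ end, mate 2 reverse-complemented from the 3′ end, both
150 bp. The number of fragments per chromosome is
`coverage · length / (2 · read_length)`, so realized coverage tracks the
request closely. Substitution errors occur at a flat per-base rate
(default 0.001); there are no indel errors and no PCR-duplicate
simulation beyond chance fragment repetition — the duplicate-removal
stage is exercised by coordinate collisions, which occur naturally at
the coverages used. The quality model is a linear decay from Q38 at
cycle 1 to Q28 at cycle 150 (a constant-quality model is available);
qualities and errors are independent, which is unrealistic but
irrelevant to every consumer in this package. A truth table maps each
read id to its fragment interval and strand.

What the simulator deliberately does not emulate: indels and structural
noise, GC-coverage bias, adapter read-through, chimeric library
artefacts, base-quality miscalibration. Passing tests therefore
demonstrate correctness of the calling logic under substitution noise
and exact TSD mechanics, not robustness to every artefact of real
libraries — for real data the SAM reader accepts alignments from a full
aligner such as bwa, and the caller consumes those.

## Read QC

A read is discarded iff (in this order, the first failing rule is
reported): N fraction > 0.10, fraction of bases below Q20 > 0.40, mean
Phred < 20. All inequalities are strict, so boundary reads (exactly 10%
N, exactly Q20 mean, exactly 40% sub-Q20) pass. N bases contribute
their recorded quality, clamped at 0. Mean quality is the arithmetic
mean of Phred scores, not the error-probability mean; tools differ
here, and the choice is documented so comparisons are possible. The
default pair policy drops the whole pair when either mate fails
(conservative for junction calling); `drop-single` keeps the surviving
mate as an orphan.

## Alignment

Seeded, ungapped, local: exact k-mers (default k = 45) of the forward
reference strand are indexed; both strands of a read are probed at
seven evenly spaced offsets, and each candidate diagonal is extended
with match +1 / mismatch −2 and an X-drop of 20 score units. Bases
beyond the extension optimum are soft clips. A read maps when its best
segment scores ≥ 40 (≈ 40 matched bases); ties break by (reference
name, position, forward strand first), so output is byte-reproducible.
Within a diagonal, equal-scoring extensions resolve to the minimal
extension (largest start, smallest end). The transgene is simply an
extra reference sequence in the same index, so junction reads anchor on
whichever side holds their longer half.

Ungapped extension is a deliberate restriction: the junction signal
lives entirely in soft clips, and indel tolerance is delegated to
external aligners via the SAM reader. Duplicate removal collapses read
pairs sharing both mates' (reference, clip-projected 5′ position,
strand), keeping the pair with the highest summed base quality (ties by
read id); it is idempotent.

## Clip realignment

Each clipped sequence (≥ 20 bp) is realigned against genome + transgene
on both strands, BLAST-style: exact 16-mers nominate target windows and
an affine-gap Smith–Waterman (match 2, mismatch −3, gap open −5, extend
−2; Biopython's PairwiseAligner) is computed on the window (clip length
+ 30 bp padding each side). Hits below 95% identity or 20 aligned bases
are discarded; one best hit per clip, ties by (target, position).
Seeding makes per-clip cost independent of genome size while preserving
the identity/length gates; a random 20-mer has a ~10⁻⁴ chance of even
nominating a window in a 200 kb toy genome, and the identity gate
removes what seeding lets through.

## Junction clustering and calling

Every genome↔transgene clip hit yields one breakpoint observation:
genome-anchored clips take their anchor position (right clips name the
last genome base before the insertion, "left flank"; left clips the
first base after it, "right flank"); transgene-anchored clips project
through the hit geometry. Orientation is read directly off the strand
of the cross-reference hit (forward ⇔ '+'). Observations within 5 bp on
the same chromosome and flank merge; the cluster breakpoint is the
modal position (ties → smallest), and a consensus clip is built by
per-column majority.

A left and right cluster pair into a call when their breakpoints are
within |TSD| + tolerance. With a duplicated target site the flanks
overlap: the right breakpoint sits at `L − |TSD| + 1`. Chance sequence
identity (microhomology) between the transgene ends and the genome
shifts every extension boundary in a cluster identically, so the
breakpoint is genuinely ambiguous from alignment alone; when a TSD
motif is configured, breakpoints snap to the nearest motif-consistent
position within the cluster tolerance — the standard resolution for
TTAA-integrating transposons. Motif-less calls keep the observed modal
breakpoint (and may be off by the homology length, which no method can
resolve from sequence). Single-sided clusters with enough support are
reported as CANDIDATE; contradictory orientations between paired
clusters flag the call AMBIGUOUS rather than dropping it.

Defaults — min clip 20 bp, cluster tolerance 5 bp, min support 3 per
junction — leave ample margin at 20× coverage (typically 15–25
supporting clips per junction on the toy genomes) while keeping 5×
coverage informative; all are exposed in `CallerConfig`.

## Hybrid-reference validation

For each call the package assembles
`genome flank (500 bp) + TSD + oriented transgene + TSD + genome flank`
— by construction identical to the transgene-bearing chromosome around
the junction — with a total hybrid→source coordinate map (the TSD
copies both map to the single genomic motif, so the inverse is defined
everywhere except that duplication). All QC-passed reads are realigned
to the hybrid; a read validates a junction when it aligns without any
soft clip and covers ≥ 20 bases on each side of the boundary. PASS
requires ≥ 3 such reads at both junctions; a support-satisfying call
that fails validation is downgraded to CANDIDATE. Flanks truncate with
a warning at chromosome ends.

The vector screen runs extract → realign → cluster with a plasmid
backbone as the extra reference and counts genome-linked junction
clusters (support ≥ 2); episomal vector reads align wholly within the
vector and produce none.

## Transmission model

Loci are unlinked, autosomal and never homozygous (the backcross design
guarantees hemizygosity), so the positive fraction of a litter is
1 − (1/2)^k. The segregation test is the exact two-sided binomial test
(probabilities ≤ the observation's summed). Its p-values are discrete:
under the null they satisfy P(p ≤ a) = a exactly at every achievable
level a and are conservative between levels — the property-test checks
this discrete form, since a continuous-uniform KS test would reject any
exact discrete test by construction.

Locus-count inference maximises the Binomial(n, 1 − 2^−k) likelihood
over k = 1..k_max (default 10). Resolution is intrinsically limited:
enumerating all counts at n = 200 gives exact recovery probabilities
0.99992, 0.98818 and 0.91270 for k = 1, 2, 3 — beyond k ≈ 3 the
expected fractions crowd toward 1 and the likelihood flattens, which is
reported (a k̂ = k_max fit is flagged "saturated") rather than hidden.
Zero positive offspring leaves k̂ undefined.

The breeding simulator transmits each of the sire's loci independently
per offspring and selects the next sire among carriers either uniformly
(`random_carrier`) or preferring the most loci (`max_locus_carrier`,
modelling selection of the strongest expressors under an
expression ∝ copy-number assumption; no quantitative expression model is
asserted, so both policies are exposed). Default litter size 10 is a
typical rat litter. With four founder loci, random-carrier selection
and six generations, ~99% of trajectories reach the absorbing
single-locus state (probed independently at 5,000 replicates).

## Expression statistics

ΔCt = Ct_target − Ct_reference per sample (replicate Cts averaged
arithmetically before differencing — the most common comparative-CT
convention); ΔΔCt subtracts the calibrator group's mean ΔCt; fold =
2^−ΔΔCt, with group folds summarised by geometric mean. No
amplification-efficiency correction is applied. The zero-noise
round-trip (panel simulated at fold F → estimate exactly F) is exact by
algebra and tested as such.

Summary t-tests use the standard pooled-Student formulas by default
(Welch optional), with SEM inputs converted to SD via sd = sem·√n.
One-tailed p is half the two-tailed p in the observed direction. The
degenerate zero-dispersion case returns t = 0, p = 1 (equal means) or
p = 0 flagged (unequal). Published sperm-analysis rows ship in the test
suite as a format fixture only: their "±" convention (SD vs SEM) and
tail convention are not recoverable, so both readings are computed and
neither is asserted against the printed p-values; all rows are
non-significant under every reading, consistent with the published
conclusion of no difference.

## Problem sizes and numerical choices

The test suite simulates toy genomes of 15–200 kb at 5–20× coverage —
sizes at which every stage's behaviour (seeding, clustering,
validation, specificity across 10 insertion-free genomes, 20 seeded
end-to-end recoveries in both orientations) is exercised in a couple of
minutes. Seeds are fixed everywhere; identical seeds give byte-identical
FASTQ and SAM output. The aligner's equivalence to an exhaustive
all-positions scan is verified at k = 11 on ≤ 200 bp references with
matching tie-break conventions.

## Known limitations

- Single-copy resolution: multiple co-located insertions are reported
  as separate calls only if their breakpoints separate by more than the
  cluster tolerance.
- No discordant-pair-only calling: clip evidence is required, so an
  insertion inside a long repeat that absorbs all clips would be missed.
- The toy aligner is substitution-only; real data with indels near the
  junction should be aligned externally and fed in as SAM.
- Gene-overlap annotation requires a user-supplied interval list; no
  genome annotation is bundled.
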