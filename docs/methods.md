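# Methods

## The screen being modeled

PDE3A-targeting "velcrins" such as DNMDP are cytotoxic because they induce
a complex between the PDE3A catalytic domain and SLFN12. A pooled deep
mutational scan of the PDE3A catalytic region (codons 668–1141 of the
full-length 1141-residue protein) expresses every possible single-codon
substitution in PDE3A-knockout cells, treats arms with DMSO, DNMDP (10 and
100 nM), or the non-cytotoxic active-site binder trequinsin (100 nM), and
sequences the integrated ORFs before (T0) and after five days of
selection. Variants that survive DNMDP but not DMSO have lost the function
that makes the complex cytotoxic; stop codons act as the loss-of-function
benchmark and remain fully functional only within the last 59 codons,
where the truncation no longer removes anything essential.

## Library design

For each codon in the region, the designer attempts all 20 non-wild-type
targets (19 missense + 1 nonsense). Candidate codons for a target amino
acid are ranked by:

1. **Descending nucleotide (Hamming) distance** from the wild-type codon.
   Single-nucleotide neighbours are used only when nothing else encodes
   the target; this keeps sequencing errors from masquerading as designed
   variants.
2. **Descending human codon-usage frequency** (a fixed per-thousand table
   embedded in `library_design.py`), as a deterministic tie-break.
3. **Alphabetical order**, as the final tie-break.

A candidate is rejected if substituting it would create any forbidden
restriction site. Only sites overlapping the edited codon can appear, so
the check scans a window of the codon ± (longest site − 1) nucleotides; a
full-sequence post-condition is enforced by tests. Because the invariant
"no variant sequence contains a forbidden site" can only hold when the
reference itself is clean, the designer raises if the input ORF already
contains a forbidden site — matching real practice, where the cloning
vector's sites are pre-recoded out of the insert. Targets whose every
candidate is rejected are recorded as `dropped` with reason
`restriction_site`; the published screen lost 7 of its 9668 targets this
way, a number that depends on the exact cDNA and is therefore not a
constant of the method.

Silent variants (188 in the published design) are placed at evenly spaced
codon indices across the region; positions whose codon has no usable
synonymous alternative (Met, Trp, or all alternatives rejected) are
skipped in favour of the next position. Each silent variant takes the
top-ranked synonymous codon under the same ranking.

Defaults: forbidden sites NheI (GCTAGC) and BamHI (GGATCC), the cloning
enzymes; both fully configurable.

## PAM-site recoding

Rescue cDNAs must not be re-cut by the knockout guide
(GTGGCAGACCATATTTCCCAA in the cellular work). `find_guide_matches` scans
both strands for guide identity immediately 5′ of an NGG PAM, reporting
+ strand coordinates. The recoder then makes one synonymous codon edit per
match, trying codons inside the protospacer/PAM footprint starting from
the PAM-proximal (seed) end, and accepts the first edit that reduces the
global match count — this guarantees the edit actually destroys the site
(a change at the N of the PAM would not). A match whose footprint offers
no synonymous escape raises an explicit error naming the match.

## Read deconvolution

The published screen used an unpublished deconvolution tool; this module
is a deliberately simple, fully specified replacement:

- 3′ bases below Q20 are trimmed from each mate; mate 2 is
  reverse-complemented and merged with mate 1 at the best exact-overlap
  offset of ≥ 20 bases (preferring disagreement-free overlaps, then
  highest identity, then longest overlap). Overlap disagreements resolve
  to the higher-quality base, mate 1 winning ties; best-overlap identity
  below 80% or mean consensus quality below Q20 classifies the pair
  low-quality.
- The consensus is anchored on the reference by its first exact 20-mer hit
  and extended without gaps (amplicon data; indels are not designed
  variants and such reads become unalignable). More than 6 mismatches is
  unalignable.
- Mismatches are grouped by reference codon: 0 changed codons → wild-type;
  1 changed codon equal to a designed alternative codon → that variant;
  1 other changed codon → unintended; ≥ 2 changed codons → multi-variant.

Every read lands in exactly one row, so counts-matrix columns always sum
to the input read count (checked as a class invariant).

## Scoring and hit calling

With `assigned(s)` = WT + designed-variant reads of sample `s` (discard
classes excluded — the least-biased denominator when junk rates vary):

    fraction(v, s) = (count(v, s) + 0.5) / (assigned(s) + 0.5)

The pseudocount (0.5 reads) keeps post-selection zeros finite. Variants
whose mean T0 fraction falls at or below the nearest-rank 8th percentile
are low-confidence and carry no downstream scores; ties at the threshold
are all flagged (with n distinct values exactly ⌈0.08 n⌉ variants are
removed). T0 was harvested once before the split into arms, so each arm
replicate is normalized by the pooled (replicate-mean) T0 fraction:

    norm(v, cond, r) = fraction(v, cond, r) / fraction(v, T0)
    LFC(v) = log2( mean_r norm(v, treat, r) / mean_r norm(v, ctrl, r) )

Z-scores standardize the 100 nM drug vs DMSO LFC over retained variants
(sample SD, n−1); a resistance hit requires LFC > mean + 1·SD **and**
LFC > 0. The SD multiplier, percentile, pseudocount, and control arm
(DMSO or trequinsin) are all parameters. Hits can be post-filtered by a
user-supplied exclusion list (e.g. substitutions predicted to unfold the
protein); no fold-stability prediction is computed here, since no
specific published method is attached to the screen.

## Structural annotation

Hit variants are aggregated by residue; each hit residue is classified by
the first matching set in the priority order active site > dimer
interface > SLFN12 interface (active-site membership being the most
specific mechanistic claim), or left unassigned. Sets can be supplied
directly (YAML/JSON residue lists) or derived from a structure: a residue
joins a set when any of its heavy atoms (hydrogens ignored — experimental
structures rarely resolve them; waters excluded) lies within the cutoff
(default 4.5 Å, a standard contact definition) of the ligand, of a
different receptor chain, or of a partner chain respectively, unioned
over receptor chains. The implementation uses a k-d tree; tests compare
it against a brute-force all-pairs oracle on synthetic coordinates, so no
deposited structures are needed to validate the geometry.

## The synthetic screen

The simulator provides ground truth for every downstream stage. Its
defaults are the study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| depth | 10⁶ | reads per sample (deep coverage of ~10⁴ variants) |
| replicates | 2 | independent multinomial draws per arm |
| representation σ | 1.0 | log-normal spread of library representation |
| dropout fraction | 0.05 | variants at ~10⁻⁴ of typical abundance, exercising the 8% filter |
| WT carrier fraction | 0.01 | wild-type reads present in every sample |
| δ (residual survival) | 0.05 | fraction of functional cells surviving the drug arms |
| error rate | 0 (≤ 0.05) | uniform per-base substitution rate in FASTQ rendering |

Selection is a single deterministic proportional-growth step — abundance
is multiplied by a survival weight and renormalized — rather than a
birth–death process; this is sufficient to induce the LFC structure of
the real screen while keeping the expected post-selection abundances in
closed form for the truth table. The fitness rule: loss-of-function
variants (nonsense at codon ≤ ORF length − 59, or members of a programmed
resistance set) have weight 1 under the drug arms; everything else
(missense, silent, WT) survives at δ; all weights are 1 at T0, DMSO, and
trequinsin, making the control arms exact replicates of T0 in
expectation.

FASTQ rendering draws each read pair from a fragment of the variant's
full sequence; by default the fragment is constrained to cover the edited
codon, so that with zero error rate the deconvolution stage reproduces
the input counts exactly — the round-trip oracle used in tests. Fragments
placed uniformly would leave a coverage-dependent fraction of reads
indistinguishable from wild type, which is realistic for tagmentation
data but makes exact recovery impossible; the flag `cover_variant=False`
restores uniform placement.

What the simulator does **not** emulate: PCR jackpotting and chimeras,
coverage bias, indels, cell-growth stochasticity, and any dose-response
difference between 10 and 100 nM drug (both arms use the same binary
fitness rule). Passing the end-to-end tests therefore demonstrates that
the scoring machinery recovers a clean signal planted under the stated
noise model, not that the pipeline is robust to every artifact of a live
screen.

## Numerical and scale choices

- All randomness flows through one `numpy` Generator seeded from the
  config; artifacts are byte-reproducible from (config, seed).
- The nearest-rank percentile is used for the T0 filter (smallest value
  covering ≥ p% of observations), making the flagged count exact under
  distinct values.
- Z-scores use the sample SD (ddof = 1); a constant LFC vector yields
  undefined Z (stored as NaN) and no hits.
- Test and acceptance problem sizes: the full-scale checks run one
  1141-codon synthetic ORF (9,654–9,668 variants after constraints) at
  10⁶ reads × 10 samples, which completes in a few seconds; unit tests
  use 30–300-codon ORFs.
- Average protein masses use the standard isotope-averaged residue table
  plus one water (18.0153 Da), matching the "theoretical mass" convention
  of SEC-MALS comparisons; monoisotopic masses and PTMs are out of scope.

## Known limitations

- The designed-library size depends on the exact cDNA: the count of
  infeasible targets (7 in the published library) is reproduced only in
  kind, not in number, on synthetic references.
- The deconvolution stage is ungapped by design; amplicons with real
  indel variants would need a different caller.
- The "bottom 8%" filter is computed on pooled-T0 mean fractions; if the
  original analysis filtered per replicate, the excluded sets could
  differ near the threshold.
- Structural classification assigns one category per residue by fixed
  priority; residues genuinely at two interfaces are reported only under
  the higher-priority one.
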