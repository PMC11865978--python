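# Methods

## The census

The core object is the dense k-mer census: an int64 array of length 20ᵏ
holding the occurrence count of every possible peptide of length *k*
(2 ≤ *k* ≤ 6) over a protein corpus. K-mers are encoded big-endian over
the fixed alphabet `A C D E F G H I K L M N P Q R S T V W Y`
(alphabetical one-letter codes), so array order equals lexicographic
order and nullomer enumeration is a linear scan for zeros. A window
advances one residue at a time and contributes to exactly one cell;
windows never cross record boundaries.

Counter width is int64: a census must be safe on corpora of 10⁸ residues
and beyond, and the 20⁶ table (64 M entries, 512 MB) is the accepted
memory ceiling — *k* > 6 is out of scope. Window indices are buffered
and tallied in ~4-million-window batches so the cost of scattering into
the 20ᵏ table is amortised over many segments.

### Nonstandard residues

Curated proteomes contain ambiguity and rare-residue letters
(X unknown, B = D/N, Z = E/Q, J = I/L, U selenocysteine,
O pyrrolysine). These are outside the 20-letter space the census
enumerates, and letting windows span them would fabricate peptide
counts. Each sequence is therefore split into maximal standard-alphabet
segments and windows are confined to segments. Residue composition, by
contrast, is tallied over *all* standard residues, including those in
segments shorter than *k*: composition is a property of the corpus, not
of countable windows. Published release-level counts from other
implementations may differ slightly if they filtered nonstandard
residues differently; any discrepancy on a shared input should be
attributable to that policy alone.

Only the canonical sequence of a UniProtKB XML entry is used (one
`sequence` element per entry; isoforms are not expanded). Entries
without a sequence element are skipped with a logged warning rather than
aborting, so partial or hand-built files remain usable. All input is
uppercased; lowercase has no meaning in proteome data.

## Null models and rarity

Expected counts use a positional-independence model:
E[*w*] = *N* · ∏ᵢ *p*(*aᵢ*) with *N* the window total. Summed over the
full 20ᵏ space this reproduces *N* exactly (since Σ*p* = 1), which the
tests assert to 10⁻⁶ relative for both model kinds.

- **Amino-acid occurrence model**: *p* is the corpus residue frequency
  vector.
- **Codon-frequency model**: *p*(a) ∝ the number of sense codons for
  *a*. The default table is the standard genetic code's synonymous-codon
  counts over the 61 sense codons — parameter-free and reproducible —
  and a user-supplied codon-usage table (e.g. organism-specific counts)
  can replace it.

Under-representation is scored with the one-sided Poisson lower tail
P(X ≤ observed | mean = expected). The Poisson family is the standard
approximation for rare-word counts, is numerically stable far beyond
means of 10⁶ (scipy's regularised incomplete gamma), and is cheap enough
to vectorise over the whole 20ᵏ space; the exact binomial
(n = *N*, p = ∏*p*(*aᵢ*)) would be an acceptable drop-in at these
scales. With expected = 0 the distribution is degenerate and the p-value
is 1. No multiple-testing correction is applied when ranking rare
k-mers: raw p-values are reported and the threshold is the caller's.
Rare-hit ordering is total and deterministic: ascending p-value, then
observed count, then lexicographic k-mer. Observed/expected ratios with
a zero denominator are written as `NA`, never as an infinity literal, to
keep CSV output portable.

Neighborhood analysis enumerates the 19·*k* single-substitution variants
of a query in (position, substituted-residue) order, each with observed
count, both expected counts, ratio and p-value. A nullomer is
*high-order* when every one of these variants is also absent; asking
this of an observed k-mer is rejected as ill-posed.

## Synthetic corpora

The generator emulates the statistical skeleton of a curated protein
corpus: record count, uniform length range, i.i.d. residue draws from a
20-entry composition (uniform by default), optional ambiguity-letter
noise at a per-position rate, guaranteed-absent motifs, and motifs
planted a requested number of times. Defaults in the test suite follow
the desk-scale study conditions: corpora of ~30–200 records with lengths
50–500 for recovery and oracle checks, and 10⁶-residue corpora where
calibration needs large expected counts.

Motif avoidance works by local resampling-and-repair: any window
matching an avoided motif has one of its positions redrawn from the
composition, rescanning all avoided motifs jointly until clean, with a
10⁴-attempt budget per motif after which the spec is rejected as
infeasible (as when the composition makes avoidance nearly
measure-one). Planting happens after repair at random non-overlapping
positions; junctions that recreate an avoided motif are repaired again
without touching planted residues, and ambiguity-letter injection skips
planted spans so the planted count survives. Avoidance is re-verified on
the finished corpus with the brute-force oracle. Generation is a pure
function of the spec; one seed drives a single `numpy` generator, so
identical specs give byte-identical corpora.

What the generator does **not** emulate: real proteomes have strong
residue autocorrelation, domain repeats, low-complexity regions and
shared evolutionary history, all of which inflate the variance of k-mer
counts relative to the i.i.d. model. Passing tests therefore demonstrate
correctness of the counting and statistics machinery, not that the
Poisson null is well-calibrated on biological data — on a real release
the p-values should be read as a ranking device, which is how they are
used.

The brute-force oracle (`brute_force_count`) is a deliberate
re-implementation by naive position-by-position string comparison. It
shares no encoding, segmentation or census code, so census/oracle
agreement on generated corpora is a genuine dual-route check. Because
query peptides are standard-alphabet, a window containing a nonstandard
letter simply fails the comparison — exactly the census's
never-span-nonstandard rule, arrived at independently.

## Numerical and format choices

- Counts CSV enumerates the *full* 20ᵏ space (header `kmer,count`,
  lexicographic), so nullomers are visible as explicit zero rows rather
  than by omission.
- Output is byte-reproducible: fixed `\n` newlines, and gzip members
  written with a zeroed timestamp and no embedded filename, so a
  `.csv.gz` written twice from one census is bit-identical.
- Calibration checks score observed counts against the *generating*
  composition, which is the exact null; the invariant that estimating
  the model from the same corpus can only make the test more
  conservative (never anti-conservative) is asserted separately.
- The empty corpus is valid everywhere: a census with zero windows,
  every k-mer a nullomer, and residue frequencies rejected as undefined.

## Scale choices

The test suite and the acceptance script run entirely on synthetic
corpora: 50 corpora of 100 records (lengths 50–500) for oracle
equivalence at k ∈ {2,3,4}; 20 random tetramers for avoidance/planting
recovery; ten 10⁶-residue corpora for calibration at α = 0.01; and a
k = 5 census (3.2 M cells) for space-size checks. These sizes make every
claim checkable in seconds while leaving the same code paths that a
full Swiss-Prot release (~2×10⁸ residues, minutes per census) exercises.

## Known limitations

- No disk-backed census; k = 6 needs ~512 MB resident.
- Uniform length distribution only in the generator.
- The XML reader is namespace-tolerant but schema-light: it takes the
  first accession, first protein fullName and the entry-level sequence;
  exotic UniProt extensions are ignored.
- Single-species analysis only; cross-species comparisons (e.g.
  peptides unique to one species) are out of scope.
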