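# pepnull

Nullomer and rare-peptide discovery in protein corpora.

A **nullomer** is a peptide of length *k* (over the 20 standard amino
acids) that never occurs anywhere in a sequence corpus such as a
UniProtKB/Swiss-Prot release. Curated proteomes are small enough that
short absent peptides exist — the 20⁴ = 160,000 tetramer space is only
just covered, and 20⁵ = 3,200,000 pentamers are far from it — and such
absent or strongly under-represented peptides are interesting leads for
peptide chemistry precisely because biology appears to avoid them.

`pepnull` is a library and command-line tool for researchers who want to
find and characterise these sequences:

- stream protein records from UniProtKB-style XML or FASTA;
- build the complete occurrence-count table over the full 20ᵏ k-mer
  space (*k* = 2…6) with a sliding window that never crosses record
  boundaries or nonstandard residues (X/B/Z/J/U/O);
- enumerate nullomers and rank observed k-mers by how far below
  expectation they fall;
- analyse a query peptide's single-substitution **mutation
  neighborhood** (19·*k* variants), its left/right **truncates**, and
  whether it is a **high-order nullomer** (all variants also absent);
- generate seeded synthetic proteomes with controlled composition,
  avoided or planted motifs, and nonstandard-residue noise, so every
  statistic can be validated without downloading a release.

## The model

Under a null model in which residues occupy window positions
independently with per-residue probabilities *p(a)*, the expected count
of a k-mer *w* = *a₁…aₖ* in a corpus with *N* windows is

    E[w] = N · ∏ᵢ p(aᵢ)

Two choices of *p* are built in: **amino-acid occurrence rates**
estimated from the corpus itself, and **codon frequencies** — by default
the synonymous sense-codon counts of the standard genetic code
(*p*(W) = 1/61, *p*(L) = 6/61), overridable with an organism-specific
codon-usage table. Under-representation of an observed count *n* is
scored with the Poisson lower tail *P*(X ≤ *n*), X ~ Poisson(E[*w*]).

## Worked example

Generate a 100-record synthetic corpus that avoids the tetramer CQWW,
then interrogate it:

```sh
$ pepnull generate demo.fa --n-records 100 --length-low 100 \
    --length-high 300 --avoid CQWW --seed 42
INFO wrote 100 synthetic records to demo.fa

$ pepnull count demo.fa counts4.csv 4
INFO census: 100 records, 20238 windows, k=4, 141008 nullomers
INFO wrote full-space counts CSV to counts4.csv

$ pepnull truncates demo.fa trunc.csv CQWW
INFO census: 100 records, 20338 windows, k=3, 616 nullomers
INFO truncates of CQWW: CQW=1, QWW=2

$ pepnull neighborhood demo.fa nbhd.csv CQWW
INFO wrote 76 neighborhood rows for CQWW to nbhd.csv
$ head -2 nbhd.csv
kmer,position,original,substituted,observed,expected_aa,expected_codon,obs_over_exp_aa,p_under_aa
AQWW,0,C,A,1,0.12723707793427136,0.011693330870981405,7.859344274760727,0.9925603094928236
```

Reading the numbers: this small corpus has 20,238 four-residue windows,
so 141,008 of the 160,000 possible tetramers are never seen — with so
few windows most of the space is necessarily empty, and CQWW is absent
by construction (it appears in `counts4.csv` with count 0). Its
truncates CQW and QWW do occur (1 and 2 times). Each neighborhood row is
one single-substitution variant with its observed count, expected counts
under both null models, the observed/expected ratio, and the Poisson
lower-tail p-value (here AQWW occurs once against an expectation of
0.13 — more often than expected, p ≈ 0.99, i.e. not under-represented).

`pepnull count` writes the full 20ᵏ-row table (nullomers included with
count 0) in lexicographic order; an output path ending `.csv.gz`
gzip-compresses it, which is advisable for k = 5 or 6. The same
commands accept a UniProtKB XML release file in place of the FASTA, in
which case the census takes minutes and, e.g., `pepnull nullomers`
reports the absent tetramers of that release.

The remaining commands: `nullomers` (absent k-mer list), `rare`
(observed k-mers with p_under below a threshold, most depleted first).

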