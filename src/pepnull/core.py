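"""Nullomer and rare-peptide discovery in protein corpora.

A nullomer is a peptide of length k (over the 20 standard amino acids)
that never occurs in a sequence corpus.  This module implements the whole
pipeline around that idea, in the order the method runs:

1.  Corpus I/O       — stream protein records from UniProtKB-style XML or
                       FASTA, write FASTA, split sequences into
                       standard-alphabet segments.
2.  K-mer census     — integer encoding of k-mers and the dense
                       occurrence-count table over the full 20**k space.
3.  Nullomer stats   — nullomer enumeration, expected counts under
                       amino-acid-composition and codon-frequency null
                       models, Poisson under-representation p-values,
                       single-substitution mutation neighborhoods,
                       left/right truncate counts, high-order nullomer
                       detection, and rare-k-mer ranking.
4.  Synthetic corpora — a seeded generator with controlled composition,
                       avoided/planted motifs and nonstandard-residue
                       injection, plus the independent brute-force
                       counting oracle.

All randomness flows through ``numpy.random.default_rng`` seeded from the
caller-supplied seed; identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import gzip
import io
import itertools
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from lxml import etree
from scipy.stats import poisson

logger = logging.getLogger("pepnull")

# ---------------------------------------------------------------------------
# Alphabet and global constants
# ---------------------------------------------------------------------------

#: The 20 standard amino acids, alphabetical by one-letter code.  This
#: ordering is fixed across the package: it defines both the integer
#: encoding of k-mers and the lexicographic order of CSV output.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SIZE: int = 20
AA_TO_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}
STANDARD_SET = frozenset(ALPHABET)

#: Ambiguity and nonstandard letters that may appear in curated proteomes:
#: X (unknown), B (D/N), Z (E/Q), J (I/L), U (selenocysteine),
#: O (pyrrolysine).
NONSTANDARD_LETTERS: str = "XBZJUO"

#: Supported window lengths.  20**6 = 64,000,000 already needs a dense
#: half-gigabyte table; larger k is out of scope.
K_MIN, K_MAX = 2, 6

#: Synonymous sense-codon counts per residue in the standard genetic code
#: (61 sense codons total).  This is the parameter-free default behind the
#: codon-frequency null model; organism-specific usage tables may be
#: supplied instead.
SENSE_CODON_COUNTS: dict[str, int] = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
    "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
    "T": 4, "V": 4, "W": 1, "Y": 2,
}

_STANDARD_RUN_RE = re.compile(f"[{ALPHABET}]+")


# ---------------------------------------------------------------------------
# Section 1 — corpus I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One corpus entry: accession, free-text description, and the
    uppercase amino-acid sequence (which may contain nonstandard letters).
    """

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be nonempty")
        if not self.sequence:
            raise ValueError(f"record {self.accession!r}: sequence is empty")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(
                f"record {self.accession!r}: sequence contains whitespace"
            )
        if self.sequence != self.sequence.upper():
            raise ValueError(
                f"record {self.accession!r}: sequence contains lowercase"
            )


@dataclass(frozen=True)
class SequenceSegment:
    """A maximal run of standard-alphabet residues within a parent record.

    ``offset`` is the 0-based start of the run within the parent sequence.
    Windows for the census never span segment boundaries, so nonstandard
    letters can never fabricate peptide counts.
    """

    parent_accession: str
    offset: int
    residues: str


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_uniprot_xml(path: str | Path) -> Iterator[ProteinRecord]:
    """Stream protein records from a UniProtKB/Swiss-Prot-style XML file.

    Entries are yielded in file order, one per ``entry`` element, using the
    entry's single canonical sequence.  Parsing is namespace-tolerant and
    streaming: parsed subtrees are discarded as soon as each entry has been
    yielded, so memory use is independent of file size.  Entries lacking a
    sequence element are skipped with a logged warning.

    Raises ``lxml.etree.XMLSyntaxError`` (which reports line/column of the
    defect) on malformed XML.
    """
    context = etree.iterparse(str(path), events=("end",))
    for _event, elem in context:
        if _localname(elem.tag) != "entry":
            continue
        accession = ""
        description = ""
        sequence = ""
        for child in elem.iter():
            name = _localname(child.tag)
            if name == "accession" and not accession:
                accession = (child.text or "").strip()
            elif name == "fullName" and not description:
                description = (child.text or "").strip()
            elif name == "sequence":
                # The canonical sequence is a direct child of <entry>;
                # isoform references live elsewhere in the schema.
                if _localname(child.getparent().tag) == "entry":
                    sequence = "".join((child.text or "").split()).upper()
        if not sequence:
            logger.warning(
                "entry %r has no sequence element; skipped",
                accession or "<no accession>",
            )
        else:
            yield ProteinRecord(
                accession=accession or "<no accession>",
                description=description,
                sequence=sequence,
            )
        # Free the parsed subtree to keep memory flat while streaming.
        elem.clear()
        parent = elem.getparent()
        if parent is not None:
            while elem.getprevious() is not None:
                del parent[0]
    del context


def read_fasta(path: str | Path) -> Iterator[ProteinRecord]:
    """Stream protein records from a multi-record FASTA file.

    The accession is the first whitespace-delimited token after ``>``; the
    description is the remainder of the header line.  Sequence lines may
    wrap and are concatenated and uppercased.  A record with a header but
    no sequence characters is an error naming that header.
    """
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has no sequence")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        yield ProteinRecord(accession=rec.id, description=desc, sequence=seq)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as standard FASTA with 60-column line wrapping and
    ``>accession description`` headers."""
    seq_records = (
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    )
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seq_records)


def read_records(path: str | Path, fmt: str = "auto") -> Iterator[ProteinRecord]:
    """Read a corpus, auto-detecting XML vs FASTA unless ``fmt`` forces one.

    Detection: a ``.xml`` extension, or a first non-whitespace byte of
    ``<``, means UniProt XML; otherwise FASTA.
    """
    if fmt == "auto":
        if str(path).endswith(".xml"):
            fmt = "xml"
        else:
            with open(path, "rb") as fh:
                head = fh.read(256).lstrip()
            fmt = "xml" if head.startswith(b"<") else "fasta"
    if fmt == "xml":
        return read_uniprot_xml(path)
    if fmt == "fasta":
        return read_fasta(path)
    raise ValueError(f"unknown input format {fmt!r}")


def segment_standard(record: ProteinRecord) -> list[SequenceSegment]:
    """Split a record into maximal standard-alphabet runs.

    Concatenating the returned segments together with the removed
    nonstandard letters reconstructs the original sequence; a sequence of
    only nonstandard letters yields an empty list.
    """
    return [
        SequenceSegment(record.accession, m.start(), m.group())
        for m in _STANDARD_RUN_RE.finditer(record.sequence)
    ]


# ---------------------------------------------------------------------------
# Section 2 — k-mer encoding and the census
# ---------------------------------------------------------------------------

def encode_kmer(peptide: str) -> int:
    """Encode a standard-alphabet k-mer (2 <= k <= 6) as its index in the
    20**k space: big-endian positional code, so encoded order equals
    lexicographic order under the fixed alphabet.
    """
    if not K_MIN <= len(peptide) <= K_MAX:
        raise ValueError(
            f"k-mer length {len(peptide)} outside supported range "
            f"[{K_MIN}, {K_MAX}]"
        )
    index = 0
    for pos, letter in enumerate(peptide):
        code = AA_TO_INDEX.get(letter)
        if code is None:
            raise ValueError(
                f"nonstandard letter {letter!r} at position {pos} in "
                f"{peptide!r}"
            )
        index = index * ALPHABET_SIZE + code
    return index


def decode_kmer(index: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for a given k."""
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k={k} outside supported range [{K_MIN}, {K_MAX}]")
    if not 0 <= index < ALPHABET_SIZE**k:
        raise ValueError(f"index {index} out of range for k={k}")
    letters = []
    for _ in range(k):
        index, code = divmod(index, ALPHABET_SIZE)
        letters.append(ALPHABET[code])
    return "".join(reversed(letters))


@dataclass
class KmerCensus:
    """The complete occurrence-count table over the 20**k k-mer space.

    ``counts[i]`` is the number of length-k windows whose encoded value is
    ``i``; ``total_windows`` is their sum.  ``residue_counts`` tallies every
    standard residue in the corpus, including residues in segments shorter
    than k (composition is a property of the corpus, not of countable
    windows).  Counters are int64, so corpora far beyond 2**32 residues
    cannot silently overflow.
    """

    k: int
    counts: np.ndarray
    total_windows: int
    residue_counts: np.ndarray
    n_records: int

    def __post_init__(self) -> None:
        if not K_MIN <= self.k <= K_MAX:
            raise ValueError(f"k={self.k} outside [{K_MIN}, {K_MAX}]")
        if len(self.counts) != ALPHABET_SIZE**self.k:
            raise ValueError(
                f"counts table has {len(self.counts)} entries, "
                f"expected {ALPHABET_SIZE ** self.k}"
            )


def _segment_codes(residues: str) -> np.ndarray:
    return np.frombuffer(
        residues.translate(_CODE_TABLE).encode("latin-1"), dtype=np.uint8
    ).astype(np.int64)


_CODE_TABLE = str.maketrans({a: chr(i) for a, i in AA_TO_INDEX.items()})


def build_census(records: Iterable[ProteinRecord], k: int) -> KmerCensus:
    """Slide a k-residue window across every standard-alphabet segment of
    every record and tally occurrences of each of the 20**k k-mers.

    Windows advance one residue at a time and never span record boundaries
    or nonstandard letters; a segment of length L contributes
    ``max(0, L - k + 1)`` windows.  The result is independent of record
    order.  An empty corpus yields a valid census with zero windows.
    """
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k={k} outside supported range [{K_MIN}, {K_MAX}]")
    space = ALPHABET_SIZE**k
    counts = np.zeros(space, dtype=np.int64)
    residue_counts = np.zeros(ALPHABET_SIZE, dtype=np.int64)
    n_records = 0
    # Window indices are buffered across segments and tallied in large
    # batches: one bincount over the 20**k space per ~4M windows instead
    # of one per segment.
    pending: list[np.ndarray] = []
    pending_size = 0
    flush_at = 4_000_000
    for record in records:
        n_records += 1
        for segment in segment_standard(record):
            codes = _segment_codes(segment.residues)
            residue_counts += np.bincount(codes, minlength=ALPHABET_SIZE)
            n_windows = len(codes) - k + 1
            if n_windows <= 0:
                continue
            window_index = np.zeros(n_windows, dtype=np.int64)
            for j in range(k):
                window_index *= ALPHABET_SIZE
                window_index += codes[j : j + n_windows]
            pending.append(window_index)
            pending_size += n_windows
            if pending_size >= flush_at:
                counts += np.bincount(np.concatenate(pending), minlength=space)
                pending, pending_size = [], 0
    if pending:
        counts += np.bincount(np.concatenate(pending), minlength=space)
    return KmerCensus(
        k=k,
        counts=counts,
        total_windows=int(counts.sum()),
        residue_counts=residue_counts,
        n_records=n_records,
    )


def count_of(census: KmerCensus, peptide: str) -> int:
    """Occurrence count of one peptide in the census."""
    if len(peptide) != census.k:
        raise ValueError(
            f"peptide length {len(peptide)} does not match census "
            f"k={census.k}"
        )
    return int(census.counts[encode_kmer(peptide)])


def residue_frequencies(census: KmerCensus) -> np.ndarray:
    """Per-residue relative frequencies over the whole corpus (length-20
    vector summing to 1)."""
    total = census.residue_counts.sum()
    if total == 0:
        raise ValueError("corpus has no standard residues; frequencies undefined")
    return census.residue_counts / total


def _iter_kmer_strings(k: int) -> Iterator[str]:
    # itertools.product over the sorted alphabet yields k-mers in both
    # lexicographic and encoded order.
    for letters in itertools.product(ALPHABET, repeat=k):
        yield "".join(letters)


def write_counts_csv(census: KmerCensus, path: str | Path) -> None:
    """Write the full-space counts table as CSV: header ``kmer,count``,
    one row per element of the 20**k space in lexicographic order
    (nullomers appear with count 0).

    A path ending ``.csv.gz`` is gzip-compressed.  Output is
    byte-reproducible for a fixed census: the gzip member carries no
    timestamp or filename.
    """
    raw: IO[bytes]
    if str(path).endswith(".gz"):
        fileobj = open(path, "wb")
        raw = gzip.GzipFile(filename="", mode="wb", fileobj=fileobj, mtime=0)
    else:
        fileobj = None
        raw = open(path, "wb")
    try:
        with io.TextIOWrapper(raw, encoding="ascii", newline="\n") as text:
            text.write("kmer,count\n")
            counts = census.counts
            chunk: list[str] = []
            for index, kmer in enumerate(_iter_kmer_strings(census.k)):
                chunk.append(f"{kmer},{counts[index]}\n")
                if len(chunk) >= 100_000:
                    text.write("".join(chunk))
                    chunk.clear()
            text.write("".join(chunk))
    finally:
        if fileobj is not None:
            fileobj.close()


def read_counts_csv(path: str | Path) -> tuple[int, np.ndarray]:
    """Parse a counts CSV (plain or gzip) back to ``(k, counts)``."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt", encoding="ascii") as fh:  # type: ignore[operator]
        header = fh.readline().strip()
        if header != "kmer,count":
            raise ValueError(f"unexpected counts CSV header {header!r}")
        first = fh.readline().strip()
        kmer, value = first.split(",")
        k = len(kmer)
        counts = np.zeros(ALPHABET_SIZE**k, dtype=np.int64)
        counts[encode_kmer(kmer)] = int(value)
        for line in fh:
            kmer, value = line.strip().split(",")
            counts[encode_kmer(kmer)] = int(value)
    return k, counts


# ---------------------------------------------------------------------------
# Section 3 — null models, nullomers and rarity statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyModel:
    """A per-residue probability vector defining the positional-independence
    null model for expected k-mer counts.

    ``kind`` records the provenance: ``aa_occurrence`` (corpus residue
    composition) or ``codon_frequency`` (synonymous-codon counts).
    """

    kind: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("aa_occurrence", "codon_frequency"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (ALPHABET_SIZE,):
            raise ValueError("probs must have exactly 20 entries")
        if (probs < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {probs.sum()!r}, not 1")
        object.__setattr__(self, "probs", probs)

    def prob(self, letter: str) -> float:
        return float(self.probs[AA_TO_INDEX[letter]])


@dataclass(frozen=True)
class NeighborhoodRow:
    """One single-substitution variant of a query k-mer, with its observed
    census count, expected counts under both null models, the obs/exp
    ratio under the amino-acid model (None when the expectation is zero),
    and the Poisson lower-tail p-value under the amino-acid model."""

    variant: str
    position: int
    original_residue: str
    substituted_residue: str
    observed: int
    expected_aa: float
    expected_codon: float
    obs_over_exp_aa: float | None
    p_under_aa: float


@dataclass(frozen=True)
class RareHit:
    """An observed (count >= 1) k-mer flagged as under-represented."""

    kmer: str
    observed: int
    expected: float
    ratio: float
    p_under: float


def enumerate_nullomers(census: KmerCensus) -> list[str]:
    """All k-mers with occurrence count zero, in lexicographic order.

    Together with the observed k-mers this partitions the full 20**k
    space.
    """
    zero_indices = np.flatnonzero(census.counts == 0)
    return [decode_kmer(int(i), census.k) for i in zero_indices]


def count_nullomers(census: KmerCensus) -> int:
    """Number of nullomers, without materialising the decoded list."""
    return int((census.counts == 0).sum())


def aa_frequency_model(census: KmerCensus) -> FrequencyModel:
    """Null model from corpus amino-acid occurrence rates."""
    return FrequencyModel(kind="aa_occurrence", probs=residue_frequencies(census))


def codon_frequency_model(
    codon_counts: dict[str, int] | Sequence[int] | None = None,
) -> FrequencyModel:
    """Null model from per-residue sense-codon counts.

    With no argument, uses the standard genetic code's synonymous-codon
    counts over the 61 sense codons (so p(W) = p(M) = 1/61, p(L) = 6/61).
    A custom table — e.g. organism-specific codon usage — may be given as
    a residue->count mapping or a length-20 sequence in alphabet order;
    all counts must be positive.
    """
    if codon_counts is None:
        codon_counts = SENSE_CODON_COUNTS
    if isinstance(codon_counts, dict):
        missing = STANDARD_SET - codon_counts.keys()
        if missing:
            raise ValueError(f"codon counts missing residues {sorted(missing)}")
        values = np.array([codon_counts[a] for a in ALPHABET], dtype=float)
    else:
        values = np.asarray(codon_counts, dtype=float)
        if values.shape != (ALPHABET_SIZE,):
            raise ValueError("codon counts must have exactly 20 entries")
    if (values <= 0).any():
        raise ValueError("all codon counts must be positive")
    return FrequencyModel(kind="codon_frequency", probs=values / values.sum())


def expected_count(kmer: str, model: FrequencyModel, total_windows: int) -> float:
    """Expected occurrence count of a k-mer: ``total_windows`` times the
    product of its per-position residue probabilities (positions
    independent under the null)."""
    if not K_MIN <= len(kmer) <= K_MAX:
        raise ValueError(
            f"k-mer length {len(kmer)} outside [{K_MIN}, {K_MAX}]"
        )
    if total_windows < 0:
        raise ValueError("total_windows must be nonnegative")
    product = 1.0
    for letter in kmer:
        product *= model.prob(letter)
    return total_windows * product


def _expected_vector(model: FrequencyModel, k: int, total_windows: int) -> np.ndarray:
    """Expected counts for the whole 20**k space, in encoded order."""
    expected = np.array([float(total_windows)])
    for _ in range(k):
        expected = np.multiply.outer(expected, model.probs).ravel()
    return expected


def underrepresentation_pvalue(observed: int, expected: float) -> float:
    """Lower-tail Poisson probability P(X <= observed) with mean
    ``expected`` — the chance of seeing a count this low or lower if the
    k-mer occurred at its model-expected rate.

    With ``expected = 0`` the distribution is degenerate at zero and the
    p-value is 1.
    """
    if observed < 0:
        raise ValueError("observed count must be nonnegative")
    if expected < 0:
        raise ValueError("expected count must be nonnegative")
    if expected == 0:
        return 1.0
    return float(poisson.cdf(observed, expected))


def mutation_neighborhood(
    census: KmerCensus,
    kmer: str,
    aa_model: FrequencyModel,
    codon_model: FrequencyModel,
) -> list[NeighborhoodRow]:
    """All 19*k single-substitution variants of ``kmer``, ordered by
    position then substituted residue, each with its observed census count
    and expected counts under both null models.
    """
    if len(kmer) != census.k:
        raise ValueError(
            f"query length {len(kmer)} does not match census k={census.k}"
        )
    for pos, letter in enumerate(kmer):
        if letter not in STANDARD_SET:
            raise ValueError(
                f"nonstandard letter {letter!r} at position {pos} in query"
            )
    rows: list[NeighborhoodRow] = []
    for position in range(census.k):
        original = kmer[position]
        for substituted in ALPHABET:
            if substituted == original:
                continue
            variant = kmer[:position] + substituted + kmer[position + 1:]
            observed = count_of(census, variant)
            exp_aa = expected_count(variant, aa_model, census.total_windows)
            exp_codon = expected_count(variant, codon_model, census.total_windows)
            ratio = observed / exp_aa if exp_aa > 0 else None
            rows.append(
                NeighborhoodRow(
                    variant=variant,
                    position=position,
                    original_residue=original,
                    substituted_residue=substituted,
                    observed=observed,
                    expected_aa=exp_aa,
                    expected_codon=exp_codon,
                    obs_over_exp_aa=ratio,
                    p_under_aa=underrepresentation_pvalue(observed, exp_aa),
                )
            )
    return rows


def truncate_counts(census_kminus1: KmerCensus, kmer: str) -> tuple[int, int]:
    """Occurrence counts of the left truncate (k-mer minus its last
    residue) and right truncate (minus its first residue) in a census of
    length k-1."""
    if census_kminus1.k != len(kmer) - 1:
        raise ValueError(
            f"census k={census_kminus1.k} does not match truncate length "
            f"{len(kmer) - 1} of {kmer!r}"
        )
    left = count_of(census_kminus1, kmer[:-1])
    right = count_of(census_kminus1, kmer[1:])
    return left, right


def is_high_order_nullomer(census: KmerCensus, kmer: str) -> bool:
    """True iff ``kmer`` is a nullomer whose entire single-substitution
    mutation neighborhood (19*k variants) is also absent from the corpus.

    Raises if ``kmer`` itself is observed (it is then not a nullomer and
    the question is ill-posed).
    """
    if count_of(census, kmer) != 0:
        raise ValueError(f"{kmer!r} is observed in the census; not a nullomer")
    for position in range(census.k):
        for substituted in ALPHABET:
            if substituted == kmer[position]:
                continue
            variant = kmer[:position] + substituted + kmer[position + 1:]
            if count_of(census, variant) != 0:
                return False
    return True


def rank_rare(
    census: KmerCensus, model: FrequencyModel, max_pvalue: float
) -> list[RareHit]:
    """Observed k-mers (count >= 1) whose Poisson lower-tail p-value under
    ``model`` is at most ``max_pvalue``, sorted by ascending p-value, then
    ascending observed count, then lexicographic k-mer.

    Nullomers are reported separately by :func:`enumerate_nullomers`, never
    as rare hits.  No multiple-testing correction is applied; the threshold
    is the caller's.
    """
    if not 0 < max_pvalue <= 1:
        raise ValueError("max_pvalue must be in (0, 1]")
    observed_idx = np.flatnonzero(census.counts > 0)
    if len(observed_idx) == 0:
        return []
    expected = _expected_vector(model, census.k, census.total_windows)[observed_idx]
    observed = census.counts[observed_idx]
    pvals = np.where(expected > 0, poisson.cdf(observed, expected), 1.0)
    keep = pvals <= max_pvalue
    hits = [
        RareHit(
            kmer=decode_kmer(int(i), census.k),
            observed=int(o),
            expected=float(e),
            ratio=float(o / e) if e > 0 else math.inf,
            p_under=float(p),
        )
        for i, o, e, p in zip(
            observed_idx[keep], observed[keep], expected[keep], pvals[keep]
        )
    ]
    hits.sort(key=lambda h: (h.p_under, h.observed, h.kmer))
    return hits


def write_nullomers_csv(census: KmerCensus, path: str | Path) -> int:
    """Write the nullomer list as a single-column CSV (header ``kmer``),
    lexicographic order; returns the number of nullomers written."""
    nullomers = enumerate_nullomers(census)
    with open(path, "w", newline="\n") as fh:
        fh.write("kmer\n")
        for kmer in nullomers:
            fh.write(kmer + "\n")
    return len(nullomers)


def write_neighborhood_csv(rows: Iterable[NeighborhoodRow], path: str | Path) -> None:
    """Write mutation-neighborhood rows as CSV.  The obs/exp ratio is
    written as ``NA`` when the expectation is zero (never an
    infinity-as-number)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "kmer,position,original,substituted,observed,"
            "expected_aa,expected_codon,obs_over_exp_aa,p_under_aa\n"
        )
        for row in rows:
            ratio = "NA" if row.obs_over_exp_aa is None else repr(row.obs_over_exp_aa)
            fh.write(
                f"{row.variant},{row.position},{row.original_residue},"
                f"{row.substituted_residue},{row.observed},"
                f"{row.expected_aa!r},{row.expected_codon!r},"
                f"{ratio},{row.p_under_aa!r}\n"
            )


# ---------------------------------------------------------------------------
# Section 4 — synthetic corpora and the brute-force oracle
# ---------------------------------------------------------------------------

_REPAIR_LIMIT = 10_000


@dataclass
class SyntheticSpec:
    """Parameters for a seeded synthetic protein corpus.

    Record lengths are uniform in ``[length_low, length_high]``; residues
    are drawn i.i.d. from ``composition`` (alphabet order; defaults to
    uniform).  Every motif in ``avoided_motifs`` is guaranteed absent from
    the finished corpus; each ``(motif, copies)`` pair in
    ``planted_motifs`` is written into the corpus at non-overlapping random
    positions.  ``nonstandard_rate`` injects ambiguity letters
    (X/B/Z/J/U/O) at the given per-position rate outside planted spans.
    Generation is a pure function of the spec: the same seed gives a
    byte-identical corpus.
    """

    n_records: int
    length_low: int
    length_high: int
    composition: Sequence[float] | None = None
    avoided_motifs: list[str] = field(default_factory=list)
    planted_motifs: list[tuple[str, int]] = field(default_factory=list)
    nonstandard_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be nonnegative")
        if not 2 <= self.length_low <= self.length_high:
            raise ValueError("need 2 <= length_low <= length_high")
        if self.composition is None:
            self.composition = np.full(ALPHABET_SIZE, 1 / ALPHABET_SIZE)
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (ALPHABET_SIZE,) or (comp < 0).any():
            raise ValueError("composition must be 20 nonnegative probabilities")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        self.composition = comp
        if not 0 <= self.nonstandard_rate < 1:
            raise ValueError("nonstandard_rate must be in [0, 1)")
        planted_set = {m for m, _ in self.planted_motifs}
        if planted_set & set(self.avoided_motifs):
            raise ValueError("avoided and planted motif sets must be disjoint")
        for motif in self.avoided_motifs + list(planted_set):
            if not motif or set(motif) - STANDARD_SET:
                raise ValueError(f"motif {motif!r} must be standard-alphabet")
        for motif, _copies in self.planted_motifs:
            for avoided in self.avoided_motifs:
                if avoided in motif:
                    raise ValueError(
                        f"planted motif {motif!r} contains avoided "
                        f"motif {avoided!r}"
                    )


def _repair_avoided(
    residues: list[str],
    avoided: list[str],
    composition: np.ndarray,
    rng: np.random.Generator,
    frozen: set[int],
) -> None:
    """Resample positions until no avoided motif occurs.  Positions in
    ``frozen`` (planted spans) are never touched; a window that cannot be
    repaired within the attempt budget is an infeasibility error."""
    if not avoided:
        return
    attempts: dict[str, int] = {motif: 0 for motif in avoided}
    while True:
        # Repairing one motif can create another, so rescan all of them
        # until the sequence is jointly clean.
        text = "".join(residues)
        hit = None
        for motif in avoided:
            start = text.find(motif)
            if start != -1:
                hit = (motif, start)
                break
        if hit is None:
            return
        motif, start = hit
        attempts[motif] += 1
        if attempts[motif] > _REPAIR_LIMIT:
            raise ValueError(
                f"could not avoid motif {motif!r} after {_REPAIR_LIMIT} "
                "repair attempts; spec is infeasible"
            )
        candidates = [p for p in range(start, start + len(motif)) if p not in frozen]
        if not candidates:
            raise ValueError(
                f"avoided motif {motif!r} arises inside planted spans; "
                "spec is infeasible"
            )
        pos = candidates[int(rng.integers(len(candidates)))]
        residues[pos] = ALPHABET[int(rng.choice(ALPHABET_SIZE, p=composition))]


def generate_proteome(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Generate a synthetic corpus according to ``spec``.

    Pipeline per the spec contract: draw lengths and residues, repair away
    avoided motifs by local resampling, plant requested motif copies at
    non-overlapping positions (re-repairing any avoided occurrence a plant
    junction creates), then inject nonstandard letters outside planted
    spans.  Avoidance is re-verified at the end: every avoided motif has
    brute-force count zero in the returned corpus.
    """
    rng = np.random.default_rng(spec.seed)
    composition = np.asarray(spec.composition, dtype=float)
    lengths = [
        int(rng.integers(spec.length_low, spec.length_high + 1))
        for _ in range(spec.n_records)
    ]
    sequences: list[list[str]] = []
    for length in lengths:
        codes = rng.choice(ALPHABET_SIZE, size=length, p=composition)
        residues = [ALPHABET[int(c)] for c in codes]
        _repair_avoided(residues, spec.avoided_motifs, composition, rng, set())
        sequences.append(residues)

    # Plant motifs at corpus-random non-overlapping positions.
    planted_spans: dict[int, set[int]] = {i: set() for i in range(len(sequences))}
    for motif, copies in spec.planted_motifs:
        m = len(motif)
        slots = [
            (rec_i, off)
            for rec_i, seq in enumerate(sequences)
            for off in range(len(seq) - m + 1)
        ]
        placed = 0
        order = rng.permutation(len(slots)) if slots else []
        for slot_idx in order:
            if placed == copies:
                break
            rec_i, off = slots[int(slot_idx)]
            span = set(range(off, off + m))
            if span & planted_spans[rec_i]:
                continue
            for j, letter in enumerate(motif):
                sequences[rec_i][off + j] = letter
            planted_spans[rec_i] |= span
            placed += 1
        if placed < copies:
            raise ValueError(
                f"could not place {copies} non-overlapping copies of "
                f"{motif!r}; corpus too small"
            )
    # Planting can create avoided occurrences at junctions; repair them
    # without touching planted residues.
    for rec_i, residues in enumerate(sequences):
        _repair_avoided(
            residues, spec.avoided_motifs, composition, rng, planted_spans[rec_i]
        )

    if spec.nonstandard_rate > 0:
        for rec_i, residues in enumerate(sequences):
            mask = rng.random(len(residues)) < spec.nonstandard_rate
            for pos in np.flatnonzero(mask):
                if int(pos) in planted_spans[rec_i]:
                    continue
                residues[int(pos)] = NONSTANDARD_LETTERS[
                    int(rng.integers(len(NONSTANDARD_LETTERS)))
                ]

    records = [
        ProteinRecord(
            accession=f"SYN{i + 1:06d}",
            description="synthetic",
            sequence="".join(residues),
        )
        for i, residues in enumerate(sequences)
    ]
    for motif in spec.avoided_motifs:
        assert brute_force_count(records, motif) == 0, motif
    return records


def brute_force_count(records: Sequence[ProteinRecord], peptide: str) -> int:
    """Independent naive oracle: total overlapping occurrences of
    ``peptide`` across all records, by position-by-position string
    comparison.

    Shares no code with the census path (no encoding, no segmentation):
    because the peptide is standard-alphabet, any window containing a
    nonstandard letter simply fails the comparison, which is exactly the
    census's never-span-nonstandard rule.
    """
    if len(peptide) < 2:
        raise ValueError("peptide must have length >= 2")
    if set(peptide) - STANDARD_SET:
        raise ValueError(f"peptide {peptide!r} must be standard-alphabet")
    m = len(peptide)
    total = 0
    for record in records:
        seq = record.sequence
        for i in range(len(seq) - m + 1):
            if seq[i : i + m] == peptide:
                total += 1
    return total
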