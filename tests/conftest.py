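"""Shared fixtures and the independent counting oracle used across tests."""

from collections import Counter

import pytest

from pepnull import ProteinRecord, SyntheticSpec, generate_proteome

STANDARD = set("ACDEFGHIKLMNPQRSTVWY")

UNIPROT_XML_TWO_ENTRIES = """\
<?xml version="1.0" encoding="UTF-8"?>
<uniprot xmlns="http://uniprot.org/uniprot">
  <entry dataset="Swiss-Prot">
    <accession>P00001</accession>
    <protein>
      <recommendedName><fullName>Alpha test protein</fullName></recommendedName>
    </protein>
    <sequence length="8" mass="900">ACDEFGHI
KLMNP</sequence>
  </entry>
  <entry dataset="Swiss-Prot">
    <accession>P00002</accession>
    <sequence length="6">MKVWWA</sequence>
  </entry>
</uniprot>
"""

UNIPROT_XML_MISSING_SEQ = """\
<?xml version="1.0" encoding="UTF-8"?>
<uniprot xmlns="http://uniprot.org/uniprot">
  <entry><accession>P00003</accession><sequence>ACDEF</sequence></entry>
  <entry><accession>P00004</accession></entry>
</uniprot>
"""


def naive_window_counts(records, k):
    """Independent census oracle: direct substring scan with a Counter.

    A window counts iff every letter in it is one of the 20 standard
    amino acids, so windows never span nonstandard letters.
    """
    counts = Counter()
    for rec in records:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) <= STANDARD:
                counts[window] += 1
    return counts


@pytest.fixture
def small_corpus():
    """A deterministic 30-record corpus with some nonstandard letters."""
    spec = SyntheticSpec(
        n_records=30,
        length_low=40,
        length_high=120,
        nonstandard_rate=0.02,
        seed=20180201,
    )
    return generate_proteome(spec)


@pytest.fixture
def xml_file(tmp_path):
    path = tmp_path / "two_entries.xml"
    path.write_text(UNIPROT_XML_TWO_ENTRIES)
    return path
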