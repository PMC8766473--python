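import textwrap

import pytest

from mitoarch import load_reference_table
from mitoarch.architecture import architecture_report
from mitoarch.synthetic_data import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def ref_record():
    return load_reference_table()


@pytest.fixture(scope="session")
def ref_report(ref_record):
    return architecture_report(ref_record)


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic genome over the packaged layout, seed 7."""
    return generate_genome(GenomeSpec(seed=7))


def make_genbank(path, length, feature_block, sequence=None):
    """Write a minimal handcrafted GenBank flat file."""
    seq = (sequence or ("atgaaataag" * (length // 10 + 1)))[:length]
    origin_lines = []
    for i in range(0, length, 60):
        chunk = seq[i:i + 60]
        parts = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        origin_lines.append(f"{i + 1:>9} {parts}")
    text = textwrap.dedent(f"""\
        LOCUS       TEST0001             {length:>7} bp    DNA     circular VRT 01-JAN-2022
        DEFINITION  synthetic test record.
        ACCESSION   TEST0001
        VERSION     TEST0001.1
        SOURCE      test organism
          ORGANISM  test organism
        FEATURES             Location/Qualifiers
             source          1..{length}
                             /organism="test organism"
        """) + feature_block + "\nORIGIN      \n" + "\n".join(origin_lines) + "\n//\n"
    path.write_text(text)
    return path
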