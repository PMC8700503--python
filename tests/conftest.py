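import numpy as np
import pandas as pd
import pytest

from hybridte.tecount import AlignmentRecord

RM_HEADER = (
    "   SW   perc perc perc  query     position in query    matching repeat  position in repeat\n"
    "score   div. del. ins.  sequence  begin end   (left)   repeat   class/family begin end (left) ID\n"
    "\n"
)


def rm_line(scaffold, begin, end, strand, name, cls, block_id, div=10.0):
    """One synthetic RepeatMasker .out data line."""
    sym = "+" if strand == "+" else "C"
    return (
        f" 1000 {div:4.1f}  0.0  0.0  {scaffold} {begin} {end} (0) {sym} "
        f"{name} {cls} 1 {end - begin + 1} (0) {block_id}\n"
    )


@pytest.fixture
def rm_text():
    """Builder for small RepeatMasker .out files."""

    def build(lines):
        return RM_HEADER + "".join(rm_line(*args) for args in lines)

    return build


@pytest.fixture
def simple_alignments():
    """3 reads on copy1 (famA), 2 on copy2 (famA), 1 on copy3 (famB)."""
    alns = []
    for i in range(3):
        alns.append(AlignmentRecord(f"r{i}", "copy1", 10 + i, "sense", 25))
    for i in range(2):
        alns.append(AlignmentRecord(f"s{i}", "copy2", 50 + i, "antisense", 25))
    alns.append(AlignmentRecord("t0", "copy3", 5, "sense", 25))
    return alns


@pytest.fixture
def copy_map():
    return {"copy1": "famA", "copy2": "famA", "copy3": "famB"}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
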