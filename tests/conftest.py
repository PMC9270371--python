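import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from xlfdr.library import LibraryPeptide, PeptideLibrary
from xlfdr.results import CrosslinkRecord


@pytest.fixture
def small_library() -> PeptideLibrary:
    """Five lysine-chemistry peptides in two crosslink groups."""
    peps = [
        LibraryPeptide("MAKTIK", "G1", "P1", 10, 3),
        LibraryPeptide("LSYDTEASIAKAK", "G1", "P2", 5, 11),
        LibraryPeptide("VAVIKAVR", "G2", "P3", 20, 5),
        LibraryPeptide("GAKWR", "G2", "P3", 7, 3),
        LibraryPeptide("APKTLR", "G2", "P4", 1, 3),
    ]
    return PeptideLibrary(library_id="small", peptides=peps)


@pytest.fixture
def groups_of(small_library) -> dict[str, str]:
    return {p.sequence: p.group_id for p in small_library.peptides}


def record(seq_a, seq_b, score=100.0, lib=None, **kw) -> CrosslinkRecord:
    """CSM record helper; fills protein/position/site from library if given."""
    fields = dict(seq_a=seq_a, seq_b=seq_b, score=score, raw_score=score)
    if lib is not None:
        for side, seq in (("a", seq_a), ("b", seq_b)):
            p = lib.get(seq)
            if p is not None:
                fields[f"protein_{side}"] = p.protein_id
                fields[f"pos_{side}"] = p.start_pos
                fields[f"site_{side}"] = p.site_pos
    fields.update(kw)
    return CrosslinkRecord(**fields)
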