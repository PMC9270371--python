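"""Synthetic peptide library model: ground truth for crosslink validation.

A validation library consists of synthetic tryptic peptides, each carrying
exactly one crosslink-able residue (K for amine-reactive chemistry, D/E for
acid-reactive chemistry).  Peptides are partitioned into crosslink groups and
each group is crosslinked in its own reaction vial, so only links joining two
peptides of the same group can be genuine.  Any reported link across groups,
or involving a sequence never synthesized, is a known false positive — the
basis of the experimentally validated FDR.

This module represents libraries, digests protected synthesis constructs to
their final tryptic form, enumerates the theoretical crosslink space
(grouped or pooled) and classifies arbitrary peptide pairs as true/false.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

AA20 = "ACDEFGHIKLMNPQRSTVWY"

Chemistry = Literal["lysine", "acidic"]
LinkClass = Literal["homeotypic", "intraprotein", "interprotein"]
TruthLabel = Literal["within_group_true", "cross_group_false", "non_library_false"]

#: residues attacked by each crosslinker chemistry
REACTIVE_RESIDUES: dict[str, frozenset[str]] = {
    "lysine": frozenset("K"),
    "acidic": frozenset("DE"),
}


class LibraryError(ValueError):
    """Invalid library definition (schema or consistency violation)."""


class InvalidConstructError(ValueError):
    """Synthesis construct violates the tag grammar."""


def _check_sequence(seq: str) -> str:
    if not seq or any(c not in AA20 for c in seq):
        raise LibraryError(
            f"sequence {seq!r} is not an uppercase string of the 20 standard residues"
        )
    return seq


def reactive_positions(sequence: str, chemistry: str) -> list[int]:
    """1-based positions of chemistry-reactive residues in *sequence*.

    The tryptic C-terminal residue is never counted: for amine chemistry the
    C-terminal lysine is azide-protected during crosslinking (reduced to a
    plain K only afterwards), and for acid chemistry the terminal K/R merely
    marks the tryptic cleavage site.
    """
    targets = REACTIVE_RESIDUES[chemistry]
    last = len(sequence)
    out = []
    for i, aa in enumerate(sequence, start=1):
        if aa in targets and not (i == last and sequence[-1] in "KR"):
            out.append(i)
    return out


@dataclass(frozen=True)
class LibraryPeptide:
    """One synthetic tryptic peptide with group and protein provenance.

    Positions are 1-based inclusive; the crosslink site in the source protein
    is ``start_pos + site_pos - 1``.
    """

    sequence: str
    group_id: str
    protein_id: str
    start_pos: int
    site_pos: int
    chemistry: str = "lysine"

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.chemistry not in REACTIVE_RESIDUES:
            raise LibraryError(f"unknown chemistry {self.chemistry!r}")
        if not (1 <= self.site_pos <= len(self.sequence)):
            raise LibraryError(
                f"site_pos {self.site_pos} outside peptide {self.sequence!r}"
            )
        sites = reactive_positions(self.sequence, self.chemistry)
        if sites != [self.site_pos]:
            raise LibraryError(
                f"peptide {self.sequence!r} ({self.chemistry}) must contain exactly "
                f"one reactive residue at site_pos={self.site_pos}; found sites {sites}"
            )

    @property
    def protein_site(self) -> int:
        """Crosslink site position in the source protein (1-based)."""
        return self.start_pos + self.site_pos - 1


@dataclass(frozen=True)
class SynthesisConstruct:
    """A protected solid-phase synthesis construct before tryptic release.

    ``n_tag``/``c_tag`` are protection tags (e.g. ``acetyl-WGGGGR`` /
    ``GGGG-amide``); decorations separated by ``-`` are ignored, only residue
    letters matter.  ``azide_k`` flags an azide-protected C-terminal lysine.
    """

    core: str
    n_tag: str | None = None
    c_tag: str | None = None
    azide_k: bool = False


_TAG_DECORATIONS = re.compile(r"(acetyl|amide|ac|nh2)", re.IGNORECASE)


def _tag_residues(tag: str) -> str:
    parts = [p for p in tag.split("-") if p and not _TAG_DECORATIONS.fullmatch(p)]
    residues = "".join(parts).upper()
    if any(c not in AA20 for c in residues):
        raise InvalidConstructError(f"tag {tag!r} contains non-residue characters")
    return residues


def digest_construct(construct: SynthesisConstruct) -> str:
    """Tryptic release of the final library peptide from a protected construct.

    Strips both protection tags and maps an azide-modified C-terminal lysine
    back to plain K (the reduced form seen by the search engine).  The N-tag,
    if present, must end in K or R — otherwise trypsin could not release the
    core and the construct is invalid.
    """
    core = construct.core
    if not core:
        raise InvalidConstructError("empty core sequence")
    _check_sequence(core.upper())
    if construct.n_tag is not None:
        residues = _tag_residues(construct.n_tag)
        if not residues or residues[-1] not in "KR":
            raise InvalidConstructError(
                f"N-terminal tag {construct.n_tag!r} does not end in K/R; "
                "tryptic release impossible"
            )
    if construct.c_tag is not None:
        _tag_residues(construct.c_tag)
    # azide-K reduction restores the plain residue letter; sequence unchanged
    return core.upper()


@dataclass
class PeptideLibrary:
    """A validated peptide library: peptides partitioned into crosslink groups."""

    library_id: str
    peptides: list[LibraryPeptide]
    _by_sequence: dict[str, LibraryPeptide] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_seq: dict[str, LibraryPeptide] = {}
        for p in self.peptides:
            prev = by_seq.get(p.sequence)
            if prev is not None and prev.group_id != p.group_id:
                raise LibraryError(
                    f"sequence {p.sequence!r} allocated to two groups "
                    f"({prev.group_id!r} and {p.group_id!r})"
                )
            by_seq.setdefault(p.sequence, p)
        self._by_sequence = by_seq

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self._by_sequence

    def get(self, sequence: str) -> LibraryPeptide | None:
        return self._by_sequence.get(sequence)

    @property
    def groups(self) -> dict[str, list[LibraryPeptide]]:
        out: dict[str, list[LibraryPeptide]] = {}
        for p in self.peptides:
            out.setdefault(p.group_id, []).append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [p.sequence for p in self.peptides],
                "group": [p.group_id for p in self.peptides],
                "protein": [p.protein_id for p in self.peptides],
                "start": [p.start_pos for p in self.peptides],
                "site": [p.site_pos for p in self.peptides],
                "chemistry": [p.chemistry for p in self.peptides],
            }
        )


#: canonical support-file column names
SUPPORT_COLUMNS = ("sequence", "group", "protein", "start", "site", "chemistry")


def load_library(
    support_file: str | Path,
    dialect: Mapping[str, str] | None = None,
    library_id: str | None = None,
) -> PeptideLibrary:
    """Read a group-allocation support file into a :class:`PeptideLibrary`.

    The support file is a delimited table (CSV by default, TSV accepted by
    extension or sniffing) with one row per library peptide.  ``dialect`` maps
    canonical column names (``sequence, group, protein, start, site,
    chemistry``) to the file's actual headers; omitted entries default to the
    canonical names.  Duplicate (sequence, group) rows collapse to one
    peptide; a sequence allocated to two groups is a consistency error.
    """
    path = Path(support_file)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] == 1 and sep == ",":  # tolerate TSV content in .csv
        df = pd.read_csv(path, sep="\t", dtype=str)

    colmap = {c: c for c in SUPPORT_COLUMNS}
    if dialect:
        colmap.update(dialect)
    missing = [colmap[c] for c in ("sequence", "group", "protein", "start", "site")
               if colmap[c] not in df.columns]
    if missing:
        raise LibraryError(f"support file {path} missing column(s): {missing}")

    has_chem = colmap["chemistry"] in df.columns
    peptides: list[LibraryPeptide] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        seq = str(row[colmap["sequence"]]).strip().upper()
        grp = str(row[colmap["group"]]).strip()
        if (seq, grp) in seen:
            continue
        seen.add((seq, grp))
        peptides.append(
            LibraryPeptide(
                sequence=seq,
                group_id=grp,
                protein_id=str(row[colmap["protein"]]).strip(),
                start_pos=int(row[colmap["start"]]),
                site_pos=int(row[colmap["site"]]),
                chemistry=str(row[colmap["chemistry"]]).strip().lower()
                if has_chem
                else "lysine",
            )
        )
    return PeptideLibrary(library_id=library_id or path.stem, peptides=peptides)


@dataclass(frozen=True)
class TheoreticalCrosslink:
    """An unordered pair of library peptides that could form a crosslink."""

    peptide_a: LibraryPeptide
    peptide_b: LibraryPeptide
    link_class: str
    same_group: bool


def _link_class(a: LibraryPeptide, b: LibraryPeptide) -> str:
    if a.sequence == b.sequence:
        return "homeotypic"
    if a.protein_id == b.protein_id:
        return "intraprotein"
    return "interprotein"


@dataclass
class TheoreticalSpace:
    """All in-silico crosslink combinations of a library under one mode.

    ``pooled`` enumerates every unordered pair including self-pairs,
    n(n+1)/2 combinations for n peptides; ``grouped`` restricts pairs to
    within-group, Σ_g n_g(n_g+1)/2.
    """

    mode: str
    crosslinks: list[TheoreticalCrosslink]

    def __len__(self) -> int:
        return len(self.crosslinks)

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(x.link_class for x in self.crosslinks)
        return {
            "homeotypic": c.get("homeotypic", 0),
            "intraprotein": c.get("intraprotein", 0),
            "interprotein": c.get("interprotein", 0),
            "total": len(self.crosslinks),
        }


def enumerate_theoretical(
    library: PeptideLibrary, mode: Literal["grouped", "pooled"] = "grouped"
) -> TheoreticalSpace:
    """Enumerate the theoretical crosslink space of *library*.

    Self-pairs (homeotypic links) are included in both modes; pooling a
    43-peptide library therefore yields 43·44/2 = 946 combinations.
    """
    if len(library) == 0:
        raise LibraryError("cannot enumerate an empty library")
    if mode not in ("grouped", "pooled"):
        raise ValueError(f"mode must be 'grouped' or 'pooled', got {mode!r}")

    def pairs(peps: list[LibraryPeptide], same_group: bool) -> Iterable[TheoreticalCrosslink]:
        for i in range(len(peps)):
            for j in range(i, len(peps)):
                a, b = peps[i], peps[j]
                yield TheoreticalCrosslink(a, b, _link_class(a, b), same_group)

    if mode == "pooled":
        xs = list(pairs(library.peptides, same_group=False))
        # a pooled pair may still be within one group
        xs = [
            TheoreticalCrosslink(
                x.peptide_a, x.peptide_b, x.link_class,
                x.peptide_a.group_id == x.peptide_b.group_id,
            )
            for x in xs
        ]
    else:
        xs = []
        for members in library.groups.values():
            xs.extend(pairs(members, same_group=True))
    return TheoreticalSpace(mode=mode, crosslinks=xs)


def classify_pair(
    seq_a: str, seq_b: str, library: PeptideLibrary
) -> tuple[TruthLabel, LinkClass | None]:
    """Assign the ground-truth label and link class of a peptide pair.

    Returns ``(label, link_class)``; ``link_class`` is None when either
    sequence is absent from the library.  Sequence identity is literal string
    equality (I/L distinct): an isobaric permutation of a library peptide is
    a non-library false positive, exactly how a wrongly annotated spectrum
    presents in practice.
    """
    a = library.get(seq_a.upper())
    b = library.get(seq_b.upper())
    if a is None or b is None:
        return "non_library_false", None
    cls = _link_class(a, b)
    if a.group_id != b.group_id:
        return "cross_group_false", cls
    return "within_group_true", cls


def near_isobaric_pairs(library: PeptideLibrary) -> list[tuple[str, str]]:
    """Diagnostic: library sequence pairs with identical residue composition.

    Such permutations (e.g. MAKLTK vs MAKTIK) have identical mass and are the
    typical source of non-library false positives.
    """
    by_comp: dict[frozenset, list[str]] = {}
    for p in library.peptides:
        key = frozenset(Counter(p.sequence).items())
        by_comp.setdefault(key, []).append(p.sequence)
    out = []
    for seqs in by_comp.values():
        uniq = sorted(set(seqs))
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                out.append((uniq[i], uniq[j]))
    return out
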