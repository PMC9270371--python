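"""Physicochemical properties and sequence context of crosslinks.

Crosslinked peptide pairs are represented in a linearized form — the two
sequences concatenated in canonical (lexicographic) order — so that standard
protein-parameter utilities built for linear peptides apply.  Computed per
crosslink: isoelectric point, aromatic fraction, monoisotopic mass (summing
the two peptides and an optional crosslinker delta), Kyte–Doolittle GRAVY
and amino-acid frequencies.  The observed amino-acid distribution can be
compared to the theoretical library expectation under the assumption that
every theoretical crosslink yields exactly one CSM, and the sequence context
of the link site is summarized as a position probability matrix over the
three neighboring residues on either side.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from pyteomics import mass as pmass

from .library import AA20, PeptideLibrary, TheoreticalSpace, enumerate_theoretical
from .results import CrosslinkRecord

#: monoisotopic mass deltas [Da] of common crosslinker additions
CROSSLINKER_MASSES = {
    "none": 0.0,
    "DSSO": 158.00376,
    "DSBU": 196.08479,
    "CDI": 25.97926,
    "DHSO": 144.01245,
}


class PropertyError(ValueError):
    """Record cannot be linearized or scored (e.g. non-standard residue)."""


@dataclass(frozen=True)
class LinearizedCrosslink:
    """A crosslinked pair flattened to one residue string.

    ``parts`` keeps the constituent peptides (needed for correct mass: one
    water per peptide chain); ``sequence`` is their lexicographic
    concatenation.  ``mass_extra`` is the crosslinker addition in Da.
    """

    sequence: str
    parts: tuple[str, str]
    mass_extra: float = 0.0


def linearize_pair(
    record: CrosslinkRecord, mass_extra: float = 0.0
) -> LinearizedCrosslink:
    """Flatten a crosslink record to its canonical linearized form."""
    a, b = sorted((record.seq_a, record.seq_b))
    if not a or not b:
        raise PropertyError("both peptide sequences must be present")
    return LinearizedCrosslink(sequence=a + b, parts=(a, b), mass_extra=mass_extra)


@dataclass
class PropertyRecord:
    """Physicochemical properties of one linearized crosslink."""

    sequence: str
    isoelectric_point: float
    aromaticity: float
    molecular_mass: float
    gravy: float
    aa_frequencies: dict[str, float]


def compute_properties(xl: LinearizedCrosslink) -> PropertyRecord:
    """Protein-parameter profile of a linearized crosslink.

    GRAVY and aromatic fraction are computed on the concatenated sequence
    (both are length-normalized averages).  The isoelectric point uses
    Henderson–Hasselbalch net-charge bisection with the ProtParam pKa table.
    Mass is the sum of the constituent peptides' monoisotopic masses (each
    with its own water) plus the crosslinker delta.
    """
    seq = xl.sequence
    if any(c not in AA20 for c in seq):
        bad = sorted({c for c in seq if c not in AA20})
        raise PropertyError(f"non-standard residue(s) {bad} in {seq!r}")
    pa = ProteinAnalysis(seq)
    mono = sum(pmass.fast_mass(p, ion_type="M") for p in xl.parts) + xl.mass_extra
    n = len(seq)
    freqs = {aa: seq.count(aa) / n for aa in AA20}
    return PropertyRecord(
        sequence=seq,
        isoelectric_point=pa.isoelectric_point(),
        aromaticity=pa.aromaticity(),
        molecular_mass=mono,
        gravy=pa.gravy(),
        aa_frequencies=freqs,
    )


def properties_table(
    records: Sequence[CrosslinkRecord], mass_extra: float = 0.0
) -> pd.DataFrame:
    """Per-crosslink property CSV content; unparseable records are skipped."""
    import logging

    rows = []
    for r in records:
        try:
            p = compute_properties(linearize_pair(r, mass_extra))
        except PropertyError as exc:
            logging.getLogger(__name__).warning("skipping record: %s", exc)
            continue
        rows.append({
            "sequence_a": r.seq_a, "sequence_b": r.seq_b,
            "linearized": p.sequence, "pI": p.isoelectric_point,
            "aromaticity": p.aromaticity, "monoisotopic_mass": p.molecular_mass,
            "gravy": p.gravy,
        })
    return pd.DataFrame(rows)


def _aa_frequencies(sequences: Sequence[str]) -> dict[str, float]:
    counts = Counter()
    for s in sequences:
        counts.update(s)
    total = sum(counts.values())
    if total == 0:
        raise PropertyError("no residues to count")
    return {aa: counts.get(aa, 0) / total for aa in AA20}


@dataclass
class DistributionComparison:
    """Observed vs theoretically expected amino-acid frequencies.

    Expected frequencies come from the library's theoretical crosslink space,
    counting each combination exactly once (the one-CSM-per-crosslink
    assumption); observed frequencies come from the identified records.
    """

    observed: dict[str, float]
    expected: dict[str, float]
    level: str

    @property
    def ratio(self) -> dict[str, float]:
        return {aa: (self.observed[aa] / self.expected[aa])
                if self.expected[aa] > 0 else float("nan")
                for aa in AA20}

    @property
    def difference(self) -> dict[str, float]:
        return {aa: self.observed[aa] - self.expected[aa] for aa in AA20}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "observed": pd.Series(self.observed),
            "expected": pd.Series(self.expected),
            "ratio": pd.Series(self.ratio),
            "difference": pd.Series(self.difference),
        }).rename_axis("amino_acid")


def distribution_comparison(
    records: Sequence[CrosslinkRecord],
    library: PeptideLibrary,
    mode: Literal["grouped", "pooled"] = "grouped",
    level: Literal["csm", "unique_link"] = "csm",
) -> DistributionComparison:
    """Compare observed residue frequencies with the library expectation.

    *records* are counted at the given level (CSM level weights each spectrum
    match; unique-link level each residue pair once — pass the appropriate
    record set).  The expectation enumerates the theoretical space in *mode*
    and counts each crosslink's linearized sequence once.
    """
    if not records:
        raise PropertyError("no identified records to compare")
    observed = _aa_frequencies([r.seq_a + r.seq_b for r in records])
    space: TheoreticalSpace = enumerate_theoretical(library, mode)
    expected = _aa_frequencies(
        [x.peptide_a.sequence + x.peptide_b.sequence for x in space.crosslinks]
    )
    return DistributionComparison(observed=observed, expected=expected, level=level)


@dataclass
class PositionProbabilityMatrix:
    """Amino-acid probabilities at offsets −w…+w around the link site.

    Offset 0 is the linked residue itself (included by declaration).  Each
    linked peptide side of each record contributes one residue per in-range
    offset; offsets beyond the peptide termini contribute nothing.  Columns
    with support are normalized to sum to 1; zero-support columns are flagged
    in ``empty_offsets`` and left all-zero.
    """

    window: int
    probabilities: pd.DataFrame  # index: AA20, columns: offsets
    support: dict[int, int]
    include_site: bool = True

    @property
    def empty_offsets(self) -> list[int]:
        return [o for o, s in self.support.items() if s == 0]


def ppm_around_site(
    records: Sequence[CrosslinkRecord], window: int = 3
) -> PositionProbabilityMatrix:
    """Position probability matrix of the link-site sequence context."""
    sides = []
    for r in records:
        if r.site_a is not None:
            sides.append((r.seq_a, r.site_a))
        if r.site_b is not None:
            sides.append((r.seq_b, r.site_b))
    if not sides:
        raise PropertyError("no records carry link-site positions")
    offsets = list(range(-window, window + 1))
    counts = {o: Counter() for o in offsets}
    for seq, site in sides:
        for o in offsets:
            pos = site + o  # 1-based
            if 1 <= pos <= len(seq):
                counts[o][seq[pos - 1]] += 1
    mat = pd.DataFrame(0.0, index=list(AA20), columns=offsets)
    support = {}
    for o in offsets:
        total = sum(counts[o].values())
        support[o] = total
        if total:
            for aa, c in counts[o].items():
                mat.loc[aa, o] = c / total
    return PositionProbabilityMatrix(window=window, probabilities=mat, support=support)


def plot_ppm(ppm: PositionProbabilityMatrix, path: str, title: str = "") -> None:
    """Stacked-bar motif plot of a position probability matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    offsets = list(ppm.probabilities.columns)
    bottom = np.zeros(len(offsets))
    cmap = plt.get_cmap("tab20")
    for i, aa in enumerate(ppm.probabilities.index):
        vals = ppm.probabilities.loc[aa].to_numpy(dtype=float)
        if vals.sum() == 0:
            continue
        ax.bar(range(len(offsets)), vals, bottom=bottom,
               color=cmap(i % 20), label=aa, width=0.8)
        bottom += vals
    ax.set_xticks(range(len(offsets)), [str(o) for o in offsets])
    ax.set_xlabel("offset from link site")
    ax.set_ylabel("probability")
    ax.legend(ncols=2, fontsize=6, loc="center left", bbox_to_anchor=(1.0, 0.5))
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_distribution(
    comparison: DistributionComparison, path: str, title: str = ""
) -> None:
    """Observed-vs-expected amino-acid frequency bar chart (area 1 each)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = np.arange(len(AA20))
    obs = [comparison.observed[a] for a in AA20]
    exp = [comparison.expected[a] for a in AA20]
    ax.bar(x - 0.2, obs, width=0.4, label="observed")
    ax.bar(x + 0.2, exp, width=0.4, label="expected (theoretical)")
    ax.set_xticks(x, list(AA20))
    ax.set_ylabel("frequency")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
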