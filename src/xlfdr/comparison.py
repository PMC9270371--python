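"""Canonical link identity and multi-set overlap analysis.

Two engines (or two replicates) report the same unique crosslink when the
peptide sequences, their originating proteins and the peptide start positions
in those proteins agree — regardless of engine, score or modification
annotation.  Link-site positions within the peptides are excluded from the
default key because engines frequently disagree on the exact site within a
peptide; a strict mode includes them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .library import PeptideLibrary
    from .results import CrosslinkRecord
    from .validation import ValidationResult

logger = logging.getLogger(__name__)

LinkKey = tuple[tuple, tuple]


def make_link_key(record: "CrosslinkRecord", strict: bool = False) -> LinkKey:
    """Canonical, swap-invariant identity of a crosslink record.

    Each side is ``(sequence, protein, position)`` — plus the link site in
    strict mode — and the two sides are ordered lexicographically, so
    ``key(A–B) == key(B–A)``.  When protein or position is missing the key
    degrades to sequence-only (with a warning) so records from sparse exports
    still compare.
    """
    def side(seq: str, prot: str, pos: int | None, site: int | None) -> tuple:
        if prot == "" or pos is None:
            return (seq,) + ((site,) if strict else ())
        return (seq, prot, pos) + ((site,) if strict else ())

    a = side(record.seq_a, record.protein_a, record.pos_a, record.site_a)
    b = side(record.seq_b, record.protein_b, record.pos_b, record.site_b)
    if len(a) != len(b) or (not strict and len(a) == 1):
        if record.protein_a == "" or record.protein_b == "" \
                or record.pos_a is None or record.pos_b is None:
            logger.warning(
                "link key for %s–%s degraded to sequence-only "
                "(missing protein/position)", record.seq_a, record.seq_b,
            )
            a = (record.seq_a,) + ((record.site_a,) if strict else ())
            b = (record.seq_b,) + ((record.site_b,) if strict else ())
    return (a, b) if a <= b else (b, a)


@dataclass
class OverlapResult:
    """Exact region partition of 2+ labeled link sets, with per-region FDR.

    Regions are keyed by the frozenset of set labels containing the link;
    every key of the union appears in exactly one region.
    """

    set_labels: tuple[str, ...]
    region_membership: dict[frozenset, list[LinkKey]]
    region_fdr: dict[frozenset, "ValidationResult"]

    @property
    def region_counts(self) -> dict[frozenset, int]:
        return {r: len(ks) for r, ks in self.region_membership.items()}

    def count(self, *labels: str) -> int:
        """Number of links exactly in the region defined by *labels*."""
        return len(self.region_membership.get(frozenset(labels), ()))


def compute_overlap(
    sets: Mapping[str, Sequence["CrosslinkRecord"]],
    library: "PeptideLibrary",
    strict: bool = False,
) -> OverlapResult:
    """Partition the union of labeled unique-link sets into exclusive regions.

    For each region the experimentally validated FDR is computed on the links
    of that region (each link represented once, by its best-scoring record).
    Any number of sets is supported programmatically; Venn rendering is
    limited to 2–3.
    """
    from .validation import validated_fdr

    labels = tuple(sets.keys())
    membership: dict[LinkKey, set[str]] = {}
    best: dict[LinkKey, "CrosslinkRecord"] = {}
    conflicts: list[LinkKey] = []
    seq_seen: dict[tuple, LinkKey] = {}
    for label, records in sets.items():
        for r in records:
            k = make_link_key(r, strict=strict)
            membership.setdefault(k, set()).add(label)
            if k not in best or r.score > best[k].score:
                best[k] = r
            seq_key = tuple(sorted((r.seq_a, r.seq_b)))
            prev = seq_seen.setdefault(seq_key, k)
            if prev != k:
                conflicts.append(k)
    if conflicts:
        logger.warning(
            "%d link(s) share peptide sequences but differ in protein/position "
            "mapping across sets; kept separate, review dialects", len(conflicts),
        )

    region_membership: dict[frozenset, list[LinkKey]] = {}
    for k, labs in membership.items():
        region_membership.setdefault(frozenset(labs), []).append(k)
    for ks in region_membership.values():
        ks.sort()

    region_fdr = {
        region: validated_fdr([best[k] for k in ks], library, level="unique_link")
        for region, ks in region_membership.items()
    }
    return OverlapResult(labels, region_membership, region_fdr)


def plot_venn(overlap: OverlapResult, path: str, title: str = "") -> None:
    """Render a 2- or 3-set Venn diagram with region counts and FDRs.

    Drawn with plain matplotlib circle patches; each region is annotated with
    its link count and validated FDR.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    from .validation import format_percent

    labels = overlap.set_labels
    n = len(labels)
    if n not in (2, 3):
        raise ValueError(f"Venn rendering supports 2-3 sets, got {n}")

    centers = {2: [(-0.45, 0.0), (0.45, 0.0)],
               3: [(-0.45, -0.26), (0.45, -0.26), (0.0, 0.52)]}[n]
    # region annotation anchor per label-subset
    anchors: dict[frozenset, tuple[float, float]] = {}
    if n == 2:
        anchors = {frozenset([labels[0]]): (-0.85, 0.0),
                   frozenset([labels[1]]): (0.85, 0.0),
                   frozenset(labels): (0.0, 0.0)}
    else:
        a, b, c = labels
        anchors = {
            frozenset([a]): (-0.85, -0.45), frozenset([b]): (0.85, -0.45),
            frozenset([c]): (0.0, 1.0),
            frozenset([a, b]): (0.0, -0.5), frozenset([a, c]): (-0.55, 0.35),
            frozenset([b, c]): (0.55, 0.35), frozenset([a, b, c]): (0.0, 0.0),
        }

    fig, ax = plt.subplots(figsize=(6, 5))
    colors = ["tab:blue", "tab:orange", "tab:green"]
    for (cx, cy), lab, col in zip(centers, labels, colors):
        ax.add_patch(Circle((cx, cy), 0.8, alpha=0.3, color=col))
        ax.annotate(lab, (cx, cy + 0.88), ha="center", fontsize=11, color=col)
    for region, (x, y) in anchors.items():
        cnt = len(overlap.region_membership.get(region, ()))
        vr = overlap.region_fdr.get(region)
        txt = str(cnt)
        if vr is not None and vr.n_total > 0:
            txt += f"\n{format_percent(vr.fdr)}"
        ax.annotate(txt, (x, y), ha="center", va="center", fontsize=9)
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.5, 1.8)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def region_table(overlap: OverlapResult):
    """Region membership as a tidy DataFrame (one row per link per region)."""
    import pandas as pd

    rows = []
    for region, keys in sorted(overlap.region_membership.items(),
                               key=lambda kv: sorted(kv[0])):
        name = " & ".join(sorted(region))
        vr = overlap.region_fdr[region]
        for k in keys:
            rows.append({
                "region": name,
                "side_a": "/".join(str(x) for x in k[0]),
                "side_b": "/".join(str(x) for x in k[1]),
                "region_fdr": vr.fdr,
            })
    return pd.DataFrame(rows)
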