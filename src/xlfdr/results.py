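"""Reading heterogeneous search-engine result exports into one record model.

Every crosslink search engine exports its CSMs in a different table layout,
with different score polarities (MS Annika-style "higher is better" vs
pLink-style e-values), decoy conventions and link-type vocabularies.  An
:class:`EngineDialect` — a small, user-auditable YAML config — declares how
one engine's export maps onto the canonical record model; nothing about an
engine is hard-coded.

After normalization all scores are higher-better (lower-better inputs are
negated, an order-preserving and invertible transform; the raw value is
retained), positions are 1-based and the two sides of a record are
interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import yaml

LinkType = Literal["crosslink", "deadend", "looplink", "linear"]

#: canonical result columns, in output order
CANONICAL_COLUMNS = (
    "sequence_a", "sequence_b", "protein_a", "protein_b",
    "position_a", "position_b", "site_a", "site_b",
    "score", "is_decoy", "link_type", "spectrum_ref",
)


class DialectError(ValueError):
    """A dialect fails to resolve against an export's columns."""


@dataclass(frozen=True)
class EngineDialect:
    """Column-mapping dialect for one engine's result export.

    ``column_map`` maps canonical field names to source column names.
    ``decoy_convention`` is either ``{"type": "column", "column": ...,
    "true_values": [...]}`` or ``{"type": "protein_prefix", "prefix": ...}``.
    ``link_type_vocabulary`` maps each canonical link type to the source
    terms that denote it.  ``position_base`` declares the export's peptide
    position convention (0- or 1-based); the normalizer converts to 1-based.
    """

    engine_name: str
    column_map: Mapping[str, str]
    score_direction: Literal["higher_better", "lower_better"] = "higher_better"
    decoy_convention: Mapping[str, object] = field(
        default_factory=lambda: {"type": "column", "column": "is_decoy",
                                 "true_values": ["true", "1", "yes"]}
    )
    link_type_vocabulary: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"crosslink": ["crosslink"], "deadend": ["deadend"],
                                 "looplink": ["looplink"], "linear": ["linear"]}
    )
    position_base: int = 1

    REQUIRED = ("sequence_a", "sequence_b", "protein_a", "protein_b",
                "position_a", "position_b", "score")

    def __post_init__(self) -> None:
        missing = [f for f in self.REQUIRED if f not in self.column_map]
        if missing:
            raise DialectError(
                f"dialect {self.engine_name!r} column_map missing fields: {missing}"
            )

    def term_to_link_type(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for canon, terms in self.link_type_vocabulary.items():
            for t in terms:
                out[str(t).strip().lower()] = canon
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "EngineDialect":
        return cls(
            engine_name=str(d.get("name", d.get("engine_name", "unnamed"))),
            column_map=dict(d["column_map"]),  # type: ignore[arg-type]
            score_direction=str(d.get("score_direction", "higher_better")),  # type: ignore[arg-type]
            decoy_convention=dict(d.get("decoy", d.get("decoy_convention", {
                "type": "column", "column": "is_decoy",
                "true_values": ["true", "1", "yes"]}))),  # type: ignore[arg-type]
            link_type_vocabulary=dict(d.get("link_type_map", d.get(
                "link_type_vocabulary",
                {"crosslink": ["crosslink"], "deadend": ["deadend"],
                 "looplink": ["looplink"], "linear": ["linear"]}))),  # type: ignore[arg-type]
            position_base=int(d.get("position_base", 1)),  # type: ignore[arg-type]
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EngineDialect":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def builtin_dialect(name: str) -> EngineDialect:
    """Load a dialect shipped with the package (``canonical``, ``evalue``)."""
    ref = resources.files("xlfdr").joinpath(f"dialects/{name}.yaml")
    if not ref.is_file():
        raise DialectError(f"no built-in dialect named {name!r}")
    return EngineDialect.from_dict(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True)
class CrosslinkRecord:
    """One normalized CSM or unique residue pair.

    Scores are always on the higher-better scale after normalization
    (``raw_score`` keeps the engine's original value).  The record is an
    unordered pair: it compares equal to its (a, b)-swap.
    """

    seq_a: str
    seq_b: str
    protein_a: str = ""
    protein_b: str = ""
    pos_a: int | None = None
    pos_b: int | None = None
    site_a: int | None = None
    site_b: int | None = None
    score: float = 0.0
    raw_score: float = 0.0
    is_decoy: bool = False
    link_type: str = "crosslink"
    level: Literal["csm", "unique_link"] = "csm"
    engine: str = ""
    replicate: str = ""
    spectrum_ref: str = ""
    n_csms: int = 1

    def _side(self, which: str) -> tuple:
        if which == "a":
            return (self.seq_a, self.protein_a, self.pos_a, self.site_a)
        return (self.seq_b, self.protein_b, self.pos_b, self.site_b)

    def _canonical_sides(self) -> tuple[tuple, tuple]:
        a, b = self._side("a"), self._side("b")
        ka = (a[0], a[1], a[2] if a[2] is not None else -1)
        kb = (b[0], b[1], b[2] if b[2] is not None else -1)
        return (a, b) if ka <= kb else (b, a)

    def canonical(self) -> "CrosslinkRecord":
        """The record with its two sides in deterministic order."""
        a, b = self._canonical_sides()
        return replace(
            self,
            seq_a=a[0], protein_a=a[1], pos_a=a[2], site_a=a[3],
            seq_b=b[0], protein_b=b[1], pos_b=b[2], site_b=b[3],
        )

    def swapped(self) -> "CrosslinkRecord":
        return replace(
            self,
            seq_a=self.seq_b, protein_a=self.protein_b,
            pos_a=self.pos_b, site_a=self.site_b,
            seq_b=self.seq_a, protein_b=self.protein_a,
            pos_b=self.pos_a, site_b=self.site_a,
        )

    def __eq__(self, other: object) -> bool:  # unordered-pair semantics
        if not isinstance(other, CrosslinkRecord):
            return NotImplemented
        def key(r: CrosslinkRecord) -> tuple:
            return (r._canonical_sides(), r.score, r.is_decoy, r.link_type,
                    r.level, r.engine, r.replicate, r.spectrum_ref)
        return key(self) == key(other)

    def __hash__(self) -> int:
        return hash((self._canonical_sides(), self.score, self.is_decoy,
                     self.link_type, self.level))

    @property
    def min_peptide_length(self) -> int:
        return min(len(self.seq_a), len(self.seq_b))


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}


def _is_decoy(row: pd.Series, dialect: EngineDialect, colmap: Mapping[str, str]) -> bool:
    conv = dialect.decoy_convention
    kind = str(conv.get("type", "column"))
    if kind == "column":
        col = str(conv.get("column", "is_decoy"))
        if col not in row.index:
            return False
        truthy = {str(v).strip().lower()
                  for v in conv.get("true_values", _TRUE_STRINGS)}  # type: ignore[arg-type]
        return str(row[col]).strip().lower() in truthy
    if kind == "protein_prefix":
        prefix = str(conv.get("prefix", "DECOY_"))
        return (str(row[colmap["protein_a"]]).startswith(prefix)
                or str(row[colmap["protein_b"]]).startswith(prefix))
    raise DialectError(f"unknown decoy convention type {kind!r}")


def _opt_int(row: pd.Series, col: str | None, shift: int) -> int | None:
    if col is None or col not in row.index:
        return None
    v = str(row[col]).strip()
    if v == "" or v.lower() == "nan":
        return None
    return int(float(v)) + shift


def read_results(
    file: str | Path,
    dialect: EngineDialect,
    replicate: str = "",
) -> list[CrosslinkRecord]:
    """Parse one engine export into normalized CSM-level records.

    One record per row.  Scores are negated when the dialect declares
    ``lower_better`` so that comparisons are always higher-better; peptide
    positions are shifted to 1-based per the dialect's ``position_base``.
    An empty table yields an empty list, not an error.
    """
    df = _read_table(file)
    cm = dict(dialect.column_map)
    required_src = [cm[f] for f in dialect.REQUIRED]
    missing = [c for c in required_src if c not in df.columns]
    if missing:
        raise DialectError(
            f"dialect {dialect.engine_name!r}: column(s) {missing} not found in {file}"
        )
    strip_prefix = ""
    if str(dialect.decoy_convention.get("type")) == "protein_prefix":
        strip_prefix = str(dialect.decoy_convention.get("prefix", "DECOY_"))
    term_map = dialect.term_to_link_type()
    shift = 1 - dialect.position_base
    records: list[CrosslinkRecord] = []
    for _, row in df.iterrows():
        raw = float(row[cm["score"]])
        link_col = cm.get("link_type")
        if link_col is not None and link_col in row.index:
            term = str(row[link_col]).strip().lower()
            link_type = term_map.get(term, term)
        else:
            link_type = "crosslink"
        prot_a = str(row[cm["protein_a"]]).strip()
        prot_b = str(row[cm["protein_b"]]).strip()
        if strip_prefix:
            prot_a = prot_a.removeprefix(strip_prefix)
            prot_b = prot_b.removeprefix(strip_prefix)
        records.append(
            CrosslinkRecord(
                seq_a=str(row[cm["sequence_a"]]).strip().upper(),
                seq_b=str(row[cm["sequence_b"]]).strip().upper(),
                protein_a=prot_a,
                protein_b=prot_b,
                pos_a=_opt_int(row, cm.get("position_a"), shift),
                pos_b=_opt_int(row, cm.get("position_b"), shift),
                site_a=_opt_int(row, cm.get("site_a"), shift),
                site_b=_opt_int(row, cm.get("site_b"), shift),
                score=-raw if dialect.score_direction == "lower_better" else raw,
                raw_score=raw,
                is_decoy=_is_decoy(row, dialect, cm),
                link_type=link_type,
                level="csm",
                engine=dialect.engine_name,
                replicate=replicate,
                spectrum_ref=str(row.get(cm.get("spectrum_ref", ""), "")),
            )
        )
    return records


def filter_targets(
    records: Iterable[CrosslinkRecord], min_short_peptide_len: int = 1
) -> list[CrosslinkRecord]:
    """Keep target inter/intra crosslinks only.

    Removes decoys and everything that is not an inter-peptide residue pair
    (dead-ends, loop-links, linear peptides), then applies the
    shorter-peptide length filter.  Idempotent.
    """
    if min_short_peptide_len < 1:
        raise ValueError("min_short_peptide_len must be >= 1")
    return [
        r for r in records
        if not r.is_decoy
        and r.link_type == "crosslink"
        and r.min_peptide_length >= min_short_peptide_len
    ]


def group_to_unique_links(records: Iterable[CrosslinkRecord]) -> list[CrosslinkRecord]:
    """Collapse CSMs to unique residue pairs.

    Records sharing a link key (canonical peptide/protein/position identity,
    see :mod:`xlfdr.comparison`) merge into one ``unique_link`` record whose
    score is the best (maximum) member CSM score and whose ``n_csms`` counts
    the members.
    """
    from .comparison import make_link_key  # deferred: avoids import cycle

    best: dict[object, CrosslinkRecord] = {}
    counts: dict[object, int] = {}
    order: list[object] = []
    for r in records:
        k = make_link_key(r)
        if k not in best:
            best[k] = r
            counts[k] = 1
            order.append(k)
        else:
            counts[k] += 1
            if r.score > best[k].score:
                best[k] = r
    return [
        replace(best[k].canonical(), level="unique_link", n_csms=counts[k],
                spectrum_ref="")
        for k in order
    ]


def to_frame(records: Iterable[CrosslinkRecord]) -> pd.DataFrame:
    """Records as a canonical-schema DataFrame (for CSV export)."""
    rows = []
    for r in records:
        rows.append({
            "sequence_a": r.seq_a, "sequence_b": r.seq_b,
            "protein_a": r.protein_a, "protein_b": r.protein_b,
            "position_a": r.pos_a, "position_b": r.pos_b,
            "site_a": r.site_a, "site_b": r.site_b,
            "score": r.score, "is_decoy": r.is_decoy,
            "link_type": r.link_type, "spectrum_ref": r.spectrum_ref,
            "level": r.level, "engine": r.engine,
            "replicate": r.replicate, "n_csms": r.n_csms,
        })
    return pd.DataFrame(rows)


def write_results(
    records: Iterable[CrosslinkRecord], path: str | Path, dialect: EngineDialect
) -> None:
    """Write records as an export in *dialect*'s layout (inverse of reading)."""
    cm = dict(dialect.column_map)
    shift = dialect.position_base - 1
    conv = dialect.decoy_convention
    inv_terms = {canon: list(terms)[0]
                 for canon, terms in dialect.link_type_vocabulary.items()}
    rows = []
    for r in records:
        raw = -r.score if dialect.score_direction == "lower_better" else r.score
        prot_a, prot_b = r.protein_a, r.protein_b
        if str(conv.get("type")) == "protein_prefix" and r.is_decoy:
            prefix = str(conv.get("prefix", "DECOY_"))
            prot_a, prot_b = prefix + prot_a, prefix + prot_b
        row: dict[str, object] = {
            cm["sequence_a"]: r.seq_a, cm["sequence_b"]: r.seq_b,
            cm["protein_a"]: prot_a, cm["protein_b"]: prot_b,
            cm["position_a"]: "" if r.pos_a is None else r.pos_a + shift,
            cm["position_b"]: "" if r.pos_b is None else r.pos_b + shift,
            cm["score"]: raw,
            cm.get("link_type", "link_type"): inv_terms.get(r.link_type, r.link_type),
        }
        if "site_a" in cm:
            row[cm["site_a"]] = "" if r.site_a is None else r.site_a + shift
            row[cm["site_b"]] = "" if r.site_b is None else r.site_b + shift
        if "spectrum_ref" in cm:
            row[cm["spectrum_ref"]] = r.spectrum_ref
        if str(conv.get("type", "column")) == "column":
            row[str(conv.get("column", "is_decoy"))] = str(r.is_decoy).lower()
        rows.append(row)
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
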