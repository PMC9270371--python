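"""Synthetic libraries and simulated search results with known ground truth.

The simulator stands in for the physical validation library: it builds a
grouped tryptic peptide library (each peptide with exactly one reactive
residue and a tryptic terminus), then emits a search-engine-style result
table containing a chosen mixture of within-group (true) links, cross-group
links, links to never-synthesized sequences and decoy rows, with scores
drawn from separate distributions for correct and incorrect identifications.
Every emitted link's planted truth label is recorded, so the whole
validation pipeline can be exercised end-to-end with no external data.

All randomness flows from one integer seed; identical configs produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .library import AA20, LibraryPeptide, PeptideLibrary
from .results import CrosslinkRecord, EngineDialect, builtin_dialect, write_results


class ConfigError(ValueError):
    """Simulation config is internally inconsistent or unsatisfiable."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated library + search-result experiment.

    Defaults mirror the benchmark library's structure: groups of 6–10
    peptides, peptide lengths 6–20, lysine chemistry, and score
    distributions well separated between correct identifications (normal,
    location 150, scale 30 — the range of typical engine scores) and
    incorrect ones (location 40, scale 20).
    """

    n_peptides: int = 100
    group_sizes: Sequence[int] | None = None  # default: sizes 6-10 summing to n
    chemistry: str = "lysine"
    min_length: int = 6
    max_length: int = 20
    n_true: int = 300
    n_cross_group: int = 4
    n_non_library: int = 0
    n_decoys: int = 20
    score_correct: tuple[float, float] = (150.0, 30.0)  # (location, scale)
    score_incorrect: tuple[float, float] = (40.0, 20.0)
    csms_per_link: int = 1
    seed: int = 0
    engine_dialect: str = "canonical"

    def resolved_group_sizes(self, rng: np.random.Generator) -> list[int]:
        if self.group_sizes is not None:
            sizes = [int(s) for s in self.group_sizes]
            if sum(sizes) != self.n_peptides:
                raise ConfigError(
                    f"group_sizes sum to {sum(sizes)}, expected n_peptides={self.n_peptides}"
                )
            if any(s < 1 for s in sizes):
                raise ConfigError("group sizes must be >= 1")
            return sizes
        sizes: list[int] = []
        left = self.n_peptides
        while left > 0:
            s = int(rng.integers(6, 11))
            if left <= 10:
                s = left
            sizes.append(min(s, left))
            left -= sizes[-1]
        return sizes

    def validate(self) -> None:
        if self.n_peptides < 1:
            raise ConfigError("n_peptides must be >= 1")
        if self.min_length < 4 or self.max_length < self.min_length:
            raise ConfigError(
                "peptide length bounds infeasible (need >= 4 residues for "
                "site + terminus + context)"
            )
        for name in ("n_true", "n_cross_group", "n_non_library", "n_decoys"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.csms_per_link < 1:
            raise ConfigError("csms_per_link must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        if d["group_sizes"] is not None:
            d["group_sizes"] = list(d["group_sizes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _random_peptide(rng: np.random.Generator, cfg: SimulationConfig,
                    taken: set[str]) -> tuple[str, int]:
    """One tryptic peptide with exactly one reactive residue; returns (seq, site)."""
    reactive = {"lysine": "K", "acidic": "DE"}[cfg.chemistry]
    # body alphabet: no K/R (tryptic specificity) and no reactive residues
    body = [a for a in AA20 if a not in "KR" and a not in reactive]
    for _ in range(1000):
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        seq = [body[i] for i in rng.integers(0, len(body), size=length)]
        site = int(rng.integers(1, length))  # 1..length-1: never the terminus
        seq[site - 1] = reactive[int(rng.integers(0, len(reactive)))]
        seq[-1] = "KR"[int(rng.integers(0, 2))]
        s = "".join(seq)
        if s not in taken:
            return s, site
    raise ConfigError("could not generate enough distinct peptides")


def generate_library(
    config: SimulationConfig, support_path: str | Path | None = None
) -> PeptideLibrary:
    """Build a random grouped peptide library; optionally write its support file."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = config.resolved_group_sizes(rng)
    peptides: list[LibraryPeptide] = []
    taken: set[str] = set()
    n_proteins = max(1, config.n_peptides // 4)
    for g, size in enumerate(sizes, start=1):
        for _ in range(size):
            seq, site = _random_peptide(rng, config, taken)
            taken.add(seq)
            peptides.append(LibraryPeptide(
                sequence=seq,
                group_id=f"G{g}",
                protein_id=f"P{int(rng.integers(1, n_proteins + 1)):04d}",
                start_pos=int(rng.integers(1, 500)),
                site_pos=site,
                chemistry=config.chemistry,
            ))
    lib = PeptideLibrary(library_id=f"sim-seed{config.seed}", peptides=peptides)
    if support_path is not None:
        lib.to_frame().to_csv(support_path, index=False)
    return lib


def _all_pairs(peps: list[LibraryPeptide], within: bool) -> list[tuple[LibraryPeptide, LibraryPeptide]]:
    out = []
    for i in range(len(peps)):
        for j in range(i, len(peps)):
            same = peps[i].group_id == peps[j].group_id
            if within == same:
                out.append((peps[i], peps[j]))
    return out


def _record_from_pair(a: LibraryPeptide, b: LibraryPeptide, score: float,
                      engine: str, spectrum: str) -> CrosslinkRecord:
    return CrosslinkRecord(
        seq_a=a.sequence, seq_b=b.sequence,
        protein_a=a.protein_id, protein_b=b.protein_id,
        pos_a=a.start_pos, pos_b=b.start_pos,
        site_a=a.site_pos, site_b=b.site_pos,
        score=score, raw_score=score,
        is_decoy=False, link_type="crosslink",
        engine=engine, spectrum_ref=spectrum,
    )


def generate_results(
    library: PeptideLibrary,
    config: SimulationConfig,
    result_path: str | Path | None = None,
    truth_path: str | Path | None = None,
    dialect: EngineDialect | None = None,
) -> tuple[list[CrosslinkRecord], pd.DataFrame]:
    """Emit simulated CSM records with planted truth labels.

    Samples ``n_true`` distinct within-group pairs, ``n_cross_group``
    distinct cross-group pairs and ``n_non_library`` pairs involving an
    invented sequence, plus ``n_decoys`` decoy rows; correct links draw
    scores from ``score_correct``, everything else from ``score_incorrect``.
    Each sampled link yields ``csms_per_link`` CSM rows.  Returns the records
    and the ground-truth table; optionally writes both (the result file in
    the configured engine dialect).
    """
    config.validate()
    if dialect is None:
        dialect = builtin_dialect(config.engine_dialect)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))

    within = _all_pairs(library.peptides, within=True)
    across = _all_pairs(library.peptides, within=False)
    if config.n_true > len(within):
        raise ConfigError(
            f"n_true={config.n_true} exceeds the {len(within)} available "
            "within-group pairs"
        )
    if config.n_cross_group > len(across):
        raise ConfigError(
            f"n_cross_group={config.n_cross_group} exceeds the {len(across)} "
            "available cross-group pairs"
        )

    def draw_scores(n: int, correct: bool) -> np.ndarray:
        loc, scale = config.score_correct if correct else config.score_incorrect
        return rng.normal(loc, scale, size=n)

    records: list[CrosslinkRecord] = []
    truth_rows: list[dict] = []
    scan = 0

    def emit(a_seq: str, b_seq: str, rec_factory, label: str, correct: bool) -> None:
        nonlocal scan
        for s in draw_scores(config.csms_per_link, correct):
            scan += 1
            records.append(rec_factory(round(float(s), 4), f"sim.raw:{scan}"))
        truth_rows.append({
            "sequence_a": a_seq, "sequence_b": b_seq, "label": label,
            "n_csms": config.csms_per_link,
        })

    idx_t = rng.choice(len(within), size=config.n_true, replace=False)
    for i in idx_t:
        a, b = within[int(i)]
        emit(a.sequence, b.sequence,
             lambda s, sp, a=a, b=b: _record_from_pair(a, b, s, dialect.engine_name, sp),
             "within_group_true", correct=True)

    idx_c = rng.choice(len(across), size=config.n_cross_group, replace=False)
    for i in idx_c:
        a, b = across[int(i)]
        emit(a.sequence, b.sequence,
             lambda s, sp, a=a, b=b: _record_from_pair(a, b, s, dialect.engine_name, sp),
             "cross_group_false", correct=False)

    taken = {p.sequence for p in library.peptides}
    for k in range(config.n_non_library):
        fake, fake_site = _random_peptide(rng, config, taken)
        taken.add(fake)
        partner = library.peptides[int(rng.integers(0, len(library.peptides)))]
        assert fake not in library  # absent by construction
        def factory(s: float, sp: str, fake=fake, fake_site=fake_site, partner=partner) -> CrosslinkRecord:
            return CrosslinkRecord(
                seq_a=fake, seq_b=partner.sequence,
                protein_a=f"X{k:04d}", protein_b=partner.protein_id,
                pos_a=1, pos_b=partner.start_pos,
                site_a=fake_site, site_b=partner.site_pos,
                score=s, raw_score=s, link_type="crosslink",
                engine=dialect.engine_name, spectrum_ref=sp,
            )
        emit(fake, partner.sequence, factory, "non_library_false", correct=False)

    for _ in range(config.n_decoys):
        scan += 1
        a = library.peptides[int(rng.integers(0, len(library.peptides)))]
        b = library.peptides[int(rng.integers(0, len(library.peptides)))]
        s = round(float(draw_scores(1, correct=False)[0]), 4)
        records.append(replace(
            _record_from_pair(a, b, s, dialect.engine_name, f"sim.raw:{scan}"),
            is_decoy=True,
        ))

    truth = pd.DataFrame(truth_rows, columns=["sequence_a", "sequence_b",
                                              "label", "n_csms"])
    if result_path is not None:
        write_results(records, result_path, dialect)
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)
    return records, truth
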