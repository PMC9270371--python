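"""Pipeline orchestration: read → filter → group → validate → report.

One :class:`RunConfig` drives the whole post-processing run and every stage
is deterministic; the report bundle (CSVs, figures, run log) lands in one
output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .comparison import compute_overlap, plot_venn, region_table
from .library import PeptideLibrary, load_library
from .results import (
    CrosslinkRecord,
    EngineDialect,
    builtin_dialect,
    filter_targets,
    group_to_unique_links,
    read_results,
    to_frame,
)
from .validation import (
    apply_score_cutoff,
    fdr_score_curve,
    plot_fdr_curves,
    validated_fdr,
)

logger = logging.getLogger(__name__)


def resolve_dialect(spec: str) -> EngineDialect:
    """A dialect by built-in name or by path to a YAML file."""
    p = Path(spec)
    if p.suffix.lower() in {".yaml", ".yml", ".json"} or p.exists():
        return EngineDialect.from_yaml(p)
    return builtin_dialect(spec)


@dataclass
class RunConfig:
    """Everything one report run needs."""

    results: list[str]
    library: str
    dialect: str = "canonical"
    level: str = "unique_link"  # csm | unique_link
    target_fdr: float | None = None
    min_short_peptide_len: int = 1
    compare_labels: list[str] = field(default_factory=list)
    mass_extra: float = 0.0
    properties: bool = False
    out_dir: str = "xlfdr_report"

    def __post_init__(self) -> None:
        if self.target_fdr is not None and not (0 < self.target_fdr <= 1):
            raise ValueError("target_fdr must be in (0, 1]")
        if self.level not in ("csm", "unique_link"):
            raise ValueError("level must be 'csm' or 'unique_link'")


def _load_and_prepare(
    path: str, dialect: EngineDialect, cfg: RunConfig, log: dict
) -> list[CrosslinkRecord]:
    csms = read_results(path, dialect, replicate=Path(path).stem)
    targets = filter_targets(csms, cfg.min_short_peptide_len)
    stage = {"input_rows": len(csms), "target_csms": len(targets),
             "removed": len(csms) - len(targets)}
    records = targets
    if cfg.level == "unique_link":
        records = group_to_unique_links(targets)
        stage["unique_links"] = len(records)
    log.setdefault("stages", {})[Path(path).name] = stage
    return records


def run_report(config: RunConfig) -> dict:
    """Execute the full post-processing pipeline; returns the run log."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dialect = resolve_dialect(config.dialect)
    library: PeptideLibrary = load_library(config.library)
    log: dict = {
        "xlfdr_version": __version__,
        "config": {k: v for k, v in config.__dict__.items()},
        "library": {"id": library.library_id, "n_peptides": len(library),
                    "n_groups": len(library.groups)},
    }

    per_file: dict[str, list[CrosslinkRecord]] = {}
    for path in config.results:
        per_file[Path(path).stem] = _load_and_prepare(path, dialect, config, log)

    merged = [r for recs in per_file.values() for r in recs]
    if not merged:
        logger.warning("no target records after filtering; zero-count report")

    vr = validated_fdr(merged, library, level=config.level)
    vr.to_frame().to_csv(out / "crosslinks_annotated.csv", index=False)
    log["validation"] = {
        "level": vr.level, "n_total": vr.n_total,
        "n_within_group": vr.n_within_group, "n_cross_group": vr.n_cross_group,
        "n_non_library": vr.n_non_library, "fdr": vr.fdr,
        "fdr_display": vr.fdr_display,
        "per_class": vr.per_class,
    }

    if merged:
        curve = fdr_score_curve(merged, library)
        import pandas as pd
        pd.DataFrame(curve, columns=["threshold", "n_retained", "fdr"]).to_csv(
            out / "fdr_score_curve.csv", index=False)
        plot_fdr_curves(curve, str(out / "curve"), config.target_fdr)

    if config.target_fdr is not None and merged:
        cut = apply_score_cutoff(merged, library, config.target_fdr)
        log["cutoff"] = {
            "target_fdr": cut.target_fdr, "threshold": cut.threshold,
            "n_retained": cut.n_retained, "achieved_fdr": cut.achieved_fdr,
            "feasible": cut.feasible,
        }
        to_frame(cut.retained).to_csv(out / "crosslinks_after_cutoff.csv",
                                      index=False)

    if len(per_file) >= 2:
        labels = config.compare_labels or list(per_file)
        sets = {lab: per_file[name]
                for lab, name in zip(labels, per_file)}
        ov = compute_overlap(sets, library)
        region_table(ov).to_csv(out / "overlap_regions.csv", index=False)
        if len(sets) in (2, 3):
            plot_venn(ov, str(out / "venn.png"))
        log["overlap"] = {
            " & ".join(sorted(region)): {
                "n": len(keys), "fdr": ov.region_fdr[region].fdr}
            for region, keys in ov.region_membership.items()
        }

    if config.properties and merged:
        from .properties import (
            distribution_comparison,
            plot_distribution,
            plot_ppm,
            ppm_around_site,
            properties_table,
        )

        properties_table(merged, config.mass_extra).to_csv(
            out / "crosslink_properties.csv", index=False)
        try:
            ppm = ppm_around_site(merged)
            ppm.probabilities.to_csv(out / "ppm_link_site.csv")
            plot_ppm(ppm, str(out / "ppm_link_site.png"))
        except Exception as exc:  # no site info is a soft failure
            logger.warning("PPM skipped: %s", exc)
        comp = distribution_comparison(merged, library, mode="grouped",
                                       level=config.level)
        comp.to_frame().to_csv(out / "aa_distribution.csv")
        plot_distribution(comp, str(out / "aa_distribution.png"))

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log
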