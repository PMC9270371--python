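"""Correct a result list to a target real FDR with a post-score cutoff.

When the engine's internal decoy-based estimate is too optimistic, the
validated-FDR-vs-score curve tells which score threshold actually reaches
the desired error rate.
"""

from xlfdr import (
    SimulationConfig,
    apply_score_cutoff,
    fdr_score_curve,
    filter_targets,
    generate_library,
    generate_results,
    group_to_unique_links,
    validated_fdr,
)

cfg = SimulationConfig(
    n_peptides=80, n_true=250, n_cross_group=12, n_non_library=3,
    seed=9,
    score_correct=(150.0, 30.0),   # engine scores of correct IDs
    score_incorrect=(60.0, 25.0),  # overlapping, as in imperfect engines
)
lib = generate_library(cfg)
records, _ = generate_results(lib, cfg)
links = group_to_unique_links(filter_targets(records))

before = validated_fdr(links, lib)
print(f"before cutoff: {before.n_total} links at FDR {before.fdr_display}")

cut = apply_score_cutoff(links, lib, target_fdr=0.01)
print(f"cutoff at normalized score >= {cut.threshold}:")
print(f"  retained {cut.n_retained} links, achieved FDR "
      f"{100 * cut.achieved_fdr:.2f} %")

curve = fdr_score_curve(links, lib)
print(f"curve has {len(curve)} thresholds; strictest point: "
      f"score {curve[0][0]}, {curve[0][1]} links, FDR {100 * curve[0][2]:.2f} %")

# The returned threshold is the least strict one meeting the target, so it
# keeps as many identifications as the target error rate allows.
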