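# Methods

## Ground-truth model

A validation library is a set of synthetic tryptic peptides partitioned into
crosslink groups; each group is crosslinked in its own vial. Each peptide
carries exactly one reactive residue of its chemistry — K for amine-reactive
(NHS-ester type) linkers, D/E for acid-reactive (hydrazide type) linkers.
The tryptic C-terminal K/R is never counted as the reactive site: for amine
chemistry the C-terminal lysine is azide-protected during the crosslinking
reaction (and reduced to plain K afterwards), for acid chemistry it is just
the cleavage site. Synthesis constructs carry an N-terminal protected tag
ending in R (the tryptic release point) and optionally a C-terminal
protected tag; digestion strips both, so the library stores only the final
tryptic sequences the search engine can see.

Truth labels are defined on peptide *sequences*, because groups are defined
on peptides: a reported link is `within_group_true` when both sequences are
library members of one group, `cross_group_false` when both are members of
different groups, and `non_library_false` when either sequence was never
synthesized. Sequence identity is literal string equality with I and L
distinct; an isobaric permutation of a library peptide is deliberately *not*
equated with it — that is exactly how a wrongly annotated spectrum presents,
and `near_isobaric_pairs()` flags such library pairs for diagnostics.

The theoretical crosslink space enumerates unordered peptide pairs including
self-pairs (homeotypic links are real and observed): pooled mode gives
n(n+1)/2 combinations, grouped mode Σ_g n_g(n_g+1)/2. Pairs are classed
homeotypic (identical sequences), intraprotein/homomeric (same source
protein) or interprotein/heteromeric.

## Validated FDR and score cutoff

FDR_validated = (#cross-group + #non-library) / #total over target records.
Both failure categories count as false but are reported separately. On CSM
level each spectrum match counts; on unique-link level CSMs are first
collapsed by link key. The empty set has FDR 0 by definition (with a logged
warning) so batch reports stay total. Displayed percentages round half-up to
one decimal (2/425 = 0.4706 % → "0.5 %"); stored values are unrounded.

The score-cutoff correction scans the distinct normalized scores from least
to most strict and returns the first threshold T where the retained set
{score ≥ T} has validated FDR ≤ target — i.e. the least strict qualifying
threshold, maximizing retained identifications. Ties at T are retained
(inclusive ≥). A consequence worth knowing: once the retained set is large
(n_true + 1 > 1/target), a single incorrect link clearing the correct-score
range no longer pushes the ratio over the target and is retained; complete
exclusion of incorrect links is only guaranteed at scales where one false
hit already violates the target.

## Record normalization

Engine exports differ in layout, score polarity, decoy convention,
link-type vocabulary and position base. A dialect (YAML) declares all five;
nothing engine-specific is hard-coded. Lower-better scores (e-values) are
negated — order-preserving and invertible — and the raw value retained.
Positions are normalized to 1-based. Decoys are recognized either by a
boolean column or by a protein-accession prefix (which is stripped).
Target filtering keeps non-decoy records of link type `crosslink` only:
dead-ends, loop-links and linear peptides are not inter-peptide residue
pairs and are removed, as is every pair whose *shorter* peptide is below
the minimum-length filter.

Unique-link grouping keys records by the canonical unordered pair of
(sequence, protein, peptide start position); the link's score is the best
member CSM score — this keeps link-level threshold filtering consistent
with CSM-level filtering — and the member count is retained. Link *sites*
within peptides are excluded from the default key because engines disagree
on intra-peptide site assignment; `strict=True` includes them. When
protein/position data are missing the key degrades to sequence-only with a
warning. Records whose sequences match across sets but whose
protein/position mapping differs are kept separate and logged as conflicts,
never silently merged.

## Properties and motifs

Crosslinks are linearized by concatenating the two sequences in
lexicographic order (the properties computed are order-invariant; the order
only fixes a deterministic display form). GRAVY (Kyte–Doolittle mean),
aromatic fraction (F+W+Y)/length and isoelectric point are computed with
Biopython's ProtParam machinery; the pI solver is the standard
Henderson–Hasselbalch net-charge bisection with ProtParam's pKa table.
Monoisotopic mass is the sum of the two peptides' masses (pyteomics; one
water per chain) plus a configurable crosslinker delta (DSSO 158.00376 Da,
DSBU 196.08479, CDI 25.97926, DHSO 144.01245; default 0 — whether a real
analysis includes the linker mass is a reporting choice, so it is explicit).

The observed amino-acid distribution is compared to the expectation obtained
by counting every theoretical crosslink of the chosen mode exactly once
(the one-CSM-per-crosslink assumption). Both whole-sequence frequencies and
the positional view are provided: the position probability matrix counts
residues at offsets −3…+3 from each linked residue on both peptide sides
(offset 0, the site itself, included and so declared); positions beyond the
peptide termini contribute nothing, columns with support are normalized to
1, zero-support columns are flagged rather than normalized. CSM-level
histograms are normalized to unit area; link-level graphics are unnormalized
counts.

Venn diagrams for 2–3 sets are drawn with plain matplotlib circle patches
and annotated with region counts and per-region validated FDR; motif plots
are per-position stacked bars of the PPM columns.

## Simulator

The generator emulates the benchmark library's structure: groups of 6–10
peptides (configurable), peptide lengths 6–20, exactly one reactive residue
never at the C-terminus, tryptic K/R terminus, body residues drawn from the
alphabet excluding K/R and the reactive class (so the single-site invariant
holds by construction). Result simulation samples distinct within-group
pairs (true), distinct cross-group pairs, invented non-library sequences and
decoy rows; scores are drawn from two normal distributions on the normalized
scale — correct: N(150, 30), incorrect: N(40, 20) by default, reflecting
score-separable but overlapping populations typical of real engines — and
each link emits a configurable number of CSMs. All randomness derives from
one integer seed; identical configs yield byte-identical files.

What the simulator does *not* model: spectra and their quality, retention
time, charge states, intensity-dependent sampling, engine-specific score
shapes, and ambiguous protein mapping. Passing tests therefore demonstrate
the correctness of the post-processing arithmetic and bookkeeping on
exactly specified inputs, not the behaviour of any search engine on real
LC-MS data.

## Numerical and design choices

- Normalization of lower-better scores by negation (not reciprocal):
  exactly invertible, no domain restrictions.
- Thresholding is inclusive (≥) on the normalized scale; deterministic
  under ties.
- FDR display rounds half-up (`decimal.ROUND_HALF_UP`), one decimal.
- pI bisection tolerance is ProtParam's default (0.01 pH).
- Coordinates are 1-based inclusive throughout; crosslink site in the
  protein is start + site − 1.
- Test and acceptance problem sizes (libraries of 40–140 peptides, record
  sets up to ~10³, 10³ randomized oracle trials) were chosen as the
  smallest scales at which every combinatorial path — ties, empty regions,
  homeotypic links, degraded keys — is exercised.

## Known limitations

- XLSX exports must be converted to CSV/TSV first; mzIdentML and vendor
  binary formats are out of scope.
- The comparison key assumes engines report consistent protein accessions;
  accession-mapping conflicts are surfaced, not resolved.
- No modelling of engine-internal target-decoy FDR, and no rescoring.
- Venn rendering stops at 3 sets; region tables have no arity limit.
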