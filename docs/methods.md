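# Methods

This note records the models, the parameters that matter, the numerical
choices, and what the synthetic tests do and do not establish.

## Scope and data model

The package analyzes records of small peptides (tokenized sequences of up
to 25 residues; bracketed tokens carry nonstandard residues opaquely and
count toward length) annotated with ring-closing intrachain bonds. Bonds
carry a kind, a linkage, 1-based inclusive positions, a head-to-tail flag
(encoded as pos1 = 1, pos2 = L) and optional chemical qualifiers. Size
classes follow the conventional cut points: ultra-short ≤ 5 residues,
short 6–25, everything longer out of the "small" scope.

## Ring ontology

The mapping (bond kind, linkage) → ring label is a closed table. Several
ring types differ only in chemistry the positions cannot express — a
five-membered Cys-derived ring is a thiazolidine, thiazoline or thiazole
depending on saturation; lanthionine vs aminovinylcysteine differs in
saturation and methylation; a diketopiperazine is the dipeptide special
case of the head-to-tail macrolactam. Refinement therefore keys on
qualifiers (ring atom count, saturation, methylation, residue identities,
α-carbon flag for disulfides) and **never guesses**: any underdetermined
case returns GENERIC with `coarse=True`. Pairs outside the table raise an
ontology error naming the offending combination. The ontology keys on
chemistry only; synthesis route is carried on the record but does not
change a label, since the same ring can arise from either route.

## Single-disulfide topology

With cysteines at n₁ < n₂ in a chain of length L, s = (L − n₂ + n₁ + 1)/L
and p = (L − n₂)/(n₁ − 1) (undefined at n₁ = 1). The decision rule is:
s < 0.5 → hairpin-like; else lasso-like when n₁ = 1 or p ≤ 0.3 or p ≥ 3;
else AMBIGUOUS. Three choices here were genuinely open:

- The lasso condition is sometimes printed in the unsatisfiable form
  "0.3 ≥ p ≥ 3"; we implement the disjunction p ≤ 0.3 **or** p ≥ 3, the
  geometric reading (one tail much longer than the other). Whether 0.3 is
  intended as 1/3 (which would make the window reciprocal-symmetric)
  cannot be settled from the definitions; 0.3 is used and is overridable
  (`p_low`, `p_high`, `s_cutoff` arguments and `RunConfig`).
- Chains with s ≥ 0.5 but balanced tails satisfy neither branch; they get
  an explicit AMBIGUOUS label rather than a silent coercion to hairpin.
- The C-LL/N-LL subtype tie (L − n₂ = n₁) breaks to C-LL, matching the
  overwhelming prevalence of C-terminal loops among one-disulfide
  peptides. This is a documented tie-break, not part of the rule.

Loop size is inclusive: a pair spaced by i residues closes a loop of
i + 2 (spacings 5 and 8 ↔ loops of 7 and 10).

## Multi-disulfide topology

Bonded cysteines are numbered along the chain **from the disulfide
endpoints**, not by scanning for C tokens, so free cysteines cannot
perturb the matching. A bond set is then a perfect matching of 1..2k; the
count is (2k)!/(2ᵏ k!), verified against exhaustive enumeration (guarded
at k ≤ 6). Classification: fully nested → LD; sequential → SR; any chord
crossing → CR. Non-crossing matchings number Catalan(k), so for k ≥ 3
there are Catalan(k) − 2 non-crossing matchings that are neither pure
scheme; the three-class scheme is silent about them, so a fourth MIXED
label is returned (a strict three-class mode folds MIXED into SR for
users who need the classical output). Tests verify the CR ⇔ crossing
equivalence by brute force over all matchings up to k = 5, and the
Catalan identity as an independent combinatorial oracle.

## DiSAAP

Counting is ordered (position j holds the first symbol, j + i + 1 the
second; identical symbols count each unordered occurrence once) and
spacing i means i residues strictly between the pair — fixed by the
spacing-to-loop-size mapping above. The primary null is a
within-sequence, composition-preserving shuffle: each null sequence is an
exact anagram of its original, so both corpus composition and the length
distribution are held fixed and only positional structure is tested.
z-scores use the null mean and sd; empirical two-sided p-values use
add-one smoothing, and Benjamini–Hochberg at a configurable level
(default 0.05) corrects across the tested spacings — the choice of
correction was open, and BH is the field default for this many weakly
dependent tests. A closed-form expectation under positional
exchangeability (for one sequence, (L−i−1)·mₐ·m_b/(L(L−1)) for distinct
symbols, (L−i−1)·m(m−1)/(L(L−1)) for identical) serves as a secondary
analytic null; it reproduces the shuffle mean (tested to 3 standard
errors at 2000 shuffles) but carries no dispersion, so it reports
observed/expected ratios only. A shuffle null without a seed is a
configuration error: reproducibility is part of the contract.

## Composition and enrichment

Composition pools residue fractions over the set; bracketed tokens pool
under the reserved symbol X. Enrichment is log₂(f_set/f_background) with a
symmetric pseudo-fraction floor (default 1e-4) for zero cells, flagged in
the output; symmetric flooring keeps the table exactly antisymmetric
under swapping set and background. The bundled background table is an
illustrative average-protein composition, clearly labelled as an example —
real analyses should supply their own background.

## ΔMIC

r = log₂(MIC_cyclic) − log₂(MIC_linear) (computed as a difference of logs
so antisymmetry is exact in floating point), in two-fold dilution units.
ΔMIC is r rounded half away from zero, because the assay is a dilution
series; raw r is reported alongside. Reliability requires |ΔMIC| ≥ 2
dilutions — one dilution is within assay error — and "more potent" means
the lower MIC. The statistic is sometimes written as sgn(r)·r, which
equals |r| and cannot express direction; the signed r is used here.

## Synthetic generator

The generator emulates curated-database records: lengths 6–25, uniform
20-letter background by default (a Cys/Gly-enriched preset mirrors the
qualitative composition of ribosomal short cyclic peptides without
claiming measured values), 1–4 disulfide bonds, and a default class mix in
which C-terminal lassos dominate single-bond records and ladders dominate
two-bond records, echoing their real prevalences qualitatively.

Placements leave a margin to every threshold so that planted labels are
unambiguous: lassos use a 7–8 residue terminal loop with at most one tail
residue on the loop side (s ≥ 0.6, p ≤ 1/6 where defined), hairpins put
both cysteines within two positions of the termini (s ≤ 1/3, hence
chains of at least 12), and multi-bond records place 2k cysteines with at
least 2 residues between consecutive ones (the steric floor: disulfides
between cysteines spaced 0–1 are not planted) before wiring them into the
nested, sequential, fully-crossed or mixed scheme. Infeasible requests
(e.g. MIXED with k = 2, or a lasso in a 14-mer) raise configuration
errors naming the constraint. Truth labels travel in a sidecar field no
analysis stage reads.

Spacing enrichment is planted multiplicatively: the number of planted
pairs is (fold − 1) times the closed-form expected count of the corpus as
generated, so the observed count lands near fold × expectation. MIC pairs
draw the linear MIC from the interior of a two-fold grid (default
0.5–256 µg/mL), shift by the planted effect (default −2 dilutions), and
add ±1 dilution of noise with probability 0.25 per side; off-grid values
are clamped and flagged.

**What passing tests show — and don't.** The closed-loop tests establish
that the classifiers invert the generator exactly under margined
placements and that the statistics recover planted signals at the stated
sizes (1000 records for topology, 500 sequences / 1000 shuffles for
spacing, 200 pairs for ΔMIC — sizes chosen so the whole pipeline runs in
seconds on one CPU). Real database records are messier: boundary cases
near s = 0.5 and p ∈ {0.3, 3}, un- or mis-annotated bonds, nonstandard
residues inside loops, and MIC values censored at assay limits. The
AMBIGUOUS and coarse labels, the validator, and the lenient reader exist
for exactly those cases, but recovery rates measured here do not transfer
to curated data.

## Numerical and I/O choices

Records are newline-delimited JSON (bonds nest naturally); a flat TSV
export serves spreadsheets. All tables are written deterministically
(`%.6g` floats, fixed column order); the report manifest records seed,
thresholds, versions and an input digest sufficient to reproduce every
table bit-exactly. Counting tables computed over user records are
corpus-dependent by nature; the package reports them for the supplied
records without claiming database-level counts.

## Known limitations

- No disulfide-bond prediction from sequence; bonds must be annotated.
- No chemical-structure parsing (SMILES/InChI) or 3-D structure; the ring
  ontology sees only kind/linkage/qualifiers.
- The analytic spacing null ignores edge effects induced by fixed motifs
  at sequence termini (the shuffle null does not).
- MIXED-class prevalence in real data is unknown; the generator's mix is
  a modelling choice, not an estimate.
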