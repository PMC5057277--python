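# Methods

## Scope and data flow

`fmapy` implements the analysis half of a functional-profiling workflow for
shotgun metagenomes and metatranscriptomes. Its contract starts at
protein-alignment tabular output ("outfmt 6"); read QC, host-read removal
and the alignment itself are upstream tools' jobs. The stages are:

1. hit filtering and best-hit KO resolution (`alignment_filter`),
2. per-sample KO quantification, raw count and RPKM (`quantify`),
3. per-KO differential-abundance testing across groups (`compare`),
4. operon/pathway enrichment over the DA KO set (`enrich`),
5. KEGG color and heatmap exports (`viz_export`),

over a reference model (`refdb`) of protein→KO assignments with amino-acid
lengths, KO→pathway memberships, and ODB3-style operon→KO member lists.

## Filtering and best-hit resolution

Hits must satisfy e-value < 10⁻³ AND percent identity > 80 %. Both
inequalities are strict; a hit at exactly either cutoff is excluded. The
thresholds are configurable (`--evalue`, `--identity`).

A read's best-hit tier is every surviving hit tied on (max bitscore, then
min e-value). The effective protein length PL(r) is the minimum protein
length within the tier, and the KO is taken from that minimum-length
protein, with lexicographic protein_id as the last tie-break. The full
chain — bitscore desc, e-value asc, length asc, id lexicographic — makes
assignment a pure function of hit values, never of file order, so outputs
are reproducible across runs, platforms and input sort orders. Paired-end
mates are treated as independent reads. Hits to proteins absent from the
reference are dropped (logged) and do not count toward the mapped-read
total.

## Quantification

Raw count of KO g = number of reads assigned to g. The RPKM uses each
read's own PL(r):

    RPKM(g) = Σ_{r∈R(g)} 1/(PL(r)·3) · (1/T) · 10⁹

Choices worth noting:

- **T** is the number of reads with a passing best-hit assignment in the
  sample (every reference protein carries a KO, so "mapped" and "assigned"
  coincide). T is recorded in every per-sample output for audit.
- **PL(r)·3** converts amino acids to nucleotides with no stop-codon
  correction; lengths are stored in amino acids everywhere else.
- RPKM is held at double precision; TSV output rounds to 3 decimals.
- Zero-count KOs are materialized as explicit zero rows only when samples
  are merged, so single-sample outputs stay sparse. Merged tables order KOs
  lexicographically and samples as given.

When all best-hit proteins share one length L the formula reduces to
count·10⁹/(3·L·T), i.e. classic RPKM with gene length 3L; the test suite
asserts this reduction and checks the general case against a naive
per-read-loop oracle at relative 10⁻¹².

## Differential abundance

Both implemented tests consume RPKM values; raw counts remain in the
outputs for external tools.

- **Kruskal–Wallis** (default): tie-corrected H, chi-square reference with
  k−1 df (scipy). An all-tied input returns p = 1 by contract rather than
  an error.
- **Quasi-Poisson GLM**: log link, group-factor design, IRLS (statsmodels;
  50 iterations max, tolerance 10⁻⁸, which in practice agrees with the
  closed-form two-group solution within ~10⁻⁶ in p). Dispersion
  φ = Pearson X²/(n−k). For two groups the reported p is the two-sided Wald
  test of the group coefficient referenced to Student-t with n−k df; for
  k > 2 a Wald F-test of the whole factor with (k−1, n−k) df. A group with
  an all-zero mean makes the log-link fit degenerate; p = 1 is returned
  with a `DegenerateFitWarning`.
- **metagenomeSeq** is deliberately an error-raising extension point: it is
  an established external package, and the exported raw-count table is its
  intended input.

Fold change is log₂((m_case + c)/(m_ref + c)) of group mean RPKM with
pseudocount c = 10⁻³ RPKM by default (configurable); the pseudocount exists
only to make zero means finite. The reference group is the first label in
the design file, overridable by flag. With more than two groups the
reported log2_fc compares the first non-reference group against the
reference; per-group means are always reported so other contrasts can be
formed downstream.

DA flag: selected p < α AND |log₂FC| > threshold, both strict; defaults
α = 0.05, threshold = 1. The selected p is raw or BH-adjusted
(`filter_on`). KOs with zero abundance in every design sample are dropped
before testing (logged), keeping enrichment universes clean. BH adjustment
is the standard step-up procedure (statsmodels).

## Enrichment

Operons pass two gates: the **all-members rule** (every deduplicated member
KO is DA) establishes candidacy, then each candidate is annotated with a
Fisher p-value. Pathways are tested whenever ≥ 1 member is DA. The 2×2
table is feature/non-feature × DA/non-DA over the chosen universe; the
two-sided p sums probabilities of all fixed-margin tables whose point
probability is ≤ the observed one (scipy's convention; verified against
brute-force enumeration at |Δ| < 10⁻¹⁰).

- The **universe** defaults to all reference KOs; `detected` mode restricts
  to KOs observed in ≥ 1 sample. Neither choice is canonical; both are
  exposed because the background materially changes p-values.
- **coverage** = |feature ∩ DA| / |feature ∩ universe|.
- **avg_log2_fc** averages over the feature's DA members only, since the
  report accompanies the DA-gene analysis; non-DA members' fold changes are
  in the comparison table.
- Size-1 features are testable but flagged (`single_member`); single-gene
  "operon" enrichment is weak evidence.
- BH q-values are computed within each feature kind over its tested set.

## Visualization exports

The KEGG color file is the two-column paste format of the online pathway
mapper: one DA KO per line, `red` when log₂FC > 0, `blue` when < 0; a DA KO
with log₂FC exactly 0 has no direction and is omitted. Hex colors are
available behind a flag for the form's bgcolor syntax. The heatmap export
is the RPKM matrix restricted to chosen KOs, with `log10p1` or
`zscore_rows` transforms; row z-scores use the population standard
deviation and zero-variance rows emit zeros. Image rendering is left to the
user's plotting tool — the tested contract is the text matrices.

## Synthetic data generator

`synthsim` emulates the pipeline's inputs with known truth:

- **Reference**: `n_kos` KOs (default 500), 1–3 proteins each, lengths
  uniform on 100–600 aa, 20 pathways of 5–15 KOs, 30 operons of 2–5 KOs
  drawn from within one pathway's members where possible (operons nest in
  pathways in real annotation).
- **Abundances**: lognormal(0, 1) base abundances normalized per group;
  spiked KOs (default 50 of 500, i.e. 10 %) multiply the case-group
  expectation by 2^±3 before renormalization, alternating sign so the
  compositional shift on unspiked KOs stays small.
- **Counts**: negative binomial around reads_per_sample × relative
  abundance with size parameter 5 (moderate over-dispersion — deliberately
  not Poisson, to stress both tests). Default 20 000 reads per sample,
  10 control vs 10 case.
- **Hits**: one primary hit per read to a random protein of its source KO,
  identity ~ Uniform(85, 99), e-value log-uniform on [10⁻³⁰, 10⁻⁵];
  optional decoy secondary hits always carry a strictly lower bitscore, so
  the true best hit is unambiguous. A noise-free setting therefore makes
  the filtered counts equal the realized truth exactly, which the tests
  assert.
- **Reproducibility**: one RNG stream per sample keyed by (seed,
  crc32(sample_id)) — adding a sample never perturbs existing ones, and a
  fixed seed gives byte-identical files.
- Truth is written per KO (group relative abundances, spike flag, true
  log₂FC) plus the realized KO × sample count matrix; since each read has
  exactly one source KO, that matrix carries the full per-read truth.

What the simulator does **not** emulate: sequence-level read error (no
FASTQ; the contract starts at alignment output), strain-level redundancy,
cross-KO homology (decoys are uniform, not homology-weighted), GC or length
biases, and compositional structure beyond the spike model. Passing the
end-to-end tests therefore demonstrates correctness of the pipeline's
computations and calibration of its tests under over-dispersed counts — not
robustness to alignment ambiguity in real communities.

## Problem sizes and observed behavior

The acceptance script runs the study-scale spiked simulation (500 KOs,
10 vs 10, 20 000 reads/sample), a 1000-KO zero-spike null, a 2000-replicate
Kruskal–Wallis null calibration (two groups of 8, negative binomial,
mean 50, size 5), and the closed-form worked cases; the whole script
completes in well under a minute on one CPU. Under these conditions the
pipeline recovers spiked KOs with sensitivity ≥ 0.9 at false-positive rate
≤ 0.1 (p < 0.05, |log₂FC| > 1), the null DA fraction stays ~1 %, and the
rank-test null rejection rate sits near the nominal 5 %. Randomly spiked
KOs essentially never cover a whole operon, so the all-members operon list
is typically empty in simulation — the operon rule is instead exercised by
dedicated fixtures.

## Known limitations

- No paired/twin-aware or covariate-adjusted testing; groups are exchangeable.
- The quasi-Poisson k > 2 p-value is a Wald F, not a deviance F; the two
  agree asymptotically but can differ at very small n.
- Taxonomic filtering of a raw annotation dump expects a pre-computed
  taxon_domain column; taxonomy resolution from raw records is out of scope.
- Multi-KO protein rows are expanded one-KO-per-record at load; a read
  hitting such a protein is attributed to whichever expanded record wins
  the tie-break, not fractionally.
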