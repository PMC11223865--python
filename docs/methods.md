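# Methods

## Problem and model

Dominant single-nucleotide variants (SNVs) can in principle be silenced by
CRISPR-Cas cleavage of the mutant allele only, but guide-RNA mismatch
tolerance makes spacer-based discrimination unreliable. `snvpam` implements
the complementary strategy: look for a *protospacer-adjacent motif created by
the variant itself*. If a Cas nuclease's PAM matches the mutant allele in the
variant's neighbourhood while matching the wild-type allele nowhere nearby,
the PAM requirement itself — which is far less mismatch-tolerant than the
spacer — confers allele selectivity.

### Search window and the qualification rule

For a PAM motif of length *L* (written in the 15-letter IUPAC code), the
search window spans *L* bases on each side of the variant, 2*L*+1 bases in
total, clipped at contig ends. The window is as tight as the physics allows:
a placement that does not overlap the variant is identical on both alleles
and can never discriminate, while any placement inside the window that *does*
fit the wild type defeats selectivity even if a second, mutant-only placement
exists — the enzyme would still cut the healthy allele nearby.

A motif **qualifies** for a variant iff

1. at least one placement of the motif (forward) or of its reverse complement
   matches the mutant window, and
2. no placement of either orientation matches the wild-type window.

Every qualifying mutant placement is reported, with its strand and its offset
relative to the variant. The canonical failure mode this rule encodes: for
the single-mismatch motif `NG` and an A→G variant with a G immediately
downstream, the motif can sit with its `N` on the variant and its `G` on the
flank — matching both alleles — so no hit is reported.

Reverse-orientation matching is implemented as forward matching of the
symbol-wise complemented, reversed motif; the complement table extends
Watson–Crick pairing to ambiguity codes (R↔Y, M↔K, B↔V, D↔H; W, S, N are
self-complementary). Wild-type matches in *either* orientation disqualify a
motif: a minus-strand PAM on the healthy allele is as dangerous as a
plus-strand one. One consequence worth knowing: both-orientation matching
means even a variant that creates only the complement of a motif (e.g. A→C
creating `CA`, the minus-strand reading of `TG`) is a genuine hit.

Windows are matched over uppercase A/C/G/T only. Any other reference
character (N, IUPAC ambiguity, soft-masked leftovers) disqualifies the
placements covering it and triggers a warning, because ambiguity cannot
guarantee allele exclusivity. Only single-nucleotide substitutions are
accepted; indels and MNVs are rejected with a clear error.

### Discrimination flag

A qualifying hit is additionally flagged (the `star` column) when the motif
symbol aligned with the variant — complemented for reverse-strand hits — is a
fully specific base equal to the mutant nucleotide. A C→G variant under an
`R` symbol qualifies, but an enzyme demanding `G` at that position is the
safer choice; the flag encodes exactly that preference. `N` never
discriminates.

### Selectivity score

Each motif carries a score used to order candidate enzymes: the sum over its
symbols of a specificity weight,

    N = 0.25;  V, H, D, B = 0.33;  M, R, W, S, Y, K = 0.50;  A, C, G, T = 1.00.

The sum (rather than, say, the mean) is deliberate: it rewards both length
and specificity, so `NNGRRT` (3.50) outranks `NG` (1.25) even though both
start with degenerate symbols. Useful identities: appending any symbol
strictly increases the score; specifying an `N` to a concrete base adds
exactly 0.75. Hits are ranked by descending score, then by the
discrimination flag, then enzyme name — deterministic throughout.

### Strict-promiscuity mode

Several enzymes recognize alternative, less-preferred motifs with reduced
efficiency. These are stored as separate flagged patterns and evaluated
independently (each in its own 2*L*+1 window) when enabled. The optional
strict mode additionally drops an enzyme whose *other* annotated motifs
match the wild type in their own windows — a conservative guard against
promiscuous cutting of the healthy allele. Default is off, because alternate
PAM affinities vary widely between enzymes.

## The packaged registry

The registry ships as a versioned TSV inside the package: 39 class-2 Cas
nucleases (types II and V) with experimentally annotated PAM patterns — 22
natural orthologs and 17 engineered variants — carrying 39 deposited
structure accessions in total. Natural/engineered classification follows the
variant designation column: entries with an engineering tag (VQR, VRER, EQR,
NG, NRRH, NRCH, NRTH, KKH, RHA, RVR, RR, RVRm, TGTV, VTTV, TTTT, TTCN) or
the engineered scaffolds xCas9/enAsCas12a are classified engineered; all
others are natural and carry an organism. User enzymes can be appended at
run time (`add_custom_cas`) or supplied as a registry file in the same
dialect; packaged entries are never mutated.

## Structural companion protocol

**Contact detection.** Given a Cas–DNA complex (PDB or mmCIF, read with
gemmi) and a user designation of the PAM nucleotides (chain + residue
numbers — author numbering of PAM positions is not derivable from the file,
so it is never guessed), the PAM-interacting residues are all protein
residues with ≥1 heavy atom within a threshold (default 4.0 Å, boundary
inclusive) of ≥1 heavy atom of the designated nucleotides. Distances are
plain minimum Euclidean atom–atom distances; hydrogens are excluded because
deposited structures vary in hydrogen content; waters and non-designated
hetero groups never count. Alternate locations are resolved to the highest
occupancy, ties to altloc `A`. The neighbour search uses a k-d tree; the
test suite checks it against a naive all-pairs scan, plus monotonicity in
the threshold and invariance under rigid motions (coordinates in PDB text
carry three decimals, so distances are compared at 10⁻² Å after a rotation
round-trip).

**Substitution candidates.** For each contact residue, every amino acid `a ≠
wt` with BLOSUM62 score `S(wt, a) ≥ threshold` is proposed (default
threshold 0, i.e. conservative replacements; configurable — candidate sets
shrink monotonically as the threshold rises). For threonine this yields
{Ala, Asn, Ser, Val}; the Thr→Asn member is exactly the replacement that
distinguishes the G-specific from the promiscuous member of the minimal-PAM
Cas12c pair.

**Conservation.** Conservation is computed from a *user-supplied* multiple
sequence alignment of homologs (aligned FASTA); homolog retrieval and
alignment are standard upstream steps left to the user's tools. The
per-column index is the mean over all sequence pairs of a normalized BLOSUM62
similarity,

    sim(a, b) = (S(a, b) − S_min) / (max(S(a,a), S(b,b)) − S_min),

with `S_min = −4` the matrix minimum over the 20 standard residues; any pair
involving a gap or non-standard symbol contributes 0. Normalizing by the
pair's own maximal self-score (rather than the global matrix maximum) makes
an invariant column score exactly 1 regardless of which residue it holds,
giving the advertised 0–1 contract with 1 = invariant. This is a
mean-pairwise-similarity index; it does not down-weight redundant sequences
the way similarity-weighted conservation schemes do, which matters for MSAs
dominated by near-duplicates. Columns where the query is gapped carry no
entry; scores map to the query's ungapped residue numbering. Conservation
*annotates* candidates (high conservation suggests functional constraint,
hence engineering risk) but never filters them.

**ΔΔG ranking.** No energy engine is bundled. The scorer is an injected
callable `(structure, mutation) → float`, deterministic for fixed inputs,
with the sign convention that negative ΔΔG means a more favourable Cas–PAM
interaction. The package provides a table-driven `MockScorer` and a
`SubprocessScorer` adapter template for external protein-design executables.
Because some engines only report their top mutant per run, ranking is
iterative: score the remaining pool, extract the most negative (ties broken
by residue number, then proposed amino acid), remove it, re-score, repeat.
For a round-independent scorer this provably equals a single sort (property-
tested); for round-dependent engines it follows the per-round minima.
A scorer failure on one candidate leaves it unscored and the run continues.
Mutant structures can be exported one PDB per candidate with the residue
renamed and side-chain atoms beyond Cβ stripped — side-chain rebuilding is
the scorer's concern.

## Cohort screening and the synthetic generator

A cohort screen aggregates per-variant finder output into (i) a 4×4
targetability matrix — the percentage of variants of each ref→alt class with
≥1 qualifying motif — and (ii) per-enzyme coverage shares. The coverage
counting unit is one (variant, enzyme, pattern) qualification event;
multiple placements of one motif at one variant collapse to a single event.
Less-preferred-motif events are excluded from the denominators by default
and included behind a flag. Unresolvable variants are skipped and counted,
never fatal.

The synthetic generator emulates the *shape* of a clinical SNV screen, not
its content: one 41-bp uniform-random A/C/G/T contig per variant with the
substitution at the centre, all randomness drawn from a single seeded
generator (identical `(n, seed)` give byte-identical cohorts). An optional
context rule plants a wild-type motif across the variant (e.g. `TA` with the
A mutated to G) and rejection-samples the flanks until a designated target
motif qualifies, so planted cohorts are 100% targetable by construction —
the test suite verifies that guarantee against an independent brute-force
matcher. What uniform-random contexts do *not* emulate: the human mutational
spectrum (transition excess, CpG hypermutability), codon structure, GC
heterogeneity, and clinical ascertainment. One visible consequence: on real
pathogenic-variant sets the maximally degenerate 2-nt motif `TN` collects
the largest coverage share, whereas on uniform-random contexts `TN` is
usually vetoed by wild-type matches and the fully specific 2-nt `TG`
(Cas12c1) leads instead. Screening tests therefore assert the robust
ranking property — a minimal-length PAM at the top, with share well above
the uniform mean — not any specific percentage. Default problem sizes
(400-variant random cohorts, 10⁴ matcher-vs-oracle instances, ~30-residue
toy complexes) were chosen as the smallest sizes at which these rankings and
equivalences are stable across seeds.

## Numerical and interface choices

- Coordinates: 1-based in all user-facing I/O (VCF POS, HGVS `g.`); 0-based
  half-open internally; conversions live in `variant_io` only.
- VCF ingestion is a tolerant minimal-dialect reader (5 whitespace-separated
  columns, `#` headers optional) so header-less variant lists work; non-SNV
  rows are skipped and counted.
- Report serialization is deterministic: fixed column order, scores to two
  decimals, distances to two decimals, conservation and ΔΔG to three.
- Online helpers (`fetch_structure` for deposited coordinates,
  `fetch_clinvar_snv` for ClinVar ids) are explicit opt-ins with timeouts;
  the core pipeline never touches the network.

## Known limitations

- No guide-RNA design, off-target scanning, or editing-efficiency
  prediction; the output is the allele-selective PAM inventory, not a
  therapeutic design.
- The conservation index approximates column conservation without
  sequence-redundancy weighting, and no claim is made to reproduce any
  specific external engine's ΔΔG values — only the orchestration and sign
  convention around a pluggable scorer.
- PAM patterns are consensus representations; enzymes vary in how sharply
  they enforce each position, so less-preferred-motif handling and the
  strict-promiscuity mode should be chosen per enzyme with the literature in
  hand.
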