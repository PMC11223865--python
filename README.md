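# snvpam

Allele-specific CRISPR targeting through SNV-derived PAMs.

Gene therapy of dominantly inherited disease needs to disrupt the mutant
allele while sparing the wild-type copy. Guide-RNA sequence alone often
cannot tell two alleles apart — Cas nucleases tolerate single mismatches in
the spacer — but the PAM (protospacer-adjacent motif) requirement is far
stricter. When a single-nucleotide variant *creates* a PAM that the healthy
allele lacks anywhere nearby, a Cas enzyme recognizing that motif cuts the
disease allele selectively. `snvpam` finds those opportunities and helps
engineer the enzymes to exploit them. It is written for genome-editing and
gene-therapy researchers triaging dominant SNVs.

## What it computes

**Finder.** For a variant and each PAM motif *P* (IUPAC string of length
*L*) from a packaged registry of 39 class-2 Cas enzymes (22 natural, 17
engineered, 39 structure accessions), the search window spans *L* bases
either side of the variant. *P* qualifies iff some placement of *P* or of
its reverse complement matches the mutant window, and **no** placement in
either orientation matches the wild-type window. Hits are ranked by a
selectivity score — the sum of per-symbol specificity weights
(N = 0.25; V/H/D/B = 0.33; M/R/W/S/Y/K = 0.50; A/C/G/T = 1.00) — and
star-flagged when the motif demands the exact mutant base at the variant.

**Structural companion.** Given a Cas–DNA complex and the designated PAM
nucleotides, it reports protein residues within a distance threshold
(default 4.0 Å, heavy atoms) of the PAM; proposes conservative
substitutions per residue (BLOSUM62 score ≥ 0 by default); annotates each
site with a 0–1 conservation index from a user-supplied alignment of
homologs; and ranks candidates through a pluggable ΔΔG scorer (negative =
more favourable Cas–PAM interaction) by iterative best-extraction.

**Screening.** Cohort-level statistics: the fraction of variants of each
ref→alt class gaining at least one allele-private PAM, and per-enzyme
coverage shares, plus a seeded synthetic-cohort generator.

See `docs/methods.md` for the full model, conventions and limitations.

## Worked example

A dominant keratin-14 blistering-disease variant is an A→G substitution in
a wild-type `TA` context. On a local reference:

```sh
$ snvpam find --fasta ref.fa --hgvs "s:g.5A>G"
enzyme      pattern  less_preferred  strand   offset  matched_sequence  star   score
Cas12c1     TG       false           forward  -1      TG                true   2.00
FnCas9-RHA  YG       false           forward  -1      TG                true   1.50
```

Read: the mutation creates a `TG` one base upstream-inclusive of the variant
(offset −1 means the motif starts one base before it). Cas12c1 reads `TG`
with a fully specific G on the mutant base (`star = true`, score 2.00), so it
can cleave the mutant allele while the wild-type `TA` offers it nothing; the
engineered YG-reading Cas9 variant is a lower-scoring alternative. Enzymes
like the `TN`-reading Cas12c2 are absent because `TN` also matches the
wild-type `TA` — no selectivity.

The structural companion on the corresponding Cas–DNA complex
(`snvpam contacts --structure 7v94.cif --pam-chain <chain> --pam-residues
<T,G> --threshold 4.0`) lists the PAM-contacting residues; `snvpam design`
then proposes conservative replacements per site — for a threonine contact
these are {A, N, S, V}, and a Thr→Asn swap at the PAM-reading position is
exactly what separates the G-specific from the promiscuous member of the
minimal-PAM Cas12c pair.

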