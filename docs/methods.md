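# Methods

This note documents the models, rules and numerical choices behind
`createscreen`, module by module, including the points where the design was
genuinely open and what the synthetic data do and do not emulate.

## Target selection

Functional residues come from two sources. Curated annotation tables
(TSV: gene, position, site_type, source) are normalized onto the closed
category set {active_site, dna_binding, dimerization, predicted} through a
packaged synonym map; lookups are case- and punctuation-insensitive, and
parenthetical qualifiers ("metal binding (predicted)") resolve through the
qualifier first. Unmatched strings fall into `predicted`, the catch-all
category, with a warning rather than an error — a screen designer should see
what was coerced, not lose rows silently. Rows with unknown genes,
non-integer or out-of-range positions are collected and raised together as
record-level errors with their row indices.

Structure-derived residues use the ligand-proximity rule: a residue is
selected when any of its atoms lies within the radius (default 5 Å,
**inclusive** — the conventional reading of "within") of any ligand atom.
PDB files are parsed with Biopython; hetero records are ligands unless their
residue name is in a configurable solvent exclusion list (water, common
ions, cryo/buffer agents), which covers cofactors such as a [2Fe-2S]
cluster. The neighbour search uses a k-d tree on ligand atoms; unit and
acceptance tests certify it against an all-pairs distance scan.

Partitioning follows a panel configuration: each sublibrary has a category
and a gene list, and a (gene, position, category) annotation joins every
sublibrary whose category and gene list match, so one gene can appear in
several sublibraries. The packaged default panel is the 23-regulator,
five-sublibrary (G1–G5) design with per-sublibrary variant counts
7,000 / 7,340 / 7,400 / 5,260 / 7,340 (34,340 total). Annotations whose
gene/category pair matches no sublibrary are reported as unassigned;
panel genes with zero targets stay in the report with a warning.
Residue positions are 1-based everywhere users see them; internal arrays
are 0-based.

## Library design

Per targeted residue the designer enumerates one substitution spec per
non-wild-type amino acid (default alphabet: all 19) plus one synonymous
control when the wild-type amino acid has more than one codon; Met and Trp
residues get a logged control-unavailable entry. Codon choices are
deterministic: substitutions install the most frequent *E. coli* K-12 codon
of the target amino acid (packaged usage table), controls the most frequent
synonymous codon differing from the wild type. Expression neutrality and
byte-identical reruns motivated frequency-ranked choices over sampling.

**Spacer selection.** Both strands are scanned for NGG PAMs whose blunt cut
site (between protospacer positions 17 and 18, i.e. 3 nt from the PAM) lies
within ±30 nt of the target codon midpoint; the nearest cut wins, ties break
to the + strand and then the leftmost genomic coordinate. The window default
keeps the edit within efficient HDR distance of the cut and is configurable.

**Repair arm.** The 142-nt arm is centered on the edited codon and carries
the codon edit plus one synonymous disruption that destroys the
protospacer/PAM match so the installed allele cannot be re-cut. Preference
order: a synonymous change inside the NGG itself, then a synonymous change
in the seed (≤10 nt from the cut site). Two refinements resolve a tension
between re-cut resistance and trackability: (i) a candidate disruption that
would leave a literal copy of the 20-nt spacer inside the arm (possible for
+-strand PAMs whose protospacer misses the edited codon) is passed over in
favor of a seed change that breaks the copy, keeping the spacer unique
within the oligo; (ii) when the amino-acid edit itself destroys the PAM, no
extra change is introduced (`pam_disruption = "edit-overlaps-PAM"`), and in
the rare corner where a duplicate spacer then survives it is recorded in the
cassette's notes rather than failing the design. Every arm is re-validated
by translating the whole edited CDS: exactly the intended residue changes
(none for controls).

**Assembly.** The cassette layout is 15-nt 5' priming + 142-nt repair arm +
20-nt junction + 20-nt spacer + 33-nt 3' priming = 230 nt. The internal
layout of the oligo is not uniquely determined by the screen design itself,
so the segments are configurable under the hard 230-nt total; the default
maximizes the homology arm. Misconfigured layouts fail at construction,
before any design runs. Designs that cannot be completed (no PAM in the
window, arm outside the provided sequence, no legal disruption) become
failure-log records, never silent drops.

## Synthetic data

Selection is multiplicative in log2 units: cassette *i* with fitness *f_i*
(log2 enrichment per epoch; an epoch abstracts one serial transfer, whose
duration in generations is not modeled) has expected post-selection
frequency `p_i' = p_i·2^(f_i·t) / Σ_j p_j·2^(f_j·t)`. Observed counts are
multinomial draws at the sequencing depth from p and p'. Library skew is
log-normal (σ = 0.6 by default), a mild, realistic unevenness from synthesis
and cloning; one pre and one post timepoint are simulated by default.

Sequencing emits one read pair per molecule: R1 = 6-nt sample barcode +
amplicon prefix, R2 = reverse complement of the amplicon suffix, each 250 nt
against the 450-nt amplicon (constant vector flanks around the 230-nt
cassette), with i.i.d. substitution errors (default 0.3 %) that always
change the base, and constant placeholder qualities. Not modeled, because
the screen's analysis makes no use of them: PCR amplification bias, indels,
chimeras, quality variation. Passing tests therefore demonstrate correctness
of the algorithms under substitution noise and sampling noise, not
robustness to structural read artifacts.

The default screen generator produces 500 cassettes — 50 residues across
random genes, 9 substitutions + 1 synonymous control each (per-residue
alphabets drawn deterministically from a fixed amino-acid order) — plants
effects in 10 substitution cassettes drawn uniformly from [2, 5] log2 units,
and sequences 10⁵ counts/read pairs per timepoint.

## Read processing

**Merging.** The best overlap is the longest suffix(R1)/prefix(revcomp R2)
overlap (≥10 nt) whose mismatch rate is ≤0.1; disagreements resolve in favor
of R1, since inputs carry constant qualities (quality-weighted resolution is
a documented extension point). A vectorized batch path shares exact
semantics with the scalar reference implementation and is property-tested
against it and against an exhaustive shift search.

**Demultiplexing** assigns a read to the unique barcode within a Hamming
tolerance (default 1) of its prefix and strips it; configurations whose
barcodes are not pairwise separated by more than twice the tolerance are
rejected up front.

**Mapping** supports two acceptance rules because the screen's two stated
constants disagree slightly (3 mismatches over 450 nt is 99.33 % identity,
not 98.3 %): identity mode (identity strictly > 98.3 %, the default) and
mismatch-count mode (≤3). Identity is computed over an end-gap-free
co-linear comparison — Hamming for equal lengths, global edit distance with
indels counted as mismatches otherwise (edlib) — with the alignment length
as denominator. The best-scoring reference wins; equal-best hits to two or
more references go to an ambiguous bin rather than being assigned
arbitrarily, because trackability depends on unique assignment. Every run
satisfies mapped + unmapped + ambiguous = total.

**Summaries.** Editing efficiency is mutant-mapped reads over the sample
total. Base-change frequencies first retain reads at ≥95 % identity to the
wild type, then divide the per-position substitution count by the number of
retained reads with perfect (100 %) identity — the screen's own, unusual
denominator, under which frequencies can exceed one; a conventional
retained-read denominator is available behind `denominator="total"`.
Length-discordant reads cannot be compared base-by-base and are excluded
from the positional tally.

## Fitness analysis

Scores are log2 ratios of post to pre frequencies over mapped reads, with
pseudocount α = 0.5 (configurable; α = 0 is supported and yields missing
values at zero counts with a warning). The null uses the sample (n−1) SD of
finite control scores — control sets can be small — and requires at least
two; the hit rule is strict (`score > μ + kσ`, k = 2), controls are never
reported as hits, and output is sorted by descending score within condition.
No multiple-testing correction is applied, matching the screen's single
cutoff rule; an empirical-FDR report (count/fraction of controls above the
cutoff) is provided but never alters calls. Fitness is per screen (one
pre/post pair), not normalized per transfer.

One subtlety matters for parameter recovery: the generative model defines
*f* relative to a neutral cassette, while every raw score shares the offset
`−log2(Σ_j p_j·2^(f_j·t))` (≈ −0.3 under the default screen, since the
planted winners dilute everyone else). Estimated effects are therefore
centered on the synonymous-control mean before comparison with planted
truth; hit calling itself uses the raw scores, exactly as the screen's rule
prescribes.

## Problem sizes and determinism

The default test suite designs pools of tens of variants and runs one
full-scale simulated screen (500 cassettes, 2×10⁵ read pairs, ~1 minute);
oracle-equivalence suites use 100 random cases per oracle with fixed seeds.
All randomness flows through `numpy.random.default_rng` seeds; same seed,
same bytes, including the written FASTA/TSV artifacts. The acceptance script
derives all sub-seeds from its `--seed` argument.

## Known limitations

- Homology search, structure prediction and database retrieval are out of
  scope; annotations and coordinates are consumed as files.
- The designer does not model synthesis constraints (GC content,
  homopolymers) or Cas9 off-target scores.
- The identity denominator for unequal-length comparisons uses the longer
  sequence as alignment length, a co-linear approximation adequate for
  amplicon reads but not for reads with large structural differences.
- The exact residue inventory of the original 23-gene panel (1,700 residues)
  is not reconstructible from published information; the packaged panel
  records gene lists and sublibrary sizes, and residue-level inputs are the
  user's.
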