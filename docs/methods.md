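# Methods

## Model

phasiRNA biogenesis leaves an arithmetic fingerprint on mapped small-RNA
reads. After a miRNA-guided cut fixes a register, RNA-dependent RNA
polymerase and Dicer-like processing release 21-nt duplexes head-to-tail,
so sense-strand 5′ ends fall on one residue class modulo 21 and antisense
5′ ends on that class minus 2 (the 2-nt 3′ overhang of each duplex).
`phaswindow` treats detection as an occupancy problem: within a genomic
window, are the start positions that carry 21-nt reads concentrated on one
register beyond what random placement allows?

The test statistic is exact. A 210-nt window contains N = 420 candidate
start positions (210 per strand); each register x ∈ [1, 21] owns m = 20 of
them (10 per strand, antisense displaced by the duplex offset); registers
partition the candidates (21 × 20 = 420). If n candidates are occupied by
at least one collapsed 21-nt species and k of them lie on register x, the
p-value is the hypergeometric upper tail P(X ≥ k) for drawing n positions
without replacement from N with m marked. Occupancy — not abundance —
enters the test, which makes it robust to single dominant species;
abundance enters later through the phase score. p-values are computed with
scipy's survival function, which the test suite verifies against exact
integer-arithmetic tail sums for every quadruple with N ≤ 60 (worst
relative deviation below 10⁻⁹; observed ~10⁻¹⁵).

Windows slide in 21-nt steps across maximal read-covered regions, the last
window extending past a region's 3′ end (ceiling rule) so trailing reads
are always tested. The window count therefore equals the covered length
divided by 21 (exactly so when region lengths are multiples of 21) and is
independent of sequencing depth.

Significant (window, register) pairs with p < 10⁻⁶ are grouped by
chromosome and absolute phase residue (window start + x − 1, mod 21);
overlapping or bookended windows on one phase track merge into a locus,
which is trimmed to its outermost on-phase occupied starts (+21 on the
right). Loci are ranked by the phase score

    score = (k − 2) · ln(1 + 10·P / (1 + U))

with P the summed on-phase abundance, U the off-phase abundance and k the
occupied on-phase positions in the trimmed extent; k ≤ 2 scores zero, so
two isolated positions (one duplex) never outrank a real ladder. Ties
break by smaller p-value, then leftmost coordinate — determinism is a
contract. The top 50 loci are retained. No multiple-testing correction is
applied: the method couples a stringent raw threshold with top-K
selection, and both knobs are exposed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `W` | 210 nt | window width, 10 phase cycles |
| `s` | 21 nt | phase length and window step |
| `p_threshold` | 1e-6 | raw hypergeometric cutoff |
| `top_k` | 50 | ranked loci retained |
| `duplex_offset` | 2 nt | antisense register displacement |
| `min_len` / `max_len` | 18 / 30 nt | library retention window (inclusive) |
| `max_hits_phasing` | 6 | genomic-multiplicity cap for the scan |
| `min_total` | 3000 | pooled-count phasiRNA threshold (strict >) over 7 samples |
| `max_phases` | 2 | dominant registers allowed per locus |
| `phase_bin_frac` | 0.10 | dominance cutoff as a fraction of locus abundance |
| `max_penalty` | 3.0 | miRNA target-site penalty cutoff (inclusive) |
| `max_distance` | 420 nt | cleavage-to-phasiRNA proximity (inclusive) |
| `flank` | 500 nt | sequence scanned around each locus for sites |

Only 21-nt species enter the scan: the phase test is a same-length
statistic, and whether other lengths should count toward occupancy is
genuinely open — we exclude them and expose `phasing_len`. Multi-mapped
species contribute their full count at every retained alignment (≤ 6)
during discovery but are tabulated once for expression, mirroring the
dual-mapping design of sRNA pipelines that align separately for discovery
(up to 20 alignments) and quantification (one alignment per read).
Per-sample counts are pooled for the scan; per-sample resolution is kept
for phasiRNA tables.

The abundance threshold is defined against a seven-library pool; with a
different sample count it scales as `min_total · n_samples / 7`
(overridable via `scale_min_total=False`), so small simulated designs
exercise the same rule. The threshold applies to raw pooled counts. The
">2 dominant registers" locus filter makes programmatic what is usually
judged from a phase graph by eye; the 10 % dominance cutoff is our choice
and is exposed.

## Trigger scanning

The complementarity score is the classical plant-target penalty: mismatch
1.0, G:U wobble 0.5, single-nucleotide bulge 1.0, each doubled within
miRNA positions 2–13, site read 3′→5′ against the miRNA 5′→3′. It is a
transparent stand-in for proprietary web-service expectation scores, with
the same ≤ 3 cutoff semantics. Bulge handling is limited to one
single-nucleotide asymmetry per duplex, keeping the scan linear; the
vectorized scanner is verified position-by-position against the reference
scorer. Cleavage is placed opposite miRNA position 10 (10 nt from the
site's 3′-paired edge); a site links to a phasiRNA when |cleavage − 5′
end| ≤ 420 nt, and register agreement (distance ≡ 0 mod 21) is recorded
as a flag but not filtered on, since the proximity rule alone defines the
linkage.

## Normalization and fold-change tables

Size factors are median-of-ratios: factor_j = median over species of
count_ij divided by the species' geometric mean, computed on species
detected in every sample (a `pseudocount` option serves sparse matrices).
A test cross-checks the estimator against an independent DESeq2
implementation. Fold-change classification is inclusive at both bounds
(suppressed ≤ 0.5, elevated ≥ 2); zero-denominator species are flagged,
not dropped. The differential rule — p < 0.001 strict AND |log₂FC| ≥ 2
inclusive — is evaluated with a two-sided exact binomial test on rounded
normalized totals under an equal-contribution null; this is a documented,
dependency-free stand-in for MA-based count tests, and downstream logic
consumes only the flags.

## The simulator

`synthetic.simulate` emulates the structure of a mapped plant sRNA-seq
library: 2 samples (a `n_samples=7` configuration mirrors a seven-tissue
design), 20 non-overlapping 420-nt loci, each with 10–20 occupied duplex
cycles (sense + antisense reads, antisense at −2 nt), negative-binomial
species counts (mean 40, dispersion 10; 3 species per locus at mean 800 so
the abundance filter has both survivors and casualties), uniform 18–30-nt
background at 5 species/kb/sample, and one planted trigger per locus: the
miRNA's exact reverse complement written into the genome so that its
cleavage position is phase-registered and 0–42 nt upstream of the first
phasiRNA. Background 21-mers landing exactly on a planted register inside
a locus are resampled, keeping truth labels unambiguous. Read sequences
are taken verbatim from the genome — a zero-mismatch mapping regime.
Identical configs (including seed) produce byte-identical output files.

What the simulator does not model: sequencing error, base-composition
bias, expression structure across tissues, miRNA hairpin precursors,
24-nt reproductive phasiRNAs, and multi-mapping reads (all planted reads
are unique). Passing recovery tests therefore demonstrates correctness of
the arithmetic and the filter chain under the stated read model, not
robustness to alignment artefacts or biological confounders on real
libraries.

## Numerical and design notes

- Coordinates are 0-based half-open throughout; SAM and GFF3 conversion
  happens only at the format boundary. Reads with indels or clipped
  CIGARs are rejected from phasing input (the model assumes perfect
  ungapped matches) and counted in the log.
- Candidate starts are all positions inside the window (N = 2·W), so the
  21 registers exactly partition the candidates. The alternative of
  counting only starts that admit a full 21-mer (N = 2·(W − 21 + 1))
  differs negligibly at W = 210.
- Degenerate inputs: k = 0 gives p = 1; a fully occupied window (n = N)
  gives p = 1 for any attainable k; empty read sets yield empty scans;
  all-zero phase profiles are discarded with reason "empty".
- Loci are called independently per read set; cross-accession comparison
  is a reporting step, not part of calling.
- Problem sizes in the test suite and acceptance script — a 200-kb
  two-chromosome genome with 20 loci for recovery, a 1.2-Mb background-only
  genome giving ~3 × 10⁵ window-register tests for the null — were chosen
  so the full suite completes in well under a minute while keeping every
  statistical check at meaningful scale.
- The per-chromosome window count is logged at INFO so the
  depth-independence of the window count is observable on any run, and
  `manifest.json` snapshots every threshold and per-stage record count.
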