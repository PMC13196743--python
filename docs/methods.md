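# Methods

## Fidelity model

Each designed junction is a 4-base overhang *o*. The probability that *o*
ligates to its Watson–Crick partner rather than any other overhang in the
reaction is estimated from a ligation-frequency matrix *m* (256×256,
ordered 4-mer pairs):

```
f(o) = [ m(o, rc(o)) + m(rc(o), o) ] / Σ_{p ∈ R} [ m(o, p) + m(rc(o), p) ]
```

where R is the set of distinct species present: every designable junction
and both backbone (vector ligation) overhangs, each together with its
reverse complement. The assembly fidelity of a junction set is the product
of per-junction fidelities, which assumes each junction is used once in a
single sequential assembly and junction outcomes are independent. Backbone
sites always appear in every denominator; whether their own two factors
multiply into the product is a switch (`fidelity_includes_backbone`, default
on).

Conventions worth stating explicitly, because the ratio form makes several
otherwise-important choices irrelevant or deliberate:

- Frequencies are used unnormalized; row scaling cancels in the ratio.
- Empirical matrices may be asymmetric. Entries are used as given and both
  orientations are summed explicitly rather than pre-symmetrizing; the
  formula above is the package's normative contract.
- Palindromic 4-mers (16 of 256) are excluded from candidate junctions:
  they ligate copies of themselves in both orientations and guarantee
  misassembly.
- A junction's reverse complement is a reaction species but never a second
  designable junction; uniqueness is enforced over junctions ∪ their
  complements ∪ backbone.

## Synthetic ligation matrices

`LigationMatrix.make_synthetic(orthogonality, seed)` places fraction
`orthogonality` of each row's mass on the correct partner and spreads the
rest over the other 255 ordered partners with seeded multiplicative jitter
(uniform in 1±0.5, renormalized per row). The jitter is essential: a
perfectly even spread would give every same-size junction set an identical
fidelity, flattening the optimization landscape and making annealing (and
its tests) vacuous. `orthogonality=1.0` is the exact identity pattern.
Because only a handful of the 255 off-target partners are ever present in a
reaction, realized per-junction fidelities are much closer to 1 than the
row orthogonality itself (e.g. ~0.996 per junction at 0.99 row
orthogonality in a 50-species reaction).

What the synthetic matrix does not emulate: the strong sequence determinants
of real ligase bias (GC-rich overhangs ligating faster, specific mismatch
tolerances), enzyme/temperature dependence, and correlations between
related overhangs. Designs validated against it demonstrate the machinery,
not the wet-lab fidelity of any particular overhang set; for production
designs supply an empirical matrix CSV.

## Layout arithmetic

With `oligo_len` = 300, `primer_len` = 20, BsaI recognition (6 nt) and a
1-nt spacer at both ends, the payload is
`300 − 2·(20+6+1) = 246 nt` of coding sequence per oligo. Fragments per
gene is the smallest F with `ceil((L_max + 4(F−1))/F) ≤ payload` (adjacent
fragments share the 4-bp junction); every gene in a library uses the same
F, sized by the longest gene, to keep per-construct assembly efficiency
comparable. This reproduces the 5-fragment 1-kb and 7-fragment 1470-nt
worked cases. `fragments_override` exists because minimal F is not always
the operational choice (e.g. 714-nt genes fit 3 fragments arithmetically
but leave almost no breakpoint slack; the four-fragment layout used for
that scale in our stress fixtures gives the annealer ~60-position windows).

Genes per subpool under a junction budget B: `floor((B − 2)/(F−1))` with
the backbone pair counted inside the budget (default), or
`floor(B/(F−1))` when the two vector sites are budgeted separately — both
conventions appear in practice, so the flag `budget_includes_backbone`
selects one. Partition is a seeded shuffle dealt round-robin, guaranteeing
pool sizes differ by at most one; a 92-subpool cap (the size of available
orthogonal primer sets) warns at partition time and errors at emission.

## Annealing

- Breakpoints are 0-based indices into the coding sequence; the overhang is
  `seq[p:p+4]`; upstream fragment ends at `p+4`, downstream begins at `p`.
  Terminal fragments carry the backbone overhangs as outer 4-mers.
- Initialization: equal-length fragments, `round(i·L/F)`, with clashing
  4-mers resolved by nearest-first (±1, ±2, …) shifts inside the legal
  window, genes scanned in input order. Deterministic; an unresolvable
  window is an error naming the gene and junction.
- Legal windows keep both flanking fragments within
  `[min_fragment_len, payload]` (defaults 20/246 nt) and are recomputed
  against current neighbors on every proposal.
- A move relocates one uniformly chosen junction to a uniformly sampled
  alternative legal position whose 4-mer keeps the set invariant-clean;
  invariant-violating positions are rejected at proposal time so the
  objective stays the pure fidelity product. Uniform sampling over the
  window (rather than local ±1 shifts) was a design choice; it mixes faster
  on the plateau-rich landscapes synthetic matrices produce.
- Temperature: geometric interpolation from 5×10⁻³ to 10⁻⁵, advanced per
  proposal (not per acceptance); improvements always accepted, worsenings
  with probability exp(ΔF/T).
- Defaults: 5000 steps × 25 restarts from seeds `base_seed + r`; ties
  across restarts go to the lowest seed, and the winning seed is recorded
  in the manifest for exact reproduction. Larger junction budgets warrant
  the 50×5000 schedule. Tests and the acceptance suite run scaled-down
  schedules (hundreds of steps, 2–10 restarts) on pools of up to 16×714-nt
  or 6×2595-nt genes, which keeps the whole suite under half a minute while
  still exercising every code path; on toy pools (≤10⁴ combinations) the
  annealed optimum is checked against exhaustive enumeration.
- `diverse_pair` selects, among replicate designs of one pool, the two
  junction sets with maximal summed per-site Hamming distance between their
  sorted junction lists — useful when assembling replicate libraries with
  different overhang solutions.

## Oligo emission

Layout per oligo: forward primer · left pad · GGTCTC · N · payload
(overhang…fragment…overhang) · N · GAGACC · right pad · rc(reverse primer);
pads split evenly with the left pad taking the odd base. Pad and spacer
bases are sampled one at a time, rejecting any base that completes a
recognition site against its upstream context; the finished oligo is then
scanned on both strands and must contain exactly the two designed
convergent sites, else the pads are resampled (capped retries). Genes are
screened for internal sites at the assembled-construct level (backbone
context included, since a site can form across the vector junction);
severity warn/error is configurable, error by default. The enzyme is a
descriptor (recognition, spacer length, overhang length), so other Type IIS
enzymes plug in; the 1-nt spacer between recognition site and overhang is
the canonical BsaI geometry.

Subpool primers come from a user table (experimentally verified orthogonal
pairs); `placeholder_primer_table` generates a synthetic stand-in of
distinct random recognition-free 20-mers for testing only — it does no Tm,
secondary-structure or cross-dimer screening.

## Reaction simulator

Deliberately minimal: independent junction choices, no re-ligation, no
concentration effects. Its purpose is validating the product-of-fidelities
prediction, not mechanistic realism. Each event starts at the vector's 5'
overhang and grows rightward; at each exposed overhang a partner species is
drawn from the fidelity model's own weights. The two orientation entries of
one duplex are pooled — `m(o,rc(o)) + m(rc(o),o)` is the correct-partner
event, `m(o,o) + m(rc(o),rc(o))` the self-pairing event — so the
per-junction correct probability equals `junction_fidelity` exactly for any
matrix, and the pool-mean simulated correct fraction converges on
`expected_yield` by construction (tested at 3σ with 10⁵ events). Wrong
partners chain into misassembled codes when a matching fragment end exists
and dead-end otherwise; dead ends count as incorrect outcomes, the way
misassemblies appear in reads. An optional digestion step re-cuts finished
constructs containing an internal recognition site (survival probability
0.1), reproducing the depletion of site-containing designs. A growth cap
(4× the longest designed code) guards against cycles.

`perfect_roundtrip` is the release gate: digest every emitted oligo and
rejoin by exact overhang identity (the identity-matrix limit); the output
must equal the input gene set exactly.

## QC metrics

- Yield = correct reads / total reads. A design is observed with ≥1 count;
  the uniformity window is fold-from-median ∈ [0.1, 10]. The fold
  denominator is the median over observed designs (zero-count designs still
  count against the observed fraction); replicate libraries are combined by
  normalizing each to its total and summing.
- Assembly codes are decoded from reads of concatenated barcodes (≥15 bp
  apart by design) at ≤3 mismatches per barcode, rejecting partial reads,
  ambiguous ties, and mixed-pool codes.
- Edit distance is Levenshtein (edlib); 0 = sequence-perfect, 1–10 is
  consistent with synthesis/sequencing error, >10 indicates assembly error.
- Coverage: Monte-Carlo coupon collector over the observed abundance
  distribution; reads discarded with the given error rate, so error is a
  uniform 1/(1−e) depth inflation. Uniform-abundance k=1 has the closed
  form n·H_n used as a cross-check.

## Fixture generators

The stress sets emulate three axes: pairwise identity (identical /
86–90% / 49–50%, achieved by bisecting a per-copy substitution rate from
the closed-form starting point `(1−r)² + r²/3 = t`), GC content (exact-count
construction, mutation with GC repair, held within 1% of target), and
tandem repeats (five unit copies with 5% per-copy divergence, DARPin-like).
Pairwise identity is positional for equal-length sets and global-alignment
based otherwise. All generated sequences are scrubbed of recognition sites
in construct context via GC-preserving transversions, mirroring
codon-optimized input. Sets are deterministic under seed and self-validate
against their bands before being returned. They do not emulate codon
structure, homopolymer pathologies, or synthesis error profiles, so passing
designs say nothing about those failure modes on real inputs.

## Known limitations

- The fidelity product ignores kinetic competition between partially
  assembled intermediates and any concentration dependence.
- The annealer's per-restart convergence is landscape-dependent; on
  strongly coupled toy instances a minority of restarts stall in
  coordinate-wise local optima, which is why restarts (and the recorded
  winning seed) exist.
- No primer thermodynamics, no vendor-format exports beyond CSV/TSV/FASTA,
  no raw-read alignment: counts enter QC pre-tabulated.
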