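# Methods

## Scope and model

`cleavemap` models the characterisation of a single-strand, sequence-specific
RNA endoribonuclease by degradome-style sequencing plus a fluorometric
cleavage assay. The enzyme modelled by the defaults recognises the tetrad
UACA and cleaves between its first and second base (U^ACA); three further
tetrads — UACC, UACU, AACA — are cleaved with much lower efficiency.
Everything is single-stranded and strand-specific: no reverse-complement
scanning is performed anywhere.

Sequences are stored in the DNA alphabet (T) and rendered as RNA (U) in
reports, mirroring the field's mixed usage (logos in DNA letters, enzymology
in RNA letters).

## Synthetic experiment

**Constructs.** `make_construct` plants the requested tetrads at
non-overlapping uniform-random positions and fills the remainder with
uniform-random bases. The finished sequence is re-scanned so the ground truth
lists *every* tetrad occurrence, incidental ones included. Two optional
design controls mimic curated construct design: a minimum spacing between
planted sites and `avoid_incidental=True`, which mutates the fill until the
motif content is exactly the deliberate one.

**Digestion.** Each of `n_molecules` copies is digested independently; every
motif occurrence is a Bernoulli cut with its rule's efficiency (defaults:
primary 0.8, suboptimal 0.15 — unreported experimentally; chosen so primary
sites dominate the top-15 while suboptimal sites reach ranks 16–25). k cuts
yield k+1 fragments that tile the molecule exactly; a fragment that starts at
a cut begins at `site + cut_offset` (for U^ACA, on the first A of ACA).

**Library.** Reads are single-end, 5′-anchored prefixes of sampled fragments
(default 50 nt, constant Q40). A background fraction (default 0.3) of draws
are random sub-fragments (uniform start, geometric length with mean
2×read-length), supplying the nonzero baseline coverage without which the
coverage ratio is undefined. Substitution errors only, default 0.1% per base.
The number of reads is `depth_target × L / read_length`; because short
fragments yield short reads, realised mean depth sits a few percent below the
target. Ligation bias, PCR duplicates, adapters and barcode chemistry are
deliberately not modelled — the simulator validates the *detection
statistic*, not library chemistry, so passing tests say nothing about those
real-data artefacts.

**Fluorescence.** Reporter time courses follow
F(t) = F0 + (Fmax − F0)(1 − e^(−kt)) with i.i.d. Gaussian noise clipped at
zero (defaults F0 = 100, Fmax = 1000 a.u., readings every minute for 60 min,
noise sd 5, triplicate). The rate is set by substrate × condition logic: the
enzyme gives k_fast (0.5/min) on an all-RNA primary tetrad at either dose,
k_slow (0.05/min) on a suboptimal tetrad only at the high dose, and 0
otherwise; RNase A gives k_fast on any RNA-containing backbone; a pure-DNA
backbone and the no-enzyme condition are always flat. A tetrad interrupted by
DNA linkages does not count as a substrate. The raw published observable is
the curve itself; the first-order form is this package's parametrisation.

## Detection

**Mapping.** Reads are aligned ungapped by seed-and-extend on exact 20-mers
(seeds at read offsets 0, 20 and len−20), scored by full-length mismatch
count with a cap (default 2). A read whose best score is tied at distinct
positions is discarded as ambiguous; reads shorter than the seed cannot be
placed and are counted as unmapped. Exact matches found through a globally
unique seed are accepted directly — a second equally good exact hit would
force that seed to be non-unique, so no ambiguity can be missed on that path.

**Coverage and RCI.** Depth is full-overlap depth (the mapping-viewer
convention), computed by difference-array accumulation and verified against
brute-force interval counting. RCI(n) = c(n+1)/c(n) is left undefined
(masked, NaN) where c(n) = 0 rather than infinite, so every defined value is
rankable. The minimum-coverage filter (default 500) applies to c(n+1), the
position actually reported.

**Selection and consensus.** Boundaries are pooled across all references and
ranked by RCI; ties break by higher c(n+1), then reference id, then smaller
position, making output order deterministic. The ±5 nt windows (total width
11, column 0 on the candidate) skip candidates within 5 nt of a reference
end. The PFM uses an additive pseudocount (default 0.5); information content
is 2 + Σ_b f_b log2 f_b bits, clipped to [0, 2]. A consensus column is called
when the majority base frequency ≥ 0.5 and IC ≥ 1 bit (majority ties break
alphabetically); both thresholds are configurable — sequence-logo practice
displays rather than calls, so the thresholds are this package's choice. The
motif span is the maximal contiguous non-N run containing offset 0, and the
cut offset within the motif is the position of offset 0 in that run.

## Fluorometric classification

Endpoint = mean intensity over the final 10% of time points after averaging
replicates. Fold change is the ratio of raw endpoint means, test over
no-enzyme control; baseline subtraction was considered and rejected because
it drives the control denominator toward zero and makes the ratio unstable —
the baseline is instead estimated explicitly (F0) by `fit_first_order`, a
bounded least-squares fit (scipy `curve_fit`, k ≥ 0) that flags
non-convergence in its result rather than raising, and short-circuits an
exactly flat series to k = 0 (the amplitude is degenerate there). The call
threshold is 2.0-fold (configurable); "low"/"high" dose are opaque condition
tags. Classification is monotone: raising the threshold can only move a call
toward uncleaved.

## Study conditions of the end-to-end scenario

The bundled motif-recovery scenario uses five 1000-nt constructs, each with
three planted UACA sites and one site per suboptimal tetrad, planted ≥ 60 nt
apart and ≥ 60 nt from the ends, with incidental tetrads scrubbed; digestion
of 300 molecules per construct; depth 2000 at read length 50, background
0.3, error 0.1%; filter 500, top-15/top-25. The sizing is deliberate:
5 × 3 = 15 primary sites make the global top-15 coincide with the primary
cut set, and 15 suboptimal sites compete for ranks 16–25, so each suboptimal
tetrad is essentially always represented there. With uniform-random fill a
1000-nt sequence would contain ~4 incidental UACA sites by chance; cut at
full efficiency these would flood the extension ranks, which is why the
scenario uses the scrubbed, spaced design (a stand-in for the curated
construct design of real experiments, whose composition is not public). The
acceptance tests replay this scenario over 20 seeds; `scripts/acceptance.py`
uses 10 seeds to keep its runtime to a few seconds — both sizes were chosen
as comfortable for a single CPU while keeping the binomial noise on the
reported fractions small.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive everywhere; SAM interop keeps SAM's own
  1-based convention. Only match-only CIGARs are accepted on ingestion; the
  simulator never emits indels, and rejecting them is safer than guessing.
- One seeded `numpy` generator per operation invocation; pipeline stages
  derive per-stage, per-item sub-seeds from the master seed (all < 2^31), so
  any stage can be re-run in isolation and byte-identical outputs follow
  from equal seeds.
- `digest` ignores a motif occurrence whose cut would fall outside the
  molecule (a cut before base 1 or after the last base cleaves nothing).
- Requesting more top-N candidates than pass the filters returns all of them
  with a logged warning rather than an error.
- An empty window set, empty FASTQ, missing control series or malformed
  backbone mask raise `ValueError` early with a named cause.

## Known limitations

- The mapper is exact-seeded and ungapped; it is built for this simulator's
  error model (substitutions ≤ ~2 per 50-nt read), not for real noisy
  libraries with indels or adapters.
- Truth-complete constructs make recall measurable, but real references
  contain nested and overlapping motif occurrences at uncontrolled spacing;
  closely spaced cuts (< read length) depress each other's RCI and are the
  main realistic failure mode, which the spaced scenario intentionally
  avoids.
- The fluorescence model is phenomenological; quenching photophysics,
  instrument drift and inner-filter effects are out of scope.
- Suboptimal-site detection depends on the efficiency ratio; with primary
  efficiency near suboptimal, top-15 purity degrades gracefully but the
  package draws no significance bounds on RCI ranks.
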