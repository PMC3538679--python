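# Methods

## Problem and model

Shotgun proteomics identifies peptides by matching each measured MS/MS
spectrum against theoretical spectra of candidate peptides whose precursor
m/z lies within a tolerance of the measured one. `pepsearch` splits this
into two independently reusable computations:

1. **Database build.** Every protein is digested with a generic enzyme rule
   (cleave after a residue set unless followed by a blocking residue;
   trypsin K/R-not-before-P by default), fragments spanning up to
   `missed_cleavages` internal sites are kept (plus, in semitryptic mode,
   every sub-fragment retaining at least one enzymatic terminus), and each
   peptide is expanded over its admissible modification states. Unique
   (sequence, modification-state) pairs are stored once, carrying the union
   of source protein ids, grouped into integer bins of width 1 Da on the
   singly-protonated m/z axis.
2. **Search.** Each spectrum is preprocessed once, routed to every bin
   overlapping `[M1 − tol, M1 + tol]` (where M1 is the z=1-equivalent
   precursor m/z), scored against the candidates passing the *exact*
   tolerance check (the bin is only a coarse filter), and the per-scan
   results are merged, ranked, truncated to `top_k`, and consolidated into
   a single X!Tandem-style XML document.

Both computations run as chains of map-shuffle-reduce jobs on a local
executor that guarantees (a) all values of a key reach exactly one reducer
invocation and (b) keys arrive in ascending order within each reducer
stream. These two contracts are what make deduplication ("each unique
peptide key reaches one reducer") and single-file consolidation in sorted
scan order ("last job has one reducer") structural rather than incidental.

## Mass model

Monoisotopic masses throughout; the charge carrier is a proton
(1.00727646688 Da), water is 18.01056468 Da. A peptide's neutral mass is
the residue-mass sum + water + modification deltas; the m/z of `[M+zH]z+`
is `(M + z·m_p)/z`. Peptides containing nonstandard letters (B, J, O, U,
X, Z, internal `*`) are rejected with a logged counter — guessing a mass
would silently corrupt the bins. Terminus modifications attach to position
1 (N) or n (C). The modification identity key rounds deltas to 5 decimals
so float noise cannot split identical states.

## Scoring

Preprocessing: (1) peaks within ±2.0 Da of the precursor m/z are dropped;
(2) intensities are square-root compressed; (3) the observed m/z range is
cut into 10 equal windows and each non-empty window is scaled so its
maximum is 50.0, making the score invariant to absolute intensity scale
and robust to locally dense noise; (4) peaks collapse into fragment bins
of 1.0005 Da, keeping the per-bin maximum. The score is the dot product of
the processed spectrum with the candidate's theoretical b/y positions
(b1..b(n−1), y1..y(n−1), singly charged; doubly-charged fragments are
added for precursor charge ≥ 3): each fragment credits the best
still-unused bin within ±0.4 Da, so a bin is never counted twice. Ties
between equal-scoring peptides break on the canonical modified-sequence
key, keeping output deterministic.

These constants (10 windows, cap 50, 1.0005 Da bins, 0.4 Da fragment
tolerance, 2.0 Da precursor exclusion) are conventional COMET-family
defaults, all exposed under `scoring:` in the config; numerical equality
with any other K-score implementation is not claimed — ranking behavior
and the invariants tested are the contract.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| missed_cleavages | 1 | sites | standard tryptic search practice |
| peptide length filter | 6–50 | residues | excludes unobservable fragments; configurable |
| bin_width | 1.0 | Da | one bin per nominal mass at z = 1 |
| precursor_tolerance | 2.0 | Da (z=1 axis) | generous desk default; ppm mode available |
| split_limit | 20 000 | peptides/split | caps per-task memory; results are provably invariant to it |
| top_k | 10 | matches/scan | retained PSM list length |
| charges (unknown) | 2–3 | — | conventional guess set for MGF blocks without CHARGE |

## Execution model choices

* The final output of every job is sorted by key (ties broken by the
  pickled value bytes). The grouping/sortedness contracts alone do not fix
  the concatenation order of different reducers' outputs; sorting makes
  results byte-identical across backends *and* reducer counts, which the
  equivalence tests assert literally.
* The partitioner is a fixed-seed blake2b hash of the serialized key —
  never Python's per-process randomized `hash` — so partitioning is stable
  across processes and runs.
* The multiprocess backend forks a process pool; mappers and reducers are
  small picklable callable objects holding their configuration. Failures
  abort the job naming the failing record/key and, in a chain, the stage
  index; there is no retry, which a cluster framework would own.
* Intermediate pairs spill to line-delimited base64-pickled temp files
  above a configurable threshold and are reloaded at reduce time.
* Database persistence is one JSON file per bin split plus a TSV catalog
  (bin, count, splits) and a meta file carrying a hash of every
  content-determining config field; a search against a database built
  under a different hash is refused rather than silently wrong.

## Synthetic data: what it does and does not emulate

The generator produces random protein sequences (K/R sampled at 3× the
other residues so tryptic peptides land mostly at 6–20 residues), then one
spectrum per selected database peptide: a peak at every singly-charged b/y
position with intensity uniform in 40–100, precursor from the mass model
at charge 1 or 2, and `⌈noise_fraction · n_fragments⌉` noise peaks placed
uniformly in the observed range but kept > fragment_tolerance away from
true fragment positions (an `allow_collisions` flag disables this).
Truth peptides are chosen only among candidates with no same-tolerance
competitor whose entire fragment set falls within the fragment tolerance
of theirs — this excludes I/L twins and K/Q near-twins, for which rank-1
identity is physically undecidable, so that "noise-free recovery = 100%"
is a clean assertion rather than a coin toss.

The default fixture is 20 proteins × 200–400 residues and 50 spectra —
sized so the full suite runs in seconds while still exercising bin splits,
shared peptides, both charges, and every pipeline stage. What passing
these tests shows is that the *machinery* (digestion, binning, routing,
scoring, merging, output) is exact and deterministic; it does not show
that the intensity model resembles real fragmentation chemistry, and no
claim is made about identification rates on real instrument data.

## Degenerate inputs and numerical notes

Empty spectra files produce a valid empty document; spectra whose peaks
are all removed by preprocessing score 0 everywhere; bins absent from the
catalog return empty lists; all floats are serialized with `repr` (exact
round-trip) so rebuilds and reruns are byte-identical. The `expect`
attribute is a defined surrogate — the number of candidates for the scan
scoring at least as high as the match — chosen because the package makes
no distributional assumptions; it is documented as non-comparable to
X!Tandem e-values.

## Known limitations

Local execution only (the executor honors, but does not distribute,
the MapReduce contracts); no decoys/FDR, protein inference, refinement
pass, neutral losses, a/c/x/z ions, or isotope-error handling; mzML
support covers centroided MS2 spectra only.
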