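# pepsearch

A desk-scale shotgun-proteomics search engine built around two ideas:

1. **A reusable m/z-binned peptide database.** A FASTA protein collection is
   digested in silico (trypsin by default, configurable missed cleavages,
   tryptic or semitryptic), expanded over fixed and variable modifications,
   deduplicated with protein provenance, and stored in 1-Da bins on the
   singly-protonated (z = 1-equivalent) m/z axis. Built once, the database
   answers the only query a search needs — *given an m/z bin, return every
   candidate peptide* — across any number of search runs.
2. **K-score-style scoring on a map-shuffle-reduce dataflow.** Each MS/MS
   spectrum is preprocessed (precursor exclusion, √-intensity compression,
   per-window max normalization, fragment binning) and scored against every
   candidate within the precursor tolerance with a normalized dot product
   over its theoretical b/y fragment ions:

   `score(S, p) = Σ_f I*(f)` — the sum over theoretical fragments *f* of
   *p* of the processed intensity `I*` in the matching fragment bin, each
   bin creditable at most once.

The whole pipeline — database build (digest/dedupe → bin/store) and search
(route/score per bin split → combine per scan → consolidate on a single
reducer) — runs as a chain of generic map-shuffle-reduce jobs with two
guarantees: all values of one key reach exactly one reducer call, and keys
arrive at each reducer in sorted order. Serial and multiprocess backends
produce byte-identical output, as do any reducer counts and bin-split
limits, so results are fully reproducible.

This is aimed at method developers and teaching: everything runs on a
laptop against synthetic or real MGF data, with ground-truth fixtures
bundled as code rather than downloads.

## Worked example

```sh
pepsearch make-fixture --out fix --seed 1        # synthetic FASTA + MGF + truth TSV
pepsearch build-db --fasta fix/proteins.fasta --config config.yaml --out db
# -> built 2124 unique modified peptides in 1145 bins at db
pepsearch search --db db --spectra fix/spectra.mgf --config config.yaml --out out.xml
# -> wrote out.xml
```

with a `config.yaml` like

```yaml
enzyme:
  cleave_after: KR
  block_if_next: P
  missed_cleavages: 1
  mode: tryptic
modifications:
  - carbamidomethyl-C   # fixed +57.02146 on C
  - oxidation-M         # variable +15.99491 on M, max 2
precursor_tolerance: 2.0   # Da, on the z=1-equivalent axis
top_k: 10
```

The 20-protein fixture digests to 2124 unique modified peptides spread over
1145 occupied 1-Da bins. The output is an X!Tandem-style XML document, one
`<group>` per scan in natural scan-id order; for the first fixture scan it
reports

```
<group id="scan00001" type="model" candidates="4" z="1" mh="1647.7444838668803">
  ... <domain seq="AWSMPSENRNYHR" score="1069.16" matched="23" ions="24" rank="1" expect="1.0"/> ...
```

i.e. 4 candidate peptides fell within ±2 Da of the measured precursor; the
rank-1 peptide matched 23 of its 24 theoretical b/y ions with a dot-product
score of 1069.2, and only 1 candidate (itself) scored at least that high
(`expect` here is simply the count of candidates with a score ≥ the
match's score — it is **not** an X!Tandem e-value). On the bundled fixture
the rank-1 peptide is the true source peptide for 50/50 scans, with or
without 20% added noise peaks.

The same machinery is available as a library:

```python
from pepsearch import SearchConfig, build_database, run_search, read_results

cfg = SearchConfig()
db = build_database("proteins.fasta", cfg, "db")
run_search("db", "spectra.mgf", cfg, "out.xml")
for scan in read_results("out.xml"):
    print(scan.scan_id, scan.matches[0].peptide.sequence, scan.matches[0].score)
```

## Limitations

No FDR/target-decoy analysis, protein inference, hyperscore/e-value
modeling, a/c/x/z ions, neutral losses, or distributed execution — the
executor is a local stand-in that honors the same key-grouping and
sorted-order contracts a cluster framework provides.
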