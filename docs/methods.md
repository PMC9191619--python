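# Methods

This note records the models, conventions, and numerical choices behind
`glyarray`, and what the synthetic-data tests do and do not demonstrate.

## Scanner files and the ATF dialect

GPR and GAL files are parsed as Axon Text Files: a magic line (`ATF 1.0`),
a count line declaring header-record and column counts, quoted
`"Key=Value"` header records, a quoted column-header row, then
tab-delimited data.  Both CRLF and LF endings are accepted and fields may
be double-quoted, matching output from both scanner families the package
targets.  Channels are inferred from column names of the form
`F<wavelength> Mean/Median` and `B<wavelength> Mean/Median`; permuting
columns does not change the parse.  Non-numeric feature cells (scanner
`Error` cells, blanks) become NaN with a recorded warning instead of
dropping the row — dropping would silently break the positional join with
the geometry.  Rows are never discarded without being counted in warnings
or errors.

GenePix Settings (GPS) files and TIFF images are archival attachments:
copied verbatim, never parsed.  The slide identifier persists through a
write→read roundtrip only via a `SlideID` header record; generic
tab-delimited exports carry no header, so their column mapping is
mandatory (there is no published default for ProScanArray column names)
and the laser wavelength is supplied by the caller (default label 532 nm).

## Geometry and replicate groups

Spot addresses are 1-based `(block, row, column)` triples throughout, for
bit-compatibility with GPR/GAL.  A geometry assigns each address a probe
key plus optional printing conditions (concentration of the arrayed
solution, or dose per spot), parsed from `"50 µM"`-style text into
(value, unit) pairs with the unit kept verbatim.  Blank grid cells carry
the reserved key `EMPTY` and are skipped during quantification by default.

A replicate group is the set of spots sharing
`(probe_key, concentration, dose)` within the replicate scope — the whole
slide by default, or per block (both within-block duplicates and
cross-block replicates occur in practice; the scope is recorded in the
written GAL so it survives roundtrips).  Probe keys are whitespace-trimmed
on read because real GAL files commonly carry trailing spaces; matching is
otherwise case-sensitive and exact.

The scan–geometry join is an inner join on address that reports matched,
scan-only, and geometry-only addresses explicitly; zero matches is a hard
error because it almost always means the wrong GAL was supplied.

## Quantification

Per-spot statistics are the scanner's four pixel summaries: mean, median,
mean − background, median − background.  Negative background-subtracted
values are kept signed by default (`clip_negative=False`) so replicate
averages stay unbiased; clipping is applied only at heatmap/display time.
Spots are excluded, in order, for: negative GenePix flag (−100 bad, −75
absent, −50 not found — any negative value excludes when
`exclude_flagged`), NaN statistic, then the outlier rule.

The averaging literature for these arrays names "mean after eliminating
outliers" without defining the criterion, so two deterministic, scale-free
rules are implemented and recorded in provenance:

* **MAD rule (default)** — exclude `x` with `|x − median| > k·MAD`,
  `k = 3`.  When `MAD = 0` (common with ≤ 4 replicates where two or more
  agree exactly), a fallback band `k·0.01·max(|median|, 1)` still catches a
  single wild value among otherwise identical replicates.
* **drop-min/max** — remove one minimum and one maximum; requires ≥ 4
  values and does nothing at zero dispersion.

Either rule is suppressed — all values kept and the group annotated
`rule-suppressed` — when applying it would leave fewer than
`min_survivors = 2` replicates, or when the group is already at that size.
Reported per group: mean of survivors, sample SD (`ddof=1`, 0 for a single
survivor), and %CV (an explicit `undefined` marker when the mean is 0,
never a division error).  Groups with no usable spot go to a rejects list.
Every input spot is accounted for exactly once: used, excluded with a
reason, or unmatched.

## Glycan sequences, dictionaries, motifs

No formal grammar for CFG-IUPAC condensed notation is published, so one is
fixed here: residues are written nonreducing→reducing; each non-root
residue is followed by an optional anomer (`a/b/α/β/ß/?`, normalized to
ASCII), an optional anomeric position digit, `-`, and the parent position
(digit or `?`); a parenthesized group branches onto the residue written
immediately after it.  Unwritten anomeric positions default to 1 for
aldoses and to unknown for ulosonic acids and ketoses (NeuAc, NeuGc, Neu,
Kdn, Kdo, Fru, ...), whose anomeric carbon is not C1.  Tokenization is
longest-match against the dictionary (so `GlcNAc` wins over `Glc`).

The monosaccharide dictionary ships with exactly 69 entries: the SNFG
symbol table with CFG-style spellings primary (`NeuAc` with synonym
`Neu5Ac`), minus five rare di-deoxynonulosonate/Dha entries, reflecting
the symbol set this kind of array catalogue actually uses.  The motif
dictionary ships exactly 60 curated substructures — blood-group A/B/H,
Lewis a/b/x/y and their sialylated forms, sialyl α2-3/α2-6/α2-8 linkages,
LacNAc types, O-glycan cores, the N-glycan trimannosyl core, and common
disaccharide units — expressed in the same grammar.  The counts are
contractual; the contents are this package's curation.

Motif matching is rooted-pattern embedding: an injective map of pattern
nodes onto tree nodes preserving parent/child relations, symbols, and
every non-wildcard anomer/linkage value (`?` anomers and unwritten
positions in the pattern match anything).  `reducing_end` pins the pattern
root to the tree root; `nonreducing_terminal` requires pattern leaves to
land on tree leaves.  Distinct embeddings are counted; correctness is
checked in the tests against an independent brute-force enumeration of all
injective node mappings (500 random tree/pattern cases, fixed seed).

Tags (Cer32, Cer42, linkers) are stored and compared separately from the
glycan sequence, so probes differing only in tag compare equal on the
glycan and distinct as probes.  Sequences in WURCS/GWS/GlycoCT/2D-TEXT are
stored verbatim; a probe whose only sequence is unparseable is excluded
from structural filters with reason `unparsed`, never via an exception.

## Heatmaps and exports

Heatmap rows (analytes) are normalized to percent of row maximum, the
standard presentation for these arrays: `100·max(raw, 0)/row_max` with
`row_max` the largest positive raw value; the division is performed before
scaling so the peak cell is exactly 100.  Rows with no positive value
become all 0 with a warning.  Normalization is idempotent and invariant to
rescaling an analyte's raw values.  z-score scaling was considered and
rejected as the default because negative-going cells confuse the
percent-of-max reading habits of array users; the `normalization="none"`
escape hatch keeps raw values available.

Exports (CSV, XLSX, JSON, HTML report) all embed the processing
provenance — input identifiers, channel, statistic, averaging method,
outlier-rule parameters, software version — sufficient to re-run
processing identically.  The JSON dialect is described by the shipped
`data/export_schema.json` and checked by a small internal structural
validator.  The MIRAGE checklist ships as versioned JSON
(`data/mirage_checklist.json`) with categories paraphrased from the
published glycan-array guideline headings; completeness validation is pure
and never raises on missing data.

## Synthetic slides: what they emulate, and what they do not

The generator emulates one fluorescence channel of a printed array: per
spot, foreground reads `true_intensity · LN(1, cv) + background` and
background reads `background · LN(1, cv/2)`, where `LN(1, cv)` is a
lognormal factor with mean 1 — multiplicative, positive, right-skewed, as
fluorescence noise is.  Foreground mean and median are independent draws
(real scanners report correlated pixel statistics; independence is the
conservative choice for testing averaging).  Contamination multiplies a
spot's foreground by `outlier_factor` with probability `outlier_prob`;
flagged spots carry GenePix flag −100.  Defaults mirror the conditions the
tests report: 200 probes at 4 replicates, noise CV 0.1, background 50
a.u., true intensities log-uniform in [500, 50000] a.u., 50 µM print
concentration, sequences cycling a 25-entry panel of well-known glycans so
structure filters have known answers.  Output is byte-deterministic given
the seed.

Not simulated: spatial artifacts (gradients, comet tails), inter-slide or
inter-batch variation, dose–response behaviour, probe-dependent background
binding.  Passing the recovery tests therefore shows the estimators are
correct under the stated noise model, not that they are robust to
spatially structured artifacts on real slides.

## Problem sizes and checks

The shipped checks run: 100-fixture write→read roundtrips for each format;
500 random motif cases against the brute-force oracle; one 200-probe ×
4-replicate slide for recovery (median relative error of the plain mean,
about 3 % ≈ cv/√n, bound at 6 %); and 20 contaminated slides (100 probes ×
6 replicates, 10 % spots at 10×) comparing the outlier-eliminated mean
against the plain mean by median absolute error.  These sizes make the
whole suite run in seconds while keeping every rate estimate stable across
seeds.

## Known limitations

* Only CFG-IUPAC condensed is parsed; GlycoCT parsing is a hook, not an
  implementation.  GlyTouCan IDs are opaque fields (no network retrieval).
* Monosaccharide matching in motifs is by exact symbol; the class-wildcard
  (any-hexose) slot is reserved but off.
* Substituent chemistry (sulfation, phosphorylation) is not modelled in
  the grammar; such probes should be filtered by key or tag.
* No inter-slide normalization or dose–response fitting; one dataset is
  one slide/analyte.
* The mandatory column map for tab-delimited scans shifts the burden of
  knowing the export schema to the caller, by design.
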