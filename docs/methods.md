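# Methods

## Scope and model of the workflow

`mitoprofile` models the post-laboratory life of an mtDNA haplotype: a
*profile* is an ordered set of variant calls in rCRS-difference
notation, produced independently by two evaluators per sample,
reconciled by a validator, stored with an append-only audit history,
annotated (haplogroup), linked to phenotypes and exported.  Projects
are typed — population, association or tumour — and the type governs
two rules taken from forensic practice: association/tumour sample IDs
must be numeric, and only association/tumour projects may combine
phenotypes with genotypes on export.  Tumour projects store one
validated profile per tissue (benign, tumour) per sample.

## Variant notation and profile algebra

The token grammar (`73G`, `309.1C`, `249del`/`249-`) is the standard
community convention for reporting differences to the rCRS; the
original report formats this tool descends from are no longer publicly
documented, so the grammar is fixed here and documented in the README.
Choices within it:

* insertion indices are 1-based per anchor position; index 0 is a
  parse error;
* `del` is the canonical deletion spelling, `-` accepted on input;
* all 15 IUPAC codes are legal observed bases so point heteroplasmy
  (e.g. `16093Y`) is representable; they are applied verbatim during
  FASTA reconstruction;
* the canonical profile order is ascending `(position,
  insertion_index)`, with duplicate keys rejected.

`apply_profile` reconstructs a sequence over user-chosen 1-based
inclusive ranges: substitutions replace, deletions omit, insertions
append after their anchor in index order, and variants outside every
range are ignored.  A substitution equal to the reference base is a
*warning*, not an error — it is the signature of a phantom mutation or
an encoding slip and the curator should see it, but blocking the
reconstruction would hide the rest of the profile.  `diff_sequences`
is the substitution-only inverse used as the round-trip oracle; indel
alignment is deliberately out of scope because alignment happens in
the upstream evaluation software.

Ranges may not wrap the circular origin: the control region is covered
by two explicit intervals (`16024-16569` and `1-576`), matching how
the ranges are conventionally printed.

## Report dialects

The two dialects (`.txt` one-token-per-line with optional `SAMPLE` and
`RANGE` lines; `.sqs` tab-separated `position/reference/observed`
table with fractional positions for insertions) are documented
stand-ins that carry every field the workflow needs — variant tokens
plus, for the `.txt` dialect, the sequenced ranges, which only that
evaluator program exports.  The filename stem is split at its *first*
underscore (the documented example has exactly one) into sample ID and
evaluator initials.

## Validation

`compare_profiles` computes the per-key symmetric difference; a key
present in both profiles with a different observed base or kind is
classified separately as a *conflict* so heteroplasmy-interpretation
splits are visibly distinct from missed calls.  Sequenced-range
disagreement is a note, never a discordance: the range is metadata
from one program, not part of the haplotype.  For a concordant pair
the lexicographically first evaluator's file is stored (determinism)
and the other filename recorded as provenance.  A third evaluation,
when escalated, is stored as chosen without requiring it to match
either earlier file — the workflow trusts the senior validator.
Re-validating an already-validated sample requires an explicit force
flag and logs the old profile as the history row's old value.

## Storage and audit

The backend is a single-file sqlite database (stdlib `sqlite3`); the
schema holds projects, samples, one profile row per
(project, sample, tissue), phenotype values in long form with a
per-column sample-specific flag, and the history table.  History rows
have the audit shape `project, employee, timestamp, location,
old_value, new_value`; they are append-only, enforced both by the API
(no update/delete methods) and by SQL triggers.  Timestamps come from
an injectable clock so a replayed workflow is byte-identical.  No-op
updates (setting a haplogroup to its current value, re-importing an
unchanged phenotype) write no history row — the audit table records
real changes only.

Roles are viewer < editor < validator < admin, a concrete rendering of
"dedicated access rights": sample-specific phenotype columns require
validator or above (denied requests are logged and the column is
withheld rather than failing the export), deletions require admin.

## Exporters

All six writers are pure functions of the validated project state, so
equal state gives byte-identical output.  Field separators are TAB for
the spreadsheet-bound formats and single spaces for Network tokens.
Choices where the target formats are under-specified:

* EMPOP frequency: both modes are provided — `1` per sample, or the
  collapsed count of identical haplotypes; frequencies sum to the
  sample count either way.
* Network: a sample name longer than 13 characters is an error, not a
  truncation, because silent truncation could merge samples; for a
  column the sample does not carry, substitution and deletion columns
  show the reference base and insertion columns show `-`; a run of ≥3
  inserted bases at one anchor triggers a warning (the downstream
  program reports duplicated headers for those).
* mtDNAmanager: grouping ranges default to `[16024-16569] [1-437]
  [438-576]` and are configurable so the 1 kb test references can use
  proportionally scaled ranges; out-of-range variants are excluded
  with a warning.
* tab-delimited: EMPOP columns plus `range` (sequenced ranges joined
  by `;`) and `tumour profiles`; for tumour projects each row shows
  the benign-tissue haplotype and the somatic alteration pattern.
* FASTA: records wrap at 70 columns; single positions are ranges of
  length one.

Somatic alterations are key-wise: gained = tumour∖benign, lost =
benign∖tumour, a changed base contributing one loss plus one gain;
patterns render as `+token`/`-token` joined by `;` in canonical order.
Tissue membership is declared at import time (`--tissue`), since the
filename convention carries no tissue field.

## Synthetic data

The fixture generators are first-class, tested code and define the
conditions everything is tested under: 1 kb uniform-random references
(long enough for realistic variant spacing, small enough that the full
suite runs in seconds), 20 samples per batch, 3–8 variants per sample
(80% substitutions, 5% of those heteroplasmic IUPAC codes, 10%
single-base insertions, 10% deletions), and a configurable
discordance rate at which evaluator B's report differs from A's by
*exactly one* injected edit — add, drop, or base-change — so the
expected number of discordant pairs is known analytically.  Tumour
fixtures plant a drawn number of gains and losses so somatic detection
has exact truth.  Every generator is a pure function of its seed.

What the generators do **not** emulate: phylogenetically coherent
haplotypes (variants are independent, not motif-structured), realistic
mutational spectra or hotspots (no 16189/309 enrichment), length
heteroplasmy beyond single-base insertions, and multi-edit evaluator
disagreements.  Passing tests therefore demonstrate the correctness of
the comparison/storage/export machinery, not performance on any real
population sample.

## Problem sizes and determinism

The oracle suites use 500 profiles (round trip), 500 pairs
(comparator), 20-sample validation batches and 100 tumour pairs —
sizes chosen so each check exercises the combinatorics broadly while
the whole suite stays interactive.  Property tests run hypothesis in
derandomised mode; all other randomness flows through
`numpy.random.default_rng` with explicit seeds.

## Known limitations

* No sequence alignment, base calling or chromatogram handling.
* No automatic haplogroup assignment — haplogroups are manual,
  audited annotations; control-region data alone cannot assign most
  haplogroups reliably, so guessing would invite false confidence.
* Indel-aware sequence diffing is out of scope (`diff_sequences` is
  substitution-only by contract).
* The embedded store is single-user; there is no network server or
  password management.
* Tumour samples are modelled as exactly one benign/tumour pair;
  multi-region sampling is not represented.
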