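# mitoprofile

Post-laboratory management of human mitochondrial DNA (mtDNA) haplotype
profiles for population-genetic, forensic and clinical laboratories:
import of evaluator mutation reports, double-evaluation validation,
audited relational storage, phenotype linkage, paired-tissue somatic
mutation detection, and export to six downstream formats.

## The problem

mtDNA haplotypes are reported in *difference notation*: a list of
positions at which a sample deviates from the revised Cambridge
Reference Sequence (rCRS), e.g. `73G 263G 309.1C 16189Y`.  Most errors
in published mtDNA data arise *after* the sequencer — transcription
slips, sample mix-ups, inconsistent alignment of length-variable
regions ("phantom mutations").  The standard countermeasure is double
evaluation: two scientists independently evaluate each sequence, a
senior validator reconciles any disagreement, and every later change to
the stored profile is audit-logged.

`mitoprofile` implements that workflow as a Python library plus a
`mitoprofile` command-line tool:

* **import** — mutation reports from two evaluator programs, recognised
  by extension (`.sqs` / `.txt`); the sample ID and evaluator initials
  come from the filename (`12334_ABC.txt` → sample `12334`, evaluator
  `ABC`).  Tumour and association projects require numeric IDs.
* **validate** — polymorphism-by-polymorphism comparison of the two
  evaluations per sample.  Concordant pairs are stored automatically;
  discordant pairs are listed (one-sided calls and same-position
  conflicts such as `16189C` vs `16189Y` are distinguished) and resolved
  by choosing one file or uploading a third evaluation.
* **store** — single-file sqlite database with an append-only history
  table (`project, employee, date, location, old value, new value`);
  sample-specific phenotype columns sit behind role-based access.
* **link** — phenotype tables joined by a user-named ID column;
  combined phenotype × polymorphism export for association and tumour
  studies; automatic somatic-mutation detection between matched benign
  and tumour profiles (`+gain;-loss` patterns).
* **export** — EMPOP rows (`ID, haplogroup, frequency, tokens`; `?` for
  an unknown haplogroup), 0/1 binary matrix, tab-delimited spreadsheet
  table (adds `range` and `tumour profiles` columns), mtDNAmanager
  grouping into the control-region ranges `[16024-16569] [1-437]
  [438-576]`, Fluxus-Network input (13-character name limit enforced),
  and FASTA over arbitrary position ranges.

## Variant token grammar

```
substitution   <position><IUPAC code>      73G   16093Y
insertion      <position>.<k><base>        309.1C   (k-th base after position)
deletion       <position>del | <position>- 249del
```

Coordinates are 1-based and inclusive.  Ranges never wrap the circular
origin; cover the control region with `16024-16569;1-576`.

## Worked example

```
$ mitoprofile fixtures --seed 3 --out demo --samples 6 --discordance 0
$ mitoprofile init --type population --name Pop1
$ mitoprofile import --project Pop1 demo/reports/*
validated	6
pending	0
$ mitoprofile haplogroup --project Pop1 S000 F1a1c
$ mitoprofile export --project Pop1 --format empop
S000	F1a1c	1	86A	179A	181A	236del	583G	800T	869del
S001	?	1	191C	245C	471T
S002	?	1	5G	657.1A	683C	827C	841.1A
S003	?	1	44del	180G	747T	795G
S004	?	1	85.1C	194A	269.1G
S005	?	1	52C	159T	295G	368A	590A	632A	678C	814C
```

Each EMPOP row is one sample: ID, haplogroup (`?` when not yet
annotated), frequency, then the variant tokens in canonical order.  All
six imports validated automatically because both evaluators agreed on
every sample (`--discordance 0`); with disagreements, `import` prints
the per-position differences and `validate --resolve SAMPLE=A|B|FILE`
stores the senior scientist's choice.  Every storage, annotation and
export lands in the audit table shown by `mitoprofile history`.

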