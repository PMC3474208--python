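# Methods

## The motif model

A *cysteine motif* at flank width k ∈ {1..5} is the window of 2k+1
residues centred on a cysteine. Windows that run past a chain terminus are
padded with `-` to the fixed length rather than truncated or discarded, so
every cysteine contributes exactly one motif at every width (conservation:
number of motif records = number of cysteines, for each k). Padded motifs
are distinct catalog keys from unpadded infixes: `--CAH` records a genuinely
N-terminal context and is never conflated with `CAH` occurring internally.
Queries pad the same way, so lookup keys always align with catalog keys.

A cysteine is **BONDED** iff it appears in at least one disulfide
annotation — PDB `SSBOND` or UniProt `FT DISULFID`. Everything else is
**FREE**, which deliberately lumps reduced cysteines with metal-coordinated
and otherwise modified ones: the archives' disulfide tags are the only
bonding evidence used, and no geometry is computed. A cysteine named by
several annotations counts as bonded once; bonding is binary per site.
Bond *scope* is INTRACHAIN/INTERCHAIN when the partner chain is known.
UniProt features annotated "Interchain" name a partner outside the entry;
such sites are bonded with `partner=None` and scope INTERCHAIN — the scope
is asserted by the record even though the partner is unresolvable, and
discarding it would erase the inter/intra distinction the catalog reports.

The **bond coefficient** of a unique (motif, k) is bonded/total over its
corpus occurrences; reports render it to three decimals with half-even
rounding (5/12 → 0.417). Coefficient 1 ⇔ ALWAYS_BONDED, 0 ⇔
ALWAYS_NONBONDED, else MIXED. The counting unit is one cysteine occurrence
per chain per protein per dataset; homomultimers therefore contribute one
count per chain copy, a choice the record schema (one row per chain
position) makes natural.

## Parsing choices

* Chain sequences come from `SEQRES` / the `SQ` block, never from resolved
  coordinates, so unresolved residues cannot silently drop cysteines.
* `SSBOND`, `HELIX` and `SHEET` use author residue numbering. The mapping
  to sequence ordinals is built from the ordered distinct (resSeq, iCode)
  pairs of the `ATOM`/`HETATM` records of each chain, aligned positionally
  to `SEQRES`; when the two disagree in length, or no `ATOM` records exist,
  the author number is read as the ordinal itself, with a warning. Public
  archives carry no machine-readable statement of the offset, so this
  fallback is the only total choice; files with gaps or exotic numbering
  should carry coordinates for the mapping to be exact.
* Annotations that cannot be resolved — unknown chain, unmappable author
  number, endpoint that is not a cysteine, feature outside the sequence —
  are *quarantined* on the entry with a warning, never silently dropped and
  never fatal. Missing `SEQRES` and an `SQ` length disagreeing with its
  declared residue count are hard errors: without a trustworthy sequence
  nothing downstream is meaningful.
* `MODRES`-mapped residues inherit the parent's one-letter code (CSO → C),
  so modified cysteines keep their sites; unknown residue names become `X`,
  and `X` can appear inside motifs but never as a centre. A handful of
  common modified residues (MSE, CSO, …) are mapped even without `MODRES`.
* All-nucleotide `SEQRES` chains raise the DNA/RNA-link flag and are not
  treated as protein chains.
* UniProt flat files are read through `Bio.SwissProt`; Biopython does not
  enforce the declared length, so that check is applied on top.
* Secondary structure is record-based (H/E/T per residue, coil `C`
  otherwise, `-` at padding); overlapping segments resolve by precedence
  H > E > T. No DSSP-style assignment from coordinates is attempted.

## Catalog semantics

* **Redundancy removal** groups entries by exact concatenated
  chain-sequence content (chains joined in chain-id order) and keeps the
  lexicographically smallest protein id — deterministic, and insensitive to
  file order.
* **merge_update** inserts only genuinely new protein ids, updating counts
  incrementally; re-merging the same files is a no-op, and one log line is
  emitted per inserted/skipped/failed entry. Merging is equivalent to
  rebuilding on the union, with one documented exception: on a nonredundant
  catalog an already-kept representative is never retracted when a later
  duplicate with a smaller id arrives (the incremental form cannot know a
  better representative was coming).
* **Propensity** is reported as the per-offset relative amino-acid
  frequency at offsets −k..−1, +1..+k, for the full population and for the
  bonded subpopulation, with padded positions excluded from denominators;
  non-empty columns sum to 1 and empty columns are all-zero, not NaN. The
  quantity users usually call "propensity" is not uniquely defined; this
  positional-frequency reading is the package's interpretation and is
  flagged as such here. Log-odds variants can be derived from the two
  tables.
* Persistence is TSV (records, stats, proteins) plus a JSON header —
  bit-exact across save/load cycles; stats stored are a fixed point of
  recomputation from records.

## The synthetic-corpus generator

`cysmotif.fixtures` emulates exactly the record vocabulary the pipeline
consumes: multi-chain entries with author-numbering offsets (drawn 1 with
probability 0.4, else uniform 2..500), intra- and inter-chain `SSBOND`s,
`FT DISULFID` features (including partner-unresolved "Interchain" ones),
record-based secondary-structure segments, engineered/mutated flags,
nucleotide chains, and `MODRES`-mapped residues. Default conditions:
20 proteins, chain lengths 60–140, 0–4 cysteines per chain, bonding
probability 0.5, interchain fraction 0.1, flag fractions 0.1/0.1/0.05 —
sizes at which every code path (two-chain entries, interchain bonds,
each flag) is exercised while a corpus builds in well under a second.

Filler residues are drawn uniformly from the 19 non-cysteine amino acids,
so every cysteine is placed deliberately and planted occurrence counts can
be exact. Planted windows are separated by at least 11 filler residues,
and a chain is re-drawn (deterministically, continuing the seeded stream)
if filler happens to complete an unintended occurrence of a planted motif
string. Planting a motif that contains additional cysteines (e.g.
`APWCGHC`) necessarily creates motif occurrences centred on the inner
cysteines with filler-determined flanks — the same coupling real sequences
exhibit, where the PDI context `APWCGHCKAL` yields both `APWCGHC` and
`CGHCKAL`.

What the generator does **not** emulate: realistic coordinates (placeholder
zeros; only numbering matters), residue composition bias, homologous
near-duplicates (only exact duplicates arise, and only if planted),
numbering gaps and insertion codes (parsers handle insertion codes; the
generator does not emit them), multi-model files, and disulfide annotations
that conflict with the sequence. Green fixtures therefore demonstrate
correctness of the record-processing logic, not robustness to every
pathology of real depositions.

## Worked-example conditions

The PDI example uses a corpus planted with `APWCGHC` 12 total / 5 bonded,
`CGHCKAL` 1/1 and `CGHCKQL` 2/0 over 15 proteins, and a 480-residue
synthetic query sequence carrying `APWCGHCKAL` at positions 49–58 and
`APWCGHCKQL` at 393–402, so the active-site cysteines fall at 52/55 and
396/399. The query sequence is a labelled synthetic stand-in, not the real
P07237 sequence. The reported coefficients (0.417, 1, 0) follow from the
planted counts by construction; `scripts/acceptance.py` recomputes them by
running the full generate → write → parse → build → query chain.

## Numerical and degenerate-input choices

* Coefficient rendering: `Decimal` quantisation, three decimals, half-even.
* `coefficient(0, ·)` is rejected; absent motifs in query reports carry
  zeros (total 0, bonded 0, coefficient 0, no class) rather than omitted
  rows.
* Duplicate protein ids in one build: last wins, with a warning.
* Empty corpus → empty catalog; empty population at a propensity offset →
  zero column.
* Validation sits at type boundaries (dataclass `__post_init__`), so
  malformed motifs, inverted segments and out-of-range counts fail at
  construction, not at use.

## Limitations

Bonding states inherit every limitation of the archive annotations:
unannotated disulfides read as FREE, and redox heterogeneity collapses to
whichever state was deposited. The author-numbering fallback can misplace
annotations in coordinate-free files whose numbering does not start at 1.
Inter-/intra-domain classification is not attempted (no domain definition
is available at the record level), and corpus-scale statistics depend
entirely on the corpus supplied — the package computes, it does not ship
data.
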