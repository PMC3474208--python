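# cysmotif

Catalogs of cysteine flanking-sequence motifs and their disulphide
bonding states, built from PDB and UniProt records.

Disulphide bonds — covalent S–S bridges between two oxidised cysteines —
stabilise protein folds, and whether a given cysteine is bonded is strongly
influenced by its immediate sequence neighbourhood. `cysmotif` is for
researchers studying or predicting cysteine bonding states from sequence:
it extracts, for every cysteine in a corpus, the *motif* consisting of the
cysteine plus its k flanking residues on each side (k = 1..5, so 2k+1
residues with the cysteine at the centre), attaches the bonding state
declared by the archive records (PDB `SSBOND`, UniProt `FT DISULFID`),
the inter-/intra-chain scope of each bond, and record-based secondary
structure (`HELIX`/`SHEET`, `FT HELIX/STRAND/TURN`), and aggregates the
result into a queryable catalog.

The central statistic is the **bond coefficient** of a unique motif m at
width k:

```
coefficient(m, k) = bonded occurrences of m / total occurrences of m
```

Motifs partition into *always bonded* (coefficient 1), *always nonbonded*
(coefficient 0) and *mixed* classes. Catalogs come in two variants: the
complete corpus, and a nonredundant one in which proteins with 100%
identical sequence content are collapsed to a single representative.
Queries — by protein id, by motif string, or by FASTA sequence — can filter
on provenance (engineered, mutated, or DNA/RNA-linked proteins).

Everything runs on local files; a seeded synthetic-corpus generator
(`cysmotif.fixtures`) produces PDB/UniProt text with exact ground truth,
so the whole pipeline is testable without downloads.

## Worked example

The classic illustration is protein disulphide isomerase (PDI), whose two
thioredoxin active-site motifs `WCGHC` share the same N-terminal context
but different C-terminal contexts. Querying a catalog with a PDI-like
sequence reports, per cysteine, its motif and the catalog statistics:

```sh
cysmotif fixtures corpus --seed 11 --n-proteins 15 \
    --plant APWCGHC:12:5 --plant CGHCKAL:1:1 --plant CGHCKQL:2:0
cysmotif build corpus --out catalog
cysmotif query fasta pdi.fa --catalog catalog --k 3
```

```
# PDI_SYN
Position  Motif    Total  Bond  Coefficient
52        APWCGHC  12     5     0.417
55        CGHCKAL  1      1     1.000
150       WRFCEKE  0      0     0.000
300       AGGCNNP  0      0     0.000
396       APWCGHC  12     5     0.417
399       CGHCKQL  2      0     0.000
```

Reading: the motif `APWCGHC` occurs 12 times in the catalog, 5 of them
bonded — a mixed motif with coefficient 5/12 = 0.417, so the first
active-site cysteine at 52/396 is ambiguous from context alone. The second
cysteine of the first site (position 55, context `CGHCKAL`) is *always
bonded* in the catalog, while the same position in the second site
(position 399, context `CGHCKQL`) is *always nonbonded*: the two
thioredoxin sites are predicted to sit in different redox states. Rows
with zeros are cysteines whose motifs are absent from the catalog.

The same is available from Python:

```python
from cysmotif import build_catalog, query_by_fasta, read_pdb_entry

entries = [read_pdb_entry(open(p).read()) for p in pdb_paths]
catalog = build_catalog(entries, k_set=(1, 2, 3, 4, 5))
rows = query_by_fasta(catalog, [("PDI", sequence)], k=3)["PDI"]
```

## Scope

Record-based annotation only: bonding states come from `SSBOND` /
`FT DISULFID` tags, never from coordinate geometry; secondary structure
comes from header records, not DSSP. Legacy PDB text is supported
(no mmCIF), and there is no network access — corpora are local files.
See `docs/methods.md` for the model, parameter and design details.
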