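# labtrace

A headless laboratory information system for small-to-medium molecular
genetics labs running Sanger sequencing and microsatellite genotyping
projects. It stores individuals, samples, physical storage locations, the
full lab workflow (DNA extraction, PCR, validation, electrophoresis, raw
files) and final sequence / genotype results in a single-file relational
database, and converts final data into standard analysis formats.

Highlights:

- **23-relation schema** with a controlled-vocabulary `codes` table
  (14 fixed classes, open values) referenced by all categorical foreign
  keys, and a declarative business-rule checker that guards every write.
- **Five-level storage tree** (adjacency list) with leaf placements,
  check-out/movement history, and path/subtree queries.
- **Full traceability**: `trace_sample` walks from any sample to its
  organism, storage path, extractions, raw blobs and final results.
- **Batch loader**: atomic migration of historical data from CSV sheets
  driven by a name/value config file, with case-insensitive foreign-key
  resolution, similar-key warnings (edit distance ≤ 1) and full rollback;
  dry-run mode supported.
- **Exports**: sequences to FASTA, NEXUS, PHYLIP, MEGA, MSF, PSI-BLAST and
  Pfam/Stockholm (with cross-project merging); microsatellites to
  one-column diploid, two-column diploid and one-column haploid matrices
  as CSV or XLSX.
- **13 predefined report types** rendered as text or CSV from external
  templates.
- **Dual-role access control** (4 system roles × 5 database roles), with
  both role matrices stored as editable data files.
- **Deterministic demo-data generator** so everything is testable offline.

## CLI

One executable, `labtrace`, with five command groups: `workflow`,
`manage`, `report`, `export`, `admin`.

```sh
labtrace --db lab.db manage init                  # create the schema
labtrace --db lab.db manage demo --seed 1         # populate demo data
labtrace --db lab.db manage sample-trace 1        # trace one sample
labtrace --db lab.db report run lab_summary
labtrace --db lab.db export seqs --marker DLOOP --projects DEMO-P1 \
         --format nexus --pad --out seqs.nex
labtrace --db lab.db export msats --projects DEMO-P2 \
         --layout two_column_diploid --out msats.csv
labtrace --db lab.db manage load --config load.conf --dry-run
labtrace --db lab.db manage load-templates samples_and_final templates/
```

Batch-loader configs are plain `name = value` files, e.g.

```
mode = samples_and_final
project = LEGACY-2019
purpose = genotyping
samples = samples.csv
microsats = microsats.csv
markers = BM1824,ETH10
ploidy = diploid
```

## Library

```python
from labtrace import init_schema, add_code
from labtrace.registry import create_project, register_individual, register_sample
from labtrace import workflow, exporters, reports

db = init_schema("lab.db")
add_code(db, "SPECIES", "BOS", "Bos taurus")
...
```

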