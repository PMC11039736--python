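# fpdenovo

De novo transcription-factor motif discovery from per-base chromatin
footprint score tracks.

Genomic footprinting turns ATAC-seq accessibility into per-base binding
scores in which short, flat-topped peaks mark protein-bound DNA
("footprints"). `fpdenovo` takes such a score track (bedGraph, or BigWig when
`pyBigWig` is installed) plus the genome FASTA and:

1. **calls footprints** with a custom peak caller (local height limit,
   width range, flat-top test, gap merging, size filter);
2. optionally **masks footprints explained by known motifs** from a JASPAR /
   MEME-minimal database, removing only the motif location so flanks are kept;
3. **iteratively generates de novo motifs** from the remaining footprint
   sequences with a built-in ZOOPS-EM finder (k-mer z-score seeding, dynamic
   knee-point e-value filter, site subtraction with flank retention,
   stagnation-based termination, final similarity clustering/merging at
   distance 0.4);
4. **characterizes the motifs**: genome-wide scanning with exact PWM score
   thresholds, open-chromatin enrichment, nearest-feature annotation,
   hypergeometric gene-set enrichment, database comparison
   (rediscovered vs novel), TF-class assignment via binding-site overlap, and
   motif-centered aggregate footprint profiles.

A **differential mode** subtracts a second condition's track (clipped at
zero) before footprint calling, isolating binding events unique to the first
condition. A **synthetic module** generates genomes with implanted motif
instances and footprint-shaped tracks so the whole pipeline is testable
without any external data.

## CLI

```sh
# make a synthetic dataset (genome, track, truth sites + motifs)
fpdenovo simulate --length 50000 --n-sites 200 --seed 1 --out sim/

# call footprints only
fpdenovo footprints --track sim/track.bedgraph --genome sim/genome.fa --out fps.bed

# end-to-end discovery (optionally with a motif database for masking)
fpdenovo run --track sim/track.bedgraph --genome sim/genome.fa \
    --w-min 9 --w-max 11 --seed 1 --out run/

# two-condition differential discovery
fpdenovo diff --track-a a.bedgraph --track-b b.bedgraph --genome genome.fa --out diff/

# downstream reports for existing motifs
fpdenovo characterize --motifs run/consensus.jaspar --genome sim/genome.fa \
    --motif-db db.jaspar --peaks peaks.bed --out reports/
```

Options can be pre-filled from a flat TOML config (`--config run.toml`);
explicit flags win. Exit codes: 0 success, 2 validation error, 3 empty
result (e.g. no footprints on identical differential tracks).

A run directory contains `footprints.bed`, per-iteration motifs
(`motifs/iteration_*.meme`), `consensus.jaspar` / `consensus.meme`,
`consensus_report.tsv`, `iterations.tsv` (pool-size trajectory) and a
`manifest.json` recording parameters, seeds and input checksums. Runs are
byte-reproducible for a fixed seed.

## Python API

```python
from fpdenovo.io_formats import read_fasta, read_score_track
from fpdenovo.footprints import FootprintParams, call_footprints
from fpdenovo.discovery import DiscoveryParams, iterative_discovery

genome = read_fasta("genome.fa")
track = read_score_track("track.bedgraph", "bedgraph",
                         {c: len(s) for c, s in genome.items()})
fps = call_footprints(track, FootprintParams())
result = iterative_discovery(fps, genome, DiscoveryParams(rng_seed=1))
for motif in result.consensus:
    print(motif.name, motif.consensus, motif.nsites, motif.evalue)
```

Modules: `io_formats` (BED/bedGraph/FASTA/JASPAR/MEME/GTF/GMT I/O and the
`GenomicInterval` / `ScoreTrack` types, 0-based half-open coordinates
throughout), `footprints`, `masking`, `motif_model`, `discovery`,
`downstream`, `synthetic`, `pipeline` + `cli`.

## Tests and acceptance

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(footprint-caller oracle equivalence, differential correctness, masking
soundness, 40/30/20/10% mixture recovery with iterative-vs-single comparison,
recovery monotonicity, differential discovery, exact statistics, merge
conservation, knee filter, aggregate profile, end-to-end determinism).
`scripts/acceptance.py` re-runs the end-to-end properties from scratch and
writes the (empty — no numeric targets are defined) acceptance report; it
exits non-zero if any property fails.
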