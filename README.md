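# imconform

Curation of multiconformer peptide ion-mobility identifications and
collisional cross-section (CCS) prediction with a two-output,
assignment-aware regressor, plus extracted-ion-mobilogram (XIM) analysis.

Peptide ions can adopt more than one gas-phase conformation, each with its
own CCS. `imconform` implements the full desk-scale workflow for working
with such data:

* **evidence_io** — read MaxQuant-`evidence.txt`-style TSV tables, apply
  the MS/MS + MS1-feature identification filter, and read/write the
  curated dataset format.
* **run_alignment** — align CCS values across runs with one additive,
  charge-specific offset per run (`y = x + b`), merging runs greedily in
  descending identification count with a 100-pair overlap gate.
* **conformer_curation** — split repeated identifications within a run
  into conformers at a 2% relative CCS tolerance, match conformers across
  runs at the same tolerance, require recurrence in ≥2 runs, drop charges
  above 4+, and emit multiconformer / uniconformer datasets plus a
  physicochemical characterization (length, charge, proline content,
  inter-conformer CCS gaps).
* **ccs_model** — encode peptidoforms as positional atomic compositions
  (C/H/N/O/S/P per residue plus modification deltas), train one- and
  two-output CCS regressors (numpy implementation, CPU-friendly), with a
  conformer loss that ties each output branch to a distinct target, the
  summed-absolute-error baseline loss, transfer learning from a
  single-output trunk, and paired / closest-prediction evaluation.
* **xim_analysis** — Mason–Schamp conversion between 1/K₀ and CCS, peak
  picking on mobilograms, multimodal-fraction and replicate
  intensity-order-reversal statistics, nearest-prediction annotation.
* **synthetic_data** — fully seeded generators for multi-run evidence
  tables (planted offsets, conformers, noise, dropout) and
  Gaussian-mixture mobilograms, with complete ground truth. The planted
  CCS surface is a documented closed form chosen for testability, not a
  physical claim.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which re-derives the
workflow's headline properties on synthetic data (loss contract, offset
recovery, curation-vs-exhaustive-search equivalence, the ≤2% median
relative error claim at desk scale, baseline ordering, transfer-learning
benefit, peak picking, Mason–Schamp round trip). The full suite takes a
few minutes on one CPU.

## CLI

All stages are wired through one entry point:

```bash
imconform simulate cohort --seed 123 --out runs/evidence.tsv
imconform curate --evidence runs/evidence.tsv \
    --out-multi multi.tsv --out-uni uni.tsv --report stats.json
imconform train    --data uni.tsv   --config train.yaml --out single.npz
imconform finetune --pretrained single.npz --data multi.tsv --out multi.npz
imconform predict  --model multi.npz --peptides peptides.tsv --out preds.tsv
imconform evaluate --model multi.npz --data multi.tsv --mode paired --out metrics.json
imconform simulate mobilograms --seed 9 --out mobs.tsv
imconform xim --mobilograms mobs_A.tsv --replicate-b mobs_B.tsv \
    --threshold 0.25 --report xim_stats.json
```

Training/architecture options live in a YAML config (see
`tests/test_cli.py` for worked examples); every command writes a JSON
manifest (command, config hash, seed, paths, version) next to its outputs.

## Conventions

* CCS in Å², mobility as inverse reduced mobility 1/K₀ in V·s/cm².
* The 2% conformer tolerance uses `|a − b| / min(a, b)` (configurable).
* Two-output predictions are emitted sorted: `ccs_small ≤ ccs_large`.
* All randomness flows from explicit seeds; identical seeds give
  byte-identical outputs.
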