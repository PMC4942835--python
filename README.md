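# sbsfold

A strings-and-binders (SBS) polymer toolkit for chromatin folding: a
bead–spring chain whose loops are mediated by diffusing binder particles,
simulated by Langevin dynamics across the coil / Θ / globule
(ordered–disordered) phase diagram, plus the inference layer that connects
the model to contact-map data:

- **model / dynamics** — FENE + WCA bead chain, color-specific bead–binder
  LJ attraction, BAOAB Langevin integration in a periodic box, reduced units
  (kT = σ = m = 1), explicit unit mapping to nm / nmol/l / bp.
- **observables** — gyration radius, contact maps, contact probability
  P_c(s) with power-law exponent fits, R²(s), binder structure factor S(k),
  many-body and triplet contact statistics, thermodynamic-state
  classification.
- **mixture** — fit an observed contact-decay curve as a convex combination
  of pure-state curves (coil / theta / disordered / ordered globule) with a
  genomic scale factor.
- **inference** — simulated-annealing recovery of per-bead binding-site
  colors and multiplicities from a target contact matrix, validated by full
  dynamics.
- **variants** — in-silico deletions with no refitting, coordinate lifting,
  and observed/expected ectopic-interaction maps.
- **synthetic** — pivot-Monte-Carlo SAW and Gaussian-chain reference
  ensembles, ground-truth block-copolymer fixtures, brute-force oracles.

## CLI

```bash
sbsfold simulate --config config.yml --seed 7 --out run
sbsfold observe --matrix run.matrix.tsv
sbsfold fit-mixture --curve ps.tsv --library library.h5
sbsfold infer --matrix target.tsv --colors 2 --out profile.bed
sbsfold mutate --profile profile.bed --delete 60:72 --out mutant.bed
sbsfold compare --wt wt.tsv --mut mut.tsv --out ectopic.tsv
sbsfold make-fixtures --out fixtures/
```

`simulate` reads a flat YAML config (chain/blocks, `e_int`, binder counts or
concentration in nmol/l, box edge, steps, seed). Every command writes a
provenance record (config hash, seed, version) and is reproducible given the
same seed.

## Notes on protocols

Collapse from an open conformation arrests in necklace-like states on
desk-scale runs; equilibrium ensembles of collapsed phases are therefore
initialized inside the phase (`assemble_system(init="globule")`) and
relaxed, which is verified to be the thermodynamic attractor. Folding
dynamics (R_g(t) from a SAW start) remain available via `init="saw"`.
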