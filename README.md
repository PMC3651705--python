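# tubopt

Side-effect-constrained optimization of tubulin-isotype drug binding
profiles for chemotherapy design.

Human β-tubulin comes in 8 isotypes (βI, βIIa, βIIb, βIII, βIVa, βIVb,
βV, βVI — genes TUBB, TUBB2A, TUBB2B, TUBB3, TUBB4A, TUBB4B, TUBB6,
TUBB1), and every cell type expresses its own distribution over them.
`tubopt` treats both a cell's expression distribution `q` and a drug's
binding preference `r` as probability 8-tuples and asks: *which drug
profile damages a given cancer the most while keeping the damage to each
healthy tissue below a per-tissue cap?*

- **damage model** — dot product `D(r, q) = rᵀq` (with a negative-KL
  alternative `D_KL(r, q) = −Σ rᵢ ln(rᵢ/qᵢ)`);
- **tissue caps** — baseline per-(tissue, route) limits modulated by a
  multiplicative pipeline: treatment aggressiveness (conservative ×0.75,
  aggressive ×1.5), local-delivery relaxation for non-target organs
  (×1.2) with heavy protection of the target organ, gender masking of
  sex-specific organs, and optional per-tissue extra protection;
- **optimization** — a linear program over the probability simplex
  (`scipy` HiGHS) for the dot objective; a convex program (SLSQP) for
  the KL objective; a closed-form vertex solution for the unconstrained
  penalized ("net benefit") variant; plus a brute-force simplex-grid
  oracle used to verify the solvers;
- **drug scoring** — per-isotype binding free energies are converted to
  affinity profiles with a Boltzmann softmax `rᵢ ∝ exp(−ΔGᵢ/RT)`,
  expected binding energy `Σ qᵢ ΔGᵢ` ranks drugs against a cell line,
  and drug cocktails combine as convex mixtures of profiles.

A published pair of per-isotype binding-energy rows for peloruside A
(PELA) and laulimalide (LAU) ships as the only real-data fixture
(`tubopt.pela_lau_energies()`); all other bundled data (the demo tissue
panel, the default weight config) is clearly-labeled illustrative
scaffolding.

## CLI

The `tubopt` entry point has five subcommands. Generate a toy data set
and optimize a profile:

```sh
tubopt simulate --seed 1 --out-dir demo/
tubopt optimize \
    --cancer-table demo/cancer.tsv --healthy-table demo/healthy.tsv \
    --weights demo/weights.yaml --cancer cancer_1 --route iv \
    --gender male --aggressiveness conservative --out result.json
```

Exit codes: `0` optimal, `2` input error, `3` infeasible constraint
system. Other subcommands:

- `tubopt evaluate --drug-energies table.tsv --temperature 310 --unit kJ/mol ...`
  — screen drugs (from an energy table or profile table) against the
  caps and rank the feasible ones by cancer damage;
- `tubopt combine --profiles drugs.tsv --coefficients 0.5,0.25,0.25 --out combo.tsv`
  — cumulative profile of a drug cocktail;
- `tubopt validate-config --weights my_weights.yaml` — schema-check a
  weight config.

Expression tables are TSV/CSV with an `isotype` first column (any
recognized spelling: `betaIII`, `βIII`, `TUBB3`) and one column per
sample; values are arbitrary non-negative units and are renormalized.
Weight configs are YAML/JSON mapping tissues to per-route baseline caps
(see `src/tubopt/data/default_weights.yaml`).

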