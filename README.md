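# bowtienet

Bow-tie structure and collective dynamics of directed networks.

The package generates directed Erdős–Rényi networks with a controlled
mean in-degree, decomposes arbitrary directed networks into their
bow-tie components (CORE, IN, OUT, tendrils, tubes, disconnected
parts, plus SOURCE/SINK sets), predicts the component sizes with
generating-function theory, and runs Kuramoto phase dynamics and
heat-bath Ising dynamics on the resulting networks — including
experiments that remove fractions of the IN component and measure the
CORE's ordering response.

## Modules

| module | contents |
| --- | --- |
| `bowtienet.network` | `DirectedNetwork`, ER sampler, edge-list I/O |
| `bowtienet.bowtie` | bow-tie decomposition, link census, external/internal in-degree ratio |
| `bowtienet.theory` | branching probabilities, SOURCE/CORE fractions, IN–CORE link count |
| `bowtienet.kuramoto` | RK4 phase integration, order parameters r_X, pair correlation C |
| `bowtienet.ising` | heat-bath sweeps, magnetization m_X, pair correlation chi, T_C estimation |
| `bowtienet.removal` | IN-node removal sweeps and critical-fraction detection |
| `bowtienet.pipeline` | study configs, structure-table rows, onset scans |
| `bowtienet.cli` | `bowtienet` command-line interface |

## CLI

```sh
bowtienet generate --n 100000 --mean-in-degree 1.5 --seed 0 --out er.txt
bowtienet decompose --edge-list er.txt --report census.tsv
bowtienet theory --mean-in-degree-grid 1.05:2.0:0.05 --out theory.tsv
bowtienet kuramoto --n 2000 --mean-in-degree 1.7 --coupling 10 --out r.tsv
bowtienet ising --n 10000 --mean-in-degree 2.0 --temperature 0 --out m.tsv
bowtienet removal-sweep --dynamics ising --n 5000 --mean-in-degree 1.4 --out sweep.tsv
bowtienet onset-scan --dynamics kuramoto --config study.yaml --out onset.tsv
bowtienet table1 --config study.yaml --out row.tsv
```

All tabular outputs are TSV with `#` header lines carrying the run
manifest (parameters, seeds, package version, manifest hash).

## Conventions

- Node ids are 0-based everywhere; edge lists are plain-text
  `tail head` pairs (use `--one-based` on import when needed).
- Randomness flows through `numpy.random.default_rng` (PCG64); the ER
  sampler draws the undirected skeleton first, then one fair-coin
  direction per link in sorted-pair order, so a `(n, c, seed)` triple
  pins down the network exactly.
- In the dynamics, node `n` is driven by its in-neighbors `m` via the
  adjacency convention `A[m, n] = 1` for a link `m -> n`.
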