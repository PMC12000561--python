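# allodyn

Desk-scale analysis of allosteric communication in protein–DNA–cofactor
complexes, modelled on the workflow used to study DNA glycosylases that
carry a [4Fe-4S] cluster: how does a metal site tens of angstroms from
the catalytic pocket influence base excision? The package takes
coordinate trajectories (multi-model PDB plus a structured-text
topology sidecar carrying charges and Lennard-Jones parameters) and
functional-assay tables (CSV), and provides:

* **Energy decomposition (EDA)** — per-fragment non-bonded interaction
  energy between a chosen fragment (a residue, the cofactor, the
  damaged nucleotide…) and the rest of the system, frame-averaged and
  broken down by partner residue, with mutant − wild-type ΔE tables.
  Coulomb with k_e = 332.0636 kcal·Å·mol⁻¹·e⁻², Lennard-Jones with
  Lorentz–Berthelot combining, AMBER-style 1-2/1-3 exclusions and 1-4
  scaling.
* **Dynamic network analysis** — one node per amino acid (Cα), two per
  nucleotide (backbone P and base nitrogen), one per cofactor group;
  edges between node pairs whose heavy-atom group distance stays
  ≤ 4.5 Å in strictly more than 75 % of frames, weighted by
  w = −ln|C| from the motion correlation; edge betweenness and the
  optimal (minimum-weight) path between, e.g., the abasic-site node and
  the cofactor node.
* **Mode contributions** — PCA of node-coordinate fluctuations
  (essential dynamics); a mode's contribution to the overall motion is
  its eigenvalue over the covariance trace.
* **Assay fitting** — glycosylase kinetics under single turnover,
  P(t) = A₀(1 − e^(−k₂t)), and multiple turnover (burst plus linear),
  P(t) = A₀(1 − e^(−k₂t)) + A₀k₃t with active fraction A₀/[E]; one-site
  binding, Y = B_max·X/(K_D + X), with saturation-aware K_D upper
  limits; fluctuation-assay mutation frequency
  f = median(resistant)/mean(viable) and fold changes.
* **Synthetic data with ground truth** — toy complexes, Gaussian
  trajectories with a prescribed node covariance (including planted
  high-correlation chains and exactly scheduled contact persistence),
  and simulated assay datasets, so every analysis can be validated by
  parameter recovery.

## Worked example

Generate a 10-residue / 4-nucleotide / cofactor toy complex with a
planted allosteric chain from the cofactor to an abasic site (pairwise
|C| = 0.9 over a 0.2 background, persistent contacts along the chain
plus a decoy route), analyze 500 frames and fit simulated assays:

```python
from allodyn.pipeline import PipelineConfig, run_pipeline

CHAIN = ["C:1:SF4", "A:5:THR", "A:7:ALA", "A:9:SER", "B:2:DT:base"]
CONTACTS = [[CHAIN[i], CHAIN[i + 1]] for i in range(4)]
DECOY = [["C:1:SF4", "A:2:GLY"], ["A:2:GLY", "B:2:DT:base"]]

cfg = PipelineConfig(values={
    "seed": 17, "outdir": "demo", "n_frames": 500,
    "close_pairs": CONTACTS + DECOY, "abasic_nucleotides": [2],
    "planted_path": CHAIN,
    "contact_schedule": [[a, b, 1.0] for a, b in CONTACTS + DECOY],
})
print(run_pipeline(cfg).report_text)
```

prints

```
# allodyn pipeline report

[simulate] atoms=91 close_pairs=6
[trajectory] frames=500 nodes=19
[correlations] written correlations.csv
[nma] leading mode fractions: 11.8%, 9.6%, 9.4%
[eda] fragment kind cofactor: total 2708.1521 +/- 4.5751 kcal/mol (coulomb 0.9982, vdw 2707.1539)
[network] 6 edges among 19 nodes
[paths] C:1:SF4 -> B:2:DT:base: C:1:SF4 - A:5:THR - A:7:ALA - A:9:SER - B:2:DT:base (total weight 0.4505)
[assays] STO k2=1.1820 /min (true 1.2000)
[assays] MTO a0=4.1450 nM k2=1.1383 k3=0.0454 active_fraction=0.829
[assays] binding KD=2.107 Bmax=99.61%
[assays] mutation frequency f=5.527e-08 (true 5e-08)
```

Reading the output: the optimal path recovers the planted chain exactly
— its total weight 0.4505 ≈ 4 × (−ln 0.9) is far below the decoy
two-hop route at background correlation (≈ 2 × 1.6); the kinetic,
binding and mutation-frequency fits recover the generator's true
parameters (k₂ = 1.2 min⁻¹, A₀ = 4 nM, k₃ = 0.05 min⁻¹, K_D = 2 nM,
f = 5×10⁻⁸) to within the 5 % simulated noise. Absolute toy energies
are arbitrary (the generated geometry is not energy-minimized; see
`docs/methods.md`) — only oracle agreement and differences between
systems carry meaning. The same stages are available from the shell via
the `allodyn` console script (`allodyn run --config cfg.yaml`,
`allodyn simulate-complex`, `allodyn eda`, `allodyn fit-binding`, …).

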