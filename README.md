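# depsikin

Quantitative NMR and kinetic-model analysis for cyclic octadepsipeptide
conformer dynamics and cation binding.

Cyclic octadepsipeptides of the PF1022A/emodepside family populate two
slowly interconverting macrocycle conformers — a C2-symmetric all-*trans*
form and an asymmetric one-*cis* form — and act as ionophores whose
symmetric conformer binds monovalent cations as 1:1 and 2:1 (sandwich)
complexes.  `depsikin` implements the four computations that connect those
observations, for NMR spectroscopists and simulators working on such
macrocycles:

1. **EXSY exchange kinetics** (`depsikin.exsy`) — site-to-site exchange
   rates from a single-mixing-time ROESY/EXSY volume matrix via the matrix
   logarithm of the normalized transfer matrix,
   `L = ln(M·M0⁻¹)/t_m`, with symmetry-pathway averaging, the
   C2 degeneracy correction `k₁' = 2k₁`, and Monte-Carlo error propagation
   for the assumed ~20% volume errors.
2. **Binding equilibria** (`depsikin.binding`) — speciation, simulation and
   multistart fitting of salt titrations under the coupled scheme
   `A ⇌ S` (K_c), `S + M ⇌ SM` (K₁), `SM + S ⇌ S₂M` (K₂), with the
   fast-exchange shift and the asymmetric:symmetric integration ratio as
   observables, explicit reporting of degenerate fits, and the lag metric
   separating two-coupled-equilibria behaviour from genuine 2:1 evidence.
3. **Markov state models** (`depsikin.msm`) — circular dihedral embedding,
   TICA, common-nearest-neighbor density clustering with noise removal,
   reversible maximum-likelihood MSM estimation, implied timescales,
   Chapman–Kolmogorov validation, and a C2-symmetry population diagnostic
   for sampling convergence.
4. **T2 relaxation** (`depsikin.relaxation`) — mono-exponential CPMG decay
   fits with calibrated asymptotic 95% confidence intervals.

Seeded generators (`depsikin.synthetic`) emulate each stage's data from its
forward model, so the whole pipeline is testable without spectra or MD
trajectories.  See `docs/methods.md` for models, assumptions, defaults and
limitations.

## Worked example

The package ships the PF1022A worked example — the EXSY cross-/diagonal
peak volumes of the three exchanging Hα sites in CDCl₃ (mixing time
0.1 s) and their magnetic fractions:

```python
from depsikin import exsy, io

volumes, network = io.packaged_worked_example()
result = exsy.extract_from_volumes(volumes, network)
print(result.rounded())
```

prints

```
{'k1': 0.16, 'k2': 0.09, 'kex': 0.25, 'k1_mech': 0.31, 'k2_mech': 0.09}
```

i.e. the averaged symmetric→asymmetric site-to-site rate is 0.16 s⁻¹, the
reverse 0.09 s⁻¹, their sum k_ex = 0.25 s⁻¹, and the mechanistic
(degeneracy-corrected) forward rate 0.31 s⁻¹.  The same computation from
the shell:

```bash
depsikin exsy --volumes src/depsikin/data/pf1022a_exsy_volumes.csv \
              --config  src/depsikin/data/pf1022a_network.yaml \
              --noise 0.2 --reps 1000 --seed 1 --out exsy.json
# k1 = 0.16 s^-1, k2 = 0.09 s^-1, kex = 0.25 s^-1
```

The `analysis/` directory holds the narrative drivers
(`01_exsy_rates.py`, `02_titration.py`, `03_msm.py`,
`04_t2_relaxation.py`); each prints what it finds and writes its tables
under `results/`.  For instance `python analysis/02_titration.py` fits a
noisy synthetic titration at the experimental design (5 mM peptide,
0–200 mM salt) and reports

```
zero-salt conformer ratio (asym:sym) = 7.0 : 1
joint shift+ratio fit: Kc = 0.1448, K1 = 142.0 1/M, K2 = 103.6 1/M (loss 0.027)
shift-only fit finds 3 distinct optimum/a within 1% of the best loss
lag metric: ratio=1 at 40.76 mM salt, 50% shift change at 10.33 mM -> lag +30.42 mM
```

— the constants are recovered from the joint observables, the shift-only
refit exposes the parameter degeneracy that limits such titrations to
qualitative interpretation, and the positive lag shows that more salt is
needed to equalise the conformer populations than to move the shift
halfway.

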