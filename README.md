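# sterilopt

Surrogate modelling and multi-objective optimization of *in vitro* seed
sterilization experiments.

## The problem

Establishing plant tissue culture starts with surface-sterilizing the
explant. The choice of disinfectant, its concentration and the immersion
time drive two competing responses: the **contamination rate** (percent of
cultures showing microbial growth — lower is better) and the **seed
germination percentage** (higher is better). Harsh treatments sterilize
well but kill seeds; mild ones leave cultures contaminated.

`sterilopt` packages a published petunia (*Petunia hybrida*) sterilization
experiment — six disinfectants (NaOCl, Ca(ClO)₂, HgCl₂, H₂O₂ on a percent
scale; NWCN-Fe and MWCNT carbon nanotubes in mg/L), each at 4–5
concentration levels × 3 immersion times, with mean ± SE of both responses —
and rebuilds the analysis chain around it:

1. **Data layer** — the printed treatment tables ship as CSV fixtures; each
   treatment is encoded as a 7-entry feature vector (one concentration slot
   per disinfectant + immersion time), min–max scaled, and split 80/20
   stratified by disinfectant.
2. **Synthetic replicates** — only means and SEs were published, so each
   treatment is expanded into *k* = 8 replicates drawn from a truncated
   normal centred on the mean with sd = SE·√k.
3. **Surrogates** — three regressors per response:
   * **MLP** 7→128→64→1, tanh hidden / linear output, trained by
     Levenberg–Marquardt (damped Gauss–Newton) with validation early
     stopping;
   * **RBF network**, Gaussian bases φ_k(x) = exp(−‖x−c_k‖²/2σ²) on
     k-means centers, output weights by linear least squares;
   * **GRNN** (Nadaraya–Watson kernel regression),
     Ŷ(x) = Σᵢ yᵢ Kσ(x, xᵢ) / Σᵢ Kσ(x, xᵢ), with the smoothing width σ
     selected by leave-one-out grid search.
4. **Evaluation** — R², RMSE and MBE per model × response × train/test
   subset; the best model is the one with the highest mean test R².
5. **Sensitivity** — leave-one-input-out retraining: VSE is the reduced
   model's test RMSE, VSR = VSE / full-model RMSE, inputs ranked by VSR.
6. **Optimizer** — from-scratch **NSGA-II** (fast non-dominated sorting,
   crowding distance, binary tournament, two-point crossover at rate 0.70,
   per-gene Gaussian mutation at rate 0.01, population 85, 800 generations)
   over the surrogate pair, per disinfectant. From the final Pareto front
   the reported solution minimizes the distance to the utopia point:
   √((C − m)² + (G − n)²), where m and n are the minimum observed
   contamination and maximum observed germination of that disinfectant's
   data.

## Worked example

`examples/04_optimize_scenario.py` trains the GRNN pair on the replicated
dataset and optimizes the Ca(ClO)₂ scenario:

```text
scenario: Ca(ClO)2 in (0.0, 9.0)%, time in (5.0, 15.0) min; utopia (m, n) = (0.0, 91.66)
final front: 85 non-dominated solutions
ideal point: 8.85% for 10.06 min -> predicted contamination 4.66%, germination 91.35%
```

Reading: within the tested box, the front member closest to the utopia
point (0% contamination, 91.66% germination) is ≈8.9% Ca(ClO)₂ for ≈10 min,
predicted to give ≈4.7% contamination and ≈91.4% germination. The other
examples cover loading/inspection (`01`), replicate expansion and the
three-model comparison grid (`02`), input sensitivity (`03`), and
optimum recovery on a synthetic ground-truth surface (`05`).

The same capabilities are available from the shell:

```bash
sterilopt evaluate --seed 0
sterilopt optimize --disinfectant CaClO2 --seed 0 --plot-out front.png
sterilopt run-all --seed 0 --outdir runs/demo   # full workflow + report.md
```

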