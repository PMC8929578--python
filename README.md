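# ononis-cns

Analysis pipeline for evaluating isoflavonoid aglycones — isoflavones,
isoflavanones and pterocarpans of the kind found in *Ononis* (restharrow)
species — as candidate central-nervous-system drugs. It covers the four
stages such a characterization needs:

1. **Shake-flask lipophilicity** (`ononis_cns.partition`) — the
   distribution coefficient at a given pH from the aqueous absorbance
   drop, log D^pH = log₁₀(((A₀ − A₁)/A₁)·R) with phase ratio
   R = V_aq/V_oct, replicate statistics, Henderson–Hasselbalch
   ionization accounting, and assignment of log P from the
   most-unionized measurement pH.
2. **PAMPA blood–brain-barrier permeability** (`ononis_cns.pampa`) —
   membrane retention MR = 1 − C_D(t)/C_D(0) − (V_A/V_D)·C_A(t)/C_D(0)
   and effective permeability

   P_e = −2.303/(A(t − τ_SS)) · (V_A·V_D/(V_A + V_D)) ·
   log₁₀[1 − ((V_A + V_D)/((1 − MR)·V_D)) · C_A(t)/C_D(0)]  (cm/s),

   replicate aggregation on the log scale, BBB+/BBB−/uncertain calls
   under three literature cutoff schemes, skeleton-class retention
   averages, and ordinary-least-squares calibration of log P_e against
   literature log BB for the standard panel.
3. **CNS drug-likeness screening** (`ononis_cns.descriptors`) —
   molecular weight from Hill formulas, fragment-additive topological
   polar surface area (17.07 Å² per carbonyl O, 9.23 per ether-type O,
   20.23 per hydroxyl), hydrogen-bond-donor counts, and verdicts
   against the BBB-penetration property ranges (MW < 450 Da,
   PSA < 70 Å², HBD 0–1, log P 2–4, log D^7.4 2–4, log P_e > −5.50).
4. **Chemical-space nearest-neighbor activity prediction**
   (`ononis_cns.chemspace`) — Euclidean distances in the 8-D
   ChemGPS-NP principal-component space, the ED < 1 proximity census,
   and the mean MAO-B IC₅₀ or selectivity index (IC₅₀ MAO-A / IC₅₀
   MAO-B, so SI > 1 means MAO-B-selective) of the 5 and 10 closest
   annotated reference inhibitors.

A synthetic-data module (`ononis_cns.synthetic`) generates every input
kind from known ground truth — shake-flask records, two-compartment
PAMPA transport, annotated 8-D reference clouds, calibration
standards — so each estimator can be validated by round-trip recovery.

## Worked example

The bundled panel carries eight compounds: six characterized aglycones
(calycosin D, formononetin, sativanone, onogenin, medicarpin,
maackiain) with measured log P / log D^7.4 / log P_e, plus
pseudobaptigenin and calycosin with structural profiles only.

```sh
ononis-cns report --out results
```

prints the descriptor table with rule verdicts and the per-scheme
classifications:

```
          id     mw   psa  hbd  logP  logD74  logPe  ... n_outliers
 calycosin_d 284.27 75.99    2  2.48    2.21  -5.60  ...        3.0
formononetin 268.27 55.76    1  2.83    2.73  -5.00  ...        0.0
  sativanone 300.31 64.99    1  3.04    2.75  -4.76  ...        0.0
    onogenin 314.29 74.22    1  3.03    2.49  -4.73  ...        1.0
  medicarpin 270.28 47.92    1  3.03    3.03  -4.45  ...        0.0
   maackiain 284.27 57.15    1  2.49    2.49  -4.48  ...        0.0

          id  logPe konczol        di mensch
 calycosin_d  -5.60    BBB+ uncertain   BBB-
formononetin  -5.00    BBB+      BBB+   BBB+
  ...
```

Five of the six compounds satisfy every BBB-penetration rule and are
BBB+ under all three classification schemes; calycosin D exceeds the
PSA and HBD limits, sits below the log P_e preference, and its call
depends on the scheme (its P_e of 2.5 × 10⁻⁶ cm/s falls inside the
2–4 × 10⁻⁶ cm/s uncertain zone). Onogenin's only outlier is its polar
surface area.

The synthetic pipeline round-trips end to end:

```sh
ononis-cns simulate --seed 1 --out sim --n-points 500
ononis-cns pampa --plate sim/pampa_plate.csv --standards sim/standards.csv --out results
```

```
compound_id  mean_logPe  sd_logPe  mean_MR  n konczol   di mensch
       demo   -5.003431  0.011845 0.296919  9    BBB+ BBB+   BBB+
standards calibration: logPe = 0.995 * logBB + -4.975 (R^2 = 0.9926, n = 6)
```

The simulated compound was generated with true P_e = 10⁻⁵ cm/s and
MR = 0.3 plus 2% concentration noise; the estimator recovers
log P_e = −5.003 ± 0.012 and MR = 0.297 from nine wells, and the
noisy standards line (true slope 1, intercept −5) is recovered by the
calibration fit.

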