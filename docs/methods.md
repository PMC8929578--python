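# Methods

## Shake-flask partitioning

A solute equilibrated between Britton–Robinson buffer and n-octanol
distributes according to D = C_oct/C_aq. With aqueous absorbance A₀
before and A₁ after partitioning, and phase ratio R = V_aq/V_oct, mass
balance gives C_oct·V_oct = (A₀ − A₁)·V_aq per unit signal, hence

    log D^pH = log10( ((A0 − A1)/A1) · R ).

The phase ratio sits **inside** the logarithm: this is forced by the
mass-balance derivation, and only this reading makes the estimate
independent of the phase ratio used (a property the tests verify for
R ∈ {20, 50, 100}, matching 10 mL buffer against 0.5/0.2/0.1 mL
octanol). Records with A₁ ≥ A₀ are rejected; an absorbance drop below
0.5% of A₀ is flagged as noise-dominated but still computed.

Replicates are summarized by the arithmetic mean and the sample SD
(n − 1 denominator); the standard error SD/√n is reported alongside,
since published tables sometimes label the dispersion either way. A
single replicate yields SD = 0 with a warning.

Ionization follows the Henderson–Hasselbalch relation for a monoprotic
acid, f_ionized = 10^(pH−pKa)/(1 + 10^(pH−pKa)), evaluated in a
branch-stable logistic form. For multiprotic compounds only the lowest
pKa is used: the second ionization of a phenol with pKa above 9 is
negligible below pH 8. log P is assigned as the log D of the
most-unionized measured pH, accepted only when the ionized fraction is
below a configurable threshold (default 5%); otherwise the module
raises rather than silently reporting a log D as log P. No
ionization-correction arithmetic is applied beyond choosing the
measurement pH — for these weak acids measured at pH 5 (isoflavones,
isoflavanones) or pH 7.4 (pterocarpans) the correction would be below
the replicate SD.

## PAMPA-BBB

Geometry defaults are the standard 96-well sandwich: filter area
A = 0.24 cm², donor volume V_D = 0.15 cm³, acceptor volume
V_A = 0.18 cm³, incubation t = 4 h, steady-state lag τ_SS = 240 s.
Concentrations enter only as the ratios C_D(t)/C_D(0) and
C_A(t)/C_D(0), so any consistent unit works.

Membrane retention is estimated first from the well's own mass balance
and then passed into the permeability equation, whose (1 − MR) factor
treats retained mass as removed from the transport equilibrium. The
equation is implemented with the conventional printed −2.303 prefactor
and base-10 logarithm. Numerical policies: MR estimates in (−0.02, 0)
are clamped to zero with a warning (absorbance noise around an
unretained compound); estimates below −0.02 raise, as does an acceptor
concentration above the MR-corrected equilibrium (log argument ≤ 0),
with the offending well named. C_A(t) = 0 maps to P_e = 0 exactly.

Replicates and days are pooled jointly and averaged on the log₁₀ scale
(log-scale error bars are how these assays are reported); per-compound
grouping is strict. Skeleton-class membrane-retention means are
reported in percent. Standards calibration is an ordinary
least-squares fit of measured log P_e on literature log BB
(scipy.stats.linregress), refusing fewer than three standards or a
zero-variance predictor.

Classification schemes, all configurable in `RunConfig`:

* **konczol** — single discriminator at log P_e = −6.0;
* **di** — uncertain zone between P_e = 2 × 10⁻⁶ and 4 × 10⁻⁶ cm/s,
  stored and compared on the P_e scale because the usual printed log
  bounds (−5.69, −5.39) are truncations of −5.699/−5.398;
* **mensch** — a single P_e cutoff. The source scheme defines its in
  vitro limit per-assay rather than as a fixed number, so the default
  here is the upper edge of the uncertain zone, 4 × 10⁻⁶ cm/s — the
  choice consistent with a −5.60 compound being called BBB− while a
  −5.00 compound is BBB+.

Exact boundary values belong to the more permeable category in every
scheme, making classification monotone in log P_e.

## Descriptors and the BBB rule screen

TPSA is fragment-additive over a curated per-compound polar-fragment
profile: 17.07 Å² per carbonyl oxygen, 9.23 per two-coordinate
ether-type oxygen, 20.23 per hydroxyl, extensible to further terms
(e.g. N–H) through the profile's extra map. All ether-type oxygens —
pyranone ring O, methoxy, methylenedioxy, pterocarpan ring O — share
the single 9.23 contribution; this uniform assignment reproduces the
printed PSA of all six panel compounds exactly. The profile is the
contract: no structure perception (SMILES/aromaticity/conformers) is
performed, which keeps the descriptor path dependency-free and exact
but limits the screen to compounds whose profiles have been curated.

Molecular weights use IUPAC standard atomic weights (C 12.011,
H 1.008, O 15.999). The medicarpin formula C₁₆H₁₄O₄ sums to 270.28 Da
while the published table prints 270.25; the discrepancy is treated as
a typographical artifact of that table and not chased. Descriptors are
reported to 2 decimals with half-up rounding; rule screening uses
unrounded values. Range boundaries: "<450" and "<70" strict, "0–1" and
"2–4" inclusive, ">−5.50" strict — the literal reading of the printed
ranges.

## Chemical-space kNN

Distances are plain Euclidean over all eight ChemGPS-NP principal
components (the first three are exported for visualization only).
Reference sets are filtered to IC₅₀(MAO-B) below a cutoff — default
10 µM; 1 µM is the other cutoff in circulation, hence the config
knob — and, for selectivity work, to compounds with both isoform
annotations. Self-matches are excluded by id, not by distance, so a
distinct compound projecting onto identical coordinates (as
regio-isomers can) remains a legitimate neighbor, flagged in the
report. Ties at the k-th rank break by reference id for
reproducibility.

The selectivity index defaults to IC₅₀(MAO-A)/IC₅₀(MAO-B): the
published experimental SIs of MAO-B-selective inhibitors are > 1
while their MAO-B IC₅₀ is the smaller value, which is only consistent
with the A-over-B ratio even where the B-over-A formula is printed.
The convention is configurable and recorded in output. IC₅₀ averaging
is arithmetic on the nM scale by default (matching how the reference
tables are described); a geometric mean is the natural alternative for
values spanning orders of magnitude and is easy to apply downstream of
the returned neighbor lists.

## Synthetic data

Generators exist so that every estimator has a ground-truth inverse:

* **Shake-flask**: A₀ ~ U[0.5, 1.5] per replicate, A₁ = A₀/(1 + D/R)
  with D = 10^logD(pH) and logD(pH) = logP − log10(1 + 10^(pH−pKa)).
  Noiseless records invert to the true log D at float precision.
* **PAMPA transport**: retention is modeled as an instantaneous
  initial partition of donor mass (fraction MR) at τ_SS, followed by
  two-compartment diffusion of the mobile mass with rate constant
  P_e·A·(1/V_D + 1/V_A). The decay is written in base 10 with the
  2.303 prefactor so the permeability estimator inverts the forward
  model exactly; it differs from the exact exponential by < 0.02%,
  within the < 0.1% agreement the ODE cross-check in the test suite
  enforces. Mass is conserved: C_D·V_D + C_A·V_A + retained =
  C_D(0)·V_D at all times. The instantaneous-partition choice mirrors
  the estimator's own assumption — kinetic membrane uptake would make
  MR time-dependent and the estimator only asymptotically consistent.
* **Reference cloud**: 8 Gaussian clusters (SD 0.6) around centers
  drawn from N(0, 1.5²) in 8-D, 2000 points by default — an occupancy
  that puts tens to a few hundred compounds inside an ED < 1 ball,
  the regime of curated inhibitor sets. The MAO-B potency field is
  log-linear in the lipophilicity axis, log₁₀ IC₅₀[nM] = 3.0 − 0.6·PC3
  (more lipophilic ⇒ more potent), optionally with lognormal scatter;
  the selectivity field is log₁₀ SI = 0.3·PC1. Both fields are smooth
  and exported (`true_ic50_field`, `true_si_field`) so kNN recovery is
  measurable against truth.
* **Standards**: six named calibration compounds on an even log BB
  grid over [−1.5, 1.0] with log P_e = slope·log BB + intercept +
  Gaussian scatter.

Noise is multiplicative Gaussian on concentrations and absorbances,
reflecting relative-error behavior of UV and HPLC quantification. Every
generator is deterministic under its seed.

What the synthetic data does *not* emulate: aqueous-boundary-layer
resistance (the stirred assay fixes it experimentally), kinetic
membrane uptake, UV spectral interference between species, pH drift,
and the descriptor structure of real chemical libraries (the cloud is
isotropic Gaussian, not a fingerprint manifold). Passing recovery
tests therefore demonstrates estimator correctness under the model's
own assumptions, not robustness to these real-data effects.

## Problem sizes and tolerances in the test suite

Recovery grids cover P_e ∈ {10⁻⁷…10⁻⁴} cm/s × MR ∈ {0, 0.2, 0.5, 0.7}
(noiseless, 5% relative tolerance) and a 6-replicate 5%-noise check at
±0.1 log units. The kNN module is compared against a pure-Python
exhaustive-sort oracle on 100 random clouds up to 10⁴ points, and
field recovery uses the default 2000-point cloud with 60 held-out
queries (Spearman ρ > 0.8). These sizes keep the whole suite within a
couple of minutes on one core while exercising each scale regime.

## Known limitations

* No structure-derived descriptor path: profiles are curated inputs.
* The log P assignment assumes monoprotic acid behavior below the
  second pKa; amphoteric or zwitterionic solutes are out of scope.
* The PAMPA model omits explicit unstirred-water-layer permeability
  deconvolution; P_e is the effective, not intrinsic membrane,
  permeability.
* Chemical-space predictions inherit whatever bias the supplied
  reference set carries; the module does not reweight or debias it.
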