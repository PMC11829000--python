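# Methods

`afmi` generates conformational ensembles of disordered and partially
disordered proteins that are consistent with the inter-residue distance
distributions, confidence scores and aligned-error estimates produced by a
protein structure predictor.  This note records the model, the numerical
choices, and what the synthetic validation experiments do and do not
demonstrate.

## From distograms to restraints

A *distogram* assigns each residue pair (i, j) a discrete probability
p^b_ij over 64 equal-width distance bins spanning 2.15625–21.84375 Å, with
the last bin absorbing all longer distances.  The restraint target and scale
for a pair are the first two moments of this distribution, computed with bin
centers (midpoints of the bin edges, including the last finite bin — the
overflow interpretation is handled by the tail filter, not by the moment).

Pairs are filtered in four stages:

1. **Tail filter.** Pairs with more than 0.02 probability at or beyond the
   last finite edge are discarded: the predictor cannot express distances
   beyond its grid, so such pairs carry censored information.
2. **Aligned-error filter.** The pair's predicted aligned error (PAE,
   symmetrized conservatively as the elementwise max) must fall below a
   per-protein cutoff: 10 Å for hydrophilic chains (mean Kyte–Doolittle
   hydropathy < −1.4, i.e. disorder-prone) that contain at least one run of
   5 residues with pLDDT > 75, and 5 Å otherwise.  The hydropathy sign
   convention matters: *negative* mean hydropathy means hydrophilic.
3. **Structured-segment exclusion.** Maximal runs of ≥ 2 consecutive
   residues with pLDDT > 75 are treated as structured.  Distance restraints
   touching them are removed, because the one-bead model cannot hold
   secondary structure; those segments are instead tethered to the predicted
   coordinates by a one-sided harmonic *RMSD wall* (energy
   ½κ(RMSD−t)² above threshold t, default κ = 10⁴ kJ mol⁻¹ nm⁻²,
   t = 0.1 nm; superposition by Kabsch SVD with forces via the envelope
   theorem).  pLDDT values are normalized to a 0–100 scale internally, so
   confidences supplied on 0–1 are read consistently.
4. **Sequence separation.** |i−j| ≥ 3; bonded and next-neighbour geometry
   is the force field's job, while other short-range pairs are kept — they
   carry much of the usable signal given the ~22 Å grid ceiling.

Each excluded pair is counted once, under the first filter that rejected it,
in the selection provenance.

## Prior: one-bead-per-residue force field

The conformational prior is a Cα-level model with the CALVADOS-2 functional
forms: harmonic bonds (k = 8033 kJ mol⁻¹ nm⁻², r₀ = 0.38 nm), a
stickiness-scaled Ashbaugh–Hatch short-range term (ε = 0.8368 kJ/mol,
per-residue σ and λ combined by arithmetic means, cutoff 2.4 nm) and
Debye–Hückel electrostatics (temperature-dependent water permittivity,
cutoff 4 nm; λ_D ≈ 0.79 nm at 0.15 M, 298 K).  Both nonbonded terms are
truncated *and shifted*, so the energy is continuous — necessary for stable
Langevin dynamics.  Residue parameters ship as a versioned JSON data file
citing their source publication.  Histidine charge follows
Henderson–Hasselbalch at pKa 6.0; termini carry +1/−1 e by default
(switchable).  A numba-compiled pair kernel accelerates the O(N²) nonbonded
loop; the numpy path is retained and the two are verified to agree to
roundoff.

## Sampling

Dynamics are NVT Langevin with the BAOAB splitting (defaults: 5 fs step,
friction 0.01 ps⁻¹, 6 replicas × 10⁶ steps in the production profile; the
test profile uses 2 replicas × 2×10⁵ steps).  BAOAB reduces exactly to
velocity Verlet at zero friction, which the energy-drift test exploits.
Replicas advance in lockstep so that energy hooks — the metainference
restraint, the RMSD wall, the metadynamics bias — see a consistent snapshot
of all replicas each step.  Runs are deterministic given the seed; each
replica's noise stream folds in its replica id.  A short steepest-descent
minimization (100 steps, backtracking line search, energy non-increasing)
precedes dynamics; during minimization overlapping beads are handled by
clamping nonbonded distances at a hard floor rather than erroring.

## Metainference restraint

The restraint energy per step is

    E = (k_B T / 2) Σ_{r,i} [d_i − f_i(X)]² / (σ_B,{r,i}² + σ_SEM,i²) + E_σ,

a Gaussian likelihood on the selected targets d_i with two error scales:
σ_SEM,i, the standard error of estimating the forward model from a finite
number of replicas, and σ_B,{r,i}, a per-replica scale absorbing all
remaining (random plus systematic) error.  The forward model f_i is
configurable: the across-replica mean distance (`replica_average`, the
maximum-entropy convention for ensemble-averaged data) or the per-replica
distance (`per_replica`, the restraint energy exactly as its defining
equation is written).  σ_B is sampled by one Metropolis-within-Gibbs sweep
per MD step — uniform proposals of half-width 0.1 Å, hard-rejected outside
[10⁻⁴, 10] Å — and σ_SEM is refreshed every 200 steps as the window average
of the instantaneous across-replica standard error (zero, with a warning,
for a single replica).  σ_B is initialized from the distogram spread, since
the defining description leaves initialization open; σ_SEM is initialized to
spread/√N_R (the a-priori estimate of replica-mean uncertainty) rather than
zero, and before the first force evaluation the hook equilibrates σ_B with
300 Gibbs sweeps against the starting structure's deviations.  Both choices
are stability requirements: a start far from (or exactly at) the targets
otherwise meets small σ values, and the resulting k_B T/σ² springs exceed
the 5 fs integrator's stability limit before the ±0.1 Å Gibbs walk can
adapt.  For the same reason the `per_replica` forward model, whose
Jeffreys-sampled σ_B tracks instantaneous deviations and can pin at the
10⁻⁴ Å lower bound, is integrable only at much smaller time steps; the
replica-averaged forward model (whose variance is floored by σ_SEM) is the
stable default.

The error-energy term E_σ is implemented exactly as its printed form,

    E_σ = k_B T Σ_{r,i} [ −log σ_B + ½ log(σ_B² + σ_SEM²) ],

with a `sigma_prior` switch: `as_printed` keeps the −log σ_B term
(equivalent to a prior p(σ) ∝ σ), `jeffreys` flips its sign (p(σ) ∝ 1/σ,
the convention of the wider metainference literature).  The choice is
consequential: under the printed form the conditional density of σ_B at
fixed deviation is non-decreasing in σ over most of the bounded range, so
σ_B drifts toward the 10 Å bound and the restraints progressively
self-deactivate.  Under the Jeffreys form the conditional peaks near the
actual deviation (mode ε/√2), which keeps restraint stiffness matched to
the residuals.  The pipeline profiles therefore default to `jeffreys`, with
the printed form available and tested; this is a deliberate, visible
correction, not a silent one.

## Enhanced sampling and reweighting

Parallel-bias well-tempered metadynamics deposits 1-D Gaussians on each
collective variable (defaults: chain radius of gyration and end-to-end
distance; hill height 0.5 kJ/mol, bias factor 10, pace 500 steps, shared
across replicas in the multiple-walker convention).  Hills are damped by the
well-tempered factor and weighted by the parallel-bias conditional
probability; the combined potential is the softmin
−k_B T log[(1/K) Σ_k exp(−V_k/k_B T)], gauged to zero at zero bias.  Bias
forces use the exact slope of the piecewise-linear grid interpolation, so
bias energy and force are mutually consistent to roundoff.  Per-protein CV
grids and hill parameters are expected to be tuned per system, as is normal
metadynamics practice.

After the run, replicas are concatenated (first 10% of each discarded as
equilibration), the *final* accumulated bias is re-evaluated exactly at
every frame's CVs by summing the stored hill history (the exact limit of
"re-running deposition at a much faster pace"), and Torrie–Valleau weights
w ∝ exp(+V/k_B T) (max-shifted for overflow safety) turn the biased
trajectory into a weighted ensemble; multinomial resampling (systematic
available) produces the final uniform-weight ensemble.  Convergence is
monitored by weighted free-energy profiles along the biased CVs over five
cumulative blocks of increasing coverage.

## Validation observables

P(r) is the weighted, normalized histogram (1 Å bins by default) of all
inter-residue distances over all frames; |i−j| ≥ 1 pairs are included, with
a flag to exclude short separations.  Distribution agreement is scored by
the Kullback–Leibler divergence with natural logarithms (nats); when grids
differ, both distributions are re-binned to the coarser grid over the union
range, and the second argument receives a redistributed pseudo-mass of
10⁻⁸ so that a model missing a populated bin is penalized finitely rather
than infinitely.  Chain compaction is summarized by the scaling exponent ν
of ⟨R_ij²⟩^½ = b·|i−j|^ν, fit by least squares in log–log space over
separations 5 ≤ |i−j| ≤ N/2; ν = 0.5 is the Flory random-coil reference
value.

## The synthetic round-trip experiment

Real predictor outputs and scattering data are deliberately out of scope,
so validation rests on a round trip built entirely from the package's own
components:

1. A 40-residue hydrophilic, uncharged sequence is generated.
2. A *reference* ensemble is produced under a modified force field — every
   λ shifted by +0.3 and the short-range well deepened 3× — starting from a
   sphere-confined compact walk.  This yields a stable collapsed globule
   (Rg ≈ 8.8 Å, ν ≈ 0.13) whose pair distances mostly lie inside the
   distogram grid.  The modification stands in for structural information
   that a predictor has and the unmodified prior lacks; starting compact is
   necessary because spontaneous coil–globule collapse exceeds desk-scale
   run lengths.
3. A distogram is back-calculated from the reference; synthetic pLDDT
   (≈40 ± 10, capped below 75, since the chain is "disordered") and PAE
   (floor 1 Å plus the per-pair distance standard deviation, emulating the
   documented PAE–fluctuation correlation) are attached.
4. Restraints are selected with the production filters, and the restrained
   simulation (6 replicas × 2×10⁵ steps) plus an unrestrained control are
   run from a reference conformation — the stand-in for the predicted
   structure the production protocol starts from — then reweighted.  The
   bias settings for this small system are deliberately mild (hills of
   0.3 kJ/mol, bias factor 5, grids spanning the physically relevant Rg and
   end-to-end ranges): per-system bias parameters are normal metadynamics
   practice, and a barrier-free 40-mer needs little help.
5. The restrained output must reproduce the reference: restrained-pair mean
   distances within 1 Å on average, D_KL(reference ‖ output) below 0.05,
   and the control strictly worse.

The replica count of this experiment matters and is kept at the production
protocol's six.  The metainference posterior is a *compromise*: restraint
stiffness is capped by the combined error σ_B² + σ_SEM², and σ_SEM — the
honest uncertainty of the replica-mean forward model — is the across-replica
pair-distance spread divided by √N_R.  With only two replicas σ_SEM is of
the order of the full thermal fluctuation (≈2 Å here, insensitive to the
bias settings), every restraint is correspondingly soft, and the posterior
equilibrates visibly expanded relative to a collapsed reference: across the
whole reference-depth axis either the divergence bound or the
control-ordering requirement then fails.  Six replicas tighten σ_SEM enough
for the posterior to sit on the reference, at a desk-scale cost (minutes on
one CPU).  Separately, mean restraints cannot narrow the prior's per-pair
fluctuations to match an arbitrarily rigid reference, which sets a floor on
distributional agreement for references far stiffer than the prior; the
default reference is a fluctuating globule, not a rigid body, for exactly
that reason.

The synthetic annotations emulate only the qualitative signatures of
predictor confidence; nothing here models a real predictor's error
statistics, nor SAXS noise, so passing the round trip demonstrates that the
machinery transports distogram information into ensembles correctly — not
that any particular accuracy would be achieved on real proteins.

## Numerical and scale choices

Benchmarks are sized for a single CPU: the thermostat check pools 128
independent oscillators; the Gibbs-sampler check pools 128 independent σ
chains over 10⁵ sweeps against a quadrature oracle (using the Jeffreys
conditional, which is concentrated enough for the printed ±0.1 Å move width
to mix on that budget — the code path is identical for both priors); the
metadynamics check recovers the analytic free energy of a bead-pair double
well, F(r) = U(r) − 2k_B T ln r, the Jacobian term included; the
Torrie–Valleau check reweights a statically tilted harmonic well and takes
its uncertainty from the spread across independent wells, which folds in
autocorrelation.  The reference generator and the round trip use the
problem sizes stated above.

## Known limitations

- Distogram distances are Cβ-based in their native convention while the
  model has Cα-level beads; the discrepancy is absorbed by σ_B (a warning
  is the user's reminder, not a correction).
- With few replicas σ_SEM is inflated (it scales as the pair-distance
  spread over √N_R), so restraints in the 2-replica pipeline test profile
  are much softer than in production; the round-trip experiment therefore
  runs at the production replica count.
- No back-mapping to all-atom structures, no chemical-shift or SAXS-profile
  back-calculation, and no handling of multi-chain systems.
- The Gibbs sampler holds σ_SEM fixed within a sweep; joint σ moves are not
  implemented.
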