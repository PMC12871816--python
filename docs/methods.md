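# Methods

`tailgate` simulates the steric gating of ribosomal A-to-P site
translocation by the flexible N-terminal tail of ribosomal protein bL27,
using a coarse-grained structure-based (Gō-type) model.  This note
documents the model, its assumptions, the synthetic study system, the
numerical choices, and the limits of what the package's tests demonstrate.

## The scientific question

During trans-translation, the tRNA-like domain (TLD) of tmRNA-SmpB moves
from the ribosomal A site to the P site.  The universally conserved
protein bL27 extends a disordered N-terminal tail toward the peptidyl
transfer center, directly in the path of that movement.  The hypothesis
under test is kinetic: the tail acts as a *dynamic steric obstacle* that
transiently blocks TLD passage, lengthening the A-site dwell time of
tmRNA-SmpB on wild-type ribosomes relative to ribosomes whose tail is
truncated — without binding it, and without changing the endpoints of the
motion.  The observable is the ratio of mean A-site dwell times
(full-length tail / truncated tail), which in-vitro kinetics place at
roughly two-fold.

## Structure-based (Gō-type) energy function

The potential is the classic single-basin native-centric form, built from
a reference structure whose coordinates define every equilibrium value:

* bonds: `V = ½ k_b (r − r₀)²` between consecutive beads of a chain;
* angles: `V = ½ k_a (θ − θ₀)²` over consecutive triples;
* dihedrals: `V = k_d [1 − cos(φ − φ₀)] + ½ k_d [1 − cos 3(φ − φ₀)]`;
* native contacts: pairs closer than a cutoff in the reference structure
  (excluding bonded pairs and near-sequence neighbours) receive a
  Lennard-Jones-form well with its minimum of depth ε exactly at the
  reference distance — `V = ε[(r₀/r)¹² − 2(r₀/r)⁶]` by default, with the
  12-10 variant available;
* excluded volume: all other pairs involving a mobile atom repel via
  `V = ε_ev[(s/r)¹² − 2(s/r)⁶ + 1]` truncated at `r = s` (the
  Weeks-Chandler-Andersen construction applied to the min-at-σ form), where
  `s` is the arithmetic mean of the two per-atom diameters.  Energy *and*
  force vanish identically at the truncation radius, so the reference
  structure is an exact stationary point of the total energy;
* optional positional restraints `V = ½ k |x − x₀|²` (used for the tail
  anchor and for pre-release equilibration).

A fully immobile substructure is treated as a rigid body with no internal
energy: no bonded terms are generated inside immobile chains and
immobile-immobile pairs are skipped by the excluded-volume sum.

Reduced units throughout: the contact depth ε is the energy unit, bead
mass is 1, k_B = 1, lengths in nm, time in τ = nm·√(m/ε).  No physical
time calibration is attempted — only dwell-time *ratios* are meaningful,
and those are invariant to the overall diffusive timescale.

### Force-field constants

No experimental source specifies these for the scaled-down system, so all
are configuration-exposed, recorded in every report, and set to
conventional coarse-grained Gō-model magnitudes:

| constant | default | units |
|---|---|---|
| k_bond | 10000 | ε/nm² |
| k_angle | 40 | ε/rad² |
| k_dihedral | 1 (multiplicities 1 and 3) | ε |
| ε_contact | 1 | ε |
| ε_ev, σ_ev | 1, 0.38 | ε, nm |
| contact cutoff | 0.55 | nm |
| min. sequence separation | 4 | residues |

Intra-chain contacts of chains declared semi-rigid get a 3× depth
multiplier (intended for folded RNA duplexes such as the TLD acceptor
stem).  For the default synthetic ligand geometry no intra-ligand pairs
fall inside the cutoff, so its rigidity comes entirely from the angle
stiffness: the persistence length k_a·b/k_BT ≈ 30 nm far exceeds the
~3.6 nm chain, which is the operative meaning of "semi-rigid" here.

### Single-basin choice

The potential is built from the **post-translocation** (P-site) endpoint,
so translocation is spontaneous relaxation from the A-site start toward
the only attractive basin.  This reproduces the observable — time to
first reach the P site — without inventing a multi-basin or targeted
scheme.  The cost is that the A-site state is not itself metastable; the
pipeline therefore prepares each event by a short equilibration with the
tracked atom restrained at the A-site position, then releases it.

## The synthetic study system

The generator builds a deliberately minimal geometry preserving the three
ingredients of the mechanism: a confining corridor, a flexible obstacle
anchored part-way along it, and a semi-rigid ligand that must pass.

* **Scaffold** (immobile): rings of beads forming a cylindrical corridor
  of radius 1.0 nm about the z axis, closed by a floor disk at the P-site
  end and a cap disk behind the A-site start.  Below 1.5 nm the corridor
  tapers into a funnel-shaped pocket of radius 0.6 nm — the stand-in for
  the snug tRNA binding site — which both guides the ligand head onto the
  axis and supplies its native-contact basin (≈10 contacts at the
  default geometry).
* **Ligand** (mobile, semi-rigid): a 12-bead zigzag helix (radius
  0.17 nm, 1.2 rad/bead), topologically linear with 0.38 nm bead spacing.
  Bead 1 is the tracked atom (the analogue of the U9 phosphorus of the
  TLD).  Its post-translocation position defines the target; the
  pre-translocation structure is the same chain displaced 3.0 nm up the
  corridor axis.  The helical (rather than perfectly straight) reference
  keeps bond angles (~2.56 rad) safely away from the θ = π coordinate
  singularity of the angle and dihedral forces.
* **Tail** (mobile, fully flexible): a 9-bead chain mimicking the bL27
  N-terminus, its anchored end held by a stiff tether (k = k_bond) one
  bead spacing inside the wall at 2.2 nm from the target — the observed
  steric bottleneck.  The tail receives *no* native contacts (contacts
  touching it are dropped when the potential is assembled): it is a
  purely entropic, disordered obstacle.  Its reference conformation is an
  arc hugging the wall; within a few hundred steps of equilibration it
  samples disordered conformations across the lumen.

The truncated-tail system is generated from the identical geometry with
the tail chain omitted (bit-identical scaffold and ligand, same atom
ids); `truncate_tail` applied to the full system produces exactly the
same structure, and a test asserts this equivalence.

What the synthetic system does **not** emulate: ribosomal secondary and
tertiary structure, sequence-specific interactions (including the HKK
charge triad of the tail), SmpB, electrostatics, solvent, and the
intersubunit motions that accompany real translocation.  Passing tests
therefore demonstrate that the package's machinery correctly measures a
steric-gating effect in a corridor model — not that the real ribosome
behaves this way; user-supplied PDB coordinates are accepted for the
latter question but are computationally out of desk scale.

## Langevin dynamics

Underdamped Langevin dynamics via BAOAB splitting: half-kick, half-drift,
exact Ornstein-Uhlenbeck velocity refresh, half-drift, half-kick.  At
zero friction the O-step is the identity and the integrator reduces to
velocity Verlet, which the energy-conservation check exploits.  Defaults:
dt = 0.002 τ, friction γ = 1.0 τ⁻¹, temperature T = 0.5 ε/k_B (well below
the contact-melting scale, so the pocket basin and ligand shape persist).
Immobile atoms are excluded from integration.

Excluded volume goes through a Verlet neighbour list (0.2 nm skin) over a
precomputed candidate-pair array; the list is rebuilt whenever any mobile
atom has moved more than half the skin since the last build, which makes
the list exact.  A test verifies bitwise-identical trajectories against
an effectively infinite skin.

All randomness (initial Maxwell-Boltzmann velocities and thermostat
noise) derives from one PCG64 generator per run, drawn in fixed-size
chunks, so runs are bitwise reproducible for a given seed.  A non-finite
coordinate aborts the run with the step index; the pipeline retries such
an event once at half the timestep and flags it.

## Experiment pipeline and analysis

Each of the `n_events` trajectories per system: (1) equilibrate 2000
steps with the tracked atom restrained at the A-site start (k = 100
ε/nm²); (2) release and integrate in 10,000-step segments, continuing
velocities across segments (only the noise stream is re-seeded, from
`SeedSequence([base_seed, stream, trajectory, segment])`, so results are
independent of execution order); (3) stop at the first segment whose
reaction coordinate d — the distance of the tracked atom from its
post-translocation position — reaches the threshold, or at the horizon.

* **Dwell time**: first passage of d below 0.3 nm, assigned to the first
  qualifying frame (frames every 50 steps = 0.1 τ; no interpolation).
  The 0.3 nm default operationalizes "arrived at the P site": the bound
  state fluctuates near d ≈ 0.1 nm.  A trajectory that never crosses is
  censored at the horizon (default 800,000 steps = 1600 τ) and enters
  mean dwell times at that value — a conservative lower bound that biases
  the fold change *toward* 1.  At the calibrated defaults censoring is
  rare (zero in 30-event pilots).
* **Occupancy**: normalized histograms of d pooled over each ensemble
  (0.1 nm bins), with a variant that truncates each series at its first
  passage; both are available because either convention is defensible.
* **Fold change**: ratio of mean dwell times, full/truncated, with a
  10,000-resample percentile bootstrap over trajectories (dwell times are
  heavy-tailed, so a distribution-free interval is used; the median ratio
  is reported alongside).

### Tail-radius calibration

The all-atom steric bulk of the tail has no unique image in a one-bead
model, so the tail bead diameter is calibrated: the truncated reference
ensemble is run once, then one reduced full-tail ensemble per candidate
diameter (default sweep 0.22, 0.30, 0.38 nm at 30 events each), and the
smallest diameter whose dwell ratio enters the target band [1.5, 3.0] is
selected.  The full ratio-vs-diameter curve, its bootstrap intervals and
a monotonicity flag are part of the calibration report; failure to reach
the band raises an error carrying the curve.  In pilot characterization
the curve rises smoothly (≈1.6 at 0.18 nm to ≈4.5 at 0.46 nm), so the
band is reachable and the selection is stable.

### Problem sizes

Default experiment: 150 events per system (300 trajectories), ≈280
atoms, horizon 1600 τ per event, a few minutes of one-CPU time per
ensemble at the calibrated radius.  The demo setting (30 events per
system, same horizon) estimates the same ratio with a wider interval and
runs in about two minutes after JIT compilation.

## Known limitations

* The A site is not modelled as a metastable basin; dwell time here is a
  first-passage time from a prepared start, not an exchange equilibrium.
* Censored events enter the mean at their censoring time rather than via
  a survival estimator; with default settings censoring is negligible,
  but short-horizon configurations underestimate long dwell times (and
  hence the fold change).
* Contact maps use the cutoff definition only; shadow-map construction is
  out of scope (the algorithm is pluggable at the `compute_contact_map`
  boundary).
* PDB input assumes one bead per residue per chain when building bonded
  topology; all-atom files parse but receive bead-chain topology.
* The trajectory container stores float32 coordinates; round-trip error
  is below 10⁻⁶ nm, adequate for every analysis tolerance in the
  package but not for restart-exact continuation.
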