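# Methods

`tmesim` simulates the coupled growth of a breast-tumor cell population and
its microvascular network on a 2-D lattice, with phenotype decisions
learned by reinforcement and distilled into a neural-network predictor.
This note records the model, its assumptions, the parameters that matter,
and the design choices made where the design was genuinely open.

## The lattice and its fields

The square domain (default 2 cm, desk preset 0.5 cm) is divided into tumor
microenvironments (TMEs) of 200 × 200 µm; a 2 cm domain holds 10⁴ TMEs.
Each TME carries homogeneous concentrations of five diffusible factors —
oxygen, glucose, TGFα, TNFα, VEGF — with material constants (normal and
maximum concentration, diffusion coefficient, vessel permeability) from the
tabulated parameter set. Every cell or vessel inside a TME sees the same
concentrations. Time advances in 1-hour *episodes*; a run is 720 episodes
(30 days).

Fields evolve by an explicit 8-neighbor (Moore) finite-difference diffusion
step plus per-TME secretion, uptake and decay terms, clamped to
[0, c_max]. Numerical choices:

* **Sub-cycling.** The literal explicit step is unstable (the diffusion
  number D·Δt/A reaches ≈ 6 for glucose). Each episode's diffusion runs in
  ceil(16·D·Δt/A) equal sub-steps so the per-step coefficient stays at or
  below 1/16, half the 8-neighbor stability bound. Sources and sinks apply
  once per episode.
* **Boundaries.** No-flux (each site exchanges only with its existing
  neighbors); with all sources off, total mass is conserved to 1e-9
  relative per episode.
* **Clamping.** The tabulated permeabilities make the transmural nutrient
  source term astronomically large; the per-episode clamp to [0, c_max]
  (with a clamp-event counter) effectively pins vascularized TMEs at the
  lumen concentration, which is the intended behavior of a perfused site.
* **VEGF balance.** Secretion, uptake and decay all evaluate on the
  episode-start concentration, as written. A hypoxic or necrotic TME
  therefore maintains an elevated VEGF level each episode even once
  vascularized — a persistent pro-angiogenic beacon that drives the
  continual intratumoral densification the model is meant to reproduce;
  the sprouting-control rules below keep the vascular response to it
  bounded.

Field initialization follows the normal-distribution profile: oxygen and
glucose start at `c_normal + (c_max − c_normal)·exp(−2·d_TME/σ²)` with
σ² = 0.3 and d_TME the mean cell–vessel distance within the TME, measured
in TME side lengths (sites lacking cells or vessels use a far-distance
sentinel of 10). The growth factors use the printed second branch, which
substitutes the (constant) diffusion coefficient for d_TME and therefore
yields a spatially uniform field ≈ c_normal; the switch
`eq1_use_dtme_for_growth_factors` restores the distance-dependent form.
VEGF starts at zero.

## Agents

**Cancer cells** (default 10⁶ at full scale, 10⁴ on the desk preset) seed
the domain center in concentric Moore rings up to the carrying capacity
(100 cells per TME — the value is never stated in the source material) with
uniformly random initial phenotypes. Phenotypes are proliferation,
migration, quiescence, hypoxia, necrosis. Mechanics per episode:

* *Migration:* 45 µm per episode (0.75 µm/min) along a straight line to a
  random point in the space-available Moore neighbor with the highest
  nutrient score (policy-scaled oxygen + glucose); the phenotype is locked
  until arrival; crossing into a full TME blocks until space appears.
* *Proliferation:* a cell accumulates cycle progress each proliferation
  episode and divides after `division_period_h` = 24 h of it — the
  in-vitro cycle time of aggressive breast-carcinoma lines. One offspring
  appears at a random point of the max-nutrient TME with space (current +
  Moore); without space the proliferation delay increments and the cell
  retries. Both cells carry the incremented division counter. A per-episode
  division would be biologically impossible and contradicts the reported
  two-week doubling scale.
* *Hypoxia / necrosis:* tick the oxygen-deficiency timer; necrosis is
  absorbing (the cell becomes inert and is never removed by default;
  `necrotic_removal_after` exists for experimentation).

Capacity-contended moves (divisions, TME crossings) are granted in seeded
random priority order against live occupancy, so no TME ever exceeds the
carrying capacity.

**Microvessels** are tip/stalk agents. A sprouting tip elongates 60 µm per
episode (1 µm/min) toward a random point in the max-VEGF TME among its
current site and Moore neighbors, depositing a stalk segment behind it at
every move, and holds the sprout phenotype until arrival. Branching spawns
a new tip aimed at the second-highest-VEGF neighbor and resets the sprout
generation's age. Anastomosis: a tip entering a TME that already contains a
non-parent segment, or another tip, fuses into the network and retires as
stalk.

Vessel sensing and growth control (model choices, each forced by a failure
mode of the literal reading):

* Vessels sense VEGF as the *maximum over their own TME and its Moore
  neighbors* — vessels are near-perfect local VEGF sinks, so own-site
  sensing reads zero everywhere and no sprout would ever start.
* All angiogenic actions (stalk sprout-sourcing, tip sprouting and
  branching) require that sensed VEGF exceed the sprouting threshold;
  unstimulated vessels are quiescent. Without this gate the
  probability-matching action roulette keeps a 15–20 % angiogenic mass
  forever and the network either freezes or explodes depending on early
  exploration luck.
* Sprout sources obey lateral inhibition (no new sprout within one TME —
  200 µm, tumor capillary spacing — of an active tip), endothelial
  maturation (a segment must be 18 episodes old, the vessel-age policy
  timescale, before sourcing; observed networks load as mature), and a
  per-segment re-sprout cooldown of the same length.
* A tip that has arrived, idles, and senses no VEGF loses tip identity and
  reverts to stalk.

## Microscopic scale

Each cell carries bound-receptor fractions for EGFR (ligand TGFα) and TNFR
(ligand TNFα) evolving by first-order mass action
db/dt = k_on·L·(1−b) − k_off·b with defaults k_on = 1 µM⁻¹s⁻¹,
k_off = 10⁻³ s⁻¹ (config section `signaling`). The update uses the exact
exponential solution of this linear ODE over the episode — the sub-stepped
Euler scheme it replaces would need ~3×10⁶ sub-steps for stability at these
rates — and shares its Hill-1 fixed point b* = k_on·L/(k_on·L + k_off).
The policy layer consumes L·b as the cell's effective TGFα/TNFα signal.

## Policies, rewards and learning

Ten behavioral policies compare a state variable x with a threshold T
(oxygen 1.175, glucose 16/8, TNFα 0.6, TGFα 0.6, VEGF 0.3, vessel age 18,
division counter 50, proliferation delay 4, oxygen-deficiency 67) and
favor actions on each side. Counters are compared raw. Concentrations are
mapped to the policy scale by per-material divisors chosen so the normal
tissue concentration lands at twice the rule threshold; VEGF, which has no
tabulated normal concentration, uses a divisor of 10 so its threshold
(3 µM raw) separates the per-episode VEGF output of a normoxic TME at
capacity (1 µM) from a hypoxic or necrotic one (8–16 µM). The crowding
rule has no printed threshold; half the carrying capacity is used,
one-sided. The three-zone glucose rule scores proliferation/migration by
tanh(x−16), necrosis by tanh(8−x), and quiescence by the band distance
tanh(min(x−8, 16−x)).

The reward for a transition is the sum over applicable rules of tanh(x−T)
for actions favored above the threshold and tanh(T−x) below; actions a rule
does not mention contribute zero. Q-values live in tabular models indexed
by the bit-vector of threshold comparisons (8 bits → 256 states for cells,
2 bits for vessels) — the minimal faithful discretization of the rule
variables — and update on-policy:
Q(s,a) ← (1−α)Q(s,a) + α[r + γ·Q(s′,a′)] with α = 0.1, γ = 0.9. Shared
tables receive the population's updates in a seeded random order through a
closed-form batch formula that reproduces the sequential result exactly.
Actions are drawn by roulette proportional to the state's Q-values
(shifted by −min+ε only when negative values are present). The reward
r_{t+1} used for the (s_t, a_t) update scores the previous action against
the state it produced.

Training runs `n_repetitions` of the full episode loop (50 at full scale,
5 on the desk preset), carrying the Q-tables and the experience dataset
across repetitions; the mean reward per repetition rises steeply after the
cold-start repetition and then plateaus.

## Experience dataset and the phenotype classifier

Each training episode a seeded subsample of transitions (default 40 cell
and 10 vessel records per episode, ~150k cell records over a desk training)
is appended to the experience dataset; the admission mechanism compares the
transition reward against a configurable threshold, unset by default so
the dataset mirrors the learned policy's action mixture. Records hold the
previous/current concentrations, TME occupancy, counters, Q-values,
phenotypes and modal neighbor phenotypes, with the chosen phenotype as the
label.

The test-phase classifier is a fully connected feedforward network with
hidden layers of 35 and 25 logistic units and a softmax output over the
agent class's phenotypes (5 for cells, 3 for vessels; two separate
models), trained with cross-entropy for up to 200 epochs at learning rate
0.01 on the [0,1]-rescaled attributes (fit subsampled to 50k records).
Q-value attributes are recorded but excluded from the inputs — they do not
exist in the test phase. During the test-phase simulation each agent's
next phenotype is *sampled* from the predicted class distribution: the
network distills a stochastic policy, and taking the argmax instead
collapses every nutrient-rich cell onto deterministic proliferation or
migration, saturating the domain and erasing the quiescent/necrotic
structure the model is supposed to reproduce. The single-record
`predict_phenotype` operation returns the argmax class with fixed-order
tie-breaking.

## Synthetic inputs

The phantom generator emulates the segmented microvascular input: a
branching random walk (default 3 trunks entering from the image edges,
branch probability 0.04 per 8-pixel step, ±35° branch deviation) rendered
as bright ~220-intensity curves on a dark ~15-intensity background at
20 µm/pixel, with optional Gaussian noise. Walkers terminate rather than
pass within 3 pixels of a foreign vessel, so noise-free phantoms are
non-overlapping and the K-means → skeleton → graph round trip recovers the
generating topology exactly. What the phantom does not emulate: contrast
heterogeneity along vessels, radius variation, imaging point-spread and
reconstruction artifacts of real microCT angiography — so passing
round-trip tests demonstrate the extraction pipeline's correctness, not
segmentation robustness on real data. The pipeline uses separate phantom
draws as the two longitudinal "subjects" (training and test inputs) and
their second time points (assimilated at episode 336 by set-union with
duplicate collapse within one TME length).

## Validation surface

Per-episode census series feed three closed-form growth models (time in
hours): Gompertz cell count (n₀, α_n, β_n) = (10⁶, 0.09, 0.01), rescaled
to the run's initial count; logistic mean vessel length
(g₀, α_g, β_g, t_½) = (0, 58.5³, 62, 360); exponential branch count
(b₀, α_b, β_b) = (0, 0.05, 16). The printed branch parameters overflow
when evaluated in hours over 720 h, so the validation path fits the
exponential form to the simulated series by least squares and reports the
agreement of the fit; the literal evaluation remains available and raises
a descriptive overflow error. "Mean vessel length" is total network length
divided by the number of node-to-node paths. Tumor area is the convex-hull
area of TMEs holding at least one viable (non-necrotic) cell. Doubling
time comes from a log-linear least-squares fit of cell count against time;
series agreement is squared Pearson correlation with its t-distribution
p-value.

## Problem sizes and reproducibility

The desk preset (0.5 cm domain = 625 TMEs, 10⁴ cells, 5 training
repetitions, 720 episodes per phase) is the configuration used by the test
suite and `scripts/acceptance.py`; all rates are per-cell and per-episode,
so growth statistics are comparable with the full-scale setting. One full
desk pipeline (training, classifier fit, test phase, validation) runs in a
few minutes on one CPU. All randomness flows from a single root seed
through named child streams (seeding, agent order, action selection,
placement, phantom, classifier initialization); identical seeds give
byte-identical census output.

## Known limitations

* The carrying capacity (100) makes the full-scale initial condition
  (10⁶ cells) exactly fill the 10⁴-TME domain; population growth at full
  scale therefore requires a larger capacity or domain. The desk preset
  starts at 16 % occupancy.
* The tabulated TNFα maximum concentration (10⁻⁶ µM) lies below its normal
  concentration (6×10⁻³ µM); the literal clamp pins the TNFα field at the
  maximum, so the TNFα policy rule effectively always favors quiescence.
* The learned phenotype mixture proliferates ~3–4 % of cell-episodes at
  desk scale, giving a doubling time near 25 d rather than the two weeks
  typical of this xenograft model; cell-count growth is cleanly exponential
  but slower than the reference. A non-saturating exponential can correlate
  with the saturating Gompertz reference at R² ≈ 0.79 at best over the
  30-day window.
* Necrotic cells persist as inert agents and keep their census weight;
  tumor shrinkage cannot occur.
* The supplementary receptor-pathway equations are represented by the
  two-parameter mass-action surrogate described above; any monotone
  saturating transduction preserves the qualitative coupling the policies
  consume.
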