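# Methods

## Scope and data model

`rrmscan` analyses coordinate trajectories of an RRM–ssRNA complex whose
binding pocket is read out by a small, fixed set of atoms: the Trp215(CE3)–
Phe230(CG) aromatic clamp, the Cys231 backbone (O acceptor and N–H donor),
the Val228 backbone O, the Lys219/Lys232 side-chain amines, and per RNA
residue the base atoms N3 (with H3 on uridine), O2 and O4. The reference
trajectory dialect is multi-model PDB over a fixed topology; binary formats
(DCD/XTC) are read through an MDAnalysis adapter behind the same frame
contract. Parsing is strict — alternate locations, insertion codes and
duplicate atom identities are rejected rather than filtered — because the
classification criteria are atom-identity-critical. Residue numbering is
1-based as in the source file; internal atom indexing is 0-based; conversions
happen only at the I/O boundary. The PDB dialect carries no time stamps, so
frame time is `frame_index × frame_interval`, with the interval a
configuration key (default 1 ns).

## Frame classification

A hydrogen bond is present when the donor–acceptor heavy-atom distance is at
most `d_max` = 3.5 Å **and** the donor–H–acceptor angle, measured at the
hydrogen, is at least `theta_min` = 135°. Both cutoffs are inclusive: the
criteria are stated as thresholds without inclusivity, and inclusive bounds
make boundary geometries classify deterministically. The angle is taken at
the hydrogen vertex, the standard near-linear H-bond convention for the
135–180° range. No donor/acceptor chemistry is inferred; the pocket
specification names every donor, hydrogen and acceptor explicitly.

Classification of a frame proceeds in a fixed rule order:

1. **Deep occupant.** Every RNA residue *i* is scored by the number of its
   present recognition bonds {N3ᵢ–H···Cys231(O), Cys231(N)–H···O2ᵢ}. The
   highest count wins; ties break to the smallest N3ᵢ–Cys231(O) distance. If
   no residue has either bond the frame is `UNBOUND` (`[]`).
2. **Partner.** A second residue *j* with a present N3ⱼ–H···Cys231(O) bond
   (the bifurcated contact) makes the frame `VERTICAL`, with the partner
   permitted upstream or downstream; otherwise a strictly downstream residue
   with a present N3–H···Val228(O) bond makes it `HORIZONTAL`. Nonconsecutive
   pairs are allowed but flagged.
3. **Clamp check.** The Trp215(CE3)–Phe230(CG) distance against the 9.0 Å
   threshold (narrow = one occupant, wide = two) is a secondary consistency
   check only: frames whose clamp disagrees with the H-bond call keep the
   call and are flagged low-confidence. The H-bond pattern is primary because
   the two published criteria are not mutually consistent (the horizontal
   state widens the clamp by only ~0.5 Å on average, yet the automated
   9.0 Å split puts both two-occupant states above it), while the per-state
   bond signatures are unambiguous.
4. **Cytidine / hybrid.** Cytidine lacks the N3–H donor, so a C residue's
   participation in a slot is scored by the Cys231(N)–H···O2 bond plus
   heavy-atom proximity of its N3 to the slot's acceptor within `d_max`.
   This proximity rule is applied uniformly to the deep, vertical-partner
   and horizontal-partner slots — our own design choice, since how hybrid
   arrangements should be detected automatically is not prescribed; without
   it a cytidine partner would be undetectable. Any occupied state involving
   a cytidine is mode `HYBRID` (occupant detail retained in the label),
   collapsing the fine taxonomy of cytidine arrangements into one class.

Lys219/Lys232 contacts with the base O4 atoms are computed as auxiliary
per-frame features in the output table but never gate the mode call.

Labels follow the clamp notation `[ … ]` with `=` for vertical and `/` for
horizontal arrangements and the 5′-most occupant written first; `parse_label`
recovers mode and occupants, with the caveat that a vertical label does not
record which of its two occupants is deep (slot assignment is positional).

**Smoothing.** MD-scale flicker is suppressed by a centred odd-window
majority vote on labels (ties keep the raw label; windows clip at the track
edges) followed by absorption of runs shorter than `min_dwell` into the
longer adjacent run (ties favour the preceding run, leftmost short run
first, iterated to a fixed point). Relabelled frames copy the state of the
nearest raw frame with the winning label, so smoothing never introduces a
state absent from the raw track. Defaults are window 1 and `min_dwell` 1
(off); the published occupancy graphs for this system were produced by
manual annotation, so any smoothing here is an explicit, documented choice
rather than a reproduction of judgment calls.

## Transition counting

A transition is **any change of the occupant residue-number multiset**
between consecutive frames; mode-only changes (e.g. vertical ↔ horizontal
re-arrangements of the same two residues, or confidence reflags) are not
transitions. Direction is the sign of the change of the mean occupant
register: increase = 3′, decrease = 5′. Using the mean makes
`[U2] → [U2=U3]` a 3′ event and `[U2=U3] → [U2]` a 5′ event, the only
reading under which a track that starts in a two-occupant state accrues
balanced counts on unbiased dynamics. Transitions into the empty pocket are
`unbind` and out of it `rebind` (neither directional); a rebind whose
occupant set differs from the last bound state is additionally a `jump`
whose direction is computed across the unbound gap. Dwell statistics are
run-length encodings by label and by mode (each frame contributes one frame
interval, so totals conserve the track duration exactly), and occupancy
intervals are maximal constant-label runs as half-open `[t_start, t_end)`
intervals tiling the track.

## Kinetic sliding model

States: `S(i)` (single, register *i*), `V(i, i±1)` (vertical toward either
neighbour, distinct states), `H(i, i+1)` (horizontal, downstream only,
matching the structural definition), `P` (pocket empty, RNA surface-attached)
and `D` (fully detached). `P` and `D` are separate because the two unbinding
depths are mechanistically distinct; both render as `[]` in trajectory space.
Channels and rate constants (all per μs):

| channel | move | default |
|---|---|---|
| `k_open_v` | S(i) → V(i, i±1), per side | 2.0 |
| `k_open_h` | S(i) → H(i, i+1) | 2.0 |
| `k_close_keep` | V/H → S retaining the original register | 2.0 |
| `k_close_shift` | V/H → S shifting to the partner register | 2.0 |
| `k_unbind` | S → P | 0.5 |
| `k_rebind` | P → S(r), split by a register kernel (default uniform) | 10.0 |
| `k_detach` | P → D | 0.2 |
| `k_attach` | D → P | 5.0 |

No measured rate constants exist for this system (state populations vary
strongly between replicate simulations), so the defaults are order-of-
magnitude placeholders chosen to put a completed one-register shift on the
~0.5 μs scale reported for the mechanism (intermediate lifetime
1/(k_close_keep + k_close_shift) = 0.25 μs, half of all closings shifting)
with unbinding an order of magnitude rarer and full detachment rarer still.
The model is a mechanism formalization, not a calibrated fit.

Cytidine enters as an acceptance multiplier `alpha_c ∈ [0, 1]` (default 0.1)
on the rate of every move that newly places a C into a pocket slot (opening
toward a C neighbour, rebinding onto a C register); uridine has acceptance 1.
This encodes "cytidine occupancy is unstable and transient" without adding a
distinct stable mode. `alpha_c = 0` removes C registers from the reachable
space exactly. Boundary registers simply lack out-of-range channels.

Simulation is the exact Gillespie algorithm with precompiled per-state
channel tables: exponential waiting time at the total exit rate, channel
chosen proportionally to rate. A master `numpy.random.SeedSequence` derives
per-replicate streams, so all stochastic outputs are bit-reproducible from
(seed, params, sequence). The default start state is `S` at the centre of the
leftmost longest uridine run (never a cytidine).

**Rate estimation** is the standard CTMC maximum-likelihood estimator per
transition class: rate = event count / multiplier-weighted exposure, where
the exposure weight per state is the class's summed channel multipliers
(α factors, kernel weights, channel multiplicity) obtained by rebuilding the
channel table with unit base rates. Confidence intervals are exact Poisson
(chi-square) intervals; zero-event classes get a one-sided interval and
zero-exposure classes are reported undefined.

**Mean first-passage times** to a target register set (a state is "arrived"
when any occupied register is in the set) are solved exactly from the linear
system `Q′ τ = −1` over the transient states. The solve is restricted to
states forward-reachable from the start; if any reachable state cannot reach
the target set, the passage time is infinite with positive probability and
`math.inf` is returned as the infinite flag.

**Scanning summaries** aggregate independent replicates: per-register
occupancy is attributed to the deep register of S/V/H states (so register
fractions plus the P/D fraction sum to one); a stall event is any entry into
a state whose occupied registers include a cytidine; and a replicate counts
as having located the longest U-stretch when its deep register first enters
the leftmost longest uridine run. Note the occupancy profile of the full
model is not register-symmetric even on poly(U): the horizontal intermediate
exists only downstream, so 3′ registers carry slightly more deep-state
exposure. The register-reversal symmetry test therefore uses the
vertical-only model (`k_open_h = 0`), and the simulated occupancy is also
checked against the exact stationary distribution of the generator.

The Lys232Ala phenotype — diffusion essentially abolished, register exchange
only through temporary dissociation — is emulated by setting
`k_open_v = k_open_h = 0`; the pipeline then reports no shift events and
only unbind/rebind jumps, which is asserted as a test.

## Synthetic data

The generator simulates the kinetic model, samples it at the frame interval,
and renders each frame from a per-mode geometry template: recognition bonds
at 2.9 Å / 165° (margins of 0.6 Å and 30° inside the criteria), clamp widths
8.3 / 9.4 / 9.2 Å for single / vertical / horizontal (chosen to respect the
9.0 Å automated split rather than the mutually inconsistent ~0.5 Å
horizontal widening), and non-occupying residues parked > 30 Å away. Each
mode's render satisfies exactly its own bond set and no other mode's
(asserted per template), so noise-free classification recovers the ground
truth at every frame by construction. Hybrid renders place the cytidine
without an N3 proton but with N3/O2 in contact range, matching the partial
contacts of hybrid arrangements.

Gaussian coordinate noise (σ per atom per axis) emulates thermal jitter
only. What the generator does **not** emulate: correlated atomic motion,
partial/distorted bond geometries near state boundaries, gradual transitions,
force-field physics, solvent, or the annotation ambiguity of real frames.
Passing round-trip tests therefore demonstrate that the classifier is an
exact inverse of the stated geometric signatures and degrades gracefully
under isotropic noise — not that it reproduces manual annotation of real MD
data. At σ = 0.15 Å a recognition bond flips with probability well under 1%
per frame (distance margin ≈ 2.9 noise SDs, angle margin ≈ 2.5), and
window-5 majority smoothing removes isolated flickers, which is why the
round-trip criterion of ≥ 95 % agreement is met with margin (measured
≈ 99.8 %).

## Numerical and design notes

* Inclusive cutoffs throughout; boundary tests are deterministic.
* Deep-slot ties break to the smallest N3–Cys231(O) distance; vote ties in
  smoothing keep the raw label; absorption ties favour the preceding run.
* The trajectory writer prints coordinates at PDB precision (3 decimals);
  round trips are exact to ±5×10⁻⁴ Å, far inside every geometric margin.
* All exposure/occupancy bookkeeping includes the final truncated dwell;
  dwell-time goodness-of-fit uses only completed dwells.
* The dwell-time exponentiality summary is the median KS p-value over five
  independent chains (10⁵ dwells total): a single KS p-value is uniform
  under the null and falls below any α at rate α, so the median gives a
  stable summary of the same hypothesis.
* Problem sizes in the validation suite (10⁴-frame round trips, 10³ random
  tracks of 10³ frames, 10⁵ dwell samples, ≥ 10⁴ events per rate class,
  10⁴ first-passage replicates on 3–5 register sequences) were chosen so the
  whole suite runs in about a minute on one CPU while keeping Monte-Carlo
  standard errors an order of magnitude below the tolerances they check.
* Rate-recovery validation uses a balanced rate set (all eight classes at
  comparable flux) so every class accrues ≥ 10⁴ events; with the mechanistic
  defaults, detachment events are deliberately rare and would dominate the
  required simulation length.

## Known limitations

* The classifier is a geometric oracle for the stated criteria; it does not
  reproduce the manual annotation judgment used for the published occupancy
  graphs, and frames where H-bond and clamp evidence disagree are resolved
  in favour of H-bonds by design.
* The kinetic model's rates are placeholders; only properties that are
  robust to the absolute rate scale (directional balance, exclusion,
  phenotypes, estimator consistency) should be read quantitatively.
* The rebinding kernel is uniform by default for lack of a stated kernel;
  real rebinding is likely local.
* Vertical states toward either neighbour are modelled, but nonconsecutive
  two-occupant arrangements (observed rarely in trajectories, and flagged by
  the classifier) have no kinetic-model counterpart.
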