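# rrmscan

Binding-pocket state annotation and sliding kinetics for RRM–poly(U)
molecular-dynamics trajectories.

## The problem

The C-terminal RNA recognition motif (RRM) of the trypanosomatid editing
factor TbRGG2 binds uridine-rich single-stranded RNA through a *single*
binding pocket: one uridine stacks between the Trp215 and Phe230 aromatic
side chains and is read out by two backbone hydrogen bonds,
N3–H···Cys231(O) and Cys231(N)–H···O2. In microsecond MD simulations this
pocket is highly dynamic: a second nucleotide transiently joins the clamp
(the **vertical** state, with bifurcated H-bonding of both N3–H donors onto
Cys231(O)) or docks on the adjacent surface patch read out by Val228(O) (the
**horizontal** state). These two-occupant intermediates let the protein slide
its binding register along the RNA one nucleotide at a time, while excursions
through a pocket-empty state let it "jump over and skip" registers. Cytidine,
which lacks the N3–H donor, cannot satisfy the recognition bonds and stalls
or evicts the complex — the structural basis of uridine selectivity.

`rrmscan` packages three things for anyone analysing this kind of trajectory
or mechanism:

1. **A geometric state classifier** (`state_classifier`). Each frame is
   assigned a mode — `SINGLE`, `VERTICAL`, `HORIZONTAL`, `HYBRID`
   (cytidine-involving), `UNBOUND` — from explicit hydrogen-bond criteria
   (donor–acceptor heavy-atom distance ≤ 3.5 Å and donor–H–acceptor angle
   ≥ 135°, both inclusive) plus the Trp215(CE3)–Phe230(CG) clamp width
   against a 9.0 Å one-vs-two-occupant threshold (used as a confidence flag,
   not a gate). States carry symbolic labels: `[U2]`, `[U1=U2]`, `[U2/U3]`,
   `[]`.
2. **Transition analytics** (`transitions`). A transition is any change of
   the occupant residue multiset between frames; direction is 5′ or 3′ by
   the change of the mean occupant register. Unbind/rebind events are
   bucketed separately, and rebinds that land on a different register are
   additionally scored as directional jumps. Dwell statistics and occupancy
   intervals round out the per-trajectory report.
3. **A kinetic sliding model** (`sliding_model`). A continuous-time Markov
   chain over states S(i), V(i, i±1), H(i, i+1), P (pocket-empty,
   surface-attached) and D (detached), simulated exactly by the Gillespie
   algorithm. Cytidine selectivity is a rate multiplier α(C) ∈ [0, 1] on
   every move that places a C in the pocket. The module also computes exact
   mean first-passage times to a register set (linear solve over the finite
   state space), maximum-likelihood rate recovery from simulated tracks with
   exact Poisson confidence intervals, and replicate-averaged scanning
   summaries (per-register occupancy, stalls at U|C boundaries, probability
   of locating the longest U-stretch).

A synthetic-trajectory generator (`synthetic_data`) ties the layers together:
it simulates the kinetic model, renders every saved frame as pseudo-atom
coordinates that realize exactly the generating state's H-bond/clamp
signature (plus optional Gaussian coordinate noise), and keeps the ground
truth, so the entire classify → count → estimate pipeline is testable without
running any molecular dynamics.

## Worked example

Generate a 5 000-frame synthetic trajectory of a poly(U) pentamer (frames
2 ns apart, exact geometric signatures), annotate it from the PDB alone, and
count register transitions:

```sh
rrmscan synth --seq UUUUU --n-frames 5000 --frame-interval-ns 2 --seed 11 --out-dir synth
rrmscan annotate --topology synth/trajectory.pdb --trajectory synth/trajectory.pdb \
                 --pocket-config synth/pocket.cfg --window 5 --out-dir annot
rrmscan transitions --track annot/state_track.tsv --name demo --out-dir trans
```

The last command prints

```
5' 25  3' 23  unbind 2  rebind 2  jump 2
```

and `trans/summary.tsv` holds the same row in the transition-table schema:

```
track  start_label  n_5prime  n_3prime  n_unbind  n_rebind  n_jump  length_us
demo   [U3]         25        23        2         2         2       10.0
```

Read: starting from the single state `[U3]`, the 10 μs track shows 25
upstream (5′) and 23 downstream (3′) register transitions — unbiased
diffusion — plus two excursions through the empty pocket, both of which
rebound at a different register (jumps). `annot/state_track.tsv` is the
per-frame occupancy track (`frame, time_ns, mode, label, …`) and
`trans/dwell_by_mode.tsv` shows the single state and the two-occupant
intermediates exchanging on the sub-μs scale (mean dwells ≈ 0.16–0.26 μs
here).

Library use mirrors the CLI:

```python
from rrmscan import SlidingParams, simulate, mfpt, ModelState

params = SlidingParams(alpha_c=0.0)          # hard cytidine exclusion
print(mfpt(params, "UUCUU", ModelState("S", 1), {5}))  # finite: unbinding bridges the C
```

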