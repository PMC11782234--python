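# Methods

## Model

Each of the 32 cells of the conduction network is a two-variable
Aliev–Panfilov unit,

    dV/dt = c [ k V (V − a1)(1 − V) − r V ] + I_coupl + I_stim
    dr/dt = c ε(V, r) [ −r − k V (V − a2 − 1) ],   ε = ε0 + r μ1*/(V + μ2*),

integrated in dimensionless model time and converted to milliseconds by
a single global `time_scale` (ms per model time unit) fixed by
calibration.  `V = 0` is an equilibrium of every cell — including
pacemakers, whose rest state is unstable but stationary — so fresh
simulations start pacemaker cells at `V = 0.02` and discard a 2,000 ms
settling pre-roll before any protocol; the pacemaker phase is then set
by the dynamics, not by the initial condition.

The network is a chain SN1–SN2–PS1–PS2–AM1–AM2–AM3 that splits at AM3
into FP1..FP8 and SP1..SP10, rejoins at PB1 and continues into
HB1..HB6.  Links are directed anterogradely; each carries a diffusion
coefficient `d` and an asymmetry coefficient `β` (β < 1 favours
anterograde conduction).  The coupling current on a branched cell is
the per-link sum `Σ d(V_up − βV) + Σ d(−V + βV_down)`, which reduces to
the standard asymmetric chain formula on unbranched runs.

Autonomic tone enters through one coefficient γ applied uniformly to
cells SN through PB (`μ1* = μ1/γ, μ2* = μ2 γ`); His-bundle cells are
outside autonomic control (γ ≡ 1).  γ schedules are piecewise constant;
the integrator restarts at every γ step and stimulus edge so that
discontinuities always fall on segment boundaries.

## Parameters

Per-segment base values (packaged as `avnode/data/cells_base.csv` and
`links_base.csv`; all dimensionless, `c` per model time unit):

| segment | a1 | a2 | k | c | ε0 | μ1 | μ2 | role |
|---|---|---|---|---|---|---|---|---|
| SN | −0.0897 (calibrated) | 0.2 | 8 | 1.0 | 0.0075 | 0.01 | 0.2 | primary pacemaker |
| PS | 0.06 | 0.1 | 8 | 0.5 | 0.007 | 0.3 | 0.3 | sinoatrial transition |
| AM | 0.08 | 0.1 | 8 | 0.55 | 0.007 | 0.3 | 0.3 | atrial muscle |
| FP | 0.10 | 0.1 | 8 | 0.5 | 0.006 | 0.075 | 0.3 | fast pathway: fast conduction, long refractoriness |
| SP | 0.07 | 0.1 | 8 | 0.6 | 0.008 | 0.15 | 0.3 | slow pathway: slow decremental conduction, short refractoriness |
| PB | 0.13 | 0.1 | 8 | 0.5 | 0.006 | 0.2 | 0.3 | penetrating bundle |
| HB | 0.13 | 0.1 | 8 | 0.55 | 0.006 | 0.35 | 0.3 | His bundle (no γ control) |

SP9 carries the latent AV-junctional pacemaker (a1 = −0.004): a barely
sub-threshold oscillator with ordinary SP conduction properties, silent
under sinus rhythm.  Couplings: atrial links d = 0.4–0.5; FP links
d = 0.25, β = 0.75; SP internal links d = 0.10, β = 0.9 with a weak
atrionodal entry (AM3→SP1, d = 0.08) and a strong distal junction
(SP10→PB1, d = 0.25).  The weak entry slows SP engagement and keeps the
refractory slow pathway from loading the atrial branch point; the
strong exit lets the decremental SP wavefront still source the compact
node.  The refractoriness gradient μ1(FP) < μ1(SP) < μ1(AM) realises
the ERP ordering atrium < SP < FP at each γ, and the small FP ε0 makes
the FP's refractory period the most γ-sensitive, as required of the
vagal response.

Variant 1 is the base.  Variant 2 scales d ×0.8 on the last three FP
links and ×1.6 on the last four SP links.  Variant 3 divides β of
SP10→PB1 by 5.  Variants 2 and 3 also shorten proximal-His
refractoriness (μ1 ×1.1 on HB1–HB3); larger reductions were found to
shorten the proximal-His action potential so much that premature
His-bundle beats no longer relay inward, defeating the edit's purpose
(easier His pacing).

## Calibration

Two printed anchors pin the free scales: the normal state (γ = 1.7)
beats at 360 ms (~166 bpm) and the sympathetic-burst state (γ = 0.57)
at 537 bpm.  The interval *ratio* between the two states depends on the
sinus cells' a1 (bisection inside a narrow physiological box, since the
coupled ratio is a shallow function of a1 and distant values degrade
burst-state conduction), and the absolute scale is a direct rescale of
`time_scale`.  The shipped model achieves 360.0 ms and 536.1 bpm.
Re-running `avnode calibrate` on the packaged tables reproduces the
shipped values; `--write` regenerates the fixture files.

## Protocols and measurement conventions

* Stimuli: 1 ms (atrial, at AM1) and 2 ms (His, at HB6) rectangular
  pulses at 1.3× the site threshold.  The threshold is found by
  bisection (1% tolerance) on a diastolic test pulse and requires a
  *propagated* response — an upstroke at the site within 10 ms plus a
  neighbouring-cell activation — because the pulse current alone can
  push V past the detection threshold without an action potential.
* Upstrokes: upward crossings of V = 0.5, localised by linear
  interpolation inside accepted solver steps, with a 25 ms per-cell
  re-arm interval.
* S1S2: nine basic beats, then one premature beat whose coupling
  interval decrements by 1 ms until block; conduction time between AM2
  and HB1 (anterograde) or HB1 and AM2 (retrograde).  The ERP is the
  longest coupling interval of the contiguous blocked run at the
  short-interval end of the scan; isolated blocked points near the
  spontaneous interval are collision noise with the running sinus, not
  refractoriness.  Responses are attributed to the test beat by
  comparison with a stimulus-free twin simulation (±3 ms).
* S1S1: ten beats per pacing interval, conduction delay of the last
  beat between AM3 and PB1, 1:1 required over the last five beats.
  Each point is re-run with initial-delay offsets {0, 37, 81} ms and
  flagged unstable when the delays spread by more than 2 ms.
* Basic trains run at the spontaneous interval minus a small overdrive
  margin (max(8 ms, 2.5%)): the sinus node is never reset-suppressed in
  this model and its post-excitation cycle is slightly shorter than its
  unperturbed period, so pacing at exactly the sinus interval loses the
  phase race.  The first S1 is phase-locked within the spontaneous
  cycle, screening a few candidate phases for one whose train actually
  traverses the node (an unlucky phase locks into a permanent
  mid-pathway collision with the spontaneous rhythm).
* ERPs that lie below the paced chain's own capture floor are reported
  as NaN with the shortest conducted interval kept as an upper bound.
  With the shipped tables this affects the anterograde SP ERP at
  γ = 0.8 and occasionally the retrograde SP ERP near γ = 1.2.

## Reentry analysis

Ladder diagrams group activation events into per-pathway wavefronts
(events of adjacent cells within 40 ms are one front); direction is the
sign of the activation-time slope along the cell order, a rise-and-fall
profile marks a collision/annihilation, and un-groupable events are
counted as ambiguous rather than classified.  A reentrant cycle is a
retrograde front in one AV pathway paired with an anterograde front in
the other; the anterograde limb names the form (SP ⇒ slow-fast, FP ⇒
fast-slow).  Up to 5 cycles is an echo; more cycles persisting to the
end of the window (the next γ change) is sustained tachycardia.

Sustainability is assessed as a fixed point: the S1S1 conduction times
of the two limbs (measured on the post-ablation preparations) are
summed on the common pacing-interval grid and intersected with the
identity line, interpolating linearly between the 1 ms grid points; a
crossing inside either limb's unstable region is marked unstable.

## Scaled problem sizes

All shipped measurements run on the 32-cell network.  The test suite
uses settling pre-rolls of 2,000 ms, observation windows of 2.5–3 s per
induction attempt, S1S1 scans truncated at 100–140 ms pacing intervals,
and outcome grids scanned at 4–6 ms premature-timing steps; these sizes
keep the full suite in a few minutes on one CPU while leaving every
measured quantity converged to well below its assertion tolerance
(halving the solver tolerances moves activation times by < 0.05 ms).

## What the calibrated model does and does not reproduce

Reproduced: the two rate anchors; clean 1:1 conduction over
γ ∈ [0.8, 2.0] with FP-first activation of the penetrating bundle and
mid-SP collision of the two wavefronts each beat; decremental SP
conduction with a steep restitution near its ERP; the ERP orderings
aERP_SP < aERP_FP at every γ with near-parity of the retrograde ERPs at
strong sympathetic tone; monotone lengthening of ERPs and sinus
interval with γ, with the FP responding more strongly than the SP; a
widening induction window under vagal tone; single-to-few-cycle
reentrant echo beats — slow-fast with premature atrial beats from
γ ≈ 1.0 upward, fast-slow with premature His beats at vagal tone — whose
cycle lengths are shorter than the sinus interval (overdrive).

Not reproduced: *sustained* AVNRT.  In this parameter set the ring has
no steady slow-conduction regime at short cycle lengths: under
repetitive engagement the slow pathway either conducts briskly or
blocks, so the reentrant cycle length alternates and the ring blocks
within one to three cycles.  The fixed-point analysis agrees — the
summation curves stay below the identity line over the conducted range
at every γ, i.e. the absence of sustained reentry and the absence of a
stable fixed point are mutually consistent, which is the mechanism the
sustainability analysis is designed to expose.  Variant 3's retrograde
ERP inversion at sympathetic tone is likewise not attained: the
weakened SP10→PB drive blocks retrograde entry only at vagal tone,
where the distal SP recovers slowly.  The scenario grid consequently
matches the expected outcome table only where echoes stand in for
sustained forms (about half of the cells for variant 1, a third for
variants 2–3).

The γ = 0.57 burst state sits on a knife edge between full 1:1
conduction at 537 bpm and selective slow-pathway block; the shipped
calibration lands on the 1:1 side, so the junctional (burst-triggered)
induction path does not elicit reentry.

## Other limitations

A single γ cannot separate sympathetic from parasympathetic effects;
there is no heart-rate variability, no second slow pathway (and hence
no slow-slow reentry), and nothing below the His bundle.  The ladder
heuristics are tuned for the wavefront speeds of this network and the
per-segment parameters are a constructed set calibrated to two printed
anchors plus qualitative constraints, not a fit to cellular recordings.
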