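# avnode

A compact simulator of the rabbit atrioventricular (AV) node conduction
system with autonomic nervous system control, for computational cardiac
electrophysiologists studying AV-nodal reentrant tachycardia (AVNRT).

The conduction system — sinus node (SN), peripheral sinus cells (PS),
atrial muscle (AM), the fast (FP) and slow (SP) AV-nodal pathways,
penetrating bundle (PB) and His bundle (HB) — is a one-dimensional
branched network of 32 Aliev–Panfilov cells:

    dV/dt = c [ k V (V − a₁)(1 − V) − r V ] + I_coupl + I_stim
    dr/dt = c ε(V, r) [ −r − k V (V − a₂ − 1) ],   ε = ε₀ + r μ₁*/(V + μ₂*)

with asymmetric nearest-neighbour coupling
`Iᵢ = dᵢ₋₁(Vᵢ₋₁ − βᵢ₋₁Vᵢ) + dᵢ(−Vᵢ + βᵢVᵢ₊₁)`.  Cells with `a₁ < 0`
self-oscillate (the sinus pacemaker and a latent AV-junctional pacemaker
in the distal slow pathway).  A single autonomic coefficient γ rescales
the refractoriness parameters of every cell from SN through PB,

    μ₁* = μ₁/γ,    μ₂* = μ₂·γ,

so that small γ (sympathetic dominance) shortens refractory periods and
speeds the pacemakers, while large γ (vagal dominance) does the
opposite.  The FP/SP ring is the substrate for reentry: typical
slow-fast AVNRT conducts down the SP and back up the FP, the atypical
fast-slow form the reverse.

On top of the network the package provides the measurement machinery of
an electrophysiology lab: S1S2 and S1S1 extrastimulus protocols,
effective refractory periods (ERPs) and conduction curves per pathway
and direction (including post-ablation preparations), Lewis ladder
diagrams, reentry episode classification (slow-fast / fast-slow,
echo / sustained), and a fixed-point sustainability analysis in which a
reentrant cycle length CL is self-consistent when the anterograde plus
retrograde limb conduction times at pacing interval CL equal CL (the
crossing of the summation curve with the identity line).

## Worked example

```python
import avnode

topo = avnode.build_variant(1)          # calibrated 32-cell network

# spontaneous rhythm under two autonomic states
print(round(avnode.sinus_interval(topo, 1.7), 1))   # 360.0  (ms, normal state)
print(round(avnode.sinus_rate(topo, 0.57), 1))      # 536.1  (bpm, sympathetic burst)

# slow-pathway ERP by S1S2 stimulation on the FP-ablated preparation
curve = avnode.run_s1s2(topo, 1.2, site="atrial", ablation="FP")
print(curve.erp)                                    # 96.0   (ms)

# a premature atrial beat in the induction window starts slow-fast reentry
from avnode.scenarios import induction_attempt
cls, *_ = induction_attempt(topo, 1.2, "PAC", 130.0)
print(cls.form, cls.persistence)                    # slow-fast echo
```

The first two numbers are the calibration anchors of the model: a
normal sinus rhythm of about 166 bpm (360 ms interval) at γ = 1.7 and a
burst rhythm of 537 bpm at γ = 0.57.  The ERP is the longest premature
coupling interval at which the test beat fails to traverse the node;
the slow pathway's ERP is below the fast pathway's at every autonomic
state, which is what opens the induction window for reentry.

A command line wraps the common workflows:

```
avnode simulate --variant 1 --protocol s1s2 --site atrial --gamma 1.0 --out run/
avnode simulate --variant 1 --scenario pac_onset --out run/
avnode sweep --erp --constraints --out sweep/
avnode calibrate
avnode render --variant 1 --gamma 1.2 --out ladder.svg
```

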