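# navmex

Markov modeling of the cardiac sodium channel NaV1.5 with an explicit
domain-III voltage-sensing domain (DIII-VSD), state-dependent mexiletine
block, and the multiscale pipeline built on top of it: voltage-clamp and
fluorometry protocol simulation, calibration to experimental summary
statistics, in silico design of a DIII-VSD "booster" co-drug, paced
ventricular-myocyte simulation with arrhythmia-trigger metrics, and 1D
fiber conduction-safety scans.

## Who this is for

Cardiac electrophysiology modelers studying why long-QT-3 mutation carriers
respond so differently to the class Ib antiarrhythmic mexiletine, and how a
hypothetical allosteric modulator ("booster") that biases the DIII-VSD
toward its activated position could rescue drug-resistant mutations such as
M1652R while the mutation R1626P remains intrinsically drug-sensitive.

## The model

The drug-free channel is a 16-state continuous-time Markov chain: three
DIII-VSD regimes — rested `R` (4 closed states), first-activated `A1`
(4 closed states), and fully activated `A2` holding the canonical 8-state
gating core `C3-C2-C1-O` with fast (`IF`), closed (`IC3`, `IC2`) and slow
(`IS`) inactivation. Opening and inactivation exist only in A2, so the
DIII-VSD guards both the pore and the local-anesthetic receptor. Mexiletine
binds exclusively from A2 states into eight non-conducting mirror states
with a fixed intrinsic affinity Kd = 156 uM for every construct; bound
inactivated states are further stabilized by a modulated-receptor factor,
and detailed balance then fixes every unbinding rate. All rates follow
k(V) = A exp(V/B); rates constrained by microscopic reversibility are
monomials of the others, so every cycle product closes exactly.

Simulated DIII-VSD fluorescence is the weighted occupancy
`(w1*A1 + A2 + bound) / total`. Construct differences in apparent
mexiletine affinity emerge from DIII-VSD position and kinetics alone:
R1626P holds its sensor up at rest (fast rested-state association, strong
interpulse retention), M1652R sits sensor-down and sheds block between
pulses.

The myocyte couples this channel into a ten Tusscher-Panfilov-style human
ventricular epicardial host (the sodium current replaced by the Markov
model, ENa tracking intracellular Na+), and the fiber couples identical
myocytes through a monodomain cable. See `docs/methods.md` for the full
formulation, protocol dialects, calibration procedure and limitations.

## Worked example

```python
from navmex.params import load_construct
from navmex import protocols as pr
from navmex.myocyte import CellConfig, run_paced_cell, steady_apd90

rp = load_construct("R1626P")         # calibrated mexiletine-sensitive mutant
mr = load_construct("M1652R")         # calibrated mexiletine-resistant mutant

print(pr.late_peak_ratio(rp))                                  # 1.011  (% late/peak current)
print(pr.run_tonic_block(rp, pr.CONC_GRID).fit["ic50"])        # 70.0   (uM)
print(pr.run_fluor_activation(rp, 0.0).fit["v_half"])          # -141.9 (mV)
f0 = pr.run_fluor_activation(mr, 0.0).fit["v_half"]            # -100.3 (mV)
f4 = pr.run_fluor_activation(mr, 4000.0).fit["v_half"]
print(f4 - f0)                                                 # -22.2  (mV, drug-induced shift)

trace = run_paced_cell(rp, CellConfig(bcl=2000.0, n_beats=100))
print(steady_apd90(trace))                                     # 1040   (ms, drug-free APD90)
```

The numbers printed above are the package's own recomputed values: the
late/persistent sodium current of the R1626P mutant is ~1% of peak, its
tonic-block IC50 is ~70 uM (an order of magnitude more sensitive than
M1652R), 4 mM mexiletine hyperpolarizes the M1652R DIII-VSD activation
curve by ~22 mV, and the R1626P myocyte paced at a bradycardic cycle length
of 2 s shows the grossly prolonged ~1-second action potentials that make
the mutation arrhythmogenic.

A command-line interface mirrors the library:

```sh
navmex protocol --construct R1626P --protocol tonic_block --out results/
navmex cell --construct M1652R --drug-um 10 --bcl 2000 --beats 100
navmex booster --out fits/
navmex fiber --construct WT --cells 30 --beats 2 --drug-um 10
```

Every CLI run writes a manifest (config hash, parameter-file hashes,
version) so outputs can be regenerated bit-identically.

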