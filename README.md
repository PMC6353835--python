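# larvalearn

Operant place-avoidance conditioning for larval zebrafish: a closed-loop
protocol engine, a virtual-larva simulator, a minimal dark-field fish
tracker, and the behavioral/statistical analysis that turns 10 Hz swim
tracks into learner classifications and memory-extinction curves.

## The assay

A single 7–10 dpf zebrafish larva swims in a 3 × 3 cm arena whose floor
is split by a horizontal midline: one half shows a *conditioned pattern*
(CS — e.g. pure black, a gray level, or a checkerboard), the other a
pure-gray background (grayscale 128). The experiment runs through four
phases — 10 min **baseline** (pattern side flips every 30–45 s), 20 min
**training**, 1 min **blackout**, 18 min **test** (pattern side flips
every 2 min). During training the loop is closed on the fish's own
behavior: after each pattern update the fish gets a 7 s decision window;
if it is then in the CS half it receives mild whole-arena electroshocks
(100 ms, 9 V) every 3 s until it leaves, and after 48 s of continuous
non-CS dwell the pattern re-randomizes. Control variants: *self-control*
(no shocks) and *unpaired* (shocks at random times, independent of
position).

Behavior is quantified per 2-min epoch (24 epochs; 5 baseline / 10
training / 9 test, blackout excluded):

- **positional index** `PI ∈ [0, 1]` — fraction of frames with the head
  in the non-CS half;
- **turning index** `TI = ½ + (s⁺ + s⁻) / (2(|s⁺| + |s⁻|))` — from
  escape turns (+1: approaching within twice a body length of the
  midline, turning > 15°, and retreating) and returns into the CS
  zone (−1);
- **visual contrast** — pattern grayscale (rounded RGB mean) minus the
  background's 128.

A fish is a **learner** when its recall-period PIs (test epochs before
the *extinction point*, the first epoch dropping below the baseline
mean) are significantly higher than its baseline PIs (Welch t-test,
recall ≥ 2 epochs). Memory length is the test time before extinction;
the group **extinction rate** is `(PI₁ − PI₂) / memory length` on the
learner-mean curve, in min⁻¹.

No public recordings exist for this assay, so the package includes a
stochastic **virtual larva** (bout-based swimming, contrast-scaled
phototaxis, shock-driven avoidance memory with saturating updates
`A ← A + η(1 − A)`, and test-phase exponential extinction
`A ← A·e^{−λt}`) whose sessions exercise the entire pipeline and whose
planted parameters the analysis must recover.

## Worked example

```bash
python examples/simulate_and_classify.py
```

simulates eight fish (four able to learn) against the red-black
checkerboard and prints:

```
fish     planted learner         p memory (s)       category
sim000      True    True   0.00098        720            mid
sim001      True    True    0.0044       1080  no_extinction
sim002      True    True     0.011        600            mid
sim003      True    True   0.00066        720            mid
sim004     False   False       nan          0  sub_threshold
sim005     False    True     0.024       1080  no_extinction
sim006     False   False       nan          0  sub_threshold
sim007     False   False      0.12        240          short

learners: 5/8 (62%)
group curve: first test-phase peak PI1 = 0.864, valley PI2 = 0.611
memory length 18 min -> extinction rate 1.41e-02 per minute
```

All four conditioned agents are recovered as learners (one control fish
is a false positive at α = 0.05, as expected at this rate); `720 s /
mid` means that fish's positional index stayed above its baseline for
six test epochs before extinguishing. Other examples:
`contrast_table.py` (pattern arithmetic), `protocol_walkthrough.py`
(closed-loop shock/update timing on a scripted trajectory),
`track_synthetic_frame.py` (render → track round trip).

A thin CLI wraps the same functions:

```bash
larvalearn simulate --protocol operant --pattern grayscale-0 --n-fish 12 --seed 1 --out sessions/
larvalearn analyze sessions/*.yaml --out summary.csv --curve-fig curves.png
larvalearn plot sessions/sim000.yaml --out trace.png
larvalearn track-demo --n-frames 20
```

Sessions are single YAML files (column-wise track plus pattern, shock
and phase records); `analyze` writes a per-fish CSV and prints the
group extinction statistics.

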