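# blisscreen

Analysis pipeline for preclinical drug-combination studies, built around
three stages that are usually stitched together ad hoc:

1. **Synergy scoring of viability screens.** Multi-dose combination
   matrices (diagonal fixed-ratio rays or full grids) across a cell-line
   panel are scored by the Bliss independence model. With fractional
   activity Fa = 1 − viability (40 % viability ⇒ Fa = 0.6), the expected
   activity of two non-interacting drugs is
   `Fa_exp = Fa1 + Fa2 − Fa1·Fa2`, and the **Excess over Bliss** at a dose
   pair is `EoB = (Fa1+2 − Fa_exp) × 100` percentage points. Each
   combination's score in a cell line is its maximal EoB; combinations are
   ranked panel-wide by the mean of per-line maxima.
2. **Transcriptomic drug-interaction classification.** For a four-arm
   expression experiment (vehicle / drug A / drug B / combination, log2
   scale), genes differentially expressed vs vehicle (moderated t,
   Benjamini–Hochberg) are tested for deviation of the combination from
   the additive expectation `E = A + B − V`; significant deviations are
   positive or negative interaction genes, and each gene gets a profile
   label encoding the rank order of its four condition means.
3. **Xenograft relative tumor volume (RTV).** Caliper diameters become
   volumes via `V = (min² × max)/2`, each mouse's RTV is final/baseline
   volume (baseline = last measurement before first dosing), RTV ≤ 1 marks
   tumor stabilization or shrinkage, and arms are compared with two-sided
   Mann–Whitney tests (exact by enumeration for combined n ≤ 16).

Because screens of this kind rarely ship their raw data, the package
includes first-class synthetic generators with known ground truth for all
three inputs (Hill-model dose-response with Bliss-null or injected-synergy
surfaces, expression matrices with planted interaction genes, exponential
tumor growth with arm-specific rate reductions), so every stage can be
validated end to end.

Intended users: scientists analyzing combination screens, and method
developers who need calibrated synthetic benchmarks for synergy or
interaction calling.

## Worked example

Simulate a 10-line screen with five drug pairs carrying injected EoB
deltas of 0/5/10/20/40 points plus realistic noise, score and rank it
(`analysis/01_simulate_inputs.py` then `analysis/02_score_and_rank.py`):

```
rank  pair          mean max EoB   injected delta
   1  pair4x             42.4             40
   2  pair3x             23.8             20
   3  pair2x             14.8             10
   4  pair1x              9.9              5
   5  pair0x              4.3              0
rank order matches injection order: True
```

The per-line maxima slightly exceed the injected delta (taking a maximum
over noisy wells biases upward — the Bliss-null pair still scores 4.3),
but the panel ranking recovers the injected ordering exactly.

The interaction classifier on a 2000-gene experiment with 250 planted
positive and 250 negative interaction genes
(`analysis/03_interaction_transcriptomics.py`):

```
DE genes: 876; interactions: 522 (59.6%) = 260 positive + 262 negative
planted-sign recovery: 100.0%; null miscall rate: 1.47%
```

And the RTV stage on a simulated four-arm xenograft study
(`analysis/04_xenograft_rtv.py`):

```
combination  median RTV   1.22   responders 0/8 (0.0%)
control      median RTV  19.03   responders 0/8 (0.0%)
...
combination vs control: p=0.0001554 [exact] ***
```

The same stages are available from the command line
(`blisscreen simulate|score|rank|deg|rtv|all`); `blisscreen all
--config cfg.yaml --outdir out/` chains them and writes a JSON manifest
whose artifacts are byte-identical across reruns of the same seeds.

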