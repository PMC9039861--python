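# plee — reproducible end-expiratory transpulmonary pressure extraction

Transpulmonary pressure, P_L = P_aw − P_es, is the distending pressure of
the lung: airway pressure minus oesophageal pressure, the latter measured
with a balloon catheter as a surrogate for pleural pressure.  Its
end-expiratory value (P_Lee) at a given set PEEP is a key quantity in
ventilation research, but it is usually read off the monitor by eye — a
clinician picks a handful of representative end-expiratory points on the
P_L(t) curve while mentally ignoring cardiac oscillations, oesophageal
contractions and surgical disturbance.  That is slow, uses a few samples
out of tens of thousands, and is prone to inter-observer bias.

This package extracts P_Lee from the raw monitor export instead, using
every representative sample:

1. **trim** — drop samples before the experiment start (`datastart` from
   the case report form) and, optionally, after its end;
2. **end-expiratory filter** — keep samples with airway pressure within
   ±1 cmH₂O of the set PEEP and flow within ±10 L/min of zero (both
   margins configurable, both bounds inclusive);
3. **Tukey's fences** — remove P_L values outside
   [Q1 − 1.5·IQR, Q3 + 1.5·IQR], discarding contractions, manipulation
   and other transients in a single pass;
4. **median** — report the median of the retained P_L values per
   (participant, set PEEP), a robust summary of the period of interest.

Around that core the package provides:

- `plee.fluxmed_io` — parser/writer for the FluxMed/FluxView raw signal
  dialect (tab-separated, `Sampling rate: 256 Hz` header, units row,
  decimal commas), the CRF table, and the one-folder-per-participant
  project layout;
- `plee.catheter_check` — occlusion-manoeuvre validation of catheter
  position (ΔP_es/ΔP_aw must lie in [0.8, 1.2]);
- `plee.cardiac_filter` — comb-notch removal of cardiac oscillations from
  P_es(t), with spectral heart-rate estimation when the rate was not
  recorded;
- `plee.plee_extraction` — the pipeline above, plus transpulmonary
  plateau pressure and driving pressure (P_Lplat − P_Lee) via the
  inspiratory-hold filter `P_aw > set PEEP + 2 cmH₂O`, and a batch driver
  over participants × PEEP levels;
- `plee.validation_stats` — Pearson correlation with Fisher-z CI and
  Bland–Altman bias/limits of agreement, for comparing the scripted
  extraction against manual readings;
- `plee.ventsim` — a single-compartment ventilator simulator
  (P_aw = PEEP + E·V + R·V̇, P_es = baseline + E_cw·V + cardiac + noise)
  that writes whole synthetic projects in the monitor dialect with known
  ground truth, so the entire pipeline is testable without recorded data.

## Worked example

Generate a synthetic 5-participant study (PEEP 15 → 10 → 5 cmH₂O, 7 min
per level at 256 Hz) and extract the medians:

```
$ plee simulate --n 5 --peep 15,10,5 --seed 42 --out demo
wrote demo: 5 participants, CRF CRF.csv, truth truth.csv

$ plee calc --project demo --crf demo/CRF.csv --peep 15,10,5 --out demo/results.csv
wrote demo/results.csv: 15 rows (0 failed)

$ head -4 demo/results.csv
id,setPEEP,medianPLee
Participant001,15,7.4
Participant001,10,2.4
Participant001,5,-2.6
```

Each row is the median end-expiratory transpulmonary pressure (cmH₂O) for
one participant at one set PEEP, rounded to one decimal.  For
Participant001 the simulator's ground truth is 7.5 / 2.5 / −2.5 cmH₂O
(set PEEP minus that participant's oesophageal baseline pressure), so the
extraction recovered each value to within 0.1 cmH₂O despite sensor noise
and a 2 cmH₂O cardiac oscillation on P_es.  `--audit` additionally writes
the per-stage sample counts (total → after trim → end-expiratory →
after outlier removal) for every row.

Other entry points: `plee occlusion` (catheter position check),
`plee defib` (cardiac-oscillation removal, writes a filtered copy in the
same dialect), `plee compare` (correlation + Bland–Altman report between
two result tables).

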