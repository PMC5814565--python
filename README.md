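# pulsebeta

Beat-by-beat estimation of peripheral arterial stiffness from
simultaneously recorded blood pressure and photoplethysmogram (PPG)
waveforms, with conversion of the stiffness index to an estimated
numeric-rating-scale pain score.

Peripheral arteries constrict rapidly under sympathetic drive, and
painful stimulation is a strong sympathetic activator.  The arterial
wall's *stiffness index* β therefore rises with pain, and — unlike the
raw PPG amplitude — can be separated from passive blood-pressure
effects by an explicit mechanical model of the wall.  `pulsebeta` is
aimed at physiological-signal researchers who want a transparent,
testable implementation of that model chain: per-heartbeat system
identification, quality gating, baseline normalization, and bounded
sigmoid mappings to stimulus level and pain score — plus a forward
simulator so every stage can be validated by parameter recovery without
any human data.

## Model

With the arterial strain taken proportional to the PPG
$P_l(t)$, blood pressure follows a log-linearized viscoelastic model

$$P_b(t) = \mu \ddot P_l(t) + \eta \dot P_l(t)
  + \exp\{\beta P_l(t) + P_{b\beta_0} + P_{b\beta nl}(P_l(t))\}$$

where $\mu$ (mmHg·s²/a.u.) is wall inertia, $\eta$ (mmHg·s/a.u.)
viscosity, $\beta$ (1/a.u.) the stiffness index, $P_{b\beta_0}$ a
standard-pressure exponent offset and $P_{b\beta nl}$ a venous term
(assumed constant within a beat).  Per heartbeat, anchored at the
R wave $t_0$:

1. **Step 1** — Maclaurin-linearize the exponential and fit
   $dP_b = \mu\, d\ddot P_l + \eta\, d\dot P_l + \beta_A\, dP_l$ by
   ordinary least squares on reference-differenced data
   ($dX(t) = X(t) - X(t_0)$).
2. **Step 2** — form the elastic residual
   $q(t) = P_b - \mu\ddot P_l - \eta\dot P_l$ and regress
   $\ln\{q(t)/q(t_0)\}$ on $dP_l(t)$ through the origin, using only
   samples above the beat's mean pressure with $q>0$; the slope is β.
   By default the two steps are then iterated to a fixed point, which
   removes the linearization bias of step 1 (see `docs/methods.md`).

Each beat gets a reconstruction $R^2$; beats with $R^2 < 0.9$ are
rejected.  β is normalized by its maximum over a no-stimulation
baseline window ($\beta_n$), and two bounded sigmoids relate $\beta_n$,
stimulus level $S$ and pain:

$$\mathrm{eNRS} = \frac{20}{1+\exp(a(\beta_n-1)^{-b})} \;(\beta_n>1),
\qquad 0 \;(\beta_n \le 1)$$

$$e\beta_n(S) = \frac{10}{1+\exp(a S^{-b})} + 1 .$$

## Worked example

Run the full chain on a synthetic 448 s stimulation block (7 trials of
20 s rest + 24 s electrocutaneous stimulation + 20 s evaluation, levels
1.5/1.0/0.5/0/0.5/1.0/1.5 × standard, stiffness coupled to the level by
a sigmoid with a=3, b=2):

```sh
pulsebeta run --seed 7 --outdir out
```

which prints

```json
{
  "n_accepted": 522,
  "n_beats": 522,
  "n_valid": 522,
  "recovery": {
    "beta_median_abs_rel_err": 0.012777443291066115,
    "n_scored": 521
  },
  "stimulus_fit": {
    "a": 3.117868705805351,
    "b": 1.9834529543235353,
    "n": 4,
    "r2": 0.9991251312448016
  },
  "warnings": []
}
```

All 522 detected beats pass the R² ≥ 0.9 gate; the estimated β tracks
the simulator's scheduled β with 1.3% median absolute relative error;
and fitting the stimulus sigmoid to the mean β_n per level recovers the
coupling (a, b) = (3.12, 1.98) against the ground truth (3, 2) with
R² = 0.999.  `out/` contains the record (`record.csv`), ground truth
(`truth.csv`), per-beat estimates (`beats.csv`), the normalized series
(`series.csv`), per-trial means (`trials.csv`), the fitted map
(`maps.json`) and an audit log of every applied setting
(`run_log.json`).

The pieces are also available separately:

```sh
pulsebeta synth --seed 1 --out rec.csv --truth truth.csv
pulsebeta estimate rec.csv --out beats.csv
pulsebeta map-pain beats.csv --baseline 222:246 --out maps.json
```

or as library functions (`synthesize_record`, `detect_r_peaks`,
`segment_beats`, `estimate_record`, `normalize_beta`, `fit_sigmoid`,
...).

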