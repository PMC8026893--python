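# nlrpipe

Can passively heard tone sequences leave a readable trace of their
*probability distribution* in the EEG?  `nlrpipe` is a simulation and
analysis pipeline around the **Neural Likelihood Response (NLR)** — a
single-trial measure defined as the within-trial amplitude difference
between the P2 and N1 latencies of the averaged mismatch response (MMR):

    NLR_i = V_i(t_P2) − V_i(t_N1)

where the latencies are identified once per participant on the averaged
deviant-minus-frequent ROI waveform, and `V_i` is trial *i*'s own
fronto-central ROI trace.  If the brain builds a probability distribution
of the experienced tones, the NLR should (1) **index** the unlikelihood of
each tone (mixed model `NLR ~ 1 + |z| + (1 | subject)` with a positive |z|
slope), (2) **correspond** in shape to the experienced distribution (a
normal curve `a + normpdf(z, b, c)·d` fits the binned negative-normalized
NLR better than a square/step approximation), and (3) **flexibly** follow a
bimodal distribution (an order-4 polynomial over five frequency intervals
beats order-2, with negative quadratic and quartic terms — a two-peaked
shape).

The package is aimed at EEG methodologists who want to stress-test this
single-trial analysis: it generates the tone designs, simulates multichannel
recordings with surprisal-scaled N1/P2 responses under a *known* generating
distribution, runs the full preprocessing and statistical battery, and
measures how reliably the programmed ground truth is recovered.

## Modules

| module | role |
| --- | --- |
| `nlrpipe.stimgen` | tone sequences: 500 reference + 4×30 interleaved tail tones, or 500-tone bimodal sets built by iterative pruning; KDE summaries; WAV rendering |
| `nlrpipe.synth_eeg` | continuous multichannel EEG with N1/P2 templates scaled by tone surprisal (or negated density), pink/white/drift noise, blink artifacts |
| `nlrpipe.preprocess` | 0.3–30 Hz zero-phase band-pass → −300…1000 ms epochs → baseline → 100 Hz resampling → average reference → 100 μV channel-trial rejection → 11-channel ROI mean |
| `nlrpipe.mmr` | averaged MMR, automated N1/P2 peak snapping, SNR-based participant QC |
| `nlrpipe.nlr` | single-trial NLR, frequency z-scores, negative normalization, 13-center z-binning, five-interval selection |
| `nlrpipe.stats` | random-intercept mixed models, normal-vs-square trust-region curve fits with paired comparison, order-2 vs order-4 orthogonal polynomial comparison |
| `nlrpipe.pipeline` | end-to-end runs, deterministic JSON reports, parameter-recovery sweeps |

## Worked example

```python
from nlrpipe.pipeline import RunConfig, run_exp1

report = run_exp1(RunConfig(experiment="exp1", n_subjects=8, seed=3, n_channels=12))
tails = report["indexing"]["tails"]
corr = report["correspondence"]["adj_r2"]
print(f"tail |z| slope: {tails['estimates'][1]:.3f} uV per SD, p = {tails['p'][1]:.2e}")
print(f"adjusted r2, normal {corr['mean_normal']:.2f} vs square {corr['mean_square']:.2f}")
```

prints (seed 3, 8 simulated subjects):

```
tail |z| slope: 0.217 uV per SD, p = 7.09e-05
adjusted r2, normal 0.78 vs square 0.89
```

The tail-set slope is positive and highly significant: simulated brain
responses grow with tone unlikelihood even though the four tail sets are
presented equally often — the indexing signature.  (Under the default
log-likelihood link the flexible square curve can edge out the normal
curve on the bins; shape-level correspondence is probed with the `density`
link, see `docs/methods.md`.)  A bimodal run:

```python
from nlrpipe.pipeline import run_exp2
from nlrpipe.synth_eeg import PopulationParams

cfg = RunConfig(experiment="exp2", n_subjects=6, seed=3, n_channels=12,
                population=PopulationParams(link="density"))
fx = run_exp2(cfg)["flexibility"]
print(fx["winner_order"], round(fx["fits"]["4"]["terms"]["quartic"]["coef"], 2))
```

```
4 -1.53
```

order 4 wins by AIC with a significantly negative quartic term: the
response over the five intervals has two peaks, mirroring the bimodal
stimulus distribution.

A thin CLI wraps the same functions:

```bash
nlr simulate-stim --experiment exp2 --seed 1 --out seq.tsv
nlr run --config run.toml --out report.json
nlr recover --gains 0.0,1.5 --replicates 20 --out recovery.csv
```

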