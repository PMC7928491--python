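# singlechan

Single-channel patch-clamp kinetics in Python: simulation of gating
records from aggregated Markov models, idealization, dwell-time mixture
inference, burst analysis, and mutant-vs-wildtype fold-change
statistics.

## Who this is for

Ion-channel electrophysiologists analysing cell-attached single-channel
records — in the motivating use case, α4β2 nicotinic acetylcholine
receptors whose high-sensitivity (HS, (α4β2)₂β2) and low-sensitivity
(LS, (α4β2)₂α4) isoforms differ in unitary amplitude classes and gating
kinetics, and whose epilepsy-associated point mutants are characterised
by fold changes of each kinetic property relative to wildtype. The same
machinery applies to any channel whose gating is an aggregated
continuous-time Markov chain.

## The model

A channel is a continuous-time Markov chain with rate matrix **Q**
(s⁻¹); each state carries a conductance class (closed at 0 pA, one or
more open classes with unitary amplitudes in pA). Only the class is
observable. Sojourn times in the closed (or open) aggregate follow a
mixture of exponentials obtained from the spectral expansion of the
class sub-generator **Q**<sub>AA</sub>:

f(t) = Σᵢ aᵢ (1/τᵢ) e^(−t/τᵢ),  τᵢ = −1/λᵢ(**Q**<sub>AA</sub>),

with areas aᵢ given by the entry-probability-weighted spectral weights.
The analysis chain mirrors standard single-channel practice:

1. **Simulation** — Gillespie sampling of the chain; rendering at
   50 kHz with a Gaussian FIR approximating the acquisition Bessel
   filter (5 kHz on-line, 1 kHz off-line), baseline noise, optional
   run-down and multi-channel contamination.
2. **Idealization** — segmental k-means (amplitude re-estimation +
   Viterbi restoration), with a half-amplitude threshold method as an
   independent oracle, followed by dead-time imposition (0.3 ms).
3. **Dwell-time inference** — left-truncated exponential-mixture
   maximum likelihood (multi-start EM); the number of components grows
   while the log-likelihood improves by more than 10 nats; an optional
   first-order missed-event correction removes the concatenation bias
   caused by unresolved gaps.
4. **Burst analysis** — critical closed time T_crit between adjacent
   closed components (equal numbers of misclassified events), burst
   segmentation, discard of mixed-amplitude bursts, k-means/BIC
   separation of small (O_S) and large (O_L) amplitude classes, and
   per-class burst statistics (proportion of bursts, openings per
   burst, burst duration, within-burst P_open).
5. **QC and statistics** — stability plots with trend tests, analysis
   windows (60 s HS / 120 s LS), a 2-SD event-rate outlier filter, and
   fold-change tests (per-patch value ÷ wildtype mean, one-sample t
   against 1.0), plus unpaired t and two-way Type II ANOVA with Tukey
   HSD.

## Worked example

```python
import singlechan as sc

model = sc.hs_like_model()                      # HS-regime gating scheme
trace, truth = sc.simulate_patch(model, duration=60.0, seed=42)
analysis = sc.analyze_patch(trace, n_open_classes=1,
                            analyzed_window_s=60.0, seed=0)

print("open-class amplitude: %.2f pA" % analysis.amplitudes[0])
print(analysis.closed_fit.summary())
print("T_crit = %.2f ms" % analysis.t_crit)
st = analysis.burst_stats["all"]
print("bursts: %d (proportion %.2f), openings/burst %.1f, P_open %.2f"
      % (st["n_bursts"], st["proportion_bursts"],
         st["mean_openings_per_burst"], st["mean_p_open"]))
```

prints

```
open-class amplitude: 1.35 pA
Exponential dwell-time mixture (closed)
  n = 218, t_min = 0.3 ms, k = 2, LL = -2214.19
  tau_1 = 0.5033 ms (26.9%)
  tau_2 = 245.7 ms (73.1%)
  warning: missed-gap compound fit (q = 0.260, gap = 0.141 ms)
T_crit = 1.94 ms
bursts: 23 (proportion 0.12), openings/burst 2.3, P_open 0.78
```

The fitted amplitude recovers the generator's 1.35 pA unitary current
exactly; the closed-dwell fit resolves the two generating components
(0.8 ms at 30 %, 250 ms at 70 % — a single 60-s patch gives noisy τ₁
estimates; medians over seeds converge on the generating values). The
`warning:` line records that the fit used the missed-event
(concatenation) correction with the gap-miss probability `q` estimated
from the open-dwell fit. T_crit separates within-burst closures from
interburst gaps; the burst summary reports the four per-class burst
statistics.

A command-line interface wraps the same pipeline
(`singlechan simulate|idealize|dwellfit|bursts|qc|compare|pipeline`,
each taking `--config <json> --seed <int>`).

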