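# gammacoh

Low-gamma (30–45 Hz) EEG **power and coherence** analysis across behavioral
and pharmacological states, for electrophysiologists studying cortical
coupling in sleep/wake recordings and NMDA-antagonist (ketamine) models.
Functional coupling between two cortical sites is quantified per 100-s
window by the magnitude-squared coherence

```
              |⟨X_b(f) · Y_b*(f)⟩_b|²
MSC(f) = ───────────────────────────────── ,   0 ≤ MSC ≤ 1,
          ⟨|X_b(f)|²⟩_b · ⟨|Y_b(f)|²⟩_b
```

averaged over Hann-tapered Welch blocks (2,048 samples at 1,024 Hz →
0.5 Hz resolution, ~100 blocks per window), variance-stabilized as the
**z′-coherence** `z′ = atanh(√MSC)` and averaged over the 30–45 Hz band.
States (alert/quiet wakefulness, NREM, REM, ketamine doses) are compared by
one-way ANOVA with Tamhane T2 post-hoc per subject, and repeated-measures
ANOVA with Bonferroni post-hoc across subjects.

Because suitable public recordings with known ground truth do not exist, the
package ships a **synthetic multichannel EEG generator**: Hann-enveloped
gamma bursts (200–500 ms, ~25 μV) on band-limited noise, with a per-state
`coupling_fraction` that splits the burst stream into a source shared across
channels and independent per-channel events. The two-channel mixing model
has the closed-form band coherence `MSC = (S/(S+N))²` (shared vs independent
in-band power), so every stage of the pipeline — window selection, filtering,
spectra, coherence, surrogates, bursts, statistics — is verifiable against
an analytic oracle.

## Worked example

```python
from gammacoh import RunConfig, run_state_comparison, default_config

states = ["AW", "QW", "NREM", "REM", "K15"]
cfg = RunConfig(states=states, seed=42,
                synthetic=default_config(states=tuple(states),
                                         dur_per_state=1300.0, seed=42))
res = run_state_comparison(cfg)
print(res.z_table.round(3).to_string(index=False))
```

```
     pair  AW_mean  AW_se  QW_mean  QW_se  NREM_mean  NREM_se  REM_mean  REM_se  K15_mean  K15_se       F
Pf-r:Pp-r    0.602  0.008    0.277  0.005      0.198     0.01     0.102   0.003     0.094   0.004 968.125
```

Each column is the mean ± SE of the band z′-coherence over twelve 100-s
windows between right prefrontal (Pf-r) and posterior-parietal (Pp-r)
channels. The pipeline recovers, from raw signal alone, the coupling
profile encoded in the presets: coherence is maximal in alert wakefulness,
intermediate in quiet wakefulness and NREM sleep, and collapses to the same
low level in REM sleep and after 15 mg/kg ketamine (Tamhane-adjusted
p < 1e-14 for K15 vs AW here, F(4, 55) in the last column). Gamma *power*
behaves differently — `res.power_table` shows QW ≈ REM ≈ K15 (~33 μV²),
about five-fold above NREM and well below AW — so decoupling under ketamine
and REM is not a power artifact.

The same analyses are scriptable from a shell (`gammacoh synth | windows |
spectrum | spectrogram | coherence | bursts | stats | all`), exchanging EDF
signals and CSV/JSON tables.

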