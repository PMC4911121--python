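# sgsc

Pulse-gated graded information propagation in spiking and mean-field
neural networks: a current-based integrate-and-fire network simulator, the
companion firing-rate (mean-field) theory for overlapping gating pulses,
circuit construction and calibration tools (graded chains, attractor
gating chains, working memory, sign-split Hadamard transforms, conditional
logic), robustness/SNR analysis, and an autonomous decision-making demo
circuit that reads a streaming input, transforms it, conditionally copies
the result, and shuts itself down.

Units throughout: time in seconds, membrane voltage reduced so that
`V_thres - V_leak = 1`, synaptic currents and couplings dimensionless.

## Layout

| module | contents |
|---|---|
| `sgsc.meanfield` | pulse schedules, window-to-window propagation operator, exact-transfer coupling `S_exact`, the `alpha(eta)` operating curve, gated rate-network integration, waveform-family fitting |
| `sgsc.spiking`   | integrate-and-fire network simulator (IID Bernoulli connectivity, delta synapses, Poisson background, refractory reset; numba-accelerated) |
| `sgsc.circuits`  | circuit blueprints, chain constructors, gating/graded calibration, linear maps, Hadamard blocks, AND gates |
| `sgsc.ratenet`   | rate-level execution of blueprints with stereotyped gating pulses |
| `sgsc.decision`  | the 50-population autonomous decision circuit |
| `sgsc.analysis`  | trial statistics, SNR/perturbation experiments, rate smoothing |
| `sgsc.fitting`   | fitting the mean-field waveform family to spiking runs |
| `sgsc.runner` / `sgsc.cli` | blueprint I/O, fixtures, experiment orchestration, CLI |

Shipped circuit configurations (YAML, regenerable from the calibration
operations) live in `src/sgsc/blueprints/`: `fig1_sgsc` (12-layer graded
transfer), `fig4_snr` (reduced-size robustness probe), `fig5_decision`
(the decision circuit).

## CLI

```sh
sgsc sexact --t0-over-tau 0.6 --eta 2.5        # exact-transfer coupling
sgsc sexact --t0-over-tau 0.6 --curve 4.0      # S_exact vs eta curve (CSV)
sgsc simulate --blueprint fig1_sgsc --duration 0.06 --seed 1 --out results/
sgsc snr --blueprint fig4_snr --trials 200 --perturbation pulse_jitter_10pct --out snr.csv
sgsc decision-demo --amplitude 24 --backend meanfield --out decision_out/
sgsc fixtures --name two_layer_toy --out toy.yaml
sgsc fit --t0 0.003 --trials 20                # mean-field fit of a spiking run
```

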