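# circaclock

Modeling toolkit for circadian core-clock and clock-controlled gene (CCG)
expression across tissues:

- **`circaclock.dde`** — constant-delay DDE integrator (method of steps on an
  embedded Runge–Kutta pair, dense output, discontinuity propagation).
- **`circaclock.models`** — the five-gene core-clock network (Bmal1,
  Rev-Erba, Per2, Cry1, Dbp) with delayed Ebox/RRE/Dbox activation and
  inhibition terms, plus the one-way-coupled CCG equation whose exponents
  are promoter element counts. Five fitted parameter sets (liver, muscle,
  adipose, lung, all-tissues consensus) ship as YAML fixtures.
- **`circaclock.phases`** — period, peak time, phase (radians, lights-on
  reference) and amplitude extraction; circular phase differences.
- **`circaclock.regfac`** — regulation-factor time series over one cycle,
  their coefficients of variation, and inter-tissue ΔCV% statistics.
- **`circaclock.estimation`** — bounded nonlinear least squares for delays /
  degradation rates (per-tissue or joint consensus) and CCG parameters, with
  95% Wald confidence intervals; numba-accelerated simulation hot path.
- **`circaclock.sensitivity`** — local finite-difference sensitivity of gene
  phases to delays and degradation rates.
- **`circaclock.pwm`** — JASPAR-style PFM parsing and both-strand PWM
  scanning at a relative-score threshold (default 0.85), producing the
  (n1, n2, n3) element counts.
- **`circaclock.synth`** — synthetic time courses on the study's 18-point
  lights-on sampling grid (triplicate, lognormal noise) and promoter FASTA
  with planted motifs, each with a regenerating truth manifest.
- **`circaclock.io` / `circaclock.cli`** — tidy-CSV/FASTA/PFM IO, run
  configuration echoing, and the `circaclock` command-line interface.

## CLI

Each subcommand writes its outputs plus the effective `run_config.yaml`
into `--out`; all randomness flows from `--seed`.

```bash
circaclock simulate --params all_tissues --out out_sim
circaclock synth --seed 1 --tissues liver,muscle,adipose,lung --out out_synth
circaclock fit --data out_synth/timecourse.csv --seed 1 --starts 3 --out out_fit
circaclock sensitivity --out out_sens
circaclock regfac --ccg-params ccg.yaml --out out_regfac
circaclock scan --fasta promoters.fa --out out_scan
circaclock fit-ccg --data ccg_timecourse.csv --counts 2,1,0 --out out_ccg
circaclock report --out out_report
```

`--params` accepts a bundled tissue name (`liver`, `muscle`, `adipose`,
`lung`, `all_tissues`) or a YAML file with the same flat keys
(`tau_Bmal1`, `d_RevErba`, `ar1`, ...). The bundled `ebox`/`rre`/`dbox`
matrices are clearly-labeled stand-ins; pass real PFMs via
`--ebox/--rre/--dbox`.

## Conventions worth knowing

- Expression values are normalized around 1; simulated profiles are divided
  by their cycle mean before any comparison with data (never inside the
  dynamics).
- Data time is hours after lights-on (light = [0,12), dark = [12,24)); the
  free-running model is aligned to clock time by a single global offset
  parameter estimated with the fit but excluded from CI reporting.
- σ² for Wald intervals defaults to ‖r‖²/df; a `sigma_mode="literal"`
  variant (‖r‖/df) exists for reproduction experiments.
- PWM scanning uses pseudocount 0.8 with a uniform background, scans both
  strands, skips windows containing N, and counts overlapping hits.
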