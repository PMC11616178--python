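# ctxbind

Schedule generation, simulation and multinomial-processing-tree (MPT)
analysis of **context binding** in auditory prime–probe (negative priming)
experiments.

## The problem

In a four-alternative negative-priming task, every trial pairs a *prime*
and a *probe* presentation of a target sound plus a to-be-ignored
distractor sound (frog, piano, drum, bell → keys F/V/J/N). When the ignored
prime distractor returns as the probe target (*ignored repetition*, IR),
the stimulus–response episode formed in the prime is retrieved and
participants tend to commit the prime's response. A task-irrelevant sine
tone (the *context*) accompanies both presentations and may repeat or
change between them. The question `ctxbind` is built for: is the context
integrated into the episode — not at all, as part of a compound with the
distractor (*configural binding*), or directly with the response
(*binary binding*) — and how does this depend on the context's inter-trial
variability, manipulated across five groups (blocked, ordered, disordered,
mixed, random)?

## The model

Probe responses in IR and control (C) trials fall into four categories
whose probabilities form one MPT tree per condition:

    p(correct)          = ci
    p(probe distractor) = (1 − ci)·psc
    p(prime response)   = (1 − ci)(1 − psc)·prr
    p(other)            = (1 − ci)(1 − psc)(1 − prr)

with *ci* correct identification, *psc* probe-stimulus confusion, and *prr*
prime-response retrieval. Restricted models are compared by the
likelihood-ratio statistic G² = 2(ll_full − ll_restricted) ~ χ²(df), with
effect size ω = √(G²/N). Per group, a three-stage battery with per-family
Holm correction tests: (1) prr_IR = prr_C per context relation (distractor
binding), (2) prr_C,repeated = prr_C,changed (binary context binding), and
(3) equality of the prr_IR − prr_C difference across context relations via
a reparameterized interaction model (configural binding). The adjusted
significance flags classify each group as none / configural / binary /
both.

## Worked example

Simulate a configural-pattern group and a binary-pattern group at the full
design size (48 participants × 384 trials each) and run the battery:

```python
import ctxbind as cb

scenarios = {"disordered": cb.scenario_preset("configural"),
             "random": cb.scenario_preset("binary")}
records, manifest = cb.simulate_study(["disordered", "random"], 48,
                                      scenarios, master_seed=7)
result = cb.run_pipeline(records)
print(result.battery.classification)
print(result.battery.prr_estimates.round(3).to_string(index=False))
```

Output:

```
{'disordered': 'configural', 'random': 'binary'}
     group trial_type context_relation    ci   psc   prr    n
disordered         IR         repeated 0.806 0.259 0.592 2050
disordered          C         repeated 0.812 0.276 0.274 2116
disordered         IR          changed 0.813 0.196 0.470 2094
disordered          C          changed 0.810 0.287 0.302 2069
    random         IR         repeated 0.803 0.287 0.594 2035
    random          C         repeated 0.795 0.240 0.434 2094
    random         IR          changed 0.798 0.273 0.450 2086
    random          C          changed 0.815 0.277 0.303 2053
```

In the disordered group the IR−C retrieval gap is larger under context
repetition (0.592 − 0.274 = 0.318) than under change (0.470 − 0.302 =
0.168) while prr_C itself barely moves — the interaction test flags it,
G²(1) = 7.34, Holm-adjusted p = 0.013, ω = 0.030 → *configural*. In the
random group prr_C jumps from 0.303 (context changed) to 0.434 (context
repeated): repeating the tone alone retrieves the prime response,
G²(1) = 11.07, adjusted p = 0.002, ω = 0.037 → *binary*. The descriptive
negative-priming RT effect in the same dataset is 55 ms (IR minus control,
correct probes).

The same steps are available from a shell:

```sh
ctxbind simulate --groups disordered,random --n-per-group 48 \
        --preset configural --seed 7 --out study
ctxbind battery --data study.csv --out report.json
ctxbind fit --tables trees.csv --interaction disordered
ctxbind recover --preset binary --group random --replicates 20 --seed 2
```

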