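# mchbca

Benefit–cost analysis (BCA) of integrated maternal–child health intervention
packages evaluated in two-stage factorial randomised trials.

Trials of preconception, pregnancy and early-childhood intervention packages
report effect sizes — absolute risk reductions (ARR) for binary outcomes,
mean differences (MD) for continuous ones — and ingredient-based delivery
costs. Health economists then need to answer a different question: *what is
the return on each dollar invested?* This package turns those trial outputs
into that answer. It is written for health economists and trialists running
economic evaluations alongside maternal/child trials in low- and
middle-income settings.

## The model

Benefits are monetized per mother–child dyad through three channels:

- **Mortality** (stillbirth and death in the first two years), valued at the
  value of a statistical life: `VSL = 100 × GNI per capita (PPP)`, income
  elasticity 1, no age adjustment. A risk reduction of ARR percentage points
  is worth `(ARR/100) × VSL`.
- **Morbidity**, valued through averted years lived with disability:
  `ΔYLD = (ARR/100) × DW × T1` with GBD-2019 disability weight `DW` and
  persistence `T1` (years), and one DALY valued at one
  `VSLY = VSL / 35`.
- **Productivity** (birth weight, stunting, wasting, cognition pathways):
  `w × f × effect × Σ_t y₀ (1+g)^t (1+r)^−t` over 35 working years from the
  earnings start age, where `f` is the fraction of lifetime earnings shifted
  per unit effect and the overlap weight `w = 0.6` prevents double counting
  across pathways that share mechanisms.

Per-dyad incremental costs come from phase unit-cost ledgers (eight
ingredient components per phase) scaled by the participant flow
(`N_preconception`, `N_pregnancy`, `N_children at 24m`):

```
cost_B = UC_pre  × N_pre  / N_child
cost_C = UC_preg × N_preg / N_child + UC_ec
cost_A = cost_B + cost_C
```

where B/C/A are the preconception-only, pregnancy-and-early-childhood, and
full-package groups versus routine care. Headline outputs are the
benefit–cost ratio `BCR = benefits / costs` and net monetary benefit
`NMB = benefits − costs`, plus one-way (tornado) sensitivity analysis over
effect sizes (at their 98.3% CI bounds), discount and growth rates, VSL,
VSLY and delivery-cost scale.

A synthetic-trial module generates individual-level two-stage factorial data
(1:1 randomisation, ~1/3 pregnancy attrition, 24-month child follow-up) so
the whole pipeline — generate → estimate crude effects → value → assemble —
is testable end to end without any external data.

## Worked example

The packaged fixture transcribes a Delhi factorial trial of integrated
health/nutrition/WaSH/psychosocial packages (2021 $PPP; unpublished
valuation inputs are calibrated — see `docs/methods.md`):

```python
from mchbca import load_packaged_study, run_full_analysis, results_frame

bundle = load_packaged_study()
print(results_frame(run_full_analysis(bundle)).to_string(index=False))
```

```
  comparison  benefits  costs  bcr     nmb
B_vs_control    8805.3 1441.3  6.1  7363.9
C_vs_control   28843.8 2926.9  9.9 25916.9
A_vs_control   16182.0 4368.2  3.7 11813.8
```

Read: every dollar spent on the preconception package returns 6.1 $PPP; the
pregnancy/early-childhood package returns 9.9 per dollar and nets
~25 917 $PPP per dyad; the full package still returns 3.7 per dollar but at
nearly triple the preconception cost. The same numbers are available from
the shell, along with the per-outcome breakdown and tornado export:

```sh
mchbca run --out results/
mchbca sensitivity --comparison C --out tornado.tsv
mchbca simulate --seed 3 --out records.csv
```

The tornado for comparison C ranks the mortality effect size as the
dominant effect-size uncertainty, and its BCR stays above 1 in every
low-case scenario of the default set.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full base-case analysis on the packaged fixture and a seeded
synthetic end-to-end recovery at n = 50 000 (estimated vs truth-implied
BCRs), printing both summaries and writing the report to `--out`.
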