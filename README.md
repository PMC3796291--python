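# mrpkpd

PK/PD modeling and therapeutic-index analysis for mineralocorticoid-receptor
(MR) antagonists in the aldosterone-infused, uninephrectomized, high-salt rat
model of hypertensive nephropathy.

MR antagonists lower albuminuria (the urinary albumin-to-creatinine ratio,
UACR) but carry a hyperkalemia risk.  This package implements, as a tested
and reusable library, the analysis chain that quantifies that trade-off for
two compounds — the non-steroidal antagonist PF-03882845 and the steroidal
comparator eplerenone:

1. **Compartmental PK** — one- and two-compartment oral models with
   first-order or zero-order (infusion-like) absorption, clearance induction
   between Days 1 and 7 of repeated dosing, a dose-dependent clearance power
   model `CL = θ₁·(30/dose)^pwr·exp(η)`, and AUC(0–last) by the linear
   trapezoidal rule.
2. **Indirect-response PD** — UACR turnover with inhibition of production,

       dUACR/dt = Kin·[1 − Imax·C/(C + IC50)] − Kout·UACR,

   started from a per-animal non-steady-state baseline (the aldosterone
   disease state), and a stimulated-input turnover for change-from-baseline
   endpoints,

       dΔ/dt = Kin,max·C/(C + EC50) − Kout·Δ,

   used for serum K⁺ (chronic) and urinary Na⁺/K⁺ (acute).  Delta endpoints
   are transformed by the double-delta rule
   `Δ(T) = (TxT − Tx0) − (VehT − Veh0)` against the pooled vehicle group.
3. **Two-stage population estimation** — per-animal PK fits (proportional
   residual error) whose parameters are then fixed while the PD systems are
   fitted to both drugs simultaneously with shared system constants
   (Kin/Kin,max, Kout, Imax) and drug-specific potencies; bootstrap or
   asymptotic confidence intervals.
4. **Therapeutic index** — potency corrected for protein binding
   (fEC50 = EC50·fu), normalized to in vitro receptor potency, and expressed
   as TI = (normalized serum-K⁺ EC50)/(normalized UACR EC50).  Within one
   drug, fu and in vitro potency cancel, so TI equals the raw EC50 ratio —
   an identity the code asserts.
5. **Synthetic study generator** — no animal-level data are deposited for
   these studies, so a seeded generator reproduces the chronic design
   (2 studies × 5 groups × 11 rats, 27 days of 6 am/4 pm BID dosing, sparse
   PK sampling, UACR on Days 0/14/25, serum K⁺ on Days 0/14/27) and the
   acute urinary Na⁺/K⁺ design (single dose; urine intervals 0–2/2–4/4–7 h
   timestamped at midpoints 1/3/5.5 h; plasma at 0/1/2/4/7 h), making every
   estimation stage testable end to end.

See `docs/methods.md` for the model assumptions, default parameters and
numerical choices.

## Worked example

```python
from mrpkpd import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=5, kind="acute", noise_off=True,
                                outdir="results/demo"))
print({k: round(v, 3) for k, v in result["na_k_fit"].params.items()})
```

prints the stage-2 estimates recovered from a noise-free synthetic acute
study pair:

```
{'kin_max': 0.9, 'kout': 0.3, 'ec50_PF-03882845': 3.1, 'ec50_eplerenone': 5.92}
```

`kin_max` (ratio-units/h) and `kout` (1/h) are the shared turnover constants
of the urinary Na⁺/K⁺ response, and the two `ec50` values are the
drug-specific half-maximal drives on the dimensionless free-concentration /
in-vitro-potency scale — equal to the generating truth because noise is off.
The same entry point with `kind="chronic"` runs the full 110-animal
two-study analysis and writes a potency/TI table (`ti_table.csv`), the
stage-1 fits, a dataset CSV and a human-readable `report.txt`.

The command-line interface mirrors the library:

```bash
mrpkpd simulate --kind chronic --seed 1 --out data.csv
mrpkpd fit-pk --data data.csv --out pk.csv
mrpkpd fit-pd --data data.csv --pk pk.csv --endpoint uacr --out uacr.json
mrpkpd fit-pd --data data.csv --pk pk.csv --endpoint delta_serum_k --out k.json
mrpkpd ti --uacr-fit uacr.json --k-fit k.json --out table.csv
mrpkpd run --seed 1 --outdir results/full   # everything at once
```

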