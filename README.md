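# poctecon

Economic model of antibiotic prescribing with point-of-care diagnostic
testing (POCT): closed-form physician welfare and prescription quantities,
the diagnostic firm's two-part tariff pricing equilibrium, and a
patient-level Monte-Carlo simulator with brute-force optimizers that
validate every closed form independently.

## The problem

Antibiotics are routinely prescribed empirically — on symptoms alone —
which over-treats self-limiting infections and fuels antimicrobial
resistance. Point-of-care tests can resolve the diagnostic uncertainty,
but whether a primary-care physician should buy the testing device depends
on how uncertain they are and on how the device manufacturer prices it.
This package implements a static two-stage game that answers when testing
is adopted, how the monopolist manufacturer prices the device, and how
many prescriptions testing avoids.

**Who it is for:** health economists and health-policy modellers studying
diagnostic-guided prescribing, antimicrobial-resistance externalities and
diagnostic-device pricing.

## The model

`N` physicians each treat a unit-mass panel of patients with symptom score
`s ~ U(0, 1)`. Antibiotics are truly needed only above an unknown
threshold `A`; a physician of uncertainty `b` believes
`A ~ U(ā − b/2, ā + b/2)`, with `b ≤ b_max = 2 min(ā, 1 − ā)`. Treating a
patient costs the effective price `p = p_a + r` (drug price plus the
internalized resistance externality) and yields health value `B`; an
untreated sick patient loses `l`. Maintained assumptions: `B > p`,
`B − p ≥ l`, `B + l > 2p`.

- **Empiric prescribing** — the optimal cutoff is
  `s*(b) = ā − b/2 + pb/(B+l)`; prescriptions `Q_Ae(b) = 1 − s*(b)`;
  welfare `W_e(b) = B − p(1−ā) − pb(B+l−p)/(2(B+l))`.
- **POCT** — under a two-part tariff `(C, t)` (device price, per-test fee)
  the physician tests the band
  `[ā − b/2 + tb/(B+l−p), ā + b/2 − tb/p]`, testing
  `T(t,b) = b[(p−t)(B+l) − p²]/(p(B+l−p))` patients; welfare
  `W_POCT(b) = B − p(1−ā) − tb[1 − t(B+l)/(2p(B+l−p))] − C`.
- **Adoption** — the physician buys the device iff
  `C ≤ b[p(B+l−p) − t(B+l)]²/(2p(B+l)(B+l−p))`; adoption is monotone in
  `b`, so the market segments at a marginal adopter `b*`.
- **Equilibrium** — by backward induction the firm sets `t = 0`, prices
  the device at the marginal adopter's cap
  `C* = b* p(B+l−p)/(2(B+l))`, and chooses `b*` to maximize
  `b(1 − G(b))` where `G` is the distribution of uncertainty across
  physicians (`b* = min(ā, 1−ā)` for uniform `G`). Testing by adopters
  reduces aggregate prescriptions by
  `N(B+l−2p)/(2(B+l)) ∫_{b*} x g(x) dx`, of which
  `N r/(B+l) ∫_{b*} x g(x) dx` is attributable to internalizing the
  resistance cost `r`.

See `docs/methods.md` for assumptions, numerical choices and known
limitations (including a documented tension between the zero-fee tariff
result and strictly uniform device pricing).

## Worked example

With the baseline economy in a scenario file:

```yaml
# baseline.yaml
parameters:
  B: 10.0      # value of cure
  l: 2.0       # disutility of untreated sickness
  p_a: 0.7     # antibiotic price
  r: 0.3       # resistance externality per prescription
  a_bar: 0.4   # expected symptom threshold
distribution:
  family: uniform
N: 100
```

```bash
poctecon equilibrium --config baseline.yaml --out out/
```

prints

```
b_star: 0.3999999999997061
C_star: 0.18333333333319862
t_star: 0.0
firm_profit: 9.16666666666667
adopter_fraction: 0.5000000000003675
welfare_adopter: 9.216666666666802
prescriptions_reduction: 12.500000000006123
internalization_reduction: 0.7500000000003675
N: 100
alternate_device_price: 0.3666666666663973
```

Read: the firm charges nothing per test and 0.1833 per device; the half of
physicians with uncertainty `b ≥ 0.4` buy it (adopter welfare 9.217 each,
equal to the marginal adopter's empiric welfare); firm profit is 9.17.
Across the 100 practices testing avoids 12.5 prescriptions per treatment
round, 0.75 of which are avoided because physicians price the resistance
cost `r` into their prescribing. `alternate_device_price` is the same
price under the alternative convention discussed in `docs/methods.md`.

Other subcommands: `closed-forms` (tabulate `s*`, `Q_Ae`, `W_e`, `T`,
`Q_APOCT`, `W_POCT` over a `b` grid), `validate` (closed forms vs. the
Monte-Carlo oracle, CSV of z-scores, non-zero exit on disagreement),
`figure` (the welfare-crossing plot marking `b*`), `simulate` (full
scenario run). The same functionality is available as a library:

```python
import poctecon as pc
params = pc.EconomicParameters(B=10, l=2, p_a=0.7, r=0.3, a_bar=0.4)
eq = pc.solve_equilibrium(params, pc.uniform_uncertainty(params.b_max), N=100)
```

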