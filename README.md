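# kinsim

Multi-level evolutionary simulation of kinship structures and descent
systems, with clan detection, phase-diagram experiments, an analytic
phase boundary, and an estimation pipeline for cross-cultural
ethnographic data.

## The problem

In many indigenous societies families are grouped into *clans* —
culturally defined kin groups that regulate marriage (whom one must
marry) and descent (which clan children belong to).  The between-clan
flow of brides forms a cycle of length `C_m` (the marriage cycle), and
the flow of children relative to their parents' clans a cycle of length
`C_d` (the descent cycle).  The classic structures are clan endogamy
(`C_m = C_d = 1`), dual organization (direct bride exchange between two
clans, `C_m = 2, C_d = 1`), generalized exchange (cyclic exchange among
three or more clans, `C_m ≥ 3, C_d = 1`) and restricted exchange
(direct exchange with children in different clans from both parents,
`C_m = C_d = 2`), with patrilineal, matrilineal or double descent.

`kinsim` asks how these structures *emerge*.  Families carry a cultural
trait `t = (t1, t2)` and a mate preference `p = (p1, p2)` (paternal and
maternal components, transmitted with Gaussian noise of scale μ).
Families cooperate with cultural kin and mates
(`exp(-min(|tᵢ-tⱼ|, |tᵢ-pⱼ|, |pᵢ-tⱼ|)²/τ²)`), compete with mating
rivals (`exp(-|pᵢ-pⱼ|²/τ²)`), and their expected offspring number is

    r = b · exp(-d_c (1 - friend) - d_m · rival)

where `friend`/`rival` are the society means of the two kernels, `d_c`
is the mortality cost of lacking cooperators and `d_m` the cost of
rivals.  Marriage is monogamous and bride-side selective: a man from
family *i* offers to family *j* with probability ∝
`exp(-|tᵢ - pⱼ|²/τ²)`.  Societies holding the families split when they
double their initial size and replace a random other society
(group-level selection).  Under these two pressures, initially uniform
traits diverge into clans, and the clans' marriage and descent
relations form exactly the structures above, depending on `(d_c, d_m)`.

## Worked example

```python
from kinsim import ModelParams, run_simulation, classify_structure

params = ModelParams(d_c=0.5, d_m=1.0, seed=0)   # b=5, mu=0.1, tau=1, N=50
result = run_simulation(params)                   # 500 generations
points = result.final_points()                    # (t1,t2,p1,p2) per family
cls = classify_structure(points, tau=params.tau, seed=params.seed)
print(cls.structure, cls.descent_system, cls.C_m, cls.C_d)
```

Running `python examples/01_simulate_and_classify.py` (this exact
computation) prints:

```
outcome: completed after 500 steps
largest society: 99 families
trait/preference spread (sd of t1,t2,p1,p2): [3.11 0.51 2.79 0.48]
clans detected: 3
marriage cycle C_m = 3, descent cycle C_d = 1
kinship structure: generalized_exchange; descent system: patrilineal
```

At moderate cooperation pressure and strong mating competition the
paternal trait `t1` has split into three clans (its spread, 3.1, is
thirty times the mutation scale, while the maternal trait `t2` never
diverged); each clan's preference sits on the next clan's trait, so
brides circulate around a three-clan ring (`C_m = 3`) while clan
membership follows the father line (`C_d = 1`, patrilineal) —
generalized exchange.

The other examples cover the phase sweep (`02`), the analytic boundary
(`03`), the empirical pipeline on a synthetic ethnographic table
(`04`), and classifier recovery of ideal clan geometries (`05`).
A thin CLI mirrors the library: `kinsim simulate|classify|sweep|
boundary|empirical|fixtures --help`.

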