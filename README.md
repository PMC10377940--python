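# chanpid — partial information decomposition via channel preorders

`chanpid` quantifies how much of the information that a set of discrete
*source* variables Y₁, …, Yₙ carries about a *target* variable T is
**redundant** — shared by every source — and assembles the resulting partial
information decomposition (PID)

    I(T; (Y₁, Y₂)) = R + U₁ + U₂ + S,

with unique components Uᵢ = I(T; Yᵢ) − R and synergy S fixed once the
redundancy R is chosen.  It is aimed at researchers in systems biology,
neuroscience and network inference who need redundancy/synergy estimates
with explicit optimality guarantees rather than point heuristics.

## The measures

Each variable Yᵢ is viewed as the output of a channel K⁽ⁱ⁾[t, y] = p(yᵢ | t)
from the target.  An *intersection information* (II) measure picks a preorder
⪯ between channels and maximizes over all "smaller" variables Q:

    I∩(Y₁, …, Yₙ → T) = max { I(Q; T) : K_Q ⪯ K⁽ⁱ⁾ for every i }.

Four preorders are implemented, each yielding a measure that satisfies the
Williams–Beer axioms:

| preorder | meaning of K_Q ⪯ K | computation |
| --- | --- | --- |
| degradation (Blackwell), `d` | K_Q = K·K_U for a stochastic K_U | exact convex maximization over a polytope (vertex enumeration, Frank–Wolfe fallback) |
| less noisy, `ln` | χ²(pK‖qK) ≥ χ²(pK_Q‖qK_Q) for all simplex pairs (p, q) | bracket: certified lower bound + sampled-constraint upper bound |
| more capable, `mc` | I(p; K_Q) ≤ I(p; K) for every target law p | bracket, as above with mutual-information constraints |
| degradation/supermodularity, `ds` | chains of degradation and JoinMeet column steps | bracket between the degradation value / certified sources and the `mc` upper bound |

Two reference measures complete the picture: `mmi` (minimum mutual
information, min_i I(T;Yᵢ)) and `det` (deterministic common part à la
Gács–Körner: the connected components of the source co-occurrence graph).
The implied chain I∩◃ ≤ I∩d ≤ I∩ln ≤ I∩mc ≤ I∩MMI and I∩d ≤ I∩ds ≤ I∩mc is
enforced in the test suite.

Decision procedures for the orders themselves ship with certificates: a
post-processing matrix K_U for degradation (decided by linear programming),
a JoinMeet step sequence for supermodularity, and witnessing simplex points
(p, q) for less-noisy / more-capable violations found on a grid.

## Worked example

```python
import chanpid as cp

joint = cp.gate_joint("AND")            # T = Y1 AND Y2, iid uniform inputs
pid = cp.pid_bivariate(joint, "d")      # redundancy via the Blackwell order
print(round(pid.redundancy.low, 3), round(pid.synergy.low, 3), round(pid.total, 3))
```

prints

```
0.311 0.5 0.811
```

i.e. the two inputs of an AND gate share 0.311 bits about the output, have
no unique information, and complement each other with 0.5 bits of synergy,
adding up to the full I(T;(Y₁,Y₂)) = 0.811 bits.

The same API handles channels directly.  For the classic 2×2 pair where the
second channel is less noisy than the first but *not* a degradation of it:

```python
K1, K2 = cp.counterexample1()
p = cp.SimplexPoint.from_weights([0.4, 0.6])
print(round(cp.ii_degradation(p, [K1, K2]).value, 3))   # 0.002
print(round(cp.ii_less_noisy(p, [K1, K2]).value, 3))    # 0.004  (= I(T;Y2))
res = cp.ii_ds(p, [K1, K2])
print(res.bound_status, round(res.lower, 3), round(res.upper, 3))
# BRACKET 0.002 0.004  — no decision procedure for the ds order is known
```

A thin CLI mirrors the library:

```bash
chanpid fixtures --name and --out fx/
chanpid decompose --measure d --joint fx/and.tsv
chanpid order-check --relation s --w k4.csv --v k3.csv   # JoinMeet certificate
```

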