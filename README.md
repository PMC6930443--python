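# clicksim

Population dynamics of *click assemblies* — immune cell circuits wired by
directional kill interactions.

A "click" is a receptor–ligand pairing between two cell types that
triggers the death of exactly one of them (NK-receptor killing, Fas/FasL
engagement, CTLA-4 transendocytosis, ...). Under two rules — a click is
exclusive to a pair of cell types, and killing is directional — a set of
populations connected by clicks forms a directed cycle: an intransitive,
rock-paper-scissors-like circuit with no global winner, where the outcome
depends on context rather than on a fixed hierarchy. `clicksim` is for
modellers who want to explore how such circuits select an immune response:
it ships the canonical four-population assembly (cytotoxic Tc maturing
into NK-receptor-bearing Tnk, helper Th maturing into regulatory Tr1,
wired Tc ⊣ Tnk ⊣ Th ⊣ Tr1 ⊣ Tc), a deterministic mean-field backend, a
stochastic lattice backend, regime diagnostics, and an exact Efron-dice
engine for the underlying intransitive logic.

## The model

The mean-field backend integrates a generalized Lotka–Volterra system for
abundances P_i on a normalized response scale:

    dP_i/dt = P_i [ r_i (1 + β_i h)(1 − Σ_j P_j / K) − d_i − Σ_{j⊣i} κ_{ji} P_j ]
              + Σ_{l→i} m_l P_l − m_i P_i

with logistic self-limitation through the shared total (capacity K),
mass-action killing κ along each click j ⊣ i, linear maturation flows m
within a lineage, and bystander help h multiplying the growth of
help-sensitive populations (β_i > 0) without touching the kill wiring.
The lattice backend realizes the same assembly as a toroidal cellular
automaton (von Neumann neighbourhoods, random-sequential contact
kill/reproduction, per-site death and maturation) with a documented
rate-to-probability mapping, and agrees with the ODE equilibrium in the
well-mixed regime. See `docs/methods.md` for the full account.

## Worked example

```python
import clicksim as cs

assembly = cs.build_canonical_4click()          # shipped calibrated 4-click
print(cs.smallest_directed_cycle(assembly))
# ['Tc', 'Tnk', 'Th', 'Tr1']

traj = cs.simulate_ode(assembly, cs.OdeParams(t_end=2500.0, n_samples=2501))
label = cs.classify_attractor(traj)
print(label.label, round(traj.column("Tr1").max(), 3))
# Tr1_dominant 0.896

eq, stable = cs.find_equilibrium(assembly, traj.final_state)
print([float(round(x, 3)) for x in eq], stable)
# [0.042, 0.09, 0.093, 0.888] True
```

At rest the regulatory population dominates a stable coexistence: Tr1
peaks at 0.896 on the normalized scale and settles at 0.888, with the
other three populations persisting at a few percent. Knocking down Tnk
flips the circuit to a cytotoxic response, and raising the bystander help
level switches it back bistably:

```python
kd = cs.build_canonical_4click({"Tnk.initial_abundance": 0.0,
                                "Tc->Tnk.maturation_rate": 0.03068})
print(cs.classify_attractor(cs.simulate_ode(kd, cs.OdeParams(t_end=800))).label)
# Tc_dominant

scan = cs.scan_bystander_help(assembly, [0.0, 2.0, 4.5],
                              cs.OdeParams(t_end=800.0, n_samples=801),
                              compute_lyapunov=False)
print([l.label for l in scan.labels])
# ['Tr1_dominant', 'Tr1_dominant', 'Tc_dominant']
```

The same logic, exactly, with dice:

```python
ok, records = cs.verify_intransitive_cycle(cs.efron_dice())
print(ok, records[0].p_win)   # True 2/3  (24/36, zero draws, every edge)
```

Or from the shell:

```
clicksim reduce --config src/clicksim/fixtures/fig1_4click.json
clicksim simulate --config src/clicksim/fixtures/fig2a.config --out out/
clicksim dice --set src/clicksim/fixtures/efron.json --match A B
```

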