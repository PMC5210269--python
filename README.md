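# minnet

MILP-based reduction of genome-scale metabolic networks to **minimum
subnetworks**: the smallest sets of reactions that still support a given
list of protected metabolites, protected reactions, and linear flux
functionalities — with exhaustive enumeration of all alternative minima.

## What it does

Given a stoichiometric model (SBML or BiGG-style JSON) and a *reduction
scenario*, minnet finds subnetworks (subsets of reactions, with all other
fluxes fixed to zero) of minimum cardinality such that:

- every **protected reaction** can carry a flux of at least `delta` in
  absolute value;
- every **protected metabolite** keeps at least one active reaction
  producing or consuming it;
- every **linear functionality** `D_f v <= d_f` (e.g. "biomass flux ≥ 1
  under anaerobic conditions", or a fraction-of-optimum requirement) is
  satisfiable *within the subnetwork* — each functionality by its own flux
  distribution, so mutually contradictory conditions (aerobic *and*
  anaerobic) are supported;
- the subnetwork retains at least `dof_min` stoichiometric degrees of
  freedom.

Alternative optima are enumerated exhaustively via integer cuts, with a
termination certificate (`exhausted=True`). A variable-reduction variant
uses one binary per *partial flux-coupling class* instead of one per
reaction, which provably yields the same minima.

## Quick start (Python)

```python
import minnet
from minnet.model_io import LinearFunctionality, ReductionScenario

net = minnet.read_model("model.xml")
scenario = ReductionScenario(
    protected_reactions={"BIOMASS"},
    functionalities=[
        LinearFunctionality.from_rows(
            "growth", [({"BIOMASS": 1.0}, ">=", 1.0)]),
    ],
    dof_min=1, delta=1e-4, encoding="indicator")
scenario = minnet.resolve_scenario(net, scenario)

sol = minnet.minimum_subnetwork(net, scenario)
print(sol.n_active, sorted(sol.active))

result = minnet.enumerate_all(net, scenario)
print(result.minimum_size, len(result.solutions), result.exhausted)
```

## Quick start (CLI)

```bash
# dead ends, blocked reactions, coupling classes
minnet preprocess model.xml --out report.tsv

# minimum subnetwork(s) for a scenario
minnet reduce model.xml scenario.yaml --out results/ --enumerate-all

# essential reactions, FVA, comparison across enumerated minima
minnet analyze model.xml --result results/result.json \
    --objective BIOMASS --out analysis/
```

Scenario file schema (YAML or JSON):

```yaml
protected_metabolites: [atp_c]
protected_reactions: [BIOMASS]
functionalities:
  - label: aerobic
    rows:
      - {coeffs: {BIOMASS: 1.0}, relation: ">=", rhs: 1.0}
  - label: anaerobic_growth
    fraction_of_optimum:
      reaction: BIOMASS
      fraction: 0.5
      fixed:
        - {coeffs: {EX_o2: 1.0}, relation: "=", rhs: 0.0}
dof_min: 1
delta: 1.0e-4       # activity threshold (recommended 1e-6 .. 1e-4)
encoding: indicator  # or bigM
```

Exit codes: `0` success, `2` validation/usage error, `3` infeasible
scenario (no subnetwork satisfies the requirements), `4` solver failure.

## Testing

```bash
pytest                       # full suite, ~30 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` checks the headline claims against an
independent brute-force oracle (explicit subset enumeration + plain LPs,
no MILP involved): on 100 seeded random networks the MILP's optimal sizes
*and* full enumerated solution families match the oracle exactly, the
big-M and indicator encodings and the coupling-class formulation agree,
and the dual-condition toy reproduces the joint-minimum < union-of-minima
phenomenon.

## Module map

| Module | Contents |
| --- | --- |
| `minnet.model_io` | `MetabolicNetwork`, scenarios, SBML/JSON/YAML I/O |
| `minnet.preprocess` | dead ends, blocked reactions, partial-coupling classes |
| `minnet.milp` | MinNW-0 / minNW / minNW_rep builders, encodings, solving |
| `minnet.backends` | GLPK adapter with incumbent verification |
| `minnet.enumeration` | integer cuts, dof filter, exhaustive enumeration |
| `minnet.analyze` | FVA, essential reactions, subnetwork comparison |
| `minnet.fixtures` | toy networks, random generators, brute-force oracle |
| `minnet.cli` | `minnet preprocess / reduce / analyze` |

See `docs/methods.md` for the mathematical formulation and design notes.
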