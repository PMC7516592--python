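"""Shared fixtures: small networks and brute-force inference oracles."""

import itertools

import pytest

from qlbn import (
    BayesNet,
    ConditionalTable,
    EvidenceMap,
    VariableSpec,
    build_network,
)


def make_two_node(p_y_given_x: float, p_y_given_not_x: float, prior: float = 0.5) -> BayesNet:
    """X -> Y over states (x, not_x) / (y, not_y)."""
    return BayesNet(
        [VariableSpec("X", ("x", "not_x")), VariableSpec("Y", ("y", "not_y"))],
        [
            ConditionalTable("X", (), {(): (prior, 1.0 - prior)}),
            ConditionalTable(
                "Y",
                ("X",),
                {
                    ("x",): (p_y_given_x, 1.0 - p_y_given_x),
                    ("not_x",): (p_y_given_not_x, 1.0 - p_y_given_not_x),
                },
            ),
        ],
    )


def brute_posterior(net: BayesNet, query: str, outcome: str, evidence: EvidenceMap) -> float:
    """Posterior by exhaustive summation over the full joint table."""
    from qlbn import joint_probability

    names = net.variable_names
    num = den = 0.0
    for combo in itertools.product(*(net.variable(n).states for n in names)):
        assignment = dict(zip(names, combo))
        if any(assignment[k] != v for k, v in evidence.items()):
            continue
        p = joint_probability(net, assignment)
        den += p
        if assignment[query] == outcome:
            num += p
    return num / den


@pytest.fixture
def pd_row_a() -> BayesNet:
    """Prisoner's Dilemma row (a): defect rates 0.84 (cooperate) / 0.97 (defect)."""
    # modelled outcome is not_y (defect); p(y|x)=0.16, p(y|not_x)=0.03
    return make_two_node(0.16, 0.03)


@pytest.fixture
def m3_net() -> BayesNet:
    """Three-configuration worked example: ternary hidden X, binary Y."""
    return build_network(
        {
            "variables": [
                {"name": "X", "states": ["x1", "x2", "x3"]},
                {"name": "Y", "states": ["y", "not_y"]},
            ],
            "tables": [
                {
                    "child": "X",
                    "parents": [],
                    "rows": [{"given": {}, "dist": {"x1": 0.2, "x2": 0.5, "x3": 0.3}}],
                },
                {
                    "child": "Y",
                    "parents": ["X"],
                    "rows": [
                        {"given": {"X": "x1"}, "dist": {"y": 0.13, "not_y": 0.87}},
                        {"given": {"X": "x2"}, "dist": {"y": 0.33, "not_y": 0.67}},
                        {"given": {"X": "x3"}, "dist": {"y": 0.23, "not_y": 0.77}},
                    ],
                },
            ],
        }
    )


@pytest.fixture
def burglar_net() -> BayesNet:
    """Burglary/earthquake -> alarm -> call topology (illustrative CPT values)."""
    return BayesNet(
        [
            VariableSpec("burglary", ("t", "f")),
            VariableSpec("earthquake", ("t", "f")),
            VariableSpec("alarm", ("t", "f")),
            VariableSpec("call", ("t", "f")),
        ],
        [
            ConditionalTable("burglary", (), {(): (0.001, 0.999)}),
            ConditionalTable("earthquake", (), {(): (0.002, 0.998)}),
            ConditionalTable(
                "alarm",
                ("burglary", "earthquake"),
                {
                    ("t", "t"): (0.95, 0.05),
                    ("t", "f"): (0.94, 0.06),
                    ("f", "t"): (0.29, 0.71),
                    ("f", "f"): (0.001, 0.999),
                },
            ),
            ConditionalTable("call", ("alarm",), {("t",): (0.9, 0.1), ("f",): (0.05, 0.95)}),
        ],
    )
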