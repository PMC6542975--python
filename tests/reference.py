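"""Independent reference implementations used as oracles in tests.

Everything here deliberately avoids eisdry's circuit machinery: random
topologies are plain nested tuples evaluated with inline complex arithmetic,
and the CPE uses complex exponentiation ``(1j*omega)**n`` rather than the
package's explicit magnitude/phase form, so agreement is a genuine
cross-check of two independent code paths.
"""

from __future__ import annotations

import numpy as np

# node forms: ("R", value) | ("C", value) | ("CPE", p, n)
#             ("series", [nodes]) | ("parallel", [nodes])


def reference_impedance(node, omega):
    kind = node[0]
    if kind == "R":
        return node[1] + 0j * omega
    if kind == "C":
        return 1.0 / (1j * omega * node[1])
    if kind == "CPE":
        return 1.0 / (node[1] * (1j * omega) ** node[2])
    parts = [reference_impedance(child, omega) for child in node[1]]
    if kind == "series":
        return sum(parts)
    if kind == "parallel":
        return 1.0 / sum(1.0 / z for z in parts)
    raise ValueError(kind)


def random_circuit_case(rng: np.random.Generator, max_elements: int = 8):
    """Random series/parallel tree of 1..max_elements elements.

    Returns (expression, params, tree) where ``expression`` and ``params``
    feed eisdry's parser/evaluator and ``tree`` feeds
    :func:`reference_impedance`.
    """
    n_elements = int(rng.integers(1, max_elements + 1))
    counter = {"i": 0}
    params: dict[str, float] = {}

    def make_element():
        counter["i"] += 1
        idx = counter["i"]
        kind = rng.choice(["R", "C", "CPE"])
        if kind == "R":
            value = 10.0 ** rng.uniform(0, 6)
            params[f"R{idx}"] = value
            return f"R{idx}", ("R", value)
        if kind == "C":
            value = 10.0 ** rng.uniform(-9, -4)
            params[f"C{idx}"] = value
            return f"C{idx}", ("C", value)
        p = 10.0 ** rng.uniform(-9, -4)
        n = rng.uniform(0.3, 1.0)
        params[f"P{idx}"] = p
        params[f"n{idx}"] = n
        return f"CPE{idx}", ("CPE", p, n)

    def build(budget: int):
        if budget == 1:
            return make_element()
        split = int(rng.integers(1, budget))
        left_expr, left_tree = build(split)
        right_expr, right_tree = build(budget - split)
        if rng.random() < 0.5:
            return f"({left_expr})-({right_expr})", ("series", [left_tree, right_tree])
        return f"({left_expr})|({right_expr})", ("parallel", [left_tree, right_tree])

    expression, tree = build(n_elements)
    return expression, params, tree
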