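"""Equivalent-circuit models: elements, a series/parallel expression language,
and the classical plant-tissue circuits as built-ins.

Element impedances (omega in rad/s):

* resistor          Z = R
* capacitor         Z = 1 / (j omega C)
* constant phase    Z = 1 / (P (j omega)^n), principal branch, i.e.
  element (CPE)     |Z| = 1 / (P omega^n) at constant phase -n*90 deg.
                    n = 1 reduces to a capacitor with C = P; n -> 0 tends to
                    a resistor 1/P.

Expression grammar: element tokens ``R<name>``, ``C<name>``, ``CPE<name>``
(the CPE may be bare ``CPE``); ``|`` is parallel, ``-`` is series, and ``|``
binds tighter than ``-``; parentheses group.  ``"Re|(Ri-Cm)"`` is the
simplified Hayden circuit.  A resistor or capacitor token is its own
parameter name; a CPE token ``CPE<x>`` contributes parameters ``P<x>`` and
``n<x>``.

The built-in circuits model current paths in plant tissue: extracellular
fluid (resistive), cell membranes (capacitive, shorting out at high
frequency - the beta dispersion) and intracellular fluid (resistive); the
double-shell model adds the vacuole behind the tonoplast as a second shell.
All built-ins are passive RC/CPE ladders: Re(Z) > 0, Im(Z) <= 0, and |Z|
non-increasing in frequency for positive parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import CircuitParseError, DomainError, ParameterError
from .spectra import ImpedanceSpectrum

__all__ = [
    "Element",
    "Series",
    "Parallel",
    "CircuitModel",
    "element_impedance",
    "parse_circuit",
    "evaluate_circuit",
    "builtin_model",
    "BUILTIN_MODELS",
]

# Default fitting bounds per parameter kind; brackets vegetable-tissue scales.
DEFAULT_BOUNDS = {
    "resistor": (1e-3, 1e9),     # ohm
    "capacitor": (1e-15, 1.0),   # farad
    "cpe_p": (1e-15, 1.0),       # S s^n
    "cpe_n": (1e-6, 1.0),        # dimensionless, (0, 1]
}


@dataclass(frozen=True)
class Element:
    """A circuit leaf: resistor, capacitor, or constant phase element.

    ``name`` is the token as written (e.g. ``"Re"``, ``"Cm"``, ``"CPE1"``).
    """

    kind: str  # "resistor" | "capacitor" | "cpe"
    name: str

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.kind == "cpe":
            suffix = self.name[3:]
            return (f"P{suffix}", f"n{suffix}")
        return (self.name,)

    @property
    def param_kinds(self) -> tuple[str, ...]:
        if self.kind == "cpe":
            return ("cpe_p", "cpe_n")
        return (self.kind,)


@dataclass(frozen=True)
class Series:
    children: tuple = ()


@dataclass(frozen=True)
class Parallel:
    children: tuple = ()


Node = Union[Element, Series, Parallel]


def element_impedance(element: Element, params: Mapping[str, float], omega):
    """Complex impedance of a single element at angular frequency omega.

    ``params`` maps the element's parameter names to values.  omega may be a
    scalar or array of positive rad/s values.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise DomainError("angular frequency must be positive")
    try:
        if element.kind == "resistor":
            (rname,) = element.param_names
            r = params[rname]
            if r <= 0:
                raise ParameterError(f"{rname} must be positive, got {r}")
            return np.broadcast_to(r + 0j, omega.shape).copy() if omega.ndim else complex(r)
        if element.kind == "capacitor":
            (cname,) = element.param_names
            c = params[cname]
            if c <= 0:
                raise ParameterError(f"{cname} must be positive, got {c}")
            return 1.0 / (1j * omega * c)
        if element.kind == "cpe":
            pname, nname = element.param_names
            p, n = params[pname], params[nname]
            if p <= 0:
                raise ParameterError(f"{pname} must be positive, got {p}")
            if not 0 < n <= 1:
                raise ParameterError(f"{nname} must lie in (0, 1], got {n}")
            # principal branch: (j omega)^n = omega^n exp(j n pi / 2)
            return 1.0 / (p * omega**n * np.exp(1j * n * np.pi / 2))
    except KeyError as exc:
        raise ParameterError(f"missing parameter {exc.args[0]!r}") from exc
    raise ParameterError(f"unknown element kind {element.kind!r}")


def _node_impedance(node: Node, params: Mapping[str, float], omega):
    if isinstance(node, Element):
        return element_impedance(node, params, omega)
    parts = [_node_impedance(child, params, omega) for child in node.children]
    if isinstance(node, Series):
        return sum(parts)
    return 1.0 / sum(1.0 / z for z in parts)


def _leaves(node: Node):
    if isinstance(node, Element):
        yield node
    else:
        for child in node.children:
            yield from _leaves(child)


@dataclass
class CircuitModel:
    """A series/parallel topology of elements with named parameters.

    ``defaults`` hold plausible starting values; ``bounds`` the box used by
    the fitter.  Both cover every parameter (filled from per-kind defaults
    when not given explicitly).
    """

    root: Node
    name: str = ""
    expression: str = ""
    defaults: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        names: list[str] = []
        kinds: dict[str, str] = {}
        for leaf in _leaves(self.root):
            for pname, pkind in zip(leaf.param_names, leaf.param_kinds):
                if pname in kinds:
                    raise CircuitParseError(f"duplicate parameter name {pname!r}")
                names.append(pname)
                kinds[pname] = pkind
        self._param_names = tuple(names)
        self._param_kinds = kinds
        for pname in names:
            self.bounds.setdefault(pname, DEFAULT_BOUNDS[kinds[pname]])
            if pname not in self.defaults:
                self.defaults[pname] = 0.8 if kinds[pname] == "cpe_n" else float(
                    np.sqrt(np.prod(self.bounds[pname]))
                )

    @property
    def param_names(self) -> tuple[str, ...]:
        return self._param_names

    @property
    def param_kinds(self) -> dict[str, str]:
        return dict(self._param_kinds)

    @property
    def n_params(self) -> int:
        return len(self._param_names)

    def impedance(self, params: Mapping[str, float], omega):
        """Complex impedance at angular frequency omega (rad/s)."""
        missing = [p for p in self._param_names if p not in params]
        if missing:
            raise ParameterError(f"missing parameters: {missing}")
        return _node_impedance(self.root, params, omega)


# ---------------------------------------------------------------------------
# expression parser: series = parallel ('-' parallel)*;
# parallel = atom ('|' atom)*; atom = element | '(' series ')'

_TOKEN_CHARS = "()-|"


def _tokenize(text: str):
    tokens = []  # (value, position)
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in _TOKEN_CHARS:
            tokens.append((ch, i))
            i += 1
            continue
        if ch.isalnum() or ch == "_":
            j = i
            while j < len(text) and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append((text[i:j], i))
            i = j
            continue
        raise CircuitParseError(f"unexpected character {ch!r}", position=i)
    return tokens


def _classify(token: str, position: int) -> Element:
    if token.startswith("CPE"):
        return Element("cpe", token)
    if token.startswith("C"):
        return Element("capacitor", token)
    if token.startswith("R"):
        return Element("resistor", token)
    raise CircuitParseError(
        f"unknown element kind in token {token!r} "
        "(expected prefix R, C or CPE)",
        position=position,
    )


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.text))

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.series()
        tok, at = self.peek()
        if tok is not None:
            raise CircuitParseError(f"unexpected token {tok!r}", position=at)
        return node

    def series(self) -> Node:
        parts = [self.parallel()]
        while self.peek()[0] == "-":
            self.next()
            parts.append(self.parallel())
        return parts[0] if len(parts) == 1 else Series(tuple(parts))

    def parallel(self) -> Node:
        parts = [self.atom()]
        while self.peek()[0] == "|":
            self.next()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else Parallel(tuple(parts))

    def atom(self) -> Node:
        tok, at = self.next()
        if tok == "(":
            node = self.series()
            close, cat = self.next()
            if close != ")":
                raise CircuitParseError("missing ')'", position=cat)
            return node
        if tok is None or tok in _TOKEN_CHARS:
            raise CircuitParseError(
                f"expected an element or '(', got {tok!r}", position=at
            )
        return _classify(tok, at)


def parse_circuit(expression: str, name: str = "",
                  defaults: Mapping[str, float] | None = None,
                  bounds: Mapping[str, tuple[float, float]] | None = None
                  ) -> CircuitModel:
    """Parse a circuit expression into a :class:`CircuitModel`.

    Raises :class:`~eisdry.errors.CircuitParseError` with the character
    position on malformed input (unbalanced parentheses, unknown element
    prefix, duplicate parameter names).
    """
    root = _Parser(expression).parse()
    return CircuitModel(
        root,
        name=name or expression,
        expression=expression,
        defaults=dict(defaults or {}),
        bounds=dict(bounds or {}),
    )


def evaluate_circuit(circuit: CircuitModel, params: Mapping[str, float],
                     frequencies: Sequence[float], label: str = ""
                     ) -> ImpedanceSpectrum:
    """Evaluate a circuit on a grid of frequencies in Hz.

    Series nodes sum impedances, parallel nodes sum admittances; omega =
    2 pi f.  Returns an :class:`~eisdry.spectra.ImpedanceSpectrum`.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequencies must be positive")
    z = circuit.impedance(params, 2.0 * np.pi * f)
    return ImpedanceSpectrum(f, np.asarray(z, dtype=complex), label=label)


# ---------------------------------------------------------------------------
# built-in plant-tissue circuits

_BUILTIN_SPECS = {
    # Hayden: extracellular resistance Re in parallel with the cellular path
    # (membrane Rm||Cm in series with intracellular Ri).
    "hayden": (
        "Re|((Rm|Cm)-Ri)",
        {"Re": 10_000.0, "Rm": 1_000.0, "Cm": 5e-8, "Ri": 2_000.0},
    ),
    # Simplified Hayden: membrane resistance ignored.
    "simplified_hayden": (
        "Re|(Ri-Cm)",
        {"Re": 10_000.0, "Ri": 2_000.0, "Cm": 5e-8},
    ),
    # CPE in place of the membrane capacitance: depressed (semi-elliptic) arc.
    "cpe_modified": (
        "Re|(Ri-CPE)",
        {"Re": 10_000.0, "Ri": 2_000.0, "P": 1e-6, "n": 0.8},
    ),
    # Double-shell: cell wall R1, plasma membrane C1, cytoplasm R2,
    # tonoplast C2, vacuole R3.
    "double_shell": (
        "R1|(C1-(R2|(C2-R3)))",
        {"R1": 10_000.0, "C1": 2e-8, "R2": 3_000.0, "C2": 5e-7, "R3": 1_000.0},
    ),
    # Dehydration model used here: a series resistor with two relaxation
    # blocks, one dispersive (CPE) and one ideal (RC).  The CPE block lets it
    # represent any single depressed arc exactly (R + ZARC is equivalent to
    # the CPE-modified topology), while the RC block adds a second time
    # constant.  The topology is configurable; this default is this package's
    # choice, not a claim about any particular tissue.
    "proposed": (
        "R1-(R2|CPE1)-(R3|C1)",
        {"R1": 500.0, "R2": 8_000.0, "P1": 1e-7, "n1": 0.8,
         "R3": 3_000.0, "C1": 2e-7},
    ),
}

BUILTIN_MODELS = tuple(_BUILTIN_SPECS)


def builtin_model(name: str) -> CircuitModel:
    """Return a named built-in circuit with default parameters and bounds.

    Valid names: ``hayden``, ``simplified_hayden``, ``cpe_modified``,
    ``double_shell``, ``proposed``.
    """
    try:
        expression, defaults = _BUILTIN_SPECS[name]
    except KeyError:
        raise LookupError(
            f"unknown model {name!r}; valid names: {', '.join(BUILTIN_MODELS)}"
        ) from None
    return parse_circuit(expression, name=name, defaults=defaults)
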