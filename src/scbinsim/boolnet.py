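"""Boolean networks: BoolNet-format I/O, dynamics and influence graphs.

A Boolean network on nodes {1..n} is a function f: {0,1}^n -> {0,1}^n;
configurations are binary vectors aligned to the node list.  Supported
dynamics are the synchronous mode (x' = f(x)) and the fully
asynchronous mode (one randomly chosen unstable node flips per step).
The influence graph carries a positive edge j -> i when flipping node j
from 0 to 1 can increase f_i in some configuration, and a negative edge
when it can decrease it; both may coexist (non-monotone dependence).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BooleanNetwork",
    "Trace",
    "parse_boolnet",
    "influence_graph",
    "async_random_walk",
    "synchronous_trace",
    "star_network",
    "bistable_switch",
    "tristable_switch",
]


# ---------------------------------------------------------------------------
# expression parsing (BoolNet "targets, factors" dialect)

_TOKEN_RE = re.compile(r"\s*(?:(?P<id>[A-Za-z_][\w.]*)|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise SyntaxError(f"cannot tokenise {text[pos:]!r}")
        if m.lastgroup:
            tokens.append((m.lastgroup, m.group(m.lastgroup)))
        pos = m.end()
        if m.end() == pos and not m.group(0):
            raise SyntaxError(f"stuck at {text[pos:]!r}")
    return tokens


class _Parser:
    """Recursive descent over  expr := term ('|' term)* ;
    term := fact ('&' fact)* ; fact := '!' fact | '(' expr ')' | id | const."""

    def __init__(self, tokens):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self, kind=None, value=None):
        k, v = self.peek()
        if kind is not None and k != kind or value is not None and v != value:
            raise SyntaxError(f"expected {value or kind}, found {v!r}")
        self.pos += 1
        return v

    def parse(self):
        node = self.expr()
        if self.pos != len(self.tokens):
            raise SyntaxError(f"trailing tokens: {self.tokens[self.pos:]}")
        return node

    def expr(self):
        parts = [self.term()]
        while self.peek() == ("op", "|"):
            self.take()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def term(self):
        parts = [self.fact()]
        while self.peek() == ("op", "&"):
            self.take()
            parts.append(self.fact())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def fact(self):
        k, v = self.peek()
        if (k, v) == ("op", "!"):
            self.take()
            return ("not", self.fact())
        if (k, v) == ("op", "("):
            self.take()
            inner = self.expr()
            self.take("op", ")")
            return inner
        if k == "id":
            self.take()
            return ("var", v)
        if k == "const":
            self.take()
            return ("const", int(v))
        raise SyntaxError(f"unexpected token {v!r}")


def _eval_ast(ast, env: dict) -> int:
    op = ast[0]
    if op == "var":
        return int(env[ast[1]])
    if op == "const":
        return ast[1]
    if op == "not":
        return 1 - _eval_ast(ast[1], env)
    if op == "and":
        return int(all(_eval_ast(a, env) for a in ast[1]))
    if op == "or":
        return int(any(_eval_ast(a, env) for a in ast[1]))
    raise ValueError(f"bad AST node {op}")


def _ast_vars(ast, acc: set) -> set:
    if ast[0] == "var":
        acc.add(ast[1])
    elif ast[0] == "not":
        _ast_vars(ast[1], acc)
    elif ast[0] in ("and", "or"):
        for a in ast[1]:
            _ast_vars(a, acc)
    return acc


# ---------------------------------------------------------------------------
# network object


class BooleanNetwork:
    """Node list plus one update function per node.

    Functions are stored as expression ASTs when parsed from text, or as
    explicit truth tables; both evaluate through :meth:`evaluate`.
    """

    def __init__(self, nodes: list[str], asts: dict | None = None,
                 tables: dict | None = None, expressions: dict | None = None):
        if len(set(nodes)) != len(nodes):
            raise ValueError("node ids must be unique")
        self.nodes = list(nodes)
        self._asts = asts or {}
        self._tables = tables or {}
        self.expressions = expressions or {}
        missing = [n for n in self.nodes if n not in self._asts and n not in self._tables]
        if missing:
            raise ValueError(f"nodes without update function: {missing}")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @classmethod
    def from_truth_table(cls, nodes: list[str], tables: dict) -> "BooleanNetwork":
        """tables[node][idx] with idx = sum_j x_j << j over the node order."""
        return cls(nodes, tables={n: np.asarray(t, dtype=int) for n, t in tables.items()})

    def _config_index(self, x) -> int:
        return int(sum(int(v) << j for j, v in enumerate(x)))

    def evaluate_node(self, node: str, x) -> int:
        if node in self._tables:
            return int(self._tables[node][self._config_index(x)])
        env = dict(zip(self.nodes, (int(v) for v in x)))
        return _eval_ast(self._asts[node], env)

    def evaluate(self, x) -> np.ndarray:
        """Componentwise image f(x) of a configuration."""
        x = np.asarray(x, dtype=int)
        if x.shape != (self.n,):
            raise ValueError(f"configuration must have length {self.n}")
        return np.array([self.evaluate_node(node, x) for node in self.nodes], dtype=int)

    def is_stable(self, x) -> bool:
        """Fixed-point test f(x) = x."""
        x = np.asarray(x, dtype=int)
        return bool(np.array_equal(self.evaluate(x), x))

    def stable_states(self) -> list[np.ndarray]:
        """Exhaustive fixed-point enumeration (small n only)."""
        if self.n > 20:
            raise ValueError("exhaustive enumeration limited to n <= 20 nodes")
        out = []
        for bits in itertools.product((0, 1), repeat=self.n):
            x = np.array(bits, dtype=int)
            if self.is_stable(x):
                out.append(x)
        return out

    def to_boolnet(self) -> str:
        """Serialise to BoolNet text ("targets, factors")."""
        lines = ["targets, factors"]
        for node in self.nodes:
            if node in self.expressions:
                expr = self.expressions[node]
            elif node in self._tables:
                expr = self._dnf(node)
            else:
                expr = _ast_to_text(self._asts[node])
            lines.append(f"{node}, {expr}")
        return "\n".join(lines) + "\n"

    def _dnf(self, node: str) -> str:
        table = self._tables[node]
        ones = [i for i in range(2 ** self.n) if table[i]]
        if not ones:
            return "0"
        if len(ones) == 2 ** self.n:
            return "1"
        terms = []
        for idx in ones:
            lits = [(name if (idx >> j) & 1 else f"!{name}")
                    for j, name in enumerate(self.nodes)]
            terms.append("(" + " & ".join(lits) + ")")
        return " | ".join(terms)


def _ast_to_text(ast) -> str:
    op = ast[0]
    if op == "var":
        return ast[1]
    if op == "const":
        return str(ast[1])
    if op == "not":
        inner = _ast_to_text(ast[1])
        return f"!{inner}" if ast[1][0] in ("var", "const", "not") else f"!({inner})"
    sep = " & " if op == "and" else " | "
    parts = []
    for a in ast[1]:
        t = _ast_to_text(a)
        if op == "and" and a[0] == "or":
            t = f"({t})"
        parts.append(t)
    return sep.join(parts)


def parse_boolnet(text: str) -> BooleanNetwork:
    """Parse BoolNet "targets, factors" text into a network."""
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines or not lines[0].lower().replace(" ", "").startswith("targets,factors"):
        raise SyntaxError('missing "targets, factors" header')
    nodes, asts, exprs = [], {}, {}
    for ln_no, ln in enumerate(lines[1:], start=2):
        if "," not in ln:
            raise SyntaxError(f"line {ln_no}: expected 'target, factors'")
        target, factors = ln.split(",", 1)
        target = target.strip()
        try:
            ast = _Parser(_tokenize(factors)).parse()
        except SyntaxError as exc:
            raise SyntaxError(f"line {ln_no}: {exc}") from exc
        if target in asts:
            raise SyntaxError(f"line {ln_no}: duplicate target {target!r}")
        nodes.append(target)
        asts[target] = ast
        exprs[target] = factors.strip()
    used = set()
    for ast in asts.values():
        _ast_vars(ast, used)
    undefined = sorted(used - set(nodes))
    if undefined:
        raise SyntaxError(f"undefined node reference(s): {undefined}")
    return BooleanNetwork(nodes, asts=asts, expressions=exprs)


# ---------------------------------------------------------------------------
# dynamics


@dataclass
class Trace:
    """Ordered configuration sequence under a named update mode."""

    configurations: list
    update_mode: str
    nodes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.configurations)

    def to_frame(self, prefix: str = "s") -> pd.DataFrame:
        """Boolean state matrix (samples x nodes) with step-numbered ids."""
        data = np.array(self.configurations, dtype=int)
        index = [f"{prefix}{i}" for i in range(len(self.configurations))]
        return pd.DataFrame(data, index=index, columns=self.nodes)

    def is_valid(self, network: BooleanNetwork) -> bool:
        """Check the consecutive-configuration invariant of the mode."""
        for a, b in zip(self.configurations[:-1], self.configurations[1:]):
            a, b = np.asarray(a), np.asarray(b)
            if self.update_mode == "synchronous":
                if not np.array_equal(b, network.evaluate(a)):
                    return False
            elif self.update_mode == "asynchronous":
                diff = np.flatnonzero(a != b)
                if diff.size != 1:
                    return False
                i = int(diff[0])
                if b[i] != network.evaluate_node(network.nodes[i], a):
                    return False
            else:
                raise ValueError(f"unknown update mode {self.update_mode!r}")
        return True


def async_random_walk(network: BooleanNetwork, x0, max_steps: int = 1000,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> Trace:
    """Fully asynchronous random walk until a stable state or max_steps.

    At each step one node whose update disagrees with its current state
    is chosen uniformly at random and flipped.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    x = np.asarray(x0, dtype=int).copy()
    configs = [x.copy()]
    for _ in range(max_steps):
        fx = network.evaluate(x)
        unstable = np.flatnonzero(fx != x)
        if unstable.size == 0:
            break
        i = int(rng.choice(unstable))
        x[i] = fx[i]
        configs.append(x.copy())
    return Trace(configs, "asynchronous", list(network.nodes))


def synchronous_trace(network: BooleanNetwork, x0, k: int) -> Trace:
    """Deterministic synchronous iteration for k steps."""
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(x0, dtype=int).copy()
    configs = [x.copy()]
    for _ in range(k):
        x = network.evaluate(x)
        configs.append(x.copy())
    return Trace(configs, "synchronous", list(network.nodes))


def influence_graph(network: BooleanNetwork) -> set[tuple[str, str, str]]:
    """Signed edges (source, target, sign) of the influence graph.

    Edge (j, i, "+") iff some configuration has f_i increasing in x_j,
    (j, i, "-") iff some has it decreasing; exhaustive over all
    configurations (guarded to n <= 20 nodes).
    """
    n = network.n
    if n > 20:
        raise ValueError("influence graph enumeration limited to n <= 20 nodes")
    edges: set[tuple[str, str, str]] = set()
    for j, src in enumerate(network.nodes):
        others = [idx for idx in range(n) if idx != j]
        for bits in itertools.product((0, 1), repeat=n - 1):
            x0 = np.zeros(n, dtype=int)
            x0[others] = bits
            x1 = x0.copy()
            x1[j] = 1
            f0, f1 = network.evaluate(x0), network.evaluate(x1)
            for i, tgt in enumerate(network.nodes):
                if f0[i] < f1[i]:
                    edges.add((src, tgt, "+"))
                elif f0[i] > f1[i]:
                    edges.add((src, tgt, "-"))
    return edges


# ---------------------------------------------------------------------------
# packaged demonstration models


def star_network(n_genes: int = 8) -> BooleanNetwork:
    """A self-sustaining transcription factor activating n independent genes.

    From (tf=1, all genes 0) the asynchronous walk activates the genes
    one per step in random order and stops at the all-active fixed
    point.
    """
    lines = ["targets, factors", "tf, tf"]
    lines += [f"g{i}, tf" for i in range(1, n_genes + 1)]
    return parse_boolnet("\n".join(lines))


def bistable_switch() -> BooleanNetwork:
    """Reprogramming scenario: a common state destabilised into two fates.

    TF6 maintains the common state and represses the mutually exclusive
    pair (TF8, TF9); activating the perturbation input TF7 shuts TF6
    down, releasing the switch, whose winner activates its own gene
    battery.
    """
    text = """
    targets, factors
    TF6, TF6 & !TF7
    TF7, TF7
    TF8, (TF8 | !TF6) & !TF9
    TF9, (TF9 | !TF6) & !TF8
    G6a, TF6
    G6b, TF6
    G8a, TF8
    G8b, TF8
    G9a, TF9
    G9b, TF9
    """
    return parse_boolnet("\n".join(ln.strip() for ln in text.strip().splitlines()))


def tristable_switch() -> BooleanNetwork:
    """Two-level differentiation: three stable fates, one via a branch point.

    From the initial signal S, fate A competes with the intermediate I;
    once I wins, fates B and C compete downstream, giving stable states
    {A}, {I,B} and {I,C} with their gene batteries.
    """
    text = """
    targets, factors
    S, S & !A & !I
    A, (A | S) & !I
    I, (I | S) & !A
    B, I & !C
    C, I & !B
    GA, A
    GI, I
    GB, B
    GC, C
    """
    return parse_boolnet("\n".join(ln.strip() for ln in text.strip().splitlines()))
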