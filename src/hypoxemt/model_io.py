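"""Reading, validating and writing Boolean regulatory network models.

The rule dialect is a line-oriented plain-text format in the BooleanNet
family::

    # comment
    name: MyModel
    inputs: Hypoxia, GF
    module: EMT = SNAI1, ZEB1
    SNAI1 *= (Hypoxia or ZEB1) and not Density_High
    ZEB1 *= SNAI1 or ZEB1

One update rule per line, ``Name *= expression``; expressions use the
lower-case operators ``and``, ``or``, ``not``, parentheses and the
constants ``True``/``False``.  Node names are case-sensitive identifiers.
Environmental inputs carry no rule: they are listed in the ``inputs:``
header (self-assignments ``X *= X`` are also accepted and treated as input
declarations, the convention used by published BooleanNet files).
"""

from __future__ import annotations

import ast
import hashlib
import keyword
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "BoolExpr",
    "NodeSpec",
    "BooleanModel",
    "ModelSyntaxError",
    "parse_expression",
    "parse_model",
    "write_model",
    "count_links",
]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class ModelSyntaxError(ValueError):
    """Raised for malformed model text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _check_name(name: str, line: int | None = None) -> str:
    if not _NAME_RE.match(name) or keyword.iskeyword(name) or name in ("True", "False"):
        raise ModelSyntaxError(f"invalid node name {name!r}", line)
    return name


class BoolExpr:
    """A Boolean expression over node identifiers.

    Wraps a restricted Python ``ast`` (``and``/``or``/``not``, names and
    the constants ``True``/``False``), keeping the normalized source text
    for serialization and the syntactic regulator list in first-appearance
    order.
    """

    __slots__ = ("text", "regulators", "_code")

    def __init__(self, text: str, line: int | None = None):
        text = text.strip()
        if not text:
            raise ModelSyntaxError("empty expression", line)
        try:
            tree = ast.parse(text, mode="eval")
        except SyntaxError as exc:
            raise ModelSyntaxError(f"cannot parse expression {text!r}: {exc.msg}", line) from None
        regulators: list[str] = []
        for node in ast.walk(tree):
            if isinstance(node, (ast.Expression, ast.BoolOp, ast.And, ast.Or, ast.Not, ast.Load)):
                continue
            if isinstance(node, ast.UnaryOp):
                if not isinstance(node.op, ast.Not):
                    raise ModelSyntaxError(f"operator not allowed in {text!r}", line)
                continue
            if isinstance(node, ast.Name):
                _check_name(node.id, line)
                if node.id not in regulators:
                    regulators.append(node.id)
                continue
            if isinstance(node, ast.Constant) and node.value in (True, False):
                continue
            raise ModelSyntaxError(
                f"only and/or/not, names and True/False allowed, got {type(node).__name__} in {text!r}",
                line,
            )
        self.text = text
        self.regulators = tuple(regulators)
        self._code = compile(tree, "<rule>", "eval")

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        """Evaluate on a complete truth assignment; returns 0 or 1."""
        env = {name: bool(assignment[name]) for name in self.regulators}
        return 1 if eval(self._code, {"__builtins__": {}}, env) else 0

    def __eq__(self, other) -> bool:
        return isinstance(other, BoolExpr) and self.text == other.text

    def __hash__(self) -> int:
        return hash(self.text)

    def __repr__(self) -> str:
        return f"BoolExpr({self.text!r})"


def parse_expression(text: str, line: int | None = None) -> BoolExpr:
    """Parse a single rule expression."""
    return BoolExpr(text, line)


@dataclass(frozen=True)
class NodeSpec:
    """One node of a Boolean model.

    ``rule`` is ``None`` for environmental inputs, which are free to be set
    by the simulation environment rather than by network logic.
    """

    name: str
    rule: BoolExpr | None = None
    module: str = ""

    @property
    def is_input(self) -> bool:
        return self.rule is None


class BooleanModel:
    """An ordered collection of named Boolean nodes with update rules."""

    def __init__(self, nodes: Iterable[NodeSpec], name: str = ""):
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        self.name = name
        if not self.nodes:
            raise ModelSyntaxError("model has no nodes")
        self.index: dict[str, int] = {}
        for i, node in enumerate(self.nodes):
            if node.name in self.index:
                raise ModelSyntaxError(f"duplicate node definition {node.name!r}")
            self.index[node.name] = i
        for node in self.nodes:
            if node.rule is not None:
                for reg in node.rule.regulators:
                    if reg not in self.index:
                        raise ModelSyntaxError(
                            f"rule for {node.name!r} references undeclared node {reg!r}"
                        )
        self.input_names: tuple[str, ...] = tuple(n.name for n in self.nodes if n.is_input)
        self.input_indices: tuple[int, ...] = tuple(
            i for i, n in enumerate(self.nodes) if n.is_input
        )
        self.free_indices: tuple[int, ...] = tuple(
            i for i, n in enumerate(self.nodes) if not n.is_input
        )
        self._rules_fn = None  # compiled synchronous rule map, built lazily

    # -- structure ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, name: str) -> NodeSpec:
        return self.nodes[self.index[name]]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def module_index(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for node in self.nodes:
            if node.module:
                groups.setdefault(node.module, []).append(node.name)
        return groups

    def regulators_of(self, name: str) -> tuple[str, ...]:
        node = self.node(name)
        if node.rule is None:
            return (name,)  # input: formally its own regulator (X *= X)
        return node.rule.regulators

    def state_from(self, values: Mapping[str, int], default: int = 0) -> tuple[int, ...]:
        """Build a full state vector from a (partial) name->value mapping."""
        for name in values:
            if name not in self.index:
                raise KeyError(f"unknown node {name!r}")
        return tuple(int(bool(values.get(n.name, default))) for n in self.nodes)

    def state_dict(self, state: tuple[int, ...]) -> dict[str, int]:
        return dict(zip(self.names, state))

    def content_hash(self) -> str:
        return hashlib.sha256(write_model(self).encode()).hexdigest()[:16]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BooleanModel)
            and self.name == other.name
            and self.nodes == other.nodes
        )

    def __repr__(self) -> str:
        return (
            f"<BooleanModel {self.name or '(unnamed)'}: {len(self)} nodes, "
            f"{len(self.input_names)} inputs, {count_links(self)} links>"
        )


def parse_model(source: str, name: str = "") -> BooleanModel:
    """Parse rule-dialect text into a validated :class:`BooleanModel`.

    Node order follows first appearance (``inputs:`` header entries first,
    then rules in file order).  Raises :class:`ModelSyntaxError` on
    undeclared regulators, duplicate definitions or empty input.
    """
    declared_inputs: list[str] = []
    rules: list[tuple[str, BoolExpr, int]] = []
    modules: dict[str, str] = {}
    model_name = name
    for lineno, raw in enumerate(source.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("name:"):
            model_name = line[len("name:"):].strip()
            continue
        if line.startswith("inputs:"):
            for tok in line[len("inputs:"):].split(","):
                tok = tok.strip()
                if tok:
                    declared_inputs.append(_check_name(tok, lineno))
            continue
        if line.startswith("module:"):
            body = line[len("module:"):]
            if "=" not in body:
                raise ModelSyntaxError("module header needs 'module: LABEL = n1, n2'", lineno)
            label, members = body.split("=", 1)
            for tok in members.split(","):
                tok = tok.strip()
                if tok:
                    modules[_check_name(tok, lineno)] = label.strip()
            continue
        if "*=" not in line:
            raise ModelSyntaxError(f"expected 'Name *= expression', got {line!r}", lineno)
        lhs, rhs = line.split("*=", 1)
        target = _check_name(lhs.strip(), lineno)
        expr = BoolExpr(rhs, lineno)
        rules.append((target, expr, lineno))

    # Self-assignment (X *= X) is the BooleanNet input convention.
    nodes: list[NodeSpec] = []
    seen: set[str] = set()
    for inp in declared_inputs:
        if inp in seen:
            raise ModelSyntaxError(f"duplicate node definition {inp!r}")
        seen.add(inp)
        nodes.append(NodeSpec(inp, None, modules.get(inp, "")))
    for target, expr, lineno in rules:
        if target in seen:
            if target in declared_inputs and expr.text == target:
                continue  # redundant self-rule for a declared input
            raise ModelSyntaxError(f"duplicate node definition {target!r}", lineno)
        seen.add(target)
        if expr.text == target:
            nodes.append(NodeSpec(target, None, modules.get(target, "")))
        else:
            nodes.append(NodeSpec(target, expr, modules.get(target, "")))
    if not nodes:
        raise ModelSyntaxError("empty model source")

    defined = {n.name for n in nodes}
    for target, expr, lineno in rules:
        for reg in expr.regulators:
            if reg not in defined:
                raise ModelSyntaxError(
                    f"rule for {target!r} references undeclared node {reg!r}", lineno
                )
    return BooleanModel(nodes, name=model_name)


def write_model(model: BooleanModel) -> str:
    """Serialize to rule-dialect text; ``parse_model`` round-trips it.

    Inputs are emitted once in the ``inputs:`` header (no self-rule lines),
    so models are normalized to inputs-first node order.
    """
    lines: list[str] = []
    if model.name:
        lines.append(f"name: {model.name}")
    if model.input_names:
        lines.append("inputs: " + ", ".join(model.input_names))
    groups = model.module_index
    for label in sorted(groups):
        lines.append(f"module: {label} = " + ", ".join(groups[label]))
    for node in model.nodes:
        if not node.is_input:
            lines.append(f"{node.name} *= {node.rule.text}")
    return "\n".join(lines) + "\n"


def count_links(model: BooleanModel) -> int:
    """Number of distinct ordered (regulator, target) pairs.

    A regulator counts when it appears syntactically in the target's rule;
    self-loops count, and each input contributes its formal self-link
    (the ``X *= X`` declaration convention).
    """
    total = 0
    for node in model.nodes:
        if node.is_input:
            total += 1
        else:
            total += len(node.rule.regulators)
    return total
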