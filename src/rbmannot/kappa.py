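"""Parser and serializer for the line-oriented Kappa subset used for annotation.

Rule-based models represent biological molecules as *agents* carrying named
*sites*; sites may hold internal states (e.g. phosphorylated vs unmodified)
and bonds to other sites.  Rules rewrite a left-hand-side pattern into a
right-hand-side pattern at some kinetic rate.  This module understands the
KaSim-3-era textual syntax (``%agent:``, ``%token:``, ``%var:``, ``%obs:``,
quoted rule labels, ``~state``, ``!n``, ``!_``, ``?``) plus annotation
comment lines beginning with ``#^``, whose content is collected verbatim for
the :mod:`rbmannot.annotations` machinery.

Not a simulator: rate expressions are kept as opaque text and ``%init:``
lines are retained unparsed.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Tuple


class KappaSyntaxError(ValueError):
    """Malformed model text.  Carries the 1-based source line and, when
    recoverable, the 1-based column of the offending fragment."""

    def __init__(self, message: str, line: Optional[int] = None,
                 column: Optional[int] = None):
        self.line = line
        self.column = column
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column else "") + ")"
        super().__init__(message + loc)


class UnlabeledRuleWarning(UserWarning):
    """A rule without a quoted label cannot be annotated or materialized."""


_NAME = r"[A-Za-z_][A-Za-z0-9_+\-]*"
_NAME_RE = re.compile(_NAME)
_AGENT_RE = re.compile(rf"^({_NAME})\s*(?:\((.*)\))?\s*$", re.S)
_SITE_TOKEN_RE = re.compile(r"~([A-Za-z0-9_+\-]+)|!(\d+)|(!_)|(\?)")


# --------------------------------------------------------------------------
# declarations

@dataclass(frozen=True)
class StateDecl:
    """A declared internal state of a site (e.g. ``u`` / ``p``)."""
    name: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("state name must be non-empty")


@dataclass(frozen=True)
class SiteDecl:
    """A declared interaction site, with its (possibly empty) state list."""
    name: str
    states: Tuple[StateDecl, ...] = ()

    def __post_init__(self):
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate state names on site {self.name!r}")

    def state_names(self) -> Tuple[str, ...]:
        return tuple(s.name for s in self.states)


@dataclass(frozen=True)
class AgentDecl:
    """An agent (or token) declaration: the anchor for entity naming."""
    name: str
    sites: Tuple[SiteDecl, ...] = ()
    is_token: bool = False

    def __post_init__(self):
        if self.is_token and self.sites:
            raise ValueError(f"token {self.name!r} must not declare sites")
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate site names on agent {self.name!r}")

    def site(self, name: str) -> Optional[SiteDecl]:
        for s in self.sites:
            if s.name == name:
                return s
        return None


def agent_state_space(agent: AgentDecl) -> int:
    """Number of distinct internal-state configurations of ``agent``.

    The product over sites of the number of declared states (stateless sites
    contribute a factor of 1).  Binding is excluded: this counts only the
    combinatorics of internal states, e.g. an agent with a 2-state and a
    3-state site can be used in six different ways.
    """
    return math.prod(max(1, len(s.states)) for s in agent.sites)


# --------------------------------------------------------------------------
# patterns

class BindingKind(str, Enum):
    UNSPECIFIED = "unspecified"   # written '?'
    UNBOUND = "unbound"           # no marker
    BOUND_TO = "bound_to"         # '!n'
    BOUND_UNKNOWN = "bound_unknown"  # '!_'


@dataclass(frozen=True)
class BindingStatus:
    kind: BindingKind
    label: Optional[int] = None

    def __post_init__(self):
        if (self.kind is BindingKind.BOUND_TO) != (self.label is not None):
            raise ValueError("bond label present iff kind is bound_to")
        if self.label is not None and self.label < 1:
            raise ValueError("bond labels are positive integers")


UNSPECIFIED = BindingStatus(BindingKind.UNSPECIFIED)
UNBOUND = BindingStatus(BindingKind.UNBOUND)
BOUND_UNKNOWN = BindingStatus(BindingKind.BOUND_UNKNOWN)


def bound_to(label: int) -> BindingStatus:
    return BindingStatus(BindingKind.BOUND_TO, label)


@dataclass(frozen=True)
class SitePattern:
    site_name: str
    state: Optional[str] = None
    binding: BindingStatus = UNBOUND


@dataclass(frozen=True)
class AgentPattern:
    agent_name: str
    sites: Tuple[SitePattern, ...] = ()
    position: int = 1  # 1-based textual position within the Pattern


@dataclass(frozen=True)
class Pattern:
    agents: Tuple[AgentPattern, ...] = ()

    def bond_labels(self) -> List[int]:
        out = []
        for ap in self.agents:
            for sp in ap.sites:
                if sp.binding.kind is BindingKind.BOUND_TO:
                    out.append(sp.binding.label)
        return out


EMPTY_PATTERN = Pattern()


# --------------------------------------------------------------------------
# rules, observables, variables, model

@dataclass(frozen=True)
class Rule:
    """A rewrite rule.  ``label`` is None for unlabeled (unannotatable) rules.

    Bidirectional rules (``<->``) are kept as a single Rule with both rates in
    ``rate`` as opaque text.  Token-transformation clauses of hybrid rules
    (after ``|``) become ``subrules``, identified by 1-based position.
    """
    label: Optional[str]
    lhs: Pattern
    rhs: Pattern
    rate: str = ""
    bidirectional: bool = False
    subrules: Tuple["Rule", ...] = ()


@dataclass(frozen=True)
class Observable:
    label: str
    pattern: Pattern


@dataclass(frozen=True)
class Variable:
    label: str
    value: str


@dataclass
class Model:
    agents: List[AgentDecl] = field(default_factory=list)
    rules: List[Rule] = field(default_factory=list)
    observables: List[Observable] = field(default_factory=list)
    variables: List[Variable] = field(default_factory=list)
    annotation_lines: List[str] = field(default_factory=list)
    inits: List[str] = field(default_factory=list)
    source_lines: List[str] = field(default_factory=list, compare=False)

    def agent(self, name: str) -> Optional[AgentDecl]:
        for a in self.agents:
            if a.name == name:
                return a
        return None


# --------------------------------------------------------------------------
# parsing helpers

def _strip_comment(line: str) -> str:
    """Remove an ordinary ``#`` comment, honouring single-quoted labels."""
    in_quote = False
    for i, ch in enumerate(line):
        if ch == "'":
            in_quote = not in_quote
        elif ch == "#" and not in_quote:
            return line[:i]
    return line


def _split_top(text: str, sep: str) -> List[str]:
    """Split on ``sep`` outside parentheses."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def _parse_site_pattern(text: str, line: int) -> SitePattern:
    text = text.strip()
    m = re.match(rf"^({_NAME})(.*)$", text, re.S)
    if not m:
        raise KappaSyntaxError(f"malformed site pattern {text!r}", line)
    name, rest = m.group(1), m.group(2).strip()
    state: Optional[str] = None
    binding: Optional[BindingStatus] = None
    pos = 0
    while pos < len(rest):
        tok = _SITE_TOKEN_RE.match(rest, pos)
        if not tok:
            raise KappaSyntaxError(
                f"malformed site pattern {text!r}", line)
        if tok.group(1):
            if state is not None:
                raise KappaSyntaxError(
                    f"site {name!r} carries more than one state", line)
            state = tok.group(1)
        elif tok.group(2):
            if binding is not None:
                raise KappaSyntaxError(
                    f"site {name!r} carries more than one binding marker", line)
            binding = bound_to(int(tok.group(2)))
        elif tok.group(3):
            if binding is not None:
                raise KappaSyntaxError(
                    f"site {name!r} carries more than one binding marker", line)
            binding = BOUND_UNKNOWN
        else:
            if binding is not None:
                raise KappaSyntaxError(
                    f"site {name!r} carries more than one binding marker", line)
            binding = UNSPECIFIED
        pos = tok.end()
    return SitePattern(name, state, binding if binding is not None else UNBOUND)


def parse_pattern(text: str, line: int = 0) -> Pattern:
    """Parse a comma-separated list of agent patterns; '' is the empty pattern."""
    text = text.strip()
    if not text:
        return EMPTY_PATTERN
    agents = []
    for pos, chunk in enumerate(_split_top(text, ","), 1):
        chunk = chunk.strip()
        m = _AGENT_RE.match(chunk)
        if not m:
            raise KappaSyntaxError(f"malformed agent pattern {chunk!r}", line)
        name, sig = m.group(1), m.group(2)
        sites: Tuple[SitePattern, ...] = ()
        if sig is not None and sig.strip():
            sites = tuple(_parse_site_pattern(s, line)
                          for s in _split_top(sig, ","))
        site_names = [s.site_name for s in sites]
        if len(set(site_names)) != len(site_names):
            raise KappaSyntaxError(
                f"duplicate site in pattern for agent {name!r}", line)
        agents.append(AgentPattern(name, sites, position=pos))
    return Pattern(tuple(agents))


def _check_bond_pairing(pattern: Pattern, line: int, side: str) -> None:
    counts: dict = {}
    for lbl in pattern.bond_labels():
        counts[lbl] = counts.get(lbl, 0) + 1
    for lbl, n in sorted(counts.items()):
        if n == 1:
            raise KappaSyntaxError(
                f"dangling bond !{lbl} on {side}: a bond label must appear "
                f"on exactly two sites", line)
        if n > 2:
            raise KappaSyntaxError(
                f"bond label !{lbl} appears {n} times on {side}; "
                f"bonds join exactly two sites", line)


def _parse_quoted_label(text: str, line: int) -> Tuple[Optional[str], str]:
    text = text.lstrip()
    if not text.startswith("'"):
        return None, text
    end = text.find("'", 1)
    if end < 0:
        raise KappaSyntaxError("unterminated rule label quote", line)
    return text[1:end], text[end + 1:]


def _parse_agent_decl(body: str, line: int, is_token: bool) -> AgentDecl:
    body = body.strip()
    m = _AGENT_RE.match(body)
    if not m:
        raise KappaSyntaxError(f"malformed declaration {body!r}", line,
                               column=1)
    name, sig = m.group(1), m.group(2)
    if is_token:
        if sig is not None and sig.strip():
            raise KappaSyntaxError(f"token {name!r} must not declare sites",
                                   line)
        return AgentDecl(name, (), is_token=True)
    sites = []
    if sig is not None and sig.strip():
        for chunk in _split_top(sig, ","):
            chunk = chunk.strip()
            m2 = re.match(rf"^({_NAME})((?:\s*~[A-Za-z0-9_+\-]+)*)\s*$", chunk)
            if not m2:
                col = body.find(chunk) + 1
                raise KappaSyntaxError(
                    f"malformed site declaration {chunk!r}", line,
                    column=col if col > 0 else None)
            states = tuple(StateDecl(s) for s in
                           re.findall(r"~([A-Za-z0-9_+\-]+)", m2.group(2)))
            try:
                sites.append(SiteDecl(m2.group(1), states))
            except ValueError as e:
                raise KappaSyntaxError(str(e), line) from None
    try:
        return AgentDecl(name, tuple(sites))
    except ValueError as e:
        raise KappaSyntaxError(str(e), line) from None


def _parse_rule(body: str, line: int) -> Rule:
    label, rest = _parse_quoted_label(body, line)
    if label is None:
        warnings.warn(
            f"line {line}: unlabeled rule cannot be annotated or materialized",
            UnlabeledRuleWarning, stacklevel=4)
    if "@" in rest:
        rest, rate = rest.rsplit("@", 1)
        rate = rate.strip()
    else:
        rate = ""
    bidirectional = "<->" in rest
    arrow = "<->" if bidirectional else "->"
    if arrow not in rest:
        raise KappaSyntaxError("rule has no '->' arrow", line)
    lhs_text, rhs_text = rest.split(arrow, 1)
    clauses = _split_top(rhs_text, "|")
    rhs_text, clause_texts = clauses[0], clauses[1:]
    lhs = parse_pattern(lhs_text, line)
    rhs = parse_pattern(rhs_text, line)
    _check_bond_pairing(lhs, line, "left-hand side")
    _check_bond_pairing(rhs, line, "right-hand side")
    subrules = []
    for ct in clause_texts:
        if "->" not in ct:
            raise KappaSyntaxError(
                f"malformed subrule clause {ct.strip()!r}", line)
        sl, sr = ct.split("->", 1)
        subrules.append(Rule(label=None,
                             lhs=parse_pattern(sl, line),
                             rhs=parse_pattern(sr, line)))
    return Rule(label, lhs, rhs, rate, bidirectional, tuple(subrules))


def _validate_against_declarations(model: Model, pattern: Pattern,
                                   line: int) -> None:
    for ap in pattern.agents:
        decl = model.agent(ap.agent_name)
        if decl is None:
            continue  # permissive: undeclared agents caught by normalization
        for sp in ap.sites:
            sd = decl.site(sp.site_name)
            if sd is None:
                raise KappaSyntaxError(
                    f"site {sp.site_name!r} is not declared on agent "
                    f"{ap.agent_name!r}", line)
            if sp.state is not None and sp.state not in sd.state_names():
                raise KappaSyntaxError(
                    f"state {sp.state!r} is not declared for site "
                    f"{ap.agent_name}.{sp.site_name}", line)


def parse_model(text: str) -> Model:
    """Parse Kappa source text into a :class:`Model`.

    Lines beginning exactly with ``#^`` are collected (delimiter stripped)
    into ``annotation_lines``; ordinary ``#`` comments are discarded.
    Raises :class:`KappaSyntaxError` on malformed declarations, dangling
    bonds, duplicate names, or (when declarations are present) undeclared
    sites/states in patterns.
    """
    model = Model(source_lines=text.splitlines())
    pattern_sites: List[Tuple[Pattern, int]] = []
    for lineno, raw in enumerate(model.source_lines, 1):
        if raw.startswith("#^"):
            model.annotation_lines.append(raw[2:])
            continue
        line = _strip_comment(raw).strip()
        if not line:
            continue
        if line.startswith("%"):
            m = re.match(r"^%([a-z]+):\s*(.*)$", line, re.S)
            if not m:
                raise KappaSyntaxError(f"malformed directive {line!r}", lineno)
            kind, body = m.group(1), m.group(2)
            if kind in ("agent", "token"):
                decl = _parse_agent_decl(body, lineno, kind == "token")
                if model.agent(decl.name) is not None:
                    raise KappaSyntaxError(
                        f"duplicate agent declaration {decl.name!r}", lineno)
                model.agents.append(decl)
            elif kind == "var":
                label, rest = _parse_quoted_label(body, lineno)
                if label is None:
                    raise KappaSyntaxError("variable requires a quoted label",
                                           lineno)
                if any(v.label == label for v in model.variables):
                    raise KappaSyntaxError(
                        f"duplicate variable label {label!r}", lineno)
                model.variables.append(Variable(label, rest.strip()))
            elif kind == "obs":
                label, rest = _parse_quoted_label(body, lineno)
                if label is None:
                    raise KappaSyntaxError("observable requires a quoted label",
                                           lineno)
                if any(o.label == label for o in model.observables):
                    raise KappaSyntaxError(
                        f"duplicate observable label {label!r}", lineno)
                pat = parse_pattern(rest, lineno)
                _check_bond_pairing(pat, lineno, "observable")
                pattern_sites.append((pat, lineno))
                model.observables.append(Observable(label, pat))
            elif kind == "init":
                model.inits.append(line)
            else:
                raise KappaSyntaxError(f"unknown directive %{kind}:", lineno)
        else:
            rule = _parse_rule(line, lineno)
            if rule.label is not None and any(
                    r.label == rule.label for r in model.rules):
                raise KappaSyntaxError(
                    f"duplicate rule label {rule.label!r}", lineno)
            for pat in (rule.lhs, rule.rhs):
                pattern_sites.append((pat, lineno))
            for sub in rule.subrules:
                pattern_sites.append((sub.lhs, lineno))
                pattern_sites.append((sub.rhs, lineno))
            model.rules.append(rule)
    if model.agents:
        for pat, lineno in pattern_sites:
            _validate_against_declarations(model, pat, lineno)
    return model


# --------------------------------------------------------------------------
# serialization

def _serialize_site_pattern(sp: SitePattern) -> str:
    out = sp.site_name
    if sp.state is not None:
        out += "~" + sp.state
    k = sp.binding.kind
    if k is BindingKind.BOUND_TO:
        out += f"!{sp.binding.label}"
    elif k is BindingKind.BOUND_UNKNOWN:
        out += "!_"
    elif k is BindingKind.UNSPECIFIED:
        out += "?"
    return out


def serialize_pattern(pattern: Pattern) -> str:
    chunks = []
    for ap in pattern.agents:
        if ap.sites:
            sig = ",".join(_serialize_site_pattern(s) for s in ap.sites)
            chunks.append(f"{ap.agent_name}({sig})")
        else:
            chunks.append(ap.agent_name)
    return ",".join(chunks)


def _serialize_rule(rule: Rule) -> str:
    parts = []
    if rule.label is not None:
        parts.append(f"'{rule.label}'")
    arrow = "<->" if rule.bidirectional else "->"
    parts.append(f"{serialize_pattern(rule.lhs)} {arrow} "
                 f"{serialize_pattern(rule.rhs)}".strip())
    for sub in rule.subrules:
        parts.append(f"| {serialize_pattern(sub.lhs)} -> "
                     f"{serialize_pattern(sub.rhs)}")
    if rule.rate:
        parts.append(f"@ {rule.rate}")
    return " ".join(parts)


def serialize_model(model: Model) -> str:
    """Emit canonical Kappa text: annotations, declarations, variables,
    rules, observables, inits.  ``parse_model(serialize_model(m)) == m`` on
    the structured fields."""
    lines: List[str] = []
    lines.extend("#^" + a for a in model.annotation_lines)
    for a in model.agents:
        if a.is_token:
            lines.append(f"%token: {a.name}")
        else:
            sigs = []
            for s in a.sites:
                sigs.append(s.name + "".join("~" + st.name for st in s.states))
            sig = ",".join(sigs)
            lines.append(f"%agent: {a.name}({sig})")
    for v in model.variables:
        lines.append(f"%var: '{v.label}' {v.value}".rstrip())
    for r in model.rules:
        lines.append(_serialize_rule(r))
    for o in model.observables:
        lines.append(f"%obs: '{o.label}' {serialize_pattern(o.pattern)}")
    lines.extend(model.inits)
    return "\n".join(lines) + ("\n" if lines else "")
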