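"""Intelligible if-then rules: induction, scoring, parsing, classification.

A rule is a conjunction of interval conditions on predictor features mapping
to a class, e.g. ``if((fev1<2.23))then low``.  Each rule carries two
class-conditional statistics on a named evaluation dataset:

* covering ``C`` — fraction of the rule's *own* class whose records satisfy
  the premise;
* error ``r`` — fraction of the *opposite* class satisfying it.

Two inducers are provided.  ``induce_rules_tree`` converts the root-to-leaf
paths of a Gini decision tree into rules.  ``induce_rules_greedy`` is a
sequential-covering learner over equal-frequency discretized features,
exposing the precision-vs-generalization trade-off (bin granularity, maximum
premise length, maximum tolerated error) typical of logic-learning rule
extractors; it is a transparent stand-in for proprietary latticization
engines, not a reimplementation of one.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .schema import (
    CLASS_HIGH,
    CLASS_LOW,
    CLASSES,
    PREDICTOR_NAMES,
    LabeledDataset,
    SchemaError,
    ValidationError,
    canonical_feature,
)

logger = logging.getLogger(__name__)

_OPS = ("<", "<=", ">", ">=")


@dataclass(frozen=True)
class Condition:
    """Single threshold condition ``feature op threshold`` in physical units."""

    feature: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature", canonical_feature(self.feature))
        object.__setattr__(self, "op", str(self.op))
        object.__setattr__(self, "threshold", float(self.threshold))
        if self.feature == "pef":
            raise ValidationError("rules may not condition on pef (the label source)")
        if self.op not in _OPS:
            raise ValidationError(f"operator must be one of {_OPS}, got {self.op!r}")
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")

    @property
    def is_upper(self) -> bool:
        return self.op in ("<", "<=")

    def satisfied(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.op == "<":
            return v < self.threshold
        if self.op == "<=":
            return v <= self.threshold
        if self.op == ">":
            return v > self.threshold
        return v >= self.threshold

    def __str__(self) -> str:
        return f"{self.feature}{self.op}{self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions -> class, with optional evaluation statistics."""

    premise: tuple[Condition, ...]
    consequence: str
    covering: float | None = field(default=None, compare=False)
    error: float | None = field(default=None, compare=False)
    p_value: float | None = field(default=None, compare=False)
    eval_tag: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.premise:
            raise ValidationError("premise must be non-empty")
        if self.consequence not in CLASSES:
            raise ValidationError(f"consequence must be one of {CLASSES}")
        lowers: dict[str, float] = {}
        uppers: dict[str, float] = {}
        for c in self.premise:
            side = uppers if c.is_upper else lowers
            if c.feature in side:
                raise ValidationError(
                    f"duplicate {'upper' if c.is_upper else 'lower'} bound on {c.feature}"
                )
            side[c.feature] = c.threshold
        for f in lowers.keys() & uppers.keys():
            if lowers[f] >= uppers[f]:
                raise ValidationError(f"contradictory bounds on {f}")

    def fires(self, features: np.ndarray) -> np.ndarray:
        """Boolean mask of records (rows over PREDICTOR_NAMES) satisfying the premise."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        mask = np.ones(X.shape[0], dtype=bool)
        for c in self.premise:
            mask &= c.satisfied(X[:, PREDICTOR_NAMES.index(c.feature)])
        return mask

    @property
    def weight(self) -> float:
        """Voting weight C*(1-r); 1.0 when the rule is unscored."""
        if self.covering is None or self.error is None:
            return 1.0
        return self.covering * (1.0 - self.error)


@dataclass
class RuleSet:
    """Ordered collection of distinct rules plus a default class."""

    rules: list[Rule]
    default_class: str
    provenance: str = "baseline"

    def __post_init__(self) -> None:
        if self.default_class not in CLASSES:
            raise ValidationError(f"default class must be one of {CLASSES}")
        seen = set()
        for r in self.rules:
            key = (r.premise, r.consequence)
            if key in seen:
                raise ValidationError(f"duplicate rule: {format_rule(r)}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


def covering_error(rule: Rule, D: LabeledDataset) -> tuple[float, float]:
    """Class-conditional covering and error of ``rule`` on ``D``.

    C = P(premise | consequence class), r = P(premise | other class).
    """
    own = D.labels == rule.consequence
    n_own = int(own.sum())
    if n_own == 0:
        raise ValidationError(f"consequence class {rule.consequence!r} absent from dataset")
    fired = rule.fires(D.features)
    n_other = int((~own).sum())
    C = float(np.sum(fired & own)) / n_own
    r = float(np.sum(fired & ~own)) / n_other if n_other else 0.0
    return C, r


def score_rules(rs: RuleSet, D: LabeledDataset, tag: str | None = None) -> RuleSet:
    """Recompute C and r of every rule on ``D`` (p-values are cleared)."""
    scored = []
    for rule in rs:
        C, r = covering_error(rule, D)
        scored.append(replace(rule, covering=C, error=r, p_value=None, eval_tag=tag))
    return RuleSet(scored, rs.default_class, rs.provenance)


def classify(rs: RuleSet, record: np.ndarray) -> str:
    """Class of one record: weighted vote of firing rules, default on none/tie."""
    return predict(rs, np.atleast_2d(record))[0]


def predict(rs: RuleSet, D: LabeledDataset | np.ndarray) -> np.ndarray:
    """Vectorized classification of every record in ``D``.

    All rules whose premise a record satisfies fire; the predicted class
    maximizes the summed firing weights ``C*(1-r)``.  No firing rule, or an
    exact tie, yields the default class.
    """
    X = D.features if isinstance(D, LabeledDataset) else np.atleast_2d(D)
    votes = {c: np.zeros(X.shape[0]) for c in CLASSES}
    for rule in rs:
        votes[rule.consequence][rule.fires(X)] += rule.weight
    out = np.full(X.shape[0], rs.default_class, dtype=object)
    hi, lo = votes[CLASS_HIGH], votes[CLASS_LOW]
    out[hi > lo] = CLASS_HIGH
    out[lo > hi] = CLASS_LOW
    return out


def _merge_bounds(conds: list[Condition]) -> tuple[Condition, ...]:
    """Keep only the tightest lower and upper bound per feature."""
    lowers: dict[str, Condition] = {}
    uppers: dict[str, Condition] = {}
    for c in conds:
        side = uppers if c.is_upper else lowers
        cur = side.get(c.feature)
        if cur is None:
            side[c.feature] = c
            continue
        if c.is_upper:
            tighter = c.threshold < cur.threshold or (
                c.threshold == cur.threshold and c.op == "<"
            )
        else:
            tighter = c.threshold > cur.threshold or (
                c.threshold == cur.threshold and c.op == ">"
            )
        if tighter:
            side[c.feature] = c
    merged = list(lowers.values()) + list(uppers.values())
    merged.sort(key=lambda c: (PREDICTOR_NAMES.index(c.feature), c.is_upper, c.threshold))
    return tuple(merged)


def _require_both_classes(D: LabeledDataset) -> None:
    counts = D.class_counts()
    if counts[CLASS_HIGH] == 0 or counts[CLASS_LOW] == 0:
        raise ValidationError("rule induction requires both classes present")


def induce_rules_tree(
    D: LabeledDataset, max_depth: int = 3, min_leaf: int = 2
) -> RuleSet:
    """Fit a Gini decision tree and convert each leaf path into one rule.

    Left branches contribute ``feature <= threshold`` conditions, right
    branches ``feature > threshold``; redundant bounds on a feature are
    merged.  Each rule's consequence is its leaf's majority class; C and r
    are computed on ``D``; the default class is the majority class of ``D``.
    """
    _require_both_classes(D)
    if max_depth < 1:
        raise ValidationError("max_depth must be >= 1")
    if D.n < 2 * min_leaf:
        raise ValidationError("need n >= 2*min_leaf records")
    y = (D.labels == CLASS_HIGH).astype(int)
    tree = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        random_state=0,
    ).fit(D.features, y)
    t = tree.tree_

    rules: list[Rule] = []

    def walk(node: int, conds: list[Condition]) -> None:
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node][0]
            consequence = CLASS_HIGH if counts[1] >= counts[0] else CLASS_LOW
            if conds:
                rules.append(Rule(_merge_bounds(conds), consequence))
            return
        feat = PREDICTOR_NAMES[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + [Condition(feat, "<=", thr)])
        walk(t.children_right[node], conds + [Condition(feat, ">", thr)])

    walk(0, [])
    counts = D.class_counts()
    default = CLASS_HIGH if counts[CLASS_HIGH] >= counts[CLASS_LOW] else CLASS_LOW
    return score_rules(RuleSet(rules, default), D, tag=D.provenance)


def _candidate_conditions(D: LabeledDataset, q_bins: int) -> list[Condition]:
    """Threshold conditions at internal equal-frequency bin edges of each feature."""
    cands: list[Condition] = []
    qs = np.linspace(0, 1, q_bins + 1)[1:-1]
    for j, name in enumerate(PREDICTOR_NAMES):
        col = D.features[:, j]
        edges = np.unique(np.quantile(col, qs))
        for e in edges:
            e = float(e)
            cands.append(Condition(name, "<=", e))
            cands.append(Condition(name, ">", e))
    return cands


def induce_rules_greedy(
    D: LabeledDataset,
    q_bins: int = 4,
    max_conditions: int = 3,
    max_error: float = 0.1,
) -> RuleSet:
    """Sequential-covering rule learner over discretized features.

    Predictors are discretized into ``q_bins`` equal-frequency intervals; for
    each class, premises grow greedily — at each step the threshold condition
    covering the most still-uncovered class records is added, preferring
    conditions that already meet the error budget — until the rule's error is
    at most ``max_error`` or ``max_conditions`` is reached.  Accepted rules
    remove the class records they cover; the loop stops when no feasible rule
    adds coverage.  An infeasible ``max_error`` yields an empty rule set with
    a warning, not an error.
    """
    _require_both_classes(D)
    if q_bins < 2:
        raise ValidationError("q_bins must be >= 2")
    if max_conditions < 1:
        raise ValidationError("max_conditions must be >= 1")
    candidates = _candidate_conditions(D, q_bins)
    cand_masks = [c.satisfied(D.features[:, PREDICTOR_NAMES.index(c.feature)]) for c in candidates]

    rules: list[Rule] = []
    for cls in (CLASS_HIGH, CLASS_LOW):
        own = D.labels == cls
        other = ~own
        n_other = max(int(other.sum()), 1)
        uncovered = own.copy()
        while uncovered.any():
            premise: list[Condition] = []
            mask = np.ones(D.n, dtype=bool)
            best_rule = None
            while len(premise) < max_conditions:
                best = None  # (feasible, gain, -err, -idx) maximized
                for idx, (cond, cmask) in enumerate(zip(candidates, cand_masks)):
                    try:
                        _merge_bounds(premise + [cond])
                        Rule(_merge_bounds(premise + [cond]), cls)
                    except ValidationError:
                        continue
                    m2 = mask & cmask
                    if np.array_equal(m2, mask):
                        continue  # vacuous here: would waste a premise slot
                    gain = int(np.sum(m2 & uncovered))
                    if gain == 0:
                        continue
                    err = float(np.sum(m2 & other)) / n_other
                    key = (err <= max_error, gain, -err, -idx)
                    if best is None or key > best[0]:
                        best = (key, cond, m2, err)
                if best is None:
                    break
                _, cond, mask, err = best
                premise.append(cond)
                if err <= max_error:
                    best_rule = Rule(_merge_bounds(premise), cls)
                    break
            if best_rule is None:
                break  # no feasible rule for the remaining records
            C, r = covering_error(best_rule, D)
            scored = replace(best_rule, covering=C, error=r, eval_tag=D.provenance)
            if any((scored.premise, scored.consequence) == (x.premise, x.consequence) for x in rules):
                break
            rules.append(scored)
            uncovered &= ~scored.fires(D.features)
    if not rules:
        logger.warning("greedy induction: max_error=%.3g infeasible, empty rule set", max_error)
    counts = D.class_counts()
    default = CLASS_HIGH if counts[CLASS_HIGH] >= counts[CLASS_LOW] else CLASS_LOW
    return RuleSet(rules, default)


# ---------------------------------------------------------------------------
# textual rule syntax:  if((fev1<2.23)∧(map<=104.18))then low (C = 41%) (r = 4.9%)

_COND_RE = re.compile(r"\(\s*([A-Za-z][\w \-]*?)\s*(<=|>=|<|>|≤|≥)\s*([-+0-9.eE]+)\s*\)")
_RULE_RE = re.compile(
    r"^\s*if\s*\(\s*(?P<premise>.+?)\s*\)\s*then\s+(?P<cls>\w+)\s*(?P<annot>.*)$",
    re.IGNORECASE,
)
_ANNOT_RE = re.compile(
    r"\(\s*(C|r|error|p)\s*=\s*([-+0-9.eE]+)\s*(%?)\s*\)", re.IGNORECASE
)


class RuleParseError(ValueError):
    """Malformed rule text; carries the offending position where known."""


def parse_rule(text: str) -> Rule:
    """Parse the printable rule syntax back into a :class:`Rule`.

    Accepts ``∧``, ``^`` or ``&`` between conditions, the unicode operators
    ``≤``/``≥``, arbitrary feature spellings resolvable by the schema
    (``FEV1``, ``heartrate``, ``diastolicpressure`` ...), and optional
    trailing ``(C = 41%) (r = 4.7%) (p = 0.003)`` annotations.
    """
    m = _RULE_RE.match(text)
    if not m:
        raise RuleParseError(f"not an if(...)then rule: {text!r}")
    premise_txt = m.group("premise")
    conds: list[Condition] = []
    pos = 0
    for cm in _COND_RE.finditer(premise_txt):
        gap = premise_txt[pos : cm.start()].strip()
        if gap and not all(ch in "∧^&" for ch in gap):
            raise RuleParseError(f"unexpected text at position {pos}: {gap!r}")
        op = {"≤": "<=", "≥": ">="}.get(cm.group(2), cm.group(2))
        try:
            conds.append(Condition(cm.group(1), op, float(cm.group(3))))
        except (SchemaError, ValidationError) as exc:
            raise RuleParseError(f"at position {cm.start()}: {exc}") from exc
        pos = cm.end()
    if not conds:
        raise RuleParseError(f"no conditions found in {text!r}")
    if premise_txt[pos:].strip():
        raise RuleParseError(f"trailing premise text at position {pos}")
    cls = m.group("cls").lower()
    if cls not in CLASSES:
        raise RuleParseError(f"unknown class {m.group('cls')!r}")
    covering = error = p_value = None
    for am in _ANNOT_RE.finditer(m.group("annot")):
        key = am.group(1).lower()
        val = float(am.group(2))
        if am.group(3):
            val /= 100.0
        if key == "c":
            covering = val
        elif key in ("r", "error"):
            error = val
        else:
            p_value = val
    return Rule(tuple(conds), cls, covering=covering, error=error, p_value=p_value)


def format_rule(rule: Rule, annotate: bool = True) -> str:
    """Render a rule in the printable syntax; inverse of :func:`parse_rule`."""
    prem = "∧".join(f"({c.feature}{c.op}{c.threshold!r})" for c in rule.premise)
    out = f"if({prem})then {rule.consequence}"
    if annotate:
        if rule.covering is not None:
            out += f" (C = {100 * rule.covering:g}%)"
        if rule.error is not None:
            out += f" (r = {100 * rule.error:g}%)"
        if rule.p_value is not None:
            out += f" (p = {rule.p_value:g})"
    return out


def serialize_ruleset(rs: RuleSet) -> str:
    lines = [f"# default: {rs.default_class}  provenance: {rs.provenance}"]
    lines += [format_rule(r) for r in rs]
    return "\n".join(lines) + "\n"


def parse_ruleset(text: str) -> RuleSet:
    default, provenance = CLASS_LOW, "baseline"
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            dm = re.search(r"default:\s*(\w+)", line)
            if dm:
                default = dm.group(1)
            pm = re.search(r"provenance:\s*(\w+)", line)
            if pm:
                provenance = pm.group(1)
            continue
        rules.append(parse_rule(line))
    return RuleSet(rules, default, provenance)
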