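"""Statistical rule validation (Fisher's Exact Test) and the augmentation workflow.

A rule is a directional claim — *premise implies class* — so each rule is
tested one-sided for enrichment of its premise within its consequence class
on a 2x2 contingency table.  Fisher's exact test is appropriate at the tiny
sample sizes this pipeline targets (tens of records).

The three-stage augmentation workflow:

1. *baseline* — rules induced and FET-filtered on the real data;
2. *candidate augmented* — rules induced and FET-filtered on the synthetic
   data;
3. *augmented* — the candidate rules re-scored (C, r) on the real data and
   kept only if they also pass FET there.

The candidate model is considered valid only if the augmented set is
non-empty: synthetic-trained knowledge must survive contact with reality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .schema import CLASS_HIGH, CLASS_LOW, LabeledDataset, ValidationError
from . import rules as rules_mod
from .rules import Rule, RuleSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RuleContingency:
    """2x2 premise-by-class counts for one rule on one dataset.

    a: premise & consequence class;  b: premise & other class;
    c: no premise & consequence class;  d: no premise & other class.
    """

    a: int
    b: int
    c: int
    d: int
    tag: str = ""

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """Premise satisfied by none or by all records: no information."""
        return (self.a + self.b) == 0 or (self.c + self.d) == 0


def rule_contingency(rule: Rule, D: LabeledDataset) -> RuleContingency:
    own = D.labels == rule.consequence
    fired = rule.fires(D.features)
    return RuleContingency(
        a=int(np.sum(fired & own)),
        b=int(np.sum(fired & ~own)),
        c=int(np.sum(~fired & own)),
        d=int(np.sum(~fired & ~own)),
        tag=D.provenance,
    )


def fet_pvalue(table: RuleContingency, two_sided: bool = False) -> float:
    """Fisher exact p-value for premise/class association (enrichment by default)."""
    if table.degenerate:
        logger.warning("degenerate contingency margin (%s); p = 1", table)
        return 1.0
    alternative = "two-sided" if two_sided else "greater"
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alternative
    )
    return float(min(p, 1.0))


def fet_rule_pvalue(rule: Rule, D: LabeledDataset, two_sided: bool = False) -> float:
    """One-sided (enrichment) Fisher exact p-value of ``rule`` on ``D``.

    Requires both classes present; a degenerate premise margin (fires on no
    record, or on every record) returns p = 1 with a logged flag.
    """
    counts = D.class_counts()
    if counts[CLASS_HIGH] == 0 or counts[CLASS_LOW] == 0:
        raise ValidationError("FET requires both classes present")
    return fet_pvalue(rule_contingency(rule, D), two_sided=two_sided)


def filter_rules_fet(
    rs: RuleSet,
    D: LabeledDataset,
    alpha: float = 0.05,
    two_sided: bool = False,
    bh_correct: bool = False,
) -> RuleSet:
    """Keep rules with FET p < ``alpha``, annotating each with its p-value.

    ``bh_correct=True`` applies a Benjamini-Hochberg step-up across the rule
    set before thresholding (an extension beyond individual-rule testing;
    off by default).
    """
    if not rs.rules:
        return RuleSet([], rs.default_class, rs.provenance)
    ps = np.array([fet_rule_pvalue(r, D, two_sided=two_sided) for r in rs])
    if alpha >= 1.0:  # vacuous filter: keep everything, still annotate
        kept = [replace(r, p_value=float(p)) for r, p in zip(rs, ps)]
        return RuleSet(kept, rs.default_class, rs.provenance)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        keep, ps_adj, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
        kept = [replace(r, p_value=float(p)) for r, p, k in zip(rs, ps_adj, keep) if k]
    else:
        kept = [replace(r, p_value=float(p)) for r, p in zip(rs, ps) if p < alpha]
    logger.info("FET filter on %s: %d/%d rules accepted (alpha=%g)",
                D.provenance, len(kept), len(rs), alpha)
    return RuleSet(kept, rs.default_class, rs.provenance)


def evaluate_ruleset(rs: RuleSet, D: LabeledDataset) -> tuple[float, float]:
    """(accuracy, F1) of the rule set's predictions on ``D``; ``high`` is positive."""
    if D.n == 0:
        raise ValidationError("cannot evaluate on an empty dataset")
    pred = rules_mod.predict(rs, D)
    accuracy = float(np.mean(pred == D.labels))
    tp = float(np.sum((pred == CLASS_HIGH) & (D.labels == CLASS_HIGH)))
    fp = float(np.sum((pred == CLASS_HIGH) & (D.labels == CLASS_LOW)))
    fn = float(np.sum((pred == CLASS_LOW) & (D.labels == CLASS_HIGH)))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return accuracy, f1


@dataclass
class StageReport:
    n_rules: int
    accuracy: float
    f1: float


@dataclass
class WorkflowResult:
    baseline: RuleSet
    candidate_augmented: RuleSet
    augmented: RuleSet
    reports: dict[str, StageReport] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        """Augmentation succeeded: synthetic-trained rules hold on real data."""
        return len(self.augmented) > 0


def _inducer(name_or_fn, **kwargs):
    if callable(name_or_fn):
        return lambda D: name_or_fn(D, **kwargs)
    if name_or_fn == "tree":
        return lambda D: rules_mod.induce_rules_tree(D, **kwargs)
    if name_or_fn == "greedy":
        return lambda D: rules_mod.induce_rules_greedy(D, **kwargs)
    raise ValidationError(f"unknown inducer {name_or_fn!r}")


def run_augmentation_workflow(
    real: LabeledDataset,
    synthetic: LabeledDataset,
    inducer="greedy",
    alpha: float = 0.05,
    two_sided: bool = False,
    **induction_kwargs,
) -> WorkflowResult:
    """Run baseline / candidate-augmented / augmented rule validation.

    Candidate rules are *not* re-induced on the real data in stage 3 — they
    are only re-scored and re-tested there, so the augmented set is always a
    subset of the candidate set.

    ``reports`` holds per-stage accuracy/F1: baseline and augmented on real
    data, candidate on both synthetic (its training data) and real data (the
    headline transfer measurement).
    """
    induce = _inducer(inducer, **induction_kwargs)

    baseline = filter_rules_fet(induce(real), real, alpha, two_sided)
    baseline.provenance = "baseline"

    candidate = filter_rules_fet(induce(synthetic), synthetic, alpha, two_sided)
    candidate.provenance = "candidate_augmented"

    rescored = rules_mod.score_rules(candidate, real, tag=real.provenance)
    augmented = filter_rules_fet(rescored, real, alpha, two_sided)
    augmented.provenance = "augmented"

    reports = {}
    for name, rs, data in (
        ("baseline_on_real", baseline, real),
        ("candidate_on_synthetic", candidate, synthetic),
        ("candidate_on_real", candidate, real),
        ("augmented_on_real", augmented, real),
    ):
        acc, f1 = evaluate_ruleset(rs, data)
        reports[name] = StageReport(len(rs), acc, f1)
    return WorkflowResult(baseline, candidate, augmented, reports)
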