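"""The flagging engine: cluster-error criteria as data.

Two built-in rulesets encode the per-variant exclusion criteria used
when curating exome-chip genotype clusters:

- ``"charge"`` — the criteria recommended by the CHARGE consortium for
  the HumanExome BeadChip;
- ``"adjusted"`` — the East-Asian-cohort adjustment of the same
  criteria, which relaxes exactly four rows: the call-frequency bound
  in the three "Freq & Call Freq" rules drops from "< 1" (any no-call)
  to "< 0.99", and the MAF bound in the "AB Freq = 0" rule rises from
  "> 0" to "> 0.0002".

Each ruleset has 17 rules in four categories. A variant may be flagged
by several rules at once; totals are therefore reported both counted
with redundancy (sum of per-rule counts) and as unique variants.

Rules are plain data (field, comparator, constant conjunctions over the
metrics table) and can be loaded from YAML, so cohort-specific rulesets
can be defined without touching code. Interval rules on Call Freq are
half-open [lo, hi) — a variant at exactly 0.99 falls through to the
MAF-combined rules — while T Mean intervals are closed [lo, hi];
equality criteria are evaluated on integer genotype counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Clause",
    "Rule",
    "FlagReport",
    "FlagSummary",
    "builtin_ruleset",
    "apply_ruleset",
    "summarize_flags",
    "summarize_counts",
    "ruleset_to_dicts",
    "ruleset_from_dicts",
    "RULESET_NAMES",
    "CATEGORIES",
    "REFERENCE_CHARGE_COUNTS",
    "REFERENCE_ADJUSTED_COUNTS",
]

RULESET_NAMES = ("charge", "adjusted")
CATEGORIES = ("clustering_error", "aa_cluster_error", "ab_cluster_error", "bb_cluster_error")
_OPS = ("lt", "le", "gt", "ge", "eq", "ne", "between_co", "between_cc")


@dataclass(frozen=True)
class Clause:
    """One predicate term: metrics field OP constant.

    ``between_co`` is [lo, hi), ``between_cc`` is [lo, hi]; both take a
    (lo, hi) tuple as value. A NaN (absent) field makes every clause
    false.
    """

    field: str
    op: str
    value: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown comparator {self.op!r}")
        if self.op.startswith("between"):
            lo, hi = self.value  # type: ignore[misc]
            if lo > hi:
                raise ValueError("interval bounds must satisfy lo <= hi")

    def evaluate(self, table: pd.DataFrame) -> np.ndarray:
        if self.field not in table.columns:
            raise KeyError(f"metrics table lacks field {self.field!r}")
        col = table[self.field].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        out = np.zeros(len(col), dtype=bool)
        v = self.value
        if self.op == "lt":
            out[ok] = col[ok] < v
        elif self.op == "le":
            out[ok] = col[ok] <= v
        elif self.op == "gt":
            out[ok] = col[ok] > v
        elif self.op == "ge":
            out[ok] = col[ok] >= v
        elif self.op == "eq":
            out[ok] = col[ok] == v
        elif self.op == "ne":
            out[ok] = col[ok] != v
        elif self.op == "between_co":
            out[ok] = (col[ok] >= v[0]) & (col[ok] < v[1])
        else:  # between_cc
            out[ok] = (col[ok] >= v[0]) & (col[ok] <= v[1])
        return out


@dataclass(frozen=True)
class Rule:
    """A flagging criterion: the conjunction of its clauses.

    ``kind`` separates geometry rules (cluster shape/position defects,
    candidates for reclustering repair) from frequency rules (the
    MAF-and-call-frequency combinations, which flag incompletely called
    rare variants rather than a repairable geometry)."""

    id: str
    category: str
    clauses: tuple[Clause, ...]
    kind: str = "geometry"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.kind not in ("geometry", "frequency"):
            raise ValueError("kind must be geometry or frequency")
        if not self.clauses:
            raise ValueError("a rule needs at least one clause")

    def evaluate(self, table: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(table), dtype=bool)
        for clause in self.clauses:
            out &= clause.evaluate(table)
        return out


def _rule(id: str, category: str, kind: str, *clauses: tuple) -> Rule:
    return Rule(id, category, tuple(Clause(*c) for c in clauses), kind)


def builtin_ruleset(name: str, ab_r_mean_max: float = 0.3) -> tuple[Rule, ...]:
    """Return the 17 rules of the named built-in ruleset.

    The AB R Mean criterion has no conventional printed cutoff; the
    default predicate is ``ab_r_mean < ab_r_mean_max`` (0.3).
    """
    if name not in RULESET_NAMES:
        raise ValueError(f"unknown ruleset {name!r}; valid names: {RULESET_NAMES}")
    adjusted = name == "adjusted"
    # the four rows that differ between the two rulesets
    cf_bound = ("call_freq", "lt", 0.99) if adjusted else ("n_nc", "ge", 1)
    ab_maf_bound = ("maf", "gt", 0.0002) if adjusted else ("mac", "ge", 1)
    return (
        _rule("call_freq_interval", "clustering_error", "geometry",
              ("call_freq", "between_co", (0.95, 0.99))),
        _rule("cluster_sep_low", "clustering_error", "geometry",
              ("cluster_sep", "lt", 0.4)),
        _rule("ab_freq_high", "clustering_error", "geometry",
              ("freq_ab", "gt", 0.6)),
        _rule("ab_r_mean_low", "clustering_error", "geometry",
              ("ab_r_mean", "lt", ab_r_mean_max)),
        _rule("het_excess_high", "clustering_error", "geometry",
              ("het_excess", "gt", 0.1)),
        _rule("het_excess_low", "clustering_error", "geometry",
              ("het_excess", "lt", -0.9)),
        _rule("rare_low_call", "clustering_error", "frequency",
              ("maf", "lt", 0.0001), cf_bound),
        _rule("aa_t_mean_shifted", "aa_cluster_error", "geometry",
              ("t_mean_aa", "between_cc", (0.2, 0.3))),
        _rule("aa_t_dev_high", "aa_cluster_error", "geometry",
              ("t_dev_aa", "gt", 0.025)),
        _rule("aa_only_low_call", "aa_cluster_error", "frequency",
              ("n_aa", "ge", 1), ("n_ab", "eq", 0), ("n_bb", "eq", 0), cf_bound),
        _rule("ab_t_mean_low", "ab_cluster_error", "geometry",
              ("t_mean_ab", "between_cc", (0.2, 0.3))),
        _rule("ab_t_mean_high", "ab_cluster_error", "geometry",
              ("t_mean_ab", "between_cc", (0.7, 0.8))),
        _rule("ab_t_dev_high", "ab_cluster_error", "geometry",
              ("t_dev_ab", "ge", 0.07)),
        _rule("no_het_minor", "ab_cluster_error", "frequency",
              ("n_ab", "eq", 0), ab_maf_bound),
        _rule("bb_t_mean_shifted", "bb_cluster_error", "geometry",
              ("t_mean_bb", "between_cc", (0.7, 0.8))),
        _rule("bb_t_dev_high", "bb_cluster_error", "geometry",
              ("t_dev_bb", "gt", 0.025)),
        _rule("bb_only_low_call", "bb_cluster_error", "frequency",
              ("n_bb", "ge", 1), ("n_aa", "eq", 0), ("n_ab", "eq", 0), cf_bound),
    )


#: Published per-rule flagged-variant counts for the CHARGE criteria on
#: a 14,647-sample Korean exome-chip cohort; used as a redundancy-
#: accounting fixture (their sum is the redundancy-counted total).
REFERENCE_CHARGE_COUNTS: dict[str, int] = {
    "call_freq_interval": 2841,
    "cluster_sep_low": 693,
    "ab_freq_high": 1,
    "ab_r_mean_low": 645,
    "het_excess_high": 13,
    "het_excess_low": 17,
    "rare_low_call": 119_896,
    "aa_t_mean_shifted": 759,
    "aa_t_dev_high": 2195,
    "aa_only_low_call": 43_012,
    "ab_t_mean_low": 847,
    "ab_t_mean_high": 2685,
    "ab_t_dev_high": 272,
    "no_het_minor": 70_597,
    "bb_t_mean_shifted": 690,
    "bb_t_dev_high": 2742,
    "bb_only_low_call": 16_352,
}

#: Same fixture for the adjusted criteria. The originally reported
#: redundancy total for this column (46,076) does not equal the sum of
#: its per-rule counts (28,796); this package defines the total as the
#: redundancy sum and does not emulate that inconsistency.
REFERENCE_ADJUSTED_COUNTS: dict[str, int] = {
    **{k: v for k, v in REFERENCE_CHARGE_COUNTS.items()},
    "rare_low_call": 2171,
    "aa_only_low_call": 561,
    "no_het_minor": 11_572,
    "bb_only_low_call": 92,
}


@dataclass
class FlagReport:
    """Rule hits over a metrics table.

    ``hits`` has one row per (variant, rule) pair with columns
    (variant_id, rule_id, category, kind); redundancy is intrinsic —
    a variant flagged by three rules contributes three rows."""

    hits: pd.DataFrame
    rule_ids: tuple[str, ...]
    categories: dict[str, str]

    def flagged_variants(self, rule_id: str | None = None) -> list[str]:
        h = self.hits
        if rule_id is not None:
            h = h[h["rule_id"] == rule_id]
        return list(dict.fromkeys(h["variant_id"]))

    def per_rule_counts(self) -> pd.Series:
        counts = self.hits["rule_id"].value_counts()
        return pd.Series({rid: int(counts.get(rid, 0)) for rid in self.rule_ids})


@dataclass
class FlagSummary:
    per_rule: pd.DataFrame
    per_category: pd.Series
    redundancy_total: int
    unique_variants: int

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.per_rule.itertuples(index=False, name=None))
        for cat, count in self.per_category.items():
            rows.append((cat, f"subtotal:{cat}", int(count)))
        rows.append(("all", "total_with_redundancy", self.redundancy_total))
        rows.append(("all", "unique_variants", self.unique_variants))
        return pd.DataFrame(rows, columns=["category", "rule_id", "n_variants"])


def apply_ruleset(table: pd.DataFrame, ruleset: Sequence[Rule]) -> FlagReport:
    """Evaluate every rule independently on every variant.

    Absent (NaN) metric fields make any predicate referencing them
    false; rules are order-independent by construction.
    """
    if "variant_id" not in table.columns:
        raise KeyError("metrics table needs a variant_id column")
    ids = table["variant_id"].to_numpy()
    frames = []
    for rule in ruleset:
        mask = rule.evaluate(table)
        if mask.any():
            frames.append(pd.DataFrame({
                "variant_id": ids[mask],
                "rule_id": rule.id,
                "category": rule.category,
                "kind": rule.kind,
            }))
    if frames:
        hits = pd.concat(frames, ignore_index=True)
    else:
        hits = pd.DataFrame(columns=["variant_id", "rule_id", "category", "kind"])
    return FlagReport(hits, tuple(r.id for r in ruleset),
                      {r.id: r.category for r in ruleset})


def summarize_counts(per_rule: Mapping[str, int],
                     categories: Mapping[str, str],
                     unique_variants: int | None = None) -> FlagSummary:
    """Summary semantics shared by live reports and printed-count
    fixtures: per-rule counts, per-category subtotals, a grand total
    counted with redundancy (the plain sum), and the unique count when
    known."""
    rows = [(categories[rid], rid, int(n)) for rid, n in per_rule.items()]
    per_rule_df = pd.DataFrame(rows, columns=["category", "rule_id", "n_variants"])
    per_category = per_rule_df.groupby("category", sort=False)["n_variants"].sum()
    total = int(per_rule_df["n_variants"].sum())
    return FlagSummary(per_rule_df, per_category, total,
                       int(unique_variants) if unique_variants is not None else total)


def summarize_flags(report: FlagReport) -> FlagSummary:
    """Per-rule counts, category subtotals, redundancy-counted total and
    unique-variant count for a FlagReport."""
    per_rule = report.per_rule_counts().to_dict()
    unique = report.hits["variant_id"].nunique()
    return summarize_counts(per_rule, report.categories, unique)


# ---------------------------------------------------------------------------
# rulesets as data

def ruleset_to_dicts(ruleset: Iterable[Rule]) -> list[dict]:
    out = []
    for rule in ruleset:
        out.append({
            "id": rule.id,
            "category": rule.category,
            "kind": rule.kind,
            "clauses": [
                {"field": c.field, "op": c.op,
                 "value": list(c.value) if isinstance(c.value, tuple) else c.value}
                for c in rule.clauses
            ],
        })
    return out


def ruleset_from_dicts(items: Iterable[Mapping]) -> tuple[Rule, ...]:
    rules = []
    for item in items:
        clauses = tuple(
            Clause(c["field"], c["op"],
                   tuple(c["value"]) if isinstance(c["value"], (list, tuple)) else c["value"])
            for c in item["clauses"]
        )
        rules.append(Rule(item["id"], item["category"], clauses,
                          item.get("kind", "geometry")))
    return tuple(rules)
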