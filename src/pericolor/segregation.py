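"""Qualitative inheritance models for pericarp pigmentation in DH populations.

A doubled-haploid (DH) line from a biparental cross is fully homozygous and,
for unlinked loci, carries the functional allele at each locus independently
with probability 1/2.  A genetic model is a boolean expression over loci
("A or (B and C)") that is true exactly when the multilocus genotype produces
pigmented pericarp.  Expected pigmented:clear ratios follow by enumerating
the 2^L equiprobable multilocus classes, and observed counts are tested
against each model by a one-way Pearson chi-square goodness-of-fit test.
"""

from __future__ import annotations

import ast
import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd
from scipy import stats

__all__ = [
    "GeneticModel",
    "SegregationTest",
    "STANDARD_MODELS",
    "dh_expected_proportion",
    "chisq_goodness_of_fit",
    "select_best_model",
    "pigment_frequency",
]


def _parse_logic(expression: str, loci: tuple[str, ...]):
    """Compile a boolean locus expression into a callable.

    Only names, ``and``, ``or``, ``not`` and parentheses are allowed.  Every
    name must be a declared locus.
    """
    tree = ast.parse(expression, mode="eval")
    declared = set(loci)

    def check(node: ast.AST) -> None:
        if isinstance(node, ast.Expression):
            check(node.body)
        elif isinstance(node, ast.BoolOp) and isinstance(node.op, (ast.And, ast.Or)):
            for v in node.values:
                check(v)
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
            check(node.operand)
        elif isinstance(node, ast.Name):
            if node.id not in declared:
                raise ValueError(
                    f"logic references undeclared locus {node.id!r}; "
                    f"declared loci: {sorted(declared)}"
                )
        else:
            raise ValueError(f"unsupported syntax in locus logic: {ast.dump(node)}")

    check(tree)
    code = compile(tree, "<locus-logic>", "eval")

    def evaluate(genotype: dict[str, bool]) -> bool:
        return bool(eval(code, {"__builtins__": {}}, dict(genotype)))

    return evaluate


@dataclass(frozen=True)
class GeneticModel:
    """A declarative pigment-inheritance model over unlinked loci.

    ``logic`` is a boolean expression in the locus labels; a locus name is
    true when the line carries the functional allele at that locus.  The DH
    expected pigmented proportion is derived by exhaustive enumeration and
    cached on first access.
    """

    name: str
    loci: tuple[str, ...]
    logic: str
    aliases: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        _parse_logic(self.logic, self.loci)  # validate eagerly

    @property
    def expected_pigmented(self) -> Fraction:
        return dh_expected_proportion(self.logic, self.loci)

    def ratio_label(self) -> str:
        p = self.expected_pigmented
        return f"{p.numerator}:{p.denominator - p.numerator}"

    def is_pigmented(self, genotype: dict[str, bool]) -> bool:
        return _parse_logic(self.logic, self.loci)(genotype)


def dh_expected_proportion(logic: str, loci: tuple[str, ...] | list[str]) -> Fraction:
    """Exact pigmented proportion in a DH population under a locus logic.

    Enumerates all ``2**L`` equiprobable fully homozygous classes and counts
    those for which the logic evaluates true.  Returns an exact rational.
    """
    loci = tuple(loci)
    if not loci:
        raise ValueError("at least one locus required")
    evaluate = _parse_logic(logic, loci)
    hits = 0
    for combo in itertools.product((False, True), repeat=len(loci)):
        if evaluate(dict(zip(loci, combo))):
            hits += 1
    return Fraction(hits, 2 ** len(loci))


#: The six standard models for DH segregation of pigmented pericarp:
#: single-gene 1:1, two additive genes 3:1, duplicate-function epistasis
#: 1:3 and 1:7, and the two three-locus mixed models 5:3 and 3:5.
STANDARD_MODELS: tuple[GeneticModel, ...] = (
    GeneticModel("Single gene", ("A",), "A"),
    GeneticModel("Two additive genes", ("A", "B"), "A or B", aliases=("additive",)),
    GeneticModel("Function in 2 genes", ("A", "B"), "A and B",
                 aliases=("2 functional genes",)),
    GeneticModel("Function in 3 genes", ("A", "B", "C"), "A and B and C"),
    GeneticModel("Functional A or functional B and C", ("A", "B", "C"),
                 "A or (B and C)"),
    GeneticModel("Functional A and functional B or C", ("A", "B", "C"),
                 "A and (B or C)"),
)


@dataclass(frozen=True)
class SegregationTest:
    """Chi-square goodness-of-fit of observed pigmented/clear counts."""

    observed_pigmented: int
    observed_clear: int
    expected_pigmented_count: float
    expected_clear_count: float
    chi_square: float
    df: int
    p_value: float
    unreliable: bool = False  # an expected count fell below 1


def chisq_goodness_of_fit(
    observed_pigmented: int, observed_clear: int, expected_proportion: float
) -> SegregationTest:
    """Pearson chi-square test of a pigmented:clear split, df = 1.

    No continuity correction is applied (one-way goodness-of-fit).
    """
    if observed_pigmented < 0 or observed_clear < 0:
        raise ValueError("counts must be nonnegative")
    total = observed_pigmented + observed_clear
    if total == 0:
        raise ValueError("total count must be positive")
    p = float(expected_proportion)
    if not 0.0 < p < 1.0:
        raise ValueError("expected proportion must be strictly between 0 and 1")
    exp_p = total * p
    exp_c = total * (1.0 - p)
    stat, pval = stats.chisquare([observed_pigmented, observed_clear], [exp_p, exp_c])
    return SegregationTest(
        observed_pigmented=observed_pigmented,
        observed_clear=observed_clear,
        expected_pigmented_count=exp_p,
        expected_clear_count=exp_c,
        chi_square=float(stat),
        df=1,
        p_value=float(pval),
        unreliable=min(exp_p, exp_c) < 1.0,
    )


def select_best_model(
    observed_pigmented: int,
    observed_clear: int,
    models: tuple[GeneticModel, ...] = STANDARD_MODELS,
    tie_tol: float = 1e-6,
) -> pd.DataFrame:
    """Test observed counts against every candidate model and rank by p-value.

    Returns a DataFrame sorted by descending p-value with a boolean
    ``best`` column; models whose p-value is within ``tie_tol`` of the
    maximum are all flagged best (ties are reported, never broken silently).
    """
    if not models:
        raise ValueError("at least one candidate model required")
    rows = []
    for m in models:
        t = chisq_goodness_of_fit(observed_pigmented, observed_clear,
                                  float(m.expected_pigmented))
        rows.append(
            {
                "model": m.name,
                "ratio": m.ratio_label(),
                "expected_proportion": float(m.expected_pigmented),
                "chi_square": t.chi_square,
                "p_value": t.p_value,
            }
        )
    table = pd.DataFrame(rows).sort_values("p_value", ascending=False, kind="stable")
    table["best"] = table["p_value"] >= table["p_value"].max() - tie_tol
    return table.reset_index(drop=True)


def pigment_frequency(observed_pigmented: int, total: int) -> float:
    """Fraction of lines scored pigmented."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= observed_pigmented <= total:
        raise ValueError("pigmented count must lie in [0, total]")
    return observed_pigmented / total
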