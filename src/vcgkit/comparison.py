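"""Rank-based statistical comparison of transformation-method accuracy.

The decision cascade applied to the per-lead MSE table:

1. **Shapiro-Wilk** normality test per (method, lead) cell.  MSE of
   biological signals is typically right-skewed, so normality is
   expected to be rejected; the result is reported but by default does
   not gate the cascade.
2. **Kruskal-Wallis** k-sample test on the pooled mid-ranks of the
   methods' MSE values within each lead,

       Q = -3(n+1) + 12/(n(n+1)) * sum_i T_i^2 / n_i,

   divided by the tie correction 1 - sum(t^3 - t)/(n^3 - n) and
   referred to the chi-square distribution with k-1 df.
3. **Dunn post-hoc** pairwise z-tests on mean ranks when the
   Kruskal-Wallis test rejects at level alpha.
4. **Compact letter display**: methods sorted by median MSE receive
   letters such that two methods share a letter iff Dunn does not
   separate them at alpha — the "homogeneous groups" read directly as
   the resulting accuracy order.

The cascade is wrapped statsmodels-style: :class:`MethodComparison` is
the model built from an MSE table, ``fit()`` returns a
:class:`MethodComparisonResults` with the per-lead test results,
letters and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import VCG_LEADS

__all__ = [
    "TestResult",
    "PosthocResult",
    "shapiro_wilk",
    "kruskal_wallis",
    "dunn_posthoc",
    "compact_letter_display",
    "MethodComparison",
    "MethodComparisonResults",
    "run_full_comparison",
]


class DegenerateInputError(ValueError):
    """Sample degenerate for the requested test (e.g. constant values)."""


@dataclass(frozen=True)
class TestResult:
    """Statistic and p-value of a single hypothesis test."""

    statistic: float
    p_value: float
    df: int | None = None
    method_name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class PosthocResult:
    """Pairwise Dunn comparison with homogeneous-group letters.

    ``z_matrix``/``p_matrix`` are k x k (z antisymmetric, p symmetric
    with unit diagonal); ``letters`` maps each method to its letter
    string; ``resulting_order`` lists (method, median, letters) sorted
    by ascending median — methods sharing a letter are not statistically
    separated at ``alpha``.
    """

    methods: tuple[str, ...]
    z_matrix: np.ndarray
    p_matrix: np.ndarray
    alpha: float
    medians: dict[str, float]
    letters: dict[str, str]
    resulting_order: list[tuple[str, float, str]]


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk W-test of normality (Royston's AS R94 algorithm).

    W = (sum a_i y_(i))^2 / sum (y_i - ybar)^2 for the ordered sample,
    with the coefficients a_i and the p-value from Royston's
    approximation (valid for 3 <= n <= 5000).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk requires n >= 3; got n = {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return TestResult(statistic=float(w), p_value=float(p), df=None,
                      method_name="shapiro-wilk")


def _rank_groups(groups: Sequence[np.ndarray]) -> tuple[list[np.ndarray], int, float]:
    """Pooled mid-ranks split back per group, plus n and the tie term sum(t^3-t)."""
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled, method="average")
    # internal consistency: pooled mid-ranks always sum to n(n+1)/2
    assert abs(ranks.sum() - n * (n + 1) / 2.0) < 1e-8 * max(n, 1), \
        "pooled rank sum violates the n(n+1)/2 identity"
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    return split, n, tie_term


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank test across k independent samples.

    Computes Q from the per-group rank sums T_i over the pooled
    mid-ranks, applies the standard tie correction, and refers
    Q to the chi-square distribution with k-1 degrees of freedom
    (an approximation that is accurate once every group has at least
    5 observations; smaller groups trigger a warning).
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group must contain at least one observation")
    n = sum(a.size for a in arrays)
    if n < 3:
        raise ValueError(f"total sample size must be >= 3; got {n}")
    if np.ptp(np.concatenate(arrays)) == 0:
        raise DegenerateInputError(
            "all observations identical; Kruskal-Wallis statistic undefined"
        )
    if any(a.size < 5 for a in arrays):
        warnings.warn(
            "some groups have fewer than 5 observations; the chi-square "
            "approximation to the Kruskal-Wallis statistic may be inaccurate",
            stacklevel=2,
        )
    rank_groups, n, tie_term = _rank_groups(arrays)
    t_sums = np.array([r.sum() for r in rank_groups])
    sizes = np.array([r.size for r in rank_groups], dtype=float)
    q = -3.0 * (n + 1) + 12.0 / (n * (n + 1)) * np.sum(t_sums**2 / sizes)
    correction = 1.0 - tie_term / (n**3 - n)
    q /= correction
    df = len(arrays) - 1
    p = float(sps.chi2.sf(q, df))
    return TestResult(statistic=float(q), p_value=p, df=df,
                      method_name="kruskal-wallis")


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    """Multiplicity adjustment over a flat vector of pairwise p-values."""
    m = p.size
    if method == "none" or m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {method!r}; expected none|bonferroni|holm")


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str],
    alpha: float = 0.05,
    adjust: str = "none",
) -> PosthocResult:
    """Dunn's pairwise z-tests on mean pooled ranks, with letter display.

    z_ij = (Rbar_i - Rbar_j) / sqrt(S2 * (1/n_i + 1/n_j)) with the
    tie-corrected rank variance S2 = n(n+1)/12 - sum(t^3-t)/(12(n-1));
    two-sided p-values from the standard normal, optionally adjusted
    (``bonferroni`` or ``holm``).  Letters and the resulting order come
    from :func:`compact_letter_display` on the adjusted p-matrix.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    labels = [str(l) for l in labels]
    if len(arrays) != len(labels):
        raise ValueError("labels must match groups")
    if len(arrays) < 2:
        raise ValueError("Dunn post-hoc requires at least 2 groups")
    if np.ptp(np.concatenate(arrays)) == 0:
        raise DegenerateInputError("all observations identical; ranks degenerate")
    rank_groups, n, tie_term = _rank_groups(arrays)
    mean_ranks = np.array([r.mean() for r in rank_groups])
    sizes = np.array([r.size for r in rank_groups], dtype=float)
    s2 = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    k = len(arrays)
    z = np.zeros((k, k))
    p = np.ones((k, k))
    iu = np.triu_indices(k, 1)
    for i, j in zip(*iu):
        denom = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zij = (mean_ranks[i] - mean_ranks[j]) / denom
        z[i, j], z[j, i] = zij, -zij
        p[i, j] = p[j, i] = 2.0 * sps.norm.sf(abs(zij))
    p_flat_adj = _adjust_pvalues(p[iu], adjust)
    p[iu] = p_flat_adj
    p[(iu[1], iu[0])] = p_flat_adj

    medians = {lab: float(np.median(a)) for lab, a in zip(labels, arrays)}
    letters, order = compact_letter_display(p, labels, medians, alpha)
    return PosthocResult(
        methods=tuple(labels), z_matrix=z, p_matrix=p, alpha=alpha,
        medians=medians, letters=letters, resulting_order=order,
    )


def compact_letter_display(
    p_matrix: np.ndarray,
    labels: Sequence[str],
    medians: dict[str, float],
    alpha: float = 0.05,
) -> tuple[dict[str, str], list[tuple[str, float, str]]]:
    """Insert-and-absorb homogeneous-group letters.

    Two methods share a letter iff their pairwise p-value is >= alpha.
    The algorithm starts from one group holding every method; each
    significant pair splits every group containing both (duplicating
    the group and deleting one member from each copy), then groups
    contained in another are absorbed.  Letters are ordered 'a', 'b',
    ... by the smallest median among each group's members, so 'a' tags
    the most accurate homogeneous group.

    Returns (letters-per-label, resulting order) where the resulting
    order lists (label, median, letters) by ascending median.
    """
    p_matrix = np.asarray(p_matrix, dtype=float)
    labels = [str(l) for l in labels]
    k = len(labels)
    if p_matrix.shape != (k, k):
        raise ValueError(f"p_matrix shape {p_matrix.shape} does not match {k} labels")
    if not np.allclose(p_matrix, p_matrix.T):
        raise ValueError("p_matrix must be symmetric")

    groups: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if p_matrix[i, j] < alpha:          # separated pair: split
                new_groups: list[set[int]] = []
                for g in groups:
                    if i in g and j in g:
                        new_groups.append(g - {i})
                        new_groups.append(g - {j})
                    else:
                        new_groups.append(g)
                # absorb: drop empty, duplicate, and subset groups
                unique: list[set[int]] = []
                for g in new_groups:
                    if g and g not in unique:
                        unique.append(g)
                groups = [g for g in unique if not any(g < h for h in unique)]

    # order letter columns by the best (smallest) median they contain
    def group_key(g: set[int]) -> float:
        return min(medians[labels[i]] for i in g)

    groups.sort(key=group_key)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for col, g in enumerate(groups):
        letter = alphabet[col] if col < len(alphabet) else f"g{col}"
        for i in sorted(g):
            letters[labels[i]] += letter
    order = sorted(
        ((lab, medians[lab], letters[lab]) for lab in labels),
        key=lambda item: item[1],
    )
    return letters, order


# ---------------------------------------------------------------------------
# model / results wrapper
# ---------------------------------------------------------------------------

@dataclass
class LeadComparison:
    """All test results for one orthogonal lead."""

    lead: str
    methods: tuple[str, ...]
    medians: dict[str, float]
    normality: dict[str, TestResult | None]
    kruskal: TestResult
    posthoc: PosthocResult | None


class MethodComparison:
    """Statistical comparison of transformation methods from an MSE table.

    Parameters
    ----------
    table : DataFrame
        Long-format MSE table with columns ``record_id``, ``method``,
        ``lead``, ``mse`` (the output of
        :func:`vcgkit.evaluate.evaluate_cohort`).
    leads : sequence of str, optional
        Leads to analyse; defaults to the leads present, in X, Y, Z
        order.

    Examples
    --------
    >>> model = MethodComparison.from_dataframe(mse_table)   # doctest: +SKIP
    >>> results = model.fit(alpha=0.05)                      # doctest: +SKIP
    >>> print(results.summary())                             # doctest: +SKIP
    """

    def __init__(self, table: pd.DataFrame, leads: Sequence[str] | None = None):
        required = {"record_id", "method", "lead", "mse"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"MSE table is missing columns {sorted(missing)}")
        if (table["mse"] < 0).any():
            raise ValueError("MSE values must be non-negative")
        self.table = table.copy()
        present = [l for l in VCG_LEADS if l in set(table["lead"])]
        extra = [l for l in table["lead"].unique() if l not in VCG_LEADS]
        self.leads = list(leads) if leads is not None else present + extra
        if not self.leads:
            raise ValueError("no leads found in the MSE table")
        self.methods = tuple(sorted(table["method"].unique()))
        if len(self.methods) < 1:
            raise ValueError("no methods found in the MSE table")

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "MethodComparison":
        return cls(table, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "MethodComparison":
        return cls(pd.read_csv(Path(path)), **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        adjust: str = "none",
        gate_on_normality: bool = False,
        pooled_normality: bool = False,
    ) -> "MethodComparisonResults":
        """Run the Shapiro-Wilk / Kruskal-Wallis / Dunn cascade per lead.

        ``gate_on_normality=True`` skips the rank tests on a lead where
        no method cell rejects normality (all Shapiro-Wilk p >= alpha);
        by default normality is reported only.  ``pooled_normality``
        tests the lead's pooled MSE sample instead of per-method cells.
        """
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1); got {alpha}")
        per_lead: dict[str, LeadComparison] = {}
        for lead in self.leads:
            sub = self.table[self.table["lead"] == lead]
            methods = tuple(m for m in self.methods if m in set(sub["method"]))
            if len(methods) < 2:
                per_lead[lead] = self._single_method_lead(lead, sub, methods)
                continue
            groups = [sub.loc[sub["method"] == m, "mse"].to_numpy(float) for m in methods]
            normality: dict[str, TestResult | None] = {}
            if pooled_normality:
                normality["pooled"] = self._safe_shapiro(np.concatenate(groups))
            else:
                for m, g in zip(methods, groups):
                    normality[m] = self._safe_shapiro(g)
            if gate_on_normality:
                tested = [r for r in normality.values() if r is not None]
                if tested and all(r.p_value >= alpha for r in tested):
                    per_lead[lead] = LeadComparison(
                        lead=lead, methods=methods,
                        medians={m: float(np.median(g)) for m, g in zip(methods, groups)},
                        normality=normality,
                        kruskal=TestResult(np.nan, 1.0, len(methods) - 1,
                                           "kruskal-wallis (skipped: data normal)"),
                        posthoc=None,
                    )
                    continue
            kw = kruskal_wallis(groups)
            posthoc = None
            if kw.p_value < alpha:
                posthoc = dunn_posthoc(groups, methods, alpha=alpha, adjust=adjust)
            per_lead[lead] = LeadComparison(
                lead=lead, methods=methods,
                medians={m: float(np.median(g)) for m, g in zip(methods, groups)},
                normality=normality, kruskal=kw, posthoc=posthoc,
            )
        return MethodComparisonResults(self, per_lead, alpha=alpha, adjust=adjust)

    @staticmethod
    def _safe_shapiro(values: np.ndarray) -> TestResult | None:
        try:
            return shapiro_wilk(values)
        except (ValueError, DegenerateInputError):
            return None

    @staticmethod
    def _single_method_lead(lead, sub, methods) -> LeadComparison:
        medians = {
            m: float(np.median(sub.loc[sub["method"] == m, "mse"])) for m in methods
        }
        return LeadComparison(
            lead=lead, methods=methods, medians=medians,
            normality={m: None for m in methods},
            kruskal=TestResult(np.nan, 1.0, None,
                               "kruskal-wallis (skipped: fewer than 2 methods)"),
            posthoc=None,
        )


class MethodComparisonResults:
    """Fitted comparison: per-lead tests, letters, and summary tables."""

    def __init__(
        self,
        model: MethodComparison,
        per_lead: dict[str, LeadComparison],
        alpha: float,
        adjust: str,
    ):
        self.model = model
        self.per_lead = per_lead
        self.alpha = alpha
        self.adjust = adjust

    @property
    def leads(self) -> list[str]:
        return list(self.per_lead)

    def letters(self, lead: str) -> dict[str, str]:
        """Letter set per method on one lead ('a' = most accurate group).

        When the Kruskal-Wallis test does not reject, no post-hoc was
        run and every method shares the single letter 'a'.
        """
        comp = self.per_lead[lead]
        if comp.posthoc is not None:
            return dict(comp.posthoc.letters)
        return {m: "a" for m in comp.methods}

    def resulting_order(self, lead: str) -> list[tuple[str, float, str]]:
        """Methods on one lead sorted by ascending median MSE with letters."""
        comp = self.per_lead[lead]
        if comp.posthoc is not None:
            return list(comp.posthoc.resulting_order)
        letters = self.letters(lead)
        return sorted(
            ((m, comp.medians[m], letters[m]) for m in comp.methods),
            key=lambda item: item[1],
        )

    def to_dict(self) -> dict:
        """Machine-readable report (JSON-serialisable)."""
        report: dict = {"alpha": self.alpha, "adjust": self.adjust, "leads": {}}
        for lead, comp in self.per_lead.items():
            entry = {
                "methods": list(comp.methods),
                "medians": comp.medians,
                "normality": {
                    m: None if r is None else
                    {"W": r.statistic, "p_value": r.p_value}
                    for m, r in comp.normality.items()
                },
                "kruskal_wallis": {
                    "Q": comp.kruskal.statistic,
                    "df": comp.kruskal.df,
                    "p_value": comp.kruskal.p_value,
                },
                "letters": self.letters(lead),
                "resulting_order": [
                    {"method": m, "median_mse": med, "letters": let}
                    for m, med, let in self.resulting_order(lead)
                ],
            }
            if comp.posthoc is not None:
                entry["dunn"] = {
                    "z": comp.posthoc.z_matrix.tolist(),
                    "p": comp.posthoc.p_matrix.tolist(),
                    "methods": list(comp.posthoc.methods),
                }
            report["leads"][lead] = entry
        return report

    def summary(self) -> str:
        """Plain-text report: per-lead tests and the letter-ranked order."""
        lines = [
            "Transformation-method accuracy comparison",
            f"alpha = {self.alpha:g}, p-adjustment = {self.adjust}",
            "=" * 58,
        ]
        for lead, comp in self.per_lead.items():
            kw = comp.kruskal
            lines.append(f"Lead {lead}:")
            if np.isnan(kw.statistic):
                lines.append(f"  {kw.method_name}")
            else:
                lines.append(
                    f"  Kruskal-Wallis Q = {kw.statistic:.4f}, "
                    f"df = {kw.df}, p = {kw.p_value:.4g}"
                    + ("  (reject H0)" if kw.p_value < self.alpha else "  (no rejection)")
                )
            sw = [
                f"{m}: p={r.p_value:.3g}" for m, r in comp.normality.items() if r is not None
            ]
            if sw:
                lines.append("  Shapiro-Wilk " + ", ".join(sw))
            lines.append("  order (median MSE, homogeneous groups):")
            for rank, (m, med, let) in enumerate(self.resulting_order(lead), 1):
                lines.append(f"    {rank}. {m:<6} {med:12.6g} mV^2   {let}")
            lines.append("-" * 58)
        return "\n".join(lines)


def run_full_comparison(
    table: pd.DataFrame, alpha: float = 0.05, adjust: str = "none", **fit_kwargs
) -> MethodComparisonResults:
    """Convenience wrapper: build :class:`MethodComparison` and fit it."""
    return MethodComparison(table).fit(alpha=alpha, adjust=adjust, **fit_kwargs)
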