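"""Statistics layer shared by all analyses.

One-way ANOVA with Tukey's multiple-comparison test and a compact letter
display, the pooled-variance unpaired t-test, Spearman rank correlation,
Benjamini–Hochberg FDR, a chi-square goodness-of-fit check for Mendelian
ratios, and comparative-C_T (ΔΔC_T) relative expression.

Group comparisons of per-fish measurements use the classical fixed-effects
("ordinary") one-way ANOVA with equal variances; a Welch variant is available
behind a flag. Pairwise letters encode the all-pairs Tukey result so that two
groups share a letter if and only if they are not significantly different at
the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupedMeasurements",
    "LetterDisplay",
    "CtTable",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "unpaired_t_test",
    "spearman_rho",
    "bh_fdr",
    "mendelian_fit",
    "ddct_relative_expression",
]


@dataclass
class GroupedMeasurements:
    """Replicate measurements keyed by group label (one value per fish/pool)."""

    groups: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for label, values in self.groups.items():
            if len(values) < 2:
                raise ValueError(f"group {label!r} has fewer than 2 values")

    def labels(self) -> list[str]:
        return list(self.groups)

    def arrays(self) -> list[np.ndarray]:
        return [np.asarray(v, dtype=float) for v in self.groups.values()]


@dataclass
class LetterDisplay:
    """Letter coding of an all-pairs comparison: shared letter == not different."""

    letters: dict[str, str]
    alpha: float = 0.05

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


@dataclass
class CtTable:
    """qPCR threshold cycles: sample -> gene -> C_T, plus normalization anchors."""

    ct: Mapping[str, Mapping[str, float]]
    reference_gene: str
    calibrator_samples: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sample, genes in self.ct.items():
            if self.reference_gene not in genes:
                raise ValueError(
                    f"reference gene {self.reference_gene!r} missing in sample {sample!r}"
                )


def one_way_anova(groups: GroupedMeasurements, welch: bool = False) -> tuple[float, float]:
    """Ordinary (fixed-effects, equal-variance) one-way ANOVA F test.

    Returns (F, p). With all groups identical the decomposition is degenerate
    (0/0); that edge is reported as F=0, p=1 rather than NaN.
    """
    arrays = groups.arrays()
    if welch:
        res = sps.alexandergovern(*arrays)
        return float(res.statistic), float(res.pvalue)
    f, p = sps.f_oneway(*arrays)
    if np.isnan(f):
        # zero within- and between-group variance: no evidence against the null
        return 0.0, 1.0
    return float(f), float(p)


def tukey_hsd(groups: GroupedMeasurements) -> dict[tuple[str, str], float]:
    """All-pairs Tukey HSD adjusted p-values (Tukey–Kramer for unbalanced groups)."""
    labels = groups.labels()
    res = sps.tukey_hsd(*groups.arrays())
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                p = float(res.pvalue[i, j])
                out[(a, b)] = 1.0 if np.isnan(p) else p
    return out


def _pairwise_matrix(
    pairwise_p: Mapping[tuple[str, str], float]
) -> tuple[list[str], np.ndarray]:
    labels: list[str] = []
    for a, b in pairwise_p:
        for x in (a, b):
            if x not in labels:
                labels.append(x)
    n = len(labels)
    mat = np.ones((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    seen = set()
    for (a, b), p in pairwise_p.items():
        i, j = idx[a], idx[b]
        if (j, i) in seen and not np.isclose(mat[j, i], p):
            raise ValueError(f"inconsistent p for pair ({a!r}, {b!r})")
        mat[i, j] = mat[j, i] = p
        seen.add((i, j))
    return labels, mat


def compact_letter_display(
    pairwise_p: Mapping[tuple[str, str], float], alpha: float = 0.05
) -> LetterDisplay:
    """Insert-and-absorb letter assignment over an all-pairs p-value matrix.

    Two groups share a letter iff their adjusted p >= alpha. The classic
    insert-and-absorb procedure starts from one letter on all groups; each
    significant pair splits any letter covering both, duplicating it into two
    letters that drop one endpoint each, then absorbs letters whose group set
    is contained in another's.
    """
    labels, mat = _pairwise_matrix(pairwise_p)
    n = len(labels)
    letters: list[set[int]] = [set(range(n))]
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] >= alpha:
                continue
            for col in [c for c in letters if i in c and j in c]:
                letters.remove(col)
                a, b = col - {i}, col - {j}
                for new in (a, b):
                    if new and not any(new <= other for other in letters):
                        letters.append(new)
            # absorb: drop any column contained in another
            letters = [
                c
                for k, c in enumerate(letters)
                if not any(c < other or (c == other and k2 < k)
                           for k2, other in enumerate(letters) if k2 != k)
            ]
    # stable letter naming: order columns by smallest member group index
    letters.sort(key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for k, col in enumerate(letters):
        ch = alphabet[k] if k < 26 else f"a{k}"
        for i in sorted(col):
            out[labels[i]] += ch
    return LetterDisplay(letters=out, alpha=alpha)


def unpaired_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        return 0.0, 1.0
    return float(t), float(p)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (ties assigned average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement.

    q_(i) = min_{j >= i} ( p_(j) * m / j ) for sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def mendelian_fit(
    observed: Mapping[str, int], expected_ratio: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson chi-square goodness of fit of genotype counts to a cross ratio.

    ``expected_ratio`` is normalized to sum to 1 (so 1:2:1 may be given as
    {"AA": 1, "Aa": 2, "aa": 1}); df = categories - 1.
    """
    if set(observed) != set(expected_ratio):
        raise ValueError("observed and expected must cover identical genotypes")
    labels = list(observed)
    obs = np.array([observed[g] for g in labels], dtype=float)
    ratio = np.array([expected_ratio[g] for g in labels], dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    total = ratio.sum()
    if not np.all(ratio > 0):
        raise ValueError("expected ratio entries must be positive")
    exp = obs.sum() * ratio / total
    chi2, p = sps.chisquare(obs, exp)
    return float(chi2), float(p)


def ddct_relative_expression(ct: CtTable, target_gene: str) -> dict[str, float]:
    """Relative mRNA level per sample by the comparative-C_T (ΔΔC_T) method.

    ΔC_T = C_T(target) − C_T(reference gene) per sample; ΔΔC_T subtracts the
    mean ΔC_T of the calibrator samples; fold change = 2^(−ΔΔC_T), so the
    calibrator group averages a fold change of 1 on the log scale.
    """
    if not ct.calibrator_samples:
        raise ValueError("calibrator sample(s) must be defined")
    dct: dict[str, float] = {}
    for sample, genes in ct.ct.items():
        if target_gene not in genes:
            raise ValueError(f"target gene {target_gene!r} missing in sample {sample!r}")
        dct[sample] = genes[target_gene] - genes[ct.reference_gene]
    missing = [s for s in ct.calibrator_samples if s not in dct]
    if missing:
        raise ValueError(f"calibrator samples absent from table: {missing}")
    baseline = float(np.mean([dct[s] for s in ct.calibrator_samples]))
    return {s: float(2.0 ** (-(d - baseline))) for s, d in dct.items()}
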