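"""Non-parametric and clade-blocked comparative analyses.

The sibling-contrast procedure labels internal nodes recursively (an
ancestor is predictor-positive only if *all* its children are positive;
its response is the mean of its children's), then collects one contrast
per internal node whose children disagree in the predictor.  Because each
contrast comes from a disjoint set of children, contrasts are
phylogenetically separate by construction.  The contrast differences are
tested against a zero median/mean by a Wilcoxon signed-rank test (exact
null enumeration for small samples, handling ties and zeros) or by a
bootstrap percentile test on the mean.

Clade blocking is provided by the Scheirer–Ray–Hare test — a two-factor
generalization of Kruskal–Wallis on ranks, with the clade as the blocking
factor — plus plain Kruskal–Wallis for single-clade cases, and by
clade-mean normalization (subtracting each clade's mean response before a
downstream parametric fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .phylo import Phylogeny

__all__ = [
    "SiblingContrast",
    "TestResult",
    "propagate_states",
    "extract_contrasts",
    "wilcoxon_signed_rank",
    "bootstrap_mean_test",
    "srh_test",
    "kruskal_wallis",
    "clade_normalize",
]


@dataclass
class SiblingContrast:
    """Response contrast at one internal node with predictor-diverse children."""

    parent_node: int
    y_plus: float
    y_minus: float

    @property
    def diff(self) -> float:
        return self.y_plus - self.y_minus


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_units: int
    method: str
    all_zero: bool = False
    components: dict = field(default_factory=dict)


def propagate_states(
    tree: Phylogeny, x: dict, y: dict
) -> tuple[dict[int, int], dict[int, float]]:
    """Recursively label internal nodes from tip states.

    ``x`` and ``y`` map tip labels to predictor (0/1) and response values.
    An internal node's predictor is 1 only if every child's is 1; its
    response is the mean of its children's responses.
    """
    x_node: dict[int, int] = {}
    y_node: dict[int, float] = {}
    for v in tree.postorder():
        if tree.is_tip(v):
            label = tree.tip_label(v)
            if label not in x or label not in y:
                raise ValueError(f"tip {label!r} lacks a predictor or response value")
            x_node[v] = int(x[label])
            y_node[v] = float(y[label])
        else:
            kids = tree.children(v)
            x_node[v] = int(all(x_node[c] == 1 for c in kids))
            y_node[v] = float(np.mean([y_node[c] for c in kids]))
    return x_node, y_node


def extract_contrasts(
    tree: Phylogeny, labels: tuple[dict[int, int], dict[int, float]]
) -> list[SiblingContrast]:
    """One contrast per internal node whose children differ in predictor.

    Multifurcations average the response within each predictor class.
    Ordered by node id for determinism; empty if the predictor never
    diverges among siblings.
    """
    x_node, y_node = labels
    contrasts: list[SiblingContrast] = []
    for v in sorted(range(tree.n_nodes)):
        if tree.is_tip(v):
            continue
        kids = tree.children(v)
        plus = [y_node[c] for c in kids if x_node[c] == 1]
        minus = [y_node[c] for c in kids if x_node[c] == 0]
        if plus and minus:
            contrasts.append(
                SiblingContrast(
                    parent_node=v,
                    y_plus=float(np.mean(plus)),
                    y_minus=float(np.mean(minus)),
                )
            )
    return contrasts


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all 2^n sign assignments (ties allowed).

    Average ranks are multiples of 1/2, so doubling makes them integers
    and the null distribution of 2·W+ is built by polynomial convolution.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(np.rint(2 * w_plus))
    p_le = float(pmf[: w2 + 1].sum())
    p_ge = float(pmf[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(diffs) -> TestResult:
    """Two-sided signed-rank test of zero median difference.

    Zeros are dropped; ties share average ranks.  The null distribution is
    enumerated exactly for n ≤ 25 and approximated by a tie-corrected,
    continuity-corrected normal beyond that.  If every difference is zero
    the result carries ``p = 1`` and the ``all_zero`` flag instead of
    raising.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; signed-rank test is uninformative")
        return TestResult(0.0, 1.0, 0, "wilcoxon-signed-rank", all_zero=True)
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        # continuity correction toward the mean
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult(w_plus, p, n, "wilcoxon-signed-rank")


def bootstrap_mean_test(diffs, B: int = 10000, seed: int = 0) -> TestResult:
    """Percentile bootstrap test of zero mean difference (two-sided).

    Resamples the differences with replacement ``B`` times; the p-value is
    twice the smaller tail fraction of the bootstrap mean distribution
    around zero, floored at 2/B (an empirical zero tail only bounds the
    p-value below the Monte-Carlo resolution).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError(f"need at least 2 differences, got {d.size}")
    if B < 100:
        raise ValueError(f"B must be at least 100, got {B}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(B, d.size))
    means = d[idx].mean(axis=1)
    frac_le = float(np.mean(means <= 0))
    frac_ge = float(np.mean(means >= 0))
    p = min(1.0, 2.0 * max(min(frac_le, frac_ge), 1.0 / B))
    return TestResult(float(d.mean()), p, int(d.size), "bootstrap-mean")


def srh_test(y, group, block) -> TestResult:
    """Scheirer–Ray–Hare rank test of a group effect with blocking.

    All observations are ranked together (average ranks for ties); sums of
    squares of the ranks are partitioned by group, block, and their
    interaction, and each H statistic is the corresponding SS divided by
    the total rank mean square MS = SS_total/(N−1), referred to a
    chi-squared distribution.  With a single block this reduces exactly to
    Kruskal–Wallis.  Block and interaction results are available in
    ``components``.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    block = np.asarray(block)
    if not (len(y) == len(group) == len(block)):
        raise ValueError("y, group, and block must have equal length")
    g_levels = np.unique(group)
    if g_levels.size < 2:
        raise ValueError(
            "only one group level present; use kruskal_wallis within the single clade"
        )
    b_levels = np.unique(block)
    N = len(y)
    ranks = stats.rankdata(y)
    grand = ranks.mean()
    ss_total = float(np.sum((ranks - grand) ** 2))
    if ss_total == 0:
        return TestResult(0.0, 1.0, N, "scheirer-ray-hare")
    ms = ss_total / (N - 1)

    def between_ss(factor_values, levels) -> float:
        ss = 0.0
        for lev in levels:
            mask = factor_values == lev
            ss += mask.sum() * (ranks[mask].mean() - grand) ** 2
        return float(ss)

    ss_group = between_ss(group, g_levels)
    ss_block = between_ss(block, b_levels)
    ss_cells = 0.0
    for g in g_levels:
        for b in b_levels:
            mask = (group == g) & (block == b)
            if mask.any():
                ss_cells += mask.sum() * (ranks[mask].mean() - grand) ** 2
    ss_inter = max(0.0, ss_cells - ss_group - ss_block)

    def make(ss: float, df: int, name: str) -> TestResult:
        h = ss / ms
        p = float(stats.chi2.sf(h, df=df)) if df > 0 else 1.0
        return TestResult(h, p, N, name)

    res = make(ss_group, g_levels.size - 1, "scheirer-ray-hare")
    res.components = {
        "block": make(ss_block, b_levels.size - 1, "srh-block"),
        "interaction": make(
            ss_inter, (g_levels.size - 1) * (b_levels.size - 1), "srh-interaction"
        ),
    }
    return res


def kruskal_wallis(y, group) -> TestResult:
    """Kruskal–Wallis H test with tie correction (chi-squared p-value)."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if np.ptp(y) == 0:
        return TestResult(0.0, 1.0, len(y), "kruskal-wallis")
    samples = [y[group == lev] for lev in levels]
    h, p = stats.kruskal(*samples)
    return TestResult(float(h), float(p), len(y), "kruskal-wallis")


def clade_normalize(y: dict, clades: dict) -> dict:
    """Subtract each clade's mean response from its members.

    ``y`` maps species to response, ``clades`` maps species to a clade id
    (see :func:`sparsecomp.phylo.assign_clades`).  Per-clade means of the
    output are exactly zero.
    """
    missing = set(y) - set(clades)
    if missing:
        raise ValueError(f"species without a clade assignment: {sorted(missing)[:5]}")
    sums: dict = {}
    counts: dict = {}
    for sp, val in y.items():
        cl = clades[sp]
        sums[cl] = sums.get(cl, 0.0) + float(val)
        counts[cl] = counts.get(cl, 0) + 1
    means = {cl: sums[cl] / counts[cl] for cl in sums}
    return {sp: float(val) - means[clades[sp]] for sp, val in y.items()}
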