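"""Trait-table screening for correlates of organelle gene counts.

For every (feature, value) pair in a categorical trait table the pipeline:

1. binarizes the feature, keeping species with a *missing* value out of
   the analysis entirely (missing is undefined, never negative — the guard
   against artifacts like "palms correlate with gene count" merely because
   palm is undefined outside plants);
2. restricts the analysis to the subtree rooted at the MRCA of all
   positive species;
3. applies an influence filter: if either predictor class has at most two
   distinct response values, every distinct value in that class must be
   observed at least 6 times (guarding against hits driven by a single
   observation);
4. fits a Brownian PGLS and a Poisson phylogenetic GEE;
5. assigns a two-character significance profile per method — ``**`` below
   the Bonferroni-corrected threshold, ``*`` below alpha uncorrected,
   ``-`` otherwise — rendered as ``plm/pglm``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import CovarianceSpec, Phylogeny, extract_subtree, mrca, prune_to_tips
from .phyloreg import (
    DegenerateDesignError,
    FitResult,
    fit_pgls,
    fit_poisson_gee,
    round_counts,
)

logger = logging.getLogger("sparsecomp")

__all__ = [
    "TraitTable",
    "FeatureResult",
    "binarize_feature",
    "restrict_to_positive_subtree",
    "influence_filter",
    "screen_features",
    "significance_profile",
    "read_trait_table",
]

MIN_OBS_PER_VALUE = 6
MAX_DISTINCT_TRIGGER = 2


class TraitTable:
    """Species-by-feature table of categorical values; NaN means missing."""

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.index.duplicated().any():
            dup = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species names: {dup[:5]}")
        self.frame = frame

    @property
    def species(self) -> list[str]:
        return list(self.frame.index)

    @property
    def features(self) -> list[str]:
        return list(self.frame.columns)

    def values_of(self, feature: str) -> list:
        if feature not in self.frame.columns:
            raise KeyError(f"unknown feature {feature!r}")
        vals = self.frame[feature].dropna().unique().tolist()
        return sorted(vals, key=str)


def read_trait_table(path) -> TraitTable:
    """Read a long-format CSV (species, feature, value) into a TraitTable."""
    long = pd.read_csv(path)
    expected = {"species", "feature", "value"}
    if not expected.issubset(long.columns):
        raise ValueError(f"trait CSV must have columns {sorted(expected)}")
    wide = long.pivot_table(
        index="species", columns="feature", values="value", aggfunc="first"
    )
    return TraitTable(wide)


@dataclass
class FeatureResult:
    """Outcome of screening one (feature, positive value) hypothesis."""

    feature: str
    positive_value: str
    n_pos: int = 0
    n_neg: int = 0
    slope_plm: float = np.nan
    p_plm: float = np.nan
    slope_pglm: float = np.nan
    p_pglm: float = np.nan
    filtered: bool = False
    reason: str = ""
    profile: str = ""

    @property
    def min_p(self) -> float:
        ps = [p for p in (self.p_plm, self.p_pglm) if np.isfinite(p)]
        return min(ps) if ps else np.inf


def _norm_name(name: str) -> str:
    return re.sub(r"\s+", " ", str(name).strip()).lower()


def binarize_feature(
    table: TraitTable, feature: str, positive_value
) -> tuple[dict[str, int], set[str]]:
    """0/1 predictor over species with the feature defined, plus the
    undefined set (species whose value is missing — excluded downstream,
    never coded 0)."""
    col = table.frame[feature] if feature in table.frame.columns else None
    if col is None:
        raise KeyError(f"unknown feature {feature!r}")
    defined = col.dropna()
    if positive_value not in set(defined):
        raise ValueError(
            f"value {positive_value!r} never occurs for feature {feature!r}"
        )
    predictor = {sp: int(val == positive_value) for sp, val in defined.items()}
    undefined = set(table.frame.index) - set(defined.index)
    return predictor, undefined


def restrict_to_positive_subtree(
    tree: Phylogeny, predictor: dict[str, int]
) -> tuple[Phylogeny, dict[str, int]]:
    """Clip the analysis to the clade spanned by the positive species.

    Returns the subtree rooted at the MRCA of all positive-labeled tips
    and the predictor restricted to it.
    """
    positives = [sp for sp, v in predictor.items() if v == 1]
    if not positives:
        raise ValueError("no positive-labeled species")
    anc = mrca(tree, positives)
    sub = extract_subtree(tree, anc)
    kept = set(sub.tip_labels())
    restricted = {sp: v for sp, v in predictor.items() if sp in kept}
    return sub, restricted


def influence_filter(
    predictor: dict[str, int],
    response: dict[str, float],
    both_classes: bool = False,
) -> tuple[bool, str]:
    """Reject hypotheses whose support hangs on a handful of observations.

    Within each predictor class, if the response takes at most two
    distinct values, each distinct value must appear at least 6 times.
    By default the requirement applies within the triggering class; set
    ``both_classes`` to require it across the pooled response values of
    both classes whenever either class triggers.
    """
    classes: dict[int, list[float]] = {0: [], 1: []}
    for sp, v in predictor.items():
        classes[v].append(response[sp])
    if not classes[0] or not classes[1]:
        raise ValueError("both predictor classes must be non-empty")
    for label, vals in classes.items():
        uniq, counts = np.unique(np.asarray(vals, dtype=float), return_counts=True)
        if uniq.size <= MAX_DISTINCT_TRIGGER:
            pool = (
                np.asarray(classes[0] + classes[1], dtype=float)
                if both_classes
                else np.asarray(vals, dtype=float)
            )
            u2, c2 = np.unique(pool, return_counts=True)
            low = c2 < MIN_OBS_PER_VALUE
            if low.any():
                bad = ", ".join(f"{v:g} (n={n})" for v, n in zip(u2[low], c2[low]))
                return False, (
                    f"class {label} has only {uniq.size} distinct response value(s) "
                    f"and under-observed values: {bad}"
                )
    return True, ""


def significance_profile(
    p_plm: float, p_pglm: float, alpha: float = 0.05, n_tests: int = 1
) -> str:
    """Per-method significance code joined as ``plm/pglm``.

    ``**`` if p < alpha/n_tests (Bonferroni), ``*`` if p < alpha, ``-``
    otherwise.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")

    def code(p: float) -> str:
        if not np.isfinite(p):
            return "-"
        if p < alpha / n_tests:
            return "**"
        if p < alpha:
            return "*"
        return "-"

    return f"{code(p_plm)}/{code(p_pglm)}"


def screen_features(
    table: TraitTable,
    response: dict[str, float],
    tree: Phylogeny,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> list[FeatureResult]:
    """Screen every (feature, value) hypothesis against the response.

    Species names across the table, response, and tree are reconciled by
    exact match after whitespace/case normalization; unmatched species are
    logged and dropped.  The Bonferroni denominator defaults to the number
    of hypotheses that reach the fitting stage; pass ``n_tests`` to
    override.  Results are sorted by their smaller p-value; filtered
    hypotheses carry a reason and no profile.
    """
    tree_names = {_norm_name(lab): lab for lab in tree.tip_labels()}
    table_names = {_norm_name(sp): sp for sp in table.species}
    resp_names = {_norm_name(sp): sp for sp in response}
    common = set(tree_names) & set(table_names) & set(resp_names)
    unmatched = (set(tree_names) | set(table_names) | set(resp_names)) - common
    if unmatched:
        logger.info("dropping %d species not present in all inputs", len(unmatched))
    if len(common) < 3:
        raise ValueError("fewer than 3 species shared by tree, table, and response")
    # work in tree-label space
    keep_labels = {tree_names[k] for k in common}
    base_tree = prune_to_tips(tree, keep_labels)
    resp = {
        tree_names[k]: float(response[resp_names[k]]) for k in common
    }
    tab_for = {tree_names[k]: table_names[k] for k in common}

    results: list[FeatureResult] = []
    for feature in table.features:
        for value in table.values_of(feature):
            res = FeatureResult(feature=feature, positive_value=str(value))
            try:
                predictor_raw, _ = binarize_feature(table, feature, value)
                predictor = {
                    lab: predictor_raw[tab_for[lab]]
                    for lab in keep_labels
                    if tab_for[lab] in predictor_raw
                }
                positives = [sp for sp, v in predictor.items() if v == 1]
                if not positives:
                    raise ValueError("no positive species after reconciliation")
                defined_tree = prune_to_tips(base_tree, set(predictor))
                sub, restricted = restrict_to_positive_subtree(
                    defined_tree, predictor
                )
                y_sub = {sp: resp[sp] for sp in restricted}
                res.n_pos = sum(restricted.values())
                res.n_neg = len(restricted) - res.n_pos
                if res.n_neg == 0 or res.n_pos == 0:
                    raise DegenerateDesignError(
                        "predictor constant within the positive subtree"
                    )
                if np.ptp(list(y_sub.values())) == 0:
                    raise DegenerateDesignError(
                        "response constant within the positive subtree"
                    )
                keep, reason = influence_filter(restricted, y_sub)
                if not keep:
                    res.filtered, res.reason = True, reason
                    results.append(res)
                    continue
                plm = fit_pgls(restricted, y_sub, sub, CovarianceSpec("brownian"))
                labels = sub.tip_labels()
                counts = dict(
                    zip(labels, round_counts([y_sub[lab] for lab in labels]))
                )
                pglm = fit_poisson_gee(restricted, counts, sub)
                res.slope_plm, res.p_plm = plm.slope, plm.p_value
                res.slope_pglm, res.p_pglm = pglm.slope, pglm.p_value
            except (DegenerateDesignError, ValueError, KeyError) as exc:
                res.filtered, res.reason = True, f"error: {exc}"
            results.append(res)

    fitted = [r for r in results if not r.filtered]
    denom = n_tests if n_tests is not None else max(len(fitted), 1)
    logger.info("Bonferroni denominator: %d hypotheses", denom)
    for r in fitted:
        r.profile = significance_profile(r.p_plm, r.p_pglm, alpha, denom)
    results.sort(key=lambda r: r.min_p)
    return results


def make_planted_trait_table(
    tree: Phylogeny,
    r: float,
    n_decoys: int = 9,
    m: float = 5.0,
    c: float = 5.0,
    y0: float = 100.0,
    decoy_prevalence: float = 0.2,
    seed: int = 0,
    shuffle_labels: bool = False,
) -> tuple["TraitTable", dict[str, float]]:
    """Synthetic screening fixture: one real correlate among decoys.

    The ``planted`` feature is clade-specific, like most real ecological
    traits: it is defined (``yes``/``no``) only within one known clade —
    the largest child of the root — and missing everywhere else, so the
    screen's positive-subtree restriction and undefined-handling are both
    exercised.  Within that clade the predictor evolves irreversibly at
    rate ``r`` and drives faster response loss with effect ``c``;
    ``n_decoys`` features are independent coin-flip traits defined for
    all species with the given carrier prevalence.  Returns the trait
    table and the rounded count response.  With ``shuffle_labels`` the
    species names of the trait table are permuted — a negative control
    that destroys every true association while preserving the table's
    marginal structure.
    """
    from .evosim import SimParams, evolve_traits

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xdeca]))
    clade_root = max(
        tree.children(tree.root), key=lambda v: len(tree.descendant_tips(v))
    )
    clade_tips = {tree.tip_label(v) for v in tree.descendant_tips(clade_root)}
    params = SimParams(r=r, m=m, c=c, p=0.0, reversible=False, y0=y0, seed=seed)
    states = evolve_traits(tree, params, innovation_root=clade_root)
    labels = tree.tip_labels()
    data = {
        "planted": [
            ("yes" if states.x_obs[v] else "no")
            if tree.tip_label(v) in clade_tips
            else None
            for v in tree.tips()
        ]
    }
    for k in range(n_decoys):
        carriers = rng.random(len(labels)) < decoy_prevalence
        data[f"decoy{k}"] = np.where(carriers, "yes", "no")
    frame = pd.DataFrame(data, index=labels)
    response = {
        tree.tip_label(v): float(np.rint(states.y_true[v])) for v in tree.tips()
    }
    if shuffle_labels:
        frame = frame.set_axis(rng.permutation(labels), axis=0)
    return TraitTable(frame), response


def results_frame(results: list[FeatureResult]) -> pd.DataFrame:
    """Tabular view of screening results (one row per hypothesis)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "positive_value": r.positive_value,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
                "slope_plm": r.slope_plm,
                "p_plm": r.p_plm,
                "slope_pglm": r.slope_pglm,
                "p_pglm": r.p_pglm,
                "filtered": r.filtered,
                "reason": r.reason,
                "profile": r.profile,
            }
            for r in results
        ]
    )
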