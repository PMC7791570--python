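"""Construction of a new risk scale from top-performing items.

The procedure mirrors how composite clinical prediction rules are often
derived from existing instruments:

1. rank every item within its source scale by AUC against the repetition
   outcome;
2. take the best item from each scale, substituting the next-best
   non-duplicate item when a scale's top item measures the same construct as
   one already selected (instruments overlap heavily);
3. combine the selected items with equal weights into an additive score;
4. choose the dichotomisation threshold by the Liu criterion (maximise
   sensitivity x specificity; Youden's J, maximising sensitivity +
   specificity - 1, is also available);
5. report accuracy on the derivation sample and on a 50% random subsample
   of it. Note this "validation" subsample is drawn from the sample the
   scale was derived on, not a disjoint holdout — the original design is
   reproduced as stated; a disjoint split is available via ``disjoint=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .accuracy import (
    AccuracyResult,
    AUCResult,
    TwoByTwo,
    dual_statistics,
    roc_auc,
    two_by_two,
)
from .errors import ConfigurationError, DegenerateInputError
from .scales import (
    DEFAULT_DUPLICATE_MAP,
    ItemDefinition,
    ScaleDefinition,
    _item_matrix,
    canonical_id,
    load_default_scales,
    recode_barratt,
)

__all__ = [
    "CutoffResult",
    "ScaleEvaluation",
    "SplitValidationResult",
    "item_auc_table",
    "select_top_items",
    "build_scale",
    "score_constructed",
    "optimal_cutoff",
    "evaluate_scale_totals",
    "split_validate",
    "DEFAULT_SCALE_ORDER",
]

DEFAULT_SCALE_ORDER: tuple[str, ...] = ("MSHR", "ReACT", "SADP", "MSPS", "BIS")


@dataclass(frozen=True)
class CutoffResult:
    """Optimal dichotomisation threshold for an additive scale.

    Episodes scoring at or above ``cutoff`` are classified high risk; the
    conventional report format is "(cutoff-1) v. >=cutoff".
    """

    cutoff: int
    criterion: str
    sensitivity: float
    specificity: float
    objective: float

    @property
    def label(self) -> str:
        return f"{self.cutoff - 1} v. ≥{self.cutoff}"


@dataclass(frozen=True)
class ScaleEvaluation:
    """Accuracy of an additive scale on one sample at a given cutoff."""

    accuracy: AccuracyResult
    auc: AUCResult
    cutoff: CutoffResult
    n: int


@dataclass(frozen=True)
class SplitValidationResult:
    derivation: ScaleEvaluation
    validation: ScaleEvaluation
    fraction: float
    seed: int


# ---------------------------------------------------------------------------
# Item ranking


def item_auc_table(
    table: pd.DataFrame,
    scales: Mapping[str, ScaleDefinition] | None = None,
    convention: str = "reversed",
) -> pd.DataFrame:
    """Per-item AUC against the outcome, one row per (item, source scale).

    Ordinal impulsiveness items are recoded to binary first; episodes missing
    an item are excluded listwise for that item only. Items absent from the
    table are skipped.
    """
    if scales is None:
        scales = load_default_scales()
    rows = []
    for sid, scale in scales.items():
        for item in scale.items:
            if item.item_id not in table.columns:
                continue
            if item.response_domain == "likert-1-10":
                continue  # global ratings are not scale items
            col = table[item.item_id]
            if item.response_domain == "ordinal-1-4":
                col = recode_barratt(col, item.reverse_scored, convention)
            res = roc_auc(col, table["outcome"])
            rows.append(
                {
                    "item_id": item.item_id,
                    "source_scale": sid,
                    "auc": res.auc,
                    "ci_low": res.ci[0],
                    "ci_high": res.ci[1],
                    "n_analysed": res.n_pos + res.n_neg,
                }
            )
    return pd.DataFrame(rows)


def select_top_items(
    auc_table: pd.DataFrame,
    duplicate_map: Mapping[str, str] | None = None,
    scale_order: Sequence[str] | None = None,
    item_order: Sequence[str] | None = None,
) -> list[str]:
    """Pick the highest-AUC item from each source scale without duplicates.

    Scales are visited in ``scale_order`` (defaults to the conventional
    instrument order, then any others sorted); within a scale items are
    ranked by descending AUC with ties broken by ``item_order`` (defaults to
    alphabetical item id — deterministic and invariant to the row order of
    the table). If a scale's best item resolves, through the duplicate map,
    to a construct already selected, its next-best non-duplicate item is
    taken; a scale whose items are all duplicated away contributes nothing
    (with a warning).
    """
    if duplicate_map is None:
        duplicate_map = DEFAULT_DUPLICATE_MAP
    present = list(dict.fromkeys(auc_table["source_scale"]))
    if scale_order is None:
        ordered = [s for s in DEFAULT_SCALE_ORDER if s in present]
        ordered += sorted(s for s in present if s not in DEFAULT_SCALE_ORDER)
    else:
        ordered = [s for s in scale_order if s in present]

    def tie_rank(item_id: str) -> tuple:
        if item_order is not None and item_id in item_order:
            return (0, list(item_order).index(item_id))
        return (1, item_id)

    selected: list[str] = []
    used: set[str] = set()
    for sid in ordered:
        sub = auc_table[auc_table["source_scale"] == sid]
        ranked = sorted(
            sub.itertuples(index=False), key=lambda r: (-r.auc, tie_rank(r.item_id))
        )
        for row in ranked:
            key = canonical_id(row.item_id, duplicate_map)
            if key in used:
                continue
            used.add(key)
            selected.append(row.item_id)
            break
        else:
            warnings.warn(
                f"scale {sid!r} contributes no item: all candidates duplicate "
                "already-selected constructs",
                stacklevel=2,
            )
    return selected


# ---------------------------------------------------------------------------
# Scale assembly and scoring


def build_scale(
    items: Sequence[str],
    scale_id: str = "constructed",
    cutoff: int = 1,
    source: Mapping[str, ItemDefinition] | None = None,
) -> ScaleDefinition:
    """Equal-weight additive scale over the given items (total = count positive).

    The items enter as binary with unit weight regardless of origin (ordinal
    items are expected pre-recoded in the episode table, or resolvable via
    ``source`` definitions carrying their recoding metadata). Any missing
    item makes the episode's total missing (listwise).
    """
    if not items:
        raise ConfigurationError("constructed scale needs at least one item")
    if len(set(items)) != len(items):
        raise ConfigurationError(f"duplicate item ids in constructed scale: {list(items)}")
    defs = []
    for iid in items:
        if source is not None and iid in source:
            src = source[iid]
            defs.append(
                ItemDefinition(
                    item_id=iid,
                    source_scale=scale_id,
                    response_domain=src.response_domain,
                    reverse_scored=src.reverse_scored,
                    weight=1,
                )
            )
        else:
            defs.append(ItemDefinition(item_id=iid, source_scale=scale_id))
    return ScaleDefinition(
        scale_id=scale_id,
        rule="threshold",
        items=tuple(defs),
        cutoff=cutoff,
        name="Constructed scale (top item per source scale)",
    )


def score_constructed(
    table: pd.DataFrame, scale: ScaleDefinition, convention: str = "reversed"
) -> pd.Series:
    """Total score of an additive scale; missing if any item is missing."""
    mat = _item_matrix(table, scale, convention)
    total = mat.sum(axis=1).astype("Int64")
    total[mat.isna().any(axis=1)] = pd.NA
    return total


def optimal_cutoff(totals, outcomes, criterion: str = "liu") -> CutoffResult:
    """Best dichotomisation threshold by exhaustive search over observed scores.

    ``criterion='liu'`` maximises sensitivity x specificity; ``'youden'``
    maximises sensitivity + specificity - 1. Every achievable threshold is
    evaluated (each unique observed total, predicting high at or above it,
    plus the degenerate nobody-high threshold); ties go to the lowest
    cutoff. Episodes with a missing total are excluded listwise.
    """
    if criterion not in ("liu", "youden"):
        raise ConfigurationError(f"unknown cutoff criterion {criterion!r}")
    t = pd.Series(pd.array(totals, dtype="Float64")).reset_index(drop=True)
    o = pd.Series(outcomes).reset_index(drop=True)
    keep = t.notna()
    x = t[keep].astype(float).to_numpy()
    y = o[keep].astype(int).to_numpy()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("cutoff search needs both outcome classes")
    candidates = sorted(set(x)) + [max(x) + 1]
    best: CutoffResult | None = None
    for c in candidates:
        pred = x >= c
        sens = float((pred & (y == 1)).sum()) / n_pos
        spec = float((~pred & (y == 0)).sum()) / n_neg
        obj = sens * spec if criterion == "liu" else sens + spec - 1.0
        if best is None or obj > best.objective:
            best = CutoffResult(int(np.ceil(c)), criterion, sens, spec, obj)
    assert best is not None
    return best


def evaluate_scale_totals(
    totals, outcomes, cutoff: CutoffResult, ci_method: str = "wilson"
) -> ScaleEvaluation:
    """Dual statistics at a fixed cutoff plus AUC of the underlying totals."""
    t = pd.Series(pd.array(totals, dtype="Float64")).reset_index(drop=True)
    o = pd.Series(outcomes).reset_index(drop=True)
    arr = t.to_numpy(dtype="float64", na_value=np.nan)
    pred = pd.Series(np.where(arr >= cutoff.cutoff, 1, 0), dtype="Int64")
    pred[np.isnan(arr)] = pd.NA
    tab = two_by_two(pred, o)
    return ScaleEvaluation(
        accuracy=dual_statistics(tab, ci_method=ci_method),
        auc=roc_auc(t, o),
        cutoff=cutoff,
        n=tab.n_analysed,
    )


def split_validate(
    table: pd.DataFrame,
    scale: ScaleDefinition,
    fraction: float = 0.5,
    seed: int = 0,
    criterion: str = "liu",
    convention: str = "reversed",
    ci_method: str = "wilson",
    disjoint: bool = False,
    stratified: bool = False,
) -> SplitValidationResult:
    """Derive the scale's cutoff and accuracy, then re-test on a random subsample.

    Derivation uses the full table (or, with ``disjoint=True``, the
    complement of the validation subsample). The validation subsample is a
    simple random ``fraction`` of episodes (stratified by outcome on
    request), scored at the derivation cutoff. Both evaluations are returned;
    the split is fully determined by ``seed``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    totals = score_constructed(table, scale, convention)
    outcomes = table["outcome"].reset_index(drop=True)
    totals = totals.reset_index(drop=True)

    rng = np.random.default_rng(seed)
    n = len(table)
    if stratified:
        idx_parts = []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(outcomes.to_numpy() == cls)
            k = int(round(fraction * len(cls_idx)))
            idx_parts.append(rng.choice(cls_idx, size=k, replace=False))
        val_idx = np.sort(np.concatenate(idx_parts))
    else:
        val_idx = np.sort(rng.choice(n, size=int(round(fraction * n)), replace=False))

    if disjoint and fraction < 1.0:
        der_idx = np.setdiff1d(np.arange(n), val_idx)
    else:
        der_idx = np.arange(n)

    def _subset(idx, name: str) -> tuple[pd.Series, pd.Series]:
        t_sub = totals.iloc[idx].reset_index(drop=True)
        o_sub = outcomes.iloc[idx].reset_index(drop=True)
        observed = o_sub[t_sub.notna()]
        if observed.nunique() < 2:
            raise DegenerateInputError(
                f"{name} sample lacks both outcome classes after exclusion"
            )
        return t_sub, o_sub

    der_totals, der_out = _subset(der_idx, "derivation")
    val_totals, val_out = _subset(val_idx, "validation")

    cut = optimal_cutoff(der_totals, der_out, criterion)
    derivation = evaluate_scale_totals(der_totals, der_out, cut, ci_method)
    validation = evaluate_scale_totals(val_totals, val_out, cut, ci_method)
    return SplitValidationResult(derivation, validation, fraction, seed)
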