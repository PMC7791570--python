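"""End-to-end analysis pipeline and table output.

Runs the full evaluation on an episode table (read from CSV or generated
synthetically): item-level repetition proportions and diagnostic accuracy,
scale-level accuracy, construction and split-sample validation of a new
scale from top-performing items, and the classification-tree sensitivity
analysis. Emits the result as tidy CSV tables plus a JSON summary, in the
spirit of STARD-style reporting (analysed/excluded flow counts per item,
dual and global accuracy side by side).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import builder as _builder
from . import cart as _cart
from .accuracy import binary_auc, dual_statistics, roc_auc, two_by_two
from .cohort import CohortConfig, generate_cohort, read_cohort
from .errors import ConfigurationError, DegenerateInputError
from .scales import (
    ScaleDefinition,
    load_default_scales,
    load_scales,
    recode_barratt,
    save_scales,
    score_any_item_scale,
    score_banded_scale,
    score_scale,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_tables", "pooled_item_frame"]

log = logging.getLogger("riskitems")

_PSYCHOMETRIC = ("MSHR", "ReACT", "SADP", "MSPS", "BIS")
_GLOBAL = ("clinician_global", "patient_global")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one input source plus analysis options."""

    input_csv: str | Path | None = None
    cohort: CohortConfig | None = None
    scale_ids: tuple[str, ...] | None = None  # None = all defined scales
    scales_yaml: str | Path | None = None
    ci_method: str = "wilson"
    cutoff_criterion: str = "liu"
    split_fraction: float = 0.5
    split_seed: int = 0
    convention: str = "reversed"
    cart_params: _cart.CartParams = field(default_factory=_cart.CartParams)
    include_cart: bool = True
    include_construction: bool = True

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.cohort is None):
            raise ConfigurationError("provide exactly one of input_csv or cohort")


@dataclass
class ReportBundle:
    """All pipeline outputs, table-shaped where possible."""

    table: pd.DataFrame
    item_repetition: pd.DataFrame  # repetition proportion by item status
    auc_table: pd.DataFrame        # global accuracy per item and per scale
    dual_stats: pd.DataFrame       # dual statistics per item
    flow_counts: pd.DataFrame      # analysed / excluded per item
    constructed: dict | None       # constructed-scale report
    constructed_scale: ScaleDefinition | None
    cart: dict | None              # tree + accuracy report
    config: RunConfig | None = None


def _resolve_scales(config: RunConfig) -> dict[str, ScaleDefinition]:
    defs = (
        load_scales(config.scales_yaml)
        if config.scales_yaml is not None
        else load_default_scales()
    )
    if config.scale_ids is None:
        return defs
    unknown = [s for s in config.scale_ids if s not in defs]
    if unknown:
        raise ConfigurationError(f"unknown scale id(s): {unknown}")
    return {s: defs[s] for s in config.scale_ids}


def pooled_item_frame(
    table: pd.DataFrame,
    scales: Mapping[str, ScaleDefinition],
    convention: str = "reversed",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Binary matrix of every pooled psychometric-scale item present in the table.

    Ordinal impulsiveness items are recoded; each unique item appears once
    with a map of the scales it belongs to.
    """
    cols: dict[str, pd.Series] = {}
    sources: dict[str, list[str]] = {}
    for sid in _PSYCHOMETRIC:
        if sid not in scales:
            continue
        for item in scales[sid].items:
            if item.item_id not in table.columns:
                continue
            sources.setdefault(item.item_id, []).append(sid)
            if item.item_id in cols:
                continue
            col = table[item.item_id]
            if item.response_domain == "ordinal-1-4":
                col = recode_barratt(col, item.reverse_scored, convention)
            else:
                col = pd.Series(pd.array(col, dtype="Float64"), index=table.index).astype("Int64")
            cols[item.item_id] = col
    return pd.DataFrame(cols, index=table.index), sources


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def _stage_done(name: str, t0: float) -> None:
    log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute scoring, accuracy, scale construction, validation and CART.

    All randomness is controlled by the config (cohort seed, split seed);
    identical configs produce identical bundles.
    """
    scales = _resolve_scales(config)

    t0 = _stage("load")
    if config.input_csv is not None:
        table = read_cohort(config.input_csv)
    else:
        table = generate_cohort(config.cohort)
    log.info("episodes: %d, repeats: %d", len(table), int(table["outcome"].sum()))
    _stage_done("load", t0)

    outcome = table["outcome"].astype(int)

    t0 = _stage("item accuracy")
    items_mat, sources = pooled_item_frame(table, scales, config.convention)
    rep_rows, dual_rows, auc_rows, flow_rows = [], [], [], []
    for item_id in items_mat.columns:
        col = items_mat[item_id]
        try:
            tab = two_by_two(col, outcome)
            acc = dual_statistics(tab, ci_method=config.ci_method)
            auc_res = roc_auc(col, outcome)
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"item {item_id!r}: {exc}") from exc
        n_item_pos = tab.tp + tab.fp
        rep_rows.append(
            {
                "item_id": item_id,
                "source_scales": "+".join(sources[item_id]),
                "n_item_positive": n_item_pos,
                "n_repeat_in_item_positive": tab.tp,
                "pct_repeat_in_item_positive": 100 * tab.tp / n_item_pos if n_item_pos else np.nan,
                "n_item_negative": tab.fn + tab.tn,
                "n_repeat_in_item_negative": tab.fn,
                "pct_repeat_in_item_negative": (
                    100 * tab.fn / (tab.fn + tab.tn) if (tab.fn + tab.tn) else np.nan
                ),
            }
        )
        dual_rows.append(
            {
                "item_id": item_id,
                "source_scales": "+".join(sources[item_id]),
                "sensitivity_pct": 100 * acc.sensitivity,
                "sensitivity_ci_low_pct": 100 * acc.sensitivity_ci[0],
                "sensitivity_ci_high_pct": 100 * acc.sensitivity_ci[1],
                "specificity_pct": 100 * acc.specificity,
                "specificity_ci_low_pct": 100 * acc.specificity_ci[0],
                "specificity_ci_high_pct": 100 * acc.specificity_ci[1],
                "ppv_pct": 100 * acc.ppv,
                "npv_pct": 100 * acc.npv,
                "lr_pos": acc.lr_pos,
                "lr_neg": acc.lr_neg,
                "n_analysed": acc.n_analysed,
                "n_excluded": acc.n_excluded,
            }
        )
        auc_rows.append(
            {
                "unit": "item",
                "id": item_id,
                "source": "+".join(sources[item_id]),
                "auc": binary_auc(tab),
                "ci_low": auc_res.ci[0],
                "ci_high": auc_res.ci[1],
                "n_analysed": tab.n_analysed,
            }
        )
        flow_rows.append(
            {"item_id": item_id, "n_analysed": tab.n_analysed, "n_excluded": tab.n_excluded}
        )
    _stage_done("item accuracy", t0)

    t0 = _stage("scale accuracy")
    for sid, scale in scales.items():
        if not all(i in table.columns for i in scale.item_ids):
            continue
        if scale.rule == "any-item":
            cls = score_any_item_scale(table, scale, config.convention)
            tab = two_by_two(cls, outcome)
            res = roc_auc(cls.map({"low": 0, "high": 1}), outcome)
            auc_val = binary_auc(tab)
            n = tab.n_analysed
        elif scale.rule == "weighted-bands":
            scored = score_banded_scale(table, scale, config.convention)
            res = roc_auc(scored["total"], outcome)
            auc_val = res.auc
            n = res.n_pos + res.n_neg
        elif scale.rule == "threshold" and sid in _GLOBAL:
            rating = table[scale.items[0].item_id]
            res = roc_auc(rating, outcome)
            auc_val = res.auc
            n = res.n_pos + res.n_neg
            cls = score_scale(table, scale, config.convention)
            tab = two_by_two(cls, outcome)
            acc = dual_statistics(tab, ci_method=config.ci_method)
            dual_rows.append(
                {
                    "item_id": scale.items[0].item_id,
                    "source_scales": sid,
                    "sensitivity_pct": 100 * acc.sensitivity,
                    "sensitivity_ci_low_pct": 100 * acc.sensitivity_ci[0],
                    "sensitivity_ci_high_pct": 100 * acc.sensitivity_ci[1],
                    "specificity_pct": 100 * acc.specificity,
                    "specificity_ci_low_pct": 100 * acc.specificity_ci[0],
                    "specificity_ci_high_pct": 100 * acc.specificity_ci[1],
                    "ppv_pct": 100 * acc.ppv,
                    "npv_pct": 100 * acc.npv,
                    "lr_pos": acc.lr_pos,
                    "lr_neg": acc.lr_neg,
                    "n_analysed": acc.n_analysed,
                    "n_excluded": acc.n_excluded,
                }
            )
        else:
            continue
        auc_rows.append(
            {
                "unit": "scale",
                "id": sid,
                "source": sid,
                "auc": auc_val,
                "ci_low": res.ci[0],
                "ci_high": res.ci[1],
                "n_analysed": n,
            }
        )
    _stage_done("scale accuracy", t0)

    constructed = None
    constructed_scale = None
    if config.include_construction:
        t0 = _stage("scale construction")
        auc_item_table = _builder.item_auc_table(table, scales, config.convention)
        if not auc_item_table.empty and auc_item_table["source_scale"].nunique() >= 2:
            selected = _builder.select_top_items(auc_item_table)
            item_defs = {
                it.item_id: it for sc in scales.values() for it in sc.items
            }
            scale = _builder.build_scale(selected, source=item_defs)
            try:
                sv = _builder.split_validate(
                    table,
                    scale,
                    fraction=config.split_fraction,
                    seed=config.split_seed,
                    criterion=config.cutoff_criterion,
                    convention=config.convention,
                    ci_method=config.ci_method,
                )
            except DegenerateInputError as exc:
                raise DegenerateInputError(f"scale construction: {exc}") from exc
            constructed_scale = dataclasses.replace(
                scale, cutoff=sv.derivation.cutoff.cutoff
            )
            constructed = {
                "items": list(selected),
                "cutoff": sv.derivation.cutoff.cutoff,
                "cutoff_label": sv.derivation.cutoff.label,
                "criterion": sv.derivation.cutoff.criterion,
                "derivation": _evaluation_dict(sv.derivation),
                "validation": _evaluation_dict(sv.validation),
                "split_fraction": sv.fraction,
                "split_seed": sv.seed,
            }
        _stage_done("scale construction", t0)

    cart_report = None
    if config.include_cart and not items_mat.empty:
        t0 = _stage("cart")
        tree = _cart.fit_tree(
            pd.concat([items_mat, outcome.rename("outcome")], axis=1),
            list(items_mat.columns),
            params=config.cart_params,
        )
        acc, auc_res = _cart.tree_accuracy(tree, items_mat, outcome)
        cart_report = {
            "tree": _cart.tree_to_dict(tree),
            "root_split": tree.split_item,
            "sensitivity_pct": 100 * acc.sensitivity,
            "specificity_pct": 100 * acc.specificity,
            "auc": auc_res.auc,
            "auc_ci": list(auc_res.ci),
            "n_analysed": acc.n_analysed,
        }
        _stage_done("cart", t0)

    return ReportBundle(
        table=table,
        item_repetition=pd.DataFrame(rep_rows),
        auc_table=pd.DataFrame(auc_rows),
        dual_stats=pd.DataFrame(dual_rows),
        flow_counts=pd.DataFrame(flow_rows),
        constructed=constructed,
        constructed_scale=constructed_scale,
        cart=cart_report,
        config=config,
    )


def _evaluation_dict(ev: _builder.ScaleEvaluation) -> dict:
    return {
        "sensitivity_pct": 100 * ev.accuracy.sensitivity,
        "sensitivity_ci_pct": [100 * v for v in ev.accuracy.sensitivity_ci],
        "specificity_pct": 100 * ev.accuracy.specificity,
        "specificity_ci_pct": [100 * v for v in ev.accuracy.specificity_ci],
        "ppv_pct": 100 * ev.accuracy.ppv,
        "npv_pct": 100 * ev.accuracy.npv,
        "auc": ev.auc.auc,
        "auc_ci": list(ev.auc.ci),
        "n": ev.n,
    }


_ROUND_RULES = {"pct": 1, "auc": 2, "ci": 2, "lr": 2}


def _formatted(df: pd.DataFrame) -> pd.DataFrame:
    """Copy with display columns rounded: percentages 1 dp, AUC/CI 2 dp."""
    out = df.copy()
    for col in out.columns:
        if col.endswith("_pct") or "pct_" in col:
            out[col] = out[col].astype(float).round(1)
        elif col in ("auc", "ci_low", "ci_high") or col.startswith("lr_"):
            out[col] = out[col].astype(float).round(2)
    return out


def write_tables(bundle: ReportBundle, outdir) -> dict[str, Path]:
    """Write the bundle as CSV tables + a JSON summary; returns name -> path.

    Numeric display follows the reporting convention (percentages to 1
    decimal place, AUC to 2); the JSON summary keeps full precision.
    Optional sections absent from the bundle are omitted and noted in the
    summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tables = {
        "item_repetition": bundle.item_repetition,
        "auc": bundle.auc_table,
        "dual_statistics": bundle.dual_stats,
        "flow_counts": bundle.flow_counts,
    }
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        _formatted(df).to_csv(p, index=False)
        paths[name] = p

    summary: dict = {
        "n_episodes": int(len(bundle.table)),
        "n_repeats": int(bundle.table["outcome"].sum()),
        "tables": sorted(tables),
    }
    if bundle.constructed is not None:
        summary["constructed_scale"] = bundle.constructed
        p = outdir / "constructed_scale.yaml"
        save_scales([bundle.constructed_scale], p)
        paths["constructed_scale"] = p
    else:
        summary["constructed_scale"] = None
    if bundle.cart is not None:
        summary["cart"] = {k: v for k, v in bundle.cart.items() if k != "tree"}
        p = outdir / "cart_tree.json"
        with open(p, "w") as fh:
            json.dump(bundle.cart["tree"], fh, indent=2)
        paths["cart_tree"] = p
    else:
        summary["cart"] = None

    p = outdir / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2)
    paths["summary"] = p
    return paths
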