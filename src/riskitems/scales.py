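"""Risk-scale definitions and scoring.

Encodes the five psychometric instruments used in self-harm risk assessment
(Manchester Self-Harm Rule, ReACT Self-Harm Rule, SAD PERSONS, Modified SAD
PERSONS, Barratt Impulsiveness Scale) plus the single-question clinician and
patient global estimates of risk, and the rules that turn item responses into
risk classes:

* ``any-item`` scales (MSHR, ReACT): the presence of any one positive item
  classifies the episode as high risk.
* ``weighted-bands`` scales (SAD PERSONS variants): a weighted total score is
  mapped onto low / medium / high bands by configured breakpoints.
* ``threshold`` scales (global 1-10 Likert ratings): dichotomised at the
  midpoint, 1-5 low vs >=6 high.
* Barratt items are ordinal 1-4 and recoded to binary (3-4 -> 1) for
  comparability with the binary scales; designated items are reverse scored.

Item sets, weights, reverse flags, duplicate links and band breakpoints are
configuration, loaded from a YAML file (``data/scales.yaml`` by default) and
never hard-coded in the scoring logic.

Missing data are handled listwise per scale/item: an episode missing any item
needed by a scale receives a missing score for that scale only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError

__all__ = [
    "ItemDefinition",
    "Band",
    "ScaleDefinition",
    "load_scales",
    "load_default_scales",
    "save_scales",
    "recode_barratt",
    "dichotomize_global",
    "score_any_item_scale",
    "score_banded_scale",
    "score_scale",
    "combined_sadp_item_set",
    "canonical_id",
    "DEFAULT_DUPLICATE_MAP",
    "RELATED_ITEM_MAP",
    "RESPONSE_DOMAINS",
]

RESPONSE_DOMAINS = ("binary", "ordinal-1-4", "likert-1-10")

#: Items that measure the same construct across instruments. Used when pooling
#: the SAD PERSONS / Modified SAD PERSONS item sets and when constructing a new
#: scale from top-performing items: at most one member of each equivalence
#: class is retained.
DEFAULT_DUPLICATE_MAP: dict[str, str] = {
    "previous_psychiatric_care": "prior_psychiatric_treatment",
    "prev_attempt_or_psych_care": "prior_psychiatric_treatment",
}

#: Weaker cross-scale relations (overlapping but distinct constructs, e.g. a
#: lifetime suicide attempt vs self-harm within the past year). Not applied by
#: default during scale construction; callers may merge this into the
#: duplicate map to enforce the stricter reading.
RELATED_ITEM_MAP: dict[str, str] = {
    "previous_suicide_attempt": "self_harm_last_year",
}


@dataclass(frozen=True)
class ItemDefinition:
    """A single scale item: identity, response domain and scoring metadata."""

    item_id: str
    source_scale: str
    response_domain: str = "binary"
    reverse_scored: bool = False
    weight: int = 1
    duplicate_of: str | None = None
    related_to: str | None = None

    def __post_init__(self) -> None:
        if self.response_domain not in RESPONSE_DOMAINS:
            raise ConfigurationError(
                f"unknown response domain {self.response_domain!r} for {self.item_id!r}"
            )
        if self.reverse_scored and self.response_domain != "ordinal-1-4":
            raise ConfigurationError(
                f"reverse scoring only applies to ordinal 1-4 items ({self.item_id!r})"
            )
        if self.weight < 1:
            raise ConfigurationError(f"item weight must be >= 1 ({self.item_id!r})")


@dataclass(frozen=True)
class Band:
    """Risk band: inclusive upper breakpoint on the total score (None = open)."""

    label: str
    max_score: int | None = None


@dataclass(frozen=True)
class ScaleDefinition:
    """One instrument: items plus the rule mapping responses to a risk class."""

    scale_id: str
    rule: str  # any-item | weighted-bands | threshold | items-only
    items: tuple[ItemDefinition, ...]
    bands: tuple[Band, ...] = ()
    cutoff: int | None = None  # threshold rule: high iff score >= cutoff
    name: str | None = None

    def __post_init__(self) -> None:
        if self.rule not in ("any-item", "weighted-bands", "threshold", "items-only"):
            raise ConfigurationError(f"unknown rule {self.rule!r} for {self.scale_id!r}")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate item ids in scale {self.scale_id!r}")
        if self.rule == "weighted-bands":
            if not self.bands:
                raise ConfigurationError(f"{self.scale_id!r}: banded scale needs bands")
            if any(b.max_score is None for b in self.bands[:-1]):
                raise ConfigurationError(
                    f"{self.scale_id!r}: only the last band may be open-ended"
                )
            breaks = [b.max_score for b in self.bands if b.max_score is not None]
            if any(a >= b for a, b in zip(breaks, breaks[1:])):
                raise ConfigurationError(
                    f"{self.scale_id!r}: band breakpoints must be strictly ascending"
                )
            if self.bands[-1].max_score is not None:
                max_total = sum(it.weight for it in self.items)
                if self.bands[-1].max_score < max_total:
                    raise ConfigurationError(
                        f"{self.scale_id!r}: bands do not cover the score range "
                        f"(max total {max_total})"
                    )
        if self.rule == "threshold" and self.cutoff is None:
            raise ConfigurationError(f"{self.scale_id!r}: threshold scale needs a cutoff")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def band_for_score(self, total: int) -> str:
        """Map a total score onto its risk-band label."""
        if self.rule != "weighted-bands":
            raise ConfigurationError(f"{self.scale_id!r} has no bands")
        for band in self.bands:
            if band.max_score is None or total <= band.max_score:
                return band.label
        raise AssertionError("bands exhausted")  # unreachable: last band open


# ---------------------------------------------------------------------------
# Serialization


def _item_from_dict(raw: Mapping, scale_id: str) -> ItemDefinition:
    return ItemDefinition(
        item_id=raw["id"],
        source_scale=scale_id,
        response_domain=raw.get("domain", "binary"),
        reverse_scored=bool(raw.get("reverse_scored", False)),
        weight=int(raw.get("weight", 1)),
        duplicate_of=raw.get("duplicate_of"),
        related_to=raw.get("related_to"),
    )


def load_scales(path) -> dict[str, ScaleDefinition]:
    """Load scale definitions from a YAML file; returns id -> definition."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _scales_from_doc(doc)


def _scales_from_doc(doc: Mapping) -> dict[str, ScaleDefinition]:
    out: dict[str, ScaleDefinition] = {}
    for raw in doc["scales"]:
        sid = raw["scale_id"]
        bands = tuple(
            Band(label=b["label"], max_score=b.get("max_score"))
            for b in raw.get("bands", [])
        )
        out[sid] = ScaleDefinition(
            scale_id=sid,
            rule=raw["rule"],
            items=tuple(_item_from_dict(it, sid) for it in raw["items"]),
            bands=bands,
            cutoff=raw.get("cutoff"),
            name=raw.get("name"),
        )
    return out


def load_default_scales() -> dict[str, ScaleDefinition]:
    """The packaged default instrument definitions."""
    ref = resources.files("riskitems").joinpath("data/scales.yaml")
    return _scales_from_doc(yaml.safe_load(ref.read_text()))


def save_scales(scales: Iterable[ScaleDefinition], path) -> None:
    """Write scale definitions in the same YAML dialect ``load_scales`` reads."""
    doc = {"scales": []}
    for sc in scales:
        raw: dict = {"scale_id": sc.scale_id, "rule": sc.rule}
        if sc.name:
            raw["name"] = sc.name
        if sc.cutoff is not None:
            raw["cutoff"] = sc.cutoff
        if sc.bands:
            raw["bands"] = [
                {"label": b.label, **({"max_score": b.max_score} if b.max_score is not None else {})}
                for b in sc.bands
            ]
        raw["items"] = []
        for it in sc.items:
            item: dict = {"id": it.item_id, "domain": it.response_domain}
            if it.weight != 1:
                item["weight"] = it.weight
            if it.reverse_scored:
                item["reverse_scored"] = True
            if it.duplicate_of:
                item["duplicate_of"] = it.duplicate_of
            if it.related_to:
                item["related_to"] = it.related_to
            raw["items"].append(item)
        doc["scales"].append(raw)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Recoding and scoring


def _as_series(values) -> tuple[pd.Series, bool]:
    if isinstance(values, pd.Series):
        return values, True
    if np.isscalar(values) or values is None or values is pd.NA:
        return pd.Series([values], dtype="object"), False
    return pd.Series(values), True


def recode_barratt(raw, reverse_scored: bool = False, convention: str = "reversed"):
    """Recode an ordinal 1-4 impulsiveness response to binary.

    A response of 3 or 4 codes as 1. Reverse-scored items are first mapped
    r -> 5 - r and then binarised, so that high impulsiveness always codes
    as 1 (``convention="reversed"``, the default). ``convention="raw"``
    applies the 3-4 rule to the raw response of reverse items instead (the
    alternative literal reading of coding reverse items from the raw score).
    Missing values propagate.

    Accepts a scalar or a Series; returns the same shape (nullable Int64 for
    Series input).
    """
    if convention not in ("reversed", "raw"):
        raise ConfigurationError(f"unknown recoding convention {convention!r}")
    series, was_series = _as_series(raw)
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.notna() & ~vals.isin([1, 2, 3, 4])
    if bad.any():
        raise DomainError(f"ordinal response outside 1-4: {series[bad].tolist()}")
    arr = pd.array(vals, dtype="Float64").to_numpy(dtype="float64", na_value=np.nan)
    if reverse_scored and convention == "reversed":
        arr = 5 - arr
    out = pd.Series(np.where(arr >= 3, 1, 0), index=series.index, dtype="Int64")
    out[np.isnan(arr)] = pd.NA
    if not was_series:
        return out.iloc[0] if out.notna().iloc[0] else pd.NA
    return out


def dichotomize_global(rating):
    """Dichotomise a 1-10 Likert risk rating at the midpoint: 1-5 low, >=6 high.

    Accepts a scalar or Series; missing propagates; values outside 1-10 raise.
    """
    series, was_series = _as_series(rating)
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.notna() & ((vals < 1) | (vals > 10))
    if bad.any():
        raise DomainError(f"Likert rating outside 1-10: {series[bad].tolist()}")
    arr = pd.array(vals, dtype="Float64").to_numpy(dtype="float64", na_value=np.nan)
    out = pd.Series(np.where(arr >= 6, "high", "low"), index=series.index, dtype="object")
    out[np.isnan(arr)] = pd.NA
    if not was_series:
        return out.iloc[0]
    return out


def _item_matrix(data, scale: ScaleDefinition, convention: str) -> pd.DataFrame:
    """Binary item matrix for a scale (Barratt items recoded), nullable Int64."""
    if isinstance(data, Mapping) and not isinstance(data, pd.DataFrame):
        data = pd.DataFrame([data])
    missing_cols = [i for i in scale.item_ids if i not in data.columns]
    if missing_cols:
        raise KeyError(f"table lacks items {missing_cols} required by {scale.scale_id!r}")
    cols = {}
    for it in scale.items:
        col = data[it.item_id]
        if it.response_domain == "ordinal-1-4":
            cols[it.item_id] = recode_barratt(col, it.reverse_scored, convention)
        else:
            vals = pd.to_numeric(col, errors="coerce")
            bad = vals.notna() & ~vals.isin([0, 1])
            if bad.any():
                raise DomainError(f"non-binary values in item {it.item_id!r}")
            out = pd.Series(vals, dtype="Float64").astype("Int64")
            cols[it.item_id] = out
    return pd.DataFrame(cols, index=data.index)


def score_any_item_scale(data, scale: ScaleDefinition, convention: str = "reversed") -> pd.Series:
    """Score an any-item rule scale: any positive item -> high risk.

    An episode with every observed item negative but at least one item missing
    cannot be ruled low and is scored missing (listwise policy); all items
    observed and negative -> low.
    """
    if scale.rule != "any-item":
        raise ConfigurationError(f"{scale.scale_id!r} is not an any-item scale")
    mat = _item_matrix(data, scale, convention)
    any_pos = (mat == 1).any(axis=1)
    any_missing = mat.isna().any(axis=1)
    out = pd.Series(np.where(any_pos, "high", "low"), index=mat.index, dtype="object")
    out[~any_pos & any_missing] = pd.NA
    return out


def score_banded_scale(data, scale: ScaleDefinition, convention: str = "reversed") -> pd.DataFrame:
    """Score a weighted-bands scale: columns ``total`` and ``band``.

    The total is the weighted sum of positive items; any missing item makes
    both total and band missing for that episode (listwise policy).
    """
    if scale.rule != "weighted-bands":
        raise ConfigurationError(f"{scale.scale_id!r} is not a banded scale")
    mat = _item_matrix(data, scale, convention)
    weights = pd.Series({it.item_id: it.weight for it in scale.items})
    total = (mat * weights).sum(axis=1).astype("Int64")
    incomplete = mat.isna().any(axis=1)
    total[incomplete] = pd.NA
    band = total.map(lambda t: scale.band_for_score(int(t)) if pd.notna(t) else pd.NA)
    return pd.DataFrame({"total": total, "band": band.astype("object")}, index=mat.index)


def score_scale(data, scale: ScaleDefinition, convention: str = "reversed"):
    """Dispatch on the scale's rule.

    Returns a risk-class Series (any-item, threshold), a total/band frame
    (weighted-bands), or raises for items-only instruments.
    """
    if scale.rule == "any-item":
        return score_any_item_scale(data, scale, convention)
    if scale.rule == "weighted-bands":
        return score_banded_scale(data, scale, convention)
    if scale.rule == "threshold":
        if len(scale.items) == 1 and scale.items[0].response_domain == "likert-1-10":
            if scale.cutoff != 6:
                series, _ = _as_series(
                    data[scale.items[0].item_id] if not np.isscalar(data) else data
                )
                vals = pd.to_numeric(series, errors="coerce")
                arr = pd.array(vals, dtype="Float64").to_numpy(
                    dtype="float64", na_value=np.nan
                )
                out = pd.Series(
                    np.where(arr >= scale.cutoff, "high", "low"),
                    index=series.index, dtype="object",
                )
                out[np.isnan(arr)] = pd.NA
                return out
            col = data[scale.items[0].item_id] if isinstance(data, pd.DataFrame) else data
            return dichotomize_global(col)
        mat = _item_matrix(data, scale, convention)
        total = mat.sum(axis=1).astype("Int64")
        total[mat.isna().any(axis=1)] = pd.NA
        arr = total.to_numpy(dtype="float64", na_value=np.nan)
        out = pd.Series(
            np.where(arr >= scale.cutoff, "high", "low"), index=mat.index, dtype="object"
        )
        out[np.isnan(arr)] = pd.NA
        return out
    raise ConfigurationError(
        f"{scale.scale_id!r} is evaluated item-by-item only (rule 'items-only')"
    )


# ---------------------------------------------------------------------------
# Item pooling


def canonical_id(item_id: str, duplicate_map: Mapping[str, str] | None = None) -> str:
    """Resolve an item id to its construct-equivalence representative."""
    dmap = DEFAULT_DUPLICATE_MAP if duplicate_map is None else duplicate_map
    seen = {item_id}
    while item_id in dmap:
        item_id = dmap[item_id]
        if item_id in seen:  # defensive: cyclic config
            raise ConfigurationError(f"cyclic duplicate map at {item_id!r}")
        seen.add(item_id)
    return item_id


def combined_sadp_item_set(
    scales: Mapping[str, ScaleDefinition] | None = None,
    duplicate_map: Mapping[str, str] | None = None,
) -> list[ItemDefinition]:
    """Pooled SAD PERSONS + Modified SAD PERSONS item set without repetition.

    The two instruments overlap; items measuring the same construct (same id,
    or linked through the duplicate map) appear once, keeping the first
    occurrence in SAD PERSONS order followed by novel Modified items. The
    result is deterministic.
    """
    if scales is None:
        scales = load_default_scales()
    out: list[ItemDefinition] = []
    seen: set[str] = set()
    for sid in ("SADP", "MSPS"):
        for it in scales[sid].items:
            key = canonical_id(it.item_id, duplicate_map)
            if key in seen:
                continue
            seen.add(key)
            out.append(it)
    return out
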