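"""Descriptor curation and threshold harmonization.

Raw odor descriptors ("fruit", "apple", "sweaty", ...) are consolidated to
canonical descriptors, mapped to semantic categories, sparse categories
merged into broader groups, and a single category per compound chosen by a
fixed priority scheme. Each final category carries a binary aroma
contribution polarity (positive / negative). Odor thresholds in mg/L are
collapsed (median by default across literature observations) and modeled as
y = -log10(threshold mg/L), so larger y means a more potent odorant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from statistics import mean, median

import yaml

logger = logging.getLogger(__name__)

#: Marker category for records whose descriptors all lack a mapping.
UNLABELED = "__unlabeled__"


@dataclass
class CurationConfig:
    """Descriptor → category → contribution rule set (user-editable YAML)."""

    synonym_map: dict[str, str] = field(default_factory=dict)
    category_map: dict[str, str] = field(default_factory=dict)
    priority_order: list[str] = field(default_factory=list)
    merge_map: dict[str, str] = field(default_factory=dict)
    polarity_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        final = {self.merge_map.get(c, c) for c in self.category_map.values()}
        missing = final - set(self.priority_order)
        if missing:
            raise ValueError(f"categories missing from priority_order: {sorted(missing)}")
        unpolarized = final - set(self.polarity_map)
        if unpolarized:
            raise ValueError(f"categories missing from polarity_map: {sorted(unpolarized)}")
        bad = set(self.polarity_map.values()) - {"positive", "negative"}
        if bad:
            raise ValueError(f"polarity values must be positive/negative, got {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CurationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            synonym_map={str(k).lower(): str(v).lower() for k, v in (raw.get("synonym_map") or {}).items()},
            category_map={str(k).lower(): str(v) for k, v in (raw.get("category_map") or {}).items()},
            priority_order=list(raw.get("priority_order") or []),
            merge_map=dict(raw.get("merge_map") or {}),
            polarity_map=dict(raw.get("polarity_map") or {}),
        )

    @classmethod
    def default(cls) -> "CurationConfig":
        ref = resources.files("odorkit.data").joinpath("curation_default.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass(frozen=True)
class ThresholdTarget:
    """A collapsed threshold observation and its -log10(mg/L) modeling value."""

    t_mg_L: float
    y: float


def consolidate_descriptors(raw: list[str], synonym_map: dict[str, str]) -> set[str]:
    """Lowercase, trim, and synonym-collapse raw descriptors to a set.

    Descriptors without a synonym entry are kept verbatim (they may still
    carry a category mapping); an empty input yields an empty set — emptiness
    never implies "odorless".
    """
    out = set()
    for d in raw:
        d = d.strip().lower()
        if not d:
            continue
        out.add(synonym_map.get(d, d))
    return out


def assign_category(descriptors: set[str], config: CurationConfig) -> str:
    """Pick one semantic category for a consolidated descriptor set.

    Each descriptor votes for category_map → merge_map; among the voted
    categories the one earliest in priority_order wins, so the result is
    independent of descriptor order. Unmapped descriptors are logged and
    ignored; if nothing maps, :data:`UNLABELED` is returned and the record
    should be excluded from training.
    """
    voted = set()
    for d in descriptors:
        cat = config.category_map.get(d)
        if cat is None:
            logger.debug("descriptor without category mapping: %r", d)
            continue
        voted.add(config.merge_map.get(cat, cat))
    if not voted:
        return UNLABELED
    rank = {c: i for i, c in enumerate(config.priority_order)}
    return min(voted, key=lambda c: rank[c])


def assign_contribution(category: str, polarity_map: dict[str, str]) -> str:
    """Binary aroma contribution ('positive'/'negative') for a final category."""
    try:
        return polarity_map[category]
    except KeyError:
        raise ValueError(
            f"category {category!r} missing from polarity_map (configuration error)"
        ) from None


def collapse_threshold(obs: list[float], policy: str = "median") -> ThresholdTarget:
    """Collapse literature threshold observations to one modeling target.

    Values <= 0 (and NaN) are dropped first; the survivors are reduced by
    the chosen policy and transformed to y = -log10(t). An empty list after
    filtering raises, and the caller excludes the record.
    """
    clean = [t for t in obs if t is not None and not math.isnan(t) and t > 0]
    if not clean:
        raise ValueError("no positive threshold observations after filtering")
    if policy == "median":
        t = float(median(clean))
    elif policy == "mean":
        t = float(mean(clean))
    else:
        raise ValueError(f"unknown collapse policy: {policy!r}")
    return ThresholdTarget(t_mg_L=t, y=-math.log10(t))


def curate_records(records, config: CurationConfig | None = None, policy: str = "median"):
    """Run the full curation over registry records.

    Returns a list of dicts with keys ``smiles``, ``category``,
    ``contribution``, ``y_neglog10_mg_L`` (None when no usable threshold),
    skipping records whose descriptors are entirely unmapped.
    """
    config = config or CurationConfig.default()
    out = []
    for rec in records:
        desc = consolidate_descriptors(rec.descriptors_raw, config.synonym_map)
        category = assign_category(desc, config)
        if category == UNLABELED:
            logger.info("record unlabeled, excluded: %s", rec.smiles_canonical)
            continue
        contribution = assign_contribution(category, config.polarity_map)
        y = None
        try:
            y = collapse_threshold(rec.threshold_obs, policy).y
        except ValueError:
            pass
        out.append(
            {
                "smiles": rec.smiles_canonical,
                "category": category,
                "contribution": contribution,
                "y_neglog10_mg_L": y,
            }
        )
    return out
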