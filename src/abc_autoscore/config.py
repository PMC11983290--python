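"""Pattern-configuration loading, validation and provenance hashing.

The whole instrument definition — opioid/negation lexicons, drug names and the
per-item expressions with their filter settings — lives in one YAML (or JSON)
file so it can be versioned, reviewed and ported between sites without code
changes.  A stable SHA-256 hash of the canonicalized config is recorded in all
outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .pattern_engine import (
    CompiledItemMatcher,
    ItemPattern,
    Lexicon,
    N_ITEMS,
    compile_item_pattern,
)


class ConfigError(ValueError):
    """The pattern-configuration file is malformed."""


@dataclasses.dataclass(frozen=True)
class PatternConfig:
    """Validated instrument definition: three lexicons plus the item patterns."""

    opioid_terms: Lexicon
    negation_terms: Lexicon
    drug_names: Lexicon
    items: tuple[ItemPattern, ...]

    @property
    def opioid_lexicon(self) -> Lexicon:
        """Opioid context terms: generic fragments plus drug names."""
        return self.opioid_terms.merged_with(self.drug_names, name="opioid_context")

    def compile(self) -> list[CompiledItemMatcher]:
        opioid = self.opioid_lexicon
        return [
            compile_item_pattern(item, opioid, self.negation_terms)
            for item in self.items
        ]

    def to_dict(self) -> dict[str, Any]:
        return {
            "lexicons": {
                "opioid_terms": list(self.opioid_terms.entries),
                "negation_terms": list(self.negation_terms.entries),
                "drug_names": list(self.drug_names.entries),
            },
            "items": [
                {
                    "item_id": it.item_id,
                    "label": it.label,
                    "core_expressions": list(it.core_expressions),
                    "require_opioid_context": it.require_opioid_context,
                    "opioid_order_constraint": it.opioid_order_constraint,
                    "negation_enabled": it.negation_enabled,
                    "exclusion_prefixes": list(it.exclusion_prefixes),
                    "scope": it.scope,
                }
                for it in self.items
            ],
        }

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form; stable across load order."""
        payload = json.dumps(self.to_dict(), sort_keys=True, ensure_ascii=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def _require(mapping: dict, key: str, context: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return mapping[key]


def pattern_config_from_dict(raw: dict[str, Any]) -> PatternConfig:
    if not isinstance(raw, dict):
        raise ConfigError("pattern config must be a mapping")
    lex = _require(raw, "lexicons", "pattern config")
    items_raw = _require(raw, "items", "pattern config")
    lexicons = {}
    for name in ("opioid_terms", "negation_terms", "drug_names"):
        entries = _require(lex, name, "lexicons")
        if not isinstance(entries, list) or not all(isinstance(e, str) for e in entries):
            raise ConfigError(f"lexicons.{name} must be a list of strings")
        lexicons[name] = Lexicon(name, tuple(entries))
    if not isinstance(items_raw, list) or not items_raw:
        raise ConfigError("items must be a non-empty list")
    items: list[ItemPattern] = []
    seen_ids: set[int] = set()
    for i, entry in enumerate(items_raw):
        if not isinstance(entry, dict):
            raise ConfigError(f"items[{i}] must be a mapping")
        item_id = _require(entry, "item_id", f"items[{i}]")
        exprs = _require(entry, "core_expressions", f"items[{i}]")
        if not isinstance(exprs, list) or not all(isinstance(e, str) for e in exprs):
            raise ConfigError(f"items[{i}].core_expressions must be a list of strings")
        try:
            item = ItemPattern(
                item_id=int(item_id),
                label=str(entry.get("label", f"item {item_id}")),
                core_expressions=tuple(exprs),
                require_opioid_context=bool(entry.get("require_opioid_context", False)),
                opioid_order_constraint=str(
                    entry.get("opioid_order_constraint", "none")
                ),
                negation_enabled=bool(entry.get("negation_enabled", True)),
                exclusion_prefixes=tuple(
                    entry.get("exclusion_prefixes", ["discharge instructions"])
                ),
            )
        except ValueError as exc:
            raise ConfigError(f"items[{i}]: {exc}") from exc
        if item.item_id in seen_ids:
            raise ConfigError(f"items[{i}]: duplicate item_id {item.item_id}")
        seen_ids.add(item.item_id)
        items.append(item)
    items.sort(key=lambda it: it.item_id)
    return PatternConfig(
        opioid_terms=lexicons["opioid_terms"],
        negation_terms=lexicons["negation_terms"],
        drug_names=lexicons["drug_names"],
        items=tuple(items),
    )


def load_pattern_config(path: str | Path) -> PatternConfig:
    """Load and schema-validate a YAML/JSON pattern-configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return pattern_config_from_dict(raw)


def default_pattern_config() -> PatternConfig:
    """The packaged reconstructed default instrument definition (20 items)."""
    ref = resources.files("abc_autoscore.data").joinpath("default_patterns.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    cfg = pattern_config_from_dict(raw)
    assert len(cfg.items) == N_ITEMS
    return cfg
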