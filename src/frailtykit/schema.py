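"""Deficit-item catalogue for a deficit-accumulation frailty index.

A frailty index counts health deficits out of a fixed catalogue of
dichotomous items. This module defines the catalogue (:class:`DeficitSchema`),
item-level coding rules that map raw survey values to ``{0, 1, missing}``,
and a loader for user-supplied YAML schemas.

The shipped 30-item default covers comorbidities, basic and instrumental
activities of daily living, physical performance, emotional, cognitive,
sensory and self-rated-health domains. It is a documented stand-in
reconstructed from published domain composition: the exact item wording of
the survey instrument is configurable, never hard-coded into the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

__all__ = [
    "DeficitItem",
    "DeficitSchema",
    "SchemaError",
    "default_schema",
    "load_schema",
    "MISSING",
]

#: Sentinel for a deficit value that could not be observed.
MISSING = -1

VALID_DOMAINS = frozenset(
    {
        "comorbidity",
        "basic-ADL",
        "instrumental-ADL",
        "physical-performance",
        "emotional",
        "cognitive",
        "self-rated-health",
        "sensory",
        "other",
    }
)


class SchemaError(ValueError):
    """Raised for malformed or inconsistent deficit schemas."""


@dataclass(frozen=True)
class DeficitItem:
    """One dichotomous deficit item.

    Parameters
    ----------
    item_id : str
        Short unique identifier, used as the cohort-table column name.
    domain : str
        One of :data:`VALID_DOMAINS`.
    description : str
        Free-text description of the deficit.
    coding : dict
        Rule mapping a raw value to ``{0, 1, missing}``. Supported types:

        ``{"type": "binary"}``
            Raw value must already be 0/1; anything non-finite is missing.
        ``{"type": "threshold", "op": "ge"|"le", "value": x}``
            Deficit when the raw value is ``>= x`` (or ``<= x``).
    """

    item_id: str
    domain: str
    description: str = ""
    coding: dict = field(default_factory=lambda: {"type": "binary"})

    def __post_init__(self) -> None:
        if self.domain not in VALID_DOMAINS:
            raise SchemaError(
                f"item {self.item_id!r}: unknown domain {self.domain!r}"
            )
        ctype = self.coding.get("type", "binary")
        if ctype not in ("binary", "threshold"):
            raise SchemaError(
                f"item {self.item_id!r}: unknown coding type {ctype!r}"
            )
        if ctype == "threshold" and self.coding.get("op") not in ("ge", "le"):
            raise SchemaError(
                f"item {self.item_id!r}: threshold coding needs op 'ge' or 'le'"
            )

    def code(self, raw) -> int:
        """Map a raw value to 0 (no deficit), 1 (deficit) or MISSING."""
        if raw is None:
            return MISSING
        try:
            val = float(raw)
        except (TypeError, ValueError):
            return MISSING
        if math.isnan(val):
            return MISSING
        ctype = self.coding.get("type", "binary")
        if ctype == "binary":
            if val in (0.0, 1.0):
                return int(val)
            return MISSING
        thr = float(self.coding["value"])
        if self.coding["op"] == "ge":
            return int(val >= thr)
        return int(val <= thr)


@dataclass(frozen=True)
class DeficitSchema:
    """Ordered catalogue of deficit items.

    ``expected_count`` is enforced at construction; the default index uses
    30 items. ``min_observed_fraction`` gates how much item missingness a
    subject may carry before their index is declared undefined.
    """

    items: tuple[DeficitItem, ...]
    expected_count: int = 30
    min_observed_fraction: float = 0.8

    def __post_init__(self) -> None:
        if len(self.items) != self.expected_count:
            raise SchemaError(
                f"schema has {len(self.items)} items, expected "
                f"{self.expected_count}"
            )
        seen: set[str] = set()
        for it in self.items:
            if it.item_id in seen:
                raise SchemaError(f"duplicate item_id {it.item_id!r}")
            seen.add(it.item_id)
        if not (0.0 < self.min_observed_fraction <= 1.0):
            raise SchemaError("min_observed_fraction must be in (0, 1]")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


def _items(domain: str, specs: Iterable[tuple[str, str]]) -> list[DeficitItem]:
    return [DeficitItem(item_id=i, domain=domain, description=d) for i, d in specs]


def default_schema() -> DeficitSchema:
    """The shipped 30-item deficit catalogue.

    Domain composition: 5 medical comorbidities, 9 basic-ADL dependencies,
    6 instrumental-ADL dependencies, and 10 single items (falls, depressive
    mood, three-word recall, serial-seven subtraction, low grip strength,
    poor self-rated health, hearing problem, dental problem, abnormal BMI,
    low quality of life). All items are pre-dichotomised (binary coding).
    """
    items: list[DeficitItem] = []
    items += _items(
        "comorbidity",
        [
            ("hypertension", "diagnosed or measured hypertension"),
            ("diabetes", "diabetes mellitus"),
            ("stroke", "history of stroke"),
            ("copd", "chronic obstructive pulmonary disease"),
            ("ckd", "chronic kidney disease"),
        ],
    )
    items += _items(
        "basic-ADL",
        [
            ("badl_bathing", "needs help bathing"),
            ("badl_dressing", "needs help dressing"),
            ("badl_eating", "needs help eating"),
            ("badl_transfer", "needs help transferring bed to chair"),
            ("badl_ambulation", "needs help with indoor ambulation"),
            ("badl_stairs", "unable to climb stairs"),
            ("badl_toileting", "needs help toileting"),
            ("badl_urinary", "urinary incontinence"),
            ("badl_fecal", "fecal incontinence"),
        ],
    )
    items += _items(
        "instrumental-ADL",
        [
            ("iadl_bills", "unable to pay bills"),
            ("iadl_medication", "unable to manage medication"),
            ("iadl_light_house", "unable to do light housework"),
            ("iadl_heavy_house", "unable to do heavy housework"),
            ("iadl_transport", "unable to use public transportation"),
            ("iadl_telephone", "unable to use the telephone"),
        ],
    )
    items += [
        DeficitItem("falls", "physical-performance", "fall in the last 6 months"),
        DeficitItem("depressive_mood", "emotional", "depressive mood"),
        DeficitItem("word_recall", "cognitive", "impaired three-word recall"),
        DeficitItem("serial_sevens", "cognitive", "impaired serial-seven subtraction"),
        DeficitItem("grip_strength", "physical-performance", "low grip strength"),
        DeficitItem("self_rated_health", "self-rated-health", "poor self-rated health"),
        DeficitItem("hearing", "sensory", "hearing problem"),
        DeficitItem("dental", "other", "dental problem"),
        DeficitItem("bmi_abnormal", "other", "abnormal body-mass index"),
        DeficitItem("low_qol", "other", "low quality-of-life score"),
    ]
    return DeficitSchema(items=tuple(items))


def load_schema(path_or_default: str = "default") -> DeficitSchema:
    """Load a deficit schema from YAML, or return the shipped default.

    The YAML layout::

        expected_count: 30          # optional, default 30
        min_observed_fraction: 0.8  # optional
        items:
          - item_id: hypertension
            domain: comorbidity
            description: ...
            coding: {type: binary}

    Raises
    ------
    SchemaError
        On duplicate ids, item-count mismatch, unknown domains or coding.
    """
    if path_or_default == "default":
        return default_schema()
    with open(path_or_default) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "items" not in raw:
        raise SchemaError(f"{path_or_default}: no 'items' section")
    items = []
    for entry in raw["items"]:
        try:
            items.append(
                DeficitItem(
                    item_id=str(entry["item_id"]),
                    domain=entry.get("domain", "other"),
                    description=entry.get("description", ""),
                    coding=entry.get("coding", {"type": "binary"}),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"schema item missing field {exc}: {entry!r}") from exc
    return DeficitSchema(
        items=tuple(items),
        expected_count=int(raw.get("expected_count", 30)),
        min_observed_fraction=float(raw.get("min_observed_fraction", 0.8)),
    )


def schema_to_yaml(schema: DeficitSchema, path: str) -> None:
    """Write a schema back to YAML (round-trips with :func:`load_schema`)."""
    doc = {
        "expected_count": schema.expected_count,
        "min_observed_fraction": schema.min_observed_fraction,
        "items": [
            {
                "item_id": it.item_id,
                "domain": it.domain,
                "description": it.description,
                "coding": dict(it.coding),
            }
            for it in schema
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
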