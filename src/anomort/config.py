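"""Pipeline configuration and cause-of-death category mapping.

Underlying causes are coded to six injury categories — transport, falls,
drownings, assault, suicide and a residual "other" — from ICD-9 external
cause codes (deaths before 1999) or ICD-10 codes (1999 onwards).  The
mapping is configuration: the default below follows standard external-cause
groupings, and any mapping with the same shape can be supplied instead.
"Other injuries" is computed but excluded from modelling by default because
its composition varies by sex, age group, state and time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

__all__ = [
    "PipelineConfig",
    "DEFAULT_ICD_MAPPING",
    "map_icd_categories",
    "INJURY_TYPES",
]

logger = logging.getLogger("anomort")

INJURY_TYPES = ["transport", "falls", "drownings", "assault", "suicide", "other"]

#: code -> category ranges per ICD revision (inclusive at the 3-character
#: level).  Standard external-cause groupings.
DEFAULT_ICD_MAPPING = {
    "icd9": {
        "transport": ["E800-E848"],
        "falls": ["E880-E888"],
        "drownings": ["E910-E910"],
        "suicide": ["E950-E959"],
        "assault": ["E960-E969"],
        "_injury_range": ["E800-E999"],
    },
    "icd10": {
        "transport": ["V01-V99"],
        "falls": ["W00-W19"],
        "drownings": ["W65-W74"],
        "suicide": ["X60-X84", "Y87-Y87"],
        "assault": ["X85-Y09"],
        "_injury_range": ["V01-Y89"],
    },
    "revision_switch_year": 1999,
}

_CODE_RE = re.compile(r"^([A-Z]*)(\d+)(?:\.(\d+))?$")


def _code_key(code: str):
    code = str(code).strip().upper()
    m = _CODE_RE.match(code)
    if not m:
        return None
    letters, major, _minor = m.groups()
    return letters, int(major[:3] if letters else major[:4])


def _in_range(key, rng: str) -> bool:
    lo, _, hi = rng.partition("-")
    hi = hi or lo
    klo, khi = _code_key(lo), _code_key(hi)
    return klo <= key <= khi


def map_icd_categories(codes, years, mapping: dict | None = None) -> list:
    """Label cause-of-death codes with injury categories.

    ``codes`` and ``years`` are parallel sequences; the ICD revision is
    chosen per record from the death year (9th before the configured switch
    year, 10th from it onward).  Injury codes outside every category range
    fall to ``"other"``; non-injury codes are excluded (labelled ``None``)
    and their count is logged.
    """
    mapping = mapping or DEFAULT_ICD_MAPPING
    switch = mapping.get("revision_switch_year", 1999)
    labels = []
    n_excluded = 0
    for code, year in zip(codes, years):
        rev = mapping["icd9"] if year < switch else mapping["icd10"]
        key = _code_key(code)
        if key is None or not any(
            _in_range(key, r) for r in rev["_injury_range"]
        ):
            labels.append(None)
            n_excluded += 1
            continue
        label = "other"
        for cat, ranges in rev.items():
            if cat.startswith("_"):
                continue
            if any(_in_range(key, r) for r in ranges):
                label = cat
                break
        labels.append(label)
    if n_excluded:
        logger.info("map_icd_categories: excluded %d non-injury codes", n_excluded)
    return labels


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Paths may be None where a stage is skipped (e.g. ``temps`` when
    state-level anomalies are supplied directly).  ``deltas`` are the
    warm-year scenario anomalies in deg C.  ``strata`` limits which
    (injury_type, sex, age_group) combinations are fitted; None fits all
    present except ``other`` injuries.
    """

    deaths: str
    population: str
    adjacency: str
    outdir: str
    anomalies: str | None = None
    temps: str | None = None
    county_to_state: str | None = None
    period_start: int | None = None
    period_end: int | None = None
    deltas: list = field(default_factory=lambda: [1.5, 2.0])
    seed: int = 0
    reference_year: int | None = None
    strata: list | None = None
    include_other: bool = False
    backend: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            cfg = cls(**raw)
        except TypeError as e:
            raise ValidationError(f"bad pipeline config: {e}") from None
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.period_start is not None and self.period_end is not None:
            if self.period_start >= self.period_end:
                raise ValidationError("analysis period start must precede end")
        if not all(np.isfinite(d) for d in self.deltas):
            raise ValidationError("scenario deltas must be finite")
        if self.anomalies is None and self.temps is None:
            raise ValidationError("need either anomalies or temps input")
        for name in ("deaths", "population", "adjacency", "anomalies", "temps",
                     "county_to_state"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"configured {name} file does not exist: {p}")

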